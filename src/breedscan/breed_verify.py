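"""Breed-label verification via bootstrapped IBS distances, neighbor joining,
and a strict majority-rule consensus tree.

The question this module answers: does every sample cluster with the other
members of the breed it is labeled as?  Pipeline: identity-by-state distances
(optionally bootstrapped over sites) -> one neighbor-joining tree per
replicate -> strict majority-rule consensus -> flag samples that fall outside
the clade holding most of their breed-mates.

Trees are held as dendropy :class:`~dendropy.Tree` objects (Newick in/out);
the neighbor-joining and consensus algorithms themselves are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .vcf_io import GenotypeMatrix, SampleMeta

__all__ = [
    "DistanceMatrix",
    "ibs_distance",
    "bootstrap_distances",
    "neighbor_joining",
    "majority_consensus",
    "flag_breed_outliers",
    "BreedFlag",
    "tree_bipartitions",
    "clade_sides",
    "read_newick",
    "write_newick",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distance matrix with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match label count")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0.0):
            raise ValueError("distances must be nonnegative")

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square (lower+upper) distance format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

def ibs_distance(
    gm: GenotypeMatrix,
    site_index: Sequence[int] | np.ndarray | None = None,
    site_weights: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise identity-by-state distance.

    For a sample pair, over sites where both calls are present,
    ``d = 1 - (#IBS2 + 0.5 * #IBS1) / #compared`` where IBS2 means identical
    genotypes and IBS1 means one shared allele.  For diploid dosages this is
    ``sum |g_i - g_j| / (2 * #compared)``, computed here with one-hot matrix
    products so missingness is handled pairwise.  ``site_weights`` (integer
    resampling counts) serve the bootstrap.
    """
    if gm.n_samples < 2:
        raise ValueError("ibs_distance needs >= 2 samples")
    G = gm.dosages
    if site_index is not None:
        G = G[:, np.asarray(site_index, dtype=int)]
    n, p = G.shape
    if p == 0:
        raise ValueError("ibs_distance needs >= 1 site")
    w = np.ones(p) if site_weights is None else np.asarray(site_weights, dtype=float)
    if w.shape != (p,):
        raise ValueError("site_weights length must match site count")
    obs = (~np.isnan(G)).astype(float)
    onehot = [((G == k) & ~np.isnan(G)).astype(float) * w for k in (0.0, 1.0, 2.0)]
    raw = [(G == k).astype(float) for k in (0.0, 1.0, 2.0)]
    # sum_s w_s |g_is - g_js| = sum_{u,v} |u-v| * (I_u W I_v^T)
    num = np.zeros((n, n))
    for u in range(3):
        for v in range(3):
            if u != v:
                num += abs(u - v) * (onehot[u] @ raw[v].T)
    denom = (obs * w) @ obs.T  # pairwise count of mutually observed sites
    no_overlap = denom == 0
    np.fill_diagonal(no_overlap, False)
    if no_overlap.any():
        i, j = np.argwhere(no_overlap)[0]
        raise ValueError(
            f"samples {gm.sample_ids[i]!r} and {gm.sample_ids[j]!r} share no "
            "mutually observed sites"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = num / (2.0 * denom)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(gm.sample_ids), d)


def bootstrap_distances(
    gm: GenotypeMatrix,
    n_boot: int = 100,
    seed: int = 0,
    site_index: Sequence[int] | None = None,
    _indices: Sequence[np.ndarray] | None = None,
) -> list[DistanceMatrix]:
    """IBS distances on ``n_boot`` site-resampled replicates.

    Each replicate resamples sites with replacement to the original site
    count (the standard phylogenetic bootstrap over characters), then
    computes :func:`ibs_distance`.  Reproducible from ``seed``.  ``_indices``
    lets tests force specific resamples.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    p = gm.n_variants if site_index is None else len(site_index)
    rng = np.random.default_rng(seed)
    out = []
    for b in range(n_boot):
        if _indices is not None:
            idx = np.asarray(_indices[b], dtype=int)
        else:
            idx = rng.integers(0, p, size=p)
        weights = np.bincount(idx, minlength=p).astype(float)
        out.append(ibs_distance(gm, site_index=site_index, site_weights=weights))
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Classical Saitou-Nei neighbor joining; returns an unrooted tree.

    At each step the pair minimizing ``Q_ij = (m-2) d_ij - r_i - r_j`` is
    joined (ties broken by the lowest index pair in current scan order) and
    branch lengths are assigned by the standard formulas.  Negative branch
    lengths are clamped to zero; clamped edges are tallied on
    ``tree.n_clamped_edges``.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    d = D.d.copy()
    tns = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = [dendropy.Node(taxon=tns.get_taxon(lab)) for lab in D.labels]
    n_clamped = 0

    def _clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0.0:
            n_clamped += 1
            return 0.0
        return x

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first occurrence of the minimum in row-major order = lowest-index pair
        a, b = np.unravel_index(np.argmin(q), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = _clamp(li)
        nodes[j].edge.length = _clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_row = 0.5 * (d[i, active] + d[j, active] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        k = d.shape[0] - 1
        d[k, active] = new_row
        d[active, k] = new_row
        d[k, k] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [k]

    # terminal three-way join at the unrooted central node
    i, j, k = active
    center = dendropy.Node()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.edge.length = _clamp(length)
        center.add_child(node)
    tree.seed_node = center
    tree.is_rooted = False
    tree.n_clamped_edges = n_clamped  # type: ignore[attr-defined]
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and consensus
# ---------------------------------------------------------------------------

def _leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side *not* containing
    the lexicographically smallest label is the canonical representation, so
    bipartitions compare across differently rooted copies of a topology.
    """
    leaves = _leaf_labels(tree)
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = leaves - below if ref in below else below
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def majority_consensus(trees: Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Strict majority-rule consensus: exactly the bipartitions in > 50% of trees.

    Retained edges carry their support fraction as the node label (and
    ``node.support``).  No greedy/extended resolution is applied: bipartitions
    at exactly half or below are absent even when compatible.
    """
    if not trees:
        raise ValueError("majority_consensus needs >= 1 tree")
    leaves = _leaf_labels(trees[0])
    for t in trees[1:]:
        if _leaf_labels(t) != leaves:
            raise ValueError("all trees must share one leaf set")
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for bip in tree_bipartitions(t):
            counts[bip] = counts.get(bip, 0) + 1
    n = len(trees)
    kept = {bip: c / n for bip, c in counts.items() if c > n / 2}

    # Majority bipartitions are pairwise compatible (any two co-occur in at
    # least one tree), so they nest: build the rooted-at-reference clade tree.
    ref = min(leaves)
    tns = dendropy.TaxonNamespace(sorted(leaves))
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    clades = sorted(kept, key=len, reverse=True)
    node_of: dict[frozenset[str], dendropy.Node] = {}

    def _parent_of(clade: frozenset[str]) -> dendropy.Node:
        best, best_node = None, root
        for other, nd in node_of.items():
            if clade < other and (best is None or len(other) < len(best)):
                best, best_node = other, nd
        return best_node

    for clade in clades:
        nd = dendropy.Node()
        nd.label = f"{kept[clade]:.2f}"
        nd.support = kept[clade]  # type: ignore[attr-defined]
        _parent_of(clade).add_child(nd)
        node_of[clade] = nd
    for leaf in sorted(leaves):
        nd = dendropy.Node(taxon=tns.get_taxon(leaf))
        smallest = None
        for clade in clades:
            if leaf in clade and (smallest is None or len(clade) < len(smallest)):
                smallest = clade
        (node_of[smallest] if smallest else root).add_child(nd)
    tree.is_rooted = False
    return tree


def clade_sides(tree: dendropy.Tree) -> list[frozenset[str]]:
    """All bipartition sides of an unrooted tree, including trivial ones."""
    leaves = _leaf_labels(tree)
    sides: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 0 < len(below) < len(leaves):
            sides.add(below)
            sides.add(leaves - below)
    return sorted(sides, key=lambda s: (len(s), sorted(s)))


@dataclass
class BreedFlag:
    sample_id: str
    breed: str
    reason: str


def flag_breed_outliers(
    tree: dendropy.Tree, meta: Sequence[SampleMeta]
) -> list[BreedFlag]:
    """Flag samples that do not cluster with the majority of their breed.

    For each breed with >= 2 samples, the breed's *home clade* is the
    bipartition side containing more than half of the breed's members that is
    purest — fewest non-breed members, then most breed members, then smallest.
    Members outside the home clade are flagged.  Singleton breeds cannot
    cluster and are skipped.
    """
    leaves = _leaf_labels(tree)
    breed_of = {s.sample_id: s.breed for s in meta}
    missing = leaves - set(breed_of)
    if missing:
        raise ValueError(f"leaves without breed labels: {sorted(missing)[:5]}")
    sides = clade_sides(tree)
    flags: list[BreedFlag] = []
    by_breed: dict[str, set[str]] = {}
    for sid in leaves:
        by_breed.setdefault(breed_of[sid], set()).add(sid)
    for breed, members in sorted(by_breed.items()):
        if len(members) < 2:
            continue
        best = None
        best_key = None
        for side in sides:
            inside = len(side & members)
            if inside <= len(members) / 2:
                continue
            key = (len(side) - inside, -inside, len(side))
            if best_key is None or key < best_key:
                best_key, best = key, side
        if best is None:
            best = leaves  # fully unresolved tree: nothing to flag against
        for sid in sorted(members - best):
            flags.append(
                BreedFlag(
                    sample_id=sid,
                    breed=breed,
                    reason=(
                        f"outside the clade holding {len(best & members)}/"
                        f"{len(members)} {breed} samples"
                    ),
                )
            )
    return flags


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
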