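"""Built-in example breed phenotype panel.

Published OFA registry prevalence (percent) of canine hip dysplasia (HD) and
elbow dysplasia (ED) for the breeds of a 230-dog whole-genome-sequencing
cohort, with the number of sequenced dogs per breed.  Illustrates the
intended phenotype-table shape — unbalanced breed sizes (1 to 51 dogs) and
breed-level prevalence standing in for missing individual phenotypes — and
feeds the worked examples.
"""

from __future__ import annotations

import pandas as pd

from .association import BreedPanel

__all__ = ["ofa_panel"]

# breed, HD prevalence %, ED prevalence %, n sequenced dogs
_OFA_ROWS = [
    ("Alaskan Malamute", 10.83, 2.97, 3),
    ("American Staffordshire Terrier", 24.39, 16.07, 2),
    ("Australian Cattle Dog", 13.44, 9.80, 5),
    ("Australian Shepherd", 5.33, 3.50, 2),
    ("Bearded Collie", 5.30, 1.94, 8),
    ("Belgian Malinois", 5.16, 8.63, 5),
    ("Bichon Frise", 5.88, 0.45, 4),
    ("Border Collie", 10.10, 1.13, 36),
    ("Boxer", 10.70, 0.73, 1),
    ("Bullmastiff", 23.97, 14.20, 2),
    ("Cavalier King Charles Spaniel", 11.35, 0.33, 3),
    ("Chow Chow", 19.17, 48.63, 1),
    ("Doberman Pinscher", 5.67, 0.82, 3),
    ("Flat Coated Retriever", 3.74, 0.68, 2),
    ("German Shepherd", 18.94, 17.83, 16),
    ("German Wirehaired Pointer", 8.02, 2.17, 1),
    ("Golden Retriever", 18.84, 9.69, 10),
    ("Great Dane", 11.62, 3.53, 1),
    ("Great Pyrenees", 8.71, 1.45, 1),
    ("Greater Swiss Mountain Dog", 15.38, 9.11, 6),
    ("Havanese", 6.25, 5.46, 3),
    ("Irish Wolfhound", 4.47, 12.30, 2),
    ("Labrador Retriever", 11.24, 9.57, 10),
    ("Leonberger", 12.72, 3.25, 51),
    ("Newfoundland", 24.75, 22.70, 2),
    ("Nova Scotia Duck Tolling Retriever", 5.81, 2.51, 1),
    ("Old English Sheepdog", 17.76, 3.36, 1),
    ("Pembroke Welsh Corgi", 16.56, 2.92, 2),
    ("Portuguese Water Dog", 10.98, 1.43, 3),
    ("Rhodesian Ridgeback", 4.42, 4.95, 4),
    ("Rottweiler", 20.07, 38.07, 3),
    ("Shetland Sheepdog", 4.16, 2.79, 3),
    ("Standard Poodle", 10.99, 2.81, 16),
    ("Tibetan Mastiff", 14.26, 13.84, 9),
    ("Vizsla", 6.19, 1.99, 2),
    ("Weimaraner", 7.94, 1.57, 2),
    ("Welsh Springer Spaniel", 10.80, 1.44, 4),
]


def ofa_panel() -> BreedPanel:
    """The 230-dog OFA hip/elbow dysplasia example panel (percent prevalence)."""
    df = pd.DataFrame(_OFA_ROWS, columns=["breed", "HD", "ED", "n"])
    return BreedPanel.from_frame(df)
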