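"""Random-coil backbone chemical shift reference (ppm).

Calpha and Halpha values follow the Wishart random-coil compilation used by
the chemical shift index method; amide N/HN columns are typical random-coil
values used only to place synthetic peaks in physical ranges.  One table
version is frozen here; prolines carry no amide proton (HN = NaN).
"""

from __future__ import annotations

import math

import pandas as pd

_NAN = math.nan

# aa -> (Calpha, Halpha, N, HN)
RANDOM_COIL = {
    "A": (52.5, 4.32, 123.8, 8.24),
    "R": (56.0, 4.34, 120.5, 8.23),
    "N": (53.1, 4.74, 118.7, 8.40),
    "D": (54.2, 4.64, 120.4, 8.34),
    "C": (58.2, 4.55, 118.8, 8.32),
    "Q": (55.7, 4.34, 119.8, 8.32),
    "E": (56.6, 4.35, 120.2, 8.42),
    "G": (45.1, 3.96, 108.8, 8.33),
    "H": (55.0, 4.73, 118.2, 8.42),
    "I": (61.1, 4.17, 119.9, 8.00),
    "L": (55.1, 4.34, 121.8, 8.16),
    "K": (56.2, 4.32, 120.4, 8.29),
    "M": (55.4, 4.48, 119.6, 8.28),
    "F": (57.7, 4.62, 120.3, 8.30),
    "P": (63.3, 4.42, 128.1, _NAN),
    "S": (58.3, 4.47, 115.7, 8.31),
    "T": (61.8, 4.35, 113.6, 8.15),
    "W": (57.5, 4.66, 121.3, 8.25),
    "Y": (57.9, 4.55, 120.3, 8.12),
    "V": (62.2, 4.12, 119.2, 8.03),
}


def random_coil_table() -> pd.DataFrame:
    """Return the frozen reference as a DataFrame indexed by one-letter code."""
    return pd.DataFrame.from_dict(
        RANDOM_COIL, orient="index", columns=["ca", "ha", "n", "hn"]
    ).rename_axis("aa")


def random_coil_shift(aa: str, nucleus: str) -> float:
    """Random-coil shift (ppm) for a residue type and nucleus in {ca,ha,n,hn}."""
    try:
        row = RANDOM_COIL[aa]
    except KeyError:
        raise ValueError(f"unknown amino-acid code {aa!r}") from None
    return dict(zip(("ca", "ha", "n", "hn"), row))[nucleus]
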