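"""Minimal NMR-STAR assigned-chemical-shift loop reader/writer.

Covers only the ``_Atom_chem_shift`` loop dialect used for backbone shift
tables (BMRB deposition style): one loop with sequence ID, residue type,
atom ID and shift value columns.  This is intentionally not a general STAR
parser.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd

# three-letter -> one-letter
_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}

_ATOM_TO_COLUMN = {"CA": "ca", "HA": "ha", "N": "n", "H": "hn", "HN": "hn"}
_COLUMN_TO_ATOM = {"ca": "CA", "ha": "HA", "n": "N", "hn": "H"}


def write_shift_loop(shifts: pd.DataFrame, path) -> None:
    """Write a shift table (residue, aa, ca/ha/n/hn) as an NMR-STAR loop."""
    lines = [
        "data_shifts", "", "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category  assigned_chemical_shifts",
        "", "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Seq_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "",
    ]
    i = 1
    for _, row in shifts.iterrows():
        comp = _AA1TO3.get(row["aa"], "UNK")
        for col, atom in _COLUMN_TO_ATOM.items():
            val = row.get(col, math.nan)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            lines.append(f"      {i:5d} {int(row['residue']):4d} {comp:4s} "
                         f"{atom:3s} {val:9.3f}")
            i += 1
    lines += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(lines))


def read_shift_loop(path) -> pd.DataFrame:
    """Read an ``_Atom_chem_shift`` loop into a shift table DataFrame."""
    text = Path(path).read_text().splitlines()
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    reading_data = False
    for raw in text:
        line = raw.strip()
        if line == "loop_":
            in_loop, reading_data, tags = True, False, []
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            tags.append(line.split(".")[-1] if "." in line else line)
            continue
        if line in ("stop_", "save_"):
            if any(t == "Val" for t in tags):
                break
            in_loop = False
            continue
        if not line or line.startswith("#"):
            continue
        reading_data = True
        rows.append(line.split())
    if not tags or not rows:
        raise ValueError(f"no assigned chemical shift loop found in {path}")

    idx = {t: i for i, t in enumerate(tags)}
    for need in ("Seq_ID", "Comp_ID", "Atom_ID", "Val"):
        if need not in idx:
            raise ValueError(f"chemical-shift loop lacks _Atom_chem_shift.{need}")

    table: dict[int, dict] = {}
    for row in rows:
        if len(row) < len(tags):
            continue
        res = int(row[idx["Seq_ID"]])
        aa = _AA3TO1.get(row[idx["Comp_ID"]].upper())
        atom = row[idx["Atom_ID"]].upper()
        col = _ATOM_TO_COLUMN.get(atom)
        if col is None:
            continue
        entry = table.setdefault(res, {"residue": res, "aa": aa})
        try:
            entry[col] = float(row[idx["Val"]])
        except ValueError:
            pass
    out = pd.DataFrame(sorted(table.values(), key=lambda d: d["residue"]))
    for col in ("ca", "ha", "n", "hn"):
        if col not in out.columns:
            out[col] = math.nan
    return out[["residue", "aa", "ca", "ha", "n", "hn"]]
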