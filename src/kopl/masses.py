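"""Residue mass tables for library quality-control calculations.

Monoisotopic residue masses follow the standard values distributed with
pyteomics; average masses are the conventional ExPASy residue-mass table.
Both are *residue* masses (peptide-bond form): a linear peptide's neutral
mass is the sum of its residue masses plus one water.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from pyteomics import mass as _ptmass

from .errors import IncompleteMassTableError

WATER_MONO = 18.0105646863
WATER_AVG = 18.01524

#: Monoisotopic residue masses (Da), standard 20 amino acids.
MONOISOTOPIC: dict[str, float] = {
    aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Average residue masses (Da), ExPASy convention.
AVERAGE: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


def default_masses(kind: str = "monoisotopic") -> dict[str, float]:
    """Return the bundled residue mass table, ``kind`` in {monoisotopic, average}."""
    if kind == "monoisotopic":
        return dict(MONOISOTOPIC)
    if kind == "average":
        return dict(AVERAGE)
    raise ValueError(f"unknown mass table kind: {kind!r}")


def read_mass_table(path: str | Path, kind: str = "monoisotopic") -> dict[str, float]:
    """Read a residue mass TSV with columns residue, monoisotopic_Da, average_Da."""
    df = pd.read_csv(path, sep="\t", dtype={"residue": str})
    col = {"monoisotopic": "monoisotopic_Da", "average": "average_Da"}[kind]
    return dict(zip(df["residue"], df[col].astype(float)))


def write_mass_table(path: str | Path) -> None:
    """Write the bundled default mass tables as TSV."""
    rows = [
        {"residue": aa, "monoisotopic_Da": MONOISOTOPIC[aa], "average_Da": AVERAGE[aa]}
        for aa in sorted(MONOISOTOPIC)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def require_masses(residues, table: dict[str, float]) -> None:
    missing = sorted({r for r in residues if r not in table})
    if missing:
        raise IncompleteMassTableError(
            f"mass table lacks residue(s): {', '.join(missing)}"
        )
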