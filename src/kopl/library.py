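"""Combinatorial model of the lysine-oriented positional-scanning library (K-OPL).

The library consists of 9-mer peptides ``G x x x K x x x G``: a central target
lysine, three degenerate flanking positions on each side drawn from 19
synthetically tractable residues (cysteine excluded), and fixed glycine
spacers at both termini.  Screening sets fix one flank residue at one offset
and leave the remaining five positions degenerate, giving 6 positions x 19
residues = 114 sets for the default design.

This module computes set enumeration, library and set sizes, the membership
relation between a concrete lysine-centred 7-mer and the sets that construct
it, and exact theoretical mass distributions of degenerate sets for synthesis
quality control.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, UnknownSetError, UnscoreableSequenceError
from .masses import WATER_MONO, require_masses

#: Canonical residue order: ACDEFGHIKLMNPQRSTVWY with cysteine removed.
DEFAULT_ALPHABET: tuple[str, ...] = tuple("ADEFGHIKLMNPQRSTVWY")

#: Flank offsets relative to the central lysine (negative = N-terminal side).
DEFAULT_FLANK_POSITIONS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)

# integer mass units: 0.1 mDa, so histogram arithmetic is exact
_MASS_SCALE = 10_000


@dataclass(frozen=True)
class SetDefinition:
    """One screening set: a single fixed residue at a single flank offset."""

    position: int
    fixed_residue: str

    @property
    def set_id(self) -> str:
        return f"P{self.position:+d}_{self.fixed_residue}"

    @classmethod
    def from_id(cls, set_id: str) -> "SetDefinition":
        try:
            pos_part, residue = set_id.split("_")
            if not pos_part.startswith("P"):
                raise ValueError
            return cls(position=int(pos_part[1:]), fixed_residue=residue)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed set_id: {set_id!r}") from exc


@dataclass(frozen=True)
class LibraryDesign:
    """The combinatorial definition of a positional-scanning lysine library.

    Parameters
    ----------
    alphabet
        Ordered residues allowed at degenerate/fixed flank positions.
    flank_positions
        Ordered integer offsets of the variable positions (0 excluded; the
        centre is always ``central_residue``).
    central_residue
        The invariant central target residue (lysine).
    n_spacer, c_spacer
        Fixed terminal spacer residues.
    tag
        Free-text description of C-terminal functionalisation; informational.
    """

    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    flank_positions: tuple[int, ...] = DEFAULT_FLANK_POSITIONS
    central_residue: str = "K"
    n_spacer: str = "G"
    c_spacer: str = "G"
    tag: str = "TEG-biotin"

    def __post_init__(self):
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        object.__setattr__(self, "flank_positions", tuple(self.flank_positions))
        if not self.alphabet:
            raise InvalidDesignError("alphabet must not be empty")
        if not self.flank_positions:
            raise InvalidDesignError("flank_positions must not be empty")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise InvalidDesignError("alphabet entries must be unique")
        if len(set(self.flank_positions)) != len(self.flank_positions):
            raise InvalidDesignError("flank positions must be unique")
        if 0 in self.flank_positions:
            raise InvalidDesignError("offset 0 is the fixed central residue")
        if len(self.central_residue) != 1:
            raise InvalidDesignError("central_residue must be a single letter")

    # -- basic arithmetic ---------------------------------------------------

    @property
    def window_width(self) -> int:
        """Width of the variable core including the centre (7 by default)."""
        return max(self.flank_positions) - min(self.flank_positions) + 1

    def enumerate_sets(self) -> list[SetDefinition]:
        """All screening sets, ordered by position then alphabet order."""
        return [
            SetDefinition(p, a)
            for p in sorted(self.flank_positions)
            for a in self.alphabet
        ]

    def library_size(self) -> int:
        """Number of unique peptides in the full library."""
        return len(self.alphabet) ** len(self.flank_positions)

    def set_size(self, s: SetDefinition) -> int:
        """Number of unique peptides in one screening set."""
        self._require_member(s)
        return len(self.alphabet) ** (len(self.flank_positions) - 1)

    def _require_member(self, s: SetDefinition) -> None:
        if s.position not in self.flank_positions or s.fixed_residue not in self.alphabet:
            raise UnknownSetError(f"set {s.set_id} is not part of this design")

    # -- 7-mer membership ---------------------------------------------------

    def core_offsets(self, core: str) -> dict[int, str]:
        """Map flank offset -> residue for a lysine-centred core sequence."""
        width = self.window_width
        if len(core) != width:
            raise UnscoreableSequenceError(
                f"core must be {width} residues, got {len(core)}"
            )
        centre = -min(self.flank_positions)
        if core[centre] != self.central_residue:
            raise UnscoreableSequenceError(
                f"central residue must be {self.central_residue!r}, "
                f"got {core[centre]!r} in {core!r}"
            )
        return {p: core[centre + p] for p in sorted(self.flank_positions)}

    def peptide_set_membership(self, core: str) -> list[SetDefinition]:
        """The sets that together construct ``core`` — one per flank position."""
        offsets = self.core_offsets(core)
        bad = sorted({r for r in offsets.values() if r not in self.alphabet})
        if bad:
            raise UnscoreableSequenceError(
                f"residue(s) outside the library alphabet in {core!r}: {', '.join(bad)}"
            )
        return [SetDefinition(p, offsets[p]) for p in sorted(self.flank_positions)]

    def is_scoreable(self, core: str) -> bool:
        try:
            self.peptide_set_membership(core)
        except UnscoreableSequenceError:
            return False
        return True

    # -- IO -----------------------------------------------------------------

    def sets_frame(self) -> pd.DataFrame:
        sets = self.enumerate_sets()
        return pd.DataFrame(
            {
                "set_id": [s.set_id for s in sets],
                "position": [s.position for s in sets],
                "fixed_residue": [s.fixed_residue for s in sets],
            }
        )

    def write_sets(self, path: str | Path) -> None:
        self.sets_frame().to_csv(path, sep="\t", index=False)


@dataclass
class MassDistribution:
    """Exact histogram of the peptide masses in one degenerate set."""

    bin_edges: np.ndarray  # length len(counts) + 1, strictly increasing (Da)
    counts: np.ndarray  # non-negative integer peptide counts per bin
    total: int = field(default=0)

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not self.total:
            self.total = int(self.counts.sum())


def _mass_counter_power(base: Counter, n: int) -> Counter:
    """Counter of sums of ``n`` independent draws (integer keys), by convolution."""
    out = Counter({0: 1})
    for _ in range(n):
        nxt = Counter()
        for m1, c1 in out.items():
            for m2, c2 in base.items():
                nxt[m1 + m2] += c1 * c2
        out = nxt
    return out


def set_mass_distribution(
    design: LibraryDesign,
    s: SetDefinition,
    residue_masses: dict[str, float],
    fixed_extra_mass: float = WATER_MONO,
    bin_width: float = 1.0,
) -> MassDistribution:
    """Theoretical mass histogram of every peptide in set ``s``.

    The multiset of peptide masses is computed exactly by iterated convolution
    of the single-position mass multiset over the degenerate positions,
    shifted by the fixed masses (spacers, central residue, the set's fixed
    residue) plus ``fixed_extra_mass`` (terminal water by default; add the tag
    mass here if modelling the functionalised library).  Bins are left-closed
    right-open, ``bin_width`` Da wide, anchored at the minimum peptide mass.
    Masses are handled at 0.1-mDa resolution so binning is deterministic.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    design._require_member(s)
    fixed_residues = [
        design.n_spacer,
        design.c_spacer,
        design.central_residue,
        s.fixed_residue,
    ]
    require_masses(list(design.alphabet) + fixed_residues, residue_masses)

    def units(x: float) -> int:
        return round(x * _MASS_SCALE)

    shift = sum(units(residue_masses[r]) for r in fixed_residues)
    shift += units(fixed_extra_mass)
    base = Counter()
    for a in design.alphabet:
        base[units(residue_masses[a])] += 1
    dist = _mass_counter_power(base, len(design.flank_positions) - 1)

    masses = sorted(dist)
    width_u = units(bin_width)
    lo = masses[0] + shift
    n_bins = (masses[-1] + shift - lo) // width_u + 1
    counts = np.zeros(int(n_bins), dtype=np.int64)
    for m, c in dist.items():
        counts[(m + shift - lo) // width_u] += c
    edges = lo / _MASS_SCALE + bin_width * np.arange(int(n_bins) + 1)
    return MassDistribution(bin_edges=edges, counts=counts)


# -- thin functional wrappers (mirror the operation names) -------------------

def enumerate_sets(design: LibraryDesign) -> list[SetDefinition]:
    return design.enumerate_sets()


def library_size(design: LibraryDesign) -> int:
    return design.library_size()


def set_size(design: LibraryDesign, s: SetDefinition) -> int:
    return design.set_size(s)


def peptide_set_membership(core: str, design: LibraryDesign) -> list[SetDefinition]:
    return design.peptide_set_membership(core)
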