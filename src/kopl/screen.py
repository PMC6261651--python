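"""Build enzyme selectivity profiles from replicated library-screen signals.

A screen measures one counts-per-minute (cpm) signal per library set per
replicate (scintillation proximity assay read-out).  The profile holds the
per-set replicate mean on the raw cpm scale plus two display normalisations:

* global — min–max over all sets, so the single most-used set maps to 1;
* positional — min–max within each flank position (heat-map column), so every
  position shows its own best (1) and worst (0) residue.

Downstream motif scoring uses the raw means only; the normalised views exist
for visualisation and cross-position comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CompletenessError, SchemaError
from .library import LibraryDesign, SetDefinition

Key = tuple[int, str]  # (flank position, fixed residue)


@dataclass(frozen=True)
class ScreenMeasurement:
    """One well: a set's cpm signal in one replicate, with optional blank."""

    set_id: str
    replicate: int
    signal: float
    blank: float | None = None


@dataclass
class SelectivityProfile:
    """Per-(position, residue) screen signal for one enzyme.

    ``raw`` is the replicate-mean cpm per set; ``global_norm`` and
    ``positional_norm`` are the two [0, 1] display views.
    """

    enzyme: str
    design: LibraryDesign
    raw: dict[Key, float]
    raw_sd: dict[Key, float] = field(default_factory=dict)
    n_replicates: dict[Key, int] = field(default_factory=dict)
    global_norm: dict[Key, float] = field(default_factory=dict)
    positional_norm: dict[Key, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table, one row per set, in canonical set order."""
        rows = []
        for s in self.design.enumerate_sets():
            k = (s.position, s.fixed_residue)
            rows.append(
                {
                    "position": s.position,
                    "residue": s.fixed_residue,
                    "raw_mean": self.raw[k],
                    "raw_sd": self.raw_sd.get(k, np.nan),
                    "n": self.n_replicates.get(k, 0),
                    "global_norm": self.global_norm.get(k, np.nan),
                    "positional_norm": self.positional_norm.get(k, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def matrix(self, view: str = "positional_norm") -> pd.DataFrame:
        """Heat-map layout: rows = residues in alphabet order, cols = positions."""
        values = {"raw": self.raw, "global_norm": self.global_norm,
                  "positional_norm": self.positional_norm}[view]
        positions = sorted(self.design.flank_positions)
        return pd.DataFrame(
            [[values[(p, a)] for p in positions] for a in self.design.alphabet],
            index=list(self.design.alphabet),
            columns=positions,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, design: LibraryDesign | None = None,
                 enzyme: str = "") -> "SelectivityProfile":
        design = design or LibraryDesign()
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        raw = {(int(r.position), r.residue): float(r.raw_mean) for r in df.itertuples()}
        prof = cls(
            enzyme=enzyme,
            design=design,
            raw=raw,
            raw_sd={(int(r.position), r.residue): float(r.raw_sd) for r in df.itertuples()},
            n_replicates={(int(r.position), r.residue): int(r.n) for r in df.itertuples()},
        )
        prof.global_norm = normalize_global(raw)
        prof.positional_norm = normalize_positional(raw, design)
        return prof

    def plot_heatmap(self, view: str = "positional_norm", ax=None):
        """Render the profile as the conventional blue(0)–red(1) heat map."""
        import matplotlib.pyplot as plt

        mat = self.matrix(view)
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 6))
        im = ax.imshow(mat.to_numpy(), cmap="coolwarm", aspect="auto",
                       vmin=0 if view != "raw" else None)
        ax.set_xticks(range(mat.shape[1]),
                      [f"{p:+d}" for p in mat.columns])
        ax.set_yticks(range(mat.shape[0]), mat.index)
        ax.set_xlabel("position relative to central K")
        ax.set_title(self.enzyme or view)
        plt.colorbar(im, ax=ax, label="cpm" if view == "raw" else view)
        return ax


def read_screen(table: str | Path, design: LibraryDesign) -> list[ScreenMeasurement]:
    """Read a screen TSV (columns set_id, replicate, signal[, blank])."""
    df = pd.read_csv(table, sep="\t")
    required = {"set_id", "replicate", "signal"}
    if not required.issubset(df.columns):
        raise SchemaError(f"screen table needs columns {sorted(required)}, "
                          f"got {list(df.columns)}")
    valid_ids = {s.set_id for s in design.enumerate_sets()}
    out: list[ScreenMeasurement] = []
    for row in df.itertuples():
        if row.set_id not in valid_ids:
            raise SchemaError(f"unknown set_id {row.set_id!r}")
        signal = float(row.signal)
        if signal < 0:
            raise ValueError(f"negative signal {signal} for set {row.set_id}")
        blank = None
        if "blank" in df.columns and not pd.isna(row.blank):
            blank = float(row.blank)
            if blank < 0:
                raise ValueError(f"negative blank {blank} for set {row.set_id}")
        out.append(ScreenMeasurement(row.set_id, int(row.replicate), signal, blank))
    seen = {m.set_id for m in out}
    missing = sorted(valid_ids - seen)
    if missing:
        raise CompletenessError(missing)
    return out


def normalize_global(raw: dict[Key, float]) -> dict[Key, float]:
    """Min–max normalise all set signals jointly onto [0, 1]."""
    vals = np.array(list(raw.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("all set signals equal; global normalisation is all-zero")
        return {k: 0.0 for k in raw}
    return {k: (v - lo) / (hi - lo) for k, v in raw.items()}


def normalize_positional(raw: dict[Key, float], design: LibraryDesign) -> dict[Key, float]:
    """Min–max normalise within each flank position (heat-map column)."""
    out: dict[Key, float] = {}
    for p in design.flank_positions:
        col = {k: v for k, v in raw.items() if k[0] == p}
        vals = np.array(list(col.values()), dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            warnings.warn(f"constant signal at position {p:+d}; column set to zero")
            out.update({k: 0.0 for k in col})
        else:
            out.update({k: (v - lo) / (hi - lo) for k, v in col.items()})
    return out


def build_profile(
    measurements: list[ScreenMeasurement],
    design: LibraryDesign,
    subtract_blank: bool = False,
    enzyme: str = "",
) -> SelectivityProfile:
    """Aggregate replicate measurements into a selectivity profile.

    Replicates are combined by unweighted arithmetic mean.  With
    ``subtract_blank`` the per-well no-enzyme blank is subtracted first and
    clamped at zero (a well cannot produce negative product signal).
    """
    per_set: dict[Key, list[float]] = {}
    for m in measurements:
        s = SetDefinition.from_id(m.set_id)
        design._require_member(s)
        x = m.signal
        if subtract_blank and m.blank is not None:
            x = max(x - m.blank, 0.0)
        per_set.setdefault((s.position, s.fixed_residue), []).append(x)

    missing = [
        s.set_id for s in design.enumerate_sets()
        if (s.position, s.fixed_residue) not in per_set
    ]
    if missing:
        raise CompletenessError(missing)

    raw = {k: float(np.mean(v)) for k, v in per_set.items()}
    raw_sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
              for k, v in per_set.items()}
    n = {k: len(v) for k, v in per_set.items()}
    return SelectivityProfile(
        enzyme=enzyme,
        design=design,
        raw=raw,
        raw_sd=raw_sd,
        n_replicates=n,
        global_norm=normalize_global(raw),
        positional_norm=normalize_positional(raw, design),
    )
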