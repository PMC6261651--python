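"""LoB scoring and proteome-wide ranking of lysine-centred 7-mers.

The lowest-bin (LoB) score of a lysine-centred 7-mer is the raw screen signal
of the least-used of the six fixed-position library sets that together spell
the sequence.  Taking the minimum rather than a positional weighting means a
single unfavourable flank residue caps the score, which deliberately
minimises false positives when ranking candidate methylation sites.

Scores stay on the raw cpm scale of one enzyme's screen; they are comparable
within a profile, not across enzymes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .library import LibraryDesign
from .screen import SelectivityProfile

_NUCLEOTIDE_LETTERS = set("ACGTUN")


@dataclass(frozen=True)
class KWindow:
    """A lysine-centred 7-mer with its 1-based lysine coordinate."""

    protein_id: str
    k_position: int
    core7: str


@dataclass
class LobResult:
    window: KWindow
    score: float
    limiting_positions: tuple[int, ...]
    scoreable: bool = True
    rank: int | None = None


@dataclass
class ExclusionReport:
    """Why lysines were skipped during window extraction."""

    counts: Counter = field(default_factory=Counter)
    records: list[tuple[str, int, str]] = field(default_factory=list)

    def add(self, protein_id: str, k_position: int, reason: str) -> None:
        self.counts[reason] += 1
        self.records.append((protein_id, k_position, reason))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["protein_id", "k_position", "reason"])


def iter_sequences(proteome) -> list[tuple[str, str]]:
    """Normalise a proteome argument to (id, sequence) pairs.

    Accepts a FASTA path, a mapping id -> sequence, or an iterable of
    Biopython SeqRecords.
    """
    if isinstance(proteome, (str, Path)):
        return [(rec.id, str(rec.seq).upper())
                for rec in SeqIO.parse(str(proteome), "fasta")]
    if isinstance(proteome, dict):
        return [(pid, seq.upper()) for pid, seq in proteome.items()]
    return [(rec.id, str(rec.seq).upper()) for rec in proteome]


def extract_windows(
    proteome, design: LibraryDesign | None = None
) -> tuple[list[KWindow], ExclusionReport]:
    """Extract every complete, scoreable lysine-centred window from a proteome.

    Lysines within three residues of a terminus are excluded (``terminal``),
    as are windows containing residues outside the library alphabet —
    cysteine, selenocysteine, or ambiguity codes (``non_alphabet``).
    """
    design = design or LibraryDesign()
    before = -min(design.flank_positions)
    after = max(design.flank_positions)
    report = ExclusionReport()
    windows: list[KWindow] = []
    entries = iter_sequences(proteome)
    if not entries:
        warnings.warn("empty proteome: no sequences found")
        return windows, report
    for pid, seq in entries:
        if seq and set(seq) <= _NUCLEOTIDE_LETTERS:
            warnings.warn(
                f"sequence {pid!r} looks like a nucleotide sequence "
                "(ACGTUN only); expected amino acids"
            )
        for i, res in enumerate(seq):
            if res != design.central_residue:
                continue
            k_pos = i + 1  # 1-based
            if i < before or i + after >= len(seq):
                report.add(pid, k_pos, "terminal")
                continue
            core = seq[i - before : i + after + 1]
            if design.is_scoreable(core):
                windows.append(KWindow(pid, k_pos, core))
            else:
                report.add(pid, k_pos, "non_alphabet")
    return windows, report


def lob_score(profile: SelectivityProfile, window: KWindow) -> LobResult:
    """Score one window: minimum raw signal over its six constructing sets."""
    design = profile.design
    sets = design.peptide_set_membership(window.core7)
    signals = {s.position: profile.raw[(s.position, s.fixed_residue)] for s in sets}
    score = min(signals.values())
    limiting = tuple(p for p in sorted(signals) if signals[p] == score)
    return LobResult(window=window, score=score, limiting_positions=limiting)


def rank_proteome(
    profile: SelectivityProfile,
    proteome,
    top_n: int | None = None,
) -> list[LobResult]:
    """Score and rank every scoreable window in a proteome.

    Sorted by score descending; ties broken by core7 lexicographic order,
    then protein_id, then k_position.  ``top_n`` truncates the ranked list.
    """
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be >= 1")
    windows, _ = extract_windows(proteome, profile.design)
    results = [lob_score(profile, w) for w in windows]
    results.sort(key=lambda r: (-r.score, r.window.core7,
                                r.window.protein_id, r.window.k_position))
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results[:top_n] if top_n is not None else results


def deduplicate_by_core(results: list[LobResult]) -> list[LobResult]:
    """Sequence-level view: one representative per distinct core7 (best rank)."""
    seen: set[str] = set()
    out = []
    for r in results:
        if r.window.core7 not in seen:
            seen.add(r.window.core7)
            out.append(r)
    return out


def find_exact(core7: str, proteome, design: LibraryDesign | None = None
               ) -> list[tuple[str, int]]:
    """All exact occurrences of ``core7`` as a complete window: (id, k_position)."""
    design = design or LibraryDesign()
    design.core_offsets(core7)  # validates length and central residue
    before = -min(design.flank_positions)
    hits: list[tuple[str, int]] = []
    for pid, seq in iter_sequences(proteome):
        start = seq.find(core7)
        while start != -1:
            hits.append((pid, start + before + 1))
            start = seq.find(core7, start + 1)
    return hits


def results_to_frame(results: list[LobResult]) -> pd.DataFrame:
    """Ranked TSV layout: rank, protein_id, k_position, core7, score, limits."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "protein_id": [r.window.protein_id for r in results],
            "k_position": [r.window.k_position for r in results],
            "core7": [r.window.core7 for r in results],
            "lob_score": [r.score for r in results],
            "limiting_positions": [
                ";".join(f"{p:+d}" for p in r.limiting_positions) for r in results
            ],
        }
    )
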