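"""Classify how missense mutations rewire lysine-methylation motifs.

Each mutation is applied to its protein, every lysine-centred window whose
7-mer overlaps the mutated position is rescored against a selectivity
profile, and the change is classified:

* ``created`` — the window is scoreable only after the mutation (a new
  central lysine, or a disqualifying flank residue such as cysteine removed);
* ``removed`` — scoreable only before (central K lost, or a disqualifying
  residue introduced);
* ``weakened`` / ``strengthened`` / ``unchanged`` — both scores exist and the
  relative change falls below −θ, above +θ, or inside the dead-band.

The dead-band θ (default 0.2, i.e. 20 % relative change) separates real
rewiring from noise-level shifts; it is explicit in every output.  The
``collapse_removed`` option folds ``removed`` into ``weakened`` for
four-class summaries (a lost site is the extreme of weakening).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import MutationParseError, ReferenceMismatchError
from .library import LibraryDesign
from .scan import KWindow, iter_sequences, lob_score
from .screen import SelectivityProfile

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
CLASSES = ("created", "removed", "weakened", "strengthened", "unchanged")

_TOKEN_RE = re.compile(r"^(?:p\.)?([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class MutationRecord:
    protein_id: str
    position: int  # 1-based
    ref_residue: str
    alt_residue: str
    source_label: str = ""


@dataclass
class ImpactRecord:
    """One mutation × one affected lysine-centred window."""

    mutation: MutationRecord
    k_position: int
    window_before: KWindow | None
    window_after: KWindow | None
    score_before: float | None
    score_after: float | None
    impact_class: str
    relative_change: float | None


def parse_mutation_token(protein_id: str, token: str,
                         source_label: str = "") -> MutationRecord:
    """Parse a compact ``D353R`` / ``p.D353R`` token into a record."""
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"unparseable mutation token: {token!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return _validated(protein_id, pos, ref, alt, source_label)


def _validated(protein_id, position, ref, alt, source_label="") -> MutationRecord:
    if ref not in STANDARD_RESIDUES:
        raise ValueError(f"non-standard reference residue {ref!r}")
    if alt not in STANDARD_RESIDUES:
        raise ValueError(f"non-standard alternate residue {alt!r}")
    if ref == alt:
        raise ValueError(f"reference and alternate residues identical ({ref})")
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return MutationRecord(protein_id, int(position), ref, alt, source_label)


def parse_mutations(table) -> list[MutationRecord]:
    """Parse a mutation table into validated records.

    ``table`` may be a TSV path (columns ``protein_id`` plus either
    ``position``/``ref``/``alt`` or a compact ``token`` column, optional
    ``source_label``), or a list of ``(protein_id, token)`` pairs /
    ``"PROT:p.D353R"`` strings.  Row-level failures are collected and raised
    together with their line numbers.
    """
    rows: list[tuple[int, dict]] = []
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, sep="\t")
        for i, row in enumerate(df.to_dict("records"), start=2):  # 1 = header
            rows.append((i, row))
    else:
        for i, item in enumerate(table, start=1):
            if isinstance(item, str):
                pid, _, tok = item.partition(":")
                rows.append((i, {"protein_id": pid, "token": tok}))
            else:
                pid, tok = item
                rows.append((i, {"protein_id": pid, "token": tok}))

    records: list[MutationRecord] = []
    errors: list[str] = []
    for line_no, row in rows:
        label = str(row.get("source_label", "") or "")
        try:
            if "token" in row and not pd.isna(row.get("token")):
                records.append(
                    parse_mutation_token(str(row["protein_id"]), str(row["token"]), label)
                )
            else:
                records.append(
                    _validated(str(row["protein_id"]), int(row["position"]),
                               str(row["ref"]).upper(), str(row["alt"]).upper(), label)
                )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        raise MutationParseError(errors)
    return records


def apply_mutation(sequence: str, m: MutationRecord) -> str:
    """Apply one substitution; the observed residue must match the reference."""
    if not (1 <= m.position <= len(sequence)):
        raise ValueError(
            f"position {m.position} outside sequence of length {len(sequence)}"
        )
    observed = sequence[m.position - 1]
    if observed != m.ref_residue:
        raise ReferenceMismatchError(m.position, m.ref_residue, observed)
    return sequence[: m.position - 1] + m.alt_residue + sequence[m.position:]


def _window_at(sequence: str, centre: int, design: LibraryDesign,
               protein_id: str) -> KWindow | None:
    """Scoreable window centred at 1-based ``centre``, else None."""
    before = -min(design.flank_positions)
    after = max(design.flank_positions)
    i = centre - 1
    if sequence[i] != design.central_residue:
        return None
    if i < before or i + after >= len(sequence):
        return None
    core = sequence[i - before : i + after + 1]
    if not design.is_scoreable(core):
        return None
    return KWindow(protein_id, centre, core)


def classify_impacts(
    profile: SelectivityProfile,
    sequence: str,
    m: MutationRecord,
    design: LibraryDesign | None = None,
    threshold: float = 0.2,
) -> list[ImpactRecord]:
    """Evaluate every window overlapping the mutated position, before vs after.

    Candidate centres are all positions within the flank span of the mutation
    that carry a lysine in either the reference or the mutated sequence.
    Centres unscoreable on both sides are not methylation targets in either
    proteome and produce no record.
    """
    design = design or profile.design
    mutated = apply_mutation(sequence, m)
    span = max(-min(design.flank_positions), max(design.flank_positions))
    records: list[ImpactRecord] = []
    for centre in range(max(1, m.position - span),
                        min(len(sequence), m.position + span) + 1):
        is_k_before = sequence[centre - 1] == design.central_residue
        is_k_after = mutated[centre - 1] == design.central_residue
        if not (is_k_before or is_k_after):
            continue
        wb = _window_at(sequence, centre, design, m.protein_id)
        wa = _window_at(mutated, centre, design, m.protein_id)
        if wb is None and wa is None:
            continue
        sb = lob_score(profile, wb).score if wb is not None else None
        sa = lob_score(profile, wa).score if wa is not None else None
        rel = None
        if wb is None:
            cls = "created"
        elif wa is None:
            cls = "removed"
        else:
            if sb > 0:
                rel = (sa - sb) / sb
                if rel < 0 and rel <= -threshold:
                    cls = "weakened"
                elif rel > 0 and rel >= threshold:
                    cls = "strengthened"
                else:
                    cls = "unchanged"
            else:
                # degenerate zero-signal baseline: any gain is a strengthening
                cls = "strengthened" if sa > sb else "unchanged"
        records.append(
            ImpactRecord(m, centre, wb, wa, sb, sa, cls, rel)
        )
    return records


def collapse_class(cls: str) -> str:
    """Map the internal five-class labelling onto the four summary classes."""
    return "weakened" if cls == "removed" else cls


def compare_proteomes(
    profile: SelectivityProfile,
    reference_proteome,
    mutations,
    threshold: float = 0.2,
    collapse_removed: bool = False,
    design: LibraryDesign | None = None,
) -> tuple[pd.DataFrame, Counter, list[str]]:
    """Rescore a mutation table against a reference proteome.

    Returns a scatter-ready impact table (one row per mutation × affected
    window), per-class counts, and a list of per-record error messages
    (missing proteins, reference mismatches) for records that were skipped.
    """
    design = design or profile.design
    seqs = dict(iter_sequences(reference_proteome))
    if not isinstance(mutations, list) or (
        mutations and not isinstance(mutations[0], MutationRecord)
    ):
        mutations = parse_mutations(mutations)
    rows = []
    errors: list[str] = []
    for m in mutations:
        seq = seqs.get(m.protein_id)
        if seq is None:
            errors.append(f"{m.protein_id}: not in proteome")
            continue
        try:
            impacts = classify_impacts(profile, seq, m, design, threshold)
        except (ReferenceMismatchError, ValueError) as exc:
            errors.append(f"{m.protein_id} {m.ref_residue}{m.position}"
                          f"{m.alt_residue}: {exc}")
            continue
        for r in impacts:
            cls = collapse_class(r.impact_class) if collapse_removed else r.impact_class
            rows.append(
                {
                    "protein_id": m.protein_id,
                    "position": m.position,
                    "ref": m.ref_residue,
                    "alt": m.alt_residue,
                    "source_label": m.source_label,
                    "k_position": r.k_position,
                    "core7_before": r.window_before.core7 if r.window_before else "",
                    "core7_after": r.window_after.core7 if r.window_after else "",
                    "score_before": r.score_before,
                    "score_after": r.score_after,
                    "relative_change": r.relative_change,
                    "impact_class": cls,
                    "threshold": threshold,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein_id", "position", "ref", "alt", "source_label", "k_position",
            "core7_before", "core7_after", "score_before", "score_after",
            "relative_change", "impact_class", "threshold",
        ],
    )
    counts = Counter(table["impact_class"]) if len(table) else Counter()
    return table, counts, errors
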