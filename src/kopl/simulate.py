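"""Seeded generators for every input the analysis consumes.

The signal model is additive: a set's expected screen signal is
``baseline + amplitude * weight(position, residue)``, with per-replicate
Gaussian (default sigma = 5 % of amplitude) or Poisson counting noise.  This
is the simplest model that reproduces the per-position preference structure
a positional-scanning screen reads out, with a controllable signal floor.

Proteomes are random background sequences with motif cores planted at known
coordinates; mutation tables are constructed so that the intended impact
class is guaranteed under the noiseless expected signals; kinetic datasets
are exact model evaluations plus seeded noise.  Every generator records its
ground truth and is byte-deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .kinetics import logistic4, mm_rate, si_rate
from .library import LibraryDesign
from .mutation import MutationRecord
from .scan import extract_windows
from .screen import ScreenMeasurement

STANDARD_20 = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MotifModel:
    """Per-(position, residue) substrate preference driving a synthetic screen."""

    weights: dict[tuple[int, str], float]
    baseline: float = 200.0
    amplitude: float = 5000.0
    noise_model: str = "gaussian"  # or "poisson"
    sigma: float | None = None  # gaussian sd; default 5% of amplitude

    def __post_init__(self):
        if self.baseline < 0 or self.amplitude <= 0:
            raise ValueError("baseline must be >= 0 and amplitude > 0")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if self.sigma is None:
            self.sigma = 0.05 * self.amplitude

    def expected_signal(self, position: int, residue: str) -> float:
        return self.baseline + self.amplitude * self.weights[(position, residue)]

    def expected_signals(self, design: LibraryDesign) -> dict[tuple[int, str], float]:
        return {
            (s.position, s.fixed_residue):
                self.expected_signal(s.position, s.fixed_residue)
            for s in design.enumerate_sets()
        }


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    planted_windows: list[tuple[str, int, str]] = field(default_factory=list)
    mutation_truth: dict[tuple[str, int, str, str], tuple[str, int]] = field(
        default_factory=dict
    )
    seeds: list[int] = field(default_factory=list)


def smyd2_like_motif(
    design: LibraryDesign | None = None,
    baseline: float = 200.0,
    amplitude: float = 5000.0,
    sigma: float | None = None,
    seed: int = 0,
) -> MotifModel:
    """A selectivity model with SMYD2-like structure.

    Strong preference for L/F/M at −1 and S at +1, basic residues (K/R)
    favoured at the outer flanks, tryptophan slightly ahead of arginine at
    −3 (the optimal core is then W/R-K-[LFM]-K-S-K-R-like).  Background
    preferences are small seeded values so ranks are fully determined.
    """
    design = design or LibraryDesign()
    rng = np.random.default_rng(seed)
    weights: dict[tuple[int, str], float] = {}
    boosts = {
        (-1, "L"): 1.00, (-1, "F"): 0.92, (-1, "M"): 0.86,
        (1, "S"): 1.00, (1, "T"): 0.55,
        (-3, "W"): 0.95, (-3, "R"): 0.86, (-3, "K"): 0.80,
        (-2, "K"): 0.88, (-2, "R"): 0.82,
        (2, "K"): 0.90, (2, "R"): 0.84,
        (3, "R"): 0.88, (3, "K"): 0.83,
    }
    for p in design.flank_positions:
        for a in design.alphabet:
            weights[(p, a)] = boosts.get(
                (p, a), float(rng.uniform(0.03, 0.25))
            )
    return MotifModel(weights=weights, baseline=baseline, amplitude=amplitude,
                      sigma=sigma)


def gen_screen(
    motif: MotifModel,
    design: LibraryDesign | None = None,
    n_replicates: int = 2,
    seed: int = 0,
) -> list[ScreenMeasurement]:
    """Simulate one replicated screen over every library set."""
    design = design or LibraryDesign()
    rng = np.random.default_rng(seed)
    out: list[ScreenMeasurement] = []
    for s in design.enumerate_sets():
        mu = motif.expected_signal(s.position, s.fixed_residue)
        for rep in range(1, n_replicates + 1):
            if motif.noise_model == "poisson":
                signal = float(rng.poisson(mu))
            else:
                signal = mu + (float(rng.normal(0.0, motif.sigma))
                               if motif.sigma > 0 else 0.0)
            out.append(ScreenMeasurement(s.set_id, rep, max(signal, 0.0)))
    return out


def screen_to_tsv(measurements: list[ScreenMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        {
            "set_id": [m.set_id for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "signal": [m.signal for m in measurements],
        }
    ).to_csv(path, sep="\t", index=False)


def gen_proteome(
    n_proteins: int = 500,
    length_range: tuple[int, int] = (200, 600),
    background_frequencies: dict[str, float] | None = None,
    planted: list[str] | list[tuple[str, int]] | None = None,
    seed: int = 0,
    design: LibraryDesign | None = None,
) -> tuple[dict[str, str], GroundTruth]:
    """Random proteome with motif cores planted at recorded coordinates.

    Background residues are drawn from ``background_frequencies`` (default:
    uniform over the 20 standard residues, so cysteine occurs and exercises
    unscoreable windows).  Planted cores are written over the background at
    random interior positions and never overlap each other.
    """
    design = design or LibraryDesign()
    width = design.window_width
    centre_off = -min(design.flank_positions)
    freqs = background_frequencies or {a: 1.0 for a in STANDARD_20}
    letters = sorted(freqs)
    probs = np.array([freqs[a] for a in letters], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("background frequencies must sum to a positive value")
    probs = probs / probs.sum()

    cores: list[str] = []
    for item in planted or []:
        if isinstance(item, tuple):
            core, mult = item
            cores.extend([core] * int(mult))
        else:
            cores.append(item)
    for core in cores:
        design.core_offsets(core)  # validates length and central residue

    rng = np.random.default_rng(seed)
    truth = GroundTruth(seeds=[seed])
    records: dict[str, str] = {}
    lengths = {}
    for i in range(n_proteins):
        pid = f"SYN{i + 1:04d}"
        n = int(rng.integers(length_range[0], length_range[1] + 1))
        records[pid] = "".join(rng.choice(letters, size=n, p=probs))
        lengths[pid] = n

    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in records}
    pids = list(records)
    for core in cores:
        placed = False
        for _ in range(2000):
            pid = pids[int(rng.integers(len(pids)))]
            n = lengths[pid]
            if n < width:
                continue
            start = int(rng.integers(0, n - width + 1))  # 0-based
            if any(start < e and start + width > s for s, e in occupied[pid]):
                continue
            seq = records[pid]
            records[pid] = seq[:start] + core + seq[start + width:]
            occupied[pid].append((start, start + width))
            truth.planted_windows.append((pid, start + centre_off + 1, core))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place planted core {core!r}: proteome too crowded"
            )
    return records, truth


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in records.items():
            fh.write(f">{pid}\n{seq}\n")


def _window_signals(core: str, design: LibraryDesign,
                    sig: dict[tuple[int, str], float]) -> dict[int, float]:
    offsets = design.core_offsets(core)
    return {p: sig[(p, offsets[p])] for p in offsets}


def gen_mutations(
    proteome: dict[str, str],
    class_mix: dict[str, int],
    motif: MotifModel,
    design: LibraryDesign | None = None,
    theta: float = 0.2,
    margin: float = 0.1,
    seed: int = 0,
) -> tuple[list[MutationRecord], GroundTruth]:
    """Construct mutations whose impact class is guaranteed by the motif.

    For every requested class the generator finds windows where the intended
    class is realised under the noiseless expected signals with at least
    ``margin`` relative-change headroom beyond the dead-band ``theta``:
    central K→R for removed, X→K in a clean context for created, a flank
    substitution that drops (raises) the limiting minimum for weakened
    (strengthened), and a non-limiting neutral swap for unchanged.  The
    intended class and target lysine are recorded per mutation.
    """
    design = design or LibraryDesign()
    sig = motif.expected_signals(design)
    rng = np.random.default_rng(seed)
    windows, _ = extract_windows(proteome, design)
    if not windows and any(class_mix.values()):
        raise GenerationError("proteome has no scoreable windows")
    order = rng.permutation(len(windows))
    centre_off = -min(design.flank_positions)

    used_positions: set[tuple[str, int]] = set()
    mutations: list[MutationRecord] = []
    truth = GroundTruth(seeds=[seed])

    def take(m: MutationRecord, cls: str, k_pos: int) -> None:
        mutations.append(m)
        used_positions.add((m.protein_id, m.position))
        truth.mutation_truth[
            (m.protein_id, m.position, m.ref_residue, m.alt_residue)
        ] = (cls, k_pos)

    def residue_at(pid: str, pos: int) -> str:
        return proteome[pid][pos - 1]

    for cls, want in class_mix.items():
        if cls not in ("created", "removed", "weakened", "strengthened",
                       "unchanged"):
            raise GenerationError(f"unknown impact class {cls!r}")
        made = 0
        if cls == "created":
            # any non-K interior position whose would-be window is scoreable
            for pid in sorted(proteome):
                seq = proteome[pid]
                for i in range(centre_off, len(seq) - (design.window_width
                                                       - centre_off - 1)):
                    if made >= want:
                        break
                    pos = i + 1
                    ref = seq[i]
                    if ref == design.central_residue or (pid, pos) in used_positions:
                        continue
                    core_after = (seq[i - centre_off:i]
                                  + design.central_residue
                                  + seq[i + 1:i + design.window_width - centre_off])
                    if not design.is_scoreable(core_after):
                        continue
                    take(MutationRecord(pid, pos, ref, design.central_residue,
                                        "synthetic"), cls, pos)
                    made += 1
                if made >= want:
                    break
        else:
            for idx in order:
                if made >= want:
                    break
                w = windows[idx]
                if (w.protein_id, w.k_position) in used_positions:
                    continue
                signals = _window_signals(w.core7, design, sig)
                score = min(signals.values())
                limiting = [p for p in signals if signals[p] == score]
                if cls == "removed":
                    take(MutationRecord(w.protein_id, w.k_position,
                                        design.central_residue, "R", "synthetic"),
                         cls, w.k_position)
                    made += 1
                    continue
                # flank-substitution classes need a unique limiting position
                if len(limiting) != 1 or score <= 0:
                    continue
                p_min = limiting[0]
                second = min(v for p, v in signals.items() if p != p_min)
                offsets = design.core_offsets(w.core7)
                if cls == "weakened":
                    target = (1.0 - theta - margin) * score
                    choices = [
                        (p, a) for p in signals for a in design.alphabet
                        if a != offsets[p] and sig[(p, a)] <= target
                        and (w.protein_id, w.k_position + p) not in used_positions
                    ]
                elif cls == "strengthened":
                    floor = (1.0 + theta + margin) * score
                    if second < floor:
                        continue
                    choices = [
                        (p_min, a) for a in design.alphabet
                        if a != offsets[p_min] and sig[(p_min, a)] >= floor
                        and (w.protein_id, w.k_position + p_min)
                        not in used_positions
                    ]
                else:  # unchanged: neutral swap away from the limiting set
                    choices = [
                        (p, a) for p in signals if p != p_min
                        for a in design.alphabet
                        if a != offsets[p] and sig[(p, a)] >= score
                        and (w.protein_id, w.k_position + p) not in used_positions
                    ]
                if not choices:
                    continue
                p, a = choices[int(rng.integers(len(choices)))]
                pos = w.k_position + p
                take(MutationRecord(w.protein_id, pos,
                                    residue_at(w.protein_id, pos), a, "synthetic"),
                     cls, w.k_position)
                made += 1
        if made < want:
            raise GenerationError(
                f"could only construct {made}/{want} mutations of class {cls!r}"
            )
    return mutations, truth


def mutations_to_tsv(mutations: list[MutationRecord], path: str | Path,
                     truth: GroundTruth | None = None) -> None:
    rows = []
    for m in mutations:
        row = {"protein_id": m.protein_id, "position": m.position,
               "ref": m.ref_residue, "alt": m.alt_residue,
               "source_label": m.source_label}
        if truth is not None:
            cls, k_pos = truth.mutation_truth[
                (m.protein_id, m.position, m.ref_residue, m.alt_residue)
            ]
            row["intended_class"] = cls
            row["target_k_position"] = k_pos
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_KINETIC_MODELS = {
    "MM": (mm_rate, ("Vmax", "Km")),
    "SI": (si_rate, ("Vmax", "Km", "Ki")),
    "4PL": (logistic4, ("top", "bottom", "IC50", "hill")),
}


def gen_kinetics(
    model: str,
    params: dict[str, float],
    concentrations,
    sigma: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    substrate_id: str = "synthetic",
) -> tuple[pd.DataFrame, dict]:
    """Exact kinetic-model evaluation plus seeded Gaussian noise.

    Returns a rate table (substrate_id, concentration_uM, rate, replicate)
    and the true parameters.
    """
    fn, names = _KINETIC_MODELS[model]
    if model != "4PL" and any(params[k] <= 0 for k in names):
        raise ValueError("kinetic parameters must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(list(concentrations), dtype=float)
    clean = fn(conc, *[params[k] for k in names])
    rows = []
    for rep in range(1, n_replicates + 1):
        noisy = clean + (rng.normal(0.0, sigma, size=len(conc))
                         if sigma > 0 else 0.0)
        for c, v in zip(conc, noisy):
            rows.append({"substrate_id": substrate_id, "concentration_uM": c,
                         "rate": float(v), "replicate": rep})
    truth = {"model": model, "params": dict(params), "sigma": sigma,
             "seed": seed}
    return pd.DataFrame(rows), truth
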