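# Methods

## The library model

A lysine-oriented positional-scanning library is defined by an ordered
alphabet (default: the canonical residue order ACDEFGHIKLMNPQRSTVWY with
cysteine removed, 19 residues), a set of flank offsets (default −3…+3
excluding 0), a fixed central lysine, and glycine spacers at both termini.
A screening set fixes one residue at one offset; the default design
therefore has 6 × 19 = 114 sets, 19⁶ = 47,045,881 unique peptides in total
and 19⁵ = 2,476,099 per set. Set identifiers are `P{±offset}_{residue}`
(e.g. `P-3_R`), and all tabular output uses the canonical alphabet order so
heat maps are reproducible bit-for-bit.

The C-terminal functionalisation (triethylene-glycol–biotin) is carried
only as an optional constant mass offset (`fixed_extra_mass`), not modelled
structurally: only its mass matters for QC. `fixed_extra_mass` defaults to
one water (18.0105646863 Da monoisotopic), the terminal correction that
turns residue-mass sums into neutral peptide masses.

### Mass distributions

The theoretical mass histogram of a degenerate set is computed exactly by
iterated convolution of the single-position mass multiset over the
degenerate positions, shifted by the fixed masses. Internally masses are
rounded to 0.1 mDa and convolved in integer units, so binning (left-closed,
right-open, anchored at the minimum mass) is deterministic and independent
of summation order; histograms agree bin-for-bin with brute-force
enumeration wherever enumeration is feasible. Both monoisotopic and average
residue-mass tables are bundled, since either envelope may be compared
against MALDI-TOF QC spectra.

## Selectivity profiles

Replicates are combined by unweighted arithmetic mean per set; the per-set
standard deviation is stored for reporting but unused downstream. Optional
per-well blank subtraction (off by default — the assay protocol this
emulates applies none) clamps at zero. Two display normalisations are
provided, both min–max onto [0, 1]: *global* (over all 114 sets) and
*positional* (within each flank-position column). Min–max is the minimal
scheme consistent with a 0–1 heat-map colour code where 1 is the most and 0
the least active set. A constant input (or column) normalises to zero with
a warning rather than dividing by zero.

## LoB scoring and ranking

The lowest-bin score of a lysine-centred 7-mer is the minimum **raw** mean
signal over the six sets that construct it. Raw cpm is used deliberately:
the score is an activity floor on the original measurement scale, so scores
are comparable within one enzyme's screen and *not* across enzymes; no
cross-enzyme comparison is offered. There is no positional weighting — a
single bad flank caps the score, which suppresses false positives at the
cost of sensitivity to single-position rescues.

Window extraction excludes lysines within three residues of a terminus
(no padding rule exists for partial windows) and windows containing
residues outside the alphabet (cysteine, selenocysteine, ambiguity codes);
exclusions are counted per reason rather than silently dropped. All protein
coordinates are 1-based. Ranking sorts by score descending with a
deterministic tie-break (core sequence, then protein id, then position);
identical cores in different proteins are retained as separate rows, with a
deduplicated per-sequence view available.

## Mutation impact classes

For each mutation, every lysine-centred window whose 7-mer overlaps the
mutated position is scored before and after the substitution. A window
scoreable only after the mutation is *created* (new central lysine, or a
disqualifying flank residue removed); scoreable only before, *removed*
(central lysine lost, or e.g. a cysteine introduced — this follows the
library's construction, which cannot represent such windows). When both
scores exist the relative change `(after − before)/before` is compared with
the dead-band θ: *weakened* at ≤ −θ, *strengthened* at ≥ +θ, otherwise
*unchanged* (at θ = 0 only exact equality is unchanged). θ defaults to 0.2;
no numeric criterion separates "changed" from "unchanged" in practice, so θ
is an explicit parameter recorded in every output row.

Design choices made where the behaviour was genuinely open:

- *removed* is kept as a fifth internal class; a `collapse_removed` option
  folds it into *weakened* for four-class summaries (a lost site is the
  extreme of weakening). Internal bookkeeping stays lossless.
- A centre whose window is unscoreable both before and after (e.g. a
  cysteine elsewhere in the flank on both sides) yields no record: it is
  not a methylation target in either proteome, so there is no impact to
  classify.
- A zero before-score makes the relative change undefined; any gain from
  zero is classified *strengthened*, equality *unchanged*.

## Detectability

Digestion uses boundary-index arithmetic: zero-missed-cleavage peptides
tile the protein exactly, and an m-missed peptide is the concatenation of
m + 1 consecutive fragments. Trypsin cuts C-terminal of K/R with the simple
"not before proline" rule (the convention of mainstream search engines, not
the full Keil exceptions); Arg-C cuts C-terminal of R; Asp-N N-terminal of
D. A lysine is *detectable* under a rule if some digest peptide containing
it has length within [`min_len`, `max_len`] — defaults 6 and 30, matching a
standard search engine's minimum peptide length and a conventional upper
bound. `methyl_blocks_cleavage` (off by default) removes the site lysine
from the protease target set first, modelling the missed cleavage a
methylated lysine commonly causes.

K/R content counts lysines/arginines among the six flanking residues
(centre excluded; the window width is a parameter). The two-sample
comparison is a label-permutation test with add-one correction,
`p = (1 + #{|d*| ≥ |d|}) / (1 + n_permutations)`. The test statistic is the
difference in **mean** K/R content: with counts confined to 0–6, group
medians are too coarse — for a fully separated 20-vs-20 binary pool, many
shuffles reproduce the maximal median gap and the median-based p-value
stays near 0.7, while the mean difference resolves the shift (p bounded by
the add-one rule). Medians and histograms are still reported.

## Kinetics

Models: Michaelis–Menten `v = Vmax·S/(Km+S)`; substrate inhibition in the
canonical uncompetitive form `v = Vmax·S/(Km+S+S²/Ki)` (rate peaks at
`S = √(Km·Ki)` and reduces to MM as Ki → ∞); inhibition dose-response as a
four-parameter logistic with positive hill slope for decreasing activity.
Fitting is bounded nonlinear least squares (scipy `curve_fit`), with
deterministic scale-free initialisation: Vmax₀ = max observed rate, Km₀ =
interpolated concentration at half-max, Ki₀ = max concentration; for the
4PL, top/bottom from the data extremes and hill₀ = 1. Non-convergence is
reported in the fit object, never raised. Rates stay in assay signal units
(cpm/min); no molar calibration, co-substrate mechanism, or progress-curve
fitting is attempted.

Model selection between MM and SI uses AICc (with a +1 parameter for the
residual variance); |ΔAICc| < 2 is flagged ambiguous. For noiseless data
the RSS is clamped at the smallest positive float so AICc stays finite.
Fits use the points exactly as given — order-invariant by construction; for
balanced replicate designs pre-averaging replicates yields the same
optimum.

## Synthetic data

The generators define the conditions under which the pipelines are tested.

- **Screens**: additive signal model — expected signal of set (p, a) is
  `baseline + amplitude · weight(p, a)` with baseline 200 cpm, amplitude
  5000 cpm, and Gaussian replicate noise of σ = 5 % of amplitude by default
  (a Poisson counting model is available); two replicates, matching a
  duplicate screen. Additive rather than multiplicative because it is the
  simplest model producing the observed heat-map structure with a
  controllable floor. The bundled SMYD2-like motif prefers L/F/M at −1, S
  at +1, basic residues at the outer flanks, and tryptophan slightly above
  arginine at −3; background weights are small seeded values in
  [0.03, 0.25] so ranks are fully determined.
- **Proteomes**: 500 proteins of 200–600 residues with background residues
  drawn i.i.d. from a frequency table (default uniform over the 20 standard
  residues, so cysteine occurs and exercises unscoreable windows); planted
  motif cores overwrite the background at random interior positions,
  never overlapping each other, with exact coordinates recorded.
- **Mutations**: constructed, not sampled — for each intended class the
  generator picks windows and substitutions whose class is guaranteed under
  the noiseless expected signals, with a 0.1 relative-change margin beyond
  the θ dead-band so the construction is robust; class recovery is
  therefore verified against a noise-free screen, which is what the
  construction guarantees.
- **Kinetics**: exact model evaluation at stated concentrations plus seeded
  Gaussian noise.

All generators are byte-deterministic given their seeds. What they do *not*
emulate: real amino-acid usage, plate-position artefacts, absolute cpm
ranges of a particular counter, correlated replicate noise, or
sequence-composition biases of real proteomes. Passing tests on this data
show the algorithms are correct and the pipelines coherent; they do not
show that a particular real enzyme's profile will be recovered at a given
noise level.

## Problem sizes and checks

The acceptance script (`scripts/acceptance.py`) recomputes, per run:
library arithmetic directly from the design; LoB-vs-enumeration agreement
on 1,000 random windows across 10 random profiles; mass-histogram-vs-
enumeration agreement on all 60 sets of four sub-library designs
(alphabets of 1–4 residues) plus the default-set total by convolution
alone; recovery of 20 planted motif windows among the top 40 ranks of a
500-protein proteome under a σ = 5 % screen; class recovery of 50
constructed mutations (10 per class); digestion tiling and
missed-cleavage-oracle agreement on 100 random sequences each;
detectability of a basic PER2-like core vs a K/R-poor context; K/R-content
shift of the top-50 ranked windows against the background with a
2,000-permutation test; and kinetic recovery (noiseless SI to machine
precision; median Km error over 100 noisy MM datasets; MM-vs-SI selection
rate on MM data; median IC50 error over 50 noisy dose-response curves).
These sizes keep a full run within a few seconds while leaving each
statistic well away from its decision boundary.

## Known limitations

- The LoB score inherits the screen's noise floor; near-tied minima make
  `limiting_positions` sensitive to replicate noise.
- Degenerate-set synthesis is assumed perfectly uniform; real coupling
  efficiencies skew the realised peptide distribution and hence the mass
  envelope.
- Detectability ignores ionisation efficiency, retention behaviour and
  spectral quality — length is the only criterion, which is the argument's
  lower bound rather than a full observability model.
- Mutation analysis is protein-coordinate only; no genome lifting,
  recurrence weighting, or isoform handling.
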