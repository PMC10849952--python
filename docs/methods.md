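# Methods

This note documents the models, parameter choices and numerical decisions
behind `halomet`, and what the synthetic-data validation does and does not
establish about behaviour on real data.

## The experimental design being analysed

A halide-depletion experiment compares the metabolome of cultures grown in
chemically matched media with and without chloride, three independent
biological replicates per condition. Metabolites whose biosynthesis
consumes the halide — including *cryptically* halogenated products whose
final structure carries no halogen — drop sharply in the depleted
condition. The analysis task is to surface those features from untargeted
LC–MS data, group them into structural families, and characterise them
(chlorine content, molecular formula, label incorporation).

The pipeline starts from centroided per-run feature lists and MS/MS peak
lists; chromatogram construction and peak deconvolution are upstream
concerns of the acquisition software and out of scope here.

## Differential statistics (`diffmet`)

**Joining.** All run features are pooled and visited in descending
intensity order. A feature joins the nearest existing row (smallest
|Δm/z|) within the m/z tolerance `max(0.01 Th, 20 ppm)` and the retention
tolerance (default 0.2 min), provided that row has no feature from the
same run; otherwise it seeds a new row. The seed's m/z and rt are the row
consensus, which makes the invariant "every member lies within the
joining tolerance of the consensus" true by construction. The procedure
is deterministic (ties broken on m/z, rt, run index) and idempotent.

**Pseudocount floor.** Before statistics, every cell below the noise
value (default 100 counts, configurable — the value is
instrument-specific) is set to that value and flagged. Censoring at the
floor can only shrink estimated fold changes of truly depleted features;
conversely, features whose depleted-side intensities fall below the
*detection limit* and enter as gap-filled floor values show inflated
apparent folds (replete mean / 100). Both behaviours are exercised and
asserted by the tests.

**Test statistic.** Fold change is `max(m_r/m_d, m_d/m_r)` of the
arithmetic condition means, stored as a magnitude ≥ 1 plus a direction
(`depleted_without_halide` when the replete mean is larger); a signed
export (negative = depleted) mirrors the supplementary-table convention.
The t statistic is the classical pooled-variance two-sample Student's t
on raw (untransformed) intensities, df = n₁+n₂−2, two-tailed p from the
t distribution; a Welch variant sits behind a flag. Whether the original
analysis tested raw or transformed abundances is not specifiable from the
record; raw is the default and is stated in the report header. Features
with zero variance in both groups are degenerate and get t = 0, p = 1,
direction `unchanged` — a deliberate convention for floor-censored rows.
No multiple-testing correction is applied by default (raw P values are
reported); Benjamini–Hochberg is available on export.

**Artifact grouping.** Features co-eluting within 0.1 min whose pairwise
m/z differences match known shifts (NH₄⁺ vs H⁺ +17.02655, Na⁺ vs H⁺
+21.98194, water loss −18.01056 Da) are grouped by transitive closure.
The designated parent is the member that explains the most other members
as its own adducts/fragments, ties broken by total intensity.

## Isotope chemistry (`chem`)

Masses and abundances for C, H, D, N, O, S, Cl, Na are embedded in a
plain-text table (version recorded in every report). D is a distinct,
isotopically pure element so labelled formulas participate in ordinary
formula arithmetic. Ionic m/z includes the electron-mass correction
(proton = 1.007276 Da) — required to reproduce reference calcd. values at
4 decimal places. Presentation rounding is round-half-even.

**Envelopes.** Per-element isotope distributions are convolved
(exponentiation-by-squaring over the convolution monoid, truncated at a
configurable number of nominal-mass offsets, default 10) and aggregated
by integer nominal-mass offset; the centroid m/z per offset is the
abundance-weighted mean. Abundances are normalised to the base peak;
peaks below 1e-4 of base are pruned (pruning can be disabled, which the
oracle tests do). Fine structure within an offset (¹³C₂ vs ³⁷Cl) is
deliberately not resolved — the data being emulated are centroided MS1
spectra. Correctness is established against a brute-force multinomial
enumeration for small formulas (≤ 6 atoms, 1e-9) and a convolution
identity `pattern(A∪B) = pattern(A) ⊛ pattern(B)` on random formula
pairs.

**Chlorine call.** `ratio = abundance(M+2)/abundance(M+0)`; flagged when
0.20 ≤ ratio ≤ 0.50 (one Cl; theoretical single-Cl contribution 0.2424 /
0.7576 ≈ 0.320, shifted upward by ¹³C₂ and ¹⁸O) or 0.50 < ratio ≤ 0.85
(two Cl), gated on M+1/M+0 ≤ 0.6 (a carbon-count plausibility check that
rejects very large CHO species whose ¹³C₂ alone reaches the window). The
windows are a calibrated choice — the underlying criterion, "intensity of
the M+2 isotopologue", is qualitative — and are configurable; the
classifier achieves ≥ 95% sensitivity and specificity on simulated
metabolite-like formulas of 300–900 Da, which is the regime the defaults
were chosen for. Very carbon-rich species (C ≳ 55) erode specificity and
heavily chlorinated, carbon-rich species can exceed the one-Cl window.

**Formula decomposition.** Exhaustive enumeration within per-element
bounds (defaults C 0–60, H 0–120, N 0–5, O 0–15, S 0–3, Cl 0–3, Na 0–1 —
wide enough for glycolipid-scale metabolites), heaviest elements first
with running mass pruning and hydrogen solved in closed form. Candidates
must fall within the ppm tolerance, pass the ring-plus-double-bond filter
(RDBE = C − (H+Cl+Na)/2 + N/2 + 1 ∈ [−0.5, 40], integral for the
even-electron adducts supported), and honour minimum-count constraints
(Cl ≥ 1 when the chlorine flag is set). Ranking is by |ppm error|, ties
by fewer heteroatoms. With realistic mass error (± a few ppm) the true
formula is guaranteed to be *in* the list (the round-trip property is
tested) but not to rank first — candidate lists are review material.

## Molecular networking (`msnet`)

**Peak filtering.** Peaks within ±17 Th of the precursor are removed (the
exclusion window suppresses residual precursor/isotope signal); a peak
survives only if it ranks in the top 6 by intensity within the ±50 Th
window centred on itself (ties toward lower m/z; idempotent).

**Modified cosine.** Peaks match directly (|Δm/z| ≤ 0.02 Th) or after
shifting by the precursor-mass difference (neutral-loss match); one peak
participates in at most one pair, as one type or the other, and fragment-
and loss-matched pairs pool into a single matched count. Weights are
√intensity scaled to unit norm per spectrum, so the score is in [0, 1]
and scale-invariant. The score maximises the matched-weight sum over
one-to-one matchings *exactly* via linear assignment. A greedy
accept-best-pairs rule is the common practice in spectral networking, but
greedy is not guaranteed to attain the optimum; since this package's
contract is equality with exhaustive matching enumeration (verified to
1e-9 on random spectra, and cross-checked against an independent
implementation on unambiguous spectra), the exact optimum is the
implementation. Edges require cosine ≥ 0.60 and ≥ 4 matched pairs; no
top-K edge pruning or component-size caps are applied by default. One
representative MS/MS spectrum per feature is used: precursor closest in
m/z, ties by total ion current.

## Label-mixture fitting (`labelfit`)

Envelopes are aligned on the nominal-offset axis anchored at the
unlabelled parent's M+0 and the observed envelope is normalised to
M+0 = 1. The fit minimises the sum of squared abundance differences over
the *measured* offsets only (theoretical peaks outside the observed
window are unmeasured, not zero) subject to non-negative weights, via
NNLS with renormalisation to fractions summing to 1 — on noiseless data
this is exact, which the closed-loop tests assert at 1e-6. Species
envelopes default to a M+0..M+5 window each (configurable). Species with
numerically identical envelopes are collapsed and reported as a joint
fraction with a warning. Label purity defaults to 1.0 (fully deuterated
positions); a purity knob (e.g. 0.99 for commercial labels) convolves
each labelled site with a two-state H/D distribution, adding light
satellites. Retention-hypothesis ranking fits unlabelled + one labelled
species per hypothesised loss count and sorts by residual; when no
hypothesis assigns ≥ 5% to a distinguishable labelled species the result
is reported as inconclusive rather than ranked.

## Synthetic ground truth (`synthetic`)

The generator emulates the *structure* of the experiment, not its
chemistry:

- replicate intensities are log-normal around the condition mean with
  CV 0.2 (typical biological LC–MS replicate variation), the depleted
  mean divided by the planted fold; values below the detection limit
  (500 counts) are censored outright so gap-filling is exercised;
- the demo experiment plants one eight-member chlorinated family with
  folds 87.5, 421.1, 607.0, 350, 240, 180, 120, 95 at abundances that
  keep depleted means above the floor, one halide-independent family,
  and 200 background features with no condition effect;
- MS/MS realism is limited to fragment templates: family members share
  7 template entries (4 sugar-like fragments + 3 hexose-like neutral
  losses, ≥ 5 shared is validated) plus unique fragments, with m/z jitter
  σ = 0.005 Th and 10% intensity jitter — enough to exercise the
  networking math, nothing like real fragmentation chemistry;
- co-eluting NH₄⁺/Na⁺ adducts and water-loss in-source fragments are
  co-emitted at the parent's retention time; MS1 envelopes carry 2%
  multiplicative abundance noise; collision energy metadata follows
  10 + 0.02·(m/z);
- per-signal mass error is uniform within ±3 ppm; retention jitter is
  0.02 min per run.

Passing tests on this generator establishes that the *algorithms* behave
as specified under the stated noise model. They do not establish
robustness to retention drift requiring alignment curves, profile-mode
artefacts, charge states |z| > 1, matrix effects, or real fragmentation
variability — all outside the generator's scope.

## Validation protocol and problem sizes

All randomness is seeded; regenerating from the same manifest is
byte-identical, as is re-running the pipeline on identical inputs.

- Null calibration: one generated 2000-feature experiment, 3 vs 3,
  CV 0.2, run through join → floor → t-test; the p < 0.05 fraction must
  land in [0.03, 0.07].
- Fold recovery: the estimate `FC = mean_replete/mean_depleted` from
  3-replicate CV-0.2 samples has ≈ 16% relative sampling SD, so a single
  experiment lands within ±20% of the planted value only ~4 times in 5 —
  that is a property of the design, not of the code. Recovery is
  therefore assessed as the median estimate over 10 seeded experiments
  per planted fold (sampling SD of the median ≈ 6%), with the
  top-of-ranking assertion checked in every individual experiment.
- End-to-end: one demo experiment (212 compounds, 6 runs) through the
  full pipeline; the planted family must arrive as the top-ranked
  component with ≥ 80% membership and all members chlorine-flagged.
- Label fitting: 100 seeded feeding trials at 2% noise for the
  hypothesis-ranking rate; 5 × 3 × 5 fraction/noise/seed grid for
  recovery error.

These sizes keep the full suite under a minute of compute while leaving
each stochastic criterion with comfortable statistical margin.

## Known limitations

- Chlorine calling is blind to bromine (not in the default element set)
  and saturates at 2 Cl; cryptically halogenated products are by design
  *not* detectable from isotopes — only via the differential statistics.
- Fold changes of floor-censored features are lower bounds (truly
  depleted) or inflated (detection-censored artifacts); interpretation
  requires the artifact-group and gap-fill flags that accompany them.
- The formula decomposer's RDBE filter assumes even-electron ions of the
  four supported adducts; radical ions would need the parity rule
  relaxed.
- One spectrum per feature means chimeric spectra are not modelled or
  detected.
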