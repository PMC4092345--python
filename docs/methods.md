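# Methods

This note documents the models and procedures implemented in `qhts_er`,
the assumptions behind the synthetic screen generator, the numerical
choices that matter, and the limits of what the test suite demonstrates.

## 1. Screen design

A screen covers nine channels: ER-bla (β-lactamase reporter on the ERα
ligand-binding domain, fluorescent readout) and ER-luc (luciferase
reporter on the full-length receptor, luminescent readout), each in
agonist and antagonist mode; one multiplexed viability channel per
platform; and a three-wavelength (blue/green/red) compound
autofluorescence assay whose blue and green channels match the bla
detection wavelengths. Each compound is titrated over 15 geometrically
spaced concentrations from 1.1 nM to 92 µM (step ≈ 2.25-fold). Titrations
follow qHTS plate practice: one concentration per 1536-well plate
(32 × 48), the same well position across the 15 plates of a run, and
three independent runs with re-permuted well positions. Every plate
reserves two columns for controls: a 16-point positive-control titration
in duplicate (17β-estradiol in agonist mode, 4-hydroxytamoxifen in
antagonist mode, a cytotoxic surfactant for viability) and ≥16 negative
(vehicle / stimulated / untreated) wells. A configurable subset of the
library (default 88 compounds) is plated twice per run as intra-plate
duplicates.

## 2. Synthetic library and raw-signal model

Compound classes and default mixture: full agonist 8 %, partial agonist
5 %, antagonist 5 %, cytotoxic-only 5 %, autofluorescent 2 %, selective
modulator 2 % (agonist through the full-length receptor, antagonist
through the isolated LBD — the pattern flavonoids show), inactive 73 %.
The ~15 % total "pharmacologically active" fraction echoes the activity
rates reported for the ERα 10K screen. Per-class truth:

* Agonist-type efficacy: full agonists N(100, 12) clipped to [85, 130] %
  of the positive-control maximum; partial agonists U(30, 60) %. AC50s are
  log-uniform over [5·c_min, c_max/20] with a 10 % "weak" tail up to
  c_max/3, so most generating curves are complete within the tested range.
  Hill slopes U(0.9, 2.2). Platform AC50s differ by a 10^N(0, 0.1) jitter.
* Antagonist-mode behavior of agonists follows receptor pharmacology:
  wells are pre-stimulated to ~EC80 of the full agonist, and a (partial)
  agonist displaces the signal toward its own efficacy level, giving a
  displaced efficacy of (E − 80)/0.8 percent — inhibition for partial
  agonists, mild activation for super-efficacious full agonists. The
  stimulation level is a config choice (the assay protocol's actual level
  is not part of the public record); EC80 is the standard antagonist-mode
  design point.
* Antagonists inhibit with efficacy U(70, 110) % and act in both
  platforms; true antagonists are modeled as non-cytotoxic in range.
* Cytotoxic compounds get a kill AC50 log-uniform over
  [10·c_min, c_max/10] (Hill slope U(1.2, 2.5)) that multiplies the signal
  of *every* cell-based channel: the viability readout falls to −100 %,
  antagonist-mode wells overshoot below −100 % (dead wells lose even the
  unstimulated baseline), and agonist-mode wells sink below 0 %. The last
  effect produces the "active antagonist inside an agonist-mode assay"
  calls that real screens report — and that agonist-mode assays cannot
  demote, having no multiplexed viability readout.
* Autofluorescent compounds add a concentration-proportional offset
  (50–120 % of the assay window at the top concentration) to fluorescent
  channels only — the bla reporter channels when the compound fluoresces
  blue/green, and the matching autofluorescence assay channels.
* Reference labels: 39 compounds labeled strong (3), strong-moderate (1),
  moderate (5 agonists + 6 antagonists), weak (15), very weak (4),
  negative (5), assigned consistently with the underlying truth (strong =
  most potent agonists, etc.).
* Binding affinities: actives get logRBA = 0.75·log10(AC50_E2/AC50) +
  N(0, 0.3) with AC50_E2 = 3×10⁻¹⁰ M — the sub-unit slope encodes
  receptor reserve (functional potency overstates affinity), so weak
  functional actives straddle the logRBA = −3 binding-inactive floor.
  Non-binders with binding data draw logRBA from U(−6, −3.05). Binding
  data cover the reference set plus a random 30 % of the library.

Raw signal: each channel has a background B and a control window
S/B-fold chosen to match typical reporter windows (bla agonist 4.6, bla
antagonist 3.3, bla viability 132.6, luc agonist 2.5, luc antagonist 8.0,
luc viability 6.1). The compound's normalized-scale effect is mapped into
raw units, multiplied by the viability factor when the compound is
cytotoxic, and offset by autofluorescence. Noise: per-well multiplicative
log-normal (sd 0.07), per-plate multiplicative random effect (sd 0.03),
additive N(0, 1) raw units, floored at a small positive value. These
defaults put simulated plate Z′ in the 0.5–0.8 band and control CVs near
7 %, matching a well-behaved screen; all of it is configurable, and a
zero-noise setting makes every downstream stage exact (the test suite
uses this for oracle checks).

Duplicate selection is stratified toward active classes (≈60 of the 88),
so the duplicate AC50 correlation — defined only over active-matched
pairs — rests on a statistically usable number of pairs. Structural
fingerprints: each family (mean size 12, class-pure) has a random
512-bit prototype (bit density 0.3); members flip each bit with
probability 0.05. Two families are planted for the enrichment analysis: a
30-member full-agonist family and a 30-member "confounded" family of 15
antagonists plus 15 cytotoxic compounds.

## 3. Normalization and QC

Per plate: activity = 100·(x − μ_neg)/(μ_pos_top − μ_neg) in activation
channels and 100·(x − μ_neg)/(μ_neg − μ_pos_top) in inhibition channels
(stimulated/untreated control = 0, full suppression = −100). The
"positive" level is the mean of the wells at the top two concentrations of
the embedded control titration — a choice, since a single-well top would
be noisier. S/B is reported as max/min of the two control levels so it
stays >1 in inhibition channels. Plates failing the conventional
thresholds (S/B > 3, CV < 10 %, Z′ > 0.5) are flagged, never dropped —
screens routinely retain marginal antagonist-mode plates. The control
titration is refit per plate; the per-assay geometric SD (fold) of the
control AC50 across plates is the screen-stability summary (values < 3 are
considered stable; simulated defaults land near 1.1–1.2).

With zero noise the Z′ of a generated plate is ≈0.997 rather than exactly
1: the top two control concentrations sit at slightly different points of
the control curve, so the "positive" wells have a tiny real spread. The
closed-form Z′ = 1 case is exercised with constructed plates whose
positive wells are identical.

## 4. Hill fitting and curve classes

Ordinary least squares on percent activity; parameters (log10 AC50, Hill
slope, top, bottom) bounded to AC50 ∈ [c_min/100, 100·c_max], slope ∈
[0.3, 8], asymptotes ∈ [−150, 150]. Initialization profiles the
asymptotes: for each of 12 candidate log-AC50 values spanning the grid ×
5 candidate slopes, top and bottom are solved by linear least squares, and
the best cell seeds one bounded trust-region refinement with an analytic
Jacobian. A fit "converges" only if it beats the flat model by ≥20 %
relative residual reduction; otherwise the titration is reported
directionless. One outlier point may be masked when doing so improves r²
by ≥0.2 — i.e. only gross single-well failures. AC50s aggregate
geometrically (log10 domain) everywhere.

Curve classes: the significance threshold is max(3·noise_sd, 20) percent,
with noise_sd the configured percent-scale noise (≈7.6 at defaults).
Class 4 = no point beyond threshold; class 3 = only the top concentration
responds, or r² < 0.6 despite response; classes 1.x require both
asymptotes reached within the tested range (model within 10 % of span at
both ends) and r² ≥ 0.9; 2.x when only the lower asymptote is supported;
the .1/.2 split is at 80 % efficacy. These thresholds follow the curve-
grading convention used by the Tox21 screening centers; the exact cutoffs
are exposed in `ClassifyConfig` because published analyses vary in them.

A screen-level pre-screen skips the optimizer for any series whose
largest excursion is below the class-4 threshold (such series cannot
grade above class 4); this is what keeps a 1,000-compound, 19,000-series
screen inside a couple of minutes on one CPU.

## 5. Activity calls

Per (compound, assay), over the triplicate curve classes with classes
{1.1, 1.2, 2.1} as conclusive activity: (i) conclusive activation and
conclusive inhibition across replicates → inconclusive; (ii) ≥2
conclusive same-direction replicates → candidate active; (iii) ≥2 class-4
and no conclusive active → inactive; (iv) anything else → poor-curve
inconclusive, labeled with the direction the non-flat replicates share.
Candidates face the counter-screens: an antagonist-mode candidate
(either direction) is demoted to the corresponding cytotoxicity
category when the replicate-median viability fit shows reproducible
inhibition with AC50 within 3-fold of the candidate AC50 or ≥50 %
viability loss at the candidate AC50; a bla-platform activation candidate
is demoted to the autofluorescence category when the compound's
blue/green autofluorescence exceeds max(3·noise_sd, 5) percent at
concentrations ≥ AC50/3. The luminescent platform is never
autofluorescence-demoted, and agonist-mode assays (no multiplexed
viability) never emit a cytotoxicity category. Majority (2-of-3) logic is
the simplest rule consistent with sub-1 % mismatch rates; the 3-fold
window and 50 % loss are exposed in `CallConfig`.

Replicate reconciliation (triplicates, and duplicates pairwise) uses the
conservative mismatch definition: a *high-quality* active (1.1/1.2)
against a flat class-4, or opposed high-quality directions. Incomplete
curves disagreeing with flats are inconclusive, not mismatches. Duplicate
pairs are compared at the outcome level — each plate instance gets its
own full decision-tree call — so a pair with one cytotoxicity-demoted
member counts as inconclusive rather than as an active match.

## 6. Evaluation

Reference scoring: agonist-mode assays are scored on the agonist-type
reference classes (the six moderate antagonists are excluded entirely);
antagonist-mode assays on the six antagonists plus the five negatives.
The primary mode drops inconclusive calls from the table; the "reviewed"
mode resolves them through an explicit per-compound override table,
mirroring manual expert review (the pipeline's own review table is built
from ground truth, i.e. it emulates a perfect reviewer — a synthetic
convenience, stated here deliberately). Metrics: sensitivity tp/(tp+fn),
specificity tn/(tn+fp), accuracy (tp+tn)/n, association p from the
two-sided Fisher exact test on [[tp, fp], [fn, tn]] (scipy's exact
hypergeometric implementation; the test suite cross-checks it against a
from-scratch log-space enumeration over margin-fixed tables).

Binding concordance: per platform, a compound is functionally active if
either mode calls it an active agonist or antagonist, inactive if both
modes call it inactive, otherwise excluded and counted as inconclusive.
Binding-active means logRBA ≥ −3. Concordance = (CP + CN)/(CP + DP + CN +
DN), association p from Fisher on [[CP, DP], [DN, CN]]. Reports round
percentages to integers and p-values to two significant figures.

## 7. SOM clustering and enrichment

A batch SOM on the binary fingerprints: square grid auto-sized to
~13 compounds per node (side = round(√(N/13)), i.e. 9×9 for N = 1,000);
codebook initialized by greedy farthest-point sampling of the
fingerprints (so no two nodes seed inside one dense family); 24 batch
epochs with a Gaussian grid neighborhood whose radius decays
exponentially from half the grid to 0.5. Compounds are assigned to the
nearest codebook vector, ties to the lowest node index. The default
assignment distance is squared Euclidean against the *continuous*
codebook — for 0/1 data this is a soft Hamming distance that retains each
prototype's bit frequencies. Assigning against the codebook thresholded
at 0.5 ('hamming'/'tanimoto' options) is also available but is not the
default: binarization collapses nearly-tied prototypes onto
almost-identical bit patterns, and a dense family then splits across two
nodes on noise bits alone — empirically this broke single-node recovery
of a planted 30-member family in roughly a quarter of seeds, while the
continuous-codebook assignment recovered it completely in all of them.

Per node and per assay endpoint, a 2×2 Fisher test of (in cluster ×
in category) flags enrichment at p < 0.01 with over-representation;
antagonist-endpoint nodes simultaneously enriched in
cytotoxicity-demoted antagonist calls are flagged confounded and excluded
from the reported enriched set. The node × endpoint matrix of signed
log10 p (positive = over-represented) is the heatmap-ready export.

## 8. Determinism and problem sizes

All randomness flows from the single config seed through named
`SeedSequence` streams (library, plates) plus the SOM seed; identical
config + seed reproduce byte-identical outputs, which the run manifest
(SHA-256 per file) makes checkable. Default problem sizes — 1,000
compounds, 88 duplicates, three runs, nine channels, 405 plates, ≈20,000
fitted series — are desk-scale stand-ins for the original ~10,500-sample
screen, chosen so a full pipeline run completes in a couple of minutes on
one CPU; the class mixture, not the library size, is what the calling
statistics are sensitive to.

## 9. What passing tests do and do not show

The generator emulates the *structure* of a qHTS screen — control
windows, plate effects, Hill-shaped pharmacology, cytotoxicity and
fluorescence artifacts, family-structured fingerprints — not its full
pathology. Real screens add spatial plate gradients (edge effects,
dispense stripes), carry-over, compound degradation and solubility
limits, fluorescence *quenching* and luciferase inhibition (named
confounders that this pipeline, like the original analysis, does not
counter-screen), and chemically meaningful fingerprint correlations.
Passing the suite therefore shows the analysis chain is correct and
well-calibrated under the stated noise model, and that the published
evaluation tables follow exactly from their printed counts; it does not
certify performance on raw public-repository exports, which should be
imported through the documented stage contracts (the plain-CSV handoff
exists precisely so a real-data import can replace `simulate`).

Known limitations: no spatial detrending before normalization; no
Bayesian or mixed-effects dose–response modeling; the 3-parameter
fallback is limited to the bottom-pinned profile start; SOM topology is
rectangular (no torus); binding concordance treats the union of modes per
platform, which is an interpretive choice where the original pooling is
ambiguous.
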