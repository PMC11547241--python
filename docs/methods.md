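# Methods

## Partition model

A chamber partitions a `V = 25 µL` reaction into `N` droplets of
`v ≈ 0.68 nL` (N defaults to 20,000, the middle of the 12,900–25,800 range
observed on the instrument; it is a parameter everywhere). Only the
partitioned fraction `N·v/V ≈ 0.54` of the reaction is read; concentrations
are nevertheless reported for the whole reaction, because the input cap
("10,000 copies/PCR ↔ 33 ng/PCR") is a whole-reaction quantity. The
ng↔copies conversion uses 3.3 pg per haploid genome equivalent so that
33 ng ↔ 10,000 copies exactly.

Template molecules of each species land in droplets independently with
per-droplet Poisson mean `λ_d = copies·v/V`. Occupancies of different
species are independent, which is what makes the conditional drop-off
estimator unbiased (below).

## Fluorescence rendering (synthetic generator)

Droplet intensity per channel = baseline (1000 au) + the summed amplitudes
of all probes fired by the droplet's occupancy + Gaussian noise
(`noise_sd = 150 au`). A probe fires when any template species in its target
set occupies the droplet; amplitudes are part of the packaged assay
definition and were chosen once so that every reachable cluster position is
separated from its neighbours by ≥ 1,500 au on at least one axis of its
gating plane — mimicking the well-separated clusters with very little rain
that the optimized bench assay shows. A `rain_fraction = 1%` of
signal-bearing droplets is attenuated by a uniform (0.2, 0.8) factor to
emulate rain; false positives are injected per detection group as a Poisson
number of empty droplets rewritten with the group's canonical signature
(partition count is conserved).

What the generator does *not* emulate: PCR efficiency kinetics, optics and
image segmentation, chip spatial effects, cfDNA fragment-size effects,
pipetting/volume variation between replicates. Inter-assay CV in simulation
is therefore pure counting statistics (~6–7% at 500 copies/PCR) and sits
below bench CVs (~10–16%); tests against the generator validate the
statistical pipeline, not instrument physics.

Co-occupancy is modeled faithfully: a droplet holding wild type plus a
776–779 substitution fires the drop-off probe and is indistinguishable from
wild type. A droplet holding a duplication is FAM⁺HEX⁺Cy5⁺; on the FAM–Cy5
plane it is superimposed on the WT cluster. The paper's actual per-group
false-positive rates are not published (only the resulting limits of blank,
3–5 droplets); the generator defaults
(S310F/Y 0.8, L755S-D769H/Y-L869R 1.3, dup 1.3, 776–779 2.0 mean
false-positive droplets per chamber) are **calibrated-to-plausible**: chosen
once so a 34-replicate blank panel yields LOB₉₅ values in the published
range, not reproductions of unpublished data.

The two exon-20 duplications are modeled at protein level (two cluster
positions); the bench assay resolves three (the two cDNA forms of
G778_P780dup separate). This affects no computed statistic.

## Gating

Gates are rectangles (polygons with the general machinery of shapely behind
them) anchored on the cluster centroids of a simulated positive control
(WT gDNA + every mutant gBlock), with half-widths of 6 observed SDs per
axis, never below 250 au. Point-in-polygon membership is boundary-inclusive;
same-plane overlaps resolve first-wins in precedence order (mutant gates
before WT). Because a droplet can hold templates of two species, per-class
counts are *membership* counts: a droplet co-occupied by wild type and an
L755S template counts in both the WT gate (FAM–Cy5) and the group gate
(FAM–HEX). The exact conservation law is

    sum(counts) − n_multi + unclassified + empty = N

with `n_multi` the extra memberships; it reduces to the naive form when no
droplet is in two classes.

The duplication cluster falls inside the WT gate on the FAM–Cy5 plane
without containing wild type; `correct_dup_overlap` removes the dup-gate
tally from the WT tally (floored at zero with a warning). The published
description of this correction is worded in the opposite direction
(subtracting WT-gate from dup-gate), which would be negative in any
realistic chamber; the implemented direction is the physically consistent
one. A small approximation remains: dup droplets that also contain wild
type are subtracted too (they are indistinguishable from dup-only
droplets), slightly undercounting WT — negligible at screening MAFs.

## Quantification

Naive estimator: `λ = −ln(1 − k/N)`, `copies/PCR = λ·V/v`. CI: normal
interval on λ with `var(λ̂) = p/(N(1−p))` propagated through the log
transform (exact Clopper–Pearson offered as `concentration_ci_exact`); at
`k = 0` the upper bound is the exact one-sided `−ln(0.05)/N`.

Conditional estimator (drop-off targets): on the WT-negative subpopulation,
`λ_mut = −ln(n_dn/n_wtneg)` with `n_wtneg = N − (WT + dup)` and
`n_dn = n_wtneg − k_mut`. The naive estimator underestimates by the factor
`e^(−λ_WT)` (≈ 0.76 at 10,000 WT copies/PCR), which the tests assert.

LOB correction subtracts the corrected blank mean `μ_corr` from the raw
count (floored at zero, fractional results allowed); the exact equation of
the original refs is not reprinted there, so the subtraction form is
isolated behind one operation (`lob_correct_counts`) and can be swapped.
MAF uses copies (not droplet counts) in numerator and denominator;
droplet-count-based MAF can be formed from the same counts if wanted for
comparison.

`copies/mL plasma = copies/PCR × dilution × (eluate 50 µL / input 15 µL)
/ plasma mL`.

## Limits

`μ_corr = μ + 1.645·σ/√N` with the *sample* SD (n−1; conservative for small
panels). LOB₉₅ = smallest integer `L` with upper-tail probability beyond `L`
at most 5% under a count model with mean `μ_corr`, evaluated two ways:
normal quantile `⌈μ + 1.645√μ⌉` and the Poisson–Chernoff bound
`e^(−μ)(eμ/k)^k ≤ 0.05`; the reported LOB is the tighter admissible of the
two, and the exact Poisson quantile is the verification oracle in tests.
Over the operating range (μ_corr ≤ 5) the normal quantile coincides with the
exact quantile or exceeds it by one droplet, so the reported LOB never
undercovers; the raw Chernoff bound alone is up to two droplets more
conservative for μ_corr ≳ 2.5.

Theoretical LOD₉₅ = smallest integer mean `d` with `P(X ≥ LOB+1 | d) ≥ 0.95`
(the vendor's exact formula is proprietary; this Poisson-tail definition is
the documented stand-in), expressed in droplets first — the positivity rule
compares droplet counts — then converted to copies/PCR at the nominal
partition count and to MAF against a 10,000 copies/PCR background. For
pooled r-replicate assays the blank mean scales to `r·μ_corr` and the limits
are recomputed on the pooled scale; the relative tail tightening is the
sensitivity gain from replication.

The positivity rule is applied to **raw** counts (LOB correction affects
quantification, not calling). Single-replicate samples with a count at or
above LOD are accepted as positive, matching the handling of
high-concentration samples assayed once; this branch is explicit in
`call_detection_group`.

Duplex confirmations reuse the corresponding screening group's limits: the
study publishes limits only for the four screening detections, and the
duplex false-positive regime is comparable.

## Validation statistics

CV% = 100·σ/μ (sample SD). Linearity: OLS R² of measured on expected
copies/PCR over 5–1000 copies/PCR in triplicate; replicate estimates are
averaged per level before the regression, the usual convention in
assay-validation linearity studies (per-replicate regression at these
partition counts is dominated by the binomial sampling of the top level and
is not what a validation report quotes). Dilution sensitivity: lowest MAF
level with ≥ 2 replicates at or above LOD₉₅, reported as the mean measured
MAF of that level's replicates.

Problem sizes used by the packaged studies: 20 seeds × 6 levels × 3
replicates for linearity; 8 chambers at 500 copies/PCR for reproducibility;
10⁴ count-level blank draws for LOB coverage and LOD detection (the
count-level fast path draws from the identical Poisson false-positive model
as the full chamber renderer, which is asserted by a distributional test);
200 full-pipeline samples for caller sensitivity/specificity.

## Cohort summaries

Prevalence denominators are patients; spectrum denominators are mutation
events (unique patient × mutation pairs), so a two-mutation patient counts
once in prevalence and twice in the spectrum. Histology strata: IBC-NST,
pure ILC, and pure+mixed ILC combined. A matched tissue pair is concordant
when every plasma mutation of the patient is found in tissue (a
tissue-negative patient with plasma mutations is discordant). Percentages
are rounded half-away-from-zero to the conventional precisions (one decimal
for prevalence, two for spectrum frequencies, integer for concordance).
`demo_cohort_table()` is a deterministic synthetic stand-in for the study's
per-patient results table, encoding only published summary counts and
per-mutation values; `simulate_cohort_table()` generates randomized cohorts
with configurable prevalence by histology (the exact ILC denominators are
parameters, not assertions, since they live in unpublished per-patient
data).

## Numerical/edge-case conventions

- Same (seed, chamber_id) ⇒ byte-identical chambers; series are
  reproducible element-wise because each chamber's RNG stream is derived
  from the pair.
- Saturated chambers (k = N, or all WT-negative droplets mutant-positive)
  raise a dedicated `SaturationError` advising dilution; `k > N` raises a
  data-integrity error.
- `k = 0` yields 0 copies with CI lower bound 0.
- MAF is clamped to [0, 100] against floating-point spill; MAF of (0, 0) is
  an error, not 0.
- Gate derivation requires ≥ 10 droplets per cluster and a control
  containing every detection class; missing classes raise with the class
  named.
- Equivocal calls carry a structured "rerun with n more replicates"
  recommendation instead of auto-resolving; screen-positive samples with no
  duplex data are reported `incomplete`, screen-positive/duplex-negative
  samples `unconfirmed`, never silently negative.

## Known limitations

- Simulated CVs and sensitivities omit pre-analytical noise, so they are
  optimistic relative to bench values; the tests treat published bench
  values as bounds or plausibility anchors, not equalities.
- The 17-variant membership is reconstructed from the assay description
  (three 776–779 substitutions are flagged `reconstructed` in the packaged
  JSON); the drop-off group detects any substitution under the probe, so
  membership naming does not change counts.
- Gates are axis-aligned rectangles per cluster; arbitrary polygons are
  accepted as first-class inputs (JSON gate files) but not derived.
- Cross-amplicon double-occupancy (e.g. S310 + L755 templates in one
  droplet) is left unclassified by design; it is negligible at clinical
  MAFs and the caller never relies on it.
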