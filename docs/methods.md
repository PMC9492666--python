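# Methods

## Scope and data flow

The pipeline covers four analyses that share one normalization contract:

1. **Screen**: raw plate signals → fraction affected (Fa) → Synergy Index
   per compound × inducer → two-inducer hit call.
2. **Confirmation**: dose-response series → median-effect fits →
   Combination Index at chosen effect levels; IC50 fold shifts; the
   drug-tolerance resistance factor.
3. **In vivo**: caliper trajectories → volumes → group-median TGI.
4. **Simulation**: generators for all three input kinds with planted,
   separately emitted ground truth.

All interchange is plain tab-separated text with a one-line header; the
`run` pipeline writes a JSON manifest with a sha256 checksum per artifact so
any hit list can be audited back to its parameters and seed.

## Normalization

Per replicate well, `viability = (signal − blank̄)/(vehiclē − blank̄)` and
`fa = 1 − viability`, clamped to [0, 1] **before** averaging. Clamping first
keeps the replicate standard deviation meaningful and bounds every quantity
downstream (Synergy Index numerators, death-fraction thresholds). Control
statistics use the mean, the ubiquitous plate-reader convention. Each plate
is its own universe: vehicle/blank means are plate-local, and a plate with
fewer than 2 vehicle or 2 blank wells (or vehicle mean ≤ blank mean) is
rejected with a logged reason rather than poisoning the pooled table. Blank
subtraction is optional (`require_blank=False` treats the blank as 0) since
some assays omit a medium-only well. fa is invariant to rescaling or
shifting all signals on a plate; property tests assert this.

## Synergy Index screen

`SI = (Fa_comb − Fa_cpd)/Fa_inducer`, computed on replicate-mean fa values.
An SI dispersion is propagated from the replicate sds in quadrature and
reported descriptively only — no test statistic is attached to SI, matching
screening practice where the index ranks pairs for confirmation. Choices:

* **ε = 0.01** minimum inducer-alone effect: the ratio is numerically
  meaningless when the inducer kills nothing. Pairs below ε are reported as
  *missing*, never as 0.
* **Hit rule**: Fa_comb ≥ 0.5 for *each* inducer (inclusive) and SI > 1 for
  *each* inducer (strict). The ≥50%-death criterion is read per pair.
* **Ranking**: descending min(SI_E, SI_R), ties by mean combination fa
  descending, then compound id — a conservative order that requires strength
  against both inducers.
* Two cell lines are combined by intersecting their hit sets (default;
  union available), the stringent choice for a screen whose hits feed
  follow-up experiments.

## Median-effect and Combination Index

The mass-action median-effect model `fa/fu = (D/Dm)^m` is fitted by
unweighted OLS on the linearizing plot `log10(fa/fu)` vs `log10 D` — the
method's canonical form, exactly reproducible, with the Pearson r of the
plot reported as the fit diagnostic. Points with fa outside (0.005, 0.995)
are excluded (log-odds undefined at 0/1; bounds configurable) and at least
3 usable points are required; a non-positive slope is a model violation and
is rejected rather than silently inverted.

The Combination Index uses the **mutually exclusive two-term form**
`CI = d1/Dx1 + d2/Dx2` — the dominant modern convention; the non-exclusive
third term is omitted. CI is reported at fa ∈ {0.5, 0.75, 0.9} by default
(configurable). Only constant-ratio designs are accepted: the combination is
fitted as a single agent on total dose, which is exactly what the two-term
CI presumes. Classification uses CI < 1 synergism / CI > 1 antagonism with
additivity only within 1e-9 of 1.

Self-consistency identities guaranteed by construction and asserted in
tests: a sham self-combination gives CI = 1 at every effect level and any
ratio; halving the combination's Dm relative to the Loewe-additive reference
halves CI; IC50 ≡ Dm ≡ dose_for_fa(fit, 0.5).

## Tumor growth inhibition

`V = L·S²/2` from caliper diameters (a swap of L and S is detected and
optionally auto-corrected); `TGI% = (Vc − Vt)/(Vc − V0)·100` on group
*medians*, robust to single outlier animals. V0 is the **control** group's
baseline median (the literal reading of the formula); a per-group-baseline
variant sits behind a flag. The endpoint defaults to the last day measured
in every group; animals missing the endpoint contribute their last
observation carried forward, with the count logged and reported. TGI > 100%
(regression below baseline) and < 0% (treated outgrew control) are legal
outputs. A control that did not grow (Vc ≤ V0) makes TGI undefined and
raises.

## Synthetic-data generators

**Screen.** Defaults are the reference conditions: 303 compounds, 10 planted
hits, both inducers killing 30% alone, Bliss excess δ = 0.35, triplicates,
additive Gaussian signal noise sd 0.02 on a vehicle-minus-blank span of
0.95. Single-agent compound effects are drawn uniformly from (0, 0.4) — a
realistic spread for a pharmacological library at one screening dose, where
most compounds are weakly cytotoxic alone. Non-hit combinations follow Bliss
independence (`fa_comb = fa_c + fa_i − fa_c·fa_i`), chosen because it makes
the true SI analytically available: `SI = 1 − fa_c` for non-hits (never > 1,
so the screen's false-positive behavior is fully attributable to noise) and
`SI = 1 − fa_c + δ/fa_i` for hits. A configuration whose planted hits cannot
reach SI > 1 in expectation is rejected up front. Signals are truncated
below at half the blank (plate readers do not report signal far under
background). Compounds are packed onto 96-well plates each carrying its own
vehicle, blank and inducer-alone wells.

**Dose-response / combinations.** Series are drawn from the median-effect
model with additive, clipped Gaussian noise on fa; with zero noise the
emitted values equal the model exactly. A constant-ratio combination is
emitted as one agent with `Dm_combo = s · Dm_ref`, where `Dm_ref =
1/(r1/Dm_a + r2/Dm_b)` is the Loewe-additive reference dose for the ratio
and the shift `s` encodes the planted synergy (s < 1) or antagonism (s > 1);
the downstream CI recovers s. When the component slopes agree the
Loewe-additive reference is itself exactly a median-effect curve, so the
construction is exact (verified against an independent bisection oracle);
with unequal slopes the combination slope is the ratio-weighted mean and the
reference is an approximation — unequal-slope additivity has no closed form.

**Xenograft.** Exponential growth `V(t) = v0·exp(g·t)` from v0 = 100 mm³
(the randomization threshold), measured every 4 days to day 28. Volumes are
emitted as caliper pairs under a fixed L/S aspect ratio of 1.25 (a
documented constant — real studies rarely report raw diameters) with 0.3 mm
Gaussian caliper noise per diameter, re-ordered so L ≥ S and floored at
0.1 mm. Truth records the closed-form noiseless TGI per group.

All randomness in a generator flows from a single `numpy` Generator seeded
per call; equal seeds give byte-identical tables. Ground truth is emitted as
a separate artifact that no pipeline stage reads.

### What the simulations do and do not emulate

The generators reproduce replicate noise, plate-local controls, dose-ladder
designs and measurement cadence, which is what the pipeline's statistics
consume. They deliberately omit spatial plate effects (edge evaporation,
gradients), optical-density nonlinearity, batch drift between plates or
cell lines, non-exponential (e.g. Gompertzian) tumor growth, and early
euthanasia censoring beyond last-observation-carried-forward. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated noise model, not robustness to those real-data
artifacts.

## Numerical choices

* fa filter bounds (0.005, 0.995); additivity tolerance 1e-9 on CI; ε = 0.01
  on the SI denominator; resistance threshold 10-fold, boundary inclusive.
* OLS on the transformed plot, no nonlinear refinement: deterministic,
  closed-form, and exactly reproducible across platforms.
* Ties in screen ranking break by mean combination fa, then lexicographic id.
* Degenerate inputs raise typed errors (failed plate, absent inducer record,
  non-monotone series, non-growing control) rather than returning sentinel
  values; the CLI maps every such error to a one-line nonzero exit.

## Problem sizes

The test suite and acceptance script use the reference screen (303
compounds × 3 arms × 3 replicates) over 100 seeds for the noisy-recovery
statistics, 9-point dose ladders for fits, and 6-animal × 5-arm xenograft
designs over 100 seeds — sizes matching the emulated study design, where
each run takes a fraction of a second.

## Known limitations

* The screen's SI carries no significance test (none is standard for this
  index); ranking plus dual-inducer confirmation is the error control.
* CI confidence intervals (e.g. by bootstrap over replicates) are not
  implemented; CI is reported as a point estimate per effect level.
* The non-exclusive (three-term) CI variant and the dose-reduction index
  are out of scope.
* Loewe-additive simulation with unequal component slopes is approximate
  (see above); tests pin only the equal-slope case to the bisection oracle.
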