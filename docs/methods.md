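# Methods

This note documents the statistical models behind each stage of the pipeline,
the defaults and why they were chosen, what the synthetic generators emulate
(and do not), and the numerical conventions.

## Per-expression-level flux cytometry (DEFAC)

### Model

A knock-out cell line is transiently rescued with a GFP-tagged construct, so
per-cell GFP intensity reports the rescuing protein's expression level.
Autophagy activity is read out through LC3: treating cells with the V-ATPase
inhibitor Bafilomycin A1 (BafA1) arrests lysosomal degradation, so the LC3
signal in the BafA1 arm represents total production while the untreated arm
retains only the undegraded fraction. Within each GFP expression level the
flux statistic is

    flux (%) = (MFI_BafA1 − MFI_untreated) / MFI_BafA1 × 100

with MFI the **geometric** mean fluorescence intensity of the LC3 channel.
The statistic is a ratio, hence invariant under any common positive rescaling
of the LC3 channel (detector gain, staining batch), and equals 0 when the two
arms are identical. It is bounded above by 100 (complete degradation);
negative values indicate the untreated arm exceeded the arrested arm — noise
or a quench artifact — and are reported, never clipped, precisely so such
artifacts stay visible.

The identical formula applies to LC3-II western-blot densitometry pairs; the
cytometric version simply evaluates it per expression bin.

### Gating and binning

1. **Dead-cell exclusion.** Events with viability-dye (7-AAD) intensity at or
   above a threshold are dropped. The threshold is instrument-dependent and
   therefore a required config value with no default.
2. **Expression levels.** Four strictly increasing GFP boundaries define five
   levels (Level 0 = GFP-negative through Level 4). Bins are left-closed,
   right-open: an event exactly on a boundary belongs to the higher level.
   Boundaries are config-first; the data-driven default places Level 0's
   upper edge at the 99.5th percentile of a mock/untransfected reference and
   splits the remainder into equal log-width bins.
3. **Sparse bins.** A level with fewer than `min_events_per_level` events
   (default 100) in either arm is flagged undefined rather than reported;
   geometric means of a handful of events are too unstable to interpret.

Level 0 flux is reported alongside the expressed levels (it estimates
untransfected background activity); interpretation is left to the user.
The denominator of the flux formula is the raw BafA1 MFI, with an optional
baseline-subtracted mode deliberately not enabled by default.

A **quench control** verifies that gross GFP MFI is unaffected by BafA1
(|ratio − 1| ≤ 0.1 by default). If BafA1 quenched GFP, level membership would
differ between arms and per-level comparisons would be invalid.

### Per-level comparisons

Replicate-level flux values are compared between constructs with a two-sided
Student's t-test per level, unadjusted by default (each level is a separate
planned comparison against the reference construct); Holm adjustment across
the level family is available. Levels with fewer than two replicates on
either side are flagged untestable.

## Screening triage

Each library drug is characterized by three plate signals: CellMask (cell
number/viability), an In-Cell-Western signal for the tagged GAG core protein
SDC1, and NanoLuc luminescence from the luciferase-tagged mutant VPS33A.
The triage, in fixed order:

1. **Vehicle normalization**, per plate: signal / mean DMSO signal. The
   vehicle point is (1, 1) by construction.
2. **Toxicity filter**: exclude drugs with CellMask ratio < 0.5.
3. **Cell-number adjustment**: GAG ratio ÷ CellMask ratio, so GAG loss that
   merely tracks cell loss does not count. This quotient is the quadrant's
   vertical axis by default (a switch restores the raw ratio).
4. **Dual-criterion quadrant**: hit ⇔ adjusted GAG ratio < 0.5 AND stability
   ratio > 2.0. Drugs lacking the luminescence reporter are unevaluable, not
   hits.
5. **Exclusions**: category tags (anticancer, topical — pure config, nothing
   hard-coded) and a second-stage patient-cell toxicity filter that removes a
   candidate only when viability falls below 0.5 in *both* fibroblasts and
   lymphoblastoid cells (conjunction).

All three thresholds are strict inequalities; a value exactly at a threshold
falls on the retained / non-hit side. The stage order is load-bearing and
pinned by a test: with the order reversed, a cytotoxic well whose adjusted
GAG ratio is small only because the denominator (cell number) collapsed would
flood the hit quadrant. Every stage records retained/excluded id lists in a
`FunnelReport` whose conservation invariant (retained + excluded = input,
chained across stages) is enforced at construction and after deserialization.
No spatial plate correction (B-score etc.) is applied — normalization is to
DMSO only.

## Kinetics and genetics statistics

**Chase decay.** Protein degradation after translation arrest
(cycloheximide) is modeled as single-exponential, value(t) = I·exp(−kt),
half-life t½ = ln 2 / k. The default fit regresses log(value) on time
(closed-form, robust); a nonlinear least-squares option pins the intercept at
the normalized 100 % pre value. Each replicate is normalized so its t = 0
point is exactly 100 %. A non-decaying series returns k ≤ 0 with half-life
flagged infinite rather than raising. Fits require ≥ 3 distinct timepoints.

**Mendelian segregation.** Genotype tallies from heterozygote crosses are
tested against 1:2:1 by Pearson chi-square on df 2 without continuity
correction (at df 2 the p-value has the closed form exp(−χ²/2)). The
textbook expected-count rule of thumb concerns the *expected* counts (11.75
and 23.5 at n = 47 — fine), not the observed ones; an exact multinomial test
is provided for sensitivity analysis and agrees in conclusion on the pooled
litter data. The test's actual type-I error at n = 47, computed by exact
enumeration of the multinomial null, is 0.0517 — the asymptotic test is well
calibrated at the study's pooled sample size, and the litter simulator
reproduces this rate.

**qPCR.** Relative transcript quantities come from a standard curve: Ct
regressed on log10(relative quantity) over a serial dilution of the
reference sample, unknowns inverted through the line, amplification
efficiency 10^(−1/slope) − 1 reported. The inversion is exact for any
log-linear series regardless of efficiency. ΔΔCt is deliberately not
implemented — the curve method is the one used. Non-monotone standards warn
but still fit.

**Group comparisons.** Student/Welch t (two-sided; one-sided only where
explicitly requested), Holm adjustment across a declared family, one-way
ANOVA + Tukey HSD, and Kruskal–Wallis + Holm-adjusted Mann–Whitney are thin
pass-throughs to scipy/statsmodels routines.

## Synthetic data

Seeds are required arguments everywhere; every generator is bit-reproducible
from (spec, seed) via a single `numpy.random.default_rng` per call.
Measurement noise is multiplicative lognormal throughout — fluorescence and
luminescence are scale-positive quantities.

**Cytometry events** (default 20 000 events × 3 replicates, 60 % transfected,
10 % dead): untransfected cells draw GFP from an autofluorescence lognormal,
transfected cells from a construct lognormal spanning several decades
(log-mean ln 3000, log-SD 1.5 against level boundaries 200/1000/5000/25000).
Each event draws a baseline LC3 level; the BafA1 arm keeps it, the untreated
arm retains the (1 − flux/100) fraction for its level, both with log-SD 0.25
measurement noise. Modeling flux as removal from the untreated arm is
algebraically equivalent, for the geometric-mean ratio, to accumulation in
the inhibited arm and is simpler to calibrate. The default truth vector
(0, 40, 60, 60, 60) % emulates a rescue that saturates above Level 1.

**Screening plates** (default 1968 drugs, 80 drugs + 8 vehicle wells per
plate): per-drug latent effects are a mixture calibrated to the published
stage proportions — toxic 346/1968; among survivors dual 18/1622, GAG-only
111/1622, stabilizer-only 34/1622 (the dual fraction far exceeds the
independent product, i.e. the two effects are positively correlated, as
observed). Raw signals are vehicle-mean × effect × lognormal noise; the SDC1
signal also scales with the viability effect so the cell-number adjustment
has real work to do.

`reference_plate` is a *deterministic* variant with exactly the published
composition and latent effects placed > 7σ from every threshold, so the
triage recomputes the printed funnel (1968 → 1622 → 129/52/18 → 11 → 7) from
raw noisy signals at any seed. It is a synthetic stand-in for the study's raw
supplementary table, which is not redistributable here; it validates the
triage logic end-to-end but — unlike a run on the real table — cannot detect
miscalibrated thresholds against real signal distributions.

**Decay courses**: 100·exp(−ln2·t/t½) with lognormal noise of the given CV;
the pre point is exactly 100 because it is the normalization anchor, not a
measurement. Defaults: timepoints {0, 6, 12, 24, 48} h, CV 5 %, 3 replicates.

**Litters**: per conceptus genotype ~ multinomial(1:2:1); homozygotes are
observed with probability `hom_survival_prob` (embryonic death removes them
from the tally). Default 6 dams with Poisson(8) litters ≈ the study's pooled
group size of 47.

### What the generators do not emulate

Instrument artifacts (spectral spillover, doublets, autofluorescence
spillover into the LC3 channel), plate spatial effects, drug dose–response,
correlated replicate effects, and litter-level genotype correlation are all
absent. Passing tests therefore demonstrate the estimators are correct under
the stated statistical model, not that the model captures every feature of
real instrument data.

## Numerical conventions

- Intensity transform default **floor-at-epsilon** (ε = smallest positive
  recorded value / 10, per channel) so geometric means are defined; arcsinh
  (cofactor 150) available, identity for pre-cleaned data. The transform is
  recorded in the table's metadata.
- Geometric MFI of an empty set is NaN (flag), of any non-positive value an
  error naming the transform policy.
- Boundary ties: left-closed right-open everywhere (levels); strict
  inequalities everywhere (screening thresholds), verified to 1 ulp.
- Degenerate equal-constant groups in a t-test return p = 1 (logged) rather
  than NaN.
- Problem sizes used by the acceptance computations: the full 1968-drug
  plate, 20 000 events × 3 replicates for flux recovery, 10 000 simulated
  litter pools of n = 47 for the calibration check, 15-point chase courses.

## Known limitations

- The FCS reader covers list-mode float/double and byte-aligned integer data
  in FCS 3.0/3.1 — the common export path — not bit-packed widths, multiple
  datasets per file, or compensation matrices (out of scope by design).
- Single-cell flux is undefined in this design (the two arms are different
  cells); the per-level population statistic is the finest available readout.
- Screening thresholds are validated against the synthetic reference plate;
  applying the pipeline to a real supplementary table requires only a
  column-mapping config, but the printed funnel counts have not been
  re-derived from the original raw file here.
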