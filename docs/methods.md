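# Methods

## Censored-residue reconstruction

Residue concentrations in a food category are modelled as lognormal,
`ln Y ~ Normal(ln GM, ln GSD)`. A surveillance dataset consists of the
detected concentrations `Y_obs` (ppm, mg chemical per kg food) and a count
of non-detects at a single detection limit (0.002 ppm throughout). The
likelihood has two parts: each detect contributes the lognormal density;
each non-detect contributes `P(Y < RL)` — the lognormal CDF at a *reporting
limit* RL that is itself a parameter, with prior `Normal(min Y_obs,
min Y_obs / 5)` truncated to `(0, min Y_obs]` (a reporting limit above an
observed detect would be contradictory). The remaining priors are
`GM ~ Normal(max Y_obs / 2, max Y_obs / 4)` truncated to positive values,
and `ln GSD ~ Normal(ln 4, ln 2)` — a lognormal prior on GSD centred on the
geometric SD observed among detects across the surveillance programme. The
scale arguments of all Normal priors are standard deviations. RL can instead
be pinned (`fix_rl=0.002`) to treat the detection limit as known.

Two likelihood modes are provided and tested for agreement: `marginalized`
(default; one CDF term multiplied by the censored count — O(1) in the number
of non-detects) and `latent` (an explicit concentration below RL per
non-detect, updated by exact inverse-CDF Gibbs sampling of the truncated
lognormal between Metropolis updates of the structural parameters). They are
statistically equivalent; the latent mode exists because the generative
formulation is sometimes wanted for posterior-predictive display.

GSD is sampled through `ln ln GSD`, which constrains GSD > 1; a lognormal
scale requires a positive log-SD, so the sub-unity region is excluded by
construction rather than by an ad-hoc bound.

Categories with a single detect get one pseudo-detect appended at the
detection limit before fitting, so the data-driven prior scales are defined.

Arithmetic moments are derived per retained draw via
`mean = GM·exp(½ ln²GSD)`, `sd = mean·√(exp(ln²GSD) − 1)` and averaged over
draws; these posterior-mean moments (`mean_est`, `std_est`) parameterize the
lognormal used downstream by the exposure simulator.

**MCMC engine.** All fits use an adaptive random-walk Metropolis sampler
(`fiprisk.mcmc`): independent chains, multivariate-normal proposals whose
covariance is re-estimated from the chain history at regular checkpoints
during warmup only (so the retained chain is time-homogeneous), proposal
scale 2.38²/d. Defaults are 4 chains × 25,000 iterations with the last 50%
of every chain retained and pooled; convergence is declared when the classic
Gelman–Rubin R̂ of every structural parameter is below 1.1. Non-convergent
fits are returned flagged, never silently re-run; the pipeline refuses to
simulate exposure from a flagged fit. Chains are initialized from a crude
censored-quantile estimate (`ln RL − s·Φ⁻¹(censoring rate)`) rather than the
prior mean — at >99% censoring the prior mean can sit ten log-units from the
posterior mass and strand a short chain.

**What recovery means at extreme censoring.** With 97.5% of samples
censored only the upper tail of the distribution is observed. When the
truth is a moderate lognormal censored at its own 97.5th percentile, the
posterior medians of GM and GSD recover the truth to well within 30%
(median signed bias ≈ +11% over ten generate-and-refit seeds). When the
truth is the far more dispersed lognormal implied by calibrating to a
published summary row (e.g. GM ≈ 8.6×10⁻⁶ ppm, GSD ≈ 16 for root
vegetables), GM itself is only weakly identified and the data-driven priors
dominate; what the model *does* reliably reproduce there is the
posterior-predictive censored fraction (within 0.2 percentage points) and
the conditional distribution above the limit — which is what the exposure
assessment consumes.

## Exposure simulation

Individuals are allocated to age (0–100) × sex strata proportionally to
registry counts by largest-remainder rounding (ties broken by stratum
order), then every populated stratum is raised to a minimum of 10 with
compensating reductions from the largest strata; totals are exact. The
default population is 200,000, the smallest round number that comfortably
supports the 10-per-stratum floor at 202 strata.

Body weight is drawn per stratum from `Normal(mean, sd)` truncated to
`[max(0.5, mean − 4sd), mean + 4sd]` kg; intakes from `Normal` truncated to
`[0, mean + 6sd]` g/day. The source material specifies truncated normals
without bounds; non-negativity is the operative constraint and the ±4–6 sd
outer bounds only remove physically impossible draws. Residues are drawn
independently per individual and category from the reconstructed lognormals
(one draw per individual: a chronic-average interpretation, matched to
comparison against a chronic reference dose; no within-person correlation
across categories, as the aggregate-dose equation has no correlation
structure). The aggregate dose is

    exposure_j = Σ_i intake_ij [g/day] × residue_ij [mg/kg] / (BW_j [kg] × 1000)

in mg/kg bw/day; the 1000 converts grams of food to kilograms. LB uses
general-population intake means (including non-consumers), UB consumer-only
means.

## Benchmark-dose modelling

The eight standard dichotomous curves are parameterized as in BMDS 3.x, e.g.
QuantalLinear `p = g + (1−g)(1−e^{−bd})`, Weibull `p = g + (1−g)(1−e^{−bd^k})`,
Multistage-2 `p = g + (1−g)(1−e^{−b₁d−b₂d²})`, LogLogistic
`p = g + (1−g)/(1+e^{−a−b ln d})`, Dichotomous Hill
`p = gv + (v−gv)/(1+e^{−a−b ln d})`; log-dose curves take their background
value at d = 0. Priors are non-informative uniform boxes: backgrounds and
plateaus on [0, 1], intercepts on [−50, 50], slopes on [0, 100] (dose scale)
or [1, 15] (log-dose slopes and powers). The ≥ 1 restriction on log-dose
slopes/powers is the package default (the standard "plausible shape"
restriction); `make_models(restricted=False)` lifts it. On the convulsion
data the restriction matters: the incidence sequence 0, 0, 3, 1, 5 of 50 has
a non-monotone bump that sub-linear shapes chase, producing benchmark-dose
draws orders of magnitude outside the dose range.

Each model is fitted by 3 chains × 50,000 iterations (retaining the last
25,000 per chain, i.e. 75,000 draws; base seed 76,316 with a fixed offset
per model), and the BMD at 10% extra risk,
`(p(BMD) − p(0))/(1 − p(0)) = 0.10`, is computed in closed form per draw
(verified against a bracketed root-finder to 1e-8).

**Model weights.** The averaged posterior mixes per-model BMD draws with
posterior model weights. The default scheme approximates each model's
marginal likelihood by the Schwarz criterion, `max ln L − (d/2) ln n` with
n the total number of animals — deliberately insensitive to the arbitrary
widths of the flat prior boxes. Two alternatives are available:
`pseudo_bma` (WAIC-based pseudo-Bayesian-model-averaging weights from the
per-dose-group pointwise log likelihoods) and `bridge` (exact marginal
likelihoods by bridge sampling under the uniform boxes). Bridge sampling is
the exact Bayesian answer *given those priors*, and on this dataset it
illustrates why flat boxes are a poor default for model comparison: weakly
identified parameters escape the Occam penalty and the most flexible model
absorbs nearly all the weight. Under the default scheme the three
two-parameter models (Logistic, Probit, Quantal Linear) share ~90% of the
weight, with the remainder spread over the five flexible models.

Invalid BMD draws (curves that never reach the benchmark response, e.g. a
Dichotomous Hill plateau below 10% extra risk) are excluded from a model's
admissible draw pool before mixture sampling.

## Probabilistic reference dose

Per averaged-BMD draw, with a single seeded stream and a documented draw
order (allometric exponent, interspecies factor, intraspecies factor):

    HD50 = BMD × (BW_animal / BW_human)^(1 − b) / A
    HDMI = HD50 / 10^F

with `b ~ Normal(0.7, 0.0243)`, `A ~ Lognormal(GM 1, GSD 1.95)`
(interspecies TK/TD), and `F ~ Lognormal(GM 0.746, GSD 1.5935)` interpreted
as the log10 human-variability factor at population incidence I = 0.01 — so
the median population factor is 10^0.746 ≈ 5.6. Interpreting the sampled
value as the factor itself (median 0.746 < 1) would make HDMI *larger* than
HD50, contradicting the protective direction of the published percentile
table, so the log10 reading is forced. HD50 is the human dose at which 50%
of the population shows ≥ 10% extra risk; HDMI the dose at which 1% does.
The pRfD is the lower 5th percentile of the HDMI uncertainty distribution
(conventionally reported as the "95th percentile" in the protective
direction); percentile tables report medians and lower 10th/5th/1st
percentiles for BMD, HD50 and HDMI.

The human body weight is 70 kg. The rat body weight is not a published
constant of the assessment; 0.35 kg (an adult male SD rat scale) is the
default and it enters through `(BW_a/70)^{1−b}` ≈ `(BW_a/70)^{0.3}`, so the
full plausible range 0.25–0.5 kg moves every human-scale quantity by about
±10%. The acceptance script reports the pRfD at 0.25, 0.35 and 0.5 kg.

**Uncertainty decomposition.** Shares of the log-scale spread of HDMI are
attributed to the four independent multiplicative components (POD,
allometric scaling, interspecies factor, human variability). The
`uncertainty_decomposition` operation offers variance shares (exact
partition for independent components) and squared log-P95/P05-span shares;
the two coincide for (log-)normal components, and the span version is used
for the full-chain report because the model-averaged BMD posterior is
heavy-tailed — a handful of near-flat-curve draws would otherwise dominate
the raw variance. On the printed data the spans give human variability ≈
52%, interspecies ≈ 30%, POD ≈ 18%, allometric ≈ 1%.

## Risk characterization

`HQ = exposure / reference`, with the deterministic ADI
(NOAEL 0.019 mg/kg/day ÷ 100 = 1.9×10⁻⁴, printed as 0.0002) or the scalar
pRfD as reference. HQ = 1 exactly counts as a non-exceedance (a
measure-zero event under continuous exposure anyway). Summaries report
counts and fractions of HQ > 1 overall, by sex, and by the age groups
0–2, 3–5, 6–11, 12–15, 16–18, 19–65, ≥66.

## Synthetic data

The generators emulate the statistical structure of the three external
databases the original assessment used, from published summary rows only.

*Residues*: for each of the 11 food categories, a lognormal (GM, GSD) is
calibrated so that `P(Y < DL)` equals the published censoring rate exactly
and the conditional mean above the DL equals the published detect-only mean
(the detect SD is then implied — three summary statistics overdetermine two
parameters; censoring rate and conditional mean are prioritized because the
downstream analysis is most sensitive to them). Per-sample datasets are then
drawn from the calibrated truth, values below the DL flagged censored, and
the generating truth serialized for recovery tests. One category's printed
detect mean equals the DL itself (a rounded single detect); its calibration
targets 1.05×DL, the closest attainable configuration.

*Demographics and intakes*: an invented but realistic age pyramid (flat to
65, exponential taper), a smooth body-weight growth curve to sex-specific
adult plateaus (68/56 kg, 15% CV), and per-category LB intake means on the
tens-of-grams scale with UB = 2×LB. These are plumbing for end-to-end tests:
passing tests show the pipeline arithmetic and distributional machinery are
right, not that any particular population's exposure is reproduced —
reproducing the published population means would require the original
consumption and registry databases.

*Dose-response*: binomial draws from any admissible model curve, for
parameter-recovery tests.

All generators are pure functions of (spec, seed).

## Problem sizes and tolerances

The dose-response chain runs at the study scale (8 models × 3 × 50,000
iterations, ~20 s). Censored-model unit tests use 4 × 8,000–25,000
iterations on datasets of 60–1,760 samples; pipeline integration tests use
3,000-iteration fits and 8,000–20,000 individuals, sizes chosen so the whole
suite stays in a few minutes while every statistical check retains clear
margins. Root-finding tolerances: BMD inversion 1e-10 relative (tested to
1e-8 against closed forms), moment-map round trip 1e-9 relative, calibration
1e-12 on the censoring probability.

## Known limitations

- Single detection limit per category; no interval censoring or multiple
  DLs.
- GM/GSD point identification fails gracefully (wide posteriors,
  prior-dominated medians) in the >99% censoring, high-GSD regime; the
  predictive distribution above the DL remains well calibrated.
- BBMD's exact model-weight formula is unpublished; BIC weights reproduce
  the published *pattern* (the two-parameter trio largest) but concentrate
  harder (~0.31 vs ~0.21 each).
- Chronic-average exposure only: no usual-intake modelling, processing
  factors, or acute assessment.
- The intraspecies factor is the WHO/IPCS default; chemical-specific
  adjustment factors are out of scope.
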