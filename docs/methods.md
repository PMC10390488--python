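# Methods

## Scope and intent

`luadsim` simulates tumor-size evolution and time to progression (TTP) in
*EGFR*-mutant lung adenocarcinoma under daily gefitinib, at the level of a
virtual population, and scores how well the simulated population
reproduces an observed arm. The model is knowledge-based rather than
fitted to individual-level data: every parameter has a
pathophysiological reading, and defaults are chosen so the default
population reproduces the headline clinical picture of a first-line
gefitinib arm (median TTP near 9 months with wide dispersion, an initial
response followed by relapse, KRAS co-mutant tumors resisting therapy).

## Tumor-growth submodel

Five states per clone (P, Q, D, K, I; 15 parameters) realize, with
exactly five ODEs per clone: proliferation, death, layering of cells in
the tumor, neo-angiogenic carrying capacity, and immune limitation of
growth. Layering is geometric rather than spatially resolved: the viable
fraction φ of a spherical tumor is the volume share of the outer shell of
depth `d_rim`. Cells outside the rim enter quiescence (rate `k_pq(1−φ)`)
and re-enter cycle inside it (`k_qp·φ`). For the vascularised human
setting `d_rim` defaults to 1 cm, so φ stays near 1 for typical lesions;
the sub-millimetre rim relevant to avascular spheroids is reached by
configuring `d_rim` (the in vitro setting's natural scale).

Two deliberate departures from the most literal reading of the structure:

* **Capacity seeding.** Carrying capacity is per clone, but it is seeded
  at `capacity_factor` (default 1.5) times the *total* initial cell
  count for every clone, not proportional to the clone's own size. A
  small resistant subclone seeded with a proportional capacity would see
  a crowding factor `1 − N_tot/K_c ≈ −1/f_res` and be annihilated at
  once, which contradicts the clinically observed relapse driven by
  pre-existing resistant clones. The biological reading: the established
  vasculature feeds the whole lesion; capacities then diverge because
  each clone grows its own vascular supply (`dK/dt ∝ P_c+Q_c`).
* **Crowding floor.** The crowding factor is floored at −1 and the
  capacity denominator at one cell. Without the floor, a clone whose
  capacity lags the total burden experiences arbitrarily large negative
  growth rates (observed O(−100)/day in wide-parameter populations),
  which is both biologically meaningless and stiff enough to destabilise
  fixed-step integration. The floor bounds overcrowding death at the
  proliferation scale λ·s·φ.

Immune pressure I is phenomenological: recruited at a saturating rate in
total burden, decaying at `d_imm`, killing both proliferating and
quiescent cells at `κ_I·I`. Because RECIST progression is referenced to
the running nadir, a stronger immune response deepens the nadir without
necessarily delaying the nadir-relative threshold; its main population
effect is on trajectory depth and, through the changed regrowth
environment, on TTP.

## Signaling, PK and PD

The signaling layer is algebraic (no ODEs). In vitro it reproduces
stimulus-response transients of pERK/pAKT after EGF or HGF stimulation
with the two-parameter surge `A_max·(t/τ)·e^{1−t/τ}` — the simplest form
whose free parameters are exactly the calibrated observables (peak
height, peak time). In vivo it reduces to a per-clone multiplier
`s = s₀(1+g_EGFR+m_prolif)(1−eff·inh)`. Resistance mutations act by
attenuating the drug's effect on the signal (`eff = Π(1−ρ_res)`), not by
abolishing binding; one parameter per mutation then reproduces both the
retained signaling of KRAS-mutant clones under full receptor blockade and
their shorter TTP.

PK is a closed-form one-compartment oral model with dose superposition
evaluated by geometric partial sums (O(1) per evaluation, verified against
brute-force 100-dose superposition at 1e-9). Defaults (F 0.6, ka 0.5/h,
ke 0.0169/h, Vd 1400 L) are package choices giving an average steady-state
concentration ≈ 0.26 mg/L for 250 mg daily, in the range reported for
gefitinib; they are not published trial constants. PD is a Hill curve with
mutation-specific IC50 multipliers; the exon 19 deletion is set more
gefitinib-sensitive than L858R (0.8 vs 1.25), T790M shifts potency 15×,
KRAS 4×. These multipliers are configurable defaults, not published
values.

## Integration

The reference integrator is LSODA (rtol 1e-6, atol 1e-3 cells) with
either a fully time-resolved PK forcing (`pk_mode="full"`) or the
steady-state average concentration (`"average"`, default): the growth
timescale is weeks, so within-day concentration swings average out.
Population-scale runs use a compiled fixed-step RK4 kernel (numba,
dt = 0.25 day) with the average-PK forcing; agreement with LSODA is
asserted in the test-suite at 2e-3 relative on the radius. Output is
daily. States are clipped at zero; undershoot beyond tolerance aborts.
A cohort of 1190 patients simulates in roughly two seconds on one core.

## Virtual population

Descriptors: sex, age, smoking, ethnicity, stage, EGFR variant,
KRAS/PIK3CA co-mutations, initial radius, initial proliferative fraction,
resistant-subclone fraction, implicit-mutation proliferation offset,
immune recruitment and kill, neo-angiogenesis rate, and a global tumor
"pace". Categorical marginals default to the trial-arm frequencies; age is
a truncated normal with the published median and its range treated as a
central 99% interval (SD from quantiles). The default population size is
ten times the real arm's progression-event count (1190 = 10×119).
Correlations, when supplied, use a Gaussian copula on Spearman rank
correlations; the default is independence.

Mechanistic marginals are package calibrations, chosen once so that the
default population shows: median TTP ≈ 9 months with interquartile range
≈ 6.5–13 months, a negative median 6-month radius change with KRAS
carriers shifted to growth, and immune, neo-angiogenesis, initial-size,
resistant-fraction and proliferation-modifier descriptors all among the
top TTP drivers. The per-patient `pace` multiplier (lognormal, σ = 0.45)
scales all growth-submodel rates together — an exact time rescaling of
the trajectory. It exists because without it the crowding feedback
homeostatically compresses TTP dispersion to an unrealistically narrow
band (log-dispersion ≈ 0.3 vs ≈ 0.6 in published arms), which in turn
makes the raw-coverage validation metric fragile even when the model is
exactly right.

## Validation statistics

Kaplan–Meier estimation and the two-group log-rank test are lightweight
numpy implementations (the protocols run them ~10⁵ times); both are
cross-checked against `lifelines` in the tests. The prediction interval
takes pointwise 2.5/97.5 percentiles of KM curves from 1000 subsamples of
real-arm size, drawn without replacement by default (with-replacement
bootstrap available via `replace=True`). Raw coverage evaluates the
observed step function at its own step times, unweighted; a
time-weighted variant is provided since the discretisation of the
observed curve is a choice. TTP is inferred from PFS/OS event lists by
removing, per death, at most one PFS event within a tolerance (default
exact; digitized curves should pass their time resolution). Fisher tests:
2×2 through `scipy.stats.fisher_exact`; r×c by exact enumeration of all
tables with the observed margins (network-style recursion, chi-square
fallback above a size cap with a logged notice).

Self-validation (observed arm = 159-patient subsample of the simulated
1190-patient population) passes both 80% thresholds essentially always.
With a fully *independent* simulated arm of 159, the protocol at these
sample sizes has an intrinsic 5–15% per-run chance that raw coverage of
~150 correlated step points by a pointwise 95% band falls below 80% —
a property of the metric, not of the model; discrimination against a
shifted arm (median halved) fails both metrics essentially always.

## Sensitivity analysis

Tornado: split at each descriptor's median (ties to the low half), impact
= 100×(median output in half − overall median)/overall median, ranked by
the larger absolute impact; defaults follow the 5000-patient, 50/50-EGFR
general-population configuration, using the two-clone default rather than
richer clone sets so each parameter appears once. Constant descriptors
get zero impact with a notice; a zero overall median is an error.

## Synthetic reference data

No trial data ship with the package. `fixtures` generates internally
consistent stand-ins: latent lognormal progression and exponential death
times per subject, PFS = min of the two, OS = death, right-censoring at
follow-up; digitized-style curves are KM estimates sampled on a regular
grid with at-risk counts. The bundled `luxlung7_like` scenario is shaped
like a 159-patient gefitinib arm (median TTP ≈ 9 months, ≈ 120
progression events over 30 months) and is labelled synthetic. What passing
tests on these fixtures show is protocol correctness and calibration
under known generative truth; they cannot show that the mechanistic
defaults match any particular real trial, since the published calibrated
parameter values and digitized curves are not redistributable.

## Known limitations

* No toxicity, death or treatment-discontinuation censoring: the only
  censoring mechanism is end of follow-up, so simulated event fractions
  exceed real PFS event fractions.
* The exact algebraic forms of the published signaling equations are not
  public; only their calibration targets (peak, peak time) constrain the
  surge form chosen here.
* Progression detection is trajectory post-processing on the daily grid
  (no sub-day interpolation, no target/non-target lesion bookkeeping).
* Demographic descriptors are carried but mechanistically inert unless
  correlations are configured; their tornado impacts are Monte-Carlo
  noise by construction.
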