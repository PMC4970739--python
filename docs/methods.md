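# Methods

## Model overview

`cdxcea` evaluates a companion-diagnostic test-and-treat strategy against a
no-testing comparator for advanced lung adenocarcinoma with a two-part
model: a decision tree that allocates the cohort to treatment pathways
according to test result, and a monthly-cycle semi-Markov cohort model that
simulates disease progression along each pathway (first-line treatment →
second-line treatment → best supportive care → death) over a 5-year,
60-cycle horizon. Costs and quality-adjusted life-years are accumulated per
cycle and discounted at 3% per year.

In the testing strategy, test-positive patients (true and false positives
alike — the tree branches on the test result, not the truth) receive
first-line erlotinib, second-line cisplatin + pemetrexed, then BSC;
test-negative and unknown-result patients receive first-line
cisplatin + pemetrexed, second-line docetaxel, then BSC. The no-testing
strategy gives everyone first-line cisplatin + pemetrexed, second-line
erlotinib, then BSC. Unknown results (inadequate tumour tissue, 11% by
default) are routed to the chemotherapy pathway, and all tested patients
incur the test cost once; re-biopsy cascades are not modelled.

## Survival machinery

Evidence enters as digitized Kaplan-Meier points per trial arm
(`time_months,survival,n_at_risk_total` CSV). Arms addressing the same
model branch are pooled as a sample-size-weighted average on the union time
grid, with right-continuous step interpolation matching K-M estimator
semantics.

Each pooled curve is extrapolated to the full horizon with a Weibull model
S(t) = exp(−(t/λ)^k), fitted two ways:

1. **Log-log regression** — OLS of ln(−ln S) on ln t, which is exactly
   linear under a Weibull law (slope = shape k, scale λ = exp(−intercept/k)).
   Points with S = 1 or t = 0 are excluded (transform undefined).
2. **Least squares on the survival scale** — minimize Σ(sᵢ − S(tᵢ))² over
   all digitized points with equal weights, using deterministic multi-start
   Nelder-Mead in log-parameter space (the regression solution plus a fixed
   5-point lattice), so results are reproducible without a seed.

The **base case uses the pointwise mean of the two fitted survival
curves**, not the mean of their parameters: the mean of two Weibull curves
is generally not Weibull, so parameter averaging would not represent the
intended average curve. Single-method extrapolation is available as
scenarios and, by construction of the pointwise mean, the base-case QALYs
lie between the two single-method results.

A fitted curve becomes a per-cycle transition schedule via the conditional
probability p_t = 1 − S(t+1)/S(t); the product Π(1−p_u) reproduces S at
every cycle boundary to 1e-10. If S reaches zero before the horizon the
remaining cycles are made absorbing.

## Cohort mechanics

Trial PFS/OS curves are measured from the start of the line they describe,
so the engine uses **semi-Markov clocks**: each line's schedules are
indexed by time since line entry, implemented with clock-expanded states.
Within a cycle, competing risks are split with **death taking priority**:
a fraction in line L with clock τ dies with probability OS_L[τ]; the
progression probability is max(0, PFS_L[τ] − OS_L[τ]) (negative values are
clamped and logged); the remainder stays with clock τ+1. Progression from
the last treatment line enters BSC with a fresh clock. Deaths evaluated at
the start of a cycle contribute no cost or utility for that cycle.

Two published OS curves are substituted by configuration (not hard-coded):
first-line erlotinib OS in mutation-positive patients uses the pooled
first-line cisplatin + gemcitabine OS of the no-testing population, and
first-line chemotherapy OS in mutation-negative patients uses the pooled
no-testing all-comers OS — the bindings any evidence base without
arm-specific OS must make.

**Costs.** Chemotherapy lines are billed at the administration cost for the
first 4 clock cycles (all patients receive four cycles of chemotherapy) and
at the non-administration cost until progression; erlotinib and BSC are
billed every occupied cycle. The test cost falls on the full tested cohort
at cycle 0, undiscounted.

**Utilities.** Pre-progression 0.6532, post-progression and BSC 0.4734 per
year, accrued as utility/12 per occupied cycle. Oral therapy adds +0.02.
Adverse-event disutility is subtracted in the line's entry cycle only (a
scenario extends it to the whole administration period). A configuration
guard rejects effective utilities outside [−0.2, 1]. The −0.043
intravenous-administration disutility is off in the base case and enabled
by the `iv_disutility` scenario, since the oral adjustment already encodes
the route-of-administration preference.

**Discounting** uses monthly factors (1+r)^(−t/12) with r = 0.03; an
optional half-cycle correction (off by default) discounts each cycle at its
midpoint.

## Parameter defaults

Costs are per cycle in 2014 USD (converted at ₩1,012.1/USD): erlotinib
2,113 (all cycles); cisplatin + pemetrexed 4,157 administration / 503
after; cisplatin + gemcitabine 3,327/454; docetaxel 3,300/616; pemetrexed
4,501/594; BSC 1,038 (all cycles); test 104. Diagnostic accuracy:
sensitivity 98.4%, specificity 89.2%, unknown 11%; mutation prevalence in
adenocarcinoma 39%.

Per-regimen adverse-event disutility totals are **not** published inputs —
only per-event disutilities are (neutropenia −0.0897, fatigue −0.0735,
nausea/vomiting −0.0480, diarrhea −0.0468, hair loss −0.0450, rash
−0.0325, anemia −0.0730, …). The defaults here are Σ(assumed incidence ×
per-event disutility) with incidence assumptions typical of each regimen's
toxicity profile: ERT 0.034 (rash-dominant), CPEM 0.070, CGEM 0.076,
DOX 0.081 (neutropenia/alopecia-heavy), PEM 0.050, BSC 0. They are a
documented fixture choice, configurable per regimen.

## Economics

`compare()` reports incremental cost and effect (intervention −
comparator); the intervention is *dominant* when cheaper and more
effective, *dominated* when costlier and less effective; otherwise the
ICER ΔC/ΔE is reported, with equal effects yielding an explicit
"undefined ICER" label. The scenario registry ships seven analyses: the two
single-method extrapolations, the alternative OS substitution for
first-line erlotinib, the ERT-PEM and CGEM-PEM regimen models, and the two
utility variants. Scenario overrides address configuration entries by
dotted path and fail loudly on unknown keys.

The tornado analysis perturbs one parameter at a time — cost parameters as
±25% scale factors, epidemiology parameters over explicit ranges
(prevalence ±10 points, unknown fraction ±5 points by default) — and
reports the ICER when the base case defines one, otherwise the incremental
net monetary benefit at a willingness-to-pay threshold (default
$30,000/QALY, configurable), which stays sign-stable where the ICER does
not. Bars are sorted by width; a failed endpoint flags its entry without
aborting the analysis.

## Synthetic data

The generator draws event times from per-arm Weibull truths, censors them
with an independent exponential process (0.02/month) plus an
administrative cutoff (24 months for PFS trials, 36 for OS, matching
typical trial follow-up), computes the product-limit estimate with
`lifelines`, and reads it off a monthly grid up to the last observed time —
emulating what figure digitization of a published K-M plot yields. A
digitized curve never extends past the end of follow-up.

`build_reference_study()` emits one curve set per model branch with the
trial counts of the pooled evidence base (PFS: 3 first-line TKI M+, 1
second-line CPEM M+, 1 first-line CPEM M−, 1 second-line DOX, 2 first-line
CPEM all-comers, 12 second-line TKI all-comers; OS: 9 CGEM, 2 CPEM
all-comers, 12 second-line TKI, 1 each elsewhere; plus CGEM PFS and
second-line pemetrexed curves so the regimen-swap scenarios have data to
bind). True medians are chosen to be clinically realistic for the setting —
first-line TKI PFS in mutation-positive patients ~13 months, clearly
dominating first-line chemotherapy PFS ~5.5 months; second-line unselected
TKI PFS ~2 months; OS medians 8–12 months; BSC ~3 months — with trial
sample sizes drawn once (120–420) from the seed. All curve values are
synthetic and labelled as such; only the parameter table (costs, utilities,
test accuracy) carries published values.

**What passing tests show — and don't.** The synthetic study demonstrates
that the pipeline recovers known truths, preserves its invariants
(conservation, monotone death, round-trip identities, mixing linearity),
and responds in the clinically expected directions (testing gains QALYs
when the TKI's PFS advantage is real; incremental cost rises with
prevalence). It does not reproduce any published base-case number: those
depend on the exact digitized curves, which exist only as supplementary
figure images. With the synthetic curve set the testing strategy is more
effective but also more costly (ICER ≈ $34k/QALY at the default seed)
rather than cost-saving; the dominance verdict is a property of the
evidence base, not of the machinery.

## Numerical choices and limitations

- Problem sizes: 60-cycle horizon with ≤3 lines per pathway gives
  clock-expanded state spaces of ~180 states; a full evaluation (15 branch
  fits + 2 strategies) takes ~1 s, and branch fits are memoized per curve
  set so scenario and tornado sweeps re-run only the cohort arithmetic.
- The least-squares fit is verified against a 200×200 grid oracle in the
  tests; the regression fit against closed-form OLS.
- Deterministic seeds throughout the generator (NumPy `SeedSequence`
  spawning per trial); identical spec + seed gives byte-identical output.
- Limitations: cohort (not individual) simulation; no probabilistic
  sensitivity analysis (deterministic and one-way only); single currency
  with no CPI logic; Weibull is the only survival family; no treatment
  waning, re-biopsy pathways, or test turnaround delays; false positives
  are assumed to experience the mutation-positive pathway curves on
  erlotinib, which likely flatters the no-consequence view of false
  positivity — an alternative curve binding can be configured.
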