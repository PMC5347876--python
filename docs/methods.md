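# Methods

## The engagement-in-care model

The measure treats out-patient HIV care as a renewal process observed
through surrogate attendance markers. Because complete appointment data
are rarely available in cohort databases, any dated CD4 count, viral load,
haemoglobin measurement or ART start/switch is taken as evidence of a
clinic attendance. Repeat tests within a short interval usually confirm a
single index visit, so attendances are grouped into **care episodes**: one
episode per 30.4-day month (anchored at study entry, the first marker)
containing at least one marker. 30.4 days = 365/12; internally a date maps
to month `days*5 // 152` (30.4 = 152/5 exactly), avoiding float boundary
errors at exact month multiples.

Each episode carries a time-updated clinical state:

* **lowest CD4** measured that month, else the most recent prior value
  carried forward (flagged);
* **CD4 change** = previous measured value − this month's lowest measured
  value (positive = drop). Defined only between *measured* values in
  different months: carried-forward values and same-month repeats (the very
  cluster the episode construct collapses) never generate drops;
* **highest viral load** that month, likewise carried forward; values
  reported below the detection limit ("<50") are stored at the bound with a
  flag, so they satisfy "≤ 50 copies/mL" and the strict "< 50" used for
  blips without guessing the true value;
* **blip status**: 51–200 copies/mL immediately following a measured value
  < 50 copies/mL (again, only between measured values);
* flags: on ART, ART started this month, new combination this month,
  within 1 month (≤ 30.4 days) of HIV diagnosis, AIDS diagnosis this month.

The **rule table** maps this state to an expected time to the next episode.
Defaults (all configurable through `RuleConfig`, serialized as YAML):

| condition | months |
|---|---|
| within 1 month of HIV diagnosis | 2 |
| AIDS diagnosis (episode month) | 2 |
| started ART | 2 |
| started new combination | 2 |
| not on ART: CD4 ≤ 350, any drop | 2 |
| not on ART: CD4 ≤ 350, no drop | 4 |
| not on ART: CD4 351–499 | 4 |
| not on ART: CD4 ≥ 500, drop ≥ 100 | 4 |
| not on ART: CD4 ≥ 500, drop < 100, VL ≥ 100 000 | 4 |
| not on ART: CD4 ≥ 500, drop < 100, VL < 100 000 | 6 |
| on ART: VL > 200 | 2 |
| on ART: VL 51–200, not a blip | 2 |
| on ART: VL 51–200, blip | 4 |
| on ART: VL ≤ 50, CD4 ≤ 200 | 4 |
| on ART: VL ≤ 50, CD4 > 200 | 6 |

All satisfied rows contribute and the **minimum** interval wins; the
untreated and on-ART blocks are not mutually exclusive gates (the ART-start
month can satisfy rows in both). Two months is the shortest interval
because a visit may fall anywhere within its month; six months is the
routine maximum for stable suppressed patients. CD4 and VL units are
cells/μL and copies/mL.

**Degenerate states.** Some states reach no row: no labs ever recorded; on
ART with VL ≤ 50 but no CD4; untreated with CD4 ≥ 500, drop < 100 and no VL
(both terminal rows of that branch condition on VL). These receive a
configurable **fallback interval of 4 months** (the midpoint of the rule
set) with condition id `fallback`, and the classify command logs how often
it fired.

**Month labels.** Follow-up months are counted from 1 (the entry month
itself is not classified). After an episode at month *m* with interval
*N*, months *m*+1 … *m*+*N* are in care; months *m*+*N*+1 up to the next
episode are out of care — including the re-attendance month itself when it
falls beyond the window. Default follow-up ends at the last episode
(censoring at the last recorded marker, so the measure captures
intermittent disengagement rather than terminal loss to follow-up); an
administrative end date can extend the final window, and both behaviours
are exposed (`--horizon censor|admin`) since each answers a different
question. Per-patient EIC = in-care months / total months.

**AIDS scope.** The AIDS condition is active only in the episode whose
month contains the AIDS diagnosis date, mirroring the construction of the
diagnosis-recency condition; it is not treated as a permanent state. The
interval for such episodes can be changed via `interval_aids`.

## Person-month analytics

Each classified month becomes one analysis row. Covariates are evaluated
at the **month midpoint** (entry + (m − 0.5) × 30.4 days; within-month
timing is otherwise arbitrary): age group (<25, 25–45, >45 years), on-ART
status, nadir and current CD4 group (<200, 200–349, ≥350 cells/μL, from
measured values only; missing until the first measurement), calendar
period (2000–2003, 2004–2007, 2008–2012) and time since entry (<1, 1–5,
5–10, >10 years). Stratified summaries report person-months and % in care
per level, with defined-but-unobserved levels reported at count 0.

Associations with being in care in any particular month are estimated by
logistic regression fitted with **generalized estimating equations**
(statsmodels `GEE`, binomial family), treating each person-month as one
entry and each patient as one cluster. The working correlation is
**exchangeable** — the standard default for repeated binary outcomes when
the fitting procedure, but not the structure, is prescribed — with robust
(sandwich) standard errors, so inference is valid even when that structure
is wrong. Months with missing modelled covariates are dropped with a
logged count (ethnicity carries an explicit "unknown" level instead).
Reference levels carry OR = 1 exactly. Non-convergence or exploding
standard errors (separation) raise an error rather than returning silent
output. A point-estimate identity pins the implementation: with equal
cluster sizes and a cluster-constant binary covariate, the GEE estimate
must equal the crude odds ratio of the aggregated 2×2 table.

## The synthetic-cohort simulator

The simulator generates cohorts with the statistical structure the
algorithm assumes, plus ground-truth labels, so every stage is testable
without restricted clinical data. Per patient: CD4 declines linearly while
untreated (default 60 ± 25 cells/μL/year from a baseline of 520 ± 180) and
recovers linearly on ART (100 cells/μL/year, ceiling 900), with
40 cells/μL measurement noise; viral load sits at a log₁₀ set-point
(4.5 ± 0.7) untreated, then decays linearly in log₁₀ to suppression over 5
months after ART start — passing through the >200 and 51–200 bands on the
way down — with blips (51–200) at probability 0.08 per suppressed visit
once at least two suppressed visits have accrued, so blip logic is
exercised. ART starts with probability 0.7 at each visit with measured
CD4 ≤ 350 (so untreated low-CD4 states also occur); regimen switches occur
at 0.05 per on-ART visit; AIDS is diagnosed at 0.3 per visit with measured
CD4 < 200. These simple parametric forms are deliberate: they are
sufficient to reach every rule-table row under the default parameters (a
coverage test asserts this), and realism beyond that is a non-goal.

Visits are **scheduled by the rule engine itself** applied to the true
(measured) state; a delay process makes a visit late with probability
`p_delay` (default 0.25), adding geometric (mean 2) or fixed extra months.
Ground-truth labels follow from the schedule and delays alone. The
closed-loop property — with full lab observation and no delays the
classifier reproduces ground truth exactly, for any seed — is the
pipeline's end-to-end check; lab-withholding ablations (`cd4_obs_prob`,
`vl_obs_prob`) perturb only carry-forward state. The 30.4-day grid means
simulated visit dates are exact month starts; real data fall anywhere in
the month, which the date-to-month mapping already handles.

Because a log-odds shift injected into the delay process has no
closed-form month-level marginal odds ratio, the calibration harness for
the association model instead draws person-month outcomes from a
beta-Bernoulli: patient-level Beta mixing preserves the marginal success
probability exactly, hence the marginal OR exactly (the GEE estimand),
with intraclass correlation 1/(1 + κ). Coverage of the 95% CI and
unbiasedness of the estimate are checked against that exact truth.

## What passing tests do and do not show

The simulator validates the *algorithmic* pipeline and the *statistical
machinery*, not epidemiological realism: it does not model pregnancy,
psychosocial or comorbidity-driven scheduling (not generally captured
electronically), resistance, adherence, mortality, or calibration to any
real cohort's marginals. Published cohort-level figures from restricted
registries (overall % in care, stratified person-month counts, fitted odds
ratios) are therefore reproducible in *structure* only. Fixed problem
sizes in the test suite (10⁴–1.5×10⁴ randomized states/sequences, cohorts
of 200–1000 patients, 200 replicates for CI coverage at 40 patients × 18
months) were chosen to make the stochastic checks stable at desk scale.

## Known limitations

* Attendance is inferred from laboratory surrogates; visits without any
  recorded test are invisible, biasing EIC downward.
* The rule table reflects monitoring guidance of the early-2010s era;
  current universal-ART guidelines would change the untreated block.
  The configuration mechanism exists for exactly this reason.
* Carry-forward of CD4/VL has no lookback limit; very stale values still
  drive scheduling (flagged on the episode, so analysts can filter).
* A same-day ART start and switch is treated as a start only; multiple
  recorded starts keep the earliest and flag the rest.
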