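# Methods

## Study model

The pipeline models the standard multi-region claims workflow for
post-transplant immunosuppression research. Each region holds seven
administrative tables (hospital discharges, drug dispensings, inhabitant
registry, mortality registry, emergency visits, co-payment exemptions,
outpatient tests) linkable only through an anonymous person identifier.
"Distributed" analysis is modelled as independent per-region invocations
of the same executable against one schema: each region validates its
bundle, reduces it to a minimal event-level analytical dataset, and the
datasets pool by concatenation with region-namespaced identifiers
(`region::id`), which makes cross-region identifier collisions impossible
by construction.

## Synthetic data generator

The generator is first-class, tested code: it is the only data source the
pipeline is evaluated on, so its defaults define the study conditions.

- **Population.** Organ mix kidney 58.3%, liver 32.1%, heart 6.3%, lung
  3.1%, pancreas/intestine 0.1% each; four regions; transplant
  admissions uniform over 2009–2019 with organ-specific mean stays
  (kidney 17 d … heart 44 d); recipient age ~ N(50, 15) truncated to
  1–80; 68% male.
- **Regimens.** Per-organ index-regimen mixtures (backbone × companion ×
  steroid co-use) encode the cell frequencies typical of each organ
  setting — e.g. kidney is dominated by TAC + antimetabolite + steroid,
  the heart setting by CsA-based therapy. Agent-level splits (MMF vs AZA,
  IR vs ER tacrolimus, generic uptake after market entry) are per-organ
  probabilities. The generic-availability calendar is synthetic
  (cyclosporine/azathioprine generic throughout, mycophenolate from
  2010-07, tacrolimus from 2013-07, no mTOR generics): it reproduces the
  structure of the market, not true authorization dates.
- **Dispensings.** Claims carry package counts, not days supplied; a drug
  dictionary maps each AIC product to 30 days per package. Index-window
  dispensings are always emitted (days 0–25 post-discharge); refills
  recur every 30 days and are kept with a per-person coverage probability
  drawn from a Beta with mean 0.8 and concentration 10 (mean 1.0 yields
  perfect adherence). A 5% per-person rate of within-class CNI switches
  (TAC↔CsA at a random day 60–400) exercises the switching detector.
- **Outcomes.** Death, rejection/graft failure, infection, diabetes and
  cancer are exponential waiting times from the day-30 landmark with
  per-organ constant hazards on the incidence-rate scale observed in such
  cohorts (e.g. kidney mortality 0.0196/PY, lung infection 0.3738/PY).
  Constant hazards are the simplest model whose rate recovery has a
  closed form. Non-fatal outcomes surface as hospitalizations with
  outcome-specific diagnosis codes; deaths enter the mortality registry.
- **Planted negatives.** Each eligibility rule receives violators at a
  default 5% rate, constructed to violate exactly one rule (early deaths
  land on days 2–29, the pre-enrolment transplant stays in 2007–2008 but
  inside the 730-day washout, and so on). Deaths of non-planted persons
  are drawn strictly after day 30, so set equality between the final
  cohort and the manifest's eligible persons is exact, not approximate.
- **Registry.** One row per recipient with quasi-identifiers, donor
  attributes and physician-reported therapy; a 5% (configurable)
  disagreement rate resamples the reported regimen from the organ's
  mixture excluding the truth label, and a 5% (configurable) key
  perturbation corrupts exactly one quasi-identifier field per affected
  row (sex flip, organ swap, ±1 month, hospital swap).

What the generator does **not** emulate: coding dialects beyond the
specific ICD-9-CM/ATC/AIC fields the pipeline reads, dose information,
induction-phase therapy, regional differences in practice, informative
censoring, or linkage error modes other than single-field corruption.
Passing tests therefore demonstrate algorithmic correctness under known
generating mechanisms, not performance on real claims.

## Design choices

- **Windows.** All intervals are half-open `[start, end)` anchored on the
  index discharge (day 0): 2-year transplant washout
  `[discharge−730 d, admission)`, L04 washout 180 days, landmark 30 days.
  730 and 180 days are used instead of calendar years/months so date
  arithmetic is reproducible without leap handling. Episodes are scanned
  from 2007-01-01 (so the 2-year washout for a 2009 cohort can see
  pre-enrolment claims) and enrolment requires index discharge in
  [2009-01-01, 2019-12-01].
- **Organ code map.** Kidney 55.6x excluding 55.61, liver 50.5x, heart
  37.5x, lung 33.5x, pancreas 52.8x, intestine 46.97. Source material in
  this field occasionally prints "469.7" for intestinal transplant; that
  is not a valid ICD-9-CM procedure code, and the map deliberately ships
  46.97.
- **Multi-organ exclusion** uses distinct organ codes within the same
  index admission — the conservative reading of "multiple organ
  transplants" absent a defined window.
- **Inclusion step 6** accepts steroids (H02AB) as well as L04 agents:
  a steroid-only maintenance regimen ("mainly steroid-based" No-CNI) is a
  real category and would be unobservable under an L04-only inclusion,
  while the washout (step 5) is L04-only by definition.
- **Eligibility order-stability.** The final membership is the episode
  set minus the union of per-rule violator sets, so any permutation of
  steps 2–6 yields the same cohort; only per-step counts depend on order.
- **Linkage ladder as configuration.** Step 1 uses all five fields; the
  default relaxation drops one field at a time (hospital, transplant
  month, birth month, organ, sex). Duplicated keys are set aside per step
  rather than discarded globally, preserving later recovery; a relaxed
  key matching multiple registry candidates yields no match —
  deterministic linkage must not guess. An unmatched record's reason is
  `duplicate-key` if its key was ever non-unique, else `no-candidate`.
- **Backbone tie rule.** Dual CNI in the landmark window is resolved by
  earliest dispensing, same-day ties to TAC (configurable); there is no
  dual-CNI maintenance category.
- **PDC/MPR.** No published convention is assumed: PDC shifts overlapping
  supplies forward (stockpiling) and counts covered days in the period;
  MPR is total supplied days over period length, reported raw and capped.
  Only dispensings dated inside the period count (no carry-in from the
  landmark). The PDC implementation (interval arithmetic) is tested
  against an independent day-grid stockpile simulation.
- **Discontinuation** is a coverage gap longer than a 60-day grace period
  (configurable) across all maintenance drugs.
- **Incidence CIs** are exact Poisson via χ² inversion:
  `[χ²(0.025, 2k)/2, χ²(0.975, 2k+2)/2] / PY × 100`. Person-years use
  exact day counts / 365.25. Outcome-specific risk sets exclude prevalent
  cases (first event before follow-up start).
- **Kaplan-Meier** processes events before censorings at tied times; the
  estimator is implemented in-package and cross-checked against lifelines
  in the test suite.
- **Rounding** for display: percentages half-up to one decimal, rates to
  two decimals. Internal computation is unrounded.
- **Concordance** compares the full backbone|companion|steroid label by
  default (a backbone×companion level is available); Cohen's kappa is the
  chance-corrected coefficient, flagged and reported as 1.0 when a margin
  is degenerate (single category) with perfect agreement.
- **Charlson banding** (0–1 / 2 / 3+) uses a shipped, editable
  diagnosis-prefix list with no claim of equivalence to any validated
  mapping.
- **MOR** takes the cluster variance as an argument; fitting the
  mixed-effects model that produces it is out of scope, so the quantile
  transformation is exposed on its own.

## Problem sizes

The test suite runs one shared synthetic study at n = 600 and dedicated
runs at n = 2,000 (eligibility truth-recovery; hazard recovery at
λ = 0.02/PY), n = 1,000 (linkage perturbation recovery ≥ 0.95) and
n = 800 (clean regimen recovery at adherence 1.0); the PDC oracle check
uses 1,000 randomized dispensing histories. The acceptance script runs
two end-to-end studies at n = 2,000. These sizes give binomial/Poisson
Monte-Carlo bands tight enough to detect implementation errors while the
whole suite completes in about a minute.

## Known limitations

- Codes are validated structurally (regex per code system), not against
  terminology services; no OMOP/Sentinel vocabulary mapping.
- The intestine cohort is vestigial (trace frequency, multi-organ fodder).
- Hazards are constant within organ: no age/period effects, no competing
  risks — the product-limit curve treats competing events as censoring.
- Registry donor fields are minimal (age, sex, living/deceased) and only
  summarized for linked persons.
- No comparative-effectiveness estimation (propensity scores, Cox HRs) or
  cost analysis; the pipeline stops at descriptive and incidence outputs.
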