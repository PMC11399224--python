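# Methods

## The surveillance model

`ppisentinel` models an hourly batch clinical-decision-support loop over a
fixed cohort of hospital cases. At every tick on the grid `t0 + k·step`
(default step 1 h) and for every included, in-hospital case, the engine
derives a *risk profile* and a *PPI status* from the data valid at that
instant and evaluates twelve alert predicates. Events between ticks are
observed at the next tick, which reproduces the latency of an hourly
review cycle.

**Risk profile.** Nine boolean exposure flags (NSAID, COX-2 inhibitor,
low-dose aspirin, non-aspirin antiplatelet, therapeutic anticoagulation,
corticosteroid ≥ 10 mg prednisone-equivalent/day, SSRI, age ≥ 65,
thrombocytes < 30 G/L) plus the number of distinct concurrently active
antiplatelet agents (aspirin at any dose counts as one agent; DAPT = ≥ 2
agents). The *countable* factor set — used by the "≥ 4 risk factors"
alert, the "and risk factor" qualifiers of alerts 7/8 and the
inappropriate-PPI predicate — is NSAID, COX-2, antiplatelet therapy (one
factor regardless of agent count), therapeutic anticoagulation, SSRI,
age ≥ 65 and thrombocytopenia. Corticosteroids are deliberately *not* in
that set: they appear only in the named combinations of alerts 3 and 10,
so a PPI whose only co-medication is a corticosteroid is still flagged as
potentially inappropriate. "Drugs associated with gastrointestinal
bleeding" is packaged as the SSRI class; the knowledge-base schema allows
extending it.

**PPI status** is `NONE`, `ORAL_ONCE_DAILY`, `ORAL_TWICE_DAILY` or
`INTRAVENOUS` (iv beats twice-daily beats once-daily). Alerts 1–11
require `NONE`; alert 12 fires only for `ORAL_ONCE_DAILY` — intravenous
and twice-daily prescriptions are treated as appropriate, on the
convention that those modes imply an active therapeutic indication. This
also keeps alert volume manageable, at the price of systematically
under-counting inappropriate use.

**Suppression and lifecycle.** Among simultaneous missing-PPI candidates
only the lowest-numbered (most clinically relevant) alert is kept; a
newly firing lower-numbered alert retires an open higher-numbered one, so
a case carries at most one live missing-PPI alert. Alerts are
deduplicated against live alerts of the same number, auto-terminate when
their predicate no longer holds, and are all terminated at discharge.
Pharmacist triage is a seeded stochastic policy: after a configurable
delay (default 4 h) a pending alert becomes an intervention message with
a per-alert probability, otherwise it is dismissed as not relevant;
intervention outcomes (accepted / not accepted / unknown) are drawn per
category. A dismissed alert stays "watched" while its trigger persists so
it does not immediately re-raise. Triage draws come from a per-case child
generator, making logs byte-reproducible under a fixed seed regardless of
how other cases evolve.

**On-demand exposure.** A pro re nata NSAID counts as exposure at time
`t` only if at least 7 administrations ("more than six") fall in the
half-open window `(t − 48 h, t]`; administrations, not prescriptions, are
counted, because the criterion is about actual intake. Other on-demand
drugs count as active while the prescription is open. The
`replicate_bug_on_demand` flag disables the gate and counts any open
on-demand NSAID prescription — a documented historical failure mode whose
only effect is to mask the inappropriate-PPI alert in patients who hold a
rarely-used NSAID reserve prescription; the flag exists to demonstrate
that sensitivity loss and is off by default.

## Thresholds and knowledge base

All cut-offs are configuration, not code, because they encode local
clinical consensus rather than universal guideline values:

| parameter | default | unit | note |
|---|---|---|---|
| corticosteroid threshold | 10 | mg prednisone-eq/day | standard equipotency factors packaged |
| low-dose aspirin maximum | 325 | mg/day | common cardiology convention |
| age threshold | 65 | years | birthday counts as attained |
| thrombocyte cut-off | < 30 | G/L | latest value at or before t; missing lab ⇒ factor absent |
| multi-factor alert | ≥ 4 | factors | countable set above |
| on-demand gate | ≥ 7 doses / 48 h | — | NSAIDs only |
| `min_exposure_hours` | 0 | h | minimum prescription validity before it counts |

Drugs are identified by ATC code (longest-prefix match) or through an
explicit alias table; free text is never matched fuzzily. Anticoagulants
carry per-agent therapeutic daily-dose thresholds (e.g. enoxaparin
≥ 80 mg/d, rivaroxaban ≥ 15 mg/d, any maintenance VKA dose); doses below
are thromboprophylaxis and not a bleeding-risk factor here. Which agents a
hospital counts as antiplatelet therapy or as therapeutic anticoagulation
is site-specific; the packaged defaults are labelled as such and are meant
to be reviewed before use on real data.

## Temporal conventions

Intervals are half-open `[start, end)`; a prescription's `end` is the
first moment it is no longer valid, avoiding double counting at switch
times. Timestamps are naive ISO-8601 in one implicit timezone; no DST
arithmetic. Age is evaluated at query time (the adult-inclusion check
uses admission). The discharge-day reference snapshot is the last
surveillance tick strictly before the discharge timestamp, clamped to
admission for very short stays.

## Evaluation

`discharge_screen` applies exactly the engine's predicates (always with
the corrected on-demand gate) at the discharge snapshot and classifies
each case MISSING / INAPPROPRIATE / NONE; the two incident categories are
mutually exclusive because their PPI preconditions conflict.
`diagnostic_performance` scores an alert log per category: a case is
test-positive if at least one alert of that category was raised during
the stay, whether or not it later auto-resolved; sensitivity and
specificity are per category, never per individual alert, and empty
denominators are reported as n/a rather than imputed.

`compare_incidence` is a 2×2 chi-square of incident vs non-incident cases
across two periods. The default is the uncorrected Pearson statistic; a
flag enables the Yates continuity correction. On the published marginals
of the inappropriate-PPI row the two variants give p ≈ 0.026 and
p ≈ 0.029 around a printed value of 0.022, so printed p-values of this
kind should be read as bounded claims: the exact variant and denominators
behind a printed value are generally ambiguous. The relative reduction
`(rate_before − rate_after)/rate_before × 100` is reported to one
decimal.

## Synthetic cohort generator

The generator emulates a two-period (baseline / intervention),
three-month discharge cohort: per-case age from four calibrated bands
(mean 58.3 y, ≥ 65 fraction 44.2%), stay length from four bands (mean
≈ 5.5 d), sex ≈ 51% female, ~8% consent refusal, ≈ 9 inert concomitant
drugs per case, per-factor exposure fractions matching the published
case counts (e.g. NSAID 443/5072, low-dose aspirin 833/5072) and a ~33%
PPI prescription rate. Incident rates default to the published per-period
values (missing 67/5178 → 24/5072; inappropriate 329/5178 → 270/5072).

Incidents are injected **by construction**: the generator picks the alert
row to realise (weighted toward the antiplatelet constellations), then
emits the minimal prescriptions/labs that make exactly that predicate
true from 48 h before discharge across the snapshot, resampling age into
the ≥ 65 band where the row requires it. Non-incident cases are built so
that *no* predicate holds at *any* tick: background factor sets are
checked against the alert truth table and, if they would fire, covered by
a once-daily PPI from admission; a background PPI without a qualifying
factor is emitted twice-daily (the convention's stand-in for an
indication the data model cannot express, marked `indicated_ppi` in the
labels); background exposures in inappropriate-PPI cases end mid-stay,
with thrombocytopenia normalised by a later lab value. Birth dates are
chosen so no birthday falls inside the stay, keeping age constant across
ticks. Labels are therefore exact by construction, which the test suite
verifies independently (zero disagreements between `discharge_screen` and
the labels on ~5500-case cohorts).

Background exposure probabilities are deflated analytically for the
exposure mass the injected incidents add, and the background PPI
probability is solved from the exact enumeration of the probability that
a background draw fires (those cases receive a covering PPI), so realised
margins land on target without rejection sampling. Same config and seed
give byte-identical CSVs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlations between risk factors beyond their
margins, readmissions (one patient per case), dose titrations, coded
diagnoses or any indication signal, irregular administration patterns,
and charting noise (wrong doses, back-dated entries). Perfect noise-free
sensitivity/specificity establishes engine correctness relative to its
own predicates, not field performance; real-world accuracy is limited by
exactly the information the synthetic cohort declares away.

## Numerical and design choices

* Tick grid anchored at the earliest admission (or a caller-supplied
  `t0`); injected exposures span wide windows around discharge so
  reference snapshots agree under any grid anchor.
* Alert 7 ranks above 8 (DAPT outranks single low-dose aspirin on top of
  therapeutic anticoagulation); "risk factor" in alerts 7/8 means any
  countable factor not already consumed by the alert's named triggers, so
  an alert cannot fire off its own trigger.
* The chi-square degenerates cleanly: identical rates report statistic 0
  and p = 1 without calling into the test.
* Problem sizes in the automated checks: exhaustive rule enumeration over
  4608 states; label soundness on a ~5500-case two-period cohort;
  end-to-end surveillance on a ~680-case single-period cohort (the full
  three-month window at hourly resolution); calibration on the full-scale
  ~5500-case intervention period.

## Known limitations

The engine checks neither PPI dosage correctness nor
prophylactic-vs-therapeutic intent; drug–drug interactions beyond the
listed class combinations are out of scope; the pharmacist's clinical
judgement is replaced by a stochastic policy and is not a model of human
triage behaviour; and the packaged dose thresholds are defaults to be
reviewed against local practice.
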