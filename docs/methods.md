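# Methods

This note documents the models and procedures behind `trajmine`, the
parameters that matter, the design choices that were genuinely open, and
what the synthetic cohorts do and do not establish about real claims data.

## Claims model and code granularity

A claim record is one hospitalization: patient and hospital identifiers,
admission date, stay duration, discharge status, demographics, one
principal ICD-10 diagnosis, an optional related diagnosis (the aetiology
when the principal is a chapter-XXI contact code), any number of
comorbidity diagnoses, procedure codes, and a stay cost in euros. Records
are read from delimited text with a canonical header; a column map adapts
other dialects. Rows failing validation are rejected individually with
their line number; a missing mandatory column aborts the read.

Diagnosis codes are normalised (upper-cased, dots stripped) and coarsened
before analysis: the first 3 characters are kept, grouping clinical
variants at the ICD-10 category level, except chapter-XXI Z-codes, which
keep up to 5 characters because the 4th/5th digits distinguish types of
contact with the health system (chemotherapy session `Z511`, radiotherapy
session `Z510`, palliative care `Z515`, plastic-surgery follow-up `Z421`,
device adjustment `Z452`). The exception list is a configurable
prefix→length map (`CodeGranularityPolicy`); the `Z`→5 default is a
deliberate coarse stand-in for a curated code list, which a user can
replace. Truncation is idempotent, so re-processing already-coarsened
data is safe.

Admission is stored as a full calendar date. Monthly-resolution sources
can still be ingested by mapping admissions to month starts upstream;
window arithmetic is plain day differencing throughout, which the
synthetic generator exercises at day resolution.

## Trajectory assembly

* **Index selection.** A stay qualifies when some diagnosis (principal,
  related or comorbidity) starts with a cohort prefix (`C50`, `D05`) *and*
  some procedure starts with a surgery prefix, and the admission falls in
  the target year. The first such stay per patient (ties on admission date
  broken by the smaller stay index, with a warning) is the index.
* **Incidence filter.** A patient whose records contain a qualifying stay
  starting within `lookback_days` (365) strictly before the index is a
  prevalent case and is excluded. The rolling lookback keeps the rule
  year-agnostic; `calendar_lookback=True` restores a literal
  previous-calendar-year check. Both the selected cohort and the rejected
  patients (reason `prevalent` / `no_candidate`) are reported.
* **Window.** The trajectory holds the index plus every stay of the
  patient beginning `0 ≤ d < window_days` (366) days after it — strict
  on the right, inclusive of same-day stays, based on admission dates
  only (stay overlap is ignored). Radiotherapy-session stays (explicit
  boolean flag in the canonical format, set by the generator) are dropped
  because such sessions are inconsistently captured across facility
  sectors in real casemix systems.
* **Indicators.** Total cost, stay count, cumulative length of stay,
  chemotherapy sessions (stays whose truncated principal diagnosis equals
  the configurable chemotherapy code `Z511`) and their cost, in-hospital
  death (any stay discharged as death — deaths outside hospital are
  invisible to claims), and age/gender at the index. All sums are over
  the trajectory's retained stays only, so the indicators are additive
  over disjoint stay lists.

## Formal Concept Analysis

The context pairs patients with the truncated principal and related
diagnoses over all their trajectory stays; comorbidity codes are excluded
by default (they describe the patient's background rather than the reason
for admission) and can be included for sensitivity analyses.

Concepts are enumerated with **Close-by-One** over attributes with a
canonicity test, extents held as integer bitmasks keyed to the context's
object order. This generates each closed set exactly once and scales to
the thousands-of-patients contexts the pipeline produces; an exhaustive
powerset-closure oracle is retained in the test suite and the two are
asserted equal on hundreds of random contexts. Cover edges (the line
diagram) are the minimal strict supersets under extent inclusion, checked
in tests against networkx's transitive reduction. Degenerate contexts
(no objects, no attributes, empty incidence) reduce to the one- or
two-concept lattices the theory prescribes.

Filtering keeps concepts with `support ≥ min_support` and
`own-object proportion ≥ min_own_prop`. The own-object proportion — the
fraction of the extent whose full code set equals the intent exactly — is
a cohesion/stability measure: noise inflates concepts whose members all
carry more specific descriptions, and those concepts have few own
objects. Every object is an own object of exactly one concept (its
description's closure), a partition property the tests verify. The top
(empty-intent) concept is retained by default as the whole-cohort
baseline even though its own-object proportion is usually 0.

## Cost tree

Filtered concepts overlap, so per-patient cost is explained by recursive
partitioning over boolean concept-membership predictors. Splits maximise
the SSE reduction `ΔSSE = n_in·n_out/n·(μ_in − μ_out)²`, computed by one
vectorised pass per node; constant (degenerate) columns such as the top
concept can never split. Growth is **best-first**: the single best
admissible split over all current leaves is applied next, so "k splits"
indexes the k globally most informative splits, which is also the
x-axis semantics of the cross-validation curve. Ties break toward the
larger SSE reduction, then the larger concept support, then the
lexicographically smaller intent, making the tree deterministic.
`min_node` (default 7) bounds child size; `min_improvement` and
`max_splits` stop growth — a deliberate cap-and-threshold substitute for
cost-complexity pruning, since tree size is chosen here by inspecting the
CV curve. Cross-validation uses a seeded random k-fold partition; for
each fold the best-first split sequence is replayed so held-out MSE is
reported for every split count 0..max_splits in one pass, normalised by
the zero-split MSE.

## Synthetic cohorts

The generator emulates a national casemix extract around one index
surgery year. Each patient draws a profile by prevalence; a profile is a
code set plus stay-count, cost, chemotherapy, death and demographic
parameters. Realism choices, all configurable:

* **Counts** Poisson (extra stays; stay durations), **costs** log-normal
  parameterised by median `m` and σ (`cost = m·exp(σZ)`), **ages**
  truncated normal (clipped to 18–99). σ = 0.4 in the default study
  config, a realistic per-stay cost dispersion (~42 % coefficient of
  variation).
* **Code coverage.** The index stay carries the profile's `C50*`/`D05*`
  anchor; each remaining non-chemotherapy code gets one dedicated
  follow-up stay; chemotherapy profiles receive `1 + Poisson(mean − 1)`
  session stays (duration 0). Every patient therefore expresses the full
  profile code set, which makes the planted profiles exactly recoverable
  as concept intents — with zero noise, the filtered lattice is exactly
  the planted sets plus the top concept.
* **Distractors.** With configurable rates, patients gain a qualifying
  surgical stay in the prior calendar year (within the rolling lookback,
  so selection must reject them as prevalent), flagged radiotherapy
  session stays inside the window, and one extra stay carrying a random
  non-profile code. Deaths are placed on the chronologically last regular
  stay, and radiotherapy sessions are never generated after a death.
* **Ground truth.** Each patient's profile, distractor flags and realized
  indicator values are emitted alongside the claims, so tests compare
  pipeline output to recorded truth rather than re-deriving it.

The default study configuration plants ten profiles spanning the clinical
spectrum of a breast-surgery cohort: in-situ carcinoma only (cheapest,
~2 stays), invasive cancer without chemotherapy, chemotherapy courses
with and without device-adjustment or aplastic-anaemia codes (~8 session
stays each), plastic-surgery reconstruction profiles (younger patients),
nodal and distant metastases, and a palliative-care profile (most
expensive, longest stays, death rate 0.69). Expected trajectory cost per
profile is analytic — `E[stays]·median·exp(σ²/2)` plus the expected noise
stay — and a concept's generating mean is the prevalence-weighted mixture
over the profiles whose code sets contain its intent, since planted sets
nest (e.g. every chemotherapy patient lies in the `C50` extent).
Prevalences and cost levels were fixed analytically so that adjacent
concepts in the expected cost ordering are separated by roughly three or
more combined standard errors at the default cohort size of 5,000, making
rank recovery a property of the design rather than of a lucky draw.

**What the synthetic cohorts do not show.** Codes within a profile are
perfectly co-expressed, costs are independent across stays, admission
dates are uniform, there is no coding drift between hospitals, and no
partial expression of profiles — all features real claims have. Passing
the recovery tests demonstrates that the pipeline's selection, mining,
filtering and costing are correct under known generating conditions, not
that the default thresholds (support ≥ 30 at n = 5,000, own proportion
≥ 0.1) are clinically tuned for any particular real cohort. Incidental
"noise profiles" (e.g. `{C50, R07}`) can legitimately pass the filter
when frequent enough, mirroring the incidental comorbidity profiles that
appear in real cohorts.

## Problem sizes and numerics

Default analysis sizes — 5,000 synthetic patients, ~15 attributes,
lattices under ~100 concepts, trees to 8 splits with 10-fold CV — run in
seconds and are the sizes the packaged acceptance script uses. The
enumeration algorithm itself handles far larger contexts (cost grows with
objects × attributes × concepts). Floating-point notes: concept measures
are exact integer/rational computations in float; split-gain ties are
detected with a 1e-9 absolute tolerance; stay costs are rounded to cents
at generation; CV fold assignment derives entirely from the user seed.
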