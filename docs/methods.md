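# Methods

## Data model

An activity is (*r*, *t*, *c*, *v*): patient, integer days from diagnosis,
dictionary code, value. Time is integer days throughout — sub-day resolution
is out of scope, and dates are accepted in ISO-8601 only (source-system date
dialects are an upstream concern). Pathways are stable-sorted by
(*t*, code); the alphabetical tie-break for concurrent activities is a
package choice (concurrency itself carries no order), made so sequence
statistics, start/terminal codes and collapsed strings are deterministic.
Informational codes are pinned to *t* = 0; an informational activity arriving
with a nonzero time is normalized to 0 with a logged warning rather than
rejected, since the payload is still usable.

Left-censored laboratory strings "&lt;x" are canonicalized to x/2 for any
positive x, generalizing the two conventional substitutions (&lt;0.1 → 0.05,
&lt;1 → 0.5); the censor flag is retained on the activity so kinetics can
report when a fit involved substituted values. Unknown codes are errors, not
silently dropped — the dictionary is the contract. Master tables keep values
as raw text (canonicalization happens at pathway construction), which makes
the CSV round trip byte-stable and preserves censoring through I/O.

## Completeness scoring

The positioning reference is the time of the *first* treatment whose code is
in the radical set {S, R, C, O, H}; active surveillance (W) is excluded
because it does not move the biomarker, and hormone therapy is included
because it does (both sets are configurable). Where several treatments
exist, using the first is a choice; the alternative (scoring against each
treatment) is not implemented. A reading exactly at the treatment time
counts as *before* — the pre-treatment baseline sampling convention.

The maximum biomarker drop is searched over *consecutive* reading pairs by
default: a treatment between adjacent readings is what directly explains the
change between them. The all-ordered-pairs alternative is available as
`ScoringConfig(pair_mode="all")`. The drop interval includes its endpoints
when searching for a substantiating treatment (a same-day treatment and
reading are concurrent, and concurrency should not defeat substantiation).
"Constant or always rising" means every consecutive difference ≥ 0 with at
least two readings, and counts as substantiated — there is no unexplained
decline.

The hybrid level maps (positioning, substantiation) as S0=(0,·), S1=(1,·),
S2=(2, not yes), S3=(3, no), S4=(2, yes), S5=(3, yes). Positioning 0/1
implies substantiation is not applicable — there is no post-treatment
reading whose change could need explaining — and the scorer enforces this
invariant. A positioning-2 pathway whose drop is unexplained maps to S2, not
below: it cannot outrank S2, whose substantiation is nominally N/A.

The drop ratio divides the maximum drop by the PSA at diagnosis, taken as
the latest reading at *t* ≤ 0, falling back to the earliest reading after
diagnosis; a zero anchor makes the ratio undefined (logged, reported as
absent). The surveillance audit restricts to patients whose first treatment
activity is W with no non-surveillance treatment in the following 365 days
(configurable horizon) and flags each configured ratio threshold.

## Kinetics

Velocity is the ordinary-least-squares slope of PSA against time in days;
doubling time is ln 2 / slope of ln PSA against time. These are the standard
log-linear definitions. Units are per-day natively (the package's time
unit), with a per-year convenience value (× 365.25) for display. A
non-positive log-slope is reported as infinite doubling time with the slope
retained, so a halving time can still be formed. Two readings at distinct
times are the minimum for a fit; fewer produce an explicit empty result from
the pathway-level helpers and an error from the raw-series functions.
Censored readings participate at their substituted value and flag the
result. Pre-treatment kinetics use readings at or before the first radical
treatment (all readings when none exists).

## Treatment regimes and summaries

A regime label is the first treatment modality plus the earliest *different*
modality starting within a day window after it; repeats of the same modality
never extend the label, and a pathway without treatment is labelled "N". The
default window is 92 days; 90 appears in some conventions, so the window is
a parameter of both the engine and the summary. Pathway length is last
minus first activity time; length from diagnosis is simply the last time.
Collapsed sequences reduce maximal runs of one code to a single symbol and
are the substrate for regex querying and the unique-sequence count.
Segmentation places boundaries at *t* = 0 and the first treatment time, with
ties at the treatment time opening the post-treatment segment.

## Synthetic cohort generator

The generator emulates a diagnosed prostate-cancer cohort at the study
conditions: completeness-class mixture (4.73, 4.04, 5.36, 20.64, 2.94,
62.29) % for S0–S5, regime mixture (47.63, 27.20, 16.70, 3.09, 1.15) % for
(H, S, W, SW, SH) with the 4.23 % remainder assigned to "no treatment", age
N(72, 9²) clipped to [40, 95], and a 21.11 % death fraction. Classes and
regimes are drawn jointly with both marginals exact: untreated pathways can
only be S0/S1, so the "N" mass is carved proportionally out of those classes
(the configuration validator rejects mixtures where that is impossible).

PSA trajectories are exponential — growth `P0·2^(t/DT)` to the treatment
that causes decline, then decay toward a nadir with a 30-day halving time —
with multiplicative log-normal reading noise (σ = 0.05) and left-censoring
below 0.1 ng/ml. The exponential form is the generator's choice; it matches
the doubling-time concept the kinetics estimate. Baselines are uniform on
5–60 ng/ml, doubling times uniform on 180–900 days, routine sampling
intervals ~90 days; none of these are calibrated to a real cohort and they
are documented as non-clinical. The first post-treatment sample is placed
deep enough into the decline (adaptively, given the growth accrued by the
treatment date) that the collapse from the last pre-treatment reading
dominates every later decrement — this is what makes the planted class
identifiable by construction rather than probabilistically.

Class recipes: S0 withholds all PSA rows; S1 withholds post-treatment rows;
S2 withholds pre-treatment rows; S3 withholds the treatment that caused the
collapse and records the regime's treatments *after* it (plus a tail reading
beyond them, so readings straddle treatment but the maximum drop goes
unexplained); S4 keeps only post-treatment readings and records a second
treatment of the same modality between the first two, so the drop is
substantiated without touching the regime label; S5 is intact. For
surveillance-regime patients needing a radical treatment, it is placed more
than 92 days after W so the regime label stays "W". A configurable fraction
of surveillance-only S1 patients receive a *hidden* treatment — monitored
rising readings, then a collapse with nothing radical recorded — planting
exactly the signal the drop-ratio audit is designed to find. Half of the
surveillance-only S1 subgroup is hidden by default so the audit always has
both positive and negative cases.

What the generator does not emulate: correlated staging/grade/age joint
distributions, registry linkage artifacts, assay changes over time,
free-text values, and irregular real-world sampling bursts. Passing
recovery tests therefore demonstrates the scorer's correctness on the
model's own terms, not robustness to every failure mode of real hospital
data.

## Numerical and I/O choices

Master tables are CSV (`Identifier,Time,Code,Value`, UTF-8, RFC 4180) sorted
by (Identifier, Time, Code) on write; numeric values print compactly
(integral floats without a decimal point, full `repr` otherwise) so a
write–read–write cycle is byte-identical. Emitted synthetic readings are
rounded to 2 decimals by default; `value_decimals=None` emits full precision
so noiseless trajectories stay exactly exponential through a round trip.
Drop-search ties break to the earliest interval. Mixture sums are validated
to 1e-9. All generator randomness flows through one seeded
`numpy.random.Generator`; a seed reproduces the master table byte for byte.

Rendering draws biomarker readings as joined markers, other timed events as
vertical lines (diagnosis solid, treatments dashed, death bold, other
diagnostics dotted) with code letters above, offset horizontally on
collision; secondary series ride a twin axis with an optional shaded normal
band. The renderer returns a manifest (kind, code, x-position per element)
so tests assert content rather than pixels; SVG output fixes the hash salt
and omits the date for determinism. A log-scale toggle covers the 0.05–1000
ng/ml dynamic range of routine PSA; linear is the default.

## Problem sizes

The test suite exercises the scorers against a brute-force enumerator on
5,000 random pathways (≤ 12 activities), the scoring invariant on 10,000,
and generator recovery on cohorts of 2,000 patients (one noiseless, one at
default noise) — sizes chosen so the whole suite completes in a few seconds
while keeping binomial standard errors small enough for 3-SE mixture checks
to be meaningful.

## Known limitations

Scores are computed against the *first* radical treatment only; pathways
with genuinely distinct treatment episodes (e.g. salvage therapy years
later) are summarized by one reference point. The substantiation rule is
biomarker-specific by design: applying it to markers moved by factors other
than recorded treatments would need additional guard rules. Guideline-
conformance scoring, survival analysis, process-mining model discovery and
sequence-similarity clustering are out of scope.
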