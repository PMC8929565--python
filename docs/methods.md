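# Methods

This note documents the models, numerical choices and limitations behind
`rtebench`, in the package's own terms.

## The efficiency model

Each supported accommodation service is a decision-making unit (DMU)
characterised by size-adjusted rates: inputs — budget per place (GBP),
places, staff FTE per service user; outputs — average length of stay
(years), occupancy (%), users moved to more independent accommodation per
place, and optionally one quality-of-care domain score scaled by service
size (`score × places / 100`, so a given quality level counts more in a
larger service).

Relative technical efficiency is the input-oriented,
variable-returns-to-scale (BCC) envelopment score: the smallest θ such
that a convex combination of peers consumes at most θ times the DMU's
inputs while producing at least its outputs. Variable returns to scale
(the convexity constraint Σλ = 1) is the right choice here because output
production in care services is not proportional to resource changes;
input orientation asks the planning-relevant question ("could the same
care be delivered with fewer resources?") — maximising outputs such as
move-on counts would be clinically meaningless as a target. No weight
restrictions are imposed.

### Solver

The LP is solved with HiGHS (`scipy.optimize.linprog`). The classical
formulation puts a non-Archimedean ε on the slack sum; any finite ε
corrupts θ, so the default is a two-phase solve: phase 1 minimises θ,
phase 2 maximises the slack sum with θ fixed. A literal ε objective
remains available (`epsilon=`) for fidelity experiments. θ is snapped to
1 within 1e-7; strong efficiency requires θ = 1 *and* zero slacks (tol
1e-6); θ = 1 with nonzero slacks is reported as weakly efficient.
Alternate optima in λ are not disambiguated — any optimal vertex is
accepted. Inside the Monte Carlo loop only θ is needed, so phase 2 is
skipped there.

Correctness is anchored two ways: a brute-force oracle that enumerates
convex weight vectors on a simplex grid (upper-bounding the LP and
converging as the grid refines; the test bound of 3× the grid resolution
covers the empirical worst case of ~1.9×), and frontier cohorts with
known truth — frontier DMUs on a strictly convex input-requirement curve,
inefficient DMUs built by dividing a frontier point's inputs by their
intended θ, which input-oriented VRS DEA must recover exactly.
Inefficient DMUs are anchored to interior frontier points because a DMU
at the extreme output level can exit the spanned output range under
perturbation and flip to self-referent efficiency.

## Adequacy interpretation

Raw values are interpreted before DEA sees them. A rule per (care type,
variable) holds an adequacy range `[lo, hi]`, a direction
(`higher_better`, `lower_better`, or `target_band`), a penalty factor
(default 2) and a transform kind. The competence scale was designed so
that the ×2 exit penalty is meaningful: in-range values map linearly onto
[0.5, 1] (oriented by direction; `target_band` peaks at the band centre),
so dividing the boundary competence by 2 places every out-of-range value
at or below every in-range value. Beyond the boundary, competence decays
hyperbolically with distance normalised by the range width
(`penalty_slope`, default 1), floored at 1e-3 so DEA data stay positive.
The `product_sum_gravity` transform defuzzifies labelled triangular or
trapezoidal membership functions by the activation-weighted mean of their
consequent competence levels (with a single antecedent, product
activation reduces to the membership itself).

Orientation for DEA: outputs use competence × 100; inputs use
1 / max(competence, 0.05) so "smaller is better" holds and inputs stay in
[1, 20]. Both preserve the competence ordering, which gives the
end-to-end guarantee (tested) that improving any variable's competence
never lowers a service's deterministic score. Scaled quality scores pass
through uninterpreted by default — they are already on a normalised,
size-aware scale.

The expert panel's actual adequacy ranges are not published, so
`default_knowledge_base` builds a provenance-marked, data-derived
stand-in: the adequate range is the per-care-type interquartile range;
inputs are `higher_better` within range (matching the one published
example, a floating-outreach budget rule on [5000, 6000] with ×2
penalty); occupancy and movers are `higher_better`; length of stay is a
`target_band` on [1, 2] years for time-limited care types (supported
housing, floating outreach, move-on residential — staying well past the
expected two-year tenancy signals a blocked care pathway) and passes
through for non-move-on residential care, where placements are not
time-limited. Findings obtained with this stand-in characterise the
pipeline, not the original expert judgement.

## Monte Carlo engine

Raw record variables (including quality scores) are perturbed with
symmetric triangular noise, mode at the observed value, support ±5%
(`variation=0.05`) — covering plausible imprecision without stress
scenarios. Rates are derived *after* perturbation so correlated rates
inherit coherent noise; integer-valued fields are perturbed continuously
because only rates enter DEA; `occupied ≤ places` is re-imposed; quality
scores are capped at 100. Zeros stay zero (multiplicative support).

Stopping rule: the relative standard error of the mean, sd/(mean·√n),
must fall to 2.5% (`stop_rel_se=0.025`) for *every* service — the
stricter per-DMU reading — checked every 10 simulations from a minimum of
30, with a cap of 500 (`n_max`, mirroring the published run count). Each
(service, iteration) perturbation stream is seeded from
(seed, iteration, attempt, crc32(service_id)), which makes full runs
byte-identical under a fixed seed *and* invariant to the order services
are listed. A failed DEA solve (numerically degenerate draw) is retried
with a fresh draw up to 3 times. Only the data are redrawn per
simulation; the knowledge base is interpreted once.

Note one consequence of per-cell noise: a cohort of *identical* services
scores exactly 1 everywhere in the deterministic sub-case, but under
independent perturbation one copy can dominate another marginally, so
simulated scores are pinned near (not exactly at) 1.

## Scenarios and comparison

Scenario 1 is the technical baseline (3 inputs / 3 outputs above); each
further scenario appends exactly one quality domain as a fourth output —
8 scenarios for residential and supported-housing types, 7 for floating
outreach (no living-environment domain). Per care type, the study runs
every scenario (baseline first), producing a service × scenario matrix of
mean RTE plus an unweighted global-average row.

Quality scenarios are compared to the baseline with a two-sided Wilcoxon
signed-rank test. Pairs are per-service mean RTE values — service-level
pairing matches per-service reporting; simulation-level pairing would
inflate n by the simulation count. Zero differences are dropped; the null
is exact for ≤ 25 remaining pairs and a tie-corrected normal
approximation beyond; all-tied input reports p = 1. No multiple-testing
correction is applied across the 6–7 comparisons (matching the reporting
convention this design follows); a Holm adjustment can be applied
downstream. Per-service impact classes use a documented rule with two
free parameters: |Δmean| must exceed δ = 0.05 *and* the two score samples
must differ on a two-sided Mann–Whitney test at α = 0.05; otherwise
neutral.

## Synthetic cohorts

The generator emulates the published QuEST per-care-type sample
statistics (mean, SD, min, max per variable). Each variable is a
truncated normal on [min, max]; the parent (μ, σ) are *moment-matched* by
least squares so the truncated distribution reproduces the published
mean/SD — plugging them in directly would shift the realised mean
whenever the bounds are asymmetric (for floating-outreach places, by
+17%). Some published pairs are unattainable: move-on residential budget
SD (285k) exceeds the ceiling √((mean−min)(max−mean)) ≈ 277k possible for
*any* distribution on that support, and supported-housing length of stay
has (mean−min)/SD ≈ 0.75 where the truncated-normal family bottoms out at
1; for those the closest family member is used and tests widen the
tolerance by exactly that irreducible gap.

Occupied places are generated as an occupancy fraction times places
(truncated normal on [0, 1], mean from the published occupancy ratio, SD
0.1), which enforces `occupied ≤ places` by construction and sidesteps
the published floating-outreach occupied-places maximum of 6 — a typo,
contradicting its own mean of 28.89; the places ceiling (80) is used
instead. Quality domain scores are truncated normals on [0, 100] with
means in the mid-50s to mid-60s, ordered supported housing > residential
> floating outreach to reflect the published quality ranking; no
per-domain statistics are published, so these are the package's choice.
Variables are independent across fields by default (no covariance
information is published); a rank-correlation option couples budget and
staff to places. Integer fields are rounded and re-clipped.

What passing tests on synthetic cohorts do *not* show: real services have
correlated resources, needs-driven heterogeneity and expert-calibrated
adequacy ranges, so absolute RTE levels and impact-class proportions from
synthetic runs characterise the method's behaviour, not English supported
accommodation itself.

## Problem sizes and defaults

Headline computations use the study's design sizes: 34 services
(supported-housing group) for the full scenario battery, 30 for the
floating-outreach determinism checks, 20-DMU frontier cohorts with true
θ ∈ {0.3, …, 1.0}, 100–300 random instances for solver validation with
grid resolutions 0.01–0.05 adapted to DMU count. Missing values are
imputed by uniform draws from observed same-care-type values (at least 3
observed required). Degenerate inputs: zero movers are legitimate (the
rate is a nonnegative output); occupancy above 100% is rejected at load
unless explicitly capped; a zero-variance adequacy range is widened
symmetrically by 10%.

## Known limitations

- The stand-in knowledge base is data-derived; results are not
  comparable to analyses run with the unpublished expert ranges.
- DEA scores are not bias-corrected (no bootstrap); with few DMUs many
  services tie at θ = 1 and discrimination comes from the Monte Carlo
  layer.
- "Stability/entropy" distribution analytics are not implemented; only
  standard summaries (mean, SD, relative SE, quantiles) are reported.
- Cross-care-type pooled DEA is deliberately unsupported — care types
  are assessed separately as distinct production technologies.
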