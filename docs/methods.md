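# Methods

## Feature model

A record reduces a 12-lead ECG to one signed ST-deviation scalar per lead,
in mm of trace deflection at standard gain (1 mm = 0.1 mV, positive =
elevation), plus sex, QRS duration (ms), conduction flags (LAFB, RBBB,
LBBB, high-degree AV block) and optional labels (culprit group, collateral
territory, in-hospital outcome). Where on the ST segment the deviation is
measured is deliberately *not* part of the feature model: the waveform
layer fixes the convention (below) and upstream data may use any
consistent one. Deviations are validated to |st| ≤ 20 mm and QRS to
[40, 300] ms; LBBB excludes LAFB/RBBB; collateral labels are only legal on
total-LM-occlusion records. Missing optional fields never influence
classification.

ST elevation is lead-wise and sex-specific: ≥ 2.0 mm (men) / ≥ 1.5 mm
(women) in V2–V3, ≥ 1.0 mm elsewhere, inclusive boundary. ST depression
has no universally quoted threshold; the package defaults to the
conventional clinical floor of 0.5 mm (inclusive), configurable per call.

## Pattern taxonomy

`classify_main` is total and deterministic, with a fixed priority that
makes ties impossible:

1. **aVR pattern** — STE set non-empty and contained in {aVR, V1}, with
   aVR elevated;
2. **aVR+aVL pattern** — aVR and aVL both elevated, no STE in V4–V6, and
   the STEMI contiguity rule (below) not met;
3. **STEMI** — STE in ≥ 2 adjacent leads of the chain V1…V6, or ≥ 2 of
   {II, III, aVF}, or (V5 ∨ V6) ∧ (I ∨ aVL);
4. **other NSTEMI** otherwise.

Consequences worth noting: STE confined to {aVR} ∪ {V1} can never be
STEMI; STE in I + aVL alone is *other NSTEMI* (no criterion requires it);
NSTEMI is by construction the complement of STEMI.

`classify_fine` refines this into twelve mutually exclusive lead-set
patterns (first match wins): the four I/aVL-precordial and precordial-only
STEMI variants, the exclusive aVR and aVR+V1 patterns, the three aVR+aVL
family members, inferior STEMI, and two residual classes. One design
choice was genuinely open: the aVR+aVL variant with *partial precordial*
involvement. We recognise it inside the aVR+aVL main pattern when V2 or V3
is either elevated or sub-threshold-elevated (≥ 0.5 mm but below the
sex-specific threshold). Tying the variant to the main pattern keeps the
fine→main projection consistent for every representable record (a
property-tested invariant), and the sub-threshold clause lets the
collateralised presentations whose anterior elevation does not reach
threshold be distinguished from the plain I+aVL+aVR pattern.

Criteria are named pure predicates in a registry. Two row semantics
coexist deliberately: *exclusive* pattern criteria (`avr_isolated`,
`avr_v1` — the whole STE set must match) and *permissive* lead-pair
criteria (`avr_avl` — both leads elevated, anything else allowed). This
split is forced by internal consistency of the study's own counts: the
aVR+aVL row (23 in the LM group) equals the sum of the three fine
aVR+aVL-family patterns (13 + 8 + 2), whereas the aVR row (11) counts only
the exclusive pattern. `i_avl_v2_v5` additionally excludes aVR so that the
two Model-1 components partition its positives — without this exclusion
the combined positive count could not equal the sum of the two rows.
Custom criteria are composable from {STE(lead), NO_STE(lead), FLAG(·),
MAIN(·)} with AND/OR/NOT, e.g. from a YAML config.

Model 1 = `avr_avl ∨ i_avl_v2_v5`; Model 2 = `model1 ∧ lafb` (any RBBB
status), which is exactly the union of the four published component
criteria (each STE criterion with isolated LAFB or LAFB+RBBB). Model 2 ⇒
Model 1 record-wise, hence sens(M2) ≤ sens(M1) and spec(M2) ≥ spec(M1) on
any labeled cohort — property-tested on 1,000 random cohorts.

## Diagnostic statistics

2×2 metrics use Wilson score 95% intervals by default: the study's
boundary operating points (0/89 false positives, 14/84 with 0 FP) make
Wald intervals degenerate while Wilson stays proper. Undefined ratios
(zero denominator) are reported as not-available, never as silent 0/0.
Exact-enumeration coverage of the Wilson interval is ≥ 92% (nominal − 3
points) across the central grid p ∈ {0.1…0.9}, n ∈ {10, 25, 50, 100};
for extreme proportions with very small n (p = 0.05, n = 10) coverage is
known to dip slightly lower (~91.4%), a documented property of the Wilson
construction.

Group tests are Pearson chi-square without continuity correction (the df
is (r−1)(c−1)), falling back to Fisher's exact test for 2×2 tables with
any expected cell < 5, and one-way ANOVA for continuous variables —
matching standard clinical-statistics practice.

The ROC construction uses every distinct observed score as a threshold
with an explicit positivity direction (`score ≥ threshold`; for QRS,
higher favours LM occlusion — no automatic direction inference). The
trapezoidal AUC under this construction equals the tie-corrected
Mann–Whitney pair statistic (ties ½), verified to 1e-12 against a
brute-force pair-counting oracle and against scikit-learn. The Youden
cutoff maximises TPR − FPR with ties broken toward the lower threshold
(maximising sensitivity at equal index); the tie-break matters because a
single printed cutoff cannot adjudicate ties. `binormal_auc` provides the
closed form Φ(Δμ/√(σ₁²+σ₀²)) as an analytic oracle.

Report percentages are rounded half-up to integer percent (the convention
of the source tables); structured reports keep full precision.

## Synthetic cohort

The generator's defaults *are* the study conditions: six groups of sizes
84 (LM occlusion), 89 (LM subtotal), 85 (pLAD), 98 (mLAD), 91 (LCX),
105 (RCA); per-group archetype allocations reproducing every criterion-row
count; conduction allocation (e.g. LM: 31 isolated LAFB — 21 in STEMI,
10 in NSTEMI — 5 isolated RBBB, 14 LAFB+RBBB, 1 LBBB); the LM collateral
split 34 vs 50 with the full pattern × collateral cross-tabulation; QRS
Gaussians per group (LM: per collateral subgroup, 112 ± 25 with and
120 ± 22 without collateral flow), truncated to [40, 300] ms by rejection;
sex and mortality margins per group; ages Gaussian clipped to [18, 100]
(cosmetic).

The published tables pin only margins; the joint allocation
(pattern × conduction × collateral) is under-determined. One feasible
allocation is fixed and versioned in code. Within the constraint system
the free choices were: the two "extra" aVR+aVL records beyond the fine
13 + 8 are realised as I+aVL+aVR with sub-threshold V2–V3 (so the STEMI
count stays 45); STEMI carries 8 of the 14 bifascicular blocks (6 with the
I,aVL,V2–V5 pattern per its own row, 2 with the V1–V5 variant) and the
NSTEMI 6 sit in the aVR+aVL family, 5 of them collateral-positive — the
unique distribution, up to within-family permutation, consistent with all
margins simultaneously. Collateral territories: 15 of 23 aVR+aVL records
fill the LAD territory (65%), 8 of 10 collateral-positive aVR-pattern
records fill both territories; the remaining territory labels (BOTH vs
LCX) are not pinned by any margin and were fixed once. Sex and mortality
are assigned independently of pattern within group (no joint data exists),
by seeded permutation at the margins.

Records are realised from archetypes: elevated leads uniform in
[threshold + 0.2, threshold + 3.0] mm, sub-threshold leads in
[0.5, threshold − 0.3] mm, depressed leads in [−2.5, −0.5] mm, all others
inside a ±0.4 mm guard band (so they can trip neither the elevation nor
the default depression predicate). aVR-pattern archetypes depress 8 leads,
realising the diffuse-depression physiology. Every realised record is
round-tripped through `classify_fine` at generation time; `validate_spec`
checks all 166 encoded marginal identities and generation refuses a spec
that fails any. Sampled mode draws archetype counts multinomially at the
study proportions and converges to them (checked at 20,000 records per
group under a fixed seed, with ~4σ binomial tolerances).

What the generator does *not* emulate: correlations the study never
reports (QRS vs conduction block within group, age/sex vs pattern, ST
magnitude distributions beyond the threshold bands, onset-to-presentation
times). Tests passing on this cohort therefore demonstrate fidelity of the
criteria and statistics to the published counts, not performance on real
ECGs — real-world ST measurement noise, borderline morphologies and
population shift are out of scope.

## Waveform layer

Beats are sums of Gaussian bumps (P, Q, R, S, T) on a flat baseline with a
raised-cosine-edged ST plateau between J and T end; QRS onset→J span
equals the requested QRS duration exactly, and fiducials are returned as
ground truth (this demonstrates the measurement convention, it is not a
delineator). ST is measured as the mean over a ±10 ms window at J + 60 ms
(configurable 40–80 ms) minus the *median* of the PR segment (50–20 ms
before QRS onset) — the median keeps QRS-tail leakage out of the baseline.
Bump widths are chosen so tails contribute < 1e-6 mm to both windows at
default heart rate (60 bpm) and QRS ≤ 140 ms; synthesis refuses
heart-rate/QRS combinations that leave < 250 ms of ST–T room, and accuracy
degrades gracefully toward ~1e-4 mm near that limit. Under 0.05 mm noise
with ≥ 4 beats averaged the round-trip error stays within 0.1 mm (seeded
Monte-Carlo). Waveform-realised versions of every cohort archetype
classify identically to their feature-level counterparts.

## Problem sizes and tolerances

The reconstruction itself is desk-scale (552 records, < 0.1 s). The QRS
ROC acceptance check averages 200 replicate cohorts (mean empirical AUC
0.757–0.762 across seeds, binormal closed form 0.759; tolerance ±0.02).
Convergence checks use 20,000–50,000 draws with explicitly computed
3–4σ tolerances; the AUC/pair-counting identity is exact to 1e-12 up to
n = 500. The monotonicity property is exercised on 1,000 random cohorts of
30 records with dense random STE sets and flags.

## Known limitations

* The fine-pattern taxonomy is tailored to the anterior/aVR presentations
  of LM disease; posterior leads V7–V9 (relevant to LCX posterior STEMI)
  are not represented, so those LCX presentations appear as residual
  STEMI/NSTEMI classes.
* Single-criterion specificities against the subtotal-occlusion group
  depend on reading its rows as exclusive patterns; for control groups
  this reading cannot be fully settled from published text and is applied
  uniformly.
* The evaluation requires an explicit control set; no default comparison
  population is assumed.
* Survival beyond in-hospital mortality is out of scope (no patient-level
  time-to-event data can be reconstructed from group margins).
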