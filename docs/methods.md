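# Methods

## Scoring conventions

**PavCA.** The session index is the arithmetic mean of the probability
differential, response bias and latency score; all three are bounded in
[−1, 1], so the index is too. Conventions the published formulas leave
open, and how this package resolves them:

- *Latency censoring.* Trials without a contact contribute the full CS
  duration (8 s) to the mean first-contact latency. This is what keeps the
  latency score inside [−1, 1]; excluding no-contact trials instead would
  unbound the component for sparse responders.
- *Latency-score parsing.* The formula is implemented as
  (food-cup latency − lever latency) / 8, i.e. the division applies to the
  whole difference — the only reading bounded in [−1, 1] and consistent
  with the index's documented range.
- *Probability.* Fraction of trials with ≥ 1 contact, not a contact rate.
- *Response bias 0/0.* A session with no lever and no food-cup contacts has
  bias 0 (indifference), so an empty session scores index 0.
- *Phenotype boundaries.* The three intervals share endpoints at ±0.5;
  the boundary is assigned to the extreme class (GT iff ≤ −0.5, ST iff
  ≥ +0.5). The choice is measure-zero empirically but must be fixed for
  determinism.
- *CS windows are half-open* [onset, offset): a contact at exactly the
  offset is ITI behavior. ITI food-cup entries are reported but never
  enter the index.
- *Terminal index* is the mean of sessions 4 and 5 only; a subject missing
  either is excluded casewise, never imputed.

**CRF.** During a 3-s presentation further active pokes are counted but do
not queue presentations (FR-1 with lockout), so earned ≤ active pokes and
deflections per reinforcer can exceed 1. Presses per reinforcer is
undefined (missing) for zero-reinforcer subjects, who are excluded
casewise from analyses of that measure only.

**CCP.** Δ-preference is post − pre time on the cocaine floor, so positive
means increased preference; an exact pre-test floor-time tie is broken by
a seeded uniform draw and logged. **CCC** contrasts are all signed
later-day − earlier-day; locomotor "sensitization" (D7−D3) is therefore
negative when stereotypy replaces forward locomotion. Subjects missing any
of days 1–8 are flagged incomplete and excluded from all contrasts.

## Statistical battery

**Mixed RM-ANOVA.** Univariate mixed-design ANOVA with Type III sums of
squares under sum-to-zero contrasts (between-group sizes are unbalanced by
construction: phenotype groups never come out equal). Each subject's
within-cell vector is projected onto orthonormal Helmert contrast
subspaces, one per within-factor combination; a between-subjects Type III
regression on each projected score reproduces the classical summation
formulas exactly on balanced designs (verified against a brute-force
oracle to 1e-8) and generalizes them to unbalanced groups. Error strata
are conventional: subjects-within-groups for between terms, subject × w
within groups for any term involving within combination w. No sphericity
correction is applied (plain univariate F, integer df). η² is classical
(SS_term / SS_total); partial η² is also reported. Subjects with any
missing within cell are excluded casewise and counted.

**Tukey HSD** uses the studentized-range distribution with the
Tukey-Kramer standard error, taking the error mean square and df from
whichever ANOVA stratum matches the probed term.

**PCA.** Eigendecomposition of the correlation matrix of complete cases;
components with eigenvalue ≥ 1 are retained; loadings are rotated by
Kaiser-normalized varimax and flagged salient at |loading| > 0.7. The
rotation uses classical pairwise planar (Jacobi-style) rotations with the
closed-form optimal angle per factor pair, sweeping until the relative
criterion change falls below 1e-6 (cap 500 sweeps). The SVD-based
alternating algorithm was rejected: it crawls near the symmetric
two-block configuration that PavCA/cocaine data produce (the unrotated
components mix the two blocks at ~45°, where its gradient step nearly
vanishes), while the closed-form pairwise angle jumps straight to the
optimum. Communalities are invariant under the rotation to 1e-8 and the
solution beats 1000 random orthogonal rotations on the criterion (both
tested). Factors are sign-oriented so each factor's largest-magnitude
loading is positive.

## Synthetic cohort generator

Two standardized latent traits per subject, (incentive salience θ_IS,
cocaine responsivity θ_CR), bivariate normal with correlation ρ
(default 0 — the independence null the analyses are designed to probe).
Females get θ_IS shifted by +0.4 SD (more lever-directed) and a ×1.35
cocaine-locomotion multiplier. Defaults follow the study schedules:
5 × 25 PavCA trials, 8-s CS, VI-90 ITIs uniform on 30–150 s (hence mean
cumulative ITI time 25 × 90 s = 37.5 min per session), 40-min CRF with 3-s
presentations, 4-trial CCP at 10 mg/kg, 8-day CCC at 15 mg/kg.

Distributional choices are generator conveniences, exposed in
`CohortConfig` and not claimed to be empirical: logistic contact
probability in session-scaled θ_IS (session ramp s/5 makes session 1
near-indifferent and sessions 4–5 trait-saturated), 1 + Poisson contact
counts, truncated-exponential latencies, log-normal locomotion baselines
with multiplicative log-normal noise, Poisson headwave bouts. CRF presses
per reinforcer track the cohort-standardized realized terminal index with
target variance explained `crf_coupling` (default 0.43, the midpoint of
the published 0.38–0.48 male/female band; realized r² at n = 1500 lands
inside the band). The CCP pre-test bias magnitude grows as θ_IS falls,
which reproduces the counter-conditioning artifact: goal-trackers bias
hardest against the future cocaine floor and therefore show the largest
Δ-preference after regression toward the mean, even though conditioning
gain itself is driven by θ_CR.

What the generator does *not* emulate: pharmacokinetics, within-session
time courses, inter-site/apparatus differences, litter or batch structure,
age covariates, and any non-monotone trait-behavior mapping. Passing tests
therefore demonstrate that the pipeline recovers the encoded structure
(independence at ρ = 0, coupling at ρ > 0, the block-structured PCA), not
that real cohorts obey this latent model.

Determinism: every component draws from an independent child stream of
`master_seed` (numpy `SeedSequence.spawn`), so identical seeds give
byte-identical outputs; event times are quantized to milliseconds, the
precision of the CSV dialect.

## Problem sizes used in validation

Cohort-level checks run at n = 1500 subjects (null independence and PCA
block structure across 20 seeds; CRF coupling; ρ = 0.6 recovery), chosen
to match the scale at which the published variance bands are stated while
keeping a full cohort simulation at a few seconds. Confidence-interval
coverage of the null correlation uses 50 replicate cohorts of n = 100 with
sex effects disabled so the true correlation is exactly zero. The
parameter-recovery oracle for ρ = 0.6 uses the exact factorization
r(index, locomotion) = r(index, g) · r(locomotion, g) with
g = exp(slope · θ_CR), valid because locomotion noise is multiplicative
and independent of the index channel.

## Known limitations

- The ANOVA supports fully-crossed within designs with complete cells per
  subject (casewise exclusion otherwise); no mixed-effects (REML) or
  multivariate (Pillai/Wilks) alternatives, and no sphericity correction.
- Tukey probes assume the pooled error stratum supplied to them; no
  Games-Howell fallback for heteroscedastic groups.
- PCA reports loadings only; no factor-score estimation.
- The event dialect is the package's own long-format CSV; native
  acquisition-system output (e.g. Med-PC raw arrays) must be converted
  upstream, and video-tracking extraction of distance/headwaves is out of
  scope — the CCP/CCC tables consume derived measures.
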