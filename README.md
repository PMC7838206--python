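# cuetraits

Scoring and statistics for addiction-related behavioral phenotyping in
outbred rats: Pavlovian conditioned approach (sign- vs goal-tracking),
conditioned reinforcement, cocaine conditioned cue preference, and cocaine
contextual conditioning — plus a synthetic cohort generator that makes the
whole pipeline testable end to end without animal data.

## Who this is for

Behavioral-phenomics groups that run large Pavlovian-conditioned-approach
(PavCA) screens and want a reproducible, validated implementation of the
standard scoring conventions and the statistical battery commonly applied
to them (mixed repeated-measures ANOVA with η², Tukey HSD probes,
per-sex correlation panels, varimax-rotated PCA).

## The measures

**PavCA index.** An 8-s lever insertion (CS) precedes response-independent
pellet delivery, 25 trials/session over 5 sessions. Per session the index
is the mean of three components, each in [−1, 1]:

- probability differential: `P(lever contact) − P(food-cup contact)` per trial;
- response bias: `(lever contacts − food-cup contacts) / (lever + food-cup contacts)`;
- latency score: `(food-cup latency − lever latency) / 8`, with per-trial
  first-contact latencies censored at the 8-s CS duration.

The terminal index is the mean of sessions 4–5; subjects are goal-trackers
(GT) at ≤ −0.5, sign-trackers (ST) at ≥ +0.5, intermediates (IN) between.

**Conditioned reinforcement (CRF).** Nosepokes into an active port earn 3-s
lever presentations (FR-1 with lockout). Scores: active/inactive pokes,
earned reinforcers, lever deflections, presses per reinforcer, and the
Incentive Value Index `(active − inactive) + lever deflections`.

**Cocaine conditioned cue preference (CCP).** Counter-conditioned floor
assignment (cocaine pairs with the less-preferred pre-test floor, 10 mg/kg,
4 cocaine/saline trial pairs); Δ-preference = post-test − pre-test time on
the cocaine floor, plus per-trial locomotion and trial-4 − trial-1
sensitization.

**Cocaine contextual conditioning (CCC).** 8-day schedule (day 1
habituation, day 2 saline baseline, days 3–7 cocaine at 15 mg/kg, day 8
drug-free probe); signed later-minus-earlier contrasts for distance and
headwave bouts: acute (D3−D2), sensitization (D7−D3), conditioned
locomotion (D2→D8).

The synthetic generator draws two standardized latent traits per subject —
incentive salience and cocaine responsivity — as a bivariate normal with
configurable correlation ρ (default 0, the independence null), with a
female shift toward lever-directed behavior and a female cocaine-locomotion
multiplier, and emits trial-level event streams and session tables in the
package's documented CSV dialects.

## Worked example

```sh
traits simulate --out sim --n 200 --seed 7
traits score --events sim/events.csv --ccp sim/ccp.csv --ccc sim/ccc.csv --out scored
traits stats --traits scored/traits.csv --sessions scored/pavca_sessions.csv --out stats
```

With this seed the cohort splits into 80 IN, 69 ST and 51 GT, with females
more lever-directed (mean terminal index 0.142 vs 0.008 in males). The
per-sex correlation panel in `stats/results.json` shows the terminal index
sharing about 38–49% of variance with CRF presses per reinforcer
(r² = 0.489 in females, 0.375 in males, n = 100 each) while being unrelated
to trial-4 cocaine locomotion (r² = 0.003 and 0.008). The varimax PCA
retains two components (eigenvalues 1.90, 1.63 of five) with the incentive
measures loading 0.91 on one factor, cocaine locomotion 0.93–0.94 on the
other, and Δ-preference salient on neither — the block structure expected
when the two traits are independent:

```
                          F1     F2
terminal_index         -0.01   0.91
presses_per_reinforcer  0.01   0.91
cocaine_dist_t1_mm      0.93   0.04
cocaine_dist_t4_mm      0.94   0.07
delta_preference_s      0.33  -0.04
```

The ANOVA tables report F, df, p and classical η² per term, e.g. for lever
contact probability the Phenotype main effect dominates
(F(2, 194) = 637.6, η² = 0.70) with a Session × Phenotype interaction
(F(8, 776) = 93.3, η² = 0.08).

## Layout

- `cuetraits.events_io` — CSV dialects, validation, manifests
- `cuetraits.pavca`, `.crf`, `.cocaine` — task scoring
- `cuetraits.stats` — mixed RM-ANOVA, Tukey HSD, correlations, varimax PCA
- `cuetraits.simulate` — latent-trait cohort generator
- `cuetraits.pipeline` / `cuetraits.cli` — orchestration and the `traits` CLI

See `docs/methods.md` for the model, numerical conventions and limitations.
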