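# sleepreg

Wrist-actigraphy sleep/wake scoring, the **Sleep Regularity Index (SRI)**, and
the cohort statistics that typically accompany it in two-group observational
sleep studies (for example stroke survivors vs healthy controls).

The package is aimed at researchers who have per-epoch activity-count exports
(30-s epochs), sleep diaries and participant metadata, and want a transparent,
scriptable route from raw counts to cohort-level inference — plus a synthetic
cohort generator with known ground truth so every stage can be validated
without access to patient data.

## What it computes

**Sleep/wake scoring.** Each worn epoch gets a score
`D_t = s * sum_k w_k a_{t+k}` over a weighted window of neighbouring activity
counts `a` (scale factor `s = 0.10` by default); `D_t < 1` classifies the
epoch as sleep. Webster's rescoring rules then correct actigraphy's low
specificity: after ≥ 4/10/15 min of wake the next 1/3/4 min of scored sleep
are rescored wake, and sleep runs of ≤ 6/10 min flanked by ≥ 10/20-min wake
runs become wake. Tap weights and rules are configuration, not code.

**Sleep Regularity Index.** For `N` days of `M` daily epochs with sleep
indicator `s_{i,j}`,

```
SRI = -100 + 200 / (M (N-1)) * sum_{j=1..M} sum_{i=1..N-1} delta(s_{i,j}, s_{i+1,j})
```

where `delta = 1` when the state 24 h later is unchanged. SRI is 100 for a
perfectly repeating pattern and ~0 for random ones. Recordings need ≥ 5 full
midnight-to-midnight days, ≤ 2 h of missing data, and (ideally) a weekend day;
failing recordings are excluded with logged reasons. Cohort quintiles label
Regular / Irregular sleepers.

**Night metrics.** TST, WASO, sleep efficiency, fragmentation index and
average sleep per 24 h, from diary-guided nocturnal sleep periods.

**Cohort statistics.** Welch t and chi-square demographics, OLS of
`SRI ~ group + age + sex` with Wald-t CIs and standardized betas,
age/sex-adjusted partial Pearson correlations with Bonferroni control, Fisher
r-to-z group comparisons, permutation subsampling of the larger arm, and a
noncentral-F sensitivity power analysis (smallest detectable Cohen's f).

## Worked example

```python
import pandas as pd
from sleepreg import SimulationSpec, simulate_cohort, run_cohort, analyze_cohort

spec = SimulationSpec(seed=11)          # 162 stroke / 60 control, 7 days, 30-s epochs
cohort = simulate_cohort(spec)          # activity counts, diaries, covariates
results, exclusions = run_cohort([(s, d) for s, d, _ in cohort.participants])

meta = pd.DataFrame({
    "participant_id": [r.participant_id for r in cohort.records],
    "group": [r.group for r in cohort.records],
    "age": [r.age for r in cohort.records],
    "sex_female": [int(r.is_female) for r in cohort.records],
    "sci": [r.sci for r in cohort.records],
})
df = results.merge(meta, on="participant_id")
analysis = analyze_cohort(df[df["valid"]], n_perm=200, seed=11)
```

which prints (via the fields of `analysis`):

```
included 220 of 222 participants
SRI mean (stroke)  : 42.58 +/- 14.28
SRI mean (control) : 52.44 +/- 14.18
OLS group effect   : beta = -8.90, 95% CI [-13.03, -4.76], p = 0.0000
model R^2          : 0.159
SRI~SCI partial r (stroke): 0.15 (p = 0.0755, n = 152)
permutation subsampling   : mean beta = -8.82, 100% of refits p<0.05
sensitivity power analysis: f = 0.1897 at n = 220
```

Two recordings failed validity screening and were excluded with logged
reasons. The stroke arm is about 6–9 SRI units less regular than controls
(the generator injects a −6 group effect on the SRI scale; any one cohort
realizes it with sampling noise), the group model explains a small share of
the SRI variance, and the permutation subsampling of the stroke arm confirms
the contrast is not an artefact of unequal group sizes.

The same flow is available from a shell:

```sh
sri simulate --config cfg.yaml --out cohort/
sri regularity --in cohort/ --out results.csv --exclusions excl.csv
sri stats --results results.csv --meta cohort/metadata.csv --out stats/
```

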