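# cogreserve

Simulation and multimodal prediction tools for the study of **cognitive
reserve** — the observation that some people's cognition is markedly better
than a standard clinical brain measure would predict.

The package is aimed at researchers in cognitive ageing and brain-health
epidemiology who want to (a) reason precisely about *reserve* versus
*maintenance* accounts of between-person differences across the lifespan,
and (b) quantify how much additional variance in a cognitive score is
explained by each further brain modality, relative to the ceiling set by the
score's measurement reliability.

## What it implements

**Lifespan trajectory model.** Individual *i*'s brain property *p* follows
`y_ip(a) = I_ip + S_ip (a − a0)`: intercepts `I` encode reserve (stable
offsets), slopes `S` encode maintenance (rates of decline), and slopes are
correlated across properties (default 0.5). Cognition is a weighted average
of the properties (default: the simple average of two). The clinical,
residual notion of cognitive reserve is the residual of OLS-regressing
cognition on one measured property — which, by construction, tracks the
unmeasured property.

**Stacked nested-CV prediction.** For feature blocks `con` (confounds),
`GMV` (grey-matter volume, 98 features), `WMI` (white-matter integrity, 48)
and `rFC` (functional connectivity, 153 = 17·18/2 network pairs), a linear
model with combined L1+L2 (elastic-net) penalty is fit in 10-fold nested
cross-validation (5 inner folds select the penalty); block predictions are
stacked by cross-fitted nonnegative least squares; the whole procedure is
repeated over 20 re-randomized fold assignments. The output is the
cumulative out-of-sample R² staircase

`R²(con) → R²(con+GMV) → R²(con+GMV+WMI) → R²(con+GMV+WMI+rFC)`

with across-repeat spread, a descriptive paired Wilcoxon p-value per
increment, and a noise ceiling of `100·r` percent for target reliability
`r`.

**Synthetic multimodal generator.** Because cohort data of this kind are
access-controlled, the pipeline is validated by parameter recovery on a
generator with known ground truth: latent-factor feature blocks, an
age-driven latent shared across brain modalities, per-block unique target
shares, and target noise calibrated so the simulated test-retest
reliability — hence the ceiling — is exact. `oracle_r2` gives the
closed-form explainable variance of any block subset. Defaults (N = 586,
shares 0.11/0.31/0.06/0.04, reliability 0.56) produce an illustrative
staircase of 11/42/48/52% under a 56% ceiling.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Generate the default synthetic cohort, run the full staircase, and compare
with the generator's closed-form oracle:

```sh
cogreserve recover --seed 0 --out demo
cat demo/partition.tsv
```

```text
block_set        r2_mean_pct  r2_sd_pct  increment_pct  increment_p  ceiling_pct
con                     10.3       0.56                              56.0
con+GMV                 42.9       0.57           32.7  9.54e-07     56.0
con+GMV+WMI             45.7       0.74            2.8  9.54e-07     56.0
con+GMV+WMI+rFC         50.2       1.01            4.5  9.54e-07     56.0
```

Reading this: confounds alone explain 10.3% of variance in the
fluid-intelligence-like score; stacking grey-matter predictions raises this
to 42.9%; white-matter and connectivity blocks add a further 2.8 and 4.5
points — each increment supported by all 20 paired repeats (exact one-sided
signed-rank p = 2⁻²⁰ ≈ 9.5e-07, descriptive) — approaching but not
exceeding the 56% reliability ceiling. The run's `manifest.json` records
the closed-form oracle for each prefix (11/42/48/52%) and each bar's
recovery error (here at most 2.3 points, within single-realisation
sampling error at N = 586); `reserve_scores.csv` holds each subject's
residual reserve score relative to the grey-matter prediction.

The same pipeline runs on real CSV feature tables:

```sh
cogreserve partition --target y.csv \
    --block con=con.csv --block GMV=gmv.csv --block WMI=wmi.csv --block rFC=rfc.csv \
    --order con,GMV,WMI,rFC --reliability 0.56 --repeats 20 --folds 10 \
    --seed 1 --out results
```

Tables are CSV with a header and a leading `subject_id` column; blocks are
aligned to the target by id, never by row order.

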