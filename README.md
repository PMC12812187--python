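# strokecea

Decision-analytic cost-effectiveness and value-of-information model for
prophylactic prevention of infections and fever in elderly patients with
acute stroke.

## The problem

Infections and fever are frequent complications in the first days after
stroke and are associated with worse functional outcome. A 2x2x2
factorial trial in patients aged 66+ with moderate-to-severe stroke
compared standard of care (SoC) against metoclopramide (Met),
ceftriaxone (Cef), paracetamol (Par) and all their combinations — eight
mutually exclusive strategies whose effects are summarized by the
distribution of the modified Rankin Scale (mRS, 0 = no symptoms … 6 =
death) at 90 days. This package turns those 90-day distributions into
lifetime economics from a Dutch health-care payer perspective (2024
euros): long-term survival, quality-adjusted life-years (QALYs), costs,
and the expected value of collecting further evidence.

The model has two parts:

* a **decision tree** for the 90-day acute phase — each strategy sends
  the cohort into the seven mRS states, which determine acute care costs
  (hospital / rehabilitation / nursing home / home days, procedures,
  follow-up) and 90-day QALYs;
* a **weekly-cycle cohort state-transition model** for up to 20 years
  (maximum age 100) — patients in mRS 0–5 face other-cause mortality
  (age-specific life-table hazard times mRS-specific hazard ratios) and
  recurrent stroke (a calibrated Weibull hazard, decreasing over time,
  adjusted by mRS group and normalized on the SoC case mix); recurrence
  redistributes patients over same-or-worse states using the SoC 90-day
  distribution.

Decisions use net monetary benefit, `NMB = QALY x lambda − Cost`, at
willingness-to-pay thresholds lambda of 20,000 / 50,000 / 80,000
euro/QALY (the Dutch proportional-shortfall bands). On top of the
deterministic model sit:

* **PSA** — 10,000-draw probabilistic sensitivity analysis (Dirichlet
  mRS vectors, gamma costs and stays, beta utilities, lognormal hazard
  ratios), with cost-effectiveness acceptability curves and frontier;
* **VOI** — EVPI; per-parameter-group EVPPI by nonparametric regression;
  EVSI for a new 8-arm mRS trial at sample sizes 160–4,000 via
  regression on conjugate posterior-mean summaries; asymptotic
  interpolation of EVSI(n); population scaling (1,291 eligible
  patients/month) and the expected net benefit of sampling (ENBS) with
  the optimal sample size.

A synthetic patient-level trial generator (with the trial's observed
missingness rates), a chained single-imputation routine, and a parameter
re-estimator round out the pipeline.

## Worked example

```python
import strokecea as sc

params = sc.load_parameters()            # bundled defaults (2024 euros)
res = sc.run_psa(params, n_draws=10_000, seed=1)
print(res.summary().round(2))
ce = res.ce_result()
print("frontier:", ce.frontier)
print("EVPI @ 50k:", round(sc.evpi(res.nmb_matrix(50_000))))
```

Output:

```
   strategy       cost  cost_se  qalys  qalys_se  undisc_qalys
        SoC  131893.26   118.25   2.11      0.00          2.25
        Par  140003.20   122.06   2.09      0.00          2.22
        Cef  137335.84   119.87   2.32      0.00          2.47
    Cef-Par  127463.20   115.22   1.90      0.00          2.02
        Met  127603.23   106.01   2.16      0.00          2.30
    Met-Par  135124.14   115.48   2.26      0.00          2.40
    Met-Cef  131800.78   108.24   2.26      0.00          2.40
Met-Cef-Par  125597.81   107.46   2.20      0.00          2.35
frontier: ['Met-Cef-Par', 'Cef']
EVPI @ 50k: 7122
```

Reading: triple therapy (Met-Cef-Par) has the lowest expected discounted
cost and saves about 6,300 euros per patient versus standard care while
adding about 0.10 QALYs, so it dominates SoC; ceftriaxone monotherapy is
the most effective option (+0.21 QALYs vs SoC) and is the only other
strategy on the efficiency frontier, at an incremental cost-effectiveness
ratio near 100,000 euro/QALY. The EVPI says resolving all parameter
uncertainty would be worth about 7,100 euros per future patient at a
50,000 euro/QALY threshold — the bulk of it attributable to the 90-day
mRS distributions, which is what motivates the EVSI/ENBS analysis of a
new mRS trial (`strokecea run-voi`).

The same analyses are available from the command line:

```bash
strokecea run-cea --seed 1 --draws 10000 --out-dir results/cea
strokecea run-psa --seed 1 --draws 10000 --out-dir results/psa
strokecea run-voi --seed 1 --draws 10000 --out-dir results/voi
strokecea simulate-trial --n-per-arm 187 --seed 1 --out-dir results/trial
strokecea estimate --trial results/trial/trial.csv --out-dir results/trial
```

Every command writes CSV tables plus a JSON manifest; `--scenario
equal_discount_3_5` switches both discount rates to 3.5%, and partial
YAML configs passed via `--config` override any bundled default.

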