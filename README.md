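# neoscore

Risk scoring for **severe neurodevelopmental impairment in very preterm
infants** (born at ≤ 30 weeks gestation), combining a weighted
term-equivalent-age MRI injury score with clinical-course covariates in
logistic risk models.

The package is aimed at researchers in neonatal neurology and clinical
biostatistics who want to study, stress-test, or extend this class of
prediction model. Because the underlying patient-level data are not public,
the package ships a seeded synthetic-cohort generator that reproduces the
published group-conditional summary statistics, so every analysis runs
end-to-end with no data download.

## The model

An infant's MRI is read in three injury domains, each contributing integer
points:

| Domain | Level | Points |
|---|---|---|
| Intraventricular hemorrhage (Papile) | grade III/IV | 5 |
| | grade I/II | 2 |
| White matter injury | multiple punctate (>2 lesions) or cystic | 5 |
| | isolated punctate (≤2 lesions) | 2 |
| Cerebellar hemorrhage | >50% of a hemisphere | 3 |
| | punctate/small (<50%) | 1 |
| | bilateral (bonus) | +1 |

The total score S ∈ [0, 14]; a subject is score-positive when S > 8. The
outcome is *severe impairment*: any Bayley-III composite (cognitive, motor,
language) ≤ 70 at 18–24 months corrected age, i.e. more than 2 SD below the
population mean.

Risk models are maximum-likelihood logistic regressions
P(severe) = expit(β₀ + xᵀβ):

* **full** — eight clinical covariates (gestational age, birth weight,
  antenatal steroids, 5-min Apgar, postnatal steroids, ventilator days,
  inotropes, severe ROP);
* **slim** — the parsimonious set from backwards stepwise selection on AIC
  (ventilator days, delivery mode, antenatal steroids, severe ROP);
* **composite** — slim + the MRI score S.

Discrimination is compared with the paired DeLong test for correlated ROC
curves; collinearity is screened with variance inflation factors (VIF > 5
flags trouble). The integer weights themselves can be re-learned with the
greedy one-feature-at-a-time escalation procedure in
`neoscore.weight_search` (see `docs/methods.md` for its semantics and
caveats).

## Worked example

```python
from neoscore import InjuryProfile, classify_by_threshold, final_weights, score_injury

profile = InjuryProfile(ivh_grade="IV", ch_size="small", wmi_lesion_count=3)
score = score_injury(profile, final_weights())
print(score, classify_by_threshold(score, 8))
```

prints `11 True`: grade IV IVH (5) + small cerebellar hemorrhage (1) +
multiple punctate WMI (5) = 11 points, above the >8 decision threshold, so
the score predicts severe impairment.

Fitting and comparing models on a synthetic cohort
(`python examples/fit_and_compare_models.py`):

```
slim clinical model : AUC 0.884  AIC 120.6  Nagelkerke R2 0.453
composite model     : AUC 0.919  AIC 87.0  Nagelkerke R2 0.673
DeLong test         : dAUC +0.034, p = 0.4349
composite @ p>0.5   : sens 0.74  spec 0.98  PPV 0.93  NPV 0.93
```

Adding the MRI score raises the in-sample AUC and sharply lowers AIC; at
this cohort size (154) the paired DeLong difference is not significant on
this seed — a useful reminder of how much sampling noise a single cohort of
this size carries. Each script in `examples/` demonstrates one capability
(scoring, cohort simulation and description, model comparison, weight
learning) and prints a short interpretation.

A command-line interface wraps the same functions:

```bash
neoscore simulate --n 154 --seed 7 --out cohort.csv
neoscore fit --cohort cohort.csv --model composite --out model.json
neoscore predict --model model.json --subject subject.json
neoscore report --cohort cohort.csv --markdown
```

`predict` emits the probability of severe impairment with a delta-method
standard error — the calculator functionality for one infant.

## Layout

- `src/neoscore/scoring.py` — injury profiles, weight tables, the score
- `src/neoscore/cohort.py` — cohort data model, CSV I/O, outcome labeling
- `src/neoscore/weight_search.py` — greedy integer weight escalation
- `src/neoscore/risk_models.py` — IRLS logistic fits, stepwise AIC, VIF, prediction
- `src/neoscore/evaluation.py` — ROC/AUC, DeLong, Fisher, Mann-Whitney, cohort report
- `src/neoscore/simulate.py` — synthetic cohort generators
- `src/neoscore/cli.py` — the command-line interface
- `docs/methods.md` — modeling assumptions, numerical choices, limitations
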