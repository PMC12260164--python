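# txlearn

Transformer X-learner for estimating individual and average treatment
effects of drug exposures on a rare 180-day binary outcome from
longitudinal prescription and admission code sequences.

## Who this is for

Pharmacoepidemiologists and methods researchers who want to estimate
heterogeneous treatment effects from routinely collected dispensing
(BNF-coded) and hospital-admission (ICD-10-coded) records — the setting
where structured clinical variables are scarce but medication and
admission streams are complete. The worked example is antihypertensive
exposure (ACE inhibitors, beta-blockers, calcium-channel blockers,
thiazides, statins) and 180-day incident COVID-19 risk across two
pandemic waves. Because such linked health records cannot be
redistributed, the package ships a synthetic-cohort simulator with known
ground truth so that every stage — cohort rules, sequence encoding, the
transformer risk models, the X-learner, and the evaluation statistics —
is testable end to end.

## The model

A transformer encoder reads each patient's 180-day lookback event
stream (tokenised BNF/ICD-10 codes with positional and day-offset
embeddings, padding-masked attention, masked mean pooling) together
with static covariates (age, sex, SIMD deprivation decile, diabetes)
and predicts the 180-day outcome probability. This risk model is the
base learner of an X-learner:

1. fit outcome surfaces μ₀ on controls and μ₁ on treated;
2. impute individual effects D¹ᵢ = Yᵢ − μ₀(xᵢ) (treated),
   D⁰ⱼ = μ₁(xⱼ) − Yⱼ (controls);
3. regress the imputations to effect surfaces τ₁, τ₀, fit a propensity
   g(x), and combine τ̂(x) = g(x)·τ₀(x) + (1 − g(x))·τ₁(x).

τ̂ is a per-patient risk difference (ITE); its population mean is the
ATE. Cohorts are built with the design's rules: age ≥ 40, complete
demographics, exposure = ≥1 dispensing with the class's BNF prefix in
the lookback window, composite earliest-of outcome, and stratified
undersampling of wave-1 negatives at the wave-1/wave-2 case ratio, the
removed negatives forming the second-wave cohort.

The transformer and the LSTM baseline run on a small, finite-difference-
verified numpy autodiff engine (`txlearn.nn`); logistic and
gradient-boosted baselines use scikit-learn and xgboost. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from txlearn.cohort import filter_eligible, label_wave
from txlearn.encoding import StaticScaler, build_vocabulary, encode_cohort
from txlearn.models import make_risk_model
from txlearn.records import STUDY_DRUGS, WAVE1
from txlearn.simulate import constant_effect_scenario, simulate_cohort
from txlearn.validation import DESK_TRANSFORMER
from txlearn.xlearner import XLearnerConfig, estimate_ate, estimate_ite, fit_xlearner

# a cohort where beta-blockers truly reduce 180-day risk by 10 points
patients, truths = simulate_cohort(constant_effect_scenario(20000, seed=1, tau=-0.10))
eligible, _ = filter_eligible(patients, WAVE1.lookback_start)
bb = STUDY_DRUGS[1]
labeled = label_wave(eligible, WAVE1, (bb,))
y = np.array([lp.y for lp in labeled])
t = np.array([lp.exposure["BB"] for lp in labeled])

vocab = build_vocabulary(labeled, wave=WAVE1)
scaler = StaticScaler().fit(labeled)
enc = encode_cohort(labeled, WAVE1, vocab, 32, scaler,
                    exclude_prefixes=bb.bnf_prefixes)  # leakage guard

xl = fit_xlearner(
    enc, t, y,
    lambda: make_risk_model("transformer", seed=1, **DESK_TRANSFORMER),
    XLearnerConfig(seed=1), drug="BB",
)
ate = estimate_ate(estimate_ite(xl, enc))
print(f"ATE {ate.ate:+.3f} (sd {ate.sd:.3f}, median {ate.median:+.3f}, n={ate.n})")
```

Output (a few minutes on one CPU):

```
ATE -0.085 (sd 0.043, median -0.090, n=20000)
```

The estimated average risk difference, −0.085, recovers the simulated
−0.10 within the sampling and model error of a 20,000-patient cohort;
the SD describes the spread of the per-patient τ̂ distribution.

The same pipeline is scriptable from the shell:

```bash
txlearn simulate --out run/sim --scenario null --n 5000 --seed 1
txlearn build-cohort --in run/sim --out run/sim --single-wave --seed 1
txlearn causal --in run/sim --out run/causal --model transformer --seed 1
txlearn compare --in run/causal --out run/compare --reference ACEI
```

producing `cohort.csv`, `ite.csv`, `ate.csv` and `comparisons.csv` with
a manifest of config hashes and file checksums per step.

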