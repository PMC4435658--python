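# tvcm — time-varying coefficient models for surveillance data

Behaviour risk factor surveillance (BRFS) systems such as Italy's PASSI
interview a fresh random sample of residents every month, producing large
repeated cross-sections with no longitudinal linkage.  Classical trend
analysis asks whether an outcome (say, smoking prevalence) moves over
time; the more interesting epidemiological question is whether the
*associations* move — is the excess smoking risk of young adults, or of
non-drinkers relative to high-risk drinkers, changing?

`tvcm` answers that question with generalized **varying coefficient
models** (VCM) estimated by P-splines.  For a binary outcome Y with
covariates Z and time modifier t,

```
logit P(Y=1) = b0 + Σj bj Zj + a0(t) + Σj Xj aj(t)
```

where the `bj` are constant log-odds ratios and each `aj(t)` is a smooth
function of calendar time represented by a cubic B-spline basis with a
second-order difference penalty on adjacent spline coefficients
(a P-spline).  Estimation maximizes the penalized log-likelihood
`l(γ) − ½ Σj λj ‖Δ² γj‖²` by penalized iteratively reweighted least
squares (Fisher scoring); the smoothing parameters λj are chosen by GCV
(default) or an approximate REML criterion.  Whether a coefficient really
varies is decided by a two-stage procedure: a screening likelihood-ratio
test of each one-varying-term model against the all-constant logistic
model, then forward selection ordered by the deviance explained on the
previous model's residuals.  Results are reported as odds-ratio-over-time
curves `OR(t) = exp(bj + aj(t))` with Bayesian credible bands.

Because real PASSI records are not public, the package ships a synthetic
surveillance generator (`tvcm.synthetic`) that emulates the design —
independent monthly samples, categorical covariates with the published
marginal distributions, and a logistic outcome with known constant and
time-varying effects — so every stage of the pipeline can be validated
against ground truth.

## Worked example

```python
import tvcm
from tvcm import (BasisSpec, TermSpec, VCMSpec,
                  screen_varying, forward_select, or_curve)
from tvcm.synthetic import preset, generate, true_or_curve

cfg = preset("bench-small", monthly_n=150)     # 4 covariates, 55 waves
data = generate(cfg, seed=7)                   # 8,250 respondents

spec = VCMSpec(
    response="smoker", family="binomial",
    terms=tuple(TermSpec(c.name, "constant", c.reference)
                for c in cfg.covariates),
    modifier="wave",
    basis=BasisSpec(n_basis=12, degree=3, domain=(1.0, 55.0)),
    penalty_order=2)

screened = screen_varying(data, spec)
fit, trace = forward_select(data, spec, screened)
print(fit.model_id())                          # LM + s(t):age3 + s(t):alcohol

curve = or_curve(fit, "age3", "18-39")
```

Output for this seed:

```
final model: LM + s(t):age3 + s(t):alcohol
AIC 9365.5  edf 16.12
OR(18-39 vs 60-69): wave 1 2.76 (2.22-3.44) -> wave 55 1.52 (1.20-1.92)
truth             : wave 1 2.84 -> wave 55 1.41
OR(non-drinker)   : wave 1 0.59 (0.48-0.73) -> wave 55 0.29 (0.23-0.37)
truth             : wave 1 0.58 -> wave 55 0.32
```

The procedure recovers exactly the two truly varying variables; the
odds ratio of the young age band declines from ~2.8 to ~1.5 across the
55 months and the fitted curve tracks the generating truth within its
95% band.

The same pipeline is available from the shell:

```sh
tvcm simulate --preset passi-like --monthly-n 200 --seed 7 --out data.csv
tvcm run run.yaml          # screening CSV, selection trace, summary, OR curves
tvcm orplot run.yaml --variable alcohol --level Non-drinker --out nd.csv
```

Exit codes: 0 success, 2 schema/config error, 3 convergence error,
4 selection error.

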