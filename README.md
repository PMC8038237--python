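# tiltam — tilted additive models

`tiltam` fits semiparametric additive regression models for continuous
outcomes in which the smooth terms are **tilted local-linear kernel
smoothers**. It was built for epidemiological settings like the one that
motivated it — modelling the fraction of the ocular surface occupied by
blood vessels (AOV) in diabetic patients as a function of clinical
covariates — where some predictors act linearly, some are factors, and
others (body-mass index, hemoglobin A1C, daily urinary protein excretion,
blood urea nitrogen) bend the outcome in ways a linear model cannot see.

## The model

With outcome Y and predictors X_1..X_p,

    Y = α + f_1(X_1) + ⋯ + f_p(X_p) + ε,   ε ~ N(0, σ²),

fitted by backfitting. Each smooth f_j is a local-linear smoother whose
observation weights 1/n are replaced by tilting weights p on the
probability simplex:

    f̂_j(x | p, h) = Σ_i n·p_i·l_i(x)·Y_i,

where l_i(x) are the standard local-linear weights with bandwidth h chosen
by leave-one-out cross-validation. The tilt p is the solution of a convex
quadratic program that pulls the fit toward an infinite-order flat-top
kernel comparator curve; the degree of tilting is itself chosen by
cross-validation, so tilting never hurts where the comparator is
uninformative. Per-term effective degrees of freedom are traces of the
tilted smoother matrices; linear-vs-smooth entry of each predictor is
decided by an F-test on the RSS decrease per degree of freedom; pointwise
confidence bands for smooth curves come from a residual bootstrap around a
mildly undersmoothed refit. See `docs/methods.md` for the full account.

A synthetic-cohort generator reproduces the statistical structure of the
motivating study (marginal means/SDs, reported pairwise correlations,
right-skewed duration/protein variables, a binary gender and 4-level eye
area factor, and known linear + smooth ground-truth effects), so the whole
pipeline is testable end to end without the restricted clinical data.

## Worked example

```python
import tiltam as tm
from tiltam.synthetic import study_terms
from tiltam.workflow import coefficient_table

cohort = tm.generate_cohort(n=2000, seed=7)   # synthetic diabetic cohort
fit = tm.backfit(cohort.table["AOV"].to_numpy(), cohort.table, study_terms())

print(f"converged in {fit.n_iter} sweeps, RSS = {fit.rss:.5f}")
print(coefficient_table(fit).round(6).to_string(index=False))
```

prints (abridged):

```
converged in 15 sweeps, RSS = 0.28915
   Predictor  Estimate  Std. Error    t Value  p-Value
         Age -0.002054    0.000081 -25.409749 0.000000
         MAP  0.000502    0.000020  24.857068 0.000000
     Area[3]  0.012978    0.000796  16.304806 0.000000
Gender[male] -0.000594    0.000586  -1.014837 0.310311
```

The generator's ground truth is Age −0.002, MAP +0.0005 and Area-3
+0.0123: every unit of age lowers AOV by 0.002, every unit of mean
arterial pressure raises it by 0.0005, and the third eye region sits
0.0123 above the reference — the fit recovers all three within two
standard errors, while correctly finding no Gender effect. The smooth
terms' effective df (e.g. A1C ≈ 17) quantify how nonlinear each estimated
curve is; `tm.bootstrap_band(fit, cohort.table, "A1C", n_boot=200,
seed=5)` brackets the A1C curve, whose estimated peak lands at 9.1 against
a true peak at 9.

The scripts in `examples/` walk through each capability: cohort
simulation, model fitting, linearity testing, confidence bands, and the
full workflow (`tiltam workflow` on the command line does the same from a
YAML config; `tiltam --help` lists all subcommands).

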