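# larvapk

Pharmacokinetic (toxicokinetic) modelling of waterborne compound exposure in
developing zebrafish larvae, using paracetamol as the paradigm compound.

Zebrafish larvae are routinely dosed by dissolving a compound in the
incubation medium, but the pharmacological effect is driven by the *internal*
exposure, and the larva is a rapidly developing organism: absorption and
elimination change from day to day. `larvapk` quantifies these processes from
longitudinal internal-amount profiles of pooled larval samples (ages 3-5 days
post fertilisation, dpf) and places the resulting larval clearance against
the interspecies allometric relationship of mature vertebrates. It is aimed
at pharmacometricians and toxicologists designing or analysing larval
waterborne-treatment experiments.

## The model

Internal amount per larva $A$ (pmole) follows zero-order absorption (constant
uptake rate $k_a$, pmole/min, valid while the medium concentration is
effectively constant) with first-order elimination ($k_e$, min⁻¹):

$$\frac{dA}{dt} = k_a - k_e A$$

Under constant treatment $A(t) = (k_a/k_e)(1 - e^{-k_e t})$; after transfer
to drug-free medium at $T_d$ the amount declines mono-exponentially.
Candidate extensions — a peripheral compartment, Michaelis–Menten
elimination — are integrated numerically and compared by likelihood ratio
test ($\chi^2$, $\alpha = 0.01$). Larval age enters through covariate
functions on $k_a$ and $k_e$ (linear, power, or discrete); the selected model
uses a discrete step on $k_a$ above 3 dpf and a power relationship
$k_e = k_{e,base}(1+slope_e)^{age-3}$ on $k_e$.

Estimation is exact Gaussian maximum likelihood with a combined residual
error (variance $v_i = \hat{A}_i^2\sigma^2_{prop} + \sigma^2_{add}$);
a single destructive measurement per pooled sample means inter-individual
variability is not separable from residual error, so no random effects are
estimated. Clearance is $CL = k_e \times V_{larva} \times 60$ (nL/h), and
bodyweight follows from volume at density 0.997 g/mL for the log–log
allometric comparison.

## Worked example

Simulate one study-design dataset (3 ages × 2 arms × 8 time points in
triplicate, pools of 5 larvae) and refit the final model:

```bash
larvapk simulate --seed 1 --out data.csv
larvapk fit --data data.csv --model final --out fit.yaml --seed 0
```

```
Parameter value                     Estimate      RSE (%)
----------------------------------------------------------
ka_base                               0.2876       5.7
factor_a                              1.0635      12.6
ke_base                             0.019518       2.9
slope_e                               0.1836      13.1
sigma2_prop                         0.091735      13.7
sigma2_add                         0.0045726      73.9
----------------------------------------------------------
OFV (-2 log-likelihood): 483.2923
n_obs=144  n_params=6  converged=True
```

`ka_base` is the 3 dpf zero-order absorption rate (pmole/min) and `factor_a`
its fractional step above 3 dpf — here absorption roughly doubles (+106%)
once the gastro-intestinal tract opens at 4 dpf. `ke_base` is the 3 dpf
elimination rate constant (min⁻¹) and `slope_e` its daily fractional increase
(~17.5%/day) as eliminating organs grow and mature. The dataset was simulated
at exactly those generating values, and the refit recovers them within a few
percent with structural-parameter RSEs well below 20%; the additive error
variance is weakly identified (high RSE) whenever proportional error
dominates, which the real analysis shows too.

The same pipeline exposes `larvapk select` (the nested-model LRT ladder),
`larvapk diagnose` (observed-vs-predicted and weighted-residual tables) and
`larvapk allometry` (interspecies clearance regression with a 95% confidence
band, fitted on mature species only). From Python, the scikit-learn-style
estimators `PKModelFit` and `AllometricScaling` wrap the same machinery.

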