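# chromodr

Quality-by-Design design-space computation for gradient liquid-chromatography
methods: face-centered central composite designs (CCD), transformed quadratic
response-surface models of chromatographic critical method attributes, and
Monte Carlo computation of the **Method Operable Design Region (MODR)** — the
set of instrument settings at which a method meets all of its acceptance
criteria with at least a stated probability.

The package is built around a published LC-CAD method optimization for eight
non-volatile fatty acids, whose 18-run dataset ships as a fixture, but every
stage (design construction, model fitting, criteria, design-space search,
synthetic data) is generic and reusable for any 3-factor gradient method.

## The model

Three critical method parameters are varied on coded levels x ∈ [−1, 1]:
flow rate (0.5–0.7 mL/min), gradient time (8–15 min), and column temperature
(30–40 °C), in a face-centered CCD (8 factorial + 6 axial + 4 center runs).
Each measured response y — the boundary times of the two critical peak pairs
and the retention factor k of the last-eluted analyte — is modeled, after a
Box-Cox-guided transform g ∈ {identity, 1/y, log₁₀ y}, as a reduced quadratic

    g(y) = b₀ + Σᵢ bᵢxᵢ + Σᵢ<ⱼ bᵢⱼxᵢxⱼ + Σᵢ bᵢᵢxᵢ²

fitted by ordinary least squares, with R², adjusted R², PRESS-based predicted
R², and a replicate-based lack-of-fit F-test as diagnostics.

The method's critical attributes are derived from the model predictions:
baseline-separation criteria S₁₋₂ and S₆₋₇ (start of the later peak minus end
of the earlier peak; positive ⇔ baseline-resolved) and k of the last peak.
Acceptance requires S₁₋₂ > 0, S₆₋₇ > 0 and k < 18.8 **jointly**. The factor
space is discretized (21 × 21 × 11 = 4851 grid points) and coefficient
uncertainty is propagated by Monte Carlo: each iteration draws one perturbed
coefficient vector per model from the fitted coefficient distribution and
evaluates the criteria everywhere; the MODR is the region where the joint
pass probability is ≥ 0.90.

## Worked example

```python
import chromodr as cd

design, responses = cd.load_fatty_acid_ccd()      # bundled 18-run dataset
models = cd.fit_study_models(design, responses)   # the five published structures

report = cd.run_report(cd.default_study_config(seed=0))
print(cd.render_report(report))
```

prints

```
Study report (seed=0, 5000 MC iterations, covariance perturbation)
design: 18 runs (4 centers), canonical order: True
model t_end_peak1: reciprocal, 5 terms, R2=0.9993 adjR2=0.9991 predR2=0.9985 LOFp=0.7790 | coefficients at printed precision: 5/5
model t_start_peak2: reciprocal, 5 terms, R2=0.9993 adjR2=0.9991 predR2=0.9987 LOFp=0.6445 | coefficients at printed precision: 5/5
model t_end_peak6: log10, 9 terms, R2=0.9997 adjR2=0.9995 predR2=0.9991 LOFp=0.9730 | coefficients at printed precision: 9/9
model t_start_peak7: log10, 9 terms, R2=0.9998 adjR2=0.9996 predR2=0.9992 LOFp=0.9650 | coefficients at printed precision: 9/9
model k_last: identity, 6 terms, R2=0.9901 adjR2=0.9860 predR2=0.9803 LOFp=0.9704 | coefficients at printed precision: 6/6
grid: 21x21x11 = 4851 points
MODR: 351/4851 points (7.2%) at threshold 0.9
published working point (0.575, 14.2, 33.0): S_12=0.062 S_67=0.024 k_last=18.14; P(all rules)=0.921 (in MODR: True)
auto-selected working point: (0.5599999999999999, 12.899999999999999, 32.0)
```

Reading this: every refit coefficient of the five models agrees with the
published coefficient table at its printed precision; the retention-factor
model explains 99 % of the variance with no lack of fit (p = 0.97 ≫ 0.05);
the published working point (0.575 mL/min, 14.2 min gradient, 33 °C) meets
all three criteria jointly with probability 0.92 ≥ 0.90 and lies inside the
computed MODR; the deepest-interior cell of the MODR sits at slightly lower
flow and shorter gradient.

The same pipeline is scriptable from the shell:

```sh
chromodr design --n-center 4 --out design.csv
chromodr simulate --design design.csv --noise matched --seed 7 --out responses.csv
chromodr fit --design design.csv --responses responses.csv --out models.json
chromodr modr --models models.json --iterations 5000 --seed 42 --out modr/
chromodr workpoint --models models.json --flow 0.575 --tgrad 14.2 --temp 33
chromodr gradient --phi-i 65 --phi-f 85 --tgrad 15 --dwell 1.37 --tr 4.94
chromodr report --seed 0
```

## Scope

The package covers the computational pipeline only: design construction,
model fitting and diagnostics, criteria arithmetic, and the probabilistic
design space. Instrument-validation quantities (LOQ, recovery, linearity,
repeatability) and detector-parameter tuning require laboratory
chromatograms and are out of scope. See `docs/methods.md` for the modeling
assumptions, numerical choices, and limitations.
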