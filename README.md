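# dktime — diffusion-kurtosis time-dependence analysis

`dktime` is a Python package for analysing how the apparent diffusivity
D(t_d) and apparent kurtosis K(t_d) of water and intracellular metabolites
depend on the diffusion time t_d, as measured by diffusion-weighted MR
spectroscopy (dMRS) or MRI of gray matter.  It is written for researchers who
want to take decay curves S(b, t_d), turn them into cumulant time series, and
ask which physical mechanism — structural disorder, inter-compartment
exchange, or cellular restriction — dominates the time dependence.

## What it computes

**Stage one** fits the cumulant representation per diffusion time:

    S(b) = S(0) · exp(−b·D + 1/6·K·b²·D²)

**Stage two** fits competing models of the time dependence and ranks them by
small-sample corrected AIC:

* structural-disorder power laws D(t_d) = D_∞ + C_D·t_d^(−θ),
  K(t_d) = K_∞ + C_K·t_d^(−θ), with the universal dynamical exponent
  θ = (p+d)/2 of a disorder class fixed (0.5 in 1D, 1 in 2D/3D) or fitted
  jointly, and the dimensionless tail ratio ξ = C_K/(C_D/D_∞) (= 2 for pure
  1D short-range disorder);
* the log-singularity form A·ln(t_d/t_c)/t_d + B (randomly oriented rods);
* the Kärger exchange kurtosis
  K(t_d) = K₀·(2t_ex/t_d)·[1 − (t_ex/t_d)(1 − e^(−t_d/t_ex))] (+ K_∞);
* the NEXI/SMEX two-compartment exchange signal (stick neurites exchanging
  with isotropic extra-neurite water), powder-averaged, fitted across b and
  t_d;
* a restricted-diffusion mixture of 20% spheres (soma) and 80% randomly
  oriented cylinders (projections), with narrow-pulse eigenmode cumulants.

Every analytic model is validated by seeded Monte-Carlo random walks
(permeable 1D membranes, two-pool exchange, reflecting spheres/disks/
intervals), and a synthetic-cohort generator reproduces the water
(6 t_d × 5 b, 16 repetitions) and metabolite (4 t_d × 7 b, 64–96 repetitions)
acquisition designs so that the whole pipeline is testable without any data
download.

## Worked example

Generate a four-subject synthetic water cohort whose kurtosis decays by
exchange (K₀ = 1.2, t_ex = 100 ms, 10% between-subject variability, SNR 100),
then run the two-stage analysis — cumulant fits per diffusion time, then the
Kärger fit to K(t_d) on t_d ≥ 42.5 ms:

```python
import numpy as np
from dktime import fitting, models
from dktime.synthdata import CohortSpec, generate_cohort, water_protocol

spec = CohortSpec(
    n_subjects=4, truth_model="karger",
    params={"D": 0.5, "K0": 1.2, "tex": 100.0},
    cv={"K0": 0.1, "tex": 0.1}, noise_sigma=0.01, seed=42,
)
curves, truth = generate_cohort(spec, water_protocol())

by_subj = {}
for c in curves:
    by_subj.setdefault(c.subject, []).append(c)

tex_hat = []
for subj, cs in sorted(by_subj.items()):
    points = [fitting.fit_cumulant(c) for c in sorted(cs, key=lambda c: c.td)]
    series = models.CumulantSeries(points=points, species="water")
    f = fitting.fit_karger(series, variant="eq5")
    tex_hat.append(f.params["tex"])
    print(f"{subj}: tex = {f.params['tex']:.1f} +- {f.se['tex']:.1f} ms")
print(f"group mean tex = {np.mean(tex_hat):.1f} ms")
```

Output:

```
subj01: tex = 79.9 +- 13.4 ms
subj02: tex = 72.0 +- 8.6 ms
subj03: tex = 104.1 +- 2.8 ms
subj04: tex = 133.0 +- 19.5 ms
group mean tex = 97.3 ms
```

The per-subject estimates scatter around their true values (89.7, 105.4,
86.8, 115.8 ms — subjects were drawn with a 10% CV around 100 ms), and the
group mean lands within a few percent of the population truth.  The same
analysis is available from the shell:

```sh
dktime synth -o signals.csv --truth-model karger \
    --param D=0.5 --param K0=1.2 --param tex=100 \
    --cv K0=0.1 --cv tex=0.1 --n-subjects 4 --noise-sigma 0.01 --seed 42
dktime analyze -i signals.csv -o report.json --model karger_eq5 --seed 0
```

which writes a JSON report with per-subject cumulant tables, fit parameters
with uncertainties, cAIC rankings, and the config hash/seed needed to
reproduce it.

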