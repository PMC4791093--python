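# dsemicro

Axon radius index mapping from **dual spin-echo (DSE) diffusion MRI** at
clinical gradient strength, using a three-compartment cylinder tissue model
and Bayesian fitting with structured informative priors.

## The problem

Diffusion MRI can in principle probe axon radii, but at the 35 mT/m
gradients of standard clinical scanners the likelihood is nearly flat in
the radius parameter and naive estimators are wildly imprecise. This
package implements an estimation pipeline for that regime:

* a **DSE protocol module** — twice-refocused pulse arrangements, effective
  waveforms, exact b-values, effective diffusion times, eddy-current
  residuals and Cramér-Rao variance bounds, with the optimized 35 mT/m
  five-arrangement protocol (TE 118.54 ms, b = 0/422/620/422/2378 s/mm²)
  built in;
* a **signal model** — for each measurement,

  `S/S0 = f_i exp(-b D_i) + f_r S_r + (1 - f_i - f_r) exp(-b (cos²a (D∥-D⊥) + D⊥))`

  where the restricted intracylinder signal `S_r` combines free axial
  diffusion with the Gaussian-phase-distribution (GPD) attenuation across
  the cylinder, evaluated in closed form for any balanced
  piecewise-constant gradient waveform via the Bessel-root eigenmode
  expansion;
* a **Monte-Carlo simulator** — random walks with specular reflection in
  periodic packed-cylinder substrates (hexagonal fixed-radius at
  intracellular fraction 0.69, or gamma-distributed radii at 0.65-0.70),
  plus Rician noise at SNR 19;
* a **Bayesian fitter** — Rician likelihood with blocked
  Metropolis-Hastings on log/logit-transformed parameters, tensor-fit
  initialization, tuned proposals (target acceptance ≈ 23%), and the
  informative priors

  `f_i ~ Beta(1.2,1.2)`, `f_r/(1-f_i) ~ Beta(5,5)`,
  `D∥ ~ LogN(-20.69,1)`, `D⊥ ~ LogN(-21.04,1)`,
  `R ~ Gamma(3.562, 1.404 µm)` (mean 5 µm).

  The per-voxel **axon radius index** is the median of the posterior R
  samples;
* **metrics** — histogram intersection H between radius distributions,
  voxelwise coefficient of variation, R², callosal subregion partitioning
  and scan-rescan relative absolute difference.

It is aimed at diffusion-MRI methods researchers who want a tested,
self-contained reference implementation of prior-regularized axon radius
index estimation for DSE data, on either synthetic substrates or 4-D
NIfTI volumes with a mask.

## Worked example

Print the built-in optimized protocol with its computed physics:

```sh
$ dsemicro protocol --table1
arr  onsets_ms              lengths_ms             b_s_mm2  diff_time_ms
1    []                     []                     0        -
2    [0.0, 91.76]           [7.34, 7.34]           422      91.76
3    [24.47, 46.45]         [21.97, 21.97]         620      21.98
4    [0.0, 91.76]           [7.34, 7.34]           422      91.76
5    [0.0, 20.6, 79.86]     [13.01, 6.83, 19.84]   2378     79.86
```

Arrangement 3 is the short-diffusion-time (22 ms) bipolar pair;
arrangements 2/4 and 5 probe long diffusion times (80-92 ms), with
arrangement 5 carrying the strongest weighting (2378 s/mm²).

Simulate a substrate of 5 µm cylinders, fit it, and summarize:

```sh
$ dsemicro simulate --radius 5e-6 --orientations 1 --snr 19 --seed 5 \
      --spins 2000 --steps 500 --out sim/
wrote 1 datasets to sim

$ cat > cfg.yaml <<EOF
burn_in: 5000
n_samples: 50
thin: 20
seed: 1
fix_f_i: true
EOF
$ dsemicro fit --scheme sim/scheme.yaml --signals sim/signals.tsv \
      --config cfg.yaml --out fit/
voxel 0: radius index 3.53 um, R2 0.957
fitted 1 voxels -> fit
```

The radius index (3.53 µm here) is the posterior median of R for this
single noisy voxel at SNR 19 — the expected precision at 35 mT/m is modest
for a 5 µm substrate, which is exactly why the pooled, multi-orientation
experiments below are used for validation — and R²
is the fraction of signal variance explained by the model at the
posterior-median parameters. `dsemicro compare A B` prints the histogram
intersection H between two radius sample files (H = 1 for identical
distributions, 0 for disjoint ones).

In Python, the same pipeline is three calls:

```python
from dsemicro import table1_protocol, generate_experiment
from dsemicro.experiments import fit_synthetic_datasets

protocol = table1_protocol()
datasets = generate_experiment([5e-6], 1, protocol, snr=19.0, seed=5,
                               n_spins=2000, n_steps=500)
posts = fit_synthetic_datasets(datasets, protocol, burn_in=5000, thin=20)
```

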