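# lungeit

2D time-difference electrical impedance tomography (EIT) for dynamic lung
imaging: a complete-electrode-model (CEM) finite-element forward solver, a
point-matching method-of-moments (PM-MoM) reconstruction with sparse
Bayesian learning (SBL), the standard regularized baselines, a synthetic
dynamic-thorax phantom generator, and the GREIT-style figure-of-merit
battery.

It is written for researchers developing or benchmarking EIT
reconstruction algorithms: everything needed to go from a parametric
breathing-thorax phantom to scored difference images runs from one
package, with no external data.

## The problem and the methods

EIT injects small currents through electrodes around the chest and images
the internal conductivity change `δσ` between two instants from the change
in boundary voltages `δV`. The forward physics is the elliptic equation
`∇·(σ∇u) = 0` with CEM (or shunt) electrode boundary conditions; the
inverse problem is severely ill-posed and conventionally solved by
regularized least squares on the linearization `δU ≈ J δσ`,

    δσ* = (JᵀJ + λ²Q)⁻¹ Jᵀ δV,

with `Q` a Tikhonov / graph-Laplacian / NOSER prior, or by iterative
non-linear variants (Gauss–Newton, total variation via a primal–dual
interior-point method, difference of absolute images).

The PM-MoM takes a different route: the governing equation is recast as a
global integral equation over the Neumann Green's function `G` of the
domain,

    u(r) = u0(r) + ∫_Ω G(r, r′) ∇ln σ(r′) · ∇u0(r′) dA′,

and the *logarithm* of conductivity is expanded over generalized
exponential radial basis functions centred on a uniform pixel grid,
`ln σ = ln σ0 + Σⱼ cⱼ θ(r, rⱼ)` with
`θ(d) = exp(−‖d‖_{p1}^{p1/p2} / 2D²)` (the Gaussian for p1 = 2, p2 = 1).
Collocating at point electrodes
yields a linear system `Mo c = δU` whose unknowns are the RBF weights —
more faithful to the non-linear physics than the Jacobian, because the
conductivity enters through its exponential.

The system is inverted either in closed form with a Laplace prior, or by
overlapping-cluster sparse Bayesian learning: `c = Ψx` with g = L − h + 1
sliding clusters of h coefficients, `x ~ N(0, blockdiag(γᵢBᵢ))` with
per-cluster scales `γᵢ` and Toeplitz intra-cluster correlations `Bᵢ`, all
estimated by an EM loop (posterior E-step, noise-variance update,
majoration–minimization scale update, capped Toeplitz correlation re-fit).
The MAP image is `σ0·exp(Σⱼ cⱼθⱼ) − σ0`.

Image quality is scored against reference images painted from the true
tissue polygons: target amplitude (TA), position error (PE), shape
deformation (SD), resolution (RES), ringing (RNG), Pearson correlation
(CC), RMSE, and the full-reference metric (GFR and per-lung FR).

## Worked example

The dynamic phantom assigns each breath state a lung admittance from an
alveolar morphology model whose two scale coefficients are calibrated
exactly to the end-expiration and end-inspiration values at 100 kHz:

```python
>>> from lungeit.phantom import BreathSchedule
>>> bs = BreathSchedule()          # P = 5, sb = 0.5, w = 1.5, si = 2
>>> for s in range(1, 6):
...     print(s, round(bs.F[s-1], 2), round(bs.lung_sigma(s), 3))
1 5.25 0.272
2 5.75 0.228
3 6.25 0.186
4 6.75 0.146
5 7.25 0.107
```

The relative lung volume F grows linearly over inhalation and the
conductivity falls from 0.272 S/m (deflated) to 0.107 S/m (inflated) as
air displaces tissue; the endpoints are matched exactly by construction
and the intermediate states follow the model.

A full scaled-down study — simulate case 1 across 5 breath states at
50 dB channel SNR, reconstruct the four difference frames with the linear
Laplace baseline, the regularized PM-MoM and PM-MoM SBL, and score them:

```python
>>> import pandas as pd
>>> from lungeit.pipeline import run_study
>>> rows = run_study(cases=(1,), methods=("laplace", "mom", "mom-sbl"),
...                  snr_db=50, seed=1, fem_elements=400, pixels=300,
...                  phantom_elements=1200)
>>> pd.DataFrame(rows).groupby("method")[["PE", "SD", "RNG", "CC"]].median().round(3)
          PE     SD    RNG     CC
method
laplace  0.106  0.444  0.166  0.763
mom      0.121  0.659  0.072  0.791
mom-sbl  0.117  0.132  0.063  0.790
```

Read: all three methods localize the lungs to about a tenth of the
half-chest width (PE, in the x-normalized units where the chest spans
[−1, 1]), but the SBL reconstruction leaks far less filtered area outside
the true lungs (SD 0.13 vs 0.44) and rings less (RNG), at equal or better
correlation with the reference image.

The same pipeline is scriptable from the shell:

```sh
lungeit simulate --case 1 --out runs/sim1
lungeit reconstruct --method mom-sbl --sim runs/sim1 --out runs/rec1
lungeit evaluate --recon runs/rec1 --sim runs/sim1 --out runs/fom.csv
```

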