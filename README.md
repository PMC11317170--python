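# dnamech

Analysis toolkit for single-molecule nanomechanics of DNA–ligand
interactions: optical-tweezers force–extension curves (FECs), their
empirical and polymer-physics modelling, instantaneous stiffness,
equilibrium binding isotherms, perturbation (force-jump and
concentration-jump) kinetics, and AFM contour statistics. It is aimed at
force-spectroscopy practitioners who record stretch/relax curves of
λ-phage DNA in the presence of an intercalating ligand (e.g. the
porphyrin TMPyP) and want a scriptable, tested pipeline from raw tables
to fitted physical parameters.

## Models

**Empirical FEC model.** A stretch curve of torsionally open dsDNA shows
entropic, enthalpic, overstretch-plateau and asymptotic regimes. The
whole curve is fitted with

```
f1(x) = 1 / (1 + exp(-(x - P1)/P2))        sigmoid: entropic + enthalpic rise
f2(x) = P3·x + P4                          line: overstretch plateau
f3(x) = -P6 / (x - P5)                     hyperbola: asymptotic branch
F(x)  = f1(x) · (f2(x) + f3(x))
```

with extension `x` in μm and force in pN. `P1` scales with the dsDNA
contour length, `P2` with its compliance, `P3` inversely with
overstretch cooperativity, `P4` with duplex stability (plateau height,
conventionally read at 25 μm), `P5` with the maximal (ssDNA-like) length
and `P6` with the asymptotic curvature.

**Polymer elasticity.** Inextensible and extensible wormlike chains,

```
F·Lp/kBT = z/Lc + 1/[4(1 - z/Lc)^2] - 1/4                    (WLC)
F·Lp/kBT = z/Lc + 1/[4(1 - z/Lc + F/κ)^2] - 1/4 - F/κ        (eWLC)
```

the eWLC being inverted per point by bracketed root finding (residual
< 1e-10). For surface-adsorbed molecules imaged by AFM,
`Lp = ⟨R²⟩/(4·Lc)`.

**Binding and kinetics.** The force-dependent ligand-induced lengthening
follows the multi-site isotherm
`ΔL(F) = (Δx_eq·Nbp/n) / (1 + e^(−F·Δx_eq/kBT)/(n·K0·C))`; observed
relaxation rates follow the Bell relation `k_obs(F) = k0·e^(F·Δx/kBT)`
and decompose linearly as `k0 = k_on·C + k_off`.

## Worked example

```python
import numpy as np
from dnamech import *
from dnamech.synthetic_data import SimulationConfig, gen_fec_mechanistic

# a seeded synthetic stretch curve: dsDNA eWLC -> 65 pN plateau -> ssDNA branch
fec = gen_fec_mechanistic(cfg=SimulationConfig(
    seed=7, extension_grid=np.arange(10.0, 31.0, 0.01)))

res = fit_polymer(fec, model="ewlc", force_window=(0.0, 20.0))
peak = stiffness_peak(stiffness_curve(smooth_force(fec)), (14.0, 18.0))
rates, _ = decompose_rates([(5.0, 7.1), (80.0, 57.9)])
cmp = compare_summary(97.31, 6.01, 75, 106.90, 6.36, 75)
```

printing, with these seeds and inputs:

```
eWLC fit (0-20 pN): Lc = 16.35 um, Lp = 52.1 nm, kappa = 1162 pN, residual SD = 0.31 pN
peak stiffness: 71.3 pN/um at 16.90 um
k_on = 0.68 /nM/s, k_off = 3.7 /s
contour increment: 9.59 nm (9.9%), Welch t = 9.49, df = 147.5, p = 5.68e-17
adsorbed Lp (treated): 12.8 nm
```

The eWLC fit recovers the generating dsDNA parameters (16.37 μm, 50 nm,
1200 pN) from the noisy low-force regime; the stiffness peak sits just
below the plateau onset; the two-point rate decomposition converts the
zero-force rates measured at 5 and 80 nM ligand into the association
rate per nM and the dissociation rate; and the Welch comparison of the
AFM contour summaries quantifies the ligand-induced lengthening of
surface-bound molecules.

A command-line interface mirrors the library:

```
dnamech simulate --seed 3 --out-dir out
dnamech fit-fec out/simulated.tsv --out-dir out
dnamech fit-polymer out/simulated.tsv --model ewlc --window 0 20 --out-dir out
dnamech stiffness out/simulated.tsv --out-dir out
dnamech run --config analysis.yaml
```

Tables are TSV/CSV with exact headers (`extension_um`, `force_pN`, …)
and `#key=value` metadata lines; results are deterministic JSON.

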