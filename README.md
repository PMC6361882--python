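# pgoe — origin-ensembles reconstruction for Compton prompt-gamma imaging

`pgoe` is a toolkit for studying proton-therapy range verification with a
three-stage pixelated Compton camera.  During proton irradiation, excited
nuclei emit prompt gammas (PGs) — dominantly at 2.31 MeV (¹⁴N), 4.44 MeV
(¹²C), 5.25 MeV (¹⁵O) and 6.13 MeV (¹⁶O) — whose spatial emission tracks
the dose deposition, so the depth of the 80%/50% distal falloff of the PG
profile is a surrogate for the Bragg-peak position.  A Compton camera
measures, per photon, 2–3 interaction positions and deposited energies,
from which each event constrains its origin to a cone; reconstructing the
emission density from tens of thousands of such cones — with realistic
(finite) energy and spatial resolution — is the problem this package
addresses.  It is aimed at researchers prototyping list-mode Compton
reconstruction and range-verification analyses without running a full
Monte Carlo transport chain.

## The algorithm

The reconstruction engine is *ordered origin ensembles with resolution
recovery* (OE-RR), a Markov-chain Monte Carlo method.  Each event `n_l`
keeps one representative origin on its cone; a Metropolis move proposes a
new point, uniformly on the (resolution-corrected) cone surface inside
the volume of interest, and accepts it with probability

    min(1, (c_j + 1) ε_i / (c_i ε_j))

where `c_i`, `c_j` are the numbers of ensemble origins in the current and
proposed voxels and `ε` are voxel sensitivities (uniform here).  One
*sweep* steps through all `N` events in order.  Resolution recovery
redraws, at every Markov step, the interaction positions uniformly over
the pixel footprint (Uniform(±D/2) transversally, Uniform(±δ_z/2) in
depth) and the first two deposited energies from N(E_i, σ_E(E_i)) with
σ_E from the detector model FWHM(E) = a + b·√E = 2.355·σ_E, so the
"guess" cones marginalize the detector blur.  Variants: `soe` (no
recovery), `oerr` (positions), `oerr_e` (positions + energies),
`oerr_e_pre` (adds a pre-calculated initial ensemble from k ≥ 1 corrected
cone samples per event).  Double events use the deposit sum as total
energy; triple events recover it from the geometric second-scatter angle,
`E' = E₂/2 + √(E₂²/4 + E₂·mₑc²/(1 − cos θ₂))`, without the third deposit.

A synthetic generator stands in for Monte Carlo transport: it samples
origins from a parametric emission model with analytically known
peak/falloff positions, constructs events exactly consistent with Compton
kinematics, then applies pixel quantization, depth error and energy blur.
With degradation disabled, every cone contains its origin to < 1e-9 rad.
See `docs/methods.md` for models, assumptions and limitations.

## Worked example

```python
import numpy as np
from pgoe import CameraGeometry
from pgoe.simulate import simulate_dataset
from pgoe.recon import ReconConfig, reconstruct
from pgoe.pipeline import measure_image

# ~45k list-mode events of the 6.13 MeV (16O) line, with detector blur
data, truth, manifest = simulate_dataset("16O", n_events=45_000, seed=1)
print("analytic truth:", {k: round(v, 2)
                          for k, v in manifest["analytic_metrics"].items()})

config = ReconConfig(variant="oerr_e_pre", n_sweeps=100, k=8, seed=1)
result = reconstruct(data, config, CameraGeometry.small_phantom())
metrics = measure_image(result.image, result.voi, smoothing_fwhm=2.0)
print("reconstructed:", {k: round(v, 2) for k, v in metrics.items()})
```

Output:

```
analytic truth: {'peak': 100.87, 'falloff80': 102.72, 'falloff50': 104.03, 'width80': 3.98}
reconstructed: {'peak': 100.5, 'falloff80': 103.56, 'falloff50': 104.84, 'width80_along': 7.3, 'width80_transverse': 3.64}
```

The emission model's smoothed profile peaks at 100.87 mm depth with the
80% (50%) distal falloff at 102.72 mm (104.03 mm); the OE-RR
reconstruction of 45,000 blurred events recovers the falloff positions —
the observables that matter for range verification — to within about
0.8 mm here (103.56 and 104.84 mm), while the width at 80% shows the
residual reconstruction broadening (7.3 mm vs 3.98 mm true).

The same pipeline is scriptable from the shell:

```bash
pgoe pipeline -c run.yaml --seed 1 -o out/
```

with a YAML config selecting the species, event count, camera preset,
reconstruction variant and VOI (`pgoe simulate`, `pgoe reconstruct` and
`pgoe metrics` run the stages separately):

```yaml
species: 16O
n_events: 45000
camera: {preset: small_phantom}
energy_model: {kind: ab_fwhm, a: -0.2892, b: 0.4332}
recon: {variant: oerr_e_pre, n_sweeps: 100, k: 8}
voi: {lo: [-0.5, -50.0, 0.0], bin: [1.0, 1.0, 1.0], dims: [1, 100, 200]}
metrics: {smoothing_fwhm: 2.0}
```

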