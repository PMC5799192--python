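# ciliaswirl

Quantification of ciliary activity and swirl-like mucus transport in
videos of cultured bronchial epithelium.

Airway epithelia clear mucus through the coordinated beating of cilia.
On air–liquid-interface cultures the beat directions often organise into
circular domains ("swirls") on which the surface fluid rotates like a
rigid body.  This package measures, from high-speed time-lapse stacks or
pre-extracted tables:

* the **active ciliated cell density** ν (fraction of the surface
  covered by beating cilia), via temporal-variance thresholding;
* per-pixel **ciliary beat frequency** (CBF) maps by temporal Fourier
  analysis;
* **beat-orientation and coherency maps** from the structure tensor of
  std-projections, and per-tuft beat axes;
* **bead trajectories**: nearest-neighbour linking, algebraic circle
  fits, angular velocities, rigid-body tests, radial velocity profiles
  and slow epithelial drift;
* **annular swirl profiles** ν_r and ⟨sin α⟩_r (α = angle between a
  tuft's beat direction and the outward radius) and their product, the
  propulsive **force proxy**;
* the **force-balance model** linking the proxy to the surface-fluid
  velocity,

      V_SF = (e/η_pc)·(φ n_c f_c / A_cc)·ν_r⟨sin α⟩_r − V_R,

  whose slope is 4×10⁻⁵ m/s (40 μm/s) at typical parameter values
  (φ = 0.1, n_c = 160, f_c = 1 pN, A_cc = 8×10⁻¹¹ m², η_pc = 5 mPa·s,
  e = 1 μm);
* the **power-law scaling** of swirl radius with ν over several decades.

A synthetic-data module generates ground-truth-labelled videos, tuft
tables, bead trajectories and scaling datasets, so the whole chain is
testable without any recording.  See `docs/methods.md` for the model,
estimator conventions and study sizes.

## Worked example

```python
import numpy as np
import ciliaswirl as cs

# a 250 fps / 3 s recording with 20% coverage of 18.3-Hz tufts
spec = cs.CiliaVideoSpec(height=128, width=128, tuft_coverage=0.2,
                         freq_choices=(18.3,), noise_sigma=0.2, seed=1)
video, truth = cs.generate_cilia_video(spec)

res = cs.activity_mask(video)                 # active density
cbf = cs.estimate_cbf_map(video)              # per-pixel CBF map
mean, sd, n = cs.summarize_cbf(cbf, res.mask)
print(f"nu = {res.nu:.3f}  (truth {truth.coverage:.3f})")
print(f"CBF = {mean:.2f} +- {sd:.2f} Hz over {n} px")

# rigid-body rotation from tracked beads
beads = cs.generate_bead_trajectories(center=(0, 0), omega=1.0,
                                      radii=np.array([50., 100., 150.]),
                                      dt=0.05, T=4.0, seed=0)
fits = [cs.fit_circle(g) for _, g in beads.groupby("track_id")]
omega, cv, rigid = cs.rigid_body_test(fits)
print(f"omega = {omega:.3f} rad/s, CV = {cv:.2e}, rigid = {rigid}")
```

Output:

```
nu = 0.202  (truth 0.202)
CBF = 18.33 +- 0.00 Hz over 3317 px
omega = 1.000 rad/s, CV = 1.58e-15, rigid = True
```

ν matches the generator's ground truth, the CBF is recovered at the
1/3-Hz resolution of a 3-s record, and the common angular velocity
across radii confirms rigid-body rotation.

A thin CLI mirrors the library:

```sh
ciliaswirl synth video --seed 1 --out stack.tif
ciliaswirl density stack.tif
ciliaswirl cbf stack.tif --band 3 30
ciliaswirl swirl tufts.csv --center 0 0 --dr 20
ciliaswirl model --params params.yaml
```

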