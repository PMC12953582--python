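# glycomem

Quantitative analysis tools for studying how sialic-acid-binding
immunoglobulin-like lectins (Siglecs) recognise ganglioside ligands
presented in a lipid bilayer, and for estimating binding affinities by
catch-and-release native mass spectrometry (CaR-nMS).

The package is aimed at computational structural biologists who have
membrane MD trajectories (as multi-model PDB or a simple columnar frame
table) and mass-spectrometry titration time courses, and want the
membrane-relative observables those studies report:

* **Bilayer surface model** — per-frame leaflet surfaces from phosphate
  marker atoms (midplane split, mean phosphate height per leaflet).
* **Glycan tilt angle θ** — the angle between the headgroup axis (C1 of
  the terminal Gal → centroid of Neu5Ac C2/C3) and the membrane normal;
  distribution summarised by a Gaussian-KDE mode.
* **Domain tilt** — angle between the Ig V-set domain's principal axis
  (PC1 of the Cα covariance, axis through the per-frame centre of mass)
  and the membrane normal.
* **Salt-bridge occupancy** — aggregated Arg-guanidinium × Neu5Ac-
  carboxylate pair distances (max over the NH1/NH2 × O11/O12 pairs by
  default) against an inclusive 5 Å threshold; occupancy is the fraction
  of frames below threshold.
* **Sidechain insertion** — percent of frames in which a sidechain's
  centre of mass lies below the leaflet surface.
* **Backbone superposition** — Kabsch least-squares RMSD over N/CA/C/O
  atoms (reflections excluded), plus pLDDT confidence binning for
  predicted models (very high > 90; high in (70, 90]).
* **COIN-CaR-nMS binding model** — the fractional occupancy of a 1:1
  site under a linearly growing ligand exposure L(t) = C_L·t,

      F(t) = DE · ([P]₀ + C_L t + K_d − √((K_d − C_L t + [P]₀)² + 4 K_d C_L t)) / (2 [P]₀),

  with observed occupancy F_t = Ab_t(ligand)/Ab_t(protein); least-squares
  fitting of (K_d, DE, C_L); nanodisc stoichiometry and concentration
  arithmetic (ε₂₈₀ = 32,430 M⁻¹cm⁻¹ for the MSP1E1 scaffold,
  [ND] = ½[MSP1E1], ~200 lipids per disc).

A synthetic-data module generates bilayer trajectories and titration
series with known ground truth (prescribed tilt distributions,
salt-bridge and insertion schedules, known K_d), so every metric is
testable without microsecond trajectories.

## Worked example

Generate a 200-frame synthetic trajectory whose salt bridge is formed in
137 frames and analyse it:

```python
import numpy as np
import glycomem as g

sched = np.zeros(200, dtype=bool); sched[:137] = True
traj = g.generate_membrane_trajectory(
    g.TrajectoryRecipe(n_frames=200, seed=42, saltbridge_schedule=sched))

dist, formed = g.salt_bridge_series(traj, g.SaltBridgeSpec(
    g.Selection("Arg122-N", atom_name=("NH1", "NH2")),
    g.Selection("Neu5Ac-O", atom_name=("O11", "O12"))))
print(f"occupancy: {100 * g.occupancy(formed):.1f}%")

surface = g.fit_bilayer_surface(traj, g.Selection("P", atom_name=("P",)))
tilt = g.glycan_tilt_series(traj, g.TiltSpec(
    g.Selection("Gal-C1", atom_name=("C1",)),
    g.Selection("Neu5Ac-C2C3", atom_name=("C2", "C3"))), surface)
print(f"tilt KDE mode: {g.kde_mode(tilt).mode:.2f} deg")
```

```
occupancy: 68.5%
tilt KDE mode: 29.71 deg
```

The occupancy equals the prescribed 137/200 schedule exactly; the KDE
mode sits near the 30° generating mode (200 frames give a ~1° mode
sampling error). Fitting a binding constant from a synthetic noiseless
titration:

```python
ds = g.generate_coin_series(g.COINRecipe(
    true_params=g.BindingParams(kd=500.0, de=0.8, cl=1.0),  # µM, -, µM/min
    p0=0.8, times=np.arange(1.0, 61.0), seed=7, noise_sigma=0.0))
fit = g.fit_kd(ds)
print(f"Kd = {fit.params.kd_mM:.4f} mM, DE = {fit.params.de:.3f}, "
      f"CL = {fit.params.cl:.3f} uM/min")
```

```
Kd = 0.5000 mM, DE = 0.800, CL = 1.000 uM/min
```

The same operations are available from the shell via the `glycomem`
entry point (`tilt`, `domain-tilt`, `saltbridge`, `insertion`, `kde`,
`rmsd`, `plddt`, `coin-fit`, `nd`, `simulate-traj`, `simulate-coin`, and
a config-driven `run`). See `glycomem --help`.

## Limitations

Inputs are assumed imaged/whole (no periodic-boundary handling), with
the bilayer built in the xy plane; binary trajectory formats (DCD/XTC)
are out of scope. See `docs/methods.md` for the model assumptions,
parameter choices, and a discussion of when K_d is statistically
identifiable from a CaR-nMS trace.
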