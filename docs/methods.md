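# Methods

This note records the models implemented in glycomem, the assumptions
behind them, the defaults and why they were chosen, and the limits of
what the synthetic-data tests demonstrate.

## Coordinate conventions

Coordinates are Ångström, time is nanoseconds for trajectories and
minutes for titrations, frames are 0-based, and concentrations are µM
internally (K_d additionally reported in mM, the conventional scale for
weak glycan–lectin interactions). Trajectories must have identical atoms
in every frame; atom selections are exact, case-sensitive, whitespace-
stripped name matches, because the metrics reference individually named
atoms (Arg NH1/NH2, Neu5Ac O11/O12, Gal C1). Inputs are assumed imaged
and whole — there is no periodic-boundary handling; this is a documented
limitation, appropriate for post-processed trajectories and for the
synthetic generator, which builds whole molecules.

## Bilayer surface model

The "membrane surface" is the phosphate plane, the standard proxy for a
phosphatidylcholine bilayer. Per frame: the midplane is the mean z of
all selected phosphate markers; each atom joins the upper leaflet if its
z is at or above the midplane, else the lower; each leaflet surface is
the mean z of its atoms. A frame with an empty leaflet is a geometry
error rather than a silent NaN. The membrane normal defaults to the
laboratory +z axis because bilayers are conventionally built in the xy
plane; a least-squares plane-fit normal is available
(`plane_fit_normal=True`) for tilted patches.

## Glycan tilt angle θ

θ is the angle between the vector from the base atom (C1 of the terminal
galactose) to the tip (the centroid of Neu5Ac C2 and C3 — the symmetric
reading of a one-base/two-tip atom construction; the tip selection is
configurable) and the membrane normal oriented toward the exterior of
the glycolipid's leaflet, decided per frame by the base atom's side of
the midplane. Values lie in [0°, 180°] and are reported in degrees to
two decimals. A frame whose axis vector is shorter than 1e-6 Å is
masked with a logged warning instead of producing an undefined angle.

## Domain tilt

The Ig V-set axis runs from the per-frame Cα centre of mass (unweighted
mean) to an auxiliary point 10 Å along the first principal component of
the Cα dynamics. By default PC1 is the leading eigenvector of the 3×3
covariance of the per-frame-COM-centred Cα coordinates pooled over all
frames (translation removed, orientational and internal spread kept),
with its sign fixed so PC1·normal ≥ 0. Because the pooled axis is a
single direction, its tilt trace is constant for a rigid domain; the
`axis_mode="per_frame"` option recomputes PC1 from each frame's own
covariance and yields a time-resolved orientation trace — this is the
mode exercised by the generator's orientation schedules. A covariance
whose top two eigenvalues coincide (relative gap ≤ 1e-9) raises an
ambiguity error.

## Salt bridge and occupancy

All pairwise distances between the cation selection (Arg NH1/NH2) and
the anion selection (Neu5Ac O11/O12) are computed per frame; the
reported distance is the maximum over the four pairs, and the bridge
counts as formed when that distance is at or below an inclusive 5.0 Å
threshold. Max-of-pairs is unusual for salt bridges (the minimum pair
distance is the common criterion, and is available via
`aggregator="min"`), but it is the stricter convention and the one this
analysis standardises on; note formed-under-max implies formed-under-min.
Occupancy is the mean of the formed flag over unmasked frames, with an
explicit `(start, stop)` frame window because production windows (e.g.
excluding an initially restrained segment) are a per-study choice.

## Sidechain insertion

The sidechain centre of mass is the unweighted mean of the residue's
standard non-backbone heavy atoms (per-residue atom lists are provided;
the selection must not cross residues). Depth is `surface_z − COM_z` for
the upper leaflet (positive = below the surface, i.e. inserted) and
mirrored for the lower leaflet; the insertion percent is the occupancy
of `depth > 0` (strict, so a COM exactly on the surface does not count).

## KDE mode extraction

Angle distributions are summarised by a Gaussian-kernel density
estimate: Scott's-rule bandwidth `n^(−1/5)·σ̂` by default (the default of
the plotting ecosystem these distributions are usually drawn with),
evaluated on a uniform 0.01° grid spanning `[min − 3h, max + 3h]`; the
mode is the grid argmax, taking the lowest grid point on an exact tie.
Fewer than 10 values is an error; a zero-variance sample returns the
single value with a degenerate flag. The density integrates to 1 within
1e-3 on the grid (trapezoid); mode recovery is tested against a
fine-histogram argmax oracle on the same sample and converges with
sample size (n = 10³ vs 10⁵).

## Backbone superposition and confidence

Backbone means {N, CA, C, O} (a `ca_only` option restricts to Cα).
Pairing is by identical (chain, residue number, atom name) or via a
caller-supplied residue correspondence table. Superposition is the
Kabsch algorithm via SVD with the determinant correction excluding
reflections; collinear point sets raise a degeneracy error since the
rotation is not unique. The fit is unweighted with no outlier trimming —
a single plain RMSD. Correctness is cross-checked against an
exhaustive quaternion-grid search (agreement to 1e-4 Å on 4-point toys)
and against an independent rotation-alignment routine.

pLDDT is read from the B-factor column of predicted-model files (the
AF-database convention). Bins are disjoint so fractions can sum:
very high is pLDDT > 90 and high is 70 < pLDDT ≤ 90, with strict
boundaries; values outside [0, 100] are rejected.

## COIN-CaR-nMS binding model

With a linear ligand exposure L(t) = C_L·t, the occupancy of a 1:1 site
follows the exact quadratic binding solution scaled by the detection
efficiency DE (see README for the closed form); F(0) = 0 and
F(t) → DE. The printed product form C_L·t is implemented exactly; a
caller-supplied exposure table L(t) hooks in non-linear flux profiles.
Observed occupancy is Ab_t(ligand)/Ab_t(protein), unclipped (DE may
exceed 1). Optional fixed-width time binning is available upstream of
the fit but off by default, since acquisition software typically
delivers 1-min-binned traces already.

Fitting minimises the unweighted SSE over (K_d, DE, C_L) in log space
(positivity by construction; DE bounded above by 5; optional per-point
weights). Because K_d and C_L enter almost solely through their ratio
whenever K_d ≫ [P]₀ (F ≈ DE·u/(1+u) with u = C_L·t/K_d, the
K_d-specific signal being the O([P]₀/K_d) ligand-depletion term), a
plain 3-parameter Levenberg–Marquardt fit stalls on a sloppy valley.
The implementation therefore concentrates DE out in closed form (it
enters linearly), profiles C_L by an inner 1-D fit, and refines K_d by
bounded scalar minimisation of the profile SSE after a deterministic
multistart ladder of K_d scales around [P]₀. The whole procedure is
deterministic given the data; standard errors come from the Jacobian at
the optimum (delta method back from log space).

**Identifiability.** On exact model data the profile refinement recovers
all three parameters to ~1e-7 relative. Under measurement noise, K_d is
statistically identifiable only in the ligand-depletion regime
K_d ≲ [P]₀, where recovery degrades gracefully with noise (median
relative error ≈ 0.09/0.18/0.41 at σ = 0.005/0.01/0.02 for K_d = 1 µM,
[P]₀ = 0.8 µM, 60 points) and improves with more time points. For
K_d ≫ [P]₀ — e.g. a 0.5 mM K_d probed at [P]₀ = 0.8 µM with exposure
reaching only ~0.12·K_d — the profile SSE is flat to within ~2% across
many decades of K_d and no estimator can separate K_d from C_L at
σ = 0.01; only the ratio K_d/C_L and DE are determined. The acceptance
suite states this honestly: the noisy-recovery check at those conditions
fails, and remains failing by design. Practical remedies are an
independently calibrated C_L, a fixed DE, or measurements at higher
[P]₀.

## Nanodisc arithmetic

Per-disc counts are the glycolipid mole fraction times the lipids per
disc (default 200), rounded to the nearest integer, with the
phospholipid count as the complement; totals scale linearly with disc
concentration (10% of 200 lipids at 5 µM discs → 100 µM ganglioside and
900 µM phospholipid). Disc concentration follows Beer–Lambert from the
scaffold-protein A₂₈₀ (ε₂₈₀ = 32,430 M⁻¹cm⁻¹ for MSP1E1) divided by the
scaffold copies per disc (default 2).

## Synthetic data: what it does and does not emulate

The generator produces only what the metrics consume: phosphate marker
atoms on two Gaussian-jittered planes (defaults: 32 per leaflet at
±19 Å, σ = 0.5 Å, in a 130 Å lateral box — the geometry of the simulated
DSPC/cholesterol patch reduced to its phosphate surface); a glycolipid
headgroup whose polar tilt is a wrapped-normal draw about a prescribed
mode (default 30° ± 5°, a realistic headgroup precession) with uniform
azimuth; a Cα cloud whose principal axes are made exactly the lab axes
so orientation schedules are realised exactly; salt-bridge marker atoms
with all four pair distances set to the scheduled value (4.0 Å formed /
8.0 Å broken by default, straddling the 5 Å criterion); and a four-atom
sidechain fragment whose centre of mass sits at the scheduled depth
relative to the realised per-frame upper surface, so scheduled
occupancies and insertion percentages are recovered exactly
(frame-quantised). Titration series are the binding model plus truncated
Gaussian noise on F, mapped to a constant protein abundance and a
proportional ligand abundance.

No lipid chemistry, cholesterol, force-field dynamics, autocorrelation
in time, or conformational coupling between subsystems is modelled.
Passing tests therefore demonstrate the correctness of the measurement
and fitting machinery on data with known truth — not that real
trajectories satisfy the generator's assumptions. Seeds are mandatory in
every recipe so no test is silently nondeterministic.

## Problem sizes

The test suite and the acceptance script use 200-frame schedules for
occupancy/insertion, 20,000 frames for distribution-mode recovery
(≈0.56° observed mode error at Scott bandwidth), 60-point titrations
with 50 replicates for noise studies, and 4–50-point clouds for
superposition checks — sizes at which every stochastic check is stable
while a full run stays around a minute on one CPU.
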