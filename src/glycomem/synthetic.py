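"""Synthetic trajectories and titration series with known ground truth.

The generators emulate only the features the metrics consume: a planar
bilayer reduced to phosphate marker atoms in two jittered leaflets (the
simulated membranes are DSPC/cholesterol, but every implemented metric
depends only on the phosphate surface and a handful of named atoms, so
lipid chemistry is not modelled); a glycolipid headgroup whose base→tip
vector precesses with a prescribed polar-tilt distribution (wrapped-normal
polar angle, uniform azimuth); a protein Cα cloud following a per-frame
orientation schedule; arginine/Neu5Ac salt-bridge marker atoms placed at
scheduled pair distances; and a sidechain whose centre of mass follows a
scheduled insertion depth relative to the realised upper surface. The
catch-and-release generator draws noisy occupancy traces from the binding
model with known (K_d, DE, C_L).

Seeds are mandatory everywhere, so nothing is silently nondeterministic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .coin import BindingParams, COINDataset, occupancy_model, write_coin_csv
from .exceptions import ValidationError
from .trajectory import (AtomRecord, Frame, Trajectory, write_frame_table,
                         write_multimodel_pdb)

__all__ = [
    "BilayerRecipe",
    "GlycolipidRecipe",
    "DomainRecipe",
    "TrajectoryRecipe",
    "COINRecipe",
    "generate_membrane_trajectory",
    "generate_coin_series",
    "reference_fixture_suite",
]

BOX_XY = 130.0  # lateral box edge, Å — matches the simulated bilayer patch
SALTBRIDGE_FORMED_D = 4.0  # Å, default scheduled distance when formed
SALTBRIDGE_BROKEN_D = 8.0  # Å, default when broken


@dataclass(frozen=True)
class BilayerRecipe:
    n_phosphates_per_leaflet: int = 32
    leaflet_z: float = 19.0  # half-thickness to the phosphate plane, Å
    z_jitter: float = 0.5    # Gaussian σ of phosphate heights, Å


@dataclass(frozen=True)
class GlycolipidRecipe:
    tilt_mode: float = 30.0      # degrees
    tilt_spread: float = 5.0     # angular σ of the wrapped-normal draw, degrees
    headgroup_length: float = 10.0  # |base→tip| in Å


@dataclass(frozen=True)
class DomainRecipe:
    n_ca: int = 40
    cloud_axes: tuple[float, float, float] = (12.0, 6.0, 3.0)  # σ along z, x, y (Å)
    orientation_schedule: tuple | None = None  # per-frame tilt about y, degrees


@dataclass
class TrajectoryRecipe:
    """Full recipe for one synthetic membrane trajectory. ``seed`` is
    mandatory; schedules default to constants of length ``n_frames``."""

    n_frames: int
    seed: int
    bilayer: BilayerRecipe = field(default_factory=BilayerRecipe)
    glycolipid: GlycolipidRecipe = field(default_factory=GlycolipidRecipe)
    domain: DomainRecipe = field(default_factory=DomainRecipe)
    saltbridge_schedule: np.ndarray | None = None  # bool (formed) or distances Å
    insertion_schedule: np.ndarray | None = None   # COM depth below surface, Å

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for name in ("saltbridge_schedule", "insertion_schedule"):
            sched = getattr(self, name)
            if sched is not None and len(np.atleast_1d(sched)) != self.n_frames:
                raise ValidationError(
                    f"{name} length {len(np.atleast_1d(sched))} != n_frames {self.n_frames}")
        osched = self.domain.orientation_schedule
        if osched is not None and len(osched) != self.n_frames:
            raise ValidationError("orientation_schedule length != n_frames")

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectoryRecipe":
        return cls(
            n_frames=int(d["n_frames"]),
            seed=int(d["seed"]),
            bilayer=BilayerRecipe(**d.get("bilayer", {})),
            glycolipid=GlycolipidRecipe(**d.get("glycolipid", {})),
            domain=DomainRecipe(**{
                **d.get("domain", {}),
                **({"orientation_schedule": tuple(d["domain"]["orientation_schedule"])}
                   if d.get("domain", {}).get("orientation_schedule") is not None else {}),
            }),
            saltbridge_schedule=(np.asarray(d["saltbridge_schedule"])
                                 if d.get("saltbridge_schedule") is not None else None),
            insertion_schedule=(np.asarray(d["insertion_schedule"], dtype=float)
                                if d.get("insertion_schedule") is not None else None),
        )


@dataclass
class COINRecipe:
    """Recipe for a noisy catch-and-release occupancy trace."""

    true_params: BindingParams
    p0: float
    times: np.ndarray
    seed: int
    noise_sigma: float = 0.0
    abundance_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        self.times = np.asarray(self.times, dtype=float)

    @classmethod
    def from_dict(cls, d: dict) -> "COINRecipe":
        return cls(true_params=BindingParams(**d["true_params"]),
                   p0=float(d["p0"]), times=np.asarray(d["times"], dtype=float),
                   seed=int(d["seed"]),
                   noise_sigma=float(d.get("noise_sigma", 0.0)),
                   abundance_scale=float(d.get("abundance_scale", 1000.0)))


# ---------------------------------------------------------------------------


def _tilt_draws(rng, mode: float, spread: float, n: int) -> np.ndarray:
    """Wrapped-normal polar-angle draws folded into [0, 180] degrees."""
    theta = rng.normal(mode, spread, size=n)
    theta = np.abs(theta)                      # reflect at 0
    theta = 180.0 - np.abs(180.0 - theta)      # reflect at 180
    return theta


def generate_membrane_trajectory(recipe: TrajectoryRecipe) -> Trajectory:
    """Emit a trajectory realising the recipe's schedules exactly.

    Atom layout per frame: two leaflets of phosphate markers (chain M,
    residue DSP, atom P); a glycolipid headgroup (chain G: GAL C1 base,
    SIA C2/C3 tip, SIA O11/O12 carboxylate); a protein Cα cloud (chain A,
    CA atoms), Arg122 guanidinium nitrogens (NH1/NH2) and a four-atom
    Trp127 sidechain fragment whose unweighted mean follows the insertion
    schedule relative to the realised upper phosphate surface.
    """
    rng = np.random.default_rng(recipe.seed)
    n_frames = recipe.n_frames
    bl, gl, dom = recipe.bilayer, recipe.glycolipid, recipe.domain
    n_p = bl.n_phosphates_per_leaflet

    sb = recipe.saltbridge_schedule
    if sb is None:
        sb_dist = np.full(n_frames, SALTBRIDGE_FORMED_D)
    else:
        sb = np.atleast_1d(sb)
        if sb.dtype == bool or set(np.unique(sb)).issubset({0, 1, True, False}):
            sb_dist = np.where(np.asarray(sb, dtype=bool),
                               SALTBRIDGE_FORMED_D, SALTBRIDGE_BROKEN_D)
        else:
            sb_dist = np.asarray(sb, dtype=float)
    ins_depth = (np.full(n_frames, 1.0) if recipe.insertion_schedule is None
                 else np.asarray(recipe.insertion_schedule, dtype=float))
    orient = (np.zeros(n_frames) if dom.orientation_schedule is None
              else np.asarray(dom.orientation_schedule, dtype=float))

    # static lateral phosphate positions; per-frame z jitter
    pxy_upper = rng.uniform(0, BOX_XY, size=(n_p, 2))
    pxy_lower = rng.uniform(0, BOX_XY, size=(n_p, 2))
    tilt = _tilt_draws(rng, gl.tilt_mode, gl.tilt_spread, n_frames)
    azim = rng.uniform(0, 2 * np.pi, size=n_frames)

    # anisotropic Cα cloud whose principal axes are EXACTLY the lab axes
    # (long axis on z), so the orientation schedule is realised exactly:
    # re-express a random draw in its own principal frame (U @ diag(S))
    sz, sx, sy = dom.cloud_axes
    raw = np.column_stack([rng.normal(0, sx, dom.n_ca),
                           rng.normal(0, sy, dom.n_ca),
                           rng.normal(0, sz, dom.n_ca)])
    raw -= raw.mean(axis=0)
    U, S, _ = np.linalg.svd(raw, full_matrices=False)
    aligned = U @ np.diag(S)          # covariance diagonal, columns by size desc
    ca_base = aligned[:, [1, 2, 0]]   # largest spread onto z, then x, y
    dom_com = np.array([65.0, 65.0, bl.leaflet_z + 15.0])

    # Trp sidechain fragment: zero-mean offsets so the COM is exact
    sc_offsets = np.array([[0.6, 0.0, 0.3], [-0.6, 0.0, 0.3],
                           [0.0, 0.6, -0.3], [0.0, -0.6, -0.3]])
    sc_names = ("CB", "CG", "CD1", "CD2")

    frames = []
    for f in range(n_frames):
        atoms: list[AtomRecord] = []
        aid = 1

        def add(name, resname, resnum, chain, pos):
            nonlocal aid
            atoms.append(AtomRecord(aid, name, resname, resnum, chain,
                                    np.asarray(pos, dtype=float)))
            aid += 1

        zu = rng.normal(bl.leaflet_z, bl.z_jitter, size=n_p)
        zl = rng.normal(-bl.leaflet_z, bl.z_jitter, size=n_p)
        for i in range(n_p):
            add("P", "DSP", i + 1, "M", [pxy_upper[i, 0], pxy_upper[i, 1], zu[i]])
        for i in range(n_p):
            add("P", "DSP", n_p + i + 1, "M", [pxy_lower[i, 0], pxy_lower[i, 1], zl[i]])
        upper_surface = float(zu.mean())

        # glycolipid: base on the nominal upper surface, tip at the drawn tilt
        base = np.array([65.0, 65.0, bl.leaflet_z])
        th, ph = np.radians(tilt[f]), azim[f]
        direction = np.array([np.sin(th) * np.cos(ph),
                              np.sin(th) * np.sin(ph), np.cos(th)])
        tip_c = base + gl.headgroup_length * direction
        perp = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([1.0, 0.0, 0.0])
        perp = 0.7 * perp / np.linalg.norm(perp)
        add("C1", "GAL", 1, "G", base)
        add("C2", "SIA", 2, "G", tip_c + perp)
        add("C3", "SIA", 2, "G", tip_c - perp)

        # salt-bridge markers: all four pair distances equal the schedule
        a_pt = np.array([70.0, 70.0, bl.leaflet_z + 8.0])
        b_pt = a_pt + np.array([sb_dist[f], 0.0, 0.0])
        add("O11", "SIA", 2, "G", b_pt)
        add("O12", "SIA", 2, "G", b_pt)

        # Cα cloud rotated about y per the orientation schedule
        a = np.radians(orient[f])
        rot_y = np.array([[np.cos(a), 0.0, np.sin(a)],
                          [0.0, 1.0, 0.0],
                          [-np.sin(a), 0.0, np.cos(a)]])
        for i, p in enumerate(ca_base @ rot_y.T + dom_com):
            add("CA", "ALA", i + 1, "A", p)
        add("NH1", "ARG", 122, "A", a_pt)
        add("NH2", "ARG", 122, "A", a_pt)

        # sidechain COM at the scheduled depth below the realised surface
        sc_com = np.array([60.0, 60.0, upper_surface - ins_depth[f]])
        for name, off in zip(sc_names, sc_offsets):
            add(name, "TRP", 127, "A", sc_com + off)

        frames.append(Frame(index=f, atoms=atoms, time_ns=f * 1.0))
    return Trajectory(frames, metadata={"source": "synthetic", "seed": recipe.seed})


def generate_coin_series(recipe: COINRecipe) -> COINDataset:
    """Noisy occupancy trace mapped to a ligand/protein abundance pair.

    F_t is the binding model plus Normal(0, noise_sigma), truncated at 0;
    the protein abundance is the constant ``abundance_scale`` and the
    ligand abundance is F_t times that scale, so the observed
    ligand/protein ratio returns F_t exactly.
    """
    rng = np.random.default_rng(recipe.seed)
    F = occupancy_model(recipe.times, recipe.true_params, recipe.p0)
    if recipe.noise_sigma > 0:
        F = F + rng.normal(0.0, recipe.noise_sigma, size=F.shape)
    F = np.maximum(F, 0.0)
    scale = recipe.abundance_scale
    return COINDataset(times=recipe.times, ab_ligand=F * scale,
                       ab_protein=np.full_like(F, scale), p0=recipe.p0)


# ---------------------------------------------------------------------------


def reference_fixture_suite(out_dir, seed: int = 20260101) -> dict:
    """Write a versioned fixture set with a ground-truth manifest.

    Files: a schedule-driven membrane trajectory (PDB + frame table) with
    137 of 200 salt-bridge frames formed and 60 of 200 frames inserted, a
    noiseless and a noisy catch-and-release series with K_d = 500 µM
    (0.5 mM), and ``manifest.json`` recording the generating truths.
    Regeneration with the same seed is byte-identical.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_frames = 200
    sb = np.zeros(n_frames, dtype=bool)
    sb[:137] = True
    ins = np.where(np.arange(n_frames) < 60, 1.0, -1.0)
    recipe = TrajectoryRecipe(
        n_frames=n_frames, seed=seed,
        bilayer=BilayerRecipe(n_phosphates_per_leaflet=16),
        glycolipid=GlycolipidRecipe(tilt_mode=30.0, tilt_spread=5.0),
        saltbridge_schedule=sb, insertion_schedule=ins,
    )
    traj = generate_membrane_trajectory(recipe)
    write_multimodel_pdb(traj, out / "traj_saltbridge.pdb")
    write_frame_table(traj, out / "traj_saltbridge.csv")

    times = np.arange(1.0, 61.0)
    truth = BindingParams(kd=500.0, de=0.8, cl=1.0)
    noiseless = generate_coin_series(COINRecipe(
        true_params=truth, p0=0.8, times=times, seed=seed, noise_sigma=0.0))
    write_coin_csv(noiseless, out / "coin_noiseless.csv")
    noisy = generate_coin_series(COINRecipe(
        true_params=truth, p0=0.8, times=times, seed=seed + 1, noise_sigma=0.01))
    write_coin_csv(noisy, out / "coin_noisy.csv")

    manifest = {
        "version": 1,
        "seed": seed,
        "traj_saltbridge.pdb": {
            "n_frames": n_frames,
            "saltbridge_occupancy": 137 / 200,
            "insertion_percent": 30.0,
            "tilt_mode_deg": 30.0,
        },
        "coin_noiseless.csv": {"kd_uM": 500.0, "kd_mM": 0.5, "de": 0.8,
                               "cl_uM_per_min": 1.0, "p0_uM": 0.8},
        "coin_noisy.csv": {"kd_uM": 500.0, "noise_sigma": 0.01, "p0_uM": 0.8},
    }
    # content digests let a re-run assert byte-identical regeneration
    for fname in ("traj_saltbridge.pdb", "traj_saltbridge.csv",
                  "coin_noiseless.csv", "coin_noisy.csv"):
        manifest.setdefault("sha256", {})[fname] = hashlib.sha256(
            (out / fname).read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
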