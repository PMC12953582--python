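"""Membrane-relative trajectory metrics.

Implements the geometric observables used to characterise how a sialylated
glycolipid headgroup and an immunoglobulin V-set lectin domain sit relative
to a lipid bilayer:

* a per-frame bilayer surface model built from phosphate marker atoms
  (phosphate plane as the standard surface proxy, leaflets split at the
  midplane);
* the glycan tilt angle θ — the angle between the vector from C1 of the
  terminal galactose to the centroid of Neu5Ac C2/C3 and the membrane
  normal;
* the domain tilt angle — the angle between the domain's principal axis
  (from the Cα covariance) and the membrane normal;
* salt-bridge distance traces (aggregated over the Arg-guanidinium ×
  Neu5Ac-carboxylate atom pairs) with threshold occupancy;
* sidechain centre-of-mass insertion below the leaflet surface;
* Gaussian-kernel density-estimate mode extraction for angle traces.

Angles are reported in degrees, distances in Å. The membrane normal is
the laboratory +z axis by default (bilayers are built in the xy plane);
a least-squares plane-fit normal is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .exceptions import DegeneracyError, GeometryError, SelectionError, ValidationError
from .trajectory import MetricSeries, Selection, Trajectory, resolve_selection

logger = logging.getLogger(__name__)

__all__ = [
    "BilayerSurface",
    "TiltSpec",
    "DomainAxisSpec",
    "SaltBridgeSpec",
    "KDEResult",
    "AngularKDE",
    "SIDECHAIN_ATOMS",
    "sidechain_selection",
    "fit_bilayer_surface",
    "glycan_tilt_series",
    "domain_tilt_series",
    "salt_bridge_series",
    "occupancy",
    "insertion_series",
    "kde_mode",
]

#: Non-backbone heavy atoms per residue type (PDB v3 naming), used to build
#: sidechain centre-of-mass selections.
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}


def sidechain_selection(residue_name: str, residue_number: int,
                        chain_id: str | None = None) -> Selection:
    """Selection of the standard non-backbone heavy atoms of one residue."""
    try:
        names = SIDECHAIN_ATOMS[residue_name]
    except KeyError:
        raise SelectionError(f"no sidechain atom list for residue type {residue_name!r}")
    return Selection(
        label=f"sidechain {residue_name}{residue_number}",
        atom_name=names,
        residue_name=(residue_name,),
        residue_number=(residue_number,),
        chain_id=(chain_id,) if chain_id is not None else None,
    )


@dataclass
class BilayerSurface:
    """Per-frame leaflet surface heights (Å) and the membrane normal."""

    midplane_z: np.ndarray
    upper_surface_z: np.ndarray
    lower_surface_z: np.ndarray
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(self.normal), 1.0):
            raise GeometryError("membrane normal must have unit length")
        if np.any(self.lower_surface_z > self.midplane_z) or \
                np.any(self.midplane_z > self.upper_surface_z):
            raise GeometryError("leaflet surfaces must bracket the midplane")


@dataclass(frozen=True)
class TiltSpec:
    """Axis construction for a glycan headgroup tilt.

    ``base_atom`` must resolve to one atom (C1 of the terminal Gal);
    ``tip_atoms`` to one or two atoms (Neu5Ac C2 and C3; tip = centroid).
    """

    base_atom: Selection
    tip_atoms: Selection


@dataclass(frozen=True)
class DomainAxisSpec:
    """Principal-axis construction for a protein domain tilt.

    The axis runs from the per-frame Cα centre of mass to an auxiliary
    point ``aux_distance`` Å along the first principal component of the
    Cα dynamics.
    """

    ca_selection: Selection
    aux_distance: float = 10.0

    def __post_init__(self) -> None:
        if self.aux_distance <= 0:
            raise ValidationError("aux_distance must be > 0")


@dataclass(frozen=True)
class SaltBridgeSpec:
    """Cation/anion atom groups, distance threshold and pair aggregator.

    The default aggregator is ``max`` over all cation×anion pairs with an
    inclusive 5.0 Å threshold (the convention used for the Arg-guanidinium
    NH1/NH2 × Neu5Ac-carboxylate O11/O12 bridge); ``min`` is the more
    common salt-bridge convention and is available.
    """

    cation_atoms: Selection
    anion_atoms: Selection
    threshold: float = 5.0
    aggregator: str = "max"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.aggregator not in ("max", "min"):
            raise ValidationError("aggregator must be 'max' or 'min'")


@dataclass
class KDEResult:
    """Gaussian-KDE density on a uniform grid with its mode (degrees)."""

    grid: np.ndarray
    density: np.ndarray
    mode: float
    bandwidth: float
    degenerate: bool = False


# ---------------------------------------------------------------------------


def fit_bilayer_surface(traj: Trajectory, phosphate_sel: Selection,
                        plane_fit_normal: bool = False) -> BilayerSurface:
    """Model the bilayer surfaces from phosphate marker atoms.

    Per frame the midplane is the mean z of all selected atoms; each atom
    joins the upper leaflet if its z is at or above the midplane and the
    lower leaflet otherwise; each leaflet surface is the mean z of its
    atoms. Raises :class:`GeometryError` if a leaflet is empty in any
    frame. With ``plane_fit_normal`` the normal comes from a least-squares
    plane through all selected atoms of frame 0; default is lab +z.
    """
    idx = resolve_selection(traj, phosphate_sel)
    z = traj.coords(idx)[:, :, 2]  # (n_frames, n_sel)
    mid = z.mean(axis=1)
    upper_mask = z >= mid[:, None]
    n_upper = upper_mask.sum(axis=1)
    n_lower = (~upper_mask).sum(axis=1)
    bad = np.flatnonzero((n_upper == 0) | (n_lower == 0))
    if bad.size:
        raise GeometryError(
            f"frame {bad[0]}: one bilayer leaflet is empty "
            f"(upper {n_upper[bad[0]]}, lower {n_lower[bad[0]]} phosphates)")
    with np.errstate(invalid="ignore"):
        upper = np.where(upper_mask, z, np.nan)
        lower = np.where(~upper_mask, z, np.nan)
        upper_z = np.nanmean(upper, axis=1)
        lower_z = np.nanmean(lower, axis=1)
    normal = np.array([0.0, 0.0, 1.0])
    if plane_fit_normal:
        pts = traj.coords(idx)[0]
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        normal = vt[2] if vt[2, 2] >= 0 else -vt[2]
    return BilayerSurface(midplane_z=mid, upper_surface_z=upper_z,
                          lower_surface_z=lower_z, normal=normal)


def _angle_deg(v: np.ndarray, n: np.ndarray) -> float:
    c = float(np.dot(v, n) / (np.linalg.norm(v) * np.linalg.norm(n)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def glycan_tilt_series(traj: Trajectory, spec: TiltSpec,
                       surface: BilayerSurface) -> MetricSeries:
    """Per-frame glycan headgroup tilt θ (degrees, in [0, 180]).

    θ is the angle between the base→tip-centroid vector and the membrane
    normal oriented toward the exterior of the glycolipid's leaflet
    (decided per frame by the base atom's side of the midplane). Frames
    with a vanishing axis vector (< 1e-6 Å) are masked with a warning.
    """
    base_idx = resolve_selection(traj, spec.base_atom)
    tip_idx = resolve_selection(traj, spec.tip_atoms)
    if len(base_idx) != 1:
        raise SelectionError(
            f"tilt base selection {spec.base_atom.label!r} must resolve to 1 atom, "
            f"got {len(base_idx)}")
    if not 1 <= len(tip_idx) <= 2:
        raise SelectionError(
            f"tilt tip selection {spec.tip_atoms.label!r} must resolve to 1-2 atoms, "
            f"got {len(tip_idx)}")
    base = traj.coords(base_idx)[:, 0, :]
    tip = traj.coords(tip_idx).mean(axis=1)
    v = tip - base
    n_frames = traj.n_frames
    values = np.zeros(n_frames)
    mask = np.ones(n_frames, dtype=bool)
    for f in range(n_frames):
        if np.linalg.norm(v[f]) < 1e-6:
            mask[f] = False
            values[f] = np.nan
            logger.warning("glycan tilt: zero-length axis in frame %d; frame masked", f)
            continue
        sign = 1.0 if base[f, 2] >= surface.midplane_z[f] else -1.0
        values[f] = _angle_deg(v[f], sign * surface.normal)
    return MetricSeries(name="glycan_tilt", unit="degree", values=values,
                        mask=mask, times_ns=traj.times_ns)


def _principal_axis(centred: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the 3x3 covariance of centred coordinates."""
    cov = centred.T @ centred / max(len(centred) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    top, second = evals[2], evals[1]
    if (top - second) <= 1e-9 * max(top, 1.0):
        raise DegeneracyError(
            "principal axis is ambiguous: top two covariance eigenvalues coincide")
    pc1 = evecs[:, 2]
    if float(np.dot(pc1, normal)) < 0:
        pc1 = -pc1
    return pc1


def domain_tilt_series(traj: Trajectory, spec: DomainAxisSpec,
                       surface: BilayerSurface,
                       axis_mode: str = "pooled") -> MetricSeries:
    """Per-frame tilt (degrees) of a domain's principal axis vs the normal.

    The axis runs from the per-frame Cα centre of mass to an auxiliary
    point ``aux_distance`` Å along PC1. With ``axis_mode="pooled"``
    (default) PC1 is the leading eigenvector of the covariance of the
    per-frame-COM-centred Cα coordinates pooled over all frames, its sign
    fixed so PC1·normal ≥ 0 — a single axis direction capturing the spread
    of the dynamics. With ``axis_mode="per_frame"`` PC1 is recomputed from
    each frame's own centred coordinates, giving a time-resolved
    orientation trace.
    """
    if axis_mode not in ("pooled", "per_frame"):
        raise ValidationError("axis_mode must be 'pooled' or 'per_frame'")
    idx = resolve_selection(traj, spec.ca_selection)
    if len(idx) < 4:
        raise SelectionError(
            f"domain axis needs >= 4 Cα atoms; selection "
            f"{spec.ca_selection.label!r} resolves to {len(idx)}")
    if traj.n_frames < 2 and axis_mode == "pooled":
        raise ValidationError("pooled PC1 needs >= 2 frames")
    coords = traj.coords(idx)  # (F, N, 3)
    centred = coords - coords.mean(axis=1, keepdims=True)
    if axis_mode == "pooled":
        pc1 = _principal_axis(centred.reshape(-1, 3), surface.normal)
        values = np.full(traj.n_frames, _angle_deg(pc1, surface.normal))
    else:
        values = np.array([
            _angle_deg(_principal_axis(centred[f], surface.normal), surface.normal)
            for f in range(traj.n_frames)
        ])
    return MetricSeries(name="domain_tilt", unit="degree", values=values,
                        times_ns=traj.times_ns)


def salt_bridge_series(traj: Trajectory, spec: SaltBridgeSpec
                       ) -> tuple[MetricSeries, MetricSeries]:
    """Per-frame aggregated cation×anion distance and formed flag.

    All pairwise distances between the cation and anion selections are
    computed each frame; the reported distance is the aggregator over
    pairs (default ``max``) and the bridge counts as formed when that
    distance is at or below the threshold (inclusive).
    """
    cat_idx = resolve_selection(traj, spec.cation_atoms)
    an_idx = resolve_selection(traj, spec.anion_atoms)
    agg = np.max if spec.aggregator == "max" else np.min
    cat = traj.coords(cat_idx)
    an = traj.coords(an_idx)
    dist = np.array([float(agg(cdist(cat[f], an[f]))) for f in range(traj.n_frames)])
    formed = (dist <= spec.threshold).astype(float)
    t = traj.times_ns
    return (
        MetricSeries(name="saltbridge_distance", unit="angstrom", values=dist, times_ns=t),
        MetricSeries(name="saltbridge_formed", unit="fraction", values=formed, times_ns=t),
    )


def occupancy(formed: MetricSeries,
              frame_range: tuple[int, int] | None = None) -> float:
    """Fraction of (unmasked) frames in which a binary flag is set.

    ``frame_range`` is a half-open ``(start, stop)`` window of frame
    indices; by default the whole series counts. Raises on an empty window
    or on non-binary unmasked values.
    """
    values, mask = formed.values, formed.mask
    if frame_range is not None:
        start, stop = frame_range
        values, mask = values[start:stop], mask[start:stop]
    values = values[mask]
    if values.size == 0:
        raise ValidationError("occupancy: empty frame range")
    if not np.all(np.isin(values, (0.0, 1.0))):
        raise ValidationError("occupancy: series is not binary on unmasked frames")
    return float(values.mean())


def insertion_series(traj: Trajectory, sidechain_sel: Selection,
                     surface: BilayerSurface, leaflet: str = "upper"
                     ) -> tuple[MetricSeries, MetricSeries]:
    """Sidechain centre-of-mass depth below a leaflet surface.

    Depth is ``surface_z − COM_z`` for the upper leaflet (positive = below
    the surface, i.e. inserted into the membrane) and mirrored for the
    lower leaflet. ``inserted`` is 1 when depth > 0; the insertion percent
    of the trace is ``occupancy(inserted)``. The selection must stay
    within a single residue.
    """
    if leaflet not in ("upper", "lower"):
        raise ValidationError("leaflet must be 'upper' or 'lower'")
    idx = resolve_selection(traj, sidechain_sel)
    residues = {(a.chain_id, a.residue_number, a.residue_name)
                for i, a in enumerate(traj.frames[0].atoms) if i in set(idx)}
    if len(residues) > 1:
        raise SelectionError(
            f"sidechain selection {sidechain_sel.label!r} crosses residues: "
            f"{sorted(residues)}")
    com_z = traj.coords(idx).mean(axis=1)[:, 2]
    if leaflet == "upper":
        depth = surface.upper_surface_z - com_z
    else:
        depth = com_z - surface.lower_surface_z
    inserted = (depth > 0).astype(float)
    t = traj.times_ns
    return (
        MetricSeries(name="insertion_depth", unit="angstrom", values=depth, times_ns=t),
        MetricSeries(name="inserted", unit="fraction", values=inserted, times_ns=t),
    )


# ---------------------------------------------------------------------------
# KDE mode extraction


class AngularKDE(BaseEstimator):
    """Gaussian-kernel density estimator with mode extraction.

    Parameters
    ----------
    bandwidth : float, optional
        Kernel bandwidth in degrees. Default is Scott's rule,
        ``n**(-1/5) * sigma_hat``.
    grid_step : float
        Resolution of the evaluation grid, degrees. The grid spans
        ``[min - 3h, max + 3h]``.

    Fitted attributes
    -----------------
    grid_, density_ : evaluation grid and normalised density.
    mode_ : grid point of maximal density (lowest grid point on a tie).
    bandwidth_ : bandwidth actually used.
    degenerate_ : True when the sample has zero variance, in which case
        ``mode_`` is the single value and no grid is built.
    """

    def __init__(self, bandwidth: float | None = None, grid_step: float = 0.01):
        self.bandwidth = bandwidth
        self.grid_step = grid_step

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size < 10:
            raise ValidationError(f"KDE needs >= 10 values, got {x.size}")
        sigma = float(np.std(x, ddof=1))
        if sigma == 0.0:
            self.degenerate_ = True
            self.mode_ = float(x[0])
            self.bandwidth_ = 0.0
            self.grid_ = np.array([self.mode_])
            self.density_ = np.array([np.inf])
            return self
        self.degenerate_ = False
        if self.bandwidth is not None:
            h = float(self.bandwidth)
            kde = stats.gaussian_kde(x, bw_method=h / sigma)
        else:
            kde = stats.gaussian_kde(x)  # Scott: n**(-1/5) * sigma_hat
            h = float(kde.factor) * sigma
        self.bandwidth_ = h
        lo, hi = x.min() - 3 * h, x.max() + 3 * h
        n_pts = int(np.floor((hi - lo) / self.grid_step)) + 1
        self.grid_ = lo + self.grid_step * np.arange(n_pts)
        self.density_ = kde(self.grid_)
        # argmax returns the first (lowest) grid point on exact ties
        self.mode_ = float(self.grid_[int(np.argmax(self.density_))])
        return self

    def result(self) -> KDEResult:
        return KDEResult(grid=self.grid_, density=self.density_,
                         mode=self.mode_, bandwidth=self.bandwidth_,
                         degenerate=self.degenerate_)


def kde_mode(values: MetricSeries | np.ndarray,
             bandwidth: float | None = None) -> KDEResult:
    """Gaussian-KDE mode of an angle trace (unmasked values only)."""
    if isinstance(values, MetricSeries):
        x = values.valid_values
    else:
        x = np.asarray(values, dtype=float)
    return AngularKDE(bandwidth=bandwidth).fit(x).result()
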