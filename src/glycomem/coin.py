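"""COIN-CaR-nMS binding-affinity model.

Concentration-independent catch-and-release native mass spectrometry
measures a protein's fractional binding-site occupancy F_t over time as
slow in-emitter mixing ramps the free-ligand exposure. With a linear
exposure L(t) = C_L·t, the equilibrium occupancy of a 1:1 site follows
the exact quadratic binding solution scaled by a detection efficiency DE::

    F_t = DE * ([P]0 + C_L t + K_d - sqrt((K_d - C_L t + [P]0)^2
                + 4 K_d C_L t)) / (2 [P]0)

so F(0) = 0 and F(t) -> DE as the ligand saturates the sites. The
observed occupancy is the ratio of released-ligand to free-protein ion
abundances, F_t = Ab_t(L) / Ab_t(P). Fitting (K_d, DE, C_L) to an
observed F_t trace by least squares yields the dissociation constant
without knowing the absolute ligand concentration.

Concentrations are µM internally; K_d is additionally reported in mM.
The module also provides the nanodisc bookkeeping used to express
membrane-embedded glycolipid ligands: per-disc lipid stoichiometry and
disc concentration from scaffold-protein absorbance at 280 nm
(Beer-Lambert, with the disc containing a fixed number of scaffold
copies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ValidationError

__all__ = [
    "COINDataset",
    "BindingParams",
    "FitResult",
    "NanodiscSpec",
    "CoinBindingModel",
    "fraction_bound",
    "occupancy_model",
    "fit_kd",
    "nd_stoichiometry",
    "nd_concentration_from_a280",
    "read_coin_csv",
    "write_coin_csv",
]


@dataclass
class COINDataset:
    """A catch-and-release time course.

    times are minutes (strictly increasing); abundances are arbitrary
    ion-count units; ``p0`` is the initial protein concentration in µM.
    """

    times: np.ndarray
    ab_ligand: np.ndarray
    ab_protein: np.ndarray
    p0: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ab_ligand = np.asarray(self.ab_ligand, dtype=float)
        self.ab_protein = np.asarray(self.ab_protein, dtype=float)
        if not (len(self.times) == len(self.ab_ligand) == len(self.ab_protein)):
            raise ValidationError("times and abundance arrays must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.ab_ligand < 0):
            raise ValidationError("ligand abundances must be >= 0")
        if self.p0 <= 0:
            raise ValidationError("p0 must be > 0")


@dataclass(frozen=True)
class BindingParams:
    """Binding-model parameters: K_d (µM), detection efficiency, C_L (µM/min)."""

    kd: float
    de: float
    cl: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.de <= 0 or self.cl <= 0:
            raise ValidationError("kd, de and cl must all be strictly positive")

    @property
    def kd_mM(self) -> float:
        return self.kd / 1000.0


@dataclass
class FitResult:
    """Least-squares fit outcome with local-curvature standard errors."""

    params: BindingParams
    residual_sse: float
    stderr: dict = field(default_factory=dict)
    n_points: int = 0
    converged: bool = False


@dataclass(frozen=True)
class NanodiscSpec:
    """Nanodisc composition: glycolipid mole fraction among ~200 lipids,
    scaffold-protein extinction coefficient and copies per disc."""

    ganglioside_mol_fraction: float
    lipids_per_nd: int = 200
    epsilon_280: float = 32430.0
    msp_per_nd: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.ganglioside_mol_fraction <= 1.0:
            raise ValidationError("ganglioside_mol_fraction must lie in [0, 1]")
        if self.lipids_per_nd <= 0 or self.epsilon_280 <= 0 or self.msp_per_nd <= 0:
            raise ValidationError("lipids_per_nd, epsilon_280, msp_per_nd must be > 0")


# ---------------------------------------------------------------------------


def fraction_bound(ds: COINDataset) -> np.ndarray:
    """Observed occupancy F_t = Ab_t(ligand) / Ab_t(protein), elementwise.

    No clipping is applied: values above 1 are legitimate when the
    detection efficiency exceeds unity.
    """
    zero = np.flatnonzero(ds.ab_protein <= 0)
    if zero.size:
        raise ValidationError(
            f"zero protein abundance at time index {zero[0]} "
            f"(t = {ds.times[zero[0]]:g} min)")
    return ds.ab_ligand / ds.ab_protein


def occupancy_model(t, params: BindingParams, p0: float,
                    exposure=None) -> np.ndarray:
    """Model occupancy F(t) for a 1:1 site under a growing ligand exposure.

    ``exposure`` optionally supplies the ligand exposure L(t) directly
    (array aligned to ``t``, µM), replacing the default linear form
    L(t) = C_L·t for non-linear flux profiles.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    L = params.cl * t if exposure is None else np.asarray(exposure, dtype=float)
    kd = params.kd
    disc = np.sqrt((kd - L + p0) ** 2 + 4.0 * kd * L)
    return params.de * (p0 + L + kd - disc) / (2.0 * p0)


class CoinBindingModel(BaseEstimator, RegressorMixin):
    """Least-squares estimator of (K_d, DE, C_L) from an occupancy trace.

    Parameters
    ----------
    p0 : float
        Initial protein concentration, µM.
    kd_init, de_init, cl_init : float, optional
        Starting values; defaults are derived from the data (DE from the
        trace maximum, C_L from the initial slope, K_d = p0).
    de_max : float
        Upper bound on the detection efficiency (default 5).
    max_multistart : int
        Number of log-spaced K_d restarts tried when the first start does
        not converge.
    weights : array-like, optional
        Per-point weights for a weighted SSE objective (default
        unweighted).

    Fitted attributes: ``kd_``, ``de_``, ``cl_`` (µM, -, µM/min),
    ``sse_``, ``stderr_`` (dict per parameter, from the Jacobian at the
    optimum), ``n_points_``, ``converged_``.

    The fit is deterministic given the data and starting values: restarts
    are a fixed log-spaced ladder, not random.
    """

    def __init__(self, p0: float = 1.0, kd_init: float | None = None,
                 de_init: float | None = None, cl_init: float | None = None,
                 de_max: float = 5.0, max_multistart: int = 5, weights=None):
        self.p0 = p0
        self.kd_init = kd_init
        self.de_init = de_init
        self.cl_init = cl_init
        self.de_max = de_max
        self.max_multistart = max_multistart
        self.weights = weights

    def _default_init(self, t, F):
        de0 = self.de_init
        if de0 is None:
            de0 = float(np.clip(np.max(F), 1e-3, 2.0))
        cl0 = self.cl_init
        if cl0 is None:
            # initial slope of F maps to C_L via dF/dt|0 ~ DE*C_L/(p0+Kd)
            k = min(5, len(t))
            slope = max(float(np.polyfit(t[:k], F[:k], 1)[0]), 1e-8)
            cl0 = slope * self.p0 / de0
        kd0 = self.kd_init if self.kd_init is not None else float(self.p0)
        return kd0, de0, cl0

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        F = np.asarray(y, dtype=float).ravel()
        if t.size != F.size:
            raise ValidationError("time and occupancy arrays must share one length")
        if t.size < 5:
            raise ValidationError(f"fit needs >= 5 time points, got {t.size}")
        w = np.ones_like(F) if self.weights is None else np.sqrt(
            np.asarray(self.weights, dtype=float))
        p0 = self.p0

        def unit_model(kd, cl):
            # occupancy at DE = 1
            L = cl * t
            disc = np.sqrt((kd - L + p0) ** 2 + 4.0 * kd * L)
            return (p0 + L + kd - disc) / (2.0 * p0)

        def best_de(m):
            # DE enters linearly, so its conditional optimum is closed-form
            denom = float(np.sum((w * m) ** 2))
            if denom <= 0:
                return 1.0
            return float(np.clip(np.sum(w * w * F * m) / denom, 1e-12, self.de_max))

        def resid(theta):
            # positivity via the log parametrisation; clip keeps exp finite
            kd, de, cl = np.exp(np.clip(theta, -40.0, 40.0))
            de = min(de, self.de_max)
            return w * (de * unit_model(kd, cl) - F)

        def solve(theta0):
            return least_squares(resid, np.clip(theta0, -40.0, 40.0),
                                 method="lm", xtol=1e-15, ftol=1e-15,
                                 gtol=1e-15, max_nfev=10000)

        def profile(log_kd, cl_start):
            """min over (DE, C_L) of the SSE at fixed K_d (variable projection)."""
            kd = float(np.exp(np.clip(log_kd, -40.0, 40.0)))

            def inner(lc):
                cl = float(np.exp(np.clip(lc[0], -40.0, 40.0)))
                m = unit_model(kd, cl)
                return w * (best_de(m) * m - F)

            sol = least_squares(inner, [np.log(max(cl_start, 1e-10))],
                                method="lm", xtol=1e-15, ftol=1e-15,
                                gtol=1e-15, max_nfev=2000)
            cl = float(np.exp(np.clip(sol.x[0], -40.0, 40.0)))
            de = best_de(unit_model(kd, cl))
            return 2.0 * sol.cost, cl, de

        kd0, de0, cl0 = self._default_init(t, F)
        # K_d and C_L are nearly ratio-degenerate when K_d >> [P]0, so the
        # restart ladder spans a wide fixed grid of K_d scales around p0
        starts = [(kd0, de0, cl0)]
        starts += [(self.p0 * 10.0 ** e, de0, cl0)
                   for e in np.linspace(-2.0, 4.0, self.max_multistart)]
        best = None
        for kd_s, de_s, cl_s in starts:
            theta0 = np.log([max(kd_s, 1e-10), min(max(de_s, 1e-6), self.de_max),
                             max(cl_s, 1e-10)])
            sol = solve(theta0)
            if best is None or sol.cost < best.cost:
                best = sol
        kd_b, de_b, cl_b = np.exp(np.clip(best.x, -40.0, 40.0))
        # refine K_d along the sloppy valley on the profiled objective
        from scipy.optimize import minimize_scalar

        span = np.log(30.0)
        opt = minimize_scalar(
            lambda lk: profile(lk, cl_b)[0],
            bounds=(np.log(kd_b) - span, np.log(kd_b) + span),
            method="bounded", options={"xatol": 1e-10, "maxiter": 200})
        sse_p, cl_p, de_p = profile(opt.x, cl_b)
        if sse_p <= 2.0 * best.cost:
            refined = np.array([float(opt.x), np.log(de_p), np.log(cl_p)])
        else:
            refined = best.x
        final = solve(refined)
        best = final if final.cost <= best.cost else best
        kd, de, cl = np.exp(np.clip(best.x, -40.0, 40.0))
        de = min(de, self.de_max)
        self.kd_, self.de_, self.cl_ = float(kd), float(de), float(cl)
        self.sse_ = float(2.0 * best.cost)
        self.n_points_ = int(t.size)
        self.converged_ = bool(best.status > 0)
        # standard errors from the quadratic approximation at the optimum,
        # back-transformed from log-parameter space (delta method)
        self.stderr_ = {}
        try:
            J = best.jac
            dof = max(t.size - 3, 1)
            cov_log = np.linalg.inv(J.T @ J) * (self.sse_ / dof)
            se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
            for name, value, se in zip(("kd", "de", "cl"),
                                       (self.kd_, self.de_, self.cl_), se_log):
                self.stderr_[name] = float(value * se)
        except np.linalg.LinAlgError:
            self.stderr_ = {k: float("nan") for k in ("kd", "de", "cl")}
        return self

    def predict(self, X):
        return occupancy_model(np.asarray(X, dtype=float).ravel(),
                               BindingParams(self.kd_, self.de_, self.cl_),
                               self.p0)

    @property
    def params_(self) -> BindingParams:
        return BindingParams(kd=self.kd_, de=self.de_, cl=self.cl_)


def fit_kd(ds: COINDataset, init: BindingParams | None = None,
           bounds: dict | None = None, weights=None,
           bin_minutes: float | None = None) -> FitResult:
    """Fit (K_d, DE, C_L) to a catch-and-release dataset.

    ``bin_minutes`` optionally averages the observed occupancy into fixed
    time bins before fitting (off by default; raw traces from the
    acquisition software are typically already 1-min binned). ``bounds``
    may carry ``de_max``.
    """
    t = ds.times
    F = fraction_bound(ds)
    if bin_minutes is not None:
        edges = np.arange(t.min(), t.max() + bin_minutes, bin_minutes)
        which = np.digitize(t, edges) - 1
        t = np.array([t[which == b].mean() for b in np.unique(which)])
        F = np.array([F[which == b].mean() for b in np.unique(which)])
    model = CoinBindingModel(
        p0=ds.p0,
        kd_init=None if init is None else init.kd,
        de_init=None if init is None else init.de,
        cl_init=None if init is None else init.cl,
        de_max=5.0 if bounds is None else bounds.get("de_max", 5.0),
        weights=weights,
    ).fit(t, F)
    return FitResult(params=model.params_, residual_sse=model.sse_,
                     stderr=model.stderr_, n_points=model.n_points_,
                     converged=model.converged_)


# ---------------------------------------------------------------------------
# Nanodisc arithmetic


def nd_stoichiometry(spec: NanodiscSpec, nd_concentration: float
                     ) -> tuple[int, int, float, float]:
    """Per-disc lipid counts and total lipid concentrations.

    Returns ``(gangliosides_per_nd, phospholipids_per_nd,
    total_ganglioside_uM, total_phospholipid_uM)`` for a disc population
    at ``nd_concentration`` µM. Counts are rounded to the nearest integer
    with the phospholipid count as the complement.
    """
    n_gang = int(round(spec.ganglioside_mol_fraction * spec.lipids_per_nd))
    n_phos = spec.lipids_per_nd - n_gang
    return (n_gang, n_phos,
            n_gang * nd_concentration, n_phos * nd_concentration)


def nd_concentration_from_a280(a280: float, path_cm: float,
                               spec: NanodiscSpec) -> float:
    """Disc concentration (µM) from scaffold-protein absorbance at 280 nm.

    Beer-Lambert gives the scaffold concentration [MSP] = A280/(ε·l); the
    disc concentration is [MSP] divided by the scaffold copies per disc.
    """
    if a280 < 0 or path_cm <= 0:
        raise ValidationError("a280 must be >= 0 and path length > 0")
    msp_uM = a280 / (spec.epsilon_280 * path_cm) * 1e6
    return msp_uM / spec.msp_per_nd


# ---------------------------------------------------------------------------
# I/O for the COIN CSV dialect: time_min,ab_ligand,ab_protein (+ JSON sidecar)


def read_coin_csv(path, p0: float | None = None) -> COINDataset:
    """Read a time course from CSV; ``p0`` (µM) comes from the argument or
    a ``<path>.json`` sidecar holding ``{"p0_uM": ...}``."""
    df = pd.read_csv(path)
    needed = {"time_min", "ab_ligand", "ab_protein"}
    if not needed.issubset(df.columns):
        raise ValidationError(
            f"{path}: COIN CSV needs columns {sorted(needed)}, got {list(df.columns)}")
    if p0 is None:
        sidecar = str(path) + ".json"
        try:
            with open(sidecar) as fh:
                p0 = float(json.load(fh)["p0_uM"])
        except FileNotFoundError:
            raise ValidationError(
                f"{path}: p0 not given and sidecar {sidecar} not found")
    return COINDataset(times=df["time_min"].to_numpy(),
                       ab_ligand=df["ab_ligand"].to_numpy(),
                       ab_protein=df["ab_protein"].to_numpy(), p0=p0)


def write_coin_csv(ds: COINDataset, path) -> None:
    """Write a time course plus its ``{"p0_uM": ...}`` sidecar."""
    pd.DataFrame({"time_min": ds.times, "ab_ligand": ds.ab_ligand,
                  "ab_protein": ds.ab_protein}).to_csv(path, index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump({"p0_uM": ds.p0}, fh)
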