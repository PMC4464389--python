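"""From a raw microprobe trace to an effective-diffusivity estimate.

A Clark-type oxygen microsensor driven along a line through a pellet
yields concentration versus probe depth.  Image analysis supplies the
pellet diameter and the depth at which the probe crosses the pellet
surface, which splits the trace into bulk, boundary-layer and in-pellet
points.  In-pellet depths are mapped to radial coordinates (the probe
axis is assumed to pass through the pellet centre) and the steady
reaction-diffusion model is fitted to them by nonlinear least squares
with the effective diffusivity as the single free parameter; the
kinetic parameters are fixed to independently determined values.

Replicate fits from the same cultivation hour are aggregated to a mean
and sample standard deviation, the form in which per-hour diffusivities
and external efficiencies are usually tabulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .pellet_model import (
    DETECTION_LIMIT_MG_L,
    MMKinetics,
    PelletGeometry,
    SolverError,
    solve_pellet_profile,
)

__all__ = [
    "OxygenProfile",
    "DiffusivityFit",
    "FitOptions",
    "classify_points",
    "depth_to_radius",
    "fit_deff",
    "aggregate_fits",
]

logger = logging.getLogger(__name__)

POINT_CLASSES = ("bulk", "boundary_layer", "pellet")

#: In-pellet concentration below which a point carries little information
#: about D_eff (signal within ~2 noise sd of zero).
LOW_SIGNAL_MG_L = 0.05


@dataclass
class OxygenProfile:
    """One classified microprobe trace through a single pellet.

    positions are probe depths (um, strictly increasing), concentrations
    in mg O2/l.  ``point_class`` assigns each point to bulk,
    boundary_layer or pellet; ``surface_depth`` is the probe depth of the
    pellet surface from image analysis.
    """

    positions: np.ndarray
    concentrations: np.ndarray
    point_class: np.ndarray
    diameter: float
    surface_depth: float
    hour: float = float("nan")
    replicate: str = ""
    censored: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.point_class = np.asarray(self.point_class, dtype=object)
        if self.positions.ndim != 1 or len(self.positions) != len(self.concentrations):
            raise ValueError("positions and concentrations must be 1-D and equal length")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if not self.diameter > 0:
            raise ValueError("pellet diameter must be positive")

    @property
    def geometry(self) -> PelletGeometry:
        return PelletGeometry(self.diameter)

    def mask(self, cls: str) -> np.ndarray:
        return self.point_class == cls

    @property
    def n_pellet_points(self) -> int:
        return int(np.sum(self.mask("pellet")))

    @property
    def c_surface_measured(self) -> float:
        """Concentration at the first in-pellet point (the pellet surface)."""
        idx = np.nonzero(self.mask("pellet"))[0]
        if len(idx) == 0:
            raise ValueError("profile has no in-pellet points")
        return float(self.concentrations[idx[0]])

    @property
    def c_bulk_measured(self) -> float:
        """Mean concentration over the bulk points."""
        m = self.mask("bulk")
        if not m.any():
            raise ValueError("profile has no bulk points")
        return float(np.mean(self.concentrations[m]))


@dataclass
class DiffusivityFit:
    """Result of a single-pellet effective-diffusivity fit."""

    d_eff_hat: float                 # um^2/s
    standard_error: float            # um^2/s
    c_surface_used: float            # mg/l
    residuals: np.ndarray            # mg/l, in-pellet points
    n_points: int
    converged: bool
    ill_conditioned: bool
    hour: float = float("nan")
    replicate: str = ""
    message: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def rms_residual(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2))) if len(self.residuals) else float("nan")

    def to_dict(self) -> dict:
        return {
            "d_eff_um2_s": self.d_eff_hat,
            "standard_error_um2_s": self.standard_error,
            "c_surface_mg_l": self.c_surface_used,
            "rms_residual_mg_l": self.rms_residual,
            "n_points": self.n_points,
            "converged": self.converged,
            "ill_conditioned": self.ill_conditioned,
            "hour": self.hour,
            "replicate": self.replicate,
            "probe_axis_assumption": "through pellet centre",
        }


@dataclass
class FitOptions:
    """Controls for :func:`fit_deff`.

    d_eff bounds bracket the plausible range for fungal pellets; the
    initial guess sits inside it.  ``fit_c_surface`` co-estimates the
    surface concentration instead of pinning it to the measured surface
    point; ``fit_kinetics`` additionally frees (r_max, K_M) for
    sensitivity studies.
    """

    d_eff_init: float = 1000.0
    d_eff_bounds: tuple[float, float] = (100.0, 5000.0)
    fit_c_surface: bool = False
    fit_kinetics: bool = False
    solver_method: str = "finite_difference"


def classify_points(
    positions,
    concentrations,
    surface_depth: float,
    boundary_layer_start: float,
    diameter: float,
    hour: float = float("nan"),
    replicate: str = "",
) -> OxygenProfile:
    """Split a raw trace into bulk / boundary-layer / in-pellet points.

    Points at depths before ``boundary_layer_start`` are bulk, between
    there and ``surface_depth`` boundary layer, and from the surface
    inward pellet.  The surface itself (depth >= surface_depth) belongs
    to the pellet, so the first pellet point carries the measured surface
    concentration.
    """
    positions = np.asarray(positions, dtype=float)
    concentrations = np.asarray(concentrations, dtype=float)
    if not (positions[0] <= surface_depth <= positions[-1]):
        raise ValueError(
            f"surface_depth {surface_depth} um outside the trace range "
            f"[{positions[0]}, {positions[-1]}] um"
        )
    if boundary_layer_start > surface_depth:
        raise ValueError("boundary_layer_start must not exceed surface_depth")
    cls = np.empty(len(positions), dtype=object)
    cls[positions < boundary_layer_start] = "bulk"
    cls[(positions >= boundary_layer_start) & (positions < surface_depth)] = "boundary_layer"
    cls[positions >= surface_depth] = "pellet"
    if np.sum((cls == "pellet") & (positions > surface_depth)) == 0:
        raise ValueError("no in-pellet points: pellet surface at or beyond the last probe depth")
    return OxygenProfile(
        positions=positions,
        concentrations=concentrations,
        point_class=cls,
        diameter=diameter,
        surface_depth=surface_depth,
        hour=hour,
        replicate=replicate,
    )


def depth_to_radius(profile: OxygenProfile):
    """Radial coordinates of the in-pellet points.

    r = R - (depth - surface_depth), assuming the probe axis passes
    through the pellet centre.  Points that would map past the centre
    (r < 0) are rejected with a warning and reported in the mask.

    Returns
    -------
    (r, c, kept) : radii (um), concentrations (mg/l) of kept points and
    the boolean keep-mask over the in-pellet points.
    """
    R = profile.geometry.radius
    m = profile.mask("pellet")
    depth = profile.positions[m]
    conc = profile.concentrations[m]
    r = R - (depth - profile.surface_depth)
    kept = r >= 0
    n_rejected = int(np.sum(~kept))
    if n_rejected:
        warnings.warn(
            f"{n_rejected} in-pellet point(s) map beyond the pellet centre "
            "(off-chord or oversized trace) and were rejected",
            stacklevel=2,
        )
    return r[kept], conc[kept], kept


def _model_profile(r, geom, kin, d_eff, c_surface, method):
    sol = solve_pellet_profile(geom, kin, d_eff, c_surface, method=method)
    return sol.interpolate(r)


def fit_deff(
    profile: OxygenProfile,
    kin: MMKinetics | None = None,
    options: FitOptions | None = None,
) -> DiffusivityFit:
    """Least-squares effective diffusivity from one classified trace.

    Minimises sum_i [c_model(r_i; D_eff) - c_i]^2 over the in-pellet
    points, with the surface concentration pinned to the measured surface
    point unless ``options.fit_c_surface``.  The asymptotic standard
    error comes from the Jacobian at the optimum.  The fit is flagged
    ill-conditioned when more than 80 % of the in-pellet points sit below
    0.05 mg/l (signal close to the detection limit), in which case the
    estimate is still returned but should be read with caution.
    """
    kin = kin or MMKinetics()
    options = options or FitOptions()
    r, c_obs, _ = depth_to_radius(profile)
    if len(r) < 4:
        raise ValueError(f"need at least 4 in-pellet points to fit, got {len(r)}")
    order = np.argsort(r)
    r, c_obs = r[order], c_obs[order]
    geom = profile.geometry
    c_surf0 = profile.c_surface_measured
    low_signal_frac = float(np.mean(c_obs < LOW_SIGNAL_MG_L))
    ill = low_signal_frac > 0.8

    lo, hi = options.d_eff_bounds
    x0 = [np.clip(options.d_eff_init, lo, hi)]
    lb, ub = [lo], [hi]
    if options.fit_c_surface:
        x0.append(max(c_surf0, DETECTION_LIMIT_MG_L))
        lb.append(0.0)
        ub.append(np.inf)
    if options.fit_kinetics:
        x0 += [kin.r_max, kin.K_M]
        lb += [0.0, 1e-6]
        ub += [np.inf, np.inf]

    def unpack(x):
        d_eff = x[0]
        c_s = x[1] if options.fit_c_surface else c_surf0
        k = (
            MMKinetics(x[-2], x[-1]) if options.fit_kinetics else kin
        )
        return d_eff, c_s, k

    def residual(x):
        d_eff, c_s, k = unpack(x)
        try:
            model = _model_profile(r, geom, k, d_eff, c_s, options.solver_method)
        except SolverError as exc:
            logger.warning("solver failure during fit at D_eff=%.1f: %s", d_eff, exc)
            return np.full_like(c_obs, 1e3)
        return model - c_obs

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = least_squares(
            residual,
            x0,
            bounds=(lb, ub),
            method="trf",
            x_scale=[max(abs(v), 1.0) for v in x0],
            xtol=1e-10,
            ftol=1e-12,
            gtol=1e-12,
        )
    converged = bool(result.success)
    res = result.fun
    n, p = len(res), len(x0)
    dof = max(n - p, 1)
    try:
        jtj = result.jac.T @ result.jac
        cov = np.linalg.inv(jtj) * (res @ res) / dof
        se = float(np.sqrt(cov[0, 0]))
    except np.linalg.LinAlgError:
        se = float("nan")
        ill = True
    d_eff_hat, c_s_hat, kin_hat = unpack(result.x)
    return DiffusivityFit(
        d_eff_hat=float(d_eff_hat),
        standard_error=se,
        c_surface_used=float(c_s_hat),
        residuals=res,
        n_points=n,
        converged=converged,
        ill_conditioned=ill,
        hour=profile.hour,
        replicate=profile.replicate,
        message=result.message,
        meta={
            "low_signal_fraction": low_signal_frac,
            "kinetics": {"r_max": kin_hat.r_max, "K_M": kin_hat.K_M},
            "fit_c_surface": options.fit_c_surface,
            "at_bound": bool(d_eff_hat <= lo * 1.0001 or d_eff_hat >= hi * 0.9999),
        },
    )


def aggregate_fits(fits, eta_external=None) -> pd.DataFrame:
    """Per-hour mean and sample sd of fitted diffusivities.

    Parameters
    ----------
    fits : iterable of DiffusivityFit
        Only converged fits enter the aggregate; hours whose group ends
        up empty are skipped with a log entry.
    eta_external : mapping, optional
        ``{(hour, replicate): eta_em}`` external efficiencies to average
        alongside.

    Returns
    -------
    DataFrame indexed by hour with columns d_eff_mean_um2_s,
    d_eff_sd_um2_s, n, single_fit (sd reported as 0 when only one fit is
    available) and, when supplied, eta_em_mean / eta_em_sd.
    """
    rows = []
    fits = list(fits)
    hours = sorted({f.hour for f in fits})
    for hour in hours:
        group = [f for f in fits if f.hour == hour and f.converged]
        if not group:
            logger.info("hour %s skipped: no converged fits", hour)
            continue
        vals = np.array([f.d_eff_hat for f in group])
        row = {
            "hour": hour,
            "d_eff_mean_um2_s": float(vals.mean()),
            "d_eff_sd_um2_s": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "n": len(vals),
            "single_fit": len(vals) == 1,
            "any_ill_conditioned": any(f.ill_conditioned for f in group),
        }
        if eta_external is not None:
            etas = [
                eta_external[(f.hour, f.replicate)]
                for f in group
                if (f.hour, f.replicate) in eta_external
            ]
            if etas:
                e = np.array(etas, dtype=float)
                row["eta_em_mean"] = float(e.mean())
                row["eta_em_sd"] = float(e.std(ddof=1)) if len(e) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("hour") if rows else pd.DataFrame()
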