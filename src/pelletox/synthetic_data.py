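"""Synthetic microprobe traces and batch fermentation records.

No raw measurements accompany the study conditions this package targets,
so every downstream stage is exercised against simulated data with known
ground truth: Clark-microsensor-like oxygen depth profiles through
single pellets (bulk plateau near air saturation, a visible
boundary-layer gradient, the internal reaction-diffusion field, Gaussian
read noise and detection-limit censoring) and shake-flask batch curves
from a small declared growth model (Monod growth on lactose with
organic-nitrogen co-limitation, a linear-growth-phase cap emulating
transfer limitation, maintenance uptake, and mixed growth-associated
lovastatin production that shuts off at lactose exhaustion).

Every generator returns the observation together with the noiseless
truth; recovery tests consume the truth only through assertions.  All
randomness flows from the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .batch_rates import BatchTimeSeries, RateSeries
from .effectiveness import (
    DEFAULT_MEDIUM_DIFFUSIVITY,
    DEFAULT_SHERWOOD,
    couple_film_pellet,
)
from .pellet_model import (
    DETECTION_LIMIT_MG_L,
    MMKinetics,
    PelletGeometry,
    PelletSolution,
    transient_no_reaction,
)
from .profile_fitting import OxygenProfile, classify_points

__all__ = [
    "ProfileScenario",
    "ProfileTruth",
    "BatchScenario",
    "generate_profile",
    "generate_profiles",
    "generate_dead_profile",
    "generate_batch",
]


@dataclass
class ProfileScenario:
    """Conditions of one simulated microprobe measurement.

    The bulk sits near air saturation (default 7.5 mg/l; saturation is
    about 8 mg/l), probe read noise has sd 0.03 mg/l and the detection
    limit is 0.01 mg/l, matching the instrument the generator emulates.
    The boundary layer is rendered one pellet radius thick, the
    quiescent-film (Sh = 2) equivalent used for the flux balance.
    """

    diameter: float = 2000.0          # um
    d_eff: float = 900.0              # um^2/s, ground truth
    kinetics: MMKinetics = field(default_factory=MMKinetics)
    c_bulk: float = 7.5               # mg/l
    sherwood: float = DEFAULT_SHERWOOD
    d_medium: float = DEFAULT_MEDIUM_DIFFUSIVITY
    probe_step: float = 50.0          # um
    noise_sd: float = 0.03            # mg/l
    detection_limit: float = DETECTION_LIMIT_MG_L
    bulk_margin: float = 300.0        # um of bulk before the film
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diameter", "d_eff", "c_bulk", "sherwood", "d_medium", "probe_step"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def geometry(self) -> PelletGeometry:
        return PelletGeometry(self.diameter)

    @property
    def surface_depth(self) -> float:
        """Probe depth of the pellet surface: bulk margin + film (= R)."""
        return self.bulk_margin + self.geometry.radius

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kinetics"] = {"r_max": self.kinetics.r_max, "K_M": self.kinetics.K_M}
        return d


@dataclass
class ProfileTruth:
    """Noiseless ground truth accompanying a generated profile."""

    scenario: ProfileScenario
    c_surface: float
    solution: PelletSolution
    positions: np.ndarray
    concentrations: np.ndarray        # noiseless model curve at the probe depths
    censored_fraction: float = 0.0


def _model_curve(scenario: ProfileScenario, solution: PelletSolution, c_surface: float):
    """Noiseless concentration versus probe depth for the whole trace."""
    R = scenario.geometry.radius
    surface = scenario.surface_depth
    # anchor the grid at the pellet surface so the surface concentration
    # is actually sampled (the probe is zeroed on the surface crossing)
    n_out = int(math.floor(surface / scenario.probe_step))
    n_in = int(math.floor(R / scenario.probe_step + 1e-9))
    depth = surface + scenario.probe_step * np.arange(-n_out, n_in + 1)
    c = np.empty(len(depth))
    bulk = depth < scenario.bulk_margin
    film = (~bulk) & (depth < surface)
    pellet = depth >= surface
    c[bulk] = scenario.c_bulk
    # quasi-steady spherical-shell profile across the film (R..2R), matched
    # continuously to the bulk at its outer edge and c_S at the surface
    r_film = R + (surface - depth[film])
    c[film] = c_surface + (scenario.c_bulk - c_surface) * (2.0 - 2.0 * R / r_film)
    r_in = np.clip(R - (depth[pellet] - surface), 0.0, R)
    c[pellet] = solution.interpolate(r_in)
    return depth, np.clip(c, 0.0, None)


def _sample(scenario: ProfileScenario, depth, c_true, rng, replicate: str, hour: float):
    noisy = c_true + rng.normal(0.0, scenario.noise_sd, size=len(c_true))
    noisy = np.clip(noisy, 0.0, None)
    censored = noisy < scenario.detection_limit
    noisy[censored] = scenario.detection_limit
    profile = classify_points(
        depth,
        noisy,
        surface_depth=scenario.surface_depth,
        boundary_layer_start=scenario.bulk_margin,
        diameter=scenario.diameter,
        hour=hour,
        replicate=replicate,
    )
    profile.censored = censored
    profile.meta.update(
        scenario=scenario.to_dict(),
        censored_fraction=float(censored.mean()),
    )
    return profile


def generate_profile(
    scenario: ProfileScenario, hour: float = float("nan"), replicate: str = "r1"
):
    """Simulate one viable-pellet microprobe trace.

    Solves the film/pellet coupling for the surface concentration,
    renders bulk, film and internal segments at the probe step, then adds
    Gaussian read noise, truncates at zero and censors below the
    detection limit (censored points are set to the detection limit and
    flagged).

    Returns
    -------
    (OxygenProfile, ProfileTruth)
    """
    profiles, truth = generate_profiles(scenario, 1, hour=hour, replicate_prefix=replicate)
    return profiles[0], truth


def generate_profiles(
    scenario: ProfileScenario,
    n_replicates: int,
    hour: float = float("nan"),
    replicate_prefix: str = "r",
):
    """Simulate ``n_replicates`` noisy traces of the same pellet state.

    The (deterministic) model curve is solved once; each replicate draws
    independent noise from the scenario seed.
    """
    c_surface, solution, _ = couple_film_pellet(
        scenario.geometry,
        scenario.kinetics,
        scenario.d_eff,
        scenario.c_bulk,
        d_medium=scenario.d_medium,
        sherwood=scenario.sherwood,
    )
    depth, c_true = _model_curve(scenario, solution, c_surface)
    rng = np.random.default_rng(scenario.seed)
    profiles = []
    frac = 0.0
    for i in range(n_replicates):
        name = replicate_prefix if n_replicates == 1 else f"{replicate_prefix}{i + 1}"
        p = _sample(scenario, depth, c_true, rng, name, hour)
        frac += p.meta["censored_fraction"]
        profiles.append(p)
    truth = ProfileTruth(
        scenario=scenario,
        c_surface=c_surface,
        solution=solution,
        positions=depth,
        concentrations=c_true,
        censored_fraction=frac / n_replicates,
    )
    return profiles, truth


def generate_dead_profile(
    scenario: ProfileScenario,
    elapsed_time_s: float,
    c_initial: float = 0.0,
    hour: float = float("nan"),
    replicate: str = "dead",
):
    """Simulate a trace through a deactivated (non-respiring) pellet.

    The internal field is the transient pure-diffusion solution at the
    given elapsed time with the surface held at the bulk concentration
    (no uptake, so no steady film gradient); sampling and noise follow
    the same pipeline as viable pellets.
    """
    if elapsed_time_s < 0:
        raise ValueError("elapsed time must be nonnegative")
    solution = transient_no_reaction(
        scenario.geometry, scenario.d_eff, scenario.c_bulk, c_initial, [elapsed_time_s]
    )[0]
    depth, c_true = _model_curve(scenario, solution, scenario.c_bulk)
    rng = np.random.default_rng(scenario.seed)
    profile = _sample(scenario, depth, c_true, rng, replicate, hour)
    truth = ProfileTruth(
        scenario=scenario,
        c_surface=scenario.c_bulk,
        solution=solution,
        positions=depth,
        concentrations=c_true,
    )
    return profile, truth


# ---------------------------------------------------------------------------
# Batch fermentation model
# ---------------------------------------------------------------------------

@dataclass
class BatchScenario:
    """A simple declared batch growth model for rate-recovery testing.

    States: biomass X (g/l), lactose LAC (g/l), organic nitrogen N
    (g/l), lovastatin LOV (mg/l).  Growth is Monod in lactose with
    nitrogen co-limitation; the realised growth rate is the harmonic
    minimum of the Monod potential and a linear-phase cap ``r_lin``
    (transfer-limited linear growth).  Lactose is consumed for growth
    (yield Y_XS) and maintenance; lovastatin forms in mixed
    growth-associated mode and shuts off with the lactose Monod factor.
    Default parameters put the trajectory magnitudes in the ranges the
    emulated cultivations show: biomass approaching ~10 g/l at ~0.1
    g/l/h, a lactose-uptake peak near 0.3 g/l/h before 72 h with
    exhaustion before 96 h, and a lovastatin peak rate near 1.5 mg/l/h
    with a titre near 90 mg/l.
    """

    lactose_0: float = 20.0       # g/l (study range 2.5-40)
    biomass_0: float = 0.1        # g/l
    nitrogen_0: float = 0.5       # g/l
    lovastatin_0: float = 0.0     # mg/l
    mu_max: float = 0.25          # 1/h
    K_lac: float = 1.0            # g/l
    K_N: float = 0.05             # g/l
    r_lin: float = 0.13           # g/l/h linear-phase growth cap
    Y_XS: float = 0.5             # g X / g LAC
    m_S: float = 0.008            # g LAC / g X / h maintenance
    Y_XN: float = 25.0            # g X / g N
    alpha_lov: float = 5.0        # mg LOV / g X (growth-associated)
    beta_lov: float = 0.16        # mg LOV / g X / h (non-growth-associated)
    t_end: float = 168.0          # h
    sample_every: float = 12.0    # h
    noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lactose_0, self.biomass_0, self.nitrogen_0, self.lovastatin_0) < 0:
            raise ValueError("initial states must be nonnegative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")

    @property
    def observation_times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 0.5 * self.sample_every, self.sample_every)

    def rhs(self, t, y):
        X, LAC, N, LOV = np.maximum(y, 0.0)
        f_lac = LAC / (self.K_lac + LAC)
        f_n = N / (self.K_N + N)
        mu_pot = self.mu_max * f_lac * f_n * X
        r_X = mu_pot * self.r_lin / (mu_pot + self.r_lin) if mu_pot > 0 else 0.0
        dX = r_X
        dLAC = -r_X / self.Y_XS - self.m_S * X * f_lac
        dN = -r_X / self.Y_XN
        dLOV = (self.alpha_lov * r_X + self.beta_lov * X) * f_lac
        return [dX, dLAC, dN, dLOV]


def generate_batch(scenario: BatchScenario):
    """Integrate the batch model and sample noisy observations.

    Returns
    -------
    (BatchTimeSeries, RateSeries)
        Noisy observations at the scenario's sampling times
        (multiplicative Gaussian noise with the given CV, truncated at
        zero) and the exact instantaneous rates on a 1 h grid, in the
        reporting sign convention (uptake positive for LAC and N).
    """
    y0 = [scenario.biomass_0, scenario.lactose_0, scenario.nitrogen_0, scenario.lovastatin_0]
    sol = solve_ivp(
        scenario.rhs,
        (0.0, scenario.t_end),
        y0,
        method="LSODA",
        rtol=1e-9,
        atol=1e-12,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"batch model integration failed: {sol.message}")

    t_obs = scenario.observation_times
    states = np.clip(sol.sol(t_obs), 0.0, None)  # rows: X, LAC, N, LOV
    rng = np.random.default_rng(scenario.seed)
    noisy = states * (1.0 + scenario.noise_cv * rng.standard_normal(states.shape))
    noisy = np.clip(noisy, 0.0, None)
    observed = BatchTimeSeries(
        times=t_obs,
        concentrations={
            "X": noisy[0],
            "LAC": noisy[1],
            "N": noisy[2],
            "LOV": noisy[3],
        },
    )

    grid = np.arange(0.0, scenario.t_end + 0.5, 1.0)
    y_grid = np.clip(sol.sol(grid), 0.0, None)
    deriv = np.array([scenario.rhs(t, y) for t, y in zip(grid, y_grid.T)]).T
    truth = RateSeries(
        times=grid,
        rates={
            "X": deriv[0],
            "LAC": -deriv[1],   # uptake sign convention
            "N": -deriv[2],
            "LOV": deriv[3],
        },
        smoothed={
            "X": y_grid[0],
            "LAC": y_grid[1],
            "N": y_grid[2],
            "LOV": y_grid[3],
        },
        boundary=np.isin(np.arange(len(grid)), [0, len(grid) - 1]),
    )
    return observed, truth
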