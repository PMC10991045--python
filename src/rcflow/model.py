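"""Kinetic model of multi-turnover electron transfer through the bacterial RC.

The reaction center (RC) is tracked over the product state space
``(P | P+) x (QA | QA-) x (QB | QB- | QBH2)`` — 12 redox states — coupled to a
finite pool of periplasmic one-electron donors.  Transitions:

* photochemical closure: an open RC ``(P, QA, b)`` undergoes charge separation
  to ``(P+, QA-, b)``; the ensemble closure flux is ``k_I * (1 - phi(x; p))``,
  i.e. every absorbed exciton that is not lost as fluorescence closes an RC,
  with ``phi`` the fluorescence yield at closed fraction ``x`` and inter-unit
  hopping probability ``p``;
* donor side: ``(P+, a, b) -> (P, a, b)`` by second-order reaction with the
  reduced donor pool, rate ``k2 * [donor]``; the pool is consumed
  stoichiometrically and never regenerated (cyt bc1 recycling is kinetically
  blocked by construction);
* acceptor side: first inter-quinone transfer ``QA- QB -> QA QB-`` (rate A1),
  second transfer ``QA- QB- -> QA QBH2`` (rate A2), and quinol/quinone
  exchange ``QBH2 -> QB`` (rate E, membrane quinone pool in large excess and
  treated as unlimited).

Two exciton-connectivity yield maps are provided: the cubic cluster
mean-field polynomial (the simulator default) and the hyperbolic
(Joliot-type) map used for redox-state reconstruction from measured traces.
They agree at the endpoints and in the initial slope but differ at
intermediate ``x`` for ``p > 0``; they are never mixed silently — the map is
an explicit argument wherever it matters.

A Gillespie-type stochastic ensemble simulator of the identical scheme acts
as an independent oracle for the deterministic mean field.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "RateParameters",
    "RCStateDistribution",
    "SimulationResult",
    "OracleResult",
    "STATE_LABELS",
    "fluorescence_yield",
    "hyperbolic_yield",
    "closed_fraction_from_yield",
    "ode_rhs",
    "simulate",
    "simulate_to_saturation",
    "stochastic_oracle",
    "load_rate_parameters",
    "save_rate_parameters",
    "PRESETS",
    "DIFFUSION_LIMIT_K2",
]

DIFFUSION_LIMIT_K2 = 1.0e10  # M^-1 s^-1, diffusion limit for donor binding

#: state index = 6*d + 3*a + b with d in (P, P+), a in (QA, QA-),
#: b in (QB, QB-, QBH2)
STATE_LABELS: tuple[tuple[str, str, str], ...] = tuple(
    (d, a, b)
    for d in ("P", "P+")
    for a in ("QA", "QA-")
    for b in ("QB", "QB-", "QBH2")
)
N_STATES = 12

_OPEN = (0, 1, 2)            # (P, QA, b): the only photochemically active states
_P_PLUS = tuple(range(6, 12))
_PQA_MINUS = (3, 4, 5)       # (P, QA-, b): closed on the acceptor side only
_A1_SRC = (3, 9)             # (d, QA-, QB)   -> (d, QA, QB-)
_A1_DST = (1, 7)
_A2_SRC = (4, 10)            # (d, QA-, QB-)  -> (d, QA, QBH2)
_A2_DST = (2, 8)
_E_SRC = (2, 5, 8, 11)       # (d, a, QBH2)   -> (d, a, QB)
_E_DST = (0, 3, 6, 9)


class ModelError(ValueError):
    """Invalid model input (parameter or state outside its domain)."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; the offending parameters are echoed."""


# --------------------------------------------------------------------------
# parameters and state containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RateParameters:
    """Kinetic and optical constants of the multi-turnover scheme.

    Attributes
    ----------
    k_I:
        Photochemical rate constant (s^-1), proportional to light intensity.
    k2:
        Bimolecular rate constant of P+ re-reduction by a pool donor
        (M^-1 s^-1); values above the ~1e10 diffusion limit trigger a warning.
    rc_conc:
        Reaction-center concentration (M).
    A1, A2:
        First and second inter-quinone electron-transfer rate constants
        (s^-1).  ``A1 = 0`` represents terbutryn inhibition.
    E:
        Quinol/quinone exchange rate constant (s^-1).
    p:
        Inter-unit exciton hopping (connectivity) probability, in [0, 1).
    pool:
        Initial reduced-donor pool size, donors per RC (dimensionless).
    """

    k_I: float
    k2: float
    rc_conc: float
    A1: float
    A2: float
    E: float
    p: float
    pool: float

    def __post_init__(self) -> None:
        for name in ("k_I", "k2", "A1", "A2", "E"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.p < 1:
            raise ModelError(f"p must be in [0, 1), got {self.p}")
        if self.pool < 0:
            raise ModelError(f"pool must be >= 0, got {self.pool}")
        if self.rc_conc <= 0:
            raise ModelError(f"rc_conc must be > 0, got {self.rc_conc}")
        if self.k2 > DIFFUSION_LIMIT_K2:
            warnings.warn(
                f"k2 = {self.k2:g} M^-1 s^-1 exceeds the diffusion limit "
                f"{DIFFUSION_LIMIT_K2:g}",
                stacklevel=2,
            )

    def replace(self, **kwargs) -> "RateParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "k_I": self.k_I, "k2": self.k2, "rc_conc": self.rc_conc,
            "A1": self.A1, "A2": self.A2, "E": self.E,
            "p": self.p, "pool": self.pool,
        }


#: Published simulation parameter sets.  ``pool_scan`` is the donor-pool
#: titration set used for the phi(P+) curvature study (pool varied 0-1.5
#: donors/RC); ``qa_redox`` is the set used for the PQA- rise/decay kinetics.
PRESETS: dict[str, RateParameters] = {
    "pool_scan": RateParameters(
        k_I=8e3, k2=1e10, rc_conc=8e-6, A1=3e4, A2=2e3, E=1e2, p=0.3, pool=1.5
    ),
    "qa_redox": RateParameters(
        k_I=2e4, k2=6e9, rc_conc=3e-6, A1=3e3, A2=1e3, E=1e2, p=0.3, pool=2.0
    ),
}

_PARAM_KEYS = ("k_I", "k2", "rc_conc", "A1", "A2", "E", "p", "pool")


def load_rate_parameters(path) -> RateParameters:
    """Load parameters from YAML or JSON with keys exactly ``k_I, k2,
    rc_conc, A1, A2, E, p, pool`` (SI units)."""
    text = open(path).read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ModelError(f"{path}: expected a mapping of parameter names")
    missing = [k for k in _PARAM_KEYS if k not in data]
    if missing:
        raise ModelError(f"{path}: missing parameter keys {missing}")
    extra = [k for k in data if k not in _PARAM_KEYS]
    if extra:
        raise ModelError(f"{path}: unknown parameter keys {extra}")
    return RateParameters(**{k: float(data[k]) for k in _PARAM_KEYS})


def save_rate_parameters(params: RateParameters, path) -> None:
    with open(path, "w") as fh:
        if str(path).endswith(".json"):
            json.dump(params.to_dict(), fh, indent=1)
        else:
            yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class RCStateDistribution:
    """Occupancy fractions over the 12 RC redox states plus donor concentration.

    ``fractions`` is indexed consistently with :data:`STATE_LABELS`; it must
    be a probability vector (sum 1 within 1e-8).  ``donor_conc`` is the
    reduced-donor concentration in M.
    """

    fractions: np.ndarray
    donor_conc: float

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", frac)
        if frac.shape != (N_STATES,):
            raise ModelError(f"fractions must have shape ({N_STATES},)")
        if np.any(frac < -1e-12) or np.any(frac > 1 + 1e-12):
            raise ModelError("fractions must lie in [0, 1]")
        if abs(frac.sum() - 1.0) > 1e-8:
            raise ModelError(f"fractions sum to {frac.sum()!r}, expected 1 ± 1e-8")
        if self.donor_conc < 0:
            raise ModelError("donor_conc must be >= 0")

    @classmethod
    def all_open(cls, params: RateParameters) -> "RCStateDistribution":
        """Dark-adapted start: every RC in (P, QA, QB), full reduced pool."""
        frac = np.zeros(N_STATES)
        frac[0] = 1.0
        return cls(frac, params.pool * params.rc_conc)

    @classmethod
    def from_dict(cls, fractions: dict, donor_conc: float) -> "RCStateDistribution":
        frac = np.zeros(N_STATES)
        for key, value in fractions.items():
            frac[STATE_LABELS.index(tuple(key))] = value
        return cls(frac, donor_conc)

    def as_dict(self) -> dict[tuple[str, str, str], float]:
        return dict(zip(STATE_LABELS, self.fractions))

    @property
    def open_fraction(self) -> float:
        return float(self.fractions[list(_OPEN)].sum())

    @property
    def closed_fraction(self) -> float:
        return 1.0 - self.open_fraction

    @property
    def p_plus(self) -> float:
        return float(self.fractions[list(_P_PLUS)].sum())

    @property
    def pqa_minus(self) -> float:
        return float(self.fractions[list(_PQA_MINUS)].sum())


# --------------------------------------------------------------------------
# yield maps
# --------------------------------------------------------------------------

def _check_domain(x, p) -> None:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ModelError(f"closed fraction x must lie in [0, 1], got {x}")
    if not 0 <= p < 1:
        raise ModelError(f"hopping probability p must lie in [0, 1), got {p}")


def fluorescence_yield(x, p: float):
    """Cluster mean-field fluorescence yield phi(x; p).

    ``phi = (1-p) x + (1-p) p x^2 + p^2 (x^2/4 + 3 x^3/4)`` — the cubic
    polynomial of the closed fraction ``x`` obtained by averaging exciton
    random walks over small clusters of connected photosynthetic units.
    Exact endpoints: phi(0) = 0, phi(1) = 1; strictly increasing in ``x``.
    """
    _check_domain(x, p)
    x = np.asarray(x, dtype=float)
    out = (1 - p) * x + (1 - p) * p * x**2 + p**2 * (x**2 / 4 + 3 * x**3 / 4)
    return float(out) if out.ndim == 0 else out


def hyperbolic_yield(x, p: float):
    """Hyperbolic (Joliot-type) yield map ``phi = x (1-p) / (1 - p x)``."""
    _check_domain(x, p)
    x = np.asarray(x, dtype=float)
    out = x * (1 - p) / (1 - p * x)
    return float(out) if out.ndim == 0 else out


def closed_fraction_from_yield(phi, p: float):
    """Invert the hyperbolic yield map: ``x = phi / (1 - p (1 - phi))``.

    This is the reconstruction formula applied to measured normalized
    variable fluorescence; it is the exact inverse of
    :func:`hyperbolic_yield`.
    """
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr > 1):
        raise ModelError(f"phi must lie in [0, 1], got {phi}")
    if not 0 <= p < 1:
        raise ModelError(f"hopping probability p must lie in [0, 1), got {p}")
    out = phi_arr / (1 - p * (1 - phi_arr))
    return float(out) if out.ndim == 0 else out


_YIELD_MAPS = {"cluster": fluorescence_yield, "hyperbolic": hyperbolic_yield}


# --------------------------------------------------------------------------
# deterministic mean-field ODE
# --------------------------------------------------------------------------

def _rhs(t: float, y: np.ndarray, params: RateParameters, k_I_eff: float,
         yield_fn) -> np.ndarray:
    """Packed RHS: y = [12 fractions, donor_conc, cumulative separations]."""
    frac = y[:N_STATES]
    donor = max(y[N_STATES], 0.0)
    dy = np.zeros_like(y)
    df = dy[:N_STATES]

    # photochemical closure: total flux k_I (1 - phi(x)), shared among the
    # open states in proportion to their occupancy
    open_tot = frac[0] + frac[1] + frac[2]
    if k_I_eff > 0 and open_tot > 0:
        x = min(max(1.0 - open_tot, 0.0), 1.0)
        flux = k_I_eff * (1.0 - yield_fn(x, params.p))
        for b in range(3):
            share = flux * frac[b] / open_tot
            df[b] -= share
            df[9 + b] += share      # (P+, QA-, b)
        dy[N_STATES + 1] = flux

    # donor side: (P+, a, b) -> (P, a, b) at k2 [donor]; pool consumed
    if params.k2 > 0 and donor > 0:
        d_rate = params.k2 * donor
        p_plus_tot = 0.0
        for i in range(6, 12):
            move = d_rate * frac[i]
            df[i] -= move
            df[i - 6] += move
            p_plus_tot += frac[i]
        dy[N_STATES] = -d_rate * p_plus_tot * params.rc_conc

    # acceptor side
    for src, dst in zip(_A1_SRC, _A1_DST):
        move = params.A1 * frac[src]
        df[src] -= move
        df[dst] += move
    for src, dst in zip(_A2_SRC, _A2_DST):
        move = params.A2 * frac[src]
        df[src] -= move
        df[dst] += move
    for src, dst in zip(_E_SRC, _E_DST):
        move = params.E * frac[src]
        df[src] -= move
        df[dst] += move
    return dy


def ode_rhs(state: RCStateDistribution, params: RateParameters,
            light_on: bool = True) -> tuple[np.ndarray, float]:
    """Time derivative of a state distribution under the reaction scheme.

    Returns ``(dfractions_dt, ddonor_conc_dt)``.  The fraction derivative
    sums to zero (mass conservation is built into every transition).
    """
    y = np.concatenate([state.fractions, [state.donor_conc, 0.0]])
    k_I_eff = params.k_I if light_on else 0.0
    dy = _rhs(0.0, y, params, k_I_eff, fluorescence_yield)
    return dy[:N_STATES], float(dy[N_STATES])


@dataclass(frozen=True)
class SimulationResult:
    """Dense trajectory of the mean-field simulation with derived observables.

    ``phi`` is computed from the closed fraction ``x`` through the yield map
    named in ``yield_map``; ``p_plus`` is the total oxidized-dimer fraction;
    ``pqa_minus`` the (P, QA-) marginal; ``cum_separations`` the running
    number of charge separations per RC.
    """

    params: RateParameters
    times: np.ndarray
    fractions: np.ndarray            # (n_times, 12)
    donor_conc: np.ndarray
    phi: np.ndarray
    p_plus: np.ndarray
    x: np.ndarray
    pqa_minus: np.ndarray
    cum_separations: np.ndarray
    light_on_duration: float
    yield_map: str = "cluster"

    @property
    def donor_per_rc(self) -> np.ndarray:
        return self.donor_conc / self.params.rc_conc

    def state_at(self, i: int) -> RCStateDistribution:
        frac = np.clip(self.fractions[i], 0.0, 1.0)
        return RCStateDistribution(frac / frac.sum(), max(self.donor_conc[i], 0.0))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time_s": self.times,
            "phi": self.phi,
            "p_plus": self.p_plus,
            "x": self.x,
            "pqa_minus": self.pqa_minus,
            "donor_per_rc": self.donor_per_rc,
            "cum_separations": self.cum_separations,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def _output_grid(total_time: float, n_points: int) -> np.ndarray:
    """Dense output grid: linear to 10 us, log-spaced beyond."""
    knee = min(1e-5, total_time / 10)
    n_lin = min(11, n_points // 4 + 2)
    lin = np.linspace(0.0, knee, n_lin)
    log = np.geomspace(knee, total_time, n_points - n_lin + 1)
    return np.unique(np.concatenate([lin, log]))


def simulate(
    params: RateParameters,
    light_on_duration: float,
    total_time: float | None = None,
    initial: RCStateDistribution | None = None,
    n_points: int = 2000,
    yield_map: str = "cluster",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimulationResult:
    """Integrate the mean-field scheme under a rectangular light pulse.

    The photochemical rate is ``k_I`` for ``t < light_on_duration`` and zero
    afterwards (continuous illumination is ``total_time == light_on_duration``,
    the default).  Output is on a fixed dense grid, linear for the first
    10 us and log-spaced beyond.
    """
    if light_on_duration <= 0:
        raise ModelError("light_on_duration must be > 0")
    if total_time is None:
        total_time = light_on_duration
    if total_time < light_on_duration:
        raise ModelError("total_time must be >= light_on_duration")
    if yield_map not in _YIELD_MAPS:
        raise ModelError(f"unknown yield_map {yield_map!r}")
    yield_fn = _YIELD_MAPS[yield_map]
    state0 = initial if initial is not None else RCStateDistribution.all_open(params)

    grid = _output_grid(total_time, n_points)
    y0 = np.concatenate([state0.fractions, [state0.donor_conc, 0.0]])

    segments = [(0.0, min(light_on_duration, total_time), params.k_I)]
    if total_time > light_on_duration:
        segments.append((light_on_duration, total_time, 0.0))

    times_out: list[np.ndarray] = []
    ys_out: list[np.ndarray] = []
    for t0, t1, k_I_eff in segments:
        mask = (grid >= t0) & (grid <= t1)
        t_eval = np.unique(np.concatenate([grid[mask], [t0, t1]]))
        sol = solve_ivp(
            _rhs, (t0, t1), y0, t_eval=t_eval, method="LSODA",
            rtol=rtol, atol=atol, args=(params, k_I_eff, yield_fn),
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE integration failed ({sol.message}) with parameters "
                f"{params.to_dict()}"
            )
        keep = np.isin(sol.t, grid[mask])
        times_out.append(sol.t[keep])
        ys_out.append(sol.y[:, keep])
        y0 = sol.y[:, -1]

    times = np.concatenate(times_out)
    ys = np.concatenate(ys_out, axis=1)
    times, unique_idx = np.unique(times, return_index=True)
    ys = ys[:, unique_idx]

    frac = np.clip(ys[:N_STATES].T, 0.0, 1.0)
    donor = np.maximum(ys[N_STATES], 0.0)
    cumsep = np.maximum.accumulate(np.maximum(ys[N_STATES + 1], 0.0))
    open_tot = frac[:, list(_OPEN)].sum(axis=1)
    x = np.clip(1.0 - open_tot, 0.0, 1.0)
    phi = np.asarray(yield_fn(x, params.p))
    p_plus = frac[:, list(_P_PLUS)].sum(axis=1)
    pqa_minus = frac[:, list(_PQA_MINUS)].sum(axis=1)

    return SimulationResult(
        params=params, times=times, fractions=frac, donor_conc=donor,
        phi=phi, p_plus=np.clip(p_plus, 0.0, 1.0), x=x,
        pqa_minus=np.clip(pqa_minus, 0.0, 1.0),
        cum_separations=cumsep, light_on_duration=light_on_duration,
        yield_map=yield_map,
    )


def expected_separations(params: RateParameters) -> float:
    """Asymptotic charge separations per RC under saturating illumination.

    Every RC closes once; each pool donor enables one further closure
    provided the acceptor side can drain QA- (A1 > 0).  Without quinol
    exchange (E = 0) the acceptor side holds at most three electrons.
    """
    if params.A1 == 0:
        return 1.0
    cap = math.inf if params.E > 0 else (3.0 if params.A2 > 0 else 2.0)
    return min(1.0 + params.pool, cap)


def simulate_to_saturation(
    params: RateParameters,
    phi_target: float = 0.995,
    n_points: int = 2000,
    yield_map: str = "cluster",
    max_doublings: int = 40,
) -> SimulationResult:
    """Simulate continuous illumination until the induction is complete.

    The horizon is doubled until the final yield exceeds ``phi_target`` and
    the cumulative number of charge separations has converged (so that the
    supplementary area above phi(t) is fully accrued, including slow
    donor-limited tails).
    """
    horizon = 20.0 * (1.0 + params.pool) / params.k_I
    previous = None
    for _ in range(max_doublings):
        result = simulate(params, horizon, n_points=n_points, yield_map=yield_map)
        saturated = result.phi[-1] >= phi_target
        converged = (
            previous is not None
            and abs(result.cum_separations[-1] - previous) <= 1e-4 * max(
                1.0, result.cum_separations[-1])
        )
        if saturated and converged:
            return result
        previous = result.cum_separations[-1]
        horizon *= 2.0
    raise IntegrationError(
        f"induction did not saturate within {horizon:g} s for parameters "
        f"{params.to_dict()}"
    )


# --------------------------------------------------------------------------
# stochastic (Gillespie) oracle
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleResult:
    """Ensemble-mean trajectory from the exact-event stochastic simulation.

    When run with several independent batches, per-batch means are retained
    so that the standard error of phi can be compared pointwise against the
    deterministic solution.
    """

    params: RateParameters
    times: np.ndarray
    phi: np.ndarray
    p_plus: np.ndarray
    x: np.ndarray
    pqa_minus: np.ndarray
    donor_per_rc: np.ndarray
    cum_separations: np.ndarray
    n_rc: int
    phi_batches: np.ndarray | None = None   # (n_batches, n_times)

    def phi_sem(self) -> np.ndarray:
        if self.phi_batches is None or self.phi_batches.shape[0] < 2:
            raise ValueError("phi SEM requires at least two batches")
        n = self.phi_batches.shape[0]
        return self.phi_batches.std(axis=0, ddof=1) / math.sqrt(n)


def _gillespie_batch(
    params: RateParameters,
    n_rc: int,
    light_on_duration: float,
    total_time: float,
    grid: np.ndarray,
    rng: np.random.Generator,
    yield_fn,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One shared-pool replicate ensemble; returns (counts, tokens, cumsep)
    recorded at each grid time."""
    counts = [0] * N_STATES
    counts[0] = n_rc
    tokens = int(round(params.pool * n_rc))
    cumsep = 0
    t = 0.0
    light_on = True
    k_I = params.k_I

    n_grid = grid.size
    rec_counts = np.zeros((n_grid, N_STATES), dtype=np.int64)
    rec_tokens = np.zeros(n_grid, dtype=np.int64)
    rec_cumsep = np.zeros(n_grid, dtype=np.int64)
    gp = 0

    def flush(up_to: float) -> None:
        nonlocal gp
        while gp < n_grid and grid[gp] <= up_to:
            rec_counts[gp] = counts
            rec_tokens[gp] = tokens
            rec_cumsep[gp] = cumsep
            gp += 1

    p = params.p
    inv_n = 1.0 / n_rc
    while t < total_time:
        open_tot = counts[0] + counts[1] + counts[2]
        if light_on and open_tot > 0:
            x = 1.0 - open_tot * inv_n
            r_exc = k_I * (1.0 - yield_fn(x, p)) * n_rc
        else:
            r_exc = 0.0
        n_pplus = sum(counts[6:12])
        donor_conc = tokens * inv_n * params.rc_conc
        r_don = params.k2 * donor_conc * n_pplus if tokens > 0 else 0.0
        r_a1 = params.A1 * (counts[3] + counts[9])
        r_a2 = params.A2 * (counts[4] + counts[10])
        r_e = params.E * (counts[2] + counts[5] + counts[8] + counts[11])
        total = r_exc + r_don + r_a1 + r_a2 + r_e
        if total <= 0.0:
            if light_on and light_on_duration < total_time:
                # nothing can happen until the light switches off
                t = light_on_duration
                light_on = False
                flush(t)
                continue
            break
        dt = rng.exponential(1.0 / total)
        if light_on and t + dt > light_on_duration:
            # piecewise-constant rates: discard the pending event at the
            # light-off boundary and resample in the dark
            t = light_on_duration
            light_on = False
            flush(t)
            continue
        t_new = t + dt
        flush(min(t_new, total_time))  # grid points before the event see the old state
        if t_new > total_time:
            break
        t = t_new

        u = rng.random() * total
        if u < r_exc:
            # choose the open state proportionally to occupancy
            v = rng.random() * open_tot
            b = 0 if v < counts[0] else (1 if v < counts[0] + counts[1] else 2)
            counts[b] -= 1
            counts[9 + b] += 1
            cumsep += 1
        elif u < r_exc + r_don:
            v = rng.random() * n_pplus
            acc = 0.0
            for i in range(6, 12):
                acc += counts[i]
                if v < acc:
                    counts[i] -= 1
                    counts[i - 6] += 1
                    break
            tokens -= 1
        elif u < r_exc + r_don + r_a1:
            src = 3 if rng.random() * (counts[3] + counts[9]) < counts[3] else 9
            counts[src] -= 1
            counts[src - 2] += 1
        elif u < r_exc + r_don + r_a1 + r_a2:
            src = 4 if rng.random() * (counts[4] + counts[10]) < counts[4] else 10
            counts[src] -= 1
            counts[src - 2] += 1
        else:
            pool_e = counts[2] + counts[5] + counts[8] + counts[11]
            v = rng.random() * pool_e
            acc = 0.0
            for src in _E_SRC:
                acc += counts[src]
                if v < acc:
                    counts[src] -= 1
                    counts[src - 2] += 1
                    break
    flush(total_time)
    return rec_counts, rec_tokens, rec_cumsep


def stochastic_oracle(
    params: RateParameters,
    n_rc: int,
    light_on_duration: float,
    total_time: float | None = None,
    seed: int = 0,
    n_points: int = 200,
    n_batches: int = 1,
    yield_map: str = "cluster",
) -> OracleResult:
    """Exact-event (Gillespie) ensemble simulation of the reaction scheme.

    ``n_rc`` reaction centers share a discrete reduced-donor pool of
    ``round(pool * n_rc)`` tokens (per batch).  The photochemical channel
    fires at the ensemble closure flux ``n_rc * k_I * (1 - phi(x; p))`` and
    closes a uniformly chosen open RC, mirroring the mean-field flux rule.
    Reproducible for a fixed seed; with ``n_batches > 1`` independent batches
    of ``n_rc // n_batches`` centers are run so the result carries a
    standard error for phi.
    """
    if n_rc < 1:
        raise ModelError("n_rc must be >= 1")
    if total_time is None:
        total_time = light_on_duration
    if yield_map not in _YIELD_MAPS:
        raise ModelError(f"unknown yield_map {yield_map!r}")
    yield_fn = _YIELD_MAPS[yield_map]
    grid = _output_grid(total_time, n_points)
    batch_size = max(1, n_rc // n_batches)

    seeds = np.random.SeedSequence(seed).spawn(n_batches)
    counts_acc = np.zeros((grid.size, N_STATES))
    tokens_acc = np.zeros(grid.size)
    cumsep_acc = np.zeros(grid.size)
    phi_batches = np.zeros((n_batches, grid.size))
    for k in range(n_batches):
        rng = np.random.default_rng(seeds[k])
        rc_counts, rc_tokens, rc_cumsep = _gillespie_batch(
            params, batch_size, light_on_duration, total_time, grid, rng, yield_fn
        )
        counts_acc += rc_counts
        tokens_acc += rc_tokens
        cumsep_acc += rc_cumsep
        x_b = 1.0 - rc_counts[:, list(_OPEN)].sum(axis=1) / batch_size
        phi_batches[k] = yield_fn(np.clip(x_b, 0.0, 1.0), params.p)

    n_total = batch_size * n_batches
    frac = counts_acc / n_total
    x = np.clip(1.0 - frac[:, list(_OPEN)].sum(axis=1), 0.0, 1.0)
    return OracleResult(
        params=params,
        times=grid,
        phi=np.asarray(yield_fn(x, params.p)),
        p_plus=frac[:, list(_P_PLUS)].sum(axis=1),
        x=x,
        pqa_minus=frac[:, list(_PQA_MINUS)].sum(axis=1),
        donor_per_rc=tokens_acc / n_total,
        cum_separations=cumsep_acc / n_total,
        n_rc=n_total,
        phi_batches=phi_batches if n_batches > 1 else None,
    )
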