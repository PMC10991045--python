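"""Dark relaxation of variable fluorescence: RC re-opening kinetics.

After a short saturating light pulse the normalized variable fluorescence
decays as closed reaction centers re-open — by electron donation to P+ on
the donor side and by inter-quinone transfer draining QA- on the acceptor
side.  Whichever side is slower is the bottleneck of the decay, so the
relaxation time discriminates donor-limited strains (slow, ms-to-s) from
acceptor-limited ones (fast, sub-ms).

Two operational definitions of the relaxation time are provided, since a
single number is reported per decay but the decay need not be exponential:
the half-time of the normalized decay (default) and the time constant of a
single-exponential fit (half-time derivable as ``tau * ln 2``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .model import RateParameters, simulate
from .traces import Trace

__all__ = ["RelaxationResult", "RelaxationError", "extract_relaxation",
           "half_time_from_points", "simulate_relaxation"]

MODELS = ("half_time", "single_exponential")


class RelaxationError(ValueError):
    """Raised when a decay cannot yield a relaxation time."""


@dataclass(frozen=True)
class RelaxationResult:
    """Relaxation time with the model that produced it.

    ``time_s`` is the half-time (``half_time`` model) or the exponential
    time constant tau (``single_exponential`` model).  ``fit_quality`` is
    the RMS residual of the exponential fit, or the local interpolation gap
    for the half-time mode (informational only).
    """

    time_s: float
    model: str
    fit_quality: float

    @property
    def half_time_s(self) -> float:
        return self.time_s if self.model == "half_time" else self.time_s * math.log(2)

    def to_dict(self) -> dict:
        return {
            "relaxation_time_s": self.time_s,
            "model": self.model,
            "fit_quality": self.fit_quality,
        }


def _validate_decay(decay: Trace) -> None:
    if decay.channel != "phi":
        raise RelaxationError(f"expected a phi trace, got {decay.channel}")
    if len(decay) < 6:
        raise RelaxationError("need at least 6 samples of the decay")
    if decay.values[0] < 0.7:
        raise RelaxationError(
            f"first sample ({decay.values[0]:.3f}) is far from 1; normalize "
            "the decay to its initial value"
        )
    tail = decay.values[-max(1, len(decay) // 5):].mean()
    if tail >= 0.2:
        raise RelaxationError(
            f"decay tail mean {tail:.3f} >= 0.2: relaxation incomplete on "
            "this window"
        )


def half_time_from_points(times: np.ndarray, values: np.ndarray) -> float:
    """Interpolated first 0.5-crossing of a decay given as bare samples.

    Used for very sparse flash-probe series (fewer points than the Trace
    container admits); no normalization checks are applied, so the caller
    is responsible for the decay starting near 1.  Times are seconds since
    light-off.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2 or times.size != values.size:
        raise RelaxationError("need >= 2 matched (time, value) samples")
    below = np.nonzero(values < 0.5)[0]
    if below.size == 0 or below[0] == 0:
        raise RelaxationError("samples do not bracket the 0.5 crossing")
    i = below[0]
    frac = (values[i - 1] - 0.5) / (values[i - 1] - values[i])
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))


def extract_relaxation(decay: Trace, model: str = "half_time") -> RelaxationResult:
    """Relaxation time of a normalized fluorescence decay.

    ``half_time``: linearly interpolated time of the first crossing of 0.5.
    ``single_exponential``: nonlinear fit of ``a * exp(-t/tau)``; tau is
    reported.  The trace's time axis must be measured from light-off (as
    :func:`simulate_relaxation` and the flash-probe generator produce); the
    first probe may arrive at t > 0 and the crossing is interpolated on the
    absolute axis.
    """
    if model not in MODELS:
        raise RelaxationError(f"model must be one of {MODELS}, got {model!r}")
    _validate_decay(decay)
    if decay.times[0] < 0:
        raise RelaxationError("decay times must be >= 0 (seconds since light-off)")
    t = decay.times
    v = decay.values

    if model == "half_time":
        below = np.nonzero(v < 0.5)[0]
        if below.size == 0:
            raise RelaxationError(
                f"signal never crosses 0.5 (min {v.min():.3f}); cannot form "
                "a half-time"
            )
        i = below[0]
        if i == 0:
            raise RelaxationError("signal starts below 0.5; not a normalized decay")
        frac = (v[i - 1] - 0.5) / (v[i - 1] - v[i])
        t_half = t[i - 1] + frac * (t[i] - t[i - 1])
        return RelaxationResult(float(t_half), model, float(t[i] - t[i - 1]))

    # single-exponential fit, initialized from the crude half-time
    v_pos = np.clip(v, 1e-9, None)
    tau0 = max(t[np.argmin(np.abs(v_pos - 0.5))] / math.log(2), t[1] - t[0])
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t, v, p0=(1.0, tau0), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RelaxationError(f"exponential fit failed to converge: {exc}") from exc
    a, tau = popt
    if tau <= 0 or not np.isfinite(tau):
        raise RelaxationError(f"exponential fit returned invalid tau = {tau!r}")
    rms = float(np.sqrt(np.mean((v - a * np.exp(-t / tau)) ** 2)))
    return RelaxationResult(float(tau), "single_exponential", rms)


def simulate_relaxation(
    params: RateParameters,
    pulse_duration: float = 5e-5,
    dark_duration: float | None = None,
    n_points: int = 2000,
    yield_map: str = "cluster",
) -> Trace:
    """Simulated post-pulse decay of normalized variable fluorescence.

    Runs the kinetic model with the light on for ``pulse_duration`` seconds
    and returns phi(t) for the dark period, rescaled to start at 1 and with
    time measured from light-off.  ``dark_duration`` defaults to a horizon
    generous enough for the slowest re-opening channel among the donor rate
    ``k2 * pool * rc_conc`` and the acceptor rates A1, A2, E.
    """
    if dark_duration is None:
        rates = [params.A1, params.A2, params.E]
        if params.pool > 0 and params.k2 > 0:
            rates.append(params.k2 * params.pool * params.rc_conc)
        positive = [r for r in rates if r > 0]
        dark_duration = 20.0 / min(positive) if positive else 100.0 * pulse_duration
    sim = simulate(
        params,
        light_on_duration=pulse_duration,
        total_time=pulse_duration + dark_duration,
        n_points=n_points,
        yield_map=yield_map,
    )
    dark = sim.times >= pulse_duration
    phi_dark = sim.phi[dark]
    if phi_dark[0] < 0.05:
        warnings.warn(
            f"pulse closed almost no RCs (phi = {phi_dark[0]:.3f} at "
            "light-off); the relaxation signal is negligible",
            stacklevel=2,
        )
        scale = max(phi_dark[0], 1e-12)
    else:
        scale = phi_dark[0]
    return Trace(
        sim.times[dark] - pulse_duration,
        np.clip(phi_dark / scale, 0.0, 1.0),
        "phi",
        {"pulse_duration_s": pulse_duration},
    )
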