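"""Redox-state reconstruction and phi(P+) correlation analysis.

With the hyperbolic connectivity map, the closed fraction is
``x = phi / (1 - p (1 - phi))`` and the four RC redox states
(PQA, P+QA, PQA-, P+QA-) satisfy a closure: from simultaneously measured
normalized variable fluorescence phi(t) and fractional oxidized dimer
P+(t) the acceptor-side states follow pointwise as

    PQA-(t) = phi / (1 - p (1 - phi)) - P+(t)
    PQA(t)  = (1 - p)(1 - phi) / (1 - p (1 - phi))

The phi-vs-P+ correlation curve classifies the donor supply: a large donor
pool keeps P+ low while QA- accumulates, so phi runs ahead of P+ and the
curve bows above the diagonal (concave); with a poor donor supply every
closed RC retains P+, the curve follows phi(x) below the diagonal and turns
convex once excitons can migrate between units (p > 0).  The signed area
between the curve and the diagonal is used as the curvature score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    RateParameters,
    closed_fraction_from_yield,
    simulate_to_saturation,
)
from .traces import Trace

__all__ = [
    "CorrelationCurve",
    "ReconstructionError",
    "reconstruct_qa_reduced",
    "reconstruct_open",
    "curvature_score",
    "correlation_from_traces",
    "correlation_from_simulation",
    "find_curvature_transition",
]

#: |score| below this is classified as the straight-line (bisectrix) case.
LINEAR_BAND = 0.01

_NEGATIVE_TOL = 0.02


class ReconstructionError(ValueError):
    """Raised for incompatible traces or degenerate correlation curves."""


@dataclass(frozen=True)
class CorrelationCurve:
    """Paired (P+, phi) samples with a signed curvature score.

    ``score = Int (phi - P+) dP+`` over the sorted pairs: positive when the
    curve lies above the diagonal (concave, donor-rich), negative when below
    (convex, donor-poor with connected units), near zero for the bisectrix.
    """

    p_plus: np.ndarray
    phi: np.ndarray
    score: float
    label: str


def _common_grid(phi: Trace, p_plus: Trace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Interpolate P+ onto the phi grid over the overlapping window."""
    if phi.channel != "phi" or p_plus.channel != "p_plus":
        raise ReconstructionError(
            f"expected channels (phi, p_plus), got ({phi.channel}, {p_plus.channel})"
        )
    lo = max(phi.times[0], p_plus.times[0])
    hi = min(phi.times[-1], p_plus.times[-1])
    if hi <= lo:
        raise ReconstructionError("phi and P+ traces do not overlap in time")
    mask = (phi.times >= lo) & (phi.times <= hi)
    times = phi.times[mask]
    return (
        times,
        np.clip(phi.values[mask], 0.0, 1.0),
        np.clip(np.interp(times, p_plus.times, p_plus.values), 0.0, 1.0),
    )


def reconstruct_qa_reduced(phi: Trace, p_plus: Trace, p: float) -> Trace:
    """Kinetics of the PQA- state from paired phi(t) and P+(t) traces.

    Pointwise ``phi / (1 - p (1 - phi)) - P+``; the P+ trace is linearly
    interpolated onto the phi grid.  Negative excursions (noise) are clipped
    at zero, with a warning when they exceed -0.02.
    """
    times, phi_v, pp_v = _common_grid(phi, p_plus)
    qa = closed_fraction_from_yield(phi_v, p) - pp_v
    worst = qa.min()
    if worst < -_NEGATIVE_TOL:
        warnings.warn(
            f"reconstructed PQA- reaches {worst:.3f}; clipping at 0 "
            "(check p or trace normalization)",
            stacklevel=2,
        )
    return Trace(times, np.clip(qa, 0.0, 1.0), "p_plus", {"state": "PQA-"})


def reconstruct_open(phi: Trace, p: float) -> Trace:
    """Kinetics of the open state, ``PQA = (1-p)(1-phi) / (1 - p (1-phi))``."""
    if phi.channel != "phi":
        raise ReconstructionError(f"expected a phi trace, got {phi.channel}")
    if not 0 <= p < 1:
        raise ReconstructionError(f"p must be in [0, 1), got {p}")
    one_minus = 1.0 - np.clip(phi.values, 0.0, 1.0)
    open_frac = (1.0 - p) * one_minus / (1.0 - p * one_minus)
    return Trace(phi.times, open_frac, "p_plus", {"state": "PQA"})


def curvature_score(
    p_plus: np.ndarray,
    phi: np.ndarray,
    linear_band: float = LINEAR_BAND,
) -> tuple[float, str]:
    """Signed curvature score of a phi(P+) correlation curve.

    Pairs are sorted by P+ and duplicates averaged; the score is the
    trapezoidal integral of (phi - P+) over P+.  Labels: ``concave`` for
    score > +linear_band (curve above the diagonal), ``convex`` for
    score < -linear_band, else ``linear``.
    """
    p_plus = np.asarray(p_plus, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if p_plus.size != phi.size or p_plus.size < 10:
        raise ReconstructionError("need >= 10 matched (P+, phi) pairs")
    if p_plus.min() > 0.05 or p_plus.max() < 0.95:
        raise ReconstructionError(
            f"P+ span [{p_plus.min():.3f}, {p_plus.max():.3f}] insufficient; "
            "need coverage from <= 0.05 to >= 0.95"
        )
    order = np.argsort(p_plus)
    pp, ph = p_plus[order], phi[order]
    uniq, inverse = np.unique(pp, return_inverse=True)
    if uniq.size < pp.size:
        ph = np.bincount(inverse, weights=ph) / np.bincount(inverse)
        pp = uniq
    score = float(np.trapezoid(ph - pp, pp))
    if score > linear_band:
        label = "concave"
    elif score < -linear_band:
        label = "convex"
    else:
        label = "linear"
    return score, label


def _build_curve(p_plus: np.ndarray, phi: np.ndarray,
                 linear_band: float) -> CorrelationCurve:
    score, label = curvature_score(p_plus, phi, linear_band)
    order = np.argsort(p_plus)
    return CorrelationCurve(p_plus[order], phi[order], score, label)


def correlation_from_traces(
    phi: Trace, p_plus: Trace, linear_band: float = LINEAR_BAND
) -> CorrelationCurve:
    """Correlation curve from measured phi(t) and P+(t) traces."""
    _, phi_v, pp_v = _common_grid(phi, p_plus)
    return _build_curve(pp_v, phi_v, linear_band)


def correlation_from_simulation(
    params: RateParameters,
    phi_target: float = 0.995,
    linear_band: float = LINEAR_BAND,
    n_points: int = 2000,
) -> CorrelationCurve:
    """Simulate continuous illumination and return the phi(P+) curve.

    Both channels are normalized to their saturation values, as in the
    experimental representation, so the curve runs from (0, 0) to (1, 1).
    """
    sim = simulate_to_saturation(params, phi_target=phi_target, n_points=n_points)
    phi = sim.phi / sim.phi[-1]
    pp = sim.p_plus / sim.p_plus[-1] if sim.p_plus[-1] > 0 else sim.p_plus
    return _build_curve(np.clip(pp, 0.0, 1.0), np.clip(phi, 0.0, 1.0), linear_band)


def find_curvature_transition(
    params: RateParameters,
    pool_grid,
    linear_band: float = LINEAR_BAND,
) -> float | None:
    """Donor-pool size at which the phi(P+) curvature changes sign.

    Each pool size on the grid is simulated to saturation and scored; the
    zero crossing of the score is located by linear interpolation between
    the bracketing grid points.  Returns ``None`` when the score does not
    change sign on the grid (a distinguished no-transition outcome, e.g. for
    p = 0 where the donor-poor limit degenerates to the bisectrix).
    """
    pool_grid = np.asarray(list(pool_grid), dtype=float)
    if pool_grid.size < 3 or np.any(np.diff(pool_grid) <= 0) or pool_grid[0] != 0:
        raise ReconstructionError("pool_grid must be increasing, >= 3 values, start at 0")
    scores = np.empty(pool_grid.size)
    for i, pool in enumerate(pool_grid):
        curve = correlation_from_simulation(
            params.replace(pool=float(pool)), linear_band=linear_band
        )
        scores[i] = curve.score
    # scores at numerical zero (e.g. the p = 0 bisectrix) carry no sign
    sign = np.sign(np.where(np.abs(scores) < 1e-6, 0.0, scores))
    flips = np.nonzero(np.diff(sign) != 0)[0]
    flips = [i for i in flips if sign[i] != 0 and sign[i + 1] != 0]
    if not flips:
        return None
    i = flips[0]
    s0, s1 = scores[i], scores[i + 1]
    return float(pool_grid[i] + (pool_grid[i + 1] - pool_grid[i]) * (-s0) / (s1 - s0))
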