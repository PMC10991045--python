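"""Analysis of bacteriochlorophyll fluorescence induction curves.

From a raw induction trace F(t) recorded under continuous excitation the
pipeline extracts the constant initial level F0 and the saturation level
Fmax, forms the normalized variable fluorescence
``phi(t) = (F(t) - F0) / (Fmax - F0)``, and derives:

* the supplementary area  ``Area = Int (1 - phi) dt``  (seconds),
* the initial slope       ``Slope = dphi/dt (t=0)``     (s^-1),
* the photochemical rate constant  ``k_I = 1 / Area``  (valid for a
  single-turnover trace, e.g. terbutryn-inhibited),
* the inter-unit connectivity      ``p = 1 - Area * Slope``,
* the number of electrons transferred per RC
  ``N = A_m / A_s``  from a multiple-turnover area paired with a
  single-turnover one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .traces import Trace, TraceError

__all__ = [
    "InductionFeatures",
    "normalize_induction",
    "supplementary_area",
    "initial_slope",
    "derive_connectivity",
    "derive_photochemical_rate",
    "electron_count",
    "analyze_induction",
    "InductionError",
]


class InductionError(ValueError):
    """Raised when an induction trace cannot support the requested analysis."""


@dataclass(frozen=True)
class InductionFeatures:
    """Quantities derived from one fluorescence induction curve."""

    F0: float
    Fmax: float
    slope: float        # s^-1, initial slope of phi
    area: float         # s, supplementary area
    k_I: float          # s^-1, photochemical rate constant (1/area)
    p: float            # connectivity (hopping probability)
    N: float | None = None  # electrons per RC, needs a paired single-turnover area

    def to_dict(self) -> dict:
        return {
            "F0": self.F0,
            "Fmax": self.Fmax,
            "slope_per_s": self.slope,
            "area_s": self.area,
            "k_I_per_s": self.k_I,
            "p": self.p,
            "N": self.N,
        }


def normalize_induction(
    raw: Trace,
    n_initial: int = 5,
    plateau_fraction: float = 0.05,
) -> tuple[Trace, float, float]:
    """Normalize a raw induction trace to variable fluorescence phi(t).

    F0 is the intercept at t = 0 of a least-squares line through the first
    ``n_initial`` samples (the instant-rise level); Fmax is the mean over
    the final ``plateau_fraction`` of the samples (the saturation plateau) —
    a tail average rather than a top-value average, so that zero-mean noise
    cancels instead of selecting its own positive excursions.  Returns
    ``(phi_trace, F0, Fmax)`` with phi clipped to [0, 1].
    """
    if raw.channel != "raw_fluorescence":
        raise InductionError(f"expected a raw_fluorescence trace, got {raw.channel}")
    values = raw.values
    if values.max() - values.min() <= 0:
        raise InductionError("trace has no rise (max equals min)")
    rho = spearmanr(raw.times, values).statistic
    if rho < 0:
        raise InductionError(
            f"trace is not increasing on average (Spearman rho = {rho:.3f})"
        )
    if not 2 <= n_initial <= len(raw):
        raise InductionError(f"n_initial must be in [2, {len(raw)}]")
    t_head, f_head = raw.times[:n_initial], values[:n_initial]
    slope_head, f0 = np.polyfit(t_head, f_head, 1)
    n_top = max(1, int(round(plateau_fraction * values.size)))
    fmax = float(values[-n_top:].mean())
    if fmax <= f0:
        raise InductionError(f"Fmax ({fmax:.4g}) must exceed F0 ({f0:.4g})")
    phi_unclipped = (values - f0) / (fmax - f0)
    trace = Trace(
        raw.times,
        np.clip(phi_unclipped, 0.0, 1.0),
        "phi",
        # kept for the area integral: clipping noisy values at 1 would
        # rectify zero-mean noise into a positive bias over the plateau
        {"values_unclipped": phi_unclipped},
    )
    return trace, float(f0), fmax


def supplementary_area(phi: Trace, saturation_tol: float = 0.01) -> float:
    """Supplementary area above the induction curve, Int (1 - phi) dt.

    The integral's nominal upper limit is infinity; it is evaluated by the
    trapezoidal rule to the end of the trace, which is valid only if the
    curve has saturated (max phi >= 1 - saturation_tol).  If the trace
    carries its unclipped normalization (``values_unclipped`` metadata from
    :func:`normalize_induction`), that is integrated so that zero-mean noise
    on the plateau cancels instead of rectifying into a positive bias.
    """
    if phi.channel != "phi":
        raise InductionError(f"expected a phi trace, got {phi.channel}")
    peak = float(phi.values.max())
    if peak < 1.0 - saturation_tol:
        raise InductionError(
            f"induction does not saturate: max phi = {peak:.4f} "
            f"< {1 - saturation_tol:.4f}; the supplementary area would be "
            "truncated (record longer or raise saturation_tol)"
        )
    values = phi.meta.get("values_unclipped", phi.values)
    return float(np.trapezoid(1.0 - np.asarray(values), phi.times))


def initial_slope(phi: Trace, fit_upper_phi: float = 0.15) -> float:
    """Initial slope of phi(t), s^-1.

    Least-squares fit of ``phi = a + s t + c t**2`` over the early samples
    with ``phi < fit_upper_phi``; the linear coefficient ``s`` is the
    t -> 0 slope.  The quadratic term absorbs the leading curvature of the
    rise (a straight-line fit is biased low by several percent over this
    window), and the free intercept absorbs the small constant offset that
    noise in the F0 estimate leaves in the normalization — forcing the fit
    through the origin would turn that offset into a slope error amplified
    by the short time span of the window.
    """
    if phi.channel != "phi":
        raise InductionError(f"expected a phi trace, got {phi.channel}")
    mask = phi.values < fit_upper_phi
    # use only the leading contiguous run so late noisy dips are excluded
    if not mask[0]:
        raise InductionError("first sample already exceeds the fit window")
    end = np.argmin(mask) if not mask.all() else mask.size
    t, v = phi.times[:end], phi.values[:end]
    keep = t > 0
    t, v = t[keep], v[keep]
    if t.size < 4:
        raise InductionError(
            f"only {t.size} samples with phi < {fit_upper_phi}; sample the "
            "early rise more densely"
        )
    u = t / t[-1]  # scale for conditioning
    design = np.column_stack([np.ones_like(u), u, u * u])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return float(coef[1] / t[-1])


def derive_connectivity(area: float, slope: float) -> float:
    """Connectivity (exciton hopping probability) ``p = 1 - Area * Slope``."""
    if area <= 0 or slope <= 0:
        raise InductionError("area and slope must be positive")
    prod = area * slope
    if prod > 1.05:
        raise InductionError(
            f"Area * Slope = {prod:.3f} > 1.05: inconsistent inputs "
            "(slope cannot exceed k_I by that much)"
        )
    if prod > 1.0:
        warnings.warn(
            f"Area * Slope = {prod:.3f} slightly exceeds 1; clamping p to 0",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - prod


def derive_photochemical_rate(area: float) -> float:
    """Photochemical rate constant ``k_I = 1 / Area`` (s^-1).

    Valid when ``area`` comes from a single-turnover induction (terbutryn
    present or donor pool exhausted), where the supplementary area is 1/k_I.
    """
    if area <= 0:
        raise InductionError("area must be positive")
    return 1.0 / area


def electron_count(area_multiple: float, area_single: float) -> float:
    """Electrons transferred per RC, ``N = A_m / A_s``.

    ``A_m`` is the supplementary area of the uninhibited (multiple-turnover)
    induction and ``A_s`` that of the single-turnover (terbutryn) one.
    """
    if area_multiple <= 0 or area_single <= 0:
        raise InductionError("areas must be positive")
    if area_multiple < 0.999 * area_single:
        warnings.warn(
            f"multiple-turnover area ({area_multiple:g} s) is smaller than "
            f"the single-turnover area ({area_single:g} s); N < 1 is "
            "physically impossible and indicates mismatched traces",
            stacklevel=2,
        )
    return area_multiple / area_single


def analyze_induction(
    raw: Trace,
    n_initial: int = 5,
    plateau_fraction: float = 0.05,
    fit_upper_phi: float = 0.15,
    saturation_tol: float = 0.01,
    single_turnover_area: float | None = None,
) -> InductionFeatures:
    """Full induction pipeline: normalize, integrate, fit, derive constants.

    When ``single_turnover_area`` (``A_s``, seconds) is supplied, the trace
    is treated as a multiple-turnover recording and the electron count
    ``N = area / A_s`` is included; ``k_I`` and ``p`` are then derived from
    the paired single-turnover area, as they require a single-turnover
    normalization.
    """
    phi, f0, fmax = normalize_induction(raw, n_initial, plateau_fraction)
    area = supplementary_area(phi, saturation_tol)
    slope = initial_slope(phi, fit_upper_phi)
    if single_turnover_area is not None:
        n_elec = electron_count(area, single_turnover_area)
        k_i = derive_photochemical_rate(single_turnover_area)
        p = derive_connectivity(single_turnover_area, slope)
    else:
        n_elec = None
        k_i = derive_photochemical_rate(area)
        p = derive_connectivity(area, slope)
    return InductionFeatures(
        F0=f0, Fmax=fmax, slope=slope, area=area, k_I=k_i, p=p, N=n_elec
    )
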