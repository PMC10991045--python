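"""Synthetic strain-panel datasets from the kinetic model.

No public raw traces exist for the fluorescence experiments this package
analyses, so this module generates them: induction and flash-probe
relaxation recordings for strain presets of *Rba. sphaeroides* (wild type
2.4.1 and the cytochrome-c2-less *cycA* mutant) and *Rvx. gelatinosus*
(wild type and the tetraheme-less *pufC* mutant), with terbutryn
(``A1 = 0``) and ferricyanide (shrunken donor pool) treatments.

Every dataset is written as a two-column CSV plus a machine-readable
ground-truth sidecar (``<name>.truth.json``) holding the generating
parameters, so analysis pipelines can be validated end-to-end against known
truth without touching simulator internals.  Generation is deterministic:
the same seed yields byte-identical files.

Preset donor-pool sizes are calibrated on the measured electron counts
(asymptotically ``N = 1 + pool``): about 4.8 electrons/RC for wild-type
*Rvx. gelatinosus*, 2.4 for *Rba. sphaeroides* 2.4.1, 2.2 for *pufC*, and a
smaller donor-limited pool for *cycA*.  Absolute pool sizes per strain are
not published; only N constrains them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import RateParameters, expected_separations, simulate_to_saturation
from .relaxation import extract_relaxation, simulate_relaxation
from .traces import Trace, write_trace

__all__ = [
    "StrainPreset",
    "STRAIN_PRESETS",
    "get_preset",
    "ferricyanide_pool",
    "generate_induction_dataset",
    "generate_relaxation_dataset",
]

#: e-folding time (hours) of the reduced donor pool under 1 mM ferricyanide,
#: set so the electron count decays to ~1 after about 4 h of treatment.
FERRICYANIDE_TAU_H = 1.2


@dataclass(frozen=True)
class StrainPreset:
    """A named strain/treatment condition with its generating parameters."""

    name: str
    params: RateParameters
    description: str = ""

    def with_terbutryn(self) -> "StrainPreset":
        """Block the QA- -> QB transfer (single-turnover condition)."""
        return StrainPreset(
            self.name + "_terbutryn",
            self.params.replace(A1=0.0),
            self.description + " + terbutryn",
        )

    def with_ferricyanide(self, duration_h: float) -> "StrainPreset":
        """Shrink the reduced donor pool by slow chemical oxidation.

        The pool decays exponentially with the treatment duration
        (e-folding time :data:`FERRICYANIDE_TAU_H` hours); oxidation during
        a measurement (~ms) is negligible against the hours-long treatment
        and is not modeled.
        """
        if duration_h < 0:
            raise ValueError("duration_h must be >= 0")
        return StrainPreset(
            f"{self.name}_fecn_{duration_h:g}h",
            self.params.replace(pool=ferricyanide_pool(self.params.pool, duration_h)),
            self.description + f" + ferricyanide {duration_h:g} h",
        )


def ferricyanide_pool(pool0: float, duration_h: float) -> float:
    """Reduced pool remaining after ``duration_h`` hours of slow oxidation."""
    return pool0 * math.exp(-duration_h / FERRICYANIDE_TAU_H)


STRAIN_PRESETS: dict[str, StrainPreset] = {
    "sphaeroides_241": StrainPreset(
        "sphaeroides_241",
        RateParameters(k_I=8.0e3, k2=1e9, rc_conc=8e-6,
                       A1=3e4, A2=2e3, E=1e2, p=0.20, pool=1.4),
        "Rba. sphaeroides wild type 2.4.1 (soluble cyt c2 pool)",
    ),
    "cycA": StrainPreset(
        "cycA",
        RateParameters(k_I=5.2e3, k2=2e5, rc_conc=8e-6,
                       A1=3e4, A2=2e3, E=1e2, p=0.22, pool=1.0),
        "Rba. sphaeroides cycA mutant (no cyt c2; donor-limited re-opening)",
    ),
    "gelatinosus_wt": StrainPreset(
        "gelatinosus_wt",
        RateParameters(k_I=9.3e3, k2=1e10, rc_conc=8e-6,
                       A1=3e4, A2=2e3, E=1e2, p=0.10, pool=3.8),
        "Rvx. gelatinosus wild type (tetraheme subunit + HiPIP/cyt c8 pool)",
    ),
    "pufC": StrainPreset(
        "pufC",
        RateParameters(k_I=8.7e3, k2=1e10, rc_conc=8e-6,
                       A1=3e4, A2=2e3, E=1e2, p=0.13, pool=1.2),
        "Rvx. gelatinosus pufC mutant (no tetraheme subunit)",
    ),
}


def get_preset(name: str, terbutryn: bool = False,
               ferricyanide_h: float | None = None) -> StrainPreset:
    """Look up a strain preset, optionally applying treatments."""
    try:
        preset = STRAIN_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(STRAIN_PRESETS)}"
        ) from None
    if ferricyanide_h is not None:
        preset = preset.with_ferricyanide(ferricyanide_h)
    if terbutryn:
        preset = preset.with_terbutryn()
    return preset


def _truth_dict(preset: StrainPreset, extra: dict) -> dict:
    params = preset.params
    return {
        "preset": preset.name,
        "params": params.to_dict(),
        "k_I": params.k_I,
        "p": params.p,
        "pool": params.pool,
        "n_electrons": expected_separations(params),
        **extra,
    }


def _write_truth(path: Path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")


def generate_induction_dataset(
    preset: StrainPreset,
    noise_sigma: float = 0.01,
    seed: int = 0,
    out_dir=".",
    f0_true: float = 1.0,
    fmax_true: float = 3.0,
    phi_target: float = 0.999,
) -> tuple[Path, Path]:
    """Generate a raw fluorescence induction recording with ground truth.

    The preset is simulated to saturation, phi mapped to raw fluorescence
    ``F = F0 + (Fmax - F0) * phi`` and multiplicative Gaussian noise of
    relative sigma ``noise_sigma`` applied.  Writes ``<name>.csv`` and
    ``<name>.truth.json`` into ``out_dir`` and returns both paths.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_to_saturation(preset.params, phi_target=phi_target)
    # emulate a realistic recording window: stop a little after saturation
    # rather than integrating noise over an arbitrarily long plateau
    t_sat = sim.times[int(np.argmax(sim.phi >= phi_target))]
    window = sim.times <= 3.0 * t_sat
    times, phi = sim.times[window], sim.phi[window]
    raw = f0_true + (fmax_true - f0_true) * phi
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        raw = raw * (1.0 + noise_sigma * rng.standard_normal(raw.size))
    trace = Trace(times, raw, "raw_fluorescence")
    csv_path = out_dir / f"{preset.name}_induction.csv"
    truth_path = out_dir / f"{preset.name}_induction.truth.json"
    write_trace(trace, csv_path)
    _write_truth(truth_path, _truth_dict(preset, {
        "kind": "induction",
        "F0": f0_true,
        "Fmax": fmax_true,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "area_s": float(np.trapezoid(1.0 - phi, times)),
    }))
    return csv_path, truth_path


def generate_relaxation_dataset(
    preset: StrainPreset,
    n_flashes: int = 15,
    noise_sigma: float = 0.01,
    seed: int = 0,
    out_dir=".",
    pulse_duration: float = 5e-5,
) -> tuple[Path, Path]:
    """Generate a sparse flash-probe relaxation recording with ground truth.

    The post-pulse decay is simulated densely, its half-time recorded as
    truth, and the decay sampled at ``n_flashes`` log-spaced probe times
    (the probe flashes are taken as non-actinic, i.e. they only read the
    yield).  Noise is multiplicative Gaussian.
    """
    if n_flashes < 4:
        raise ValueError("need at least 4 probe flashes")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dense = simulate_relaxation(preset.params, pulse_duration=pulse_duration)
    half_time = extract_relaxation(dense, model="half_time").time_s

    # probe times spanning two decades around the half-time
    t_probe = np.geomspace(half_time / 10, min(half_time * 10, dense.times[-1]),
                           n_flashes)
    values = np.interp(t_probe, dense.times, dense.values)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + noise_sigma * rng.standard_normal(values.size))
    values = np.clip(values, 0.0, 1.05)
    trace = Trace(t_probe, values, "phi") if n_flashes >= 8 else None
    csv_path = out_dir / f"{preset.name}_relaxation.csv"
    truth_path = out_dir / f"{preset.name}_relaxation.truth.json"
    if trace is not None:
        write_trace(trace, csv_path)
    else:
        # fewer than the Trace minimum: write the CSV directly
        import pandas as pd

        pd.DataFrame({"time_s": t_probe, "value": values}).to_csv(
            csv_path, index=False, float_format="%.12g"
        )
    _write_truth(truth_path, _truth_dict(preset, {
        "kind": "relaxation",
        "pulse_duration_s": pulse_duration,
        "half_time_s": half_time,
        "n_flashes": n_flashes,
        "noise_sigma": noise_sigma,
        "seed": seed,
    }))
    return csv_path, truth_path
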