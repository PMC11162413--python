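"""Device-level configuration: strains, sources, and the physical gate model.

A `DeviceConfig` bundles everything needed to turn an abstract receiver
design plus a spatial layout into a simulation: the grid physics, the
source model (inducer droplets or sender colonies), the strain library
(one dose-response per activation kind), colony growth parameters, and the
digital read-out convention.

Strain parameters are documented reconstructions chosen so that the
decision thresholds of each response sit inside the concentration range a
384-well-pitch layout can actually produce (the "distance ladder" of a
droplet or sender field at commitment time); see the package methods note
for the derivation.  The steep effective Hill coefficients of the bandpass
stand in for the ultrasensitivity of an amplifying activation cascade with
strong repression.

The digital verdict of a receiver follows its response polarity: an
activating strain (highpass/bandpass) is ON when its fluorescence fold
change exceeds ``decision_ratio``; an inverting strain (lowpass/bandstop),
which is bright at zero input, is ON when its fold change stays above
``1/decision_ratio``.  The *normalized activity* of a receiver is its fold
change divided by its verdict threshold, so activity > 1 always means ON
and activities are comparable across strain polarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .simulator import (
    DEFAULT_DROPLET_DOSE,
    ColonySpec,
    DoseResponse,
    SimGrid,
    SourceSpec,
    activity_threshold,
    simulate_field,
)

__all__ = [
    "DeviceConfig",
    "iptg_strains",
    "narrow_bandpass",
    "hsl_strains",
    "droplet_device",
    "sender_device",
    "activity_threshold",
    "decision_crossings",
    "radial_concentration",
]


def iptg_strains() -> dict[str, DoseResponse]:
    """Default IPTG-responsive receiver strains (droplet experiments)."""
    return {
        "highpass": DoseResponse("highpass", basal=0.01, v_max=1.0, K_act=0.034, n_act=4.0),
        "lowpass": DoseResponse("lowpass", basal=0.01, v_max=1.0, K_act=0.034, n_act=4.0),
        "bandpass": DoseResponse(
            "bandpass", basal=0.01, v_max=1.0,
            K_act=0.005, n_act=8.0, K_rep=0.0175, n_rep=12.0,
        ),
        "bandstop": DoseResponse(
            "bandstop", basal=0.01, v_max=1.0,
            K_act=0.005, n_act=8.0, K_rep=0.0175, n_rep=12.0,
        ),
    }


def narrow_bandpass() -> DoseResponse:
    """Low-gain bandpass variant with a narrow decision band.

    Lowering the output dynamic range (a weaker output promoter or a
    higher repressor dose, the knob that sets the band in a T7/PhlF-style
    circuit) pulls the two fold-change decision crossings together: this
    variant reads ON only over roughly a factor 1.8 in concentration,
    versus a factor ~10 for the default bandpass.  Gates whose
    sub-functions must separate concentration levels closer than a factor
    of two (e.g. a receiver ON for two-input states but OFF for both the
    single-input and three-input states) need this narrow band.
    """
    return DoseResponse(
        "bandpass", basal=0.01, v_max=0.05,
        K_act=0.0064, n_act=8.0, K_rep=0.0077, n_rep=12.0,
    )


def hsl_strains() -> dict[str, DoseResponse]:
    """Default 3OC6-HSL-responsive strains (sender-colony experiments);
    the highpass and lowpass respond at matched concentrations."""
    return {
        "highpass": DoseResponse("highpass", basal=0.01, v_max=1.0, K_act=0.023, n_act=4.0),
        "lowpass": DoseResponse("lowpass", basal=0.01, v_max=1.0, K_act=0.023, n_act=4.0),
    }


@dataclass(frozen=True)
class DeviceConfig:
    """Physics + strain library + read-out convention for one device."""

    grid: SimGrid = SimGrid()
    strains: dict[str, DoseResponse] = field(default_factory=iptg_strains)
    source_kind: str = "droplet"
    dose: float = DEFAULT_DROPLET_DOSE
    production_rate: float = 1.25
    commit_time: float = 6.0
    t_read: float = 20.0
    decision_ratio: float = 1.5
    pitch: float = 4.5
    min_separation: float = 4.5
    growth_rate: float = 0.7
    capacity: float = 1.0
    lag: float = 2.0
    initial_biomass: float = 0.01

    def source(self, position: tuple[float, float]) -> SourceSpec:
        if self.source_kind == "droplet":
            return SourceSpec(position, "droplet", dose=self.dose)
        return SourceSpec(
            position, "sender", dose=0.0, production_rate=self.production_rate
        )

    def colony(self, position: tuple[float, float], kind: str) -> ColonySpec:
        if kind not in self.strains:
            raise ValueError(f"no strain with a {kind!r} response in this device")
        return ColonySpec(
            position,
            self.strains[kind],
            growth_rate=self.growth_rate,
            capacity=self.capacity,
            lag=self.lag,
            initial_biomass=self.initial_biomass,
            commit_time=self.commit_time,
        )


def droplet_device(**overrides) -> DeviceConfig:
    """IPTG droplet device with default strains."""
    return DeviceConfig(**overrides)


def sender_device(**overrides) -> DeviceConfig:
    """Sender-colony device: HSL highpass/lowpass receivers."""
    overrides.setdefault("strains", hsl_strains())
    overrides.setdefault("source_kind", "sender")
    return DeviceConfig(**overrides)


def decision_crossings(
    dr: DoseResponse, decision_ratio: float, u_max: float = 1.0
) -> tuple[float, ...]:
    """Concentrations where the verdict of a strain flips.

    Returns the crossings of normalized activity = 1 on (0, u_max): one
    value for highpass/lowpass, two (band edges) for bandpass/bandstop.
    """
    thr = activity_threshold(dr.kind, decision_ratio)
    r0 = float(dr.rate(0.0))

    def g(logu):
        return float(dr.rate(np.exp(logu))) / r0 - thr

    logs = np.linspace(np.log(1e-8), np.log(u_max), 2000)
    vals = np.array([g(x) for x in logs])
    crossings = []
    for i in range(len(logs) - 1):
        if vals[i] == 0.0:
            crossings.append(float(np.exp(logs[i])))
        elif vals[i] * vals[i + 1] < 0:
            x = brentq(g, logs[i], logs[i + 1])
            crossings.append(float(np.exp(x)))
    return tuple(crossings)


def radial_concentration(cfg: DeviceConfig, max_radius: float = 25.0) -> tuple[
    np.ndarray, np.ndarray
]:
    """Committed concentration versus distance from a single source.

    Simulates one source on a quiet domain large enough that the boundary
    is irrelevant and reads the field at ``commit_time`` along a ray.
    Used for seeding layouts; actual predictions always re-simulate the
    real geometry.
    """
    pad = 8.0
    side = 2 * (max_radius + pad)
    grid = replace(cfg.grid, extent=(side, side))
    center = (side / 2, side / 2)
    snaps = simulate_field(grid, [cfg.source(center)], cfg.commit_time)
    f = snaps[cfg.commit_time]
    iy, ix = grid.index_of(center)
    n = int(max_radius / grid.spacing)
    radii = np.arange(n) * grid.spacing
    return radii, f[iy, ix : ix + n].copy()
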