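"""Synthetic characterization data and dose-response fitting.

Receiver strains are characterized by measuring fluorescence across a
titration of inducer concentrations (or, on plates, distances from a
droplet).  This module generates such tables from a known dose-response
with multiplicative log-normal measurement noise, and fits Hill-type
dose-response models back from them — the parameter-recovery loop used to
validate that a characterization protocol pins down the strain parameters
the device model needs.

Fitting is least squares on log fluorescence (fluorescence noise on plates
and in plate readers is predominantly multiplicative).  Diagnostics include
a Wald–Wolfowitz runs test on the concentration-ordered residual signs: a
model of the wrong shape (say, a highpass fit to bandpass data) leaves
long same-sign residual runs that the test flags as curvature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .simulator import DoseResponse, SourceSpec

__all__ = [
    "SenderModel",
    "generate_characterization",
    "fit_dose_response",
    "FitDiagnostics",
    "FitError",
]


@dataclass(frozen=True)
class SenderModel:
    """A biosensing sender colony: produces the diffusible signal when its
    environmental input is present, with optional leak when absent."""

    production_rate: float = 1.25  # amount/h when induced
    leak_rate: float = 0.0

    def __post_init__(self):
        if not 0 <= self.leak_rate <= self.production_rate:
            raise ValueError("need 0 <= leak_rate <= production_rate")

    def source(self, position: tuple[float, float], env_input: bool) -> SourceSpec:
        rate = self.production_rate if env_input else self.leak_rate
        return SourceSpec(position, "sender", dose=0.0, production_rate=rate)


def generate_characterization(
    dose_response: DoseResponse,
    concentrations: Sequence[float],
    noise_cv: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    od: float = 1.0,
) -> pd.DataFrame:
    """Synthetic titration table around a known dose-response curve.

    Noise is multiplicative log-normal with coefficient of variation
    ``noise_cv`` (median-preserving: at ``noise_cv = 0`` the values lie
    exactly on the curve).  Columns: concentration, replicate,
    fluorescence, od.  Seed-reproducible.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    conc = np.asarray(list(concentrations), dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be nonnegative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    rows = []
    for rep in range(1, replicates + 1):
        mu = dose_response.rate(conc)
        noise = np.exp(sigma * rng.standard_normal(conc.shape)) if sigma else 1.0
        rows.append(
            pd.DataFrame(
                {
                    "concentration": conc,
                    "replicate": rep,
                    "fluorescence": mu * noise,
                    "od": od,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class FitDiagnostics:
    """Residual summary of a dose-response fit (log-fluorescence scale)."""

    rmse: float
    n_points: int
    residuals: tuple[float, ...]
    runs_z: float  # Wald–Wolfowitz z-score of residual-sign runs
    curvature_flag: bool  # True when runs are too few: systematic misfit


class FitError(RuntimeError):
    """Fit failure; carries the residuals of the best attempt, if any."""

    def __init__(self, message: str, residuals: Optional[np.ndarray] = None):
        super().__init__(message)
        self.residuals = residuals


def _runs_test(signs: np.ndarray) -> float:
    """Z-score of the number of sign runs; large negative = too few runs."""
    n_pos = int((signs > 0).sum())
    n_neg = int((signs <= 0).sum())
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0:
        return -float(n)  # one long run: maximal curvature signal
    runs = 1 + int((signs[1:] != signs[:-1]).sum())
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 0.0
    return (runs - mu) / math.sqrt(var)


def _model(kind: str):
    if kind in ("highpass", "lowpass"):

        def f(u, basal, v_max, K, n):
            dr = DoseResponse(kind, basal=basal, v_max=v_max, K_act=K, n_act=n)
            return np.log(dr.rate(u))

        return f, ("basal", "v_max", "K_act", "n_act")

    def f(u, basal, v_max, Ka, na, Kr, nr):
        dr = DoseResponse(
            kind, basal=basal, v_max=v_max, K_act=Ka, n_act=na, K_rep=Kr, n_rep=nr
        )
        return np.log(dr.rate(u))

    return f, ("basal", "v_max", "K_act", "n_act", "K_rep", "n_rep")


def fit_dose_response(
    table: pd.DataFrame, kind: str
) -> tuple[DoseResponse, FitDiagnostics]:
    """Least-squares fit of a dose-response model on log fluorescence.

    Requires at least 6 distinct concentrations.  Raises :class:`FitError`
    (with residuals of the failed attempt) instead of failing silently.
    """
    conc = np.asarray(table["concentration"], dtype=float)
    fluo = np.asarray(table["fluorescence"], dtype=float)
    distinct = np.unique(conc)
    if len(distinct) < 6:
        raise ValueError(
            f"need >= 6 distinct concentrations to fit, got {len(distinct)}"
        )
    if (fluo <= 0).any():
        raise ValueError("fluorescence must be positive for a log-scale fit")
    pos = distinct[distinct > 0]
    lo, hi = float(fluo.min()), float(fluo.max())
    k_mid = float(np.sqrt(pos.min() * pos.max()))
    model, names = _model(kind)
    if kind in ("highpass", "lowpass"):
        p0 = [max(lo, 1e-9), hi, k_mid, 2.0]
        bounds = ([1e-12, 1e-9, pos.min() / 10, 0.2], [hi, 10 * hi, pos.max() * 10, 30])
    else:
        p0 = [max(lo, 1e-9), hi, k_mid / 3, 2.0, k_mid * 3, 2.0]
        bounds = (
            [1e-12, 1e-9, pos.min() / 10, 0.2, pos.min() / 10, 0.2],
            [hi, 10 * hi, pos.max() * 10, 30, pos.max() * 30, 30],
        )
    try:
        popt, _ = curve_fit(
            model, conc, np.log(fluo), p0=p0, bounds=bounds, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        resid = np.log(fluo) - model(conc, *p0)
        raise FitError(f"dose-response fit did not converge: {exc}", resid) from exc
    kwargs = dict(zip(names, (float(v) for v in popt)))
    if kind in ("bandpass", "bandstop") and kwargs["K_act"] >= kwargs["K_rep"]:
        resid = np.log(fluo) - model(conc, *popt)
        raise FitError(
            "fit converged to an invalid band (K_act >= K_rep)", resid
        )
    fitted = DoseResponse(kind, **kwargs)
    resid = np.log(fluo) - np.log(fitted.rate(conc))
    # residuals ordered by concentration: a wrong-shape model leaves long
    # same-sign stretches that survive replicate noise
    order = np.argsort(conc, kind="stable")
    z = _runs_test(np.sign(resid[order]))
    diags = FitDiagnostics(
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=len(conc),
        residuals=tuple(float(r) for r in resid),
        runs_z=z,
        curvature_flag=bool(z < -1.96),
    )
    return fitted, diags
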