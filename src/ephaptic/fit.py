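"""Parameter estimation for the sensillum circuit.

The central routine is :func:`global_fit`: a simultaneous nonlinear
least-squares fit of |LFP| dose-response data from one or more sensilla,
with a single set of circuit constants shared across all sensilla,
per-neuron odorant sensitivities, and — for sensilla whose dendritic
surfaces were not measured — the smaller neuron's dendrite area plus the
spike/LFP slope ratio ``r`` as free parameters, the larger neuron's dendrite
area being implied by ``r`` through the slope-ratio relation.

Also provides the empirical Hill fit used for measured dose-response curves
and the ordinary least-squares line fit used for spike-rate-vs-LFP points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .circuit import (
    LN10,
    CalibrationError,
    CommonParams,
    ModelError,
    NonPhysicalParameterError,
    ORNSpec,
    SensillumModel,
    calibrate_resting,
    dendrite_area_from_ratio,
    dendritic_resistance,
    input_resistance,
    spike_lfp_ratio,
)
from .circuit import _solve_closed  # closed-form Kirchhoff solve (vectorized)

logger = logging.getLogger(__name__)

__all__ = [
    "FitFailureError",
    "DoseResponseDataset",
    "FitConfig",
    "FitResult",
    "HillFit",
    "LinearFit",
    "predict_lfp",
    "model_residuals",
    "global_fit",
    "hill_fit",
    "linear_fit",
]

COMMON_NAMES = ("E_A", "rho_s", "rho_d0", "n", "g_max")
DEFAULT_COMMON_BOUNDS = {
    "E_A": (20.0, 150.0),
    "rho_s": (5.0, 150.0),
    "rho_d0": (2.0, 80.0),
    "n": (0.2, 2.0),
    "g_max": (1.0, 50.0),
}
_PENALTY = 1.0e3  # residual value for infeasible parameter sets


class FitFailureError(ModelError, RuntimeError):
    """A fit could not be carried out or produced no usable optimum."""


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

class DoseResponseDataset:
    """Long-format |LFP| dose-response measurements with replicate structure.

    Wraps a DataFrame with columns ``sensillum, orn, odorant,
    x_log10_dilution, replicate, lfp_mV`` (``odorant`` optional).
    """

    REQUIRED = ("sensillum", "orn", "x_log10_dilution", "replicate", "lfp_mV")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "DoseResponseDataset":
        return cls(pd.read_csv(path, comment="#"))

    @property
    def sensilla(self) -> list[str]:
        return sorted(self.frame["sensillum"].unique())

    def summarize(self) -> pd.DataFrame:
        """Replicate mean and s.e.m. per (sensillum, orn, dilution)."""
        g = self.frame.groupby(["sensillum", "orn", "x_log10_dilution"])["lfp_mV"]
        out = g.agg(mean_lfp_mV="mean", sem_lfp_mV="sem", n="count").reset_index()
        return out.sort_values(["sensillum", "orn", "x_log10_dilution"],
                               ignore_index=True)


# ---------------------------------------------------------------------------
# Fit configuration and result
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Free/fixed structure, bounds and optimizer settings for a global fit.

    ``sensilla`` maps sensillum name to its ``(orn1, orn2)`` specs; the specs'
    ``k_od`` and ``A_d`` fields provide initial values.  A sensillum whose
    two ``A_d_is_measured`` flags are both set keeps its dendrite areas
    fixed; otherwise ``A_d2`` and the slope ratio ``r`` are free and ``A_d1``
    is implied.  ``V_0`` is always fixed (-60 mV by convention).
    """

    sensilla: dict[str, tuple[ORNSpec, ORNSpec]]
    common_init: CommonParams | None = None
    common_free: tuple[str, ...] = COMMON_NAMES
    common_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMMON_BOUNDS))
    k_od_bounds: tuple[float, float] = (-10.0, 1.0)
    A_d_bounds: tuple[float, float] = (4.0, 150.0)
    r_bounds: tuple[float, float] = (1.0 + 1e-6, 5.0)
    n_starts: int = 32
    seed: int = 0
    weighting: Literal["unweighted", "inverse_sem"] = "unweighted"
    jitter: float = 0.2

    def __post_init__(self) -> None:
        for name in self.common_free:
            if name not in COMMON_NAMES:
                raise ValueError(f"unknown common parameter {name!r}")
            lo, hi = self.common_bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")

    def sensillum_mode(self, name: str) -> str:
        o1, o2 = self.sensilla[name]
        return "measured" if (o1.A_d_is_measured and o2.A_d_is_measured) else "ratio"


@dataclass
class FitResult:
    """Outcome of a (multistart) global fit."""

    params: dict[str, float]
    objective: float
    residuals: np.ndarray
    per_start: list[dict]
    n_data: int
    success: bool
    under_determined: bool = False
    message: str = ""

    def model_for(self, name: str, config: FitConfig) -> SensillumModel:
        """Rebuild the calibrated sensillum model implied by the fitted parameters."""
        common, specs = _build_structures(self.params, config)
        o1, o2 = specs[name]
        return calibrate_resting(common, o1, o2, name=name)


# ---------------------------------------------------------------------------
# Parameter vector packing
# ---------------------------------------------------------------------------

def _pack_spec(config: FitConfig) -> list[tuple[str, float, float, float]]:
    """(name, init, lo, hi) for each free parameter, in a fixed order."""
    common = config.common_init or CommonParams(
        E_A=77.0, V_0=-60.0, rho_s=30.0, rho_d0=17.0, n=0.7, g_max=10.0)
    entries: list[tuple[str, float, float, float]] = []
    for name in config.common_free:
        lo, hi = config.common_bounds[name]
        entries.append((name, float(np.clip(getattr(common, name), lo, hi)), lo, hi))
    for sens in sorted(config.sensilla):
        o1, o2 = config.sensilla[sens]
        klo, khi = config.k_od_bounds
        entries.append((f"{sens}.k_od1", float(np.clip(o1.k_od, klo, khi)), klo, khi))
        entries.append((f"{sens}.k_od2", float(np.clip(o2.k_od, klo, khi)), klo, khi))
        if config.sensillum_mode(sens) == "ratio":
            alo, ahi = config.A_d_bounds
            ad2 = o2.A_d if o2.A_d is not None else 0.5 * (alo + ahi)
            entries.append((f"{sens}.A_d2", float(np.clip(ad2, alo, ahi)), alo, ahi))
            rlo, rhi = config.r_bounds
            r0 = 0.5 * (rlo + rhi)
            if o1.A_d is not None and o2.A_d is not None:
                try:
                    r0 = spike_lfp_ratio(calibrate_resting(common, o1, o2, name=sens))
                except ModelError:
                    pass
            entries.append((f"{sens}.r", float(np.clip(r0, rlo, rhi)), rlo, rhi))
    return entries


def _build_structures(params: Mapping[str, float], config: FitConfig
                      ) -> tuple[CommonParams, dict[str, tuple[ORNSpec, ORNSpec]]]:
    """Materialize CommonParams and per-sensillum ORN specs from a parameter map.

    Raises :class:`ModelError` subclasses for infeasible combinations (the
    residual function converts those into a finite penalty).
    """
    base = config.common_init or CommonParams(
        E_A=77.0, V_0=-60.0, rho_s=30.0, rho_d0=17.0, n=0.7, g_max=10.0)
    kw = {name: params.get(name, getattr(base, name)) for name in COMMON_NAMES}
    common = CommonParams(V_0=base.V_0, **kw)
    specs: dict[str, tuple[ORNSpec, ORNSpec]] = {}
    for sens in sorted(config.sensilla):
        o1, o2 = config.sensilla[sens]
        k1 = params.get(f"{sens}.k_od1", o1.k_od)
        k2 = params.get(f"{sens}.k_od2", o2.k_od)
        if config.sensillum_mode(sens) == "ratio":
            A_d2 = params.get(f"{sens}.A_d2", o2.A_d)
            o2_new = ORNSpec(o2.label, o2.A_s, A_d2, k2, A_d_is_measured=False)
            if f"{sens}.r" in params:
                A_d1 = dendrite_area_from_ratio(params[f"{sens}.r"], o1, o2_new, common)
            else:
                A_d1 = params.get(f"{sens}.A_d1", o1.A_d)
            o1_new = ORNSpec(o1.label, o1.A_s, A_d1, k1, A_d_is_measured=False)
        else:
            o1_new = ORNSpec(o1.label, o1.A_s, o1.A_d, k1, A_d_is_measured=True)
            o2_new = ORNSpec(o2.label, o2.A_s, o2.A_d, k2, A_d_is_measured=True)
        specs[sens] = (o1_new, o2_new)
    return common, specs


# ---------------------------------------------------------------------------
# Forward prediction and residuals
# ---------------------------------------------------------------------------

def predict_lfp(model: SensillumModel, x, stimulated: int) -> np.ndarray:
    """Model |LFP| responses at log10 dilutions ``x`` (vectorized closed form).

    Single-odorant stimulation of one ORN with the neighbor unstimulated;
    the response is the field change from the resting state.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    gains = model.gain_from_dilution(stimulated, x)
    R_d1_0 = model.R_d(1, 0.0)
    R_d2_0 = model.R_d(2, 0.0)
    R_1 = model.R_in1 + R_d1_0
    R_2 = model.R_in2 + R_d2_0
    VA0 = _solve_closed(model.common.E_A, model.E_1, model.E_2, R_1, R_2)[0]
    if stimulated == 1:
        R_1 = model.R_in1 + dendritic_resistance(model.orn1.A_d, model.common.rho_d0, gains)
    else:
        R_2 = model.R_in2 + dendritic_resistance(model.orn2.A_d, model.common.rho_d0, gains)
    VA = _solve_closed(model.common.E_A, model.E_1, model.E_2, R_1, R_2)[0]
    return np.abs(np.asarray(VA) - VA0)


def _stimulated_index(sens: str, orn_label: str, specs) -> int:
    o1, o2 = specs[sens]
    if orn_label == o1.label:
        return 1
    if orn_label == o2.label:
        return 2
    raise ValueError(f"dataset ORN label {orn_label!r} matches neither "
                     f"{o1.label!r} nor {o2.label!r} of sensillum {sens!r}")


def _prepare_targets(summary: pd.DataFrame, config: FitConfig) -> list[tuple]:
    """Precompute per-(sensillum, ORN) target arrays for the residual loop."""
    targets = []
    for (sens, orn), grp in summary.groupby(["sensillum", "orn"], sort=True):
        idx = _stimulated_index(sens, orn, config.sensilla)
        x = grp["x_log10_dilution"].to_numpy()
        mean = grp["mean_lfp_mV"].to_numpy()
        if config.weighting == "inverse_sem":
            sem = grp["sem_lfp_mV"].to_numpy()
            fallback = np.nanmax(sem) if np.isfinite(sem).any() else 1.0
            w = 1.0 / np.where(np.isfinite(sem) & (sem > 0), sem, fallback or 1.0)
        else:
            w = np.ones_like(mean)
        targets.append((sens, idx, x, mean, w))
    return targets


def _residuals_from_targets(params: Mapping[str, float], targets: list[tuple],
                            config: FitConfig) -> np.ndarray:
    n_data = sum(len(t[3]) for t in targets)
    try:
        common, specs = _build_structures(params, config)
        models = {sens: calibrate_resting(common, *specs[sens], name=sens)
                  for sens in {t[0] for t in targets}}
    except (CalibrationError, NonPhysicalParameterError, ModelError):
        return np.full(n_data, _PENALTY)
    res = np.empty(n_data)
    pos = 0
    for sens, idx, x, mean, w in targets:
        pred = predict_lfp(models[sens], x, idx)
        res[pos:pos + len(x)] = (pred - mean) * w
        pos += len(x)
    return res


def model_residuals(params: Mapping[str, float], datasets: DoseResponseDataset,
                    config: FitConfig, summary: pd.DataFrame | None = None
                    ) -> np.ndarray:
    """Residuals (model minus measured mean |LFP|) for a parameter map.

    One residual per (sensillum, ORN, dilution); optionally weighted by the
    inverse replicate s.e.m.  Parameter maps for which the circuit cannot be
    calibrated (or the implied dendrite area is non-physical) return a large
    finite penalty in every entry so optimizers can back out gracefully.
    """
    if summary is None:
        summary = datasets.summarize()
    for sens in datasets.sensilla:
        if sens not in config.sensilla:
            raise ValueError(f"dataset sensillum {sens!r} has no model specification")
    return _residuals_from_targets(params, _prepare_targets(summary, config), config)


# ---------------------------------------------------------------------------
# Global multistart fit
# ---------------------------------------------------------------------------

def _jittered_starts(entries, n_starts: int, jitter: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    x0 = np.array([e[1] for e in entries])
    lo = np.array([e[2] for e in entries])
    hi = np.array([e[3] for e in entries])
    starts = [x0]
    for _ in range(n_starts - 1):
        scale = jitter * np.maximum(np.abs(x0), 1.0)
        starts.append(np.clip(x0 + rng.uniform(-1.0, 1.0, size=x0.size) * scale,
                              lo + 1e-9, hi - 1e-9))
    return np.array(starts)


def global_fit(datasets: DoseResponseDataset, config: FitConfig) -> FitResult:
    """Simultaneous least-squares fit of all sensilla in ``datasets``.

    Runs ``config.n_starts`` trust-region-reflective fits from seeded,
    jittered initial values and returns the best.  The result records every
    start's outcome; the reported parameter map includes the fixed values,
    and for ratio-mode sensilla the implied ``A_d1``.
    """
    summary = datasets.summarize()
    counts = summary.groupby(["sensillum", "orn"]).size()
    if (counts < 4).any():
        raise ValueError("each ORN needs measurements at >= 4 concentrations")
    entries = _pack_spec(config)
    if not entries:
        raise ValueError("no free parameters")
    names = [e[0] for e in entries]
    lo = np.array([e[2] for e in entries])
    hi = np.array([e[3] for e in entries])

    under = (len(datasets.sensilla) == 1
             and set(config.common_free) == set(COMMON_NAMES))
    msg = ("fit of a single sensillum with all shared circuit constants free "
           "is under-determined; constrain common parameters or fit several "
           "sensilla jointly" if under else "")
    if under:
        logger.warning(msg)

    targets = _prepare_targets(summary, config)

    def fun(x: np.ndarray) -> np.ndarray:
        return _residuals_from_targets(dict(zip(names, x)), targets, config)

    per_start: list[dict] = []
    best = None
    for i, x0 in enumerate(_jittered_starts(entries, config.n_starts,
                                            config.jitter, config.seed)):
        try:
            sol = optimize.least_squares(fun, x0, bounds=(lo, hi), method="trf",
                                         x_scale="jac", ftol=1e-12, xtol=1e-12,
                                         gtol=1e-12, max_nfev=4000)
            obj = float(np.sum(sol.fun ** 2))
            feasible = obj < 0.5 * _PENALTY ** 2 * len(summary)
            per_start.append({"start": i, "objective": obj, "success": bool(sol.status > 0),
                              "feasible": feasible})
            if feasible and (best is None or obj < best[0]):
                best = (obj, sol)
        except Exception as exc:  # noqa: BLE001 - record, don't abort the multistart
            logger.debug("start %d failed: %s", i, exc)
            per_start.append({"start": i, "objective": np.inf, "success": False,
                              "feasible": False})
    if best is None:
        raise FitFailureError("all starts infeasible or failed; "
                              f"outcomes: {per_start}")
    obj, sol = best

    params = dict(zip(names, [float(v) for v in sol.x]))
    common, specs = _build_structures(params, config)
    full = dict(params)
    for name in COMMON_NAMES:
        full.setdefault(name, float(getattr(common, name)))
    full["V_0"] = float(common.V_0)
    for sens in sorted(config.sensilla):
        o1, o2 = specs[sens]
        full[f"{sens}.A_d1"] = float(o1.A_d)
        full[f"{sens}.A_d2"] = float(o2.A_d)
        full.setdefault(f"{sens}.k_od1", float(o1.k_od))
        full.setdefault(f"{sens}.k_od2", float(o2.k_od))
    logger.info("global fit: best objective %.6g over %d starts", obj, config.n_starts)
    return FitResult(params=full, objective=obj, residuals=sol.fun,
                     per_start=per_start, n_data=len(summary), success=True,
                     under_determined=under, message=msg)


# ---------------------------------------------------------------------------
# Empirical fits (Hill dose-response, linear spike-vs-LFP)
# ---------------------------------------------------------------------------

class HillFit(NamedTuple):
    plateau: float
    k_half: float
    n_hill: float


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    slope_stderr: float
    intercept_stderr: float


def hill_fit(x, response) -> HillFit:
    """Fit ``response = plateau / (1 + 10**(n*(k_half - x)))`` to a curve.

    Needs at least four points spanning rise and plateau; degenerate (flat)
    data raise :class:`FitFailureError`, as does any fit that fails to beat
    the best constant fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size or x.size < 4:
        raise FitFailureError("hill_fit needs >= 4 (x, response) pairs")
    if np.ptp(y) == 0:
        raise FitFailureError("responses are constant; Hill fit is degenerate")

    y_max = float(np.max(y))
    half = 0.5 * y_max
    above = y >= half
    k0 = float(x[np.argmax(above)]) if above.any() else float(np.median(x))

    def fun(p):
        plateau, k, n = p
        return plateau * expit(LN10 * n * (x - k)) - y

    sol = optimize.least_squares(
        fun, x0=[y_max, k0, 1.0],
        bounds=([1e-9, np.min(x) - 20.0, 1e-3], [np.inf, np.max(x) + 20.0, 20.0]),
        method="trf", x_scale="jac", ftol=1e-14, xtol=1e-14)
    sse = float(np.sum(sol.fun ** 2))
    sse_const = float(np.sum((y - y.mean()) ** 2))
    if not sol.status > 0 or sse > sse_const:
        raise FitFailureError("Hill fit did not converge to anything better "
                              "than a constant")
    return HillFit(plateau=float(sol.x[0]), k_half=float(sol.x[1]),
                   n_hill=float(sol.x[2]))


def linear_fit(points: Sequence[tuple[float, float]]) -> LinearFit:
    """Ordinary least-squares line through (|LFP|, spike-rate) points.

    The slope is the empirical spike/LFP ratio.  Requires >= 3 points with
    non-constant abscissa.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise FitFailureError("linear_fit needs >= 3 (x, y) pairs")
    xs, ys = pts[:, 0], pts[:, 1]
    if np.ptp(xs) == 0:
        raise FitFailureError("abscissa values are all identical")
    res = stats.linregress(xs, ys)
    return LinearFit(slope=float(res.slope), intercept=float(res.intercept),
                     slope_stderr=float(res.stderr),
                     intercept_stderr=float(res.intercept_stderr))
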