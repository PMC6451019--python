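"""Forward-simulation scenarios for a calibrated sensillum.

Steady-state dose-response curves and the derived quantities used to
characterize ephaptic interaction: the (linear) relation between an ORN's
depolarization and the field response, the asymmetry of mutual inhibition,
the sublinearity of binary-mixture responses, and the hypothetical in which
both neurons express the same receptor so that size alone differentiates
them.

All "LFP responses" are ``|delta V_A|`` relative to the pre-stimulus
baseline; when a background activation of the neighbor is imposed, the
baseline is the background-only steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuit import (
    ParameterError,
    SensillumModel,
    StimulusState,
    activation_fraction,
    conductance_gain,
    solve_circuit,
)

__all__ = [
    "DEFAULT_X_GRID",
    "DoseResponseCurve",
    "VmLfpRelation",
    "AsymmetryReport",
    "dose_response",
    "saturating_lfp",
    "depolarization_vs_lfp",
    "asymmetry_report",
    "mixture_linearity_deficit",
    "same_receptor_scenario",
    "curves_to_frame",
]

# -10..0 log10 dilution in steps of 0.25 covers every tabulated sensitivity
DEFAULT_X_GRID = np.round(np.arange(-10.0, 0.0 + 1e-9, 0.25), 6)


@dataclass(frozen=True)
class DoseResponseCurve:
    """|LFP| and membrane potentials of one ORN swept over dilution.

    ``background`` is the neighbor's constant activation fraction; membrane
    potentials are absolute (mV), the LFP is the change from the
    background-only baseline.
    """

    orn_label: str
    stimulated: int
    x_grid: np.ndarray
    lfp: np.ndarray
    vm_active: np.ndarray
    vm_neighbor: np.ndarray
    background: float
    baseline_VA: float
    saturating_lfp: float


@dataclass(frozen=True)
class VmLfpRelation:
    """Paired (|LFP|, membrane depolarization) series and their slope."""

    orn_label: str
    lfp: np.ndarray
    delta_vm: np.ndarray
    slope: float


@dataclass(frozen=True)
class AsymmetryReport:
    """Saturating membrane-potential changes for one stimulation direction.

    ``ratio_neighbor_over_active`` = |neighbor hyperpolarization| /
    |active-neuron depolarization|; larger means stronger ephaptic inhibition
    exerted by the active neuron.
    """

    stimulated: int
    stimulated_label: str
    background: float
    dVm_active_max: float
    dVm_neighbor_max: float
    ratio_neighbor_over_active: float


def _stimulus(model: SensillumModel, stimulated: int, g_stim: float,
              background_fraction: float) -> StimulusState:
    g_bg = conductance_gain(background_fraction, model.common.g_max)
    if stimulated == 1:
        return StimulusState(g1=g_stim, g2=g_bg)
    return StimulusState(g1=g_bg, g2=g_stim)


def dose_response(model: SensillumModel, stimulated: int,
                  x_grid: np.ndarray | None = None,
                  background_fraction: float = 0.0) -> DoseResponseCurve:
    """Sweep one ORN's odorant dilution with the neighbor at a fixed background.

    Returns the |LFP| response (field change from the background-only
    baseline) and both membrane potentials at each grid point, plus the
    saturating |LFP| in the infinite-concentration limit.
    """
    if stimulated not in (1, 2):
        raise ValueError(f"stimulated must be 1 or 2, got {stimulated}")
    if not 0.0 <= background_fraction <= 1.0:
        raise ParameterError(f"background fraction must lie in [0, 1], got {background_fraction}")
    x_grid = DEFAULT_X_GRID if x_grid is None else np.asarray(x_grid, dtype=float)
    if x_grid.size == 0:
        raise ValueError("x_grid must not be empty")

    orn = model.orn1 if stimulated == 1 else model.orn2
    base = solve_circuit(model, _stimulus(model, stimulated, 0.0, background_fraction))

    frac = activation_fraction(x_grid, orn.k_od, model.common.n)
    gains = conductance_gain(frac, model.common.g_max)
    lfp = np.empty_like(x_grid)
    vm_active = np.empty_like(x_grid)
    vm_neighbor = np.empty_like(x_grid)
    for i, g in enumerate(np.atleast_1d(gains)):
        sol = solve_circuit(model, _stimulus(model, stimulated, float(g), background_fraction))
        lfp[i] = abs(sol.V_A - base.V_A)
        vm_active[i] = sol.V_m1 if stimulated == 1 else sol.V_m2
        vm_neighbor[i] = sol.V_m2 if stimulated == 1 else sol.V_m1
    sat = solve_circuit(model, _stimulus(model, stimulated, model.common.g_max,
                                         background_fraction))
    return DoseResponseCurve(
        orn_label=orn.label, stimulated=stimulated, x_grid=x_grid,
        lfp=lfp, vm_active=vm_active, vm_neighbor=vm_neighbor,
        background=background_fraction, baseline_VA=base.V_A,
        saturating_lfp=abs(sat.V_A - base.V_A),
    )


def saturating_lfp(model: SensillumModel, stimulated: int,
                   background_fraction: float = 0.0) -> float:
    """|LFP| response at full activation of one ORN (infinite-dose limit)."""
    base = solve_circuit(model, _stimulus(model, stimulated, 0.0, background_fraction))
    sat = solve_circuit(model, _stimulus(model, stimulated, model.common.g_max,
                                         background_fraction))
    return abs(sat.V_A - base.V_A)


def depolarization_vs_lfp(model: SensillumModel, stimulated: int,
                          x_grid: np.ndarray | None = None) -> VmLfpRelation:
    """Depolarization of the stimulated ORN against its |LFP| response.

    The relation is exactly linear because the neighbor's resistance does
    not change: the slope is ``R_in,stim * (1 + 1/R_neighbor,0)``.
    """
    curve = dose_response(model, stimulated, x_grid=x_grid, background_fraction=0.0)
    delta_vm = curve.vm_active - model.common.V_0
    if stimulated == 1:
        slope = model.R_in1 * (1.0 + 1.0 / (model.R_in2 + model.R_d(2, 0.0)))
    else:
        slope = model.R_in2 * (1.0 + 1.0 / (model.R_in1 + model.R_d(1, 0.0)))
    return VmLfpRelation(orn_label=curve.orn_label, lfp=curve.lfp,
                         delta_vm=delta_vm, slope=slope)


def asymmetry_report(model: SensillumModel,
                     background_levels: tuple[float, ...] = (0.0, 0.5)
                     ) -> list[AsymmetryReport]:
    """Strength of mutual ephaptic inhibition in both directions.

    For each stimulation direction and background level, saturate the
    stimulated ORN and report the maximal membrane-potential changes of both
    neurons (relative to the background-only baseline) and their ratio.
    """
    reports = []
    for stimulated in (1, 2):
        orn = model.orn1 if stimulated == 1 else model.orn2
        for bg in background_levels:
            base = solve_circuit(model, _stimulus(model, stimulated, 0.0, bg))
            sat = solve_circuit(model, _stimulus(model, stimulated, model.common.g_max, bg))
            if stimulated == 1:
                d_active = sat.V_m1 - base.V_m1
                d_neighbor = sat.V_m2 - base.V_m2
            else:
                d_active = sat.V_m2 - base.V_m2
                d_neighbor = sat.V_m1 - base.V_m1
            reports.append(AsymmetryReport(
                stimulated=stimulated, stimulated_label=orn.label, background=bg,
                dVm_active_max=d_active, dVm_neighbor_max=d_neighbor,
                ratio_neighbor_over_active=abs(d_neighbor) / abs(d_active),
            ))
    return reports


def mixture_linearity_deficit(model: SensillumModel, x1: float, x2: float) -> float:
    """Sublinearity of the field response to a binary odorant mixture, mV.

    ``deficit = (|dV_A(x1 alone)| + |dV_A(x2 alone)|) - |dV_A(x1 and x2)|``.
    Nonnegative for this passive circuit; its size measures how strongly the
    two transduction currents compete for the shared field.  ``x = -inf``
    encodes an absent component; ``x = +inf`` a saturating one.
    """
    g1 = model.gain_from_dilution(1, x1)
    g2 = model.gain_from_dilution(2, x2)
    base = solve_circuit(model, StimulusState(0.0, 0.0))
    l1 = abs(solve_circuit(model, StimulusState(g1, 0.0)).V_A - base.V_A)
    l2 = abs(solve_circuit(model, StimulusState(0.0, g2)).V_A - base.V_A)
    joint = abs(solve_circuit(model, StimulusState(g1, g2)).V_A - base.V_A)
    return (l1 + l2) - joint


def same_receptor_scenario(model: SensillumModel, shared_k_od: float,
                           x_grid: np.ndarray | None = None
                           ) -> tuple[DoseResponseCurve, DoseResponseCurve]:
    """Both neurons given an identical odorant sensitivity.

    Isolates the morphometric contribution: with sensitivity equalized, any
    difference between the two dose-response curves (saturating |LFP|,
    depolarization per mV of field) is due to size alone.
    """
    shared = model.with_shared_k_od(shared_k_od)
    return (dose_response(shared, 1, x_grid=x_grid),
            dose_response(shared, 2, x_grid=x_grid))


def curves_to_frame(curves: list[DoseResponseCurve], sensillum: str) -> pd.DataFrame:
    """Tidy long-format table of dose-response curves (one row per grid point)."""
    rows = []
    for c in curves:
        for x, lfp, va, vn in zip(c.x_grid, c.lfp, c.vm_active, c.vm_neighbor):
            rows.append((sensillum, c.orn_label, c.background, x, lfp, va, vn))
    return pd.DataFrame(rows, columns=[
        "sensillum", "orn", "background_fraction", "x_log10_dilution",
        "lfp_mV", "vm_active_mV", "vm_neighbor_mV"])
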