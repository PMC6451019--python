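"""Passive electric circuit of a two-neuron insect sensillum.

A sensillum houses two olfactory receptor neurons (ORNs) whose sensory
dendrites share a small lymph space held at the transepithelial potential
``V_A`` by an auxiliary cell.  Each cell is a Thevenin branch: the auxiliary
cell is a battery ``E_A`` behind the reference resistance ``R_A``; each ORN is
a somatic battery ``E_i`` behind the somatic input resistance ``R_in,i`` in
series with an odorant-dependent dendritic resistance ``R_d,i``.  Kirchhoff's
laws for the three branch currents give a linear system whose solution yields
``V_A`` and the two transmembrane potentials ``V_m1``, ``V_m2``.

Because all three branches share the lymph node, opening transduction
channels in one neuron (lowering its ``R_d``) pulls ``V_A`` down and thereby
hyperpolarizes its neighbor — the ephaptic interaction this package models.

Conventions
-----------
* All resistances are rescaled by ``R_A`` (so ``R_A = 1`` and resistivities
  carry units of um^2); currents are in mV per unit ``R_A`` (arbitrary units).
* ``orn1`` is the large-spike "A" neuron, ``orn2`` the small-spike "B" neuron.
* The model is steady-state: capacitive currents are zero by assumption.

Odorant activation follows a Hill function of the log10 dilution ``x``:
the fraction of activated receptors is ``1 / (1 + 10**(n*(k_od - x)))`` and
multiplies the maximal conductance gain ``g_max``, so the dendritic
resistance is ``R_d = rho_d0 / (A_d * (1 + g))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.special import expit

LN10 = math.log(10.0)

__all__ = [
    "ModelError",
    "ParameterError",
    "CalibrationError",
    "NonPhysicalParameterError",
    "CommonParams",
    "ORNSpec",
    "StimulusState",
    "CircuitSolution",
    "RestingClosedForm",
    "CableSegment",
    "SensillumModel",
    "activation_fraction",
    "conductance_gain",
    "input_resistance",
    "dendritic_resistance",
    "cable_input_resistance",
    "solve_circuit",
    "calibrate_resting",
    "ephaptic_delta_vm",
    "spike_lfp_ratio",
    "dendrite_area_from_ratio",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ModelError(Exception):
    """Base class for circuit-model errors."""


class ParameterError(ModelError, ValueError):
    """A parameter violates its domain (non-positive area, negative gain, ...)."""


class CalibrationError(ModelError, ArithmeticError):
    """Resting-battery calibration is infeasible or internally inconsistent."""


class NonPhysicalParameterError(ModelError, ValueError):
    """A derived quantity (e.g. a dendritic resistance) would be non-physical."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommonParams:
    """Sensillum-independent circuit constants.

    Parameters
    ----------
    E_A : float
        Auxiliary-cell battery, mV.
    V_0 : float
        ORN resting membrane potential, mV.
    rho_s : float
        Soma membrane resistivity rescaled by ``R_A``, um^2.
    rho_d0 : float
        Basal dendritic membrane resistivity rescaled by ``R_A``, um^2.
    n : float
        Hill coefficient of odorant activation, dimensionless.
    g_max : float
        Maximal activation-induced conductance gain (basal resistivity times
        maximal induced conductivity), dimensionless.
    """

    E_A: float
    V_0: float
    rho_s: float
    rho_d0: float
    n: float
    g_max: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in
                   (self.E_A, self.V_0, self.rho_s, self.rho_d0, self.n, self.g_max)):
            raise ParameterError("common parameters must be finite")
        if self.rho_s <= 0:
            raise ParameterError(f"rho_s must be > 0, got {self.rho_s}")
        if self.rho_d0 <= 0:
            raise ParameterError(f"rho_d0 must be > 0, got {self.rho_d0}")
        if self.n <= 0:
            raise ParameterError(f"Hill coefficient n must be > 0, got {self.n}")
        if self.g_max < 0:
            raise ParameterError(f"g_max must be >= 0, got {self.g_max}")
        if self.E_A <= self.V_0:
            raise ParameterError(
                f"E_A ({self.E_A}) must exceed V_0 ({self.V_0}): "
                "E_A - V_0 is the driving force for the resting currents")


@dataclass(frozen=True)
class ORNSpec:
    """One neuron's morphometry and odorant sensitivity.

    ``A_s``/``A_d`` are soma and outer-dendrite surface areas in um^2;
    ``k_od`` is the log10 odorant dilution at half-maximal receptor
    activation.  ``A_d`` may be ``None`` for a neuron whose dendritic surface
    is a free fitting parameter rather than a measured quantity
    (``A_d_is_measured`` records which it was).
    """

    label: str
    A_s: float
    A_d: float | None = None
    k_od: float = 0.0
    A_d_is_measured: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.A_s) and self.A_s > 0):
            raise ParameterError(f"{self.label}: soma area A_s must be > 0, got {self.A_s}")
        if self.A_d is not None and not (math.isfinite(self.A_d) and self.A_d > 0):
            raise ParameterError(f"{self.label}: dendrite area A_d must be > 0, got {self.A_d}")
        if not math.isfinite(self.k_od):
            raise ParameterError(f"{self.label}: k_od must be finite, got {self.k_od}")


@dataclass(frozen=True)
class StimulusState:
    """Activation-induced conductance gains for the two ORNs.

    ``g = 0`` encodes "no stimulus"; gains are produced from log10 dilutions
    by :func:`activation_fraction` and :func:`conductance_gain`.
    """

    g1: float = 0.0
    g2: float = 0.0

    def __post_init__(self) -> None:
        if self.g1 < 0 or self.g2 < 0:
            raise ParameterError(f"conductance gains must be >= 0, got ({self.g1}, {self.g2})")


@dataclass(frozen=True)
class CircuitSolution:
    """Solved steady state of the circuit for one stimulus.

    Voltages in mV; currents in mV per unit ``R_A`` (arbitrary units);
    resistances dimensionless (rescaled by ``R_A``).
    """

    V_A: float
    V_m1: float
    V_m2: float
    I_A: float
    I_1: float
    I_2: float
    R_1: float
    R_2: float
    R_in1: float
    R_in2: float
    R_d1: float
    R_d2: float


@dataclass(frozen=True)
class RestingClosedForm:
    """Closed-form intermediates of the resting-battery calibration.

    ``xi0`` measures the resting asymmetry between the two ORN branches
    (zero for identical neurons); ``Theta0`` rescales the common driving
    force ``E_A - V_0``.  ``E_T``/``R_T`` are the Thevenin battery and
    resistance of the combined neuronal branch at rest.
    """

    xi0: float
    Theta0: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    E_T: float
    R_T: float


@dataclass(frozen=True)
class CableSegment:
    """Uniform leaky cylinder with an open (lymph) end and a sealed end.

    ``r_m`` is membrane resistance in resistance-times-length form, ``r_a``
    axial resistivity per length, ``L`` length.  The electrotonic length is
    ``l = L * sqrt(r_a / r_m)`` and ``R_inf = sqrt(r_m * r_a)`` is the input
    resistance of a semi-infinite cable.
    """

    r_m: float
    r_a: float
    L: float

    def __post_init__(self) -> None:
        if self.r_m <= 0 or self.r_a <= 0:
            raise ParameterError("cable resistivities must be > 0")
        if self.L <= 0:
            raise ParameterError(f"cable length must be > 0, got {self.L}")

    @property
    def l(self) -> float:
        return self.L * math.sqrt(self.r_a / self.r_m)

    @property
    def R_inf(self) -> float:
        return math.sqrt(self.r_m * self.r_a)


# ---------------------------------------------------------------------------
# Elementary resistances and activation
# ---------------------------------------------------------------------------

def activation_fraction(x, k_od: float, n: float):
    """Fraction of activated receptors at log10 dilution ``x``.

    Evaluates the Hill function ``1 / (1 + 10**(n*(k_od - x)))`` through the
    logistic for numerical stability.  ``x`` may be a scalar or array;
    ``x = -inf`` (no odorant) gives 0 and ``x = +inf`` (saturation) gives 1.
    """
    if not (math.isfinite(k_od) and math.isfinite(n)):
        raise ParameterError("k_od and n must be finite")
    if n <= 0:
        raise ParameterError(f"Hill coefficient n must be > 0, got {n}")
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ParameterError("dilution x must not be NaN")
    out = expit(LN10 * n * (x - k_od))
    return float(out) if out.ndim == 0 else out


def conductance_gain(fraction, g_max: float):
    """Conductance gain ``g = g_max * fraction`` for a receptor-activation fraction."""
    if g_max < 0:
        raise ParameterError(f"g_max must be >= 0, got {g_max}")
    fraction = np.asarray(fraction, dtype=float)
    if ((fraction < 0) | (fraction > 1)).any():
        raise ParameterError("activation fraction must lie in [0, 1]")
    out = g_max * fraction
    return float(out) if out.ndim == 0 else out


def input_resistance(A_s: float, rho_s: float) -> float:
    """Somatic input resistance ``R_in = rho_s / A_s`` (dimensionless, R_A-rescaled)."""
    if A_s <= 0:
        raise ParameterError(f"soma area must be > 0, got {A_s}")
    if rho_s <= 0:
        raise ParameterError(f"rho_s must be > 0, got {rho_s}")
    return rho_s / A_s


def dendritic_resistance(A_d: float, rho_d0: float, g):
    """Dendritic resistance ``R_d = rho_d0 / (A_d * (1 + g))``.

    Strictly decreasing in the conductance gain ``g``; at ``g = 0`` it is the
    basal value ``rho_d0 / A_d``, and it shunts to 0 as ``g`` grows.
    """
    if A_d <= 0:
        raise ParameterError(f"dendrite area must be > 0, got {A_d}")
    if rho_d0 <= 0:
        raise ParameterError(f"rho_d0 must be > 0, got {rho_d0}")
    g = np.asarray(g, dtype=float)
    if (g < 0).any():
        raise ParameterError("conductance gain g must be >= 0")
    out = rho_d0 / (A_d * (1.0 + g))
    return float(out) if out.ndim == 0 else out


def cable_input_resistance(seg: CableSegment) -> float:
    """Exact cable-theory input resistance ``sqrt(r_m*r_a) * coth(l)``.

    For electrotonic length ``l << 1`` this approaches the lumped value
    ``r_m / L`` used for the sensillar dendrites (relative error ~ l**2/3).
    """
    return seg.R_inf / math.tanh(seg.l)


# ---------------------------------------------------------------------------
# The calibrated sensillum and the Kirchhoff solve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensillumModel:
    """A calibrated two-ORN sensillum circuit.

    Produced by :func:`calibrate_resting`; ``E_1``/``E_2`` are the somatic
    batteries that put both neurons at ``V_0`` in the unstimulated state.
    ``R_A`` is fixed to 1 by the rescaling convention.
    """

    common: CommonParams
    orn1: ORNSpec
    orn2: ORNSpec
    E_1: float
    E_2: float
    name: str = ""
    resting: RestingClosedForm | None = field(default=None, compare=False)
    R_A: float = 1.0

    @property
    def R_in1(self) -> float:
        return input_resistance(self.orn1.A_s, self.common.rho_s)

    @property
    def R_in2(self) -> float:
        return input_resistance(self.orn2.A_s, self.common.rho_s)

    def R_d(self, which: int, g: float = 0.0) -> float:
        orn = self.orn1 if which == 1 else self.orn2
        if orn.A_d is None:
            raise ParameterError(f"{orn.label}: dendrite area is unset")
        return dendritic_resistance(orn.A_d, self.common.rho_d0, g)

    def total_resistances(self, stim: StimulusState) -> tuple[float, float]:
        """Total branch resistances ``R_i = R_in,i + R_d,i(g_i)``."""
        return (self.R_in1 + self.R_d(1, stim.g1),
                self.R_in2 + self.R_d(2, stim.g2))

    def gain_from_dilution(self, which: int, x) -> float:
        """Conductance gain of ORN ``which`` at log10 dilution ``x``."""
        orn = self.orn1 if which == 1 else self.orn2
        return conductance_gain(activation_fraction(x, orn.k_od, self.common.n),
                                self.common.g_max)

    def with_shared_k_od(self, k_od: float) -> "SensillumModel":
        """Copy with both neurons given the same odorant sensitivity.

        Calibration is unaffected: the batteries depend only on morphometry.
        """
        return replace(self,
                       orn1=replace(self.orn1, k_od=k_od),
                       orn2=replace(self.orn2, k_od=k_od))


def _solve_closed(E_A, E_1, E_2, R_1, R_2):
    """Closed-form branch currents and node voltage (vectorizes over R_1/R_2).

    The two neuronal branches form a Thevenin equivalent with battery
    ``E_T = (E_1*R_2 + E_2*R_1)/(R_1+R_2)`` and resistance
    ``R_T = R_1*R_2/(R_1+R_2)`` in series with the auxiliary branch (R_A=1).
    """
    Rsum = R_1 + R_2
    E_T = (E_1 * R_2 + E_2 * R_1) / Rsum
    R_T = R_1 * R_2 / Rsum
    I_A = (E_T - E_A) / (R_T + 1.0)
    I_1 = (E_2 - E_1) / Rsum - I_A * R_2 / Rsum
    I_2 = (E_1 - E_2) / Rsum - I_A * R_1 / Rsum
    V_A = E_A + I_A
    return V_A, I_A, I_1, I_2, E_T, R_T


def _solve_direct(E_A, E_1, E_2, R_1, R_2):
    """Assemble and solve the four Kirchhoff equations for (V_A, I_A, I_1, I_2)."""
    A = np.array([[1.0, -1.0, 0.0, 0.0],
                  [1.0, 0.0, -R_1, 0.0],
                  [1.0, 0.0, 0.0, -R_2],
                  [0.0, 1.0, 1.0, 1.0]])
    b = np.array([E_A, E_1, E_2, 0.0])
    try:
        V_A, I_A, I_1, I_2 = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate R=0
        raise ModelError(f"singular circuit system: {exc}") from exc
    return V_A, I_A, I_1, I_2


def solve_circuit(model: SensillumModel, stim: StimulusState,
                  method: Literal["closed_form", "direct"] = "closed_form") -> CircuitSolution:
    """Solve the sensillum circuit for one stimulus state.

    ``method="closed_form"`` uses the Thevenin expressions; ``"direct"``
    assembles and solves the 4x4 linear system.  The two agree to better
    than 1e-9 relative and either may be used as a cross-check on the other.
    """
    R_1, R_2 = model.total_resistances(stim)
    if method == "closed_form":
        V_A, I_A, I_1, I_2, _, _ = _solve_closed(model.common.E_A, model.E_1, model.E_2, R_1, R_2)
    elif method == "direct":
        V_A, I_A, I_1, I_2 = _solve_direct(model.common.E_A, model.E_1, model.E_2, R_1, R_2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CircuitSolution(
        V_A=float(V_A),
        V_m1=float(model.E_1 + model.R_in1 * I_1),
        V_m2=float(model.E_2 + model.R_in2 * I_2),
        I_A=float(I_A), I_1=float(I_1), I_2=float(I_2),
        R_1=R_1, R_2=R_2,
        R_in1=model.R_in1, R_in2=model.R_in2,
        R_d1=R_1 - model.R_in1, R_d2=R_2 - model.R_in2,
    )


# ---------------------------------------------------------------------------
# Resting-state calibration
# ---------------------------------------------------------------------------

_CONSISTENCY_TOL_MV = 1e-6


def _resting_closed_form(common: CommonParams, R_in1, R_in2, R_1, R_2) -> RestingClosedForm:
    den = R_1 * R_2 + R_1 + R_2
    alpha1 = (1.0 + R_2 / 2.0) / den
    beta1 = R_2 / den
    alpha2 = (1.0 + R_1 / 2.0) / den
    beta2 = R_1 / den
    xi_den = 1.0 - R_in1 * alpha1 - R_in2 * alpha2
    if xi_den == 0:
        raise CalibrationError("calibration infeasible: xi0 denominator is zero")
    xi0 = (R_in1 * beta1 - R_in2 * beta2) / xi_den
    th_den = 1.0 - 0.5 * (R_in1 * (xi0 * alpha1 + beta1) + R_in2 * (-xi0 * alpha2 + beta2))
    if th_den <= 0:
        raise CalibrationError("calibration infeasible: Theta0 denominator <= 0")
    Theta0 = 1.0 / th_den
    drive = common.E_A - common.V_0
    E_1 = common.E_A - drive * Theta0 * (1.0 + xi0 / 2.0)
    E_2 = common.E_A - drive * Theta0 * (1.0 - xi0 / 2.0)
    E_T = (E_1 * R_2 + E_2 * R_1) / (R_1 + R_2)
    R_T = R_1 * R_2 / (R_1 + R_2)
    return RestingClosedForm(xi0=xi0, Theta0=Theta0, alpha1=alpha1, alpha2=alpha2,
                             beta1=beta1, beta2=beta2, E_T=E_T, R_T=R_T), E_1, E_2


def resting_currents_closed_form(common: CommonParams, rest: RestingClosedForm):
    """Closed-form resting branch currents from the calibration intermediates."""
    drive = common.E_A - common.V_0
    I_A = -drive * rest.Theta0 * (rest.xi0 * (rest.alpha1 - rest.alpha2)
                                  + rest.beta1 + rest.beta2)
    I_1 = drive * rest.Theta0 * (rest.xi0 * rest.alpha1 + rest.beta1)
    I_2 = drive * rest.Theta0 * (-rest.xi0 * rest.alpha2 + rest.beta2)
    return I_A, I_1, I_2


def calibrate_resting(common: CommonParams, orn1: ORNSpec, orn2: ORNSpec,
                      name: str = "") -> SensillumModel:
    """Choose somatic batteries so both neurons rest at ``V_0``.

    Canonically solves the six-equation linear system (four Kirchhoff
    equations plus ``V_m1 = V_m2 = V_0``) for ``(V_A, I_A, I_1, I_2, E_1,
    E_2)`` at zero activation, then cross-checks the closed-form expressions
    for the batteries and resting currents; any disagreement beyond 1e-6 mV
    is raised as an internal :class:`CalibrationError`.
    """
    if orn1.A_d is None or orn2.A_d is None:
        raise ParameterError("calibration requires both dendrite areas to be set")
    R_in1 = input_resistance(orn1.A_s, common.rho_s)
    R_in2 = input_resistance(orn2.A_s, common.rho_s)
    R_1 = R_in1 + dendritic_resistance(orn1.A_d, common.rho_d0, 0.0)
    R_2 = R_in2 + dendritic_resistance(orn2.A_d, common.rho_d0, 0.0)

    # direct constrained solve: unknowns (V_A, I_A, I_1, I_2, E_1, E_2)
    A = np.array([
        [1.0, -1.0, 0.0, 0.0, 0.0, 0.0],     # V_A - I_A*R_A = E_A
        [1.0, 0.0, -R_1, 0.0, -1.0, 0.0],    # V_A - I_1*R_1 - E_1 = 0
        [1.0, 0.0, 0.0, -R_2, 0.0, -1.0],    # V_A - I_2*R_2 - E_2 = 0
        [0.0, 1.0, 1.0, 1.0, 0.0, 0.0],      # current conservation
        [0.0, 0.0, R_in1, 0.0, 1.0, 0.0],    # E_1 + R_in1*I_1 = V_0
        [0.0, 0.0, 0.0, R_in2, 0.0, 1.0],    # E_2 + R_in2*I_2 = V_0
    ])
    b = np.array([common.E_A, 0.0, 0.0, 0.0, common.V_0, common.V_0])
    try:
        _, I_A, I_1, I_2, E_1, E_2 = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise CalibrationError(f"calibration system singular: {exc}") from exc

    rest, E_1_cf, E_2_cf = _resting_closed_form(common, R_in1, R_in2, R_1, R_2)
    if abs(E_1_cf - E_1) > _CONSISTENCY_TOL_MV or abs(E_2_cf - E_2) > _CONSISTENCY_TOL_MV:
        raise CalibrationError(
            "internal inconsistency: closed-form batteries deviate from the "
            f"constrained solve by ({E_1_cf - E_1:.3g}, {E_2_cf - E_2:.3g}) mV")
    I_A_cf, I_1_cf, I_2_cf = resting_currents_closed_form(common, rest)
    scale = max(abs(I_A), abs(I_1), abs(I_2), 1e-30)
    if max(abs(I_A_cf - I_A), abs(I_1_cf - I_1), abs(I_2_cf - I_2)) > 1e-9 * scale:
        raise CalibrationError("internal inconsistency: closed-form resting currents "
                               "deviate from the constrained solve")

    return SensillumModel(common=common, orn1=orn1, orn2=orn2,
                          E_1=float(E_1), E_2=float(E_2), name=name, resting=rest)


# ---------------------------------------------------------------------------
# Ephaptic relations and the spike/LFP-ratio constraint
# ---------------------------------------------------------------------------

def ephaptic_delta_vm(delta_VA: float, model: SensillumModel,
                      stimulated: int, neighbor_g: float = 0.0) -> tuple[float, float]:
    """Membrane-potential changes produced by a field change ``delta_VA``.

    Valid while the *neighbor's* resistance is unchanged (its gain held at
    ``neighbor_g``).  For ORN1 stimulated:
    ``dVm1 = -dVA * R_in1 * (1 + 1/R_2)`` and ``dVm2 = dVA * R_in2 / R_2``;
    symmetrically for ORN2.  Returns ``(dVm_stimulated, dVm_neighbor)``.
    """
    if stimulated not in (1, 2):
        raise ValueError(f"stimulated must be 1 or 2, got {stimulated}")
    if stimulated == 1:
        R_nb = model.R_in2 + model.R_d(2, neighbor_g)
        dvm_stim = -delta_VA * model.R_in1 * (1.0 + 1.0 / R_nb)
        dvm_nb = delta_VA * model.R_in2 / R_nb
    else:
        R_nb = model.R_in1 + model.R_d(1, neighbor_g)
        dvm_stim = -delta_VA * model.R_in2 * (1.0 + 1.0 / R_nb)
        dvm_nb = delta_VA * model.R_in1 / R_nb
    return dvm_stim, dvm_nb


def spike_lfp_ratio(model: SensillumModel) -> float:
    """Predicted ratio of the "A" to "B" spike-rate-vs-LFP slopes.

    ``r = R_in2*(1 + 1/R_1,0) / (R_in1*(1 + 1/R_2,0))`` with basal (zero
    activation) resistances; ``r > 1`` means the larger neuron's membrane
    potential moves less per mV of field change than its neighbor's.
    """
    R_10 = model.R_in1 + model.R_d(1, 0.0)
    R_20 = model.R_in2 + model.R_d(2, 0.0)
    if R_10 <= 0 or R_20 <= 0 or model.R_in1 <= 0:
        raise ParameterError("basal resistances must be positive")
    return (model.R_in2 * (1.0 + 1.0 / R_10)) / (model.R_in1 * (1.0 + 1.0 / R_20))


def dendrite_area_from_ratio(r: float, orn1_spec: ORNSpec, orn2_spec: ORNSpec,
                             common: CommonParams) -> float:
    """Infer ORN1's dendritic surface from the measured spike/LFP slope ratio.

    Inverts the slope-ratio relation: with ``kappa = R_in1/R_in2`` and the
    basal ``R_2,0`` from ORN2's known dendrite,
    ``R_1,0 = R_2,0 / (r*kappa + R_2,0*(r*kappa - 1))`` and
    ``A_d1 = rho_d0 / (R_1,0 - R_in1)``.  Raises
    :class:`NonPhysicalParameterError` when the implied dendritic resistance
    would be non-positive.
    """
    if r <= 0:
        raise ParameterError(f"slope ratio r must be > 0, got {r}")
    if orn2_spec.A_d is None:
        raise ParameterError(f"{orn2_spec.label}: A_d must be set to invert the ratio")
    R_in1 = input_resistance(orn1_spec.A_s, common.rho_s)
    R_in2 = input_resistance(orn2_spec.A_s, common.rho_s)
    R_20 = R_in2 + dendritic_resistance(orn2_spec.A_d, common.rho_d0, 0.0)
    kappa = R_in1 / R_in2
    den = r * kappa + R_20 * (r * kappa - 1.0)
    if den <= 0:
        raise NonPhysicalParameterError(
            f"slope ratio r={r} implies a non-positive basal resistance denominator")
    R_10 = R_20 / den
    if R_10 <= R_in1:
        raise NonPhysicalParameterError(
            f"slope ratio r={r} implies R_1,0 = {R_10:.4g} <= R_in1 = {R_in1:.4g} "
            "(non-positive dendritic resistance)")
    return common.rho_d0 / (R_10 - R_in1)
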