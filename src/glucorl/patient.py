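"""Hovorka compartmental model of glucose-insulin dynamics in type 1 diabetes.

The virtual patient is the five-compartment-group Hovorka model: two serial
subcutaneous insulin depots, plasma insulin, three first-order insulin-action
states (glucose transport, disposal, and suppression of endogenous glucose
production), two serial gut-absorption compartments, a two-pool glucose
kinetics subsystem (accessible + non-accessible), and an interstitial glucose
compartment that plays the role of a CGM signal.

Internally glucose is tracked in mmol; the sensed blood glucose is exposed in
mg/dL via the conversion factor 18.016 (mg/dL per mmol/L).

The integrator is a fixed-step classical Runge-Kutta (RK4) scheme with 1-min
outer steps and 6 inner sub-steps, which makes every trajectory bit-exactly
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "MGDL_PER_MMOLL",
    "MMOL_PER_G_CHO",
    "PatientParameters",
    "PatientState",
    "InvalidStateError",
    "InfeasibleParameterError",
    "derivatives",
    "integrate_minute",
    "measure_bg",
    "find_steady_state",
    "steady_state_at_basal",
    "load_patient",
    "save_patient",
    "default_patient",
]

#: mg/dL of glucose per mmol/L (molar mass of glucose 180.16 g/mol).
MGDL_PER_MMOLL = 18.016

#: mmol of glucose per gram of carbohydrate.
MMOL_PER_G_CHO = 1000.0 / 180.16

#: BG sensor saturation bounds, mg/dL.
BG_SENSOR_MIN = 0.0
BG_SENSOR_MAX = 500.0

_SUBSTEPS_PER_MIN = 6


class InvalidStateError(ValueError):
    """Raised when a patient state contains non-finite values."""


class InfeasibleParameterError(RuntimeError):
    """Raised when no basal rate in the search bracket yields the target BG."""


class IntegrationError(RuntimeError):
    """Raised when the ODE step produces a non-finite state."""


@dataclass(frozen=True)
class PatientParameters:
    """Physiological constants of one virtual patient.

    Defaults are the nominal Hovorka-model values for a 70 kg adult with
    type 1 diabetes. Rates are per minute; volumes per kg body weight.
    """

    body_weight: float = 70.0          # kg
    k12: float = 0.066                 # glucose transfer, non-accessible -> accessible (1/min)
    ka1: float = 0.006                 # activation of transport action (1/min)
    ka2: float = 0.06                  # activation of disposal action (1/min)
    ka3: float = 0.03                  # activation of EGP-suppression action (1/min)
    s_it: float = 51.2e-4              # sensitivity of transport (per mU/L)
    s_id: float = 8.2e-4               # sensitivity of disposal (per mU/L)
    s_ie: float = 520e-4               # sensitivity of EGP suppression (L/mU)
    ke: float = 0.138                  # plasma insulin elimination (1/min)
    v_i: float = 0.12                  # insulin distribution volume (L/kg)
    v_g: float = 0.16                  # glucose distribution volume (L/kg)
    ag: float = 0.8                    # carbohydrate bioavailability (fraction)
    t_max_g: float = 40.0              # gut absorption time-to-maximum (min)
    t_max_i: float = 55.0              # s.c. insulin absorption time constant (min)
    egp_0: float = 0.0161              # endogenous glucose production at zero insulin (mmol/kg/min)
    f_01: float = 0.0097               # non-insulin-dependent glucose flux (mmol/kg/min)
    k_int: float = 0.073               # plasma-interstitium equilibration (1/min)
    sensor_compartment: str = "interstitial"  # "interstitial" (CGM analogue) or "plasma"
    icr_g_per_u: float | None = None   # insulin-to-carb ratio; None = not yet calibrated

    def __post_init__(self) -> None:
        rate_like = (
            "body_weight k12 ka1 ka2 ka3 s_it s_id s_ie ke v_i v_g "
            "t_max_g t_max_i egp_0 f_01 k_int"
        ).split()
        for name in rate_like:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if not 0 < self.ag <= 1:
            raise ValueError("carb bioavailability must lie in (0, 1]")
        if self.sensor_compartment not in ("interstitial", "plasma"):
            raise ValueError("sensor_compartment must be 'interstitial' or 'plasma'")

    # flat tuple used by the float-only fast path of the integrator
    def _packed(self) -> tuple:
        bw = self.body_weight
        return (
            self.k12, self.ka1, self.ka2, self.ka3,
            self.s_it, self.s_id, self.s_ie,
            self.ke, self.v_i * bw, self.v_g * bw,
            self.ag, self.t_max_g, self.t_max_i,
            self.egp_0 * bw, self.f_01 * bw, self.k_int,
        )


_STATE_FIELDS = (
    "sc_insulin_1", "sc_insulin_2", "plasma_insulin",
    "x_transport", "x_disposal", "x_egp",
    "gut_carbs_1", "gut_carbs_2",
    "glucose_accessible", "glucose_nonaccessible", "interstitial_glucose",
)


@dataclass(frozen=True)
class PatientState:
    """Compartment quantities of the virtual patient at one instant.

    Units: insulin depots in mU, plasma insulin in mU/L, action states
    dimensionless (1/min for transport/disposal), gut and plasma glucose in
    mmol, interstitial glucose in mmol/L.
    """

    sc_insulin_1: float
    sc_insulin_2: float
    plasma_insulin: float
    x_transport: float
    x_disposal: float
    x_egp: float
    gut_carbs_1: float
    gut_carbs_2: float
    glucose_accessible: float
    glucose_nonaccessible: float
    interstitial_glucose: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, values) -> "PatientState":
        return cls(*(float(v) for v in values))

    def validate(self) -> None:
        for f in _STATE_FIELDS:
            if not math.isfinite(getattr(self, f)):
                raise InvalidStateError(f"non-finite state field {f!r}")


def _deriv(y: tuple, p: tuple, insulin_mu_min: float, carbs_mmol_min: float) -> tuple:
    """Time derivatives of the 11 compartments (float-only hot path)."""
    (k12, ka1, ka2, ka3, s_it, s_id, s_ie,
     ke, vi_l, vg_l, ag, tmaxg, tmaxi, egp_b, f01_b, kint) = p
    s1, s2, i_p, x1, x2, x3, d1, d2, q1, q2, c = y

    d_s1 = insulin_mu_min - s1 / tmaxi
    d_s2 = (s1 - s2) / tmaxi
    d_ip = s2 / (tmaxi * vi_l) - ke * i_p

    d_x1 = ka1 * (s_it * i_p - x1)
    d_x2 = ka2 * (s_id * i_p - x2)
    d_x3 = ka3 * (s_ie * i_p - x3)

    d_d1 = ag * carbs_mmol_min - d1 / tmaxg
    d_d2 = (d1 - d2) / tmaxg
    u_g = d2 / tmaxg

    g = q1 / vg_l
    f01_c = f01_b if g >= 4.5 else f01_b * g / 4.5
    f_r = 0.003 * (g - 9.0) * vg_l if g >= 9.0 else 0.0
    d_q1 = -f01_c - f_r - x1 * q1 + k12 * q2 + u_g + egp_b * (1.0 - x3)
    d_q2 = x1 * q1 - (k12 + x2) * q2

    d_c = kint * (g - c)
    return (d_s1, d_s2, d_ip, d_x1, d_x2, d_x3, d_d1, d_d2, d_q1, d_q2, d_c)


def derivatives(
    state: PatientState,
    params: PatientParameters,
    insulin_infusion: float,
    carb_ingestion: float,
) -> PatientState:
    """Instantaneous time derivatives of every compartment.

    Parameters
    ----------
    insulin_infusion : float
        Subcutaneous insulin delivery rate, mU/min (basal + any bolus).
    carb_ingestion : float
        Carbohydrate ingestion rate, g/min.

    Returns
    -------
    PatientState
        Each field holds the corresponding time derivative (per minute).
    """
    if insulin_infusion < 0 or carb_ingestion < 0:
        raise ValueError("insulin and carbohydrate inputs must be non-negative")
    state.validate()
    rates = _deriv(
        tuple(state.as_array()), params._packed(),
        float(insulin_infusion), float(carb_ingestion) * MMOL_PER_G_CHO,
    )
    return PatientState(*rates)


def _rk4_minute(y: tuple, p: tuple, u: float, d_mmol: float, n_sub: int) -> tuple:
    h = 1.0 / n_sub
    for _ in range(n_sub):
        k1 = _deriv(y, p, u, d_mmol)
        y2 = tuple(a + 0.5 * h * b for a, b in zip(y, k1))
        k2 = _deriv(y2, p, u, d_mmol)
        y3 = tuple(a + 0.5 * h * b for a, b in zip(y, k2))
        k3 = _deriv(y3, p, u, d_mmol)
        y4 = tuple(a + h * b for a, b in zip(y, k3))
        k4 = _deriv(y4, p, u, d_mmol)
        y = tuple(
            a + (h / 6.0) * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
        )
    return y


def integrate_minute(
    state: PatientState,
    params: PatientParameters,
    insulin_infusion: float,
    carb_ingestion: float,
    n_substeps: int = _SUBSTEPS_PER_MIN,
) -> PatientState:
    """Advance the patient exactly one simulated minute.

    Inputs are held constant over the minute. Deterministic: identical
    arguments give bit-identical results. Compartments are clipped at zero
    after the step as a guard against numerical undershoot under extreme
    insulin.
    """
    if insulin_infusion < 0 or carb_ingestion < 0:
        raise ValueError("insulin and carbohydrate inputs must be non-negative")
    state.validate()
    y = _rk4_minute(
        tuple(state.as_array()), params._packed(),
        float(insulin_infusion), float(carb_ingestion) * MMOL_PER_G_CHO,
        n_substeps,
    )
    if not all(math.isfinite(v) for v in y):
        raise IntegrationError(
            f"non-finite state after 1-min RK4 step (u={insulin_infusion}, "
            f"carbs={carb_ingestion})"
        )
    return PatientState(*(v if v > 0.0 else 0.0 for v in y))


def measure_bg(state: PatientState, params: PatientParameters) -> float:
    """Sensed blood glucose in mg/dL, clipped to the sensor range [0, 500].

    By default the interstitial (CGM-analogue) compartment is read; set
    ``sensor_compartment='plasma'`` on the parameters to read plasma glucose.
    """
    if params.sensor_compartment == "plasma":
        conc = state.glucose_accessible / (params.v_g * params.body_weight)
    else:
        conc = state.interstitial_glucose
    return min(max(conc * MGDL_PER_MMOLL, BG_SENSOR_MIN), BG_SENSOR_MAX)


def steady_state_at_basal(params: PatientParameters, basal: float) -> PatientState:
    """Closed-form-plus-root equilibrium state under a constant basal rate."""
    p = params._packed()
    (k12, ka1, ka2, ka3, s_it, s_id, s_ie,
     ke, vi_l, vg_l, ag, tmaxg, tmaxi, egp_b, f01_b, kint) = p
    s1 = s2 = basal * tmaxi
    i_p = basal / (ke * vi_l)
    x1, x2, x3 = s_it * i_p, s_id * i_p, s_ie * i_p

    def glucose_balance(g: float) -> float:
        q1 = g * vg_l
        f01_c = f01_b if g >= 4.5 else f01_b * g / 4.5
        f_r = 0.003 * (g - 9.0) * vg_l if g >= 9.0 else 0.0
        # net insulin-dependent utilisation once Q2 is at its own equilibrium
        util = x1 * q1 * x2 / (k12 + x2) if (k12 + x2) > 0 else 0.0
        return egp_b * max(1.0 - x3, 0.0) - f01_c - f_r - util

    # with EGP fully suppressed (heavy insulin) there is no positive root:
    # the fasting equilibrium collapses to zero glucose
    if glucose_balance(1e-9) <= 0.0:
        g_ss = 0.0
    else:
        g_ss = brentq(glucose_balance, 1e-9, 50.0, xtol=1e-12, rtol=1e-14)
    q1 = g_ss * vg_l
    q2 = x1 * q1 / (k12 + x2)
    return PatientState(s1, s2, i_p, x1, x2, x3, 0.0, 0.0, q1, q2, g_ss)


def find_steady_state(
    params: PatientParameters,
    target_bg: float,
    basal_bracket: tuple[float, float] = (0.0, 50.0),
) -> tuple[PatientState, float]:
    """Basal rate and equilibrium state that hold BG at ``target_bg``.

    The optimal basal rate b* is the constant subcutaneous infusion for which
    the model has a zero-derivative equilibrium whose sensed BG equals the
    target; it is found by root-finding on the fasting steady-state glucose.

    Parameters
    ----------
    target_bg : float
        Reference BG in mg/dL; must lie in the normoglycemic interior (70, 180).

    Returns
    -------
    (PatientState, float)
        The equilibrium compartment state and the basal rate b* in mU/min.
    """
    if not 70.0 < target_bg < 180.0:
        raise ValueError("target BG must lie strictly inside (70, 180) mg/dL")
    target_mmol = target_bg / MGDL_PER_MMOLL

    def residual(u: float) -> float:
        st = steady_state_at_basal(params, u)
        return st.glucose_accessible / (params.v_g * params.body_weight) - target_mmol

    lo, hi = basal_bracket
    try:
        bstar = brentq(residual, lo + 1e-9, hi, xtol=1e-10, rtol=1e-12)
    except ValueError as exc:
        raise InfeasibleParameterError(
            f"no basal rate in [{lo}, {hi}] mU/min reaches {target_bg} mg/dL"
        ) from exc
    return steady_state_at_basal(params, bstar), bstar


# ---------------------------------------------------------------------------
# patient config I/O

_PARAM_KEYS = [f.name for f in fields(PatientParameters)]


def save_patient(params: PatientParameters, path) -> None:
    """Write a patient parameter set as a flat YAML mapping."""
    data = {k: getattr(params, k) for k in _PARAM_KEYS}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_patient(path) -> PatientParameters:
    """Read a patient parameter set from a flat YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    unknown = set(data) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown patient parameter keys: {sorted(unknown)}")
    return PatientParameters(**data)


def default_patient() -> PatientParameters:
    """The packaged 70 kg virtual patient (nominal parameters + frozen ICR)."""
    ref = resources.files("glucorl").joinpath("data/patient_70kg.yaml")
    data = yaml.safe_load(ref.read_text())
    return PatientParameters(**data)
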