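"""Series R-L-C circuit models of coordination modules.

A motif is abstracted as a series resistor-inductor-capacitor circuit
driven by a source, with the output (transmitted energy) measured across
the capacitor.  Each edge contributes one unit inductor in parallel, so a
motif with m edges has effective inductance L_eff = L_unit / m: denser
modules have lower inductance and damp activity oscillations more
strongly.  The single-stage transfer function is the textbook second-order
low-pass

    H(s) = wn^2 / (s^2 + 2 zeta wn s + wn^2),
    wn = 1 / sqrt(L_eff C),   zeta = (R / 2) sqrt(C / L_eff),

with unit DC gain.  Calibrating R so that a chosen edge count m_critical
is critically damped gives zeta(m) = sqrt(m / m_critical): sparser motifs
ring (sub-critical, oscillatory overshoot), denser ones over-damp and slow
the transient.  Signal transmission between modules is modeled by
cascading identical stages (transfer functions multiply); "signal loss" in
over-critical motifs is transient attenuation — the DC gain of every
cascade remains exactly 1.

All quantities are dimensionless (L_unit = C = 1 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "RlcModel",
    "TransferFunction",
    "StepResponse",
    "effective_inductance",
    "single_stage_tf",
    "cascade",
    "step_response",
    "calibrate",
    "rlc_for_edges",
    "transmission_analysis",
]

_ZETA_TOL = 1e-6
DEFAULT_M_CRITICAL = 10


def effective_inductance(m: int, L_unit: float = 1.0) -> float:
    """Parallel combination of one unit inductor per edge: L_eff = L_unit/m."""
    if m < 1:
        raise ValueError("edge count must be >= 1")
    if L_unit <= 0:
        raise ValueError("L_unit must be > 0")
    return L_unit / m


@dataclass(frozen=True)
class RlcModel:
    """Series R-L-C parameterization of an m-edge module."""

    R: float
    C: float
    L_unit: float
    m: int

    def __post_init__(self):
        if self.R <= 0 or self.C <= 0 or self.L_unit <= 0:
            raise ValueError("R, C and L_unit must be > 0")
        if self.m < 1:
            raise ValueError("edge count must be >= 1")

    @property
    def L_eff(self) -> float:
        return effective_inductance(self.m, self.L_unit)

    @property
    def omega_n(self) -> float:
        return 1.0 / math.sqrt(self.L_eff * self.C)

    @property
    def zeta(self) -> float:
        return (self.R / 2.0) * math.sqrt(self.C / self.L_eff)

    @property
    def damping_class(self) -> str:
        z = self.zeta
        if abs(z - 1.0) <= _ZETA_TOL:
            return "critical"
        return "under" if z < 1.0 else "over"


@dataclass(frozen=True)
class TransferFunction:
    """Rational transfer function in the Laplace variable s."""

    num: tuple
    den: tuple

    def __post_init__(self):
        num = tuple(float(c) for c in np.trim_zeros(np.atleast_1d(self.num), "f"))
        den = tuple(float(c) for c in np.trim_zeros(np.atleast_1d(self.den), "f"))
        if not den:
            raise ValueError("zero denominator")
        if len(num) > len(den):
            raise ValueError("transfer function must be proper (deg num <= deg den)")
        object.__setattr__(self, "num", num)
        object.__setattr__(self, "den", den)

    @property
    def dc_gain(self) -> float:
        if self.den[-1] == 0:
            return math.inf
        return (self.num[-1] if self.num else 0.0) / self.den[-1]

    @property
    def poles(self) -> np.ndarray:
        return np.roots(self.den)

    @property
    def is_stable(self) -> bool:
        return bool(np.all(self.poles.real < 0))


def single_stage_tf(model: RlcModel) -> TransferFunction:
    """Voltage divider across C of the series R-L-C circuit:
    H(s) = wn^2 / (s^2 + 2 zeta wn s + wn^2)."""
    wn = model.omega_n
    z = model.zeta
    return TransferFunction(num=(wn**2,), den=(1.0, 2.0 * z * wn, wn**2))


def cascade(tfs) -> TransferFunction:
    """Product of transfer functions (stage-wise signal transmission)."""
    tfs = list(tfs)
    if not tfs:
        raise ValueError("cascade of zero stages")
    num = np.array([1.0])
    den = np.array([1.0])
    for tf in tfs:
        num = np.polymul(num, np.asarray(tf.num))
        den = np.polymul(den, np.asarray(tf.den))
    return TransferFunction(num=tuple(num), den=tuple(den))


@dataclass
class StepResponse:
    t: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    final_value: float
    overshoot: float           # fraction of the final value, clipped at 0
    settling_time: float       # last exit from the +/-2% band
    oscillatory: bool

    @property
    def rise_time_10_90(self) -> float:
        fv = self.final_value
        above10 = np.nonzero(self.y >= 0.1 * fv)[0]
        above90 = np.nonzero(self.y >= 0.9 * fv)[0]
        if len(above10) == 0 or len(above90) == 0:
            return float("nan")
        return float(self.t[above90[0]] - self.t[above10[0]])


def _default_t_end(tf: TransferFunction) -> float:
    slowest = min(-tf.poles.real)
    return 12.0 / slowest


def step_response(
    tf: TransferFunction,
    t_end: float | None = None,
    n_points: int = 2000,
) -> StepResponse:
    """Unit-step response by simulation of the state-space realization.

    The input is piecewise constant, so the zero-order-hold discretization
    used by the simulator is exact at the grid points.  Unstable transfer
    functions are rejected.
    """
    if not tf.is_stable:
        raise ValueError("unstable transfer function (pole with Re >= 0)")
    if t_end is None:
        t_end = _default_t_end(tf)
    t = np.linspace(0.0, t_end, n_points)
    lti = sps.lti(list(tf.num), list(tf.den))
    _, y, _ = sps.lsim(lti, U=np.ones_like(t), T=t)
    y = np.asarray(y)
    fv = tf.dc_gain
    overshoot = max(0.0, float((y.max() - fv) / fv))
    band = 0.02 * abs(fv)
    outside = np.nonzero(np.abs(y - fv) > band)[0]
    settling = float(t[outside[-1] + 1]) if len(outside) and outside[-1] + 1 < len(t) else 0.0
    # oscillatory if the response crosses its final value more than once
    crossings = int(np.sum(np.diff(np.sign(y - fv)) != 0))
    return StepResponse(
        t=t, y=y, final_value=float(fv), overshoot=overshoot,
        settling_time=settling, oscillatory=crossings > 1 or overshoot > 1e-9,
    )


def calibrate(
    m_critical: int = DEFAULT_M_CRITICAL,
    C: float = 1.0,
    L_unit: float = 1.0,
) -> float:
    """Resistance giving critical damping at ``m_critical`` edges:
    R = 2 sqrt(L_unit / (m_critical C)); then zeta(m) = sqrt(m/m_critical)."""
    if m_critical < 1:
        raise ValueError("m_critical must be >= 1")
    return 2.0 * math.sqrt(L_unit / (m_critical * C))


def rlc_for_edges(
    m: int,
    m_critical: int = DEFAULT_M_CRITICAL,
    C: float = 1.0,
    L_unit: float = 1.0,
) -> RlcModel:
    """Calibrated model for an m-edge motif (R fixed by ``calibrate``)."""
    return RlcModel(R=calibrate(m_critical, C, L_unit), C=C, L_unit=L_unit, m=m)


_REGIME_BY_CLASS = {"under": "sub-critical", "critical": "critical", "over": "over-critical"}


def transmission_analysis(
    m: int,
    levels: int = 2,
    m_critical: int = DEFAULT_M_CRITICAL,
    C: float = 1.0,
    L_unit: float = 1.0,
    t_end: float | None = None,
    n_points: int = 2000,
) -> dict:
    """Signal transmission through ``levels`` cascaded identical calibrated
    modules of edge count ``m``.

    Reports the per-level step responses (signal arriving after each
    module), a regime label (sub-critical: oscillatory overshoot;
    critical: fastest non-oscillatory; over-critical: slower rise with an
    attenuated transient), and the transient attenuation of the terminal
    response relative to the critical case, measured as the ratio of peak
    signal slew rates.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    model = rlc_for_edges(m, m_critical, C, L_unit)
    stage = single_stage_tf(model)
    crit_stage = single_stage_tf(rlc_for_edges(m_critical, m_critical, C, L_unit))
    if t_end is None:
        # shared horizon so per-level curves are comparable
        t_end = max(
            _default_t_end(cascade([stage] * levels)),
            _default_t_end(cascade([crit_stage] * levels)),
        )
    responses = []
    for level in range(1, levels + 1):
        tf = cascade([stage] * level)
        responses.append(step_response(tf, t_end=t_end, n_points=n_points))
    terminal = responses[-1]
    crit_resp = step_response(cascade([crit_stage] * levels), t_end=t_end, n_points=n_points)

    def peak_slew(resp: StepResponse) -> float:
        return float(np.max(np.gradient(resp.y, resp.t)))

    return {
        "m": m,
        "levels": levels,
        "zeta": model.zeta,
        "regime": _REGIME_BY_CLASS[model.damping_class],
        "responses": responses,
        "terminal_overshoot": terminal.overshoot,
        "terminal_rise_time": terminal.rise_time_10_90,
        "attenuation_vs_critical": peak_slew(terminal) / peak_slew(crit_resp),
    }
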