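"""Parametric ("invented") pulmonary arterial flow profile.

When instantaneous PA flow is not measured — the usual clinical
situation — stroke work is computed against a parametric flow waveform:
a damped half-sine during ejection, a brief negative lobe representing
pulmonary-valve regurgitation (0.04 s total), and zero flow through the
rest of diastole.  The amplitude factor ``A`` carries no physical units
of its own: it is calibrated per subject so the whole-cycle mean of the
profile equals that subject's cardiac output (ml/min).

Piecewise definition, with t in seconds from ejection onset::

    Q(t) = A * SV * exp(-3 t) * sin(pi t / t_es)        0 < t < t_es + 0.02
    Q(t) = Q(t_es + 0.02) * (1 - (t - t_es - 0.02)/0.02)
                                                t_es + 0.02 < t < t_es + 0.04
    Q(t) = 0                                    t_es + 0.04 < t < t_ed

The sine continues past t_es, so the first branch goes negative on
(t_es, t_es + 0.02) and the linear ramp of the second branch returns it
continuously to zero at t_es + 0.04 — the stated 0.04 s regurgitation
window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateProfileError, InvalidArgumentError

__all__ = ["InventedFlowParams", "invented_flow", "calibrate_amplitude"]

#: exponential decay rate of the ejection lobe (1/s)
DECAY_RATE = 3.0
#: assumed duration of pulmonary valve regurgitation (s)
T_REGURGITATION = 0.04


@dataclass(frozen=True)
class InventedFlowParams:
    """Parameters of the invented flow profile.

    Attributes
    ----------
    A:
        Amplitude proportionality factor (dimensionless); calibrated so
        the cycle-mean flow equals cardiac output.
    SV:
        Stroke volume (ml).
    t_es:
        End of RV ejection (s from ejection onset).
    t_ed:
        End of diastole, i.e. cycle length (s).
    t_reg:
        Regurgitation duration (s), fixed at 0.04 by the model.
    decay:
        Exponential decay rate (1/s), fixed at 3 by the model.
    """

    A: float
    SV: float
    t_es: float
    t_ed: float
    t_reg: float = T_REGURGITATION
    decay: float = DECAY_RATE

    def __post_init__(self) -> None:
        if not (0 < self.t_es < self.t_ed):
            raise InvalidArgumentError("require 0 < t_es < t_ed")
        if self.t_es + self.t_reg > self.t_ed:
            raise InvalidArgumentError("regurgitation window exceeds cycle")
        if self.SV <= 0:
            raise InvalidArgumentError("SV must be positive")
        if self.A <= 0:
            raise InvalidArgumentError("A must be positive")


def invented_flow(t: np.ndarray | float, p: InventedFlowParams) -> np.ndarray | float:
    """Evaluate the invented flow profile (ml/min) at time(s) ``t``.

    ``t`` is measured from ejection onset and must lie in [0, t_ed].
    Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > p.t_ed):
        raise InvalidArgumentError("t outside [0, t_ed]")
    half = p.t_reg / 2.0  # 0.02 s: end of the sine branch
    t_knee = p.t_es + half

    sine = p.A * p.SV * np.exp(-p.decay * t_arr) * np.sin(np.pi * t_arr / p.t_es)
    q_knee = p.A * p.SV * np.exp(-p.decay * t_knee) * np.sin(np.pi * t_knee / p.t_es)
    ramp = q_knee * (1.0 - (t_arr - t_knee) / half)

    out = np.where(
        t_arr < t_knee,
        sine,
        np.where(t_arr < p.t_es + p.t_reg, ramp, 0.0),
    )
    return float(out) if np.isscalar(t) else out


def _unit_profile_mean(p: InventedFlowParams, grid_hz: float) -> float:
    """Whole-cycle mean of the profile with A = 1, by trapezoidal
    quadrature on a ``grid_hz`` grid."""
    unit = replace(p, A=1.0)
    n = max(3, int(round(p.t_ed * grid_hz)) + 1)
    t = np.linspace(0.0, p.t_ed, n)
    q = invented_flow(t, unit)
    return float(np.trapezoid(q, t) / p.t_ed)


def calibrate_amplitude(
    p: InventedFlowParams, CO: float, *, grid_hz: float = 1000.0
) -> InventedFlowParams:
    """Set ``A`` so the cycle-mean of the profile equals cardiac output.

    The profile is linear in A, so ``A = CO / mean(profile | A = 1)``
    with the mean taken over the full cycle [0, t_ed] (cardiac output is
    a per-cycle mean, so the zero-flow diastolic interval counts).

    Parameters
    ----------
    p:
        Profile parameters; the incoming ``A`` is ignored.
    CO:
        Target cardiac output (ml/min), positive.
    grid_hz:
        Quadrature grid density for the unit-profile mean (default
        1 kHz).
    """
    if CO <= 0:
        raise InvalidArgumentError("CO must be positive")
    m = _unit_profile_mean(p, grid_hz)
    if m <= 0:
        raise DegenerateProfileError(
            "unit-amplitude profile has non-positive mean "
            "(t_es too short relative to the regurgitation window)"
        )
    return replace(p, A=CO / m)
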