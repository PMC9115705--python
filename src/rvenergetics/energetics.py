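"""Right-ventricular energetic model: power output, oxygen coupling,
efficiency.

The model treats RV total power output (TPO, J/min) as the sum of
isovolumic power — the cost of raising ventricular contents to ejection
pressure — and stroke power, and couples TPO linearly to myocardial
oxygen consumption at the theoretical efficiency of oxidative
phosphorylation, 20.2 J per ml O2.  Two variants are implemented:

* the original left-ventricular formulation transplanted to the RV
  ("elbeery"): isovolumic power HR·mRV_EP·(RV_EDV − V0)·1.33e-4, stroke
  power from the trapezoidal pressure–flow integral over ejection;
* the adjusted formulation: isovolumic power
  HR·(mRV_EP − RV_EDP)·RV_ESV·1.33e-4 (a lower bound — only the residual
  end-systolic volume is raised, and preload pressure is credited to the
  left ventricle), with closed-form stroke power
  HR·mPAP·SV·1.33e-4 + 0.156·PP, whose second term estimates oscillatory
  (pulsatile) power as proportional to PA pulse pressure.

RV efficiency is useful (non-pulsatile) stroke power, mPAP·CO·1.33e-4,
divided by TPO.

All scalar operations broadcast over numpy arrays, so a whole cohort can
be evaluated in one call by passing array-valued states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    InvalidArgumentError,
    InvalidInputError,
    UndefinedEfficiencyError,
)
from .waveforms import BeatWindow, PressureTrace

__all__ = [
    "HemodynamicState",
    "OxygenState",
    "ModelConstants",
    "PowerBreakdown",
    "DEFAULT_CONSTANTS",
    "total_mechanical_energy",
    "o2_rate_from_power",
    "power_from_o2_rate",
    "oxygen_delivery_rate",
    "isovolumic_power_elbeery",
    "isovolumic_power_adjusted",
    "stroke_power_integrated",
    "stroke_power_adjusted",
    "useful_stroke_power",
    "total_power_output",
    "rv_efficiency",
    "l_per_min_to_ml_per_min",
    "ml_per_min_to_l_per_min",
    "kpa_to_mmhg",
    "mmhg_to_kpa",
]

Variant = Literal["elbeery", "adjusted"]

_REL_TOL = 1e-6  # tolerance for derived-field consistency checks


def _all(x) -> bool:
    return bool(np.all(x))


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants and fixed coefficients of the model.

    k_o2      : 20.2 J per ml O2 — oxidative-phosphorylation efficiency
                with mixed substrates.
    k_hb      : 1.34 ml O2 per g hemoglobin — O2 carrying capacity.
    k_mmhgml  : 1.33e-4 J per mmHg·ml — pressure-volume unit conversion.
    k_osc     : 0.156 J/min per mmHg — oscillatory-power coefficient
                multiplying PA pulse pressure.
    t_reg     : 0.04 s — pulmonary-valve regurgitation duration.
    """

    k_o2: float = 20.2
    k_hb: float = 1.34
    k_mmhgml: float = 1.33e-4
    k_osc: float = 0.156
    t_reg: float = 0.04

    def __post_init__(self) -> None:
        for name in ("k_o2", "k_hb", "k_mmhgml", "k_osc", "t_reg"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class HemodynamicState:
    """One subject's (or one vectorized cohort's) scalar hemodynamics.

    Units: pressures mmHg, volumes ml, HR beats/min, CO ml/min, EF and
    fractions dimensionless.  Derived-field identities (CO = HR·SV,
    EF = SV/RV_EDV, RV_ESV = RV_EDV − SV) are enforced to rounding
    tolerance at construction.  Fields may be numpy arrays of equal
    shape for vectorized cohort evaluation.
    """

    HR: np.ndarray | float
    mPAP: np.ndarray | float
    PP: np.ndarray | float
    SV: np.ndarray | float
    CO: np.ndarray | float
    mRV_EP: np.ndarray | float
    RV_EDP: np.ndarray | float
    RV_EDV: np.ndarray | float
    RV_ESV: np.ndarray | float
    EF: np.ndarray | float
    V0: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        pos = dict(
            HR=self.HR, mPAP=self.mPAP, PP=self.PP, SV=self.SV, CO=self.CO,
            mRV_EP=self.mRV_EP, RV_EDP=self.RV_EDP, RV_EDV=self.RV_EDV,
            RV_ESV=self.RV_ESV, EF=self.EF,
        )
        for name, v in pos.items():
            if not _all(np.asarray(v) > 0):
                raise InvalidArgumentError(f"{name} must be positive")
        if not _all(np.asarray(self.V0) >= 0):
            raise InvalidArgumentError("V0 must be non-negative")
        if not _all(self.mRV_EP > self.RV_EDP):
            raise InvalidArgumentError("mRV_EP must exceed RV_EDP")

        def close(a, b):
            return _all(np.abs(a - b) <= _REL_TOL * np.maximum(np.abs(a), np.abs(b)))

        if not close(self.CO, self.HR * self.SV):
            raise InvalidArgumentError("CO must equal HR × SV")
        if not close(self.EF, self.SV / self.RV_EDV):
            raise InvalidArgumentError("EF must equal SV / RV_EDV")
        if not close(self.RV_ESV, self.RV_EDV - self.SV):
            raise InvalidArgumentError("RV_ESV must equal RV_EDV − SV")

    @classmethod
    def from_measurements(
        cls,
        *,
        HR,
        mPAP,
        PP,
        CO,
        EF,
        mRV_EP,
        RV_EDP,
        V0=0.0,
    ) -> "HemodynamicState":
        """Build a consistent state from the independent measurements,
        deriving SV = CO/HR, RV_EDV = SV/EF, RV_ESV = RV_EDV − SV."""
        SV = np.asarray(CO, dtype=float) / HR
        RV_EDV = SV / EF
        return cls(
            HR=HR, mPAP=mPAP, PP=PP, SV=SV, CO=np.asarray(CO, dtype=float),
            mRV_EP=mRV_EP, RV_EDP=RV_EDP, RV_EDV=RV_EDV,
            RV_ESV=RV_EDV - SV, EF=np.asarray(EF, dtype=float), V0=V0,
        )


@dataclass(frozen=True)
class OxygenState:
    """Oxygen-supply variables of the right coronary circulation.

    Sa    : arterial oxygen saturation (fraction, 0–1]
    OEF   : RV oxygen extraction fraction (0–1]
    Q_RCA : right coronary flow (ml/min)
    Chb   : hemoglobin concentration (g/ml)
    """

    Sa: np.ndarray | float
    OEF: np.ndarray | float
    Q_RCA: np.ndarray | float
    Chb: np.ndarray | float

    def __post_init__(self) -> None:
        if not (_all(np.asarray(self.Sa) > 0) and _all(np.asarray(self.Sa) <= 1)):
            raise InvalidArgumentError("Sa must be in (0, 1]")
        if not (_all(np.asarray(self.OEF) > 0) and _all(np.asarray(self.OEF) <= 1)):
            raise InvalidArgumentError("OEF must be in (0, 1]")
        if not _all(np.asarray(self.Q_RCA) > 0):
            raise InvalidArgumentError("Q_RCA must be positive")
        if not _all(np.asarray(self.Chb) > 0):
            raise InvalidArgumentError("Chb must be positive")


@dataclass(frozen=True)
class PowerBreakdown:
    """Decomposition of total RV power output (all J/min).

    ``total = isovolumic + stroke`` always.  For the adjusted
    closed-form path ``stroke = useful_stroke + pulsatile_stroke``; for
    the integrated path the split is not available and those fields are
    NaN.
    """

    variant: Variant
    isovolumic: np.ndarray | float
    stroke: np.ndarray | float
    total: np.ndarray | float
    useful_stroke: np.ndarray | float = np.nan
    pulsatile_stroke: np.ndarray | float = np.nan


# ---------------------------------------------------------------------------
# oxygen / energy coupling

def total_mechanical_energy(
    o2_per_beat, c: ModelConstants = DEFAULT_CONSTANTS
):
    """Per-beat mechanical energy (J) from per-beat O2 consumption (ml),
    at 20.2 J per ml O2 (anaerobic contribution neglected)."""
    if not _all(np.asarray(o2_per_beat) >= 0):
        raise InvalidArgumentError("O2 consumption must be non-negative")
    return c.k_o2 * o2_per_beat


def o2_rate_from_power(tpo, c: ModelConstants = DEFAULT_CONSTANTS):
    """O2 consumption rate (ml/min) implied by a total power output
    (J/min)."""
    if not _all(np.asarray(tpo) >= 0):
        raise InvalidArgumentError("power must be non-negative")
    return tpo / c.k_o2

def power_from_o2_rate(rate, c: ModelConstants = DEFAULT_CONSTANTS):
    """Inverse of :func:`o2_rate_from_power`."""
    if not _all(np.asarray(rate) >= 0):
        raise InvalidArgumentError("rate must be non-negative")
    return rate * c.k_o2


def oxygen_delivery_rate(ox: OxygenState, c: ModelConstants = DEFAULT_CONSTANTS):
    """Rate of O2 extraction by the RV free wall (ml O2/min):
    1.34 · OEF · Q_RCA · Sa · Chb."""
    return c.k_hb * ox.OEF * ox.Q_RCA * ox.Sa * ox.Chb


# ---------------------------------------------------------------------------
# isovolumic power

def isovolumic_power_elbeery(
    h: HemodynamicState, c: ModelConstants = DEFAULT_CONSTANTS
):
    """Original-model isovolumic power:
    HR · mRV_EP · (RV_EDV − V0) · 1.33e-4 (J/min)."""
    if not _all(h.RV_EDV > h.V0):
        raise InvalidArgumentError("RV_EDV must exceed V0")
    return h.HR * h.mRV_EP * (h.RV_EDV - h.V0) * c.k_mmhgml


def isovolumic_power_adjusted(
    h: HemodynamicState, c: ModelConstants = DEFAULT_CONSTANTS
):
    """Adjusted-model isovolumic power:
    HR · (mRV_EP − RV_EDP) · RV_ESV · 1.33e-4 (J/min).

    Only the residual end-systolic volume is raised, and the
    end-diastolic pressure — work done by the left ventricle via venous
    return — is subtracted, giving a lower bound on total RV work.
    """
    if not _all(h.mRV_EP > h.RV_EDP):
        raise InvalidArgumentError("mRV_EP must exceed RV_EDP")
    return h.HR * (h.mRV_EP - h.RV_EDP) * h.RV_ESV * c.k_mmhgml


# ---------------------------------------------------------------------------
# stroke power

def stroke_power_integrated(
    pa_pressure: PressureTrace,
    pa_flow: PressureTrace,
    windows: Sequence[BeatWindow],
    c: ModelConstants = DEFAULT_CONSTANTS,
    *,
    n_beats: int = 5,
    tail: float | None = None,
) -> float:
    """Stroke power (J/min) from the trapezoidal pressure–flow integral.

    Per beat, P_PA(t)·Q_PA(t) is integrated over the ejection window
    [t_start, t_es + tail] and divided by that beat's ejection period T;
    the returned value is the mean over the first ``n_beats`` beats.

    ``tail`` defaults to the 0.04 s regurgitation window, appropriate
    when Q_PA is the invented profile (so negative regurgitant work is
    captured); pass ``tail=0.0`` for measured flow.
    """
    if abs(pa_pressure.rate - pa_flow.rate) > 1e-9 or abs(
        pa_pressure.t0 - pa_flow.t0
    ) > 1e-9:
        raise InvalidInputError("pressure and flow traces share no time base")
    if len(windows) < n_beats:
        raise InvalidInputError(
            f"need >= {n_beats} beats, got {len(windows)} windows"
        )
    if tail is None:
        tail = c.t_reg
    powers = []
    for w in windows[:n_beats]:
        t_hi = min(w.t_es + tail, w.t_ed)
        n = max(2, int(np.ceil((t_hi - w.t_start) * pa_pressure.rate)) + 1)
        t = np.linspace(w.t_start, t_hi, n)
        integrand = pa_pressure.value_at(t) * pa_flow.value_at(t)
        work = np.trapezoid(integrand, t)  # mmHg · ml/min · s
        powers.append(work / w.ejection_period * c.k_mmhgml)
    return float(np.mean(powers))


def stroke_power_adjusted(
    h: HemodynamicState, c: ModelConstants = DEFAULT_CONSTANTS
):
    """Adjusted-model closed-form stroke power (J/min):
    HR·mPAP·SV·1.33e-4 + 0.156·PP.

    The first addend is the zeroth-harmonic (useful) stroke power, the
    second the oscillatory estimate proportional to pulse pressure.
    Returns ``(useful, pulsatile)``; their sum is the stroke power.
    """
    useful = h.HR * h.mPAP * h.SV * c.k_mmhgml
    pulsatile = c.k_osc * h.PP
    return useful, pulsatile


def useful_stroke_power(
    h: HemodynamicState, c: ModelConstants = DEFAULT_CONSTANTS
):
    """Non-pulsatile (zeroth-harmonic) stroke power, mPAP·CO·1.33e-4
    (J/min) — the numerator of RV efficiency."""
    return h.mPAP * h.CO * c.k_mmhgml


# ---------------------------------------------------------------------------
# total power and efficiency

def total_power_output(
    h: HemodynamicState,
    variant: Variant = "adjusted",
    stroke_source: Literal["integrated", "closed_form"] = "closed_form",
    *,
    pa_pressure: PressureTrace | None = None,
    pa_flow: PressureTrace | None = None,
    windows: Sequence[BeatWindow] | None = None,
    c: ModelConstants = DEFAULT_CONSTANTS,
    n_beats: int = 5,
    tail: float | None = None,
) -> PowerBreakdown:
    """Total RV power output as isovolumic + stroke power.

    ``stroke_source='integrated'`` requires PA pressure/flow traces with
    beat windows (the measured-flow or invented-profile waveform path);
    ``'closed_form'`` uses the scalar adjusted stroke formula and
    suffices for tabulated hemodynamics.
    """
    if variant == "elbeery":
        iso = isovolumic_power_elbeery(h, c)
    elif variant == "adjusted":
        iso = isovolumic_power_adjusted(h, c)
    else:
        raise InvalidArgumentError(f"unknown variant {variant!r}")

    if stroke_source == "integrated":
        if pa_pressure is None or pa_flow is None or windows is None:
            raise InvalidArgumentError(
                "integrated stroke power needs pa_pressure, pa_flow, windows"
            )
        stroke = stroke_power_integrated(
            pa_pressure, pa_flow, windows, c, n_beats=n_beats, tail=tail
        )
        useful = pulsatile = np.nan
    elif stroke_source == "closed_form":
        useful, pulsatile = stroke_power_adjusted(h, c)
        stroke = useful + pulsatile
    else:
        raise InvalidArgumentError(f"unknown stroke_source {stroke_source!r}")

    return PowerBreakdown(
        variant=variant,
        isovolumic=iso,
        stroke=stroke,
        total=iso + stroke,
        useful_stroke=useful,
        pulsatile_stroke=pulsatile,
    )


def rv_efficiency(
    pb: PowerBreakdown,
    h: HemodynamicState,
    c: ModelConstants = DEFAULT_CONSTANTS,
):
    """RV efficiency: useful stroke power / total power output.

    Lies in (0, 1] for physiologic inputs under the adjusted closed-form
    path (useful ≤ stroke ≤ total by construction).
    """
    if not _all(np.asarray(pb.total) > 0):
        raise UndefinedEfficiencyError("total power must be positive")
    return useful_stroke_power(h, c) / pb.total


# ---------------------------------------------------------------------------
# unit converters (I/O boundaries only; internals are mmHg/ml/min/J)

def l_per_min_to_ml_per_min(x):
    return np.asarray(x, dtype=float) * 1000.0


def ml_per_min_to_l_per_min(x):
    return np.asarray(x, dtype=float) / 1000.0


def kpa_to_mmhg(x):
    return np.asarray(x, dtype=float) * 7.50061683


def mmhg_to_kpa(x):
    return np.asarray(x, dtype=float) / 7.50061683
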