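"""Synthetic cohorts and waveforms with the statistical structure the
energetic model assumes.

No patient or animal data are deposited with the study this package
models, so validation runs on synthetic inputs built here:

* clinical cohorts — per-NYHA-class hemodynamic/oxygen scalars drawn
  from truncated normals whose means/SDs follow the published group
  summaries (idiopathic PAH, classes II/III/IV), with dependent
  quantities (SV, RV_EDV, RV_ESV) derived rather than drawn so every row
  is internally consistent, and myocardial O2 consumption generated from
  the model's own energy-coupling relation plus multiplicative noise;
* per-subject beat waveforms — raised-cosine RV systole on a flat
  diastolic floor, PA pressure with raised-cosine upstroke and
  exponential diastolic decay calibrated exactly to the subject's mPAP
  and pulse pressure, and PA flow from the calibrated invented profile
  (clinical) or a smooth systolic pulse integrating to SV (animal);
  ground-truth beat timings are returned for oracle tests;
* animal time-series — the four pulmonary-banding/hypoxia conditions
  (ΔZ0 ∈ {0, 4} mmHg/(L/min) × Sa ∈ {1.00, 0.75}), sampled at baseline
  and every 40 simulated minutes over 4 hours, with right coronary flow
  back-derived from oxygen demand.

Truncated-normal draws are moment-matched: the underlying location is
solved so the *truncated* mean equals the published group mean (without
this, bounded fields such as the NYHA-IV oxygen extraction fraction,
0.9 ± 0.08 truncated at 1, would generate visibly below their published
means).  All draws descend from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .energetics import (
    DEFAULT_CONSTANTS,
    HemodynamicState,
    ModelConstants,
    stroke_power_integrated,
    isovolumic_power_adjusted,
    total_power_output,
)
from .errors import InvalidArgumentError, InvalidSpecError
from .flow_profile import InventedFlowParams, calibrate_amplitude, invented_flow
from .waveforms import BeatWindow, PressureTrace

__all__ = [
    "FieldDist",
    "GroupParams",
    "CohortSpec",
    "AnimalProtocolSpec",
    "ANIMAL_CONDITIONS",
    "generate_clinical_cohort",
    "generate_beat_waveforms",
    "generate_animal_timeseries",
]


# ---------------------------------------------------------------------------
# distribution machinery

@lru_cache(maxsize=None)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of the underlying normal whose [lo, hi]-truncation has
    the requested mean.  Cached: the solve is reused across draws."""

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(truncnorm.mean(a, b, loc=mu, scale=sd))

    return brentq(
        lambda mu: trunc_mean(mu) - mean, mean - 6 * sd, mean + 6 * sd, xtol=1e-10
    )


@dataclass(frozen=True)
class FieldDist:
    """Truncated-normal marginal for one scalar field.

    ``mean``/``sd`` are the published (observed) moments; ``lo``/``hi``
    physiologic truncation bounds.  Sampling moment-matches the mean: the
    underlying normal location is solved so the truncated distribution's
    mean equals ``mean``.
    """

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidSpecError("sd must be non-negative")
        if not (self.lo < self.hi):
            raise InvalidSpecError("empty truncation support")
        if not (self.lo < self.mean < self.hi):
            raise InvalidSpecError(
                f"target mean {self.mean} outside support ({self.lo}, {self.hi})"
            )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, self.mean)
        mu = _matched_loc(self.mean, self.sd, self.lo, self.hi)
        a, b = (self.lo - mu) / self.sd, (self.hi - mu) / self.sd
        return truncnorm.rvs(a, b, loc=mu, scale=self.sd, size=n, random_state=rng)


@dataclass(frozen=True)
class GroupParams:
    """Marginal distributions for one clinical group.

    mPAP/pressures in mmHg, CO in L/min, EF/OEF/Sa fractions, Q_RCA in
    ml/min, Chb in g/ml, HR in beats/min.  ``mrv_ep_gradient`` is the
    assumed excess of mean RV ejection pressure over mPAP;
    ``pp_fraction`` the assumed PA pulse pressure as a fraction of mPAP.
    """

    mpap: FieldDist
    co_l_min: FieldDist
    ef: FieldDist
    q_rca: FieldDist
    oef: FieldDist
    hr: FieldDist
    rv_edp: FieldDist
    sa: FieldDist
    chb: FieldDist
    mrv_ep_gradient: float = 3.0
    pp_fraction: float = 0.8


def _chb() -> FieldDist:
    return FieldDist(0.14, 0.015, 0.08, 0.20)


#: published group summaries (mean ± SD) for the idiopathic-PAH cohort,
#: supplemented with documented physiologic assumptions for fields the
#: study did not tabulate (HR, RV_EDP, Sa, Chb, and the mRV_EP / PP
#: construction rules).
DEFAULT_CLINICAL_GROUPS: Mapping[str, GroupParams] = {
    "NYHA_II": GroupParams(
        mpap=FieldDist(47.4, 11.7, 15.0, 110.0),
        co_l_min=FieldDist(5.6, 0.9, 1.5, 10.0),
        ef=FieldDist(0.46, 0.133, 0.08, 0.80),
        q_rca=FieldDist(47.5, 15.5, 8.0, 150.0),
        oef=FieldDist(0.60, 0.15, 0.10, 1.0),
        hr=FieldDist(78.0, 10.0, 45.0, 130.0),
        rv_edp=FieldDist(8.0, 3.0, 1.0, 25.0),
        sa=FieldDist(0.94, 0.03, 0.70, 1.0),
        chb=_chb(),
    ),
    "NYHA_III": GroupParams(
        mpap=FieldDist(58.8, 13.3, 15.0, 120.0),
        co_l_min=FieldDist(4.2, 1.1, 1.0, 9.0),
        ef=FieldDist(0.31, 0.035, 0.08, 0.70),
        q_rca=FieldDist(64.6, 20.8, 8.0, 170.0),
        oef=FieldDist(0.70, 0.16, 0.10, 1.0),
        hr=FieldDist(85.0, 11.0, 45.0, 140.0),
        rv_edp=FieldDist(11.0, 4.0, 1.0, 28.0),
        sa=FieldDist(0.92, 0.04, 0.65, 1.0),
        chb=_chb(),
    ),
    "NYHA_IV": GroupParams(
        mpap=FieldDist(65.3, 22.9, 15.0, 140.0),
        co_l_min=FieldDist(3.5, 1.4, 0.8, 8.0),
        ef=FieldDist(0.19, 0.044, 0.05, 0.60),
        q_rca=FieldDist(55.2, 12.6, 8.0, 150.0),
        oef=FieldDist(0.90, 0.08, 0.30, 1.0),
        hr=FieldDist(90.0, 12.0, 45.0, 145.0),
        rv_edp=FieldDist(14.0, 4.0, 1.0, 30.0),
        sa=FieldDist(0.90, 0.05, 0.60, 1.0),
        chb=_chb(),
    ),
}

DEFAULT_N_PER_GROUP: Mapping[str, int] = {"NYHA_II": 8, "NYHA_III": 4, "NYHA_IV": 3}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic clinical cohort.

    ``noise_cv`` is the multiplicative noise SD on the generated O2
    consumption rate; ``anaerobic_offset`` a constant power (J/min)
    added independently of O2, zero by default (anaerobic sources are
    assumed negligible); ``mvo2_variant`` chooses which model's total
    power the O2 consumption is generated from.
    """

    groups: Mapping[str, GroupParams] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_GROUPS)
    )
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    noise_cv: float = 0.05
    anaerobic_offset: float = 0.0
    mvo2_variant: str = "adjusted"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidSpecError("noise_cv must be non-negative")
        if self.mvo2_variant not in ("elbeery", "adjusted"):
            raise InvalidSpecError("mvo2_variant must be elbeery or adjusted")
        unknown = set(self.n_per_group) - set(self.groups)
        if unknown:
            raise InvalidSpecError(f"n_per_group for unknown groups {unknown}")


def generate_clinical_cohort(
    spec: CohortSpec, c: ModelConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Draw a synthetic clinical cohort table.

    Per subject: group-level fields are drawn from moment-matched
    truncated normals; SV = CO/HR, RV_EDV = SV/EF, RV_ESV = RV_EDV − SV
    are derived; mRV_EP = mPAP + gradient and PP = pp_fraction · mPAP by
    the documented construction rules; both model variants' total power
    is computed closed-form; and
    mvo2 = TPO(variant)/20.2 · (1 + ε) + anaerobic_offset/20.2 with
    ε ~ N(0, noise_cv).  Deterministic under a fixed seed.

    Returns a DataFrame in the package's cohort-table dialect (units in
    column names).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, params in spec.groups.items():
        n = int(spec.n_per_group.get(group, 0))
        if n == 0:
            continue
        mpap = params.mpap.sample(n, rng)
        co_ml = params.co_l_min.sample(n, rng) * 1000.0
        ef = params.ef.sample(n, rng)
        q_rca = params.q_rca.sample(n, rng)
        oef = params.oef.sample(n, rng)
        hr = params.hr.sample(n, rng)
        rv_edp = params.rv_edp.sample(n, rng)
        sa = params.sa.sample(n, rng)
        chb = params.chb.sample(n, rng)

        mrv_ep = mpap + params.mrv_ep_gradient
        # preload cannot approach ejection pressure; rare extreme draws
        # are clipped rather than rejected to keep moments intact
        rv_edp = np.minimum(rv_edp, 0.5 * mrv_ep)
        pp = params.pp_fraction * mpap

        h = HemodynamicState.from_measurements(
            HR=hr, mPAP=mpap, PP=pp, CO=co_ml, EF=ef,
            mRV_EP=mrv_ep, RV_EDP=rv_edp,
        )
        tpo_adj = total_power_output(h, "adjusted", "closed_form", c=c)
        tpo_elb = total_power_output(h, "elbeery", "closed_form", c=c)
        tpo_src = tpo_adj.total if spec.mvo2_variant == "adjusted" else tpo_elb.total

        eps = rng.normal(0.0, spec.noise_cv, size=n) if spec.noise_cv > 0 else 0.0
        mvo2 = tpo_src / c.k_o2 * (1.0 + eps) + spec.anaerobic_offset / c.k_o2
        mvo2 = np.maximum(mvo2, 1e-9)

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{group}_{i:05d}" for i in range(n)],
                    "group": group,
                    "hr_bpm": hr,
                    "mpap_mmHg": mpap,
                    "pp_mmHg": pp,
                    "sv_ml": h.SV,
                    "co_ml_min": co_ml,
                    "mrv_ep_mmHg": mrv_ep,
                    "rv_edp_mmHg": rv_edp,
                    "rv_edv_ml": h.RV_EDV,
                    "rv_esv_ml": h.RV_ESV,
                    "ef_frac": ef,
                    "sa_frac": sa,
                    "oef_frac": oef,
                    "q_rca_ml_min": q_rca,
                    "chb_g_ml": chb,
                    "mvo2_ml_min": mvo2,
                }
            )
        )
    if not frames:
        raise InvalidSpecError("cohort spec yields no subjects")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# waveform synthesis

def _beat_timing(hr: float) -> tuple[float, float, float, float]:
    """Return (period, bump_start, bump_width, ejection_period).

    The RV systolic bump is a raised cosine of width W; its derivative
    extrema sit at W/4 and 3W/4, which define the ground-truth ejection
    window consistently with derivative-based detection.
    """
    period = 60.0 / hr
    t_ej = min(0.3 * np.sqrt(period / 0.8), 0.3 * period)
    w = 2.0 * t_ej
    return period, 0.02, w, t_ej


def generate_beat_waveforms(
    h: HemodynamicState,
    rate: float = 1000.0,
    *,
    n_beats: int = 8,
    flow_shape: str = "invented",
    pa_decay_rate: float = 5.0,
    c: ModelConstants = DEFAULT_CONSTANTS,
) -> dict:
    """Synthesize RV pressure, PA pressure and PA flow traces for one
    subject, with ground-truth beat timings.

    The RV trace is a raised-cosine systolic bump on the diastolic floor
    RV_EDP, scaled so the mean pressure over the ground-truth ejection
    window equals mRV_EP.  The PA trace has a raised-cosine upstroke
    over ejection and an exponential diastolic decay, calibrated so its
    time-mean is exactly mPAP and its range exactly PP.  PA flow is the
    invented profile calibrated to CO (``flow_shape='invented'``) or a
    raised-cosine systolic pulse whose per-beat integral is SV
    (``flow_shape='pulse'``, the measured-flow emulation).

    Returns a dict with keys ``rv``, ``pa``, ``flow`` (PressureTrace)
    and ``windows`` (list of ground-truth BeatWindow, one per beat).
    """
    if rate < 50.0:
        raise InvalidArgumentError("sampling rate too low to resolve systole")
    if flow_shape not in ("invented", "pulse"):
        raise InvalidArgumentError("flow_shape must be 'invented' or 'pulse'")
    hr = float(np.asarray(h.HR))
    period, bump0, w, t_ej = _beat_timing(hr)
    tau_start = bump0 + w / 4.0
    tau_es = bump0 + 3.0 * w / 4.0

    # sample a hair past the (n_beats+1)-th onset so detection closes
    # the n_beats-th cycle
    total = n_beats * period + tau_start + 0.05
    t = np.arange(0.0, total, 1.0 / rate)
    tau = np.mod(t, period)

    # RV pressure: raised-cosine bump; mean over [W/4, 3W/4] of the bump
    # is EDP + amp/2 * (1 + 2/pi), solved for amp
    edp = float(np.asarray(h.RV_EDP))
    amp = (float(np.asarray(h.mRV_EP)) - edp) / (0.5 * (1.0 + 2.0 / np.pi))
    in_bump = (tau >= bump0) & (tau < bump0 + w)
    rv = np.full_like(t, edp)
    rv[in_bump] = edp + amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * (tau[in_bump] - bump0) / w))

    # PA pressure: raised-cosine upstroke over [tau_start, tau_es] from
    # the decayed end-diastolic value up to the peak, then exponential
    # decay over D = period - t_ej (wrapping through the cycle start).
    # Writing the beat as pdia + ppn * shape(tau) with shape in
    # [e^{-lam D}, 1], the amplitude ppn and offset pdia are solved so
    # the range is exactly PP and the cycle mean exactly mPAP.
    lam = pa_decay_rate
    D = period - t_ej
    pp = float(np.asarray(h.PP))
    mpap = float(np.asarray(h.mPAP))
    e_d = np.exp(-lam * D)
    ppn = pp / (1.0 - e_d)
    mean_shape = (t_ej * (1.0 + e_d) / 2.0 + (1.0 - e_d) / lam) / period
    pdia = mpap - ppn * mean_shape
    pa = np.empty_like(t)
    rising = (tau >= tau_start) & (tau < tau_es)
    rc = 0.5 * (1.0 - np.cos(np.pi * (tau[rising] - tau_start) / t_ej))
    pa[rising] = pdia + ppn * (e_d + (1.0 - e_d) * rc)
    # decay time since end of ejection, wrapping across the cycle start
    u = np.mod(tau - tau_es, period)
    decaying = ~rising
    pa[decaying] = pdia + ppn * np.exp(-lam * u[decaying])

    # PA flow
    sv = float(np.asarray(h.SV))
    co = float(np.asarray(h.CO))
    flow = np.zeros_like(t)
    if flow_shape == "invented":
        params = calibrate_amplitude(
            InventedFlowParams(A=1.0, SV=sv, t_es=t_ej, t_ed=period),
            co,
            grid_hz=max(rate, 1000.0),
        )
        # profile time runs from ejection onset; zero before onset
        tq = np.mod(tau - tau_start, period)
        flow = np.asarray(invented_flow(tq, params))
    else:
        qpeak = 120.0 * sv / t_ej  # ml/min; integral over t_ej = SV ml
        ej = rising
        flow[ej] = qpeak * 0.5 * (1.0 - np.cos(2.0 * np.pi * (tau[ej] - tau_start) / t_ej))

    windows = [
        BeatWindow(
            t_start=k * period + tau_start,
            t_es=k * period + tau_es,
            t_ed=(k + 1) * period + tau_start,
        )
        for k in range(n_beats)
    ]
    return {
        "rv": PressureTrace(rv, rate, "RV_pressure"),
        "pa": PressureTrace(pa, rate, "PA_pressure"),
        "flow": PressureTrace(flow, rate, "PA_flow"),
        "windows": windows,
    }


# ---------------------------------------------------------------------------
# animal protocol

#: condition code -> (delta_z0 [mmHg/(L/min)], Sa target, OEF)
ANIMAL_CONDITIONS: Mapping[str, tuple[float, float, float]] = {
    "N-N": (0.0, 1.00, 0.50),
    "H-N": (4.0, 1.00, 0.50),
    "N-H": (0.0, 0.75, 0.60),
    "H-H": (4.0, 0.75, 0.60),
}


@dataclass(frozen=True)
class AnimalProtocolSpec:
    """One animal's banding/hypoxia protocol.

    ``condition`` fixes the afterload increment ΔZ0, the arterial
    saturation target and the assumed oxygen extraction fraction (0.50
    normoxic, 0.60 hypoxic).  Baseline hemodynamics are healthy-sheep
    defaults; waveforms are sampled at 250 Hz.  Data rows are produced
    at baseline and every 40 simulated minutes for 4 hours.
    """

    condition: str
    subject_id: str = "sheep_00"
    baseline_hr: float = 95.0
    baseline_mpap: float = 18.0
    baseline_co_l_min: float = 5.0
    baseline_ef: float = 0.45
    baseline_rv_edp: float = 5.0
    pp_fraction: float = 0.7
    mrv_ep_gradient: float = 3.0
    chb_g_ml: float = 0.10
    noise_cv: float = 0.03
    mvo2_noise_cv: float = 0.05
    rate_hz: float = 250.0
    duration_min: float = 240.0
    interval_min: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in ANIMAL_CONDITIONS:
            raise InvalidSpecError(
                f"condition must be one of {sorted(ANIMAL_CONDITIONS)}"
            )

    @property
    def delta_z0(self) -> float:
        return ANIMAL_CONDITIONS[self.condition][0]

    @property
    def sa_target(self) -> float:
        return ANIMAL_CONDITIONS[self.condition][1]

    @property
    def oef(self) -> float:
        return ANIMAL_CONDITIONS[self.condition][2]


def generate_animal_timeseries(
    spec: AnimalProtocolSpec, c: ModelConstants = DEFAULT_CONSTANTS
) -> tuple[pd.DataFrame, dict]:
    """Simulate one animal's protocol: a baseline row plus one row every
    40 simulated minutes, with 250 Hz waveforms per row.

    Banding raises mPAP over baseline by ΔZ0 × CO (L/min); hypoxia sets
    Sa to 0.75 and selects OEF = 0.60.  O2 consumption is generated from
    the adjusted model's total power with the measured-flow (integrated)
    stroke path, and right coronary flow is back-derived from that
    demand through the delivery relation — supply matches demand, as the
    coupling hypothesis assumes.

    Returns ``(rows, waveforms)`` where ``waveforms`` maps row index to
    the dict produced by :func:`generate_beat_waveforms`.
    """
    rng = np.random.default_rng(spec.seed)
    times = [0.0] + list(
        np.arange(spec.interval_min, spec.duration_min + 1e-9, spec.interval_min)
    )
    rows = []
    waves: dict[int, dict] = {}
    for i, t_min in enumerate(times):
        at_baseline = t_min == 0.0
        jitter = lambda x: x * (1.0 + rng.normal(0.0, spec.noise_cv))
        hr = jitter(spec.baseline_hr)
        co_l = jitter(spec.baseline_co_l_min)
        ef = min(0.9, jitter(spec.baseline_ef))
        edp = jitter(spec.baseline_rv_edp)
        dz0 = 0.0 if at_baseline else spec.delta_z0
        sa = 1.0 if at_baseline else spec.sa_target
        oef = 0.50 if at_baseline else spec.oef
        mpap = jitter(spec.baseline_mpap) + dz0 * co_l
        mrv_ep = mpap + spec.mrv_ep_gradient
        pp = spec.pp_fraction * mpap
        edp = min(edp, 0.5 * mrv_ep)

        h = HemodynamicState.from_measurements(
            HR=hr, mPAP=mpap, PP=pp, CO=co_l * 1000.0, EF=ef,
            mRV_EP=mrv_ep, RV_EDP=edp,
        )
        wf = generate_beat_waveforms(h, spec.rate_hz, flow_shape="pulse", c=c)
        stroke = stroke_power_integrated(
            wf["pa"], wf["flow"], wf["windows"], c, tail=0.0
        )
        iso = float(isovolumic_power_adjusted(h, c))
        tpo = iso + stroke
        mvo2 = tpo / c.k_o2 * (1.0 + rng.normal(0.0, spec.mvo2_noise_cv))
        mvo2 = max(mvo2, 1e-9)
        q_rca = mvo2 / (c.k_hb * oef * sa * spec.chb_g_ml)

        rows.append(
            {
                "subject_id": spec.subject_id,
                "group": "baseline" if at_baseline else spec.condition,
                "time_min": t_min,
                "hr_bpm": hr,
                "mpap_mmHg": mpap,
                "pp_mmHg": pp,
                "sv_ml": float(np.asarray(h.SV)),
                "co_ml_min": co_l * 1000.0,
                "mrv_ep_mmHg": mrv_ep,
                "rv_edp_mmHg": edp,
                "rv_edv_ml": float(np.asarray(h.RV_EDV)),
                "rv_esv_ml": float(np.asarray(h.RV_ESV)),
                "ef_frac": ef,
                "sa_frac": sa,
                "oef_frac": oef,
                "q_rca_ml_min": q_rca,
                "chb_g_ml": spec.chb_g_ml,
                "mvo2_ml_min": mvo2,
            }
        )
        waves[i] = wf
    return pd.DataFrame(rows), waves
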