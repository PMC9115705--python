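"""Cohort-level validation statistics for the energetic model.

Four analyses mirror the study's validation layer:

* OLS regression of total power output (response) on myocardial O2
  consumption rate (predictor), with t-tests and 95% confidence
  intervals for slope and intercept — the slope should approach the
  oxidative-phosphorylation constant (20.2 J/ml O2) and the intercept
  zero if anaerobic power is negligible;
* the same machinery with RV efficiency as response (expected negative
  slope: inefficient ventricles need more oxygen);
* group-wise mean ± SEM of the isovolumic / useful-stroke /
  pulsatile-stroke fractions of total power, with NYHA III and IV
  pooled;
* a one-way MANOVA (Pillai's trace by default) comparing NYHA II
  against pooled III/IV on (efficiency under each model variant, MVO2
  rate), with Bonferroni-corrected Welch post hoc tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.multivariate.manova import MANOVA

from .energetics import PowerBreakdown
from .errors import (
    DegenerateDesignError,
    InvalidArgumentError,
    RankDeficiencyError,
)

__all__ = [
    "CohortRecord",
    "RegressionResult",
    "records_from_table",
    "fit_power_oxygen_regression",
    "efficiency_oxygen_correlation",
    "power_fraction_summary",
    "class_comparison_manova",
    "pooled_class",
    "plot_regression",
]

#: NYHA pooling used throughout the validation layer
POOL_MAP = {"NYHA_II": "NYHA_II", "NYHA_III": "NYHA_III_IV", "NYHA_IV": "NYHA_III_IV"}


@dataclass(frozen=True)
class CohortRecord:
    """One subject's model outputs paired with measured/simulated MVO2."""

    subject_id: str
    group: str
    mvo2_rate: float
    breakdown_elbeery: PowerBreakdown
    breakdown_adjusted: PowerBreakdown
    efficiency_elbeery: float
    efficiency_adjusted: float

    def __post_init__(self) -> None:
        if self.mvo2_rate <= 0:
            raise InvalidArgumentError("mvo2_rate must be positive")

    def breakdown(self, variant: str) -> PowerBreakdown:
        return (
            self.breakdown_adjusted if variant == "adjusted" else self.breakdown_elbeery
        )

    def efficiency(self, variant: str) -> float:
        return (
            self.efficiency_adjusted if variant == "adjusted" else self.efficiency_elbeery
        )


@dataclass(frozen=True)
class RegressionResult:
    """Simple-OLS summary: y = slope·x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    slope_p: float
    intercept_p: float
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    n: int


def pooled_class(group: str) -> str:
    """Map an NYHA label to its pooled analysis class; other labels
    (e.g. animal condition codes) pass through unchanged."""
    return POOL_MAP.get(group, group)


def records_from_table(results: pd.DataFrame) -> list[CohortRecord]:
    """Assemble CohortRecords from a computed-results table (one row per
    subject with both variants' breakdown columns)."""
    records = []
    for _, r in results.iterrows():
        records.append(
            CohortRecord(
                subject_id=str(r["subject_id"]),
                group=str(r["group"]),
                mvo2_rate=float(r["mvo2_ml_min"]),
                breakdown_elbeery=PowerBreakdown(
                    variant="elbeery",
                    isovolumic=float(r["iso_elbeery_j_min"]),
                    stroke=float(r["stroke_elbeery_j_min"]),
                    total=float(r["tpo_elbeery_j_min"]),
                    useful_stroke=float(r.get("useful_j_min", np.nan)),
                    pulsatile_stroke=float(r.get("pulsatile_j_min", np.nan)),
                ),
                breakdown_adjusted=PowerBreakdown(
                    variant="adjusted",
                    isovolumic=float(r["iso_adjusted_j_min"]),
                    stroke=float(r["stroke_adjusted_j_min"]),
                    total=float(r["tpo_adjusted_j_min"]),
                    useful_stroke=float(r.get("useful_j_min", np.nan)),
                    pulsatile_stroke=float(r.get("pulsatile_j_min", np.nan)),
                ),
                efficiency_elbeery=float(r["eff_elbeery"]),
                efficiency_adjusted=float(r["eff_adjusted"]),
            )
        )
    return records


def _simple_ols(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InvalidArgumentError("need n >= 3 for regression")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        slope_p=float(model.pvalues[1]),
        intercept_p=float(model.pvalues[0]),
        slope_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci95=(float(ci[0, 0]), float(ci[0, 1])),
        n=int(x.size),
    )


def fit_power_oxygen_regression(
    records: Sequence[CohortRecord], variant: str = "adjusted"
) -> RegressionResult:
    """OLS of total power output (J/min) on MVO2 rate (ml/min).

    The slope estimates the energy yield per ml O2; the intercept the
    oxygen-independent (anaerobic) power.
    """
    x = np.array([r.mvo2_rate for r in records])
    y = np.array([r.breakdown(variant).total for r in records])
    return _simple_ols(x, y)


def efficiency_oxygen_correlation(
    records: Sequence[CohortRecord], variant: str = "adjusted"
) -> RegressionResult:
    """OLS of RV efficiency on MVO2 rate; expected negative slope."""
    x = np.array([r.mvo2_rate for r in records])
    y = np.array([r.efficiency(variant) for r in records])
    return _simple_ols(x, y)


def power_fraction_summary(
    records: Sequence[CohortRecord], variant: str = "adjusted"
) -> pd.DataFrame:
    """Group-wise mean ± SEM of power fractions of total (percent).

    Fractions are isovolumic, useful-stroke and pulsatile-stroke power
    over total power (they sum to 1 for the closed-form path).  NYHA III
    and IV are pooled.  SEM is sd/sqrt(n) (ddof=1), reported as NaN for
    single-record groups.
    """
    rows = []
    for r in records:
        b = r.breakdown(variant)
        rows.append(
            {
                "pooled_group": pooled_class(r.group),
                "isovolumic": b.isovolumic / b.total,
                "useful_stroke": b.useful_stroke / b.total,
                "pulsatile_stroke": b.pulsatile_stroke / b.total,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for grp, g in df.groupby("pooled_group", sort=True):
        n = len(g)
        for comp in ("isovolumic", "useful_stroke", "pulsatile_stroke"):
            vals = g[comp].to_numpy()
            out.append(
                {
                    "pooled_group": grp,
                    "component": comp,
                    "mean_pct": 100.0 * float(np.mean(vals)),
                    "sem_pct": (
                        100.0 * float(np.std(vals, ddof=1) / np.sqrt(n))
                        if n > 1
                        else np.nan
                    ),
                    "n": n,
                }
            )
    return pd.DataFrame(out)


def class_comparison_manova(
    records: Sequence[CohortRecord],
    statistic: Literal["pillai", "wilks"] = "pillai",
) -> dict:
    """One-way MANOVA of NYHA II vs pooled III/IV on three dependent
    variables: efficiency (original model), efficiency (adjusted model)
    and MVO2 rate; Welch post hoc tests with Bonferroni factor 3.

    Returns a dict with the overall p-value, the test statistic used,
    and per-variable post hoc results (raw and corrected p).
    """
    data = pd.DataFrame(
        {
            "cls": [pooled_class(r.group) for r in records],
            "eff_elbeery": [r.efficiency_elbeery for r in records],
            "eff_adjusted": [r.efficiency_adjusted for r in records],
            "mvo2": [r.mvo2_rate for r in records],
        }
    )
    classes = sorted(data["cls"].unique())
    if len(classes) != 2:
        raise InvalidArgumentError(f"need exactly two classes, got {classes}")
    counts = data["cls"].value_counts()
    if counts.min() < 2:
        raise InvalidArgumentError("each class needs n >= 2")
    dvs = ["eff_elbeery", "eff_adjusted", "mvo2"]

    # degenerate null case: identical class means give zero
    # between-group scatter, hence statistic 0 and p = 1 by convention
    means = data.groupby("cls")[dvs].mean().to_numpy()
    scale = np.abs(means).max() or 1.0
    if np.allclose(means[0], means[1], rtol=0, atol=1e-12 * scale):
        return {
            "statistic": statistic,
            "stat_value": 0.0,
            "p_value": 1.0,
            "classes": classes,
            "n_per_class": {k: int(v) for k, v in counts.items()},
            "posthoc": {},
        }
    if len(data) - 2 < len(dvs):
        raise RankDeficiencyError(
            "error degrees of freedom below the number of dependent "
            "variables; drop a variable or add subjects"
        )
    for cls, g in data.groupby("cls"):
        cov = np.cov(g[dvs].to_numpy().T)
        if g[dvs].shape[0] > len(dvs) and np.linalg.matrix_rank(cov) < len(dvs):
            raise RankDeficiencyError(
                "within-group covariance is singular; drop a dependent variable"
            )
    try:
        mv = MANOVA.from_formula(
            "eff_elbeery + eff_adjusted + mvo2 ~ cls", data=data
        )
        table = mv.mv_test().results["cls"]["stat"]
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RankDeficiencyError(
            "within-group covariance is singular; drop a dependent variable"
        ) from exc
    row = "Pillai's trace" if statistic == "pillai" else "Wilks' lambda"
    overall_p = float(table.loc[row, "Pr > F"])
    stat_value = float(table.loc[row, "Value"])

    posthoc = {}
    g1 = data[data["cls"] == classes[0]]
    g2 = data[data["cls"] == classes[1]]
    for dv in dvs:
        t, p = stats.ttest_ind(g1[dv], g2[dv], equal_var=False)
        posthoc[dv] = {
            "t": float(t),
            "p_raw": float(p),
            "p_bonferroni": float(min(1.0, p * len(dvs))),
            "mean_" + classes[0]: float(g1[dv].mean()),
            "mean_" + classes[1]: float(g2[dv].mean()),
        }
    return {
        "statistic": statistic,
        "stat_value": stat_value,
        "p_value": overall_p,
        "classes": classes,
        "n_per_class": {k: int(v) for k, v in counts.items()},
        "posthoc": posthoc,
    }


def plot_regression(
    records: Sequence[CohortRecord],
    variant: str,
    path: str,
    *,
    response: Literal["power", "efficiency"] = "power",
) -> None:
    """Scatter of the cohort with the fitted line and 95% CI band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([r.mvo2_rate for r in records])
    if response == "power":
        y = np.array([r.breakdown(variant).total for r in records])
        ylabel = "Total power output (J/min)"
    else:
        y = np.array([r.efficiency(variant) for r in records])
        ylabel = "RV efficiency"
    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), 100)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.7)
    ax.plot(grid, pred["mean"], color="k")
    ax.fill_between(grid, pred["mean_ci_lower"], pred["mean_ci_upper"], alpha=0.25)
    ax.set_xlabel("MVO2 rate (ml/min)")
    ax.set_ylabel(ylabel)
    ax.set_title(f"{variant} model (n={x.size}, R²={model.rsquared:.2f})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
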