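"""Hazard-ratio reporting for fitted joint models.

The association coefficient alpha is a log-hazard per unit of the shared
quantity (FVC%-predicted slope per year, or FVC% predicted itself).  A
k-unit *decrease* therefore multiplies the hazard by exp(-k*alpha), so
reported hazard ratios above 1 mean decline is harmful.  Confidence
intervals are Wald intervals mapped through the same exponential
(delta method on the log scale, where they are exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .joint import JointModelFit

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class HazardRatioReport:
    """Hazard ratios for k-unit declines with Wald CIs and p-value."""

    alpha: float
    alpha_se: float
    table: pd.DataFrame  # columns: units, hr, ci_low, ci_high
    p_value: float
    significant: bool
    endpoint: str
    period: str
    association: str
    n: int
    n_events: int

    def hr(self, k: float) -> float:
        return float(np.exp(-k * self.alpha))


def hazard_ratio_for_decline(
    alpha: float, alpha_se: float, units
) -> pd.DataFrame:
    """HR(k) = exp(-k*alpha) with 95% Wald CI, low < high."""
    units = np.atleast_1d(np.asarray(units, dtype=float))
    z = norm.ppf(0.975)
    hr = np.exp(-units * alpha)
    a = np.exp(-units * (alpha - z * alpha_se))
    b = np.exp(-units * (alpha + z * alpha_se))
    return pd.DataFrame(
        {
            "units": units,
            "hr": hr,
            "ci_low": np.minimum(a, b),
            "ci_high": np.maximum(a, b),
        }
    )


def hazard_ratio_report(fit: JointModelFit, units=(1, 3, 5)) -> HazardRatioReport:
    """Hazard ratios for 1/3/5-unit FVC declines with Wald inference."""
    alpha, se = fit.alpha, fit.alpha_se
    table = hazard_ratio_for_decline(alpha, se, units)
    if se > 0 and np.isfinite(se):
        p = float(2.0 * norm.sf(abs(alpha) / se))
    else:
        p = 1.0 if alpha == 0 else float("nan")
    return HazardRatioReport(
        alpha=alpha,
        alpha_se=se,
        table=table,
        p_value=p,
        significant=bool(p <= SIGNIFICANCE_LEVEL),
        endpoint=fit.spec.endpoint,
        period=fit.spec.period,
        association=fit.spec.association,
        n=fit.n,
        n_events=fit.n_events,
    )


def risk_curve(fit: JointModelFit, decline_grid=None) -> pd.DataFrame:
    """Pointwise HR(d) over a grid of FVC declines (default (0, 10] by 0.1)."""
    if decline_grid is None:
        decline_grid = np.round(np.arange(0.1, 10.0 + 1e-9, 0.1), 10)
    df = hazard_ratio_for_decline(fit.alpha, fit.alpha_se, decline_grid)
    return df.rename(columns={"units": "decline"})


def publication_table(fit: JointModelFit, report: HazardRatioReport) -> pd.DataFrame:
    """Long-format table mirroring the usual two-block presentation:
    longitudinal sub-model (arm slope difference), then the time-to-event
    block with event counts and HR rows per k-unit decline."""
    z = norm.ppf(0.975)
    i_tx = fit.names.index("arm_x_time_years")
    slope_diff = float(fit.params.beta[4])
    se_tx = float(np.sqrt(fit.vcov[i_tx, i_tx]))
    p_tx = float(2.0 * norm.sf(abs(slope_diff) / se_tx)) if se_tx > 0 else float("nan")
    rows = [
        {
            "block": "longitudinal",
            "quantity": "slope_difference_treated_vs_control",
            "estimate": slope_diff,
            "ci_low": slope_diff - z * se_tx,
            "ci_high": slope_diff + z * se_tx,
            "p_value": p_tx,
        },
        {
            "block": "time_to_event",
            "quantity": "n_patients_with_event",
            "estimate": report.n_events,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": np.nan,
        },
        {
            "block": "time_to_event",
            "quantity": "event_pct",
            "estimate": round(100.0 * report.n_events / report.n, 1),
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p_value": np.nan,
        },
    ]
    for _, r in report.table.iterrows():
        rows.append(
            {
                "block": "time_to_event",
                "quantity": f"hr_{r['units']:g}_unit_decrease",
                "estimate": r["hr"],
                "ci_low": r["ci_low"],
                "ci_high": r["ci_high"],
                "p_value": report.p_value,
            }
        )
    df = pd.DataFrame(rows)
    df.insert(0, "endpoint", report.endpoint)
    df.insert(1, "period", report.period)
    df.insert(2, "association", report.association)
    return df


def coefficient_listing(fit: JointModelFit) -> pd.DataFrame:
    """Full coefficient listing: every free parameter with its SE on the
    estimation (transformed) scale."""
    from .joint import pack

    est = pack(fit.params)
    ses = np.sqrt(np.diag(fit.vcov))
    return pd.DataFrame({"parameter": fit.names, "estimate": est, "se": ses})
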