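"""Costs, utilities, discounting, and cost-effectiveness comparison.

The cost ledger uses the eight reporting categories of the base-case results
table: treatment (binder drug), HK (per-event management cost by severity),
CKD (stage and NYHA disease-management costs), RRT (dialysis and transplant
state costs), MACE, hospitalisation, RAASi drug usage, and RAASi titration
(an administration cost charged at every discontinuation, down-titration or
return-to-optimal event). Costs and QALYs are discounted at the same annual
rate (3.5% by default) with the factor indexed by cycle start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .parameters import ParameterSet

if TYPE_CHECKING:  # pragma: no cover
    from .engine import TrajectoryResult
    from .states import CohortVector

log = logging.getLogger(__name__)

COST_CATEGORIES = ("treatment", "HK", "CKD", "RRT", "MACE", "hospitalisation",
                   "RAASi drug", "RAASi titration")


def discount_factor(month: int | float, annual_rate: float) -> float:
    """(1 + r)^(-month/12), with month counted from cycle start (month 0 = 1)."""
    if month < 0:
        raise ValueError("month must be >= 0")
    return float((1.0 + annual_rate) ** (-month / 12.0))


def cycle_economics(cohort: "CohortVector", events: dict[str, float],
                    p: ParameterSet, on_treatment_mass: float
                    ) -> tuple[dict[str, float], float, float]:
    """Undiscounted (ledger, QALY, LY) for one cycle.

    State costs and utilities weight the cycle's occupancy; event costs and
    one-off disutilities weight the cycle's expected event counts. QALYs and
    life years are in year units (1/12 per cycle of occupancy). A negative
    cycle QALY (disutility exceeding utility mass, a config inconsistency)
    is clamped at zero with a warning.
    """
    co, hf = cohort.ckd_only, cohort.hf
    ckd_occ = co.sum(axis=(1, 2, 3)) + hf.sum(axis=(1, 2, 3, 4))   # (5,)
    nyha_occ = hf.sum(axis=(0, 2, 3, 4))                            # (4,)
    raasi_occ = (co.sum(axis=(0, 1, 3)) + hf.sum(axis=(0, 1, 2, 4)))  # (3,)
    alive = cohort.alive_mass

    c = p.costs.state_monthly
    ckd_cost = np.array([c["ckd3"].mean, c["ckd4"].mean, c["ckd5"].mean,
                         c["dialysis"].mean, c["transplant"].mean])
    nyha_cost = np.array([c["nyha1"].mean, c["nyha2"].mean, c["nyha3"].mean,
                          c["nyha4"].mean])
    hk_cost = p.costs.hk_event.means()
    hk_events = np.array([events.get("hk_5_55", 0.0),
                          events.get("hk_55_6", 0.0),
                          events.get("hk_gt6", 0.0)])
    titration_events = (events.get("raasi_discontinuation", 0.0)
                        + events.get("raasi_down_titration", 0.0)
                        + events.get("raasi_return", 0.0))

    ledger = {
        "treatment": on_treatment_mass * p.treatment.monthly_drug_cost.mean,
        "HK": float(hk_events @ hk_cost),
        "CKD": float(ckd_occ[:3] @ ckd_cost[:3] + nyha_occ @ nyha_cost),
        "RRT": float(ckd_occ[3:] @ ckd_cost[3:]),
        "MACE": events.get("mace", 0.0) * p.costs.mace_event.mean,
        "hospitalisation": (events.get("hospitalisation", 0.0)
                            * p.costs.hospitalisation_event.mean),
        "RAASi drug": float(raasi_occ[0] * p.costs.raasi_monthly_max.mean
                            + raasi_occ[1] * p.costs.raasi_monthly_submax.mean),
        "RAASi titration": titration_events * p.costs.raasi_titration_event.mean,
    }

    u = p.utilities.state
    u_ckd = np.array([u["ckd3"].mean, u["ckd4"].mean, u["ckd5"].mean,
                      u["dialysis"].mean, u["transplant"].mean])
    u_nyha = np.array([u["nyha1"].mean, u["nyha2"].mean, u["nyha3"].mean,
                       u["nyha4"].mean])
    # CKD+HF utility is the worse of the two single-condition utilities
    u_joint = np.minimum(u_ckd[:, None], u_nyha[None, :])           # (5, 4)
    util_mass = float(co.sum(axis=(1, 2, 3)) @ u_ckd
                      + (hf.sum(axis=(2, 3, 4)) * u_joint).sum())
    disutility = float(
        hk_events @ p.utilities.disutility_hk.means()
        + events.get("mace", 0.0) * p.utilities.disutility_mace.mean
        + events.get("hospitalisation", 0.0)
        * p.utilities.disutility_hospitalisation.mean)
    qaly = util_mass / 12.0 - disutility
    if qaly < 0.0:
        log.warning("cycle QALY %.5f clamped at 0 (disutility exceeds "
                    "utility mass; check event disutilities)", qaly)
        qaly = 0.0
    ly = alive / 12.0
    return ledger, qaly, ly


@dataclass
class CEAResult:
    """Paired-arm cost-effectiveness comparison."""

    arm_a: str
    arm_b: str
    cost_a: float
    cost_b: float
    cost_a_undisc: float
    cost_b_undisc: float
    ly_a: float
    ly_b: float
    ly_a_undisc: float
    ly_b_undisc: float
    qaly_a: float
    qaly_b: float
    qaly_a_undisc: float
    qaly_b_undisc: float
    cost_by_category_a: dict[str, float]
    cost_by_category_b: dict[str, float]
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.cost_a - self.cost_b

    @property
    def delta_qaly(self) -> float:
        return self.qaly_a - self.qaly_b

    @property
    def delta_ly(self) -> float:
        return self.ly_a - self.ly_b

    @property
    def dominance(self) -> str:
        dc, dq = self.delta_cost, self.delta_qaly
        if dq > 0 and dc <= 0:
            return "dominant"
        if dq <= 0 and dc >= 0 and (dq < 0 or dc > 0):
            return "dominated"
        if dq == 0 and dc == 0:
            return "tradeoff"
        return "tradeoff"

    @property
    def icer(self) -> float | None:
        """Incremental cost per QALY; None when dQALY = 0 (no division)."""
        if self.delta_qaly == 0.0:
            return None
        return self.delta_cost / self.delta_qaly

    @property
    def icer_undiscounted(self) -> float | None:
        dq = self.qaly_a_undisc - self.qaly_b_undisc
        if dq == 0.0:
            return None
        return (self.cost_a_undisc - self.cost_b_undisc) / dq

    def nmb(self, wtp: float | None = None) -> float:
        """Net monetary benefit wtp*dQALY - dCost of arm a vs arm b."""
        w = self.wtp if wtp is None else wtp
        return w * self.delta_qaly - self.delta_cost

    def to_dict(self) -> dict:
        return {
            "arms": [self.arm_a, self.arm_b],
            "discounted": {
                "cost": [self.cost_a, self.cost_b],
                "ly": [self.ly_a, self.ly_b],
                "qaly": [self.qaly_a, self.qaly_b],
                "incremental_cost": self.delta_cost,
                "incremental_ly": self.delta_ly,
                "incremental_qaly": self.delta_qaly,
                "icer": self.icer,
            },
            "undiscounted": {
                "cost": [self.cost_a_undisc, self.cost_b_undisc],
                "ly": [self.ly_a_undisc, self.ly_b_undisc],
                "qaly": [self.qaly_a_undisc, self.qaly_b_undisc],
                "icer": self.icer_undiscounted,
            },
            "cost_by_category": {self.arm_a: self.cost_by_category_a,
                                 self.arm_b: self.cost_by_category_b},
            "dominance": self.dominance,
            "nmb_at_wtp": {str(self.wtp): self.nmb()},
        }

    def to_table(self):
        """Base-case results in the shape of the published results table."""
        import pandas as pd
        rows = []
        for label, disc in (("Discounted", True), ("Undiscounted", False)):
            ca = self.cost_a if disc else self.cost_a_undisc
            cb = self.cost_b if disc else self.cost_b_undisc
            rows.append([label, "Total costs (GBP)", ca, cb, ca - cb])
            if disc:
                for cat in COST_CATEGORIES:
                    a = self.cost_by_category_a[cat]
                    b = self.cost_by_category_b[cat]
                    rows.append([label, f"  {cat}", a, b, a - b])
            la = self.ly_a if disc else self.ly_a_undisc
            lb = self.ly_b if disc else self.ly_b_undisc
            qa = self.qaly_a if disc else self.qaly_a_undisc
            qb = self.qaly_b if disc else self.qaly_b_undisc
            icer = self.icer if disc else self.icer_undiscounted
            rows.append([label, "Total life years", la, lb, la - lb])
            rows.append([label, "Total QALYs", qa, qb, qa - qb])
            rows.append([label, "ICER (GBP/QALY)", np.nan, np.nan,
                         np.nan if icer is None else icer])
        return pd.DataFrame(rows, columns=["results", "quantity", self.arm_a,
                                           self.arm_b, "incremental"])


def compute_cea(a: "TrajectoryResult", b: "TrajectoryResult",
                wtp: float = 20_000.0) -> CEAResult:
    """Compare arm a (intervention) against arm b (comparator)."""
    return CEAResult(
        arm_a=a.arm, arm_b=b.arm,
        cost_a=a.total_cost(True), cost_b=b.total_cost(True),
        cost_a_undisc=a.total_cost(False), cost_b_undisc=b.total_cost(False),
        ly_a=a.total_ly(True), ly_b=b.total_ly(True),
        ly_a_undisc=a.total_ly(False), ly_b_undisc=b.total_ly(False),
        qaly_a=a.total_qaly(True), qaly_b=b.total_qaly(True),
        qaly_a_undisc=a.total_qaly(False), qaly_b_undisc=b.total_qaly(False),
        cost_by_category_a=a.cost_by_category(True),
        cost_by_category_b=b.cost_by_category(True),
        wtp=wtp)
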