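"""Result-generating procedures: base case, probabilistic and one-way
sensitivity analyses, the hyperkalaemia-incidence sweep, and the lifetime
optimal-RAASi value grid."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .economics import CEAResult, compute_cea
from .engine import run_cohort
from .parameters import (ParameterSet, SamplingError, get_param,
                         sample_parameters)
from .potassium import annual_rate_to_monthly_prob
from .reference import neutralise_treatment_effects

log = logging.getLogger(__name__)

__all__ = ["run_base_case", "run_psa", "run_owsa", "run_hk_sweep",
           "run_raasi_value", "PSAResult", "SweepResult", "RAASiValueResult"]


def run_base_case(p: ParameterSet, wtp: float = 20_000.0) -> CEAResult:
    """Deterministic lifetime comparison of both arms at the point estimates."""
    a = run_cohort("patiromer", p)
    b = run_cohort("soc", p)
    return compute_cea(a, b, wtp=wtp)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAResult:
    seed: int
    n_draws: int
    n_skipped: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    wtp_grid: np.ndarray

    def ceac(self, wtp: float | np.ndarray | None = None) -> np.ndarray:
        """Probability cost-effective: share of draws with positive NMB."""
        w = np.atleast_1d(self.wtp_grid if wtp is None else wtp).astype(float)
        nmb = w[:, None] * self.delta_qaly[None, :] - self.delta_cost[None, :]
        return (nmb > 0).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"draw": np.arange(1, self.n_draws + 1),
                             "delta_cost": self.delta_cost,
                             "delta_qaly": self.delta_qaly})

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid,
                             "probability_cost_effective": self.ceac()})


def run_psa(p: ParameterSet, n_draws: int = 1000, seed: int = 1,
            wtp_grid: Optional[Sequence[float]] = None) -> PSAResult:
    """Monte-Carlo over the parameter distributions; reproducible by seed.

    Each draw samples one ParameterSet realisation and reruns both arms;
    draws whose distributions cannot be moment-matched are skipped (counted
    and logged), which does not consume extra random numbers beyond the
    failed draw.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    grid = np.asarray(wtp_grid if wtp_grid is not None
                      else np.arange(0, 50_001, 2_500), dtype=float)
    d_cost, d_qaly = [], []
    skipped = 0
    for i in range(n_draws):
        try:
            draw = sample_parameters(p, rng)
            res = run_base_case(draw)
        except SamplingError as exc:
            skipped += 1
            log.warning("PSA draw %d skipped: %s", i + 1, exc)
            continue
        d_cost.append(res.delta_cost)
        d_qaly.append(res.delta_qaly)
    return PSAResult(seed=seed, n_draws=len(d_cost), n_skipped=skipped,
                     delta_cost=np.array(d_cost), delta_qaly=np.array(d_qaly),
                     wtp_grid=grid)


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class OwsaEntry:
    name: str
    path: str               # dotted Param path, or settings attribute
    low: float
    high: float
    kind: str = "param"     # "param" or "setting"


def default_owsa_entries(p: ParameterSet) -> list[OwsaEntry]:
    """The most influential inputs: discounting, horizon, baseline age, the
    RAASi effect on CKD progression, and RAASi/treatment discontinuation."""
    def pm(path: str, name: str) -> OwsaEntry:
        param = get_param(p, path)
        lo = param.mean - 1.96 * param.se
        hi = param.mean + 1.96 * param.se
        return OwsaEntry(name=name, path=path, low=lo, high=hi)

    return [
        OwsaEntry("discount rate", "settings.discount_rate_annual",
                  0.0, 0.06, kind="setting"),
        OwsaEntry("horizon age", "settings.horizon_age", 80.0, 100.0,
                  kind="setting"),
        pm("demographics.age_years", "baseline age"),
        pm("modifiers.raasi.ckd_progression.discontinued",
           "RAASi effect on CKD progression (discontinued)"),
        pm("raasi.months2_3_soc.discontinue_from_max",
           "RAASi discontinuation (months 2-3, SoC)"),
        pm("treatment.monthly_discontinuation", "treatment discontinuation"),
    ]


def _with_override(p: ParameterSet, entry: OwsaEntry,
                   value: float) -> ParameterSet:
    q = p.model_copy(deep=True)
    if entry.kind == "setting":
        obj = q
        parts = entry.path.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        setattr(obj, parts[-1], value)
    else:
        get_param(q, entry.path).mean = value
    return q


def run_owsa(p: ParameterSet,
             entries: Optional[list[OwsaEntry]] = None) -> pd.DataFrame:
    """One-way tornado table: ICER at each parameter's low and high value
    with everything else at base, sorted by ICER span."""
    entries = entries if entries is not None else default_owsa_entries(p)
    base = run_base_case(p)
    rows = []
    for entry in entries:
        icers = {}
        skip = False
        for side, value in (("low", entry.low), ("high", entry.high)):
            try:
                res = run_base_case(_with_override(p, entry, value))
            except (ValueError, FloatingPointError) as exc:
                log.warning("OWSA entry %r %s=%r skipped: %s",
                            entry.name, side, value, exc)
                skip = True
                break
            icers[side] = res.icer if res.icer is not None else np.nan
        if skip:
            continue
        rows.append({"parameter": entry.name, "low_value": entry.low,
                     "high_value": entry.high, "icer_low": icers["low"],
                     "icer_high": icers["high"],
                     "icer_base": base.icer,
                     "span": abs(icers["high"] - icers["low"])})
    return pd.DataFrame(rows).sort_values(
        "span", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# hyperkalaemia incidence sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Incremental (cost, QALY, LY) vs the zero-incidence reference, per
    severity category and annual event rate."""

    rates: np.ndarray
    table: pd.DataFrame   # columns: category, rate, d_cost, d_qaly, d_ly

    def loss(self, category: str, rate: float, what: str = "qaly") -> float:
        """Loss (reference minus swept) for one cell; positive = worse."""
        t = self.table
        row = t[(t.category == category) & (np.isclose(t.rate, rate))]
        return float(-row[f"d_{what}"].iloc[0])

    def gain(self, category: str, rate: float, what: str = "cost") -> float:
        return -self.loss(category, rate, what)


_SWEEP_CATEGORIES = ("k_5_55", "k_55_6", "k_gt6")


def _sweep_config(p: ParameterSet, category: Optional[str],
                  monthly_prob: float) -> ParameterSet:
    """SoC-only configuration for the sweep: no binder effect, a cohort that
    starts normokalaemic, and a single severity category's incidence set to
    the given monthly probability in every phase (others zero)."""
    q = neutralise_treatment_effects(p)
    s = q.start
    for pr in (s.k_5_55, s.k_55_6, s.k_gt6):
        pr.mean = 0.0
    s.k_le5.mean = 1.0
    for triple in (q.hk.month1, q.hk.months2_3_patiromer, q.hk.months2_3_soc,
                   q.hk.subsequent_patiromer, q.hk.subsequent_soc):
        for name in _SWEEP_CATEGORIES:
            getattr(triple, name).mean = \
                monthly_prob if name == category else 0.0
    return q


def run_hk_sweep(p: ParameterSet,
                 rates: Optional[Sequence[float]] = None,
                 categories: Sequence[str] = _SWEEP_CATEGORIES) -> SweepResult:
    """Vary the annual hyperkalaemia rate of one severity category at a time
    over 0-0.5/year and report lifetime increments vs no incidence."""
    rates = np.asarray(rates if rates is not None
                       else np.linspace(0.0, 0.5, 11))
    ref = run_cohort("soc", _sweep_config(p, None, 0.0))
    ref_cost, ref_qaly, ref_ly = (ref.total_cost(True), ref.total_qaly(True),
                                  ref.total_ly(True))
    rows = []
    for category in categories:
        for rate in rates:
            if rate == 0.0:
                rows.append({"category": category, "rate": 0.0,
                             "d_cost": 0.0, "d_qaly": 0.0, "d_ly": 0.0})
                continue
            cfg = _sweep_config(p, category,
                                annual_rate_to_monthly_prob(float(rate)))
            res = run_cohort("soc", cfg)
            rows.append({"category": category, "rate": float(rate),
                         "d_cost": res.total_cost(True) - ref_cost,
                         "d_qaly": res.total_qaly(True) - ref_qaly,
                         "d_ly": res.total_ly(True) - ref_ly})
    return SweepResult(rates=rates, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# value of lifetime optimal RAASi management
# ---------------------------------------------------------------------------

@dataclass
class RAASiValueResult:
    table: pd.DataFrame  # age, ckd_stage, hf, management, cost, qaly, ly

    def cell(self, age: int, stage: int, hf: bool, management: str) -> dict:
        t = self.table
        row = t[(t.age == age) & (t.ckd_stage == stage) & (t.hf == hf)
                & (t.management == management)]
        return row.iloc[0].to_dict()

    def qaly_gain(self, age: int, stage: int, hf: bool) -> float:
        return (self.cell(age, stage, hf, "optimal")["qaly"]
                - self.cell(age, stage, hf, "none")["qaly"])


def run_raasi_value(p: ParameterSet,
                    ages: Sequence[int] = (40, 50, 60, 70),
                    stages: Sequence[int] = (3, 4, 5),
                    hf_status: Sequence[bool] = (False, True)
                    ) -> RAASiValueResult:
    """48-cell grid of lifetime discounted cost and QALYs for hypothetical
    cohorts under lifelong optimal RAASi use vs never using RAASi, without
    binder treatment, across baseline age, starting CKD stage and HF status.
    The age-dependent ESRD inputs are active throughout."""
    rows = []
    for age in ages:
        for stage in stages:
            for hf in hf_status:
                q = neutralise_treatment_effects(p)
                q.demographics.age_years.mean = float(age)
                s = q.start
                s.ckd3.mean, s.ckd4.mean, s.ckd5.mean = (
                    float(stage == 3), float(stage == 4), float(stage == 5))
                s.hf_share.mean = 1.0 if hf else 0.0
                for management, pin in (("optimal", "max"), ("none", "none")):
                    res = run_cohort("soc", q, pin_raasi=pin)
                    rows.append({"age": age, "ckd_stage": stage, "hf": hf,
                                 "management": management,
                                 "cost": res.total_cost(True),
                                 "qaly": res.total_qaly(True),
                                 "ly": res.total_ly(True)})
    return RAASiValueResult(table=pd.DataFrame(rows))
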