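"""Monthly-cycle cohort propagation and a microsimulation validation oracle.

Within-cycle event ordering (the model's canonical convention):

1. the potassium category is re-drawn from the phase/arm incidence table
   (cycle 1 keeps the baseline categories; the month-1 incidence row is used
   for event counting only),
2. RAASi status transitions given the new category (from month 2),
3. economics accrue on the post-update occupancy (start-of-cycle convention:
   mass dying this cycle still contributes this cycle's occupancy),
4. clinical events and transitions (MACE, hospitalisation, death, CKD and
   NYHA chain moves) with modifiers from the post-update statuses,
5. end-of-cycle treatment-status updates (month-1 response split, the
   10.33%/month stop, forced stop at ESRD, re-treatment) taking effect from
   the next cycle, so the month in which a patient stops is still an exposed
   month.

The microsimulation propagates individuals through exactly the same
per-cycle probabilities by Monte-Carlo sampling and provides the standard
errors used to validate the cohort engine's expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .economics import COST_CATEGORIES, cycle_economics, discount_factor
from .parameters import ParameterSet
from .potassium import hk_category_distribution, hk_incidence, \
    raasi_transition_matrix
from .progression import (ckd_transition_matrix, death_prob_grids,
                          event_prob_grids, nyha_transition_matrix)
from .states import (N_TX_INTERNAL, TX_OFF_ELIGIBLE, TX_OFF_INELIGIBLE, TX_ON,
                     CohortVector, RAASiStatus, build_initial_cohort)
from .treatment import apply_end_of_cycle_treatment_updates

Arm = Literal["patiromer", "soc"]

EVENT_KINDS = ("hk_5_55", "hk_55_6", "hk_gt6", "mace", "hospitalisation",
               "raasi_discontinuation", "raasi_down_titration", "raasi_return",
               "dialysis_entry", "transplant_entry", "death")


@dataclass
class TrajectoryResult:
    """Per-cycle accumulators for one arm."""

    arm: str
    ages: np.ndarray                      # age at cycle start
    alive: np.ndarray                     # alive mass during each cycle
    dead: np.ndarray                      # dead mass at cycle start
    on_treatment: np.ndarray              # exposed mass during each cycle
    ckd_occupancy: np.ndarray             # (n_cycles, 5) CKD-state marginal
    events: dict[str, np.ndarray]         # expected events per cycle
    cost_undisc: dict[str, np.ndarray]    # per category, per cycle
    cost_disc: dict[str, np.ndarray]
    ly_undisc: np.ndarray
    ly_disc: np.ndarray
    qaly_undisc: np.ndarray
    qaly_disc: np.ndarray
    #: microsimulation only: per-individual lifetime totals for SE estimation
    individual: Optional[dict[str, np.ndarray]] = None

    @property
    def n_cycles(self) -> int:
        return len(self.alive)

    def total_cost(self, discounted: bool = True) -> float:
        ledger = self.cost_disc if discounted else self.cost_undisc
        return float(sum(v.sum() for v in ledger.values()))

    def cost_by_category(self, discounted: bool = True) -> dict[str, float]:
        ledger = self.cost_disc if discounted else self.cost_undisc
        return {k: float(v.sum()) for k, v in ledger.items()}

    def total_ly(self, discounted: bool = True) -> float:
        return float((self.ly_disc if discounted else self.ly_undisc).sum())

    def total_qaly(self, discounted: bool = True) -> float:
        return float((self.qaly_disc if discounted else self.qaly_undisc).sum())

    def total_events(self, kind: str) -> float:
        return float(self.events[kind].sum())

    def summary(self) -> dict:
        return {
            "arm": self.arm,
            "cycles": self.n_cycles,
            "ly_discounted": self.total_ly(True),
            "ly_undiscounted": self.total_ly(False),
            "qaly_discounted": self.total_qaly(True),
            "qaly_undiscounted": self.total_qaly(False),
            "cost_discounted": self.total_cost(True),
            "cost_undiscounted": self.total_cost(False),
            "cost_by_category_discounted": self.cost_by_category(True),
            "events": {k: self.total_events(k) for k in EVENT_KINDS},
            "mean_months_on_treatment": float(self.on_treatment.sum()),
        }

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = {"cycle": np.arange(1, self.n_cycles + 1),
                "age": self.ages, "alive": self.alive,
                "on_treatment": self.on_treatment,
                "ly_disc": self.ly_disc, "qaly_disc": self.qaly_disc}
        for k, v in self.events.items():
            rows[f"events_{k}"] = v
        for k, v in self.cost_disc.items():
            rows[f"cost_disc_{k.replace(' ', '_')}"] = v
        return pd.DataFrame(rows)


def mean_treatment_duration(a: TrajectoryResult) -> float:
    """Average months of binder exposure per entering patient."""
    return float(a.on_treatment.sum())


def events_per_1000(a: TrajectoryResult, b: TrajectoryResult,
                    kind: str) -> float:
    """Events avoided per 1,000 patients: 1000 * (events in b - events in a)."""
    if a.n_cycles != b.n_cycles and abs(a.alive[-1]) > 1e-9 \
            and abs(b.alive[-1]) > 1e-9:
        pass  # horizons may differ by the mass cutoff; totals remain comparable
    return 1000.0 * (b.total_events(kind) - a.total_events(kind))


@dataclass
class _CycleProbs:
    kdist: np.ndarray           # (2 on/off, 3 raasi, 4 K)
    raasi_mat: np.ndarray | None  # (2 on/off, 4 K, 3, 3) or None in month 1
    death_ckd: np.ndarray       # (5, 4, 3)
    death_hf: np.ndarray        # (5, 4, 4, 3)
    mace_ckd: np.ndarray
    mace_hf: np.ndarray
    hosp_ckd: np.ndarray
    hosp_hf: np.ndarray
    ckd_mat: np.ndarray         # (3 raasi, 5, 5)
    nyha_mat: np.ndarray        # (4, 4)


def _build_cycle_probs(p: ParameterSet, month: int, age: float,
                       pin_raasi: Optional[str]) -> _CycleProbs:
    kdist = np.stack([hk_category_distribution(month, False, p),
                      hk_category_distribution(month, True, p)])
    if month >= 2 and pin_raasi is None:
        rmat = np.stack([raasi_transition_matrix(month, False, p),
                         raasi_transition_matrix(month, True, p)])
    else:
        rmat = None
    dc, dh = death_prob_grids(p, age)
    mc, mh = event_prob_grids(p, age, "mace")
    hc, hh = event_prob_grids(p, age, "hospitalisation")
    return _CycleProbs(kdist=kdist, raasi_mat=rmat, death_ckd=dc, death_hf=dh,
                       mace_ckd=mc, mace_hf=mh, hosp_ckd=hc, hosp_hf=hh,
                       ckd_mat=ckd_transition_matrix(age, p),
                       nyha_mat=nyha_transition_matrix(p))


# on/off index per internal treatment layer (1 = on-patiromer columns)
_TX_EFFECTIVE = np.array([1, 0, 0])


def run_cohort(arm: Arm, p: ParameterSet,
               horizon_age: Optional[float] = None,
               pin_raasi: Optional[Literal["max", "none"]] = None,
               discount: bool = True) -> TrajectoryResult:
    """Propagate the cohort over the lifetime horizon; deterministic.

    ``pin_raasi`` freezes RAASi status for the optimal-management scenarios:
    ``"max"`` holds the whole cohort at max dose with no titration changes,
    ``"none"`` starts everyone discontinued with no return.
    """
    settings = p.settings
    horizon_age = horizon_age if horizon_age is not None else settings.horizon_age
    rate = settings.discount_rate_annual if discount else 0.0

    cohort = build_initial_cohort(p, arm=arm)
    if pin_raasi == "none":
        for arr in (cohort.ckd_only, cohort.hf):
            mass = arr[..., RAASiStatus.MAX_DOSE, :].copy()
            arr[..., RAASiStatus.MAX_DOSE, :] = 0.0
            arr[..., RAASiStatus.DISCONTINUED, :] += mass

    ages, alive, dead_mass, on_tx, ckd_occ = [], [], [], [], []
    per_cycle_events: dict[str, list] = {k: [] for k in EVENT_KINDS}
    cost_u: dict[str, list] = {c: [] for c in COST_CATEGORIES}
    cost_d: dict[str, list] = {c: [] for c in COST_CATEGORIES}
    ly_u, ly_d, qaly_u, qaly_d = [], [], [], []

    month = 0
    probs_cache: dict[tuple, _CycleProbs] = {}
    while cohort.age < horizon_age and cohort.alive_mass >= settings.min_alive_mass:
        month += 1
        # probabilities depend on month only through its phase, and on age
        # only through the completed year (life table, ESRD knots)
        key = (min(month, 4), int(np.floor(cohort.age)))
        probs = probs_cache.get(key)
        if probs is None:
            probs = _build_cycle_probs(p, month, cohort.age, pin_raasi)
            probs_cache[key] = probs
        ev = {k: 0.0 for k in EVENT_KINDS}

        # 1. potassium category draw ------------------------------------
        if month == 1:
            triple = hk_incidence(1, arm == "patiromer", p)
            a0 = cohort.alive_mass
            ev["hk_5_55"], ev["hk_55_6"], ev["hk_gt6"] = a0 * triple
        else:
            for name in ("ckd_only", "hf"):
                arr = getattr(cohort, name)
                k_ax = arr.ndim - 3
                tot = arr.sum(axis=k_ax)               # (..., r, t)
                dist = probs.kdist[_TX_EFFECTIVE]      # (t, r, K)
                new = np.einsum("...rt,trk->...krt", tot, dist)
                setattr(cohort, name, new)
                flat = tot.reshape(-1, 3, N_TX_INTERNAL)
                sev = np.einsum("xrt,trk->k", flat, dist)
                ev["hk_5_55"] += sev[1]
                ev["hk_55_6"] += sev[2]
                ev["hk_gt6"] += sev[3]

        # 2. RAASi transitions -------------------------------------------
        if probs.raasi_mat is not None:
            rmat = probs.raasi_mat[_TX_EFFECTIVE]      # (t, 4K, 3, 3)
            for name in ("ckd_only", "hf"):
                arr = getattr(cohort, name)
                flows = np.einsum("...krt,tkrs->...krst", arr, rmat)
                ev["raasi_discontinuation"] += float(
                    flows[..., 0, 2, :].sum() + flows[..., 1, 2, :].sum())
                ev["raasi_down_titration"] += float(flows[..., 0, 1, :].sum())
                ev["raasi_return"] += float(flows[..., 2, 0, :].sum())
                setattr(cohort, name, flows.sum(axis=arr.ndim - 2))

        # 3/4. clinical event expectations --------------------------------
        co, hf = cohort.ckd_only, cohort.hf
        co_occ = co.sum(axis=-1)                       # (5, 4K, 3R)
        hf_occ = hf.sum(axis=-1)                       # (5, 4N, 4K, 3R)
        ev["mace"] = float((co_occ * probs.mace_ckd).sum()
                           + (hf_occ * probs.mace_hf).sum())
        ev["hospitalisation"] = float((co_occ * probs.hosp_ckd).sum()
                                      + (hf_occ * probs.hosp_hf).sum())
        ev["death"] = float((co_occ * probs.death_ckd).sum()
                            + (hf_occ * probs.death_hf).sum())

        # economics on start-of-cycle occupancy ---------------------------
        on_mass = float(co[..., TX_ON].sum() + hf[..., TX_ON].sum())
        ledger, qaly, ly = cycle_economics(cohort, ev, p, on_mass)
        df = discount_factor(month - 1, rate)
        ages.append(cohort.age)
        alive.append(cohort.alive_mass)
        dead_mass.append(cohort.dead)
        on_tx.append(on_mass)
        ckd_occ.append(co.sum(axis=(1, 2, 3)) + hf.sum(axis=(1, 2, 3, 4)))
        for k in EVENT_KINDS:
            per_cycle_events[k].append(ev[k])
        for c in COST_CATEGORIES:
            cost_u[c].append(ledger[c])
            cost_d[c].append(ledger[c] * df)
        ly_u.append(ly)
        ly_d.append(ly * df)
        qaly_u.append(qaly)
        qaly_d.append(qaly * df)

        # 4. deaths and chain transitions ---------------------------------
        surv_co = co * (1.0 - probs.death_ckd[..., None])
        surv_hf = hf * (1.0 - probs.death_hf[..., None])
        cohort.dead += float((co * probs.death_ckd[..., None]).sum()
                             + (hf * probs.death_hf[..., None]).sum())
        ev_dial = (np.einsum("krt,r->", surv_co[2], probs.ckd_mat[:, 2, 3])
                   + np.einsum("nkrt,r->", surv_hf[2], probs.ckd_mat[:, 2, 3]))
        ev_tx = 0.0
        for c_from in (2, 3):
            ev_tx += (np.einsum("krt,r->", surv_co[c_from],
                                probs.ckd_mat[:, c_from, 4])
                      + np.einsum("nkrt,r->", surv_hf[c_from],
                                  probs.ckd_mat[:, c_from, 4]))
        per_cycle_events["dialysis_entry"][-1] += float(ev_dial)
        per_cycle_events["transplant_entry"][-1] += float(ev_tx)
        cohort.ckd_only = np.einsum("ckrt,rcd->dkrt", surv_co, probs.ckd_mat)
        moved = np.einsum("cnkrt,rcd->dnkrt", surv_hf, probs.ckd_mat)
        cohort.hf = np.einsum("dnkrt,nm->dmkrt", moved, probs.nyha_mat)

        # 5. end-of-cycle treatment updates -------------------------------
        if arm == "patiromer":
            apply_end_of_cycle_treatment_updates(cohort, month, p)
            if month == 1:
                _apply_month1_raasi_hold(cohort, p, per_cycle_events)
        elif month == 1:
            _apply_month1_raasi_hold(cohort, p, per_cycle_events)

        if not (np.isfinite(cohort.ckd_only).all()
                and np.isfinite(cohort.hf).all()):
            raise FloatingPointError(f"non-finite occupancy at cycle {month}")
        if abs(cohort.total_mass - 1.0) > 1e-9:
            raise FloatingPointError(
                f"mass not conserved at cycle {month}: {cohort.total_mass}")
        cohort.age += 1.0 / 12.0

    result = TrajectoryResult(
        arm=arm, ages=np.array(ages), alive=np.array(alive),
        dead=np.array(dead_mass), on_treatment=np.array(on_tx),
        ckd_occupancy=np.array(ckd_occ),
        events={k: np.array(v) for k, v in per_cycle_events.items()},
        cost_undisc={c: np.array(v) for c, v in cost_u.items()},
        cost_disc={c: np.array(v) for c, v in cost_d.items()},
        ly_undisc=np.array(ly_u), ly_disc=np.array(ly_d),
        qaly_undisc=np.array(qaly_u), qaly_disc=np.array(qaly_d))
    if settings.half_cycle_correction and result.n_cycles:
        _half_cycle_adjust(result)
    return result


def _apply_month1_raasi_hold(cohort: CohortVector, p: ParameterSet,
                             per_cycle_events: dict) -> None:
    """End-of-month-1 adjustment for the proportion still on RAASi.

    RAASi is held fixed during month 1; any shortfall from full persistence
    (the reference fixture uses a neutral 1.0) moves max-dose mass to
    discontinued at the month boundary. Treated responders use the
    patiromer-arm proportion, everyone else the SoC proportion.
    """
    p_on = {True: p.raasi.month1_on_raasi_patiromer.mean,
            False: p.raasi.month1_on_raasi_soc.mean}
    if p_on[True] == 1.0 and p_on[False] == 1.0:
        return
    moved = 0.0
    for arr in (cohort.ckd_only, cohort.hf):
        for t in range(N_TX_INTERNAL):
            frac = 1.0 - p_on[t == TX_ON]
            if frac <= 0:
                continue
            flow = frac * arr[..., RAASiStatus.MAX_DOSE, t].copy()
            arr[..., RAASiStatus.MAX_DOSE, t] -= flow
            arr[..., RAASiStatus.DISCONTINUED, t] += flow
            moved += float(flow.sum())
    per_cycle_events["raasi_discontinuation"][-1] += moved


def _half_cycle_adjust(result: TrajectoryResult) -> None:
    """Telescoped trapezoid correction on occupancy-based streams (life
    years, QALYs and per-state/per-month costs); event-driven costs are not
    corrected. Residual occupancy at the horizon contributes nothing."""
    for stream in (result.ly_undisc, result.ly_disc,
                   result.qaly_undisc, result.qaly_disc):
        stream[0] *= 0.5
    for ledger in (result.cost_undisc, result.cost_disc):
        for cat in ("CKD", "RRT", "treatment", "RAASi drug"):
            ledger[cat][0] *= 0.5


# ---------------------------------------------------------------------------
# microsimulation oracle
# ---------------------------------------------------------------------------

def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one category per row of a (n, k) probability matrix."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])
    return (cum < u[:, None]).sum(axis=1).clip(0, prob_rows.shape[1] - 1)


def run_microsimulation(arm: Arm, p: ParameterSet, n_individuals: int,
                        seed: int, horizon_age: Optional[float] = None,
                        pin_raasi: Optional[str] = None) -> TrajectoryResult:
    """Individual-level Monte-Carlo with the cohort engine's per-cycle
    probabilities; the independent propagation path used to validate the
    cohort expectations. Seeded and reproducible."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    settings = p.settings
    horizon_age = horizon_age if horizon_age is not None else settings.horizon_age
    rate = settings.discount_rate_annual
    n = n_individuals

    s = p.start
    has_hf = rng.random(n) < s.hf_share.mean
    ckd = _sample_rows(np.tile(np.array([s.ckd3.mean, s.ckd4.mean,
                                         s.ckd5.mean, 0.0, 0.0]), (n, 1)), rng)
    nyha = _sample_rows(np.tile(np.array([s.nyha1.mean, s.nyha2.mean,
                                          s.nyha3.mean, s.nyha4.mean]),
                                (n, 1)), rng)
    nyha = np.where(has_hf, nyha, 0)
    k = _sample_rows(np.tile(np.array([s.k_le5.mean, s.k_5_55.mean,
                                       s.k_55_6.mean, s.k_gt6.mean]),
                             (n, 1)), rng)
    raasi = np.full(n, int(RAASiStatus.MAX_DOSE))
    if pin_raasi == "none":
        raasi[:] = int(RAASiStatus.DISCONTINUED)
    tx = np.full(n, TX_ON if arm == "patiromer" else TX_OFF_INELIGIBLE)
    alive_idx = np.arange(n)
    age = p.demographics.age_years.mean

    ind = {"ly": np.zeros(n), "qaly": np.zeros(n), "cost": np.zeros(n),
           "on_months": np.zeros(n)}
    for kind in EVENT_KINDS:
        ind[kind] = np.zeros(n)

    ages, alive_mass, dead_c, on_mass_c, ckd_occ_c = [], [], [], [], []
    per_cycle_events: dict[str, list] = {kk: [] for kk in EVENT_KINDS}
    cost_u = {c: [] for c in COST_CATEGORIES}
    cost_d = {c: [] for c in COST_CATEGORIES}
    ly_u, ly_d, qaly_u, qaly_d = [], [], [], []

    u_state = _utility_lookup(p)
    c_state = _state_cost_lookup(p)
    hk_cost = p.costs.hk_event.means()
    hk_dis = p.utilities.disutility_hk.means()
    raasi_cost = np.array([p.costs.raasi_monthly_max.mean,
                           p.costs.raasi_monthly_submax.mean, 0.0])

    month = 0
    while age < horizon_age and alive_idx.size >= 1 \
            and alive_idx.size / n >= settings.min_alive_mass:
        month += 1
        probs = _build_cycle_probs(p, month, age, pin_raasi)
        m = alive_idx.size
        on = (tx == TX_ON).astype(int)
        ev = {kk: np.zeros(m) for kk in EVENT_KINDS}

        # 1. potassium ---------------------------------------------------
        if month == 1:
            triple = hk_incidence(1, arm == "patiromer", p)
            dist = np.concatenate([[1.0 - triple.sum()], triple])
            hk_draw = _sample_rows(np.tile(dist, (m, 1)), rng)
            for sidx, kind in ((1, "hk_5_55"), (2, "hk_55_6"), (3, "hk_gt6")):
                ev[kind] = (hk_draw == sidx).astype(float)
            hk_event_sev = hk_draw  # 0 = none
        else:
            rows = probs.kdist[_TX_EFFECTIVE[tx], raasi]     # (m, 4)
            k = _sample_rows(rows, rng)
            for sidx, kind in ((1, "hk_5_55"), (2, "hk_55_6"), (3, "hk_gt6")):
                ev[kind] = (k == sidx).astype(float)
            hk_event_sev = k

        # 2. RAASi -------------------------------------------------------
        if probs.raasi_mat is not None:
            rows = probs.raasi_mat[_TX_EFFECTIVE[tx], k, raasi]  # (m, 3)
            new_r = _sample_rows(rows, rng)
            ev["raasi_discontinuation"] = ((raasi <= 1) & (new_r == 2)) * 1.0
            ev["raasi_down_titration"] = ((raasi == 0) & (new_r == 1)) * 1.0
            ev["raasi_return"] = ((raasi == 2) & (new_r == 0)) * 1.0
            raasi = new_r

        # clinical event draws -------------------------------------------
        d_prob = np.where(has_hf[alive_idx],
                          probs.death_hf[ckd, nyha, k, raasi],
                          probs.death_ckd[ckd, k, raasi])
        mace_p = np.where(has_hf[alive_idx],
                          probs.mace_hf[ckd, nyha, k, raasi],
                          probs.mace_ckd[ckd, k, raasi])
        hosp_p = np.where(has_hf[alive_idx],
                          probs.hosp_hf[ckd, nyha, k, raasi],
                          probs.hosp_ckd[ckd, k, raasi])
        ev["mace"] = (rng.random(m) < mace_p).astype(float)
        ev["hospitalisation"] = (rng.random(m) < hosp_p).astype(float)
        died = rng.random(m) < d_prob
        ev["death"] = died.astype(float)

        # 3. economics on start-of-cycle occupancy -------------------------
        df = discount_factor(month - 1, rate)
        util = np.where(has_hf[alive_idx],
                        np.minimum(u_state["ckd"][ckd], u_state["nyha"][nyha]),
                        u_state["ckd"][ckd])
        state_cost = c_state["ckd"][ckd] \
            + np.where(has_hf[alive_idx], c_state["nyha"][nyha], 0.0)
        event_cost = (hk_cost[np.maximum(hk_event_sev - 1, 0)]
                      * (hk_event_sev > 0)
                      + ev["mace"] * p.costs.mace_event.mean
                      + ev["hospitalisation"] * p.costs.hospitalisation_event.mean
                      + (ev["raasi_discontinuation"] + ev["raasi_down_titration"]
                         + ev["raasi_return"]) * p.costs.raasi_titration_event.mean)
        drug_cost = on * p.treatment.monthly_drug_cost.mean + raasi_cost[raasi]
        total_cost = state_cost + event_cost + drug_cost
        disutil = (hk_dis[np.maximum(hk_event_sev - 1, 0)] * (hk_event_sev > 0)
                   + ev["mace"] * p.utilities.disutility_mace.mean
                   + ev["hospitalisation"]
                   * p.utilities.disutility_hospitalisation.mean)
        cyc_qaly = util / 12.0 - disutil

        ind["ly"][alive_idx] += df / 12.0
        ind["qaly"][alive_idx] += df * cyc_qaly
        ind["cost"][alive_idx] += df * total_cost
        ind["on_months"][alive_idx] += on
        for kind in EVENT_KINDS:
            ind[kind][alive_idx] += ev[kind]

        ages.append(age)
        alive_mass.append(m / n)
        dead_c.append(1.0 - m / n)
        on_mass_c.append(on.sum() / n)
        ckd_occ_c.append(np.bincount(ckd, minlength=5) / n)
        for kind in EVENT_KINDS:
            per_cycle_events[kind].append(ev[kind].sum() / n)
        ledger_u = _microsim_ledger(state_cost, event_cost, on, raasi, ckd,
                                    nyha, has_hf[alive_idx], ev, p,
                                    hk_event_sev)
        for c in COST_CATEGORIES:
            cost_u[c].append(ledger_u[c] / n)
            cost_d[c].append(ledger_u[c] * df / n)
        ly_u.append(m / n / 12.0)
        ly_d.append(df * m / n / 12.0)
        qaly_u.append(cyc_qaly.sum() / n)
        qaly_d.append(df * cyc_qaly.sum() / n)

        # 4. chain transitions for survivors -------------------------------
        surv = ~died
        rows_ckd = probs.ckd_mat[raasi, ckd]                  # (m, 5)
        new_ckd = _sample_rows(rows_ckd, rng)
        dial_in = surv & (ckd != 3) & (new_ckd == 3)
        tx_in = surv & (ckd != 4) & (new_ckd == 4)
        ind["dialysis_entry"][alive_idx[dial_in]] += 1
        ind["transplant_entry"][alive_idx[tx_in]] += 1
        per_cycle_events["dialysis_entry"][-1] += dial_in.sum() / n
        per_cycle_events["transplant_entry"][-1] += tx_in.sum() / n
        ckd = new_ckd
        hf_mask = has_hf[alive_idx]
        if hf_mask.any():
            new_nyha = _sample_rows(probs.nyha_mat[nyha], rng)
            nyha = np.where(hf_mask, new_nyha, nyha)

        # 5. end-of-cycle treatment updates --------------------------------
        if arm == "patiromer":
            if month == 1:
                responders = rng.random(m) < p.treatment.response.mean
                tx = np.where((tx == TX_ON) & ~responders,
                              TX_OFF_INELIGIBLE, tx)
            else:
                stop = rng.random(m) < p.treatment.monthly_discontinuation.mean
                was_on = tx == TX_ON
                esrd = ckd >= 3
                tx = np.where(was_on & esrd, TX_OFF_INELIGIBLE, tx)
                tx = np.where(was_on & ~esrd & stop, TX_OFF_ELIGIBLE, tx)
                if month >= p.treatment.retrigger_start_month:
                    retrig = (tx == TX_OFF_ELIGIBLE) & ~esrd \
                        & (k >= p.treatment.retrigger_category)
                    tx = np.where(retrig, TX_ON, tx)

        # compact to survivors
        alive_idx = alive_idx[surv]
        ckd, nyha, k, raasi, tx = (a[surv] for a in (ckd, nyha, k, raasi, tx))
        age += 1.0 / 12.0

    return TrajectoryResult(
        arm=arm, ages=np.array(ages), alive=np.array(alive_mass),
        dead=np.array(dead_c), on_treatment=np.array(on_mass_c),
        ckd_occupancy=np.array(ckd_occ_c),
        events={kk: np.array(v) for kk, v in per_cycle_events.items()},
        cost_undisc={c: np.array(v) for c, v in cost_u.items()},
        cost_disc={c: np.array(v) for c, v in cost_d.items()},
        ly_undisc=np.array(ly_u), ly_disc=np.array(ly_d),
        qaly_undisc=np.array(qaly_u), qaly_disc=np.array(qaly_d),
        individual=ind)


def _utility_lookup(p: ParameterSet) -> dict[str, np.ndarray]:
    u = p.utilities.state
    return {"ckd": np.array([u["ckd3"].mean, u["ckd4"].mean, u["ckd5"].mean,
                             u["dialysis"].mean, u["transplant"].mean]),
            "nyha": np.array([u["nyha1"].mean, u["nyha2"].mean,
                              u["nyha3"].mean, u["nyha4"].mean])}


def _state_cost_lookup(p: ParameterSet) -> dict[str, np.ndarray]:
    c = p.costs.state_monthly
    return {"ckd": np.array([c["ckd3"].mean, c["ckd4"].mean, c["ckd5"].mean,
                             c["dialysis"].mean, c["transplant"].mean]),
            "nyha": np.array([c["nyha1"].mean, c["nyha2"].mean,
                              c["nyha3"].mean, c["nyha4"].mean])}


def _microsim_ledger(state_cost, event_cost, on, raasi, ckd, nyha, hf_mask,
                     ev, p: ParameterSet, hk_sev) -> dict[str, float]:
    c_state = _state_cost_lookup(p)
    hk_cost = p.costs.hk_event.means()
    raasi_cost = np.array([p.costs.raasi_monthly_max.mean,
                           p.costs.raasi_monthly_submax.mean, 0.0])
    ckd_mgmt = np.where(ckd < 3, c_state["ckd"][ckd], 0.0) \
        + np.where(hf_mask, c_state["nyha"][nyha], 0.0)
    rrt = np.where(ckd >= 3, c_state["ckd"][ckd], 0.0)
    return {
        "treatment": float((on * p.treatment.monthly_drug_cost.mean).sum()),
        "HK": float((hk_cost[np.maximum(hk_sev - 1, 0)] * (hk_sev > 0)).sum()),
        "CKD": float(ckd_mgmt.sum()),
        "RRT": float(rrt.sum()),
        "MACE": float(ev["mace"].sum() * p.costs.mace_event.mean),
        "hospitalisation": float(ev["hospitalisation"].sum()
                                 * p.costs.hospitalisation_event.mean),
        "RAASi drug": float(raasi_cost[raasi].sum()),
        "RAASi titration": float(
            (ev["raasi_discontinuation"] + ev["raasi_down_titration"]
             + ev["raasi_return"]).sum() * p.costs.raasi_titration_event.mean),
    }
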