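"""Clinical progression: CKD/NYHA chains, ESRD, events and mortality.

Modifiers (hazard ratios for RAASi status and potassium category) are applied
on the rate scale, ``p' = 1 - (1 - p)**hr``, the standard mapping consistent
with ratios estimated on rates rather than probabilities. For the CKD+HF
subcohort, MACE, hospitalisation and mortality are estimated separately from
the CKD and HF chains and the higher of the two probabilities is applied.
Background mortality acts as a floor: whenever the (sex-blended, monthly)
life-table probability exceeds the modelled disease-based probability, the
life-table value is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import LifeTable, ParameterSet
from .states import CKDState, RAASiStatus


def apply_modifier(base_prob: float | np.ndarray,
                   modifier: float | np.ndarray) -> float | np.ndarray:
    """Rate-scale hazard-ratio application: 1 - (1 - p)^hr."""
    return 1.0 - (1.0 - base_prob) ** modifier


def combined_event_prob(ckd_prob: float | np.ndarray,
                        hf_prob: float | np.ndarray) -> float | np.ndarray:
    """The higher of the two single-disease probabilities (CKD+HF rule)."""
    return np.maximum(ckd_prob, hf_prob)


@dataclass(frozen=True)
class EsrdBlock:
    transplant_from_ckd5: float
    transplant_from_dialysis: float
    death_on_dialysis: float
    death_with_transplant: float


def esrd_params_for_age(age: float, p: ParameterSet) -> EsrdBlock:
    """Age-dependent ESRD inputs via the configured age rule.

    Default is a step function holding the value from the nearest knot at or
    below the current age (clamped to the table span); linear interpolation
    between knots is available via ``esrd.rule = "linear"``.
    """
    knots = np.asarray(p.esrd.knots, dtype=float)

    def at(row) -> float:
        vals = row.means()
        if p.esrd.rule == "linear":
            return float(np.interp(age, knots, vals))
        i = int(np.searchsorted(knots, age, side="right") - 1)
        return float(vals[int(np.clip(i, 0, len(knots) - 1))])

    return EsrdBlock(
        transplant_from_ckd5=at(p.esrd.transplant_from_ckd5),
        transplant_from_dialysis=at(p.esrd.transplant_from_dialysis),
        death_on_dialysis=at(p.esrd.death_on_dialysis),
        death_with_transplant=at(p.esrd.death_with_transplant))


def raasi_progression_modifiers(p: ParameterSet) -> np.ndarray:
    """CKD-progression hazard ratio per RAASi status (max dose = 1)."""
    m = p.modifiers.raasi.ckd_progression
    return np.array([1.0, m["submax"].mean, m["discontinued"].mean])


def ckd_transition_matrix(age: float, p: ParameterSet) -> np.ndarray:
    """Monthly CKD-chain transition matrix, shape (3 raasi, 5, 5).

    Rows are conditional on surviving the cycle; death is handled separately
    so every row sums to 1. Progression is forward-only; transplant does not
    fail back to dialysis.
    """
    esrd = esrd_params_for_age(age, p)
    hrs = raasi_progression_modifiers(p)
    mat = np.zeros((3, 5, 5))
    for r, hr in enumerate(hrs):
        p34 = apply_modifier(p.ckd.prog_3_to_4.mean, hr)
        p45 = apply_modifier(p.ckd.prog_4_to_5.mean, hr)
        p5d = apply_modifier(p.ckd.prog_5_to_dialysis.mean, hr)
        m = mat[r]
        m[CKDState.CKD3, CKDState.CKD4] = p34
        m[CKDState.CKD3, CKDState.CKD3] = 1.0 - p34
        m[CKDState.CKD4, CKDState.CKD5] = p45
        m[CKDState.CKD4, CKDState.CKD4] = 1.0 - p45
        m[CKDState.CKD5, CKDState.DIALYSIS] = p5d
        m[CKDState.CKD5, CKDState.TRANSPLANT] = esrd.transplant_from_ckd5
        leave = p5d + esrd.transplant_from_ckd5
        if leave > 1.0:
            raise ValueError(
                f"CKD5 exit probabilities sum to {leave:.4f} > 1 "
                f"(raasi status {RAASiStatus(r).name}); inconsistent config")
        m[CKDState.CKD5, CKDState.CKD5] = 1.0 - leave
        m[CKDState.DIALYSIS, CKDState.TRANSPLANT] = esrd.transplant_from_dialysis
        m[CKDState.DIALYSIS, CKDState.DIALYSIS] = \
            1.0 - esrd.transplant_from_dialysis
        m[CKDState.TRANSPLANT, CKDState.TRANSPLANT] = 1.0
    return mat


def ckd_transition_probs(state: CKDState, age: float, raasi: RAASiStatus,
                         p: ParameterSet) -> np.ndarray:
    """Distribution over the next CKD state for one (state, age, RAASi) cell."""
    return ckd_transition_matrix(age, p)[int(raasi), int(state)]


def nyha_transition_matrix(p: ParameterSet) -> np.ndarray:
    """Monthly NYHA transition matrix (4x4), conditional on survival."""
    w = p.hf.worsen
    i = p.hf.improve
    m = np.zeros((4, 4))
    m[0, 1] = w["nyha1"].mean
    m[1, 2] = w["nyha2"].mean
    m[2, 3] = w["nyha3"].mean
    m[1, 0] = i["nyha2"].mean
    m[2, 1] = i["nyha3"].mean
    m[3, 2] = i["nyha4"].mean
    for row in range(4):
        stay = 1.0 - m[row].sum()
        if stay < 0:
            raise ValueError(f"NYHA row {row} exit probabilities exceed 1")
        m[row, row] = stay
    return m


def _modifier_grids(p: ParameterSet, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """(K HR vector len 4, RAASi HR vector len 3) for one outcome."""
    km = p.modifiers.potassium
    rm = p.modifiers.raasi
    kd = getattr(km, outcome)
    rd = getattr(rm, outcome)
    k = np.array([1.0, kd["k_5_55"].mean, kd["k_55_6"].mean, kd["k_gt6"].mean])
    r = np.array([1.0, rd["submax"].mean, rd["discontinued"].mean])
    return k, r


def event_prob_grids(p: ParameterSet, age: float,
                     outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """Monthly event probabilities for MACE or hospitalisation.

    Returns ``(ckd_only, hf)`` grids of shape (5, 4, 3) and (5, 4, 4, 3):
    CKD x [NYHA] x K x RAASi, with the CKD+HF grid using the higher of the
    CKD-based and NYHA-based baselines before modifiers.
    """
    cb = getattr(p.ckd, outcome)
    hb = getattr(p.hf, outcome)
    base_ckd = np.array([cb["ckd3"].mean, cb["ckd4"].mean, cb["ckd5"].mean,
                         cb["dialysis"].mean, cb["transplant"].mean])
    base_hf = np.array([hb["nyha1"].mean, hb["nyha2"].mean, hb["nyha3"].mean,
                        hb["nyha4"].mean])
    k_hr, r_hr = _modifier_grids(p, outcome)
    hr = k_hr[:, None] * r_hr[None, :]                       # (4K, 3R)
    ckd_only = apply_modifier(base_ckd[:, None, None], hr[None, :, :])
    combined = combined_event_prob(base_ckd[:, None], base_hf[None, :])  # (5,4)
    hf = apply_modifier(combined[:, :, None, None], hr[None, None, :, :])
    return ckd_only, hf


def death_prob_grids(p: ParameterSet, age: float,
                     life_table: LifeTable | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Monthly all-cause death probabilities, shapes (5,4,3) and (5,4,4,3).

    Disease-based mortality (CKD-state baseline, for ESRD the age-dependent
    table; NYHA baseline for the HF chain, combined by the max rule) is
    modified by potassium and RAASi hazard ratios, then floored by the
    sex-blended monthly life-table probability.
    """
    lt = life_table or p.life_table
    esrd = esrd_params_for_age(age, p)
    d = p.ckd.death
    base_ckd = np.array([d["ckd3"].mean, d["ckd4"].mean, d["ckd5"].mean,
                         esrd.death_on_dialysis, esrd.death_with_transplant])
    hb = p.hf.death
    base_hf = np.array([hb["nyha1"].mean, hb["nyha2"].mean, hb["nyha3"].mean,
                        hb["nyha4"].mean])
    k_hr, r_hr = _modifier_grids(p, "death")
    hr = k_hr[:, None] * r_hr[None, :]
    modelled_ckd = apply_modifier(base_ckd[:, None, None], hr[None, :, :])
    combined = combined_event_prob(base_ckd[:, None], base_hf[None, :])
    modelled_hf = apply_modifier(combined[:, :, None, None],
                                 hr[None, None, :, :])
    floor = lt.monthly_q(age, p.demographics.proportion_female.mean)
    return np.maximum(modelled_ckd, floor), np.maximum(modelled_hf, floor)


def mortality_prob(modelled: float, age: float, p: ParameterSet,
                   life_table: LifeTable | None = None) -> float:
    """Scalar max rule: the greater of modelled and life-table mortality."""
    lt = life_table or p.life_table
    return max(modelled,
               lt.monthly_q(age, p.demographics.proportion_female.mean))
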