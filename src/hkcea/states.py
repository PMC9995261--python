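"""Factored health-state space and initial cohort construction.

The cohort is split into two subcohorts fixed at entry: CKD-only and CKD+HF
(patients without HF at baseline never develop it). Within a subcohort the
state is the product of a CKD chain (stages 3-5, then dialysis or transplant),
for the CKD+HF subcohort an NYHA chain (I-IV), the current potassium category,
RAASi status and treatment status, with a single shared absorbing Dead state.

Axis index conventions used throughout the engine:

* CKD:   0=CKD3, 1=CKD4, 2=CKD5, 3=Dialysis, 4=Transplant
* NYHA:  0=I, 1=II, 2=III, 3=IV
* K:     0=(<=5), 1=(5-5.5], 2=(5.5-6], 3=(>6) mmol/l
* RAASi: 0=MaxDose, 1=SubMaxDose, 2=Discontinued
* Tx:    public: 0=OnPatiromerResponder, 1=OffTreatment.
         The engine refines OffTreatment into a retrigger-eligible layer
         (stopped via the monthly discontinuation rate) and an ineligible
         layer (month-1 non-responders, post-ESRD stoppers); only the former
         may restart treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from itertools import product

import numpy as np
import pandas as pd

from .parameters import ParameterSet


class CKDState(IntEnum):
    CKD3 = 0
    CKD4 = 1
    CKD5 = 2
    DIALYSIS = 3
    TRANSPLANT = 4


class HFState(IntEnum):
    NYHA_I = 0
    NYHA_II = 1
    NYHA_III = 2
    NYHA_IV = 3


class PotassiumCategory(IntEnum):
    K_LE5 = 0
    K_5_55 = 1
    K_55_6 = 2
    K_GT6 = 3


class RAASiStatus(IntEnum):
    MAX_DOSE = 0
    SUBMAX_DOSE = 1
    DISCONTINUED = 2


class TreatmentStatus(IntEnum):
    ON_PATIROMER_RESPONDER = 0
    OFF_TREATMENT = 1


# internal treatment layers (engine refinement of the public 2-level status)
TX_ON = 0
TX_OFF_ELIGIBLE = 1     # stopped at 10.33%/month; may re-trigger
TX_OFF_INELIGIBLE = 2   # non-responder or stopped at ESRD; never re-triggers
N_TX_INTERNAL = 3

ESRD_STATES = (CKDState.DIALYSIS, CKDState.TRANSPLANT)

K_PERSISTENT = -1  # sentinel: cycle keeps the incoming potassium distribution


def enumerate_states(has_hf: bool) -> list[tuple]:
    """Deterministic ordered list of public model states.

    Alive states are the product CKD x [NYHA] x K x RAASi x Tx in the
    documented axis order (Dead collapsed to a single trailing state):
    5*4*3*2 + 1 = 121 states for the CKD-only subcohort, 5*4*4*3*2 + 1 = 481
    with the NYHA axis.
    """
    axes = [list(CKDState)]
    if has_hf:
        axes.append(list(HFState))
    axes += [list(PotassiumCategory), list(RAASiStatus), list(TreatmentStatus)]
    states: list[tuple] = [combo for combo in product(*axes)]
    states.append(("DEAD",))
    return states


def state_manifest(has_hf: bool) -> pd.DataFrame:
    """State-space manifest (state id + factor levels) for audit export."""
    rows = []
    for i, s in enumerate(enumerate_states(has_hf)):
        if s == ("DEAD",):
            rows.append({"state_id": i, "ckd": "DEAD"})
            continue
        row = {"state_id": i, "ckd": s[0].name}
        j = 1
        if has_hf:
            row["nyha"] = s[j].name
            j += 1
        row["potassium"] = s[j].name
        row["raasi"] = s[j + 1].name
        row["treatment"] = s[j + 2].name
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortVector:
    """Occupancy mass over the factored space at one cycle.

    ``ckd_only`` has shape (5, 4, 3, 3): CKD x K x RAASi x internal Tx layer.
    ``hf`` has shape (5, 4, 4, 3, 3): CKD x NYHA x K x RAASi x Tx layer.
    Total mass (dead included) is 1 at every cycle.
    """

    ckd_only: np.ndarray
    hf: np.ndarray
    dead: float
    age: float

    @property
    def alive_mass(self) -> float:
        return float(self.ckd_only.sum() + self.hf.sum())

    @property
    def total_mass(self) -> float:
        return self.alive_mass + self.dead

    def copy(self) -> "CohortVector":
        return CohortVector(self.ckd_only.copy(), self.hf.copy(),
                            self.dead, self.age)


def build_initial_cohort(p: ParameterSet, arm: str = "patiromer") -> CohortVector:
    """Initial cohort from the starting marginal distributions.

    The joint distribution is the product of the published marginals
    (CKD stage, NYHA class and potassium category independent at entry).
    Everyone starts on max-dose RAASi; in the treatment arm everyone starts
    on patiromer pending the month-1 response split, in the SoC arm nobody
    ever receives it.
    """
    if arm not in ("patiromer", "soc"):
        raise ValueError(f"unknown arm {arm!r}")
    s = p.start
    ckd = np.array([s.ckd3.mean, s.ckd4.mean, s.ckd5.mean, 0.0, 0.0])
    nyha = np.array([s.nyha1.mean, s.nyha2.mean, s.nyha3.mean, s.nyha4.mean])
    k = np.array([s.k_le5.mean, s.k_5_55.mean, s.k_55_6.mean, s.k_gt6.mean])
    for name, dist in (("ckd", ckd), ("nyha", nyha), ("potassium", k)):
        if abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError(f"starting {name} distribution sums to {dist.sum()}")

    hf_share = s.hf_share.mean
    tx_layer = TX_ON if arm == "patiromer" else TX_OFF_INELIGIBLE

    ckd_only = np.zeros((5, 4, 3, N_TX_INTERNAL))
    ckd_only[:, :, RAASiStatus.MAX_DOSE, tx_layer] = \
        (1.0 - hf_share) * np.outer(ckd, k)
    hf = np.zeros((5, 4, 4, 3, N_TX_INTERNAL))
    hf[:, :, :, RAASiStatus.MAX_DOSE, tx_layer] = \
        hf_share * np.einsum("c,n,k->cnk", ckd, nyha, k)

    return CohortVector(ckd_only=ckd_only, hf=hf, dead=0.0,
                        age=p.demographics.age_years.mean)
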