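"""Patiromer exposure dynamics.

All treatment-arm patients receive the binder for at least one month. At the
end of month 1 the on-treatment mass is split into responders (60.93%), who
continue on treatment and treated-arm event rates, and non-responders, who
stop and incur SoC risks from month 2 with no legacy effect. From month 2
responders stop at a constant 10.33%/month, or with certainty on reaching
ESRD (dialysis or transplant). A patient who stopped via the monthly
discontinuation rate restarts treatment if a later cycle's potassium category
is 5.5-6 mmol/l or worse; re-entry resumes responder event rates without a
second response split, incurs drug cost again, and is uncapped in episode
count. Status changes take effect from the next cycle: the month in which a
patient stops still counts as an exposed (and costed) month, which is what
makes mean exposure with re-treatment disabled equal the geometric closed
form response*(1 + 1/discontinuation) + (1-response)*1.
"""

from __future__ import annotations

from .parameters import ParameterSet
from .states import (ESRD_STATES, TX_OFF_ELIGIBLE, TX_OFF_INELIGIBLE, TX_ON,
                     CKDState, CohortVector, PotassiumCategory)


def resolve_month1_response(cohort: CohortVector, p: ParameterSet,
                            arm: str = "patiromer") -> CohortVector:
    """Split end-of-month-1 on-treatment mass into responders / stopped.

    Applying it to the SoC arm is an error, as is applying it twice (the
    split happens exactly once, at the end of cycle 1).
    """
    if arm != "patiromer":
        raise ValueError("month-1 response resolution applies to the "
                         "treatment arm only")
    if cohort.ckd_only[..., TX_OFF_INELIGIBLE].sum() > 0 \
            or cohort.hf[..., TX_OFF_INELIGIBLE].sum() > 0:
        raise ValueError("month-1 response already resolved for this cohort")
    out = cohort.copy()
    resp = p.treatment.response.mean
    for arr in (out.ckd_only, out.hf):
        on = arr[..., TX_ON].copy()
        arr[..., TX_ON] = resp * on
        arr[..., TX_OFF_INELIGIBLE] += (1.0 - resp) * on
    return out


def treatment_exit_prob(state: CKDState | int, month: int,
                        p: ParameterSet) -> float:
    """Monthly probability that an on-treatment responder stops this month."""
    if month < 2:
        raise ValueError("minimum exposure is one month; exits begin month 2")
    if CKDState(state) in ESRD_STATES:
        return 1.0
    return p.treatment.monthly_discontinuation.mean


def retreatment_trigger(k_cat: PotassiumCategory | int,
                        p: ParameterSet) -> bool:
    """Whether this cycle's potassium category restarts a stopped patient."""
    return int(k_cat) >= p.treatment.retrigger_category


def apply_end_of_cycle_treatment_updates(cohort: CohortVector, month: int,
                                         p: ParameterSet) -> dict[str, float]:
    """In-place end-of-cycle treatment status update for the treatment arm.

    Month 1: response split. Months >= 2: on-treatment mass in ESRD states
    stops for good; other on-treatment mass stops at the monthly rate into
    the re-trigger-eligible layer; eligible off-treatment mass whose current
    potassium category meets the re-treatment threshold (and which is not in
    ESRD) moves back on treatment. Returns the stopped/restarted flows.
    """
    flows = {"stopped": 0.0, "restarted": 0.0}
    if month == 1:
        resp = p.treatment.response.mean
        for arr in (cohort.ckd_only, cohort.hf):
            on = arr[..., TX_ON].copy()
            arr[..., TX_ON] = resp * on
            arr[..., TX_OFF_INELIGIBLE] += (1.0 - resp) * on
        flows["stopped"] = float("nan")  # non-response, not discontinuation
        return flows

    d = p.treatment.monthly_discontinuation.mean
    k0 = p.treatment.retrigger_category
    allow = (month >= p.treatment.retrigger_start_month)
    for arr in (cohort.ckd_only, cohort.hf):
        on = arr[..., TX_ON].copy()
        # forced stop at ESRD (CKD axis is axis 0 in both layouts)
        esrd = on[3:5, ...]
        arr[3:5, ..., TX_ON] = 0.0
        arr[3:5, ..., TX_OFF_INELIGIBLE] += esrd
        # voluntary stop elsewhere
        alive_on = on[:3, ...]
        arr[:3, ..., TX_ON] = (1.0 - d) * alive_on
        arr[:3, ..., TX_OFF_ELIGIBLE] += d * alive_on
        flows["stopped"] += float(d * alive_on.sum())
        if allow:
            # K axis is the one before RAASi: index -2 among leading axes
            elig = arr[..., TX_OFF_ELIGIBLE]
            k_axis = elig.ndim - 2
            sel = [slice(None)] * elig.ndim
            sel[k_axis] = slice(k0, None)
            sel[0] = slice(0, 3)  # not ESRD
            restart = elig[tuple(sel)].copy()
            elig[tuple(sel)] = 0.0
            arr[..., TX_ON][tuple(sel)] += restart
            flows["restarted"] += float(restart.sum())
        if p.treatment.retreat_nonresponders and allow:
            inel = arr[..., TX_OFF_INELIGIBLE]
            sel = [slice(None)] * inel.ndim
            sel[inel.ndim - 2] = slice(k0, None)
            sel[0] = slice(0, 3)
            restart = inel[tuple(sel)].copy()
            inel[tuple(sel)] = 0.0
            arr[..., TX_ON][tuple(sel)] += restart
            flows["restarted"] += float(restart.sum())
    return flows
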