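"""Monthly potassium-category incidence and RAASi status dynamics.

The potassium category is re-drawn every cycle from the phase- and
arm-dependent incidence table (no persistence beyond the cycle in which a
hyperkalaemia event occurs); the baseline starting categories apply to cycle
1's event-modifier logic only. Phases: month 1 (identical across arms),
months 2-3 (trial-informed, arm-specific), and subsequent months (registry
rates for SoC, binder rates for treated responders). The residual probability
is normokalaemia.

RAASi transitions begin in month 2 (month 1 holds RAASi fixed while the
month-1 response resolves). From max dose a patient may down-titrate or
discontinue; from sub-max dose only discontinue (no return to max); from
discontinued, return to optimal use at 3.51%/month regardless of potassium.
Months 2-3 rates are a single row; potassium stratification begins at
month 4. Off-treatment patients use SoC columns everywhere (no legacy
effect).
"""

from __future__ import annotations

import numpy as np

from .parameters import ParameterSet, RAASiRates, SeverityTriple
from .states import PotassiumCategory, RAASiStatus


def annual_rate_to_monthly_prob(rate: float) -> float:
    """Constant-hazard conversion of an annual event rate to a monthly
    probability: 1 - exp(-rate/12)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return float(1.0 - np.exp(-rate / 12.0))


def _phase_triple(month: int, on_patiromer: bool,
                  p: ParameterSet) -> SeverityTriple:
    if month < 1:
        raise ValueError("month indexing starts at 1")
    if month == 1:
        return p.hk.month1
    if month <= 3:
        return (p.hk.months2_3_patiromer if on_patiromer
                else p.hk.months2_3_soc)
    return (p.hk.subsequent_patiromer if on_patiromer
            else p.hk.subsequent_soc)


def hk_incidence(month: int, on_patiromer: bool,
                 p: ParameterSet) -> np.ndarray:
    """Monthly probability triple (K 5-5.5, 5.5-6, >6) for the cycle."""
    return _phase_triple(month, on_patiromer, p).means()


def hk_category_distribution(month: int, on_patiromer: bool,
                             p: ParameterSet) -> np.ndarray:
    """Per-RAASi-status distribution over the four potassium categories,
    shape (3 raasi, 4 K).

    RAASi exposure raises hyperkalaemia incidence, so the severity triple is
    scaled per RAASi status with the configured hazard ratios (rate scale)
    before assigning the residual to normokalaemia.
    """
    triple = hk_incidence(month, on_patiromer, p)
    hk_hr = p.modifiers.raasi.hk_incidence
    hrs = np.array([1.0, hk_hr["submax"].mean, hk_hr["discontinued"].mean])
    scaled = 1.0 - (1.0 - triple[None, :]) ** hrs[:, None]   # (3, 3)
    total = scaled.sum(axis=1)
    if np.any(total > 1.0):
        scaled = np.where(total[:, None] > 1.0,
                          scaled / total[:, None], scaled)
        total = np.minimum(total, 1.0)
    out = np.empty((3, 4))
    out[:, 0] = 1.0 - total
    out[:, 1:] = scaled
    return out


def _rates_for(month: int, k_cat: int, on_patiromer: bool,
               p: ParameterSet) -> RAASiRates:
    if month <= 3:
        return (p.raasi.months2_3_patiromer if on_patiromer
                else p.raasi.months2_3_soc)
    byk = (p.raasi.subsequent_patiromer if on_patiromer
           else p.raasi.subsequent_soc)
    key = ("k_le5", "k_5_55", "k_55_6", "k_gt6")[k_cat]
    return getattr(byk, key)


def raasi_transition(k_cat: PotassiumCategory | int, status: RAASiStatus | int,
                     month: int, on_patiromer: bool,
                     p: ParameterSet) -> np.ndarray:
    """Distribution over next RAASi status (Max, SubMax, Discontinued)."""
    if month < 2:
        raise ValueError("RAASi transitions begin in month 2")
    return raasi_transition_matrix(month, on_patiromer, p)[int(k_cat),
                                                           int(status)]


def raasi_transition_matrix(month: int, on_patiromer: bool,
                            p: ParameterSet) -> np.ndarray:
    """Monthly RAASi transition matrix, shape (4 K, 3 from, 3 to)."""
    if month < 2:
        raise ValueError("RAASi transitions begin in month 2")
    ret = p.raasi.return_to_optimal.mean
    out = np.zeros((4, 3, 3))
    for k in range(4):
        r = _rates_for(month, k, on_patiromer, p)
        disc = r.discontinue_from_max.mean
        down = r.down_titrate_from_max.mean
        sub = r.discontinue_from_submax.mean
        if disc + down > 1.0:
            raise ValueError(
                f"from-max RAASi probabilities sum to {disc + down:.4f} > 1 "
                f"(month {month}, K category {k})")
        m = out[k]
        m[RAASiStatus.MAX_DOSE] = [1.0 - disc - down, down, disc]
        m[RAASiStatus.SUBMAX_DOSE] = [0.0, 1.0 - sub, sub]
        m[RAASiStatus.DISCONTINUED] = [ret, 0.0, 1.0 - ret]
    return out
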