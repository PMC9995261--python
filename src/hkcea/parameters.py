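"""Model parameters: schema, loading, validation, and probabilistic sampling.

Every uncertain scalar in the model is a :class:`Param` carrying its point
estimate (``mean``), standard error (``se``), the sampling family used in
probabilistic sensitivity analysis (beta for probabilities and (dis)utilities,
gamma for costs and hazard/odds ratios, normal for demographics), and a
provenance flag distinguishing values printed in the main text of the source
evidence from placeholder values standing in for supplementary appendices.

``se = 0`` denotes a fixed (degenerate) parameter: sampling returns the mean
exactly, which is how structural zeros (e.g. the NYHA IV starting share) stay
exactly zero across all probabilistic draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

Provenance = Literal["paper-main-text", "supplementary-placeholder", "user"]
Family = Literal["beta", "gamma", "normal"]


class SamplingError(ValueError):
    """Raised when a distribution cannot be moment-matched to (mean, se)."""


class Param(BaseModel):
    """One uncertain scalar with its PSA distribution specification."""

    model_config = ConfigDict(frozen=False)

    mean: float
    se: float = 0.0
    family: Family = "beta"
    provenance: Provenance = "paper-main-text"
    #: optional truncation bounds for normal draws (e.g. a proportion)
    bounds: Optional[tuple[float, float]] = None

    def sample(self, rng: np.random.Generator, name: str = "") -> float:
        if self.se == 0.0:
            return self.mean
        m, s = self.mean, self.se
        if self.family == "beta":
            if m <= 0.0 or m >= 1.0 or s * s >= m * (1.0 - m):
                raise SamplingError(
                    f"beta moment matching infeasible for {name!r}: "
                    f"mean={m}, se={s} (requires 0<mean<1 and se^2<mean(1-mean))"
                )
            nu = m * (1.0 - m) / (s * s) - 1.0
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        if self.family == "gamma":
            if m <= 0.0:
                raise SamplingError(f"gamma requires mean>0 for {name!r}")
            shape = m * m / (s * s)
            scale = s * s / m
            return float(rng.gamma(shape, scale))
        # normal, optionally truncated by rejection
        for _ in range(10_000):
            x = float(rng.normal(m, s))
            if self.bounds is None or (self.bounds[0] <= x <= self.bounds[1]):
                return x
        raise SamplingError(f"truncated normal rejection failed for {name!r}")


def _p(mean: float, se: float = 0.0, family: Family = "beta",
       provenance: Provenance = "paper-main-text",
       bounds: Optional[tuple[float, float]] = None) -> Param:
    return Param(mean=mean, se=se, family=family, provenance=provenance,
                 bounds=bounds)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class Demographics(BaseModel):
    age_years: Param
    proportion_female: Param


class StartingDistribution(BaseModel):
    """Marginal starting shares; each block must sum to 1 (within 1e-9)."""

    hf_share: Param
    ckd3: Param
    ckd4: Param
    ckd5: Param
    nyha1: Param
    nyha2: Param
    nyha3: Param
    nyha4: Param
    k_le5: Param
    k_5_55: Param
    k_55_6: Param
    k_gt6: Param


class SeverityTriple(BaseModel):
    """Monthly probabilities for the three hyperkalaemia severity bands
    (5-5.5, 5.5-6, >6 mmol/l); the residual is normokalaemia (K <= 5)."""

    k_5_55: Param
    k_55_6: Param
    k_gt6: Param

    def means(self) -> np.ndarray:
        return np.array([self.k_5_55.mean, self.k_55_6.mean, self.k_gt6.mean])


class HKIncidence(BaseModel):
    month1: SeverityTriple              # identical across arms by construction
    months2_3_patiromer: SeverityTriple
    months2_3_soc: SeverityTriple
    subsequent_patiromer: SeverityTriple
    subsequent_soc: SeverityTriple


class RAASiRates(BaseModel):
    """Monthly probabilities of RAASi change from a given dose level."""

    discontinue_from_max: Param
    down_titrate_from_max: Param
    discontinue_from_submax: Param


class RAASiByK(BaseModel):
    k_le5: RAASiRates
    k_5_55: RAASiRates
    k_55_6: RAASiRates
    k_gt6: RAASiRates


class RAASiTransitions(BaseModel):
    months2_3_soc: RAASiRates            # single row, not K-stratified
    months2_3_patiromer: RAASiRates
    subsequent_soc: RAASiByK
    subsequent_patiromer: RAASiByK
    return_to_optimal: Param             # Discontinued -> MaxDose, any K
    #: proportion still on (max-dose) RAASi at the end of month 1, per arm;
    #: value not printed in the source main text, held as a neutral placeholder
    month1_on_raasi_soc: Param
    month1_on_raasi_patiromer: Param


class TreatmentParameters(BaseModel):
    response: Param                      # month-1 responder share
    monthly_discontinuation: Param       # from month 2, constant
    #: potassium category (index into K_le5..K_gt6) at or above which an
    #: off-treatment patient restarts the binder
    retrigger_category: int = 2          # K 5.5-6 or worse
    #: first cycle in which re-treatment may occur
    retrigger_start_month: int = 2
    #: whether month-1 non-responders are eligible for re-treatment
    retreat_nonresponders: bool = False
    monthly_drug_cost: Param = Field(
        default_factory=lambda: _p(172.50, 17.25, "gamma",
                                   "supplementary-placeholder"))


class EsrdAgeRow(BaseModel):
    """Age-knot values (ages 40/50/60/70) for one ESRD quantity."""

    age40: Param
    age50: Param
    age60: Param
    age70: Param

    def means(self) -> np.ndarray:
        return np.array([self.age40.mean, self.age50.mean,
                         self.age60.mean, self.age70.mean])


class EsrdParameters(BaseModel):
    knots: tuple[int, int, int, int] = (40, 50, 60, 70)
    rule: Literal["step", "linear"] = "step"
    transplant_from_ckd5: EsrdAgeRow
    transplant_from_dialysis: EsrdAgeRow
    death_on_dialysis: EsrdAgeRow
    death_with_transplant: EsrdAgeRow


class CKDBaselines(BaseModel):
    """Baseline monthly transition/event probabilities for the CKD chain,
    referenced to a max-dose RAASi, normokalaemic patient."""

    prog_3_to_4: Param
    prog_4_to_5: Param
    prog_5_to_dialysis: Param
    mace: dict[str, Param]               # keys ckd3..transplant
    hospitalisation: dict[str, Param]
    death: dict[str, Param]              # ckd3/ckd4/ckd5 only; ESRD uses the
    #                                      age-dependent table


class HFBaselines(BaseModel):
    """Baseline monthly NYHA transition and event probabilities."""

    worsen: dict[str, Param]             # nyha1->2, nyha2->3, nyha3->4
    improve: dict[str, Param]            # nyha2->1, nyha3->2, nyha4->3
    mace: dict[str, Param]               # keys nyha1..nyha4
    hospitalisation: dict[str, Param]
    death: dict[str, Param]


class RAASiModifiers(BaseModel):
    """Hazard ratios vs max-dose RAASi, applied on the rate scale."""

    ckd_progression: dict[str, Param]    # keys submax, discontinued
    mace: dict[str, Param]
    hospitalisation: dict[str, Param]
    death: dict[str, Param]
    hk_incidence: dict[str, Param]       # < 1: less RAASi, less hyperkalaemia


class PotassiumModifiers(BaseModel):
    """Hazard ratios vs normokalaemia (K <= 5), applied on the rate scale."""

    mace: dict[str, Param]               # keys k_5_55, k_55_6, k_gt6
    hospitalisation: dict[str, Param]
    death: dict[str, Param]


class Modifiers(BaseModel):
    raasi: RAASiModifiers
    potassium: PotassiumModifiers


class Costs(BaseModel):
    """All costs in GBP; state costs are per month, event costs per event."""

    state_monthly: dict[str, Param]      # ckd3..transplant, nyha1..nyha4
    hk_event: SeverityTriple             # 0 / 223.11 / 2933.49
    mace_event: Param
    hospitalisation_event: Param
    raasi_titration_event: Param         # per discontinuation/down/return
    raasi_monthly_max: Param
    raasi_monthly_submax: Param


class Utilities(BaseModel):
    state: dict[str, Param]              # ckd3..transplant, nyha1..nyha4
    disutility_hk: SeverityTriple        # one-off per event
    disutility_mace: Param
    disutility_hospitalisation: Param


class Settings(BaseModel):
    discount_rate_annual: float = 0.035
    horizon_age: float = 100.0
    min_alive_mass: float = 1e-4
    half_cycle_correction: bool = False


class LifeTable(BaseModel):
    """Annual all-cause mortality probabilities qx by single year of age."""

    ages: list[int]
    qx_female: list[float]
    qx_male: list[float]

    def annual_q(self, age: float, proportion_female: float) -> float:
        """Sex-blended annual probability at floor(age), clamped to the span."""
        i = int(np.clip(np.floor(age) - self.ages[0], 0, len(self.ages) - 1))
        return (proportion_female * self.qx_female[i]
                + (1.0 - proportion_female) * self.qx_male[i])

    def monthly_q(self, age: float, proportion_female: float) -> float:
        qf = self.qx_female
        qm = self.qx_male
        i = int(np.clip(np.floor(age) - self.ages[0], 0, len(self.ages) - 1))
        mf = 1.0 - (1.0 - qf[i]) ** (1.0 / 12.0)
        mm = 1.0 - (1.0 - qm[i]) ** (1.0 / 12.0)
        return proportion_female * mf + (1.0 - proportion_female) * mm

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        rows = []
        for age, qf, qm in zip(self.ages, self.qx_female, self.qx_male):
            rows.append({"age": age, "sex": "female", "qx": qf})
            rows.append({"age": age, "sex": "male", "qx": qm})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        import pandas as pd
        df = pd.read_csv(path)
        f = df[df.sex == "female"].sort_values("age")
        m = df[df.sex == "male"].sort_values("age")
        if list(f.age) != list(m.age):
            raise ValueError("life table must cover the same ages for both sexes")
        return cls(ages=[int(a) for a in f.age],
                   qx_female=list(f.qx), qx_male=list(m.qx))


class ParameterSet(BaseModel):
    """The complete model input."""

    schema_version: str = "1"
    demographics: Demographics
    start: StartingDistribution
    hk: HKIncidence
    raasi: RAASiTransitions
    treatment: TreatmentParameters
    esrd: EsrdParameters
    ckd: CKDBaselines
    hf: HFBaselines
    modifiers: Modifiers
    costs: Costs
    utilities: Utilities
    settings: Settings = Field(default_factory=Settings)
    life_table: LifeTable


# ---------------------------------------------------------------------------
# traversal, sampling, validation, I/O
# ---------------------------------------------------------------------------

def iter_params(model: BaseModel, prefix: str = "") -> Iterator[tuple[str, Param]]:
    """Yield (dotted path, Param) for every Param leaf, in declaration order.

    The order is deterministic, which makes probabilistic draws reproducible
    bit-for-bit for a given seed.
    """
    for name in type(model).model_fields:
        value = getattr(model, name)
        path = f"{prefix}{name}"
        if isinstance(value, Param):
            yield path, value
        elif isinstance(value, BaseModel):
            yield from iter_params(value, path + ".")
        elif isinstance(value, dict):
            for key in value:  # dicts keep insertion order
                item = value[key]
                if isinstance(item, Param):
                    yield f"{path}.{key}", item
                elif isinstance(item, BaseModel):
                    yield from iter_params(item, f"{path}.{key}.")


def get_param(p: ParameterSet, path: str) -> Param:
    obj = p
    parts = path.split(".")
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, dict) else getattr(obj, part)
    last = parts[-1]
    return obj[last] if isinstance(obj, dict) else getattr(obj, last)


def sample_parameters(base: ParameterSet,
                      rng: np.random.Generator) -> ParameterSet:
    """Draw one probabilistic-sensitivity-analysis realisation.

    Probabilities and (dis)utilities are drawn from moment-matched beta
    distributions, costs and hazard ratios from gamma, demographics from
    (truncated) normal. Parameters with ``se = 0`` are returned unchanged.
    Sampled marginal starting distributions are renormalised to sum to one;
    severity triples and from-max RAASi pairs are rescaled only if a draw
    pushes their sum above one.
    """
    draw = base.model_copy(deep=True)
    for path, param in iter_params(draw):
        param.mean = param.sample(rng, path)
        param.se = 0.0
    _renormalise(draw)
    return draw


def _renormalise(p: ParameterSet) -> None:
    s = p.start
    for group in ([s.ckd3, s.ckd4, s.ckd5],
                  [s.nyha1, s.nyha2, s.nyha3, s.nyha4],
                  [s.k_le5, s.k_5_55, s.k_55_6, s.k_gt6]):
        total = sum(q.mean for q in group)
        if total > 0:
            for q in group:
                q.mean /= total
    for triple in (p.hk.month1, p.hk.months2_3_patiromer, p.hk.months2_3_soc,
                   p.hk.subsequent_patiromer, p.hk.subsequent_soc):
        total = triple.k_5_55.mean + triple.k_55_6.mean + triple.k_gt6.mean
        if total > 1.0:
            for q in (triple.k_5_55, triple.k_55_6, triple.k_gt6):
                q.mean /= total
    def _cap(rates: RAASiRates) -> None:
        total = rates.discontinue_from_max.mean + rates.down_titrate_from_max.mean
        if total > 1.0:
            rates.discontinue_from_max.mean /= total
            rates.down_titrate_from_max.mean /= total
    for rates in (p.raasi.months2_3_soc, p.raasi.months2_3_patiromer):
        _cap(rates)
    for byk in (p.raasi.subsequent_soc, p.raasi.subsequent_patiromer):
        for k in ("k_le5", "k_5_55", "k_55_6", "k_gt6"):
            _cap(getattr(byk, k))


@dataclass(frozen=True)
class Violation:
    field: str
    value: float
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates {self.rule}"


def validate_parameters(p: ParameterSet) -> list[Violation]:
    """Check every type invariant; violations are returned, never raised."""
    out: list[Violation] = []

    def check(path: str, value: float, lo: float | None, hi: float | None,
              rule: str) -> None:
        if lo is not None and value < lo:
            out.append(Violation(path, value, rule))
        elif hi is not None and value > hi:
            out.append(Violation(path, value, rule))

    for path, param in iter_params(p):
        if param.se < 0:
            out.append(Violation(path + ".se", param.se, "se >= 0"))
        if param.family == "beta":
            check(path, param.mean, 0.0, 1.0, "probability/utility in [0,1]")
        elif param.family == "gamma":
            check(path, param.mean, 0.0, None, "cost/ratio >= 0")
            if param.se > 0 and param.mean <= 0:
                out.append(Violation(path, param.mean,
                                     "gamma with se>0 requires mean > 0"))

    s = p.start
    for name, group in (
            ("start.ckd", [s.ckd3, s.ckd4, s.ckd5]),
            ("start.nyha", [s.nyha1, s.nyha2, s.nyha3, s.nyha4]),
            ("start.potassium", [s.k_le5, s.k_5_55, s.k_55_6, s.k_gt6])):
        total = sum(q.mean for q in group)
        if abs(total - 1.0) > 1e-9:
            out.append(Violation(name, total, "starting distribution sums to 1"))

    for name, triple in (("hk.month1", p.hk.month1),
                         ("hk.months2_3_patiromer", p.hk.months2_3_patiromer),
                         ("hk.months2_3_soc", p.hk.months2_3_soc),
                         ("hk.subsequent_patiromer", p.hk.subsequent_patiromer),
                         ("hk.subsequent_soc", p.hk.subsequent_soc)):
        if triple.means().sum() > 1.0 + 1e-12:
            out.append(Violation(name, float(triple.means().sum()),
                                 "severity probabilities sum <= 1"))

    def check_rates(name: str, rates: RAASiRates) -> None:
        total = (rates.discontinue_from_max.mean
                 + rates.down_titrate_from_max.mean)
        if total > 1.0 + 1e-12:
            out.append(Violation(name, total, "from-max probabilities sum <= 1"))

    check_rates("raasi.months2_3_soc", p.raasi.months2_3_soc)
    check_rates("raasi.months2_3_patiromer", p.raasi.months2_3_patiromer)
    for arm, byk in (("soc", p.raasi.subsequent_soc),
                     ("patiromer", p.raasi.subsequent_patiromer)):
        for k in ("k_le5", "k_5_55", "k_55_6", "k_gt6"):
            check_rates(f"raasi.subsequent_{arm}.{k}", getattr(byk, k))

    for group, kind in ((p.modifiers.raasi.ckd_progression, "raasi"),
                        (p.modifiers.raasi.mace, "raasi"),
                        (p.modifiers.raasi.hospitalisation, "raasi"),
                        (p.modifiers.raasi.death, "raasi"),
                        (p.modifiers.raasi.hk_incidence, "raasi"),
                        (p.modifiers.potassium.mace, "potassium"),
                        (p.modifiers.potassium.hospitalisation, "potassium"),
                        (p.modifiers.potassium.death, "potassium")):
        for key, param in group.items():
            if param.mean <= 0:
                out.append(Violation(f"modifiers.{kind}.{key}", param.mean,
                                     "modifier > 0"))

    for i, q in enumerate(p.life_table.qx_female + p.life_table.qx_male):
        if not (0.0 <= q <= 1.0):
            out.append(Violation(f"life_table[{i}]", q, "qx in [0,1]"))

    return out


def save_parameters(p: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    data = p.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a configuration file (YAML or JSON).

    Blocks absent from the file are filled from the reference fixture, with
    their provenance flags preserved, so a config need only state what it
    overrides. Schema violations raise pydantic's named-field errors; value
    violations raise ``ValueError`` listing field and bound.
    """
    from .reference import make_reference_fixture

    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a mapping")
    defaults = make_reference_fixture().model_dump(mode="json")
    p = ParameterSet.model_validate(_deep_merge(defaults, data))
    violations = validate_parameters(p)
    if violations:
        raise ValueError(
            "invalid parameter file:\n" + "\n".join(str(v) for v in violations))
    return p
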