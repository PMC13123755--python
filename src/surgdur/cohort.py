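"""Seeded synthetic pediatric-urology cohort generator.

Emulates the marginal statistics of a single-center cohort of 4526 pediatric
urological surgeries (four primary procedures; durations averaging 38.6 min
with SD 24.9), the messy free-text conventions of real surgical-plan strings,
and a known ground-truth log-linear duration model so that every downstream
stage (parsing, plan normalization, text structuring, model fitting,
importance ranking) can be tested against recorded truth.

The duration model is
    log d = beta0 + beta_proc(p) + beta_bil * 1[any bilateral plan]
            + beta_extra * (n_planned - 1) + beta_exp * z_exp + eps,
eps ~ N(0, sigma_log), which makes surgery duration log-normal within strata
and the primary procedure the dominant predictor.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats
from scipy.special import ndtri

from . import catalog
from .catalog import (
    BILATERAL,
    CIRCUMCISION,
    HIGH_LIGATION,
    ORCHIDOPEXY,
    PENILE_LENGTHENING,
    PRIMARY_PROCEDURES,
    UNILATERAL,
    lateral_form,
)

__all__ = [
    "CohortSpec",
    "CaseRecord",
    "CaseTruth",
    "Cohort",
    "default_spec",
    "generate_cohort",
    "messify_plan",
    "render_narratives",
    "age_to_text",
    "write_cohort_jsonl",
    "read_cohort_jsonl",
    "write_truth_jsonl",
    "cohort_to_dataframe",
]

# ---------------------------------------------------------------------------
# Calibrated default parameters (solved numerically at build time so that the
# generator's population marginals match the emulated cohort: duration mean
# 38.6 / SD 24.9 min, age mean 5.3 / SD 3.7 y, weight mean 24.6 / SD 14.6 kg)
# ---------------------------------------------------------------------------

AGE_MU_LOG = 1.5257238883801352
AGE_SIGMA_LOG = 0.8648125893028191
AGE_MAX_YEARS = 17.0

WEIGHT_SLOPE = 2.7       # kg per year
WEIGHT_QUAD = 0.05       # kg per year^2
WEIGHT_INTERCEPT = 8.201652779456378
WEIGHT_NOISE_SD_LOG = 0.25592967784139453

DURATION_INTERCEPT = 3.077857736490454
DURATION_SIGMA_LOG = 0.3586291592766262

#: per-procedure log-duration effects relative to penile lengthening
DEFAULT_PROC_EFFECTS: dict[str, float] = {
    PENILE_LENGTHENING: 0.0,
    HIGH_LIGATION: 0.52,
    ORCHIDOPEXY: 0.90,
    CIRCUMCISION: -0.62,
}

DEFAULT_PROCEDURE_MIX: dict[str, float] = {
    PENILE_LENGTHENING: 0.457,
    HIGH_LIGATION: 0.256,
    ORCHIDOPEXY: 0.207,
    CIRCUMCISION: 0.080,
}

#: auxiliary planned procedures (canonical name, sampling weight)
AUX_PROCEDURES: tuple[tuple[str, float], ...] = (
    ("frenuloplasty", 0.18),
    ("penile nevus excision", 0.10),
    ("penile cyst excision", 0.10),
    ("penile scar excision", 0.05),
    ("meatoplasty", 0.10),
    ("scrotoplasty", 0.08),
    ("cystoscopy", 0.10),
    ("urethral dilation", 0.05),
    (lateral_form("hydrocelectomy", UNILATERAL), 0.09),
    (lateral_form("inguinal hernia repair", UNILATERAL), 0.07),
    ("penoscrotal web repair", 0.03),
    ("umbilical hernia repair", 0.03),
    ("sacrococcygeal dimple excision", 0.02),  # deliberately outside the 23-category map
)

DEFAULT_MISSINGNESS: dict[str, float] = {
    "age_text": 0.02,
    "weight": 0.02,
    "surgeon_years": 0.03,
    "surgeon_volume": 0.03,
    "prepuce": 0.15,
    "testicular": 0.20,
    "scrotal": 0.25,
    "penile": 0.20,
}


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


class AgeModel(BaseModel):
    """Truncated log-normal age distribution on [0, max_years]."""

    mu_log: float = AGE_MU_LOG
    sigma_log: float = Field(AGE_SIGMA_LOG, gt=0)
    max_years: float = Field(AGE_MAX_YEARS, gt=0)


class WeightModel(BaseModel):
    """Weight = quadratic growth curve of age times log-normal noise."""

    intercept: float = WEIGHT_INTERCEPT
    slope: float = WEIGHT_SLOPE
    quad: float = WEIGHT_QUAD
    noise_sd_log: float = Field(WEIGHT_NOISE_SD_LOG, gt=0)
    min_kg: float = 5.0
    max_kg: float = 140.0


class DurationModel(BaseModel):
    """Log-scale linear model of surgery duration (minutes)."""

    intercept: float = DURATION_INTERCEPT
    proc_effects: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PROC_EFFECTS))
    bilateral: float = 0.40
    extra_plan: float = 0.15
    experience: float = -0.08
    experience_center: float = 21.05
    experience_scale: float = 11.2868
    sigma_log: float = Field(DURATION_SIGMA_LOG, gt=0)

    @model_validator(mode="after")
    def _check_procs(self):
        missing = set(PRIMARY_PROCEDURES) - set(self.proc_effects)
        if missing:
            raise ValueError(f"proc_effects missing procedures: {sorted(missing)}")
        return self


class CohortSpec(BaseModel):
    """Full parameterization of a synthetic cohort draw."""

    n_cases: int = Field(4526, ge=1)
    seed: int = 42
    procedure_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_PROCEDURE_MIX))
    age: AgeModel = Field(default_factory=AgeModel)
    weight: WeightModel = Field(default_factory=WeightModel)
    n_surgeons: int = Field(31, ge=2)  # includes the "unknown" roster slot
    surgeon_experience_range: tuple[float, float] = (1.5, 40.6)
    surgeon_volume_range: tuple[int, int] = (2, 863)
    p_unknown_surgeon: float = Field(0.03, ge=0, le=1)
    bilateral_prob: float = Field(0.30, ge=0, le=1)
    preputioplasty_prob: float = Field(0.80, ge=0, le=1)
    aux_procedure_prob: float = Field(0.09, ge=0, le=1)
    missingness_rates: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    messiness: bool = True
    narrative_signal: bool = True
    locale: str = "en"
    duration_model: DurationModel = Field(default_factory=DurationModel)
    #: documented population marginals (mean, sd) implied by the defaults
    expected_marginals: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "duration_min": (38.6, 24.9),
            "age_years": (5.3, 3.7),
            "weight_kg": (24.6, 14.6),
        }
    )

    @field_validator("procedure_mix")
    @classmethod
    def _mix_valid(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(PRIMARY_PROCEDURES):
            raise ValueError(
                f"procedure_mix keys must be exactly {sorted(PRIMARY_PROCEDURES)}"
            )
        if any(p < 0 for p in v.values()):
            raise ValueError("procedure_mix probabilities must be nonnegative")
        if abs(sum(v.values()) - 1.0) > 1e-6:
            raise ValueError(f"procedure_mix must sum to 1, got {sum(v.values())}")
        return v

    @field_validator("missingness_rates")
    @classmethod
    def _rates_valid(cls, v: dict[str, float]) -> dict[str, float]:
        for k, r in v.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness_rates[{k!r}] must be in [0, 1], got {r}")
        return v

    @field_validator("locale")
    @classmethod
    def _locale_valid(cls, v: str) -> str:
        if v != "en":
            raise ValueError(f"unsupported locale {v!r}; only 'en' is implemented")
        return v


def default_spec(n_cases: int = 4526, seed: int = 42, **overrides) -> CohortSpec:
    """The study-conditions spec: calibrated defaults at the stated cohort size."""
    return CohortSpec(n_cases=n_cases, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Records and truth
# ---------------------------------------------------------------------------


@dataclass
class CaseRecord:
    """One surgical case as it would appear in the raw export."""

    case_id: str
    age_text: str
    weight_kg: float | None
    primary_procedure: str
    surgeon_name: str
    surgeon_years: float | None
    surgeon_volume: int | None
    diagnoses_raw: str
    plan_raw: str
    narratives: dict[str, str | None]
    note: str
    duration_min: float

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CaseRecord":
        return cls(**d)


@dataclass
class CaseTruth:
    """Generator-side ground truth for one case, for oracle tests."""

    case_id: str
    age_years: float
    canonical_plan: list[str]
    diagnoses: list[str]
    narrative_attrs: dict[str, str]
    narrative_sentences: dict[str, str]
    side: str
    latent_surgeon_years: float
    linear_predictor: float
    log_duration: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """Generated cohort plus its truth table and the spec that produced it."""

    spec: CohortSpec
    records: list[CaseRecord]
    truths: list[CaseTruth]
    surgeon_roster: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def durations(self) -> np.ndarray:
        return np.array([r.duration_min for r in self.records])


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------


def age_to_text(age_years: float) -> str:
    """Render fractional years as the EMR's "Y years M months" convention."""
    years = int(age_years)
    months = int(round((age_years - years) * 12))
    if months == 12:
        years, months = years + 1, 0
    return f"{years} years {months} months"


def messify_plan(
    canonical_list: list[str],
    seed_or_rng: int | np.random.Generator,
    messiness: bool = True,
) -> str:
    """Render a canonical plan list as a raw, delimiter-messy plan string.

    Laterality markers ("(unilateral)"/"(bilateral)") become side wording
    ("right-sided ...", "bilateral ..."); procedure names may be replaced by
    synonym variants; the items are joined by a randomly chosen delimiter
    style. With ``messiness=False`` the canonical names are joined verbatim
    by " + " (a single procedure comes back unchanged). Every rendering
    normalizes back to ``canonical_list``.
    """
    if not canonical_list:
        raise ValueError("canonical plan list must be non-empty")
    if not messiness:
        return " + ".join(canonical_list)
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    parts: list[str] = []
    for item in canonical_list:
        base, laterality = _split_laterality(item)
        variants = (base,) + catalog.SYNONYMS.get(base, ())
        surface = variants[rng.integers(len(variants))]
        if laterality == UNILATERAL:
            prefix = catalog.UNILATERAL_PREFIXES[rng.integers(len(catalog.UNILATERAL_PREFIXES))]
            surface = prefix + surface
        elif laterality == BILATERAL:
            surface = catalog.BILATERAL_PREFIX + surface
        parts.append(surface)
    delim = catalog.DELIMITER_STYLES[rng.integers(len(catalog.DELIMITER_STYLES))]
    return delim.join(parts)


def _split_laterality(canonical: str) -> tuple[str, str | None]:
    for lat in (UNILATERAL, BILATERAL):
        suffix = f" ({lat})"
        if canonical.endswith(suffix):
            return canonical[: -len(suffix)], lat
    return canonical, None


def _draw_narrative_attrs(
    primary: str, laterality: str | None, side: str, rng: np.random.Generator,
    signal: bool,
) -> dict[str, str]:
    """Attribute key per narrative field; tied to the case truth when
    ``signal`` is on, independent of it otherwise."""

    def pick(keys: list[str], probs: list[float]) -> str:
        return keys[rng.choice(len(keys), p=np.asarray(probs) / np.sum(probs))]

    if not signal:
        return {
            f: pick(list(catalog.NARRATIVE_SENTENCES[f]), [1.0] * len(catalog.NARRATIVE_SENTENCES[f]))
            for f in catalog.NARRATIVE_FIELDS
        }
    attrs: dict[str, str] = {}
    # prepuce
    if primary in (PENILE_LENGTHENING, CIRCUMCISION):
        attrs["prepuce"] = pick(
            ["phimosis_tight", "phimosis_retractable", "redundant", "normal"],
            [0.50, 0.38, 0.06, 0.06],
        )
    else:
        attrs["prepuce"] = pick(["normal", "phimosis_retractable", "redundant"], [0.60, 0.25, 0.15])
    # testicular
    if primary == ORCHIDOPEXY:
        if laterality == BILATERAL:
            attrs["testicular"] = "bilateral_undescended"
        else:
            attrs["testicular"] = pick(["unilateral_undescended", "retractile"], [0.9, 0.1])
    else:
        attrs["testicular"] = pick(["both_descended", "retractile"], [0.92, 0.08])
    # scrotal
    if primary == HIGH_LIGATION:
        if laterality == BILATERAL:
            attrs["scrotal"] = "bilateral_swelling"
        else:
            attrs["scrotal"] = pick(["unilateral_swelling", "well_developed"], [0.85, 0.15])
    elif primary == ORCHIDOPEXY:
        attrs["scrotal"] = pick(["underdeveloped", "well_developed"], [0.3, 0.7])
    else:
        attrs["scrotal"] = pick(["well_developed", "underdeveloped"], [0.9, 0.1])
    # penile
    if primary == PENILE_LENGTHENING:
        attrs["penile"] = pick(["concealed", "small", "normal"], [0.85, 0.10, 0.05])
    else:
        attrs["penile"] = pick(["normal", "small"], [0.88, 0.12])
    return attrs


def render_narratives(
    attrs: dict[str, str],
    side: str,
    rng: np.random.Generator,
    missingness: dict[str, float],
    templates: dict[str, dict[str, str]] | None = None,
) -> dict[str, str | None]:
    """Render the 4 per-field narrative sentences from attribute keys,
    honouring per-field missingness; a field with no template is absent."""
    templates = templates if templates is not None else catalog.NARRATIVE_SENTENCES
    out: dict[str, str | None] = {}
    for fld in catalog.NARRATIVE_FIELDS:
        drop = rng.random() < missingness.get(fld, 0.0)
        tmpl = templates.get(fld, {}).get(attrs.get(fld, ""), None)
        out[fld] = None if (drop or tmpl is None) else tmpl.format(side=side)
    return out


def _compose_note(
    age_years: float, narratives: dict[str, str | None], rng: np.random.Generator
) -> str:
    years = int(age_years)
    months = int(round((age_years - years) * 12))
    if months == 12:
        years, months = years + 1, 0
    sents = [catalog.ADMISSION_TEMPLATE.format(years=years, months=months)]
    sents += [s for s in narratives.values() if s]
    sents.append(catalog.NOTE_BOILERPLATE[rng.integers(len(catalog.NOTE_BOILERPLATE))])
    return " ".join(sents)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort; identical spec+seed is byte-identical."""
    rng = np.random.default_rng(spec.seed)
    procs = list(PRIMARY_PROCEDURES)
    mix = np.array([spec.procedure_mix[p] for p in procs])

    # surgeon roster (fixed per cohort)
    lo_e, hi_e = spec.surgeon_experience_range
    lo_v, hi_v = spec.surgeon_volume_range
    roster: dict[str, dict] = {}
    for i in range(spec.n_surgeons - 1):
        roster[f"Surgeon {i + 1:02d}"] = {
            "years": float(np.round(rng.uniform(lo_e, hi_e), 1)),
            "volume": int(rng.integers(lo_v, hi_v + 1)),
        }
    roster["unknown"] = {"years": None, "volume": None}
    named = [n for n in roster if n != "unknown"]
    # center/scale the experience effect on the realized roster so the
    # marginal duration distribution does not drift with the roster draw
    named_years = np.array([roster[n]["years"] for n in named], dtype=float)
    exp_center = float(named_years.mean()) if named else spec.duration_model.experience_center
    exp_scale = float(named_years.std()) or spec.duration_model.experience_scale

    # truncated log-normal ages via inverse CDF: a = exp(mu + sigma * ndtri(u))
    age_cdf_max = float(
        stats.norm.cdf((np.log(spec.age.max_years) - spec.age.mu_log) / spec.age.sigma_log)
    )
    dm = spec.duration_model
    aux_names = [a for a, _ in AUX_PROCEDURES]
    aux_w = np.array([w for _, w in AUX_PROCEDURES])
    aux_w = aux_w / aux_w.sum()

    # the emulated cohort is a census with fixed per-procedure counts, so the
    # primary-procedure mix is assigned as exact stratified counts (largest-
    # remainder rounding) and shuffled, not drawn i.i.d.
    exact = spec.n_cases * mix
    counts = np.floor(exact).astype(int)
    remainder = spec.n_cases - counts.sum()
    for j in np.argsort(-(exact - counts))[:remainder]:
        counts[j] += 1
    proc_assignment = rng.permutation(np.repeat(np.arange(len(procs)), counts))

    records: list[CaseRecord] = []
    truths: list[CaseTruth] = []
    for i in range(spec.n_cases):
        case_id = f"C{i + 1:06d}"
        # demographics
        age = float(
            np.exp(spec.age.mu_log + spec.age.sigma_log * ndtri(rng.uniform(0.0, age_cdf_max)))
        )
        g = spec.weight.intercept + spec.weight.slope * age + spec.weight.quad * age**2
        w_noise = np.exp(
            rng.normal(0.0, spec.weight.noise_sd_log) - spec.weight.noise_sd_log**2 / 2
        )
        weight = float(np.clip(g * w_noise, spec.weight.min_kg, spec.weight.max_kg))

        # procedure, laterality, plan
        primary = procs[proc_assignment[i]]
        side = "left" if rng.random() < 0.5 else "right"
        laterality: str | None = None
        plan: list[str] = []
        if primary in (HIGH_LIGATION, ORCHIDOPEXY):
            laterality = BILATERAL if rng.random() < spec.bilateral_prob else UNILATERAL
            plan.append(lateral_form(primary, laterality))
        else:
            plan.append(primary)
        if primary == PENILE_LENGTHENING and rng.random() < spec.preputioplasty_prob:
            plan.append("preputioplasty")
        if rng.random() < spec.aux_procedure_prob:
            extra = aux_names[rng.choice(len(aux_names), p=aux_w)]
            if extra not in plan:
                plan.append(extra)

        # diagnoses
        diagnoses: list[str] = []
        d_label, d_p = catalog.PRIMARY_DIAGNOSES[primary]
        if rng.random() < d_p:
            diagnoses.append(d_label)
        for label, p in catalog.CO_DIAGNOSES[primary]:
            if rng.random() < p and label not in diagnoses:
                diagnoses.append(label)
        for label, p in catalog.RARE_DIAGNOSES:
            if rng.random() < p and label not in diagnoses:
                diagnoses.append(label)
        if not diagnoses:
            diagnoses.append(d_label)

        # surgeon
        if rng.random() < spec.p_unknown_surgeon:
            surgeon = "unknown"
            latent_years = exp_center
            s_years: float | None = None
            s_volume: int | None = None
        else:
            surgeon = named[rng.integers(len(named))]
            latent_years = roster[surgeon]["years"]
            s_years = latent_years
            s_volume = roster[surgeon]["volume"]

        # duration from the log-linear truth model
        z_exp = (latent_years - exp_center) / exp_scale
        eta = (
            dm.intercept
            + dm.proc_effects[primary]
            + dm.bilateral * float(any(f"({BILATERAL})" in p for p in plan))
            + dm.extra_plan * (len(plan) - 1)
            + dm.experience * z_exp
        )
        log_d = eta + rng.normal(0.0, dm.sigma_log)
        duration = float(np.exp(log_d))

        # narratives and note
        attrs = _draw_narrative_attrs(primary, laterality, side, rng, spec.narrative_signal)
        narratives = render_narratives(attrs, side, rng, spec.missingness_rates)
        note = _compose_note(age, narratives, rng)

        # field-level missingness on the structured side
        miss = spec.missingness_rates
        age_text = "" if rng.random() < miss.get("age_text", 0.0) else age_to_text(age)
        weight_out = None if rng.random() < miss.get("weight", 0.0) else round(weight, 1)
        if s_years is not None and rng.random() < miss.get("surgeon_years", 0.0):
            s_years = None
        if s_volume is not None and rng.random() < miss.get("surgeon_volume", 0.0):
            s_volume = None

        plan_raw = messify_plan(plan, rng, messiness=spec.messiness)

        records.append(
            CaseRecord(
                case_id=case_id,
                age_text=age_text,
                weight_kg=weight_out,
                primary_procedure=primary,
                surgeon_name=surgeon,
                surgeon_years=s_years,
                surgeon_volume=s_volume,
                diagnoses_raw=", ".join(diagnoses),
                plan_raw=plan_raw,
                narratives=narratives,
                note=note,
                duration_min=round(duration, 1),
            )
        )
        truths.append(
            CaseTruth(
                case_id=case_id,
                age_years=age,
                canonical_plan=plan,
                diagnoses=diagnoses,
                narrative_attrs=attrs,
                narrative_sentences={f: s for f, s in narratives.items() if s},
                side=side,
                latent_surgeon_years=latent_years,
                linear_predictor=eta,
                log_duration=log_d,
            )
        )
    return Cohort(spec=spec, records=records, truths=truths, surgeon_roster=roster)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "case_id", "age_text", "weight_kg", "primary_procedure", "surgeon_name",
    "surgeon_years", "surgeon_volume", "diagnoses_raw", "plan_raw",
    "narrative_prepuce", "narrative_testicular", "narrative_scrotal",
    "narrative_penile", "note", "duration_min",
]


def cohort_to_dataframe(records: list[CaseRecord]):
    import pandas as pd

    rows = []
    for r in records:
        d = r.to_dict()
        narr = d.pop("narratives")
        for fld in catalog.NARRATIVE_FIELDS:
            d[f"narrative_{fld}"] = narr.get(fld)
        rows.append(d)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort_jsonl(records: list[CaseRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_cohort_jsonl(path) -> list[CaseRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(CaseRecord.from_dict(json.loads(line)))
    return out


def write_truth_jsonl(truths: list[CaseTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            fh.write(json.dumps(t.to_dict()) + "\n")
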