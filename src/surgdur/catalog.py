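"""Domain catalogs for pediatric-urology surgical plans and narratives.

These tables define (a) the four primary procedure categories, (b) the
canonical surgical-plan vocabulary with its synonym/laterality surface
variants, (c) the consolidation of canonical procedures into 23 standardized
categories (including the residual "other surgical procedures"), and (d) the
sentence templates used by the synthetic narrative renderer and its
rule-based extraction counterpart.
"""

from __future__ import annotations

import re

# -- primary procedures ------------------------------------------------------

PENILE_LENGTHENING = "penile lengthening"
HIGH_LIGATION = "laparoscopic high ligation of the processus vaginalis"
ORCHIDOPEXY = "orchidopexy"
CIRCUMCISION = "circumcision"

PRIMARY_PROCEDURES: tuple[str, ...] = (
    PENILE_LENGTHENING,
    HIGH_LIGATION,
    ORCHIDOPEXY,
    CIRCUMCISION,
)

# procedures for which left/right matters; unilateral forms are pooled while
# bilateral forms are kept distinct (bilaterality changes operative time)
LATERAL_PROCEDURES: frozenset[str] = frozenset(
    {
        HIGH_LIGATION,
        ORCHIDOPEXY,
        "inguinal hernia repair",
        "hydrocelectomy",
        "varicocelectomy",
        "orchiectomy",
    }
)

UNILATERAL = "unilateral"
BILATERAL = "bilateral"


def lateral_form(base: str, laterality: str) -> str:
    return f"{base} ({laterality})"


# -- synonym table -----------------------------------------------------------
# canonical base name -> alternative surface spellings seen in raw plans
SYNONYMS: dict[str, tuple[str, ...]] = {
    HIGH_LIGATION: (
        "high ligation of the processus vaginalis",
        "laparoscopic high ligation",
    ),
    ORCHIDOPEXY: ("orchiopexy",),
    CIRCUMCISION: (
        "circumcision (stapler)",
        "circumcision (ligation)",
        "circumcision (manual suture)",
    ),
    PENILE_LENGTHENING: ("penile lengthening surgery",),
    "preputioplasty": ("prepuce plasty",),
    "hydrocelectomy": ("excision of hydrocele",),
    "frenuloplasty": ("frenulum plasty",),
    "penile nevus excision": ("excision of penile nevus",),
    "penile cyst excision": ("excision of penile cyst",),
}

def _strip_laterality(name: str) -> str:
    for lat in (" (unilateral)", " (bilateral)"):
        if name.endswith(lat):
            return name[: -len(lat)]
    return name


#: surface token (casefolded) -> canonical base name
VARIANT_TO_BASE: dict[str, str] = {}


def _register_base(base: str) -> None:
    VARIANT_TO_BASE.setdefault(base.casefold(), base)


for _base, _variants in SYNONYMS.items():
    _register_base(_base)
    for _v in _variants:
        VARIANT_TO_BASE[_v.casefold()] = _base

# -- consolidation into 23 standardized procedure categories -----------------

OTHER_CATEGORY = "other surgical procedures"

STANDARD_CATEGORIES: tuple[str, ...] = (
    PENILE_LENGTHENING,
    lateral_form(HIGH_LIGATION, UNILATERAL),
    lateral_form(HIGH_LIGATION, BILATERAL),
    lateral_form(ORCHIDOPEXY, UNILATERAL),
    lateral_form(ORCHIDOPEXY, BILATERAL),
    CIRCUMCISION,
    "preputioplasty",
    "penile lesion excision",
    "hypospadias repair",
    "meatoplasty",
    "scrotoplasty",
    "cystoscopy",
    "urethral dilation",
    "chordee correction",
    lateral_form("inguinal hernia repair", UNILATERAL),
    lateral_form("inguinal hernia repair", BILATERAL),
    lateral_form("varicocelectomy", UNILATERAL),
    lateral_form("varicocelectomy", BILATERAL),
    lateral_form("hydrocelectomy", UNILATERAL),
    lateral_form("hydrocelectomy", BILATERAL),
    lateral_form("orchiectomy", UNILATERAL),
    "frenuloplasty",
    OTHER_CATEGORY,
)

#: canonical procedure -> standardized category (unmapped -> OTHER_CATEGORY)
CONSOLIDATION_MAP: dict[str, str] = {c: c for c in STANDARD_CATEGORIES}
CONSOLIDATION_MAP.update(
    {
        "penile nevus excision": "penile lesion excision",
        "penile cyst excision": "penile lesion excision",
        "penile scar excision": "penile lesion excision",
        "penoscrotal web repair": OTHER_CATEGORY,
        "umbilical hernia repair": OTHER_CATEGORY,
        lateral_form("orchiectomy", BILATERAL): OTHER_CATEGORY,
    }
)

# every canonical base (with laterality stripped) is its own surface form
for _name in list(STANDARD_CATEGORIES) + list(CONSOLIDATION_MAP):
    if _name != OTHER_CATEGORY:
        _register_base(_strip_laterality(_name))

# -- raw-plan surface conventions -------------------------------------------

#: delimiter styles used when rendering messy raw plan strings
DELIMITER_STYLES: tuple[str, ...] = (" + ", "+", ", ", "，", " simultaneously perform ")

#: regex splitting a raw plan on any of the delimiter conventions
PLAN_SPLIT_RE = re.compile(r"\s*(?:\+|,|，|、|;|simultaneously\s+perform)\s*", re.IGNORECASE)

UNILATERAL_PREFIXES: tuple[str, ...] = ("left-sided ", "right-sided ", "left ", "right ")
BILATERAL_PREFIX = "bilateral "

# -- diagnoses ---------------------------------------------------------------

#: diagnosis implied by each primary procedure (probability of being recorded)
PRIMARY_DIAGNOSES: dict[str, tuple[str, float]] = {
    PENILE_LENGTHENING: ("concealed penis", 0.85),
    HIGH_LIGATION: ("hydrocele", 0.90),
    ORCHIDOPEXY: ("cryptorchidism", 0.70),
    CIRCUMCISION: ("phimosis", 0.90),
}

#: co-diagnosis (label, probability) pairs drawn per primary procedure
CO_DIAGNOSES: dict[str, tuple[tuple[str, float], ...]] = {
    PENILE_LENGTHENING: (("phimosis", 0.35), ("redundant prepuce", 0.15)),
    HIGH_LIGATION: (("inguinal hernia", 0.10), ("phimosis", 0.08)),
    ORCHIDOPEXY: (("incomplete testicular descent", 0.30), ("inguinal hernia", 0.05)),
    CIRCUMCISION: (("redundant prepuce", 0.30), ("balanitis", 0.08)),
}

#: independent low-frequency diagnoses exercising the rare-type bucket
RARE_DIAGNOSES: tuple[tuple[str, float], ...] = (
    ("urethral polyp", 0.0015),
    ("penile nevus", 0.0020),
    ("scrotal hemangioma", 0.0010),
)

# -- narrative sentence catalog ----------------------------------------------

NARRATIVE_FIELDS: tuple[str, ...] = ("prepuce", "testicular", "scrotal", "penile")

#: field -> attribute key -> sentence template ({side} filled at render time)
NARRATIVE_SENTENCES: dict[str, dict[str, str]] = {
    "prepuce": {
        "phimosis_retractable": (
            "Phimosis prepuce, can be manually retracted to expose the glans."
        ),
        "phimosis_tight": (
            "Phimosis prepuce, cannot be retracted to expose the glans."
        ),
        "redundant": "The prepuce is redundant but fully retractable.",
        "normal": "The prepuce is normal and fully retractable.",
    },
    "testicular": {
        "both_descended": (
            "Both testes are located within the scrotum and are well-developed."
        ),
        "unilateral_undescended": (
            "The {side} testis is not palpable within the scrotum."
        ),
        "bilateral_undescended": "Neither testis is palpable within the scrotum.",
        "retractile": "The {side} testis is retractile but can be brought into the scrotum.",
    },
    "scrotal": {
        "well_developed": "Scrotum is well-developed.",
        "underdeveloped": "The scrotum is underdeveloped.",
        "unilateral_swelling": (
            "A cystic swelling is present on the {side} side of the scrotum."
        ),
        "bilateral_swelling": "Cystic swelling is present on both sides of the scrotum.",
    },
    "penile": {
        "normal": "The penis is normally developed.",
        "small": "The penis appears shorter than expected for age.",
        "concealed": (
            "The penis appears small, with only the distal half of the glans visible "
            "on the body surface in the supine position."
        ),
    },
}

#: neutral boilerplate appended to the synthetic note (carries no signal)
NOTE_BOILERPLATE: tuple[str, ...] = (
    "Routine preoperative preparation has been completed.",
    "No known drug allergies.",
    "Preoperative electrocardiogram and chest radiograph show no abnormalities.",
    "The child is in good general condition and tolerates activity well.",
)

ADMISSION_TEMPLATE = (
    "The child, aged {years} years {months} months, was admitted for elective surgery."
)
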