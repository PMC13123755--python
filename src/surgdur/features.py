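"""Feature engineering: parsing, imputation, encoding and assembly.

Turns raw case records into the grouped representation the models consume:

* numerics (age, weight, surgeon experience/volume) parsed, imputed and
  standardized with training-only statistics;
* the primary procedure (and optionally the surgeon name) one-hot encoded;
* multilabel preoperative diagnoses with a >=10-occurrence vocabulary and a
  "rare type" bucket;
* surgical plans normalized from messy raw strings (delimiters, synonyms,
  left/right pooled to unilateral) and consolidated into 23 standardized
  procedure categories, then multilabel encoded;
* the 4 structured narrative fields embedded to 256-d vectors each and
  concatenated (missing text -> null vector).

Two surgeon configurations exist: "name" (identity one-hot; roster-bound)
and "metrics" (years of practice + annual surgical volume; generalizes to
unseen surgeons).
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass

import numpy as np

from sklearn.base import BaseEstimator, TransformerMixin

from . import catalog
from .catalog import (
    BILATERAL,
    CONSOLIDATION_MAP,
    LATERAL_PROCEDURES,
    OTHER_CATEGORY,
    PLAN_SPLIT_RE,
    UNILATERAL,
    VARIANT_TO_BASE,
    lateral_form,
)
from .cohort import CaseRecord
from .embedding import EMBED_DIM, HashingEmbedder
from .textstruct import RuleBackend

logger = logging.getLogger(__name__)

__all__ = [
    "parse_age",
    "impute_age",
    "fit_weight_bins",
    "impute_weight",
    "Standardizer",
    "build_multilabel_vocab",
    "encode_multilabel",
    "decode_multilabel",
    "normalize_plan",
    "consolidate_plans",
    "FeatureGroup",
    "EncodingSchema",
    "FeatureBundle",
    "CohortFeaturizer",
]

RARE_LABEL = "rare type"

# ---------------------------------------------------------------------------
# Scalar parsing and imputation rules
# ---------------------------------------------------------------------------

_AGE_RE = re.compile(r"^\s*(\d+)\s*years?(?:\s*(\d+)\s*months?)?\s*$", re.IGNORECASE)
_MONTHS_ONLY_RE = re.compile(r"^\s*(\d+)\s*months?\s*$", re.IGNORECASE)


def parse_age(age_text: str | None) -> float | None:
    """Convert "x years x months" to fractional years; unparseable -> None."""
    if not age_text:
        return None
    m = _AGE_RE.match(age_text)
    if m:
        years = int(m.group(1))
        months = int(m.group(2)) if m.group(2) else 0
        return years + months / 12.0
    m = _MONTHS_ONLY_RE.match(age_text)
    if m:
        return int(m.group(1)) / 12.0
    logger.debug("unparseable age text %r", age_text)
    return None


def impute_age(
    parsed: float | None, extracted: float | None, training_mean: float
) -> float:
    """Parsed age wins; else the note-extracted age; else the training mean."""
    if parsed is not None:
        return parsed
    if extracted is not None:
        return extracted
    logger.warning("age missing from both record and note; using training mean")
    return training_mean


def fit_weight_bins(
    ages: np.ndarray, weights: list[float | None], plausible: tuple[float, float]
) -> dict[int, float]:
    """Mean weight per integer-year age bin, from plausible training values."""
    sums: dict[int, list[float]] = {}
    for a, w in zip(ages, weights):
        if w is not None and plausible[0] <= w <= plausible[1]:
            sums.setdefault(int(a), []).append(float(w))
    if not sums:
        raise ValueError("no plausible weights in any age bin; cannot fit imputer")
    return {b: float(np.mean(v)) for b, v in sums.items()}


def impute_weight(
    weight: float | None, age: float, bins: dict[int, float],
    plausible: tuple[float, float],
) -> float:
    """Plausible weights pass through; otherwise the age bin's mean weight
    (nearest populated bin if the case's own bin is empty)."""
    if weight is not None and plausible[0] <= weight <= plausible[1]:
        return float(weight)
    b = int(age)
    if b in bins:
        return bins[b]
    nearest = min(bins, key=lambda k: (abs(k - b), k))
    return bins[nearest]


@dataclass(frozen=True)
class Standardizer:
    """z = (x - mean)/sd with an exact inverse; fitted on training rows."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, values) -> "Standardizer":
        x = np.asarray(values, dtype=float)
        if x.size < 2 or np.unique(x).size < 2:
            raise ValueError("standardizer needs at least 2 distinct values")
        sd = float(x.std(ddof=0))
        if sd == 0.0:
            raise ValueError("zero standard deviation")
        return cls(mean=float(x.mean()), sd=sd)

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.sd + self.mean


# ---------------------------------------------------------------------------
# Multilabel encoding
# ---------------------------------------------------------------------------


def build_multilabel_vocab(
    label_lists: list[list[str]], min_count: int = 10, rare_label: str = RARE_LABEL
) -> list[str]:
    """Labels with >= min_count training occurrences, in first-appearance
    order, plus the rare bucket (always last, always present)."""
    counts: dict[str, int] = {}
    order: list[str] = []
    for labels in label_lists:
        for lab in labels:
            if lab not in counts:
                counts[lab] = 0
                order.append(lab)
            counts[lab] += 1
    vocab = [lab for lab in order if counts[lab] >= min_count and lab != rare_label]
    vocab.append(rare_label)
    return vocab


def encode_multilabel(
    labels: list[str], vocab: list[str], rare_label: str = RARE_LABEL
) -> np.ndarray:
    """Binary indicator vector; labels outside the vocabulary set the rare
    bucket; an empty label list encodes as all zeros."""
    vec = np.zeros(len(vocab))
    index = {lab: i for i, lab in enumerate(vocab)}
    for lab in labels:
        vec[index.get(lab, index[rare_label])] = 1.0
    return vec


def decode_multilabel(
    vec: np.ndarray, vocab: list[str]
) -> list[str]:
    return [lab for lab, v in zip(vocab, vec) if v > 0.5]


# ---------------------------------------------------------------------------
# Plan normalization and consolidation
# ---------------------------------------------------------------------------


def _clean(token: str) -> str:
    return " ".join(token.split()).casefold()


def normalize_plan(
    plan_raw: str | None, synonym_map: dict[str, str] | None = None
) -> list[str]:
    """Split a messy raw plan on its delimiter conventions and map each token
    to a canonical procedure.

    Left/right wording collapses to the pooled "(unilateral)" form; explicit
    bilateral wording keeps its own "(bilateral)" form; synonyms map to the
    canonical name; duplicates are dropped preserving order. Idempotent on
    canonical input; unrecognized tokens pass through cleaned (the
    consolidation step routes them to the residual category).
    """
    if synonym_map is None:
        synonym_map = VARIANT_TO_BASE
    if not plan_raw or not plan_raw.strip():
        logger.warning("empty surgical plan string")
        return []
    out: list[str] = []
    for token in PLAN_SPLIT_RE.split(plan_raw):
        tok = _clean(token)
        if not tok:
            continue
        laterality: str | None = None
        for lat in (UNILATERAL, BILATERAL):
            suffix = f"({lat})"
            if tok.endswith(suffix):
                laterality = lat
                tok = tok[: -len(suffix)].strip()
                break
        if laterality is None:
            if tok.startswith(catalog.BILATERAL_PREFIX):
                laterality = BILATERAL
                tok = tok[len(catalog.BILATERAL_PREFIX):]
            else:
                for prefix in catalog.UNILATERAL_PREFIXES:
                    if tok.startswith(prefix):
                        laterality = UNILATERAL
                        tok = tok[len(prefix):]
                        break
        base = synonym_map.get(tok)
        if base is None:
            canonical = _clean(token)  # unknown surface form, kept verbatim
        elif base in LATERAL_PROCEDURES:
            canonical = lateral_form(base, laterality or UNILATERAL)
        else:
            canonical = base
        if canonical not in out:
            out.append(canonical)
    return out


def consolidate_plans(
    canonical_list: list[str], consolidation_map: dict[str, str] | None = None
) -> list[str]:
    """Map canonical procedures into the 23 standardized categories; anything
    unmapped goes to the residual "other surgical procedures" category."""
    cmap = consolidation_map if consolidation_map is not None else CONSOLIDATION_MAP
    out: list[str] = []
    for proc in canonical_list:
        cat = cmap.get(proc, OTHER_CATEGORY)
        if cat not in out:
            out.append(cat)
    return out


# ---------------------------------------------------------------------------
# Fitted schema and assembled bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureGroup:
    """A contiguous column span belonging to one logical feature."""

    name: str
    start: int
    stop: int
    head: str  # "tabular" | "text"

    @property
    def width(self) -> int:
        return self.stop - self.start


@dataclass
class EncodingSchema:
    """All state fitted on training rows, serializable for exact reruns."""

    surgeon_config: str
    min_count: int
    log_target: bool
    text_mode: str
    onehot_vocabularies: dict[str, list[str]]
    multilabel_vocabularies: dict[str, list[str]]
    rare_labels: dict[str, str]
    numeric_stats: dict[str, tuple[float, float]]       # mean, sd per numeric
    numeric_means: dict[str, float]                     # imputation means
    target_stats: tuple[float, float]
    age_group_weights: dict[int, float]
    weight_plausible: tuple[float, float]
    layout: list[FeatureGroup]

    def to_dict(self) -> dict:
        d = {
            "surgeon_config": self.surgeon_config,
            "min_count": self.min_count,
            "log_target": self.log_target,
            "text_mode": self.text_mode,
            "onehot_vocabularies": self.onehot_vocabularies,
            "multilabel_vocabularies": self.multilabel_vocabularies,
            "rare_labels": self.rare_labels,
            "numeric_stats": {k: list(v) for k, v in self.numeric_stats.items()},
            "numeric_means": self.numeric_means,
            "target_stats": list(self.target_stats),
            "age_group_weights": {str(k): v for k, v in self.age_group_weights.items()},
            "weight_plausible": list(self.weight_plausible),
            "layout": [[g.name, g.start, g.stop, g.head] for g in self.layout],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EncodingSchema":
        return cls(
            surgeon_config=d["surgeon_config"],
            min_count=d["min_count"],
            log_target=d["log_target"],
            text_mode=d["text_mode"],
            onehot_vocabularies=d["onehot_vocabularies"],
            multilabel_vocabularies=d["multilabel_vocabularies"],
            rare_labels=d["rare_labels"],
            numeric_stats={k: (v[0], v[1]) for k, v in d["numeric_stats"].items()},
            numeric_means=d["numeric_means"],
            target_stats=(d["target_stats"][0], d["target_stats"][1]),
            age_group_weights={int(k): v for k, v in d["age_group_weights"].items()},
            weight_plausible=(d["weight_plausible"][0], d["weight_plausible"][1]),
            layout=[FeatureGroup(*row) for row in d["layout"]],
        )

    def fingerprint(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def groups(self, head: str | None = None) -> list[FeatureGroup]:
        return [g for g in self.layout if head is None or g.head == head]


@dataclass
class FeatureBundle:
    """Assembled model inputs for a set of cases."""

    tabular: np.ndarray
    text: np.ndarray
    y_std: np.ndarray
    y_min: np.ndarray
    layout: list[FeatureGroup]
    schema_fingerprint: str = ""

    def __post_init__(self):
        n = len(self.y_min)
        if not (self.tabular.shape[0] == self.text.shape[0] == len(self.y_std) == n):
            raise ValueError("feature blocks and targets disagree on row count")
        for name, block in (("tabular", self.tabular), ("text", self.text)):
            if block.size and not np.all(np.isfinite(block)):
                raise ValueError(f"non-finite values in {name} block")

    @property
    def n(self) -> int:
        return len(self.y_min)

    def rows(self, idx) -> "FeatureBundle":
        return FeatureBundle(
            tabular=self.tabular[idx],
            text=self.text[idx],
            y_std=self.y_std[idx],
            y_min=self.y_min[idx],
            layout=self.layout,
            schema_fingerprint=self.schema_fingerprint,
        )

    def concat_matrix(self) -> np.ndarray:
        return np.hstack([self.tabular, self.text])


# ---------------------------------------------------------------------------
# The featurizer
# ---------------------------------------------------------------------------


class CohortFeaturizer(BaseEstimator, TransformerMixin):
    """Fit encoding rules on training cases; transform cases to features.

    Parameters
    ----------
    surgeon_config : "metrics" or "name"
        "metrics" uses years of practice + annual volume (generalizable);
        "name" one-hot encodes the surgeon identity.
    min_count : int
        Occurrence threshold for multilabel vocabularies; rarer labels fall
        into the rare bucket ("rare type" for diagnoses, the residual
        category for plans).
    log_target : bool
        If True, standardize log-minutes instead of raw minutes.
    text_mode : "structured", "whole_note" or "none"
        Structured-field embeddings (4 x 256), a single whole-note embedding
        (256), or no text block.
    extractor, embedder
        Pluggable backends; default to the deterministic offline ones.
    """

    def __init__(
        self,
        surgeon_config: str = "metrics",
        min_count: int = 10,
        log_target: bool = False,
        text_mode: str = "structured",
        extractor=None,
        embedder=None,
        weight_plausible: tuple[float, float] = (5.0, 140.0),
    ):
        self.surgeon_config = surgeon_config
        self.min_count = min_count
        self.log_target = log_target
        self.text_mode = text_mode
        self.extractor = extractor
        self.embedder = embedder
        self.weight_plausible = weight_plausible

    # -- fitting -------------------------------------------------------------

    def fit(self, records: list[CaseRecord], y=None) -> "CohortFeaturizer":
        if self.surgeon_config not in ("metrics", "name"):
            raise ValueError("surgeon_config must be 'metrics' or 'name'")
        if self.text_mode not in ("structured", "whole_note", "none"):
            raise ValueError("text_mode must be 'structured', 'whole_note' or 'none'")
        extractor = self.extractor if self.extractor is not None else RuleBackend()
        embedder = self.embedder if self.embedder is not None else HashingEmbedder()
        self._extractor_ = extractor
        self._embedder_ = embedder

        extracted = [extractor.extract(r.note) for r in records]
        parsed = [parse_age(r.age_text) for r in records]
        known = [
            p if p is not None else e.extracted_age
            for p, e in zip(parsed, extracted)
        ]
        known_vals = [a for a in known if a is not None]
        if not known_vals:
            raise ValueError("no resolvable ages in training data")
        age_mean = float(np.mean(known_vals))
        ages = np.array([a if a is not None else age_mean for a in known])

        bins = fit_weight_bins(ages, [r.weight_kg for r in records], self.weight_plausible)
        weights = np.array([
            impute_weight(r.weight_kg, a, bins, self.weight_plausible)
            for r, a in zip(records, ages)
        ])

        numeric_stats: dict[str, tuple[float, float]] = {}
        numeric_means: dict[str, float] = {}
        for name, values in (("age", ages), ("weight", weights)):
            s = Standardizer.fit(values)
            numeric_stats[name] = (s.mean, s.sd)
        numeric_means["age"] = age_mean

        onehot: dict[str, list[str]] = {}
        onehot["primary_procedure"] = _first_appearance(
            [r.primary_procedure for r in records]
        )
        if self.surgeon_config == "name":
            onehot["surgeon_name"] = _first_appearance([r.surgeon_name for r in records])
        else:
            for attr in ("surgeon_years", "surgeon_volume"):
                vals = [getattr(r, attr) for r in records]
                present = [float(v) for v in vals if v is not None]
                if not present:
                    raise ValueError(f"no training values for {attr}")
                mean = float(np.mean(present))
                numeric_means[attr] = mean
                filled = np.array([float(v) if v is not None else mean for v in vals])
                s = Standardizer.fit(filled)
                numeric_stats[attr] = (s.mean, s.sd)

        diag_lists = [_split_diagnoses(r.diagnoses_raw) for r in records]
        plan_lists = [consolidate_plans(normalize_plan(r.plan_raw)) for r in records]
        multilabel = {
            "diagnosis": build_multilabel_vocab(diag_lists, self.min_count, RARE_LABEL),
            "plan": build_multilabel_vocab(plan_lists, self.min_count, OTHER_CATEGORY),
        }
        rare_labels = {"diagnosis": RARE_LABEL, "plan": OTHER_CATEGORY}

        y_min = np.array([r.duration_min for r in records], dtype=float)
        target_vals = np.log(y_min) if self.log_target else y_min
        t = Standardizer.fit(target_vals)

        layout = self._build_layout(onehot, multilabel)
        self.schema_ = EncodingSchema(
            surgeon_config=self.surgeon_config,
            min_count=self.min_count,
            log_target=self.log_target,
            text_mode=self.text_mode,
            onehot_vocabularies=onehot,
            multilabel_vocabularies=multilabel,
            rare_labels=rare_labels,
            numeric_stats=numeric_stats,
            numeric_means=numeric_means,
            target_stats=(t.mean, t.sd),
            age_group_weights=bins,
            weight_plausible=self.weight_plausible,
            layout=layout,
        )
        return self

    def _build_layout(self, onehot, multilabel) -> list[FeatureGroup]:
        layout: list[FeatureGroup] = []
        col = 0

        def add(name: str, width: int, head: str):
            nonlocal col
            layout.append(FeatureGroup(name, col, col + width, head))
            col += width

        add("age", 1, "tabular")
        add("weight", 1, "tabular")
        if self.surgeon_config == "metrics":
            add("surgeon_years", 1, "tabular")
            add("surgeon_volume", 1, "tabular")
        else:
            add("surgeon_name", len(onehot["surgeon_name"]), "tabular")
        add("primary_procedure", len(onehot["primary_procedure"]), "tabular")
        add("diagnosis", len(multilabel["diagnosis"]), "tabular")
        add("plan", len(multilabel["plan"]), "tabular")
        col = 0
        if self.text_mode == "structured":
            for fld in catalog.NARRATIVE_FIELDS:
                layout.append(
                    FeatureGroup(f"text_{fld}", col, col + EMBED_DIM, "text")
                )
                col += EMBED_DIM
        elif self.text_mode == "whole_note":
            layout.append(FeatureGroup("text_note", 0, EMBED_DIM, "text"))
        return layout

    # -- transforming --------------------------------------------------------

    def transform(self, records: list[CaseRecord]) -> FeatureBundle:
        schema = self.schema_  # AttributeError if unfitted, as in sklearn
        extractor = self._extractor_
        embedder = self._embedder_
        n = len(records)

        extracted = [extractor.extract(r.note) for r in records]
        ages = np.array([
            impute_age(parse_age(r.age_text), e.extracted_age, schema.numeric_means["age"])
            for r, e in zip(records, extracted)
        ])
        weights = np.array([
            impute_weight(r.weight_kg, a, schema.age_group_weights, schema.weight_plausible)
            for r, a in zip(records, ages)
        ])

        cols: list[np.ndarray] = []
        for name, values in (("age", ages), ("weight", weights)):
            mean, sd = schema.numeric_stats[name]
            cols.append(((values - mean) / sd)[:, None])
        if schema.surgeon_config == "metrics":
            for attr in ("surgeon_years", "surgeon_volume"):
                mean_imp = schema.numeric_means[attr]
                vals = np.array([
                    float(v) if (v := getattr(r, attr)) is not None else mean_imp
                    for r in records
                ])
                mean, sd = schema.numeric_stats[attr]
                cols.append(((vals - mean) / sd)[:, None])
        else:
            cols.append(_onehot_block(
                [r.surgeon_name for r in records],
                schema.onehot_vocabularies["surgeon_name"], "surgeon_name",
            ))
        cols.append(_onehot_block(
            [r.primary_procedure for r in records],
            schema.onehot_vocabularies["primary_procedure"], "primary_procedure",
        ))
        diag_vocab = schema.multilabel_vocabularies["diagnosis"]
        cols.append(np.vstack([
            encode_multilabel(_split_diagnoses(r.diagnoses_raw), diag_vocab, RARE_LABEL)
            for r in records
        ]))
        plan_vocab = schema.multilabel_vocabularies["plan"]
        cols.append(np.vstack([
            encode_multilabel(
                consolidate_plans(normalize_plan(r.plan_raw)), plan_vocab, OTHER_CATEGORY
            )
            for r in records
        ]))
        tabular = np.hstack(cols)

        d_tab = sum(g.width for g in schema.groups("tabular"))
        if tabular.shape[1] != d_tab:
            raise ValueError(
                f"assembled tabular width {tabular.shape[1]} != layout width {d_tab}"
            )

        if schema.text_mode == "structured":
            blocks = []
            for fld in catalog.NARRATIVE_FIELDS:
                texts = [
                    fv.value if (fv := e.fields.get(fld)) is not None else None
                    for e in extracted
                ]
                blocks.append(embedder.embed_batch(texts))
            text = np.hstack(blocks) if n else np.zeros((0, 4 * EMBED_DIM))
        elif schema.text_mode == "whole_note":
            text = embedder.embed_batch([r.note for r in records])
        else:
            text = np.zeros((n, 0))

        y_min = np.array([r.duration_min for r in records], dtype=float)
        t_mean, t_sd = schema.target_stats
        target_vals = np.log(y_min) if schema.log_target else y_min
        y_std = (target_vals - t_mean) / t_sd

        return FeatureBundle(
            tabular=tabular,
            text=text,
            y_std=y_std,
            y_min=y_min,
            layout=schema.layout,
            schema_fingerprint=schema.fingerprint(),
        )

    # -- target helpers ------------------------------------------------------

    def to_minutes(self, y_std: np.ndarray) -> np.ndarray:
        """Invert the target standardization back to minutes."""
        t_mean, t_sd = self.schema_.target_stats
        vals = np.asarray(y_std) * t_sd + t_mean
        return np.exp(vals) if self.schema_.log_target else vals


def _first_appearance(values: list[str]) -> list[str]:
    seen: list[str] = []
    for v in values:
        if v not in seen:
            seen.append(v)
    return seen


def _split_diagnoses(raw: str | None) -> list[str]:
    if not raw:
        return []
    return [t.strip() for t in re.split(r"[,，]", raw) if t.strip()]


def _onehot_block(values: list[str], vocab: list[str], name: str) -> np.ndarray:
    index = {v: i for i, v in enumerate(vocab)}
    out = np.zeros((len(values), len(vocab)))
    for i, v in enumerate(values):
        j = index.get(v)
        if j is None:
            logger.warning("unseen %s category %r encoded as all-zero row", name, v)
        else:
            out[i, j] = 1.0
    return out
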