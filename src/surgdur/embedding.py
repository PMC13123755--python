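"""Fixed-length (256-d) text embeddings with a deterministic offline default.

The offline embedder hashes character n-grams into 256 buckets (signed
feature hashing) and scales to unit norm — deterministic across runs and
platforms, with no weights to download. Missing or empty text maps to the
null (all-zero) vector; a case's text representation is the concatenation of
its 4 structured-field vectors in the fixed order prepuce, testicular,
scrotal, penile (4 x 256 = 1024).

A remote backend for a hosted embedding service is provided behind the same
interface; its responses are validated to length 256 and passed through
unnormalized.
"""

from __future__ import annotations

import json
import urllib.request
from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction.text import HashingVectorizer

from .catalog import NARRATIVE_FIELDS
from .textstruct import RetriableBackendError, StructuredFields

__all__ = [
    "EMBED_DIM",
    "EmbeddingVector",
    "HashingEmbedder",
    "RemoteEmbedder",
    "CachingEmbedder",
    "embed",
    "embed_case",
]

EMBED_DIM = 256


@dataclass(frozen=True)
class EmbeddingVector:
    """A 256-d text vector tagged with its source field."""

    values: np.ndarray
    source_field: str = ""
    is_null: bool = False

    def __post_init__(self):
        if self.values.shape != (EMBED_DIM,):
            raise ValueError(f"embedding must have length {EMBED_DIM}, got {self.values.shape}")
        if self.is_null and np.any(self.values):
            raise ValueError("null embedding must be all zeros")


class HashingEmbedder:
    """Offline deterministic embedder: char n-gram hashing + unit norm."""

    def __init__(self, dim: int = EMBED_DIM, ngram_range: tuple[int, int] = (3, 5)):
        self.dim = dim
        self._vec = HashingVectorizer(
            n_features=dim,
            analyzer="char_wb",
            ngram_range=ngram_range,
            norm="l2",
            alternate_sign=True,
        )

    def embed(self, text: str | None) -> np.ndarray:
        return self.embed_batch([text])[0]

    def embed_batch(self, texts: list[str | None]) -> np.ndarray:
        """Vectorized batch embedding; None/blank rows become null vectors."""
        cleaned = [" ".join(t.split()) if t else "" for t in texts]
        out = np.zeros((len(cleaned), self.dim))
        nonempty = [i for i, t in enumerate(cleaned) if t]
        if nonempty:
            mat = self._vec.transform([cleaned[i] for i in nonempty]).toarray()
            out[nonempty] = mat
        return out


class RemoteEmbedder:
    """Client for a hosted 256-d embedding service (validated pass-through)."""

    def __init__(self, endpoint: str, model: str = "", api_key: str = "",
                 timeout: float = 30.0):
        self.endpoint = endpoint
        self.model = model
        self.api_key = api_key
        self.timeout = timeout

    def embed(self, text: str | None) -> np.ndarray:
        if not text:
            return np.zeros(EMBED_DIM)
        payload = json.dumps({"model": self.model, "input": text}).encode()
        req = urllib.request.Request(
            self.endpoint, data=payload,
            headers={"Content-Type": "application/json",
                     "Authorization": f"Bearer {self.api_key}"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = json.loads(resp.read().decode())
        except (OSError, ValueError) as exc:
            raise RetriableBackendError(f"embedding backend transport failure: {exc}") from exc
        vec = np.asarray(body["embedding"], dtype=float)
        if vec.shape != (EMBED_DIM,):
            raise ValueError(f"remote embedding has length {vec.size}, expected {EMBED_DIM}")
        return vec

    def embed_batch(self, texts: list[str | None]) -> np.ndarray:
        return np.stack([self.embed(t) for t in texts])


class CachingEmbedder:
    """Memoizing wrapper: identical text hits the backend exactly once."""

    def __init__(self, backend):
        self.backend = backend
        self._cache: dict[str, np.ndarray] = {}
        self.n_backend_calls = 0

    def embed(self, text: str | None) -> np.ndarray:
        key = text or ""
        if key not in self._cache:
            self.n_backend_calls += 1
            self._cache[key] = self.backend.embed(text)
        return self._cache[key]

    def embed_batch(self, texts: list[str | None]) -> np.ndarray:
        return np.stack([self.embed(t) for t in texts])


def embed(text: str | None, backend, source_field: str = "") -> EmbeddingVector:
    """Embed one text; missing/empty text yields the null vector."""
    values = backend.embed(text)
    return EmbeddingVector(values=values, source_field=source_field,
                           is_null=not bool(text) and not np.any(values))


def embed_case(fields: StructuredFields | dict[str, str | None], backend) -> np.ndarray:
    """Concatenate the 4 field embeddings in fixed field order (1024-d)."""
    texts: list[str | None] = []
    for fld in NARRATIVE_FIELDS:
        if isinstance(fields, StructuredFields):
            fv = fields.fields.get(fld)
            texts.append(fv.value if fv is not None else None)
        else:
            texts.append(fields.get(fld))
    return backend.embed_batch(texts).ravel()
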