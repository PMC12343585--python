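"""Pluggable text-encoder and masked-LM interfaces plus deterministic mocks.

Real pretrained encoders (e.g. a BERT-family token encoder and a
sentence-level encoder) can be plugged in by implementing the
:class:`TokenEncoder`, :class:`UnitEncoder` or :class:`MaskedLanguageModel`
protocols.  The mock implementations below are deterministic functions of
their seed and their input, so the whole pipeline builds and tests offline.
"""

from __future__ import annotations

import hashlib
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

__all__ = [
    "TokenEncoder",
    "UnitEncoder",
    "MaskedLanguageModel",
    "HashTokenEncoder",
    "HashUnitEncoder",
    "ArchiveEncoder",
    "UniformMaskedLM",
    "OracleMaskedLM",
    "ConstantProbMaskedLM",
    "HashMaskedLM",
]


@runtime_checkable
class TokenEncoder(Protocol):
    """Maps text to an ordered token sequence and one embedding row per token.

    Implementations must exclude special sequence-start/end markers from the
    returned matrix: a unit of 7 characters yields a (7, d) matrix.
    """

    d: int

    def encode(self, text: str) -> tuple[list[str], np.ndarray]:
        """Return (tokens, matrix of shape (n_tokens, d)) in reading order."""
        ...


@runtime_checkable
class UnitEncoder(Protocol):
    """Maps a whole unit of text directly to a single d-vector."""

    d: int

    def encode_unit(self, text: str) -> np.ndarray:
        ...


@runtime_checkable
class MaskedLanguageModel(Protocol):
    """Single-mask predictor over a fixed vocabulary.

    ``predict(tokens, i)`` returns the probability distribution over the
    vocabulary for position ``i`` when that position is masked and all other
    tokens are left unchanged.  ``token_index`` maps a token string to its
    vocabulary index.
    """

    vocab_size: int

    def predict(self, tokens: Sequence[str], masked_index: int) -> np.ndarray:
        ...

    def token_index(self, token: str) -> int:
        ...


def _stable_seed(*parts: object, base_seed: int = 0) -> int:
    """Deterministic 63-bit seed from arbitrary string-able parts."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(base_seed).encode())
    for p in parts:
        h.update(b"\x1f")
        h.update(str(p).encode("utf-8"))
    return int.from_bytes(h.digest(), "little") >> 1


def _tokenize(text: str, mode: str) -> list[str]:
    text = text.strip()
    if mode == "char":
        return [c for c in text if not c.isspace()]
    if mode == "whitespace":
        return text.split()
    raise ValueError(f"unknown tokenize mode: {mode!r}")


class HashTokenEncoder:
    """Deterministic pseudo-contextual token encoder.

    Each token's vector is a seeded standard-normal draw keyed on the token
    identity; an optional context component keyed on (position, left context)
    makes vectors context-sensitive, loosely emulating how contextual
    embeddings differ for the same token in different sentences.

    Parameters
    ----------
    d : embedding dimensionality (default 768, the BERT-base width).
    seed : master seed; same (seed, text) always yields the same matrix.
    tokenize : "char" (one token per non-space character, suited to
        logographic scripts) or "whitespace".
    context_weight : in [0, 1); 0 gives static (context-free) embeddings.
    """

    def __init__(self, d: int = 768, seed: int = 0, tokenize: str = "char",
                 context_weight: float = 0.3):
        if d < 2:
            raise ValueError("embedding dimension must be >= 2")
        self.d = int(d)
        self.seed = int(seed)
        self.tokenize = tokenize
        self.context_weight = float(context_weight)

    def encode(self, text: str) -> tuple[list[str], np.ndarray]:
        tokens = _tokenize(text, self.tokenize)
        if not tokens:
            raise ValueError("text produced zero tokens")
        rows = np.empty((len(tokens), self.d))
        for i, tok in enumerate(tokens):
            rng = np.random.default_rng(_stable_seed("tok", tok, base_seed=self.seed))
            base = rng.standard_normal(self.d)
            if self.context_weight > 0:
                ctx_key = "|".join(tokens[:i])
                crng = np.random.default_rng(
                    _stable_seed("ctx", i, ctx_key, base_seed=self.seed))
                ctx = crng.standard_normal(self.d)
                rows[i] = (1.0 - self.context_weight) * base + self.context_weight * ctx
            else:
                rows[i] = base
        return tokens, rows


class HashUnitEncoder:
    """Deterministic direct unit-level encoder (sentence-encoder analogue)."""

    def __init__(self, d: int = 768, seed: int = 0, normalize: bool = False):
        if d < 2:
            raise ValueError("embedding dimension must be >= 2")
        self.d = int(d)
        self.seed = int(seed)
        self.normalize = bool(normalize)

    def encode_unit(self, text: str) -> np.ndarray:
        text = text.strip()
        if not text:
            raise ValueError("empty unit text")
        rng = np.random.default_rng(_stable_seed("unit", text, base_seed=self.seed))
        v = rng.standard_normal(self.d)
        if self.normalize:
            v = v / np.linalg.norm(v)
        return v


class ArchiveEncoder:
    """Token+unit 'encoder' backed by a precomputed embedding archive.

    Looks units up by unit_id instead of encoding text; used when embeddings
    were computed elsewhere (a real LLM, or the synthetic generator).
    """

    def __init__(self, archive: dict[str, dict[str, np.ndarray]]):
        self._archive = archive
        any_m = next(iter(archive.values()))["M"]
        self.d = int(any_m.shape[1])

    def lookup(self, unit_id: str) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Return (tokens, token matrix, direct unit vector) for unit_id."""
        try:
            entry = self._archive[unit_id]
        except KeyError:
            raise KeyError(f"unit_id {unit_id!r} not present in embedding archive")
        return list(entry["tokens"]), entry["M"], entry["unit_vector"]


class UniformMaskedLM:
    """Mock LM assigning probability 1/V to every vocabulary entry."""

    def __init__(self, vocab_size: int = 100):
        self.vocab_size = int(vocab_size)

    def predict(self, tokens: Sequence[str], masked_index: int) -> np.ndarray:
        return np.full(self.vocab_size, 1.0 / self.vocab_size)

    def token_index(self, token: str) -> int:
        return _stable_seed("vocab", token) % self.vocab_size


class OracleMaskedLM:
    """Mock LM placing probability 1 on the true token (surprisal 0)."""

    def __init__(self, vocab_size: int = 100):
        self.vocab_size = int(vocab_size)

    def token_index(self, token: str) -> int:
        return _stable_seed("vocab", token) % self.vocab_size

    def predict(self, tokens: Sequence[str], masked_index: int) -> np.ndarray:
        dist = np.zeros(self.vocab_size)
        dist[self.token_index(tokens[masked_index])] = 1.0
        return dist


class ConstantProbMaskedLM:
    """Mock LM giving the true token a fixed probability p at every position."""

    def __init__(self, p: float, vocab_size: int = 100):
        if not 0.0 < p <= 1.0:
            raise ValueError("p must be in (0, 1]")
        self.p = float(p)
        self.vocab_size = int(vocab_size)

    def token_index(self, token: str) -> int:
        return _stable_seed("vocab", token) % self.vocab_size

    def predict(self, tokens: Sequence[str], masked_index: int) -> np.ndarray:
        idx = self.token_index(tokens[masked_index])
        rest = (1.0 - self.p) / max(self.vocab_size - 1, 1)
        dist = np.full(self.vocab_size, rest)
        dist[idx] = self.p
        return dist


class HashMaskedLM:
    """Deterministic stochastic-looking mock LM.

    The predicted distribution is a softmax of seeded normals keyed on the
    full (context, position) pair, so predictions are context-dependent and
    exactly reproducible for a given seed.  ``sharpness`` scales the logits:
    0 recovers the uniform LM, larger values concentrate mass.
    """

    def __init__(self, vocab_size: int = 100, seed: int = 0, sharpness: float = 2.0):
        self.vocab_size = int(vocab_size)
        self.seed = int(seed)
        self.sharpness = float(sharpness)

    def token_index(self, token: str) -> int:
        return _stable_seed("vocab", token) % self.vocab_size

    def predict(self, tokens: Sequence[str], masked_index: int) -> np.ndarray:
        key = "|".join(tokens[:masked_index]) + "\x00" + "|".join(tokens[masked_index + 1:])
        rng = np.random.default_rng(
            _stable_seed("mlm", masked_index, key, base_seed=self.seed))
        logits = self.sharpness * rng.standard_normal(self.vocab_size)
        logits -= logits.max()
        p = np.exp(logits)
        return p / p.sum()
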