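"""Masked-language-model surprisal of reading units.

For each token position in turn the position is masked (all other tokens
unchanged), the LM's probability for the original token is read off, and the
token-level surprisal is its negative log.  Summing over all positions gives
the unit's cumulative surprisal — one number per unit quantifying overall
unpredictability under the LM.

Surprisal is reported in nats by default; pass ``base=2`` for bits.  A small
probability floor keeps degenerate LMs (exact zeros) from producing
infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoders import MaskedLanguageModel

__all__ = ["SurprisalResult", "token_surprisal", "cumulative_surprisal",
           "per_token_table", "PROB_FLOOR"]

#: Probability floor applied before taking the log.
PROB_FLOOR = 1e-12


@dataclass
class SurprisalResult:
    unit_id: str
    per_token: list[tuple[str, float, float]]  # (token, probability, surprisal)
    cumulative: float

    def __post_init__(self) -> None:
        assert all(s >= 0.0 for _, _, s in self.per_token)
        assert math.isclose(self.cumulative,
                            sum(s for _, _, s in self.per_token),
                            rel_tol=1e-12, abs_tol=1e-12)


def _check_distribution(dist: np.ndarray, lm: MaskedLanguageModel) -> None:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (lm.vocab_size,):
        raise ValueError(
            f"masked LM returned distribution of shape {dist.shape}, "
            f"expected ({lm.vocab_size},)")
    if np.any(dist < 0):
        raise ValueError("masked LM returned negative probabilities")
    total = float(dist.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(
            f"masked LM distribution sums to {total:.8f}, not 1 within 1e-6")


def token_surprisal(
    tokens: Sequence[str],
    i: int,
    lm: MaskedLanguageModel,
    floor: float = PROB_FLOOR,
    base: float = math.e,
) -> tuple[float, float]:
    """Probability and surprisal of the true token at masked position ``i``."""
    if not 0 <= i < len(tokens):
        raise IndexError(f"masked index {i} out of range for {len(tokens)} tokens")
    dist = lm.predict(tokens, i)
    _check_distribution(dist, lm)
    p = float(np.asarray(dist)[lm.token_index(tokens[i])])
    s = -math.log(max(p, floor)) / math.log(base)
    return p, max(s, 0.0)


def cumulative_surprisal(
    tokens: Sequence[str],
    lm: MaskedLanguageModel,
    floor: float = PROB_FLOOR,
    base: float = math.e,
    unit_id: str = "",
) -> SurprisalResult:
    """Mask each position once and sum the per-token surprisals.

    Performs exactly ``len(tokens)`` single-mask LM evaluations.  Special
    tokens must not be in ``tokens``: every element is masked and scored.
    """
    tokens = list(tokens)
    if len(tokens) < 1:
        raise ValueError(f"unit {unit_id!r}: no tokens to score")
    per_token = []
    for i, tok in enumerate(tokens):
        p, s = token_surprisal(tokens, i, lm, floor=floor, base=base)
        per_token.append((tok, p, s))
    return SurprisalResult(unit_id=unit_id, per_token=per_token,
                           cumulative=float(sum(s for _, _, s in per_token)))


def per_token_table(results: list[SurprisalResult]):
    """Long-format per-token table (unit_id, position, token, probability,
    surprisal) across units, e.g. for a TSV export."""
    import pandas as pd

    rows = [{"unit_id": r.unit_id, "position": i, "token": tok,
             "probability": p, "surprisal": s}
            for r in results for i, (tok, p, s) in enumerate(r.per_token)]
    return pd.DataFrame(rows, columns=["unit_id", "position", "token",
                                       "probability", "surprisal"])
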