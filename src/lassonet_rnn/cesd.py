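"""CESD-10 depression-scale scoring and binary labeling.

Each of the 10 items is answered on a 4-option frequency scale
(1 = "Rarely or none of the time" ... 4 = "Most or all of the time").
Items 5 and 8 are positively worded and reverse-scored; the total runs
0-30 and a score strictly above 10 defines the depressive group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CESDResponse",
    "POSITIVE_ITEMS",
    "score_cesd",
    "label_depression",
    "score_frame",
]

#: 1-based indices of the positively worded (reverse-scored) items.
POSITIVE_ITEMS = (5, 8)

N_ITEMS = 10
_VALID_OPTIONS = frozenset({1, 2, 3, 4})


@dataclass(frozen=True)
class CESDResponse:
    """One respondent's 10 option indices, each in {1, 2, 3, 4}."""

    options: tuple[int, ...]

    def __post_init__(self) -> None:
        opts = tuple(int(o) for o in self.options)
        object.__setattr__(self, "options", opts)
        if len(opts) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} item responses, got {len(opts)}")
        bad = [o for o in opts if o not in _VALID_OPTIONS]
        if bad:
            raise ValueError(f"option indices must be in {{1,2,3,4}}, got {bad}")


def score_cesd(resp: CESDResponse | Sequence[int]) -> int:
    """Total CESD-10 score in [0, 30].

    Negative items score ``option - 1`` (0..3 ascending with frequency);
    the positive items 5 and 8 score ``4 - option`` (3..0 descending).
    """
    if not isinstance(resp, CESDResponse):
        resp = CESDResponse(tuple(resp))
    total = 0
    for item, option in enumerate(resp.options, start=1):
        total += (4 - option) if item in POSITIVE_ITEMS else (option - 1)
    return total


def label_depression(score: int) -> int:
    """1 (depressive group) iff score > 10, else 0."""
    score = int(score)
    if not 0 <= score <= 30:
        raise ValueError(f"CESD-10 score must be in [0, 30], got {score}")
    return int(score > 10)


def score_frame(df: pd.DataFrame, prefix: str = "cesd_q") -> pd.DataFrame:
    """Score a table with columns ``cesd_q1``..``cesd_q10``.

    Returns a copy with added ``cesd_score`` and ``depressed`` columns.
    Rows with missing or invalid item responses raise.
    """
    cols = [f"{prefix}{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing CESD item columns: {missing}")
    block = df[cols]
    if block.isna().any().any():
        raise ValueError("missing item responses are not scored; drop or impute upstream")
    scores = np.array([score_cesd(tuple(row)) for row in block.to_numpy(dtype=np.int64)])
    out = df.copy()
    out["cesd_score"] = scores
    out["depressed"] = (scores > 10).astype(np.int64)
    return out
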