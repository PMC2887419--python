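"""Expression breadth and bidirectional-promoter coexpression statistics.

A gene counts as expressed in a tissue when its signal exceeds 200 (strict).
The coexpression value of a gene pair is the fraction of tissues in which
the two genes are concordant — both expressed or both not expressed —
among the tissues with expression data for both. Pairs with a value of at
most 0.2 are divergent, exactly 1.0 coexpressed, anything else intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError

__all__ = [
    "ExpressionParams",
    "CoexpressionResult",
    "expression_breadth",
    "coexpression_value",
    "load_expression_table",
]


@dataclass(frozen=True)
class ExpressionParams:
    expressed_min_signal: float = 200.0  # strict >
    divergent_max: float = 0.2
    coexpressed_value: float = 1.0

    def __post_init__(self) -> None:
        if self.expressed_min_signal <= 0 or self.divergent_max <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class CoexpressionResult:
    value: float
    klass: str  # "divergent" | "coexpressed" | "intermediate"
    n_tissues: int


def load_expression_table(path) -> pd.DataFrame:
    """Read a tab-delimited expression table: gene, tissue, signal."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "tissue", "signal") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    return df


def _aligned(signals_a, signals_b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(signals_a, (Mapping, pd.Series)) and isinstance(signals_b, (Mapping, pd.Series)):
        sa = pd.Series(signals_a).dropna()
        sb = pd.Series(signals_b).dropna()
        common = sa.index.intersection(sb.index)
        return sa[common].to_numpy(float), sb[common].to_numpy(float)
    a = np.asarray(signals_a, dtype=float)
    b = np.asarray(signals_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"mismatched tissue panels: {a.shape} vs {b.shape}")
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def expression_breadth(signals: Sequence[float], params: ExpressionParams = ExpressionParams()) -> float:
    """Fraction of tissues with signal above the expression cutoff."""
    a = np.asarray(signals, dtype=float)
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise InsufficientDataError("expression breadth needs >= 1 tissue with data")
    return float(np.mean(a > params.expressed_min_signal))


def coexpression_value(
    signals_a, signals_b, params: ExpressionParams = ExpressionParams()
) -> CoexpressionResult:
    """Concordance of two genes' on/off expression profiles.

    Accepts aligned sequences or tissue-indexed mappings/Series; tissues
    missing a signal for either gene are excluded from numerator and
    denominator. Symmetric in its arguments; self-coexpression is 1.0.
    """
    a, b = _aligned(signals_a, signals_b)
    if a.size == 0:
        raise InsufficientDataError("no tissues with expression data for both genes")
    on_a = a > params.expressed_min_signal
    on_b = b > params.expressed_min_signal
    value = float(np.mean(on_a == on_b))
    if value <= params.divergent_max:
        klass = "divergent"
    elif value == params.coexpressed_value:
        klass = "coexpressed"
    else:
        klass = "intermediate"
    return CoexpressionResult(value=value, klass=klass, n_tissues=int(a.size))
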