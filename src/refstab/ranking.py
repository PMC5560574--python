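"""Comprehensive reference-gene ranking: geometric mean of per-method ranks.

Each stability method produces a rank per candidate; the comprehensive
stability value of a candidate is the geometric mean of its ranks across
the methods, and the final order sorts these ascending. With k candidates
the value is bounded in [1, k], reaching either bound only when all methods
agree unanimously.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import DataError, DomainError
from .stability import StabilityResult, rank_ascending


def ranks_from_stability(result: StabilityResult | pd.Series) -> pd.Series:
    """Rank vector (ascending, average ties) from a stability result.

    A :class:`StabilityResult` that already carries ranks (e.g. geNorm's
    finalist convention, where the two last-surviving genes share rank 1)
    keeps them; a bare Series of stability values is ranked here.
    """
    if isinstance(result, StabilityResult):
        return result.ranks.astype(float)
    return rank_ascending(result)


def geometric_mean_ranks(ranks: pd.DataFrame) -> pd.Series:
    """Row-wise geometric mean of a genes x methods rank table."""
    arr = ranks.to_numpy(float)
    if not np.isfinite(arr).all() or (arr < 1).any():
        raise DomainError("ranks must be finite and >= 1")
    return pd.Series(np.exp(np.log(arr).mean(axis=1)), index=ranks.index, name="stability")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in printed stability tables."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP)
    )


@dataclass
class ComprehensiveRanking:
    """Aggregated ranking across methods.

    ``table`` has one row per primer pair with each method's rank, the
    geometric-mean ``stability`` value and the ``final_rank`` position
    (ascending stability; ties broken by mean rank, then primer_pair_id).
    """

    table: pd.DataFrame
    methods: tuple[str, ...]

    @property
    def final_order(self) -> list[str]:
        return list(self.table.sort_values("final_rank").index)

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        out = self.table.copy()
        out["stability"] = out["stability"].map(lambda v: round_half_up(v, ndigits))
        out.index.name = "primer_pair"
        return out.reset_index().sort_values("final_rank", ignore_index=True)


def comprehensive_rank(results: list[StabilityResult | pd.Series]) -> ComprehensiveRanking:
    """Aggregate per-method stability results into a comprehensive ranking.

    All results must cover the identical primer-pair set; a mismatch raises
    with the differing genes listed. Non-integer (tied) ranks enter the
    geometric mean as-is. The aggregation is symmetric in the methods.
    """
    rank_vecs = []
    names = []
    for i, res in enumerate(results):
        r = ranks_from_stability(res)
        name = res.method if isinstance(res, StabilityResult) else (r.name or f"method{i + 1}")
        names.append(name)
        rank_vecs.append(r.rename(name))
    base = set(rank_vecs[0].index)
    for r in rank_vecs[1:]:
        if set(r.index) != base:
            only_a = sorted(base - set(r.index))
            only_b = sorted(set(r.index) - base)
            raise DataError(
                f"methods cover different primer-pair sets; only in first: {only_a}, "
                f"only in {r.name}: {only_b}"
            )
    ranks = pd.concat([r.sort_index() for r in rank_vecs], axis=1)
    stability = geometric_mean_ranks(ranks)
    mean_rank = ranks.mean(axis=1)
    order = sorted(
        ranks.index, key=lambda g: (stability[g], mean_rank[g], g)
    )
    final_rank = pd.Series({g: i + 1 for i, g in enumerate(order)}, name="final_rank")
    table = ranks.copy()
    table["stability"] = stability
    table["final_rank"] = final_rank
    return ComprehensiveRanking(table=table, methods=tuple(names))
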