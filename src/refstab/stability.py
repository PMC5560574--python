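"""Candidate reference-gene stability statistics.

Four classical methods, each implemented from its definition:

* **geNorm** — a gene's M value is the mean, over all other candidates, of
  the sample standard deviation of the pairwise log2 expression ratio.
  Genes are ranked by iterative elimination of the highest-M gene; the
  pairwise variation V(n/n+1) compares normalization factors built from the
  top n versus n+1 genes.
* **NormFinder** — model-based: fit an additive genes + samples model to
  log2 expression and score each gene by the size of its residuals
  (optionally the unbiased variance estimator, optionally a grouped
  inter/intra-group decomposition).
* **BestKeeper** — descriptive: per-gene Ct standard deviation (plus mean,
  mean absolute deviation, CV%, and the Pearson correlation with the
  BestKeeper index, the per-sample geometric mean Ct).
* **comparative delta-Ct** — a gene's stability is the mean, over all other
  genes, of the standard deviation of their per-sample Ct difference.

All standard deviations use the n-1 (sample) denominator. Lower stability
means a better (smaller) rank. Missing cells exclude the affected sample
pairwise, never the whole gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ctdata import CtMatrix, RQMatrix
from .errors import DomainError, InsufficientDataError

METHODS = ("genorm", "normfinder", "bestkeeper", "delta_ct")


@dataclass
class StabilityResult:
    """Per-gene stability values and ranks for one method.

    ``values`` and ``ranks`` are Series indexed by primer_pair_id; lower
    stability implies a smaller rank. ``extras`` holds method-specific
    tables (geNorm elimination order and V(n/n+1); BestKeeper descriptive
    table; NormFinder mode).
    """

    method: str
    values: pd.Series
    ranks: pd.Series
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"method": self.method, "stability": self.values, "rank": self.ranks}
        )
        df.index.name = "primer_pair"
        return df.reset_index().sort_values(["rank", "primer_pair"], ignore_index=True)


def rank_ascending(values: pd.Series) -> pd.Series:
    """Ascending ranks with average ties (lower stability = rank 1)."""
    if not np.isfinite(values.to_numpy(float)).all():
        raise DomainError("cannot rank non-finite stability values")
    return values.rank(method="average")


def _pairwise_sd(x: pd.DataFrame) -> pd.DataFrame:
    """Matrix of sample SDs of row differences x_j - x_k (pairwise-complete)."""
    genes = x.index
    out = pd.DataFrame(np.nan, index=genes, columns=genes)
    arr = x.to_numpy(float)
    for j in range(len(genes)):
        for k in range(j + 1, len(genes)):
            d = arr[j] - arr[k]
            d = d[np.isfinite(d)]
            if len(d) < 2:
                raise InsufficientDataError(
                    f"fewer than 2 complete samples shared by {genes[j]} and {genes[k]}"
                )
            sd = float(np.std(d, ddof=1))
            out.iat[j, k] = out.iat[k, j] = sd
    return out


# ---------------------------------------------------------------------------
# geNorm


def genorm_m_values(rq: RQMatrix, subset: list[str] | None = None) -> pd.Series:
    """geNorm expression-stability measure M for each candidate.

    M_j = mean over k != j of the sample SD of log2(RQ_j / RQ_k).
    """
    vals = rq.values if subset is None else rq.values.loc[list(subset)]
    if len(vals.index) < 2:
        raise InsufficientDataError("geNorm needs at least 2 primer pairs")
    if vals.shape[1] < 2:
        raise InsufficientDataError("geNorm needs at least 2 samples")
    arr = vals.to_numpy(float)
    if np.any(arr[np.isfinite(arr)] <= 0):
        raise DomainError("geNorm requires strictly positive relative quantities")
    logx = np.log2(vals)
    v = _pairwise_sd(logx)
    m = v.mean(axis=1, skipna=True)
    m.name = "M"
    return m


def genorm_rank(rq: RQMatrix, finalists_rank_one: bool = True) -> StabilityResult:
    """Rank candidates by iterative elimination of the least stable gene.

    The gene with the highest M is removed and M values recomputed until two
    genes remain. The two finalists cannot be ordered by geNorm and both
    receive rank 1 by default (competition ranking: the next gene gets
    rank 3); ``finalists_rank_one=False`` instead orders them by their final
    M. Ties in M are broken by eliminating the lexicographically greatest
    primer_pair_id, making the elimination order deterministic.

    The reported stability value per gene is its M at the elimination step
    (finalists: their final-round M).
    """
    genes = list(rq.values.index)
    k = len(genes)
    if k < 3:
        raise InsufficientDataError("geNorm ranking needs at least 3 primer pairs")
    remaining = sorted(genes)
    elimination: list[str] = []
    values = pd.Series(np.nan, index=pd.Index(genes, name="primer_pair"), name="M")
    m_history = []
    while len(remaining) > 2:
        m = genorm_m_values(rq, subset=remaining)
        m_history.append(m.copy())
        worst_m = m.max()
        worst = max(g for g in remaining if m[g] == worst_m)  # lexicographic tie-break
        values[worst] = m[worst]
        elimination.append(worst)
        remaining = [g for g in remaining if g != worst]
    final_m = genorm_m_values(rq, subset=remaining)
    m_history.append(final_m.copy())
    for g in remaining:
        values[g] = final_m[g]

    ranks = pd.Series(np.nan, index=values.index, name="rank")
    finalists = sorted(remaining)
    if finalists_rank_one:
        for g in finalists:
            ranks[g] = 1.0
        next_rank = 3  # competition ranking after the tied finalists
    else:
        order = sorted(finalists, key=lambda g: (final_m[g], g))
        ranks[order[0]], ranks[order[1]] = 1.0, 2.0
        next_rank = 3
    for i, g in enumerate(reversed(elimination)):
        ranks[g] = float(next_rank + i)

    return StabilityResult(
        method="genorm",
        values=values,
        ranks=ranks,
        extras={
            "elimination_order": elimination,
            "finalists": finalists,
            "finalists_rank_one": finalists_rank_one,
            "m_history": m_history,
        },
    )


def genorm_pairwise_variation(rq: RQMatrix, ranked_genes: list[str]) -> pd.Series:
    """Pairwise variation V(n/n+1) for n = 2..k-1 over a ranked gene list.

    NF_n(s) is the geometric mean of the RQ of the top-n genes in sample s;
    V(n/n+1) is the sample SD over s of log2(NF_n / NF_{n+1}). Small V means
    adding the (n+1)-th gene barely changes the normalization factor.
    """
    k = len(ranked_genes)
    if k < 3:
        raise InsufficientDataError("pairwise variation needs at least 3 ranked genes")
    logx = np.log2(rq.values.loc[list(ranked_genes)]).to_numpy(float)
    out = {}
    for n in range(2, k):
        log_nf_n = logx[:n].mean(axis=0)
        log_nf_n1 = logx[: n + 1].mean(axis=0)
        d = log_nf_n - log_nf_n1
        d = d[np.isfinite(d)]
        if len(d) < 2:
            raise InsufficientDataError("pairwise variation needs >= 2 complete samples")
        out[f"V{n}/{n + 1}"] = float(np.std(d, ddof=1))
    return pd.Series(out, name="V")


# ---------------------------------------------------------------------------
# NormFinder


def normfinder_stability(
    y: pd.DataFrame,
    groups: pd.Series | None = None,
    bias_corrected: bool = False,
) -> StabilityResult:
    """Model-based stability from a complete log2 expression matrix.

    Ungrouped mode fits the additive model ``y_ij = gene_i + sample_j + e_ij``
    by double centering; gene i's stability is the root mean square of its
    residuals, ``sqrt(sum_j r_ij^2 / (n - 1))``. With ``bias_corrected=True``
    the unbiased gene-variance estimator for double-centered residuals is
    used instead (requires >= 3 genes); negative estimates are floored at 0.

    Grouped mode (``groups``: Series mapping sample -> group label, >= 2
    samples per group) scores each gene by the average over groups of
    |inter-group deviation| + sqrt(within-group variance / n_g) — the
    inter/intra decomposition without shrinkage of the group deviations.
    """
    if y.isna().to_numpy().any():
        raise DomainError("NormFinder requires a complete matrix (impute or drop first)")
    k, n = y.shape
    if n < 2:
        raise InsufficientDataError("NormFinder needs at least 2 samples")
    if k < 2:
        raise InsufficientDataError("NormFinder needs at least 2 genes")

    extras: dict = {"mode": "ungrouped", "bias_corrected": bias_corrected}
    arr = y.to_numpy(float)

    if groups is None:
        r = arr - arr.mean(axis=1, keepdims=True) - arr.mean(axis=0, keepdims=True) + arr.mean()
        z = (r**2).sum(axis=1) / (n - 1)
        if bias_corrected:
            if k < 3:
                raise InsufficientDataError("bias correction needs at least 3 genes")
            total = z.sum() * k / (k - 1)
            var = np.maximum((z - total / k**2) * k / (k - 2), 0.0)
            stab = np.sqrt(var)
        else:
            stab = np.sqrt(z)
    else:
        groups = groups.reindex(y.columns)
        if groups.isna().any():
            raise DomainError("every sample needs a group label")
        labels = groups.unique()
        if any((groups == g).sum() < 2 for g in labels):
            raise InsufficientDataError("each group needs at least 2 samples")
        extras["mode"] = "grouped-simplified"
        d = np.zeros((k, len(labels)))
        score = np.zeros((k, len(labels)))
        for gi, g in enumerate(labels):
            sub = arr[:, (groups == g).to_numpy()]
            ng = sub.shape[1]
            rg = sub - sub.mean(axis=1, keepdims=True) - sub.mean(axis=0, keepdims=True) + sub.mean()
            gamma2 = (rg**2).sum(axis=1) / (ng - 1)
            d[:, gi] = sub.mean(axis=1) - sub.mean()
            score[:, gi] = np.sqrt(gamma2 / ng)
        d -= d.mean(axis=1, keepdims=True)  # gene deviations sum to zero over groups
        stab = (np.abs(d) + score).mean(axis=1)
        extras["group_deviations"] = pd.DataFrame(d, index=y.index, columns=labels)

    values = pd.Series(stab, index=y.index, name="stability")
    values.index.name = "primer_pair"
    return StabilityResult(
        method="normfinder", values=values, ranks=rank_ascending(values), extras=extras
    )


# ---------------------------------------------------------------------------
# BestKeeper


def bestkeeper_stability(ct: CtMatrix) -> StabilityResult:
    """Descriptive BestKeeper statistics on a replicate-aggregated Ct matrix.

    Per gene: mean Ct, sample SD, mean absolute deviation from the mean, and
    CV% = SD/mean x 100. The BestKeeper index is the per-sample geometric
    mean of Ct over all candidates; each gene's Pearson r against the index
    goes to ``extras`` (NaN and flagged when either side is constant).
    Ranking is by SD ascending.
    """
    wide = ct.pivot()
    if wide.shape[1] < 2:
        raise InsufficientDataError("BestKeeper needs at least 2 samples")
    rows = {}
    for g in wide.index:
        v = wide.loc[g].dropna().to_numpy(float)
        if len(v) < 2:
            raise InsufficientDataError(f"{g}: fewer than 2 samples with Ct")
        mean = float(v.mean())
        if mean == 0:
            raise DomainError(f"{g}: zero mean Ct, CV undefined")
        rows[g] = {
            "mean_ct": mean,
            "sd": float(np.std(v, ddof=1)),
            "mad": float(np.abs(v - mean).mean()),
            "cv_pct": float(np.std(v, ddof=1) / mean * 100.0),
        }
    table = pd.DataFrame.from_dict(rows, orient="index").loc[wide.index]

    # BestKeeper index: per-sample geometric mean over complete candidates
    index = pd.Series(
        np.exp(np.log(wide).mean(axis=0, skipna=True)), index=wide.columns, name="bk_index"
    )
    corr, pvals, degenerate = {}, {}, []
    for g in wide.index:
        mask = wide.loc[g].notna()
        x, yv = wide.loc[g, mask].to_numpy(float), index[mask].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(yv) == 0:
            corr[g], pvals[g] = np.nan, np.nan
            degenerate.append(g)
        else:
            r, p = sps.pearsonr(x, yv)
            corr[g], pvals[g] = float(r), float(p)
    table["r_vs_index"] = pd.Series(corr)
    table["p_vs_index"] = pd.Series(pvals)

    values = table["sd"].rename("stability")
    values.index.name = "primer_pair"
    return StabilityResult(
        method="bestkeeper",
        values=values,
        ranks=rank_ascending(values),
        extras={"table": table, "index": index, "constant_input": degenerate},
    )


# ---------------------------------------------------------------------------
# comparative delta-Ct


def delta_ct_stability(ct: CtMatrix) -> StabilityResult:
    """Comparative delta-Ct stability on a replicate-aggregated Ct matrix.

    For each gene pair the per-sample Ct difference is formed; a gene's
    stability is the mean SD of its differences against all other genes.
    """
    wide = ct.pivot()
    if wide.shape[0] < 2:
        raise InsufficientDataError("delta-Ct needs at least 2 genes")
    if wide.shape[1] < 2:
        raise InsufficientDataError("delta-Ct needs at least 2 samples")
    sd = _pairwise_sd(wide)
    values = sd.mean(axis=1, skipna=True).rename("stability")
    values.index.name = "primer_pair"
    return StabilityResult(
        method="delta_ct",
        values=values,
        ranks=rank_ascending(values),
        extras={"pairwise_sd": sd},
    )
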