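"""Independent brute-force recomputations of every stability statistic.

Plain-Python loops over dict-of-dicts inputs, using ``statistics.stdev``
(n-1 denominator) and ``math`` only — deliberately sharing no code path
with the package implementations they check.
"""

import math
import statistics


def genorm_m_brute(rq: dict) -> dict:
    """rq: {gene: {sample: value}} -> {gene: M}."""
    genes = sorted(rq)
    samples = sorted(rq[genes[0]])
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratios = [math.log2(rq[j][s] / rq[k][s]) for s in samples]
            sds.append(statistics.stdev(ratios))
        out[j] = sum(sds) / len(sds)
    return out


def genorm_v_brute(rq: dict, ranked: list) -> dict:
    """Pairwise variation V(n/n+1) for n = 2..k-1 from a ranked gene list."""
    samples = sorted(rq[ranked[0]])
    out = {}
    for n in range(2, len(ranked)):
        diffs = []
        for s in samples:
            nf_n = math.prod(rq[g][s] for g in ranked[:n]) ** (1.0 / n)
            nf_n1 = math.prod(rq[g][s] for g in ranked[: n + 1]) ** (1.0 / (n + 1))
            diffs.append(math.log2(nf_n / nf_n1))
        out[n] = statistics.stdev(diffs)
    return out


def delta_ct_brute(ct: dict) -> dict:
    """ct: {gene: {sample: Ct}} -> {gene: mean pairwise delta-Ct SD}."""
    genes = sorted(ct)
    samples = sorted(ct[genes[0]])
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            diffs = [ct[j][s] - ct[k][s] for s in samples]
            sds.append(statistics.stdev(diffs))
        out[j] = sum(sds) / len(sds)
    return out


def bestkeeper_sd_brute(ct: dict) -> dict:
    """Per-gene sample SD of Ct."""
    return {g: statistics.stdev(list(d.values())) for g, d in ct.items()}


def normfinder_brute(y: dict) -> dict:
    """y: {gene: {sample: log2 value}} -> {gene: sqrt(sum resid^2/(n-1))}."""
    genes = sorted(y)
    samples = sorted(y[genes[0]])
    k, n = len(genes), len(samples)
    grand = sum(y[g][s] for g in genes for s in samples) / (k * n)
    gene_mean = {g: sum(y[g][s] for s in samples) / n for g in genes}
    sample_mean = {s: sum(y[g][s] for g in genes) / k for s in samples}
    out = {}
    for g in genes:
        ss = sum((y[g][s] - gene_mean[g] - sample_mean[s] + grand) ** 2 for s in samples)
        out[g] = math.sqrt(ss / (n - 1))
    return out


def geomean_brute(xs) -> float:
    return math.prod(xs) ** (1.0 / len(xs))
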