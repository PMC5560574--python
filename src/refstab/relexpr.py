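"""Target-gene expression normalized against reference gene(s).

Per sample the target's efficiency-corrected quantity is divided by the
normalization factor (geometric mean over references of their quantities),
the ratios are rescaled so a designated calibrator group averages exactly 1,
and mean +/- standard error is reported per (organ, gender[, priming]) over
biological replicates (plants), not technical replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctdata import CtMatrix, PrimerPairInfo
from .errors import DataError, InsufficientDataError


@dataclass
class RelExprProfile:
    """Normalized expression of one target gene.

    ``per_sample``: one calibrated ratio per sample with its metadata (the
    table downstream ANOVA-style comparisons consume). ``profile``: mean,
    standard error and n per (organ, gender, priming) group.
    """

    target: str
    references: tuple[str, ...]
    calibrator: tuple[str, str]
    per_sample: pd.DataFrame
    profile: pd.DataFrame


def relative_expression(
    ct: CtMatrix,
    target: str,
    references: list[str],
    primers: dict[str, PrimerPairInfo],
    calibrator: tuple[str, str] = ("organ", "leaf"),
) -> RelExprProfile:
    """Normalize ``target`` against ``references`` on a replicate-aggregated matrix.

    Per sample s: ratio(s) = base_t^(-Ct_t,s) / geomean_r base_r^(-Ct_r,s),
    then all ratios are divided by the grand mean of the calibrator group
    (default: leaf samples), whose reported mean is therefore exactly 1.
    Samples missing the target or any reference are excluded with a warning.
    """
    wide = ct.pivot()
    needed = [target, *references]
    absent = [g for g in needed if g not in wide.index]
    if absent:
        raise DataError(f"primer pair(s) not in Ct matrix: {absent}")
    no_eff = [g for g in needed if g not in primers]
    if no_eff:
        raise DataError(f"no efficiency for primer pair(s): {no_eff}")

    sub = wide.loc[needed]
    complete = sub.notna().all(axis=0)
    dropped = [s for s in sub.columns if not complete[s]]
    if dropped:
        warnings.warn(
            f"excluding {len(dropped)} sample(s) missing target or reference Ct: {dropped}",
            stacklevel=2,
        )
    sub = sub.loc[:, complete]
    if sub.shape[1] == 0:
        raise InsufficientDataError("no sample has both target and all references")

    log2q = pd.DataFrame(
        {s: [-sub.at[g, s] * np.log2(primers[g].base) for g in needed] for s in sub.columns},
        index=needed,
    )
    log2_ratio = log2q.loc[target] - log2q.loc[references].mean(axis=0)
    ratio = np.power(2.0, log2_ratio)

    meta = ct.samples.loc[ratio.index]
    key, value = calibrator
    cal_mask = meta[key] == value
    if not cal_mask.any():
        raise DataError(f"no sample in calibrator group {key}={value!r}")
    ratio = ratio / ratio[cal_mask].mean()

    per_sample = meta.copy()
    per_sample["ratio"] = ratio
    per_sample.index.name = "sample_id"

    group_keys = ["organ", "gender", "priming"]
    profile = (
        per_sample.groupby(group_keys)["ratio"]
        .agg(mean="mean", se=lambda v: np.std(v, ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    return RelExprProfile(
        target=target,
        references=tuple(references),
        calibrator=calibrator,
        per_sample=per_sample.reset_index(),
        profile=profile,
    )
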