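"""Data model, I/O and transformations for qPCR threshold-cycle (Ct) tables.

The central containers are :class:`CtMatrix` (long-format technical-replicate
Ct values keyed by primer pair, sample and replicate, with per-sample
metadata) and :class:`RQMatrix` (efficiency-corrected relative quantities,
one value per primer pair and sample, scaled so each primer pair's maximum
is exactly 1).

Relative quantities follow the standard efficiency-corrected transform

    RQ(g, s) = (1 + E_g) ** (Ctmin_g - Ct_{g,s})

where ``E_g`` is the primer pair's qPCR efficiency (1.0 = perfect doubling)
and ``Ctmin_g`` is the minimum Ct of that primer pair over the samples under
analysis, so the most-expressed sample gets RQ = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, IntegrityError, SchemaError

ORGANS = ("bud", "leaf", "root", "pollen")
GENDERS = ("F", "H")
PRIMINGS = ("oligo_dT", "random")

#: canonical long-format column order
CT_COLUMNS = (
    "sample_id",
    "plant_id",
    "organ",
    "gender",
    "priming",
    "dataset_tag",
    "primer_pair",
    "replicate",
    "ct",
)

META_COLUMNS = ("plant_id", "organ", "gender", "priming", "dataset_tag")

MAX_CT = 50.0  # 50-cycle programme; Ct beyond the run length is invalid


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one cDNA sample (one plant x organ x priming)."""

    sample_id: str
    plant_id: str
    organ: str
    gender: str
    priming: str
    dataset_tag: str = ""

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ConfigError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if self.gender not in GENDERS:
            raise ConfigError(f"unknown gender {self.gender!r}; expected one of {GENDERS}")
        if self.priming not in PRIMINGS:
            raise ConfigError(f"unknown priming {self.priming!r}; expected one of {PRIMINGS}")


@dataclass(frozen=True)
class PrimerPairInfo:
    """A qPCR assay: primer sequences, amplicon length and efficiency.

    ``efficiency`` is the per-cycle gain minus one, in [0, 1]; the
    amplification base is ``1 + efficiency`` (2.0 for a perfect assay).
    Efficiencies below 0.95 and amplicon lengths outside 90-200 bp fall
    outside the usual assay-inclusion envelope and raise a warning only.
    """

    gene_symbol: str
    primer_pair_id: str
    forward_seq: str
    reverse_seq: str
    amplicon_length: int = 0
    efficiency: float = 1.0
    annealing_temp: float = 60.0

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward_seq), ("reverse", self.reverse_seq)):
            if len(seq) < 15:
                raise DomainError(
                    f"{name} primer of {self.primer_pair_id} is {len(seq)} nt; minimum is 15"
                )
            if set(seq.upper()) - set("ACGTN"):
                raise DomainError(f"{name} primer of {self.primer_pair_id} is not a DNA string")
        if not 0.0 <= self.efficiency <= 1.0:
            raise DomainError(
                f"efficiency {self.efficiency} of {self.primer_pair_id} outside [0, 1]"
            )
        if self.efficiency < 0.95:
            warnings.warn(
                f"{self.primer_pair_id}: efficiency {self.efficiency} below the 0.95 "
                "inclusion threshold (base < 1.95)",
                stacklevel=2,
            )
        if self.amplicon_length and not 90 <= self.amplicon_length <= 200:
            warnings.warn(
                f"{self.primer_pair_id}: amplicon length {self.amplicon_length} outside 90-200 bp",
                stacklevel=2,
            )

    @property
    def base(self) -> float:
        """Amplification base ``1 + efficiency``."""
        return 1.0 + self.efficiency


@dataclass
class CtMatrix:
    """Technical-replicate Ct values in long format plus sample metadata.

    ``data`` has columns (primer_pair, sample_id, replicate, ct); missing Ct
    values are explicit NaN rows, never silently dropped. ``samples`` is
    indexed by sample_id and carries plant_id/organ/gender/priming/dataset_tag.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    parse_failures: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"primer_pair", "sample_id", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"CtMatrix data missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["primer_pair", "sample_id", "replicate"])
        if dup.any():
            key = self.data.loc[dup.idxmax(), ["primer_pair", "sample_id", "replicate"]]
            raise IntegrityError(
                "duplicate (primer_pair, sample, replicate) key: "
                f"({key['primer_pair']}, {key['sample_id']}, {key['replicate']})"
            )
        ct = self.data["ct"]
        bad = ct.notna() & ~((ct > 0) & (ct <= MAX_CT))
        if bad.any():
            raise DomainError(
                f"{int(bad.sum())} Ct value(s) outside (0, {MAX_CT}]; first offending "
                f"value {ct[bad].iloc[0]!r}"
            )
        unknown = set(self.data["sample_id"]) - set(self.samples.index)
        if unknown:
            raise IntegrityError(f"Ct rows reference unknown samples: {sorted(unknown)[:5]}")

    # -- basic views -------------------------------------------------------

    @property
    def primer_pairs(self) -> list[str]:
        return sorted(self.data["primer_pair"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    def n_entries(self, include_missing: bool = False) -> int:
        """Number of Ct observations (by default only non-missing ones)."""
        if include_missing:
            return len(self.data)
        return int(self.data["ct"].notna().sum())

    def sample_meta(self, sample_id: str) -> SampleMeta:
        row = self.samples.loc[sample_id]
        return SampleMeta(sample_id=sample_id, **{c: row[c] for c in META_COLUMNS})

    def subset(self, dataset_tag: str | None = None, priming: str | None = None) -> "CtMatrix":
        """Restrict to one analysis subset; Ctmin scaling is then self-contained."""
        keep = pd.Series(True, index=self.samples.index)
        if dataset_tag is not None:
            keep &= self.samples["dataset_tag"] == dataset_tag
        if priming is not None:
            if priming not in PRIMINGS:
                raise ConfigError(f"unknown priming {priming!r}")
            keep &= self.samples["priming"] == priming
        samples = self.samples.loc[keep]
        data = self.data[self.data["sample_id"].isin(samples.index)].reset_index(drop=True)
        return CtMatrix(data=data, samples=samples.copy())

    def pivot(self) -> pd.DataFrame:
        """Genes x samples wide table; requires one replicate per cell."""
        counts = self.data.groupby(["primer_pair", "sample_id"])["replicate"].count()
        if (counts > 1).any():
            raise IntegrityError(
                "matrix still holds technical replicates; aggregate_replicates() first"
            )
        wide = self.data.pivot(index="primer_pair", columns="sample_id", values="ct")
        return wide.sort_index(axis=0).sort_index(axis=1)


@dataclass
class RQMatrix:
    """Relative quantities, genes x samples; per-gene maximum is exactly 1."""

    values: pd.DataFrame  # index primer_pair, columns sample_id
    base: pd.Series  # per primer pair, 1 + efficiency
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise DomainError("relative quantities must be strictly positive")

    def log2(self) -> pd.DataFrame:
        """log2-scale expression; NormFinder's native input."""
        return np.log2(self.values)


# ---------------------------------------------------------------------------
# I/O


def load_ct_table(
    path,
    schema: dict[str, str] | None = None,
    sep: str | None = None,
) -> CtMatrix:
    """Load a long-format delimited Ct table into a validated :class:`CtMatrix`.

    Parameters
    ----------
    path
        TSV/CSV file with columns ``sample_id, plant_id, organ, gender,
        priming, dataset_tag, primer_pair, replicate, ct`` (rename through
        ``schema``: a map from canonical name to the file's column name).
    schema
        Optional column-name mapping, e.g. ``{"ct": "Cq"}``.
    sep
        Field separator; inferred from the file extension when omitted.

    Rows whose Ct does not parse as a number are kept as explicit missing
    values and reported (with 1-based line numbers) in
    ``CtMatrix.parse_failures``.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)
    missing = set(CT_COLUMNS) - set(raw.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")

    ct_num = pd.to_numeric(raw["ct"], errors="coerce")
    failures = [
        (i + 2, raw["ct"].iloc[i])  # +2: 1-based, plus header line
        for i in np.flatnonzero(ct_num.isna().to_numpy())
        if raw["ct"].iloc[i] not in ("", "NA", "NaN", "nan")
    ]

    data = pd.DataFrame(
        {
            "primer_pair": raw["primer_pair"],
            "sample_id": raw["sample_id"],
            "replicate": pd.to_numeric(raw["replicate"]).astype(int),
            "ct": ct_num,
        }
    )
    samples = (
        raw[["sample_id", *META_COLUMNS]].drop_duplicates("sample_id").set_index("sample_id")
    )
    for sid, row in samples.iterrows():
        SampleMeta(sample_id=sid, **{c: row[c] for c in META_COLUMNS})  # validates enums
    return CtMatrix(data=data.reset_index(drop=True), samples=samples, parse_failures=failures)


def write_ct_table(ct: CtMatrix, path) -> None:
    """Write a CtMatrix back to canonical long-format TSV (round-trip safe)."""
    out = ct.data.merge(ct.samples.reset_index(), on="sample_id", how="left")
    out = out[list(CT_COLUMNS)]
    out.to_csv(path, sep="\t", index=False)


def load_primer_table(path, sep: str = "\t") -> dict[str, PrimerPairInfo]:
    """Load a primer/efficiency table (one row per primer pair)."""
    raw = pd.read_csv(path, sep=sep, comment="#")
    need = {"gene_symbol", "primer_pair", "forward_seq", "reverse_seq", "efficiency"}
    missing = need - set(raw.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    out = {}
    for _, r in raw.iterrows():
        out[r["primer_pair"]] = PrimerPairInfo(
            gene_symbol=r["gene_symbol"],
            primer_pair_id=r["primer_pair"],
            forward_seq=r["forward_seq"],
            reverse_seq=r["reverse_seq"],
            amplicon_length=int(r.get("amplicon_length", 0) or 0),
            efficiency=float(r["efficiency"]),
            annealing_temp=float(r.get("annealing_temp", 60.0) or 60.0),
        )
    return out


# ---------------------------------------------------------------------------
# Transformations


def aggregate_replicates(ct: CtMatrix, method: str = "mean") -> CtMatrix:
    """Collapse technical replicates to one Ct per (primer pair, sample).

    ``method="none"`` returns the input unchanged (replicates fed to the
    downstream statistics as independent observations). Missing replicates
    are ignored in the mean/median; a cell with no finite replicate stays
    explicitly missing.
    """
    if method == "none":
        return ct
    if method not in ("mean", "median"):
        raise ConfigError(f"unknown aggregation method {method!r}")
    agg = (
        ct.data.groupby(["primer_pair", "sample_id"], sort=False)["ct"]
        .agg(method)
        .reset_index()
    )
    agg["replicate"] = 0
    agg = agg[["primer_pair", "sample_id", "replicate", "ct"]]
    return CtMatrix(data=agg, samples=ct.samples.copy())


def replicates_as_samples(ct: CtMatrix) -> CtMatrix:
    """Promote each technical replicate to its own pseudo-sample.

    Reproduces the usage in which all technical Ct replicates are fed to the
    stability methods as independent observations. Pseudo-sample ids are
    ``<sample_id>#r<replicate>``; metadata is copied from the parent sample.
    """
    data = ct.data.copy()
    data["sample_id"] = (
        data["sample_id"].astype(str) + "#r" + data["replicate"].astype(str)
    )
    data["replicate"] = 0
    samples = ct.samples.loc[ct.data["sample_id"]].copy()
    samples.index = data["sample_id"].to_numpy()
    samples = samples[~samples.index.duplicated()]
    samples.index.name = "sample_id"
    return CtMatrix(data=data.reset_index(drop=True), samples=samples)


def to_relative_quantities(ct: CtMatrix, primers: dict[str, PrimerPairInfo]) -> RQMatrix:
    """Efficiency-corrected relative quantities from a replicate-aggregated matrix.

    RQ(g, s) = base_g ** (Ctmin_g - Ct_{g,s}); Ctmin is taken over the samples
    present in ``ct``, so subset first to keep each dataset self-contained.
    """
    wide = ct.pivot()
    missing_eff = [g for g in wide.index if g not in primers]
    if missing_eff:
        raise SchemaError(f"no efficiency for primer pair(s): {missing_eff}")
    base = pd.Series({g: primers[g].base for g in wide.index}, name="base")
    ctmin = wide.min(axis=1)
    rq = pd.DataFrame(
        np.power(base.to_numpy()[:, None], (ctmin.to_numpy()[:, None] - wide.to_numpy())),
        index=wide.index,
        columns=wide.columns,
    )
    samples = ct.samples.loc[[s for s in wide.columns]]
    return RQMatrix(values=rq, base=base, samples=samples)


def ct_summary(ct: CtMatrix, group_by: list[str] | None = None) -> pd.DataFrame:
    """Per-primer-pair distribution summary of pooled replicate Ct values.

    Returns median, 25th/75th percentile (linear interpolation), min, max and
    n for each primer pair, optionally split by sample-metadata keys
    (``organ``, ``priming``, ...).
    """
    group_by = list(group_by or [])
    unknown = [g for g in group_by if g not in META_COLUMNS]
    if unknown:
        raise ConfigError(f"unknown group key(s) {unknown}; valid keys: {list(META_COLUMNS)}")
    merged = ct.data.merge(ct.samples.reset_index(), on="sample_id", how="left")
    merged = merged[merged["ct"].notna()]
    if merged.empty:
        raise DomainError("no finite Ct values to summarize")

    def _summarize(vals: pd.Series) -> pd.Series:
        q25, med, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        return pd.Series(
            {
                "median": med,
                "q25": q25,
                "q75": q75,
                "min": vals.min(),
                "max": vals.max(),
                "n": len(vals),
            }
        )

    keys = ["primer_pair", *group_by]
    out = merged.groupby(keys)["ct"].apply(_summarize).unstack()
    out["n"] = out["n"].astype(int)
    return out.reset_index()
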