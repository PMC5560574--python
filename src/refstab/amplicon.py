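"""Amplicon read-coverage validation of reference-gene stability.

RNA-seq reads are aligned, exactly and full-length, to short primer-anchored
reference segments (each primer plus up to 30 nt of flank on either side,
giving 160 mappable bases for a standard pair of 20-nt primers). Summed
per-base depth is converted to an RPKM-equivalent using an edge-adjusted
effective length: a position inside the primer can be covered by every
overlapping read, while flank positions ramp down towards the segment ends,
averaging 50% of the plateau depth — so each flank base contributes half a
fully-mappable base (the standard 160-nt reference has an adjusted length
of 100 nt). Candidates are then ranked by the coefficient of variation of
their RPKM-equivalents across samples.

With total_depth = sum of per-base depths and uniform read length L, the
number of aligned reads is total_depth / L and

    rpkm_eq = (total_depth / L) * 1e9 / (adjusted_length * total_reads)

i.e. reads per kilobase of effective length per million total reads.

Alignment requires a zero-mismatch, full-length match entirely within a
segment, on either strand, so an exact substring matcher implements the
contract directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .ctdata import PrimerPairInfo
from .errors import DataError, DomainError, InsufficientDataError

DEFAULT_FLANK = 30
DEFAULT_READ_LENGTH = 50
DEFAULT_FLANK_WEIGHT = 0.5


@dataclass(frozen=True)
class Segment:
    """One mappable segment: up-flank + primer + down-flank on the template."""

    sequence: str
    up_flank: int
    primer_len: int
    down_flank: int
    template_start: int  # 0-based half-open coordinates on the template

    def __post_init__(self) -> None:
        if len(self.sequence) != self.up_flank + self.primer_len + self.down_flank:
            raise DataError("segment length does not match flank/primer decomposition")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def template_end(self) -> int:
        return self.template_start + self.length


@dataclass(frozen=True)
class VariantReference:
    """One template variant of a primer pair: two non-overlapping segments."""

    variant_id: str
    segments: tuple[Segment, Segment]

    @property
    def mappable_length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass
class AmpliconReference:
    """All mappable reference segments for one primer pair.

    Polymorphic flanking regions can require several template variants; the
    standard case is a single variant with 160 mappable bases (two 20-nt
    primers, four full 30-nt flanks).
    """

    primer_pair_id: str
    variants: list[VariantReference] = field(default_factory=list)

    @property
    def mappable_length(self) -> int:
        return sum(v.mappable_length for v in self.variants)


def _find_unique(template: str, pattern: str, label: str) -> int:
    first = template.find(pattern)
    if first < 0:
        raise DataError(f"{label} not found on template")
    if template.find(pattern, first + 1) >= 0:
        raise DataError(f"{label} occurs more than once on template")
    return first


def build_mappable_reference(
    template: str,
    primers: PrimerPairInfo,
    flank: int = DEFAULT_FLANK,
    variant_id: str = "v1",
) -> AmpliconReference:
    """Build the primer-anchored mappable reference from one template.

    Each primer (the reverse primer as its reverse complement) must occur
    exactly once on the template; its segment extends ``flank`` nt on both
    sides, truncated at the template ends. The two segments must not overlap.
    Additional template variants can be appended with
    :func:`add_reference_variant`.
    """
    template = template.upper()
    ref = AmpliconReference(primer_pair_id=primers.primer_pair_id)
    add_reference_variant(ref, template, primers, flank=flank, variant_id=variant_id)
    return ref


def add_reference_variant(
    ref: AmpliconReference,
    template: str,
    primers: PrimerPairInfo,
    flank: int = DEFAULT_FLANK,
    variant_id: str | None = None,
) -> AmpliconReference:
    """Locate both primers on ``template`` and append a variant to ``ref``."""
    template = template.upper()
    fwd = primers.forward_seq.upper()
    rev = reverse_complement(primers.reverse_seq.upper())
    segs = []
    for label, primer in (
        (f"forward primer of {primers.primer_pair_id}", fwd),
        (f"reverse primer of {primers.primer_pair_id}", rev),
    ):
        start = _find_unique(template, primer, label)
        seg_start = max(0, start - flank)
        seg_end = min(len(template), start + len(primer) + flank)
        segs.append(
            Segment(
                sequence=template[seg_start:seg_end],
                up_flank=start - seg_start,
                primer_len=len(primer),
                down_flank=seg_end - (start + len(primer)),
                template_start=seg_start,
            )
        )
    a, b = sorted(segs, key=lambda s: s.template_start)
    if a.template_end > b.template_start:
        raise DataError(
            f"mappable segments of {primers.primer_pair_id} overlap on the template"
        )
    ref.variants.append(
        VariantReference(
            variant_id=variant_id or f"v{len(ref.variants) + 1}", segments=(segs[0], segs[1])
        )
    )
    return ref


def compute_adjusted_length(
    ref: AmpliconReference, flank_weight: float = DEFAULT_FLANK_WEIGHT
) -> float:
    """Edge-adjusted effective length of a reference.

    Primer bases count fully; flank bases count ``flank_weight`` each
    (default 0.5, the average flank coverage relative to the plateau). The
    standard 160-nt single-variant reference gives 100 nt.
    """
    total = 0.0
    for v in ref.variants:
        for s in v.segments:
            total += s.primer_len + flank_weight * (s.up_flank + s.down_flank)
    return total


def _variant_adjusted_length(v: VariantReference, flank_weight: float) -> float:
    return sum(s.primer_len + flank_weight * (s.up_flank + s.down_flank) for s in v.segments)


@dataclass
class DepthResult:
    """Per-base match depth for each variant segment, plus totals."""

    primer_pair_id: str
    depths: dict[tuple[str, int], np.ndarray]  # (variant_id, segment index) -> depth vector
    total_depth: float
    aligned_reads: int
    per_variant_depth: dict[str, float]


def align_and_depth(
    reads: Iterable,
    ref: AmpliconReference,
    count_all_variants: bool = False,
) -> DepthResult:
    """Exact full-length alignment of reads to the reference segments.

    A read counts iff it matches a segment exactly over its whole length,
    entirely within the segment, on either strand. By default a read is
    counted once per primer pair, at its first match in declared variant and
    segment order (``count_all_variants=True`` restores plain per-variant
    counting, in which a read hitting several variants contributes to each).
    Reads longer than every segment are simply unaligned. Empty read sets
    yield zero depth.
    """
    depths = {
        (v.variant_id, i): np.zeros(seg.length, dtype=np.int64)
        for v in ref.variants
        for i, seg in enumerate(v.segments)
    }
    aligned = 0
    for read in reads:
        seq = str(getattr(read, "seq", read)).upper()
        rc = reverse_complement(seq)
        hit = False
        for v in ref.variants:
            for i, seg in enumerate(v.segments):
                pos = seg.sequence.find(seq)
                if pos < 0:
                    pos = seg.sequence.find(rc)
                if pos >= 0:
                    depths[(v.variant_id, i)][pos : pos + len(seq)] += 1
                    hit = True
                    break  # one segment per variant
            if hit and not count_all_variants:
                break
        if hit:
            aligned += 1
    per_variant = {
        v.variant_id: float(sum(depths[(v.variant_id, i)].sum() for i in range(len(v.segments))))
        for v in ref.variants
    }
    return DepthResult(
        primer_pair_id=ref.primer_pair_id,
        depths=depths,
        total_depth=float(sum(per_variant.values())),
        aligned_reads=aligned,
        per_variant_depth=per_variant,
    )


def rpkm_equivalent(
    total_depth: float,
    adjusted_length: float,
    total_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
) -> float:
    """RPKM-equivalent from summed per-base depth.

    ``(total_depth / read_length) * 1e9 / (adjusted_length * total_reads)``:
    reads per kilobase of edge-adjusted length per million total reads.
    """
    if total_reads <= 0:
        raise DomainError("total_reads must be positive")
    if adjusted_length <= 0:
        raise DomainError("adjusted_length must be positive")
    return (total_depth / read_length) * 1e9 / (adjusted_length * total_reads)


def coverage_for_pair(
    reads: Iterable,
    ref: AmpliconReference,
    total_reads: int,
    read_length: int = DEFAULT_READ_LENGTH,
    flank_weight: float = DEFAULT_FLANK_WEIGHT,
    count_all_variants: bool = False,
) -> tuple[float, DepthResult]:
    """Align reads and return the primer pair's RPKM-equivalent.

    Each variant is normalized by its own adjusted length and the variant
    values are summed.
    """
    depth = align_and_depth(reads, ref, count_all_variants=count_all_variants)
    value = sum(
        rpkm_equivalent(
            depth.per_variant_depth[v.variant_id],
            _variant_adjusted_length(v, flank_weight),
            total_reads,
            read_length,
        )
        for v in ref.variants
    )
    return value, depth


def summarize_cv(values: pd.DataFrame) -> pd.DataFrame:
    """Cross-sample summary and CV ranking of per-sample RPKM-equivalents.

    ``values``: primer pairs x samples. Returns mean, sample SD, CV = sd/mean,
    mfc = max/min, ranked ascending by CV (ties: lexicographic by primer
    pair). A zero mean leaves CV undefined (NaN) and flags the row; flagged
    rows sort last.
    """
    if values.shape[1] < 2:
        raise InsufficientDataError("CV needs at least 2 samples")
    rows = {}
    for g in values.index:
        v = values.loc[g].to_numpy(float)
        mean = float(v.mean())
        sd = float(np.std(v, ddof=1))
        undefined = mean == 0
        vmin = float(v.min())
        rows[g] = {
            "mean": mean,
            "sd": sd,
            "cv": np.nan if undefined else sd / mean,
            "mfc": float(v.max()) / vmin if vmin > 0 else np.nan,
            "cv_undefined": undefined,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    order = sorted(
        out.index,
        key=lambda g: (np.inf if np.isnan(out.at[g, "cv"]) else out.at[g, "cv"], g),
    )
    out = out.loc[order]
    out["rank"] = range(1, len(out) + 1)
    out.index.name = "primer_pair"
    return out
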