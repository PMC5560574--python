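"""Synthetic qPCR and read-set generators with known ground truth.

The Ct generator emulates a reference-gene study across organs of a
gynodioecious plant: per-gene baseline Ct, organ and gender effects, a
global upward Ct shift for random-primed cDNA (random hexamers reverse
transcribe rRNA too, diluting mRNA-derived cDNA by several cycles),
per-sample biological noise on the Ct scale (multiplicative on expression)
and technical-replicate noise. Each gene carries a designed stability
class, so recovery of the designed-stable gene by the stability statistics
can be asserted.

The read generator draws uniform-start, fixed-length single-end reads from
transcript templates proportional to per-sample abundances, the sampling
model under which amplicon coverage statistics have closed-form
expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .amplicon import AmpliconReference, _variant_adjusted_length
from .ctdata import CtMatrix, GENDERS, ORGANS, PRIMINGS, PrimerPairInfo
from .errors import ConfigError

PRIMING_SHORT = {"oligo_dT": "oligo", "random": "random"}


@dataclass
class GeneSim:
    """Design of one simulated primer pair / gene."""

    primer_pair_id: str
    baseline_ct: float
    gene_symbol: str = ""
    efficiency: float = 1.0
    organ_effects: dict = field(default_factory=dict)  # organ -> cycles
    gender_effects: dict = field(default_factory=dict)  # gender -> cycles
    noise_sd: float = 0.5  # biological, cycles
    stability_class: str = "variable"  # "stable" | "variable"
    primings: tuple = PRIMINGS

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"{self.primer_pair_id}: noise_sd must be >= 0")
        if self.stability_class not in ("stable", "variable"):
            raise ConfigError(f"{self.primer_pair_id}: bad stability class {self.stability_class!r}")
        for o in self.organ_effects:
            if o not in ORGANS:
                raise ConfigError(f"{self.primer_pair_id}: unknown organ {o!r}")
        for g in self.gender_effects:
            if g not in GENDERS:
                raise ConfigError(f"{self.primer_pair_id}: unknown gender {g!r}")
        for p in self.primings:
            if p not in PRIMINGS:
                raise ConfigError(f"{self.primer_pair_id}: unknown priming {p!r}")


@dataclass
class CtSimConfig:
    """Full design of a simulated Ct dataset."""

    genes: list  # of GeneSim
    plants: list  # of (plant_id, gender)
    organs: tuple = ("bud", "leaf", "root")
    primings: tuple = PRIMINGS
    priming_shift: float = 4.0  # cycles added under random priming
    tech_noise_sd: float = 0.15  # cycles, per technical replicate
    replicates: int = 4
    dataset_tag: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        for o in self.organs:
            if o not in ORGANS:
                raise ConfigError(f"unknown organ {o!r}")
        for p in self.primings:
            if p not in PRIMINGS:
                raise ConfigError(f"unknown priming {p!r}")
        if self.tech_noise_sd < 0 or self.replicates < 1:
            raise ConfigError("tech_noise_sd must be >= 0 and replicates >= 1")


def simulate_ct_dataset(cfg: CtSimConfig) -> tuple[CtMatrix, pd.DataFrame]:
    """Draw a Ct dataset from the design; returns (matrix, truth table).

    Ct = baseline + organ effect + gender effect + priming shift (random
    priming only) + biological noise (per gene x plant x organ, shared by
    the two primings of the same RNA sample) + technical noise (per
    replicate). The truth table records each gene's designed stability
    class and noise sd. Fixing the seed reproduces the dataset exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    meta_rows = {}
    bio_noise = {
        (g.primer_pair_id, plant, organ): rng.normal(0.0, g.noise_sd)
        for g in cfg.genes
        for plant, _ in cfg.plants
        for organ in cfg.organs
    }
    for plant, gender in cfg.plants:
        for organ in cfg.organs:
            if organ == "pollen" and gender != "H":
                continue  # females shed no pollen
            for priming in cfg.primings:
                sid = f"{cfg.dataset_tag}_{plant}_{organ}_{PRIMING_SHORT[priming]}"
                meta_rows[sid] = {
                    "plant_id": plant,
                    "organ": organ,
                    "gender": gender,
                    "priming": priming,
                    "dataset_tag": cfg.dataset_tag,
                }
                for g in cfg.genes:
                    if priming not in g.primings:
                        continue
                    mu = (
                        g.baseline_ct
                        + g.organ_effects.get(organ, 0.0)
                        + g.gender_effects.get(gender, 0.0)
                        + (cfg.priming_shift if priming == "random" else 0.0)
                        + bio_noise[(g.primer_pair_id, plant, organ)]
                    )
                    for rep in range(1, cfg.replicates + 1):
                        ct_val = mu + rng.normal(0.0, cfg.tech_noise_sd)
                        rows.append((g.primer_pair_id, sid, rep, ct_val))
    data = pd.DataFrame(rows, columns=["primer_pair", "sample_id", "replicate", "ct"])
    samples = pd.DataFrame.from_dict(meta_rows, orient="index")
    samples.index.name = "sample_id"
    truth = pd.DataFrame(
        [
            {
                "primer_pair": g.primer_pair_id,
                "gene_symbol": g.gene_symbol or g.primer_pair_id,
                "baseline_ct": g.baseline_ct,
                "efficiency": g.efficiency,
                "noise_sd": g.noise_sd,
                "stability_class": g.stability_class,
            }
            for g in cfg.genes
        ]
    )
    return CtMatrix(data=data, samples=samples), truth


def primer_infos(cfg: CtSimConfig) -> dict[str, PrimerPairInfo]:
    """Placeholder primer records carrying each simulated gene's efficiency."""
    out = {}
    for g in cfg.genes:
        out[g.primer_pair_id] = PrimerPairInfo(
            gene_symbol=g.gene_symbol or g.primer_pair_id,
            primer_pair_id=g.primer_pair_id,
            forward_seq="ACGT" * 5,
            reverse_seq="TGCA" * 5,
            amplicon_length=120,
            efficiency=g.efficiency,
        )
    return out


# Efficiencies and assay names mirror a typical single-study qPCR panel
# (two assays each for ELF1a and GAPDH, one for the rest; 18S measurable
# only in random-primed cDNA since rRNA lacks a poly(A) tail).
_DEFAULT_GENES = [
    ("Sv_GAPDH 1", "SvGAPDH", 22.0, 1.0, 0.10, "stable", PRIMINGS),
    ("Sv_ACT", "SvACT", 21.0, 0.96, 0.15, "stable", PRIMINGS),
    ("Sv_ELF 1", "SvELF", 20.0, 1.0, 0.35, "variable", PRIMINGS),
    ("Sv_GAPDH 2", "SvGAPDH", 24.5, 0.98, 0.45, "variable", PRIMINGS),
    ("Sv_ELF 2", "SvELF", 23.0, 1.0, 0.60, "variable", PRIMINGS),
    ("Sv_COG", "SvCOG", 28.0, 1.0, 0.75, "variable", PRIMINGS),
    ("Sv_TUB A", "SvTUBA", 24.0, 1.0, 0.90, "variable", PRIMINGS),
    ("Sv_TUB B", "SvTUBB", 25.0, 1.0, 1.10, "variable", PRIMINGS),
    ("Sv_CYP", "SvCYP", 26.0, 1.0, 1.60, "variable", PRIMINGS),
    ("Sv_18S rRNA", "18S rRNA", 10.0, 1.0, 1.00, "variable", ("random",)),
]

#: mild organ effects for "stable" genes, larger ones (pollen especially)
#: for variable genes — pollen transcriptomes diverge most from sporophyte.
_ORGAN_EFFECTS = {
    "stable": {"bud": 0.0, "leaf": 0.1, "root": 0.2, "pollen": 0.3},
    "variable": {"bud": 0.0, "leaf": 0.5, "root": 1.0, "pollen": 2.5},
}


def default_study_config(
    group: str = "H_BLRP", seed: int = 0, include_18s: bool = True
) -> CtSimConfig:
    """Study-design defaults for the two plant groups.

    ``H_BLRP``: 4 hermaphrodite plants, organs bud/leaf/root/pollen.
    ``HF_BLR``: 3 female + 3 hermaphrodite plants, organs bud/leaf/root.
    Both primings, +4-cycle random-priming shift, 4 technical replicates
    with 0.15-cycle noise.
    """
    if group == "H_BLRP":
        plants = [(f"H{i}", "H") for i in range(1, 5)]
        organs = ("bud", "leaf", "root", "pollen")
    elif group == "HF_BLR":
        plants = [(f"F{i}", "F") for i in range(1, 4)] + [(f"H{i}", "H") for i in range(1, 4)]
        organs = ("bud", "leaf", "root")
    else:
        raise ConfigError(f"unknown study group {group!r}")
    genes = [
        GeneSim(
            primer_pair_id=pid,
            gene_symbol=sym,
            baseline_ct=base,
            efficiency=eff,
            organ_effects=_ORGAN_EFFECTS[cls],
            gender_effects={"F": 0.0, "H": 0.1 if cls == "variable" else 0.0},
            noise_sd=sd,
            stability_class=cls,
            primings=primings,
        )
        for pid, sym, base, eff, sd, cls, primings in _DEFAULT_GENES
        if include_18s or pid != "Sv_18S rRNA"
    ]
    return CtSimConfig(
        genes=genes, plants=plants, organs=organs, dataset_tag=group, seed=seed
    )


def recovery_config(seed: int = 0) -> CtSimConfig:
    """Benchmark design for stability-recovery experiments.

    Nine genes whose only stability driver is biological noise: one designed
    stable (sd 0.1 cycles) and eight with escalating noise from 0.5 to 2.0
    cycles; no organ or gender effects, oligo(dT) priming only. The sampling
    frame is the pollen-free study group (3 F + 3 H plants, organs
    bud/leaf/root, 4 technical replicates — 18 biological samples). The
    stable gene should reach comprehensive rank 1 in nearly every draw.
    """
    sds = [0.1] + list(np.linspace(0.5, 2.0, 8))
    genes = [
        GeneSim(
            primer_pair_id=f"G{i + 1:02d}",
            baseline_ct=20.0 + i,
            noise_sd=float(sd),
            stability_class="stable" if i == 0 else "variable",
        )
        for i, sd in enumerate(sds)
    ]
    plants = [(f"F{i}", "F") for i in range(1, 4)] + [(f"H{i}", "H") for i in range(1, 4)]
    return CtSimConfig(
        genes=genes,
        plants=plants,
        organs=("bud", "leaf", "root"),
        primings=("oligo_dT",),
        replicates=4,
        dataset_tag="RECOVERY",
        seed=seed,
    )


def config_from_yaml(path) -> CtSimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        genes = [GeneSim(**g) for g in raw.pop("genes")]
        plants = [tuple(p) for p in raw.pop("plants")]
        for key in ("organs", "primings"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return CtSimConfig(genes=genes, plants=plants, **raw)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"bad Ct simulation config {path}: {exc}") from exc


def config_to_yaml(cfg: CtSimConfig, path) -> None:
    raw = asdict(cfg)
    raw["plants"] = [list(p) for p in cfg.plants]
    for g in raw["genes"]:
        g["primings"] = list(g["primings"])
    raw["organs"], raw["primings"] = list(cfg.organs), list(cfg.primings)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class ReadSimConfig:
    """Uniform single-end read sampling from transcript templates."""

    templates: dict  # template_id -> sequence
    abundances: dict  # sample_id -> {template_id: relative abundance >= 0}
    total_reads: dict  # sample_id -> int
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for sample, ab in self.abundances.items():
            for tid, a in ab.items():
                if tid not in self.templates:
                    raise ConfigError(f"{sample}: unknown template {tid!r}")
                if a < 0:
                    raise ConfigError(f"{sample}/{tid}: abundance must be >= 0")
                if a > 0 and len(self.templates[tid]) < self.read_length:
                    raise ConfigError(
                        f"template {tid} shorter than read length {self.read_length}"
                    )


def simulate_read_set(cfg: ReadSimConfig) -> dict[str, list[SeqRecord]]:
    """Draw reads per sample: template chosen proportional to abundance,
    start position uniform along the template. Deterministic under a fixed
    seed."""
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, list[SeqRecord]] = {}
    for sample in sorted(cfg.abundances):
        ab = cfg.abundances[sample]
        tids = sorted(t for t, a in ab.items() if a > 0)
        records: list[SeqRecord] = []
        n_total = int(cfg.total_reads[sample])
        if tids:
            p = np.array([ab[t] for t in tids], float)
            counts = rng.multinomial(n_total, p / p.sum())
            i = 0
            for tid, n_t in zip(tids, counts):
                seq = cfg.templates[tid]
                starts = rng.integers(0, len(seq) - cfg.read_length + 1, size=n_t)
                for s in starts:
                    records.append(
                        SeqRecord(
                            Seq(seq[s : s + cfg.read_length]),
                            id=f"{sample}:{i}",
                            description=f"{tid}:{s}",
                        )
                    )
                    i += 1
        out[sample] = records
    return out


def write_fastq(records: list[SeqRecord], path) -> None:
    """Write reads as FASTQ with uniform maximal quality."""
    for r in records:
        r.letter_annotations.setdefault("phred_quality", [40] * len(r.seq))
    SeqIO.write(records, path, "fastq")


def expected_rpkm(
    ref: AmpliconReference,
    template_id: str,
    cfg: ReadSimConfig,
    sample: str,
    flank_weight: float = 0.5,
) -> float:
    """Closed-form expected RPKM-equivalent under the uniform read model.

    A read from the template aligns to a segment iff its start falls within
    the segment's (length - read_length + 1) eligible positions out of
    (template_length - read_length + 1) possible starts.
    """
    ab = cfg.abundances[sample]
    p_template = ab.get(template_id, 0.0) / sum(ab.values())
    n_template = cfg.total_reads[sample] * p_template
    tlen = len(cfg.templates[template_id])
    rl = cfg.read_length
    value = 0.0
    for v in ref.variants:
        eligible = sum(max(0, s.length - rl + 1) for s in v.segments)
        exp_reads = n_template * eligible / (tlen - rl + 1)
        adj = _variant_adjusted_length(v, flank_weight)
        value += exp_reads * 1e9 / (adj * cfg.total_reads[sample])
    return value


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string (template scaffolds for read simulation)."""
    return "".join(rng.choice(list("ACGT"), size=length))
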