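import numpy as np
import pandas as pd
import pytest

from refstab.ctdata import CtMatrix, PrimerPairInfo, RQMatrix


def make_samples(sample_ids, organ="leaf", gender="H", priming="oligo_dT", tag="T"):
    df = pd.DataFrame(
        {
            "plant_id": [f"p{i}" for i in range(len(sample_ids))],
            "organ": organ if isinstance(organ, list) else [organ] * len(sample_ids),
            "gender": gender if isinstance(gender, list) else [gender] * len(sample_ids),
            "priming": priming if isinstance(priming, list) else [priming] * len(sample_ids),
            "dataset_tag": [tag] * len(sample_ids),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return df


def make_ct(values: dict, **meta) -> CtMatrix:
    """CtMatrix from {gene: {sample: ct}} (replicate-aggregated) or
    {gene: {sample: [ct, ...]}} (technical replicates)."""
    rows = []
    sample_ids = sorted({s for d in values.values() for s in d})
    for g, d in values.items():
        for s, ct in d.items():
            reps = ct if isinstance(ct, (list, tuple)) else [ct]
            single = not isinstance(ct, (list, tuple))
            for i, c in enumerate(reps):
                rows.append((g, s, 0 if single else i + 1, c))
    data = pd.DataFrame(rows, columns=["primer_pair", "sample_id", "replicate", "ct"])
    return CtMatrix(data=data, samples=make_samples(sample_ids, **meta))


def make_rq(values: dict) -> RQMatrix:
    """RQMatrix from {gene: [rq per sample]}; base 2 throughout."""
    df = pd.DataFrame(values).T
    df.columns = [f"s{i + 1}" for i in range(df.shape[1])]
    return RQMatrix(values=df, base=pd.Series(2.0, index=df.index))


def make_primer(pid="P1", efficiency=1.0, **kw) -> PrimerPairInfo:
    defaults = dict(
        gene_symbol=pid,
        primer_pair_id=pid,
        forward_seq="ACGTACGTACGTACGTACGT",
        reverse_seq="TGCATGCATGCATGCATGCA",
        amplicon_length=120,
        efficiency=efficiency,
    )
    defaults.update(kw)
    return PrimerPairInfo(**defaults)


@pytest.fixture
def rq_abc() -> RQMatrix:
    """Three genes, two samples: A and B co-regulated, C divergent."""
    return make_rq({"A": [1, 0.5], "B": [1, 0.5], "C": [1, 0.125]})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20171)
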