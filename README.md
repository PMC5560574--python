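# refstab

Reference-gene stability analysis for RT-qPCR experiments, with an
RNA-seq amplicon-coverage cross-check.

Accurate RT-qPCR quantification of a target transcript requires dividing
by the signal of one or more *reference genes* whose expression is invariant
across the tissues, genders and cDNA-priming chemistries under study.
`refstab` is for researchers choosing such references — e.g. across buds,
leaves, roots and pollen of a gynodioecious plant with both oligo(dT)- and
random-primed cDNA. It implements, from their definitions:

* **geNorm** — M<sub>j</sub> = mean over genes k ≠ j of the sample SD of
  log₂(RQ<sub>j</sub>/RQ<sub>k</sub>); iterative elimination of the
  highest-M gene; pairwise variation V(n/n+1) = SD of
  log₂(NF<sub>n</sub>/NF<sub>n+1</sub>), NF<sub>n</sub> the geometric mean
  of the top-n genes.
* **NormFinder** — residuals of the additive model
  y<sub>ij</sub> = gene<sub>i</sub> + sample<sub>j</sub> + ε<sub>ij</sub>
  on log₂ expression; stability<sub>i</sub> = √(Σ<sub>j</sub> r<sub>ij</sub>²/(n−1)),
  with optional unbiased-variance and grouped inter/intra modes.
* **BestKeeper** — per-gene Ct SD (plus mean, MAD, CV% and the Pearson
  correlation with the per-sample geometric-mean Ct index).
* **comparative ΔCt** — mean SD of a gene's pairwise per-sample Ct
  differences against every other candidate.
* **Comprehensive ranking** — the geometric mean of a gene's four method
  ranks (the RefFinder aggregation), ascending.
* **Amplicon coverage CV** — reads aligned exactly and full-length to
  160-nt primer-anchored references (two 20-nt primers, four 30-nt flanks),
  converted to an RPKM-equivalent with an edge-adjusted effective length of
  100 nt, and candidates ranked by the coefficient of variation across
  samples.
* **Relative expression** — efficiency-corrected target/reference ratios,
  calibrated so a designated group (default: leaf) averages 1.

Relative quantities use RQ(g,s) = (1+E<sub>g</sub>)^(Ct<sub>min,g</sub> − Ct<sub>g,s</sub>)
with per-assay efficiency E; all SDs use the n−1 denominator.

Synthetic-data generators (`refstab.simulate`) reproduce the study design —
per-gene baseline Ct, organ/gender effects, a +4-cycle shift for
random-primed cDNA, technical-replicate noise, and uniform read sampling
from transcripts — so every stage is testable with known ground truth.

## Worked example

```sh
refstab simulate-ct --group HF_BLR --seed 3 --out sim
refstab stability --ct sim/ct_table.tsv --primers sim/primers.tsv \
        --priming oligo_dT --out stab
```

prints `most stable candidates: Sv_ACT, Sv_GAPDH 1` and writes
`stab/comprehensive_ranking.tsv`, which for this seed begins

```
primer_pair     genorm  normfinder  bestkeeper  delta_ct  stability  final_rank
Sv_ACT          1.0     1.0         2.0         1.0       1.19       1
Sv_GAPDH 1      1.0     2.0         1.0         2.0       1.41       2
Sv_GAPDH 2      3.0     3.0         3.0         3.0       3.0        3
```

Here the two simulated low-noise genes are the geNorm finalists (shared
rank 1) and hold the smallest geometric-mean stability, i.e. they are the
recommended reference pair; `stability` is bounded by the candidate count
and equals 1 only under unanimous first place. Per-method tables and the
geNorm V(n/n+1) series land in the same directory, each stamped with the
run's manifest hash.

The same library surface is importable directly
(`refstab.genorm_rank`, `refstab.comprehensive_rank`, ...), and
`refstab amplicon-cv` / `refstab relexpr` drive the coverage and
normalization analyses.

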