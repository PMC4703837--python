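# madzyd

**Maternal versus zygotic definition of embryonic chromatin state from
transcription-blocked ChIP-seq.**

During early vertebrate development the embryonic genome is transcriptionally
silent until zygotic genome activation, yet chromatin marks such as H3K4me3
(permissive promoter mark), H3K27me3 (Polycomb repression) and p300 binding
(active enhancers) appear around that time. Are they placed by maternally
deposited factors, or do they require the embryo's own transcription? Blocking
RNA polymerase II with α-amanitin and comparing ChIP-seq of blocked versus
control embryos at mid-gastrulation (stage 11) answers the question region by
region: a feature still acquired under blockade in both replicates is
**maternally defined (MaD)**, a feature lost in both replicates — or first
appearing after stage 11 — is **zygotically defined (ZyD)**, and everything
replicate-inconsistent or below threshold is **not defined (ND)**.

`madzyd` implements this classification and the analyses built on it, for
epigenomics researchers who want a tested, reusable and fully synthetic-data-
verifiable version of the workflow:

- **Signal normalization** — RPKM, *relative RPKM* (peak RPKM divided by the
  95th-percentile RPKM of random background regions, nearest-rank), the
  high-input exclusion filter (≥75 % of a peak in 1-kb bins with >65 input
  reads) and background-enrichment filtering.
- **MA differential model** — M = log₂((x+c)/(y+c)), A = ½·log₂((x+c)(y+c)),
  a robust (Tukey bisquare / Theil–Sen) trend fit on common peaks,
  rescaled M, and the Audic–Claverie count statistic
  P(y│x) = (x+y)! / (x!·y!·2^(x+y+1)) evaluated as exact one-sided tails.
- **MaD/ZyD classification** — per-replicate lost / increased / unchanged /
  maintained calls at the published operating point (M > 1, −log₁₀ p > 5 for
  H3K27me3 or 1.3 for H3K4me3/p300, relative RPKM > 1 at the comparison and
  reference stages), cross-replicate consensus, gene-level rules on promoter
  windows (±250 bp for H3K4me3, ±2.5 kb for H3K27me3) and GREAT-style
  basal-plus-extension regulatory domains for p300.
- **Enhancer clusters** — 12.5-kb stitching, ranked-signal elbow cutoff,
  per-stage/total EC regions, seeding analysis and exact hypergeometric
  enrichment of MaD/ZyD peaks in ECs.
- **Motif activity** — the linear response model E_ps = c̃_p + c_s +
  Σ_m N_pm·A_ms fitted by centered ridge regression, with per-motif z-scores
  and selection at |z| > 13.
- **Methylation logic** — coverage-weighted promoter methylation, CpG density,
  Bio-CAP-ratio or bisulfite hypomethylation calls, and the joint chromatin ×
  methylation tables.
- **Chromatin-state dynamics** — 200-bp state matrices, the modified-genome
  mask, per-stage coverage and exactly conserved Sankey transition flows.
- **Synthetic data** — generators that plant ground truth for every stage
  (depleted replicate counts, growing enhancer clusters, bimodal methylomes,
  planted motif activities, Markovian state tracks), so the whole analysis
  runs and is verified without any download.

## Worked example

```python
from madzyd.config import PipelineConfig
from madzyd.pipeline import run_amanitin_analysis
from madzyd.simulate import SimulationConfig, simulate_amanitin_experiment

config = PipelineConfig(seed=7, apply_input_filter=False)
dataset = simulate_amanitin_experiment(SimulationConfig(seed=7))
result = run_amanitin_analysis(dataset, config)
print(result["summary"]["label_counts"])
print(result["summary"]["recall"])
```

prints

```
{'MaD': 1168, 'ZyD': 500, 'ND': 332}
{'MaD': 0.9724540902, 'ZyD': 0.994, 'ambiguous_as_ND': 0.9866666667}
```

Of 2,000 simulated peaks (60 % planted MaD, 25 % ZyD, 15 % ambiguous —
depleted in exactly one replicate), the classifier labels 1,168 MaD, 500 ZyD
and 332 ND; 97 % of planted-MaD and 99 % of planted-ZyD peaks receive their
true label, and 99 % of the ambiguous peaks correctly fall into ND. The
`examples/` directory holds one short script per capability (differential
model, enhancer clusters, motif activity, methylation logic, state dynamics,
full pipeline), each printing the numbers it computes and what they mean.

The same pipeline is scriptable from the shell:

```bash
madzyd run-all --seed 7 --out out/       # all stages + summary.json
madzyd simulate --seed 7 --out sim/      # just the synthetic datasets
madzyd manorm counts.tsv -x ctrl -y aman --out ma.tsv
```

`run-all` with a fixed seed and config reproduces `summary.json` byte for
byte.

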