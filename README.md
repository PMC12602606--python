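# pannetsub

Multi-omic subtype discovery for pancreatic neuroendocrine tumors
(PanNETs) with loss of Menin, DAXX, or ATRX.

PanNETs carrying *MEN1* mutations alone ("alpha-like" tumors, epigenetically
resembling pancreatic alpha cells) behave very differently from tumors with
combined *MEN1* + *DAXX/ATRX* loss ("ADM" tumors), which show global
hypomethylation, alternative lengthening of telomeres (ALT) and chromosomal
instability — and the ADM group is itself transcriptionally heterogeneous.
`pannetsub` implements the full two-level analysis used to dissect this
hierarchy, as a tested, reusable pipeline:

1. **Methylation level** — consensus clustering (resampled hierarchical
   clustering on 1 − Pearson correlation, ward.D2 inner / average final
   linkage) of the 2000 most variable probes by MAD separates alpha-like from
   ADM tumors; differential methylation (per-probe linear model on β values,
   Benjamini-Hochberg), chromatin-state over-representation (one-sided Fisher),
   and sub-telomeric / peri-centromeric median-methylation statistics (Welch
   t-test) characterize the split.
2. **Expression level** — within ADM samples, consensus clustering of the 2000
   most variable genes finds transcriptomic subtypes; each subtype is profiled
   by one-vs-rest negative-binomial Wald tests (median-of-ratios size factors,
   trend-shrunk moments dispersion), preranked gene-set enrichment, and
   rank-sum signature scores (MLP1-style).
3. **Integration** — for every significant DEG, Spearman correlation between
   promoter-probe M values, M = log2(β/(1−β)), and variance-stabilized
   expression flags candidate epigenetically driven genes at
   ρ < −0.6 and BH-adjusted p < 0.05.
4. **Clinical** — Kaplan-Meier / log-rank disease-free-survival comparison and
   Pearson chi-squared tests with simulated p (fixed-margin Monte Carlo) for
   categorical associations such as tumor size above/below 2.5 cm.

Because the original patient cohorts live under controlled-access accessions,
the package ships a **synthetic cohort generator** (`pannetsub.synthetic`)
that plants every effect the pipeline must detect — the two-level subtype
structure, ADM-specific DMPs and structural-region hypomethylation,
subtype-specific expression programs, a two-subtype signature, and
promoter-coupled genes — and records them in a ground-truth ledger so
recovery can be scored exactly.

## Worked example

```python
import pannetsub as ps
from pannetsub.pipeline import PipelineConfig, run_methylation_level

cohort = ps.simulate_cohort(ps.CohortConfig(), seed=1)   # ~100 samples
config = PipelineConfig(reps=200, max_k_methylation=4, seed=1)
res = run_methylation_level(cohort.beta, cohort.manifest,
                            cohort.sheet, cohort.genome, config)

print(res["labels"].value_counts().to_dict())
print(res["region_tests"][["region_class", "mean_difference", "p_value"]])
```

```
{'ADM': 70, 'alpha_like': 30}
      region_class  mean_difference        p_value
0  pericentromeric        -0.151633   2.271720e-67
1     subtelomeric        -0.154449  4.082539e-106
```

The k = 2 consensus clusters reproduce the planted alpha-like/ADM split
(the cluster enriched for DAXX/ATRX-lost samples is named ADM), and the
per-sample median methylation of both structural region classes is lower in
ADM by ≈ 0.15 β units — the planted shift — with Welch p far below 0.01.

The command-line interface wraps the same library:

```bash
pannet simulate --seed 1 --out cohort/           # synthetic cohort + truth ledger
pannet run --config pipeline.yaml --seed 1 --out run/
```

Every stage writes plain TSV tables plus a `provenance.json` (config echo,
seed, input SHA-256 hashes); two runs with the same config and seed produce
byte-identical run directories.

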