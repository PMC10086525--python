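# agesig

Conserved immune-aging signature discovery across mouse strains and tissues.

Immune aging studies profile multiple strains and tissues and ask which
age-related changes are *shared* — conserved signatures are the best
candidates for general mechanisms (e.g. the activation of Jun/Fos members of
the AP-1 transcription-factor complex, a driver candidate for inflammaging).
`agesig` packages the statistical core of such a study as a tested, seeded,
desk-scale pipeline:

* **Age association** — per-(strain, tissue) negative-binomial GLMs of
  feature counts on continuous age (sex as covariate), with CPM filtering,
  TMM normalization, moment dispersion with shrinkage, Wald t-tests, BH FDR,
  and differential calls at fdr < 0.05 and |log2FC| > 1.
* **MAG conservation score** — per tissue, the geometric mean of a gene's
  inverse significance ranks across strains, `m_t = (prod_s 1/r_{g,s,t})^(1/S)`,
  summed over tissues, `M_g = sum_t m_t`; genes are ranked by descending
  `M_g` to surface the most conserved aging genes.
* **Preranked GSEA** on the MAG ranking with a gene-label permutation null,
  add-one p-values, NES against the mean positive null ES, leading-edge
  reporting, and an exhaustive-enumeration mode for small lists.
* **PVCA** — variance attribution to design factors (tissue, strain, age,
  sex) via per-PC REML variance components.
* **Module enrichment** (hypergeometric upper tail, BH), set-overlap tests,
  and a Wilcoxon rank-sum utility.
* **Regulatory statistics** — consensus peaks (≥ 2-sample support),
  nearest-TSS annotation, footprint purity filtering (> 0.9), TF footprint
  enrichment in opening/closing peaks vs age-stable background, cross-tissue
  TF sharing, ±100 kb locus footprint counts, and aggregate cut-site
  profiles.
* **Cell-composition trends** — OLS slopes of cell-type percentages on age
  with BH correction.
* **Synthetic-data generators** for all of the above with recorded ground
  truth, so every stage is testable end to end without external data.

See `docs/methods.md` for the models, defaults, and design choices.

## Worked example

Simulate a 2-strain × 4-tissue study with a 5-gene conserved activation
signature planted at log2FC 2, fit every stratum, aggregate to MAG scores,
and test the planted set on the MAG ranking:

```python
from agesig import simdata, diffassoc, conservation

cfg = simdata.SimConfig(seed=1, n_genes=2000, replicates_per_age=4)
counts, samples, truth = simdata.generate_study(cfg)

results = diffassoc.fit_all_strata(counts, samples)
ranks = {label: conservation.rank_stratum(df) for label, df in results.items()}
mag = conservation.mag_scores(ranks, list(cfg.strains), list(cfg.tissues))
print(mag.sort_values("final_rank").head(6)[["mag_total", "final_rank", "direction"]])

gsea = conservation.preranked_gsea(
    mag["mag_total"], truth.planted_sets["conserved"], n_perm=10_000, seed=1
)
print(f"ES={gsea.es:.3f}  NES={gsea.nes:.3f}  p={gsea.p:.4f}")
```

Output:

```
        mag_total  final_rank  direction
gene
Fosb     2.991564           1          1
Jun      1.965306           2          1
Junb     1.628235           3          1
Maff     0.781459           4          1
Fos      0.191250           5          1
g00737   0.074010           6          0
ES=1.000  NES=2.528  p=0.0001
```

The five planted genes occupy the top five MAG ranks, all with consistent
upward direction across strata (`direction = 1`), and their gene set is
strongly enriched at the top of the conservation ranking — the planted
analogue of an AP-1-like conserved aging signature. `mag_total` is bounded
by the number of tissues (4 here); a value near 3 means the gene ranks at or
near the top in both strains in most tissues.

The same analysis runs from the shell:

```bash
agesig run-all --seed 1 --outdir run1          # full pipeline on synthetic data
agesig gsea --seed 1 --outdir run2             # one stage (plus dependencies)
```

Each run writes per-stage TSVs and a `manifest.json` with parameters and
SHA-256 hashes of every output; identical configs and seeds reproduce
identical hashes.

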