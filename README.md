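# mirmaster

Integrated inference of microRNA master regulators and logical modeling of
hepatic glucose/lipid metabolism.

`mirmaster` is a Python library for studies that pair a liver transcriptome
with a miRNome across dietary conditions (a lean reference and two high-fat
lineages, `HFoleic` and `HFepa`) and ask *which miRNAs drive the phenotype's
gene signature, and what do the resulting regulations imply for glucose and
lipid fluxes?*  It provides four connected analysis blocks plus a synthetic
data generator with recorded ground truth, so every stage is verifiable by
parameter recovery:

1. **Differential expression & signatures** (`mirmaster.diffexpr`) —
   quantile normalization, per-contrast t-tests on log2 values,
   Benjamini–Hochberg/Yekutieli FDR, and the phenotype signature
   (up = log2FC > 0, down = log2FC < 0, at FDR-adjusted *p* < 0.05).
2. **miRNA Master Regulator Analysis** (`mirmaster.mmra`) — a four-step
   filter chain: (i) miRNA differential expression (|log2FC| > 0.25,
   *p* < 0.01); (ii) one-sided Fisher enrichment of 2-of-3
   database-consensus targets in the signature; (iii) a mutual-information
   network built around each candidate miRNA (the miRNA is the only hub;
   edges require MI above a permutation-null-calibrated significance
   threshold) enriched in the signature; (iv) per-gene bidirectional
   stepwise OLS with AIC (= *n*·ln(RSS/*n*) + 2*k*) as the stop criterion —
   a (miRNA, gene) pair survives iff the miRNA is selected in that gene's
   model.
3. **Enrichment** (`mirmaster.enrichment`) — unweighted gene-set enrichment
   as a two-sample Kolmogorov–Smirnov test on the fold-change-ranked gene
   list, and gene → reaction → pathway mapping with condition attributes
   (1 = HFoleic only, 2 = HFepa only, 3 = both) and one-tailed Fisher
   pathway enrichment.
4. **Logical modeling** (`mirmaster.logic`) — a multi-valued logical-model
   engine (threshold rules, clamping perturbations, exhaustive stable-state
   search) shipping a 24-component / 37-interaction model of hepatic
   metabolism in which the ternary coactivator Pgc-1α primes the
   Irs2 → Akt arm of insulin signaling that shuts down gluconeogenesis
   after feeding.

## Worked example

```python
from mirmaster import SimulationConfig, generate_study, generate_target_databases, run_mmra
from mirmaster.mmra import desk_scale_config

config = SimulationConfig(seed=1)              # 500 genes x 60 miRNAs, n = 9/8/7
study = generate_study(config)                 # planted repressive regulations
dbset = generate_target_databases(study.truth, config)
result = run_mmra(study, dbset, "HFepa_vs_reference", desk_scale_config(seed=1))
```

Running `python examples/run_mmra.py` prints:

```
step 1 (DE miRNAs        ):  14 candidate miRNAs
step 2 (target-enriched  ):   7 candidate miRNAs
step 3 (network-enriched ):   7 candidate miRNAs
step 4 (SLR-selected     ):   7 candidate miRNAs

surviving miRNA-gene pairs: 40
recall    : 88% of the 40 planted pairs
precision : 88% of reported pairs are planted
```

The filter chain narrows 14 differentially expressed miRNAs down to the 7
planted regulators (the 40-pair planted network is recovered at 88%
recall/precision on this seed), and recovered pairs show the expected
anti-correlated pattern: down-regulated genes regulated by up-regulated
miRNAs and vice versa.

`python examples/logical_model.py` prints the context-dependent stable
states of the hepatic model — feeding activates Irs2/Akt and the anabolic
programs while silencing gluconeogenesis; fasting activates gluconeogenesis
and lipolysis; a Pgc-1α knockout during fasting abolishes gluconeogenesis
but not lipolysis; and ectopic Irs2 during fasting suppresses
gluconeogenesis while Pgc-1α settles at its intermediate level.

The other examples cover the generator (`simulate_study.py`), enrichment
(`pathway_enrichment.py`) and the orchestrated pipeline with its hashed run
manifest (`full_pipeline.py`).  A thin CLI mirrors the stages:

```bash
mirmaster simulate --out study/ --seed 1
mirmaster mmra --genes study/genes.tsv --mirnas study/mirnas.tsv \
    --annotation study/annotation.tsv --targets study/targets.tsv \
    --contrast HFepa_vs_reference --out results/
mirmaster logic --out environments.tsv
mirmaster all --out run/ --seed 1
```

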