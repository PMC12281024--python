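# dietlink

Curation and association analysis for DNA-metabarcoding diet studies of
Arctic herbivores, built around the analysis chain of a multi-year
Svalbard reindeer rumen survey: trnL plant-diet metabarcoding, 16S rumen
microbiome profiling, and autumn body mass.

The package is aimed at molecular ecologists who have a replicate-level
MOTU read table (diet), an ASV count table (microbiome) and host
covariates, and want a tested, reproducible route from raw counts to the
diet–microbiome–body-mass statistics — plus a synthetic-study generator
with complete ground truth for validating every stage.

## What it computes

**Curation** of a MOTU × PCR-replicate count table:

1. basic MOTU filter — sequences < 10 bp or ≤ 10 reads dataset-wide;
2. iterative PCR-replicate outlier filter: on read-proportion profiles,
   each replicate's Euclidean distance to its sample average (*dw*) is
   compared with the distribution of pairwise distances between sample
   averages (*db*); replicates beyond the crossing point of the two
   distance densities are failed PCRs and are removed, iterating until
   stable; samples left with a single replicate are dropped;
3. replicate averaging with equal weight (proportions first), giving
   relative read abundances (RRA) per sample;
4. RRA/identity filter — MOTUs never reaching 1% RRA in any sample, or
   with best reference-database identity < 94%, are discarded;
5. aggregation of MOTUs into plant families and functional groups.

**Diversity**: Hill numbers `(Σ p_i^q)^(1/(1−q))` (q = 1 is the
exponential of Shannon entropy), Chao1 richness
`S_obs + F1²/(2 F2)` with the bias-corrected form when F2 = 0, common
scaling of 16S samples to the smallest read depth, and the arcsine
square-root transform for proportion responses.

**Association**: Bray–Curtis dissimilarities `Σ|x−y| / Σ(x+y)`; the
Mantel permutation test (Pearson or Spearman) between the diet and
microbiome distance matrices; sequential-term PERMANOVA on the
Gower-centred matrix `G = −½ J (D∘D) J` with the model order
valley → year → Salix, so the dietary *Salix* term is tested after the
spatial and annual confounders; and a piecewise path decomposition from
two standardised OLS equations,

    diversity ~ Salix            ->  a
    mass      ~ Salix + diversity ->  c' (direct), b

with the microbiome-mediated (indirect) effect `a·b` and total effect
`c' + a·b`.

**Synthetic studies** (`dietlink.simulate`): ~97 animals across 4
valleys × 7 years, 3 PCR replicates each, a 39-MOTU diet in 14 families
and 8 functional groups whose *Salix* fraction rises with annual NDVI
and grass fraction with July temperature, planted failed-PCR replicates
and artefact MOTUs (registered with the rule that should catch them), a
microbiome whose composition and diversity covary with dietary *Salix*,
and body mass generated from known direct and microbiome-mediated path
coefficients.

## Worked example

```python
from dietlink import io

cfg = io.RunConfig(seed=1, out_dir="demo_out", n_perm=10_000)
summary = io.run_pipeline(cfg)   # simulate -> curate -> ... -> path

m = summary["mantel"]
print(f"Mantel r = {m.statistic:.3f}  (p = {m.p_value:.2g})")
print(summary["permanova"].loc["salix"].round(4).to_dict())
for metric, pm in summary["paths"].items():
    print(f"{metric}: a={pm.a:.3f} b={pm.b:.3f} c'={pm.c_direct:.3f} "
          f"indirect={pm.indirect:.3f}")
```

prints

```
Mantel r = 0.421  (p = 0.0001)
{'df': 1.0, 'ss': 0.4189, 'pseudo_f': 10.2737, 'r2': 0.0807, 'p_value': 0.0001}
shannon: a=0.485 b=-0.062 c'=0.635 indirect=-0.030
chao1: a=0.285 b=-0.081 c'=0.628 indirect=-0.023
```

Reading: diet and microbiome composition are strongly associated at the
individual level (Mantel r = 0.42); dietary *Salix* explains a
significant share of microbiome variation after valley and year
(R² = 0.08, p = 0.0001); and the direct path from *Salix* to body mass
(c' ≈ 0.63) dominates the small negative microbiome-mediated path
(a·b ≈ −0.03). The run also wrote curated RRA tables, a per-sample
diversity table, the PERMANOVA table and an audit log of every removal
under `demo_out/`.

The same stages are available from the shell:

```bash
dietlink all --seed 1 --out-dir demo_out --n-perm 10000
dietlink simulate --seed 7 --out-dir study_out
dietlink curate --diet-counts study_out/study/diet_replicate_counts.tsv \
    --replicate-map study_out/study/replicate_to_sample.tsv \
    --motu-meta study_out/study/motu_metadata.tsv --out-dir curated
```

All tables are tab-separated text; identical config + seed give
byte-identical outputs.

## Data availability note

The original study's raw sequencing data are in the SRA under
PRJNA1052483 (trnL diet metabarcoding) and PRJNA1044740 (16S microbiome).
This package does not download or process reads; it consumes count
tables (read-level processing belongs to OBITools/dada2 upstream).
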