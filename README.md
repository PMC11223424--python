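# cagmicro

Bacterial **co-abundance group (CAG)** analysis of paired tumor/normal
mucosal 16S rRNA genus profiles, built for colorectal-cancer microbiome
studies where single-taxon contrasts are too noisy and community-level
structure is the signal of interest.

## The problem and the method

Mucosal biopsies from colorectal-cancer surgery come in pairs: tumor tissue
(TT) and adjacent normal tissue (NT) from the same patient. Individual
genera disagree between cohorts, so instead of a one-organism-one-disease
reading, genera whose abundances co-vary across samples are grouped into
CAGs and the community units are compared:

1. **Diversity contrasts.** Counts are rarefied to a common depth; alpha
   indices (ACE, Chao1, Observed, Pielou, Shannon, Gini-Simpson) are
   compared TT vs NT; beta diversity uses Bray-Curtis dissimilarity
   d(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) with PCoA ordination and a one-way
   PERMANOVA pseudo-F permutation test on the distance matrix.
2. **Discriminant taxa.** An LDA-effect-size procedure: a Kruskal-Wallis
   screen per genus, then bootstrapped linear-discriminant effect sizes on
   the 100,000-sum scale; a genus is a biomarker when
   log₁₀(effect + 1) ≥ 3.5.
3. **CAG construction** (the core). Genera with mean relative abundance
   > 0.1% in both tissues are clustered by Ward linkage (ward.D2 convention)
   on d = 1 − Spearman ρ between genus profiles; cutting the dendrogram at
   k = 4 defines the CAGs. Per-sample CAG abundance is the raw sum of member
   genera. Samples are then Ward-clustered on Bray-Curtis distances between
   CAG profiles into g = 6 sample groups; a sample group dominated by one
   CAG can be excluded and the tissue contrasts re-run.
4. **Clinical associations.** In tumor samples only: Mann-Whitney/
   Kruskal-Wallis contrasts of CAG abundance across clinical categories
   (microsatellite status, stage, Ki-67) and Spearman correlations with
   serum tumor markers (CEA, CA199, CA125, CA153, AFP), with pairwise
   missing-value handling and BH-adjusted p-values alongside raw ones.

Because the underlying cohort data are deposited as raw reads, the package
ships a **synthetic-data generator** that emulates the statistical structure
the analysis assumes — four genus blocks sized 14/12/11/10 with within-block
correlation ρ = 0.8, tissue multipliers (block 2 tumor-enriched ×3, blocks
3–4 normal-enriched ×0.4/×0.6), paired patients, uniform 10k–50k sequencing
depths, background clutter genera, and clinical covariates tied to block
factors — so every stage of the pipeline is verifiable against planted
ground truth.

## Worked example

```python
import cagmicro as cm

ds = cm.simulate(cm.SimulationConfig(n_patients=250, seed=42))
rare = cm.rarefy(ds.table, 16_864, seed=1)
rel = cm.to_relative(rare)
meta = ds.meta.loc[rel.samples]

model = cm.build_cag_model(rel, meta, k=4)
prof = cm.cag_profiles(rel, model)
for r in cm.compare_cag_abundance(prof, meta):
    print(f"{r.feature}: median {r.group_medians['TT']:.2f}% (TT) vs "
          f"{r.group_medians['NT']:.2f}% (NT), p = {r.p_value:.3g}")

perm = cm.permanova(cm.bray_curtis(rel), meta["tissue"].to_numpy(),
                    n_perm=999, seed=2)
print(f"PERMANOVA: pseudo-F = {perm.pseudo_F:.2f}, p = {perm.p_value:.3g}")
print(cm.truth_metrics(ds, model))
```

prints

```
CAG1: median 70.21% (TT) vs 72.13% (NT), p = 0.779
CAG2: median 15.00% (TT) vs 4.95% (NT), p = 1.83e-42
CAG3: median 6.61% (TT) vs 16.19% (NT), p = 9.12e-29
CAG4: median 3.14% (TT) vs 4.52% (NT), p = 2.17e-08
PERMANOVA: pseudo-F = 65.28, p = 0.001
{'genus_ari': 1.0, 'n_structured_assigned': 47}
```

Reading: the dominant block (CAG1) shows no tissue contrast; the planted
tumor-enriched block (CAG2) has a three-fold higher median in tumor tissue;
the planted normal-enriched blocks (CAG3, CAG4) go the other way; community
composition separates the tissues (PERMANOVA at its minimal Monte-Carlo p);
and the genus→CAG partition recovered the planted blocks exactly
(adjusted Rand index 1.0 over all 47 structured genera).

The same analysis is scriptable end-to-end:

```bash
cagmicro run --seed 0 --out results/run0      # full pipeline, JSON report
cagmicro simulate --n-patients 250 --seed 0 --out data/
cagmicro cag --table data/table.tsv --metadata data/metadata.tsv --out results/cag
```

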