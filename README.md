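# epsbloom

Do marine bacteria ramp up exopolysaccharide (EPS) production after a
phosphate/nitrate influx?  `epsbloom` implements the quantitative analysis
behind that question for two complementary settings:

* **Environment side** — metatranscriptomic read counts mapped to a catalog
  of metagenome-assembled genomes (MAGs) across a 30-timepoint algal bloom
  whose two phases are separated by a nutrient peak.  The package computes
  TPM normalization, per-MAG relative activity, marker-gene (MG)
  normalization against 10 universal single-copy COG families, detects
  candidate EPS biosynthesis gene clusters (alginate, cellulose,
  wzx/wzy-dependent), and tests phase-2 vs phase-1 shifts with a one-sided
  permutation test.
* **Laboratory side** — Alcian-Blue staining of transparent exopolymeric
  particles (TEP) quantified as Xanthan-Gum (XG) mass equivalents through a
  calibration curve, with per-cell normalization and a one-tailed two-sample
  t-test between nutrient regimes.

A fully seeded synthetic-study generator reproduces the *shape* of the real
data (MAGs, ORFs, planted marker genes and EPS operons, negative-binomial
counts with planted phase-2 effects, assay plates), so every pipeline stage
is testable offline.

## The statistics at the core

With `c_is` the reads of ORF *i* in sample *s* and `L_i` the ORF length in
kb:

* **TPM**: `TPM_is = (c_is / L_i) / Σ_j (c_js / L_j) × 10^6` — each sample
  sums to one million.
* **MAG relative activity**:
  `activity_js = (Σ TPM of MAG j's ORFs / Σ TPM in s) / (MAG j length / total MAG length)`
  — 1 means transcription proportional to genomic representation.
* **MG normalization**:
  `v_is = (c_is / L_i) / median over MAG's 10 marker ORFs of (c_ms / L_m)`
  — a relative per-genome transcript number; any common per-sample factor
  cancels in the ratio.
* **TEP**: `TEP = (A_sample − A_filter_blank) / (m787 × V)` with `m787` the
  OLS slope of the XG calibration line (absorbance at 787 nm per µg XG) and
  `V` the filtered volume; per-cell values divide by the cell density.

## Worked example

```python
import epsbloom
from epsbloom.simulate import SimulationConfig, generate_community, generate_counts

cfg = SimulationConfig.study_default(seed=7)   # 50 MAGs, 30 samples,
com = generate_community(cfg)                  # 5 active MAGs (f_act=4),
counts, samples = generate_counts(com, cfg)    # 3 elevated EPS clusters (f_eps=4)

tpm = epsbloom.tpm_normalize(counts, com.orfs)
act = epsbloom.mag_activity(tpm, com.orfs, com.mags)
print(epsbloom.compare_phases(act.matrix, samples).head(6).round(4))
```

```
        mean_phase1  mean_phase2  log2_ratio    stat  p_value  rank
MAG003      10.3166      19.7750      0.9387  9.4584   0.0001     1
MAG002       1.1324       2.1637      0.9342  1.0314   0.0001     2
MAG001       2.0179       3.8529      0.9331  1.8350   0.0001     3
MAG005       1.3776       2.5628      0.8955  1.1852   0.0001     4
MAG004       0.5186       0.9306      0.8436  0.4120   0.0001     5
MAG006       0.3927       0.2132     -0.8812 -0.1795   1.0000     6
```

The five MAGs whose phase-2 abundance was boosted 4-fold (MAG001–MAG005)
occupy the top five ranks with log2 activity ratios near 1 (relative
activity is share-based, so boosting five genomes deflates everyone's
share, compressing the raw 4-fold effect) and permutation p ≈ 1e-4, the
smallest value 10,000 label permutations can resolve.

Cluster detection plus MG-normalized expression ranks the planted
4-fold-upregulated EPS operons above the planted unchanged ones:

```
                            log2_ratio  p_value  rank
MAG007:cellulose:MAG007_c3      2.6039   0.0005     1
MAG006:alginate:MAG006_c2       2.5103   0.0001     2
MAG008:wzx_wzy:MAG008_c1        2.1188   0.0001     3
MAG011:wzx_wzy:MAG011_c2        1.1419   0.1061     4
MAG009:alginate:MAG009_c3       0.2885   0.1260     5
MAG010:cellulose:MAG010_c3     -0.4941   0.9638     6
```

On the laboratory side, a synthetic assay plate (2 organisms × 2 nutrient
regimes × 3 replicates) calibrated on the five-standard XG dilution series
recovers `m787 = 0.019993` absorbance/µg (truth 0.02, r² = 0.99996) and
finds the planted 2-fold regime effect in both organisms (one-sided
p < 1e-4).

## Command line

```bash
epsbloom all --config config.yaml --outdir results/    # environment pipeline
epsbloom tep --config config.yaml --outdir results/    # laboratory pipeline
```

Verbs `simulate | normalize | activity | clusters | expression` stop after
the named stage.  The YAML config has sections `synthetic` (or `inputs`
pointing to FASTA/GFF3/TSV files), `activity`, `clusters`, and `tep`; every
run writes a manifest with the config hash and seed, and reruns are
byte-identical.

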