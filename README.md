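# rootclines

Projection-based genotype–environment association (GEA) for root anatomy.

Landrace collections are georeferenced and genotyped at scale, but root
anatomical phenotyping is expensive, so only small panels ever get measured.
`rootclines` implements the strategy of fitting environment→trait models on
a small phenotyped training panel and *projecting* the traits onto a large
genotyped panel, so that genome-wide association can be run on trait axes
instead of one-descriptor-at-a-time environmental GEA. Around that core it
provides the full supporting workflow: simplified digital root
cross-sections with axial/radial hydraulic properties, phenotype clustering,
mixed-model BLUPs, and gene-level association with candidate pooling and
cluster-level allele-frequency clines — plus a synthetic-study generator
with recorded ground truth that makes every stage testable end to end.

## The model in brief

* **Trait models.** For each trait y, an all-relevant shadow-feature
  (Boruta-style) screen selects environmental descriptors, then a random
  forest (5,000 trees, ⌊p/3⌋ split candidates) fits y from the confirmed
  descriptors; quality is out-of-bag percent variance explained. Fitted
  models predict ŷ for every genotyped, georeferenced accession.
* **Hydraulics.** From anatomical parameters a concentric-ring
  cross-section is reconstructed; axial conductance is the Hagen–Poiseuille
  sum over metaxylem vessels, Kx = Σ π d⁴/(128 μ), and radial conductance
  composes per-layer membrane and apoplastic paths in series, with a
  Casparian strip blocking the apoplast at the endodermis:
  1/Kr = Σᵢ 1/(g_mem,i + g_apo,i), kr = Kr/(2π r L).
* **Clustering.** Projected traits are z-scored (|z| > 3 outliers removed)
  and partitioned around k = 7 medoids; composite per-cluster anatomies are
  built from median traits.
* **Association.** y (projected trait, observed-trait BLUP, or descriptor)
  is regressed on dosages with the leading 5 eigenvectors of the genetic
  relationship matrix as covariates; per gene, SNPs within ±2.5 kb windows
  are aggregated by principal-components regression and F-tested (a
  single-SNP gene reduces exactly to the SNP's Wald t²). Top-100 gene sets
  per analysis are pooled and intersected.

`docs/methods.md` documents every model, default and numerical choice, and
what the synthetic studies do and do not establish.

## Worked example

Simulate a study and run the full pipeline from the command line:

```bash
rootclines simulate --outdir demo --seed 5 --n-train 40 --n-target 120 \
    --n-descriptors 15 --n-informative 4 --n-snps 400 --n-genes 40
rootclines run-full demo/run_config.yaml
```

which prints (paths abridged):

```
descriptors_train: demo/descriptors_train.csv
genotypes_vcf: demo/genotypes_target.vcf
annotation: demo/genes.gff3
run_config: demo/run_config.yaml
...
completed 8 stages; manifest hash 41e4406610d80bf8
```

The run directory (`demo/results/`) then contains, among others,
`trait_models.csv` (per-trait OOB R² and descriptor counts),
`projected_traits.csv` (120 accessions × modeled traits),
`cluster_hydraulics.csv` (per-cluster composite kr/Kr/Kx),
`gene_associations.csv` (gene-level F and p per analysis) and
`overlap_percent.csv` (candidate-set overlap between the projected-trait
and environmental analyses). Re-running with the same config reproduces
every file byte for byte — the manifest hash is the check.

The same workflow is available as a library:

```python
from rootclines import SimConfig, simulate_study
from rootclines.envmodels import boruta_select, fit_trait_model, project

study = simulate_study(SimConfig(n_train=200, n_target=400, seed=1))
X = study.train_descriptors
sel = boruta_select(study.traits["NMV"].to_numpy(),
                    X[[c for c in X if c.startswith("env_")]], trait="NMV")
model = fit_trait_model(study.traits["NMV"].to_numpy(),
                        study.train_descriptors, sel, trait="NMV")
projection = project([model], study.target_descriptors)
```

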