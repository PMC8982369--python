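# gpforward

Forward-validation benchmarking of linear and tree-ensemble genomic
prediction models on simulated multigenerational outbred populations.

The package contains everything needed to run the comparison end to end
with no external data:

- **`gpforward.simulate`** — synthetic population generator: 8 binary
  founder haplotypes dropped through nonoverlapping generations of unequal
  size (default 97/48/200/184/99/197 animals for generations
  4/5/7/8/9/11) with recombinant mosaic gametes, plus complex-trait
  simulation (additive QTL, additive-by-additive SNP pairs, fixed effects
  of diet/sex/litter/generation) with exact realized-variance targeting.
- **`gpforward.qc`** — marker/animal quality control (MAF < 0.05, call
  rate < 0.90, adjacent-SNP |r| > 0.80 pruning), pairwise LD r², mean
  imputation.
- **`gpforward.pheno`** — OLS precorrection of fixed effects (y*),
  additive GRM `G = ZZ'/m` from centered/standardized genotypes, its
  Hadamard square for additive-by-additive relationships, and a Gibbs
  sampler for one- or two-component variance estimation.
- **`gpforward.linear`** — Bayesian GBLUP (Gibbs; validation animals
  predicted via `G_vr G_rr^-1 a_hat`, SNP effects by back-solving),
  BayesB (point-mass/scaled-t mixture prior, single-site Gibbs), and an
  elastic net by coordinate descent in the convention where alpha = 1 is
  pure ridge and alpha = 0 pure lasso, with the two-step
  alpha-grid/lambda-path tuner.
- **`gpforward.gbm`** — gradient-boosted regression trees with exact
  greedy split enumeration (numba-accelerated), training-RMSE early
  stopping, percent-scale feature importance, and grid-search tuning on a
  seeded 80–20 reference split.
- **`gpforward.evaluate`** — forward validation (train on older
  generations, predict the youngest), accuracy (Pearson r) with bootstrap
  intervals, RRMSE, generation-gap scenarios (NoGAP/GAP9/GAP89 with
  quota-constrained N=300 reference resampling over replicates),
  GBM-importance marker preselection refits (SNP100/250/500/1000), and
  top-animal / top-SNP overlap analyses with an LD (r² > 0.90)
  equivalence.

## CLI

All stages are exposed through one entry point:

```bash
gpforward simulate  --config sim.yaml --seed 1 --out simdir/
gpforward qc        --in simdir/panel.tsv --map simdir/map.tsv --seed 1 --out qc/
gpforward precorrect --pheno simdir/traits.csv --out ystar.csv
gpforward grm       --panel qc/panel.tsv --map qc/map.tsv --kind additive --out G
gpforward fit       --model gblup|bayesb|enet|gbm --panel qc/panel.tsv --map qc/map.tsv \
                    --ystar ystar.csv --seed 1 --out fit.json
gpforward predict   --fit fit.json --panel qc/panel.tsv --map qc/map.tsv --out pred.csv
gpforward importance --fit fit.json --out importance.csv
gpforward evaluate  --config run.yaml
```

`sim.yaml` holds the population design and one `TraitArchitecture` per
trait name; `run.yaml` names the panel/map/traits files, model list,
seed, scenario and preselection settings, and the output directory (see
`tests/test_io_cli.py` for minimal working configs).

Genotype panels travel as plain TSV (dosages 0/1/2, `NA` missing) with a
SNP-map sidecar (`snp_id`, `chrom`, `cm`); trait tables as CSV. A minimal
unphased VCF writer/reader and a PLINK `.raw`-style reader are included.

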