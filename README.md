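# repeatgs

Genome-enabled prediction toolkit for repeated-record traits in
biparental (F1) crosses. It covers the full analysis chain:

- **`repeatgs.simulate`** — F1 progeny simulation (phased heterozygous
  parents, Haldane recombination on a cM map) and repeated-record
  phenotypes under an additive + permanent-environment + year + residual
  model, with the true effects returned for recovery testing.
- **`repeatgs.io` / `repeatgs.qc`** — delimited genotype matrix and VCF
  import/export, phenotype tables, and the editing rules: sample
  call-rate (discard at ≤ 0.90), SNP call-rate / monomorphic-in-all-crosses
  filters, within-cross MAF filter (< 0.01), and per-cross QC summaries.
- **`repeatgs.impute`** — an imputer-agnostic masking benchmark
  (13-rate grid from 1% to 30%, 10 replicates per rate) with reference
  imputers (per-locus mode; LD-aware k-NN haplotype vote) and a hook for
  external command-line tools.
- **`repeatgs.kinship`** — genomic relationship matrix
  `G = (1/L) Σ Z_l Z_l' / (4 p_l (1−p_l))` (self-kinship ≈ ½; a
  `standard` scale with unit diagonal is available), the `1 − G`
  distance, classical MDS, cross-level mean kinships and a
  neighbour-joining tree with Newick output.
- **`repeatgs.gblup`** — the repeatability mixed model
  `y = Xb + Za + W pe + e` with `a ~ N(0, G σ²_a)`, fitted by REML
  (monotone EM with average-information acceleration and boundary
  handling) or by a Gibbs sampler with scaled-inverse-chi-square priors;
  heritability `h² = σ²_a / σ²_total`, repeatability
  `R = (σ²_a + σ²_pe) / σ²_total`, variance partition, record
  prediction and GEBV accuracy `PA / √h²`.
- **`repeatgs.crossval`** — record-level 5-fold cross-validation
  repeated 100 times (500 replicates of h², R and predictive ability),
  summaries, and a packaged per-cross published results table used for
  trait-level average checks.
- **`repeatgs.cli`** — `repeatgs` command with subcommands `simulate`,
  `qc`, `impute-bench`, `structure`, `fit`, `cv`, `accept` and
  `pipeline` (YAML-configured end-to-end run with a reproducible JSON
  manifest).

## CLI quick start

```bash
# simulate three crosses and run everything end to end
cat > config.yaml <<EOF
seed: 1
out_dir: run
n_crosses: 3
n_progeny: 40
n_snp: 240
cv_repetitions: 10
EOF
repeatgs pipeline --config config.yaml

# or stage by stage
repeatgs simulate --n-progeny 150 --n-snp 800 --n-crosses 3 --out sim
repeatgs qc --genotypes sim/genotypes.csv --out qc
repeatgs impute-bench --genotypes qc/genotypes_qc.csv --imputer knn --out bench
repeatgs structure --genotypes qc/genotypes_qc.csv --out structure
repeatgs cv --genotypes sim/genotypes.csv --phenotypes sim/phenotypes.csv --out cv
```

## Data formats

- Genotype matrix: CSV, header `plant_id[,cross],<snp ids...>`, integer
  codes 0/1/2 counting the alternate allele, `NA` for missing.
- VCF: plain-text, biallelic, GT field only (`./.` → missing).
- Phenotypes: CSV with columns `plant,year,trait,value` (long format,
  one row per plant-year record).
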