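# gonadpipe

Proteogenomics for species without a reference genome. `gonadpipe`
turns stranded long-read gonad transcriptomes (e.g. PacBio full-length
cDNA of salamander testis and ovary) into (1) gene-level expression
tables with a sex-bias statistic and (2) a protein search database for
sperm proteomics, then carries detected peptides through protein-group
inference and label-free quantification. A synthetic-data generator with
attached ground truth makes every stage testable without any download.

The pipeline stages:

- **read clustering** — gene-level clusters from raw reads, either
  imported from an external greedy clustering tool or via a built-in
  greedy k-mer-containment pass;
- **expression** — per-cluster TPM (`1e6 * count / total_reads`; no
  length term — one read is one transcript), and the pseudocounted sex
  ratio with replicate averaging,

      log10((mean testis TPM + 1) / (mean ovary TPM + 1)),

  with clusters called sex-biased at a strict >10-fold difference and
  ranked from most ovary-biased to most testis-biased;
- **ORF calling** — all Met-to-stop coding sequences of >= 30 residues
  in the three forward frames, reduced per read to the longest
  non-overlapping set; translations on >= 2 reads form the search
  database;
- **in-silico digestion** — tryptic peptides (<= 1 missed cleavage,
  K/R not before P) of 7-30 residues whose +2H/+3H precursor m/z lies
  in 396.43-1,002.70 Th, with fixed carbamidomethyl-Cys;
- **protein inference** — clusters sharing >= 2 observed peptides merge
  into protein groups (connected components); groups with >= 3 peptides
  are quantified as the mean of their three most intense peptides
  (top-3), normalized to the most abundant group;
- **motif annotation** — a gap-bounded cysteine-spacing scanner for
  three-finger-protein candidates
  (`.{2}C.{5,30}C.{2,20}C.{5,30}C.{2,20}C.{5,30}CC.{4}CN`) plus
  residue-composition descriptors.

## Worked example

Simulate the default study design (50 genes, 2 tissues x 2 biological
replicates, 5,000 reads per sample, 4 genes with a true 100-fold tissue
bias), then cluster, quantify and compare against the generator's truth:

```python
import gonadpipe as gp

cfg = gp.SimulationConfig(seed=1)
rec = gp.run_transcriptome_recovery(cfg)
conf = gp.bias_confusion(rec.gene_table)
print("clusters:", rec.n_clusters)
print("sensitivity: %.2f  specificity: %.2f"
      % (conf["sensitivity"], conf["specificity"]))
biased = rec.gene_table[rec.gene_table.true_bias != "unbiased"]
print(biased[["gene_id", "true_bias", "true_log10_ratio",
              "est_log10_ratio", "est_bias"]].round(2).to_string(index=False))
```

prints

```
clusters: 50
sensitivity: 1.00  specificity: 1.00
gene_id true_bias  true_log10_ratio  est_log10_ratio est_bias
   g000    testis               2.0             2.13   testis
   g001    testis               2.0             2.00   testis
   g002     ovary              -2.0            -2.03    ovary
   g003     ovary              -2.0            -1.93    ovary
```

Every gene comes back as its own cluster, all four planted biased genes
are called in the right tissue, and their estimated log10 sex ratios sit
within sampling noise of the true value 2 (the read counts are
multinomial, so a tenth of a log unit of scatter is expected at this
depth). The proteomics arm digests the same 50 ground-truth proteins,
simulates a detection table at 80% peptide detection probability, and
recovers the genes as distinct protein groups with top-3 abundances:

```python
prec = gp.run_proteomics_recovery(cfg)
print("groups:", len(prec.groups), "recovered: %.2f" % prec.recovered_fraction)
```

```
groups: 50 recovered: 1.00
```

Scalar pieces are usable on their own, e.g. the sex ratio of a gene with
printed testis/ovary TPMs of 1,872 and 52:

```python
>>> gp.report_round(gp.sex_ratio(1872, 52))
1.55
```

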