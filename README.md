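# cometh

Read-level CpG methylation analysis for bisulfite sequencing data:

* **Quantifiers** — four per-site methylation rates computed from read-level
  CpG call patterns:
  * `wemics` — weights each methylated read by *m/c*, the length of the
    consecutive-methylated run containing the site over the read's CpG
    count, then takes A/(A + n_u) with A the weight sum;
  * `chalm` — fraction of covering reads carrying ≥ 1 methylated CpG;
  * `camda` — fraction of covering reads that are partially methylated but
    unmethylated at the site;
  * `meanm` — classic mean methylation, (n_m − n_p)/(n_m + n_u).
* **Paired DMR caller** — de-novo differentially methylated region detection
  on matched tumor/normal per-site methylation, using recursive binary
  segmentation scored by an exact Wilcoxon signed-rank test (dynamic-program
  null distribution for n ≤ 25 without ties, tie-corrected normal
  approximation otherwise), Benjamini–Hochberg correction, and the standard
  filters (≥ 3 CpGs, mean difference ≥ 0.1, q ≤ 0.05, 200 bp merge).
  An unpaired Mann–Whitney mode is included for comparison.
* **Integration statistics** — promoter windows, DMR→gene assignment with
  five-way Hyper/Hypo × Up/Down/NS classification, CpG-island
  shore/shelf/inteCGI context, motif merging and occupancy, TFBM activity
  scores (Spearman r × log2 fold change), and nested variance-explained OLS
  models.
* **Simulator** — paired tumor/normal read sets from a two-state Markov
  epiallele model with tunable methylation level, co-methylation
  persistence, coverage and CpGs per read, planted DMRs with a truth table,
  and an expression layer with a planted methylation correlation.

## Input formats

* **SAM/BAM** with a Bismark-dialect per-base methylation call tag
  (`XM:Z:`, `Z` = methylated CpG, `z` = unmethylated CpG). Both strands are
  collapsed onto the forward-strand C; secondary/supplementary/duplicate
  records are skipped; paired-end mate overlap is counted once.
* **READPAT** — a plain-text fixture format, one read per line:
  `read_id<TAB>chrom<TAB>strand<TAB>pos1,pos2,...<TAB>CALLS` with calls over
  `{M,U}` and 1-based forward-strand C coordinates.
* Per-site methylation tables for the DMR caller: TSV with `chrom`, `pos`,
  then `tumor_<id>`/`normal_<id>` columns in [0, 1].

Site output is TSV or bedGraph (0-based half-open CpG dinucleotide
intervals); DMRs are BED6+ rows.

## CLI

```sh
# per-site quantification, all four methods
cometh quant sample.readpat --method all --out sites.tsv

# region-level aggregation over a BED file
cometh quant sample.sam --method wemics --regions promoters.bed

# paired DMR calling
cometh dmr sites_matrix.tsv --mode paired --min-cpg 3 --min-diff 0.1 \
    --q 0.05 --max-gap 300 --merge-dist 200 --out dmrs.bed

# row-wise methylation/expression correlation
cometh integrate correlate meth.tsv expr.tsv --method pearson

# DMR-gene assignment + five-way classification; activity scores; OLS models
cometh integrate classify dmrs.bed genes.tsv deg.tsv
cometh integrate activity tfbm_meth.tsv expr.tsv --tumor-samples t1,t2,t3
cometh integrate variance gene_table.tsv

# synthetic paired cohort (see tests/test_cli.py for the config format)
cometh simulate cohort --config cohort.cfg --seed 7 --out sim/
```

All commands are deterministic given their inputs and `--seed`; outputs
carry a provenance header and a JSON run summary is written next to file
outputs.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (quantifier
identities against an exact rational-arithmetic oracle, signed-rank DP vs
brute-force enumeration, type-I error calibration, planted-DMR recovery,
planted-correlation recovery, CLI determinism). The full suite takes a few
minutes on one CPU.

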