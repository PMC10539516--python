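# sdscan

Identify a sex-determination system (XY or ZW) from RADseq genotype
matrices.  The package reimplements, as a tested pipeline, the bespoke
computations of a treefrog sex-chromosome study:

* **genotypes** — VCF + metadata I/O, per-call depth masking, call-rate /
  MAF / sample-missingness filters, technical-replicate deduplication and
  mismatch-rate estimation;
* **simulate** — synthetic F1 mapping families (sex-specific
  recombination, genotyping error, missingness, negative-binomial depth)
  and sexed adult cohorts carrying an XY/ZW locus with distance-decaying
  linkage plus heterogametic-sex-specific RADtags, all with full truth
  tables for testing;
* **mendel** — the seven-model Mendelian segregation filter (AAxAA,
  BBxBB, AAxBB, AAxAB, BBxAB, ABxAB, ABxMissing) with a 2% error
  allowance, chi-square goodness of fit at alpha = 0.005, single-parent
  imputation and silencing of incompatible offspring genotypes;
* **sexlink** — five sex-linkage detection criteria (four
  genotype-frequency thresholds on SNPs, one presence/absence screen on
  RADtags) evaluated in both XY and ZW orientation behind a 60% per-sex
  call-rate gate;
* **permtest** — a sex-label permutation null (default 10,000 reps) with
  empirical upper 95%/99% quantiles and add-one empirical p-values;
* **assoc** — relatedness/structure prefiltering, a codominant
  (likelihood-ratio chi-square) genotype-sex association scan with
  Benjamini-Hochberg FDR control, and QQ-table output;
* **maps** — linkage-map cleanup (multi-LG RADtags, dangling terminal
  tags), sex-averaged map merging ((male + female)/2 with interpolation
  of single-sex markers), per-LG summary metrics including the F:M
  length ratio, genome coverage `1 - exp(-2dn/L)`, and marker placement.

## Command line

```bash
sdscan simulate --preset cohort --out-dir sim --seed 1      # synthetic data
sdscan filter   --vcf in.vcf --meta meta.tsv --out-vcf f.vcf
sdscan segfilter --vcf fam.vcf --meta fam.tsv --out-vcf seg.vcf --report seg.tsv
sdscan sexscan  --vcf f.vcf --meta meta.tsv --out calls.tsv
sdscan permtest --vcf f.vcf --meta meta.tsv --out perm.tsv --n-perm 10000 --seed 1
sdscan assoc    --vcf f.vcf --meta meta.tsv --out assoc.tsv
sdscan merge    --male male.tsv --female female.tsv --out avg.tsv
sdscan mapstats --male male.tsv --female female.tsv --out stats.tsv
sdscan run      --config pipeline.yaml                      # all stages
```

`sdscan run` consumes a YAML `PipelineConfig` (see `sdscan.cli`); every
random operation takes an explicit seed and reruns are deterministic.

Sample metadata is a TSV with columns `sample_id`, `role`
(mother/father/offspring/adult), `sex` (M/F/unknown) and optional
`replicate_group`.  Linkage maps are TSVs with columns `lg`,
`marker_id`, `radtag_id`, `pos_cM`.

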