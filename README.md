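# catd

Padlock-probe capture toolkit for simultaneous genotyping of large genomic
deletions and small DNA mutations from targeted sequencing data.

Large deletions with flexible boundaries are read out positively by
**Cat-D** probes: a deletion-spanning pre-amplification tags the amplicon
with an artificial adapter, and a padlock probe whose extension arm anchors
in that adapter captures a product only when the deletion allele amplified.
**Kebab** probes tile the commonly deleted interval, so loss of their
products marks a homozygous deletion; **SNP** probes read small mutations
inside their captured gap. The package covers the computational side of the
assay:

- `catd.probe_design` — adapter, Cat-D, Kebab and SNP probe design under
  arm constraints (both arms >= 20 nt, nearest-neighbor Tm near 55 °C,
  exact-match arm uniqueness, a self-complementarity screen).
- `catd.read_counting` — expected capture products, exact-match counting of
  the first 88 nt of each read, and depth normalization to 200 K reads per
  sample.
- `catd.genotype_calling` — standard weight (mean of wild-type controls),
  raw genotype scores (inverted for Kebab), scale-to-100, thresholding,
  wt/het/hom/compound-het resolution and the 5% minor-allele-fraction caller.
- `catd.simulator` — synthetic references, libraries, cohorts (default: 8
  samples in duplicate + 2 singletons = 18 libraries, ~184 K reads each, 36
  probes) with truth tables.
- `catd.pipeline` + `catd.cli` — simulate -> count -> call orchestration,
  duplicate-concordance statistics and a schema-validated JSON run report.

## CLI

```sh
# design a probe library from a reference and target definitions
catd design --reference ref.fa --deletions del.bed --common common.bed \
    --snps snps.tsv --n-catd 5 --n-kebab 17 --seed 1 -o libdir/

# simulate a cohort (FASTQs, sample sheet, truth table, library)
catd simulate --config sim.yaml --seed 1 -o simdir/

# count reads by exact 88-nt match and depth-normalize
catd count --library simdir/library --samples simdir/samples.tsv \
    --target-depth 200000 -o counts.tsv

# genotype scores and calls
catd call --counts counts.tsv --samples simdir/samples.tsv \
    --threshold-rule fold --maf 0.05 -o calls/

# everything in one go on a simulated cohort
catd run --config run.yaml -o out/
```

`sim.yaml` holds `catd.simulator.SimConfig` fields (`seed`, `depth`,
`error_rate`, `junk_fraction`, `cohort_plan`, ...); `run.yaml` may nest them
under `sim:` plus pipeline settings (`threshold_rule`, `fold`, `k`, `maf`,
`target_depth`, `pseudocount`).

Outputs: `counts.tsv` (long per-sample x per-product counts),
`scores.tsv` (headcount, standard weight, raw/scaled genotype scores,
threshold, call per panel), `calls.tsv` (one genotype call per sample per
target), `report.json` (mapping stats, thresholds, duplicate Pearson r,
flags).

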