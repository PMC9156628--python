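# haplosel

Population-genetic contrasts between **haploid-biased** (male-biased),
**diploid-biased** (female-biased) and **constitutively expressed** genes in a
haplodiploid genome, built as a tested, reusable pipeline:

- **Expression classification** — pairwise up-regulation calls per (sex,
  tissue) group from an RNA-seq count matrix (median-of-ratios normalization,
  Welch t-test on log2(x+1), Benjamini–Hochberg FDR within each comparison),
  with adult and larval datasets classified separately and merged.
- **Codon-aware popgen statistics** — NG86 synonymous/nonsynonymous site
  counting, per-gene πS/πNS with a minor-allele-frequency filter, Pn/Ps and
  fixed-difference Dn/Ds counts versus a single-haplotype outgroup (multi-hit
  codons resolved by pathway averaging), GC content and CpG observed/expected.
- **Selection tests** — per-gene McDonald–Kreitman χ² test, Direction of
  Selection (DoS), positive-selection flagging, and two-proportion contrasts
  between gene classes.
- **Marey-map recombination rates** — monotone shape-preserving interpolation
  of (bp, cM) linkage markers, per-gene rates in cM/Mb.
- **Relaxed-selection null model** — the fixation-rate map ω(g) = g/(1−e^(−g))
  with class-specific exposure coefficients; inversion of observed
  constitutive dN/dS to γ = 2Nₑs; the two-fold polymorphism expectation for
  sex-biased genes; postcopulatory-sexual-selection exposure scaling with the
  harmonic mean mate number H.
- **Comparisons** — one-way ANOVA, ANCOVA with a GC covariate (type-II SS),
  Tukey HSD, and OLS regressions on log2 expression bias.
- **Synthetic data** — a seeded generator for every pipeline input (CDS
  FASTA, GFF3, VCF with AC/AN, outgroup table, count matrix, metadata,
  linkage map) with planted ground truth, so every stage is testable offline.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact printed
arithmetic, oracle equivalences, calibration and recovery checks, and the
2,000-gene deterministic demo).

## Command line

```sh
haplosel demo --seed 1 --outdir out/            # synthetic end-to-end run
haplosel simulate --n-genes 500 --seed 2 --outdir sim/
haplosel validate --vcf sim/ingroup.vcf --gff sim/genes.gff3
haplosel classify --counts sim/counts.tsv --sample-meta sim/samples.tsv \
    --alpha 0.01 --min-total 10 --outdir cls/
haplosel popgen --fasta sim/cds.fasta --gff sim/genes.gff3 \
    --vcf sim/ingroup.vcf --outgroup sim/outgroup.tsv --maf 0.01 --out popgen.tsv
haplosel mk --popgen-table popgen.tsv --p-max 0.05 --dos-min 0 --out mk.tsv
haplosel recomb --gff sim/genes.gff3 --linkage-map sim/linkage_map.tsv --out rates.tsv
haplosel expect --pnps-constitutive 0.10 --omega-constitutive 0.092 --out expect.tsv
haplosel run --config pipeline.yaml                # full pipeline on real inputs
```

`haplosel demo` writes a per-gene master table (class label, πS, πNS, Pn/Ps,
Dn/Ds, DoS, MK p, GC, CpGo/e, recombination rate), class summaries with model
expectations, comparison statistics, and a JSON manifest recording the seed,
every threshold, per-stage gene-drop counts and the master-table checksum.

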