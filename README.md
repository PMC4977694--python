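# isomirkit

Tools for quantifying 5'isomiRs — mature microRNA variants whose 5' end is
shifted relative to the annotated (canonical) sequence — from small-RNA
sequencing reads, and for the downstream analyses that make them
biologically interesting: detecting highly expressed miRNA/5'isomiR pairs,
scanning 3'UTRs for the shifted seed's target sites, filtering
downregulated genes, and relating isoform expression to clinical variables
in patient cohorts.

Because the seed (nucleotides 2–8) is the primary determinant of target
recognition, a one-base 5' shift gives an isomiR a different target
spectrum from its canonical counterpart: for miR-140-3p, the canonical seed
`ACCACAG` becomes `CCACAGG` in the +1 isomiR, so the two species repress
overlapping but distinct gene sets. The package is aimed at computational
biologists who want a small, fully tested, end-to-end pipeline for this
class of analysis, with a synthetic-data generator that plants known ground
truth at every stage.

## The model in brief

Reads are adapter-trimmed (exact suffix/prefix match), placed on precursor
hairpins by exact matching (sense strand, 0 mismatches), and described by
offsets `d5|d3` relative to the annotated mature (`+1|+2` = starts one base
in, ends two bases past). All 18–24 nt reads sharing a 5' offset collapse
into one isoform group `(miRNA, d5)`; counts are normalised to reads per
million (rpm) of collapsed weight, so each sample's rpm sums to 10⁶. A
miRNA/5'isomiR pair is *highly expressed* when

- mean canonical rpm across samples ≥ 100, and
- (mean isomiR rpm) / (mean canonical rpm) ≥ 0.2 (i.e. at least 1:5).

Downstream, genes count as downregulated under a condition when
treated/control expression < 0.65 with Benjamini–Hochberg-corrected
p < 0.05 in every required cell line; cohort analyses use Pearson
correlation, two-tailed unpaired t tests, and a two-group log-rank test
between the upper and lower expression quartiles.

## Worked example

The packaged expression table (12 isoform rows × 8 breast cell lines)
contains the six candidate miRNA/5'isomiR pairs; all six pass the default
criteria, and for miR-140-3p the isomiR out-expresses the canonical form:

```python
>>> from isomirkit import detect_pairs, load_breast_panel_rpm, seed_of
>>> for c in detect_pairs(load_breast_panel_rpm()):
...     print(f"{c.mirna_name:12s} canonical={c.canonical_mean_rpm:7.1f} "
...           f"isomir={c.isomir_mean_rpm:7.1f} ratio={c.ratio:.2f} passes={c.passes}")
miR-10a-5p   canonical= 2959.2 isomir= 1333.2 ratio=0.45 passes=True
miR-1307-3p  canonical= 1258.9 isomir=  457.8 ratio=0.36 passes=True
miR-140-3p   canonical=  208.3 isomir=  383.1 ratio=1.84 passes=True
miR-183-5p   canonical=  986.4 isomir=  808.3 ratio=0.82 passes=True
miR-203-3p   canonical= 1759.7 isomir=  875.5 ratio=0.50 passes=True
miR-30a-3p   canonical=  346.6 isomir=  103.3 ratio=0.30 passes=True
>>> seed_of("UACCACAGGGUAGAACCACGG"), seed_of("ACCACAGGGUAGAACCACGGAC")
('ACCACAG', 'CCACAGG')
```

`ratio=1.84` for miR-140-3p means the +1 isomiR is expressed almost twice
as highly as the canonical miRNA on average — the configuration that makes
this pair the headline case.

The same stages are available from the shell:

```sh
isomirkit simulate --config sim.yaml --out-dir sim/        # synthetic inputs
isomirkit quantify --reads S1=sim/S1.fastq.gz \
    --precursors sim/precursors.fa --matures sim/matures.gff3 \
    --adapter TGGAATTCTCGGGTGCCAAGG --out-dir quant/
isomirkit pairs --matrix quant/rpm_matrix.tsv --out-dir pairs/
isomirkit seedscan --utrs utrs.fa --mature UACCACAGGGUAGAACCACGG \
    --offset 1 --out-dir scan/
isomirkit de --table de_table.tsv --cell-lines LineA,LineB --out-dir de/
isomirkit cohort --patients cohort.tsv --out-dir cohort/
```

Every subcommand writes a JSON manifest (version, parameters, input
checksums, seed) next to its outputs.

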