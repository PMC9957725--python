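# utrland

Analysis toolkit for the 5′UTR isoform translational landscape: from
CAGE-style transcription start site (CTSS) tag counts and a genome it
computes promoter architecture, 5′TOP and PRTE motif scores, polysome
heavy/light translational-efficiency readouts, 5′UTR sequence features,
and isoform-level PSI survival stratification. A synthetic-data
generator with planted ground truth stands in for raw sequencing data,
so the whole pipeline is testable offline.

## Modules

| module | what it does |
| --- | --- |
| `utrland.motif_features` | TOP / TOP-like classification, PRTE 9-mer scanning, NUG/uORF counting, GC content, Nussinov-style folding proxy (external folder pluggable) |
| `utrland.ctss_promoters` | CTSS tables, tags-per-million, distance clustering, 0.1–0.9 quantile promoter width with the sharp (<10 bp) / broad cut, gene TSS profiles, TOPscore (Σ fᵢ·min(Lᵢ,16)), PRTE score per million mapped reads, TSS-window read fractions |
| `utrland.translation_readouts` | HP/LP ratio with low/middle/high classes (cuts at 1 and 3), gene TE = ribo RPKM / RNA RPKM with the RNA rpkm>1 and optional base-mean>25 filters, two-sample KS, Benjamini–Hochberg, Fisher-exact differential cluster usage, mTORC1-dependency and reporter TE |
| `utrland.isoform_survival` | PSI per isoform, splice-event ratios, nearest-rank quartile stratification, Kaplan–Meier, log-rank, univariate Cox (Breslow/Efron, Newton–Raphson) |
| `utrland.synthetic_data` | seeded genome/annotation with planted promoter classes and motifs, multinomial CTSS tables, logistic polysome splits, negative-binomial ribo/RNA counts, exponential survival cohorts tied to PSI |
| `utrland.io_cli` | FASTA/GTF/BED6/CTSS/TSV readers and writers, pipeline driver, click CLI |

Coordinates are 0-based half-open internally; CTSS files are 1-based and
converted at I/O. Minus-strand sequences are reverse-complemented before
motif scans.

## CLI

```sh
utrland simulate --out sim/ --seed 1 --depth 100000 --polysome
utrland cluster sim/ctss_A_rep1.tsv
utrland width sim/ctss_A_rep1.tsv
utrland features CUUUUGGAC GGGAAACCC
utrland te --counts sim/ribo_rna_counts.tsv
utrland diffclusters --ctss-a a1.tsv --ctss-b b1.tsv
utrland survival --tpm sim/transcript_tpm.tsv --survival sim/survival.tsv \
    --transcript tx_risk
utrland run-all --config pipeline.json --out report/
utrland fixtures --out fixtures/
```

`run-all` takes a JSON file with `PipelineConfig` fields (paths to
genome/annotation/CTSS tables plus thresholds; every default matches the
published cutoffs) and writes per-stage TSV tables and a `report.json`
with config hash and warnings. Exit codes: 0 ok, 2 configuration error,
3 data error.

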