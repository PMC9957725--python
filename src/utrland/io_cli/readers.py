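"""Readers and writers for the pipeline's standard formats.

All coordinates are converted to the internal 0-based half-open
convention at the I/O boundary: CTSS files carry 1-based positions, GTF
is 1-based inclusive, BED is already 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from pyfaidx import Fasta

from ..ctss_promoters import CtssRecord, CtssTable


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_fasta(path: str | Path) -> Fasta:
    """Open an indexed FASTA; chromosome access returns sequence objects
    whose ``str()`` is the full sequence."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def read_gtf_genes(path: str | Path) -> dict[str, tuple[str, int, int, str]]:
    """Gene intervals from a GTF: gene_id -> (chrom, start, end, strand),
    0-based half-open."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="warning",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = {}
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise DataError(f"gene {feat.id}: strand {feat.strand!r} not supported")
        genes[feat.id] = (feat.seqid, feat.start - 1, feat.end, feat.strand)
    if not genes:
        raise DataError(f"no gene features found in {path}")
    return genes


def read_ctss(
    path: str | Path,
    sample_id: str | None = None,
    condition: str = "",
    fraction: str = "total",
) -> CtssTable:
    """Read a CTSS TSV (chrom, 1-based pos, strand, count; '#' comments).

    Positions are converted to the internal 0-based convention.
    """
    path = Path(path)
    records = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise DataError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, pos_s, strand, count_s = fields
            try:
                pos = int(pos_s)
                count = int(count_s)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer pos/count") from exc
            if pos < 1:
                raise DataError(f"{path}:{lineno}: 1-based position must be >= 1")
            if strand not in ("+", "-"):
                raise DataError(f"{path}:{lineno}: invalid strand {strand!r}")
            records.append(CtssRecord(chrom=chrom, pos=pos - 1, strand=strand, count=count))
    return CtssTable(
        sample_id=sample_id or path.stem,
        records=records,
        condition=condition,
        fraction=fraction,
    )


def write_ctss(table: CtssTable, path: str | Path) -> None:
    """Write a CTSS table (1-based positions, sorted by chrom, pos, strand)."""
    with Path(path).open("w") as fh:
        fh.write(f"# sample: {table.sample_id}\n")
        for r in sorted(table.records, key=lambda r: (r.chrom, r.pos, r.strand)):
            fh.write(f"{r.chrom}\t{r.pos + 1}\t{r.strand}\t{r.count}\n")


def read_bed_windows(path: str | Path) -> dict[str, list[tuple[str, int, int, str]]]:
    """TSS windows from BED6; name field must be ``gene_id:window_index``.

    Windows are returned per gene in window-index order.  Strand '.' is
    rejected because read fractions are strand-specific.
    """
    path = Path(path)
    per_gene: dict[str, list[tuple[int, str, int, int, str]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise DataError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            if strand not in ("+", "-"):
                raise DataError(
                    f"{path}:{lineno}: strand {strand!r} rejected (required for windows)"
                )
            if ":" not in name:
                raise DataError(f"{path}:{lineno}: window name must be gene_id:window_index")
            gene_id, widx = name.rsplit(":", 1)
            try:
                start, end = int(start_s), int(end_s)
                order = int(widx.lstrip("w"))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: malformed BED fields") from exc
            if end <= start:
                raise DataError(f"{path}:{lineno}: empty interval")
            per_gene.setdefault(gene_id, []).append((order, chrom, start, end, strand))
    return {
        gene: [(c, s, e, st) for _, c, s, e, st in sorted(wins)]
        for gene, wins in per_gene.items()
    }


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Generic TSV with a header row."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
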