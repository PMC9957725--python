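"""Synthetic genome, CTSS, count and survival data with planted truth.

Generates a toy genome plus annotation where each gene carries a known
promoter architecture (sharp TOP, sharp non-TOP, broad mixed, or
PRTE-carrying), simulates CAGE-style CTSS tag tables per condition and
replicate, splits tags into light/heavy polysome fractions with
logistic odds driven by the planted features, draws negative-binomial
ribo/RNA counts with planted translational-efficiency shifts, and draws
exponential survival cohorts whose hazard is tied to an isoform PSI
covariate.  Every dataset is reproducible from its seed and serialized
together with its planted truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ctss_promoters import CtssRecord, CtssTable
from .motif_features import has_prte, reverse_complement, scan_prte

__all__ = [
    "SimulationConfig",
    "GeneTruth",
    "PlantedTruth",
    "make_genome",
    "simulate_ctss",
    "simulate_polysome_split",
    "simulate_ribo_rna",
    "simulate_survival",
    "write_dataset",
]

PROMOTER_CLASSES = ("sharp_top", "broad_mixed", "sharp_nontop", "prte_plus")

_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "T")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """All knobs of the simulator; the seed fixes every downstream draw."""

    n_genes_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "sharp_top": 15,
            "broad_mixed": 10,
            "sharp_nontop": 15,
            "prte_plus": 10,
        }
    )
    utr_length_range: tuple[int, int] = (30, 300)
    cds_length: int = 300
    depth: int = 100_000
    replicates: int = 2
    genes_per_chrom: int = 50
    broad_tss_sd: float = 8.0
    sharp_tss_sd: float = 0.0
    top_tract_range: tuple[int, int] = (5, 9)  # run length incl. the +1 C
    expression_sd: float = 1.0
    # heavy-polysome odds: logistic(b0 + b_top*TOP + b_prte*PRTE + b_len*z + b_gc*z)
    beta0: float = 0.0
    beta_top: float = 0.0
    beta_prte: float = 0.0
    beta_len: float = 0.0
    beta_gc: float = 0.0
    # ribo/RNA counts
    nb_dispersion: float = 0.1
    te_shift_log2: float = 0.0
    te_shift_fraction: float = 0.0
    # survival
    n_patients: int = 200
    beta_s: float = 0.0
    baseline_hazard: float = 0.02
    censor_fraction: float = 0.3
    # TSS-window switch (broad_mixed genes get 3 promoter windows)
    window_weights_a: tuple[float, float, float] = (0.2, 0.1, 0.7)
    window_weights_b: tuple[float, float, float] = (0.2, 0.1, 0.7)
    seed: int = 0

    def rng(self, stage: str) -> np.random.Generator:
        """One independent stream per simulation stage, keyed by the seed.

        The stage key uses crc32, not the builtin ``hash``, so streams
        are stable across processes and platforms.
        """
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stage.encode())])
        )


@dataclass
class GeneTruth:
    """Planted ground truth for one synthetic gene."""

    gene_id: str
    chrom: str
    strand: str
    promoter_class: str
    tss: int  # modal TSS, 0-based genomic coordinate of the +1 base
    utr_length: int
    gene_start: int  # 0-based half-open gene interval
    gene_end: int
    is_top: bool
    has_prte: bool
    tract_length: int
    tss_sd: float
    expression: float = 1.0
    gc: float = 0.5
    hp_prob: float = 0.5
    te_shift_log2: float = 0.0
    windows: Optional[list[tuple[int, int]]] = None  # 0-based half-open, genomic


@dataclass
class PlantedTruth:
    """Genome, annotation and per-gene truth for one simulated dataset."""

    genome: dict[str, str]
    genes: list[GeneTruth]

    def gene_intervals(self) -> dict[str, tuple[str, int, int, str]]:
        return {
            g.gene_id: (g.chrom, g.gene_start, g.gene_end, g.strand)
            for g in self.genes
        }

    def by_id(self) -> dict[str, GeneTruth]:
        return {g.gene_id: g for g in self.genes}

    def windows_by_gene(self) -> dict[str, list[tuple[str, int, int, str]]]:
        return {
            g.gene_id: [(g.chrom, s, e, g.strand) for s, e in g.windows]
            for g in self.genes
            if g.windows is not None
        }


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


class _ChromWriter:
    """Mutable chromosome supporting transcript-strand base planting."""

    def __init__(self, seq: list[str]):
        self.seq = seq

    def plant(self, pos: int, strand: str, bases: str, offset: int = 0) -> None:
        """Write ``bases`` in transcript orientation starting ``offset`` nt
        downstream of the 5' end at ``pos`` (rightward on +, leftward on -)."""
        for i, b in enumerate(bases, start=offset):
            if strand == "+":
                self.seq[pos + i] = b
            else:
                self.seq[pos - i] = _COMPLEMENT[b]

    def read(self, pos: int, strand: str, length: int) -> str:
        if strand == "+":
            return "".join(self.seq[pos : pos + length])
        return reverse_complement("".join(self.seq[max(0, pos - length + 1) : pos + 1]))


def _scrub_prte(
    writer: _ChromWriter,
    pos: int,
    strand: str,
    length: int,
    protected: tuple[int, int],
    rng: np.random.Generator,
) -> None:
    """Destroy accidental PRTE 9-mers in the transcript-strand window of
    ``length`` nt starting at ``pos``, leaving offsets inside the
    ``protected`` [start, end) range untouched."""
    p_lo, p_hi = protected
    for _ in range(30):
        window = writer.read(pos, strand, length)
        dirty = [
            h for h in scan_prte(window)
            if not (p_lo <= h.offset and h.offset + 9 <= p_hi)
        ]
        if not dirty:
            return
        for h in dirty:
            # mutate the invariant T (position 6 of the 9-mer) to a purine,
            # unless that base sits inside the protected motif
            off = h.offset + 5
            if p_lo <= off < p_hi:
                off = h.offset if h.offset < p_lo else h.offset + 8
            writer.plant(pos, strand, str(rng.choice(_PURINES)), offset=off)


def make_genome(config: SimulationConfig) -> PlantedTruth:
    """Build a synthetic genome + annotation with planted promoter classes.

    sharp_top genes get a C + (tract_length - 1) pyrimidine tract at the
    modal TSS followed by a purine terminator; sharp_nontop genes get a
    purine at +1; prte_plus genes get a purine at +1 and a valid PRTE
    9-mer planted inside the 5'UTR; broad_mixed genes get a TOP tract at
    the modal TSS and a wide TSS spread with three promoter windows.
    Accidental PRTE 9-mers within the modeled 75-nt read window of each
    modal TSS are scrubbed so PRTE truth is exact.
    """
    rng = config.rng("genome")
    gene_specs: list[str] = []
    for cls in PROMOTER_CLASSES:
        gene_specs += [cls] * config.n_genes_per_class.get(cls, 0)
    n_genes = len(gene_specs)
    if n_genes == 0:
        raise ValueError("no genes configured")
    order = rng.permutation(n_genes)
    gene_specs = [gene_specs[i] for i in order]

    lo, hi = config.utr_length_range
    pad = 200  # margin per gene for broad promoters and minus strands
    slot = hi + config.cds_length + 2 * pad

    genes: list[GeneTruth] = []
    genome: dict[str, str] = {}
    n_chroms = math.ceil(n_genes / config.genes_per_chrom)
    gi = 0
    for ci in range(n_chroms):
        chrom = f"chrS{ci + 1}"
        chrom_genes = gene_specs[
            ci * config.genes_per_chrom : (ci + 1) * config.genes_per_chrom
        ]
        chrom_len = slot * len(chrom_genes) + pad
        writer = _ChromWriter(list(rng.choice(_BASES, size=chrom_len)))
        for si, cls in enumerate(chrom_genes):
            gi += 1
            gene_id = f"g{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            utr_len = int(rng.integers(lo, hi + 1))
            is_top = cls in ("sharp_top", "broad_mixed")
            plants_prte = cls == "prte_plus"
            tract = int(rng.integers(*config.top_tract_range)) if is_top else 0

            slot_start = si * slot + pad
            if strand == "+":
                tss = slot_start
                gene_start = max(0, tss - pad // 2)
                gene_end = tss + utr_len + config.cds_length
            else:
                tss = slot_start + utr_len + config.cds_length
                gene_start = tss - utr_len - config.cds_length
                gene_end = min(chrom_len, tss + pad // 2)

            protected = (0, 0)
            if is_top:
                # C + pyrimidines + purine terminator (terminator keeps the
                # planted run from extending into an unintended PRTE)
                tract_seq = "C" + "".join(rng.choice(_PYRIMIDINES, size=tract - 1))
                writer.plant(tss, strand, tract_seq + str(rng.choice(_PURINES)))
                protected = (0, tract + 1)
            else:
                writer.plant(tss, strand, str(rng.choice(_PURINES)))
            if plants_prte:
                prte = "".join(rng.choice(_PYRIMIDINES, size=9))
                prte = prte[:5] + "T" + prte[6:]
                offset = int(rng.integers(10, max(11, min(utr_len, 66) - 9)))
                # purine fences so the pyrimidine run is exactly the 9-mer
                writer.plant(tss, strand, str(rng.choice(_PURINES)), offset=offset - 1)
                writer.plant(tss, strand, prte, offset=offset)
                writer.plant(tss, strand, str(rng.choice(_PURINES)), offset=offset + 9)
                protected = (offset, offset + 9)
            _scrub_prte(writer, tss, strand, 75, protected, rng)
            if plants_prte:
                assert has_prte(writer.read(tss, strand, 75))

            tss_sd = config.broad_tss_sd if cls == "broad_mixed" else config.sharp_tss_sd
            windows = None
            if cls == "broad_mixed":
                # three 12-bp windows tiling the promoter around the modal TSS
                if strand == "+":
                    w0 = tss - 18
                    windows = [(w0 + 12 * k, w0 + 12 * (k + 1)) for k in range(3)]
                else:
                    w0 = tss + 18
                    windows = [
                        (w0 - 12 * (k + 1) + 1, w0 - 12 * k + 1) for k in range(3)
                    ]
            utr_seq = writer.read(tss, strand, utr_len)
            genes.append(
                GeneTruth(
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    promoter_class=cls,
                    tss=tss,
                    utr_length=utr_len,
                    gene_start=gene_start,
                    gene_end=gene_end,
                    is_top=is_top,
                    has_prte=plants_prte,
                    tract_length=tract,
                    tss_sd=tss_sd,
                    gc=(utr_seq.count("G") + utr_seq.count("C")) / len(utr_seq),
                    windows=windows,
                )
            )
        genome[chrom] = "".join(writer.seq)

    truth = PlantedTruth(genome=genome, genes=genes)
    _assign_expression_and_odds(truth, config)
    return truth


def _assign_expression_and_odds(truth: PlantedTruth, config: SimulationConfig) -> None:
    rng = config.rng("expression")
    shift_rng = config.rng("te_shift")
    lens = np.array([g.utr_length for g in truth.genes], dtype=float)
    gcs = np.array([g.gc for g in truth.genes], dtype=float)
    z_len = (lens - lens.mean()) / (lens.std() or 1.0)
    z_gc = (gcs - gcs.mean()) / (gcs.std() or 1.0)
    for i, g in enumerate(truth.genes):
        g.expression = float(rng.lognormal(mean=0.0, sigma=config.expression_sd))
        eta = (
            config.beta0
            + config.beta_top * g.is_top
            + config.beta_prte * g.has_prte
            + config.beta_len * z_len[i]
            + config.beta_gc * z_gc[i]
        )
        g.hp_prob = _sigmoid(eta)
        if config.te_shift_fraction > 0 and shift_rng.random() < config.te_shift_fraction:
            g.te_shift_log2 = config.te_shift_log2


def _tss_weights(g: GeneTruth) -> tuple[np.ndarray, np.ndarray]:
    """Discretized-Gaussian TSS positions and weights around the modal TSS."""
    if g.tss_sd <= 0:
        return np.array([g.tss]), np.array([1.0])
    half = int(math.ceil(3 * g.tss_sd))
    offsets = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (offsets / g.tss_sd) ** 2)
    return g.tss + offsets, w / w.sum()


def _apply_window_weights(
    g: GeneTruth,
    positions: np.ndarray,
    weights: np.ndarray,
    target: tuple[float, float, float],
) -> np.ndarray:
    """Rescale TSS weights so the gene's promoter windows carry the planted
    per-condition shares; mass outside all windows keeps its share."""
    assignment = np.full(len(positions), -1)
    for wi, (start, end) in enumerate(g.windows):
        inside = (positions >= start) & (positions < end)
        assignment[inside] = wi
    w = weights.copy()
    in_any = assignment >= 0
    budget = max(0.0, 1.0 - w[~in_any].sum())
    t = np.asarray(target, dtype=float)
    t = t / t.sum()
    for wi in range(len(g.windows)):
        sel = assignment == wi
        cur = w[sel].sum()
        if cur > 0:
            w[sel] *= budget * t[wi] / cur
    return w / w.sum()


def simulate_ctss(
    truth: PlantedTruth,
    config: SimulationConfig,
    condition: str = "A",
    replicate: int = 1,
) -> CtssTable:
    """Multinomial CAGE tag counts.

    ``depth`` tags are spread over genes by lognormal expression and
    within each gene over discretized-Gaussian TSS positions;
    broad_mixed genes use per-condition window weights (the planted
    TSS-window switch).  Total counts equal ``depth`` exactly.
    """
    rng = config.rng(f"ctss:{condition}:{replicate}")
    expr = np.array([g.expression for g in truth.genes])
    gene_tags = rng.multinomial(config.depth, expr / expr.sum())
    counts: dict[tuple[str, int, str], int] = {}
    for g, n_tags in zip(truth.genes, gene_tags):
        if n_tags == 0:
            continue
        positions, weights = _tss_weights(g)
        if g.windows is not None:
            target = (
                config.window_weights_a if condition == "A" else config.window_weights_b
            )
            weights = _apply_window_weights(g, positions, weights, target)
        alloc = rng.multinomial(n_tags, weights)
        for p, c in zip(positions, alloc):
            if c > 0:
                key = (g.chrom, int(p), g.strand)
                counts[key] = counts.get(key, 0) + int(c)
    records = [
        CtssRecord(chrom=c, pos=p, strand=s, count=n)
        for (c, p, s), n in sorted(counts.items())
    ]
    return CtssTable(
        sample_id=f"{condition}_rep{replicate}",
        records=records,
        condition=condition,
        fraction="total",
    )


def simulate_polysome_split(
    table: CtssTable,
    truth: PlantedTruth,
    config: SimulationConfig,
) -> tuple[CtssTable, CtssTable]:
    """Split each tag into light/heavy polysome fractions.

    Tag-level assignment to HP is binomial with the gene's planted
    logistic probability; tags outside any gene use prob 0.5.  LP + HP
    counts equal the input counts at every position.
    """
    rng = config.rng(f"polysome:{table.sample_id}")
    intervals = truth.gene_intervals()
    by_id = truth.by_id()
    lp_records, hp_records = [], []
    for r in table.records:
        p = 0.5
        for gid, (chrom, start, end, strand) in intervals.items():
            if chrom == r.chrom and strand == r.strand and start <= r.pos < end:
                p = by_id[gid].hp_prob
                break
        hp = int(rng.binomial(r.count, p))
        lp = r.count - hp
        if hp:
            hp_records.append(CtssRecord(r.chrom, r.pos, r.strand, hp))
        if lp:
            lp_records.append(CtssRecord(r.chrom, r.pos, r.strand, lp))
    base = table.sample_id
    return (
        CtssTable(f"{base}_LP", lp_records, condition=table.condition, fraction="LP"),
        CtssTable(f"{base}_HP", hp_records, condition=table.condition, fraction="HP"),
    )


def simulate_ribo_rna(
    truth: PlantedTruth,
    config: SimulationConfig,
    mean_depth_per_gene: float = 2000.0,
) -> pd.DataFrame:
    """Negative-binomial ribo/RNA counts for two conditions.

    RNA means are proportional to expression x length; ribo means apply
    the gene's planted TE shift in condition B only.  Columns: gene_id,
    length, rna_A, ribo_A, rna_B, ribo_B.
    """
    rng = config.rng("ribo_rna")
    size = 1.0 / config.nb_dispersion
    lens = np.array([g.utr_length + config.cds_length for g in truth.genes], float)
    expr = np.array([g.expression for g in truth.genes])
    rel = expr * lens / lens.mean()
    scale = mean_depth_per_gene * len(truth.genes) / rel.sum()

    def nb(mean: float) -> int:
        return int(rng.negative_binomial(size, size / (size + mean))) if mean > 0 else 0

    rows = []
    for g, mu in zip(truth.genes, rel * scale):
        rows.append(
            {
                "gene_id": g.gene_id,
                "length": int(g.utr_length + config.cds_length),
                "rna_A": nb(mu),
                "ribo_A": nb(mu),
                "rna_B": nb(mu),
                "ribo_B": nb(mu * 2.0**g.te_shift_log2),
            }
        )
    return pd.DataFrame(rows)


def simulate_survival(
    config: SimulationConfig,
    covariate: str = "psi",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival cohort whose hazard is tied to an isoform PSI covariate.

    A three-isoform gene is simulated per patient; the risk isoform's
    PSI varies across patients and drives the hazard
    h0 * exp(beta_s * z), where z is the standardized PSI (or a binary
    top/bottom-half indicator for ``covariate="binary"``).  Censoring is
    independent exponential calibrated to the target fraction.

    Returns (expression frame with transcript_id/gene_id/patient columns,
    survival frame with patient_id/time_months/event).
    """
    rng = config.rng("survival")
    n = config.n_patients
    patients = [f"p{i + 1:04d}" for i in range(n)]
    psi_risk = rng.beta(2.0, 2.0, size=n)
    gene_tpm = rng.lognormal(mean=3.0, sigma=0.5, size=n)
    rest = rng.dirichlet((1.0, 1.0), size=n)
    mat = np.vstack(
        [
            gene_tpm * psi_risk,
            gene_tpm * (1 - psi_risk) * rest[:, 0],
            gene_tpm * (1 - psi_risk) * rest[:, 1],
        ]
    )
    tpm = pd.concat(
        [
            pd.DataFrame(
                {
                    "transcript_id": ["tx_risk", "tx_alt1", "tx_alt2"],
                    "gene_id": ["gene1"] * 3,
                }
            ),
            pd.DataFrame(mat, columns=patients),
        ],
        axis=1,
    )

    if covariate == "binary":
        z = (psi_risk > np.median(psi_risk)).astype(float)
    elif covariate == "psi":
        z = (psi_risk - psi_risk.mean()) / (psi_risk.std() or 1.0)
    else:
        raise ValueError(f"unknown covariate type {covariate!r}")
    hazard = config.baseline_hazard * np.exp(config.beta_s * z)
    t_event = rng.exponential(1.0 / hazard)
    if config.censor_fraction > 0:
        cf = config.censor_fraction
        rate_c = config.baseline_hazard * cf / (1 - cf)
        t_cens = rng.exponential(1.0 / rate_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.maximum(np.minimum(t_event, t_cens), 1e-6)
    event = (t_event <= t_cens).astype(int)
    surv = pd.DataFrame({"patient_id": patients, "time_months": time, "event": event})
    return tpm, surv


def write_dataset(
    truth: PlantedTruth,
    config: SimulationConfig,
    outdir: str | Path,
    conditions: tuple[str, ...] = ("A", "B"),
    polysome: bool = False,
) -> dict[str, Path]:
    """Write FASTA, GTF, BED windows, CTSS TSVs, count/survival tables and
    the truth JSON under one output directory."""
    from .io_cli.readers import write_ctss

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    with fasta.open("w") as fh:
        for chrom, seq in truth.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["genome"] = fasta

    gtf = out / "annotation.gtf"
    with gtf.open("w") as fh:
        for g in truth.genes:
            for feature, attrs in (
                ("gene", f'gene_id "{g.gene_id}";'),
                (
                    "transcript",
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";',
                ),
            ):
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            "utrland_sim",
                            feature,
                            str(g.gene_start + 1),
                            str(g.gene_end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    paths["annotation"] = gtf

    for cond in conditions:
        for rep in range(1, config.replicates + 1):
            table = simulate_ctss(truth, config, condition=cond, replicate=rep)
            p = out / f"ctss_{cond}_rep{rep}.tsv"
            write_ctss(table, p)
            paths[f"ctss_{cond}_rep{rep}"] = p
            if polysome:
                lp, hp = simulate_polysome_split(table, truth, config)
                for frac_table, frac in ((lp, "LP"), (hp, "HP")):
                    fp = out / f"ctss_{cond}_rep{rep}_{frac}.tsv"
                    write_ctss(frac_table, fp)
                    paths[f"ctss_{cond}_rep{rep}_{frac}"] = fp

    counts = simulate_ribo_rna(truth, config)
    paths["counts"] = out / "ribo_rna_counts.tsv"
    counts.to_csv(paths["counts"], sep="\t", index=False)

    tpm, surv = simulate_survival(config)
    paths["transcript_tpm"] = out / "transcript_tpm.tsv"
    tpm.to_csv(paths["transcript_tpm"], sep="\t", index=False)
    paths["survival"] = out / "survival.tsv"
    surv.to_csv(paths["survival"], sep="\t", index=False)

    bed = out / "windows.bed"
    with bed.open("w") as fh:
        for g in truth.genes:
            if g.windows is None:
                continue
            for wi, (start, end) in enumerate(g.windows, start=1):
                fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}:w{wi}\t0\t{g.strand}\n")
    paths["windows"] = bed

    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(
        json.dumps({"genes": [dataclasses.asdict(g) for g in truth.genes]}, indent=1)
    )
    paths["config"] = out / "config.json"
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(config), indent=1, default=list)
    )
    return paths
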