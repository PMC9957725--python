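"""Polysome and ribosome-profiling translational-efficiency readouts.

Heavy/light polysome tag ratios with low/middle/high classes, gene-level
translational efficiency (ribo RPKM / RNA RPKM) with filtering and a
two-sample Kolmogorov-Smirnov comparison, Fisher-exact differential
cluster usage with Benjamini-Hochberg correction, and the reporter-based
mTORC1-dependency statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "TeRatioResult",
    "GeneTeResult",
    "KsResult",
    "DifferentialClusterResult",
    "te_class",
    "hp_lp_ratio",
    "gene_te",
    "rpkm",
    "ks_two_sample",
    "bh_adjust",
    "differential_cluster_usage",
    "mtorc1_dependency",
    "reporter_te",
    "normalize_reporter_batch",
]

logger = logging.getLogger(__name__)

TE_LOW_CUT = 1.0
TE_HIGH_CUT = 3.0


def te_class(ratio: float, low_cut: float = TE_LOW_CUT, high_cut: float = TE_HIGH_CUT) -> str:
    """Classify an HP/LP ratio: low (< 1), middle (1-3 inclusive), high (> 3)."""
    if ratio < low_cut:
        return "low"
    if ratio > high_cut:
        return "high"
    return "middle"


@dataclass(frozen=True)
class TeRatioResult:
    """HP/LP tag ratio for one region as a translational-efficiency proxy."""

    region_id: str
    hp_norm: float
    lp_norm: float
    ratio: Optional[float]
    te_class: Optional[str]


def hp_lp_ratio(
    hp_tpm: Mapping[str, Sequence[float]] | Mapping[str, float],
    lp_tpm: Mapping[str, Sequence[float]] | Mapping[str, float],
    regions: Optional[Sequence[str]] = None,
) -> list[TeRatioResult]:
    """Per-region heavy/light polysome ratio and TE class.

    ``hp_tpm`` / ``lp_tpm`` map region ids to tpm-normalized abundances,
    either scalars or per-replicate sequences (replicates are averaged
    before the ratio).  Regions with zero light-polysome signal are
    reported with an undefined ratio; regions absent from both fractions
    are skipped with a log entry.
    """
    if regions is None:
        regions = sorted(set(hp_tpm) | set(lp_tpm))
    results = []
    for rid in regions:
        if rid not in hp_tpm and rid not in lp_tpm:
            logger.info("hp_lp_ratio: region %s absent from both fractions, skipped", rid)
            continue
        hp = float(np.mean(np.atleast_1d(np.asarray(hp_tpm.get(rid, 0.0), dtype=float))))
        lp = float(np.mean(np.atleast_1d(np.asarray(lp_tpm.get(rid, 0.0), dtype=float))))
        if lp == 0.0:
            results.append(TeRatioResult(rid, hp, lp, None, None))
        else:
            ratio = hp / lp
            results.append(TeRatioResult(rid, hp, lp, ratio, te_class(ratio)))
    return results


def rpkm(count: float, length_bp: float, lib_size: float) -> float:
    """Reads per kilobase per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("feature length must be positive")
    if lib_size <= 0:
        raise ValueError("library size must be positive")
    return count / (length_bp / 1e3) / (lib_size / 1e6)


@dataclass(frozen=True)
class GeneTeResult:
    """Gene-level translational efficiency: ribo RPKM / RNA RPKM."""

    gene_id: str
    ribo_rpkm: float
    rna_rpkm: float
    te: Optional[float]
    passes_filters: bool


def gene_te(
    ribo_counts: Mapping[str, float],
    rna_counts: Mapping[str, float],
    lengths: Mapping[str, float],
    ribo_lib_size: Optional[float] = None,
    rna_lib_size: Optional[float] = None,
    min_rna_rpkm: float = 1.0,
    min_base_mean: Optional[float] = None,
) -> list[GeneTeResult]:
    """Translational efficiency per gene with the RNA rpkm > 1 filter.

    ``min_base_mean`` optionally additionally requires the mean of the
    ribo and RNA raw counts to exceed the given value (the base-mean
    filter).  Library sizes default to the column sums.
    """
    genes = sorted(set(ribo_counts) & set(rna_counts))
    ribo_lib = ribo_lib_size if ribo_lib_size is not None else sum(ribo_counts.values())
    rna_lib = rna_lib_size if rna_lib_size is not None else sum(rna_counts.values())
    results = []
    for g in genes:
        rr = rpkm(ribo_counts[g], lengths[g], ribo_lib)
        nr = rpkm(rna_counts[g], lengths[g], rna_lib)
        passes = nr > min_rna_rpkm
        if min_base_mean is not None:
            passes = passes and (ribo_counts[g] + rna_counts[g]) / 2 > min_base_mean
        te = rr / nr if passes else None
        results.append(GeneTeResult(g, rr, nr, te, passes))
    return results


def te_log2fc(
    te_a: Mapping[str, float],
    te_b: Mapping[str, float],
) -> dict[str, float]:
    """log2(TE_b / TE_a) for genes with finite TE in both conditions."""
    return {
        g: math.log2(te_b[g] / te_a[g])
        for g in sorted(set(te_a) & set(te_b))
        if te_a[g] and te_b[g] and te_a[g] > 0 and te_b[g] > 0
    }


@dataclass(frozen=True)
class KsResult:
    D: float
    p: float


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum distance between the two empirical CDFs; the
    p-value uses the asymptotic Kolmogorov distribution evaluated at
    sqrt(n_eff) * D with n_eff = nx*ny/(nx+ny).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / nx
    cdf_y = np.searchsorted(y, grid, side="right") / ny
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    n_eff = nx * ny / (nx + ny)
    p = float(special.kolmogorov(math.sqrt(n_eff) * D))
    return KsResult(D=D, p=min(1.0, p))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    padj_(i) = min_{j >= i} (m/j) * p_(j), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class DifferentialClusterResult:
    """Fisher-exact differential usage of one tag cluster between conditions."""

    cluster_id: str
    count_a: int
    count_b: int
    log2fc: float
    p: float
    padj: float = float("nan")


def differential_cluster_usage(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    lib_a: Optional[int] = None,
    lib_b: Optional[int] = None,
    pseudocount: float = 0.5,
) -> list[DifferentialClusterResult]:
    """Differential cluster usage between two conditions.

    Replicates must be summed per condition beforehand.  Each cluster's
    tags are tested against the remaining library tags with a two-sided
    Fisher exact test; log2 fold change is computed on tags-per-million
    with a pseudocount; p-values are Benjamini-Hochberg adjusted.

    This is a deliberately self-contained substitute for a
    negative-binomial differential-expression model.
    """
    clusters = sorted(set(counts_a) | set(counts_b))
    tot_a = lib_a if lib_a is not None else sum(counts_a.values())
    tot_b = lib_b if lib_b is not None else sum(counts_b.values())
    if tot_a <= 0 or tot_b <= 0:
        raise ValueError("zero total tags in a condition")
    results = []
    for cid in clusters:
        a = int(counts_a.get(cid, 0))
        b = int(counts_b.get(cid, 0))
        table = [[a, tot_a - a], [b, tot_b - b]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        tpm_a = (a + pseudocount) / tot_a * 1e6
        tpm_b = (b + pseudocount) / tot_b * 1e6
        results.append(
            DifferentialClusterResult(
                cluster_id=cid,
                count_a=a,
                count_b=b,
                log2fc=math.log2(tpm_b / tpm_a),
                p=float(p),
            )
        )
    padj = bh_adjust([r.p for r in results])
    return [
        DifferentialClusterResult(r.cluster_id, r.count_a, r.count_b, r.log2fc, r.p, float(q))
        for r, q in zip(results, padj)
    ]


def mtorc1_dependency(
    scc_ctrl: float,
    scc_torin: float,
    wt_torin: float,
    rel_tol: float = 1e-9,
) -> float:
    """mTORC1 dependency of a reporter:
    (SCC no Torin - SCC Torin) / (SCC no Torin - WT Torin).

    Raises ``ZeroDivisionError`` when the denominator is within
    ``rel_tol * scc_ctrl`` of zero.
    """
    den = scc_ctrl - wt_torin
    if abs(den) <= rel_tol * abs(scc_ctrl):
        raise ZeroDivisionError(
            f"mTORC1 dependency undefined: SCC ctrl ({scc_ctrl}) and WT Torin "
            f"({wt_torin}) TE values coincide"
        )
    return (scc_ctrl - scc_torin) / den


def reporter_te(firefly: float, renilla: float, mrna_level: float) -> float:
    """Reporter translational efficiency: (firefly/renilla) / mRNA level."""
    if renilla <= 0 or mrna_level <= 0 or firefly <= 0:
        raise ValueError("firefly, renilla and mRNA level must all be positive")
    return (firefly / renilla) / mrna_level


def normalize_reporter_batch(
    te_values: Mapping[str, float],
    reference: str,
) -> dict[str, float]:
    """Express reporter TE values as percent of a reference construct (=100)."""
    if reference not in te_values:
        raise KeyError(f"reference construct {reference!r} not measured")
    ref = te_values[reference]
    if ref <= 0:
        raise ValueError("reference TE must be positive")
    return {k: v / ref * 100.0 for k, v in te_values.items()}
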