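"""Unit and property tests for CTSS clustering, widths and scores."""

import itertools

import numpy as np
import pytest

from utrland.ctss_promoters import (
    CtssRecord,
    CtssTable,
    GeneTssProfile,
    TagCluster,
    cluster_ctss,
    filter_min_avg_reads,
    normalize_tpm,
    prte_score,
    quantile_width,
    topscore,
    build_profile,
    tss_sequence,
    window_read_fractions,
)

# ---------------------------------------------------------------- oracles


def transitive_closure_partition(positions, maxdist):
    """Brute-force union over all pairs within maxdist."""
    positions = sorted(set(positions))
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a, b in itertools.combinations(positions, 2):
        if abs(a - b) <= maxdist:
            parent[find(a)] = find(b)
    groups = {}
    for p in positions:
        groups.setdefault(find(p), set()).add(p)
    return sorted(frozenset(g) for g in groups.values())


def cumulative_quantile_pos(positions_counts, q, ascending=True):
    """Direct cumulative enumeration."""
    items = sorted(positions_counts.items(), reverse=not ascending)
    total = sum(c for _, c in items)
    cum = 0
    for pos, c in items:
        cum += c
        if cum / total >= q - 1e-12:
            return pos
    raise AssertionError("unreachable")


def rec(chrom, pos, strand, count):
    return CtssRecord(chrom=chrom, pos=pos, strand=strand, count=count)


# ---------------------------------------------------------------- tpm


def test_tpm_example():
    t = CtssTable("s", [rec("c", 10, "+", 2), rec("c", 20, "+", 8)])
    tpm = normalize_tpm(t)
    assert tpm[("c", 10, "+")] == pytest.approx(200_000)
    assert tpm[("c", 20, "+")] == pytest.approx(800_000)


def test_tpm_single_record_and_conservation(rng):
    t = CtssTable("s", [rec("c", 5, "-", 7)])
    assert normalize_tpm(t)[("c", 5, "-")] == pytest.approx(1e6)
    records = [
        rec("c", int(p), "+", int(c) + 1)
        for p, c in zip(rng.choice(10_000, 200, replace=False), rng.integers(0, 50, 200))
    ]
    total = sum(normalize_tpm(CtssTable("s", records)).values())
    assert total == pytest.approx(1e6, abs=1e-6)


def test_tpm_empty_table_errors():
    with pytest.raises(ValueError):
        normalize_tpm(CtssTable("s", []))


def test_duplicate_positions_rejected():
    with pytest.raises(ValueError):
        CtssTable("s", [rec("c", 1, "+", 1), rec("c", 1, "+", 2)])


# ---------------------------------------------------------------- clustering


def test_cluster_example():
    records = [rec("c", p, "+", 1) for p in (100, 105, 130)]
    clusters = cluster_ctss(records, maxdist=20)
    assert [sorted(c.positions) for c in clusters] == [[100, 105], [130]]


def test_cluster_singleton():
    clusters = cluster_ctss([rec("c", 7, "-", 3)])
    assert len(clusters) == 1
    assert clusters[0].span == (7, 8)


def test_cluster_strand_and_chrom_separation():
    records = [rec("c", 100, "+", 1), rec("c", 101, "-", 1), rec("d", 100, "+", 1)]
    assert len(cluster_ctss(records)) == 3


def test_cluster_matches_transitive_closure(rng):
    for _ in range(20):
        positions = rng.choice(2_000, size=200, replace=False)
        records = [rec("c", int(p), "+", 1) for p in positions]
        clusters = cluster_ctss(records, maxdist=20)
        got = sorted(frozenset(c.positions) for c in clusters)
        assert got == transitive_closure_partition(positions, 20)


def test_cluster_order_independent(rng):
    positions = rng.choice(500, size=60, replace=False)
    records = [rec("c", int(p), "+", int(c)) for p, c in zip(positions, rng.integers(1, 9, 60))]
    a = cluster_ctss(records)
    b = cluster_ctss(list(reversed(records)))
    assert sorted(c.span for c in a) == sorted(c.span for c in b)


# ---------------------------------------------------------------- widths


def test_width_single_position():
    c = TagCluster("c", "+", {50: 10})
    pw = quantile_width(c)
    assert (pw.width, pw.shape) == (1, "sharp")


def test_width_10_uniform_positions():
    c = TagCluster("c", "+", {p: 1 for p in range(1, 11)})
    pw = quantile_width(c)
    assert pw.q_low_pos == 1
    assert pw.q_high_pos == 9
    assert pw.width == 9
    assert pw.shape == "sharp"


def test_width_15_uniform_positions_broad():
    c = TagCluster("c", "+", {p: 1 for p in range(1, 16)})
    pw = quantile_width(c)
    assert pw.width >= 10
    assert pw.shape == "broad"


def test_width_matches_cumulative_enumeration(rng):
    for _ in range(50):
        n = int(rng.integers(1, 30))
        positions = sorted(rng.choice(200, size=n, replace=False))
        pc = {int(p): int(c) for p, c in zip(positions, rng.integers(1, 20, n))}
        for strand in "+-":
            c = TagCluster("c", strand, pc)
            pw = quantile_width(c)
            asc = strand == "+"
            assert pw.q_low_pos == cumulative_quantile_pos(pc, 0.1, ascending=asc)
            assert pw.q_high_pos == cumulative_quantile_pos(pc, 0.9, ascending=asc)
            assert pw.width == abs(pw.q_high_pos - pw.q_low_pos) + 1


def test_width_boundary_at_10():
    c = TagCluster("c", "+", {p: 1 for p in range(10)})  # width 9 -> sharp
    assert quantile_width(c).shape == "sharp"
    c = TagCluster("c", "+", {p: 1 for p in range(12)})  # 12 uniform
    pw = quantile_width(c)
    assert pw.width == 10  # q_low at pos 1, q_high at pos 10: boundary width
    assert pw.shape == "broad"


def test_width_monotone_under_spread(rng):
    # mean-preserving spread: moving half the tags outward never shrinks width
    narrow = TagCluster("c", "+", {100: 4, 101: 4})
    wide = TagCluster("c", "+", {95: 2, 100: 2, 101: 2, 106: 2})
    assert quantile_width(wide).width >= quantile_width(narrow).width


def test_width_empty_cluster_errors():
    with pytest.raises(ValueError):
        quantile_width(TagCluster("c", "+", {}))


# ---------------------------------------------------------------- topscore


def _profile(fracs, runs):
    counts = [int(round(f * 1000)) for f in fracs]
    return GeneTssProfile(
        gene_id="g", strand="+", positions=list(range(len(fracs))),
        counts=counts, run_lengths=runs,
    )


def test_topscore_single_tss():
    genome = {"c": "CTTTT" + "A" * 20}
    prof = build_profile("g", "+", "c", {0: 10}, genome)
    assert topscore(prof).topscore == pytest.approx(5)


def test_topscore_split_example():
    rec_ = topscore(_profile([0.5, 0.5], [5, 0]))
    assert rec_.topscore == pytest.approx(2.5)
    assert rec_.is_top_gt2


def test_topscore_capped():
    genome = {"c": "C" * 20 + "A" * 20}
    prof = build_profile("g", "+", "c", {0: 10}, genome)
    assert topscore(prof).topscore == pytest.approx(16)


def test_topscore_bounds_and_homogeneous(rng):
    for _ in range(50):
        n = int(rng.integers(1, 8))
        counts = rng.integers(1, 100, n)
        runs = [int(r) for r in rng.integers(0, 25, n)]
        prof = GeneTssProfile("g", "+", list(range(n)), [int(c) for c in counts],
                              run_lengths=runs)
        s = topscore(prof).topscore
        assert 0 <= s <= 16
    hom = GeneTssProfile("g", "+", [0, 1], [3, 7], run_lengths=[6, 6])
    assert topscore(hom).topscore == pytest.approx(6)
    purine = GeneTssProfile("g", "+", [0, 1], [3, 7], run_lengths=[0, 0])
    assert topscore(purine).topscore == 0


def test_topscore_minus_strand():
    # minus-strand TSS at pos 9: transcript reads leftward, complemented
    # transcript base i = complement(genome[9 - i]): C,T,T,T,T then G (break)
    genome = {"c": "AAAAC" + "AAAAG" + "A" * 10}
    prof = build_profile("g", "-", "c", {9: 5}, genome)
    assert topscore(prof).topscore == pytest.approx(5)


def test_zero_tag_profile_errors():
    with pytest.raises(ValueError):
        GeneTssProfile("g", "+", [0], [0])


# ---------------------------------------------------------------- read filter


def test_read_filter_boundaries():
    kept = filter_min_avg_reads({"a": [600, 600], "b": [500, 500]})
    assert set(kept) == {"a"}


def test_read_filter_matches_loop(rng):
    table = {f"g{i}": rng.integers(0, 1200, 3).tolist() for i in range(50)}
    kept = filter_min_avg_reads(table)
    expected = {g for g, counts in table.items() if sum(counts) / len(counts) > 500}
    assert set(kept) == expected


# ---------------------------------------------------------------- PRTE score


def test_prte_score_arithmetic_and_flag():
    # gene spanning [0, 100); all 30 tags see a planted PRTE
    genome = {"c": "A" * 10 + "CCTTCTTCC" + "A" * 100}
    intervals = {"g1": ("c", 0, 100, "+")}
    lib_filler = CtssRecord("c", 150, "+", 2_000_000 - 30)  # outside gene
    table = CtssTable("s", [CtssRecord("c", 5, "+", 30), lib_filler])
    genome["c"] += "A" * 100
    [record] = prte_score(table, genome, intervals)
    assert record.prte_score == pytest.approx(15.0)
    assert record.prte_flag


def test_prte_score_exactly_10_not_flagged():
    genome = {"c": "A" * 10 + "CCTTCTTCC" + "A" * 200}
    intervals = {"g1": ("c", 0, 100, "+")}
    table = CtssTable(
        "s", [CtssRecord("c", 5, "+", 10), CtssRecord("c", 150, "+", 1_000_000 - 10)]
    )
    [record] = prte_score(table, genome, intervals)
    assert record.prte_score == pytest.approx(10.0)
    assert not record.prte_flag


def test_prte_score_requires_motif_within_read():
    # PRTE placed beyond the 75-nt read window: no score
    genome = {"c": "A" * 80 + "CCTTCTTCC" + "A" * 100}
    intervals = {"g1": ("c", 0, 150, "+")}
    table = CtssTable("s", [CtssRecord("c", 0, "+", 100)])
    assert prte_score(table, genome, intervals) == []


def test_prte_score_conservation(small_truth, small_config):
    from utrland.synthetic_data import simulate_ctss

    table = simulate_ctss(small_truth, small_config)
    records = prte_score(table, small_truth.genome, small_truth.gene_intervals())
    total_prte = sum(r.prte_score for r in records) / 1e6 * table.library_size
    assert total_prte <= table.library_size


# ---------------------------------------------------------------- windows


def test_window_fraction_examples():
    windows = {"g": [("c", 0, 10, "+"), ("c", 10, 20, "+"), ("c", 20, 30, "+")]}
    table = CtssTable(
        "s",
        [rec("c", 1, "+", 30), rec("c", 11, "+", 10), rec("c", 21, "+", 60)],
    )
    fracs = window_read_fractions(table, windows)["g"]
    assert fracs == pytest.approx([0.3, 0.1, 0.6])


def test_window_fraction_all_in_one():
    windows = {"g": [("c", 0, 10, "+"), ("c", 10, 20, "+"), ("c", 20, 30, "+")]}
    table = CtssTable("s", [rec("c", 5, "+", 12)])
    assert window_read_fractions(table, windows)["g"] == pytest.approx([1, 0, 0])


def test_window_fraction_zero_tags_missing():
    windows = {"g": [("c", 0, 10, "+")]}
    table = CtssTable("s", [rec("c", 50, "+", 5)])
    assert window_read_fractions(table, windows)["g"] is None


def test_window_fraction_strand_specific():
    windows = {"g": [("c", 0, 10, "-")]}
    table = CtssTable("s", [rec("c", 5, "+", 5)])
    assert window_read_fractions(table, windows)["g"] is None


# ---------------------------------------------------------------- sequences


def test_tss_sequence_strands():
    genome = {"c": "ACGTACGTAC"}
    assert tss_sequence(genome, "c", 2, "+", 4) == "GTAC"
    # minus strand: 5' end at pos 7 reads leftward, complemented:
    # bases 7,6,5,4 = T,G,C,A -> A,C,G,T
    assert tss_sequence(genome, "c", 7, "-", 4) == "ACGT"
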