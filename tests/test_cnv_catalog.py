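import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvscape.cnv_catalog import (
    filter_cnvs,
    genome_coverage,
    length_comparison,
    locus_frequencies,
    per_sample_counts,
    summarize_catalog,
)
from cnvscape.sv_io import MISSING, GenomeIndex

from conftest import make_record, make_table, random_table


# -- filter_cnvs -------------------------------------------------------------


def _carriers(n, total=6):
    return tuple([1] * n + [0] * (total - n))


def test_filter_below_length_removed():
    t = make_table([make_record("a", end=999, genotypes=_carriers(5))], n_samples=6)
    assert len(filter_cnvs(t)) == 0


def test_filter_singleton_removed():
    t = make_table([make_record("a", end=5000, genotypes=_carriers(1))], n_samples=6)
    assert len(filter_cnvs(t)) == 0


def test_filter_toy_table_brute_force():
    specs = [(500, 0), (1000, 1), (2000, 2), (2000, 3), (2000, 6), (2000, 2)]
    records = [
        make_record(f"r{i}", start=i * 10_000, end=i * 10_000 + length,
                    genotypes=_carriers(nc))
        for i, (length, nc) in enumerate(specs)
    ]
    t = make_table(records, n_samples=6)
    got = {r.locus_id for r in filter_cnvs(t).records}
    # independent brute-force re-scan
    expected = {
        f"r{i}" for i, (length, nc) in enumerate(specs) if length >= 1000 and nc >= 2
    }
    assert got == expected == {"r2", "r3", "r4", "r5"}


def test_filter_idempotent_and_order_insensitive():
    rng = np.random.default_rng(0)
    genome = GenomeIndex(("s1",), (10_000_000,))
    t = random_table(rng, genome, 50, n_samples=6)
    once = filter_cnvs(t)
    twice = filter_cnvs(once)
    assert once.records == twice.records
    shuffled = make_table(list(reversed(t.records)), n_samples=6)
    assert {r.locus_id for r in filter_cnvs(shuffled).records} == {
        r.locus_id for r in once.records
    }


def test_filter_bad_params():
    t = make_table([make_record()])
    with pytest.raises(ValueError):
        filter_cnvs(t, min_length=0)
    with pytest.raises(ValueError):
        filter_cnvs(t, min_carriers=-1)


def test_filter_conservation_del_plus_dup():
    rng = np.random.default_rng(1)
    genome = GenomeIndex(("s1",), (10_000_000,))
    t = filter_cnvs(random_table(rng, genome, 80, n_samples=6))
    genome = GenomeIndex(("s1",), (10_000_000,))
    s = summarize_catalog(t, genome)
    assert s.n_total == s.n_del + s.n_dup


# -- per_sample_counts -------------------------------------------------------


def test_per_sample_all_carriers():
    t = make_table([make_record(genotypes=(1,) * 20)], n_samples=20)
    counts, mean, mn, mx = per_sample_counts(t)
    assert all(c == 1 for c in counts.values())
    assert mean == 1 and mn == 1 and mx == 1


def test_per_sample_missing_not_counted():
    t = make_table(
        [make_record("a", genotypes=(MISSING, 1)), make_record("b", start=5000, end=6000, genotypes=(MISSING, 0))],
        n_samples=2,
    )
    counts, _, _, _ = per_sample_counts(t)
    assert counts["smp1"] == 0
    assert counts["smp2"] == 1


def test_per_sample_counts_loop_oracle():
    rng = np.random.default_rng(7)
    genome = GenomeIndex(("s1",), (10_000_000,))
    t = random_table(rng, genome, 50, n_samples=5)
    counts, mean, mn, mx = per_sample_counts(t)
    oracle = {s: 0 for s in t.samples}
    for r in t.records:
        for s, g in zip(t.samples, r.genotypes):
            if g >= 1:
                oracle[s] += 1
    assert counts == oracle
    assert mean == pytest.approx(np.mean(list(oracle.values())))
    assert (mn, mx) == (min(oracle.values()), max(oracle.values()))


# -- locus_frequencies -------------------------------------------------------


def test_frequency_all_carriers_is_one():
    t = make_table([make_record(genotypes=(1, 2, MISSING))], n_samples=3)
    freqs, mean = locus_frequencies(t)
    assert freqs[0] == 1.0 and mean == 1.0


def test_frequency_direct_ratio():
    t = make_table([make_record(genotypes=(1,) * 7 + (0,) * 13)], n_samples=20)
    freqs, _ = locus_frequencies(t)
    assert freqs[0] == pytest.approx(0.35)


def test_frequency_loop_oracle():
    rng = np.random.default_rng(3)
    genome = GenomeIndex(("s1",), (10_000_000,))
    t = random_table(rng, genome, 40, n_samples=6)
    freqs, mean = locus_frequencies(t)
    oracle = []
    for r in t.records:
        called = [g for g in r.genotypes if g != MISSING]
        oracle.append(sum(1 for g in called if g >= 1) / len(called))
    assert freqs == pytest.approx(oracle)
    assert mean == pytest.approx(np.mean(oracle))


def test_frequency_min_carriers_bound():
    # any locus surviving min_carriers=2 with 20 samples has frequency >= 0.1
    rng = np.random.default_rng(11)
    genome = GenomeIndex(("s1",), (10_000_000,))
    t = filter_cnvs(random_table(rng, genome, 100, n_samples=20))
    freqs, _ = locus_frequencies(t)
    assert (freqs >= 0.1 - 1e-12).all()


# -- genome_coverage ---------------------------------------------------------


def test_coverage_full_genome():
    genome = GenomeIndex(("s1",), (1_000,))
    t = make_table([make_record("a", "s1", 0, 1000)])
    covered, frac = genome_coverage(t, genome)
    assert covered == 1000 and frac == 1.0


def test_coverage_union_arithmetic():
    genome = GenomeIndex(("s1",), (1_000,))
    t = make_table(
        [make_record("a", "s1", 0, 100), make_record("b", "s1", 50, 150)]
    )
    covered, _ = genome_coverage(t, genome)
    assert covered == 150


def test_coverage_base_mask_oracle():
    genome = GenomeIndex(("s1", "s2"), (50_000, 30_000))
    rng = np.random.default_rng(5)
    records = []
    for i in range(200):
        si = int(rng.integers(0, 2))
        scaffold = genome.names[si]
        length = int(rng.integers(1, 2_000))
        start = int(rng.integers(0, genome.lengths[si] - length))
        records.append(make_record(f"c{i}", scaffold, start, start + length))
    t = make_table(records)
    covered, frac = genome_coverage(t, genome)
    masks = {n: np.zeros(l, dtype=bool) for n, l in zip(genome.names, genome.lengths)}
    for r in t.records:
        masks[r.scaffold][r.start : r.end] = True
    oracle = sum(int(m.sum()) for m in masks.values())
    assert covered == oracle
    assert frac == oracle / genome.total_length


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 100)), max_size=30))
def test_coverage_monotone_and_bounded(intervals):
    genome = GenomeIndex(("s1",), (1_000,))
    records = [
        make_record(f"c{i}", "s1", s, s + l) for i, (s, l) in enumerate(intervals)
    ]
    total = 0
    prev = 0
    for k in range(len(records) + 1):
        t = make_table(records[:k]) if k else make_table([make_record()])
        if k == 0:
            continue
        covered, _ = genome_coverage(t, genome)
        assert covered >= prev  # adding records never decreases coverage
        prev = covered
        total = sum(r.length for r in records[:k])
        assert covered <= total  # union <= sum of lengths


# -- length_comparison (Welch) ----------------------------------------------


def test_welch_identical_samples():
    r = length_comparison([10, 20, 30], [10, 20, 30])
    assert r.t == pytest.approx(0.0)
    assert r.p_two_sided == pytest.approx(1.0)


def test_welch_closed_form():
    # hand evaluation: a={10,12,14} (mean 12, var 4), b={1,2,3} (mean 2, var 1)
    # t = 10 / sqrt(4/3 + 1/3) = 7.745966692...
    # df = (5/3)^2 / ((4/3)^2/2 + (1/3)^2/2) = 50/17 = 2.941176...
    r = length_comparison([10, 12, 14], [1, 2, 3])
    assert r.t == pytest.approx(7.745966692414834)
    assert r.df == pytest.approx(50 / 17)
    assert r.mean_a == 12 and r.mean_b == 2


def test_welch_scale_invariance():
    a, b = [10, 12, 14, 13], [1, 2, 3, 9]
    r1 = length_comparison(a, b)
    r2 = length_comparison([x * 1000 for x in a], [x * 1000 for x in b])
    assert r1.t == pytest.approx(r2.t)
    assert r1.df == pytest.approx(r2.df)
    assert r1.p_two_sided == pytest.approx(r2.p_two_sided)


def test_welch_sign_convention():
    r = length_comparison([100, 110, 120], [1, 2, 3])
    assert r.t > 0  # mean_a > mean_b


def test_welch_errors():
    with pytest.raises(ValueError):
        length_comparison([1], [1, 2])
    with pytest.raises(ValueError):
        length_comparison([5, 5, 5], [3, 3, 3])


# -- summarize_catalog -------------------------------------------------------


def test_summary_empty_table():
    genome = GenomeIndex(("s1",), (1_000,))
    t = make_table([make_record()], n_samples=2)
    t.records = []
    s = summarize_catalog(t, genome)
    assert s.n_total == 0 and s.n_del == 0 and s.n_dup == 0
    assert s.covered_bp == 0 and s.coverage_fraction == 0.0
    assert math.isnan(s.mean_locus_frequency)


def test_summary_only_dels():
    t = make_table(
        [make_record("a", svtype="DEL"), make_record("b", start=5000, end=6000, svtype="DEL")]
    )
    genome = GenomeIndex(("s1",), (10_000,))
    s = summarize_catalog(t, genome)
    assert s.n_dup == 0 and s.n_total == s.n_del == 2


def test_summary_field_by_field_oracle():
    rng = np.random.default_rng(13)
    genome = GenomeIndex(("s1", "s2", "s3"), (200_000, 150_000, 100_000))
    records = []
    for i in range(100):
        si = int(rng.integers(0, 3))
        length = int(rng.integers(1_000, 5_000))
        start = int(rng.integers(0, genome.lengths[si] - length))
        gts = tuple(int(g) for g in rng.choice([0, 1, 2, MISSING], size=8))
        svtype = "DEL" if rng.random() < 0.8 else "DUP"
        records.append(
            make_record(f"c{i}", genome.names[si], start, start + length, svtype, gts)
        )
    t = make_table(records, n_samples=8)
    s = summarize_catalog(t, genome)

    assert s.n_total == 100
    assert s.n_del == sum(1 for r in records if r.svtype == "DEL")
    assert s.n_dup == sum(1 for r in records if r.svtype == "DUP")
    assert s.mean_length == pytest.approx(np.mean([r.end - r.start for r in records]))
    exp_counts = {
        smp: sum(1 for r in records if r.genotypes[i] >= 1)
        for i, smp in enumerate(t.samples)
    }
    assert s.per_sample_counts == exp_counts
    assert s.min_per_sample == min(exp_counts.values())
    assert s.max_per_sample == max(exp_counts.values())
    freqs = []
    for r in records:
        called = [g for g in r.genotypes if g != MISSING]
        if called:
            freqs.append(sum(1 for g in called if g >= 1) / len(called))
    assert s.mean_locus_frequency == pytest.approx(np.mean(freqs))
    masks = {n: np.zeros(l, dtype=bool) for n, l in zip(genome.names, genome.lengths)}
    for r in records:
        masks[r.scaffold][r.start : r.end] = True
    assert s.covered_bp == sum(int(m.sum()) for m in masks.values())
    assert s.n_scaffolds_with_cnv == len({r.scaffold for r in records})
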