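"""f-statistics: hand examples, scalar reference equality, invariances, jackknife."""

import numpy as np
import pandas as pd
import pytest

from popstrata import (
    FreqTable,
    d_test,
    f3_test,
    jackknife,
    make_blocks,
    make_component_set,
    outgroup_f3,
    population_freqs,
    screen_trios,
    simulate_unadmixed,
    uniform_map,
    variant_table,
)
from popstrata.fstats import FStatError
from popstrata.io_qc import MISSING

from conftest import build_gm


def freq_table(freq, n_alleles, pops=None, chroms=None):
    """Construct a FreqTable directly from arrays (pops x variants)."""
    freq = np.asarray(freq, dtype=float)
    P, V = freq.shape
    pops = pops or [f"P{i}" for i in range(P)]
    variants = pd.DataFrame(
        {
            "id": [f"v{j}" for j in range(V)],
            "chromosome": chroms or ["1"] * V,
            "position_bp": np.arange(V) * 10_000,
            "genetic_pos_cM": np.arange(V, dtype=float),
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return FreqTable(pops, variants, freq, np.asarray(n_alleles, dtype=float))


# ---------------------------------------------------------------------------
# population_freqs
# ---------------------------------------------------------------------------


def test_population_freqs_hand_count():
    gm = build_gm(np.array([[0], [1], [2]], dtype=np.int16))
    ft = population_freqs(gm)
    assert ft.freq[0, 0] == 0.5
    assert ft.n_alleles[0, 0] == 6


def test_all_missing_cell_excluded():
    calls = np.array([[MISSING, 1], [MISSING, 2]], dtype=np.int16)
    gm = build_gm(calls)
    ft = population_freqs(gm)
    assert ft.n_alleles[0, 0] == 0 and np.isnan(ft.freq[0, 0])


def test_monomorphic_correction_zero():
    gm = build_gm(np.array([[2], [2], [2]], dtype=np.int16))
    ft = population_freqs(gm)
    assert ft.freq[0, 0] == 1.0
    assert ft.het_correction("pop")[0] == 0.0


# ---------------------------------------------------------------------------
# f3
# ---------------------------------------------------------------------------


def test_f3_hand_example_minus_quarter():
    """a=0.5 everywhere, b/c perfectly anticorrelated, corrections 0 -> f3 = -0.25."""
    a = [0.5, 0.5, 0.5, 0.5]
    b = [1.0, 0.0, 1.0, 0.0]
    c = [0.0, 1.0, 0.0, 1.0]
    ft = freq_table([a, b, c], np.full((3, 4), np.inf), pops=["A", "B", "C"])
    blocks = make_blocks(ft.variants, 2)
    res = f3_test(ft, "A", "B", "C", blocks)
    assert res.value == pytest.approx(-0.25, abs=1e-15)
    assert res.se == pytest.approx(0.0, abs=1e-12)


def test_f3_nonnegative_when_sources_equal():
    rng = np.random.default_rng(40)
    b = rng.uniform(0.1, 0.9, 50)
    a = rng.uniform(0.1, 0.9, 50)
    ft = freq_table([a, b, b], np.full((3, 50), np.inf), pops=["A", "B", "C"])
    blocks = make_blocks(ft.variants, 5)
    res = f3_test(ft, "A", "B", "C", blocks)
    assert res.value >= 0


def test_f3_symmetric_in_sources():
    rng = np.random.default_rng(41)
    f = rng.uniform(0.05, 0.95, (3, 100))
    ft = freq_table(f, np.full((3, 100), 40), pops=["A", "B", "C"])
    blocks = make_blocks(ft.variants, 5)
    r1 = f3_test(ft, "A", "B", "C", blocks)
    r2 = f3_test(ft, "A", "C", "B", blocks)
    assert r1.value == r2.value and r1.se == r2.se


def test_f3_allele_relabeling_invariance():
    rng = np.random.default_rng(42)
    f = rng.uniform(0.05, 0.95, (3, 100))
    ft = freq_table(f, np.full((3, 100), 40), pops=["A", "B", "C"])
    ft_flip = freq_table(1 - f, np.full((3, 100), 40), pops=["A", "B", "C"])
    blocks = make_blocks(ft.variants, 5)
    assert f3_test(ft, "A", "B", "C", blocks).value == pytest.approx(
        f3_test(ft_flip, "A", "B", "C", blocks).value, abs=1e-15
    )


def test_f3_vectorized_equals_scalar_reference():
    """Criterion check at unit scale: per-site python loop vs the pipeline."""
    rng = np.random.default_rng(43)
    f = rng.uniform(0.02, 0.98, (5, 200))
    n = rng.integers(10, 60, (5, 200)).astype(float)
    ft = freq_table(f, n, chroms=["1"] * 100 + ["2"] * 100)
    blocks = make_blocks(ft.variants, 8)
    res = f3_test(ft, "P0", "P1", "P2", blocks)
    terms = [
        (f[0, s] - f[1, s]) * (f[0, s] - f[2, s]) - f[0, s] * (1 - f[0, s]) / (n[0, s] - 1)
        for s in range(200)
    ]
    assert res.value == pytest.approx(np.mean(terms), abs=1e-12)


# ---------------------------------------------------------------------------
# D
# ---------------------------------------------------------------------------


def test_d_hand_example_unity():
    w = [1.0, 1.0, 1.0, 1.0]
    x = [0.0, 0.0, 0.0, 0.0]
    y = [1.0, 0.0, 1.0, 0.0]
    z = [0.0, 0.0, 0.0, 0.0]
    ft = freq_table([w, x, y, z], np.full((4, 4), 20), pops=["W", "X", "Y", "Z"])
    blocks = make_blocks(ft.variants, 2)
    res = d_test(ft, "W", "X", "Y", "Z", blocks)
    assert res.value == pytest.approx(1.0, abs=1e-15)


def test_d_zero_when_sister_pops_equal():
    rng = np.random.default_rng(44)
    w, x, y = (rng.uniform(0.1, 0.9, 60) for _ in range(3))
    ft = freq_table([w, x, y, y], np.full((4, 60), 30), pops=["W", "X", "Y", "Z"])
    blocks = make_blocks(ft.variants, 4)
    assert d_test(ft, "W", "X", "Y", "Z", blocks).value == pytest.approx(0.0, abs=1e-15)


def test_d_antisymmetries_exact():
    rng = np.random.default_rng(45)
    f = rng.uniform(0.05, 0.95, (4, 80))
    ft = freq_table(f, np.full((4, 80), 30), pops=["W", "X", "Y", "Z"])
    blocks = make_blocks(ft.variants, 4)
    d = d_test(ft, "W", "X", "Y", "Z", blocks).value
    assert d_test(ft, "X", "W", "Y", "Z", blocks).value == pytest.approx(-d, abs=1e-15)
    assert d_test(ft, "W", "X", "Z", "Y", blocks).value == pytest.approx(-d, abs=1e-15)


def test_d_vectorized_equals_scalar_reference():
    rng = np.random.default_rng(46)
    f = rng.uniform(0.02, 0.98, (5, 200))
    n = rng.integers(4, 40, (5, 200)).astype(float)
    ft = freq_table(f, n)
    blocks = make_blocks(ft.variants, 10)
    res = d_test(ft, "P0", "P1", "P2", "P3", blocks)
    num = den = 0.0
    for s in range(200):
        w, x, y, z = f[0, s], f[1, s], f[2, s], f[3, s]
        num += (w - x) * (y - z)
        den += (w + x - 2 * w * x) * (y + z - 2 * y * z)
    assert res.value == pytest.approx(num / den, abs=1e-12)


def test_d_requires_distinct_populations():
    f = np.random.default_rng(47).uniform(0.1, 0.9, (4, 20))
    ft = freq_table(f, np.full((4, 20), 10))
    with pytest.raises(FStatError):
        d_test(ft, "P0", "P0", "P1", "P2", make_blocks(ft.variants, 2))


# ---------------------------------------------------------------------------
# outgroup f3
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def star_freqs():
    comps = make_component_set({"X": 0.08, "Y": 0.12, "O": 0.25}, 20_000, seed=48)
    gmap = uniform_map(10, 100.0)
    var = variant_table(20_000, gmap)
    parts = [simulate_unadmixed(c, 30, seed=49 + i, variants=var) for i, c in enumerate(comps)]
    samples = pd.concat([p.samples for p in parts], ignore_index=True)
    calls = np.vstack([p.calls for p in parts])
    from popstrata import GenotypeMatrix

    return population_freqs(GenotypeMatrix(samples, var, calls))


def test_outgroup_f3_self_exceeds_cross(star_freqs):
    blocks = make_blocks(star_freqs.variants, 100)
    self_f3 = outgroup_f3(star_freqs, "X", "X", "O", blocks).value
    cross_f3 = outgroup_f3(star_freqs, "X", "Y", "O", blocks).value
    assert self_f3 > cross_f3


def test_outgroup_f3_symmetric(star_freqs):
    blocks = make_blocks(star_freqs.variants, 100)
    a = outgroup_f3(star_freqs, "X", "Y", "O", blocks)
    b = outgroup_f3(star_freqs, "Y", "X", "O", blocks)
    assert a.value == b.value


# ---------------------------------------------------------------------------
# blocks & jackknife
# ---------------------------------------------------------------------------


def test_blocks_equal_split_single_chromosome():
    var = freq_table(np.zeros((1, 100)), np.ones((1, 100))).variants
    bp = make_blocks(var, 10)
    assert bp.n_blocks == 10
    assert np.all(bp.counts == 10)


def test_blocks_genome_scale_within_chromosome_bound():
    var = variant_table(100_000, uniform_map(22, 100.0))
    bp = make_blocks(var, 997)
    assert abs(bp.n_blocks - 997) <= 22
    assert bp.counts.sum() == 100_000


def test_blocks_partition_preserves_order():
    var = variant_table(500, uniform_map(5, 80.0))
    bp = make_blocks(var, 20)
    assert np.all(np.diff(bp.block_of) >= 0)
    assert np.bincount(bp.block_of).tolist() == bp.counts.tolist()


def test_blocks_more_than_variants_rejected():
    var = variant_table(10, uniform_map(1, 10.0))
    with pytest.raises(FStatError):
        make_blocks(var, 11)


def test_jackknife_identical_blocks_zero_se():
    sums = np.full(10, 5.0)
    weights = np.full(10, 1.0)
    est, se = jackknife(sums, weights)
    assert est == 5.0 and se == pytest.approx(0.0, abs=1e-12)


def test_jackknife_iid_normal_matches_sd_over_sqrt_n():
    rng = np.random.default_rng(50)
    vals = rng.normal(0, 1, 200)
    est, se = jackknife(vals, np.ones(200))
    assert se == pytest.approx(vals.std(ddof=1) / np.sqrt(200), rel=0.20)


def test_jackknife_matches_brute_force_delete_one():
    sums = np.array([2.0, 5.0, 3.0, 8.0, 1.0])
    weights = np.array([1.0, 2.0, 1.0, 3.0, 1.0])
    est, se = jackknife(sums, weights)
    T, W = sums.sum(), weights.sum()
    assert est == T / W
    # Independent recomputation of the Busing weighted jackknife.
    g = 5
    theta_del = np.array([(T - sums[j]) / (W - weights[j]) for j in range(g)])
    h = W / weights
    theta_J = g * est - np.sum((1 - weights / W) * theta_del)
    tau = h * est - (h - 1) * theta_del
    var = np.sum((tau - theta_J) ** 2 / (h - 1)) / g
    assert se == pytest.approx(np.sqrt(var), abs=1e-14)


def test_jackknife_needs_two_blocks():
    with pytest.raises(FStatError):
        jackknife([1.0], [1.0])


# ---------------------------------------------------------------------------
# trio screen
# ---------------------------------------------------------------------------


def test_screen_trio_count_fourteen_groups():
    rng = np.random.default_rng(51)
    f = rng.uniform(0.1, 0.9, (14, 40))
    ft = freq_table(f, np.full((14, 40), 30), pops=[f"G{i:02d}" for i in range(14)])
    blocks = make_blocks(ft.variants, 4)
    table = screen_trios(ft, None, blocks)
    assert len(table) == 14 * (13 * 12 // 2)  # 1092


def test_screen_requires_three_groups():
    f = np.random.default_rng(52).uniform(0.1, 0.9, (2, 20))
    ft = freq_table(f, np.full((2, 20), 10))
    with pytest.raises(FStatError):
        screen_trios(ft, None, make_blocks(ft.variants, 2))
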