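"""Segment post-processing, W_AB sharing matrices and ROH detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popstrata import (
    IBDSegmentSet,
    ROHParams,
    filter_min_length,
    make_component_freqs,
    read_segments,
    roh_detect,
    sharing_matrix,
    simulate_isolate,
    simulate_unadmixed,
    stitch_segments,
    uniform_map,
    variant_table,
    within_population_summary,
    write_segments,
)
from popstrata.ibd_sharing import SegmentError
from popstrata.io_qc import MISSING

from conftest import build_gm


def seg_df(rows):
    return pd.DataFrame(rows, columns=["sample_1", "sample_2", "chromosome", "start_cM", "end_cM"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_segment_round_trip(tmp_path):
    s = IBDSegmentSet(seg_df([("a", "b", "1", 0.0, 2.5), ("c", "a", "2", 1.0, 4.0)]))
    write_segments(s, tmp_path / "s.tsv")
    assert read_segments(tmp_path / "s.tsv").equals(s)


def test_bad_row_rejected_with_line_number(tmp_path):
    (tmp_path / "bad.tsv").write_text(
        "sample_1\tsample_2\tchromosome\tstart_cM\tend_cM\n"
        "a\tb\t1\t0.0\t2.0\n"
        "a\tc\t1\t3.0\t3.0\n"
    )
    with pytest.raises(SegmentError, match="line.*3"):
        read_segments(tmp_path / "bad.tsv")


def test_three_row_fixture_canonical_ordering(tmp_path):
    (tmp_path / "f.tsv").write_text(
        "sample_1\tsample_2\tchromosome\tstart_cM\tend_cM\n"
        "b\ta\t1\t0.0\t2.0\n"
        "c\tb\t2\t1.0\t3.5\n"
        "a\tc\t1\t5.0\t6.0\n"
    )
    s = read_segments(tmp_path / "f.tsv")
    assert len(s) == 3
    assert (s.segments["sample_1"] <= s.segments["sample_2"]).all()
    assert set(map(tuple, s.segments[["sample_1", "sample_2"]].values)) == {
        ("a", "b"), ("b", "c"), ("a", "c")
    }


def test_nonpositive_length_rejected_on_construction():
    with pytest.raises(SegmentError):
        IBDSegmentSet(seg_df([("a", "b", "1", 2.0, 2.0)]))


# ---------------------------------------------------------------------------
# stitch / filter
# ---------------------------------------------------------------------------


def test_stitch_merges_small_gap():
    s = IBDSegmentSet(seg_df([("a", "b", "1", 0.0, 3.0), ("a", "b", "1", 3.3, 6.3)]))
    out = stitch_segments(s, max_gap_cM=0.5)
    assert len(out) == 1
    assert out.lengths_cM[0] == pytest.approx(6.3)


def test_stitch_keeps_large_gap():
    s = IBDSegmentSet(seg_df([("a", "b", "1", 0.0, 3.0), ("a", "b", "1", 5.0, 8.0)]))
    assert len(stitch_segments(s, max_gap_cM=0.5)) == 2


def test_stitch_respects_pair_and_chromosome():
    s = IBDSegmentSet(
        seg_df([("a", "b", "1", 0.0, 3.0), ("a", "c", "1", 3.1, 6.0), ("a", "b", "2", 3.1, 6.0)])
    )
    assert len(stitch_segments(s, 0.5)) == 3


def test_stitch_idempotent():
    rng = np.random.default_rng(70)
    rows = [
        ("a", "b", "1", x, x + rng.uniform(0.5, 2.0))
        for x in np.cumsum(rng.uniform(0.1, 3.0, 20))
    ]
    s = IBDSegmentSet(seg_df(rows))
    once = stitch_segments(s, 0.5)
    twice = stitch_segments(once, 0.5)
    assert twice.equals(once)


def test_filter_strictly_longer_than_min():
    s = IBDSegmentSet(
        seg_df(
            [
                ("a", "b", "1", 0.0, 1.0),   # exactly 1.0 -> removed
                ("a", "b", "2", 0.0, 1.01),  # kept
                ("a", "c", "1", 0.0, 0.5),
                ("b", "c", "1", 0.0, 5.0),
                ("a", "b", "3", 1.0, 1.9),
            ]
        )
    )
    out = filter_min_length(s, 1.0)
    assert len(out) == 2
    assert sorted(out.lengths_cM.round(4)) == [1.01, 5.0]


@given(gap=st.floats(0.0, 2.0), min_cm=st.floats(0.5, 3.0))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_stitch_then_filter_retains_at_least_as_much(gap, min_cm):
    """Stitching can only promote short fragments past the length filter."""
    rows = [
        ("a", "b", "1", 0.0, 0.9),
        ("a", "b", "1", 1.2, 2.0),
        ("a", "b", "1", 4.0, 4.8),
        ("c", "d", "1", 0.0, 2.6),
    ]
    s = IBDSegmentSet(seg_df(rows))
    direct = filter_min_length(s, min_cm).lengths_cM.sum()
    stitched = filter_min_length(stitch_segments(s, gap), min_cm).lengths_cM.sum()
    assert stitched >= direct - 1e-12


# ---------------------------------------------------------------------------
# sharing matrix
# ---------------------------------------------------------------------------


def test_cross_population_w_hand_toy():
    """One 3 cM segment between 2+2 individuals: W = 3 / (2*2) = 0.75."""
    s = IBDSegmentSet(seg_df([("a1", "b1", "1", 0.0, 3.0)]))
    pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    mat = sharing_matrix(s, pops)
    assert mat.value("A", "B") == pytest.approx(0.75)
    assert mat.value("B", "A") == pytest.approx(0.75)  # symmetry


def test_within_population_w_hand_toy():
    """One 2 cM segment within a 3-member population: W = 2 / 3 pairs."""
    s = IBDSegmentSet(seg_df([("a1", "a2", "1", 1.0, 3.0)]))
    pops = {"a1": "A", "a2": "A", "a3": "A"}
    mat = sharing_matrix(s, pops)
    assert mat.value("A", "A") == pytest.approx(2.0 / 3.0)


def test_length_class_assignment_and_sum_conservation():
    s = IBDSegmentSet(
        seg_df(
            [
                ("a1", "b1", "1", 0.0, 4.5),   # class 4-5
                ("a1", "b1", "2", 0.0, 1.5),   # class 1-2
                ("a2", "b2", "1", 0.0, 7.0),   # class >5
            ]
        )
    )
    pops = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    mat = sharing_matrix(s, pops)
    assert mat.value("A", "B", "4-5") == pytest.approx(4.5 / 4)
    assert mat.value("A", "B", "1-2") == pytest.approx(1.5 / 4)
    assert mat.value("A", "B", ">5") == pytest.approx(7.0 / 4)
    class_sum = sum(
        mat.value("A", "B", c) for c in ["1-2", "2-3", "3-4", "4-5", ">5"]
    )
    assert class_sum == pytest.approx(mat.value("A", "B"))


def test_boundary_length_maps_to_one_class():
    s = IBDSegmentSet(seg_df([("a1", "b1", "1", 0.0, 4.0)]))  # exactly 4 -> [4,5)
    pops = {"a1": "A", "b1": "B"}
    mat = sharing_matrix(s, pops)
    assert mat.value("A", "B", "4-5") > 0
    assert mat.value("A", "B", "3-4") == 0.0


def test_segment_order_permutation_invariance():
    rng = np.random.default_rng(71)
    rows = [
        (f"a{i%3}", f"b{i%2}", str(i % 2 + 1), float(i), float(i) + rng.uniform(1, 5))
        for i in range(12)
    ]
    pops = {f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(2)}
    m1 = sharing_matrix(IBDSegmentSet(seg_df(rows)), pops)
    m2 = sharing_matrix(IBDSegmentSet(seg_df(rows[::-1])), pops)
    pd.testing.assert_series_equal(m1.table, m2.table)


def test_unlabeled_sample_rejected():
    s = IBDSegmentSet(seg_df([("a", "b", "1", 0.0, 2.0)]))
    with pytest.raises(SegmentError, match="unlabeled"):
        sharing_matrix(s, {"a": "A"})


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------


def test_fully_heterozygous_individual_has_no_runs():
    calls = np.ones((1, 500), dtype=np.int16)
    gm = build_gm(calls, positions=np.arange(500) * 10_000, cm=np.arange(500) * 0.01)
    assert roh_detect(gm) == []


def test_planted_homozygous_stretch_detected():
    """A 5 Mb homozygous stretch at 1 SNP / 10 kb yields one covering run."""
    rng = np.random.default_rng(72)
    n = 2000  # 20 Mb chromosome
    calls = rng.choice([0, 1, 2], size=(1, n), p=[0.3, 0.4, 0.3]).astype(np.int16)
    start, end = 700, 1200  # 5 Mb of SNPs
    calls[0, start:end] = rng.choice([0, 2], size=end - start)
    pos = np.arange(n) * 10_000
    gm = build_gm(calls, positions=pos, cm=pos / 1e6)
    runs = roh_detect(gm)
    assert len(runs) == 1
    run = runs[0]
    planted = (pos[start], pos[end - 1])
    overlap = min(run.end_bp, planted[1]) - max(run.start_bp, planted[0])
    assert overlap >= 0.9 * (planted[1] - planted[0])


def test_runs_satisfy_parameter_constraints():
    rng = np.random.default_rng(73)
    n = 3000
    calls = rng.choice([0, 1, 2], size=(2, n), p=[0.25, 0.5, 0.25]).astype(np.int16)
    calls[0, 200:900] = rng.choice([0, 2], size=700)
    calls[1, 1500:2600] = rng.choice([0, 2], size=1100)
    pos = np.arange(n) * 8_000
    gm = build_gm(calls, positions=pos, cm=pos / 1e6)
    params = ROHParams()
    for run in roh_detect(gm, params):
        assert run.n_snps >= params.min_snps
        assert run.length_kb >= params.min_length_kb
        assert run.length_kb / run.n_snps <= params.max_kb_per_snp


def test_unsorted_variants_rejected():
    calls = np.zeros((1, 10), dtype=np.int16)
    pos = np.arange(10)[::-1] * 1000
    gm = build_gm(calls, positions=pos, cm=np.arange(10, dtype=float))
    with pytest.raises(ValueError, match="unsorted"):
        roh_detect(gm)


@pytest.fixture(scope="module")
def isolate_vs_panmictic():
    comp = make_component_freqs(4000, fst=0.05, seed=74, maf_range=(0.1, 0.5))
    gmap = uniform_map(1, 100.0)
    var = variant_table(4000, gmap)  # 25 kb spacing on a 100 Mb chromosome
    iso = simulate_isolate(comp, 10, 15, seed=75, variants=var, gmap=gmap, population="iso")
    pan = simulate_unadmixed(comp, 15, seed=76, variants=var, population="pan")
    return iso, pan


def test_isolate_has_more_roh_than_panmictic(isolate_vs_panmictic):
    iso, pan = isolate_vs_panmictic
    iso_total = sum(r.length_kb for r in roh_detect(iso))
    pan_total = sum(r.length_kb for r in roh_detect(pan))
    assert iso_total > pan_total


def test_within_population_summary_ranks_isolate_first(isolate_vs_panmictic):
    iso, pan = isolate_vs_panmictic
    from popstrata import GenotypeMatrix, plant_ibd_segments

    samples = pd.concat([iso.samples, pan.samples], ignore_index=True)
    gm = GenotypeMatrix(samples, iso.variants.copy(), np.vstack([iso.calls, pan.calls]))
    members = {
        "iso": iso.samples["id"].tolist(),
        "pan": pan.samples["id"].tolist(),
    }
    base = plant_ibd_segments(members, 0.3, seed=77, gmap=uniform_map(1, 100.0))
    boost = plant_ibd_segments(
        members, 2.0, seed=78, gmap=uniform_map(1, 100.0), population_pairs=[("iso", "iso")]
    )
    segs = IBDSegmentSet(pd.concat([base.segments, boost.segments], ignore_index=True))
    table = within_population_summary(segs, gm).set_index("population")
    assert table.loc["iso", "W_within"] > table.loc["pan", "W_within"]
    assert table.loc["iso", "mean_roh_total_kb"] > table.loc["pan", "mean_roh_total_kb"]


def test_single_member_population_flagged():
    gm = build_gm(
        np.zeros((3, 50), dtype=np.int16),
        populations=["solo", "duo", "duo"],
        positions=np.arange(50) * 1000,
        cm=np.arange(50) * 0.001,
    )
    segs = IBDSegmentSet(seg_df([("s1", "s2", "1", 0.0, 2.0)]))
    table = within_population_summary(segs, gm).set_index("population")
    assert np.isnan(table.loc["solo", "W_within"])
    assert bool(table.loc["solo", "small_sample"])


def test_empty_segment_set_gives_zeros_not_errors():
    gm = build_gm(
        np.ones((4, 30), dtype=np.int16),
        populations=["A", "A", "B", "B"],
        positions=np.arange(30) * 1000,
        cm=np.arange(30) * 0.001,
    )
    empty = IBDSegmentSet(pd.DataFrame(columns=["sample_1", "sample_2", "chromosome", "start_cM", "end_cM"]))
    table = within_population_summary(empty, gm).set_index("population")
    assert table["W_within"].fillna(0).eq(0).all()
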