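"""IBD-segment post-processing, between/within-population sharing and ROH.

Segment calls (e.g. BEAGLE fastIBD consensus output, after gap-aware
post-processing) are consumed here, never produced: the module stitches
spuriously broken blocks, applies the strict >1 cM length filter, and reduces
the surviving segments to the W_AB sharing statistic — total IBD length shared
between two populations divided by the number of individual pairs — both in
total and within half-open length classes [1,2), [2,3), [3,4), [4,5), [5,inf)
cM. Runs of homozygosity are detected from genotypes with the PLINK-default
sliding-window parameters.

Coordinates are genetic (cM); ROH works on physical positions (bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix

SEGMENT_COLUMNS = ["sample_1", "sample_2", "chromosome", "start_cM", "end_cM"]

#: Default half-open length classes in cM; the last is unbounded above.
DEFAULT_LENGTH_CLASSES = ((1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0), (5.0, np.inf))

TOTAL_CLASS = "total"


class SegmentError(ValueError):
    """Raised for malformed IBD segment data."""


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    """Order each pair lexicographically so unordered pairs compare equal."""
    df = df.copy()
    swap = df["sample_1"] > df["sample_2"]
    s1 = df["sample_1"].where(~swap, df["sample_2"])
    s2 = df["sample_2"].where(~swap, df["sample_1"])
    df["sample_1"], df["sample_2"] = s1, s2
    return df


@dataclass
class IBDSegmentSet:
    """A collection of pairwise IBD segments with cM coordinates.

    ``segments`` columns: sample_1, sample_2 (canonically ordered), chromosome,
    start_cM, end_cM. Lengths are strictly positive by construction.
    """

    segments: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.segments
        if df.empty and list(df.columns) != SEGMENT_COLUMNS:
            df = pd.DataFrame(columns=SEGMENT_COLUMNS)
        df = df[SEGMENT_COLUMNS].copy()
        df["start_cM"] = df["start_cM"].astype(float)
        df["end_cM"] = df["end_cM"].astype(float)
        bad = df["end_cM"] <= df["start_cM"]
        if bad.any():
            raise SegmentError(
                f"non-positive segment length at row(s) {list(df.index[bad])}"
            )
        self.segments = _canonical(df).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def lengths_cM(self) -> np.ndarray:
        return (self.segments["end_cM"] - self.segments["start_cM"]).to_numpy()

    def sorted(self) -> "IBDSegmentSet":
        df = self.segments.sort_values(
            ["sample_1", "sample_2", "chromosome", "start_cM"], kind="stable"
        ).reset_index(drop=True)
        return IBDSegmentSet(df, self.provenance)

    def equals(self, other: "IBDSegmentSet") -> bool:
        a, b = self.sorted().segments, other.sorted().segments
        return a.shape == b.shape and bool(
            (a[["sample_1", "sample_2", "chromosome"]].values == b[["sample_1", "sample_2", "chromosome"]].values).all()
            and np.allclose(a[["start_cM", "end_cM"]], b[["start_cM", "end_cM"]])
        )


def read_segments(path) -> IBDSegmentSet:
    """Read a segment TSV (header: sample_1 sample_2 chromosome start_cM end_cM)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_1": str, "sample_2": str, "chromosome": str})
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise SegmentError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df["end_cM"].astype(float) <= df["start_cM"].astype(float)
    if bad.any():
        # +2: header line plus 1-based numbering.
        rows = [int(i) + 2 for i in df.index[bad]]
        raise SegmentError(f"{path}: end_cM <= start_cM at line(s) {rows}")
    return IBDSegmentSet(df, provenance=str(path))


def write_segments(segset: IBDSegmentSet, path) -> Path:
    path = Path(path)
    segset.segments.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def stitch_segments(segset: IBDSegmentSet, max_gap_cM: float = 0.5) -> IBDSegmentSet:
    """Merge same-pair, same-chromosome segments separated by gaps <= *max_gap_cM*.

    Mirrors the gap-closing post-processing applied to fastIBD calls, where low
    marker density breaks long IBD blocks into pieces; run before length
    filtering. Idempotent.
    """
    if max_gap_cM < 0:
        raise ValueError("max_gap_cM must be >= 0")
    df = segset.sorted().segments
    out = []
    for _, grp in df.groupby(["sample_1", "sample_2", "chromosome"], sort=False):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is None:
                cur = [row.sample_1, row.sample_2, row.chromosome, row.start_cM, row.end_cM]
            elif row.start_cM - cur[4] <= max_gap_cM:
                cur[4] = max(cur[4], row.end_cM)
            else:
                out.append(tuple(cur))
                cur = [row.sample_1, row.sample_2, row.chromosome, row.start_cM, row.end_cM]
        if cur is not None:
            out.append(tuple(cur))
    return IBDSegmentSet(pd.DataFrame(out, columns=SEGMENT_COLUMNS), segset.provenance)


def filter_min_length(segset: IBDSegmentSet, min_cM: float = 1.0) -> IBDSegmentSet:
    """Keep only segments strictly longer than *min_cM* (default the 1 cM power cutoff)."""
    keep = segset.lengths_cM > min_cM
    return IBDSegmentSet(segset.segments.loc[keep], segset.provenance)


# ---------------------------------------------------------------------------
# Sharing matrices (W_AB)
# ---------------------------------------------------------------------------


@dataclass
class SharingMatrix:
    """W values (cM per individual pair) for every population pair and length class.

    ``table`` is indexed by (pop_a, pop_b, length_class) with pop_a <= pop_b;
    ``length_class`` is "total" or a "lo-hi" label. Symmetric by construction.
    """

    table: pd.Series
    populations: list[str]
    class_labels: list[str]

    def value(self, pop_a: str, pop_b: str, length_class: str = TOTAL_CLASS) -> float:
        a, b = sorted((pop_a, pop_b))
        return float(self.table.loc[(a, b, length_class)])

    def to_frame(self) -> pd.DataFrame:
        df = self.table.rename("W").reset_index()
        df.columns = ["pop_a", "pop_b", "length_class", "W"]
        return df


def _class_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"


def sharing_matrix(
    segset: IBDSegmentSet,
    sample_populations: dict[str, str],
    length_classes=DEFAULT_LENGTH_CLASSES,
) -> SharingMatrix:
    """Compute W for every population pair, in total and per length class.

    W_AB = total shared length / (n_A * n_B) across populations;
    W_AA = total shared length / (n_A * (n_A - 1) / 2) within a population.
    Each segment contributes to exactly one half-open class [lo, hi) plus the
    total. Populations are taken from *sample_populations* (every sample in
    the segment set must be labeled; populations with no segments get W = 0).
    """
    unlabeled = (
        set(segset.segments["sample_1"]) | set(segset.segments["sample_2"])
    ) - set(sample_populations)
    if unlabeled:
        raise SegmentError(f"unlabeled sample(s) in segment set: {sorted(unlabeled)}")
    pops = sorted(set(sample_populations.values()))
    sizes = pd.Series(list(sample_populations.values())).value_counts().to_dict()
    labels = [TOTAL_CLASS] + [_class_label(lo, hi) for lo, hi in length_classes]

    totals: dict[tuple[str, str, str], float] = {}
    for a, b in combinations(pops, 2):
        for lab in labels:
            totals[(a, b, lab)] = 0.0
    for a in pops:
        for lab in labels:
            totals[(a, a, lab)] = 0.0

    df = segset.segments
    lengths = segset.lengths_cM
    for k, row in enumerate(df.itertuples(index=False)):
        pa = sample_populations[row.sample_1]
        pb = sample_populations[row.sample_2]
        key_ab = tuple(sorted((pa, pb)))
        ln = lengths[k]
        totals[(*key_ab, TOTAL_CLASS)] += ln
        for lo, hi in length_classes:
            if lo <= ln < hi:
                totals[(*key_ab, _class_label(lo, hi))] += ln
                break

    values = {}
    for (a, b, lab), tot in totals.items():
        if a == b:
            n = sizes[a]
            denom = n * (n - 1) / 2
            if denom == 0:
                values[(a, b, lab)] = np.nan
                continue
        else:
            denom = sizes[a] * sizes[b]
        values[(a, b, lab)] = tot / denom
    idx = pd.MultiIndex.from_tuples(values.keys(), names=["pop_a", "pop_b", "length_class"])
    return SharingMatrix(pd.Series(values.values(), index=idx).sort_index(), pops, labels)


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROHParams:
    """PLINK-default ROH parameters restated explicitly.

    Scanning windows of ``window_snps`` consecutive SNPs tolerate at most
    ``window_max_het`` heterozygous and ``window_max_missing`` missing calls;
    a SNP enters a run when the fraction of homozygous windows covering it is
    at least ``hit_threshold``. Candidate runs must then span at least
    ``min_snps`` SNPs and ``min_length_kb`` kb, at a density of at most
    ``max_kb_per_snp`` kb per SNP, with no internal gap above ``max_gap_kb``.
    """

    window_snps: int = 50
    window_max_het: int = 1
    window_max_missing: int = 5
    hit_threshold: float = 0.05
    min_snps: int = 100
    min_length_kb: float = 1000.0
    max_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0


@dataclass
class ROHRun:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp) / 1000.0


def _roh_one_chromosome(
    genotypes: np.ndarray, positions: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int]]:
    """Return (start_idx, end_idx inclusive, n_snps) runs for one sample/chromosome."""
    m = len(genotypes)
    if m == 0:
        return []
    het = genotypes == 1
    miss = genotypes == MISSING
    W = params.window_snps
    n_windows = m - W + 1
    eligible = np.zeros(m, dtype=bool)
    if n_windows > 0:
        het_c = np.concatenate([[0], np.cumsum(het)])
        mis_c = np.concatenate([[0], np.cumsum(miss)])
        starts = np.arange(n_windows)
        ok = (
            (het_c[starts + W] - het_c[starts] <= params.window_max_het)
            & (mis_c[starts + W] - mis_c[starts] <= params.window_max_missing)
        )
        # SNP k is covered by window starts in [max(0, k-W+1), min(k, n_windows-1)].
        ok_c = np.concatenate([[0], np.cumsum(ok)])
        k = np.arange(m)
        lo = np.maximum(0, k - W + 1)
        hi = np.minimum(k, n_windows - 1)
        hits = ok_c[hi + 1] - ok_c[lo]
        cover = hi - lo + 1
        eligible = hits / cover >= params.hit_threshold
    # A heterozygous SNP itself never belongs to a run.
    eligible &= ~het

    runs: list[tuple[int, int, int]] = []
    i = 0
    while i < m:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < m and eligible[j + 1] and (
            positions[j + 1] - positions[j] <= params.max_gap_kb * 1000
        ):
            j += 1
        n_snps = int(np.count_nonzero(~miss[i : j + 1]))
        length_kb = (positions[j] - positions[i]) / 1000.0
        if (
            n_snps >= params.min_snps
            and length_kb >= params.min_length_kb
            and (length_kb / max(n_snps, 1)) <= params.max_kb_per_snp
        ):
            runs.append((i, j, n_snps))
        i = j + 1
    return runs


def roh_detect(gm: GenotypeMatrix, params: ROHParams | None = None) -> list[ROHRun]:
    """Detect runs of homozygosity per sample with PLINK-default settings."""
    params = params or ROHParams()
    chrom = gm.variants["chromosome"].to_numpy()
    pos = gm.variants["position_bp"].to_numpy()
    out: list[ROHRun] = []
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        cpos = pos[cidx]
        if np.any(np.diff(cpos) < 0):
            raise ValueError(f"variants unsorted on chromosome {c}")
        for i in range(gm.n_samples):
            g = gm.calls[i, cidx]
            for a, b, n_snps in _roh_one_chromosome(g, cpos, params):
                out.append(
                    ROHRun(
                        sample_id=gm.samples["id"].iloc[i],
                        chromosome=str(c),
                        start_bp=int(cpos[a]),
                        end_bp=int(cpos[b]),
                        n_snps=n_snps,
                    )
                )
    return out


def roh_to_frame(runs: list[ROHRun]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "chromosome": r.chromosome,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_snps": r.n_snps,
                "length_kb": r.length_kb,
            }
            for r in runs
        ],
        columns=["sample_id", "chromosome", "start_bp", "end_bp", "n_snps", "length_kb"],
    )


def within_population_summary(
    segset: IBDSegmentSet,
    gm: GenotypeMatrix,
    roh_params: ROHParams | None = None,
    min_pop_size: int = 10,
) -> pd.DataFrame:
    """Per-population within-population IBD sharing and ROH summary.

    Columns: population, n, W_within (mean pairwise within-population sharing,
    cM per pair; NaN for n < 2), mean_roh_count, mean_roh_total_kb,
    small_sample (True when n < *min_pop_size*, flagging pooling candidates).
    """
    sample_pops = dict(zip(gm.samples["id"], gm.samples["population"]))
    mat = sharing_matrix(segset, sample_pops) if len(segset) else None
    runs = roh_to_frame(roh_detect(gm, roh_params))
    rows = []
    for pop, grp in gm.samples.groupby("population", sort=True):
        n = len(grp)
        if n >= 2:
            w = mat.value(pop, pop) if mat is not None else 0.0
        else:
            w = np.nan
        sub = runs[runs["sample_id"].isin(grp["id"])]
        per_sample_counts = sub.groupby("sample_id").size().reindex(grp["id"], fill_value=0)
        per_sample_kb = (
            sub.groupby("sample_id")["length_kb"].sum().reindex(grp["id"], fill_value=0.0)
        )
        rows.append(
            {
                "population": pop,
                "n": n,
                "W_within": w,
                "mean_roh_count": float(per_sample_counts.mean()),
                "mean_roh_total_kb": float(per_sample_kb.mean()),
                "small_sample": n < min_pop_size,
            }
        )
    return pd.DataFrame(rows)
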