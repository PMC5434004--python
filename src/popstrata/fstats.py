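"""Allele-frequency f-statistics with weighted block jackknife.

Implements the admixture screen built on f3(A; B, C) — per site
(a-b)(a-c) minus the finite-sample heterozygosity correction a(1-a)/(n_A - 1)
on the target — the four-population D statistic (ABBA-BABA), and outgroup-f3
shared-drift estimation. Standard errors come from a weighted delete-one-block
jackknife over contiguous, chromosome-respecting variant blocks (997 by
default); a trio is flagged as an admixture signal when Z = f3/SE < -2.

The statistic pipeline is fully vectorized over sites; variants lacking a
defined frequency in any involved population are dropped per statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix

DEFAULT_N_BLOCKS = 997
Z_ADMIXTURE_THRESHOLD = -2.0


class FStatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Population frequencies
# ---------------------------------------------------------------------------


@dataclass
class FreqTable:
    """Per-(population, variant) allele_b frequencies and allele counts.

    ``freq``: (P, V) frequency of allele_b over non-missing calls (NaN at
    n = 0); ``n_alleles``: (P, V) non-missing allele observations (2 per
    called genotype). The heterozygosity correction a(1-a)/(n-1) is available
    via :meth:`het_correction` (NaN when n < 2).
    """

    populations: list[str]
    variants: pd.DataFrame
    freq: np.ndarray
    n_alleles: np.ndarray

    def __post_init__(self) -> None:
        P, V = len(self.populations), len(self.variants)
        if self.freq.shape != (P, V) or self.n_alleles.shape != (P, V):
            raise FStatError("frequency table dimensions inconsistent")

    def index_of(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise FStatError(f"population {pop!r} not in frequency table") from None

    def het_correction(self, pop: str) -> np.ndarray:
        i = self.index_of(pop)
        a, n = self.freq[i], self.n_alleles[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = a * (1.0 - a) / (n - 1.0)
        out[n < 2] = np.nan
        return out


def population_freqs(gm: GenotypeMatrix, grouping: str = "population") -> FreqTable:
    """Allele_b frequency and allele count per label of the *grouping* column."""
    if grouping not in gm.samples.columns:
        raise FStatError(f"no sample column {grouping!r}")
    labels = gm.samples[grouping].to_numpy()
    pops = sorted(pd.unique(labels))
    P, V = len(pops), gm.n_variants
    freq = np.full((P, V), np.nan)
    n_alleles = np.zeros((P, V), dtype=np.int64)
    obs = gm.calls != MISSING
    dose = np.where(obs, gm.calls, 0)
    for k, pop in enumerate(pops):
        rows = labels == pop
        n = 2 * obs[rows].sum(axis=0)
        s = dose[rows].sum(axis=0)
        n_alleles[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(n > 0, s / np.where(n > 0, n, 1), np.nan)
    return FreqTable(pops, gm.variants.copy(), freq, n_alleles)


# ---------------------------------------------------------------------------
# Blocks and jackknife
# ---------------------------------------------------------------------------


@dataclass
class BlockPartition:
    """Contiguous, chromosome-respecting variant blocks for the jackknife.

    ``block_of``: per-variant block index (0..n_blocks-1, non-decreasing);
    ``counts``: variants per block (the jackknife weights).
    """

    block_of: np.ndarray
    counts: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.counts)


def make_blocks(variants: pd.DataFrame, n_blocks: int = DEFAULT_N_BLOCKS) -> BlockPartition:
    """Split the (sorted) variant list into ~equal-count contiguous blocks.

    Blocks never span chromosomes: the requested count is apportioned to
    chromosomes by variant share (at least one block each), so the realized
    total can differ from *n_blocks* by at most one per chromosome.
    """
    V = len(variants)
    if n_blocks > V:
        raise FStatError(f"requested {n_blocks} blocks for {V} variants")
    chrom = variants["chromosome"].to_numpy()
    uniq = list(pd.unique(chrom))
    sizes = np.array([np.count_nonzero(chrom == c) for c in uniq])
    alloc = np.maximum(1, np.round(n_blocks * sizes / V).astype(int))
    alloc = np.minimum(alloc, sizes)
    block_of = np.empty(V, dtype=np.int64)
    counts: list[int] = []
    next_block = 0
    for c, m, k in zip(uniq, sizes, alloc):
        cidx = np.flatnonzero(chrom == c)
        bounds = np.linspace(0, m, k + 1).round().astype(int)
        for b in range(k):
            seg = cidx[bounds[b] : bounds[b + 1]]
            block_of[seg] = next_block
            counts.append(len(seg))
            next_block += 1
    return BlockPartition(block_of, np.array(counts))


def weighted_jackknife(
    estimate: float, delete_one: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Busing-style weighted delete-one jackknife (estimate, SE).

    *delete_one[j]* is the statistic recomputed without block j; *weights[j]*
    is block j's weight (its share of the data). Returns the bias-corrected
    estimate and its standard error.
    """
    weights = np.asarray(weights, dtype=float)
    delete_one = np.asarray(delete_one, dtype=float)
    if len(weights) < 2 or np.any(weights <= 0):
        raise FStatError("need >= 2 blocks with positive weight")
    g = len(weights)
    W = weights.sum()
    h = W / weights
    theta_J = g * estimate - np.sum((1.0 - weights / W) * delete_one)
    tau = h * estimate - (h - 1.0) * delete_one
    var = np.sum((tau - theta_J) ** 2 / (h - 1.0)) / g
    return float(theta_J), float(np.sqrt(max(var, 0.0)))


def jackknife(per_block_sums: np.ndarray, per_block_weights: np.ndarray) -> tuple[float, float]:
    """Jackknife mean of a block-summed statistic: estimate = sum(S)/sum(w)."""
    s = np.asarray(per_block_sums, dtype=float)
    w = np.asarray(per_block_weights, dtype=float)
    pos = w > 0
    s, w = s[pos], w[pos]
    if len(w) < 2:
        raise FStatError("need >= 2 blocks with positive weight")
    T, W = s.sum(), w.sum()
    est = T / W
    delete_one = (T - s) / (W - w)
    _, se = weighted_jackknife(est, delete_one, w)
    return est, se


# ---------------------------------------------------------------------------
# f3 / D statistics
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """One f3/D/outgroup-f3 result with jackknife uncertainty."""

    kind: str
    populations: tuple[str, ...]
    value: float
    se: float
    z: float
    n_blocks: int
    n_variants_used: int

    @property
    def admixture_flagged(self) -> bool:
        """f3 admixture evidence at the conventional Z < -2 cutoff."""
        return self.kind == "f3" and self.z < Z_ADMIXTURE_THRESHOLD


def _block_mean_result(
    kind: str,
    pops: tuple[str, ...],
    terms: np.ndarray,
    usable: np.ndarray,
    blocks: BlockPartition,
) -> TestResult:
    sums = np.bincount(
        blocks.block_of[usable], weights=terms[usable], minlength=blocks.n_blocks
    )
    cnts = np.bincount(blocks.block_of[usable], minlength=blocks.n_blocks).astype(float)
    if np.count_nonzero(cnts > 0) < 2:
        raise FStatError(f"{kind}: fewer than 2 usable blocks")
    est, se = jackknife(sums[cnts > 0], cnts[cnts > 0])
    z = est / se if se > 0 else np.inf * np.sign(est) if est != 0 else 0.0
    return TestResult(kind, pops, float(est), float(se), float(z), int((cnts > 0).sum()), int(usable.sum()))


def f3_test(
    freqs: FreqTable, A: str, B: str, C: str, blocks: BlockPartition
) -> TestResult:
    """f3(A; B, C): significantly negative (Z < -2) indicates A is admixed
    between sources related to B and C.

    Per usable site the term is (a-b)(a-c) - a(1-a)/(n_A-1); the statistic is
    the variant-count-weighted mean with a weighted block jackknife SE. Sites
    require n >= 2 alleles in A (for the correction) and a defined frequency
    in B and C.
    """
    ia, ib, ic = freqs.index_of(A), freqs.index_of(B), freqs.index_of(C)
    a, b, c = freqs.freq[ia], freqs.freq[ib], freqs.freq[ic]
    corr = freqs.het_correction(A)
    usable = (
        (freqs.n_alleles[ia] >= 2)
        & (freqs.n_alleles[ib] >= 1)
        & (freqs.n_alleles[ic] >= 1)
    )
    terms = np.where(usable, (a - b) * (a - c) - corr, 0.0)
    return _block_mean_result("f3", (A, B, C), terms, usable, blocks)


def outgroup_f3(
    freqs: FreqTable, X: str, Y: str, outgroup: str, blocks: BlockPartition
) -> TestResult:
    """Shared-drift f3 with the outgroup as target: larger = X,Y genetically closer."""
    res = f3_test(freqs, outgroup, X, Y, blocks)
    return TestResult(
        "outgroup_f3", (X, Y, outgroup), res.value, res.se, res.z, res.n_blocks, res.n_variants_used
    )


def d_test(
    freqs: FreqTable, W: str, X: str, Y: str, Z: str, blocks: BlockPartition
) -> TestResult:
    """ABBA-BABA D(W, X; Y, Z) with block-jackknife Z-score.

    D = sum_s (w-x)(y-z) / sum_s (w+x-2wx)(y+z-2yz) over sites with defined
    frequencies in all four populations; nonzero D rejects treeness.
    """
    if len({W, X, Y, Z}) != 4:
        raise FStatError("D test requires four distinct populations")
    iw, ix, iy, iz = (freqs.index_of(p) for p in (W, X, Y, Z))
    w, x, y, z = freqs.freq[iw], freqs.freq[ix], freqs.freq[iy], freqs.freq[iz]
    usable = (
        (freqs.n_alleles[iw] >= 1)
        & (freqs.n_alleles[ix] >= 1)
        & (freqs.n_alleles[iy] >= 1)
        & (freqs.n_alleles[iz] >= 1)
    )
    num = np.where(usable, (w - x) * (y - z), 0.0)
    den = np.where(usable, (w + x - 2 * w * x) * (y + z - 2 * y * z), 0.0)
    nb = blocks.n_blocks
    num_s = np.bincount(blocks.block_of[usable], weights=num[usable], minlength=nb)
    den_s = np.bincount(blocks.block_of[usable], weights=den[usable], minlength=nb)
    cnt_s = np.bincount(blocks.block_of[usable], minlength=nb).astype(float)
    T_num, T_den = num_s.sum(), den_s.sum()
    if T_den == 0:
        raise FStatError("D test: zero denominator sum")
    est = T_num / T_den
    pos = cnt_s > 0
    if pos.sum() < 2:
        raise FStatError("D test: fewer than 2 usable blocks")
    with np.errstate(invalid="ignore", divide="ignore"):
        delete_one = (T_num - num_s[pos]) / (T_den - den_s[pos])
    _, se = weighted_jackknife(est, delete_one, cnt_s[pos])
    z = est / se if se > 0 else np.inf * np.sign(est) if est != 0 else 0.0
    return TestResult(
        "D", (W, X, Y, Z), float(est), float(se), float(z), int(pos.sum()), int(usable.sum())
    )


# ---------------------------------------------------------------------------
# All-trios admixture screen
# ---------------------------------------------------------------------------


def screen_trios(
    freqs: FreqTable,
    groups: list[str] | None = None,
    blocks: BlockPartition | None = None,
    z_threshold: float = Z_ADMIXTURE_THRESHOLD,
) -> pd.DataFrame:
    """f3(target; B, C) for every target and unordered source pair.

    For g groups this evaluates g * C(g-1, 2) trios; rows with Z below
    *z_threshold* carry ``flagged = True``. Returns a table with columns
    target, source1, source2, f3, se, z, n_snps, flagged.
    """
    groups = groups if groups is not None else list(freqs.populations)
    if len(groups) < 3:
        raise FStatError("screen requires at least 3 groups")
    if blocks is None:
        blocks = make_blocks(freqs.variants, min(DEFAULT_N_BLOCKS, len(freqs.variants)))
    rows = []
    for target in groups:
        others = [g for g in groups if g != target]
        for b, c in combinations(others, 2):
            res = f3_test(freqs, target, b, c, blocks)
            rows.append(
                {
                    "target": target,
                    "source1": b,
                    "source2": c,
                    "f3": res.value,
                    "se": res.se,
                    "z": res.z,
                    "n_snps": res.n_variants_used,
                    "flagged": res.z < z_threshold,
                }
            )
    return pd.DataFrame(rows)
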