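"""Admixture dating from the exponential decay of admixture LD.

A single admixture pulse G generations ago leaves covariance between linked
loci that decays as exp(-G d) with genetic distance d (in Morgans). The
weighted-LD curve a(d) averages, over intra-chromosome variant pairs (s, t)
binned by distance, the product w_s w_t C_st where the weights
w = p_ref1 - p_ref2 are allele-frequency contrasts between two reference
populations and C_st is the (diploid genotype) covariance across target
individuals divided by 2 to approximate haplotype-scale LD under random
mating. Fitting a(d) = A exp(-G d) + c by nonlinear least squares yields the
admixture date in generations, converted to years with a generation time of
28 years; estimates beyond 100 generations are flagged as past the method's
detection threshold. Uncertainty comes from a delete-one-chromosome jackknife
refit.

Defaults: bin width 0.1 cM, d in [0.5, 30] cM (the lower cutoff suppresses
background LD).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_qc import MISSING, GenotypeMatrix

GENERATION_TIME_YEARS = 28.0
DETECTION_LIMIT_GENERATIONS = 100.0


class DatingError(ValueError):
    pass


@dataclass
class WeightedLDCurve:
    """Binned weighted-LD averages with per-chromosome sums for the jackknife."""

    bin_mid_cM: np.ndarray
    a_d: np.ndarray
    n_pairs: np.ndarray
    chrom_labels: list[str]
    chrom_sums: np.ndarray  # (n_chrom, n_bins) weighted sums
    chrom_counts: np.ndarray  # (n_chrom, n_bins) pair counts

    def drop_chromosome(self, label: str) -> "WeightedLDCurve":
        keep = [i for i, c in enumerate(self.chrom_labels) if c != label]
        sums = self.chrom_sums[keep].sum(axis=0)
        counts = self.chrom_counts[keep].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return WeightedLDCurve(
            self.bin_mid_cM,
            a,
            counts,
            [self.chrom_labels[i] for i in keep],
            self.chrom_sums[keep],
            self.chrom_counts[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid_cM": self.bin_mid_cM, "a_d": self.a_d, "n_pairs": self.n_pairs}
        )


@dataclass
class AdmixtureDate:
    """A fitted admixture-LD decay: G in generations, optionally in years."""

    G_hat: float
    se_G: float
    amplitude: float
    affine: float
    converged: bool
    n_bins: int
    date_years: float | None = None
    se_years: float | None = None
    generation_time: float | None = None
    beyond_threshold: bool = False


def _pairwise_cov(calls: np.ndarray) -> np.ndarray:
    """Genotype covariance matrix across individuals, mean-imputing missing calls."""
    g = calls.astype(float)
    bad = calls == MISSING
    if bad.any():
        col_mean = np.where(
            (~bad).sum(axis=0) > 0,
            np.where(bad, 0, g).sum(axis=0) / np.maximum((~bad).sum(axis=0), 1),
            0.0,
        )
        g = np.where(bad, col_mean[None, :], g)
    g = g - g.mean(axis=0)
    n = g.shape[0]
    return g.T @ g / (n - 1)


def weighted_ld_curve(
    gm_target: GenotypeMatrix,
    ref1_freq: np.ndarray,
    ref2_freq: np.ndarray,
    bin_width_cM: float = 0.1,
    d_min_cM: float = 0.5,
    d_max_cM: float = 30.0,
) -> WeightedLDCurve:
    """Binned weighted LD a(d) for the target against two reference frequency vectors.

    *ref1_freq*/*ref2_freq* are allele_b frequencies aligned with the target's
    variants (e.g. rows of a FreqTable). Sites where either reference
    frequency is undefined are dropped. Pairs are intra-chromosome only.
    """
    ref1_freq = np.asarray(ref1_freq, dtype=float)
    ref2_freq = np.asarray(ref2_freq, dtype=float)
    if ref1_freq.shape != (gm_target.n_variants,) or ref2_freq.shape != (gm_target.n_variants,):
        raise DatingError("reference frequency vectors must align with target variants")
    if gm_target.n_samples < 2:
        raise DatingError("target population too small")
    w_all = ref1_freq - ref2_freq
    ok = np.isfinite(w_all)
    edges = np.arange(d_min_cM, d_max_cM + bin_width_cM, bin_width_cM)
    n_bins = len(edges) - 1
    mids = (edges[:-1] + edges[1:]) / 2
    chroms = list(pd.unique(gm_target.variants["chromosome"]))
    chrom_sums = np.zeros((len(chroms), n_bins))
    chrom_counts = np.zeros((len(chroms), n_bins), dtype=np.int64)
    chrom_arr = gm_target.variants["chromosome"].to_numpy()
    cm = gm_target.variants["genetic_pos_cM"].to_numpy()
    for ci, c in enumerate(chroms):
        vidx = np.flatnonzero((chrom_arr == c) & ok)
        if len(vidx) < 2:
            continue
        C = _pairwise_cov(gm_target.calls[:, vidx]) / 2.0
        w = w_all[vidx]
        prod = np.outer(w, w) * C
        d = np.abs(cm[vidx][:, None] - cm[vidx][None, :])
        iu = np.triu_indices(len(vidx), k=1)
        dv, pv = d[iu], prod[iu]
        sel = (dv >= d_min_cM) & (dv <= d_max_cM)
        if not sel.any():
            continue
        bins = np.clip(((dv[sel] - d_min_cM) / bin_width_cM).astype(int), 0, n_bins - 1)
        chrom_sums[ci] += np.bincount(bins, weights=pv[sel], minlength=n_bins)
        chrom_counts[ci] += np.bincount(bins, minlength=n_bins)
    counts = chrom_counts.sum(axis=0)
    if counts.sum() == 0:
        raise DatingError("no variant pairs in the requested distance range")
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(counts > 0, chrom_sums.sum(axis=0) / np.maximum(counts, 1), np.nan)
    return WeightedLDCurve(mids, a, counts, [str(c) for c in chroms], chrom_sums, chrom_counts)


def _fit_curve_once(d_cM: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    """Least-squares fit of a(d) = A exp(-G d_M) + c; returns (A, G, c)."""
    d_M = d_cM / 100.0
    # Log-linear initialization on the positive part.
    c0 = float(np.nanmin(a))
    resid = a - c0 + 1e-12
    pos = resid > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(d_M[pos], np.log(resid[pos]), 1)
        G0 = float(np.clip(-slope, 1.0, 500.0))
        A0 = float(np.exp(intercept))
    else:
        G0, A0 = 20.0, float(np.nanmax(a) - c0)
    popt, _ = curve_fit(
        lambda d, A, G, c: A * np.exp(-G * d) + c,
        d_M,
        a,
        p0=[A0, G0, c0],
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def fit_decay(curve: WeightedLDCurve, min_bins: int = 5) -> AdmixtureDate:
    """Fit the exponential decay and jackknife G over chromosomes.

    Degenerate inputs (flat curve, vanishing amplitude, non-convergence)
    return ``converged = False`` with ``G_hat = nan`` rather than a spurious
    finite date; a negative fitted amplitude is likewise reported unconverged.
    """
    good = np.isfinite(curve.a_d) & (curve.n_pairs > 0)
    if good.sum() < min_bins:
        raise DatingError(f"need >= {min_bins} populated bins, have {int(good.sum())}")
    d, a = curve.bin_mid_cM[good], curve.a_d[good]
    scale = float(np.std(a))
    try:
        A, G, c = _fit_curve_once(d, a)
    except RuntimeError:
        return AdmixtureDate(np.nan, np.nan, np.nan, np.nan, False, int(good.sum()))
    # Flat curve: fitted amplitude indistinguishable from residual noise.
    resid_sd = float(np.std(a - (A * np.exp(-G * d / 100.0) + c)))
    degenerate = (A <= 0) or (abs(A) < 1e-3 * max(scale, 1e-300)) or G <= 0 or scale == 0
    if degenerate:
        return AdmixtureDate(np.nan, np.nan, A, c, False, int(good.sum()))
    # Delete-one-chromosome jackknife on G.
    g_del = []
    for label in curve.chrom_labels:
        sub = curve.drop_chromosome(label)
        gsub = np.isfinite(sub.a_d) & (sub.n_pairs > 0)
        if gsub.sum() < min_bins:
            continue
        try:
            _, Gj, _ = _fit_curve_once(sub.bin_mid_cM[gsub], sub.a_d[gsub])
            g_del.append(Gj)
        except RuntimeError:
            continue
    if len(g_del) >= 2:
        g_del_arr = np.array(g_del)
        m = len(g_del_arr)
        se = float(np.sqrt((m - 1) / m * np.sum((g_del_arr - g_del_arr.mean()) ** 2)))
    else:
        se = np.nan
    return AdmixtureDate(G, se, A, c, True, int(good.sum()))


def to_years(
    date: AdmixtureDate, generation_time: float = GENERATION_TIME_YEARS
) -> AdmixtureDate:
    """Convert generations to years and flag dates past the detection limit."""
    if not date.converged or not np.isfinite(date.G_hat) or date.G_hat <= 0:
        raise DatingError("cannot convert an unconverged or non-positive date")
    return replace(
        date,
        date_years=date.G_hat * generation_time,
        se_years=date.se_G * generation_time if np.isfinite(date.se_G) else None,
        generation_time=generation_time,
        beyond_threshold=date.G_hat > DETECTION_LIMIT_GENERATIONS,
    )
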