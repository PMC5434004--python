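"""Genotype dataset I/O, quality control, relatedness filtering, merging and LD pruning.

The central container is :class:`GenotypeMatrix`: a samples × variants matrix of
diploid genotype calls counting copies of ``allele_b`` (0, 1, 2; missing is -1),
with per-sample and per-variant metadata held in pandas DataFrames.

Two text interchange formats are supported:

* **EIGENSTRAT** triplets (``.geno``/``.snp``/``.ind``). The ``.geno`` digit is
  the number of copies of the reference allele (``allele_a``), ``9`` = missing;
  the ``.snp`` file stores genetic position in Morgans.
* **PLINK text** (``.ped``/``.map``), space-delimited allele pairs, missing
  ``0 0``. Because ``.map`` carries no allele columns, the writer also emits a
  ``.ref`` sidecar (variant id, allele_a, allele_b) so that allele orientation
  round-trips; without it the loader orients alleles lexicographically.

Sample ``group`` and ``era`` annotations are analysis-level labels that the
interchange formats cannot represent; loaders default ``group`` to the
population label and ``era`` to ``modern``.

QC follows the strict inequalities of the source conventions: a variant is kept
iff its call rate exceeds ``min_snp_callrate``, an individual iff its
missingness is below ``max_ind_missing``, and a pair of individuals is flagged
as related iff PiHat exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

#: DNA complement used for strand harmonization during merging.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Allele pairs that cannot be distinguished from their strand flip.
_AMBIGUOUS_SETS = ({"A", "T"}, {"C", "G"})

VARIANT_COLUMNS = ["id", "chromosome", "position_bp", "genetic_pos_cM", "allele_a", "allele_b"]
SAMPLE_COLUMNS = ["id", "population", "group", "era"]


class DatasetError(ValueError):
    """Raised for inconsistent, unparseable or degenerate genotype datasets."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with sample and variant metadata.

    Attributes
    ----------
    samples : DataFrame with columns id, population, group, era
    variants : DataFrame with columns id, chromosome, position_bp,
        genetic_pos_cM, allele_a, allele_b
    calls : int16 array (n_samples, n_variants); each entry counts copies of
        allele_b, with :data:`MISSING` (-1) for no-calls.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise DatasetError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise DatasetError(f"invalid genotype value(s): {np.unique(self.calls[bad])}")
        if self.samples["id"].duplicated().any():
            dupes = self.samples.loc[self.samples["id"].duplicated(), "id"].tolist()
            raise DatasetError(f"duplicate sample id(s): {dupes}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples.copy(), self.variants.copy(), self.calls.copy())

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given variant positional indices."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples.copy(), self.variants.iloc[index].copy(), self.calls[:, index].copy()
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples.iloc[index].copy(), self.variants.copy(), self.calls[index, :].copy()
        )

    def allele_b_freq(self) -> np.ndarray:
        """Pooled allele_b frequency per variant (NaN where fully missing)."""
        obs = self.calls != MISSING
        n = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, self.calls, 0).sum(axis=0) / np.where(n > 0, n, np.nan)

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality up to text round-trip precision of genetic positions."""
        exact_cols = ["id", "chromosome", "position_bp", "allele_a", "allele_b"]
        return (
            self.samples[["id", "population"]].equals(other.samples[["id", "population"]])
            and self.variants[exact_cols]
            .reset_index(drop=True)
            .equals(other.variants[exact_cols].reset_index(drop=True))
            and np.allclose(
                self.variants["genetic_pos_cM"], other.variants["genetic_pos_cM"], atol=1e-5
            )
            and np.array_equal(self.calls, other.calls)
        )


def make_samples(ids, populations, groups=None, eras=None) -> pd.DataFrame:
    """Assemble a sample table, defaulting group to population and era to modern."""
    ids = list(ids)
    populations = list(populations)
    return pd.DataFrame(
        {
            "id": ids,
            "population": populations,
            "group": list(groups) if groups is not None else populations,
            "era": list(eras) if eras is not None else ["modern"] * len(ids),
        }
    )


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def _paths(prefix, format: str) -> dict[str, Path]:
    prefix = Path(prefix)
    if format == "eigenstrat":
        exts = {"geno": ".geno", "snp": ".snp", "ind": ".ind"}
    elif format == "plink_text":
        exts = {"ped": ".ped", "map": ".map", "ref": ".ref"}
    else:
        raise ValueError(f"unknown format {format!r}")
    return {k: prefix.with_suffix(v) for k, v in exts.items()}


def save_dataset(gm: GenotypeMatrix, prefix, format: str = "eigenstrat") -> dict[str, Path]:
    """Write *gm* under *prefix* in the requested format; returns the file map."""
    p = _paths(prefix, format)
    if format == "eigenstrat":
        # geno digit counts reference (allele_a) copies: digit = 2 - call.
        digits = np.where(gm.calls == MISSING, 9, 2 - gm.calls).astype(np.int8)
        with open(p["geno"], "w") as fh:
            for j in range(gm.n_variants):
                fh.write("".join(map(str, digits[:, j])) + "\n")
        with open(p["snp"], "w") as fh:
            for v in gm.variants.itertuples(index=False):
                fh.write(
                    f"{v.id}\t{v.chromosome}\t{v.genetic_pos_cM / 100.0:.8f}"
                    f"\t{int(v.position_bp)}\t{v.allele_a}\t{v.allele_b}\n"
                )
        with open(p["ind"], "w") as fh:
            for s in gm.samples.itertuples(index=False):
                fh.write(f"{s.id}\tU\t{s.population}\n")
    else:
        with open(p["ped"], "w") as fh:
            for i, s in enumerate(gm.samples.itertuples(index=False)):
                fields = [s.population, s.id, "0", "0", "0", "-9"]
                for j, v in enumerate(gm.variants.itertuples(index=False)):
                    c = gm.calls[i, j]
                    if c == MISSING:
                        fields += ["0", "0"]
                    else:
                        fields += [v.allele_a] * (2 - c) + [v.allele_b] * c
                fh.write(" ".join(fields) + "\n")
        with open(p["map"], "w") as fh:
            for v in gm.variants.itertuples(index=False):
                fh.write(f"{v.chromosome}\t{v.id}\t{v.genetic_pos_cM:.8f}\t{int(v.position_bp)}\n")
        with open(p["ref"], "w") as fh:
            for v in gm.variants.itertuples(index=False):
                fh.write(f"{v.id}\t{v.allele_a}\t{v.allele_b}\n")
    return p


def load_dataset(prefix, format: str = "eigenstrat") -> GenotypeMatrix:
    """Read a genotype dataset written by :func:`save_dataset` (or compatible)."""
    p = _paths(prefix, format)
    if format == "eigenstrat":
        return _load_eigenstrat(p)
    return _load_plink_text(p)


def _load_eigenstrat(p: dict[str, Path]) -> GenotypeMatrix:
    snp = pd.read_csv(
        p["snp"],
        sep=r"\s+",
        header=None,
        names=["id", "chromosome", "genetic_pos_M", "position_bp", "allele_a", "allele_b"],
        dtype={"id": str, "chromosome": str, "allele_a": str, "allele_b": str},
    )
    variants = pd.DataFrame(
        {
            "id": snp["id"],
            "chromosome": snp["chromosome"],
            "position_bp": snp["position_bp"].astype(np.int64),
            "genetic_pos_cM": snp["genetic_pos_M"].astype(float) * 100.0,
            "allele_a": snp["allele_a"],
            "allele_b": snp["allele_b"],
        }
    )
    ind = pd.read_csv(
        p["ind"], sep=r"\s+", header=None, names=["id", "sex", "population"], dtype=str
    )
    samples = make_samples(ind["id"], ind["population"])
    rows = []
    with open(p["geno"]) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if len(line) != len(samples):
                raise DatasetError(
                    f"{p['geno']}:{lineno}: {len(line)} genotypes for {len(samples)} samples"
                )
            if not set(line) <= set("0129"):
                raise DatasetError(f"{p['geno']}:{lineno}: unparseable genotype symbol")
            rows.append(np.frombuffer(line.encode(), dtype=np.uint8) - ord("0"))
    if len(rows) != len(variants):
        raise DatasetError(
            f"{p['geno']}: {len(rows)} variant rows but {len(variants)} .snp records"
        )
    digits = (
        np.array(rows, dtype=np.int16).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    calls = np.where(digits == 9, MISSING, 2 - digits)
    return GenotypeMatrix(samples, variants, calls)


def _load_plink_text(p: dict[str, Path]) -> GenotypeMatrix:
    mp = pd.read_csv(
        p["map"],
        sep=r"\s+",
        header=None,
        names=["chromosome", "id", "genetic_pos_cM", "position_bp"],
        dtype={"chromosome": str, "id": str},
    )
    n_var = len(mp)
    ref = None
    if p["ref"].exists():
        ref = pd.read_csv(
            p["ref"], sep=r"\s+", header=None, names=["id", "allele_a", "allele_b"], dtype=str
        ).set_index("id")
    ids, pops, genos = [], [], []
    with open(p["ped"]) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise DatasetError(
                    f"{p['ped']}:{lineno}: expected {6 + 2 * n_var} fields, got {len(parts)}"
                )
            pops.append(parts[0])
            ids.append(parts[1])
            genos.append(parts[6:])
    samples = make_samples(ids, pops)
    pairs = np.array(genos, dtype=object).reshape(len(ids), n_var, 2) if ids else np.empty(
        (0, n_var, 2), dtype=object
    )
    calls = np.full((len(ids), n_var), MISSING, dtype=np.int16)
    allele_a, allele_b = [], []
    for j in range(n_var):
        vid = mp["id"].iloc[j]
        if ref is not None and vid in ref.index:
            a, b = ref.loc[vid, "allele_a"], ref.loc[vid, "allele_b"]
        else:
            observed = sorted(
                {x for x in pairs[:, j, :].ravel() if x != "0"}
            )
            if len(observed) > 2:
                raise DatasetError(f"variant {vid}: more than two alleles {observed}")
            observed += ["N"] * (2 - len(observed))
            a, b = observed[0], observed[1]
        allele_a.append(a)
        allele_b.append(b)
        for i in range(len(ids)):
            x, y = pairs[i, j]
            if x == "0" or y == "0":
                continue
            if not {x, y} <= {a, b}:
                raise DatasetError(f"variant {vid}, sample {ids[i]}: unknown allele {x}/{y}")
            calls[i, j] = (x == b) + (y == b)
    variants = pd.DataFrame(
        {
            "id": mp["id"],
            "chromosome": mp["chromosome"],
            "position_bp": mp["position_bp"].astype(np.int64),
            "genetic_pos_cM": mp["genetic_pos_cM"].astype(float),
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypeMatrix(samples, variants, calls)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def remove_ambiguous_sites(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Drop strand-ambiguous A/T and C/G variants; samples are untouched."""
    sets = [
        {a, b} for a, b in zip(gm.variants["allele_a"], gm.variants["allele_b"])
    ]
    keep = np.array([s not in _AMBIGUOUS_SETS for s in sets])
    return gm.take_variants(np.flatnonzero(keep))


def apply_qc_filters(
    gm: GenotypeMatrix, min_snp_callrate: float = 0.90, max_ind_missing: float = 0.01
) -> GenotypeMatrix:
    """Variant call-rate filter followed by individual missingness filter.

    A variant survives iff its call rate is strictly above *min_snp_callrate*;
    an individual survives iff, on the surviving variants, its fraction of
    missing calls is strictly below *max_ind_missing*. The variant filter runs
    first so that individual missingness is judged on usable sites only.
    """
    if not (0 <= min_snp_callrate <= 1 and 0 <= max_ind_missing <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    obs = gm.calls != MISSING
    if gm.n_samples == 0:
        raise DatasetError("no samples in input")
    callrate = obs.mean(axis=0) if gm.n_samples else np.zeros(gm.n_variants)
    gm2 = gm.take_variants(np.flatnonzero(callrate > min_snp_callrate))
    if gm2.n_variants == 0:
        ind_missing = np.zeros(gm2.n_samples)
    else:
        ind_missing = (gm2.calls == MISSING).mean(axis=1)
    keep = ind_missing < max_ind_missing
    if not keep.any():
        raise DatasetError("QC removed every sample")
    return gm2.take_samples(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Relatedness (PiHat)
# ---------------------------------------------------------------------------


@dataclass
class KinshipTable:
    """Unordered-pair PiHat estimates (method-of-moments IBD sharing)."""

    pairs: pd.DataFrame  # columns: id1, id2, pihat

    def pihat(self, a: str, b: str) -> float:
        m = ((self.pairs["id1"] == a) & (self.pairs["id2"] == b)) | (
            (self.pairs["id1"] == b) & (self.pairs["id2"] == a)
        )
        sub = self.pairs.loc[m, "pihat"]
        if sub.empty:
            raise KeyError(f"no pair ({a}, {b})")
        return float(sub.iloc[0])


def _pihat_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Purcell-style method-of-moments PiHat for all sample pairs.

    Uses per-site expected IBS probabilities conditional on sharing 0/1/2
    alleles IBD, with allele frequencies estimated from the sample itself.
    Estimates are clamped to [0, 1].
    """
    g = gm.calls
    obs = g != MISSING
    p = gm.allele_b_freq()
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    q = 1.0 - p
    # Per-site P(IBS = s | IBD = k) under Hardy-Weinberg.
    e0_ibd0 = 2 * p**2 * q**2
    e1_ibd0 = 4 * p**3 * q + 4 * p * q**3
    e2_ibd0 = p**4 + q**4 + 4 * p**2 * q**2
    e1_ibd1 = 2 * p**2 * q + 2 * p * q**2
    e2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2
    n = gm.n_samples
    out = np.full((n, n), np.nan)
    for i, j in combinations(range(n), 2):
        valid = obs[i] & obs[j] & informative
        if not valid.any():
            raise DatasetError(
                f"no informative sites shared by {gm.samples['id'].iloc[i]} "
                f"and {gm.samples['id'].iloc[j]}"
            )
        gi, gj = g[i, valid], g[j, valid]
        ibs = 2 - np.abs(gi - gj)
        # Opposite homozygotes are the only IBS-0 state.
        ibs0 = ((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))
        n0 = np.count_nonzero(ibs0)
        n2 = np.count_nonzero(ibs == 2)
        n1 = valid.sum() - n0 - n2
        s_e0_0 = e0_ibd0[valid].sum()
        s_e1_0 = e1_ibd0[valid].sum()
        s_e2_0 = e2_ibd0[valid].sum()
        s_e1_1 = e1_ibd1[valid].sum()
        s_e2_1 = e2_ibd1[valid].sum()
        p0 = n0 / s_e0_0 if s_e0_0 > 0 else 0.0
        p1 = (n1 - p0 * s_e1_0) / s_e1_1 if s_e1_1 > 0 else 0.0
        p2 = n2 - p0 * s_e2_0 - p1 * s_e2_1  # remaining sites, scale of counts
        p2 /= valid.sum()
        p0, p1 = p0, p1
        # Clamp the IBD-state proportions onto [0, 1] and renormalize.
        probs = np.clip([p0, p1, p2], 0.0, 1.0)
        total = probs.sum()
        if total > 0:
            probs = probs / total
        pihat = float(np.clip(probs[1] / 2 + probs[2], 0.0, 1.0))
        out[i, j] = out[j, i] = pihat
    return out


def relatedness_filter(
    gm: GenotypeMatrix, threshold: float = 0.125
) -> tuple[GenotypeMatrix, KinshipTable]:
    """Estimate pairwise PiHat and drop one member of each pair above *threshold*.

    The member with more missing genotypes is removed; ties are broken by
    removing the lexicographically larger sample id. Removal iterates until no
    retained pair exceeds the threshold.
    """
    if gm.n_samples < 2:
        raise DatasetError("need at least two samples")
    p = gm.allele_b_freq()
    if not np.any(np.isfinite(p) & (p > 0) & (p < 1)):
        raise DatasetError("all sites monomorphic or missing; PiHat undefined")
    mat = _pihat_matrix(gm)
    ids = gm.samples["id"].tolist()
    missing_count = (gm.calls == MISSING).sum(axis=1)
    pairs = pd.DataFrame(
        [
            {"id1": ids[i], "id2": ids[j], "pihat": mat[i, j]}
            for i, j in combinations(range(len(ids)), 2)
        ]
    )
    retained = set(range(len(ids)))
    while True:
        offending = [
            (i, j)
            for i, j in combinations(sorted(retained), 2)
            if mat[i, j] > threshold
        ]
        if not offending:
            break
        i, j = offending[0]
        if missing_count[i] != missing_count[j]:
            drop = i if missing_count[i] > missing_count[j] else j
        else:
            drop = i if ids[i] > ids[j] else j
        retained.discard(drop)
    kept = sorted(retained)
    return gm.take_samples(np.array(kept)), KinshipTable(pairs)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


def merge_datasets(gm1: GenotypeMatrix, gm2: GenotypeMatrix) -> GenotypeMatrix:
    """Merge on the intersection of variant ids, harmonizing allele encodings.

    Assumes strand-ambiguous sites were already removed from both inputs
    (:func:`remove_ambiguous_sites`); a shared variant whose alleles in *gm2*
    are swapped and/or strand-complemented relative to *gm1* is recoded onto
    *gm1*'s orientation (a swap flips each call c to 2 - c). Positions are not
    used for matching; a position disagreement raises a warning only.
    """
    common = set(gm1.variants["id"]) & set(gm2.variants["id"])
    idx1 = np.flatnonzero(gm1.variants["id"].isin(common))
    sub1 = gm1.take_variants(idx1)
    order = {vid: k for k, vid in enumerate(sub1.variants["id"])}
    idx2 = np.flatnonzero(gm2.variants["id"].isin(common))
    sub2 = gm2.take_variants(idx2)
    perm = np.argsort([order[vid] for vid in sub2.variants["id"]], kind="stable")
    sub2 = sub2.take_variants(perm)

    overlap = set(gm1.samples["id"]) & set(gm2.samples["id"])
    if overlap:
        raise DatasetError(f"duplicate sample id(s) across datasets: {sorted(overlap)}")

    calls2 = sub2.calls.copy()
    for k in range(sub1.n_variants):
        a1, b1 = sub1.variants["allele_a"].iloc[k], sub1.variants["allele_b"].iloc[k]
        a2, b2 = sub2.variants["allele_a"].iloc[k], sub2.variants["allele_b"].iloc[k]
        ca2 = _COMPLEMENT.get(a2, a2)
        cb2 = _COMPLEMENT.get(b2, b2)
        if (a2, b2) == (a1, b1) or (ca2, cb2) == (a1, b1):
            flip = False
        elif (b2, a2) == (a1, b1) or (cb2, ca2) == (a1, b1):
            flip = True
        else:
            raise DatasetError(
                f"variant {sub1.variants['id'].iloc[k]}: incompatible alleles "
                f"{a1}/{b1} vs {a2}/{b2}"
            )
        if flip:
            col = calls2[:, k]
            calls2[:, k] = np.where(col == MISSING, MISSING, 2 - col)
        p1 = sub1.variants["position_bp"].iloc[k]
        p2 = sub2.variants["position_bp"].iloc[k]
        if p1 != p2:
            warnings.warn(
                f"variant {sub1.variants['id'].iloc[k]}: position differs ({p1} vs {p2})",
                stacklevel=2,
            )
    samples = pd.concat([sub1.samples, sub2.samples], ignore_index=True)
    calls = np.vstack([sub1.calls, calls2])
    return GenotypeMatrix(samples, sub1.variants.copy(), calls)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages, pairwise-complete."""
    valid = (x != MISSING) & (y != MISSING)
    if valid.sum() < 2:
        return 0.0
    xv = x[valid].astype(float)
    yv = y[valid].astype(float)
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def ld_prune(
    gm: GenotypeMatrix, r2_max: float = 0.1, window_snps: int = 50, step_snps: int = 10
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on genotype-dosage r².

    Within each window of *window_snps* consecutive variants (advanced by
    *step_snps*), pairs still retained are scanned left to right and the
    right-hand member of any pair with r² > *r2_max* is removed. Windows never
    span chromosomes.
    """
    keep = np.ones(gm.n_variants, dtype=bool)
    chrom = gm.variants["chromosome"].to_numpy()
    for c in pd.unique(chrom):
        cidx = np.flatnonzero(chrom == c)
        m = len(cidx)
        for start in range(0, m, step_snps):
            window = cidx[start : start + window_snps]
            active = [j for j in window if keep[j]]
            for ai in range(len(active)):
                a = active[ai]
                if not keep[a]:
                    continue
                for b in active[ai + 1 :]:
                    if not keep[b]:
                        continue
                    if _r2(gm.calls[:, a], gm.calls[:, b]) > r2_max:
                        keep[b] = False
            if start + window_snps >= m:
                break
    return gm.take_variants(np.flatnonzero(keep))
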