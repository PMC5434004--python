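"""Frequency-standardized PCA with least-squares projection, and supervised
ancestry-proportion estimation with fixed component allele frequencies.

PCA standardizes each variant by its mean genotype and the binomial scale
sqrt(p(1-p)) (p = mean/2), mean-imputes missing calls for fitting, and
projects new samples — ancient or low-coverage — by solving a least-squares
problem restricted to each sample's non-missing variants, the behaviour of
smartpca's lsqproject mode.

Ancestry proportions are estimated per individual by maximizing the binomial
admixture log-likelihood sum_s [g_s log(sum_k q_k F_ks) + (2-g_s)
log(sum_k q_k (1-F_ks))] over the simplex with multiplicative EM updates,
holding the component frequency table F fixed. F comes from labeled reference
populations (pooled allele counts, clamped away from 0/1); simulated
"100% component" individuals anchor the interpretation of each component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeMatrix
from .synthetic_data import ComponentModel, simulate_unadmixed

FREQ_CLAMP = 1e-5


class AncestryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Standardization constants, loadings and scores of a fitted PCA."""

    mean: np.ndarray  # per-variant mean genotype
    scale: np.ndarray  # per-variant sqrt(p(1-p)), floor-clamped
    loadings: np.ndarray  # (n_variants, k)
    eigenvalues: np.ndarray  # (k,), non-increasing
    scores: pd.DataFrame  # training sample scores (id, population, PC1..)
    variant_ids: pd.Index


def fit_pca(gm: GenotypeMatrix, k: int = 10) -> PCAModel:
    """Top-k PCA of frequency-standardized genotypes (missing mean-imputed)."""
    if k > min(gm.n_samples, gm.n_variants):
        raise AncestryError(f"k={k} exceeds matrix rank bound")
    obs = gm.calls != MISSING
    if not obs.any(axis=0).all():
        raise AncestryError("variant(s) with no called genotypes")
    g = gm.calls.astype(float)
    mean = np.where(obs, g, 0).sum(axis=0) / obs.sum(axis=0)
    p = mean / 2.0
    scale = np.sqrt(np.maximum(p * (1 - p), 1e-12))
    x = np.where(obs, g, mean[None, :])
    x = (x - mean[None, :]) / scale[None, :]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    eig = s**2 / max(gm.n_samples - 1, 1)
    scores = pd.DataFrame(u * s, columns=[f"PC{i+1}" for i in range(k)])
    scores.insert(0, "population", gm.samples["population"].to_numpy())
    scores.insert(0, "id", gm.samples["id"].to_numpy())
    return PCAModel(mean, scale, vt.T, eig, scores, pd.Index(gm.variants["id"]))


def lsq_project(model: PCAModel, gm_new: GenotypeMatrix) -> pd.DataFrame:
    """Project new samples with per-sample least squares on non-missing variants.

    The new dataset must carry the model's variant set in the model's order.
    A sample with zero non-missing overlap raises.
    """
    if not model.variant_ids.equals(pd.Index(gm_new.variants["id"])):
        raise AncestryError("projection dataset must share the model's variant set")
    k = model.loadings.shape[1]
    out = np.zeros((gm_new.n_samples, k))
    for i in range(gm_new.n_samples):
        obs = gm_new.calls[i] != MISSING
        if not obs.any():
            raise AncestryError(
                f"sample {gm_new.samples['id'].iloc[i]} has no called genotypes"
            )
        x = (gm_new.calls[i, obs] - model.mean[obs]) / model.scale[obs]
        beta, *_ = np.linalg.lstsq(model.loadings[obs], x, rcond=None)
        out[i] = beta
    scores = pd.DataFrame(out, columns=[f"PC{i+1}" for i in range(k)])
    scores.insert(0, "population", gm_new.samples["population"].to_numpy())
    scores.insert(0, "id", gm_new.samples["id"].to_numpy())
    return scores


# ---------------------------------------------------------------------------
# Supervised ancestry proportions
# ---------------------------------------------------------------------------


def estimate_component_freqs(
    gm: GenotypeMatrix, labeled_reference_pops: dict[str, list[str]]
) -> pd.DataFrame:
    """Component allele frequencies from pooled reference-population counts.

    Returns a (component × variant) frequency DataFrame, clamped to
    [1e-5, 1 - 1e-5] so the admixture likelihood stays finite.
    """
    pops = gm.samples["population"].to_numpy()
    rows = {}
    for comp, refs in labeled_reference_pops.items():
        sel = np.isin(pops, refs)
        if not sel.any():
            raise AncestryError(f"component {comp!r} has no reference individuals")
        calls = gm.calls[sel]
        obs = calls != MISSING
        n = 2 * obs.sum(axis=0)
        cnt = np.where(obs, calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, cnt / np.maximum(n, 1), 0.5)
        rows[comp] = np.clip(f, FREQ_CLAMP, 1 - FREQ_CLAMP)
    return pd.DataFrame(rows, index=gm.variants["id"]).T


def simulate_component_individuals(
    F: pd.DataFrame,
    n_per_component: int = 100,
    seed: int = 0,
    variants: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Simulate non-admixed individuals belonging 100% to each component.

    With the four-component default design and n=100 this yields the 400
    anchor individuals used to tag components. Sample populations record the
    source component as ``sim_<component>``.
    """
    from .io_qc import GenotypeMatrix as GM

    parts = []
    for j, (comp, freqs) in enumerate(F.iterrows()):
        model = ComponentModel(comp, freqs.to_numpy(dtype=float), 0.0, freqs.to_numpy(dtype=float))
        parts.append(
            simulate_unadmixed(
                model,
                n_per_component,
                seed=seed + j,
                variants=variants,
                population=f"sim_{comp}",
            )
        )
    samples = pd.concat([p.samples for p in parts], ignore_index=True)
    calls = np.vstack([p.calls for p in parts])
    return GM(samples, parts[0].variants.copy(), calls)


@dataclass
class QMatrix:
    """Per-individual ancestry proportions with EM diagnostics.

    ``q`` rows lie on the simplex; ``loglik_trace`` is the total
    log-likelihood after each EM sweep (non-decreasing by construction).
    """

    individuals: list[str]
    components: list[str]
    q: np.ndarray
    loglik_trace: np.ndarray
    converged: np.ndarray  # per-individual

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.q, columns=self.components)
        df.insert(0, "individual", self.individuals)
        return df


def supervised_q(
    gm: GenotypeMatrix,
    F: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> QMatrix:
    """EM estimation of ancestry proportions with fixed component frequencies.

    Maximizes the binomial admixture log-likelihood per individual over the
    simplex via multiplicative updates; missing genotypes are skipped
    per site. Convergence: total log-likelihood gain < *tol* per sweep (each
    individual also tracked separately against *max_iter*).
    """
    comps = list(F.index)
    K = len(comps)
    Fm = np.clip(F.to_numpy(dtype=float), FREQ_CLAMP, 1 - FREQ_CLAMP)  # (K, V)
    if Fm.shape[1] != gm.n_variants:
        raise AncestryError("F does not match the genotype variant set")
    g = gm.calls.astype(float)
    obs = gm.calls != MISSING
    g = np.where(obs, g, 0.0)
    two_minus_g = np.where(obs, 2.0 - g, 0.0)
    S = obs.sum(axis=1).astype(float)  # non-missing sites per individual
    if np.any(S == 0):
        raise AncestryError("individual(s) with no called genotypes")
    n = gm.n_samples
    if K == 1:
        q = np.ones((n, 1))
        ll = _admixture_loglik(g, two_minus_g, q, Fm)
        return QMatrix(gm.samples["id"].tolist(), comps, q, np.array([ll]), np.ones(n, bool))
    q = np.full((n, K), 1.0 / K)
    trace = [_admixture_loglik(g, two_minus_g, q, Fm)]
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        P = q @ Fm  # (n, V) expected allele_b dose probability
        P = np.clip(P, FREQ_CLAMP, 1 - FREQ_CLAMP)
        term = (g / P) @ Fm.T + (two_minus_g / (1.0 - P)) @ (1.0 - Fm).T  # (n, K)
        q_new = q * term / (2.0 * S[:, None])
        q_new /= q_new.sum(axis=1, keepdims=True)
        q = q_new
        ll = _admixture_loglik(g, two_minus_g, q, Fm)
        gain = ll - trace[-1]
        trace.append(ll)
        if gain < tol:
            converged[:] = True
            break
    return QMatrix(gm.samples["id"].tolist(), comps, q, np.array(trace), converged)


def _admixture_loglik(g, two_minus_g, q, Fm) -> float:
    P = np.clip(q @ Fm, FREQ_CLAMP, 1 - FREQ_CLAMP)
    return float(np.sum(g * np.log(P) + two_minus_g * np.log(1.0 - P)))
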