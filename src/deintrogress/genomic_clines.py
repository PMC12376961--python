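"""Locus-specific introgression tests via genomic clines.

For each locus the three genotype categories (0, 1 or 2 copies of the
reference allele) are regressed on the genome-wide hybrid index h by
multinomial logistic regression. The neutral expectation — each of an
individual's two allele copies is of hatchery ancestry with probability h,
then carries the reference allele at the corresponding parental frequency —
gives category probabilities ((1-m)^2, 2m(1-m), m^2) with
m = h*pH + (1-h)*pW. The deviance of the fitted cline against this neutral
model is calibrated against refits of neutral simulated cohorts; significant
loci are called "reduced" or "increased" introgression by the sign of the
mean observed-minus-expected hatchery-allele dosage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .popgen import AlleleFreqs, fdr_adjust, per_locus_theta, rank_discriminating_loci

__all__ = [
    "ClineFit",
    "select_informative_loci",
    "fit_genomic_cline",
    "fit_clines",
    "simulate_neutral_null",
    "classify_introgression",
]

_RIDGE = 1e-6  # tiny L2 penalty keeps separated fits finite; identical in null refits


@dataclass
class ClineFit:
    locus_id: str
    coef: np.ndarray               # (2, 2): rows = categories 1,2 vs 0; cols = (intercept, slope on h)
    loglik_fitted: float
    loglik_neutral: float
    deviance_vs_neutral: float
    direction_statistic: float     # mean(observed - neutral-expected HAT-allele dosage)
    n_used: int
    degenerate: bool               # single observed genotype category
    p_value: float = np.nan
    q_value: float = np.nan
    verdict: str = "untested"      # reduced | increased | neutral | untested

    def genotype_probs(self, h: np.ndarray) -> np.ndarray:
        """Fitted category probabilities (len(h) x 3); rows sum to 1."""
        h = np.asarray(h, dtype=float)
        eta = self.coef[:, 0][None, :] + self.coef[:, 1][None, :] * h[:, None]
        expeta = np.exp(eta - eta.max(axis=1, keepdims=True).clip(min=0))
        denom = np.exp(-eta.max(axis=1, keepdims=True).clip(min=0)) + expeta.sum(axis=1, keepdims=True)
        p12 = expeta / denom
        p0 = 1.0 - p12.sum(axis=1, keepdims=True)
        return np.hstack([p0, p12])


# ---------------------------------------------------------------------------
# Informative-locus selection
# ---------------------------------------------------------------------------

def select_informative_loci(
    gm: GenotypeMatrix,
    wild_ref: Sequence[str],
    hat_ref: Sequence[str],
    loading_top_frac: float = 0.05,
    fst_min: float = 0.03,
    external_outliers: Sequence[str] = (),
) -> pd.DataFrame:
    """Union of three informativeness criteria with per-locus provenance.

    (a) top ``loading_top_frac`` between-reference discriminating loci,
    (b) per-locus theta between references above ``fst_min``,
    (c) an externally supplied outlier list.
    Returns a frame (locus_id, top_loading, fst_above_min, external) holding
    only retained loci, in matrix order.
    """
    if not len(wild_ref) or not len(hat_ref):
        raise ValueError("reference groups must be non-empty")
    top = set(rank_discriminating_loci(gm, wild_ref, hat_ref, loading_top_frac))
    theta = per_locus_theta(gm, wild_ref, hat_ref)
    known = set(gm.locus_ids)
    unknown_ext = set(external_outliers) - known
    if unknown_ext:
        raise ValueError(f"external outliers not in matrix: {sorted(unknown_ext)[:5]}")
    ext = set(external_outliers)
    rows = []
    for j, lid in enumerate(gm.locus_ids):
        crit = (
            lid in top,
            bool(~np.isnan(theta[j]) and theta[j] > fst_min),
            lid in ext,
        )
        if any(crit):
            rows.append((lid, *crit))
    if not rows:
        raise ValueError("no locus satisfies any informativeness criterion")
    return pd.DataFrame(
        rows, columns=["locus_id", "top_loading", "fst_above_min", "external"]
    )


# ---------------------------------------------------------------------------
# Multinomial cline fit (batched Newton)
# ---------------------------------------------------------------------------

def _fit_multinomial_batch(
    h: np.ndarray,
    G: np.ndarray,
    W: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-7,
    beta_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """ML multinomial-logit fit of genotype category on h for many loci at once.

    h: (n,) predictor; G: (n, L) categories in {0,1,2}; W: (n, L) 0/1 weights.
    Linear predictor eta_k = a_k + b_k*h for categories k=1,2 against
    reference category 0. Returns (beta (L,2,2), loglik (L,)). A tiny ridge
    penalty keeps perfectly separated fits finite; the returned loglik is the
    unpenalised one.
    """
    n, L = G.shape
    X = np.stack([np.ones_like(h), h], axis=1)              # (n, 2)
    Y = np.stack([G == 1, G == 2], axis=2).astype(float)    # (n, L, 2)
    beta = np.zeros((L, 2, 2)) if beta_init is None else beta_init.copy()
    XXT = np.einsum("nc,nd->ncd", X, X)                     # (n, 2, 2)

    def probs(beta):
        eta = np.einsum("nc,lkc->nlk", X, beta)             # (n, L, 2)
        emax = np.clip(eta.max(axis=2, keepdims=True), 0, None)
        ex = np.exp(eta - emax)
        denom = np.exp(-emax[..., 0]) + ex.sum(axis=2)      # (n, L)
        return ex / denom[..., None], denom, emax[..., 0]

    def penalised_ll(beta):
        P, denom, emax = probs(beta)
        eta = np.einsum("nc,lkc->nlk", X, beta)
        ll = (Y * eta).sum(axis=2) - (np.log(denom) + emax)
        return (W * ll).sum(axis=0) - 0.5 * _RIDGE * (beta**2).sum(axis=(1, 2))

    ll = penalised_ll(beta)
    for _ in range(max_iter):
        P, _, _ = probs(beta)
        R = (Y - P) * W[:, :, None]                         # (n, L, 2)
        grad = np.einsum("nlk,nc->lkc", R, X) - _RIDGE * beta
        # Hessian blocks H[(k,c),(k',c')] = -sum_i w P_k (delta - P_k') X_c X_c'
        PW = P * W[:, :, None]
        Hkk = np.einsum("nlk,ncd->lkcd", PW * (1 - P), XXT)
        Hcross = np.einsum("nl,ncd->lcd", PW[..., 0] * P[..., 1], XXT)
        Hfull = np.zeros((L, 4, 4))
        Hfull[:, 0:2, 0:2] = Hkk[:, 0]
        Hfull[:, 2:4, 2:4] = Hkk[:, 1]
        Hfull[:, 0:2, 2:4] = -Hcross
        Hfull[:, 2:4, 0:2] = -Hcross.transpose(0, 2, 1)
        Hfull += _RIDGE * np.eye(4)[None, :, :]
        g_flat = grad.reshape(L, 4)
        try:
            step = np.linalg.solve(Hfull, g_flat[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.linalg.solve(Hfull + 1e-6 * np.eye(4)[None], g_flat[..., None])[..., 0]
        new_beta = beta + step.reshape(L, 2, 2)
        new_ll = penalised_ll(new_beta)
        # per-locus step halving where the penalised objective worsened
        worse = new_ll < ll - 1e-12
        halvings = 0
        while worse.any() and halvings < 20:
            step[worse] *= 0.5
            new_beta = beta + step.reshape(L, 2, 2)
            new_ll = penalised_ll(new_beta)
            worse = new_ll < ll - 1e-12
            halvings += 1
        improved = new_ll >= ll
        beta = np.where(improved[:, None, None], new_beta, beta)
        gain = np.where(improved, new_ll - ll, 0.0)
        ll = np.where(improved, new_ll, ll)
        if gain.max(initial=0.0) < tol:
            break
    # unpenalised loglik
    P, denom, emax = probs(beta)
    eta = np.einsum("nc,lkc->nlk", X, beta)
    ll_raw = ((Y * eta).sum(axis=2) - (np.log(denom) + emax)) * W
    return beta, ll_raw.sum(axis=0)


def _neutral_loglik_and_direction(
    h: np.ndarray, G: np.ndarray, W: np.ndarray, p_w: np.ndarray, p_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Neutral-model category loglik and mean HAT-allele dosage departure.

    The departure is oriented on the hatchery-associated allele (the allele
    more frequent in the hatchery pool), so a negative value always means the
    hatchery variant is under-represented regardless of which allele the
    dosage happens to count.
    """
    m = np.clip(h[:, None] * p_h[None, :] + (1 - h[:, None]) * p_w[None, :], 1e-9, 1 - 1e-9)
    ll_cat = np.select(
        [G == 0, G == 1, G == 2],
        [2 * np.log1p(-m), np.log(2 * m * (1 - m)), 2 * np.log(m)],
    )
    ll = (W * ll_cat).sum(axis=0)
    orient = np.sign(p_h - p_w)  # reference-allele departure -> HAT-allele departure
    with np.errstate(invalid="ignore"):
        direction = orient * np.where(
            W.sum(axis=0) > 0,
            (W * (G - 2 * m)).sum(axis=0) / np.maximum(W.sum(axis=0), 1),
            np.nan,
        )
    return ll, direction


def fit_clines(
    gm: GenotypeMatrix,
    h: np.ndarray,
    wild_freqs: AlleleFreqs,
    hat_freqs: AlleleFreqs,
    loci: Sequence[str] | None = None,
    min_individuals: int = 10,
) -> list[ClineFit]:
    """Fit genomic clines for a set of loci against one hybrid-index vector."""
    h = np.asarray(h, dtype=float)
    if len(h) != gm.n_individuals:
        raise ValueError("h must align with matrix individuals")
    sub = gm if loci is None else gm.subset(loci=list(loci))
    lut = {lid: j for j, lid in enumerate(wild_freqs.locus_ids)}
    cols = [lut[lid] for lid in sub.locus_ids]
    p_w = np.asarray(wild_freqs.freq, float)[cols]
    p_h = np.asarray(hat_freqs.freq, float)[cols]
    ok_ind = ~np.isnan(h)
    G = sub.dosage.astype(float)
    W = ((~sub.missing) & ok_ind[:, None]).astype(float)
    n_used = W.sum(axis=0).astype(int)
    if (n_used < min_individuals).all():
        raise ValueError(f"no locus with >= {min_individuals} usable individuals")
    h_safe = np.where(ok_ind, h, 0.0)
    beta, ll_fit = _fit_multinomial_batch(h_safe, G, W)
    ll_neu, direction = _neutral_loglik_and_direction(h_safe, G, W, p_w, p_h)
    fits = []
    for j, lid in enumerate(sub.locus_ids):
        cats = {int(c) for c in G[W[:, j] > 0, j]}
        fits.append(
            ClineFit(
                locus_id=lid,
                coef=beta[j],
                loglik_fitted=float(ll_fit[j]),
                loglik_neutral=float(ll_neu[j]),
                deviance_vs_neutral=float(2 * (ll_fit[j] - ll_neu[j])),
                direction_statistic=float(direction[j]),
                n_used=int(n_used[j]),
                degenerate=len(cats) <= 1,
            )
        )
    return fits


def fit_genomic_cline(
    genotypes: np.ndarray,
    h: np.ndarray,
    p_wild: float,
    p_hat: float,
    locus_id: str = "locus",
    min_individuals: int = 10,
) -> ClineFit:
    """Single-locus convenience wrapper around :func:`fit_clines` internals."""
    g = np.asarray(genotypes, dtype=float)
    h = np.asarray(h, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(h)
    if ok.sum() < min_individuals:
        raise ValueError(f"need >= {min_individuals} individuals with h and genotype")
    G = np.where(ok, g, 0.0)[:, None]
    W = ok.astype(float)[:, None]
    h_safe = np.where(ok, h, 0.0)
    beta, ll_fit = _fit_multinomial_batch(h_safe, G, W)
    ll_neu, direction = _neutral_loglik_and_direction(
        h_safe, G, W, np.array([p_wild]), np.array([p_hat])
    )
    cats = {int(c) for c in G[W[:, 0] > 0, 0]}
    return ClineFit(
        locus_id=locus_id,
        coef=beta[0],
        loglik_fitted=float(ll_fit[0]),
        loglik_neutral=float(ll_neu[0]),
        deviance_vs_neutral=float(2 * (ll_fit[0] - ll_neu[0])),
        direction_statistic=float(direction[0]),
        n_used=int(W.sum()),
        degenerate=len(cats) <= 1,
    )


# ---------------------------------------------------------------------------
# Neutral null
# ---------------------------------------------------------------------------

@dataclass
class NeutralNull:
    locus_ids: list[str]
    deviance: np.ndarray    # (n_refits, L)
    direction: np.ndarray   # (n_refits, L)
    n_individuals: int
    cohort_size: int


def simulate_neutral_null(
    h_values: np.ndarray,
    wild_freqs: AlleleFreqs,
    hat_freqs: AlleleFreqs,
    loci: Sequence[str] | None = None,
    n_individuals: int = 2000,
    n_refits: int = 999,
    cohort_size: int | None = None,
    seed: int | None = None,
) -> NeutralNull:
    """Simulated neutral-admixture null distributions of deviance and direction.

    A pool of ``n_individuals`` admixed genotypes is simulated by resampling
    the observed hybrid-index distribution and drawing each allele copy from
    the parental frequency of its (Bernoulli-h) ancestry. Observed-cohort-
    sized subsamples of the pool are refit with the same cline model to build
    per-locus null distributions.
    """
    h_obs = np.asarray(h_values, dtype=float)
    h_obs = h_obs[~np.isnan(h_obs)]
    if len(h_obs) == 0:
        raise ValueError("no defined h values")
    if cohort_size is None:
        cohort_size = len(h_obs)
    if cohort_size > n_individuals:
        raise ValueError("cohort_size exceeds simulated pool size")
    lids = list(loci) if loci is not None else list(wild_freqs.locus_ids)
    lut = {lid: j for j, lid in enumerate(wild_freqs.locus_ids)}
    cols = [lut[lid] for lid in lids]
    p_w = np.asarray(wild_freqs.freq, float)[cols]
    p_h = np.asarray(hat_freqs.freq, float)[cols]

    rng = np.random.default_rng(seed)
    h_pool = rng.choice(h_obs, size=n_individuals, replace=True)
    m = np.clip(h_pool[:, None] * p_h[None, :] + (1 - h_pool[:, None]) * p_w[None, :], 0, 1)
    G_pool = rng.binomial(2, m).astype(float)

    L = len(lids)
    # warm start every refit from the pooled-population fit
    beta_pool, _ = _fit_multinomial_batch(h_pool, G_pool, np.ones_like(G_pool))
    dev = np.empty((n_refits, L))
    direc = np.empty((n_refits, L))
    for b in range(n_refits):
        idx = rng.choice(n_individuals, size=cohort_size, replace=False)
        h_sub = h_pool[idx]
        G_sub = G_pool[idx]
        W = np.ones_like(G_sub)
        _, ll_fit = _fit_multinomial_batch(h_sub, G_sub, W, beta_init=beta_pool)
        ll_neu, d = _neutral_loglik_and_direction(h_sub, G_sub, W, p_w, p_h)
        dev[b] = 2 * (ll_fit - ll_neu)
        direc[b] = d
    return NeutralNull(
        locus_ids=lids,
        deviance=dev,
        direction=direc,
        n_individuals=n_individuals,
        cohort_size=cohort_size,
    )


# ---------------------------------------------------------------------------
# Verdicts
# ---------------------------------------------------------------------------

def classify_introgression(
    fits: Sequence[ClineFit],
    null: NeutralNull,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Complete cline fits with permutation p-values, FDR and verdicts.

    The p-value is the two-sided rank of the observed deviance in the
    locus-specific null distribution; after BH adjustment across tested loci,
    significant loci are called "reduced" (direction statistic < 0, hatchery
    allele under-represented) or "increased" (> 0); everything else is
    neutral.
    """
    if null.deviance.shape[0] < 500:
        raise ValueError("null distribution needs >= 500 replicates")
    lut = {lid: j for j, lid in enumerate(null.locus_ids)}
    pvals = []
    for fit in fits:
        j = lut[fit.locus_id]
        col = null.deviance[:, j]
        if np.allclose(col, col[0]):
            raise ValueError(f"zero-variance null at locus {fit.locus_id}")
        B = len(col)
        p_hi = (1 + np.sum(col >= fit.deviance_vs_neutral - 1e-12)) / (B + 1)
        p_lo = (1 + np.sum(col <= fit.deviance_vs_neutral + 1e-12)) / (B + 1)
        pvals.append(min(1.0, 2 * min(p_hi, p_lo)))
    qvals = fdr_adjust(pvals)
    rows = []
    for fit, p, q in zip(fits, pvals, qvals):
        fit.p_value = float(p)
        fit.q_value = float(q)
        if q < alpha and fit.direction_statistic < 0:
            fit.verdict = "reduced"
        elif q < alpha and fit.direction_statistic > 0:
            fit.verdict = "increased"
        else:
            fit.verdict = "neutral"
        rows.append(
            (
                fit.locus_id,
                fit.deviance_vs_neutral,
                fit.direction_statistic,
                fit.p_value,
                fit.q_value,
                fit.verdict,
                fit.n_used,
                fit.degenerate,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "deviance",
            "direction_statistic",
            "p_value",
            "q_value",
            "verdict",
            "n_used",
            "degenerate",
        ],
    )
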