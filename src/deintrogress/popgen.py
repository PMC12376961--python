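"""Population-genetic summary statistics.

Allele frequencies, expected heterozygosity (unbiased gene diversity),
Hardy-Weinberg exact tests, Weir & Cockerham's theta (FST) with bootstrap
confidence intervals, permutation G tests of sample differentiation, PCA of
the dosage matrix, ranking of between-group discriminating loci, and
Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotype_io import CollectionMeta, GenotypeMatrix, meta_by_sample

__all__ = [
    "AlleleFreqs",
    "ThetaResult",
    "allele_freqs",
    "expected_heterozygosity",
    "hwe_exact",
    "wc_theta",
    "g_test_differentiation",
    "pca",
    "rank_discriminating_loci",
    "fdr_adjust",
]


@dataclass
class AlleleFreqs:
    """Per-locus reference-allele frequencies within one collection.

    ``freq`` is NaN where ``n_alleles`` is zero (no non-missing calls).
    """

    collection_label: str
    locus_ids: list[str]
    freq: np.ndarray
    n_alleles: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_alleles = np.asarray(self.n_alleles, dtype=int)
        defined = self.n_alleles > 0
        if np.any((self.freq[defined] < 0) | (self.freq[defined] > 1)):
            raise ValueError("allele frequency outside [0, 1]")


def _group_members(
    gm: GenotypeMatrix, meta: Sequence[CollectionMeta]
) -> dict[str, list[str]]:
    bysample = meta_by_sample(meta)
    groups: dict[str, list[str]] = {}
    for s in gm.individuals:
        groups.setdefault(bysample[s].collection_label, []).append(s)
    return groups


def allele_freqs(
    gm: GenotypeMatrix,
    meta: Sequence[CollectionMeta] | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, AlleleFreqs]:
    """Reference-allele frequency per locus per collection.

    Groups come either from metadata (collection_label) or an explicit
    label -> sample_ids mapping.
    """
    if groups is None:
        if meta is None:
            raise ValueError("need either meta or explicit groups")
        groups = _group_members(gm, meta)
    out: dict[str, AlleleFreqs] = {}
    for label, members in groups.items():
        if not len(members):
            raise ValueError(f"empty group {label!r}")
        sub = gm.subset(list(members))
        n_alleles = 2 * (~sub.missing).sum(axis=0)
        dose_sum = np.where(~sub.missing, sub.dosage, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            freq = np.where(n_alleles > 0, dose_sum / np.maximum(n_alleles, 1), np.nan)
        out[label] = AlleleFreqs(label, gm.locus_ids, freq, n_alleles)
    return out


def expected_heterozygosity(freqs: AlleleFreqs) -> float:
    """Mean unbiased expected heterozygosity over defined loci.

    Per locus: 2p(1-p) * n/(n-1) with n the number of non-missing allele
    copies (Nei's small-sample correction), averaged over loci with n >= 2.
    """
    ok = freqs.n_alleles >= 2
    if not ok.any():
        raise ValueError("no locus with enough data for heterozygosity")
    p = freqs.freq[ok]
    n = freqs.n_alleles[ok].astype(float)
    h = 2 * p * (1 - p) * n / (n - 1)
    return float(h.mean())


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_exact_pvalue(n_het: int, n_ref: int, n_total: int) -> float:
    """Two-sided exact conditional HWE test (probability ordering).

    ``n_het`` observed heterozygotes, ``n_ref`` reference-allele copies,
    ``n_total`` diploid individuals. Enumerates every heterozygote count
    compatible with the allele counts (Levene/Haldane distribution) and sums
    probabilities <= that of the observed table.
    """
    n_alt = 2 * n_total - n_ref
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het | n_ref) up to a shared constant
    logp = np.array(
        [
            h * np.log(2.0)
            - lgamma((n_ref - h) / 2 + 1)
            - lgamma(h + 1)
            - lgamma((n_alt - h) / 2 + 1)
            for h in hets
        ]
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs = p[np.searchsorted(hets, n_het)]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def hwe_exact(
    gm: GenotypeMatrix,
    meta: Sequence[CollectionMeta] | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Exact HWE p-values per locus per collection.

    Returns a tidy frame (collection, locus_id, n, p_value, monomorphic).
    Monomorphic loci get p = 1 with a flag. Loci with fewer than two
    non-missing individuals in a collection get NaN.
    """
    if groups is None:
        if meta is None:
            raise ValueError("need either meta or explicit groups")
        groups = _group_members(gm, meta)
    rows = []
    for label, members in groups.items():
        sub = gm.subset(list(members))
        for j, lid in enumerate(gm.locus_ids):
            obs = sub.dosage[~sub.missing[:, j], j]
            n = len(obs)
            if n < 2:
                rows.append((label, lid, n, np.nan, False))
                continue
            n_ref = int(obs.sum())
            mono = n_ref == 0 or n_ref == 2 * n
            pval = 1.0 if mono else _hwe_exact_pvalue(int((obs == 1).sum()), n_ref, n)
            rows.append((label, lid, n, pval, mono))
    return pd.DataFrame(
        rows, columns=["collection", "locus_id", "n", "p_value", "monomorphic"]
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

@dataclass
class ThetaResult:
    pops: tuple[str, ...]
    theta_multilocus: float
    theta_per_locus: np.ndarray
    locus_ids: list[str]
    ci_low: float | None = None
    ci_high: float | None = None
    n_bootstrap: int = 0
    ci_level: float = 0.95


def _wc_components(
    dosage: np.ndarray, missing: np.ndarray, pop_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    ``pop_idx`` holds row indices per population. Returns arrays of shape
    (n_loci,); loci with < 2 populations containing data yield zeros.
    """
    r = len(pop_idx)
    L = dosage.shape[1]
    n_i = np.zeros((r, L))
    p_i = np.zeros((r, L))
    h_i = np.zeros((r, L))
    for k, rows in enumerate(pop_idx):
        d = dosage[rows]
        m = missing[rows]
        cnt = (~m).sum(axis=0)
        n_i[k] = cnt
        with np.errstate(invalid="ignore"):
            p_i[k] = np.where(cnt > 0, np.where(~m, d, 0).sum(axis=0) / (2 * np.maximum(cnt, 1)), 0.0)
            h_i[k] = np.where(
                cnt > 0, np.where(~m, d == 1, False).sum(axis=0) / np.maximum(cnt, 1), 0.0
            )
    # treat populations without data at a locus as absent (weights zero)
    present = n_i > 0
    r_eff = present.sum(axis=0).astype(float)
    nbar = n_i.sum(axis=0) / np.maximum(r_eff, 1)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i**2).sum(axis=0) / np.maximum(nsum, 1e-300)) / np.maximum(
            r_eff - 1, 1e-300
        )
        pbar = (n_i * p_i).sum(axis=0) / np.maximum(nsum, 1e-300)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / np.maximum(
            (r_eff - 1) * nbar, 1e-300
        )
        hbar = (n_i * h_i).sum(axis=0) / np.maximum(nsum, 1e-300)
        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2
            - (pbar * (1 - pbar) - (r_eff - 1) / r_eff * s2 - hbar / 4)
            / np.maximum(nbar - 1, 1e-300)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            pbar * (1 - pbar)
            - (r_eff - 1) / r_eff * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = r_eff < 2
    a[bad] = b[bad] = c[bad] = 0.0
    return a, b, c


def wc_theta(
    gm: GenotypeMatrix,
    pops: Mapping[str, Sequence[str]],
    n_bootstrap: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> ThetaResult:
    """Weir & Cockerham's theta across >= 2 collections.

    The multi-locus estimate is the ratio of summed variance components
    (sum a / sum (a+b+c)); per-locus estimates are reported as computed and
    may be negative. Confidence intervals are percentile bootstrap over
    individuals resampled within populations.
    """
    labels = tuple(pops)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    pop_idx = []
    for lab in labels:
        members = list(pops[lab])
        if len(members) < 2:
            raise ValueError(f"population {lab!r} has fewer than 2 individuals")
        pop_idx.append(np.array([gm.individual_index(s) for s in members], dtype=int))

    def estimate(idx_list: list[np.ndarray]) -> tuple[float, np.ndarray]:
        a, b, c = _wc_components(gm.dosage, gm.missing, idx_list)
        denom = a + b + c
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
        total = denom.sum()
        multi = float(a.sum() / total) if total != 0 else np.nan
        return multi, per_locus

    multi, per_locus = estimate(pop_idx)
    ci_low = ci_high = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b_i in range(n_bootstrap):
            res = [rng.choice(idx, size=len(idx), replace=True) for idx in pop_idx]
            boots[b_i], _ = estimate(res)
        alpha = 1 - ci_level
        ci_low, ci_high = np.nanpercentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        # resampling individuals inflates differentiation slightly at small n;
        # widen so the interval always contains the point estimate
        ci_low = float(min(ci_low, multi))
        ci_high = float(max(ci_high, multi))
    return ThetaResult(
        pops=labels,
        theta_multilocus=multi,
        theta_per_locus=per_locus,
        locus_ids=gm.locus_ids,
        ci_low=ci_low,
        ci_high=ci_high,
        n_bootstrap=n_bootstrap,
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# G test of sample differentiation
# ---------------------------------------------------------------------------

def _g_stats(dosage, missing, mask_a) -> np.ndarray:
    """Per-locus G statistic of the 2x2 allele-count table between two groups."""
    counts = []
    for mask in (mask_a, ~mask_a):
        d = dosage[mask]
        m = missing[mask]
        ref = np.where(~m, d, 0).sum(axis=0).astype(float)
        tot = 2.0 * (~m).sum(axis=0)
        counts.append((ref, tot - ref))
    obs = np.stack([counts[0][0], counts[0][1], counts[1][0], counts[1][1]])  # (4, L)
    row = np.stack([obs[0] + obs[1], obs[2] + obs[3]])
    col = np.stack([obs[0] + obs[2], obs[1] + obs[3]])
    total = row.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        exp = np.stack(
            [
                row[0] * col[0],
                row[0] * col[1],
                row[1] * col[0],
                row[1] * col[1],
            ]
        ) / np.maximum(total, 1e-300)
        terms = np.where(obs > 0, obs * np.log(np.maximum(obs, 1e-300) / np.maximum(exp, 1e-300)), 0.0)
    return 2.0 * terms.sum(axis=0)


def g_test_differentiation(
    gm: GenotypeMatrix,
    pop_a: Sequence[str],
    pop_b: Sequence[str],
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Permutation G test per locus plus Fisher-combined p across loci.

    Individuals are permuted across the two collections; per-locus p-values
    are (1 + #{G_perm >= G_obs}) / (n_perm + 1). Loci monomorphic across both
    collections are excluded from the Fisher combination.
    """
    if not len(pop_a) or not len(pop_b):
        raise ValueError("both collections must be non-empty")
    sub = gm.subset(list(pop_a) + list(pop_b))
    mask_a = np.zeros(sub.n_individuals, dtype=bool)
    mask_a[: len(pop_a)] = True
    g_obs = _g_stats(sub.dosage, sub.missing, mask_a)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(sub.n_loci)
    for _ in range(n_perm):
        perm = rng.permutation(sub.n_individuals)
        exceed += _g_stats(sub.dosage[perm], sub.missing[perm], mask_a) >= g_obs - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    ref = np.where(~sub.missing, sub.dosage, 0).sum(axis=0)
    tot = 2 * (~sub.missing).sum(axis=0)
    poly = (ref > 0) & (ref < tot)
    table = pd.DataFrame(
        {"locus_id": sub.locus_ids, "g_stat": g_obs, "p_value": pvals, "polymorphic": poly}
    )
    if poly.any():
        chi2 = -2.0 * np.log(pvals[poly]).sum()
        combined = float(stats.chi2.sf(chi2, 2 * int(poly.sum())))
    else:
        combined = np.nan
    return table, combined


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: np.ndarray        # individuals x axes
    loadings: np.ndarray           # loci x axes
    explained_variance_ratio: np.ndarray
    individuals: list[str]
    locus_ids: list[str]


def pca(gm: GenotypeMatrix, scale: bool = False, n_axes: int | None = None) -> PCAResult:
    """Principal components of the centered dosage matrix.

    Missing cells are mean-imputed per locus. With ``scale=True`` columns are
    divided by sqrt(p(1-p)) (Patterson scaling).
    """
    if gm.n_individuals < 2 or gm.n_loci < 2:
        raise ValueError("PCA needs >= 2 individuals and >= 2 loci")
    d = gm.dosage.astype(float)
    d[gm.missing] = np.nan
    if np.isnan(d).all(axis=0).any():
        raise ValueError("locus with no data; filter before PCA")
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean, d) - mean
    if scale:
        p = mean / 2
        denom = np.sqrt(np.maximum(p * (1 - p), 1e-12))
        d = d / denom
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else var
    k = len(s) if n_axes is None else min(n_axes, len(s))
    return PCAResult(
        coordinates=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        explained_variance_ratio=ratio[:k],
        individuals=gm.individuals,
        locus_ids=gm.locus_ids,
    )


# ---------------------------------------------------------------------------
# Locus ranking + FDR
# ---------------------------------------------------------------------------

def per_locus_theta(
    gm: GenotypeMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> np.ndarray:
    """Per-locus Weir-Cockerham theta between two groups (NaN where undefined)."""
    idx = [
        np.array([gm.individual_index(s) for s in group_a], dtype=int),
        np.array([gm.individual_index(s) for s in group_b], dtype=int),
    ]
    a, b, c = _wc_components(gm.dosage, gm.missing, idx)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)


def rank_discriminating_loci(
    gm: GenotypeMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    top_frac: float = 0.05,
) -> list[str]:
    """Loci ranked by between-group differentiation (per-locus theta), top fraction.

    Fills the role of picking the strongest between-group discriminators
    (upper PC-loading fraction in a discriminant analysis); here ranked by
    per-locus theta directly. Ties and NaNs resolve by input order (stable sort,
    NaN last).
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both groups must be non-empty")
    if not (0 < top_frac <= 1):
        raise ValueError("top_frac must lie in (0, 1]")
    theta = per_locus_theta(gm, group_a, group_b)
    key = np.where(np.isnan(theta), -np.inf, theta)
    order = np.argsort(-key, kind="stable")
    n_top = max(1, int(np.ceil(top_frac * gm.n_loci)))
    return [gm.locus_ids[j] for j in order[:n_top]]


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
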