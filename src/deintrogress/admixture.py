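"""Two-source admixture-coefficient estimation.

Model: individual i has an admixture coefficient q_i, the proportion of its
genome derived from the hatchery (HAT) source. At each locus its two allele
copies are independently of HAT origin with probability q_i; a HAT-derived
copy carries the reference allele with probability p_H (the HAT cluster
frequency), a wild-derived copy with probability p_W. The reference-allele
dosage g at a locus is therefore Binomial(2, m) with
m = q * p_H + (1 - q) * p_W, and loci are independent given q.

``estimate_admixture`` maximises the joint likelihood over all q and both
cluster frequency vectors by EM (reference individuals pinned to q = 0 or 1
anchor the labels). ``hybrid_index`` maximises the same likelihood per
individual with cluster frequencies frozen at supplied parental tables — the
hybrid-index h of a genomic-cline analysis is exactly q under frozen
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .popgen import AlleleFreqs

__all__ = [
    "AdmixtureFit",
    "HybridIndex",
    "estimate_admixture",
    "hybrid_index",
    "compare_panels",
]

_EPS_FREQ = 1e-6  # cluster frequencies are kept off the 0/1 boundary


@dataclass
class AdmixtureFit:
    individuals: list[str]
    q: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    cluster_freqs: tuple[AlleleFreqs, AlleleFreqs]  # (wild-side, hatchery-side)
    loglik: float
    n_restarts: int
    converged: bool
    n_loci_used: np.ndarray  # non-missing loci per individual

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.individuals,
                "q": self.q,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_loci_used": self.n_loci_used,
            }
        )


@dataclass
class HybridIndex:
    individuals: list[str]
    h: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    undefined: np.ndarray  # True where no informative non-missing locus
    wild_freqs: AlleleFreqs
    hat_freqs: AlleleFreqs


def _loglik(g, miss, q, p_w, p_h) -> float:
    """Joint log-likelihood; includes the binomial coefficient (log 2 for hets)."""
    m = np.clip(q[:, None] * p_h + (1 - q[:, None]) * p_w, 1e-12, 1 - 1e-12)
    ll = g * np.log(m) + (2 - g) * np.log1p(-m) + (g == 1) * np.log(2.0)
    return float(np.where(miss, 0.0, ll).sum())


def _em_q_update(g, miss, q, p_w, p_h):
    """One E+M step for q with frozen frequencies; returns (new q, per-copy posteriors)."""
    m = np.clip(q[:, None] * p_h + (1 - q[:, None]) * p_w, 1e-12, 1 - 1e-12)
    a_ref = q[:, None] * p_h / m
    a_non = q[:, None] * (1 - p_h) / (1 - m)
    e_hat = np.where(miss, 0.0, g * a_ref + (2 - g) * a_non)
    copies = 2.0 * (~miss).sum(axis=1)
    with np.errstate(invalid="ignore"):
        q_new = np.where(copies > 0, e_hat.sum(axis=1) / np.maximum(copies, 1), np.nan)
    return q_new, (a_ref, a_non, m)


def estimate_admixture(
    gm: GenotypeMatrix,
    reference_labels: Mapping[str, str],
    hat_freqs: AlleleFreqs | None = None,
    n_restarts: int = 5,
    max_iter: int = 300,
    tol: float = 1e-5,
    n_bootstrap: int = 200,
    ci_level: float = 0.90,
    seed: int | None = None,
) -> AdmixtureFit:
    """Supervised K=2 admixture estimation by EM.

    ``reference_labels`` maps sample_id to one of {"wild_ref", "hat_ref",
    "unknown"}; reference individuals are pinned at q = 0 / q = 1 and anchor
    which cluster is "hatchery". At least one hat_ref individual (or a
    supplied ``hat_freqs`` table) is required — without any anchor the model
    is unidentifiable up to label swap.

    Restarts jitter the frequency initialisation; the best log-likelihood is
    kept and ``converged`` records whether all restarts agreed on q to within
    0.01. Per-individual CIs are percentile bootstrap over loci with cluster
    frequencies frozen at the fitted values.
    """
    roles = {s: reference_labels.get(s, "unknown") for s in gm.individuals}
    bad = {r for r in roles.values() if r not in ("wild_ref", "hat_ref", "unknown")}
    if bad:
        raise ValueError(f"unknown reference labels: {sorted(bad)}")
    is_hat = np.array([roles[s] == "hat_ref" for s in gm.individuals])
    is_wild = np.array([roles[s] == "wild_ref" for s in gm.individuals])
    is_unknown = ~(is_hat | is_wild)
    if not is_hat.any() and hat_freqs is None:
        raise ValueError(
            "no hatchery anchor: supply hat_ref individuals or a hat_freqs table"
        )
    if not is_unknown.any():
        raise ValueError("no unknown individuals to estimate")

    g = gm.dosage.astype(float)
    miss = gm.missing
    n, L = g.shape
    rng = np.random.default_rng(seed)

    # initial frequencies from whatever anchors exist
    def counts(mask):
        if not mask.any():
            return None
        sel = mask[:, None] & ~miss
        tot = 2.0 * sel.sum(axis=0)
        ref = np.where(sel, g, 0.0).sum(axis=0)
        return np.where(tot > 0, (ref + 0.5) / (tot + 1.0), 0.5)

    p_h0 = counts(is_hat)
    if p_h0 is None:
        p_h0 = np.asarray(hat_freqs.freq, dtype=float)
    p_w0 = counts(is_wild)
    if p_w0 is None:
        # no wild anchor: start the wild cluster from the pooled unknowns
        p_w0 = counts(is_unknown)

    best = None
    q_runs = []
    for r in range(n_restarts):
        if r == 0:
            p_w, p_h = p_w0.copy(), p_h0.copy()
        else:
            p_w = np.clip(p_w0 + rng.normal(0, 0.02, L), 0.02, 0.98)
            p_h = np.clip(p_h0 + rng.normal(0, 0.02, L), 0.02, 0.98)
        q = np.full(n, 0.5)
        q[is_hat] = 1.0
        q[is_wild] = 0.0
        p_w = np.clip(p_w, _EPS_FREQ, 1 - _EPS_FREQ)
        p_h = np.clip(p_h, _EPS_FREQ, 1 - _EPS_FREQ)

        W = (~miss).astype(float)
        Gm = g * W                      # masked ref-allele copies
        G2 = (2.0 - g) * W              # masked alt-allele copies
        copies = 2.0 * W.sum(axis=1)
        col_ref = Gm.sum(axis=0)
        col_all = Gm.sum(axis=0) + G2.sum(axis=0)
        for _ in range(max_iter):
            # E-step: posterior hatchery ancestry per ref / non-ref allele copy
            m = q[:, None] * (p_h - p_w) + p_w
            a_ref = (q[:, None] * p_h) / m
            a_non = (q[:, None] * (1 - p_h)) / (1 - m)
            hr = Gm * a_ref
            hn = G2 * a_non
            with np.errstate(invalid="ignore"):
                q_new = np.where(
                    copies > 0, (hr.sum(axis=1) + hn.sum(axis=1)) / np.maximum(copies, 1), q
                )
            q_new[is_hat] = 1.0
            q_new[is_wild] = 0.0
            # M-step: cluster frequencies from fractional-ancestry copy counts
            hat_ref_copies = hr.sum(axis=0)
            hat_all_copies = hat_ref_copies + hn.sum(axis=0)
            wild_ref_copies = col_ref - hat_ref_copies
            wild_all_copies = col_all - hat_all_copies
            p_h = np.clip(
                np.where(hat_all_copies > 0, hat_ref_copies / np.maximum(hat_all_copies, 1e-12), p_h),
                _EPS_FREQ,
                1 - _EPS_FREQ,
            )
            p_w = np.clip(
                np.where(wild_all_copies > 0, wild_ref_copies / np.maximum(wild_all_copies, 1e-12), p_w),
                _EPS_FREQ,
                1 - _EPS_FREQ,
            )
            q_new = np.clip(q_new, 0.0, 1.0)
            dq = float(np.max(np.abs(q_new - q)))
            q = q_new
            if dq < tol:
                break
        ll_prev = _loglik(g, miss, q, p_w, p_h)
        q_runs.append(q.copy())
        if best is None or ll_prev > best[0]:
            best = (ll_prev, q.copy(), p_w.copy(), p_h.copy())

    ll_best, q, p_w, p_h = best
    spread = max(
        (float(np.abs(qr - q).max()) for qr in q_runs), default=0.0
    )
    converged = spread < 0.01

    # CIs: bootstrap over loci, q re-maximised with frozen cluster frequencies
    alpha = 1 - ci_level
    ci_low = q.copy()
    ci_high = q.copy()
    if n_bootstrap > 0:
        qs = np.empty((n_bootstrap, n))
        for b in range(n_bootstrap):
            cols = rng.integers(0, L, size=L)
            qs[b] = _solve_q(
                g[:, cols], miss[:, cols], p_w[cols], p_h[cols], q_init=q
            )
        ci_low = np.percentile(qs, 100 * alpha / 2, axis=0)
        ci_high = np.percentile(qs, 100 * (1 - alpha / 2), axis=0)
        ci_low = np.minimum(ci_low, q)
        ci_high = np.maximum(ci_high, q)

    wild_af = AlleleFreqs("cluster_wild", gm.locus_ids, p_w, np.full(L, 2 * n))
    hat_af = AlleleFreqs("cluster_hat", gm.locus_ids, p_h, np.full(L, 2 * n))
    return AdmixtureFit(
        individuals=gm.individuals,
        q=q,
        ci_low=ci_low,
        ci_high=ci_high,
        cluster_freqs=(wild_af, hat_af),
        loglik=ll_best,
        n_restarts=n_restarts,
        converged=converged,
        n_loci_used=(~miss).sum(axis=1),
    )


def _solve_q(g, miss, p_w, p_h, q_init=None, max_iter=300, tol=1e-9) -> np.ndarray:
    """Per-individual ML of q with frozen frequencies (vectorised EM fixed point)."""
    n = g.shape[0]
    q = np.full(n, 0.5) if q_init is None else np.clip(np.asarray(q_init, float).copy(), 0.0, 1.0)
    for _ in range(max_iter):
        q_new, _ = _em_q_update(g, miss, q, p_w, p_h)
        q_new = np.where(np.isnan(q_new), q, np.clip(q_new, 0.0, 1.0))
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    return q


def hybrid_index(
    gm: GenotypeMatrix,
    wild_freqs: AlleleFreqs,
    hat_freqs: AlleleFreqs,
    n_bootstrap: int = 0,
    ci_level: float = 0.90,
    seed: int | None = None,
) -> HybridIndex:
    """Maximum-likelihood hybrid index under fixed parental allele frequencies."""
    p_w = np.clip(np.asarray(wild_freqs.freq, float), _EPS_FREQ, 1 - _EPS_FREQ)
    p_h = np.clip(np.asarray(hat_freqs.freq, float), _EPS_FREQ, 1 - _EPS_FREQ)
    if len(p_w) != gm.n_loci or len(p_h) != gm.n_loci:
        raise ValueError("frequency tables must cover every locus in the matrix")
    g = gm.dosage.astype(float)
    miss = gm.missing
    informative = np.abs(p_w - p_h) > 1e-12
    usable = (~miss) & informative[None, :]
    undefined = ~usable.any(axis=1)
    h = _solve_q(g, miss, p_w, p_h)
    h[undefined] = np.nan
    ci_low, ci_high = h.copy(), h.copy()
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        L = gm.n_loci
        hs = np.empty((n_bootstrap, gm.n_individuals))
        for b in range(n_bootstrap):
            cols = rng.integers(0, L, size=L)
            hs[b] = _solve_q(g[:, cols], miss[:, cols], p_w[cols], p_h[cols], q_init=h)
        alpha = 1 - ci_level
        ci_low = np.nanpercentile(hs, 100 * alpha / 2, axis=0)
        ci_high = np.nanpercentile(hs, 100 * (1 - alpha / 2), axis=0)
    return HybridIndex(
        individuals=gm.individuals,
        h=h,
        ci_low=ci_low,
        ci_high=ci_high,
        undefined=undefined,
        wild_freqs=wild_freqs,
        hat_freqs=hat_freqs,
    )


@dataclass
class PanelComparison:
    pairs: pd.DataFrame  # sample_id, q_full, q_subset
    r_squared: float
    slope: float
    intercept: float


def compare_panels(fit_full: AdmixtureFit, fit_subset: AdmixtureFit) -> PanelComparison:
    """Pair q estimates from two marker panels on shared individuals.

    Returns the paired values, squared Pearson correlation and the
    least-squares regression (subset on full).
    """
    shared = [s for s in fit_full.individuals if s in set(fit_subset.individuals)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared individuals")
    idx_f = {s: i for i, s in enumerate(fit_full.individuals)}
    idx_s = {s: i for i, s in enumerate(fit_subset.individuals)}
    x = np.array([fit_full.q[idx_f[s]] for s in shared])
    y = np.array([fit_subset.q[idx_s[s]] for s in shared])
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return PanelComparison(
        pairs=pd.DataFrame({"sample_id": shared, "q_full": x, "q_subset": y}),
        r_squared=float(r**2),
        slope=float(slope),
        intercept=float(intercept),
    )
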