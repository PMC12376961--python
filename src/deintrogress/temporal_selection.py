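"""Drift-versus-selection likelihood-ratio scan over temporal allele counts.

Per locus, observed allele counts at sampled generations are modelled by a
hidden-Markov Wright-Fisher chain: the hidden state is the population count
of the reference allele (0 .. 2Ne), per-generation transitions are binomial
draws of 2Ne copies at the post-selection frequency p* = p(1+s)/(1+ps)
(genic selection, fitness 1+s on the reference allele), and each sample of n
allele copies is a binomial emission at the current state frequency. The
initial state distribution is the posterior of a uniform prior over states
given the first sample; the first sample is conditioned on, not scored.

The drift model is s = 0; the alternative maximises s over a grid refined by
bounded scalar optimisation, and the LRT 2*(ll_sel - ll_drift) is referred
to a chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import CollectionMeta, GenotypeMatrix
from .popgen import fdr_adjust

__all__ = [
    "TemporalSeries",
    "SelectionTestResult",
    "years_to_generations",
    "wf_loglik",
    "fit_selection",
    "scan_selection",
]

DEFAULT_S_GRID = np.round(np.arange(-0.5, 0.5 + 1e-9, 0.01), 10)


@dataclass(frozen=True)
class TemporalSeries:
    """Ordered (generation, alleles_sampled, ref_allele_count) observations."""

    locus_id: str
    observations: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        gens = [o[0] for o in self.observations]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise ValueError("generation indices must be strictly increasing")
        for g, n, x in self.observations:
            if not (0 <= x <= n):
                raise ValueError(f"count {x} outside [0, {n}] at generation {g}")

    def is_monomorphic(self) -> bool:
        """True when every sample is fixed for the same allele."""
        counts = [(n, x) for _, n, x in self.observations]
        return all(x == 0 for n, x in counts) or all(x == n for n, x in counts)


@dataclass
class SelectionTestResult:
    locus_id: str
    Ne: int
    s_hat: float
    loglik_drift: float
    loglik_sel: float
    lrt: float
    p_value: float
    q_value: float = np.nan
    flagged: bool = False  # unidentifiable (monomorphic) series


# ---------------------------------------------------------------------------
# Generations
# ---------------------------------------------------------------------------

def years_to_generations(
    years: Sequence[float], generation_time: float = 3.5
) -> np.ndarray:
    """Map calendar years to integer generation indices (round to nearest).

    Collections whose years round to the same index share that index and are
    meant to be pooled by the caller.
    """
    years = np.asarray(years, dtype=float)
    if np.any(np.diff(years) < 0):
        raise ValueError("years must be non-decreasing")
    if len(years) == 0:
        return np.array([], dtype=int)
    return np.rint((years - years[0]) / generation_time).astype(int)


# ---------------------------------------------------------------------------
# Forward likelihood
# ---------------------------------------------------------------------------

_TRANSITION_CACHE: dict[tuple[int, float], np.ndarray] = {}


def _transition_matrix(Ne: int, s: float) -> np.ndarray:
    """Row-stochastic 2Ne+1 state transition matrix under drift + genic selection."""
    key = (Ne, round(float(s), 12))
    cached = _TRANSITION_CACHE.get(key)
    if cached is not None:
        return cached
    K = 2 * Ne
    p = np.arange(K + 1) / K
    p_star = p * (1 + s) / (1 + p * s)
    k = np.arange(K + 1)
    T = stats.binom.pmf(k[None, :], K, p_star[:, None])
    if len(_TRANSITION_CACHE) > 64:
        _TRANSITION_CACHE.clear()
    _TRANSITION_CACHE[key] = T
    return T


def _emissions(Ne: int, obs: Sequence[tuple[int, int, int]]) -> list[np.ndarray]:
    p = np.arange(2 * Ne + 1) / (2 * Ne)
    return [stats.binom.pmf(x, n, p) for _, n, x in obs]


def wf_loglik(series: TemporalSeries, Ne: int, s: float) -> float:
    """Log-probability of all observations after the first, given Ne and s."""
    if Ne < 2:
        raise ValueError("Ne must be >= 2")
    if not (-1 < s < 1):
        raise ValueError("|s| must be < 1")
    obs = series.observations
    if len(obs) < 1:
        raise ValueError("empty series")
    emis = _emissions(Ne, obs)
    alpha = emis[0].copy()  # uniform prior over states x first-sample likelihood
    total = alpha.sum()
    if total <= 0:
        raise ValueError("first sample impossible under every state")
    alpha /= total
    if len(obs) == 1:
        return 0.0
    T = _transition_matrix(Ne, s)
    ll = 0.0
    prev_gen = obs[0][0]
    for t in range(1, len(obs)):
        gen = obs[t][0]
        for _ in range(gen - prev_gen):
            alpha = alpha @ T
        alpha = alpha * emis[t]
        step = alpha.sum()
        if step <= 0:
            return -np.inf
        ll += np.log(step)
        alpha /= step
        prev_gen = gen
    return float(ll)


def _forward_batch(
    obs_matrix: list[tuple[int, np.ndarray, np.ndarray]],
    Ne: int,
    s: float,
) -> np.ndarray:
    """Forward log-likelihoods for many loci sharing a sampling schedule.

    ``obs_matrix`` is a list of (generation, n_vector, x_vector) with vectors
    over loci. Loci with n = 0 at a time point contribute no emission there.
    """
    K = 2 * Ne
    p = np.arange(K + 1) / K
    gens = [g for g, _, _ in obs_matrix]
    L = len(obs_matrix[0][1])

    def emis(n_vec, x_vec):
        e = stats.binom.pmf(x_vec[:, None], n_vec[:, None], p[None, :])
        return np.where(n_vec[:, None] > 0, e, 1.0)  # no data -> flat emission

    alpha = emis(obs_matrix[0][1], obs_matrix[0][2])
    total = alpha.sum(axis=1, keepdims=True)
    alpha = alpha / np.maximum(total, 1e-300)
    ll = np.zeros(L)
    T = _transition_matrix(Ne, s)
    prev = gens[0]
    for t in range(1, len(obs_matrix)):
        for _ in range(gens[t] - prev):
            alpha = alpha @ T
        alpha = alpha * emis(obs_matrix[t][1], obs_matrix[t][2])
        step = alpha.sum(axis=1)
        ll += np.log(np.maximum(step, 1e-300))
        alpha = alpha / np.maximum(step[:, None], 1e-300)
        prev = gens[t]
    return ll


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_selection(
    series: TemporalSeries,
    Ne: int,
    s_grid: np.ndarray = DEFAULT_S_GRID,
    refine: bool = True,
) -> SelectionTestResult:
    """Grid-plus-refinement ML of s and drift-vs-selection LRT for one locus."""
    if len(series.observations) < 2:
        raise ValueError("need >= 2 observations")
    if series.is_monomorphic():
        ll0 = wf_loglik(series, Ne, 0.0)
        return SelectionTestResult(
            locus_id=series.locus_id,
            Ne=Ne,
            s_hat=0.0,
            loglik_drift=ll0,
            loglik_sel=ll0,
            lrt=0.0,
            p_value=1.0,
            flagged=True,
        )
    lls = np.array([wf_loglik(series, Ne, s) for s in s_grid])
    ll_drift = wf_loglik(series, Ne, 0.0)
    best = int(np.argmax(lls))
    s_hat, ll_sel = float(s_grid[best]), float(lls[best])
    if refine:
        lo = s_grid[max(best - 1, 0)]
        hi = s_grid[min(best + 1, len(s_grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda s: -wf_loglik(series, Ne, s),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-4, "maxiter": 30},
            )
            if -res.fun > ll_sel:
                s_hat, ll_sel = float(res.x), float(-res.fun)
    lrt = max(0.0, 2.0 * (ll_sel - ll_drift))
    return SelectionTestResult(
        locus_id=series.locus_id,
        Ne=Ne,
        s_hat=s_hat,
        loglik_drift=ll_drift,
        loglik_sel=ll_sel,
        lrt=lrt,
        p_value=float(stats.chi2.sf(lrt, 1)),
    )


def fit_selection_many(
    series_list: Sequence[TemporalSeries],
    Ne: int,
    s_grid: np.ndarray = DEFAULT_S_GRID,
    refine: bool = True,
) -> list[SelectionTestResult]:
    """Fit many loci sharing one sampling schedule (vectorised grid stage)."""
    if not series_list:
        return []
    gens = [o[0] for o in series_list[0].observations]
    if any([o[0] for o in s.observations] != gens for s in series_list):
        # fall back to per-locus fits when schedules differ
        return [fit_selection(s, Ne, s_grid, refine) for s in series_list]
    obs_matrix = [
        (
            g,
            np.array([s.observations[t][1] for s in series_list]),
            np.array([s.observations[t][2] for s in series_list]),
        )
        for t, g in enumerate(gens)
    ]
    grid_ll = np.stack([_forward_batch(obs_matrix, Ne, s) for s in s_grid])  # (S, L)
    ll_drift = _forward_batch(obs_matrix, Ne, 0.0)
    results = []
    for j, series in enumerate(series_list):
        if series.is_monomorphic():
            results.append(
                SelectionTestResult(
                    series.locus_id, Ne, 0.0, ll_drift[j], ll_drift[j], 0.0, 1.0,
                    flagged=True,
                )
            )
            continue
        best = int(np.argmax(grid_ll[:, j]))
        s_hat, ll_sel = float(s_grid[best]), float(grid_ll[best, j])
        if refine:
            lo = s_grid[max(best - 1, 0)]
            hi = s_grid[min(best + 1, len(s_grid) - 1)]
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda s: -wf_loglik(series, Ne, s),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-4, "maxiter": 30},
                )
                if -res.fun > ll_sel:
                    s_hat, ll_sel = float(res.x), float(-res.fun)
        lrt = max(0.0, 2.0 * (ll_sel - ll_drift[j]))
        results.append(
            SelectionTestResult(
                series.locus_id,
                Ne,
                s_hat,
                float(ll_drift[j]),
                ll_sel,
                lrt,
                float(stats.chi2.sf(lrt, 1)),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def build_temporal_series(
    gm: GenotypeMatrix,
    meta: Sequence[CollectionMeta],
    include_samples: Sequence[str],
    generation_time: float = 3.5,
) -> list[TemporalSeries]:
    """Per-locus allele-count series over pooled generations.

    Collections are mapped to generation indices from their years (rounded at
    ``generation_time``); collections landing on the same index are pooled.
    """
    bysample = {m.sample_id: m for m in meta}
    include = [s for s in include_samples if s in gm._ind_index]
    if not include:
        raise ValueError("no included samples present in matrix")
    years = sorted({bysample[s].year for s in include})
    gen_of_year = dict(zip(years, years_to_generations(years, generation_time)))
    gens = sorted(set(gen_of_year.values()))
    if len(gens) < 2:
        raise ValueError("fewer than 2 pooled generations; temporal scan impossible")
    rows_by_gen = {
        g: [gm.individual_index(s) for s in include if gen_of_year[bysample[s].year] == g]
        for g in gens
    }
    series = []
    counts = {}
    for g in gens:
        rows = np.array(rows_by_gen[g], dtype=int)
        sub_d = gm.dosage[rows]
        sub_m = gm.missing[rows]
        n = 2 * (~sub_m).sum(axis=0)
        x = np.where(~sub_m, sub_d, 0).sum(axis=0)
        counts[g] = (n, x)
    for j, lid in enumerate(gm.locus_ids):
        obs = tuple(
            (g, int(counts[g][0][j]), int(counts[g][1][j]))
            for g in gens
            if counts[g][0][j] > 0
        )
        if len(obs) >= 2:
            series.append(TemporalSeries(lid, obs))
    return series


def scan_selection(
    gm: GenotypeMatrix,
    meta: Sequence[CollectionMeta],
    hybrid_class: Mapping[str, str],
    Ne_list: Sequence[int] = (100, 200),
    generation_time: float = 3.5,
    s_grid: np.ndarray = DEFAULT_S_GRID,
    alpha: float = 0.05,
    keep_classes: Sequence[str] = ("WILD", "BC_WILD", "F1"),
) -> pd.DataFrame:
    """Per-locus drift-vs-selection LRT scan over temporal collections.

    Restricts to individuals whose hybrid class is wild, low- or medium-
    admixed (WILD / BC_WILD / F1 intervals), pools collections by generation,
    fits each locus under every Ne scenario and BH-adjusts p-values within
    each scenario. ``outlier`` marks q_value < alpha.
    """
    include = [
        s for s in gm.individuals if hybrid_class.get(s) in set(keep_classes)
    ]
    series = build_temporal_series(gm, meta, include, generation_time)
    frames = []
    for Ne in Ne_list:
        results = fit_selection_many(series, Ne, s_grid)
        df = pd.DataFrame(
            {
                "locus_id": [r.locus_id for r in results],
                "Ne": Ne,
                "s_hat": [r.s_hat for r in results],
                "lrt": [r.lrt for r in results],
                "p_value": [r.p_value for r in results],
                "flagged": [r.flagged for r in results],
            }
        )
        testable = ~df["flagged"]
        q = np.full(len(df), np.nan)
        q[testable.to_numpy()] = fdr_adjust(df.loc[testable, "p_value"].to_numpy())
        df["q_value"] = q
        df["outlier"] = df["q_value"] < alpha
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
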