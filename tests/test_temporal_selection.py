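"""Wright-Fisher forward likelihood, selection LRT and the temporal scan."""

import itertools

import numpy as np
import pytest
from scipy import stats

from deintrogress.genotype_io import CollectionMeta
from deintrogress.temporal_selection import (
    TemporalSeries,
    build_temporal_series,
    fit_selection,
    fit_selection_many,
    scan_selection,
    wf_loglik,
    years_to_generations,
)

from conftest import make_gm


def _simulate_locus(rng, Ne, s, p0, n_gens=6, n_alleles=60):
    """Forward-simulate one locus and return its sampled TemporalSeries."""
    K = 2 * Ne
    cnt = rng.binomial(K, p0)
    obs = []
    for g in range(n_gens):
        p = cnt / K
        obs.append((g, n_alleles, int(rng.binomial(n_alleles, p))))
        p_star = p * (1 + s) / (1 + p * s)
        cnt = rng.binomial(K, p_star)
    return TemporalSeries("sim", tuple(obs))


class TestYearsToGenerations:
    @pytest.mark.parametrize(
        "years,expected",
        [
            ((2001, 2010), [0, 3]),     # round(9 / 3.5) = 3
            ((2004, 2004), [0, 0]),     # same year pools to one index
            ((2004, 2024), [0, 6]),     # round(20 / 3.5) = 6
            ((2001, 2004, 2010, 2024), [0, 1, 3, 7]),
        ],
    )
    def test_examples(self, years, expected):
        assert list(years_to_generations(years)) == expected

    def test_decreasing_years_error(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            years_to_generations([2010, 2001])


class TestWfLoglik:
    def _brute_force(self, series, Ne, s):
        """Exhaustive summation over all hidden state paths."""
        K = 2 * Ne
        p = np.arange(K + 1) / K
        obs = series.observations
        gens = [o[0] for o in obs]
        init = stats.binom.pmf(obs[0][2], obs[0][1], p)
        init = init / init.sum()
        p_star = p * (1 + s) / (1 + p * s)
        T = stats.binom.pmf(np.arange(K + 1)[None, :], K, p_star[:, None])
        total_steps = gens[-1] - gens[0]
        tot = 0.0
        for start in range(K + 1):
            for path in itertools.product(range(K + 1), repeat=total_steps):
                states = [start] + list(path)
                pr = init[start]
                for a, b in zip(states, states[1:]):
                    pr *= T[a, b]
                for t in range(1, len(obs)):
                    g, n, x = obs[t]
                    pr *= stats.binom.pmf(x, n, p[states[g - gens[0]]])
                tot += pr
        return np.log(tot)

    @pytest.mark.parametrize("Ne,s", [(2, 0.0), (2, 0.3), (2, -0.2), (3, 0.15)])
    def test_matches_path_enumeration(self, Ne, s):
        series = TemporalSeries("l", ((0, 10, 4), (2, 12, 7), (3, 8, 2)))
        assert wf_loglik(series, Ne, s) == pytest.approx(
            self._brute_force(series, Ne, s), abs=1e-10
        )

    def test_stable_data_prefers_no_selection(self):
        series = TemporalSeries("l", ((0, 200, 100), (1, 200, 100)))
        assert wf_loglik(series, 100, 0.0) > wf_loglik(series, 100, 0.5)

    def test_single_observation_zero(self):
        assert wf_loglik(TemporalSeries("l", ((0, 30, 12),)), 50, 0.2) == 0.0

    def test_polarity_flip_reparameterisation(self):
        series = TemporalSeries("l", ((0, 40, 13), (1, 36, 20), (3, 44, 30)))
        flipped = TemporalSeries(
            "l", tuple((g, n, n - x) for g, n, x in series.observations)
        )
        for s in (0.0, 0.25, -0.3):
            s_prime = -s / (1 + s)
            assert wf_loglik(series, 20, s) == pytest.approx(
                wf_loglik(flipped, 20, s_prime), abs=1e-9
            )


class TestFitSelection:
    def test_lrt_nonnegative_and_chisq_pvalue(self):
        rng = np.random.default_rng(20)
        series = _simulate_locus(rng, 100, 0.2, 0.4)
        res = fit_selection(series, 100)
        assert res.lrt >= 0
        assert res.p_value == pytest.approx(stats.chi2.sf(res.lrt, 1))
        assert -0.5 <= res.s_hat <= 0.5

    def test_monomorphic_flagged(self):
        series = TemporalSeries("l", ((0, 20, 0), (2, 30, 0)))
        res = fit_selection(series, 100)
        assert res.flagged and res.p_value == 1.0 and res.s_hat == 0.0

    def test_null_calibration(self):
        # drift-only data: empirical type-I near nominal (scaled-down replicate
        # count here; the full 500-locus check runs in the acceptance suite)
        rng = np.random.default_rng(21)
        null = [_simulate_locus(rng, 200, 0.0, rng.uniform(0.2, 0.8)) for _ in range(120)]
        res = fit_selection_many(null, 200)
        pv = np.array([r.p_value for r in res if not r.flagged])
        assert 0.005 <= (pv < 0.05).mean() <= 0.12

    def test_sign_recovery_under_strong_selection(self):
        rng = np.random.default_rng(22)
        sims = [_simulate_locus(rng, 200, 0.3, 0.5) for _ in range(40)]
        res = fit_selection_many(sims, 200)
        assert np.mean([r.s_hat > 0 for r in res]) >= 0.9

    def test_batched_fit_equals_scalar_fit(self):
        rng = np.random.default_rng(23)
        sims = [_simulate_locus(rng, 50, 0.1, 0.5, n_gens=4, n_alleles=30) for _ in range(5)]
        grid = np.round(np.arange(-0.3, 0.31, 0.05), 10)
        many = fit_selection_many(sims, 50, s_grid=grid, refine=False)
        for series, r in zip(sims, many):
            single = fit_selection(series, 50, s_grid=grid, refine=False)
            assert r.s_hat == pytest.approx(single.s_hat)
            assert r.lrt == pytest.approx(single.lrt, abs=1e-9)


class TestScan:
    def _temporal_dataset(self, rng, n_loci=12, n_per=15):
        years = [2001, 2008, 2015]
        rows, meta = [], []
        for yi, year in enumerate(years):
            p = 0.5 - 0.05 * yi
            geno = rng.binomial(2, p, size=(n_per, n_loci))
            for i in range(n_per):
                sid = f"y{year}_{i}"
                rows.append(geno[i])
                meta.append(CollectionMeta(sid, f"c{year}", "river", year, "wild_caught"))
        from deintrogress.genotype_io import GenotypeMatrix, LocusInfo

        loci = [LocusInfo(f"L{j}", ("A", "B")) for j in range(n_loci)]
        gm = GenotypeMatrix([m.sample_id for m in meta], loci, np.vstack(rows))
        return gm, meta

    def test_series_pooling_by_generation(self):
        rng = np.random.default_rng(24)
        gm, meta = self._temporal_dataset(rng)
        series = build_temporal_series(gm, meta, [m.sample_id for m in meta])
        gens = [o[0] for o in series[0].observations]
        assert gens == [0, 2, 4]  # 2001, 2008, 2015 at 3.5 y/generation
        assert series[0].observations[0][1] == 30  # 15 individuals x 2

    def test_scan_restricts_classes_and_adjusts_fdr(self):
        rng = np.random.default_rng(25)
        gm, meta = self._temporal_dataset(rng)
        classes = {m.sample_id: ("WILD" if i % 2 else "HAT") for i, m in enumerate(meta)}
        scan = scan_selection(gm, meta, classes, Ne_list=[50], s_grid=np.round(np.arange(-0.3, 0.31, 0.05), 10))
        assert set(scan["Ne"]) == {50}
        testable = scan[~scan["flagged"]]
        assert (testable["q_value"] >= testable["p_value"] - 1e-12).all()

    def test_scan_recovers_selected_loci_in_stocking_scenario(self):
        """A one-pulse stocking scenario with five moderately differentiated
        loci under s = 0.25 against the hatchery allele: the Ne = 200 scan
        recovers most of them after FDR with few false positives."""
        from deintrogress.synthetic_data import (
            ScenarioConfig,
            SelectedLocus,
            simulate_stocking_scenario,
        )

        cfg = ScenarioConfig(
            n_loci=288,
            Ne=200,
            generations=8,
            stocking_schedule=(0.5,),
            selected_loci=tuple(SelectedLocus(j, 0.25) for j in range(5)),
            selected_freqs=(0.3, 0.7),
            sampling_schedule=tuple((g, 100) for g in range(1, 9)),
            rivers=("R1",),
            seed=78,
        )
        gm, meta, truth = simulate_stocking_scenario(cfg)
        wild_ids = [m.sample_id for m in meta if m.role == "wild_caught"]
        classes = {s: "F1" for s in wild_ids}  # whole cohort in scan classes
        scan = scan_selection(gm.subset(wild_ids), meta, classes, Ne_list=[200])
        true_sel = {truth.locus_ids[s.locus_index] for s in truth.selected}
        outliers = set(scan.loc[scan["outlier"].fillna(False), "locus_id"])
        assert len(outliers & true_sel) >= 3
        assert len(outliers - true_sel) <= 3  # enrichment, not noise

    def test_too_few_generations_error(self):
        rng = np.random.default_rng(26)
        gm, meta = self._temporal_dataset(rng)
        same_year = [m for m in meta if m.year == 2001]
        with pytest.raises(ValueError, match="fewer than 2"):
            build_temporal_series(gm, meta, [m.sample_id for m in same_year])
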