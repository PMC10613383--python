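import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from degef.genome import GenomeLayout
from degef.scan import (
    NullModel,
    bh_correct,
    build_grid,
    call_clusters,
    empirical_pvalues,
    enrichment_scores,
    fit_null,
    run_scan,
    window_pvalue_count,
    window_pvalue_empirical,
)
from degef.scoring import ScanConfig, prepare_genes
from degef.synth import SynthSpec, generate_deg_table

from conftest import make_genes


class TestBuildGrid:
    def test_overlapping_windows_with_truncated_tail(self):
        layout = GenomeLayout({"A": 1000})
        grid = build_grid(layout, width=500, step=200)
        got = list(zip(grid.windows["start"], grid.windows["end"]))
        assert got == [(0, 500), (200, 700), (400, 900), (600, 1000),
                       (800, 1000)]

    def test_short_arm_single_truncated_window(self):
        layout = GenomeLayout({"A": 300})
        grid = build_grid(layout, width=500, step=300)
        got = list(zip(grid.windows["start"], grid.windows["end"]))
        assert got == [(0, 300)]

    def test_windows_never_cross_centromere(self, toy_layout):
        grid = build_grid(toy_layout, width=200, step=100)
        cen = toy_layout.centromere_interval("A")
        on_a = grid.windows[grid.windows["chrom"] == "A"]
        for _, w in on_a.iterrows():
            assert w["end"] <= cen.start or w["start"] >= cen.end

    def test_step_spacing_and_width_invariant(self, toy_layout):
        grid = build_grid(toy_layout, width=150, step=50)
        for _, sub in grid.windows.groupby("arm"):
            starts = sub["start"].to_numpy()
            assert np.all(np.diff(starts) == 50)
            widths = (sub["end"] - sub["start"]).to_numpy()
            # all full width except possibly truncated at the arm end
            assert np.all(widths[:-1] >= widths[1:] - 0)
            assert widths.max() <= 150

    def test_invalid_parameters(self, toy_layout):
        with pytest.raises(ValueError):
            build_grid(toy_layout, width=0, step=1)
        with pytest.raises(ValueError):
            build_grid(toy_layout, width=100, step=200)


class TestEnrichmentScores:
    def scores_track(self, toy_layout, genes, method="count",
                     direction="upregulated"):
        prepared = prepare_genes(genes, toy_layout)
        grid = build_grid(toy_layout, width=100, step=100)
        return enrichment_scores(grid, prepared, method, direction)

    def test_empty_window_and_direct_sum(self, toy_layout):
        genes = make_genes([
            ("g1", "A", 10, 2.0, 0.01),    # up, score 1
            ("g2", "A", 20, 0.1, 0.50),    # ns, score 0
            ("g3", "A", 30, 1.5, 0.02),    # up, score 1
        ])
        track = self.scores_track(toy_layout, genes)
        first = track.table.iloc[0]
        assert first["n"] == 3 and first["es"] == 2.0
        rest = track.table.iloc[1:]
        assert (rest["n"] == 0).all() and (rest["es"] == 0).all()

    def test_tss_move_past_window_end_brute_force(self, toy_layout):
        # moving one in-window gene's TSS past the window end must drop n
        # by one and es by its score, verified against a brute-force re-sum
        genes = make_genes([
            ("g1", "A", 50, 2.0, 0.01),
            ("g2", "A", 99, 3.0, 0.001),
            ("g3", "A", 150, 1.5, 0.02),
        ])
        moved = genes.copy()
        moved.loc[moved["gene_id"] == "g2", "tss"] = 100  # half-open exit

        def brute(gene_df, ws, we):
            prepared = prepare_genes(gene_df, toy_layout)
            from degef.scoring import raw_scores
            sc = raw_scores(prepared["status"], prepared["log2fc"],
                            prepared["fdr"], "foldchange", "upregulated")
            mask = ((prepared["chrom"] == "A") & (prepared["tss"] >= ws)
                    & (prepared["tss"] < we))
            return mask.sum(), sc[mask.to_numpy()].sum()

        for df in (genes, moved):
            track = self.scores_track(toy_layout, df, method="foldchange")
            w0 = track.table.iloc[0]
            n, es = brute(df, w0["start"], w0["end"])
            assert w0["n"] == n and w0["es"] == pytest.approx(es)
        t_before = self.scores_track(toy_layout, genes, method="foldchange")
        t_after = self.scores_track(toy_layout, moved, method="foldchange")
        assert t_before.table.iloc[0]["n"] - t_after.table.iloc[0]["n"] == 1
        assert t_before.table.iloc[0]["es"] - t_after.table.iloc[0]["es"] \
            == pytest.approx(3.0)

    def test_window_membership_ids(self, toy_layout):
        genes = make_genes([("g1", "A", 10, 2.0, 0.01),
                            ("g2", "B", 10, 0.0, 0.9)])
        track = self.scores_track(toy_layout, genes)
        assert track.window_gene_ids(0) == ["g1"]


class TestFitNull:
    def test_count_frequency(self, toy_layout):
        recs = [("g%d" % i, "A", 10 + i, 2.0, 0.01) for i in range(10)]
        recs += [("h%d" % i, "A", 100 + i, 0.0, 0.9) for i in range(90)]
        genes = prepare_genes(make_genes(recs), toy_layout)
        null = fit_null(genes, ScanConfig(method="count"))
        assert null.p_hat == pytest.approx(0.10)

    def test_degenerate_all_ns(self, toy_layout):
        genes = prepare_genes(
            make_genes([("g1", "A", 10, 0.0, 0.9), ("g2", "A", 20, 0.0, 0.8)]),
            toy_layout,
        )
        assert fit_null(genes, ScanConfig(method="count")).p_hat == 0.0
        null = fit_null(genes, ScanConfig(method="significance"))
        assert null.mu == 0.0 and null.sigma == 0.0

    def test_pool_moments_hand_computed(self, toy_layout):
        # raw scores {0, 0, 2, 4}: mu = 1.5, population sigma = sqrt(2.75)
        genes = make_genes([
            ("g1", "A", 10, 0.0, 0.9),
            ("g2", "A", 20, 0.0, 0.8),
            ("g3", "A", 30, 2.0, 0.01),
            ("g4", "A", 40, 4.0, 0.02),
        ])
        null = fit_null(prepare_genes(genes, toy_layout),
                        ScanConfig(method="foldchange"))
        assert null.mu == pytest.approx(1.5)
        assert null.sigma == pytest.approx(np.sqrt(2.75))

    def test_empty_table_rejected(self):
        empty = pd.DataFrame(columns=["status", "log2fc", "fdr"])
        with pytest.raises(ValueError):
            fit_null(empty, ScanConfig())


class TestCountPvalue:
    def null(self, p_hat):
        return NullModel(method="count", p_hat=p_hat)

    def test_survival_at_the_mean_is_half(self):
        assert window_pvalue_count(4.0, 20, self.null(0.2)) == pytest.approx(0.5)

    def test_gene_desert_is_never_significant(self):
        assert window_pvalue_count(0.0, 0, self.null(0.2)) == 1.0

    def test_degenerate_variance(self):
        assert window_pvalue_count(0.0, 10, self.null(0.0)) == 1.0
        assert window_pvalue_count(10.0, 10, self.null(1.0)) == 1.0

    def test_matches_numerically_integrated_gaussian(self):
        # oracle: direct numerical integration of the stated density
        es, n, p_hat = 8.0, 20, 0.2
        mean, var = n * p_hat, n * p_hat * (1 - p_hat)
        pdf = lambda x: np.exp(-((x - mean) ** 2) / (2 * var)) / np.sqrt(
            2 * np.pi * var
        )
        oracle, _ = integrate.quad(pdf, es, np.inf)
        got = window_pvalue_count(es, n, self.null(p_hat))
        assert got == pytest.approx(oracle, abs=1e-12)


class TestEmpiricalPvalue:
    def null(self, pool, t=30, x=6400):
        pool = np.asarray(pool, dtype=float)
        return NullModel(method="significance", pool=pool,
                         mu=float(pool.mean()), sigma=float(pool.std()),
                         t=t, x=x)

    def test_es_zero_with_nonnegative_pool(self):
        rng = np.random.default_rng(0)
        p = window_pvalue_empirical(0.0, 3, self.null([0, 0, 1, 2]), rng)
        assert p == 1.0

    def test_two_coin_enumeration(self):
        # pool {0, 1}, n = 2, es = 2: exact tail = 1/4 by enumeration
        rng = np.random.default_rng(1)
        null = self.null([0.0, 1.0], x=100_000)
        p = window_pvalue_empirical(2.0, 2, null, rng)
        se = np.sqrt(0.25 * 0.75 / null.x)
        assert abs(p - 0.25) < 3 * se + 2 / (null.x + 1)

    def test_seed_reproducibility(self):
        null = self.null(np.arange(10.0))
        p1 = window_pvalue_empirical(20.0, 4, null,
                                     np.random.default_rng(7))
        p2 = window_pvalue_empirical(20.0, 4, null,
                                     np.random.default_rng(7))
        assert p1 == p2

    def test_n_zero_and_clt_branch(self):
        null = self.null(np.arange(10.0), t=5)
        rng = np.random.default_rng(0)
        assert window_pvalue_empirical(1.0, 0, null, rng) == 1.0
        # n >= t takes the Gaussian branch: mean n*mu, sd sigma*sqrt(n)
        got = window_pvalue_empirical(30.0, 6, null, rng)
        want = stats.norm.sf(30.0, 6 * null.mu, null.sigma * np.sqrt(6))
        assert got == pytest.approx(want)

    def test_degenerate_sigma(self):
        null = self.null(np.full(5, 2.0), t=2)
        rng = np.random.default_rng(0)
        assert window_pvalue_empirical(5.9, 3, null, rng) == 1.0
        assert window_pvalue_empirical(6.1, 3, null, rng) == pytest.approx(
            1e-300
        )

    def test_batch_agrees_with_singles_in_distribution(self):
        # shared-null batch p-values match single-window calls within
        # bootstrap Monte-Carlo error
        rng = np.random.default_rng(3)
        pool = rng.exponential(1.0, 500)
        null = self.null(pool, x=20_000)
        es = np.array([3.0, 6.0, 9.0])
        n = np.array([4, 4, 4])
        batch = empirical_pvalues(es, n, null, np.random.default_rng(11))
        for e, pb in zip(es, batch):
            ps = window_pvalue_empirical(
                float(e), 4, null, np.random.default_rng(12)
            )
            se = np.sqrt(max(pb * (1 - pb), 1e-6) / null.x)
            assert abs(pb - ps) < 4 * se + 2 / null.x

    def test_clt_matches_bootstrap_above_switch(self):
        # for n >= t and a well-behaved pool the Gaussian tail tracks the
        # bootstrap within 0.02 between the 50th and 99.9th percentiles
        rng = np.random.default_rng(5)
        pool = rng.gamma(2.0, 1.0, 5000)
        null = self.null(pool, t=30, x=6400)
        n = 40
        sums = pool[rng.integers(0, len(pool), (150_000, n))].sum(axis=1)
        es_grid = np.quantile(sums, [0.5, 0.8, 0.9, 0.95, 0.99, 0.999])
        boot = np.array(
            [(1 + (sums >= e).sum()) / (1 + len(sums)) for e in es_grid]
        )
        gauss = stats.norm.sf(es_grid, n * null.mu, null.sigma * np.sqrt(n))
        assert np.max(np.abs(boot - gauss)) < 0.02


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(bh_correct([1.0, 1.0, 1.0]), 1.0)
        assert bh_correct([0.3])[0] == pytest.approx(0.3)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           )
    @settings(max_examples=300, derandomize=True)
    def test_matches_stepup_oracle(self, pvals):
        # independent hand-coded step-up: q_i = min over j >= i of
        # p_(j) * m / j, capped at 1
        p = np.asarray(pvals)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, m + 1)
        oracle_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(oracle_sorted, 1.0)
        np.testing.assert_allclose(bh_correct(p), oracle, atol=1e-12)

    def test_fdr_not_below_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        assert np.all(bh_correct(p) >= p - 1e-15)


class TestCallClusters:
    def track_with_fdr(self, toy_layout, fdr_by_index):
        genes = make_genes([("g1", "A", 10, 2.0, 0.01)])
        prepared = prepare_genes(genes, toy_layout)
        grid = build_grid(toy_layout, width=100, step=50)
        track = enrichment_scores(grid, prepared, "count", "upregulated")
        track.table["p"] = 1.0
        track.table["fdr"] = 1.0
        arm_a = track.table[track.table["arm"] == "A:p"]
        for idx, f in fdr_by_index.items():
            row = arm_a[arm_a["idx"] == idx].index[0]
            track.table.loc[row, "fdr"] = f
        return track

    def test_run_decomposition(self, toy_layout):
        track = self.track_with_fdr(
            toy_layout, {3: 0.01, 4: 0.02, 5: 0.01, 7: 0.03}
        )
        clusters = call_clusters(track, 0.05, "upregulated")
        spans = [(c.interval.start, c.interval.end) for c in clusters]
        assert len(clusters) == 2
        assert spans[0] == (150, 350)  # windows 3..5: [150,250)..[250,350)
        assert spans[1] == (350, 400)  # truncated window 7 alone

    def test_no_significant_windows(self, toy_layout):
        track = self.track_with_fdr(toy_layout, {})
        assert call_clusters(track, 0.05, "upregulated") == []

    def test_single_window_cluster_has_window_width(self, toy_layout):
        track = self.track_with_fdr(toy_layout, {0: 0.001})
        (c,) = call_clusters(track, 0.05, "upregulated")
        assert c.interval.length == 100
        assert c.min_fdr == pytest.approx(0.001)
        assert c.gene_ids == ["g1"] and c.de_gene_ids == ["g1"]

    @given(sig=st.lists(st.booleans(), min_size=1, max_size=40))
    @settings(max_examples=150, derandomize=True)
    def test_matches_run_oracle(self, sig):
        # brute-force run decomposition over one arm
        grid = build_grid(GenomeLayout({"C": 5000}), width=200, step=100)
        k = min(len(sig), len(grid.windows))
        fdr = np.ones(len(grid.windows))
        fdr[:k] = [0.01 if s else 0.9 for s in sig[:k]]
        genes = prepare_genes(make_genes([("g1", "C", 1, 2.0, 0.01)]),
                              GenomeLayout({"C": 5000}))
        from degef.scan import EnrichmentTrack
        table = grid.windows.copy()
        table["n"] = 0
        table["es"] = 0.0
        table["p"] = fdr
        table["fdr"] = fdr
        track = EnrichmentTrack(grid=grid, table=table, genes=genes,
                                lo=np.zeros(len(table), dtype=int),
                                hi=np.zeros(len(table), dtype=int))
        clusters = call_clusters(track, 0.05, "upregulated")
        runs = 0
        prev = False
        for s in (fdr < 0.05):
            if s and not prev:
                runs += 1
            prev = s
        assert len(clusters) == runs


class TestRunScan:
    def test_direction_symmetry_end_to_end(self):
        from degef.evaluation import direction_symmetry_check

        assert direction_symmetry_check(seed=2, method="count")
        assert direction_symmetry_check(seed=2, method="significance")

    def test_same_seed_is_deterministic(self):
        spec = SynthSpec(seed=9)
        genes, _ = generate_deg_table(spec)
        cfg = ScanConfig(method="foldchange", seed=9)
        t1, c1 = run_scan(genes, spec.layout, cfg)
        t2, c2 = run_scan(genes, spec.layout, cfg)
        assert t1.table.equals(t2.table)
        assert [(c.interval, c.min_fdr) for c in c1] == \
            [(c.interval, c.min_fdr) for c in c2]

    def test_fdr_never_below_p_on_real_track(self):
        spec = SynthSpec(seed=4)
        genes, _ = generate_deg_table(spec)
        track, _ = run_scan(genes, spec.layout, ScanConfig(seed=4))
        t = track.table
        assert np.all(t["fdr"] >= t["p"] - 1e-15)
        assert np.all((t["p"] >= 0) & (t["p"] <= 1))
        assert np.all(t["es"] >= 0)

    def test_count_calibration_at_dense_windows(self):
        # with ~40 genes per window the plain normal tail is close to
        # nominal; allow 2 points for binomial skew and ES discreteness
        fracs = []
        for seed in range(2):
            spec = SynthSpec(genes_per_mb=80.0, seed=seed)
            genes, _ = generate_deg_table(spec)
            track, _ = run_scan(genes, spec.layout,
                                ScanConfig(method="count", seed=seed))
            t = track.table[track.table["n"] >= 30]
            fracs.append(float((t["p"] < 0.05).mean()))
        assert np.mean(fracs) <= 0.07
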