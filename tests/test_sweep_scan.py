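"""Window construction, CLR scoring, candidate selection, and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from tetrapop import popgen_stats as pg
from tetrapop import sweep_scan as scan
from tetrapop import synthetic_data as syn
from tetrapop.inheritance_sim import InheritanceModel


def brute_force_tilted_clr(window_counts, background_props, n_grid=20001):
    """Grid-search oracle for the tilted composite likelihood ratio.

    Maximises the window log-likelihood over the exponential tilting
    parameter on a dense lambda grid, independently of the analytic
    implementation's concave optimiser.
    """
    cls = np.arange(1, background_props.size + 1, dtype=float)
    cls = cls - (cls * background_props).sum()

    def loglik(lam):
        x = np.log(background_props) + lam * cls
        x -= x.max()
        log_p = x - np.log(np.exp(x).sum())
        occ = window_counts > 0
        return (window_counts[occ] * log_p[occ]).sum()

    ll0 = loglik(0.0)
    best = max(loglik(lam) for lam in np.linspace(0.0, scan.LAMBDA_MAX, n_grid))
    return max(2 * (best - ll0), 0.0)


class TestWindows:
    def test_blocking_rule(self):
        ks = np.arange(250) % 46 + 1
        ws = scan.make_windows("g", ks)
        assert [w.n_snps for w in ws] == [100, 100, 50]
        assert [w.partial for w in ws] == [False, False, True]

    def test_short_gene_single_partial_window(self):
        ws = scan.make_windows("g", np.ones(40, dtype=int))
        assert len(ws) == 1 and ws[0].partial and ws[0].n_snps == 40

    def test_exactly_one_full_window(self):
        ws = scan.make_windows("g", np.ones(100, dtype=int))
        assert len(ws) == 1 and not ws[0].partial

    def test_no_snps_no_windows(self):
        assert scan.make_windows("g", np.array([], dtype=int)) == []

    def test_windows_follow_positional_order(self):
        ks = np.array([1, 2, 3, 4])
        pos = np.array([40, 10, 30, 20])
        ws = scan.make_windows("g", ks, positions=pos, window_snps=2)
        np.testing.assert_array_equal(ws[0].derived_counts, [2, 4])


class TestClr:
    def test_window_matching_background_scores_zero(self):
        bg = np.full(47, 1 / 47)
        counts = np.repeat(np.arange(1, 48), 2)  # uniform across classes
        w = scan.Window("g", 0, counts, partial=False)
        assert scan.clr_score(w, bg) == pytest.approx(0.0, abs=1e-12)

    def test_extreme_window_worked_example(self):
        """100 SNPs all in class 47 vs a uniform 47-class background:
        CLR = 2 * 100 * ln(47) ~ 770 (the tilted alternative converges on the
        class-47 point mass)."""
        bg = np.full(47, 1 / 47)
        w = scan.Window("g", 0, np.full(100, 47), partial=False)
        assert scan.clr_score(w, bg) == pytest.approx(200 * np.log(47), rel=1e-9)
        assert scan.clr_score(w, bg) == pytest.approx(770.0, abs=0.5)

    def test_order_invariance(self, rng):
        bg = scan.background_proportions(np.arange(1, 48)[::-1].astype(float))
        ks = rng.integers(1, 48, size=100)
        a = scan.clr_score(scan.Window("g", 0, ks, False), bg)
        b = scan.clr_score(scan.Window("g", 0, rng.permutation(ks), False), bg)
        assert a == pytest.approx(b)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(15):
            bg_counts = rng.integers(0, 50, size=47).astype(float)
            bg_counts[rng.integers(47)] += 100
            q = scan.background_proportions(bg_counts)
            ks = rng.integers(1, 48, size=int(rng.integers(5, 120)))
            w = scan.Window("g", 0, ks, False)
            counts = np.bincount(ks, minlength=48)[1:].astype(float)
            got = scan.clr_score(w, q)
            oracle = brute_force_tilted_clr(counts, q)
            # the concave optimiser must match (and never fall below) the grid
            assert got >= oracle - 1e-9
            assert got == pytest.approx(oracle, abs=0.05)

    def test_nonnegative_and_monotone_in_skew(self):
        """CLR grows as window mass moves from typical to rare classes."""
        bg_counts = (1 / np.arange(1, 48)) * 1000
        q = scan.background_proportions(bg_counts)
        scores = []
        for n_high in (0, 20, 50, 80, 100):
            ks = np.concatenate([np.full(100 - n_high, 1), np.full(n_high, 47)])
            scores.append(scan.clr_score(scan.Window("g", 0, ks, False), q))
        assert all(s >= 0 for s in scores)
        assert all(b > a for a, b in zip(scores[1:], scores[2:]))

    def test_zero_mass_background_class_pseudocount(self):
        bg_counts = np.zeros(47)
        bg_counts[0] = 1000  # all background mass in class 1
        q = scan.background_proportions(bg_counts)
        w = scan.Window("g", 0, np.full(5, 40), False)
        assert np.isfinite(scan.clr_score(w, q))


class TestCandidates:
    def _frames(self, n_genes, rng):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "pi_bp": rng.uniform(0.01, 0.05, size=n_genes),
        })
        wins = pd.DataFrame({
            "gene_id": genes["gene_id"],
            "clr": rng.uniform(0, 50, size=n_genes),
        })
        return genes, wins

    def test_intersection_rule(self, rng):
        genes, wins = self._frames(100, rng)
        out = scan.select_candidates(genes, wins)
        t = out.table
        flagged = t[t["candidate"]]
        assert (flagged["max_clr"] >= out.clr_threshold).all()
        assert (flagged["pi_bp"] <= out.pi_threshold).all()
        unflagged = t[~t["candidate"]]
        assert (
            (unflagged["max_clr"] < out.clr_threshold)
            | (unflagged["pi_bp"] > out.pi_threshold)
        ).all()

    def test_zero_tails_empty_list(self, rng):
        genes, wins = self._frames(50, rng)
        out = scan.select_candidates(genes, wins, clr_tail=0.0, pi_tail=0.0)
        assert not out.candidates

    def test_degenerate_input_reported(self, rng):
        genes = pd.DataFrame({"gene_id": [f"g{i}" for i in range(30)],
                              "pi_bp": 0.02})
        wins = pd.DataFrame({"gene_id": genes["gene_id"], "clr": 1.0})
        out = scan.select_candidates(genes, wins)
        assert out.degenerate and not out.candidates

    def test_too_few_genes_rejected(self, rng):
        genes, wins = self._frames(10, rng)
        with pytest.raises(ValueError):
            scan.select_candidates(genes, wins)

    def test_sweep_recovery_experiment(self, rng):
        """Strongly swept genes land in both 5% tails; neutral genes rarely do."""
        cfg = syn.SimConfig(seed=1)
        model = InheritanceModel("tetrasomic")
        genes = syn.make_gene_models(syn.SimConfig(seed=5, n_genes=400), rng)
        swept = {g.gene_id for g in genes[::20]}  # 20 of 400
        rows, all_k = [], {}
        for g in genes:
            s = syn.simulate_population(g, cfg, model, rng)
            if g.gene_id in swept:
                s = syn.inject_sweep(s, 0.9, rng)
            k = s.derived_counts()
            all_k[g.gene_id] = k
            rows.append({"gene_id": g.gene_id,
                         "pi_bp": pg.pi(k, 48, g.length)})
        genes_df = pd.DataFrame(rows)
        bg = np.concatenate(list(all_k.values()))
        q = scan.background_proportions(
            pg.build_sfs(bg, "unfolded").counts.astype(float)
        )
        win_rows = []
        for gid, k in all_k.items():
            for w in scan.make_windows(gid, k):
                win_rows.append({"gene_id": gid, "clr": scan.clr_score(w, q)})
        out = scan.select_candidates(genes_df, pd.DataFrame(win_rows))
        hits = out.candidates
        recovered = len(hits & swept) / len(swept)
        false_flags = len(hits - swept) / (len(genes) - len(swept))
        assert recovered >= 0.8
        assert false_flags <= 0.05


class TestIndependence:
    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        assert scan.check_independence(x, x) == pytest.approx(1.0)
        assert scan.check_independence(x, -x) == pytest.approx(1.0)

    def test_independent_values_near_zero(self, rng):
        r2 = scan.check_independence(rng.normal(size=4000), rng.normal(size=4000))
        assert r2 < 0.01

    def test_constant_vector_is_nan(self):
        assert np.isnan(scan.check_independence(np.ones(5), np.arange(5.0)))


class TestEnrichment:
    def test_meiosis_style_table(self):
        """8 of 59 set genes among 192 candidates in a ~20k universe is a
        strong enrichment (one-sided p << 0.001)."""
        res = scan.enrichment_from_counts(8, 51, 184, 20006)
        assert res.p_value < 1e-6
        assert res.in_set_candidate_fraction == pytest.approx(8 / 59)
        assert res.fold_enrichment > 10

    def test_p_equals_hypergeometric_tail_exactly(self, rng):
        for _ in range(10):
            a, b, c, d = rng.integers(0, 30, size=4) + [1, 5, 5, 50]
            res = scan.enrichment_from_counts(a, b, c, d)
            n, K, N = a + b + c + d, a + b, a + c
            tail = hypergeom.sf(a - 1, n, K, N)
            assert res.p_value == pytest.approx(tail, rel=1e-10)

    def test_set_identical_to_candidates(self):
        uni = {f"g{i}" for i in range(100)}
        cand = {f"g{i}" for i in range(5)}
        res = scan.enrichment_test(cand, cand, uni)
        assert res.p_value < 1e-7
        assert res.fold_enrichment == pytest.approx(20.0)  # 1 / (5/100)

    def test_null_sets_give_uniform_p(self, rng):
        """Random same-size sets produce p-values matching the permutation
        distribution (KS-style bound on the empirical CDF)."""
        uni = [f"g{i}" for i in range(400)]
        cand = set(uni[:40])
        ps = []
        for _ in range(300):
            s = set(rng.choice(uni, size=30, replace=False))
            ps.append(scan.enrichment_test(cand, s, set(uni)).p_value)
        ps = np.sort(ps)
        # discrete p-values are conservative: P(p <= x) <= x under the null
        grid = np.linspace(0.05, 1.0, 20)
        emp = np.searchsorted(ps, grid, side="right") / len(ps)
        assert (emp <= grid + 0.07).all()

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            scan.enrichment_test(set(), set(), set())
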