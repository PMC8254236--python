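"""Ground-truth and reproducibility checks for the synthetic generators."""

import numpy as np
import pytest
from scipy import stats

from serous import simulate, survival, tables
from serous.io import MotifPWM


class TestSimulateExpression:
    def test_match_moments_reproduces_published_summary_exactly(self):
        """The regenerated discovery cohort realizes every printed per-group
        mean and SD to 1e-9, including the skewed low-abundance genes."""
        for comparison in tables.COMPARISONS:
            em = simulate.simulate_discovery_cohort(comparison, seed=11)
            pairs = tables.summary_pairs(comparison)
            g1, g2 = tables.COMPARISON_GROUPS[comparison]
            for r in pairs.itertuples():
                for grp, m, s in ((g1, r.m1, r.s1), (g2, r.m2, r.s2)):
                    v = em.values.loc[r.gene, em.samples_in(grp)].to_numpy()
                    assert v.min() >= 0
                    assert abs(v.mean() - m) < 1e-9
                    assert abs(v.std(ddof=1) - s) < 1e-9

    def test_zero_sd_gives_constant_columns(self):
        effects = {"g1": {"A": (5.0, 0.0), "B": (2.0, 0.0)}}
        em = simulate.simulate_expression(effects, [("A", 3), ("B", 4)], seed=0)
        assert (em.values.loc["g1", em.samples_in("A")] == 5.0).all()
        assert (em.values.loc["g1", em.samples_in("B")] == 2.0).all()

    def test_seed_determinism(self):
        effects = {"g": {"A": (10.0, 3.0)}}
        a = simulate.simulate_expression(effects, [("A", 6)], seed=42)
        b = simulate.simulate_expression(effects, [("A", 6)], seed=42)
        assert a.values.equals(b.values)

    def test_negative_sd_is_error(self):
        with pytest.raises(ValueError):
            simulate.simulate_expression({"g": {"A": (1.0, -1.0)}}, [("A", 3)])

    def test_moments_converge_without_matching(self):
        effects = {"g": {"A": (50.0, 5.0)}}
        em = simulate.simulate_expression(effects, [("A", 10_000)], seed=1)
        v = em.values.loc["g"].to_numpy()
        assert abs(v.mean() - 50.0) < 0.2
        assert abs(v.std(ddof=1) - 5.0) < 0.2


class TestSimulatePromoters:
    def test_full_coverage_plants_every_foreground_sequence(self, rng):
        motif = simulate.random_pwm(rng, 10, motif_id="m")
        fg, bg, truth = simulate.simulate_promoters(
            [(motif, 1.0, 0.0)], n_foreground=10, promoter_length=200, seed=0)
        fg_rows = truth[truth["set"] == "fg"]
        assert len(fg_rows) == 10
        assert set(fg_rows["sequence"]) == set(fg)
        assert len(truth[truth["set"] == "bg"]) == 0

    def test_planted_counts_match_rounded_fractions(self, rng):
        motif = simulate.random_pwm(rng, 8, motif_id="m")
        fg, bg, truth = simulate.simulate_promoters(
            [(motif, 0.8, 0.1)], n_foreground=20, promoter_length=300, seed=3)
        assert len(bg) == 80  # background defaults to 4x foreground
        assert len(truth[truth["set"] == "fg"]) == 16
        assert len(truth[truth["set"] == "bg"]) == 8

    def test_planted_site_is_present_at_recorded_position(self, rng):
        motif = simulate.random_pwm(rng, 8, sharpness=1 - 1e-12,
                                    concentration=1e9, motif_id="m")
        fg, _, truth = simulate.simulate_promoters(
            [(motif, 1.0, 0.0)], n_foreground=5, promoter_length=100, seed=2)
        from serous.io import reverse_complement
        consensus = motif.consensus()
        for row in truth.itertuples():
            window = fg[row.sequence][row.position:row.position + 8]
            expected = consensus if row.strand == "+" else reverse_complement(consensus)
            assert window == expected

    def test_seed_determinism(self, rng):
        motif = simulate.random_pwm(rng, 8, motif_id="m")
        a = simulate.simulate_promoters([(motif, 0.5, 0.1)], seed=9,
                                        promoter_length=150)
        b = simulate.simulate_promoters([(motif, 0.5, 0.1)], seed=9,
                                        promoter_length=150)
        assert a[0] == b[0] and a[1] == b[1]

    def test_motif_longer_than_promoter_is_error(self, rng):
        motif = simulate.random_pwm(rng, 10, motif_id="m")
        with pytest.raises(ValueError):
            simulate.simulate_promoters([(motif, 1.0, 0.0)], promoter_length=5)


class TestSimulateSurvival:
    @pytest.fixture
    def cohort(self):
        effects = {f"g{i}": {"G": (20.0, 5.0)} for i in range(3)}
        return simulate.simulate_expression(effects, [("G", 200)], seed=5)

    def test_full_censoring(self, cohort):
        t = simulate.simulate_survival(cohort, censoring_rate=1.0, seed=0)
        assert (t["event"] == 0).all()

    def test_null_hazard_logrank_calibrated(self, cohort):
        """With no expression-hazard link, random splits give uniform
        logrank p-values (K-S over replicates)."""
        rng = np.random.default_rng(77)
        pvals = []
        for rep in range(200):
            t = simulate.simulate_survival(cohort, censoring_rate=0.2, seed=rep)
            idx = rng.permutation(len(t))
            a, b = t.iloc[idx[:100]], t.iloc[idx[100:]]
            pvals.append(survival.logrank(a["time"], a["event"],
                                          b["time"], b["event"])[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_hazard_detected(self, cohort):
        """A log-hazard of 2 per SD yields high logrank power at n=200."""
        hits = 0
        for rep in range(25):
            t = simulate.simulate_survival(
                cohort, hazard_coefs={"g0": 2.0}, censoring_rate=0.1, seed=rep)
            hi = t["g0"] > t["g0"].median()
            _, p = survival.logrank(t.loc[hi, "time"], t.loc[hi, "event"],
                                    t.loc[~hi, "time"], t.loc[~hi, "event"])
            hits += p < 0.05
        assert hits >= 23  # power > 0.9

    def test_diploid_flag_all_set_when_no_coefficients(self, cohort):
        t = simulate.simulate_survival(cohort, seed=0)
        assert (t["diploid"] == 1).all()

    def test_negative_baseline_is_error(self, cohort):
        with pytest.raises(ValueError):
            simulate.simulate_survival(cohort, baseline_hazard=-1.0)


class TestSimulateGO:
    @pytest.fixture
    def cohort(self):
        effects = {f"g{i}": {"G": (30.0, 6.0)} for i in range(60)}
        return simulate.simulate_expression(effects, [("G", 4)], seed=8)

    def test_empty_plant_leaves_matrix_unchanged(self, cohort):
        ann, shifted = simulate.simulate_go_annotation(cohort, seed=1)
        assert shifted.values.equals(cohort.values)
        assert len(ann.terms()) >= 30

    def test_planted_term_shifts_expression(self, cohort):
        ann, shifted = simulate.simulate_go_annotation(
            cohort, planted=[("GO:PLANT", 2.0, 10)], seed=1)
        members = [g for g, ts in ann.gene2terms.items() if "GO:PLANT" in ts]
        assert len(members) == 10
        ratio = (shifted.values.loc[members] / cohort.values.loc[members])
        assert np.allclose(ratio, 4.0)

    def test_oversized_plant_is_error(self, cohort):
        with pytest.raises(ValueError):
            simulate.simulate_go_annotation(cohort, planted=[("GO:X", 1.0, 10_000)])

    def test_dag_is_tree_rooted_at_first_term(self, cohort):
        ann, _ = simulate.simulate_go_annotation(cohort, n_terms=20, seed=3)
        # every non-root term has exactly one parent
        assert all(len(p) == 1 for p in ann.term_parents.values())
        assert len(ann.term_parents) == 19


class TestBetaMatrixAndPWM:
    def test_beta_matrix_in_unit_interval(self):
        df = simulate.simulate_beta_matrix(100, 10, seed=0)
        assert df.shape == (100, 10)
        assert df.to_numpy().min() >= 0 and df.to_numpy().max() <= 1

    def test_random_pwm_valid_and_distinct_columns(self, rng):
        m = simulate.random_pwm(rng, 12, motif_id="x")
        assert isinstance(m, MotifPWM) and len(m) == 12
        # Dirichlet jitter: no two columns exactly equal
        assert len({tuple(c) for c in m.matrix}) == 12
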