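"""Promoter extraction, PWM scanning, ranking, matching and overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from serous import motifs, simulate
from serous.io import GenomicInterval, MotifPWM, reverse_complement


@pytest.fixture
def uniform_bg():
    return np.full(4, 0.25)


class TestExtractPromoters:
    GENOME = {"chr1": "".join("ACGT"[(i // 7) % 4] for i in range(6000))}

    def test_plus_strand_interval_convention(self):
        tss = [GenomicInterval("chr1", 5000, 5001, "+", "g")]
        ps = motifs.extract_promoters(tss, self.GENOME, width=2000)
        assert ps.sequences["g"] == self.GENOME["chr1"][3000:5000]
        assert ps.truncated == set()

    def test_minus_strand_reverse_complement(self):
        tss = [GenomicInterval("chr1", 1000, 1001, "-", "g")]
        ps = motifs.extract_promoters(tss, self.GENOME, width=2000)
        assert ps.sequences["g"] == reverse_complement(
            self.GENOME["chr1"][1000:3000])

    def test_sentinel_sequence_recovered_byte_identical(self, rng):
        upstream = "".join(rng.choice(list("ACGT"), 2000))
        genome = {"chrS": "A" * 100 + upstream + "G" * 50}
        tss = [GenomicInterval("chrS", 2100, 2101, "+", "g")]
        ps = motifs.extract_promoters(tss, genome, width=2000)
        assert ps.sequences["g"] == upstream

    def test_edge_truncation_flagged(self):
        tss = [GenomicInterval("chr1", 500, 501, "+", "g")]
        ps = motifs.extract_promoters(tss, self.GENOME, width=2000)
        assert len(ps.sequences["g"]) == 500
        assert "g" in ps.truncated

    def test_missing_chromosome_is_error(self):
        with pytest.raises(KeyError):
            motifs.extract_promoters(
                [GenomicInterval("chrX", 10, 11, "+", "g")], self.GENOME)

    def test_fully_off_contig_is_error(self):
        with pytest.raises(ValueError):
            motifs.extract_promoters(
                [GenomicInterval("chr1", 0, 1, "+", "g")], self.GENOME)


class TestScanPWM:
    def test_null_tail_matches_exhaustive_enumeration(self, rng, uniform_bg):
        """DP null tail equals brute-force enumeration over all 4^6 windows
        on the same discretized score grid."""
        m = simulate.random_pwm(rng, 6, motif_id="m")
        lo = motifs.logodds_matrix(m, uniform_bg)
        im, _ = motifs.discretize_logodds(lo)
        scores, _, tail = motifs.null_score_distribution(im, uniform_bg)
        acc: dict = {}
        for w in itertools.product(range(4), repeat=6):
            s = sum(int(im[i, b]) for i, b in enumerate(w))
            acc[s] = acc.get(s, 0.0) + 0.25 ** 6
        for s, _p in acc.items():
            oracle_tail = sum(v for k, v in acc.items() if k >= s)
            i = int(np.searchsorted(scores, s))
            assert tail[i] == pytest.approx(oracle_tail, abs=1e-12)

    def test_planted_consensus_hit_at_position_and_strand(self, rng):
        m = simulate.random_pwm(rng, 10, sharpness=0.95, concentration=100,
                                motif_id="m")
        base = "".join(rng.choice(list("ACGT"), 300))
        cons = m.consensus()
        fwd = base[:50] + cons + base[60:300]
        rev = base[:120] + reverse_complement(cons) + base[130:300]
        occ = motifs.scan_pwm({"fwd": fwd, "rev": rev}, [m], p_threshold=1e-4)
        assert occ.presence.loc["fwd", "m"] == 1
        assert occ.presence.loc["rev", "m"] == 1
        _, pos_f, strand_f = occ.best[("fwd", "m")]
        _, pos_r, strand_r = occ.best[("rev", "m")]
        assert (pos_f, strand_f) == (50, "+")
        assert (pos_r, strand_r) == (120, "-")

    def test_uniform_motif_never_hits(self, rng, uniform_bg):
        """A motif equal to the background has zero log-odds everywhere, so
        no window can be rarer than any p threshold below 1."""
        m = MotifPWM("uni", np.full((8, 4), 0.25))
        seqs = {"s": "".join(rng.choice(list("ACGT"), 500))}
        occ = motifs.scan_pwm(seqs, [m], p_threshold=0.5, background=uniform_bg)
        assert occ.presence.loc["s", "uni"] == 0

    def test_hits_invariant_to_promoter_order(self, rng):
        m = simulate.random_pwm(rng, 10, sharpness=0.95, concentration=100,
                                motif_id="m")
        seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), 400))
                for i in range(6)}
        occ1 = motifs.scan_pwm(seqs, [m])
        occ2 = motifs.scan_pwm(dict(reversed(seqs.items())), [m])
        assert occ1.presence.sort_index().equals(occ2.presence.sort_index())

    def test_strand_symmetry(self, rng):
        """Scanning reverse-complemented sequences yields identical
        presence calls."""
        m = simulate.random_pwm(rng, 10, sharpness=0.95, concentration=100,
                                motif_id="m")
        seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), 400))
                for i in range(6)}
        rc = {k: reverse_complement(v) for k, v in seqs.items()}
        bg = np.full(4, 0.25)
        occ1 = motifs.scan_pwm(seqs, [m], background=bg)
        occ2 = motifs.scan_pwm(rc, [m], background=bg)
        assert occ1.presence.equals(occ2.presence)

    def test_n_windows_skipped(self, rng, uniform_bg):
        """A consensus site interrupted by N yields no hit because every
        window spanning the N is skipped; the intact site hits."""
        m = simulate.random_pwm(rng, 8, sharpness=0.95, concentration=100,
                                motif_id="m")
        cons = m.consensus()
        broken = cons[:4] + "N" + cons[4:]  # every 8-window contains the N
        occ = motifs.scan_pwm({"ok": cons, "broken": broken}, [m],
                              p_threshold=1e-3, background=uniform_bg)
        assert occ.presence.loc["ok", "m"] == 1
        assert occ.presence.loc["broken", "m"] == 0

    def test_zero_probability_without_pseudocount_is_error(self, uniform_bg):
        mat = np.tile([1.0, 0.0, 0.0, 0.0], (6, 1))
        m = MotifPWM("hard", mat, pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            motifs.logodds_matrix(m, uniform_bg)


class TestRankingAndCoverage:
    def _occurrence(self, rng, n_fg=30, n_bg=120, n_noise=20, signal_rate=0.9):
        cols = {"signal": np.concatenate([
            rng.random(n_fg) < signal_rate, rng.random(n_bg) < 0.05])}
        for i in range(n_noise):
            cols[f"noise{i:02d}"] = rng.random(n_fg + n_bg) < 0.3
        presence = pd.DataFrame(cols).astype(np.int8)
        presence.index = [f"fg{i}" for i in range(n_fg)] + \
                         [f"bg{i}" for i in range(n_bg)]
        labels = pd.Series(["fg"] * n_fg + ["bg"] * n_bg, index=presence.index)
        return presence, labels

    def test_separating_motif_ranks_first_both_criteria(self, rng):
        hits = 0
        for seed in range(10):
            presence, labels = self._occurrence(np.random.default_rng(seed))
            ranking = motifs.rf_rank_motifs(presence, labels, seed=seed,
                                            n_estimators=100)
            row = ranking.set_index("motif").loc["signal"]
            hits += (row["gini_rank"] == 1 and row["infogain_rank"] == 1)
        assert hits >= 9

    def test_k_equal_to_motif_count_retains_all(self, rng):
        presence, labels = self._occurrence(rng)
        ranking = motifs.rf_rank_motifs(presence, labels, k=21, seed=0,
                                        n_estimators=50)
        assert ranking["kept"].all()

    def test_coverage_equals_classwise_column_means(self, rng):
        presence, labels = self._occurrence(rng)
        cov = motifs.coverage(presence, labels)
        fg_rows = presence[labels == "fg"]
        bg_rows = presence[labels == "bg"]
        assert np.allclose(cov["c_fg"], fg_rows.mean(axis=0))
        assert np.allclose(cov["c_bg"], bg_rows.mean(axis=0))

    @pytest.mark.parametrize("c_fg,c_bg,regime,kept", [
        (0.55, 0.30, "A", True),
        (0.55, 0.30, "B", False),
        (1.00, 0.00, "A", True),
        (1.00, 0.00, "B", True),
        (0.45, 0.10, "A", False),
        (0.90, 0.40, "B", False),
    ])
    def test_coverage_filter_regimes(self, c_fg, c_bg, regime, kept):
        df = pd.DataFrame([{"motif": "m", "c_fg": c_fg, "c_bg": c_bg,
                            "kept": True}])
        out = motifs.coverage_filter(df, regime=regime)
        assert (len(out) == 1) is kept

    def test_near_duplicates_deduplicated_keeping_higher_coverage(self, known_motifs):
        a = known_motifs[0]
        dup = MotifPWM("dup_of_a", a.matrix.copy())
        df = pd.DataFrame([
            {"motif": a.motif_id, "c_fg": 0.9, "c_bg": 0.1, "kept": True},
            {"motif": "dup_of_a", "c_fg": 0.7, "c_bg": 0.1, "kept": True},
        ])
        out = motifs.coverage_filter(df, "A", motifs=[a, dup], seed=0)
        assert list(out["motif"]) == [a.motif_id]

    def test_single_motif_accuracy_worked_cases(self):
        presence = pd.DataFrame(
            {"hit_all_fg": [1, 1, 0, 0, 0], "absent": [0, 0, 0, 0, 0]},
            index=["f1", "f2", "b1", "b2", "b3"], dtype=np.int8)
        labels = pd.Series(["fg", "fg", "bg", "bg", "bg"], index=presence.index)
        assert motifs.single_motif_accuracy(presence, "hit_all_fg", labels) == 1.0
        assert motifs.single_motif_accuracy(presence, "absent", labels) == 0.6


class TestMatchMotif:
    def test_identity_gives_zero_distance_minimal_p(self, known_motifs):
        q = known_motifs[0]
        m = motifs.match_motif(q, known_motifs, n_null=2000, seed=0)
        assert m.target == q.motif_id
        assert m.distance == pytest.approx(0.0, abs=1e-12)
        assert m.p == pytest.approx(1 / 2001, rel=0.01)

    def test_reverse_complement_matches_at_reversed_orientation(self, known_motifs):
        q = known_motifs[1].reverse_complement()
        q.motif_id = "rc_query"
        m = motifs.match_motif(q, known_motifs, n_null=2000, seed=0)
        assert m.target == known_motifs[1].motif_id
        assert m.distance == pytest.approx(0.0, abs=1e-12)
        assert m.orientation == "-"

    def test_uniform_query_distance_closed_form(self):
        """Uniform query vs one sharp motif aligned full-length: distance is
        the mean per-column sqrt(sum (0.25 - q_b)^2)."""
        sharp = np.tile([0.91, 0.03, 0.03, 0.03], (6, 1))
        target = MotifPWM("t", sharp)
        query = MotifPWM("u", np.full((6, 4), 0.25))
        d, off, orient = motifs._best_alignment(query.matrix, target.matrix)
        expected = np.sqrt(((0.25 - sharp[0]) ** 2).sum())
        assert d == pytest.approx(expected, abs=1e-12)

    def test_insufficient_overlap_returns_none(self, known_motifs):
        q = MotifPWM("tiny", np.full((4, 4), 0.25))
        assert motifs.match_motif(q, known_motifs, n_null=10,
                                  min_overlap=30) is None


class TestTFBSOverlaps:
    def test_containment_and_halfopen_abutment(self):
        promoters = [GenomicInterval("chr1", 100, 300, "+", "p1")]
        tfbs = {
            "INSIDE": [GenomicInterval("chr1", 150, 160, "+", "a")],
            "ABUT": [GenomicInterval("chr1", 300, 310, "+", "b")],
        }
        out = motifs.count_tfbs_overlaps(promoters, tfbs).set_index("tf")
        assert out.loc["INSIDE", "n_promoters"] == 1
        assert out.loc["ABUT", "n_promoters"] == 0

    def test_counts_match_bruteforce_oracle(self, rng):
        promoters = [GenomicInterval("chr1", int(s), int(s) + 200, "+", f"p{i}")
                     for i, s in enumerate(rng.integers(0, 10_000, 50))]
        tfbs = {f"TF{j}": [GenomicInterval("chr1", int(s), int(s) + 30, "+", ".")
                           for s in rng.integers(0, 10_000, 40)]
                for j in range(5)}
        out = motifs.count_tfbs_overlaps(promoters, tfbs).set_index("tf")
        for tf, sites in tfbs.items():
            oracle = sum(any(p.overlaps(s) for s in sites) for p in promoters)
            assert out.loc[tf, "n_promoters"] == oracle

    def test_chromosome_mismatch_is_error(self):
        promoters = [GenomicInterval("chr1", 0, 100, "+", "p")]
        with pytest.raises(ValueError, match="chr9"):
            motifs.count_tfbs_overlaps(
                promoters, {"TF": [GenomicInterval("chr9", 0, 50, "+", ".")]})

    def test_ranked_by_count_then_name(self):
        promoters = [GenomicInterval("chr1", i * 100, i * 100 + 50, "+", f"p{i}")
                     for i in range(3)]
        tfbs = {
            "B": [GenomicInterval("chr1", 0, 260, "+", ".")],
            "A": [GenomicInterval("chr1", 0, 60, "+", ".")],
            "C": [GenomicInterval("chr1", 0, 60, "+", ".")],
        }
        out = motifs.count_tfbs_overlaps(promoters, tfbs)
        assert list(out["tf"]) == ["B", "A", "C"]


class TestKmerSeeds:
    def test_planted_kmer_is_top_seed_with_informative_pwm(self, rng):
        plant = "GATTACCA"
        fg = {}
        for i in range(20):
            s = "".join(rng.choice(list("ACGT"), 150))
            if i < 16:  # 80% coverage
                pos = int(rng.integers(0, 142))
                s = s[:pos] + plant + s[pos + 8:]
            fg[f"f{i}"] = s
        bg = {f"b{i}": "".join(rng.choice(list("ACGT"), 150))
              for i in range(80)}
        pwms, table = motifs.kmer_seed_discovery(fg, bg, k=8, n_seeds=3)
        assert table.iloc[0]["kmer"] in (plant, reverse_complement(plant))
        top = pwms[0]
        assert top.information_content().mean() > 1.0

    def test_identical_sets_give_zero_z(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 100))
                for i in range(10)}
        _, table = motifs.kmer_seed_discovery(seqs, dict(seqs), k=6, n_seeds=1)
        assert np.allclose(table["z"], 0.0)

    def test_k_longer_than_sequence_is_error(self):
        with pytest.raises(ValueError):
            motifs.kmer_seed_discovery({"a": "ACGT"}, {"b": "ACGT"}, k=10)
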