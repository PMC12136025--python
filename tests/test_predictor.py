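import math

import numpy as np
import pytest
from sklearn.base import clone

from cpsort.fixtures import oracle_score, sample_window, default_plastid_profile, default_ppc_profile
from cpsort.io_formats import ProteinRecord, SignalPrediction, write_predictions_table
from cpsort.matrixlib import RESIDUES, WindowSet, build_scoring_matrix
from cpsort.predictor import (
    PLUS1_SET,
    PredictorConfig,
    ScanError,
    TargetingClassifier,
    classify_protein,
    classify_simple_cutoff,
    predict_batch,
    scan_cleavage_sites,
    transit_score,
    window_contributions,
)

from conftest import embed_window

LOG2_20 = math.log2(20)
CONSENSUS_WINDOW = "ACDEFGHIKLMNPQRSTVWYACDEF"


def sp(rid, site):
    return SignalPrediction(rid, "targetp2", "SP", site, 0.95)


def random_sequence(rng, length):
    return "".join(RESIDUES[i] for i in rng.integers(20, size=length))


class TestWindowContributions:
    def test_consensus_sequence_recovers_info(self, conserved_matrix):
        seq = embed_window(CONSENSUS_WINDOW, 10)
        vals, truncated = window_contributions(seq, 10, conserved_matrix)
        assert not truncated
        assert np.allclose(vals, conserved_matrix.info, atol=1e-9)

    def test_unseen_residue_contributes_zero(self, conserved_matrix):
        seq = embed_window("W" + CONSENSUS_WINDOW[1:], 10)
        vals, _ = window_contributions(seq, 10, conserved_matrix)
        assert vals[0] == 0.0

    def test_truncated_window_flagged(self, conserved_matrix):
        seq = embed_window(CONSENSUS_WINDOW, 10, tail="")[:20]
        vals, truncated = window_contributions(seq, 10, conserved_matrix)
        assert truncated
        assert np.all(vals[15:] == 0.0)  # columns beyond the sequence end

    def test_site_out_of_range(self, conserved_matrix):
        with pytest.raises(ScanError, match="out of range"):
            window_contributions("MKLV", 9, conserved_matrix)

    def test_oracle_equivalence_on_random_pairs(self, plastid_matrix, ppc_matrix):
        """Window and transit scores match the naive re-scoring oracle to
        1e-9 on 1,000 random (sequence, site) pairs."""
        rng = np.random.default_rng(99)
        worst = 0.0
        for k in range(1000):
            matrix = plastid_matrix if k % 2 == 0 else ppc_matrix
            seq = random_sequence(rng, int(rng.integers(30, 120)))
            site = int(rng.integers(1, len(seq) + 1))
            vals, _ = window_contributions(seq, site, matrix)
            worst = max(worst, abs(float(vals.sum()) - oracle_score(seq, site, matrix, "window25")))
            worst = max(
                worst,
                abs(transit_score(seq, site, matrix) - oracle_score(seq, site, matrix, "transit20")),
            )
        assert worst < 1e-9

    def test_max_residue_substitution_never_decreases_score(self, plastid_matrix):
        """Replacing any window position by the column's best residue can
        only raise the window score."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = random_sequence(rng, 80)
            site = int(rng.integers(6, 50))
            base, _ = window_contributions(seq, site, plastid_matrix)
            j = int(rng.integers(25))
            offset = (list(range(-5, 0)) + list(range(1, 21)))[j]
            pos = site + offset + (1 if offset < 0 else 0)
            if not (1 <= pos <= len(seq)):
                continue
            best = RESIDUES[int(np.argmax(plastid_matrix.contribution[:, j]))]
            mutated = seq[: pos - 1] + best + seq[pos:]
            vals, _ = window_contributions(mutated, site, plastid_matrix)
            assert vals.sum() >= base.sum() - 1e-12


class TestScan:
    def test_radius_zero_keeps_predicted_site(self, plastid_matrix):
        seq = embed_window(sample_window(default_plastid_profile(), np.random.default_rng(0)), 12)
        res = scan_cleavage_sites(seq, 12, plastid_matrix, radius=0)
        assert res.best_site == 12
        assert res.candidate_sites == (12,)

    def test_offset_motif_found_by_scan(self, plastid_matrix):
        """Motif planted one residue downstream of the predicted site is
        recovered at radius 2; exhaustive scoring confirms the argmax."""
        window = sample_window(default_plastid_profile().with_conservation(1.0),
                               np.random.default_rng(1))
        seq = embed_window(window, 13)
        res = scan_cleavage_sites(seq, 12, plastid_matrix, radius=2)
        assert res.best_site == 13
        exhaustive = {s: oracle_score(seq, s, plastid_matrix, "window25") for s in range(10, 15)}
        assert res.best_site == max(exhaustive, key=exhaustive.get)
        assert res.best_window_score == pytest.approx(max(exhaustive.values()), abs=1e-9)

    def test_tie_breaks_to_n_terminus(self, conserved_matrix):
        seq = "A" * 60  # scores identically (zero) everywhere: tie
        res = scan_cleavage_sites(seq, 10, conserved_matrix, radius=2)
        assert res.best_site == 8

    def test_contributions_sum_to_window_score(self, plastid_matrix, benchmark_results):
        for r in benchmark_results:
            if r.scan is not None:
                assert sum(r.scan.contributions) == pytest.approx(r.scan.best_window_score, abs=1e-9)
                assert r.scan.best_site in r.scan.candidate_sites
                assert r.scan.best_window_score == pytest.approx(max(r.scan.window_scores))


class TestTransitScore:
    def test_consensus_closed_form(self, conserved_matrix):
        seq = embed_window(CONSENSUS_WINDOW, 10)
        assert transit_score(seq, 10, conserved_matrix) == pytest.approx(20 * LOG2_20, abs=1e-9)

    def test_unseen_everywhere_scores_zero(self, conserved_matrix):
        # rotate the transit region by one: every residue lands in a column
        # that never saw it in training
        t = CONSENSUS_WINDOW[5:]
        seq = embed_window(CONSENSUS_WINDOW[:5] + t[1:] + t[0], 10)
        assert transit_score(seq, 10, conserved_matrix) == 0.0


class TestDecisionTree:
    def test_mtp_forwarded_without_scoring(self, default_config):
        prot = ProteinRecord("m1", "", "MKKKKKKKKK")
        pred = SignalPrediction("m1", "targetp2", "mTP")
        r = classify_protein(prot, pred, default_config)
        assert r.category == "mitochondrion"
        assert r.scan is None and r.transit_score_plastid is None

    def test_other_forwarded(self, default_config):
        r = classify_protein(
            ProteinRecord("o1", "", "MKL"), SignalPrediction("o1", "targetp2", "other"), default_config
        )
        assert r.category == "other" and r.confidence == "none"

    def test_planted_plastid_consensus_is_high_confidence(self, default_config):
        window = sample_window(default_plastid_profile().with_conservation(1.0),
                               np.random.default_rng(2))
        prot = ProteinRecord("p1", "", embed_window(window, 18, tail="A" * 20))
        r = classify_protein(prot, sp("p1", 18), default_config)
        assert r.category == "plastid" and r.confidence == "high"
        assert r.plus1_residue in PLUS1_SET
        assert r.transit_score_plastid > default_config.t_high

    def test_planted_ppc_signal_classified_ppc(self, default_config):
        window = sample_window(default_ppc_profile().with_conservation(1.0),
                               np.random.default_rng(3))
        prot = ProteinRecord("q1", "", embed_window(window, 18, tail="D" * 20))
        r = classify_protein(prot, sp("q1", 18), default_config)
        assert r.category == "PPC"
        assert r.plus1_residue not in PLUS1_SET
        assert r.transit_score_ppc >= default_config.t_ppc
        assert r.transit_score_plastid <= default_config.t_low

    def test_sp_with_unusable_site(self, default_config):
        pred = SignalPrediction("u1", "targetp2", "SP", None, site_known=False)
        r = classify_protein(ProteinRecord("u1", "", "MKLVVL"), pred, default_config)
        assert r.category == "SP-other" and "site-unknown" in r.flags

    def test_site_at_or_past_sequence_end_is_unusable(self, default_config):
        r = classify_protein(ProteinRecord("u2", "", "MKLVVL"), sp("u2", 6), default_config)
        assert r.category == "SP-other" and "site-unknown" in r.flags

    def test_ppc_plus1_exclusion_toggle(self, plastid_matrix, ppc_matrix):
        """With the +1 exclusion off, an F/Y/W/L +1 no longer blocks PPC.

        The +1 residue L sits in the excluded set but is nearly unobserved in
        the plastid training set, so with a slightly raised low-confidence
        threshold the protein falls through the plastid tiers and the PPC
        branch decides."""
        window = sample_window(default_ppc_profile().with_conservation(1.0),
                               np.random.default_rng(4))
        window = window[:5] + "L" + window[6:]  # excluded +1 on a PPC backbone
        prot = ProteinRecord("x1", "", embed_window(window, 18, tail="D" * 20))
        strict = PredictorConfig(plastid_matrix=plastid_matrix, ppc_matrix=ppc_matrix,
                                 t_low=0.5)
        relaxed = PredictorConfig(plastid_matrix=plastid_matrix, ppc_matrix=ppc_matrix,
                                  t_low=0.5, ppc_plus1_exclusion=False)
        assert classify_protein(prot, sp("x1", 18), strict).category == "SP-other"
        assert classify_protein(prot, sp("x1", 18), relaxed).category == "PPC"

    def test_high_confidence_set_is_subset_of_all_plastid(self, benchmark_results):
        high = {r.id for r in benchmark_results
                if r.category == "plastid" and r.confidence == "high"}
        all_plastid = {r.id for r in benchmark_results if r.category == "plastid"}
        assert high and high <= all_plastid

    def test_categories_mutually_exclusive_and_ppc_only_for_sp(self, benchmark, benchmark_results):
        proteome, _, _ = benchmark
        assert len(benchmark_results) == len(proteome.proteins)
        for r in benchmark_results:
            if r.category == "PPC":
                assert r.input_category == "SP"
                assert r.transit_score_plastid <= 0.0  # never a plastid call


class TestSimpleCutoff:
    def test_infinite_cutoffs(self, benchmark, plastid_matrix):
        proteome, preds, _ = benchmark
        by_id = {p.id: p for p in proteome.proteins}
        hi = [classify_simple_cutoff(by_id[p.id], p, plastid_matrix, math.inf)
              for p in preds if p.id in by_id]
        assert not any(r.category == "plastid" for r in hi)
        lo = [classify_simple_cutoff(by_id[p.id], p, plastid_matrix, -math.inf)
              for p in preds if p.id in by_id]
        for r in lo:
            if r.input_category == "SP" and "site-unknown" not in r.flags:
                assert r.category == "plastid" and r.confidence == "none"

    def test_threshold_matches_oracle(self, benchmark, plastid_matrix):
        proteome, preds, _ = benchmark
        by_id = {p.id: p for p in proteome.proteins}
        cutoff = 10.0
        for pred in preds:
            prot = by_id[pred.id]
            r = classify_simple_cutoff(prot, pred, plastid_matrix, cutoff)
            if r.input_category == "SP" and r.scan is not None:
                expected = oracle_score(prot.sequence, r.scan.best_site, plastid_matrix, "transit20")
                assert (r.category == "plastid") == (expected > cutoff)


class TestBatchAndDeterminism:
    def test_empty_input(self, default_config):
        assert predict_batch([], [], default_config) == []

    def test_category_counts_match_plan(self, benchmark, benchmark_results):
        proteome, _, _ = benchmark
        truth = {t.id: t.truth for t in proteome.truth}
        # forwarded classes are recovered exactly; planted SP classes mostly
        mito = [r for r in benchmark_results if truth[r.id] == "mTP"]
        assert all(r.category == "mitochondrion" for r in mito)
        other = [r for r in benchmark_results if truth[r.id] == "other"]
        assert all(r.category == "other" for r in other)

    def test_rerun_byte_identical(self, tmp_path, benchmark, default_config):
        proteome, preds, _ = benchmark
        outs = []
        for name in ("a.tsv", "b.tsv"):
            res = predict_batch(list(proteome.proteins), preds, default_config)
            p = tmp_path / name
            write_predictions_table(res, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]


class TestTargetingClassifierEstimator:
    def test_fit_predict_with_default_matrices(self, benchmark):
        proteome, preds, _ = benchmark
        by_id = {p.id: p for p in proteome.proteins}
        X = [(by_id[p.id], p) for p in preds]
        clf = TargetingClassifier().fit()
        y = clf.predict(X)
        assert set(y) <= set(clf.classes_)
        assert len(y) == len(X)

    def test_param_roundtrip_and_clone(self):
        clf = TargetingClassifier(t_high=3.0, scan_radius=1, ppc_matrix=None)
        params = clf.get_params()
        assert params["t_high"] == 3.0 and params["scan_radius"] == 1
        clf2 = clone(clf).set_params(t_low=-1.0)
        assert clf2.get_params()["t_low"] == -1.0
        clf2.fit()
        assert clf2.ppc_matrix_ is None

    def test_accepts_plain_sequences(self):
        clf = TargetingClassifier(ppc_matrix=None).fit()
        pred = SignalPrediction("s1", "targetp2", "other")
        assert clf.predict([("MKLV", pred)])[0] == "other"
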