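"""Bray-Curtis distances, PAM clustering, CST naming and bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from cvmbarrier.cst import (CSTClassifier, PAMKMedoids, assign_cst_labels,
                            bray_curtis_matrix, carry_forward_cst,
                            participant_cst_mobility_average)
from cvmbarrier.simulate import simulate_composition_table


def _table(rows, taxa=None):
    taxa = taxa or [f"t{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=taxa,
                        index=[f"s{i}" for i in range(len(rows))])


class TestBrayCurtis:
    def test_hand_cases(self):
        t = _table([[0.8, 0.2], [0.2, 0.8], [0.8, 0.2], [1.0, 0.0]],
                   ["a", "b"])
        dm = bray_curtis_matrix(t)
        assert dm.iloc[0, 2] == pytest.approx(0.0)      # identical rows
        assert dm.iloc[0, 1] == pytest.approx(0.6)      # sum(min) = 0.4
        t2 = _table([[1.0, 0.0], [0.0, 1.0]], ["a", "b"])
        assert bray_curtis_matrix(t2).iloc[0, 1] == pytest.approx(1.0)

    def test_matches_closed_form(self):
        r = np.random.default_rng(0)
        rows = r.dirichlet(np.ones(6), size=10)
        dm = bray_curtis_matrix(_table(rows.tolist()))
        # BC = 1 - 2 sum(min)/(sum a + sum b), direct evaluation
        for i in range(10):
            for j in range(10):
                expect = 1 - 2 * np.minimum(rows[i], rows[j]).sum() / (
                    rows[i].sum() + rows[j].sum())
                assert dm.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetry_range_zero_diagonal(self):
        r = np.random.default_rng(1)
        dm = bray_curtis_matrix(
            _table(r.dirichlet(np.ones(5), size=12).tolist())).to_numpy()
        np.testing.assert_allclose(dm, dm.T, atol=1e-15)
        assert np.all(np.diag(dm) == 0)
        assert dm.min() >= 0 and dm.max() <= 1

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            bray_curtis_matrix(_table([[0.5, 0.2], [0.5, 0.5]]))
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis_matrix(_table([[1.2, -0.2], [0.5, 0.5]]))


class TestPAM:
    def _blob_distances(self, sizes, within=0.03, between=0.9, seed=0):
        r = np.random.default_rng(seed)
        n = sum(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        D = np.where(labels[:, None] == labels[None, :],
                     within * r.random((n, n)), between + 0.05 * r.random((n, n)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        return D, labels

    def test_recovers_planted_blobs(self):
        D, labels = self._blob_distances([20, 15, 25])
        pam = PAMKMedoids(n_clusters=3).fit(D)
        # perfect partition up to relabeling
        for c in range(3):
            assert len(set(labels[pam.labels_ == c])) == 1

    def test_k_equals_n_zero_objective(self):
        D, _ = self._blob_distances([3, 3])
        pam = PAMKMedoids(n_clusters=6).fit(D)
        assert pam.inertia_ == 0.0
        assert sorted(pam.medoid_indices_) == list(range(6))

    def test_swap_never_worse_than_build(self):
        r = np.random.default_rng(5)
        X = r.random((40, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        pam = PAMKMedoids(n_clusters=4).fit(D)
        assert pam.inertia_ <= pam.build_inertia_ + 1e-12

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            PAMKMedoids(n_clusters=5).fit(np.zeros((3, 3)))

    def test_permutation_invariance_up_to_relabeling(self):
        D, _ = self._blob_distances([10, 12, 8], seed=3)
        perm = np.random.default_rng(1).permutation(len(D))
        a = PAMKMedoids(n_clusters=3).fit(D)
        b = PAMKMedoids(n_clusters=3).fit(D[np.ix_(perm, perm)])
        # same partition after undoing the permutation
        la = a.labels_
        lb = np.empty_like(la)
        lb[perm] = b.labels_
        from itertools import permutations
        assert any(np.all(la == np.array([m[v] for v in lb]))
                   for m in [dict(enumerate(p))
                             for p in permutations(range(3))])


class TestAssignCST:
    def test_medoid_dominance_names_cluster(self):
        taxa = ["L. crispatus", "L. iners", "G. vaginalis", "A. vaginae"]
        t = _table([[0.9, 0.05, 0.03, 0.02],
                    [0.85, 0.1, 0.03, 0.02],
                    [0.05, 0.25, 0.28, 0.42],
                    [0.1, 0.2, 0.3, 0.4]], taxa)
        dm = bray_curtis_matrix(t).to_numpy()
        pam = PAMKMedoids(n_clusters=2).fit(dm)
        out = assign_cst_labels(pam.labels_, pam.medoid_indices_, t)
        by_sample = {a.sample_id: a.cst for a in out}
        assert by_sample["s0"] == "I" and by_sample["s1"] == "I"
        assert by_sample["s2"] == "IV" and by_sample["s3"] == "IV"

    def test_polymicrobial_medoid_is_iv(self):
        taxa = ["L. crispatus", "L. iners", "G. vaginalis", "A. vaginae"]
        t = _table([[0.25, 0.25, 0.25, 0.25],
                    [0.2, 0.3, 0.25, 0.25],
                    [0.9, 0.04, 0.03, 0.03],
                    [0.88, 0.06, 0.03, 0.03]], taxa)
        clf = CSTClassifier(n_clusters=2).fit(t)
        assert set(zip(t.index, clf.labels_)) == {
            ("s0", "IV"), ("s1", "IV"), ("s2", "I"), ("s3", "I")}

    def test_end_to_end_recovery_on_synthetic_table(self):
        r = np.random.default_rng(0)
        labels = list(r.choice(["I", "II", "III", "IV", "V"],
                               p=[0.3, 0.1, 0.25, 0.25, 0.1], size=200))
        table = simulate_composition_table(labels, seed=1)
        clf = CSTClassifier(n_clusters=5).fit(table)
        assert np.mean(np.array(labels) == clf.labels_) >= 0.95

    def test_duplicate_lactobacillus_clusters_tie_break(self, caplog):
        import logging
        taxa = ["L. crispatus", "L. iners", "G. vaginalis", "A. vaginae"]
        # two well-separated clusters both crispatus-dominated
        t = _table([[0.95, 0.03, 0.01, 0.01]] * 3
                   + [[0.55, 0.05, 0.2, 0.2]] * 3, taxa)
        dm = bray_curtis_matrix(t).to_numpy()
        pam = PAMKMedoids(n_clusters=2).fit(dm)
        with caplog.at_level(logging.WARNING):
            out = assign_cst_labels(pam.labels_, pam.medoid_indices_, t)
        csts = {a.cst for a in out}
        assert csts == {"I", "IV"}
        assert any("two clusters" in r.message for r in caplog.records)


class TestCarryForward:
    def test_last_cst_persists_to_delivery(self):
        tl = pd.DataFrame({"week": [12.0, 20.0], "cst": ["III", "I"]})
        out = carry_forward_cst(tl, delivery_week=38.0)
        assert list(out["cst"]) == ["III", "I"]
        last = out.iloc[-1]
        assert last["week_start"] == 20.0 and last["week_end"] == 38.0
        assert not last["observed"]

    def test_single_sample_spans_pregnancy(self):
        out = carry_forward_cst(
            pd.DataFrame({"week": [15.0], "cst": ["IV"]}), 39.0)
        assert len(out) == 1
        assert out.iloc[0]["week_end"] == 39.0

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError):
            carry_forward_cst(pd.DataFrame({"week": [], "cst": []}), 39.0)


class TestParticipantMobilityAverage:
    def test_arithmetic_mean_within_cst(self):
        mobility = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "probe": ["MPP100"] * 3,
            "mobile_fraction": [0.1, 0.2, 0.3]})
        assign = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "participant_id": ["P0"] * 3,
            "cst": ["I"] * 3})
        out = participant_cst_mobility_average(mobility, assign)
        assert len(out) == 1
        assert out.loc[0, "mobile_fraction"] == pytest.approx(0.2)

    def test_two_csts_two_rows(self):
        mobility = pd.DataFrame({
            "sample_id": ["a", "b"], "probe": ["MPP100"] * 2,
            "mobile_fraction": [0.1, 0.5]})
        assign = pd.DataFrame({
            "sample_id": ["a", "b"], "participant_id": ["P0"] * 2,
            "cst": ["I", "IV"]})
        assert len(participant_cst_mobility_average(mobility, assign)) == 2

    def test_orphans_dropped_empty_join_ok(self):
        mobility = pd.DataFrame({
            "sample_id": ["z"], "probe": ["MPP100"],
            "mobile_fraction": [0.4]})
        assign = pd.DataFrame(columns=["sample_id", "participant_id", "cst"])
        out = participant_cst_mobility_average(mobility, assign)
        assert out.empty
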