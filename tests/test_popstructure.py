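"""PCA, DAPC, STRUCTURE post-processing and kinship."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tetragwas import popstructure as ps
from tests.conftest import make_genotypes


def clustered_scores(rng, n_per=50, k=3, sep=20.0, dim=40):
    # dim mirrors retained PCA scores: cluster structure plus noise
    # dimensions that subdividing a true cluster cannot compress
    centers = rng.normal(scale=sep, size=(k, dim))
    pts = np.vstack([centers[i] + rng.normal(size=(n_per, dim))
                     for i in range(k)])
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels


class TestPcaDosage:
    def test_duplicated_samples_identical_scores(self, rng):
        dosage = rng.integers(0, 5, size=(6, 20)).astype(float)
        dosage[5] = dosage[0]
        g = make_genotypes(dosage, positions=list(range(1, 21)))
        scores, _ = ps.pca_dosage(g, 3)
        np.testing.assert_allclose(scores[5], scores[0], atol=1e-10)

    def test_explained_variance_bounded_and_sorted(self, rng):
        dosage = rng.integers(0, 5, size=(10, 15)).astype(float)
        g = make_genotypes(dosage, positions=list(range(1, 16)))
        x = g.imputed_dosage()
        total = ((x - x.mean(axis=0)) ** 2).sum() / (len(x) - 1)
        _, ev = ps.pca_dosage(g, 5)
        assert np.all(np.diff(ev) <= 1e-9)
        assert ev.sum() <= total + 1e-8

    def test_progeny_midway_between_parents(self):
        # dosage of each "progeny" is the exact average of its two parents,
        # so its PCA position is the parents' midpoint
        p1 = np.array([0.0, 4, 0, 4, 0, 4, 2, 2])
        p2 = np.array([4.0, 0, 4, 0, 4, 0, 2, 2])
        child = (p1 + p2) / 2
        g = make_genotypes(np.vstack([p1, p2, child, p1, p2]),
                           positions=list(range(1, 9)),
                           dosage_kind="posterior_mean")
        scores, _ = ps.pca_dosage(g, 2)
        np.testing.assert_allclose(scores[2], (scores[0] + scores[1]) / 2,
                                   atol=1e-10)

    def test_too_many_components_rejected(self, rng):
        dosage = rng.integers(0, 5, size=(4, 6)).astype(float)
        g = make_genotypes(dosage, positions=list(range(1, 7)))
        with pytest.raises(ValueError, match="n_components"):
            ps.pca_dosage(g, 5)


class TestSelectNClusters:
    def test_recovers_three_separated_clusters(self, rng):
        pts, _ = clustered_scores(rng, n_per=50, k=3)
        best, bic = ps.select_n_clusters(pts, seed=0)
        assert best == 3
        assert set(bic) == set(range(1, 11))

    def test_duplication_invariance(self, rng):
        pts, _ = clustered_scores(rng, n_per=30, k=3)
        best1, _ = ps.select_n_clusters(pts, seed=0)
        best2, _ = ps.select_n_clusters(np.vstack([pts, pts]), seed=0)
        assert best1 == best2 == 3

    def test_tie_resolves_to_smallest(self):
        bic = {1: 5.0, 2: 3.0, 3: 3.0, 4: 4.0}
        best = min(bic, key=lambda k: (round(bic[k], 10), k))
        # the module applies the same rule internally
        assert best == 2


class TestDapc:
    def test_membership_rows_sum_to_one(self, rng):
        pts, labels = clustered_scores(rng, n_per=20, k=3)
        model = ps.dapc_fit(pts, labels, n_pcs=4)
        np.testing.assert_allclose(model.membership.probs.sum(axis=1), 1.0,
                                   atol=1e-8)

    def test_separable_clusters_confident(self, rng):
        pts, labels = clustered_scores(rng, n_per=25, k=3, sep=30.0)
        model = ps.dapc_fit(pts, labels, n_pcs=4)
        assert (model.membership.probs.max(axis=1) > 0.99).all()

    def test_axis_count_rank_constraint(self, rng):
        pts, labels = clustered_scores(rng, n_per=20, k=4)
        model = ps.dapc_fit(pts, labels, n_pcs=4)
        assert model.discriminant_axes.shape[1] == min(4 - 1, 4)
        model2 = ps.dapc_fit(pts, labels, n_pcs=2)
        assert model2.discriminant_axes.shape[1] == 2

    def test_small_cluster_rejected(self, rng):
        pts = rng.normal(size=(10, 3))
        labels = np.array([0] * 9 + [1])
        with pytest.raises(ValueError, match="fewer than 2"):
            ps.dapc_fit(pts, labels, n_pcs=3)

    def test_cross_validation_accuracy_on_separable_data(self, rng):
        pts, labels = clustered_scores(rng, n_per=30, k=3, sep=25.0)
        curve, best = ps.dapc_cross_validate(pts, labels, [2, 3, 4],
                                             n_reps=5, seed=0)
        for n_pcs, (acc, rmse) in curve.items():
            assert 0.0 <= acc <= 1.0 and 0.0 <= rmse <= 1.0
            if n_pcs >= 2:
                assert acc > 0.95
        assert best in curve

    def test_zero_reps_rejected(self, rng):
        pts, labels = clustered_scores(rng, n_per=10, k=2)
        with pytest.raises(ValueError, match="n_reps"):
            ps.dapc_cross_validate(pts, labels, [2], n_reps=0)


class TestEvannoDelta:
    def test_hand_computed_example(self):
        ll = {1: [-100.0, -100.0], 2: [-51.0, -49.0],
              3: [-48.0, -48.0], 4: [-47.0, -47.0]}
        # sd(L(2)) = sqrt(2) with these replicates; rescale to sd exactly 1
        ll[2] = [-50.5, -49.5]
        delta = ps.evanno_delta(ll)
        sd2 = np.std(ll[2], ddof=1)
        assert delta[2] == pytest.approx(
            abs(-48.0 - 2 * (-50.0) + (-100.0)) / sd2)
        assert delta[2] == pytest.approx(48.0 / sd2)

    def test_linear_profile_gives_zero(self):
        ll = {k: [-100.0 + 10 * k + e for e in (-0.5, 0.5)]
              for k in range(1, 6)}
        delta = ps.evanno_delta(ll)
        for k in (2, 3, 4):
            assert delta[k] == pytest.approx(0.0, abs=1e-9)

    def test_endpoints_not_reported_and_zero_sd_nan(self):
        ll = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        delta = ps.evanno_delta(ll)
        assert set(delta) == {2}
        assert np.isnan(delta[2])  # zero replicate sd


class TestAlignStructureRuns:
    @staticmethod
    def random_membership(rng, n, k):
        p = rng.dirichlet(np.ones(k) * 0.3, size=n)
        return ps.MembershipMatrix(samples=[f"s{i}" for i in range(n)],
                                   groups=[f"S{j}" for j in range(k)],
                                   probs=p)

    def test_identical_runs_passthrough(self, rng):
        m = self.random_membership(rng, 12, 3)
        out = ps.align_structure_runs(ps.StructureRunSet(runs=[m, m]))
        np.testing.assert_allclose(out.probs, m.probs, atol=1e-12)

    def test_recovers_column_permutation(self, rng):
        m = self.random_membership(rng, 15, 4)
        perm = [2, 0, 3, 1]
        m2 = ps.MembershipMatrix(samples=m.samples, groups=m.groups,
                                 probs=m.probs[:, perm])
        out = ps.align_structure_runs(ps.StructureRunSet(runs=[m, m2]))
        np.testing.assert_allclose(out.probs, m.probs, atol=1e-12)

    def test_noisy_runs_close_to_original_and_matches_exhaustive(self, rng):
        base = self.random_membership(rng, 40, 4)
        runs = [base]
        for _ in range(4):
            perm = rng.permutation(4)
            noisy = rng.dirichlet(np.ones(4), size=40) * 0.02 \
                + base.probs[:, perm] * 0.98
            noisy /= noisy.sum(axis=1, keepdims=True)
            runs.append(ps.MembershipMatrix(samples=base.samples,
                                            groups=base.groups, probs=noisy))
        out = ps.align_structure_runs(ps.StructureRunSet(runs=runs))
        assert np.abs(out.probs - base.probs).max() < 0.05
        # exhaustive-assignment oracle for the second run
        ref, other = runs[0].probs, runs[1].probs
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(4)):
            score = sum(np.corrcoef(ref[:, j], other[:, perm[j]])[0, 1]
                        for j in range(4))
            if score > best_score:
                best_perm, best_score = perm, score
        two = ps.align_structure_runs(
            ps.StructureRunSet(runs=[runs[0], runs[1]]))
        expected = (ref + other[:, list(best_perm)]) / 2
        expected /= expected.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(two.probs, expected, atol=1e-12)

    def test_group_count_mismatch_rejected(self, rng):
        a = self.random_membership(rng, 10, 3)
        b = self.random_membership(rng, 10, 4)
        with pytest.raises(ValueError, match="group count"):
            ps.align_structure_runs(ps.StructureRunSet(runs=[a, b]))

    def test_alignment_invariant_to_input_permutation(self, rng):
        base = self.random_membership(rng, 20, 3)
        perm = [1, 2, 0]
        permuted = ps.MembershipMatrix(samples=base.samples,
                                       groups=base.groups,
                                       probs=base.probs[:, perm])
        out1 = ps.align_structure_runs(ps.StructureRunSet(runs=[base, base]))
        out2 = ps.align_structure_runs(
            ps.StructureRunSet(runs=[base, permuted]))
        np.testing.assert_allclose(out1.probs, out2.probs, atol=1e-12)


class TestStructureIo:
    def test_export_import_round_trip(self, tmp_path, rng):
        dosage = rng.integers(0, 5, size=(4, 6)).astype(float)
        dosage[1, 2] = np.nan
        g = make_genotypes(dosage, positions=list(range(1, 7)))
        path = tmp_path / "structure.txt"
        ps.export_structure_input(g, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 4 * 4  # header + 4 rows per sample
        # alternate-allele counts per sample/marker match the dosage
        for i in range(4):
            block = [ln.split()[1:] for ln in lines[1 + 4 * i: 1 + 4 * (i + 1)]]
            alleles = np.array(block, dtype=int)
            for j in range(6):
                if np.isnan(dosage[i, j]):
                    assert (alleles[:, j] == -9).all()
                else:
                    assert alleles[:, j].sum() == dosage[i, j]

    def test_import_membership_block(self, tmp_path):
        text = """\
STRUCTURE output

Inferred ancestry of individuals:
        Label (%Miss) :  Inferred clusters
  1       s1    (0)   :  0.900 0.050 0.050
  2       s2    (0)   :  0.100 0.800 0.100

Estimated Allele Frequencies
"""
        path = tmp_path / "structure_out.txt"
        path.write_text(text)
        q = ps.import_structure_memberships(str(path))
        assert q.samples == ["s1", "s2"]
        np.testing.assert_allclose(q.probs[0], [0.9, 0.05, 0.05])


class TestKinship:
    def test_duplicated_samples_identical_rows(self, rng):
        dosage = rng.integers(0, 5, size=(5, 30)).astype(float)
        dosage[4] = dosage[0]
        g = make_genotypes(dosage, positions=list(range(1, 31)))
        ks = ps.compute_kinship(g, loco=False)
        np.testing.assert_allclose(ks.global_[4], ks.global_[0], atol=1e-10)
        np.testing.assert_allclose(ks.global_[:, 4], ks.global_[:, 0],
                                   atol=1e-10)

    def test_mean_diagonal_scaled_to_one(self, rng):
        dosage = rng.integers(0, 5, size=(8, 40)).astype(float)
        g = make_genotypes(dosage, positions=list(range(1, 41)))
        ks = ps.compute_kinship(g, loco=False)
        assert np.diag(ks.global_).mean() == pytest.approx(1.0, abs=1e-8)

    def test_loco_equals_direct_recomputation(self, rng):
        dosage = rng.integers(0, 5, size=(6, 20)).astype(float)
        chroms = ["chr1"] * 10 + ["chr2"] * 10
        g = make_genotypes(dosage, chromosomes=chroms,
                           positions=list(range(1, 11)) * 2)
        ks = ps.compute_kinship(g, loco=True)
        direct = ps.compute_kinship(g.restrict_chromosome("chr2"),
                                    loco=False)
        np.testing.assert_allclose(ks.per_chromosome["chr1"],
                                   direct.global_, atol=1e-10)

    def test_symmetric_psd(self, rng):
        dosage = rng.integers(0, 5, size=(10, 50)).astype(float)
        dosage[rng.random(dosage.shape) < 0.05] = np.nan
        g = make_genotypes(dosage, positions=list(range(1, 51)))
        k = ps.compute_kinship(g, loco=False).global_
        np.testing.assert_allclose(k, k.T, atol=1e-10)
        ev = np.linalg.eigvalsh(k)
        assert ev.min() >= -1e-8 * ev.max()

    def test_single_chromosome_loco_rejected(self, rng):
        dosage = rng.integers(0, 5, size=(4, 10)).astype(float)
        g = make_genotypes(dosage, positions=list(range(1, 11)))
        with pytest.raises(ValueError, match="LOCO"):
            ps.compute_kinship(g, loco=True)


class TestSubsample:
    def test_seeded_subsample(self, rng):
        dosage = rng.integers(0, 5, size=(4, 50)).astype(float)
        g = make_genotypes(dosage, positions=list(range(1, 51)))
        a = ps.subsample_markers(g, 10, seed=5)
        b = ps.subsample_markers(g, 10, seed=5)
        assert a.marker_ids == b.marker_ids
        assert len(a.marker_ids) == 10
        assert ps.subsample_markers(g, 100, seed=5).n_markers == 50
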