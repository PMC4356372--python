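"""Peak search, shape descriptors, labelling, SVM classification."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from nucleofit.crystal_maps import (
    AtomicModel,
    UnitCell,
    compute_structure_factors,
    synthesize_map,
)
from nucleofit.fiber import HelixSpec, generate_helix
from nucleofit.phosphate_detect import (
    PeakFeatures,
    PhosphateSet,
    compute_features,
    find_peaks,
    label_peaks,
    predict_phosphates,
    train_classifier,
)
from nucleofit.validate import match_point_sets

from conftest import P2_OPS, blob_map, blob_model


class TestFindPeaks:
    def test_single_gaussian_single_peak(self, toy_cell):
        dmap = blob_map([(10.0, 12.0, 14.0)], toy_cell)
        peaks = find_peaks(dmap, min_height=2.0)
        assert len(peaks) == 1
        step = 30.0 / min(dmap.shape)
        assert np.linalg.norm(peaks[0].position - [10, 12, 14]) < step

    def test_close_doublet_suppressed_to_stronger(self, toy_cell):
        strong = AtomicModel.from_rows([
            ("P", "P", "PO4", 1, "X", (10.0, 10.0, 10.0), 10.0, 1.0),
            ("O", "O", "PO4", 2, "X", (13.0, 10.0, 10.0), 10.0, 1.0),
        ])
        dmap = synthesize_map(compute_structure_factors(strong, toy_cell,
                                                        d_min=2.5))
        peaks = find_peaks(dmap, min_height=2.0)
        near = [p for p in peaks
                if np.linalg.norm(p.position - [11.5, 10, 10]) < 4.0]
        assert len(near) == 1  # the weaker of the pair is suppressed
        assert np.linalg.norm(near[0].position - [10, 10, 10]) < 1.0

    def test_five_separated_gaussians(self, toy_cell):
        centers = [(5, 5, 5), (15, 5, 5), (5, 15, 5), (5, 5, 15),
                   (15, 15, 15)]
        peaks = find_peaks(blob_map(centers, toy_cell), min_height=2.0)
        assert len(peaks) == 5

    def test_sorted_descending_and_min_separation(self, helix_map_4A):
        peaks = find_peaks(helix_map_4A)
        values = [p.value for p in peaks]
        assert values == sorted(values, reverse=True)
        pos = np.array([p.position for p in peaks])
        from nucleofit.crystal_maps import min_symmetry_distance

        for i in range(len(pos)):
            others = np.delete(pos, i, axis=0)
            d = min_symmetry_distance(pos[i], others, helix_map_4A.cell,
                                      helix_map_4A.ops)
            assert d[0] >= 4.0 - 1e-6

    def test_periodic_suppression_across_cell_boundary(self, toy_cell):
        # two blobs 3 A apart through the periodic boundary
        dmap = blob_map([(1.0, 10.0, 10.0), (28.0, 10.0, 10.0)], toy_cell)
        peaks = find_peaks(dmap, min_height=2.0)
        assert len(peaks) == 1


class TestFeatures:
    def test_spherical_peak_has_unit_opposed_correlation(self, toy_cell):
        dmap = blob_map([(15.0, 15.0, 15.0)], toy_cell)
        peaks = find_peaks(dmap, min_height=2.0)
        feats = compute_features(dmap, peaks, scale=False)
        assert feats[0].opposed_correlation == pytest.approx(1.0, abs=0.05)
        assert feats[0].inertia_ratio == pytest.approx(0.0, abs=0.05)

    def test_tetrahedral_cluster_negative_opposed_correlation(self, toy_cell):
        c = np.array([15.0, 15.0, 15.0])
        verts = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1),
                          (-1, -1, 1)]) / np.sqrt(3.0)
        dmap = blob_map([tuple(c + 1.56 * v) for v in verts], toy_cell,
                        element="O")
        # the cluster maximum is at the centroid
        peaks = find_peaks(dmap, min_height=1.0)
        centre_peak = min(peaks,
                          key=lambda p: np.linalg.norm(p.position - c))
        feats = compute_features(dmap, [centre_peak], scale=False)
        assert feats[0].opposed_correlation < 0.0

    def test_rank_convention_strongest_is_one(self, helix_map_4A):
        peaks = find_peaks(helix_map_4A)
        feats = compute_features(helix_map_4A, peaks)
        raw = compute_features(helix_map_4A, peaks, scale=False)
        means = [f.rank_intensity for f in raw]
        assert feats[int(np.argmax(means))].rank_intensity == 1.0
        assert feats[int(np.argmin(means))].rank_intensity == 0.0
        for f in feats:
            assert 0.0 <= f.rank_intensity <= 1.0
            assert 0.0 <= f.opposed_correlation <= 1.0
            assert 0.0 <= f.inertia_ratio <= 1.0

    def test_inertia_ratio_nonpositive_before_scaling(self, helix_map_4A):
        peaks = find_peaks(helix_map_4A)
        raw = compute_features(helix_map_4A, peaks, scale=False)
        assert all(f.inertia_ratio <= 1e-9 for f in raw)

    def test_rigid_motion_invariance(self):
        """Raw features of the phosphate peaks are unchanged (within grid
        noise) when the underlying model is rigidly moved in the cell."""
        hel = generate_helix(HelixSpec("A-RNA", 4)).fragment
        cell = UnitCell(36, 36, 36)

        def mean_features(R, t):
            model = hel.transformed(R, t)
            dmap = synthesize_map(compute_structure_factors(model, cell,
                                                            d_min=2.5),
                                  grid_factor=4.0)
            peaks = find_peaks(dmap)
            feats = compute_features(dmap, peaks, scale=False)
            order = np.argsort([-p.value for p in peaks])[:6]
            return np.array([feats[i].as_array() for i in order]).mean(axis=0)

        a = mean_features(np.eye(3), np.array([16.0, 16.0, 10.0]))
        for state in (1, 2):
            R = Rotation.random(random_state=state).as_matrix()
            b = mean_features(R, np.array([18.0, 14.0, 16.0]))
            assert abs(a[0] - b[0]) / a[0] < 0.05   # mean intensity, relative
            assert np.allclose(a[1:], b[1:], atol=0.05)  # shape features


class TestLabelling:
    def test_exact_hit_and_near_miss(self, helix_map_4A, helix_crystal):
        truth, cell = helix_crystal
        from nucleofit.phosphate_detect import Peak

        p0 = truth.atoms_named("P")[0]
        peaks = [Peak(p0.copy(), 5.0),
                 Peak(p0 + np.array([1.6, 0, 0]), 4.0)]
        labels = label_peaks(peaks, truth, cell)
        # the displaced peak may still sit near ANOTHER P; check explicitly
        assert labels[0] == 1
        d = np.linalg.norm(truth.atoms_named("P")
                           - (p0 + np.array([1.6, 0, 0])), axis=1).min()
        assert labels[1] == int(d < 1.5)

    def test_symmetry_mate_counts_as_hit(self):
        cell = UnitCell(20, 20, 20)
        ref = blob_model([(3.0, 4.0, 5.0)])
        from nucleofit.phosphate_detect import Peak

        # image under the two-fold (-x, y, -z) is (-3, 4, -5) = (17, 4, 15)
        peak = Peak(np.array([17.0, 4.0, 15.0 + 1.4]), 5.0)
        labels = label_peaks([peak], ref, cell, P2_OPS)
        assert labels[0] == 1
        # brute-force oracle over all operator images and lattice shifts
        best = np.inf
        for R, t in P2_OPS:
            frac = cell.fractionalize(np.array([[3.0, 4.0, 5.0]]))[0]
            img = frac @ R.T + t
            for sh in np.ndindex(3, 3, 3):
                g = img + np.array(sh) - 1
                d = np.linalg.norm(cell.orthogonalize(g) - peak.position)
                best = min(best, d)
        assert (best < 1.5) == bool(labels[0])

    def test_reference_without_p_errors(self, helix_map_4A):
        from nucleofit.phosphate_detect import Peak

        ref = blob_model([(1, 1, 1)], element="O")
        with pytest.raises(ValueError):
            label_peaks([Peak(np.zeros(3), 1.0)], ref,
                        helix_map_4A.cell)


class TestClassifier:
    def _separable_data(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        pos = rng.normal([0.8, 0.8, 0.8], 0.05, (n // 2, 3))
        neg = rng.normal([0.2, 0.2, 0.2], 0.05, (n // 2, 3))
        X = np.vstack([pos, neg]).clip(0, 1)
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        feats = [PeakFeatures(*row) for row in X]
        return feats, y

    def test_separable_data_high_recall(self):
        feats, y = self._separable_data()
        clf = train_classifier(feats, y, seed=1)
        assert clf.cv_recall >= 0.99

    def test_single_class_errors(self):
        feats, y = self._separable_data()
        with pytest.raises(ValueError):
            train_classifier(feats, np.ones_like(y), seed=1)

    def test_same_seed_same_hyperparameters(self):
        feats, y = self._separable_data()
        a = train_classifier(feats, y, seed=7)
        b = train_classifier(feats, y, seed=7)
        assert a.best_params == b.best_params

    def test_label_permutation_destroys_precision(self):
        """With permuted labels the classifier cannot beat the class prior:
        held-out precision collapses to roughly the positive fraction."""
        rng = np.random.default_rng(3)
        n = 160
        X = rng.uniform(0, 1, (n, 3))
        y = (X[:, 0] + X[:, 1] > 1.0).astype(int)
        feats = [PeakFeatures(*row) for row in X]
        prior = y.mean()
        precisions = []
        for rep in range(5):
            perm = rng.permutation(y)
            try:
                clf = train_classifier(feats[:n // 2], perm[:n // 2],
                                       seed=rep)
            except ValueError:
                continue
            pred = clf.predict(feats[n // 2:])
            truth = perm[n // 2:]
            if pred.sum():
                precisions.append(truth[pred == 1].mean())
        assert precisions, "no repeats produced positive predictions"
        assert np.mean(precisions) == pytest.approx(prior, abs=0.15)


class TestPrediction:
    def test_planted_duplex_recovery(self, helix_map_good, helix_crystal,
                                     suite_classifier):
        truth, cell = helix_crystal
        phos = predict_phosphates(helix_map_good, suite_classifier,
                                  expected_nucleotides=16)
        ref_p = truth.atoms_named("P")
        pairs = match_point_sets(phos.positions, ref_p, cell)
        assert len(pairs) / len(ref_p) >= 0.8

    def test_rejecting_classifier_gives_empty_set(self, helix_map_4A):
        class _Reject:
            def predict(self, feats):
                return np.zeros(len(feats), int)

            def decision_scores(self, feats):
                return -np.ones(len(feats))

        phos = predict_phosphates(helix_map_4A, _Reject())
        assert len(phos) == 0

    def test_greedy_assignment_equals_hungarian(self):
        """On phosphate-like instances (reference points separated by more
        than twice the 1.5 Å cutoff) the greedy one-to-one matching count
        equals the optimal assignment, for up to 20 points."""
        cell = UnitCell(60, 60, 60)
        rng = np.random.default_rng(11)
        for _case in range(20):
            # well-separated reference points, as real P patterns are
            ref = []
            while len(ref) < 15:
                q = rng.uniform(5, 55, 3)
                if not ref or np.linalg.norm(np.array(ref) - q,
                                             axis=1).min() > 5.0:
                    ref.append(q)
            ref = np.array(ref)
            hits = ref[rng.random(len(ref)) < 0.7] \
                + rng.uniform(-0.7, 0.7, (0, 3)).sum()  # subset of refs
            hits = hits + rng.uniform(-0.7, 0.7, hits.shape)
            decoys = rng.uniform(5, 55, (5, 3))
            pred = np.vstack([hits, decoys])
            pairs = match_point_sets(pred, ref, cell, cutoff=1.5)
            d = np.linalg.norm(pred[:, None] - ref[None], axis=-1)
            big = 1e6
            cost = np.where(d < 1.5, d, big)
            ri, ci = linear_sum_assignment(cost)
            optimal = int((cost[ri, ci] < big).sum())
            assert len(pairs) == optimal
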