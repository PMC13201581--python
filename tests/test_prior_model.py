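import numpy as np
import pytest
from lobeprior import prior_model as pm
from lobeprior.metrics import dice
from lobeprior.volume_io import CTVolume, LabelMap, default_affine


def lm(labels):
    labels = np.asarray(labels, dtype=np.int16)
    return LabelMap(labels, (1, 1, 1), default_affine((1, 1, 1)))


def cv(data, normalized=True):
    return CTVolume(np.asarray(data, float), (1, 1, 1),
                    default_affine((1, 1, 1)), normalized=normalized)


def brute_force_partition(d, threshold):
    """Flood-fill over the >= threshold adjacency as an independent oracle."""
    n = len(d)
    unvisited = set(range(n))
    groups = []
    while unvisited:
        start = min(unvisited)
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            unvisited.discard(i)
            stack.extend(j for j in range(n)
                         if j not in comp and d[i, j] >= threshold)
        groups.append(sorted(comp))
    groups.sort(key=lambda g: g[0])
    return groups


class TestGrouping:
    def test_identical_maps_single_group(self, phantom48_clean):
        _, lab, _ = phantom48_clean
        g = pm.group_by_dice([lab, lab.copy(), lab.copy()])
        assert g.groups == [[0, 1, 2]]
        np.testing.assert_allclose(g.dice_matrix, 1.0)

    def test_disjoint_anatomies_singletons(self):
        a = np.zeros((34, 34, 34), dtype=np.int16)
        b = np.zeros((34, 34, 34), dtype=np.int16)
        for k in range(1, 6):
            a[k * 2, :4, :4] = k
            b[k * 2 + 20, 30:, 30:] = k
        g = pm.group_by_dice([lm(a), lm(b)])
        assert g.groups == [[0], [1]]

    def test_mixed_grids_rejected(self, phantom48_clean):
        _, lab, _ = phantom48_clean
        other = lm(np.zeros((34, 34, 34), dtype=np.int16))
        with pytest.raises(ValueError):
            pm.group_by_dice([lab, other])

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 9))
            d = rng.random((n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 1.0)
            got = pm.group_from_matrix(d, 0.80)
            assert got.groups == brute_force_partition(d, 0.80)

    def test_partition_covers_all_members_once(self, cohort6):
        labs = [l for _, l in cohort6]
        g = pm.group_by_dice(labs, threshold=0.85)
        members = sorted(i for grp in g.groups for i in grp)
        assert members == list(range(6))


class TestBuildAtlas:
    def test_single_member_prior_is_one_hot_presmoothing(self, phantom48_clean):
        vol, lab, _ = phantom48_clean
        atlas = pm.build_atlas([(cv(vol.intensities), lab)], sigma=0.0)
        for k in range(1, 6):
            np.testing.assert_array_equal(atlas.probs[k - 1] > 0.5,
                                          lab.labels == k)

    def test_two_member_disagreement_is_half_half(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        b = np.zeros((4, 4, 4), dtype=np.int16)
        a[1, 1, 1], b[1, 1, 1] = 2, 3
        members = [(cv(np.zeros((4, 4, 4))), lm(a)),
                   (cv(np.zeros((4, 4, 4))), lm(b))]
        # sigma=0 keeps the raw label fractions
        atlas = pm.build_atlas(members, sigma=0.0)
        assert atlas.probs[1, 1, 1, 1] == pytest.approx(0.5)
        assert atlas.probs[2, 1, 1, 1] == pytest.approx(0.5)

    def test_channel_sums_one_on_support(self, cohort6):
        members = [(cv(c.intensities / 1000.0), l) for c, l in cohort6]
        atlas = pm.build_atlas(members, sigma=1.0)
        sums = atlas.probs.sum(axis=0)
        assert np.abs(sums[atlas.support] - 1.0).max() < 1e-6
        assert np.all(sums[~atlas.support] == 0.0)
        assert atlas.probs.min() >= 0.0 and atlas.probs.max() <= 1.0

    def test_permutation_invariant(self, cohort6):
        members = [(cv(c.intensities / 1000.0), l) for c, l in cohort6[:4]]
        a1 = pm.build_atlas(members)
        a2 = pm.build_atlas(members[::-1])
        np.testing.assert_allclose(a1.probs, a2.probs, atol=1e-12)

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            pm.build_atlas([])


class TestCompositeSimilarity:
    def test_identical_images_forced_terms(self, rng):
        a = cv(rng.random((16, 16, 16)))
        from lobeprior.similarity import mutual_information

        score = pm.composite_similarity(a, a)
        mi_self = mutual_information(a.intensities, a.intensities)
        assert score == pytest.approx(2.0 + mi_self)

    def test_negated_image_zero_ncc_term(self, rng):
        x = rng.random((16, 16, 16))
        a, b = cv(x), cv(1.0 - x)
        from lobeprior.similarity import mse, mutual_information

        score = pm.composite_similarity(a, b)
        expected = (1.0 / (1.0 + mse(x, 1.0 - x)) + 0.0
                    + mutual_information(x, 1.0 - x))
        assert score == pytest.approx(expected)

    def test_independent_noise_oracle_terms(self):
        r0 = np.random.default_rng(0).random((64, 64, 64))
        r1 = np.random.default_rng(1).random((64, 64, 64))
        from lobeprior.similarity import mse, mutual_information, ncc

        score = pm.composite_similarity(cv(r0), cv(r1))
        expected = (1.0 / (1.0 + mse(r0, r1)) + (ncc(r0, r1) + 1.0) / 2.0
                    + mutual_information(r0, r1))
        assert score == pytest.approx(expected, abs=1e-9)

    def test_self_similarity_dominates(self, cohort6):
        from lobeprior.volume_io import normalize_hu

        vols = [normalize_hu(c) for c, _ in cohort6[:3]]
        for a in vols:
            self_score = pm.composite_similarity(a, a)
            for b in vols:
                if b is a:
                    continue
                assert self_score >= pm.composite_similarity(a, b)

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pm.composite_similarity(cv(rng.random((8, 8, 8))),
                                    cv(rng.random((9, 8, 8))))


class TestFillFromAtlas:
    @pytest.fixture()
    def atlas48(self, cohort6):
        members = [(cv(c.intensities / 1000.0), l) for c, l in cohort6]
        return pm.build_atlas(members, sigma=1.0)

    def test_complete_segmentation_unchanged(self, cohort6, atlas48):
        _, lab = cohort6[0]
        lung = (lab.labels >= 1) & (lab.labels <= 5)
        out = pm.fill_from_atlas(lab, lung, atlas48)
        np.testing.assert_array_equal(out.labels, lab.labels)

    def test_carved_hole_recovered_with_true_lobe(self, cohort6, atlas48):
        _, lab = cohort6[0]
        carved = lab.labels.copy()
        center = np.argwhere(carved == 3).mean(axis=0).astype(int)
        sl = tuple(slice(c - 5, c + 5) for c in center)
        hole = np.zeros(carved.shape, bool)
        hole[sl] = carved[sl] == 3
        carved[hole] = 0
        lung = (lab.labels >= 1) & (lab.labels <= 5)
        out = pm.fill_from_atlas(LabelMap(carved, lab.spacing, lab.affine),
                                 lung, atlas48)
        assert not (lung & (out.labels == 0)).any()
        assert (out.labels[hole] == 3).mean() >= 0.95

    def test_tie_breaks_to_lower_channel(self):
        probs = np.zeros((5, 34, 34, 34))
        probs[1] = 0.5
        probs[2] = 0.5
        atlas = pm.ProbAtlas(probs, cv(np.zeros((34, 34, 34))), 0, 1)
        seg = lm(np.zeros((34, 34, 34), dtype=np.int16))
        lung = np.zeros((34, 34, 34), bool)
        lung[10:20, 10:20, 10:20] = True
        out = pm.fill_from_atlas(seg, lung, atlas)
        assert np.all(out.labels[lung] == 2)  # channel idx 1 -> lobe code 2

    def test_no_support_falls_back_to_nearest_label(self):
        probs = np.zeros((5, 34, 34, 34))
        atlas = pm.ProbAtlas(probs, cv(np.zeros((34, 34, 34))), 0, 1)
        seg_arr = np.zeros((34, 34, 34), dtype=np.int16)
        seg_arr[0:5] = 4
        lung = np.zeros((34, 34, 34), bool)
        lung[0:8] = True
        out = pm.fill_from_atlas(lm(seg_arr), lung, atlas)
        assert np.all(out.labels[lung] == 4)


class TestSelectAtlas:
    def test_reference_input_selects_own_atlas(self, cohort6):
        from lobeprior.volume_io import normalize_hu

        vols = [(normalize_hu(c), l) for c, l in cohort6]
        a0 = pm.build_atlas([vols[0]], group_id=0, reference=vols[0][0])
        a1 = pm.build_atlas([vols[3]], group_id=1, reference=vols[3][0])
        atlas, t = pm.select_atlas(vols[0][0], [a0, a1], levels=(10, 5))
        assert atlas.group_id == 0

    def test_single_atlas_returned_directly(self, cohort6):
        from lobeprior.volume_io import normalize_hu

        vols = [(normalize_hu(c), l) for c, l in cohort6]
        a0 = pm.build_atlas([vols[0]], group_id=0, reference=vols[0][0])
        atlas, t = pm.select_atlas(vols[1][0], [a0], levels=(10, 5))
        assert atlas is a0
        assert t.forward_field is not None

    def test_empty_list_rejected(self, cohort6):
        from lobeprior.volume_io import normalize_hu

        with pytest.raises(ValueError):
            pm.select_atlas(normalize_hu(cohort6[0][0]), [])
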