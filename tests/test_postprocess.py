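import numpy as np
import pytest
from scipy import ndimage

from lobeprior import prior_model as pm
from lobeprior.network import StagePrediction
from lobeprior.postprocess import finalize, fuse_decoders, largest_component
from lobeprior.volume_io import CTVolume, default_affine


def brute_largest_component(mask):
    """Flood-fill (26-neighborhood) oracle."""
    mask = np.asarray(mask, bool)
    best = np.zeros_like(mask)
    visited = np.zeros_like(mask)
    offsets = [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1)
               for c in (-1, 0, 1) if (a, b, c) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask & ~visited)):
        if visited[start]:
            continue
        comp = []
        stack = [start]
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for o in offsets:
                n = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) \
                        and mask[n] and not visited[n]:
                    visited[n] = True
                    stack.append(n)
        if len(comp) > best.sum():
            best = np.zeros_like(mask)
            best[tuple(np.array(comp).T)] = True
    return best


class TestLargestComponent:
    def test_keeps_bigger_of_two_blobs(self):
        m = np.zeros((12, 12, 12), bool)
        m[1:6, 1:6, 1:6] = True      # 125 voxels
        m[9:11, 9:11, 9:11] = True   # 8 voxels
        out = largest_component(m)
        assert out[2, 2, 2] and not out[9, 9, 9]

    def test_single_blob_unchanged(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:5, 2:5, 2:5] = True
        np.testing.assert_array_equal(largest_component(m), m)

    def test_empty_input_empty_output(self):
        assert not largest_component(np.zeros((4, 4, 4), bool)).any()

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(20):
            m = rng.random((12, 12, 12)) > 0.8
            got = largest_component(m)
            want = brute_largest_component(m)
            assert got.sum() == want.sum()  # unique size -> same component
            lab, _ = ndimage.label(m, structure=np.ones((3, 3, 3)))
            assert len(np.unique(lab[got])) <= 2  # one component (+0)


def pred_from(act):
    return StagePrediction(np.asarray(act, dtype=np.float32), stage=2)


class TestFuseDecoders:
    def _base_act(self, shape=(8, 8, 8)):
        act = np.zeros((7,) + shape, dtype=np.float32)
        act[5] = 0.9  # whole lung everywhere
        return act

    def test_highest_lobe_activation_wins(self):
        act = self._base_act()
        act[0] = 0.9
        act[1] = 0.6
        fr = fuse_decoders(pred_from(act))
        assert np.all(fr.labels.labels == 1)

    def test_below_threshold_becomes_gap(self):
        act = self._base_act()
        act[:5] = 0.4
        act[6] = 0.3
        fr = fuse_decoders(pred_from(act))
        assert np.all(fr.labels.labels == 0)
        np.testing.assert_array_equal(fr.gap_mask, fr.lung_mask)

    def test_activation_outside_lung_disregarded(self):
        act = np.zeros((7, 8, 8, 8), dtype=np.float32)
        act[5, :4] = 0.9          # lung only in lower half
        act[0] = 0.95             # lobe confident everywhere
        fr = fuse_decoders(pred_from(act))
        assert np.all(fr.labels.labels[:4] == 1)
        assert np.all(fr.labels.labels[4:] == 0)

    def test_airway_assigned_when_argmax(self):
        act = self._base_act()
        act[6] = 0.95
        act[2] = 0.7
        fr = fuse_decoders(pred_from(act))
        assert np.all(fr.labels.labels == 6)

    def test_tie_breaks_to_lowest_channel(self):
        act = self._base_act()
        act[1] = 0.8
        act[3] = 0.8
        fr = fuse_decoders(pred_from(act))
        assert np.all(fr.labels.labels == 2)  # channel 1 -> lobe code 2

    def test_lung_mask_drops_small_satellite_components(self):
        act = np.zeros((7, 12, 12, 12), dtype=np.float32)
        act[5, 1:8, 1:8, 1:8] = 0.9
        act[5, 10:12, 10:12, 10:12] = 0.9  # small satellite
        fr = fuse_decoders(pred_from(act))
        assert fr.lung_mask[2, 2, 2] and not fr.lung_mask[11, 11, 11]

    def test_lung_mask_keeps_both_disjoint_lungs(self):
        act = np.zeros((7, 12, 12, 12), dtype=np.float32)
        act[5, :, :, 1:5] = 0.9   # left lung
        act[5, :, :, 7:11] = 0.9  # right lung, disjoint
        fr = fuse_decoders(pred_from(act))
        assert fr.lung_mask[6, 6, 2] and fr.lung_mask[6, 6, 8]

    def test_out_of_range_activations_rejected(self):
        act = self._base_act()
        act[0, 0, 0, 0] = 1.5
        with pytest.raises(FloatingPointError):
            fuse_decoders(pred_from(act))

    def test_per_decoder_satellite_components_dropped(self):
        act = self._base_act((12, 12, 12))
        act[0, 1:8, 1:8, 1:8] = 0.9
        act[0, 10:12, 10:12, 10:12] = 0.99  # disconnected satellite
        fr = fuse_decoders(pred_from(act))
        assert fr.labels.labels[11, 11, 11] != 1


class TestFinalize:
    def test_no_gaps_identity_transform_is_cleanup_only(self, phantom48_clean):
        vol, lab, _ = phantom48_clean
        act = np.zeros((7,) + lab.shape, dtype=np.float32)
        for k in range(1, 6):
            act[k - 1][lab.labels == k] = 0.9
        act[5][(lab.labels >= 1) & (lab.labels <= 5)] = 0.9
        act[6][lab.labels == 6] = 0.9
        fr = fuse_decoders(pred_from(act))
        native = CTVolume(vol.intensities, vol.spacing, vol.affine)
        out = finalize(fr, None, None, native)
        assert out.shape == native.shape
        lung = (lab.labels >= 1) & (lab.labels <= 5)
        agree = (out.labels == lab.labels)[lung].mean()
        assert agree > 0.99

    def test_carved_region_filled_by_prior(self, cohort6):
        vol, lab = cohort6[0]
        members = [(CTVolume(c.intensities / 1000.0, c.spacing, c.affine,
                             True), l) for c, l in cohort6]
        atlas = pm.build_atlas(members, sigma=1.0)
        act = np.zeros((7,) + lab.shape, dtype=np.float32)
        for k in range(1, 6):
            act[k - 1][lab.labels == k] = 0.9
        act[5][(lab.labels >= 1) & (lab.labels <= 5)] = 0.9
        # zero network confidence in a 10^3 region inside RLL
        center = np.argwhere(lab.labels == 3).mean(axis=0).astype(int)
        sl = tuple(slice(c - 5, c + 5) for c in center)
        carved = np.zeros(lab.shape, bool)
        carved[sl] = True
        act[:5][:, carved] = 0.0
        fr = fuse_decoders(pred_from(act))
        assert fr.gap_mask.any()
        native = CTVolume(vol.intensities, vol.spacing, vol.affine)
        out = finalize(fr, atlas, None, native)
        lung = fr.lung_mask
        assert not (lung & (out.labels == 0)).any()
        hole_lung = carved & lung
        assert (out.labels[hole_lung] == 3).mean() >= 0.95

    def test_native_shape_restored(self, phantom48_clean):
        vol, lab, _ = phantom48_clean
        act = np.zeros((7,) + lab.shape, dtype=np.float32)
        act[5][(lab.labels >= 1) & (lab.labels <= 5)] = 0.9
        act[0][(lab.labels >= 1) & (lab.labels <= 5)] = 0.9
        fr = fuse_decoders(pred_from(act))
        native = CTVolume(np.zeros((40, 44, 48)), (1.2, 1.1, 1.0),
                          default_affine((1.2, 1.1, 1.0)))
        out = finalize(fr, None, None, native)
        assert out.shape == (40, 44, 48)

    def test_each_lobe_single_connected_component(self, phantom48_clean, rng):
        _, lab, _ = phantom48_clean
        act = np.zeros((7,) + lab.shape, dtype=np.float32)
        for k in range(1, 6):
            act[k - 1][lab.labels == k] = 0.9
        act[5][(lab.labels >= 1) & (lab.labels <= 5)] = 0.9
        # sprinkle noise voxels
        noise = rng.random(lab.shape) > 0.995
        act[1][noise] = 0.95
        fr = fuse_decoders(pred_from(act))
        native = CTVolume(np.zeros(lab.shape), (1, 1, 1),
                          default_affine((1, 1, 1)))
        out = finalize(fr, None, None, native)
        for k in range(1, 6):
            _, n = ndimage.label(out.labels == k, np.ones((3, 3, 3)))
            assert n == 1
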