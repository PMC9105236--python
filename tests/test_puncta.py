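"""Maxima detection and confocal cross-check: brute-force oracle equivalence,
threshold monotonicity, translation equivariance, recall/precision on
ground-truthed volumes, artifact removal."""

import numpy as np
import pytest

from synaptect.puncta import confocal_crosscheck, detect_maxima, read_puncta_csv
from synaptect.synthetic import VolumeSpec, generate_synapse_volume, render_spots
from synaptect.volume import ImageVolume

VOXEL = (0.02, 0.02, 0.05)


def brute_force_maxima(data: np.ndarray, min_intensity: float) -> set[tuple[int, int, int]]:
    """Exhaustive neighbourhood scan implementing the detection rule directly:
    no 26-neighbour greater, every equal neighbour lexicographically larger."""
    nz, ny, nx = data.shape
    out = set()
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                v = data[z, y, x]
                if v < min_intensity or v <= 0:
                    continue
                ok = True
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if dz == dy == dx == 0:
                                continue
                            zz, yy, xx = z + dz, y + dy, x + dx
                            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                                continue
                            w = data[zz, yy, xx]
                            if w > v or (w == v and (zz, yy, xx) < (z, y, x)):
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if ok:
                    out.add((z, y, x))
    return out


def make_volume(data, modality="STED", channel="pre", voxel=VOXEL):
    return ImageVolume(np.asarray(data, dtype=float), np.asarray(voxel), modality, channel)


def match_counts(found_um: np.ndarray, truth_um: np.ndarray, radius_um: float = 0.1):
    """Greedy nearest-neighbour one-to-one matching by brute force."""
    if len(found_um) == 0 or len(truth_um) == 0:
        return 0
    d = np.linalg.norm(found_um[:, None, :] - truth_um[None, :, :], axis=2)
    matched = 0
    used_f, used_t = set(), set()
    for _ in range(min(len(found_um), len(truth_um))):
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] > radius_um:
            break
        matched += 1
        d[i, :] = np.inf
        d[:, j] = np.inf
    return matched


class TestDetectMaxima:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan_exactly(self, seed):
        # small integer-valued volumes force plateaus, exercising tie-breaks
        rng = np.random.default_rng(seed)
        data = rng.integers(0, 6, size=(8, 10, 9)).astype(float)
        vol = make_volume(data)
        found = detect_maxima(vol, min_intensity=2.0, min_separation_nm=0.0,
                              refine_subvoxel=False)
        got = {tuple(i) for i in vol.um_to_index(found.coords_um)}
        assert got == brute_force_maxima(data, 2.0)

    def test_single_spot_found_at_its_centre(self):
        grid = np.zeros((20, 50, 50))
        centre = np.array([[0.5, 0.5, 0.5]])
        render_spots(grid, VOXEL, centre, 60.0, 10.0)
        found = detect_maxima(make_volume(grid), min_intensity=1e-6)
        assert len(found) == 1
        assert np.linalg.norm(found.coords_um[0] - centre[0]) < max(VOXEL) / 2

    def test_close_pair_suppressed_to_brighter(self):
        grid = np.zeros((20, 50, 50))
        bright, dim = np.array([0.5, 0.5, 0.5]), np.array([0.55, 0.5, 0.5])
        render_spots(grid, VOXEL, bright[None], 60.0, 10.0)
        render_spots(grid, VOXEL, dim[None], 60.0, 5.0)
        found = detect_maxima(make_volume(grid), min_intensity=1e-6,
                              min_separation_nm=200.0)
        assert len(found) == 1
        assert np.linalg.norm(found.coords_um[0] - bright) < 0.05

    def test_empty_cases(self):
        assert len(detect_maxima(make_volume(np.zeros((5, 5, 5))))) == 0
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        assert len(detect_maxima(make_volume(data), min_intensity=2.0)) == 0

    def test_non_sted_volume_rejected(self):
        with pytest.raises(ValueError, match="STED"):
            detect_maxima(make_volume(np.zeros((5, 5, 5)), modality="confocal"))

    def test_raising_threshold_never_adds_punctae(self):
        rng = np.random.default_rng(5)
        data = rng.gamma(2.0, 1.0, size=(10, 20, 20))
        vol = make_volume(data)
        counts = [
            len(detect_maxima(vol, min_intensity=th, min_separation_nm=0.0))
            for th in (1.0, 2.0, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        grid = np.zeros((20, 40, 40))
        render_spots(grid, VOXEL, np.array([[0.3, 0.35, 0.4]]), 60.0, 10.0)
        vol = make_volume(grid)
        shifted = make_volume(np.roll(grid, (2, 3, -4), axis=(0, 1, 2)))
        a = detect_maxima(vol, min_intensity=1e-6)
        b = detect_maxima(shifted, min_intensity=1e-6)
        offset_um = np.array([-4 * VOXEL[0], 3 * VOXEL[1], 2 * VOXEL[2]])
        np.testing.assert_allclose(b.coords_um, a.coords_um + offset_um, atol=1e-9)

    def test_recall_and_precision_on_ground_truth(self):
        # well-separated punctae at SNR 10: >= 95% recall and precision at
        # a 100 nm match radius against the generator's truth
        spec = VolumeSpec(
            size_um=(5.0, 5.0, 2.0), voxel_um=VOXEL, synapse_density=0.0,
            distractor_density_pre=0.8, distractor_density_post=0.0,
            sted_only_artifact_density=0.0, snr=10.0, seed=13,
        )
        sted_pre, _, _, _, truth = generate_synapse_volume(spec)
        found = detect_maxima(sted_pre, min_intensity=5.0)
        n_true = len(truth.pre_loci)
        matched = match_counts(found.coords_um, truth.pre_loci)
        assert n_true > 20
        assert matched / n_true >= 0.95          # recall
        assert matched / len(found) >= 0.95      # precision


class TestConfocalCrosscheck:
    def _volumes_with_artifacts(self):
        shape = (20, 200, 200)  # 4 x 4 x 1 um at VOXEL
        true_pts = np.array([[1.0, 1.0, 0.5], [3.0, 1.2, 0.4], [1.2, 3.0, 0.6]])
        artifacts = np.array([[3.0, 3.0, 0.5], [1.5, 1.6, 0.3]])
        rng = np.random.default_rng(0)
        sted = np.zeros(shape)
        render_spots(sted, VOXEL, true_pts, 60.0, 10.0)
        render_spots(sted, VOXEL, artifacts, 60.0, 10.0)
        sted += np.abs(rng.normal(0, 0.02, size=shape))
        conf = np.zeros(shape)
        render_spots(conf, VOXEL, true_pts, 250.0, 10.0)
        return make_volume(sted), make_volume(conf, modality="confocal"), true_pts, artifacts

    def test_sted_only_artifacts_removed_true_punctae_kept(self):
        sted, conf, true_pts, artifacts = self._volumes_with_artifacts()
        raw = detect_maxima(sted, min_intensity=0.15)
        assert len(raw) == len(true_pts) + len(artifacts)
        kept = confocal_crosscheck(raw, conf)
        assert len(kept) == len(true_pts)
        assert match_counts(kept.coords_um, true_pts) == len(true_pts)
        assert kept.provenance == "confocal_validated"

    def test_zero_confocal_validates_nothing(self):
        sted, conf, *_ = self._volumes_with_artifacts()
        raw = detect_maxima(sted, min_intensity=0.15)
        empty_conf = make_volume(np.zeros(conf.data.shape), modality="confocal")
        assert len(confocal_crosscheck(raw, empty_conf)) == 0

    def test_empty_input_empty_output(self):
        _, conf, *_ = self._volumes_with_artifacts()
        raw = detect_maxima(make_volume(np.zeros(conf.data.shape)))
        assert len(confocal_crosscheck(raw, conf)) == 0

    def test_channel_and_frame_mismatch_rejected(self):
        sted, conf, *_ = self._volumes_with_artifacts()
        raw = detect_maxima(sted, min_intensity=0.15)
        wrong_channel = make_volume(conf.data, modality="confocal", channel="post")
        with pytest.raises(ValueError, match="channel"):
            confocal_crosscheck(raw, wrong_channel)
        wrong_frame = make_volume(conf.data[:, :50, :50], modality="confocal")
        with pytest.raises(ValueError, match="frame"):
            confocal_crosscheck(raw, wrong_frame)

    def test_retained_set_is_subset_and_monotone_in_threshold(self):
        sted, conf, *_ = self._volumes_with_artifacts()
        raw = detect_maxima(sted, min_intensity=0.15)
        sizes = [
            len(confocal_crosscheck(raw, conf, conf_threshold=th))
            for th in (0.01, 0.1, 1.0, 10.0)
        ]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] <= len(raw)


def test_puncta_csv_roundtrip(tmp_path):
    grid = np.zeros((10, 20, 20))
    render_spots(grid, VOXEL, np.array([[0.2, 0.2, 0.25]]), 60.0, 5.0)
    found = detect_maxima(make_volume(grid), min_intensity=1e-6)
    path = found.to_csv(tmp_path / "p.csv")
    back = read_puncta_csv(path)
    np.testing.assert_allclose(back.coords_um, found.coords_um, atol=1e-9)
    assert back.channel == found.channel
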