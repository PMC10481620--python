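import numpy as np
import pytest

from cysgan.evaluation import ap50
from cysgan.representations import (BCDMaps, decode_bcd, encode_bc,
                                    encode_bcd)
from cysgan.synthetic import PhantomSpec, sample_instances
from cysgan.volumes_io import InstanceLabels


def bruteforce_bcd_distance(lbl, d_clip_in=8.0, d_clip_out=16.0):
    """Independent all-pairs oracle for the signed distance channel.

    Inside an instance: Euclidean distance to the nearest *boundary voxel*
    of that instance (instance voxels with an in-volume 6-neighbour of a
    different label). Background: distance to the nearest foreground voxel,
    negated. Both clipped and normalised.
    """
    shape = lbl.shape
    coords = np.argwhere(np.ones(shape, dtype=bool))
    d = np.zeros(shape, dtype=np.float64)
    fg_pts = np.argwhere(lbl > 0)

    def neighbors(pt):
        for ax in range(3):
            for dlt in (-1, 1):
                q = pt.copy()
                q[ax] += dlt
                if 0 <= q[ax] < shape[ax]:
                    yield tuple(q)

    boundary = {}
    for pt in fg_pts:
        lid = lbl[tuple(pt)]
        if any(lbl[q] != lid for q in neighbors(pt)):
            boundary.setdefault(lid, []).append(pt)
    for pt in coords:
        t = tuple(pt)
        lid = lbl[t]
        if lid > 0:
            bnd = boundary.get(lid)
            if not bnd:
                d[t] = 1.0
                continue
            dist = min(np.sqrt(((pt - b) ** 2).sum()) for b in bnd)
            d[t] = min(dist, d_clip_in) / d_clip_in
        else:
            if fg_pts.size == 0:
                d[t] = -1.0
                continue
            dist = np.sqrt(((fg_pts - pt) ** 2).sum(axis=1)).min()
            d[t] = -min(dist, d_clip_out) / d_clip_out
    return d


class TestEncode:
    def test_empty_labels(self):
        lbl = InstanceLabels(np.zeros((6, 6, 6), dtype=np.int32))
        maps = encode_bcd(lbl)
        assert np.all(maps.B == 0)
        assert np.all(maps.C == 0)
        assert np.all(maps.D == -1.0)

    def test_cube_center_and_shell_distances(self):
        lbl = np.zeros((9, 9, 9), dtype=np.int32)
        lbl[2:7, 2:7, 2:7] = 1
        maps = encode_bcd(InstanceLabels(lbl), d_clip_in=2.0)
        assert maps.D[4, 4, 4] == 1.0          # centre: distance 2 >= clip
        assert maps.D[4, 4, 3] == 0.5          # face-adjacent to boundary
        assert maps.D[4, 4, 2] == 0.0          # boundary voxel itself

    def test_touching_cubes_contour_both_sides(self, two_cubes_touching):
        maps = encode_bcd(two_cubes_touching, contour_radius=1)
        assert np.all(maps.C[4:8, 4:8, 5] == 1)
        assert np.all(maps.C[4:8, 4:8, 6] == 1)

    def test_touching_interface_distance_zero(self, two_cubes_touching):
        maps = encode_bcd(two_cubes_touching)
        assert np.all(maps.D[4:8, 4:8, 5] == 0.0)
        assert np.all(maps.D[4:8, 4:8, 6] == 0.0)

    @pytest.mark.parametrize("case", ["separated", "touching"])
    def test_distance_channel_matches_bruteforce(self, case,
                                                 two_cubes_touching,
                                                 separated_cubes):
        lbl = {"separated": separated_cubes.data[:16, :16, :16],
               "touching": two_cubes_touching.data}[case]
        maps = encode_bcd(InstanceLabels(np.ascontiguousarray(lbl)))
        oracle = bruteforce_bcd_distance(lbl)
        assert np.array_equal(maps.D.astype(np.float64), oracle)

    def test_permutation_invariance(self, separated_cubes):
        maps = encode_bcd(separated_cubes)
        perm = separated_cubes.data.copy()
        perm[perm == 1] = 99
        maps2 = encode_bcd(InstanceLabels(perm))
        for a, b in ((maps.B, maps2.B), (maps.C, maps2.C),
                     (maps.D, maps2.D)):
            assert np.array_equal(a, b)

    def test_clip_bounds(self, separated_cubes):
        maps = encode_bcd(separated_cubes, d_clip_in=2, d_clip_out=3)
        assert maps.D.min() >= -1.0 and maps.D.max() <= 1.0
        assert np.all(maps.B[maps.D > 0] == 1)

    def test_encode_bc_matches_bcd_channels(self, two_cubes_touching):
        bc = encode_bc(two_cubes_touching)
        bcd = encode_bcd(two_cubes_touching)
        assert np.array_equal(bc.B, bcd.B)
        assert np.array_equal(bc.C, bcd.C)
        assert bc.D is None


class TestDecode:
    def test_roundtrip_exact_on_separated(self, separated_cubes):
        dec = decode_bcd(encode_bcd(separated_cubes), min_seed_size=1,
                         min_instance_size=1)
        assert ap50(dec, separated_cubes) == 1.0
        # exact up to permutation
        for pid in dec.ids():
            gt_vals = separated_cubes.data[dec.data == pid]
            assert len(set(gt_vals)) == 1

    def test_all_background(self):
        maps = BCDMaps(B=np.zeros((8, 8, 8), dtype=np.float32),
                       C=np.zeros((8, 8, 8), dtype=np.float32),
                       D=-np.ones((8, 8, 8), dtype=np.float32))
        dec = decode_bcd(maps)
        assert dec.ids().size == 0

    def test_touching_cubes_split(self, two_cubes_touching):
        dec = decode_bcd(encode_bcd(two_cubes_touching), min_seed_size=1,
                         min_instance_size=1)
        assert dec.ids().size == 2
        # per-voxel agreement >= 0.95 after best ID matching
        agree = 0
        for pid in dec.ids():
            vals, counts = np.unique(
                two_cubes_touching.data[dec.data == pid],
                return_counts=True)
            agree += counts.max()
        assert agree / (two_cubes_touching.data > 0).sum() >= 0.95

    def test_bc_mode_roundtrip(self, separated_cubes):
        dec = decode_bcd(encode_bc(separated_cubes), min_seed_size=1,
                         min_instance_size=1)
        assert ap50(dec, separated_cubes) == 1.0

    def test_noise_robustness_within_threshold_margins(self, rng,
                                                       separated_cubes):
        maps = encode_bcd(separated_cubes)
        clean = decode_bcd(maps, min_seed_size=1, min_instance_size=1)
        noisy = BCDMaps(
            B=np.clip(maps.B + rng.uniform(-0.05, 0.05, maps.B.shape), 0, 1)
            .astype(np.float32),
            C=np.clip(maps.C + rng.uniform(-0.05, 0.05, maps.C.shape), 0, 1)
            .astype(np.float32),
            D=maps.D)
        dec = decode_bcd(noisy, min_seed_size=1, min_instance_size=1)
        assert dec.ids().size == clean.ids().size

    def test_ids_consecutive_and_deterministic(self):
        spec = PhantomSpec(shape=(40, 40, 40), n_instances=8,
                           radius_range=(3, 4.5), min_spacing=12, seed=3)
        lbl = sample_instances(spec)
        dec1 = decode_bcd(encode_bcd(lbl))
        dec2 = decode_bcd(encode_bcd(lbl))
        assert np.array_equal(dec1.data, dec2.data)
        ids = dec1.ids()
        assert np.array_equal(ids, np.arange(1, ids.size + 1))


class TestSerialization:
    def test_stack_roundtrip(self, tmp_path, separated_cubes):
        maps = encode_bcd(separated_cubes)
        path = str(tmp_path / "maps.h5")
        maps.save(path)
        back = BCDMaps.load(path)
        assert np.array_equal(back.stack(), maps.stack())
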