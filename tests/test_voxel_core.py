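"""Mask algebra, volumes, overlap fractions and NIfTI round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petgtv import (
    BinaryMask,
    EmptyReferenceError,
    GeometryError,
    StructureSet,
    VoxelGrid,
    composite_and_common,
    intersect,
    overlap_fraction,
    read_grid,
    read_mask,
    unite,
    volume,
    write_grid,
    write_mask,
)

from conftest import make_grid, make_mask


# -- brute-force per-voxel oracles (independent of the implementation) ------

def brute_volume(mask):
    count = 0
    nx, ny, nz = mask.values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask.values[i, j, k]:
                    count += 1
    sx, sy, sz = mask.spacing
    return count * sx * sy * sz / 1000.0


def brute_combine(a, b, op):
    out = np.zeros(a.values.shape, dtype=bool)
    nx, ny, nz = a.values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                out[i, j, k] = op(bool(a.values[i, j, k]), bool(b.values[i, j, k]))
    return out


class TestVolume:
    def test_counted_voxels_times_voxel_volume(self):
        arr = np.zeros((20, 20, 20), dtype=bool)
        arr.ravel()[:1000] = True
        mask = make_mask(arr, spacing=(2.0, 2.0, 2.0))
        assert volume(mask) == pytest.approx(8.0)

    def test_empty_mask_has_zero_volume(self):
        assert volume(make_mask(np.zeros((4, 4, 4)))) == 0.0

    def test_digitized_sphere_matches_voxel_center_count(self):
        # radius 10 mm sphere at 1 mm isotropic spacing, centered on voxel (12,12,12)
        n, r, c = 25, 10.0, 12.0
        expected = 0
        arr = np.zeros((n, n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if (i - c) ** 2 + (j - c) ** 2 + (k - c) ** 2 <= r**2:
                        arr[i, j, k] = True
                        expected += 1
        assert volume(make_mask(arr)) == pytest.approx(expected / 1000.0)


class TestAlgebra:
    def test_intersect_idempotent_and_disjoint(self):
        a = make_mask(np.eye(4)[None, :, :].repeat(4, axis=0))
        assert np.array_equal(intersect(a, a).values, a.values)
        b = make_mask(~a.values)
        assert intersect(a, b).n_voxels == 0
        assert unite(a, a).n_voxels == a.n_voxels

    def test_partial_overlap_counts(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a.ravel()[:8] = True  # 8 voxels
        b.ravel()[4:10] = True  # 6 voxels, 4 shared
        am, bm = make_mask(a), make_mask(b)
        assert intersect(am, bm).n_voxels == 4
        assert unite(am, bm).n_voxels == 10

    def test_disjoint_union_is_additive(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a.ravel()[:8] = True
        b.ravel()[20:26] = True
        assert unite(make_mask(a), make_mask(b)).n_voxels == 14

    def test_geometry_mismatch_raises(self):
        a = make_mask(np.ones((4, 4, 4)))
        b = make_mask(np.ones((4, 4, 4)), spacing=(2.0, 1.0, 1.0))
        c = make_mask(np.ones((5, 4, 4)))
        for other in (b, c):
            with pytest.raises(GeometryError):
                intersect(a, other)
            with pytest.raises(GeometryError):
                unite(a, other)
            with pytest.raises(GeometryError):
                overlap_fraction(a, other)

    def test_random_masks_equal_brute_force(self, rng):
        for _ in range(25):
            shape = tuple(rng.integers(2, 9, size=3))
            a = make_mask(rng.random(shape) < 0.4)
            b = make_mask(rng.random(shape) < 0.4)
            assert np.array_equal(
                intersect(a, b).values, brute_combine(a, b, lambda x, y: x and y)
            )
            assert np.array_equal(
                unite(a, b).values, brute_combine(a, b, lambda x, y: x or y)
            )
            assert volume(a) == pytest.approx(brute_volume(a))


class TestOverlapFraction:
    def test_containment_gives_one(self):
        big = np.zeros((5, 5, 5), dtype=bool)
        big[1:4, 1:4, 1:4] = True
        small = np.zeros((5, 5, 5), dtype=bool)
        small[2, 2, 2] = True
        assert overlap_fraction(make_mask(big), make_mask(small)) == 1.0

    def test_disjoint_gives_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert overlap_fraction(make_mask(a), make_mask(b)) == 0.0

    def test_half_overlap(self):
        ref = np.zeros((4, 4, 4), dtype=bool)
        ref.ravel()[:8] = True
        a = np.zeros((4, 4, 4), dtype=bool)
        a.ravel()[4:12] = True  # 4 of ref's 8 voxels
        assert overlap_fraction(make_mask(a), make_mask(ref)) == pytest.approx(0.5)

    def test_empty_reference_raises(self):
        a = make_mask(np.ones((3, 3, 3)))
        with pytest.raises(EmptyReferenceError):
            overlap_fraction(a, make_mask(np.zeros((3, 3, 3))))

    def test_scale_invariant_under_uniform_spacing_change(self, rng):
        shape = (6, 6, 6)
        a_arr = rng.random(shape) < 0.5
        r_arr = rng.random(shape) < 0.5
        r_arr[0, 0, 0] = True
        of1 = overlap_fraction(make_mask(a_arr), make_mask(r_arr))
        of2 = overlap_fraction(
            make_mask(a_arr, spacing=(3.0, 3.0, 3.0)),
            make_mask(r_arr, spacing=(3.0, 3.0, 3.0)),
        )
        assert of1 == of2


class TestCompositeAndCommon:
    def test_identical_masks(self):
        m = make_mask(np.ones((3, 3, 3)))
        comp, comm = composite_and_common([m, m, m])
        assert np.array_equal(comp.values, m.values)
        assert np.array_equal(comm.values, m.values)

    def test_nested_masks(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        c = np.zeros((6, 6, 6), dtype=bool)
        a[2:4, 2:4, 2:4] = True
        b[1:5, 1:5, 1:5] = True
        c[0:6, 0:6, 0:6] = True
        comp, comm = composite_and_common([make_mask(a), make_mask(b), make_mask(c)])
        assert np.array_equal(comp.values, c)
        assert np.array_equal(comm.values, a)

    def test_three_random_masks_match_brute_force(self, rng):
        shape = (7, 7, 7)
        masks = [make_mask(rng.random(shape) < 0.5) for _ in range(3)]
        comp, comm = composite_and_common(masks)
        expect_comp = masks[0].values | masks[1].values | masks[2].values
        expect_comm = masks[0].values & masks[1].values & masks[2].values
        assert np.array_equal(comp.values, expect_comp)
        assert np.array_equal(comm.values, expect_comm)
        for m in masks:
            assert np.all(comm.values <= m.values)
            assert np.all(m.values <= comp.values)

    def test_fewer_than_two_masks_rejected(self):
        with pytest.raises(ValueError):
            composite_and_common([make_mask(np.ones((2, 2, 2)))])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_inclusion_exclusion_property(seed):
    """vol(a) + vol(b) == vol(a∪b) + vol(a∩b) for random mask pairs."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, 12, size=3))
    spacing = tuple(rng.uniform(0.5, 3.0, size=3))
    a = BinaryMask(rng.random(shape) < 0.5, spacing)
    b = BinaryMask(rng.random(shape) < 0.5, spacing)
    lhs = volume(a) + volume(b)
    rhs = volume(unite(a, b)) + volume(intersect(a, b))
    assert lhs == pytest.approx(rhs, abs=1e-12)
    # monotonicity: a∩b ⊆ a ⊆ a∪b
    assert volume(intersect(a, b)) <= volume(a) <= volume(unite(a, b))
    if a.values.any():
        assert overlap_fraction(unite(a, b), a) == 1.0


class TestNiftiIO:
    def test_mask_round_trip(self, rng, tmp_path):
        arr = rng.random((16, 16, 16)) < 0.5
        mask = make_mask(arr, spacing=(1.5, 2.0, 2.5), origin=(3.0, -2.0, 10.0))
        path = tmp_path / "mask.nii.gz"
        write_mask(mask, path)
        back = read_mask(path)
        assert np.array_equal(back.values, mask.values)
        assert back.spacing == pytest.approx(mask.spacing, abs=1e-6)
        assert back.origin == pytest.approx(mask.origin, abs=1e-6)

    def test_grid_round_trip_lossless(self, rng, tmp_path):
        grid = make_grid(rng.normal(size=(9, 10, 11)), spacing=(2.0, 2.0, 3.0))
        path = tmp_path / "grid.nii.gz"
        write_grid(grid, path)
        back = read_grid(path)
        assert np.max(np.abs(back.values - grid.values)) == 0.0

    def test_non_binary_mask_file_rejected(self, tmp_path):
        import nibabel as nib

        arr = np.zeros((4, 4, 4), dtype=np.int16)
        arr[1, 1, 1] = 2
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(tmp_path / "bad.nii.gz"))
        with pytest.raises(ValueError, match="non-binary"):
            read_mask(tmp_path / "bad.nii.gz")

    def test_non_3d_rejected(self, tmp_path):
        import nibabel as nib

        arr = np.zeros((4, 4), dtype=np.uint8)
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(tmp_path / "flat.nii.gz"))
        with pytest.raises(ValueError):
            read_mask(tmp_path / "flat.nii.gz")


class TestTypes:
    def test_grid_rejects_nonfinite_and_bad_spacing(self):
        with pytest.raises(ValueError):
            VoxelGrid(np.full((2, 2, 2), np.nan), (1, 1, 1))
        with pytest.raises(ValueError):
            VoxelGrid(np.zeros((2, 2, 2)), (0.0, 1, 1))

    def test_mask_rejects_non_binary_values(self):
        with pytest.raises(ValueError):
            BinaryMask(np.full((2, 2, 2), 2.0), (1, 1, 1))


class TestStructureSet:
    def test_duplicate_key_rejected(self):
        s = StructureSet()
        m = make_mask(np.ones((3, 3, 3)))
        s.add("1", "CT", "a", 1, m)
        with pytest.raises(ValueError, match="duplicate"):
            s.add("1", "CT", "a", 1, m)

    def test_patient_geometry_consistency_enforced(self):
        s = StructureSet()
        s.add("1", "CT", "a", 1, make_mask(np.ones((3, 3, 3))))
        with pytest.raises(GeometryError):
            s.add("1", "PETCT", "a", 1, make_mask(np.ones((4, 4, 4))))
        # a different patient may use a different geometry
        s.add("2", "CT", "a", 1, make_mask(np.ones((4, 4, 4))))

    def test_save_load_round_trip(self, rng, tmp_path):
        s = StructureSet()
        for obs in ("1", "2"):
            for ses in (1, 2):
                s.add("1", "CT", obs, ses, make_mask(rng.random((5, 5, 5)) < 0.5))
        sidecar = s.save(tmp_path / "out")
        back = StructureSet.load(sidecar)
        assert len(back) == 4
        for (key, mask), (bkey, bmask) in zip(s, back):
            assert key == bkey
            assert np.array_equal(mask.values, bmask.values)
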