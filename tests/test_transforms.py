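"""Affine/displacement chains, label warping, downsampling."""

import numpy as np
import pytest

from axonatlas.atlas import ParcellationVolume
from axonatlas.synthetic import make_transform
from axonatlas.transforms import (
    AffineTransform,
    DisplacementField,
    FieldInversionError,
    TransformChain,
    apply_to_labels,
    apply_to_points,
    downsample_volume,
    invert,
    load_chain,
    load_elastix_affine,
    save_chain,
)


def test_affine_invariants():
    with pytest.raises(ValueError):
        AffineTransform(np.zeros((4, 4)))
    m = np.eye(4)
    m[3] = (1, 0, 0, 1)
    with pytest.raises(ValueError):
        AffineTransform(m)


def test_identity_and_translation_chains(rng):
    pts = rng.uniform(0, 100, (20, 3))
    assert np.allclose(apply_to_points(TransformChain.identity(), pts), pts)
    tr = make_transform("translation", {"offset": (100, 0, 0)})
    out = apply_to_points(tr, pts)
    assert np.allclose(out[:, 0], pts[:, 0] + 100)
    assert np.allclose(out[:, 1:], pts[:, 1:])
    inv = invert(tr)
    assert np.allclose(apply_to_points(inv, out), pts)


def test_affine_inverse_round_trip(rng):
    chain = make_transform("affine", seed=3)
    pts = rng.uniform(-500, 500, (200, 3))
    back = apply_to_points(invert(chain), apply_to_points(chain, pts))
    assert np.abs(back - pts).max() < 1e-6


def test_rigid_preserves_lengths(rng):
    chain = make_transform("rigid", {"angle_deg": 10, "axis": 1,
                                     "center": (50, 50, 50)})
    pts = rng.uniform(0, 100, (50, 3))
    d0 = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    d1 = np.linalg.norm(np.diff(apply_to_points(chain, pts), axis=0), axis=1)
    assert np.allclose(d0, d1, atol=1e-9)


def test_smooth_field_round_trip_residual(rng):
    chain = make_transform("smooth_field",
                           {"shape": (12, 12, 12), "voxel_size": (500, 500, 500),
                            "max_displacement_um": 20}, seed=5)
    pts = rng.uniform(800, 5200, (100, 3))
    back = invert(chain).apply(chain.apply(pts))
    assert np.linalg.norm(back - pts, axis=1).max() < 0.05


def test_field_inversion_nonconvergence_raises():
    # displacement gradient >> 1 breaks the fixed-point contraction
    offsets = np.zeros((4, 4, 4, 3))
    offsets[..., 0] = np.linspace(0, 3000, 4)[:, None, None] * -1.5
    field = DisplacementField(offsets, (10.0, 10.0, 10.0))
    chain = TransformChain([field])
    with pytest.raises(FieldInversionError):
        invert(chain, max_iter=5).apply(np.array([[20.0, 20.0, 20.0]]))


def test_out_of_support_points_get_zero_offset():
    field = DisplacementField(np.full((4, 4, 4, 3), 7.0), (10.0, 10.0, 10.0))
    far = np.array([[1e4, 1e4, 1e4]])
    assert np.allclose(field.displacement_at(far), 0.0)
    assert not field.support_mask(far)[0]


# -- label warping ---------------------------------------------------------

def _vol(rng, shape=(10, 8, 6)):
    return ParcellationVolume(rng.integers(0, 5, shape).astype(np.int32),
                              (25.0, 25.0, 25.0))


def test_apply_to_labels_identity_is_voxel_identical(rng):
    vol = _vol(rng)
    out = apply_to_labels(TransformChain.identity(), vol)
    assert np.array_equal(out.labels, vol.labels)


def test_apply_to_labels_one_voxel_translation(rng):
    vol = _vol(rng)
    chain = make_transform("translation", {"offset": (25.0, 0, 0)})
    out = apply_to_labels(chain, vol)
    assert np.array_equal(out.labels[1:], vol.labels[:-1])
    assert np.all(out.labels[0] == 0)        # border fills with 0


def test_label_warp_pull_back_consistency(rng):
    vol = _vol(rng, (12, 12, 12))
    chain = make_transform("affine", seed=9)
    warped = apply_to_labels(chain, vol)
    inv = invert(chain)
    pts = rng.uniform(0, 300, (1000, 3))
    # exact oracle: the warped label at p is the source label at the
    # inverse-mapped center of p's output voxel (nearest-neighbour pull-back)
    centers = (np.floor(pts / 25.0) + 0.5) * 25.0
    expected = vol.lookup(inv.apply(centers))
    assert np.array_equal(warped.lookup(pts), expected)
    # and it agrees with direct point-mapping away from voxel boundaries:
    # points whose own inverse image shares the center's source voxel
    direct_idx = np.floor(inv.apply(pts) / 25.0)
    center_idx = np.floor(inv.apply(centers) / 25.0)
    same = np.all(direct_idx == center_idx, axis=1)
    assert np.array_equal(warped.lookup(pts)[same],
                          vol.lookup(inv.apply(pts))[same])


def test_warp_never_invents_labels(rng):
    vol = _vol(rng)
    chain = make_transform("affine", seed=4)
    out = apply_to_labels(chain, vol)
    assert set(np.unique(out.labels)) <= set(np.unique(vol.labels)) | {0}


# -- downsampling ----------------------------------------------------------

def test_downsample_anisotropic_stack_geometry():
    stack = np.zeros((50, 50, 5))
    out = downsample_volume(stack, (0.8, 0.8, 5.0), 25.0, "mean")
    assert out.shape == (2, 2, 1)


def test_downsample_constant_stack():
    out = downsample_volume(np.full((8, 8, 8), 3.25), (1, 1, 1), 2.0, "mean")
    assert np.allclose(out, 3.25)


def test_downsample_mean_matches_brute_force(rng):
    stack = rng.random((13, 9, 7))
    vs, tv = (2.0, 3.0, 5.0), 15.0
    out = downsample_volume(stack, vs, tv, "mean")
    acc = np.zeros(out.shape)
    cnt = np.zeros(out.shape)
    for i in range(13):
        for j in range(9):
            for k in range(7):
                oi = min(int((i + 0.5) * vs[0] / tv), out.shape[0] - 1)
                oj = min(int((j + 0.5) * vs[1] / tv), out.shape[1] - 1)
                ok = min(int((k + 0.5) * vs[2] / tv), out.shape[2] - 1)
                acc[oi, oj, ok] += stack[i, j, k]
                cnt[oi, oj, ok] += 1
    assert np.abs(out - acc / cnt).max() < 1e-9


def test_downsample_mode_majority_and_no_new_labels(rng):
    lab = rng.integers(0, 4, (12, 12, 12)).astype(np.int32)
    out = downsample_volume(lab, (5, 5, 5), 10.0, "mode")
    assert out.shape == (6, 6, 6)
    assert set(np.unique(out)) <= set(np.unique(lab))
    block = lab[:2, :2, :2]
    vals, counts = np.unique(block, return_counts=True)
    assert out[0, 0, 0] == vals[np.argmax(counts)]


def test_downsample_upsampling_rejected():
    with pytest.raises(ValueError):
        downsample_volume(np.zeros((4, 4, 4)), (25, 25, 25), 5.0, "mean")


# -- serialization ---------------------------------------------------------

def test_chain_save_load_round_trip(tmp_path, rng):
    affine = make_transform("affine", seed=2).components[0]
    field = make_transform("smooth_field",
                           {"shape": (6, 6, 6), "voxel_size": (100, 100, 100),
                            "max_displacement_um": 5}, seed=8).components[0]
    chain = TransformChain([affine, field])
    save_chain(chain, tmp_path / "transform.json")
    back = load_chain(tmp_path / "transform.json")
    pts = rng.uniform(0, 500, (50, 3))
    assert np.allclose(back.apply(pts), chain.apply(pts), atol=1e-5)


def test_elastix_affine_import(tmp_path):
    text = """(Transform "AffineTransform")
(TransformParameters 1 0 0 0 1 0 0 0 1 10 20 30)
(CenterOfRotationPoint 0 0 0)
"""
    p = tmp_path / "TransformParameters.0.txt"
    p.write_text(text)
    aff = load_elastix_affine(p)
    assert np.allclose(aff.apply([[1, 2, 3]]), [[11, 22, 33]])
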