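"""T1 pipeline numerics: extraction, bias correction, resampling,
affine and nonlinear registration, and catalog-integrated runs."""

import numpy as np
import pytest

from mrifuse.preprocess import (
    RigidScaleTransform,
    Volume,
    apply_transform,
    correct_bias,
    default_affine,
    extract_brain,
    jacobian_determinant,
    register_affine,
    register_nonlinear,
    run_pipeline,
    warp_volume,
)
from mrifuse.synthetic_data import make_subject_image


from _util import dice as _dice, register_one_image as _register_one_image


# ---------------------------------------------------------------------------
# transforms and resampling


def test_transform_matrix_roundtrip():
    t = RigidScaleTransform(np.deg2rad([4.0, -7.0, 2.5]), [3.0, -8.0, 1.0], 1.07)
    back = RigidScaleTransform.from_matrix(t.matrix)
    assert np.allclose(back.rotations, t.rotations)
    assert np.allclose(back.translations, t.translations)
    assert np.isclose(back.scale, t.scale)
    ident = t.matrix @ t.inverse().matrix
    assert np.allclose(ident, np.eye(4), atol=1e-10)


def test_transform_txt_io(tmp_path):
    t = RigidScaleTransform(np.deg2rad([1.0, 2.0, 3.0]), [1.0, 2.0, 3.0], 0.95)
    t.save_txt(tmp_path / "aff.txt")
    assert len((tmp_path / "aff.txt").read_text().splitlines()) == 4
    back = RigidScaleTransform.load_txt(tmp_path / "aff.txt")
    assert np.allclose(back.matrix, t.matrix)


def test_apply_identity_preserves_volume(template64):
    tpl, _ = template64
    out = apply_transform(tpl, RigidScaleTransform(), target=tpl)
    assert np.allclose(out.data, tpl.data, atol=1e-10)


def test_apply_integer_voxel_translation_is_exact():
    shape = (24, 24, 24)
    vol = Volume(np.zeros(shape), default_affine(shape, 2.0))
    vol.data[8:16, 8:16, 8:16] = 1.0
    t = RigidScaleTransform(translations=[4.0, -4.0, 8.0])  # 2, -2, 4 voxels
    out = apply_transform(vol, t, target=vol)
    assert np.array_equal(out.data[10:18, 6:14, 12:20], vol.data[8:16, 8:16, 8:16])


def test_apply_roundtrip_recovers_original(template64, rng):
    tpl, mask = template64
    t = RigidScaleTransform(np.deg2rad(rng.uniform(-8, 8, 3)),
                            rng.uniform(-8, 8, 3), 1.05)
    fwd = apply_transform(tpl, t, target=tpl)
    back = apply_transform(fwd, t.inverse(), target=tpl)
    sel = mask.data > 0
    r = np.corrcoef(back.data[sel], tpl.data[sel])[0, 1]
    assert r >= 0.99


# ---------------------------------------------------------------------------
# brain extraction


def test_extract_brain_recovers_true_mask(template64, rng):
    tpl, mask = template64
    vol, gt = make_subject_image(tpl, mask, rng)
    est = extract_brain(vol)
    assert _dice(est.data, gt.brain_mask) >= 0.95
    # single connected component
    from scipy import ndimage
    _, n = ndimage.label(est.data > 0)
    assert n == 1


def test_extract_brain_rejects_constant_volume():
    vol = Volume(np.zeros((16, 16, 16)), default_affine((16, 16, 16)))
    with pytest.raises(ValueError, match="constant"):
        extract_brain(vol)


def test_extract_brain_idempotent_on_own_output(template64, rng):
    tpl, mask = template64
    vol, _ = make_subject_image(tpl, mask, rng)
    first = extract_brain(vol)
    binary = Volume(np.asarray(first.data, dtype=float), first.affine)
    again = extract_brain(binary)
    assert np.array_equal(again.data > 0, first.data > 0)


# ---------------------------------------------------------------------------
# bias correction


def test_correct_bias_recovers_known_field_and_reduces_cov(template64):
    tpl, mask = template64
    corrs, cov_drop = [], []
    for seed in (1, 2, 3, 4, 5):
        rng = np.random.default_rng(seed)
        vol, gt = make_subject_image(tpl, mask, rng)
        est_mask = extract_brain(vol)
        corrected, field = correct_bias(vol, est_mask, order=2)
        sel = gt.brain_mask > 0
        corrs.append(np.corrcoef(field.data[sel], gt.bias_field[sel])[0, 1])
        cov_before = vol.data[sel].std() / vol.data[sel].mean()
        cov_after = corrected.data[sel].std() / corrected.data[sel].mean()
        cov_drop.append(cov_after < cov_before)
    assert np.median(corrs) >= 0.9
    assert all(cov_drop)


def test_correct_bias_flat_field_near_identity(template64, rng):
    tpl, mask = template64
    vol, gt = make_subject_image(tpl, mask, rng, bias_amplitude=0.0, noise_sd=0.0)
    own_mask = extract_brain(vol)
    corrected, field = correct_bias(vol, own_mask, order=2)
    sel = own_mask.data > 0
    assert np.abs(field.data[sel] - 1.0).max() < 0.12
    assert np.allclose(corrected.data[sel], vol.data[sel], rtol=0.15)


def test_correct_bias_field_positive_mean_one(template64, rng):
    tpl, mask = template64
    vol, _ = make_subject_image(tpl, mask, rng)
    _, field = correct_bias(vol, mask)
    assert (field.data > 0).all()
    assert np.isclose(field.data[mask.data > 0].mean(), 1.0)


def test_correct_bias_validates_inputs(template64):
    tpl, mask = template64
    with pytest.raises(ValueError, match="order"):
        correct_bias(tpl, mask, order=7)
    empty = Volume(np.zeros_like(np.asarray(mask.data)), mask.affine)
    with pytest.raises(ValueError, match="empty"):
        correct_bias(tpl, empty)
    shifted = Volume(tpl.data - 0.5, tpl.affine)
    with pytest.raises(ValueError, match="nonpositive"):
        correct_bias(shifted, mask, on_nonpositive="error")


# ---------------------------------------------------------------------------
# affine registration


def test_register_identity_case(template64):
    tpl, mask = template64
    res = register_affine(tpl, tpl, mask)
    assert np.rad2deg(np.abs(res.transform.rotations)).max() < 0.3
    assert np.abs(res.transform.translations).max() < 0.5
    assert abs(res.transform.scale - 1.0) < 0.005
    assert res.similarity >= res.initial_similarity
    assert res.similarity > 0.99


def test_register_recovers_known_transform(template64):
    tpl, mask = template64
    rng = np.random.default_rng(5)
    vol, gt = make_subject_image(tpl, mask, rng, bias_amplitude=0.0, noise_sd=0.02)
    res = register_affine(vol, tpl, mask)
    true, est = gt.transform, res.transform
    Rt = true.matrix[:3, :3] / true.scale
    Re = est.matrix[:3, :3] / est.scale
    angle = np.rad2deg(np.arccos(np.clip((np.trace(Rt.T @ Re) - 1) / 2, -1, 1)))
    assert angle <= 3.0
    assert np.linalg.norm(est.translations - true.translations) <= 2.5  # 1 voxel
    assert abs(est.scale - true.scale) / true.scale <= 0.025
    assert res.similarity >= 0.9


def test_register_rejects_constant_image(template64):
    tpl, mask = template64
    flat = Volume(np.ones_like(np.asarray(tpl.data)), tpl.affine)
    with pytest.raises(ValueError):
        register_affine(flat, tpl, mask)


def test_registration_commutes_with_bias_correction(template64):
    """Same transform (within tolerance) with and without bias on input."""
    tpl, mask = template64
    rng = np.random.default_rng(9)
    vol, gt = make_subject_image(tpl, mask, rng)
    clean = Volume(np.asarray(vol.data) / gt.bias_field, vol.affine)
    corrected, _ = correct_bias(vol, extract_brain(vol), order=2)
    t1 = register_affine(clean, tpl, mask).transform
    t2 = register_affine(corrected, tpl, mask).transform
    assert np.linalg.norm(t1.translations - t2.translations) < 2.5
    assert abs(t1.scale - t2.scale) < 0.02


# ---------------------------------------------------------------------------
# nonlinear registration


def test_nonlinear_identity_gives_near_zero_field(template64):
    tpl, _ = template64
    field = register_nonlinear(tpl, tpl)
    assert (np.abs(field) / tpl.voxel_sizes).max() < 0.5


def test_nonlinear_improves_similarity_and_preserves_topology(template64):
    tpl, mask = template64
    rng = np.random.default_rng(101)
    vol, gt = make_subject_image(tpl, mask, rng, bump_amplitude_mm=4.0)
    corrected, _ = correct_bias(vol, extract_brain(vol), order=2)
    aff = register_affine(corrected, tpl, mask)
    field = register_nonlinear(aff.resampled, tpl)
    warped = apply_transform(corrected, aff.transform, field_mm=field, target=tpl)
    sel = np.asarray(mask.data) > 0
    r_aff = np.corrcoef(aff.resampled.data[sel], tpl.data[sel])[0, 1]
    r_nl = np.corrcoef(warped.data[sel], tpl.data[sel])[0, 1]
    assert r_nl > r_aff
    jac = jacobian_determinant(field, tpl.voxel_sizes)
    assert jac.min() > 0  # no folding


def test_warp_volume_matches_apply_transform_field_path(template64):
    tpl, _ = template64
    field = np.zeros(tuple(tpl.shape) + (3,))
    field[..., 0] = 2.5  # one voxel along x
    shifted = warp_volume(tpl, field)
    assert np.allclose(shifted.data[:-1], np.asarray(tpl.data)[1:], atol=1e-8)


# ---------------------------------------------------------------------------
# catalog-integrated pipeline


def test_run_pipeline_affine_writes_three_artifacts(cat, template32, tmp_path, rng):
    tpl, mask = template32
    vol, _ = make_subject_image(tpl, mask, rng)
    src = tmp_path / "img.nii.gz"
    vol.to_nifti(src)
    image_id = _register_one_image(cat, src)
    res = run_pipeline(cat, image_id, tpl, mask, "affine", tmp_path / "store")
    assert set(res.paths) == {"registered_image", "brain_mask", "affine_matrix"}
    assert cat.count("preprocess_file") == 3
    assert cat.fetch("image", image_id)["preprocessing_status"] == "affine"
    assert cat.audit_files() == []
    # rerun replaces artifacts without duplicating rows
    run_pipeline(cat, image_id, tpl, mask, "affine", tmp_path / "store")
    assert cat.count("preprocess_file") == 3


def test_run_pipeline_nonlinear_adds_warp(cat, template32, tmp_path, rng):
    tpl, mask = template32
    vol, _ = make_subject_image(tpl, mask, rng)
    src = tmp_path / "img.nii.gz"
    vol.to_nifti(src)
    image_id = _register_one_image(cat, src)
    res = run_pipeline(cat, image_id, tpl, mask, "nonlinear", tmp_path / "store")
    assert "nonlinear_warp" in res.paths
    assert cat.count("preprocess_file") == 4
    assert cat.fetch("image", image_id)["preprocessing_status"] == "nonlinear"


def test_run_pipeline_missing_file_is_atomic(cat, template32, tmp_path):
    tpl, mask = template32
    image_id = _register_one_image(cat, tmp_path / "missing.nii.gz")
    with pytest.raises(FileNotFoundError):
        run_pipeline(cat, image_id, tpl, mask, "affine", tmp_path / "store")
    assert cat.count("preprocess_file") == 0


def test_pipeline_outputs_are_deterministic(cat, template32, tmp_path, rng):
    tpl, mask = template32
    vol, _ = make_subject_image(tpl, mask, rng)
    src = tmp_path / "img.nii.gz"
    vol.to_nifti(src)
    image_id = _register_one_image(cat, src)
    run_pipeline(cat, image_id, tpl, mask, "affine", tmp_path / "s1")
    run_pipeline(cat, image_id, tpl, mask, "affine", tmp_path / "s2")
    for name in ("registered_image.nii.gz", "brain_mask.nii.gz", "affine_matrix.txt"):
        a = (tmp_path / "s1" / str(image_id) / "affine" / name).read_bytes()
        b = (tmp_path / "s2" / str(image_id) / "affine" / name).read_bytes()
        assert a == b
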