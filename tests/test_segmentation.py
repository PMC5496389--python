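import numpy as np
import pytest

from cmrquant.errors import ConfigurationError, DataError, DimensionError
from cmrquant.phantom import Noise, build_phantom, simulate_gre_series, simulate_lge_image, simulate_t2prep_series
from cmrquant.relaxometry import ParameterMap, fit_exponential_map
from cmrquant.segmentation import (
    RemoteReference,
    segment_edema,
    segment_hemorrhage,
    segment_infarct_fwhm,
    segment_mvo,
    select_remote,
)

from conftest import small_spec


def pmap_from(values, mask=None, kind="me_gre"):
    """ParameterMap with the given relaxation times, all voxels valid."""
    v = np.asarray(values, dtype=float)
    valid = np.ones(v.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    return ParameterMap(
        relaxation_time=v,
        amplitude=np.full(v.shape, 100.0),
        residual_norm=np.zeros(v.shape),
        valid=valid,
        reason=np.where(valid, 0, 3).astype(np.uint8),
        contrast_kind=kind,
    )


def dice(a, b):
    s = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / s if s else float("nan")


# --------------------------------------------------------------------------- #
# remote selection
# --------------------------------------------------------------------------- #


class TestSelectRemote:
    def test_antipodal_convention(self, iphem_noiseless):
        gt = iphem_noiseless
        remote = select_remote(gt.myocardium_mask, (120.0, 40.0), width_deg=60.0)
        from cmrquant.phantom import polar_grid

        spec = gt.spec
        _, theta = polar_grid(spec.matrix, spec.center_rc(), spec.voxel_size)
        angles = theta[None].repeat(spec.n_slices, axis=0)[remote]
        # all remote voxels within [270, 330), the sector centered at 300
        assert (((angles - 270.0) % 360.0) < 60.0).all()

    def test_full_circle_width_rejected(self, iphem_noiseless):
        with pytest.raises(ConfigurationError):
            select_remote(iphem_noiseless.myocardium_mask, (120.0, 40.0), width_deg=360.0)

    def test_overlapping_width_rejected(self, iphem_noiseless):
        with pytest.raises(ConfigurationError):
            select_remote(iphem_noiseless.myocardium_mask, (120.0, 90.0), width_deg=300.0)

    def test_empty_myocardium_rejected(self):
        with pytest.raises(DataError):
            select_remote(np.zeros((2, 8, 8), dtype=bool), (120.0, 40.0))

    @pytest.mark.parametrize("arm", ["+HEM", "I-HEM", "I+HEM"])
    def test_remote_disjoint_from_edema_truth(self, phantoms_noiseless, arm):
        gt = phantoms_noiseless[arm]
        g = gt.spec.geometry
        remote = select_remote(
            gt.myocardium_mask,
            (g.lesion_theta_center_deg, g.lesion_theta_width_deg),
            voxel_size=gt.spec.voxel_size,
        )
        assert not (remote & gt.edema_mask).any()

    def test_mask_based_lesion_direction(self, iphem_noiseless):
        gt = iphem_noiseless
        remote = select_remote(gt.myocardium_mask, gt.edema_mask, voxel_size=gt.spec.voxel_size)
        assert remote.any()
        assert not (remote & gt.edema_mask).any()


# --------------------------------------------------------------------------- #
# hemorrhage criterion
# --------------------------------------------------------------------------- #


class TestSegmentHemorrhage:
    def _grid(self):
        t2star = np.full((1, 4, 4), 35.0)
        myo = np.ones((1, 4, 4), dtype=bool)
        return t2star, myo

    def test_below_threshold_labeled(self):
        t2star, myo = self._grid()
        t2star[0, 0, :3] = 19.0
        lesion = segment_hemorrhage(pmap_from(t2star), myo)
        assert lesion.mask[0, 0, :3].all()
        assert lesion.mask.sum() == 3

    def test_exactly_20_not_labeled(self):
        t2star, myo = self._grid()
        t2star[0, 0, :3] = 20.0
        lesion = segment_hemorrhage(pmap_from(t2star), myo)
        assert not lesion.mask.any()

    def test_healthy_phantom_empty(self, phantoms_noiseless):
        gt = phantoms_noiseless["healthy"]
        pmap = fit_exponential_map(simulate_gre_series(gt), gt.myocardium_mask)
        assert not segment_hemorrhage(pmap, gt.myocardium_mask).mask.any()

    def test_invalid_voxels_never_labeled(self):
        t2star, myo = self._grid()
        t2star[0, 0, :] = 10.0
        valid = np.ones_like(myo)
        valid[0, 0, 0] = False
        lesion = segment_hemorrhage(pmap_from(t2star, mask=valid), myo)
        assert not lesion.mask[0, 0, 0]
        assert lesion.mask[0, 0, 1:].all()

    def test_threshold_monotonicity(self, iphem_noiseless):
        gt = iphem_noiseless
        pmap = fit_exponential_map(simulate_gre_series(gt), gt.myocardium_mask)
        masks = [
            segment_hemorrhage(pmap, gt.myocardium_mask, threshold_ms=thr).mask
            for thr in (15.0, 20.0, 30.0)
        ]
        assert (masks[0] <= masks[1]).all() and (masks[1] <= masks[2]).all()

    def test_provenance_records_threshold(self):
        t2star, myo = self._grid()
        lesion = segment_hemorrhage(pmap_from(t2star), myo, threshold_ms=22.5)
        assert lesion.provenance["threshold_ms"] == 22.5
        assert lesion.provenance["criterion"] == "t2star_below_threshold"

    def test_exact_criterion_on_noiseless_phantom(self, iphem_noiseless):
        gt = iphem_noiseless
        pmap = fit_exponential_map(simulate_gre_series(gt), gt.myocardium_mask)
        lesion = segment_hemorrhage(pmap, gt.myocardium_mask)
        expected = gt.myocardium_mask & pmap.valid & (pmap.relaxation_time < 20.0)
        assert np.array_equal(lesion.mask, expected)
        assert np.array_equal(lesion.mask, gt.hemorrhage_mask)


# --------------------------------------------------------------------------- #
# edema criterion
# --------------------------------------------------------------------------- #


class TestSegmentEdema:
    def _remote(self, mean=38.0, sd=2.0):
        return RemoteReference(mask=np.zeros((1, 4, 4), dtype=bool), mean_t2=mean, sd_t2=sd)

    def test_boundary_strictly_above_cutoff(self):
        t2 = np.full((1, 4, 4), 38.0)
        t2[0, 0, :3] = 43.0
        t2[0, 1, :3] = 42.0
        myo = np.ones((1, 4, 4), dtype=bool)
        lesion = segment_edema(pmap_from(t2, kind="t2prep"), myo, self._remote())
        assert lesion.mask[0, 0, :3].all()
        assert not lesion.mask[0, 1, :3].any()

    def test_homogeneous_map_empty(self):
        t2 = np.full((1, 4, 4), 38.0)
        myo = np.ones((1, 4, 4), dtype=bool)
        assert not segment_edema(pmap_from(t2), myo, self._remote()).mask.any()

    def test_undefined_remote_sd_rejected(self):
        t2 = np.full((1, 4, 4), 38.0)
        myo = np.ones((1, 4, 4), dtype=bool)
        with pytest.raises(ConfigurationError, match="select_remote"):
            segment_edema(pmap_from(t2), myo, self._remote(sd=float("nan")))

    def _iphem_context(self, gt):
        t2_map = fit_exponential_map(simulate_t2prep_series(gt), gt.myocardium_mask)
        g = gt.spec.geometry
        remote_mask = select_remote(
            gt.myocardium_mask,
            (g.lesion_theta_center_deg, g.lesion_theta_width_deg),
            voxel_size=gt.spec.voxel_size,
        )
        return t2_map, RemoteReference.from_maps(remote_mask, t2_map=t2_map)

    def test_hemorrhagic_core_filled_via_enclosure(self, iphem_noiseless):
        # low-T2 core is below the cutoff yet labeled as edema (no companions given)
        gt = iphem_noiseless
        t2_map, remote = self._iphem_context(gt)
        lesion = segment_edema(t2_map, gt.myocardium_mask, remote)
        assert lesion.mask[gt.hemorrhage_mask].all()

    def test_hemorrhagic_core_filled_via_companion(self, iphem_noiseless):
        gt = iphem_noiseless
        t2_map, remote = self._iphem_context(gt)
        lesion = segment_edema(
            t2_map, gt.myocardium_mask, remote, companion_cores=(gt.hemorrhage_mask,)
        )
        assert lesion.mask[gt.hemorrhage_mask].all()
        assert lesion.provenance["core_fill_voxels"] >= int(gt.hemorrhage_mask.sum())

    def test_noiseless_recovery_matches_truth(self, iphem_noiseless):
        gt = iphem_noiseless
        t2_map, remote = self._iphem_context(gt)
        lesion = segment_edema(t2_map, gt.myocardium_mask, remote)
        assert np.array_equal(lesion.mask, gt.edema_mask)

    def test_sd_multiplier_monotonicity(self, phantoms_noiseless):
        gt = phantoms_noiseless["I-HEM"]
        t2_map, remote = self._iphem_context(gt)
        masks = [
            segment_edema(t2_map, gt.myocardium_mask, remote, sd_multiplier=m).mask
            for m in (1.0, 2.0, 4.0)
        ]
        assert (masks[2] <= masks[1]).all() and (masks[1] <= masks[0]).all()


# --------------------------------------------------------------------------- #
# FWHM infarct
# --------------------------------------------------------------------------- #


class TestSegmentInfarctFwhm:
    def test_toy_profile(self):
        # half-maximum rule applied to a 1-D intensity profile
        img = np.array([[[10.0, 10.0, 80.0, 100.0, 60.0, 10.0]]])
        myo = np.ones((1, 1, 6), dtype=bool)
        remote = np.zeros_like(myo)
        remote[0, 0, :2] = True
        lesion = segment_infarct_fwhm(img, myo, remote_mask=remote)
        assert np.array_equal(lesion.mask[0, 0], [False, False, True, True, True, False])
        assert lesion.provenance["reference_max"] == 100.0
        assert lesion.provenance["half_max"] == 50.0

    def test_hem_only_phantom_empty(self, phantoms_noiseless):
        gt = phantoms_noiseless["+HEM"]
        lge = simulate_lge_image(gt)
        g = gt.spec.geometry
        remote = select_remote(
            gt.myocardium_mask,
            (g.lesion_theta_center_deg, g.lesion_theta_width_deg),
            voxel_size=gt.spec.voxel_size,
        )
        lesion = segment_infarct_fwhm(lge, gt.myocardium_mask, remote_mask=remote)
        assert not lesion.mask.any()
        assert lesion.provenance["note"] == "below_enhancement_floor"

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(1234)
        for _ in range(10):
            spec = small_spec(
                "I+HEM",
                lesion_theta_center_deg=float(rng.uniform(0, 360)),
                lesion_theta_width_deg=float(rng.uniform(60, 140)),
                infarct_transmurality=float(rng.uniform(0.5, 0.9)),
                mvo_fraction=0.0,
            )
            gt = build_phantom(spec)
            lge = simulate_lge_image(gt)
            img = lge.frame(0)
            myo = gt.myocardium_mask
            lesion = segment_infarct_fwhm(lge, myo)
            # oracle: explicit scan labeling every voxel >= half the myocardial max
            oracle = myo & (img >= 0.5 * img[myo].max())
            assert np.array_equal(lesion.mask, oracle)

    def test_empty_myocardium_rejected(self):
        with pytest.raises(DataError):
            segment_infarct_fwhm(np.zeros((1, 4, 4)), np.zeros((1, 4, 4), dtype=bool))

    def test_seed_region_restricts_reference(self):
        img = np.array([[[10.0, 100.0, 40.0, 40.0]]])
        myo = np.ones((1, 1, 4), dtype=bool)
        seed = np.zeros_like(myo)
        seed[0, 0, 2:] = True
        lesion = segment_infarct_fwhm(img, myo, seed_region=seed, min_component_size=1)
        assert lesion.provenance["reference_max"] == 40.0


# --------------------------------------------------------------------------- #
# MVO growth
# --------------------------------------------------------------------------- #


def iphem_lge_context(gt):
    lge = simulate_lge_image(gt)
    lesion = segment_infarct_fwhm(lge, gt.myocardium_mask)
    return lge, lesion


class TestSegmentMvo:
    def test_noiseless_core_matches_truth(self, iphem_noiseless):
        gt = iphem_noiseless
        lge, infarct = iphem_lge_context(gt)
        mvo = segment_mvo(lge, infarct.mask)
        # oracle: the phantom's enclosed sub-threshold component is the truth mask
        assert dice(mvo.mask, gt.mvo_mask) >= 0.95

    def test_ihem_phantom_empty(self, phantoms_noiseless):
        gt = phantoms_noiseless["I-HEM"]
        lge, infarct = iphem_lge_context(gt)
        assert infarct.mask.any()
        assert not segment_mvo(lge, infarct.mask).mask.any()

    def test_region_touching_outside_excluded(self):
        # dark core open to the array border through a dark channel: not enclosed
        img = np.full((3, 7, 7), 0.0)
        infarct = np.zeros((3, 7, 7), dtype=bool)
        img[1, 2:5, 2:5] = 100.0
        infarct[1, 2:5, 2:5] = True
        img[1, 3, 3] = 5.0
        infarct[1, 3, 3] = False  # dark core inside the ring, but open along z
        mvo = segment_mvo(img, infarct)
        assert not mvo.mask.any()

    def test_enclosed_core_found_in_toy_volume(self):
        img = np.full((3, 7, 7), 100.0)
        infarct = np.ones((3, 7, 7), dtype=bool)
        img[1, 3, 3] = 5.0
        infarct[1, 3, 3] = False
        mvo = segment_mvo(img, infarct, min_component_size=1)
        assert mvo.mask.sum() == 1 and mvo.mask[1, 3, 3]

    def test_seed_point_growth(self, iphem_noiseless):
        gt = iphem_noiseless
        lge, infarct = iphem_lge_context(gt)
        seed = tuple(np.argwhere(gt.mvo_mask)[0])
        mvo = segment_mvo(lge, infarct.mask, seed_point=seed)
        assert dice(mvo.mask, gt.mvo_mask) >= 0.95

    def test_seed_outside_bounding_region_rejected(self, iphem_noiseless):
        gt = iphem_noiseless
        lge, infarct = iphem_lge_context(gt)
        with pytest.raises(ConfigurationError):
            segment_mvo(lge, infarct.mask, seed_point=(0, 0, 0))

    def test_empty_infarct_rejected(self):
        with pytest.raises(DataError):
            segment_mvo(np.zeros((1, 4, 4)), np.zeros((1, 4, 4), dtype=bool))

    def test_rerun_identical(self, iphem_noiseless):
        gt = iphem_noiseless
        lge, infarct = iphem_lge_context(gt)
        a = segment_mvo(lge, infarct.mask)
        b = segment_mvo(lge, infarct.mask)
        assert np.array_equal(a.mask, b.mask)

    def test_containment_in_combined_infarct(self, iphem_noiseless):
        gt = iphem_noiseless
        lge, infarct = iphem_lge_context(gt)
        mvo = segment_mvo(lge, infarct.mask)
        combined = infarct.mask | mvo.mask
        assert not (mvo.mask & ~combined).any()
        assert mvo.mask.any()


# --------------------------------------------------------------------------- #
# noise robustness
# --------------------------------------------------------------------------- #


def test_hemorrhage_dice_at_snr20():
    spec = small_spec("I+HEM", noise="rician", snr=20.0, seed=21)
    gt = build_phantom(spec)
    pmap = fit_exponential_map(simulate_gre_series(gt), gt.myocardium_mask)
    lesion = segment_hemorrhage(pmap, gt.myocardium_mask)
    assert dice(lesion.mask, gt.hemorrhage_mask) >= 0.8


def test_grid_mismatch_rejected(iphem_noiseless):
    gt = iphem_noiseless
    pmap = fit_exponential_map(simulate_gre_series(gt), gt.myocardium_mask)
    with pytest.raises(DimensionError):
        segment_hemorrhage(pmap, np.ones((1, 2, 2), dtype=bool))
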