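"""IDP operators against hand arithmetic, loop oracles and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clinidp.grids import VolumeGrid
from clinidp.idp import (
    ExtractionConfig,
    csf_mask_structure,
    detect_mislocalised,
    extract_all,
    lesion_mask_gm,
    lobar_gm_volumes,
    nbm_volumes,
    psmd,
    regional_diffusion,
    tract_volume,
    tractwise_wmh_volumes,
)

from conftest import (
    grid,
    loop_overlap_volume,
    loop_weighted_mean,
    loop_weighted_volume,
    sort_interpolate_percentile,
)

SHAPE = (6, 6, 6)


def _rand_fraction(seed):
    return np.random.default_rng(seed).uniform(size=SHAPE)


def _rand_mask(seed, p=0.4):
    return (np.random.default_rng(seed).uniform(size=SHAPE) < p).astype(float)


class TestLesionMasking:
    def test_identity_when_no_lesions(self):
        gm = grid(_rand_fraction(0))
        out = lesion_mask_gm(gm, grid(np.zeros(SHAPE)))
        np.testing.assert_array_equal(out.data, gm.data)

    def test_forced_arithmetic(self):
        gm = grid(np.ones(SHAPE), voxel=(2, 2, 2))
        wmh = np.zeros(SHAPE)
        wmh[0, 0, :3] = 1
        out = lesion_mask_gm(gm, grid(wmh, voxel=(2, 2, 2)))
        # GM volume drops by exactly 3 voxels x 8 mm^3
        assert (gm.data.sum() - out.data.sum()) * 8 == pytest.approx(24.0)

    @given(seed=st.integers(0, 100))
    def test_elementwise_oracle(self, seed):
        gm, wmh = _rand_fraction(seed), _rand_mask(seed + 1)
        out = lesion_mask_gm(grid(gm), grid(wmh))
        np.testing.assert_array_equal(out.data, gm * (1 - wmh))

    @given(seed=st.integers(0, 50))
    def test_never_increases_gm(self, seed):
        gm, wmh = _rand_fraction(seed), _rand_mask(seed + 1)
        out = lesion_mask_gm(grid(gm), grid(wmh))
        assert (out.data <= gm).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            lesion_mask_gm(grid(np.zeros(SHAPE)), grid(np.zeros((5, 5, 5))))


class TestCSFMasking:
    def test_identity_when_no_csf(self):
        m = grid(_rand_mask(2))
        out = csf_mask_structure(m, grid(np.zeros(SHAPE)))
        np.testing.assert_array_equal(out.data, m.data)

    def test_volume_exactly_halved(self):
        m = np.zeros(SHAPE)
        m[2, 2, :4] = 1
        csf = np.zeros(SHAPE)
        csf[2, 2, :2] = 1.0
        out = csf_mask_structure(grid(m), grid(csf), csf_threshold=0.5)
        assert out.data.sum() == pytest.approx(m.sum() / 2)

    @given(seed=st.integers(0, 100))
    def test_voxelwise_rule_and_monotonicity(self, seed):
        m, csf = _rand_mask(seed), _rand_fraction(seed + 1)
        out = csf_mask_structure(grid(m), grid(csf), 0.5)
        np.testing.assert_array_equal(out.data, m * (csf <= 0.5))
        assert out.data.sum() <= m.sum()

    def test_threshold_validated(self):
        with pytest.raises(ValueError, match="csf_threshold"):
            csf_mask_structure(grid(_rand_mask(1)), grid(np.zeros(SHAPE)), 0.0)


class TestMislocalisation:
    def test_full_overlap_detected(self):
        m = _rand_mask(3)
        assert detect_mislocalised(grid(m), grid(np.ones(SHAPE))) is True

    def test_disjoint_not_detected(self):
        m = np.zeros(SHAPE)
        m[0, 0, 0] = 1
        csf = np.zeros(SHAPE)
        csf[5, 5, 5] = 1
        assert detect_mislocalised(grid(m), grid(csf)) is False

    def test_half_overlap_below_full_threshold(self):
        m = np.zeros(SHAPE)
        m[1, 1, :4] = 1
        csf = np.zeros(SHAPE)
        csf[1, 1, :2] = 1  # 50% of the structure
        assert detect_mislocalised(grid(m), grid(csf), 1.0) is False
        assert detect_mislocalised(grid(m), grid(csf), 0.5) is True

    def test_empty_structure_errors(self):
        with pytest.raises(ValueError, match="empty"):
            detect_mislocalised(grid(np.zeros(SHAPE)), grid(np.ones(SHAPE)))


class TestVolumeOperators:
    def _lobes(self, voxel=(2, 2, 2)):
        masks = {}
        for i, name in enumerate(("frontal", "parietal", "temporal", "occipital")):
            m = np.zeros(SHAPE)
            m[i, :, :] = 1
            masks[name] = grid(m, voxel=voxel)
        return masks

    def test_lobar_zero_gm(self):
        vols = lobar_gm_volumes(grid(np.zeros(SHAPE), voxel=(2, 2, 2)), self._lobes())
        assert set(vols) == {"frontal", "parietal", "temporal", "occipital"}
        assert all(v == 0 for v in vols.values())

    def test_lobar_forced_arithmetic(self):
        gm = np.zeros(SHAPE)
        gm[0, :, :] = 1.0  # 36 voxels of pure GM in the 'frontal' slab
        vols = lobar_gm_volumes(grid(gm, voxel=(2, 2, 2)), self._lobes())
        assert vols["frontal"] == pytest.approx(36 * 8.0)
        assert vols["parietal"] == 0

    def test_lobar_missing_mask_rejected(self):
        masks = self._lobes()
        masks.pop("occipital")
        with pytest.raises(ValueError, match="missing lobe"):
            lobar_gm_volumes(grid(np.zeros(SHAPE), voxel=(2, 2, 2)), masks)

    def test_wmh_empty_mask(self):
        tracts = {f"t{i}": grid(_rand_mask(i)) for i in range(48)}
        vols = tractwise_wmh_volumes(grid(np.zeros(SHAPE)), tracts)
        assert len(vols) == 48 and all(v == 0 for v in vols.values())

    def test_wmh_constructed_overlap(self):
        wmh = np.zeros(SHAPE)
        wmh[2, :5, :4] = 1
        tract = np.zeros(SHAPE)
        tract[2, :2, :5] = 1  # overlap is 2*4 = 8... constructed: rows 0-1, cols 0-3
        vols = tractwise_wmh_volumes(
            grid(wmh, voxel=(2, 2, 2)), {"t": grid(tract, voxel=(2, 2, 2))}
        )
        expected = loop_weighted_volume(wmh, tract, 8.0)
        assert vols["t"] == pytest.approx(expected)

    def test_nbm_weighted_sum(self):
        mask = np.zeros(SHAPE)
        mask[1:3, 1:3, 1:3] = 1  # 8 voxels
        gm = np.full(SHAPE, 0.5)
        vols = nbm_volumes({"nbm_l": grid(mask), "nbm_r": grid(mask)}, grid(gm))
        assert vols["nbm_l"] == pytest.approx(0.5 * 8 * 1.0)
        with pytest.raises(ValueError, match="hemisphere"):
            nbm_volumes({"nbm_l": grid(mask)}, grid(gm))


class TestPSMD:
    def _skel(self):
        s = np.zeros((5, 5, 5))
        s[2, :, :] = 1
        return grid(s)

    def test_constant_md_gives_zero(self):
        assert psmd(grid(np.full((5, 5, 5), 7e-4)), self._skel()) == 0.0

    def test_sorted_values_oracle(self):
        md = np.zeros((5, 5, 5))
        md[2, :, :] = np.arange(1, 26, dtype=float).reshape(5, 5)
        got = psmd(grid(md), self._skel())
        values = np.arange(1, 26, dtype=float)
        expected = sort_interpolate_percentile(values, 95) - sort_interpolate_percentile(values, 5)
        assert got == pytest.approx(expected)

    @given(seed=st.integers(0, 50), c=st.floats(0.1, 10), shift=st.floats(-1, 1))
    def test_translation_invariant_and_homogeneous(self, seed, c, shift):
        rng = np.random.default_rng(seed)
        md = rng.uniform(0, 2, size=(5, 5, 5))
        skel = self._skel()
        base = psmd(grid(md), skel)
        assert psmd(grid(md + shift + 2), skel) == pytest.approx(base + 0, abs=1e-9)
        assert psmd(grid(md * c), skel) == pytest.approx(c * base, rel=1e-9)

    def test_empty_skeleton_errors(self):
        with pytest.raises(ValueError, match="empty"):
            psmd(grid(np.ones((5, 5, 5))), grid(np.zeros((5, 5, 5))))


class TestTractVolume:
    def test_zero_density(self):
        assert tract_volume(grid(np.zeros(SHAPE))) == 0.0

    def test_counting_oracle(self):
        d = np.zeros(SHAPE)
        d.ravel()[:20] = 0.01
        assert tract_volume(grid(d, voxel=(2, 2, 2))) == pytest.approx(160.0)

    def test_boundary_is_strict(self):
        d = np.full(SHAPE, 0.005)
        assert tract_volume(grid(d)) == 0.0

    def test_negative_density_rejected(self):
        d = np.zeros(SHAPE)
        d[0, 0, 0] = -0.1
        g = VolumeGrid(d, (1, 1, 1))
        with pytest.raises(ValueError, match="non-negative"):
            tract_volume(g)


class TestRegionalDiffusion:
    def test_constant_field(self):
        md = np.full(SHAPE, 3.0)
        mo = np.full(SHAPE, -0.2)
        roi = {"r": grid(_rand_mask(5))}
        gm = grid(_rand_fraction(6) * 0.9 + 0.05)
        out = regional_diffusion(grid(md), grid(mo), roi, gm)
        assert out["r"]["md"] == pytest.approx(3.0)
        assert out["r"]["mo"] == pytest.approx(-0.2)

    def test_hand_weighted_mean(self):
        md = np.zeros(SHAPE)
        md[0, 0, 0], md[0, 0, 1] = 1.0, 3.0
        gm = np.zeros(SHAPE)
        gm[0, 0, 0], gm[0, 0, 1] = 0.25, 0.75  # weights 1:3
        roi = np.zeros(SHAPE)
        roi[0, 0, :2] = 1
        out = regional_diffusion(grid(md), grid(md), {"r": grid(roi)}, grid(gm))
        assert out["r"]["md"] == pytest.approx(2.5)

    def test_zero_weight_emits_missing(self):
        roi = {"r": grid(_rand_mask(7))}
        out = regional_diffusion(
            grid(np.ones(SHAPE)), grid(np.ones(SHAPE)), roi, grid(np.zeros(SHAPE))
        )
        assert math.isnan(out["r"]["md"]) and math.isnan(out["r"]["mo"])


class TestExtractAll:
    def test_emits_110_idps(self, default_phantom):
        subject, atlas, _ = default_phantom
        table = extract_all(subject, atlas)
        assert table["idp_name"].nunique() == 110
        assert table.shape[0] == 110

    def test_deterministic(self, default_phantom):
        subject, atlas, _ = default_phantom
        a = extract_all(subject, atlas)
        b = extract_all(subject, atlas)
        assert a.equals(b)

    def test_modality_tags(self, default_phantom):
        subject, atlas, _ = default_phantom
        counts = extract_all(subject, atlas)["modality"].value_counts().to_dict()
        assert counts == {"dMRI": 56, "T2-FLAIR": 48, "T1": 6}

    def test_volume_idps_match_loop_oracle(self, small_phantom):
        """Every volume IDP equals the brute-force voxel-count oracle."""
        subject, atlas, _ = small_phantom
        table = extract_all(subject, atlas).set_index("idp_name")["value"]
        voxvol = subject.gm_pve.voxel_volume
        gm_corr = subject.gm_pve.data * (1 - subject.wmh_mask.data)
        for lobe, mask in atlas.lobar_masks.items():
            expected = loop_weighted_volume(gm_corr, mask.data, voxvol)
            assert table[f"lobar_gm_{lobe}"] == pytest.approx(expected)
        for tract in ["wm_tract_01", "wm_tract_25", "wm_tract_48"]:
            expected = loop_overlap_volume(
                subject.wmh_mask.data, atlas.wm_tract_masks[tract].data, voxvol
            )
            assert table[f"wmh_{tract}"] == pytest.approx(expected)
        for side, mask in atlas.nbm_masks.items():
            expected = loop_weighted_volume(gm_corr, mask.data, voxvol)
            assert table[f"{side}_volume"] == pytest.approx(expected)

    def test_regional_means_match_loop_oracle(self, small_phantom):
        subject, atlas, _ = small_phantom
        table = extract_all(subject, atlas).set_index("idp_name")["value"]
        gm_corr = subject.gm_pve.data * (1 - subject.wmh_mask.data)
        roi = atlas.gm_roi_masks["precuneus_l"].data
        expected = loop_weighted_mean(subject.md_map.data, gm_corr, roi)
        assert table["regional_md_precuneus_l"] == pytest.approx(expected)

    def test_lobar_sum_bounded_by_total_gm(self, small_phantom):
        subject, atlas, _ = small_phantom
        table = extract_all(subject, atlas).set_index("idp_name")["value"]
        gm_corr = subject.gm_pve.data * (1 - subject.wmh_mask.data)
        total_gm = gm_corr.sum() * subject.gm_pve.voxel_volume
        lobar_sum = sum(table[f"lobar_gm_{l}"] for l in atlas.lobar_masks)
        assert lobar_sum <= total_gm + 1e-9

    def test_mislocalised_structure_yields_missing(self, default_phantom):
        subject, atlas, _ = default_phantom
        # flood the right amygdala with CSF so it is detected as mislocalised
        csf = subject.csf_map.data.copy()
        csf[subject.structure_masks["amygdala_r"].data.astype(bool)] = 1.0
        import dataclasses

        flooded = dataclasses.replace(
            subject, csf_map=VolumeGrid(csf, subject.csf_map.voxel_size)
        )
        table = extract_all(flooded, atlas)
        assert "amygdala_r" in table.attrs["mislocalised_structures"]
        row = table.set_index("idp_name")["value"]
        assert math.isnan(row["regional_md_amygdala_r"])
        assert table["idp_name"].nunique() == 110  # count preserved

    def test_atlas_composition_enforced(self, default_phantom):
        subject, atlas, _ = default_phantom
        cfg = ExtractionConfig(n_wm_tracts=40)
        with pytest.raises(ValueError, match="expected 40"):
            extract_all(subject, atlas, cfg)
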