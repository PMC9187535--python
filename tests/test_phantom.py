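import hashlib

import numpy as np
import pytest

from ctriage import (
    LesionSpec,
    PhantomSpec,
    default_lesion_spec,
    inject_lesion,
    make_cohort,
    make_normal_phantom,
)
from ctriage.phantom import (
    DEFAULT_TISSUE_HU,
    LESION_KINDS,
    TISSUE_LABELS,
    PhantomSpecError,
    phantom_brain_mask,
)


class TestNormalPhantom:
    def test_zero_noise_equals_compartment_means(self, clean_phantom):
        v, labels = clean_phantom
        for name, code in TISSUE_LABELS.items():
            region = labels == code
            assert region.any()
            assert np.all(v.values[region] == DEFAULT_TISSUE_HU[name])

    def test_deterministic_given_seed(self):
        a, _ = make_normal_phantom(PhantomSpec(seed=42))
        b, _ = make_normal_phantom(PhantomSpec(seed=42))
        assert np.array_equal(a.values, b.values)
        c, _ = make_normal_phantom(PhantomSpec(seed=43))
        assert not np.array_equal(a.values, c.values)

    def test_noise_sd_matches_model(self, clean_phantom):
        v0, labels = clean_phantom
        v, _ = make_normal_phantom(PhantomSpec(noise_sd_hu=3.0, seed=5))
        brain = phantom_brain_mask(labels, v0).values
        residual = (v.values - v0.values)[brain]
        assert residual.size > 10_000
        assert abs(residual.std(ddof=1) - 3.0) < 0.2

    def test_grid_too_small_rejected(self):
        with pytest.raises(PhantomSpecError):
            make_normal_phantom(PhantomSpec(grid_shape=(16, 16, 16)))

    def test_negative_noise_rejected(self):
        with pytest.raises(PhantomSpecError):
            PhantomSpec(noise_sd_hu=-1.0)


class TestLesionSpec:
    def test_kind_and_polarity_validation(self):
        with pytest.raises(PhantomSpecError):
            LesionSpec(kind="tumour")
        with pytest.raises(PhantomSpecError):
            LesionSpec(kind="hvs", delta_hu=-5.0)  # hvs must be hyperdense
        with pytest.raises(PhantomSpecError):
            LesionSpec(kind="chronic_ischemia", delta_hu=+5.0)
        with pytest.raises(PhantomSpecError):
            LesionSpec(kind="lacunar_dwm", size_mm=0.0)


class TestInjectLesion:
    def test_null_delta_leaves_volume_unchanged(self, clean_phantom):
        v, labels = clean_phantom
        spec = LesionSpec(kind="chronic_ischemia", center_frac=(0.75, 0.65, 0.6),
                          size_mm=20.0, delta_hu=0.0)
        out, mask = inject_lesion(v, labels, spec)
        assert np.array_equal(out.values, v.values)
        assert mask.n_voxels > 0

    def test_input_volume_not_mutated(self, clean_phantom):
        v, labels = clean_phantom
        before = v.values.copy()
        inject_lesion(v, labels, default_lesion_spec("lacunar_dwm"))
        assert np.array_equal(v.values, before)

    def test_lacunar_sphere_volume_matches_analytic(self, clean_phantom):
        v, labels = clean_phantom
        spec = LesionSpec(kind="lacunar_dwm", center_frac=(0.4, 0.45, 0.55),
                          size_mm=8.0, delta_hu=-15.0)
        _, mask = inject_lesion(v, labels, spec)
        # 8 mm radius on a 2 mm grid = 4-voxel radius sphere
        analytic = 4.0 / 3.0 * np.pi * 4.0**3
        assert abs(mask.n_voxels - analytic) / analytic < 0.15

    def test_hvs_exceeds_contralateral_ratio(self, clean_phantom):
        v, labels = clean_phantom
        out, mask = inject_lesion(v, labels, default_lesion_spec("hvs"))
        tube_mean = out.values[mask.values].mean()
        # mirror the tube across the midline for the contralateral sample
        flipped = mask.values[::-1, :, :]
        contralateral = out.values[flipped & ~mask.values].mean()
        assert tube_mean > 1.2 * contralateral

    def test_changes_confined_to_feather_band(self, clean_phantom):
        from scipy import ndimage

        v, labels = clean_phantom
        out, mask = inject_lesion(v, labels, default_lesion_spec("subacute_ischemia"))
        changed = out.values != v.values
        band = ndimage.binary_dilation(mask.values, structure=np.ones((3, 3, 3), bool))
        assert np.all(band[changed])

    @pytest.mark.parametrize("kind", LESION_KINDS)
    def test_lesion_mean_shift_sign(self, clean_phantom, kind):
        v, labels = clean_phantom
        out, mask = inject_lesion(v, labels, default_lesion_spec(kind))
        shift = out.values[mask.values].mean() - v.values[mask.values].mean()
        assert shift > 0 if kind == "hvs" else shift < 0

    def test_lesion_mask_inside_brain(self, clean_phantom):
        v, labels = clean_phantom
        brain = phantom_brain_mask(labels, v).values
        for kind in LESION_KINDS:
            _, mask = inject_lesion(v, labels, default_lesion_spec(kind))
            assert np.all(brain[mask.values])

    def test_lesion_outside_brain_rejected(self, clean_phantom):
        v, labels = clean_phantom
        spec = LesionSpec(kind="lacunar_dwm", center_frac=(3.0, 3.0, 3.0),
                          size_mm=5.0, delta_hu=-15.0)
        with pytest.raises(PhantomSpecError, match="outside"):
            inject_lesion(v, labels, spec)


class TestCohort:
    def test_counts_and_labels(self, tmp_path):
        manifest = make_cohort(
            n_train_normal=3,
            n_test_normal=2,
            n_test_lesion_per_kind={"chronic_ischemia": 1, "hvs": 1},
            spec=PhantomSpec(),
            seed=7,
            out_dir=tmp_path / "cohort",
        )
        assert len(manifest) == 7
        train = manifest[manifest["split"] == "train"]
        assert len(train) == 3 and (train["truth_label"] == "normal").all()
        lesions = manifest[manifest["truth_label"] == "pathological"]
        assert len(lesions) == 2
        assert all((tmp_path / "cohort").joinpath(p).name for p in manifest["scan_path"])

    def test_same_seed_byte_identical(self, tmp_path):
        kwargs = dict(
            n_train_normal=1, n_test_normal=1,
            n_test_lesion_per_kind={"lacunar_dwm": 1},
            spec=PhantomSpec(), seed=3,
        )
        m1 = make_cohort(out_dir=tmp_path / "a", **kwargs)
        m2 = make_cohort(out_dir=tmp_path / "b", **kwargs)

        def digest(path):
            import gzip

            return hashlib.sha256(gzip.open(path).read()).hexdigest()

        for p1, p2 in zip(m1["scan_path"], m2["scan_path"]):
            assert digest(p1) == digest(p2)

    def test_lesion_masks_subset_of_brain(self, tmp_path):
        from ctriage import compute_brain_mask, read_mask, read_volume

        manifest = make_cohort(
            n_train_normal=0, n_test_normal=0,
            n_test_lesion_per_kind={k: 1 for k in LESION_KINDS},
            spec=PhantomSpec(noise_sd_hu=0.0), seed=5,
            out_dir=tmp_path / "c",
        )
        for row in manifest.itertuples():
            brain = compute_brain_mask(read_volume(row.scan_path))
            lesion = read_mask(row.lesion_mask_path)
            # lesion voxels (hypodense or hyperdense, still soft tissue)
            # always lie within the brain compartment
            assert np.all(brain.values[lesion.values])
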