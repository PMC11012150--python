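"""Generator correctness: determinism, geometry, photon statistics, presets."""

import dataclasses

import numpy as np
import pytest

from bifor.errors import InvalidSceneSpec
from bifor.io import read_stack
from bifor.synthetic import (
    PRESETS,
    SceneSpec,
    apply_noise,
    generate_condition_dataset,
    generate_scene,
    render_scene,
    sample_scene_specs,
)


def test_zero_signal_scene_emits_masks(small_spec):
    """All amplitudes and read noise zero: channels are all-zero, truth masks remain."""
    spec = dataclasses.replace(
        small_spec, dapi_amplitude=0.0, locus_amplitude=0.0,
        locus_amplitude_green_bg=0.0, read_noise_sd=0.0,
    )
    stack, truth = generate_scene(spec)
    for role, arr in stack.channels.items():
        assert not arr.any(), f"channel {role} not all zero"
    assert truth.nucleus_mask.any()
    assert truth.locus_mask.any()


def test_fixed_seed_is_bit_identical(small_spec):
    spec = dataclasses.replace(small_spec, seed=77)
    stack1, truth1 = generate_scene(spec)
    stack2, truth2 = generate_scene(spec)
    for role in stack1.channels:
        np.testing.assert_array_equal(stack1.channels[role], stack2.channels[role])
    np.testing.assert_array_equal(truth1.nucleus_mask, truth2.nucleus_mask)
    other, _ = generate_scene(dataclasses.replace(spec, seed=78))
    assert not np.array_equal(stack1.channels["green"], other.channels["green"])


def test_locus_mask_contained_in_nucleus():
    """Containment holds across the jittered specs the dataset generator draws."""
    specs = sample_scene_specs(PRESETS["SCR_EXD_WT"], 4, 2, seed=5, base=None)
    assert len(specs) == 8
    for _, _, spec in specs:
        _, truth = generate_scene(spec)
        assert truth.locus_mask.any()
        assert not (truth.locus_mask & ~truth.nucleus_mask).any()


def test_enrichment_is_multiplicative_on_ideal_green(small_spec):
    """beta scales the pre-noise green maximum at the locus by exactly (1+beta)."""
    flat = dataclasses.replace(small_spec, band_contrast=0.0, seed=3)
    null = render_scene(dataclasses.replace(flat, enrichment_beta=0.0))
    boosted = render_scene(dataclasses.replace(flat, enrichment_beta=2.0))
    m0 = null.ideal["green"][null.truth.locus_mask].max()
    m1 = boosted.ideal["green"][boosted.truth.locus_mask].max()
    assert m1 == pytest.approx(3.0 * m0, rel=0, abs=1e-4)


def test_null_scene_shows_no_locus_enrichment(small_spec):
    """Monte-Carlo oracle: with beta=0 the mean green inside the locus matches
    an equal-size off-locus nuclear region, within the CI over 50 seeds."""
    diffs = []
    for seed in range(50):
        spec = dataclasses.replace(small_spec, band_contrast=0.0, enrichment_beta=0.0, seed=seed)
        stack, truth = generate_scene(spec)
        green = stack.channels["green"]
        mirrored = truth.locus_mask[::-1, ::-1]  # point reflection through the nucleus centre
        assert mirrored.sum() == truth.locus_mask.sum()
        assert not (mirrored & truth.locus_mask).any()
        assert not (mirrored & ~truth.nucleus_mask).any()
        diffs.append(green[truth.locus_mask].mean() - green[mirrored].mean())
    diffs = np.asarray(diffs)
    sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
    assert abs(diffs.mean()) < 3.5 * sem + 1e-9


def test_poisson_variance_matches_mean():
    """Shot-noise model: var equals the expected intensity within 10 percent."""
    lam = 60.0
    field = np.full((400, 400), lam, dtype=np.float32)
    noisy = apply_noise(field, read_noise_sd=0.0, rng=np.random.default_rng(11))
    assert field.size >= 10**5
    assert noisy.var() / lam == pytest.approx(1.0, abs=0.1)
    assert noisy.mean() == pytest.approx(lam, rel=0.02)


def test_condition_presets_encode_study_design():
    enriched = {"SCR_EXD_WT", "SCR_EXD_CONS", "UBX_EXD_CONS"}
    for name, preset in PRESETS.items():
        if name in enriched:
            assert preset.enrichment_beta > 0
        else:
            assert preset.enrichment_beta == 0.0
    assert PRESETS["UBX_EXD_WT"].green_background == 3.0 * PRESETS["SCR_EXD_WT"].green_background
    assert PRESETS["SCR_EXD_MUT"].locus_amplitude < PRESETS["SCR_EXD_WT"].locus_amplitude


@pytest.mark.parametrize(
    "overrides",
    [
        {"locus_center": (48.0, 95.0)},           # outside the nucleus ellipsoid
        {"nucleus_axes": (48.0, 48.0)},           # no room for the 3-sigma PSF margin
        {"green_band_coupling": 1.5},
        {"enrichment_beta": -0.5},
    ],
)
def test_invalid_specs_are_rejected(small_spec, overrides):
    spec = dataclasses.replace(small_spec, **overrides)
    with pytest.raises(InvalidSceneSpec):
        spec.validate()


def test_empty_dataset(tmp_path):
    paths, manifest = generate_condition_dataset(PRESETS["SCR_EXD_WT"], 0, 3, 1, tmp_path / "d")
    assert paths == []
    assert len(manifest) == 0
    assert not (tmp_path / "d").exists()


def test_dataset_regeneration_is_identical(tmp_path, small_spec):
    """Same seed twice: identical manifests and identical stack bytes."""
    kwargs = dict(n_nuclei_per_replicate=3, n_replicates=2, seed=9, base=small_spec)
    paths1, man1 = generate_condition_dataset(PRESETS["SCR_EXD_MUT"], outdir=tmp_path / "a", **kwargs)
    paths2, man2 = generate_condition_dataset(PRESETS["SCR_EXD_MUT"], outdir=tmp_path / "b", **kwargs)
    assert [p.name for p in paths1] == [p.name for p in paths2]
    man1 = man1.drop(columns="path")
    man2 = man2.drop(columns="path")
    assert man1.equals(man2)
    for p1, p2 in zip(paths1, paths2):
        assert p1.read_bytes() == p2.read_bytes()


def test_mut_dataset_is_all_null(tmp_path, small_spec):
    """The binding-site-mutant condition carries no enrichment in any scene."""
    _, manifest = generate_condition_dataset(
        PRESETS["SCR_EXD_MUT"], 4, 2, seed=3, outdir=tmp_path / "mut", base=small_spec
    )
    assert (manifest["beta_true"] == 0.0).all()
    stack = read_stack(manifest["path"].iloc[0])
    assert set(stack.channels) == {"dapi", "red", "green"}


def test_3d_scene_generation():
    spec = SceneSpec(
        shape=(20, 96, 96),
        voxel_size=(0.2, 0.06, 0.06),
        nucleus_axes=(5.0, 28.0, 36.0),
        locus_center=(9.5, 48.0, 58.0),
        locus_sigma=(1.0, 2.0, 2.0),
        psf_sigma=(1.0, 0.85, 0.85),
    )
    stack, truth = generate_scene(spec)
    assert stack.shape == (20, 96, 96)
    assert truth.locus_mask.any()
    assert not (truth.locus_mask & ~truth.nucleus_mask).any()
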