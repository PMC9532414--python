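"""Determinism, geometry and invariants of the synthetic root generator."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

import iterroot as ir
from iterroot import RootSceneSpec, generate_sample, generate_skeleton
from iterroot.synthetic_roots import (GenerationError, Polyline,
                                      SceneValidationError, rasterize_mask,
                                      render_image)

SMALL = dict(height_px=192, width_px=192, max_steps=40, n_primary_roots=2)


class TestSpecValidation:
    @pytest.mark.parametrize("field,value", [
        ("height_px", 32),
        ("branch_prob_per_step", 1.5),
        ("thickness_decay", 0.0),
        ("initial_thickness_px", 0.5),
        ("root_intensity_mean", 1.2),
        ("droplet_count", -1),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(SceneValidationError, match=field):
            RootSceneSpec(**{field: value})


class TestGenerateSkeleton:
    def test_branching_disabled_gives_single_polyline(self):
        spec = RootSceneSpec(max_branch_depth=0, n_primary_roots=1, **{
            k: v for k, v in SMALL.items() if k != "n_primary_roots"})
        skel = generate_skeleton(spec, np.random.default_rng(spec.seed))
        assert len(skel) == 1
        assert skel[0].depth == 0

    def test_same_seed_reproduces_polylines(self):
        spec = RootSceneSpec(**SMALL, seed=5)
        a = generate_skeleton(spec, np.random.default_rng(spec.seed))
        b = generate_skeleton(spec, np.random.default_rng(spec.seed))
        assert len(a) == len(b)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.points, lb.points)
            assert (la.depth, la.tree) == (lb.depth, lb.tree)

    def test_every_point_inside_bounds(self):
        spec = RootSceneSpec(**SMALL, seed=3)
        for line in generate_skeleton(spec, np.random.default_rng(spec.seed)):
            assert (line.points[:, 0] >= 0).all()
            assert (line.points[:, 0] <= spec.height_px - 1).all()
            assert (line.points[:, 1] >= 0).all()
            assert (line.points[:, 1] <= spec.width_px - 1).all()

    def test_certain_branching_count_matches_rng_replay_oracle(self):
        """With branch probability 1 and depth limit 1, every parent step
        spawns one child, so polyline count = 1 + parent steps; verified
        by independently replaying the draw sequence."""
        spec = RootSceneSpec(height_px=512, width_px=512, n_primary_roots=1,
                             branch_prob_per_step=1.0, max_branch_depth=1,
                             max_steps=10, seed=13)
        skel = generate_skeleton(spec, np.random.default_rng(spec.seed))

        # independent replay of the same stream
        rng = np.random.default_rng(spec.seed)
        col = rng.uniform(0.15 * spec.width_px, 0.85 * spec.width_px)
        row = rng.uniform(2.0, 0.06 * spec.height_px)
        heading = rng.normal(0.0, 0.2)
        pos = np.array([row, col])
        h, w = spec.height_px, spec.width_px

        def child_draws(start, hd, steps):
            p = start.copy()
            for _ in range(steps):
                hd = 0.95 * hd + rng.normal(0.0, spec.curvature_noise_sd)
                p = p + spec.step_length_px * np.array(
                    [math.cos(hd), math.sin(hd)])
                if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
                    return

        spawns = 0
        step = 0
        while step < spec.max_steps:
            heading = 0.95 * heading + rng.normal(0.0, spec.curvature_noise_sd)
            pos = pos + spec.step_length_px * np.array(
                [math.cos(heading), math.sin(heading)])
            if not (0 <= pos[0] <= h - 1 and 0 <= pos[1] <= w - 1):
                break
            step += 1
            assert rng.random() < 1.0  # branch decision, always fires
            side = 1.0 if rng.random() < 0.5 else -1.0
            angle = rng.uniform(0.35, 1.0)
            child_draws(pos, heading + side * angle, spec.max_steps - step)
            spawns += 1
        assert len(skel) == 1 + spawns
        assert sum(1 for l in skel if l.depth == 1) == spawns


class TestRasterizeMask:
    def test_empty_skeleton_gives_empty_mask(self):
        spec = RootSceneSpec(**SMALL)
        assert rasterize_mask([], spec).sum() == 0

    def test_straight_line_foreground_count_bounded(self):
        spec = RootSceneSpec(height_px=64, width_px=128,
                             initial_thickness_px=1.0)
        length = 80
        line = Polyline(points=np.array([[32.0, 10.0], [32.0, 10.0 + length]]))
        count = int(rasterize_mask([line], spec).sum())
        assert length <= count <= 3 * length

    def test_nonintersecting_trees_match_component_count_oracle(self):
        spec = RootSceneSpec(seed=2, n_primary_roots=3, height_px=256,
                             width_px=256, max_steps=50)
        skel = generate_skeleton(spec, np.random.default_rng(spec.seed))
        eight = np.ones((3, 3))
        per_tree = [rasterize_mask([l for l in skel if l.tree == t], spec)
                    for t in range(3)]
        # oracle precondition: trees do not touch
        assert (sum(ndimage.binary_dilation(m, eight).astype(int)
                    for m in per_tree) <= 1).all()
        union = rasterize_mask(skel, spec)
        _, n = ndimage.label(union, structure=eight)
        assert n == spec.n_primary_roots
        for m in per_tree:
            assert ndimage.label(m, structure=eight)[1] == 1


class TestRenderImage:
    def _noiseless(self):
        return RootSceneSpec(**SMALL, curvature_noise_sd=0.1,
                             root_intensity_sd=0.0, background_sd=0.0,
                             sensor_noise_sd=0.0, droplet_count=0,
                             dust_count=0, include_stem=False)

    def test_noiseless_render_has_exactly_two_levels(self):
        spec = self._noiseless()
        rng = np.random.default_rng(spec.seed)
        skel = generate_skeleton(spec, rng)
        mask = rasterize_mask(skel, spec)
        img = render_image(mask, skel, spec, rng)
        values = np.unique(img)
        assert set(np.round(values, 6)) == {
            round(spec.background_mean, 6), round(spec.root_intensity_mean, 6)}

    def test_threshold_at_midpoint_recovers_mask(self):
        spec = self._noiseless()
        rng = np.random.default_rng(spec.seed)
        skel = generate_skeleton(spec, rng)
        mask = rasterize_mask(skel, spec)
        img = render_image(mask, skel, spec, rng)
        mid = (spec.background_mean + spec.root_intensity_mean) / 2
        np.testing.assert_array_equal((img[:, :, 0] > mid).astype(np.uint8), mask)

    def test_roots_brighter_than_background(self):
        sample = generate_sample(RootSceneSpec(**SMALL, seed=9))
        fg = sample.image[sample.mask.astype(bool)].mean()
        bg = sample.image[~sample.mask.astype(bool)].mean()
        assert fg > bg

    def test_distractors_change_image_but_not_mask(self):
        base = RootSceneSpec(**SMALL, seed=4, droplet_count=0, dust_count=0,
                             include_stem=False)
        noisy = replace(base, droplet_count=4, dust_count=30, include_stem=True)
        a, b = generate_sample(base), generate_sample(noisy)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert not np.array_equal(a.image, b.image)


class TestGenerateSample:
    def test_equal_specs_give_bit_identical_samples(self):
        spec = RootSceneSpec(**SMALL, seed=11)
        a, b = generate_sample(spec), generate_sample(spec)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_different_seeds_give_different_images(self):
        a = generate_sample(RootSceneSpec(**SMALL, seed=1))
        b = generate_sample(RootSceneSpec(**SMALL, seed=2))
        assert not np.array_equal(a.image, b.image)

    def test_invariants_hold_across_random_specs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            spec = RootSceneSpec(
                height_px=int(rng.integers(64, 160)),
                width_px=int(rng.integers(64, 160)),
                n_primary_roots=int(rng.integers(1, 3)),
                max_steps=int(rng.integers(15, 40)),
                branch_prob_per_step=float(rng.uniform(0, 0.08)),
                initial_thickness_px=float(rng.uniform(1.5, 4)),
                droplet_count=int(rng.integers(0, 3)),
                dust_count=int(rng.integers(0, 10)),
                droplet_radius_range_px=(3.0, 8.0),
                include_stem=bool(rng.random() < 0.5),
                seed=int(rng.integers(0, 10_000)),
            )
            try:
                s = generate_sample(spec)
            except GenerationError:
                continue  # degenerate draw rejected by the generator itself
            assert s.image.shape[:2] == s.mask.shape
            assert 0.0 < s.mask.mean() < 0.5
            assert s.image.min() >= 0.0 and s.image.max() <= 1.0
            for line in s.skeleton:
                assert (line.points >= 0).all()
                assert (line.points[:, 0] <= spec.height_px - 1).all()
                assert (line.points[:, 1] <= spec.width_px - 1).all()

    def test_default_scenes_are_foreground_sparse(self):
        for seed in range(5):
            s = generate_sample(RootSceneSpec(seed=seed))
            assert s.mask.mean() < 0.2


class TestGenerateDataset:
    def test_split_sizes_conserve_count(self, tmp_path):
        spec = RootSceneSpec(**SMALL)
        manifest = ir.generate_dataset(spec, 10, (0.7, 0.15, 0.15), tmp_path)
        counts = manifest["split"].value_counts()
        assert counts.sum() == 10
        assert counts["train"] == 7
        assert set(counts.index) <= {"train", "test", "validation"}

    def test_regeneration_is_reproducible(self, tmp_path):
        spec = RootSceneSpec(**SMALL, seed=21)
        a = ir.generate_dataset(spec, 6, (0.5, 0.25, 0.25), tmp_path / "a")
        b = ir.generate_dataset(spec, 6, (0.5, 0.25, 0.25), tmp_path / "b")
        assert list(a["split"]) == list(b["split"])

    def test_manifest_rows_round_trip(self, tmp_path):
        from iterroot.pipeline import read_image, read_mask
        spec = RootSceneSpec(**SMALL, seed=33)
        manifest = ir.generate_dataset(spec, 4, (0.5, 0.25, 0.25), tmp_path)
        for i, row in manifest.iterrows():
            sample = generate_sample(replace(spec, seed=spec.seed + i))
            img = read_image(row["image_path"])
            msk = read_mask(row["mask_path"])
            np.testing.assert_array_equal(msk, sample.mask)
            # 8-bit quantization on write
            assert np.abs(img - sample.image).max() <= 1 / 255 + 1e-9

    def test_bad_fractions_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="sum to 1"):
            ir.generate_dataset(RootSceneSpec(**SMALL), 4, (0.5, 0.2, 0.2),
                                tmp_path)
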