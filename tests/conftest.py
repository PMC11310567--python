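import dataclasses

import numpy as np
import pytest

from elaioscan import config, pipeline, seedsynth


def small_scene_params(**kw):
    """Compact scene used throughout the suite: fewer, same-sized seeds."""
    base = dict(image_width_px=450, image_height_px=450, n_seeds=12,
                noise_sigma=0.0, stripe_prob=0.7, rng_seed=0)
    base.update(kw)
    return seedsynth.SceneParams(**base)


@pytest.fixture(scope="session")
def clean_scene():
    """One noise-free scene with its exact truth."""
    params = small_scene_params(rng_seed=7)
    image, truth = seedsynth.generate_scene(params)
    return params, image, truth


@pytest.fixture(scope="session")
def crop_pool():
    """Preprocessed pool of ~100 labeled seed crops from noisy scenes.

    Shared by detector and self-training tests; built once per session.
    """
    cfg = config.PipelineConfig(
        n_scenes=2,
        scene=seedsynth.SceneParams(n_seeds=50, image_width_px=900,
                                    image_height_px=900, noise_sigma=4.0,
                                    stripe_prob=0.7),
        rng_seed=0,
    ).reseed()
    items, lines = pipeline.build_pool(cfg)
    return items


@pytest.fixture(scope="session")
def clean_crop_pool():
    """Noise-free, stripe-free crops (easy regime for the color model)."""
    cfg = config.PipelineConfig(
        n_scenes=1,
        scene=seedsynth.SceneParams(n_seeds=50, image_width_px=900,
                                    image_height_px=900, noise_sigma=0.0,
                                    stripe_prob=0.0),
        rng_seed=11,
    )
    cfg = dataclasses.replace(cfg, rng_seed=11).reseed()
    items, _ = pipeline.build_pool(cfg)
    return items


def random_mask(rng, h=24, w=24, p=0.4):
    m = rng.random((h, w)) < p
    if not m.any():
        m[h // 2, w // 2] = True
    return m
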