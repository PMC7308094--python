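import numpy as np
import pytest

import conemosaic as cm


@pytest.fixture(scope="session")
def flat_preset():
    """Spatially constant class fractions (20% true S, no M-only): the
    exchangeable-label condition under which the shuffled null is exact."""
    return cm.StrainPreset(
        "flat",
        cm.Logistic(0.2, 0.2, 0.0, 250.0),
        cm.Logistic(0.0, 0.0, 0.0, 150.0),
        cm.Logistic(0.7, 0.7, 0.0, 400.0),
        cm.Logistic(0.7, 0.7, 0.0, 400.0),
    )


@pytest.fixture(scope="session")
def small_disk_mosaic(flat_preset):
    """~2,300 cones on a 300 μm disk with a flat 10% true-S fraction."""
    disk = cm.Disk(0.0, 0.0, 300.0)
    pts = cm.generate_positions(
        cm.MosaicSpec(retina_radius_um=300.0, density_profile=8000.0, seed=31), disk
    )
    rng = np.random.default_rng(32)
    labels = rng.random(len(pts)) < 0.1
    return cm.MosaicSample(pts, labels, disk)


@pytest.fixture(scope="session")
def full_retina_mosaic():
    """Whole-retina pigmented mosaic at reduced density (shared, read-only)."""
    spec = cm.MosaicSpec(retina_radius_um=1800.0, density_profile=8000.0, seed=11)
    pts = cm.generate_positions(spec)
    return cm.assign_types(
        pts, cm.pigmented(), seed=12, region=cm.Disk(0.0, 0.0, 1800.0)
    )


@pytest.fixture(scope="session")
def rendered_field():
    """A 200 μm square field rendered noise-free with ~50 well-separated
    cones, plus its ground truth and frame."""
    side = 200.0
    sq = cm.Rect(0.0, 0.0, side, side)
    spec = cm.MosaicSpec(
        retina_radius_um=side, density_profile=50 / (side / 1000.0) ** 2,
        hard_core_um=10.0, seed=1,
    )
    pts = cm.generate_positions(spec, sq)
    mosaic = cm.assign_types(pts, cm.pigmented(), seed=2, region=sq)
    img, truth, frame = cm.render_image(
        mosaic, cm.RenderSpec(noise="none"), "m", region=sq
    )
    return img, truth, frame
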