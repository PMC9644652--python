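import numpy as np
import pytest

from betalat import pipeline, synthetic


@pytest.fixture(scope="session")
def anatomy():
    """Small toy head + grid shared across tests (32 sensors, 20-mm grid)."""
    return synthetic.make_toy_anatomy(n_chan=32, grid_spacing=20.0, seed=1)


@pytest.fixture(scope="session")
def rois():
    from betalat.laterality import default_rois

    return default_rois(synthetic.TOY_ROI_LABELS)


def source_voxel(grid, side="left", roi="IFG"):
    """A stable source site: the voxel nearest the ROI-label centroid."""
    labels = synthetic.TOY_ROI_LABELS[roi]
    label = labels[0][0] if side == "left" else labels[1][0]
    return pipeline._closest_voxel_in_label(grid, label)


def erd_epochs(head, grid, side="left", ratio=0.89, seed=0, n_trials=60,
               sfreq=480.0, noise_sd=5e-14, background_sd=5e-14, extra=()):
    """Synthetic subject with one lateralized beta-ERD source (plus extras)."""
    sources = [synthetic.SourceSpec(grid_index=source_voxel(grid, side), ratio=ratio)]
    sources += list(extra)
    cfg = synthetic.SimulationConfig(
        n_trials=n_trials, sfreq=sfreq, sources=tuple(sources),
        noise_sd=noise_sd, background_sd=background_sd, seed=seed)
    return synthetic.simulate_epochs(cfg, head, grid), cfg


def rng_seeds(base, n):
    return [int(base * 1000 + i) for i in range(n)]
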