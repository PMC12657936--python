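import numpy as np
import pytest

from tensiongrad import flim, synthgen as sg


@pytest.fixture(scope="session")
def cfg() -> sg.TcspcConfig:
    return sg.TcspcConfig()


@pytest.fixture(scope="session")
def irf(cfg) -> flim.IrfCurve:
    return sg.make_irf(cfg)


@pytest.fixture(scope="session")
def cross_scene() -> sg.SceneTruth:
    spec = sg.SceneSpec(shape="cross", baseline_tau=4.5, linear_slope=0.01,
                        edge_amplitude=0.2, seed=0)
    return sg.make_scene(spec)


def lifetime_from_truth(truth, cfg, seed, mean_photons=30, mask_threshold=20):
    """Simulate photons for a scene and run the standard estimation chain."""
    stack = sg.simulate_tcspc_image(truth, cfg, seed=seed, mean_photons=mean_photons)
    img = flim.lifetime_image(stack, sg.make_irf(cfg))
    return flim.mask_low_counts(img, mask_threshold)


def arrival_time_sd(tau_bar: float, cfg) -> float:
    """Per-photon arrival-time SD of the configured bi-exponential mixture.

    Shot-noise floor for any photon-weighted ROI mean: sd / sqrt(n_photons).
    """
    t1, t2 = cfg.tau_pair
    a1 = (t2 - tau_bar) / (t2 - t1) if t2 > t1 else 1.0
    second = 2.0 * (a1 * t1**2 + (1 - a1) * t2**2)
    return float(np.sqrt(second - tau_bar**2 + cfg.irf_sigma**2))
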