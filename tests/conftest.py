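import numpy as np
import pytest

from paws import Config, simulate_feature_cohort, simulate_withdrawal


@pytest.fixture(scope="session")
def config() -> Config:
    return Config()


@pytest.fixture(scope="session")
def hp_trial(config):
    """A deterministic heavy-pinprick trial with 4 programmed shakes."""
    return simulate_withdrawal(
        "hp", seed=7, config=config, n_shakes=4, shake_freq_hz=20.0,
        peak_height=16.0, guard_hold_s=0.5,
    )


@pytest.fixture(scope="session")
def cohort():
    """A 400-trial feature cohort from a known proportional-odds model."""
    beta = np.array([1.5, 1.0, 0.75, 0.5, 1.0, 0.75, 0.5])
    cuts = np.array([-2.0, 0.0, 2.0])
    table, latents = simulate_feature_cohort(
        n_strains=10, mice_per_strain=10, beta_star=beta,
        cutpoints_star=cuts, seed=42, trials_per_mouse=4,
    )
    return table, latents, beta, cuts


def gaussian_bump_trajectory(
    height=10.0, center=0.5, sigma=0.05, duration=1.0, fps=2000.0, x_const=3.0
):
    """A smooth single-arc withdrawal: Gaussian bump in y, constant x."""
    from paws import Trajectory

    n = int(duration * fps) + 1
    t = np.arange(n) / fps
    y = height * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    x = np.full(n, x_const)
    return Trajectory(times=t, x=x, y=y, fps=fps)
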