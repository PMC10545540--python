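import numpy as np
import pytest

import photoline as pl

RATE = 100.0


@pytest.fixture(scope="session")
def short_config():
    """3-minute session config used for fast integration tests."""
    return pl.GenConfig(duration=180.0)


@pytest.fixture(scope="session")
def vglut2_session(short_config):
    return pl.generate_session(pl.VGLUT2, short_config, seed=11)


@pytest.fixture(scope="session")
def vglut2_analysis(vglut2_session):
    session, _ = vglut2_session
    return pl.analyze_session(session)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def full_cohort():
    """10 recordings per subtype at the default 15-min study conditions,
    fully analyzed.  Shared by the validation and acceptance tests."""
    pairs = pl.generate_cohort(pl.DEFAULT_PROFILES, 10, base_seed=0)
    ca = pl.analyze_cohort([s for s, _ in pairs])
    truths = [t for _, t in pairs]
    return ca, truths


def flat_session(n_bins=6000, value=5.0, rate=100.0):
    """Constant-fluorescence binned session."""
    return pl.BinnedSession(
        bin_rate=rate,
        f470=np.full(n_bins, value),
        f405=np.full(n_bins, value / 2.0),
        velocity=np.zeros(n_bins),
        lick=np.zeros(n_bins),
    )


def kernel_trace(n_bins, peak_bins, amps, tau_rise=0.05, tau_decay=0.4,
                 rate=100.0):
    """Sum of unit-peak transient kernels with peaks at given bins."""
    from photoline._filters import diff_of_exp_kernel, kernel_peak_time
    k = diff_of_exp_kernel(tau_rise, tau_decay, rate)
    pk = int(round(kernel_peak_time(tau_rise, tau_decay) * rate))
    out = np.zeros(n_bins)
    for b, a in zip(np.atleast_1d(peak_bins), np.atleast_1d(amps)):
        start = int(b) - pk
        seg = k[max(0, -start): max(0, min(k.size, n_bins - start))]
        out[max(0, start): max(0, start) + seg.size] += a * seg
    return out
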