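"""Shared fixtures: toy runs built from first principles and one
full-scale synthetic cohort reused across integration tests."""

import numpy as np
import pytest

from diaflav import chemcore, cli, synthgen
from diaflav.dbio import MSRun, Spectrum


def make_run(spikes, n_scans=60, dt=0.005, noise=0.0, sample_id="toy", seed=0):
    """Hand-built two-channel run: ``spikes`` is a list of
    (mz, rt, sigma, height, level) tuples; no m/z jitter, optional flat
    noise peaks."""
    rng = np.random.default_rng(seed)
    spectra = []
    for i in range(n_scans):
        for level in (1, 2):
            t = i * dt + (0.5 * dt if level == 2 else 0.0)
            mzs, ints = [], []
            for mz, rt, sigma, height, lv in spikes:
                if lv != level:
                    continue
                amp = height * np.exp(-0.5 * ((t - rt) / sigma) ** 2)
                if amp >= 1.0:
                    mzs.append(mz)
                    ints.append(amp)
            if noise > 0:
                mzs.extend(rng.uniform(50, 1000, 3))
                ints.extend(rng.uniform(0.5, 1.0, 3) * noise)
            order = np.argsort(mzs)
            spectra.append(
                Spectrum(2 * i + (level - 1), t, level, "negative",
                         np.array(mzs, dtype=float)[order],
                         np.array(ints, dtype=float)[order])
            )
    return MSRun(sample_id=sample_id, spectra=spectra, run_length=n_scans * dt)


@pytest.fixture(scope="session")
def fragment_db():
    return chemcore.build_fragment_db()


#: cohort study conditions: 20 spikes, 3 samples, 10 Hz per channel
COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort():
    runs, truth = synthgen.make_cohort(n_spikes=20, n_samples=3, seed=COHORT_SEED)
    return runs, truth


@pytest.fixture(scope="session")
def cohort_result(cohort, fragment_db):
    runs, truth = cohort
    result = cli.run_pipeline(
        runs, synthgen.cohort_compound_db(truth), fragment_db, figures=False
    )
    return runs, truth, result
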