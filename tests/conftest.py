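"""Shared fixtures: phantoms and extractions reused across the suite.

Session scope keeps the expensive factorizations to a handful per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import idifpet as ip
from idifpet.kinetics import feng_aif, fine_grid, frame_average


#: Fast-but-accurate factorization settings used throughout the suite: the
#: data-driven start dominates in practice, so a few extra Latin-hypercube
#: starts suffice at desk scale.
FAST_MBMF = dict(n_starts=4, max_nfev=400, seed=0)


@pytest.fixture(scope="session")
def noisefree_phantom():
    truth = ip.default_truth("HAB-like", seed=1, noise_cv=0.0)
    image, label_map, truth = ip.simulate_phantom(truth)
    return image, label_map, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    truth = ip.default_truth("HAB-like", seed=7, noise_cv=0.05)
    image, label_map, truth = ip.simulate_phantom(truth)
    return image, label_map, truth


@pytest.fixture(scope="session")
def noisy_extraction(noisy_phantom):
    image, label_map, _ = noisy_phantom
    return ip.extract_idif(image, label_map, ip.MBMFConfig(**FAST_MBMF))


@pytest.fixture(scope="session")
def true_aif_frames(noisy_phantom):
    """Frame-averaged true whole-blood input of the noisy phantom."""
    _, _, truth = noisy_phantom
    grid = fine_grid(truth.schedule.ends_s[-1] / 60.0)
    return frame_average(grid, feng_aif(truth.feng, grid), truth.schedule)


@pytest.fixture(scope="session")
def recovery_runs(noisy_phantom, noisy_extraction):
    """Three noisy phantom subjects with full IDIF extractions, the
    desk-scale analogue of a small validation cohort."""
    runs = [(noisy_phantom[0], noisy_phantom[1], noisy_phantom[2],
             noisy_extraction)]
    for seed in (11, 23):
        truth = ip.default_truth("HAB-like", seed=seed, noise_cv=0.05)
        image, label_map, truth = ip.simulate_phantom(truth)
        ext = ip.extract_idif(image, label_map, ip.MBMFConfig(**FAST_MBMF))
        runs.append((image, label_map, truth, ext))
    return runs


@pytest.fixture(scope="session")
def noisefree_voxel_matrix(noisefree_phantom):
    image, label_map, _ = noisefree_phantom
    mask = ip.segment_carotid(image, label_map)
    return ip.build_matrix(image, mask), mask


@pytest.fixture(scope="session")
def truth_params(noisefree_phantom):
    _, _, truth = noisefree_phantom
    return ip.ParameterSet(truth.feng, truth.region_kinetics["background"])
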