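"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from entpet import features, workflow
from entpet.geometry import DetectorGeometry
from entpet.simulator import SourceConfig, generate_decays


@pytest.fixture(scope="session")
def geometry():
    return DetectorGeometry()


@pytest.fixture(scope="session")
def source():
    return SourceConfig()


@pytest.fixture(scope="session")
def truth_run(geometry, source):
    """Moderate unstaged run keeping ground-truth angles and transport
    results for distribution-level checks."""
    hits, info = generate_decays(geometry, source, 300_000, mode="entangled",
                                 rng_seed=101, only_complete_groups=False,
                                 _return_truth=True)
    return hits, info


@pytest.fixture(scope="session")
def small_dataset(geometry, source):
    """~8000 labeled samples from the default end-to-end pipeline."""
    X, y, info = workflow.build_dataset(
        8000, geometry=geometry, source=source,
        seeds=workflow.DatasetSeeds(5), chunk_decays=7_000_000)
    return X, y, info


@pytest.fixture(scope="session")
def unblurred_true_samples(geometry, source):
    """True-pairing samples with blurring disabled (positions still binned)
    plus a matching un-binned variant, for angle-consistency checks."""
    from entpet.simulator import EnergyModel

    hits, _ = generate_decays(geometry, source, 3_000_000, rng_seed=3,
                              only_complete_groups=True,
                              true_sum_range=(400.0, 622.0))
    em = EnergyModel(reference_resolution=0.0)
    binned = workflow.process_hits(hits, geometry, energy_model=em,
                                   fraction_random=0.0)
    Xb, yb = features.assemble_matrix(binned)

    class _ExactGeometry(DetectorGeometry):
        def voxelize(self, points):  # identity: keep exact positions
            pts = np.asarray(points, dtype=float)
            return pts.copy()

    exact = workflow.process_hits(hits, _ExactGeometry(), energy_model=em,
                                  fraction_random=0.0)
    Xe, ye = features.assemble_matrix(exact)
    return (Xb, yb), (Xe, ye)
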