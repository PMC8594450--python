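"""Shared fixtures: calibrated study configs and small simulated datasets.

Session-scoped fixtures hold the expensive artifacts (ensembles, trained
networks) shared across acceptance tests; unit tests use tiny local data.
"""

from __future__ import annotations

import pytest

from iqtask._rng import stream_rng
from iqtask.config import (
    MC_CLB_AMPLITUDE,
    RAYLEIGH_CLB_AMPLITUDE,
    RAYLEIGH_SIGNAL_AMPLITUDE,
)
from iqtask.imaging import ImagingEnsemble, build_task_ensembles
from iqtask.observers import central_crop
from iqtask.phantoms import CLBParams, MCClusterSpec, RayleighSignalSpec


def crop_ensemble(ens: ImagingEnsemble, size: int) -> ImagingEnsemble:
    """Centre-crop every image of an ensemble (drops the clean stack)."""
    return ImagingEnsemble(
        central_crop(ens.images, size), ens.labels, ens.resolution_class,
        dict(ens.generation_spec),
    )


@pytest.fixture(scope="session")
def ray_clb_small() -> CLBParams:
    """Calibrated texture on a reduced 64x64 field for training studies."""
    return CLBParams(field_size=64, amplitude=RAYLEIGH_CLB_AMPLITUDE)


@pytest.fixture(scope="session")
def ray_signal() -> RayleighSignalSpec:
    return RayleighSignalSpec(signal_length=8, amplitude=RAYLEIGH_SIGNAL_AMPLITUDE)


@pytest.fixture(scope="session")
def mc_spec_tight() -> MCClusterSpec:
    """MC clusters for the scaled observer studies: confined near the canvas
    centre so a 32x32 observer crop of a 64x64 field always contains the
    whole cluster, and with 6-10 px calcifications so the signal survives the
    blur/downsample chain at this scale."""
    return MCClusterSpec(
        cluster_radius=12.0, mc_size_range=(6, 10), n_mcs_range=(6, 12), centroid_spread=4.0
    )


@pytest.fixture(scope="session")
def rayleigh_sets(ray_clb_small, ray_signal):
    """Field-64 Rayleigh train/val/test HR+LR ensembles (L=8)."""
    out = {}
    for name, n, idx in (("train", 150, 0), ("val", 40, 1), ("test", 300, 2)):
        out[name] = build_task_ensembles(
            "rayleigh", n, stream_rng(101, "clb", idx),
            clb=ray_clb_small, signal_spec=ray_signal, signal_lengths=8,
            keep_clean=True,
        )
    return out


@pytest.fixture(scope="session")
def mc_sets(mc_spec_tight):
    """Field-64 MC-task train/val/test HR+LR ensembles (tight clusters)."""
    clb = CLBParams(field_size=64, amplitude=MC_CLB_AMPLITUDE)
    out = {}
    for name, n, idx in (("train", 300, 0), ("val", 50, 1), ("test", 300, 2)):
        out[name] = build_task_ensembles(
            "mc", n, stream_rng(202, "clb", idx),
            clb=clb, mc_spec=mc_spec_tight, keep_clean=True,
        )
    return out


@pytest.fixture(scope="session")
def mc_srcnn(mc_sets):
    """Default-architecture (3-layer) SRCNN trained on the MC task at
    reduced width/scale; shared by the SR-fidelity and capacity tests."""
    from iqtask.nn import SRCNN, SRNetworkSpec, TrainingConfig, train_sr

    model = SRCNN(SRNetworkSpec(n_layers=3, hidden_channels=8), stream_rng(202, "init"), zero_last=True)
    hr_tr, lr_tr = mc_sets["train"]
    hr_va, lr_va = mc_sets["val"]
    train_sr(model, lr_tr, hr_tr,
             TrainingConfig(learning_rate=1e-3, max_epochs=15, seed=202),
             lr_va, hr_va)
    return model


@pytest.fixture(scope="session")
def ray_srcnn(rayleigh_sets):
    """3-layer SRCNN trained on the field-64 Rayleigh task."""
    from iqtask.nn import SRCNN, SRNetworkSpec, TrainingConfig, train_sr

    model = SRCNN(SRNetworkSpec(n_layers=3, hidden_channels=8), stream_rng(101, "init"), zero_last=True)
    hr_tr, lr_tr = rayleigh_sets["train"]
    hr_va, lr_va = rayleigh_sets["val"]
    train_sr(model, lr_tr, hr_tr,
             TrainingConfig(learning_rate=1e-3, max_epochs=15, seed=101),
             lr_va, hr_va)
    return model
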