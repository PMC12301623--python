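"""Shared fixtures: small simulated pullbacks reused across test modules.

Problem sizes are deliberately reduced (short pullbacks, 32-64 A-lines per
frame) so the full forward/inverse chain stays fast; tests that depend on
fine azimuthal sampling of the transmission offset use the full 512 A-lines
per frame on a short pullback instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from catheter_psoct.acquisition import AcquisitionConfig, CatheterModel, simulate_pullback
from catheter_psoct.phantom import LayerSpec, PhantomConfig, Trajectory, build_dbs_phantom
from catheter_psoct.reconstruction import ReconstructionConfig, reconstruct_pullback


def ang_diff_deg(a, b, period=180.0):
    """Signed circular difference in (-period/2, period/2]."""
    d = (np.asarray(a) - np.asarray(b)) % period
    return np.where(d > period / 2, d - period, d)


def short_phantom_config(length_mm=6.0):
    """GM / circumferential-WM / GM stack over a short trajectory."""
    return PhantomConfig(
        length_mm=length_mm,
        layers=(
            LayerSpec("cortex_gm", 0.0, 1.0),
            LayerSpec("wm", 1.0, length_mm - 1.0),
            LayerSpec("deep_gm", length_mm - 1.0, length_mm),
        ),
        inclusions=(),
    )


NOISE_FREE_ACQ = dict(
    alines_per_frame=32, depth_range_mm=0.8, speckle=False, detector_noise_sigma=0.0
)
#: Noise-free runs switch the speckle filter off (it exists to average speckle)
#: and need no azimuthal offset smoothing.
NOISE_FREE_RECON = dict(axial_sigma_px=0.0, lateral_sigma_pairs=0.0,
                        offset_smoothing_window_pairs=1)


def pair_truth(raw):
    """Ground truth at A-line-pair resolution (even A-line of each pair)."""
    return raw.true_retardance[:, 0::2, :], raw.true_orientation[:, 0::2, :]


def tissue_mask(raw, lb):
    """Pixels valid for truth comparison: masked, in tissue, truth defined."""
    _, tr_ori = pair_truth(raw)
    m = lb.mask & np.isfinite(tr_ori)
    m[: raw.sheath_band[1]] = False
    return m


@pytest.fixture(scope="session")
def short_phantom():
    return build_dbs_phantom(short_phantom_config(), seed=0)


@pytest.fixture(scope="session")
def oracle_run(short_phantom):
    """Noise-free, transmission-identity pullback and its reconstruction."""
    traj = Trajectory(length_mm=6.0)
    acq = AcquisitionConfig(**NOISE_FREE_ACQ)
    cat = CatheterModel(offset_amplitude_deg=0.0, drift_amplitude_deg=0.0)
    raw = simulate_pullback(short_phantom, traj, cat, acq, seed=11)
    cfg = ReconstructionConfig(**NOISE_FREE_RECON, compensation_enabled=False)
    return raw, reconstruct_pullback(raw, cfg)


@pytest.fixture(scope="session")
def transmission_run(short_phantom):
    """Noise-free pullback with the default azimuth-varying transmission."""
    traj = Trajectory(length_mm=6.0)
    acq = AcquisitionConfig(**NOISE_FREE_ACQ)
    raw = simulate_pullback(short_phantom, traj, CatheterModel(), acq, seed=12)
    cfg = ReconstructionConfig(**NOISE_FREE_RECON)
    return raw, reconstruct_pullback(raw, cfg)


@pytest.fixture(scope="session")
def tract_run():
    """Noise-free pullback through a lab-fixed horizontal-fiber tract."""
    cfgp = PhantomConfig(
        length_mm=2.0,
        layers=(LayerSpec("tract", 0.0, 2.0),),
        inclusions=(),
    )
    ph = build_dbs_phantom(cfgp, seed=0)
    traj = Trajectory(length_mm=2.0)
    acq = AcquisitionConfig(
        alines_per_frame=64, depth_range_mm=0.8, speckle=False, detector_noise_sigma=0.0
    )
    cat = CatheterModel(offset_amplitude_deg=0.0, drift_amplitude_deg=0.0)
    raw = simulate_pullback(ph, traj, cat, acq, seed=13)
    cfg = ReconstructionConfig(**NOISE_FREE_RECON, compensation_enabled=False)
    return raw, reconstruct_pullback(raw, cfg)
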