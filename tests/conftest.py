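"""Shared fixtures: reduced-size synthetic acquisitions with known ground truth.

The recovery fixtures run the full chain (simulate -> clutter filter ->
power Doppler -> detrend -> GLM -> descriptors) on a 16 x 16 plane sampled
at 250 Hz with 100-pixel-blocks (2.5 Hz power-Doppler rate), a 100-pixel
responding patch and the standard 20/20/20 x 10 stimulation protocol.
These dimensions keep the per-trace sample count (block x pixels x trials)
close to the full-scale acquisition, which is what the descriptor
signal-to-noise depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import fuslink as fl


def disk_mask(nz: int, nx: int, n_px: int, center: tuple[int, int] | None = None) -> np.ndarray:
    """Smallest centred disk containing at least n_px pixels."""
    cz, cx = center if center is not None else (nz // 2, nx // 2)
    zz, xx = np.ogrid[:nz, :nx]
    d2 = (zz - cz) ** 2 + (xx - cx) ** 2
    for r2 in range(0, nz * nx):
        m = d2 <= r2
        if m.sum() >= n_px:
            return m
    raise ValueError("mask does not fit")


@dataclass
class RecoveryResult:
    seed: int
    truth: fl.GroundTruth
    descriptors: fl.DescriptorSet
    dice: float
    movie: fl.PowerDopplerMovie
    amap: fl.ActivationMap


RECOVERY_PROTOCOL = fl.make_stimulus_protocol(20, 20, 20, 10)
RECOVERY_N_ACTIVE = 100
RECOVERY_RATE_HZ = 250.0
RECOVERY_BLOCK = 100  # -> 2.5 Hz power-Doppler rate
RECOVERY_N_REMOVE = 15


def run_recovery(seed: int, amplitude_pct: float = 15.0, rise_tau_s: float = 2.0,
                 n_active: int = RECOVERY_N_ACTIVE, repetitions: int | None = None) -> RecoveryResult:
    """One full pipeline pass on a reduced synthetic acquisition."""
    protocol = (RECOVERY_PROTOCOL if repetitions is None
                else fl.make_stimulus_protocol(20, 20, 20, repetitions))
    active = disk_mask(16, 16, n_active)
    cfg = fl.SimulationConfig(
        nz=16, nx=16, ultrafast_rate_hz=RECOVERY_RATE_HZ,
        duration_s=protocol.total_duration_s, tissue_rank=8,
        active_mask=active, response_amplitude_pct=amplitude_pct,
        rise_tau_s=rise_tau_s, seed=seed, pd_block_size=RECOVERY_BLOCK,
    )
    stack, truth = fl.simulate_ultrafast_stack(cfg, protocol)
    filtered = fl.svd_clutter_filter(stack, RECOVERY_N_REMOVE)
    movie = fl.detrend(fl.power_doppler(filtered, RECOVERY_BLOCK), order=1)
    design = fl.build_design_matrix(protocol, movie.frame_rate_hz, n_frames=movie.n_frames)
    amap = fl.glm_activation(movie, design, alpha_family=0.05)
    ds = fl.compute_descriptors(movie, amap, None, protocol)
    inter = int((amap.active & truth.active_mask).sum())
    denom = int(amap.active.sum()) + int(truth.active_mask.sum())
    dice = 2 * inter / denom if denom else 0.0
    return RecoveryResult(seed, truth, ds, dice, movie, amap)


@pytest.fixture(scope="session")
def recovery_runs() -> list[RecoveryResult]:
    """Twenty seeded pipeline passes at the default synthetic conditions."""
    return [run_recovery(seed) for seed in range(20)]
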