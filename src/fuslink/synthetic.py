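"""Synthetic acquisition generator for the functional-ultrasound pipeline.

Every input the analysis chain consumes can be generated here with known
ground truth: ultrafast complex frame stacks (low-rank tissue clutter +
vascular blood signal whose power follows a stimulus-locked cerebral blood
volume response + white complex noise), immunofluorescence section images
with per-region staining levels, and per-animal cohort tables in which the
hemodynamic descriptors are linearly linked to regional myelin content.

The generative signal model is the standard three-subspace decomposition
that motivates SVD clutter filtering in ultrafast Doppler: a high-energy,
spatiotemporally coherent (low-rank) tissue component, a spatially sparse
blood component with rapidly decorrelating phase, and isotropic complex
Gaussian noise.  Blood is modelled as circular complex Gaussian with
time-varying variance — power Doppler only ever sees ``|s|^2``, so Doppler
frequency content is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "StimulusProtocol",
    "SimulationConfig",
    "GroundTruth",
    "HistologySpec",
    "CohortSpec",
    "make_stimulus_protocol",
    "simulate_ultrafast_stack",
    "generate_histology_sections",
    "generate_cohort",
    "cbv_response_curve",
    "default_region_masks",
    "HISTOLOGY_REGIONS",
    "DESCRIPTOR_COLUMNS",
]

DESCRIPTOR_COLUMNS = ("n_active_pixels", "delta_cbv_pct", "rise_time_s")

#: tissue regions quantified on a section, plus an extra-cerebral background zone
HISTOLOGY_REGIONS = (
    "cortex",
    "corpus_callosum",
    "hippocampus",
    "thalamus",
    "internal_capsule",
)


@dataclass(frozen=True)
class StimulusProtocol:
    """Block-design whisker-stimulation timeline.

    A baseline period is followed by ``repetitions`` cycles of
    (stimulation, rest).  The default experiment (20 s baseline, 20 s
    stimulation, 20 s rest, 10 repetitions) lasts 420 s in total.
    """

    baseline_s: float
    stim_s: float
    rest_s: float
    repetitions: int
    stim_freq_hz: float = 4.0  # whisker deflection rate; metadata only

    def __post_init__(self) -> None:
        for name in ("baseline_s", "stim_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.repetitions < 1:
            raise ValueError(f"repetitions must be >= 1, got {self.repetitions}")

    @property
    def total_duration_s(self) -> float:
        return self.baseline_s + self.repetitions * (self.stim_s + self.rest_s)

    @property
    def cycle_s(self) -> float:
        return self.stim_s + self.rest_s

    def onsets_s(self) -> np.ndarray:
        """Stimulation onset times, one per repetition."""
        return self.baseline_s + np.arange(self.repetitions) * self.cycle_s

    def epochs_s(self) -> list[tuple[float, float]]:
        """Ordered (on, off) stimulation intervals."""
        return [(float(t), float(t) + self.stim_s) for t in self.onsets_s()]

    def boxcar(self, times_s: np.ndarray) -> np.ndarray:
        """Sample the stimulation indicator at the given times (on: on <= t < off)."""
        t = np.asarray(times_s, dtype=float)
        out = np.zeros_like(t)
        for on, off in self.epochs_s():
            out[(t >= on) & (t < off)] = 1.0
        return out


def make_stimulus_protocol(
    baseline_s: float, stim_s: float, rest_s: float, repetitions: int, stim_freq_hz: float = 4.0
) -> StimulusProtocol:
    """Build a validated block-design protocol.

    ``make_stimulus_protocol(20, 20, 20, 10)`` reproduces the 420-s
    acquisition used throughout: 20 s baseline then ten 20 s-on / 20 s-off
    cycles.
    """
    return StimulusProtocol(baseline_s, stim_s, rest_s, int(repetitions), stim_freq_hz)


@dataclass
class SimulationConfig:
    """Parameters of one synthetic ultrafast acquisition.

    The defaults describe the emulated acquisition: a 64 x 64 pixel coronal
    plane sampled at 500 Hz (11 tilted plane waves compounded from a
    5,500 Hz pulse-repetition frequency), a plateau CBV increase of 15 % in
    the active region with an exponential rise constant of 2 s, and tissue
    clutter carrying 100x the blood energy.
    """

    nz: int = 64
    nx: int = 64
    ultrafast_rate_hz: float = 500.0
    duration_s: float = 420.0
    tissue_rank: int = 8
    tissue_to_blood_energy_ratio: float = 100.0
    vessel_mask: np.ndarray | None = None
    active_mask: np.ndarray | None = None
    response_amplitude_pct: float = 15.0
    rise_tau_s: float = 2.0
    decay_tau_s: float = 3.0
    onset_delay_s: float = 0.0
    noise_sigma: float = 0.1
    seed: int = 0
    pd_block_size: int | None = None  # ultrafast frames per ground-truth CBV sample
    pixel_size_mm: tuple[float, float] = (0.1, 0.1)

    def __post_init__(self) -> None:
        if self.nz < 1 or self.nx < 1:
            raise ValueError("grid dimensions must be positive")
        if self.ultrafast_rate_hz <= 0:
            raise ValueError("ultrafast_rate_hz must be > 0")
        if self.tissue_to_blood_energy_ratio <= 1:
            raise ValueError("tissue_to_blood_energy_ratio must exceed 1")
        if self.response_amplitude_pct < 0:
            raise ValueError("response_amplitude_pct must be >= 0")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("time constants must be > 0")
        if self.vessel_mask is None:
            self.vessel_mask, default_active = _default_masks(self.nz, self.nx)
            if self.active_mask is None:
                self.active_mask = default_active
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        if self.active_mask is None:
            self.active_mask = self.vessel_mask.copy()
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if self.vessel_mask.shape != (self.nz, self.nx) or self.active_mask.shape != (self.nz, self.nx):
            raise ValueError("masks must have shape (nz, nx)")
        if np.any(self.active_mask & ~self.vessel_mask):
            raise ValueError("active_mask must be a subset of vessel_mask")


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover from one synthetic acquisition."""

    active_mask: np.ndarray
    response_amplitude_pct: float
    theoretical_rise_time_s: float  # rise_tau * ln 9 for the exponential-rise model
    cbv_curve: np.ndarray  # per power-Doppler frame, in % of baseline
    cbv_rate_hz: float


def _default_masks(nz: int, nx: int) -> tuple[np.ndarray, np.ndarray]:
    """A fully perfused plane with a compact responding patch.

    Every pixel of the imaged plane carries blood signal (in vivo, all
    brain tissue is capillarised at the fUS voxel scale); only the patch
    responds to stimulation.
    """
    vessel = np.ones((nz, nx), dtype=bool)
    cz, cx = nz // 3, nx // 2
    zz, xx = np.ogrid[:nz, :nx]
    active = (zz - cz) ** 2 + (xx - cx) ** 2 <= (min(nz, nx) // 8) ** 2
    return vessel, active


def cbv_response_curve(times_s: np.ndarray, protocol: StimulusProtocol, amplitude_pct: float,
                       rise_tau_s: float, decay_tau_s: float, onset_delay_s: float = 0.0) -> np.ndarray:
    """Stimulus-locked ΔCBV(t) in percent of baseline.

    During each stimulation epoch the response rises exponentially to the
    plateau ``amplitude_pct`` (after an optional onset delay); at stimulus
    offset it decays exponentially from its end-of-epoch value.  Outside
    the first baseline the decay tail is truncated at the next onset.
    """
    t = np.asarray(times_s, dtype=float)
    delta = np.zeros_like(t)
    epochs = protocol.epochs_s()
    for k, (on, off) in enumerate(epochs):
        t_rise_start = on + onset_delay_s
        rising = (t >= t_rise_start) & (t < off)
        delta[rising] = amplitude_pct * (1.0 - np.exp(-(t[rising] - t_rise_start) / rise_tau_s))
        end_val = amplitude_pct * (1.0 - math.exp(-max(off - t_rise_start, 0.0) / rise_tau_s))
        next_on = epochs[k + 1][0] if k + 1 < len(epochs) else np.inf
        decaying = (t >= off) & (t < next_on)
        delta[decaying] = end_val * np.exp(-(t[decaying] - off) / decay_tau_s)
    return delta


def simulate_ultrafast_stack(config: SimulationConfig, protocol: StimulusProtocol):
    """Generate one beamformed complex ultrafast stack plus its ground truth.

    Returns ``(stack, truth)`` where ``stack`` is an
    :class:`~fuslink.doppler.UltrafastStack` whose frames are

    ``tissue + blood + noise``

    - tissue: sum of ``tissue_rank`` rank-1 (spatial map x slow temporal
      trace) components, energy-scaled to ``tissue_to_blood_energy_ratio``
      times the expected blood energy;
    - blood: zero-mean circular complex Gaussian on ``vessel_mask`` whose
      instantaneous power is ``baseline * (1 + Δ(t)/100)``, with Δ(t) the
      exponential rise/decay response on ``active_mask`` only;
    - noise: i.i.d. complex Gaussian, std ``noise_sigma`` per component pair.

    Deterministic for a fixed ``config.seed``.
    """
    from .doppler import UltrafastStack  # local import to avoid a cycle

    if abs(config.duration_s - protocol.total_duration_s) > 1e-9:
        raise ValueError(
            f"config.duration_s ({config.duration_s}) must match protocol total "
            f"duration ({protocol.total_duration_s})"
        )
    rng = np.random.default_rng(config.seed)
    nz, nx = config.nz, config.nx
    nt = int(round(config.duration_s * config.ultrafast_rate_hz))
    t = np.arange(nt) / config.ultrafast_rate_hz

    delta_t = cbv_response_curve(t, protocol, config.response_amplitude_pct,
                                 config.rise_tau_s, config.decay_tau_s, config.onset_delay_s)

    # --- blood + noise ----------------------------------------------------
    # Both are independent circular complex Gaussians, so they are drawn as
    # one sample whose per-pixel, per-time variance is the sum
    # blood_power(t) + noise_sigma^2.  Blood baseline power is 1 in every
    # vessel pixel; active pixels are modulated by (1 + delta(t)/100).
    vessel = config.vessel_mask
    active = config.active_mask
    baseline_power = 1.0
    var = np.full((nz * nx, nt), config.noise_sigma ** 2, dtype=np.float32)
    var[vessel.ravel(), :] += baseline_power
    var[active.ravel(), :] += baseline_power * (delta_t / 100.0).astype(np.float32)
    expected_blood_energy = baseline_power * (
        float(vessel.sum()) * nt + float(active.sum()) * float(delta_t.sum()) / 100.0
    )
    re = rng.standard_normal((nz * nx, nt), dtype=np.float32)
    im = rng.standard_normal((nz * nx, nt), dtype=np.float32)
    amp = np.sqrt(var / 2.0)
    frames = (amp * re).astype(np.float32) + 1j * (amp * im)
    frames = frames.astype(np.complex64)
    del re, im, amp, var

    # --- tissue: rank-limited, spatially smooth, slowly modulated ---------
    tissue = np.zeros((nz * nx, nt), dtype=np.complex64)
    for _ in range(config.tissue_rank):
        spat = rng.standard_normal((nz, nx)) + 1j * rng.standard_normal((nz, nx))
        spat = gaussian_filter(spat.real, sigma=max(nz, nx) / 12) + 1j * gaussian_filter(
            spat.imag, sigma=max(nz, nx) / 12
        )
        f = rng.uniform(0.02, 0.3)  # Hz, slow physiological drift band
        phase = rng.uniform(0, 2 * np.pi)
        temporal = (1.0 + 0.3 * np.sin(2 * np.pi * f * t + phase)) * np.exp(
            1j * rng.uniform(0, 2 * np.pi)
        )
        tissue += np.outer(spat.ravel().astype(np.complex64), temporal.astype(np.complex64))
    tissue_energy = float(np.vdot(tissue, tissue).real)
    if tissue_energy > 0:
        tissue *= np.float32(
            math.sqrt(config.tissue_to_blood_energy_ratio * expected_blood_energy / tissue_energy)
        )

    frames += tissue
    del tissue
    frames = frames.reshape(nz, nx, nt)

    block = config.pd_block_size or max(1, int(round(config.ultrafast_rate_hz / 2.5)))
    n_pd = nt // block
    cbv_curve = delta_t[: n_pd * block].reshape(n_pd, block).mean(axis=1)

    stack = UltrafastStack(frames=frames, ultrafast_rate_hz=config.ultrafast_rate_hz,
                           pixel_size_mm=config.pixel_size_mm)
    truth = GroundTruth(
        active_mask=active.copy(),
        response_amplitude_pct=config.response_amplitude_pct,
        theoretical_rise_time_s=config.rise_tau_s * math.log(9.0),
        cbv_curve=cbv_curve,
        cbv_rate_hz=config.ultrafast_rate_hz / block,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# histology sections
# ---------------------------------------------------------------------------

@dataclass
class HistologySpec:
    """Parameters of a batch of synthetic myelin-stained sections.

    ``region_intensity`` maps each tissue region (and ``"background"``) to
    its mean 8-bit gray level; pixels are drawn Normal(mean, sd), clipped
    to [0, 255] and quantised.  One labelled mask image is shared by all
    sections of an animal.
    """

    region_intensity: dict[str, float]
    intensity_noise_sd: float = 5.0
    sections_per_animal: int = 2
    shape: tuple[int, int] = (128, 128)
    region_masks: np.ndarray | None = None  # labelled image; 0 = unassigned
    region_labels: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_noise_sd < 0:
            raise ValueError("intensity_noise_sd must be >= 0")
        if self.sections_per_animal < 1:
            raise ValueError("sections_per_animal must be >= 1")
        for region, level in self.region_intensity.items():
            if not 0 <= level <= 255:
                raise ValueError(f"intensity for {region!r} outside [0, 255]: {level}")
        if self.region_masks is None:
            self.region_masks, self.region_labels = default_region_masks(self.shape)
        if self.region_labels is None:
            raise ValueError("region_labels required when region_masks is given")
        missing = set(self.region_intensity) - set(self.region_labels)
        if missing:
            raise ValueError(f"intensities given for unknown regions: {sorted(missing)}")


def default_region_masks(shape: tuple[int, int] = (128, 128)) -> tuple[np.ndarray, dict[str, int]]:
    """A simple labelled coronal-section layout.

    Horizontal bands stand in for cortex, corpus callosum, hippocampus,
    thalamus and internal capsule; a strip along the top edge, disjoint
    from all tissue, is the extra-cerebral background zone used for
    background subtraction.
    """
    h, w = shape
    labels = {name: i + 1 for i, name in enumerate(HISTOLOGY_REGIONS)}
    labels["background"] = len(HISTOLOGY_REGIONS) + 1
    img = np.zeros(shape, dtype=np.uint8)
    img[: h // 8, :] = labels["background"]
    bands = np.linspace(h // 6, h - h // 12, len(HISTOLOGY_REGIONS) + 1).astype(int)
    for i, name in enumerate(HISTOLOGY_REGIONS):
        img[bands[i]: bands[i + 1], w // 8: w - w // 8] = labels[name]
    return img, labels


def generate_histology_sections(spec: HistologySpec):
    """Generate ``sections_per_animal`` 8-bit grayscale sections.

    Returns a list of ``(image, region_masks, region_labels)`` tuples.
    Pixel values in each labelled region are Normal(region mean, sd),
    clipped to [0, 255], rounded to integers.  Unlabelled pixels are 0.
    Deterministic under a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    masks = spec.region_masks
    labels = spec.region_labels
    out = []
    for _ in range(spec.sections_per_animal):
        img = np.zeros(spec.shape, dtype=float)
        for region, mean in spec.region_intensity.items():
            sel = masks == labels[region]
            img[sel] = mean + spec.intensity_noise_sd * rng.standard_normal(int(sel.sum()))
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        out.append((img, masks.copy(), dict(labels)))
    return out


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    label: str
    n_animals: int
    myelin_mean: float  # anchor-region myelin level, mean gray units
    myelin_sd: float

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("each group needs at least 2 animals")
        if self.myelin_sd < 0:
            raise ValueError("myelin_sd must be >= 0")


@dataclass
class CohortSpec:
    """Generative model of a cohort with a known descriptor→myelin link.

    For each region, myelin is ``intercept + β·descriptors + ε`` with
    ``ε ~ Normal(0, residual_sd)``.  The first region in
    ``link_coefficients`` is the *anchor*: each animal's anchor myelin is
    drawn from its group distribution and the anchor link is inverted to
    produce the descriptors (the descriptor with the largest |β| is solved
    for; the others are drawn from the cohort-level descriptor
    distributions).  Remaining regions are generated forward from the
    shared descriptors.  Default coefficients carry the negative rise-time
    effect reported for demyelination: β_rise = −1.57 (S1BF, the anchor),
    −1.38 (thalamus), −2.26 (internal capsule).
    """

    groups: list[GroupSpec]
    # region -> (intercept, beta_pixels, beta_dcbv, beta_rise)
    link_coefficients: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "s1bf": (120.0, 0.0, 0.0, -1.57),
            "thalamus": (110.0, 0.0, 0.0, -1.38),
            "internal_capsule": (100.0, 0.0, 0.0, -2.26),
        }
    )
    residual_sd: float = 1.0
    # cohort-level distributions for freely drawn descriptors: (mean, sd)
    descriptor_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "n_active_pixels": (600.0, 150.0),
            "delta_cbv_pct": (15.0, 4.0),
            "rise_time_s": (3.5, 1.0),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if not self.link_coefficients:
            raise ValueError("link_coefficients must name at least one region")
        for region, coefs in self.link_coefficients.items():
            if len(coefs) != 4:
                raise ValueError(f"{region}: expected (intercept, b_pixels, b_dcbv, b_rise)")
            if not np.all(np.isfinite(coefs)):
                raise ValueError(f"{region}: non-finite link coefficients")


def generate_cohort(spec: CohortSpec):
    """Generate a tidy per-animal cohort table.

    Columns: ``animal_id, group, n_active_pixels, delta_cbv_pct,
    rise_time_s, mbp_<region>...``.  Ordinary least squares of any
    ``mbp_<region>`` column on the three descriptors is unbiased for that
    region's link coefficients.  Deterministic under ``spec.seed``.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    anchor = next(iter(spec.link_coefficients))
    a_int, *a_betas = spec.link_coefficients[anchor]
    a_betas = np.asarray(a_betas, dtype=float)
    solve_idx = int(np.argmax(np.abs(a_betas))) if np.any(a_betas != 0) else None

    rows = []
    animal = 0
    for grp in spec.groups:
        for _ in range(grp.n_animals):
            d = np.array([
                rng.normal(*spec.descriptor_means["n_active_pixels"]),
                rng.normal(*spec.descriptor_means["delta_cbv_pct"]),
                rng.normal(*spec.descriptor_means["rise_time_s"]),
            ])
            if solve_idx is not None:
                target = rng.normal(grp.myelin_mean, grp.myelin_sd)
                others = a_int + a_betas @ d - a_betas[solve_idx] * d[solve_idx]
                d[solve_idx] = (target - others) / a_betas[solve_idx]
            d[0] = np.rint(max(d[0], 0.0))  # pixel counts are non-negative integers
            d[2] = max(d[2], 0.05)  # rise time cannot be negative
            row = {
                "animal_id": f"m{animal:03d}",
                "group": grp.label,
                "n_active_pixels": d[0],
                "delta_cbv_pct": d[1],
                "rise_time_s": d[2],
            }
            for region, (intercept, *betas) in spec.link_coefficients.items():
                mu = intercept + np.asarray(betas) @ d
                row[f"mbp_{region}"] = mu + rng.normal(0.0, spec.residual_sd)
            rows.append(row)
            animal += 1
    return pd.DataFrame(rows)
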