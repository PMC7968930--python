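"""Synthetic-data generators with planted ground truth.

Each generator is a pure function of a *truth* object and a seed: rerunning
with the same arguments returns byte-identical data, and the truth is always
returned alongside the data so downstream estimators can be tested as
recovery problems.

The generators emulate the statistical structure of the real inputs only as
far as the downstream quantifications assume it:

- ``gen_timelapse`` — midline fluorescence of a straightened sporogenic
  hypha: ladder-like Gaussian rings whose amplitude rises linearly to a
  peak and decays linearly (assembly → constriction → disassembly), on a
  constant background with additive Gaussian noise clipped at zero.
- ``gen_coverage`` — per-base sequencing depth for ChIP replicates and a
  control strain: negative-binomial counts around a common baseline, with
  planted multiplicative enrichment regions in the replicates only.
- ``gen_kinetics`` — linear inorganic-phosphate release read out as
  620 nm absorbance through a linear standard curve, including the 2x
  dilution of an equal-volume acid quench.
- ``gen_spore_lengths`` — replicate-labelled spore lengths from a normal
  distribution truncated at zero by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingTruth",
    "TimeLapseTruth",
    "CoverageTruth",
    "KineticsTruth",
    "gen_timelapse",
    "profile_stack_to_image",
    "gen_coverage",
    "gen_kinetics",
    "gen_spore_lengths",
    "QUENCH_DILUTION",
]

#: Equal-volume perchloric-acid quench halves every concentration before the
#: colorimetric read-out; generators and estimators share this constant.
QUENCH_DILUTION = 2.0


@dataclass(frozen=True)
class RingTruth:
    """One planted Z-ring: where it sits and how its intensity evolves.

    The amplitude rises linearly from 0 at ``t_assemble`` to
    ``peak_amplitude`` at ``t_peak``, falls linearly back to 0 at
    ``t_disassemble``, and is 0 outside that interval.  The spatial profile
    is a Gaussian of standard deviation ``sigma`` (µm) centred at
    ``position`` (µm along the hypha).
    """

    position: float
    t_assemble: float
    t_peak: float
    t_disassemble: float
    peak_amplitude: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.t_assemble < self.t_peak < self.t_disassemble):
            raise ValueError(
                "ring lifecycle must satisfy t_assemble < t_peak < t_disassemble"
            )
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")

    def amplitude_at(self, t: float | np.ndarray) -> np.ndarray:
        """Piecewise-linear lifecycle amplitude at time ``t`` (minutes)."""
        t = np.asarray(t, dtype=float)
        rise = (t - self.t_assemble) / (self.t_peak - self.t_assemble)
        fall = (self.t_disassemble - t) / (self.t_disassemble - self.t_peak)
        amp = self.peak_amplitude * np.minimum(rise, fall)
        return np.clip(amp, 0.0, None)


@dataclass(frozen=True)
class TimeLapseTruth:
    """Ground truth for a straightened-hypha fluorescence time-lapse.

    Defaults correspond to a 240 min movie sampled every 10 min at
    0.1 µm/px over a 20 µm hypha.  ``n_positions`` fixes the length of the
    rendered midline in pixels.
    """

    rings: tuple[RingTruth, ...] = ()
    background_level: float = 50.0
    noise_sd: float = 10.0
    frame_interval: float = 10.0
    pixel_size: float = 0.1
    n_frames: int = 24
    n_positions: int = 200

    def __post_init__(self) -> None:
        object.__setattr__(self, "rings", tuple(self.rings))
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.n_positions) * self.pixel_size

    def noiseless_stack(self) -> np.ndarray:
        """Closed-form expectation of the stack (frames x positions)."""
        x = self.positions_um
        stack = np.full((self.n_frames, self.n_positions), self.background_level,
                        dtype=float)
        for ring in self.rings:
            profile = np.exp(-0.5 * ((x - ring.position) / ring.sigma) ** 2)
            amps = ring.amplitude_at(self.times)
            stack += amps[:, None] * profile[None, :]
        return stack


def gen_timelapse(
    truth: TimeLapseTruth, seed: int
) -> tuple[np.ndarray, TimeLapseTruth]:
    """Render a midline fluorescence stack (frames x positions) plus truth.

    Each frame is background + the sum of ring Gaussians scaled by their
    lifecycle amplitude at the frame time, plus i.i.d. Gaussian noise;
    values are clipped at 0 (intensities cannot be negative).
    """
    rng = np.random.default_rng(seed)
    stack = truth.noiseless_stack()
    if truth.noise_sd > 0:
        stack = stack + rng.normal(0.0, truth.noise_sd, size=stack.shape)
    return np.clip(stack, 0.0, None), truth


def profile_stack_to_image(
    stack: np.ndarray, width: int = 21
) -> np.ndarray:
    """Tile a (frames x positions) midline stack into (frames x width x positions).

    Convenience for exercising 2-D image operations (kymograph extraction,
    ROI traces) on synthetic data: the hypha is rendered as ``width`` rows
    of identical intensity, i.e. a straightened hypha with a flat transverse
    profile.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    stack = np.asarray(stack, dtype=float)
    return np.repeat(stack[:, None, :], width, axis=1)


@dataclass(frozen=True)
class CoverageTruth:
    """Planted truth for replicate ChIP coverage plus a control track.

    ``regions`` are half-open ``(start, end, fold)`` intervals (0-based bp)
    where the replicate mean depth is multiplied by ``fold``; the control
    carries the baseline only.  ``dispersion`` is the negative-binomial
    size parameter: variance = mean + mean^2 / dispersion, so the model
    tends to Poisson as dispersion grows.
    """

    contig_length: int = 50_000
    baseline_mean: float = 50.0
    dispersion: float = 5.0
    regions: tuple[tuple[int, int, float], ...] = ()
    n_replicates: int = 3
    seed: int = 0
    contig: str = "chr"

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(tuple(r) for r in self.regions))
        if self.contig_length < 1:
            raise ValueError("contig_length must be >= 1")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for start, end, fold in self.regions:
            if not (0 <= start < end <= self.contig_length):
                raise ValueError(f"region ({start}, {end}) outside contig")
            if fold < 1:
                raise ValueError("region fold must be >= 1")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    # NB(size=r, p=r/(r+mu)) has mean mu and variance mu + mu^2/r
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def gen_coverage(truth: CoverageTruth):
    """Draw replicate and control depth tracks; deterministic in truth.seed.

    Returns ``(replicates, control, truth)`` where each track is a
    :class:`sephkit.chip.DepthTrack`.
    """
    from sephkit.chip import DepthTrack

    rng = np.random.default_rng(truth.seed)
    mean = np.full(truth.contig_length, float(truth.baseline_mean))
    for start, end, fold in truth.regions:
        mean[start:end] *= fold
    replicates = [
        DepthTrack(truth.contig, _nb_draw(rng, mean, truth.dispersion))
        for _ in range(truth.n_replicates)
    ]
    baseline = np.full(truth.contig_length, float(truth.baseline_mean))
    control = DepthTrack(truth.contig, _nb_draw(rng, baseline, truth.dispersion))
    return replicates, control, truth


@dataclass(frozen=True)
class KineticsTruth:
    """Planted truth for a phosphate-release (malachite-green) time course.

    ``rate_per_enzyme`` is GTP hydrolysed per enzyme per minute, so the Pi
    production rate is ``rate_per_enzyme * enzyme_conc`` µM/min.  Sampling
    defaults to 0, 2.5, 5, 7.5 and 10 min.  The equal-volume acid quench
    dilutes the reaction ``dilution``-fold before the absorbance read-out.
    """

    rate_per_enzyme: float = 1.12
    enzyme_conc: float = 3.5
    times: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0)
    noise_sd: float = 0.5
    standard_slope: float = 0.01
    standard_intercept: float = 0.05
    dilution: float = QUENCH_DILUTION

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if self.rate_per_enzyme < 0:
            raise ValueError("rate_per_enzyme must be >= 0")
        t = np.asarray(self.times)
        if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.standard_slope <= 0:
            raise ValueError("standard_slope must be positive")
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")

    def true_pi(self, t: np.ndarray | float) -> np.ndarray:
        """Reaction-tube Pi concentration (µM) at time t, before the quench."""
        return self.rate_per_enzyme * self.enzyme_conc * np.asarray(t, dtype=float)


def gen_kinetics(truth: KineticsTruth, seed: int):
    """Generate a noisy absorbance time course and noiseless Pi standards.

    Returns ``(series, standards, truth)``: a
    :class:`sephkit.kinetics.KineticsSeries` and a DataFrame of
    ``(pi_uM, absorbance)`` standards spanning the quenched Pi range.
    Noise is additive on the quenched Pi concentration (pipetting and
    colour-development error), then mapped through the standard curve.
    """
    from sephkit.kinetics import KineticsSeries

    rng = np.random.default_rng(seed)
    t = np.asarray(truth.times)
    pi_quenched = truth.true_pi(t) / truth.dilution
    if truth.noise_sd > 0:
        pi_quenched = pi_quenched + rng.normal(0.0, truth.noise_sd, size=t.shape)
    absorbance = truth.standard_slope * pi_quenched + truth.standard_intercept
    series = KineticsSeries(times=t, absorbance=absorbance,
                            enzyme_conc=truth.enzyme_conc)
    hi = max(truth.true_pi(t[-1]) / truth.dilution, 10.0)
    pi_std = np.linspace(0.0, hi, 8)
    standards = pd.DataFrame({
        "pi_uM": pi_std,
        "absorbance": truth.standard_slope * pi_std + truth.standard_intercept,
    })
    return series, standards, truth


def gen_spore_lengths(
    mean: float = 1.3,
    sd: float = 0.2,
    n_per_rep: int = 350,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-labelled spore lengths (µm), normal truncated at 0.

    Defaults model the standard measurement design of 350 spores per
    biological replicate with three replicates.  Non-positive draws are
    resampled, which leaves the mean essentially unchanged at realistic
    coefficients of variation.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n_per_rep < 1 or n_reps < 1:
        raise ValueError("n_per_rep and n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for rep in range(1, n_reps + 1):
        if sd == 0:
            lengths = np.full(n_per_rep, float(mean))
        else:
            lengths = rng.normal(mean, sd, size=n_per_rep)
            while np.any(lengths <= 0):
                bad = lengths <= 0
                lengths[bad] = rng.normal(mean, sd, size=bad.sum())
        frames.append(pd.DataFrame({"replicate": rep, "length_um": lengths}))
    return pd.concat(frames, ignore_index=True)
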