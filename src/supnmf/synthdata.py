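"""Synthetic MALDI-like spectra with weak class-discriminative patterns.

The generator emulates the structure that motivates supervised NMF: every
spectrum is a positive mixture of a handful of *dominant* spectral
patterns shared by all spectra, while class-1 spectra additionally carry
*discriminative* patterns whose amplitude is only a fraction
(``effect_ratio``) of the dominant ones.  Spectra come in groups
(emulating TMA slides measured in separate runs) with a multiplicative
log-normal batch factor per group, plus additive Gaussian channel noise
(the sum truncated at zero to keep intensities non-negative).

Patterns are sums of Gaussian-shaped peaks on the m/z axis — sufficient
to exercise the factorization and classification machinery; isotope
envelopes, m/z jitter and instrument noise models are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataio import SpectraDataset

__all__ = ["SynthSpec", "GroundTruth", "generate_patterns", "generate_dataset"]


@dataclass
class SynthSpec:
    """Parameters of the synthetic-spectra generator.

    The defaults are the "paper-shaped" preset: 8 groups x 100 spectra of
    length m=500, 8 dominant and 2 discriminative patterns at an
    effect-to-dominant amplitude ratio of 0.15 — a desk-scale stand-in
    for a TMA classification dataset with two roughly balanced classes.
    """

    n_groups: int = 8
    spectra_per_group: int = 100
    m: int = 500
    p_dominant: int = 8
    n_discriminative: int = 2
    peak_width: float = 2.0
    effect_ratio: float = 0.15
    batch_sd: float = 0.15
    noise_sd: float = 0.01
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "spectra_per_group", "m", "p_dominant",
                     "n_discriminative"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.effect_ratio <= 1:
            raise ValueError("effect_ratio must lie in (0, 1]")
        if not 0 < self.class_balance < 1:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.batch_sd < 0 or self.noise_sd < 0:
            raise ValueError("batch_sd and noise_sd must be >= 0")
        if self.m < 10 * self.p_dominant:
            raise ValueError(
                "m must be at least 10 * p_dominant so peaks are resolvable"
            )


@dataclass
class GroundTruth:
    """The planted structure behind a synthetic dataset (for recovery tests)."""

    dominant_patterns: np.ndarray        # p_dominant x m, unit l2 rows
    discriminative_patterns: np.ndarray  # n_discriminative x m, l2 = effect_ratio
    dominant_coefficients: np.ndarray    # n x p_dominant
    discriminative_coefficients: np.ndarray  # n x n_discriminative (0 for class 0)
    batch_factors: np.ndarray            # one per group


def _peak_pattern(rng: np.random.Generator, m: int, width: float) -> np.ndarray:
    """Sum of 3-8 Gaussian peaks at random channel centers, unit l2 norm."""
    n_peaks = int(rng.integers(3, 9))
    centers = rng.uniform(0, m - 1, size=n_peaks)
    heights = rng.uniform(0.5, 1.5, size=n_peaks)
    channels = np.arange(m)
    pattern = np.zeros(m)
    for c, h in zip(centers, heights):
        pattern += h * np.exp(-0.5 * ((channels - c) / width) ** 2)
    return pattern / np.linalg.norm(pattern)


def generate_patterns(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw the dominant (unit-norm) and discriminative (scaled) patterns.

    Deterministic given ``spec.seed``; all patterns are non-negative with
    l2 norm 1 (dominant) or ``effect_ratio`` (discriminative).
    """
    rng = np.random.default_rng(spec.seed)
    dominant = np.stack(
        [_peak_pattern(rng, spec.m, spec.peak_width)
         for _ in range(spec.p_dominant)]
    )
    discriminative = spec.effect_ratio * np.stack(
        [_peak_pattern(rng, spec.m, spec.peak_width)
         for _ in range(spec.n_discriminative)]
    )
    return dominant, discriminative


def generate_dataset(spec: SynthSpec) -> tuple[SpectraDataset, GroundTruth]:
    """Generate a labeled, grouped synthetic dataset plus its ground truth.

    Spectrum i in group g with class label c is

    ``y_i = b_g * (sum_k c_ik d_k + c * sum_j e_ij s_j) + noise``

    with positive mixing coefficients ``c_ik, e_ij ~ U(0.5, 1.5)``, batch
    factor ``b_g = exp(N(0, batch_sd^2))`` shared by group g, and Gaussian
    channel noise of sd ``noise_sd`` (sum clipped at zero).  Labels are
    Bernoulli(``class_balance``) per spectrum.
    """
    # patterns use spec.seed directly (so they match generate_patterns);
    # sampling uses a child stream to stay independent of the pattern draws
    rng = np.random.default_rng([spec.seed, 1])
    dominant, discriminative = generate_patterns(spec)
    n = spec.n_groups * spec.spectra_per_group
    groups = np.repeat(
        [f"G{g + 1}" for g in range(spec.n_groups)], spec.spectra_per_group
    )
    labels = (rng.random(n) < spec.class_balance).astype(int)
    coef_dom = rng.uniform(0.5, 1.5, size=(n, spec.p_dominant))
    coef_disc = rng.uniform(0.5, 1.5, size=(n, spec.n_discriminative))
    coef_disc *= labels[:, None]
    batch = np.exp(rng.normal(0.0, spec.batch_sd, size=spec.n_groups))
    batch_per_spectrum = np.repeat(batch, spec.spectra_per_group)
    signal = coef_dom @ dominant + coef_disc @ discriminative
    Y = batch_per_spectrum[:, None] * signal
    if spec.noise_sd > 0:
        Y = Y + rng.normal(0.0, spec.noise_sd, size=Y.shape)
    Y = np.maximum(Y, 0.0)
    mz = np.linspace(800.0, 3500.0, spec.m)
    ds = SpectraDataset(
        intensities=Y,
        mz_axis=mz,
        labels=labels,
        groups=groups,
        spectrum_ids=np.array([f"s{i:05d}" for i in range(n)], dtype=object),
    )
    truth = GroundTruth(
        dominant_patterns=dominant,
        discriminative_patterns=discriminative,
        dominant_coefficients=coef_dom,
        discriminative_coefficients=coef_disc,
        batch_factors=batch,
    )
    return ds, truth
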