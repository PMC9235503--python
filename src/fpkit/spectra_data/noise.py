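"""Noise simulation: intensity jitter, peak dropout and spurious peaks.

Noise peaks get masses drawn from a pool of peaks observed in other measured
spectra, so simulated spectra are not trivially distinguishable from real
ones (uniform random masses would be).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from fpkit.spectra_data.model import Spectrum


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the noise model.

    drop_fraction:
        Fraction of peaks removed (the base peak is never removed).
    intensity_jitter_sd:
        Standard deviation of the log-normal multiplicative intensity jitter.
    n_noise_peaks:
        Number of spurious peaks to add; masses come from ``peak_pool``.
    noise_intensity_quantile:
        Added peaks get intensities sampled uniformly below this quantile of
        the original peak intensities.
    """

    drop_fraction: float = 0.2
    intensity_jitter_sd: float = 0.3
    n_noise_peaks: int = 0
    noise_intensity_quantile: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_fraction < 1.0:
            raise ValueError("drop_fraction must be in [0, 1)")
        if self.intensity_jitter_sd < 0:
            raise ValueError("intensity_jitter_sd must be non-negative")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be non-negative")
        if not 0.0 <= self.noise_intensity_quantile <= 1.0:
            raise ValueError("noise_intensity_quantile must be in [0, 1]")


def simulate_noise(
    s: Spectrum,
    peak_pool: Sequence[float],
    params: NoiseParams,
    seed: int,
) -> Spectrum:
    """Return a noisy copy of ``s``; bit-reproducible for a fixed seed.

    Retained peaks are multiplicatively jittered; ``drop_fraction`` of the
    non-base peaks are removed; ``n_noise_peaks`` spurious peaks are added
    with m/z sampled from ``peak_pool`` (restricted to masses at or below the
    precursor) and low intensities. Peaks are re-sorted by construction of
    the returned :class:`Spectrum`.
    """
    if not s.peaks:
        raise ValueError("cannot add noise to an empty spectrum")
    if params.n_noise_peaks > 0 and len(peak_pool) == 0:
        raise ValueError("peak_pool must be non-empty when n_noise_peaks > 0")

    rng = np.random.default_rng(seed)
    mz = s.mz
    inten = s.intensities
    n = len(mz)
    base = int(np.argmax(inten))

    # Dropout: a deterministic count of non-base peaks, chosen at random.
    n_drop = int(round(params.drop_fraction * (n - 1)))
    keep = np.ones(n, dtype=bool)
    if n_drop > 0:
        droppable = np.array([i for i in range(n) if i != base])
        drop = rng.choice(droppable, size=n_drop, replace=False)
        keep[drop] = False
    mz, inten = mz[keep], inten[keep]

    if params.intensity_jitter_sd > 0:
        factors = rng.lognormal(
            mean=0.0, sigma=params.intensity_jitter_sd, size=len(inten)
        )
        inten = inten * factors

    new_peaks = list(zip(mz, inten))
    if params.n_noise_peaks > 0:
        pool = np.asarray(peak_pool, dtype=float)
        if s.precursor_mz is not None:
            pool = pool[pool <= s.precursor_mz]
            if len(pool) == 0:
                raise ValueError(
                    "no peak_pool masses at or below the precursor m/z"
                )
        ceiling = float(np.quantile(s.intensities, params.noise_intensity_quantile))
        if ceiling <= 0:
            ceiling = float(s.intensities.max()) * 0.01
        noise_mz = rng.choice(pool, size=params.n_noise_peaks, replace=True)
        noise_int = rng.uniform(0.0, ceiling, size=params.n_noise_peaks)
        # Zero intensities are legal but uninformative; nudge off zero.
        noise_int = np.maximum(noise_int, ceiling * 1e-3)
        new_peaks.extend(zip(noise_mz, noise_int))

    return s.with_peaks(new_peaks)
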