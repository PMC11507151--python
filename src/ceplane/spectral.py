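"""Welch power-spectral-density estimation and band summaries.

Each channel's PSD is the average periodogram of overlapping
Hamming-weighted blocks (2 s blocks advanced in 1 s steps by default; at
200 Hz a 60 s record yields exactly 59 blocks and a frequency resolution
of 0.5 Hz).  The averaged spectrum is then normalized to unit total power
over the analysis range [0.5, 100) Hz, which removes the (arbitrary)
amplitude scale of intracranial voltage recordings and drops the DC bin,
meaningless after zero-padding and mean removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SpectralEstimate",
    "BandScheme",
    "CLINICAL_BANDS",
    "welch_psd",
    "group_psd_summary",
    "band_power",
    "peak_frequency",
]


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided, unit-sum PSD of a single channel."""

    freqs: np.ndarray
    power: np.ndarray
    channel_id: str = ""
    n_blocks: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")
        if abs(power.sum() - 1.0) > 1e-9:
            raise ValueError(f"power sums to {power.sum():.12g}, not 1")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


@dataclass(frozen=True)
class BandScheme:
    """Named contiguous frequency bands with [low, high) edges in Hz."""

    bands: dict = field(default_factory=lambda: dict(CLINICAL_BANDS))

    def __post_init__(self) -> None:
        edges = sorted(self.bands.values())
        for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
            if lo > hi or hi > lo2:
                raise ValueError("bands must be non-overlapping with low <= high")
        for lo, hi in edges:
            if lo < 0:
                raise ValueError("band edges must be >= 0")


# conventional clinical EEG bands (Hz); gamma capped at the 200 Hz Nyquist
CLINICAL_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}


def n_welch_blocks(n_samples: int, fs: float, block_s: float, step_s: float) -> int:
    """Number of overlapping Welch blocks: floor((T - block)/step) + 1."""
    return int(np.floor((n_samples / fs - block_s) / step_s)) + 1


def welch_psd(
    x: np.ndarray,
    fs: float,
    block_s: float = 2.0,
    step_s: float = 1.0,
    channel_id: str = "",
    norm_range: tuple[float, float] = (0.5, 100.0),
) -> SpectralEstimate:
    """Welch PSD of one channel, normalized to unit total power.

    Blocks of ``round(block_s * fs)`` samples advanced by
    ``round(step_s * fs)`` are mean-detrended, Hamming-weighted,
    periodogram'd and averaged.  Bins inside ``norm_range`` (clipped to
    the Nyquist frequency) are kept and rescaled to sum to 1.

    Raises ``ValueError`` when the input is shorter than one block.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(block_s * fs))
    step = int(round(step_s * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"input of {len(x)} samples is shorter than one {nperseg}-sample block"
        )
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg - step,
        detrend="constant",
        scaling="density",
    )
    lo, hi = norm_range
    hi = min(hi, fs / 2.0)
    keep = (freqs >= lo) & (freqs < hi)
    if hi == fs / 2.0 and not np.any(freqs[keep] == hi):
        # keep the Nyquist bin when the range is capped by it
        keep |= freqs == hi
    freqs, power = freqs[keep], power[keep]
    total = power.sum()
    if total <= 0:
        raise ValueError("signal has no power in the analysis range")
    return SpectralEstimate(
        freqs=freqs,
        power=power / total,
        channel_id=channel_id,
        n_blocks=n_welch_blocks(len(x), fs, block_s, step_s),
    )


def group_psd_summary(
    estimates: list[SpectralEstimate],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise median and quartile curves across channels.

    Returns ``(freqs, median, q1, q3)``.  All estimates must share one
    frequency grid.
    """
    if not estimates:
        raise ValueError("need at least one spectral estimate")
    freqs = estimates[0].freqs
    for est in estimates[1:]:
        if est.freqs.shape != freqs.shape or not np.allclose(est.freqs, freqs):
            raise ValueError("spectral estimates are on different frequency grids")
    stack = np.vstack([est.power for est in estimates])
    return (
        freqs,
        np.median(stack, axis=0),
        np.percentile(stack, 25, axis=0),
        np.percentile(stack, 75, axis=0),
    )


def band_power(est: SpectralEstimate, scheme: BandScheme | None = None) -> dict:
    """Fraction of (normalized) power in each named band.

    Fractions are >= 0 and sum to at most 1; bins outside every band are
    excluded.  An empty band (low == high) contributes 0.
    """
    if scheme is None:
        scheme = BandScheme()
    out = {}
    for name, (lo, hi) in scheme.bands.items():
        mask = (est.freqs >= lo) & (est.freqs < hi)
        out[name] = float(est.power[mask].sum())
    return out


def peak_frequency(
    freqs: np.ndarray, power: np.ndarray, fmin: float = 2.0, fmax: float = 20.0
) -> float:
    """Frequency of maximal power within [fmin, fmax].

    Intended for locating the dominant oscillatory (theta/alpha) peak of a
    PSD or a group-median curve; the lower cutoff keeps the 1/f upturn at
    the lowest frequencies from masking the peak.
    """
    mask = (freqs >= fmin) & (freqs <= fmax)
    if not mask.any():
        raise ValueError("no frequency bins inside the search range")
    sub_f, sub_p = freqs[mask], power[mask]
    return float(sub_f[np.argmax(sub_p)])
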