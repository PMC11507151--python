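"""Synthetic iEEG-like cohorts with known statistical structure.

Real intracranial recordings are not redistributable, so every downstream
stage of the pipeline is exercised on surrogate cohorts whose generative
parameters are known exactly: per-channel voltage series at a fixed
sampling rate with

* a 1/f-like colored-noise background (power ~ f^-beta),
* an optional narrow-band oscillatory peak carrying a controlled fraction
  of the total variance (emulating the theta/alpha peaks of wake iEEG),
* an optional tail of exact zeros (emulating records zero-padded to a
  uniform length),

plus a per-channel metadata table (patient id, sex, age, region,
hemisphere).  Group differences are injected as controlled shifts in the
spectral exponent and in the peak frequency between the sexes.

Colored noise is synthesized spectrally: complex Gaussian Fourier
coefficients with standard deviation proportional to f^(-beta/2),
inverse-FFT'd and standardized.  This is an exact stationary Gaussian
process with expected power spectrum f^(-beta), in O(n log n); drawing
the coefficient *amplitudes* (not only the phases) at random is what
makes distinct channels and windows behave as independent realizations,
which the null calibration of the downstream rank tests relies on.  Each
channel draws from its own RNG stream derived from (seed, patient index,
channel index), so adding channels never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import METADATA_COLUMNS, SignalRecord

__all__ = [
    "GroupEffect",
    "CohortSpec",
    "gen_colored_noise",
    "gen_oscillatory_channel",
    "gen_logistic_map",
    "gen_cohort",
]


@dataclass(frozen=True)
class GroupEffect:
    """Injected spectral differences between the sexes.

    ``beta_*`` are the spectral exponents of the 1/f background
    (power ~ f^-beta); ``peak_freq_*`` the centre of the oscillatory peak
    in Hz; ``peak_amplitude`` the fraction of total variance carried by
    the peak; ``pad_tail_s`` the length of the trailing run of exact
    zeros.  Defaults: a wake-like 1/f slope of 1.5 for both sexes, a
    theta-alpha-boundary peak at 7.5 Hz (female) vs 9.0 Hz (male)
    carrying 30% of the variance, and an 8 s zero tail so a 68 s record
    holds 60 s of signal.
    """

    beta_female: float = 1.5
    beta_male: float = 1.5
    peak_freq_female: float = 7.5
    peak_freq_male: float = 9.0
    peak_amplitude: float = 0.3
    pad_tail_s: float = 8.0

    def __post_init__(self) -> None:
        for name in ("beta_female", "beta_male"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.peak_amplitude < 1:
            raise ValueError("peak_amplitude must be in [0, 1)")
        if self.pad_tail_s < 0:
            raise ValueError("pad_tail_s must be >= 0")

    def params_for(self, sex: str) -> tuple[float, float]:
        if sex == "F":
            return self.beta_female, self.peak_freq_female
        if sex == "M":
            return self.beta_male, self.peak_freq_male
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Design of one synthetic region cohort.

    ``age_law`` maps sex to (mean, sd) of a normal age law truncated to
    [18, 65] years and rounded to whole years.  Defaults mirror a typical
    analyzed region: 5 patients per sex, 2 channels each, 68 s records at
    200 Hz, female/male mean ages around 30/36 years.
    """

    n_female_patients: int = 5
    n_male_patients: int = 5
    channels_per_patient: int = 2
    region_label: str = "synthetic region"
    hemisphere: str = "L"
    duration_s: float = 68.0
    fs: float = 200.0
    age_law: dict = field(
        default_factory=lambda: {"F": (30.0, 10.0), "M": (36.0, 10.0)}
    )
    effect: GroupEffect = field(default_factory=GroupEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female_patients < 0 or self.n_male_patients < 0:
            raise ValueError("patient counts must be >= 0")
        if self.channels_per_patient < 0:
            raise ValueError("channels_per_patient must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        if self.effect.pad_tail_s >= self.duration_s:
            raise ValueError("pad_tail_s must be shorter than duration_s")
        for f in (self.effect.peak_freq_female, self.effect.peak_freq_male):
            if not 0 < f < self.fs / 2:
                raise ValueError("peak frequencies must lie in (0, fs/2)")


def _spectral_noise(
    n: int, fs: float, amplitude_profile: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Stationary Gaussian noise with the given one-sided spectral profile.

    Complex Gaussian rFFT coefficients scaled by the profile; both the
    amplitudes and the phases are random, so separate calls yield
    independent realizations of the same process.
    """
    n_freq = n // 2 + 1
    coeff = amplitude_profile * (
        rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    )
    coeff[0] = 0.0  # zero mean
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real  # Nyquist bin must be real
    x = np.fft.irfft(coeff, n=n)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def gen_colored_noise(
    n: int, fs: float, beta: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-variance noise whose power spectrum decays as f^-beta.

    beta = 0 gives spectrally white noise, beta = 2 a Brownian-like red
    spectrum.  Deterministic for a fixed seed.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    return _spectral_noise(n, fs, amp, rng)


def gen_oscillatory_channel(
    n: int,
    fs: float,
    beta: float,
    peak_freq: float,
    peak_amplitude: float,
    seed: int | np.random.Generator,
    peak_bandwidth: float = 1.0,
) -> np.ndarray:
    """Colored-noise background plus a narrow-band oscillatory component.

    The peak is band-limited noise with a Gaussian spectral envelope of
    standard deviation ``peak_bandwidth/2`` Hz centred at ``peak_freq``,
    scaled to carry the fraction ``peak_amplitude`` of the total variance
    (the background carries ``1 - peak_amplitude``).  With
    ``peak_amplitude = 0`` the output is identical to
    :func:`gen_colored_noise` under the same seed.
    """
    if not 0 < peak_freq < fs / 2:
        raise ValueError(
            f"peak_freq must lie in (0, fs/2) = (0, {fs / 2}), got {peak_freq}"
        )
    if not 0 <= peak_amplitude < 1:
        raise ValueError(f"peak_amplitude must be in [0, 1), got {peak_amplitude}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    background = gen_colored_noise(n, fs, beta, rng)
    if peak_amplitude == 0:
        return background
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = peak_bandwidth / 2.0
    envelope = np.exp(-0.5 * ((freqs - peak_freq) / sigma) ** 2)
    peak = _spectral_noise(n, fs, envelope, rng)
    return np.sqrt(1.0 - peak_amplitude) * background + np.sqrt(peak_amplitude) * peak


def gen_logistic_map(
    n: int, r: float = 4.0, x0: float = 0.3, burn_in: int = 0
) -> np.ndarray:
    """Iterates of the logistic map x_{t+1} = r x_t (1 - x_t).

    The fully chaotic regime (r = 4) is the standard fixture for
    ordinal-pattern analysis: it is deterministic yet broadband, sits in
    the high-complexity band of the complexity-entropy plane, and at
    embedding dimension 3 never produces three strictly decreasing
    consecutive values (a "forbidden pattern" that white noise cannot
    avoid).
    """
    if not 0 < x0 < 1:
        raise ValueError(f"x0 must lie in (0, 1), got {x0}")
    if not 0 < r <= 4:
        raise ValueError(f"r must lie in (0, 4], got {r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    total = n + burn_in
    x = np.empty(total)
    x[0] = x0
    for t in range(total - 1):
        x[t + 1] = r * x[t] * (1.0 - x[t])
    return x[burn_in:]


def _truncated_normal_age(
    rng: np.random.Generator, mean: float, sd: float, lo: float = 18.0, hi: float = 65.0
) -> int:
    """One age draw: normal(mean, sd) truncated to [lo, hi], whole years."""
    for _ in range(1000):
        a = rng.normal(mean, sd)
        if lo <= a <= hi:
            return int(round(a))
    return int(round(np.clip(mean, lo, hi)))


def gen_cohort(spec: CohortSpec) -> tuple[list[SignalRecord], pd.DataFrame]:
    """Generate all channels and the metadata table for one cohort.

    Patient ids are ``F01, F02, ...`` / ``M01, ...``; channel ids append
    ``c1, c2, ...``.  Each channel's signal and each patient's age come
    from an RNG stream seeded by (spec.seed, patient index, channel
    index), so the output is reproducible and independent of generation
    order.  When ``effect.pad_tail_s > 0`` the last samples of every
    channel are exact zeros.
    """
    fs = spec.fs
    n_total = int(round(spec.duration_s * fs))
    n_pad = int(round(spec.effect.pad_tail_s * fs))
    n_signal = n_total - n_pad

    records: list[SignalRecord] = []
    rows: list[dict] = []
    sexes = [("F", spec.n_female_patients), ("M", spec.n_male_patients)]
    for sex_idx, (sex, n_patients) in enumerate(sexes):
        beta, peak_freq = spec.effect.params_for(sex)
        mean_age, sd_age = spec.age_law[sex]
        for p in range(n_patients):
            age_rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, sex_idx, p, 10**6])
            )
            age = _truncated_normal_age(age_rng, mean_age, sd_age)
            patient_id = f"{sex}{p + 1:02d}"
            for c in range(spec.channels_per_patient):
                rng = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, sex_idx, p, c])
                )
                x = gen_oscillatory_channel(
                    n_signal, fs, beta, peak_freq, spec.effect.peak_amplitude, rng
                )
                if n_pad > 0:
                    x = np.concatenate([x, np.zeros(n_pad)])
                channel_id = f"{patient_id}c{c + 1}"
                records.append(
                    SignalRecord(
                        channel_id=channel_id,
                        patient_id=patient_id,
                        sex=sex,
                        age=age,
                        region=spec.region_label,
                        hemisphere=spec.hemisphere,
                        fs=fs,
                        data=x,
                    )
                )
                rows.append(
                    {
                        "patient_id": patient_id,
                        "sex": sex,
                        "age": age,
                        "region": spec.region_label,
                        "hemisphere": spec.hemisphere,
                        "channel_id": channel_id,
                        "fs_hz": fs,
                    }
                )
    metadata = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    return records, metadata


def null_pair_spec(spec: CohortSpec) -> CohortSpec:
    """The same cohort design with every sex difference removed.

    Both sexes inherit the female generative parameters, so any detected
    F/M difference is a false positive by construction.
    """
    eff = spec.effect
    return replace(
        spec,
        effect=replace(
            eff,
            beta_male=eff.beta_female,
            peak_freq_male=eff.peak_freq_female,
        ),
        age_law={"F": spec.age_law["F"], "M": spec.age_law["F"]},
    )
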