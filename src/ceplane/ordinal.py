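"""Bandt-Pompe ordinal-pattern symbolization.

A time series is mapped to a probability distribution over the D! ordinal
patterns of its D-point embedded vectors.  Only the *rank order* of the
values inside each vector matters, so the distribution is invariant under
any strictly increasing transform of the signal amplitude.  The embedded
vectors are the overlapping tuples

    (x_t, x_{t+tau}, ..., x_{t+(D-1)tau}),   t = 0 .. n-1,

with n = M - (D-1)*tau for a series of M samples.  Each vector is reduced
to the permutation that sorts it ascending (ties broken by temporal order:
the earlier sample is ranked lower), and the permutation is identified by
its lexicographic rank in [0, D!-1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "EmbeddingConfig",
    "OrdinalPDF",
    "Window",
    "pattern_index",
    "bp_pdf",
    "window_iter",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the ordinal embedding and the windowing scheme.

    Parameters
    ----------
    D : int
        Embedding dimension (number of samples per ordinal vector), >= 2.
    tau : int
        Embedding delay in samples, >= 1.
    window_s : float
        Length of the non-overlapping analysis windows, in seconds.
    min_oversampling : float
        The window must contain at least ``min_oversampling * D!`` embedded
        vectors for the pattern histogram to be statistically meaningful
        (the M >> D! requirement).  Below this a warning is emitted; below
        ``1 * D!`` the window is rejected.
    """

    D: int = 6
    tau: int = 1
    window_s: float = 15.0
    min_oversampling: float = 5.0

    def __post_init__(self) -> None:
        if self.D < 2:
            raise ValueError(f"embedding dimension D must be >= 2, got {self.D}")
        if self.tau < 1:
            raise ValueError(f"embedding delay tau must be >= 1, got {self.tau}")
        if self.window_s <= 0:
            raise ValueError(f"window_s must be > 0, got {self.window_s}")

    @property
    def n_patterns(self) -> int:
        """Number of possible ordinal patterns, D!."""
        return math.factorial(self.D)

    def window_samples(self, fs: float) -> int:
        """Window length in samples at sampling rate ``fs``."""
        return int(round(self.window_s * fs))


@dataclass(frozen=True)
class OrdinalPDF:
    """Histogram of ordinal patterns for one stretch of signal.

    ``counts[j]`` is the number of embedded vectors whose sorting
    permutation has lexicographic rank ``j``; ``probs`` are the relative
    frequencies.  ``n_vectors = M - (D-1)*tau`` for an input of M samples.
    """

    D: int
    tau: int
    counts: np.ndarray
    n_vectors: int
    probs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (math.factorial(self.D),):
            raise ValueError(
                f"counts must have length D! = {math.factorial(self.D)}, "
                f"got {counts.shape}"
            )
        total = int(counts.sum())
        if total != self.n_vectors:
            raise ValueError(
                f"counts sum to {total} but n_vectors is {self.n_vectors}"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "probs", counts / float(total))


def _lehmer_rank(perms: np.ndarray) -> np.ndarray:
    """Lexicographic rank of each permutation row of ``perms`` (shape (n, D))."""
    n, D = perms.shape
    ranks = np.zeros(n, dtype=np.int64)
    for i in range(D - 1):
        # count entries to the right that are smaller: the i-th Lehmer digit
        smaller = (perms[:, i + 1 :] < perms[:, i : i + 1]).sum(axis=1)
        ranks += smaller * math.factorial(D - 1 - i)
    return ranks


def pattern_index(v: np.ndarray, D: int | None = None) -> int:
    """Ordinal pattern id of one D-length vector.

    The id is the lexicographic rank of the permutation that sorts ``v``
    ascending, with ties broken by temporal order (the earlier sample is
    ranked lower, i.e. a stable sort).  A strictly increasing vector maps
    to 0; a strictly decreasing one to D!-1.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1:
        raise ValueError("pattern_index expects a 1-D vector")
    if D is not None and len(v) != D:
        raise ValueError(f"expected a vector of length {D}, got {len(v)}")
    perm = np.argsort(v, kind="stable")
    return int(_lehmer_rank(perm[None, :])[0])


def _embed(x: np.ndarray, D: int, tau: int) -> np.ndarray:
    """All overlapping embedded vectors of ``x`` as an (n, D) array."""
    span = (D - 1) * tau + 1
    return sliding_window_view(x, span)[:, ::tau]


def bp_pdf(x: np.ndarray, cfg: EmbeddingConfig) -> OrdinalPDF:
    """Ordinal-pattern probability distribution of a series.

    Parameters
    ----------
    x : array-like of shape (M,)
        Finite-valued series with M >= (D-1)*tau + 1 samples.
    cfg : EmbeddingConfig

    Returns
    -------
    OrdinalPDF with counts over all n = M - (D-1)*tau embedded vectors.

    Raises
    ------
    ValueError
        If the series is too short for a single embedded vector, or
        contains non-finite values.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("bp_pdf expects a 1-D series")
    M = len(x)
    span = (cfg.D - 1) * cfg.tau + 1
    if M < span:
        raise ValueError(
            f"series of {M} samples is too short for D={cfg.D}, tau={cfg.tau} "
            f"(needs at least {span})"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("bp_pdf requires finite-valued input (found NaN/inf)")
    n_states = cfg.n_patterns
    n_vectors = M - (cfg.D - 1) * cfg.tau
    if n_vectors < n_states:
        raise ValueError(
            f"{n_vectors} embedded vectors cannot populate {n_states} patterns; "
            f"series violates M >> D!"
        )
    if n_vectors < cfg.min_oversampling * n_states:
        warnings.warn(
            f"only {n_vectors} embedded vectors for {n_states} patterns; "
            f"the ordinal histogram may be undersampled (M >> D! is marginal)",
            stacklevel=2,
        )
    perms = np.argsort(_embed(x, cfg.D, cfg.tau), axis=1, kind="stable")
    ranks = _lehmer_rank(perms)
    counts = np.bincount(ranks, minlength=n_states)
    return OrdinalPDF(D=cfg.D, tau=cfg.tau, counts=counts, n_vectors=n_vectors)


@dataclass(frozen=True)
class Window:
    """One non-overlapping analysis window of a channel."""

    data: np.ndarray
    index: int
    start_sample: int
    is_padding: bool


def _has_constant_run(x: np.ndarray, min_run: int) -> bool:
    """True if ``x`` contains >= min_run identical consecutive values."""
    if min_run <= 1:
        return len(x) > 0
    if len(x) < min_run:
        return False
    same = np.diff(x) == 0
    if not same.any():
        return False
    # longest run of True in `same` plus one
    padded = np.concatenate(([False], same, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    run_lengths = edges[1::2] - edges[::2] + 1
    return bool(run_lengths.max() >= min_run)


def window_iter(x: np.ndarray, fs: float, cfg: EmbeddingConfig) -> Iterator[Window]:
    """Consecutive non-overlapping windows of ``round(window_s * fs)`` samples.

    Windows are cut from the start of ``x``; a trailing partial window is
    discarded.  A window is flagged ``is_padding`` when it contains a run of
    at least ``fs/2`` identical consecutive values — the signature of the
    zero-padding tails appended to make records a uniform length, which
    would otherwise inject a spurious constant-pattern mass into the
    ordinal histogram.
    """
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    x = np.asarray(x, dtype=float)
    w = cfg.window_samples(fs)
    min_run = max(2, int(np.ceil(fs / 2)))
    for i in range(len(x) // w):
        start = i * w
        chunk = x[start : start + w]
        yield Window(
            data=chunk,
            index=i,
            start_sample=start,
            is_padding=_has_constant_run(chunk, min_run),
        )
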