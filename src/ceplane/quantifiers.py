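"""Information-theoretic quantifiers on ordinal-pattern distributions.

Two quantifiers characterize a signal's dynamics on the complexity-entropy
causality plane:

* normalized permutation Shannon entropy  H[P] = S[P] / log2(N), where
  S[P] = -sum_j p_j log2 p_j and N = D! is the number of ordinal states;
* MPR statistical complexity  C = Q_J[P, P_e] * H[P], where
  Q_J = Q_0 * J[P, P_e] is the disequilibrium, J the Jensen-Shannon
  divergence between P and the uniform distribution P_e (written in terms
  of the normalized entropy), and Q_0 = 1 / J[delta, P_e] the constant
  that scales Q_J to [0, 1] (delta = any point mass).

C vanishes at both extremes — perfect order (H = 0) and full randomness
(H = 1, where J = 0) — and is maximal for structured, e.g. chaotic,
dynamics in between.  All logarithms are base 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .ordinal import EmbeddingConfig, bp_pdf, window_iter

__all__ = [
    "QuantifierPoint",
    "shannon_entropy",
    "normalized_entropy",
    "jensen_shannon",
    "q0",
    "mpr_complexity",
    "channel_quantifiers",
]

# probabilities at or below this are numerical zeros in entropy sums
_P_FLOOR = 1e-15


@dataclass(frozen=True)
class QuantifierPoint:
    """One (H, C) point of the complexity-entropy plane."""

    H: float
    C: float
    D: int
    N: int
    window_index: int
    channel_id: str


def _validate_pdf(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 1 or len(P) < 1:
        raise ValueError("probability vector must be 1-D and non-empty")
    if np.any(P < 0):
        raise ValueError("probability vector has negative entries")
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {P.sum():.12g}, not 1")
    return P


def shannon_entropy(P: np.ndarray) -> float:
    """Shannon entropy S[P] = -sum p_j log2 p_j, in bits (0*log 0 = 0)."""
    P = _validate_pdf(P)
    nz = P[P > _P_FLOOR]
    return float(-(nz * np.log2(nz)).sum())


def normalized_entropy(P: np.ndarray) -> float:
    """Normalized entropy H[P] = S[P] / log2(N), in [0, 1]."""
    P = _validate_pdf(P)
    N = len(P)
    if N < 2:
        raise ValueError("normalized entropy needs at least 2 states")
    return shannon_entropy(P) / np.log2(N)


def jensen_shannon(P: np.ndarray, Pe: np.ndarray) -> float:
    """Jensen-Shannon divergence J[P, Pe] in normalized-entropy form.

    J = H[(P+Pe)/2] - H[P]/2 - H[Pe]/2, with H the normalized entropy.
    Symmetric, >= 0, and 0 iff P == Pe.
    """
    P = _validate_pdf(P)
    Pe = _validate_pdf(Pe)
    if len(P) != len(Pe):
        raise ValueError(f"distributions have different lengths ({len(P)} vs {len(Pe)})")
    j = normalized_entropy((P + Pe) / 2.0) - normalized_entropy(P) / 2.0 \
        - normalized_entropy(Pe) / 2.0
    # tiny negative values are floating-point noise around J = 0
    return max(j, 0.0)


@lru_cache(maxsize=None)
def q0(N: int) -> float:
    """Disequilibrium normalization constant Q_0 for N states.

    Defined as 1 / J[delta, P_e] with delta a point mass and P_e uniform,
    so that Q_J = Q_0 * J equals exactly 1 at a point mass.  Evaluated
    numerically from the same J used everywhere else, which keeps the
    complexity values consistent by construction.
    """
    if N < 2:
        raise ValueError("Q0 needs at least 2 states")
    delta = np.zeros(N)
    delta[0] = 1.0
    return 1.0 / jensen_shannon(delta, np.full(N, 1.0 / N))


def mpr_complexity(P: np.ndarray, Pe: np.ndarray | None = None) -> float:
    """MPR statistical complexity C = Q_0 * J[P, Pe] * H[P], in [0, 1]."""
    P = _validate_pdf(P)
    N = len(P)
    if Pe is None:
        Pe = np.full(N, 1.0 / N)
    return q0(N) * jensen_shannon(P, Pe) * normalized_entropy(P)


def channel_quantifiers(
    record,
    cfg: EmbeddingConfig,
    fs: float | None = None,
    include_padding: bool = False,
) -> list[QuantifierPoint]:
    """(H, C) for every retained window of one channel.

    The channel is cut into non-overlapping windows of ``cfg.window_s``
    seconds; windows flagged as padding (zero-pad tails) are skipped unless
    ``include_padding`` is set.  ``record`` is anything with ``data``,
    ``fs`` and ``channel_id`` attributes, or a bare array if ``fs`` is
    given.

    Returns an empty list (with a warning) when no window is retained.
    """
    if hasattr(record, "data"):
        x = record.data
        fs = record.fs if fs is None else fs
        channel_id = getattr(record, "channel_id", "")
    else:
        x = np.asarray(record)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
        channel_id = ""

    points: list[QuantifierPoint] = []
    N = cfg.n_patterns
    for win in window_iter(x, fs, cfg):
        if win.is_padding and not include_padding:
            continue
        pdf = bp_pdf(win.data, cfg)
        H = normalized_entropy(pdf.probs)
        C = mpr_complexity(pdf.probs)
        points.append(
            QuantifierPoint(
                H=H, C=C, D=cfg.D, N=N, window_index=win.index, channel_id=channel_id
            )
        )
    if not points:
        warnings.warn(
            f"channel {channel_id!r}: no retained windows "
            f"(signal shorter than one window, or all windows are padding)",
            stacklevel=2,
        )
    return points
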