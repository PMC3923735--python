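"""Channel statistics and the two-sided F-test for variance equality.

The correction is validated by comparing the b* distribution before and
after processing: a method that preserves chromaticity leaves the b*
variance unchanged (large p), while correcting in RGB shifts it (small p).
Pixels are treated as independent observations — statistically optimistic,
but it is the convention under which the test is defined here.

The ``display_scale`` option maps LAB channels to the 0–255 convention of
common image editors (L* × 255/100; a*, b* + 128; clamped), so reported
means are comparable with 8-bit histogram readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

__all__ = ["ChannelStats", "FTestResult", "channel_stats", "variance_f_test"]

_CHANNELS = {"L": 0, "a": 1, "b": 2}


@dataclass(frozen=True)
class ChannelStats:
    mean: float
    variance: float  # unbiased, n-1 denominator
    n: int
    histogram: np.ndarray  # 256 bin counts


@dataclass(frozen=True)
class FTestResult:
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    reject_at_alpha: bool
    alpha: float = 0.05


def channel_stats(lab: np.ndarray, channel: str, display_scale: bool = False) -> ChannelStats:
    """Mean, unbiased variance and a 256-bin histogram of one LAB channel.

    With ``display_scale`` the values are first mapped to 0–255 (see module
    docstring) and binned over [0, 256); otherwise the native range is
    binned: [0, 100] for L*, [−128, 128] for a*/b*.
    """
    if channel not in _CHANNELS:
        raise ValidationError(f"channel must be one of {sorted(_CHANNELS)}, got {channel!r}")
    lab = np.asarray(lab, dtype=float)
    v = lab[..., _CHANNELS[channel]].ravel()
    if v.size < 2:
        raise ValidationError("channel statistics need at least 2 pixels")
    if display_scale:
        v = v * (255.0 / 100.0) if channel == "L" else v + 128.0
        v = np.clip(v, 0.0, 255.0)
        lo, hi = 0.0, 256.0
    else:
        lo, hi = (0.0, 100.0) if channel == "L" else (-128.0, 128.0)
        v = np.clip(v, lo, hi)
    hist, _ = np.histogram(v, bins=256, range=(lo, hi))
    return ChannelStats(
        mean=float(v.mean()),
        variance=float(v.var(ddof=1)),
        n=int(v.size),
        histogram=hist,
    )


def variance_f_test(sample1, sample2, alpha: float = 0.05) -> FTestResult:
    """Two-sided F-test of equal variances for two normal samples.

    ``F = s1²/s2²`` with degrees of freedom ``(n1−1, n2−1)``;
    ``p = min(1, 2·min(P(F ≤ f), P(F ≥ f)))``; the null is rejected when
    ``p < alpha``.  Swapping the samples inverts F but leaves p unchanged.
    """
    s1 = np.asarray(sample1, dtype=float).ravel()
    s2 = np.asarray(sample2, dtype=float).ravel()
    if s1.size < 2 or s2.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    v1, v2 = s1.var(ddof=1), s2.var(ddof=1)
    if v1 == 0.0 or v2 == 0.0:
        raise ValidationError("degenerate sample: zero variance")
    f = float(v1 / v2)
    df1, df2 = s1.size - 1, s2.size - 1
    dist = stats.f(df1, df2)
    p = float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))
    return FTestResult(
        f_statistic=f,
        df1=df1,
        df2=df2,
        p_value=p,
        reject_at_alpha=bool(p < alpha),
        alpha=alpha,
    )
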