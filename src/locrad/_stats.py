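"""First-order statistics kernel shared by the local-map and aggregation stages.

Twelve first-order descriptors of a value multiset: mean, median, excess
kurtosis, skewness, histogram entropy, histogram uniformity, interquartile
range, coefficient of variation, standard deviation, median absolute
deviation, and mean/median of the last decile (values at or above the 90th
percentile).

Conventions (frozen so that every caller and every test oracle agrees):

* quantiles use linear interpolation between order statistics (type 7);
* skewness = m3 / m2^1.5 and kurtosis = m4 / m2^2 - 3 with population
  (divide-by-n) moments; both are 0 when m2 == 0;
* standard deviation uses the n-1 divisor (0 for a single value);
* entropy = -sum p_i log2 p_i (bits) and uniformity = sum p_i^2 over the
  probabilities of an equal-width histogram whose span is supplied by the
  caller (values outside the span fall into the edge bins);
* CV = SD / |mean|, forced to 0 when |mean| <= an absolute guard supplied
  by the caller (windows straddling 0 HU would otherwise explode).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = ["LocalStat", "STAT_ORDER", "HistogramSpec", "local_stats", "stats_batch"]


class LocalStat(Enum):
    """The 12 first-order statistics, with their short report codes."""

    MEAN = "Mn"
    MEDIAN = "M"
    KURT = "K"
    SKEW = "S"
    ENTROPY = "E"
    UNIF = "U"
    IQR = "IQR"
    CV = "CV"
    SD = "SD"
    MAD = "MAD"
    MEAN90 = "Mn90th"
    MED90 = "M90th"

    @property
    def code(self) -> str:
        return self.value


#: canonical column order used throughout the package
STAT_ORDER: tuple[LocalStat, ...] = tuple(LocalStat)

_CODE_TO_STAT = {s.value: s for s in LocalStat}


def stat_from_code(code: str) -> LocalStat:
    try:
        return _CODE_TO_STAT[code]
    except KeyError:
        raise KeyError(f"unknown statistic code {code!r}") from None


@dataclass(frozen=True)
class HistogramSpec:
    """Equal-width histogram used for entropy/uniformity.

    ``lo``/``hi`` span the histogram; values outside are clipped into the
    edge bins.  A degenerate span (``hi <= lo``) puts everything into one
    bin, so entropy is 0 and uniformity 1.
    """

    lo: float
    hi: float
    n_bins: int = 16

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise ValueError("histogram bounds must be finite")

    @classmethod
    def from_values(cls, values: np.ndarray, n_bins: int = 16) -> "HistogramSpec":
        v = np.asarray(values, dtype=float)
        return cls(lo=float(v.min()), hi=float(v.max()), n_bins=n_bins)


def _stats_chunk(w: np.ndarray, hist: HistogramSpec, cv_guard_abs: float) -> np.ndarray:
    n, k = w.shape
    out = np.empty((n, 12))

    mean = w.mean(axis=1)
    q25, med, q75, q90 = np.quantile(w, (0.25, 0.5, 0.75, 0.9), axis=1)

    d = w - mean[:, None]
    d2 = d * d
    m2 = d2.mean(axis=1)
    m3 = (d2 * d).mean(axis=1)
    m4 = (d2 * d2).mean(axis=1)
    ok = m2 > 0
    skew = np.zeros(n)
    kurt = np.zeros(n)
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    kurt[ok] = m4[ok] / (m2[ok] * m2[ok]) - 3.0

    sd = w.std(axis=1, ddof=1) if k > 1 else np.zeros(n)
    iqr = q75 - q25
    mad = np.median(np.abs(w - med[:, None]), axis=1)

    # last decile: values >= 90th percentile (never empty: the max qualifies)
    rows = np.arange(n)
    s_desc = np.sort(w, axis=1)[:, ::-1]
    cnt = (w >= q90[:, None]).sum(axis=1)
    mean90 = np.cumsum(s_desc, axis=1)[rows, cnt - 1] / cnt
    med90 = 0.5 * (s_desc[rows, (cnt - 1) // 2] + s_desc[rows, cnt // 2])

    span = hist.hi - hist.lo
    if span > 0:
        idx = np.floor((w - hist.lo) / span * hist.n_bins).astype(np.int64)
        np.clip(idx, 0, hist.n_bins - 1, out=idx)
    else:
        idx = np.zeros((n, k), dtype=np.int64)
    counts = np.zeros((n, hist.n_bins))
    np.add.at(counts, (rows[:, None], idx), 1.0)
    p = counts / k
    pos = p > 0
    ent = -np.where(pos, p * np.log2(np.where(pos, p, 1.0)), 0.0).sum(axis=1) + 0.0
    unif = (p * p).sum(axis=1)

    amean = np.abs(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(amean <= cv_guard_abs, 0.0, sd / np.where(amean > 0, amean, 1.0))

    for j, col in enumerate(
        (mean, med, kurt, skew, ent, unif, iqr, cv, sd, mad, mean90, med90)
    ):
        out[:, j] = col
    return out


def stats_batch(
    windows: np.ndarray,
    hist: HistogramSpec,
    cv_guard_abs: float = 0.0,
    chunk: int = 32768,
) -> np.ndarray:
    """Compute the 12 statistics for each row of ``windows``.

    Parameters
    ----------
    windows
        2D ``(n_windows, window_size)`` array of finite values.  Rows are
        independent; the result for a row does not depend on the others.
    hist
        Histogram span/bin-count used by entropy and uniformity.
    cv_guard_abs
        Absolute |mean| threshold below which CV is reported as 0.
    chunk
        Rows processed per pass (bounds peak memory on large batches).

    Returns
    -------
    ``(n_windows, 12)`` array, columns ordered as :data:`STAT_ORDER`.
    """
    w = np.ascontiguousarray(windows, dtype=float)
    if w.ndim != 2 or w.shape[1] < 1:
        raise ValueError("windows must be a 2D array with at least one column")
    if not np.all(np.isfinite(w)):
        raise ValueError("window values must be finite")
    n = w.shape[0]
    if n <= chunk:
        return _stats_chunk(w, hist, cv_guard_abs)
    out = np.empty((n, 12))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        out[start:stop] = _stats_chunk(w[start:stop], hist, cv_guard_abs)
    return out


def local_stats(
    values: np.ndarray,
    hist: HistogramSpec | None = None,
    *,
    n_bins: int = 16,
    cv_guard_eps: float = 1e-6,
) -> dict[LocalStat, float]:
    """The 12 first-order statistics of one value multiset.

    When ``hist`` is omitted the histogram spans the multiset's own
    min-max with ``n_bins`` bins, and the CV guard is
    ``cv_guard_eps * (hi - lo)``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("local_stats requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("local_stats requires finite values")
    if hist is None:
        hist = HistogramSpec.from_values(v, n_bins=n_bins)
    guard = cv_guard_eps * (hist.hi - hist.lo)
    row = stats_batch(v[None, :], hist, cv_guard_abs=guard)[0]
    return {stat: float(row[j]) for j, stat in enumerate(STAT_ORDER)}
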