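"""The eight EEG biomarker families and the subjects x features table.

Three families quantify slowing of the EEG (band power from the squared
FFT magnitude, the per-second amplitude change rate, and the
zero-crossing interval), four quantify loss of signal complexity
(Tsallis entropy, Higuchi fractal dimension, Lempel-Ziv complexity and
approximate entropy), and magnitude-squared coherence quantifies loss of
inter-channel functional connectivity.  Each method yields 25 features
per location: one per band plus 20 ordered band ratios, where a ratio
feature is the same method's value on the two band-filtered signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

from .io import EegRecord, band_filter_bank
from .montage import (
    BANDS,
    BAND_NAMES,
    BandDef,
    COHERENCE_METHOD,
    FeatureId,
    SINGLE_CHANNEL_METHODS,
    band_specs,
    channel_pairs,
)

logger = logging.getLogger(__name__)

try:  # optional JIT kernels; pure-Python fallbacks below
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _chebyshev_counts_sorted(emb: np.ndarray, r: float) -> np.ndarray:
    """Per-point neighbour counts (Chebyshev distance <= r, self included).

    ``emb`` must be sorted by its first column; the scan window on the
    first coordinate bounds the Chebyshev ball.
    """
    n, m = emb.shape
    counts = np.ones(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            if emb[j, 0] - emb[i, 0] > r:
                break
            ok = True
            for d in range(1, m):
                diff = emb[i, d] - emb[j, d]
                if diff > r or -diff > r:
                    ok = False
                    break
            if ok:
                counts[i] += 1
                counts[j] += 1
    return counts


#: Default Tsallis quantisation states and entropic index.
TSEN_K = 2200
TSEN_Q = 0.5
#: Default Higuchi maximum delay.
HFD_KMAX = 8
#: Default approximate-entropy run length and tolerance factor (times SD).
APEN_M = 2
APEN_R_FACTOR = 0.15
#: Welch settings for coherence: segment length in seconds and overlap.
WELCH_SEG_S = 2.0
WELCH_OVERLAP = 0.5


def tsallis_entropy(x: np.ndarray, k_states: int = TSEN_K, q: float = TSEN_Q) -> float:
    """Tsallis entropy of the amplitude distribution.

    Amplitudes are quantised into ``k_states`` equal-width bins spanning
    [min, max]; with bin probabilities ``P_i`` the entropy is
    ``sum(P_i - P_i**q) / (q - 1)``.  Empty bins contribute zero.  A
    constant signal occupies a single bin and scores 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if k_states < 2:
        raise ValueError("need at least 2 quantisation states")
    if q == 1:
        raise ValueError("q must differ from 1 (q=1 is the Shannon limit)")
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=k_states, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(np.sum(p - p**q) / (q - 1))


def higuchi_fd(x: np.ndarray, kmax: int = HFD_KMAX) -> float:
    """Higuchi fractal dimension of a time series.

    For each delay ``k`` the mean normalised curve length ``L(k)`` over
    the ``k`` subseries offsets is computed; since ``L(k) ~ k**-D`` the
    dimension is the negative slope of the least-squares fit of
    ``ln L(k)`` on ``ln k``.  Smooth curves score near 1, uncorrelated
    noise near 2.  A constant signal has zero curve length everywhere and
    scores 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * kmax:
        raise ValueError(f"need at least 2*kmax={2 * kmax} samples, got {n}")
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            sub = x[m::k]
            if sub.size < 2:
                continue
            nseg = sub.size - 1
            norm = (n - 1) / (nseg * k)
            lengths.append(np.abs(np.diff(sub)).sum() * norm / k)
        lk[k - 1] = np.mean(lengths)
    if np.all(lk == 0):
        logger.info("constant signal: Higuchi curve length zero, returning 1.0")
        return 1.0
    kk = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(kk), np.log(lk), 1)[0]
    return float(-slope)


def higuchi_curve_length_mean(x: np.ndarray, kmax: int = HFD_KMAX) -> float:
    """Mean of the Higuchi curve lengths L(k) over k (no log-log fit).

    A literal curve-length average exposed for comparison with the
    canonical slope estimator; not used by the default pipeline.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2 * kmax:
        raise ValueError(f"need at least 2*kmax={2 * kmax} samples, got {n}")
    lk = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            sub = x[m::k]
            if sub.size < 2:
                continue
            nseg = sub.size - 1
            norm = (n - 1) / (nseg * k)
            lengths.append(np.abs(np.diff(sub)).sum() * norm / k)
        lk.append(np.mean(lengths))
    return float(np.mean(lk))


def _lz76_phrase_count(bits: np.ndarray) -> int:
    """Number of phrases in the Lempel-Ziv (1976) exhaustive history.

    Scans left to right; a phrase closes when extending it by the next
    symbol produces a word that does not occur in the sequence read so
    far (Kaspar-Schuster formulation).
    """
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    c = 1
    i = 1  # start of current phrase
    while i < n:
        j = i
        # grow the phrase while s[i:j+1] occurs in s[:j]
        while j < n and s[i:j + 1] in s[:j]:
            j += 1
        c += 1
        i = j + 1 if j < n else n
    return c


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalised Lempel-Ziv complexity of the median-binarised signal.

    The signal is binarised at its median (values >= median map to 1),
    the exhaustive-history phrase count ``c(N)`` is computed, and
    normalised by its random-sequence upper bound ``N / log2(N)``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    bits = x >= np.median(x)
    c = _lz76_phrase_count(bits)
    return float(c / (n / np.log2(n)))


def lempel_ziv_phrase_count(bits) -> int:
    """Exhaustive-history phrase count of an already-binarised sequence."""
    return _lz76_phrase_count(np.asarray([int(b) for b in bits], dtype=bool))


def approximate_entropy(x: np.ndarray, m: int = APEN_M,
                        r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) with self-matches included.

    Template vectors of lengths ``m`` and ``m+1`` are compared under the
    Chebyshev (maximum) distance; ``phi_m`` is the mean log fraction of
    templates within tolerance ``r`` and ApEn is ``phi_m - phi_{m+1}``.
    Default tolerance is ``0.15 * SD(x)``.  Neighbour counting uses a
    k-d tree, equivalent to the quadratic double loop.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples")
    if r is None:
        r = APEN_R_FACTOR * float(np.std(x))
    if r <= 0:
        # a constant signal has SD 0: every template matches every other
        if np.ptp(x) == 0:
            return 0.0
        raise ValueError("tolerance r must be positive")

    def phi(mm: int) -> float:
        emb = sliding_window_view(x, mm)
        if HAVE_NUMBA:
            order = np.argsort(emb[:, 0], kind="stable")
            counts = _chebyshev_counts_sorted(
                np.ascontiguousarray(emb[order]), r)
        else:
            counts = cKDTree(emb).query_ball_point(emb, r, p=np.inf,
                                                   return_length=True)
        return float(np.mean(np.log(counts / (n - mm + 1))))

    return phi(m) - phi(m + 1)


def zero_crossing_interval(x: np.ndarray, fs: float) -> float:
    """Mean time between successive positive-to-negative zero crossings.

    A crossing occurs at sample ``t`` when ``x[t] > 0`` and
    ``x[t+1] < 0`` (both strict: exact zeros neither open nor close a
    crossing).  Longer intervals indicate a slower dominant rhythm.
    Returns NaN when fewer than two crossings exist.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    t = np.flatnonzero((x[:-1] > 0) & (x[1:] < 0))
    if t.size < 2:
        logger.info("fewer than 2 zero crossings; interval undefined")
        return float("nan")
    return float((t[-1] - t[0]) / (t.size - 1) / fs)


def amplitude_change_rate(x: np.ndarray, fs: float) -> float:
    """Mean per-second EEG amplitude change rate in microvolts/second.

    The sample-to-sample differences are partitioned into complete
    one-second blocks of ``fs`` differences each; in each block the
    summed differences are divided by the summed sample intervals (one
    second), and the block rates are averaged.  The signed sum
    telescopes, so each block rate is the amplitude drift across that
    second; a trailing partial block is dropped.
    """
    x = np.asarray(x, dtype=float)
    fs_i = int(round(fs))
    k = (x.size - 1) // fs_i  # complete blocks of fs differences
    if k < 1:
        raise ValueError("need at least one full second of differences")
    ends = x[np.arange(k + 1) * fs_i]
    return float(np.mean(np.diff(ends)))  # dt sum per block is exactly 1 s


def band_power(x: np.ndarray, fs: float, band: BandDef | str) -> float:
    """Mean power spectral mass in a band, from the squared FFT magnitude.

    Power is ``|FFT(x)|**2 / N`` over positive frequencies, averaged
    over the bins with frequency in ``[lo, hi)``; units microvolts^2.
    """
    if isinstance(band, str):
        lo, hi = BANDS[band]
        band = BandDef(band, lo, hi)
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not mask.any():
        raise ValueError(f"no FFT bins inside {band.lo}-{band.hi} Hz")
    return float(spec[mask].mean())


def _welch_segments(x: np.ndarray, fs: float) -> np.ndarray:
    """Hann-windowed FFT segments (n_seg x n_freq) for Welch estimates."""
    nper = int(round(WELCH_SEG_S * fs))
    step = int(round(nper * (1 - WELCH_OVERLAP)))
    n = x.size
    if n < nper:
        raise ValueError(f"need at least {WELCH_SEG_S} s of data")
    starts = range(0, n - nper + 1, step)
    win = np.hanning(nper)
    segs = np.stack([x[s:s + nper] * win for s in starts])
    segs = segs - segs.mean(axis=1, keepdims=True)
    return np.fft.rfft(segs, axis=1)


def msc_coherence(a: np.ndarray, b: np.ndarray, fs: float,
                  band: BandDef | str) -> float:
    """Band-averaged magnitude-squared coherence of two channels.

    Welch cross- and auto-spectra (2 s Hann segments, 50% overlap) give
    ``|P_ab|**2 / (P_aa * P_bb)`` per frequency; the value returned is
    the mean over frequencies in the band and lies in [0, 1].
    """
    if isinstance(band, str):
        lo, hi = BANDS[band]
        band = BandDef(band, lo, hi)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("channels must have equal length")
    if a.size < 4 * fs:
        raise ValueError("need at least 4 s of data for Welch coherence")
    fa = _welch_segments(a, fs)
    fb = _welch_segments(b, fs)
    msc = _msc_from_segments(fa, fb)
    freqs = np.fft.rfftfreq(int(round(WELCH_SEG_S * fs)), d=1 / fs)
    lo_edge = max(band.lo, freqs[1])  # skip the DC bin
    mask = (freqs >= lo_edge) & (freqs < band.hi)
    return float(msc[mask].mean())


def _msc_from_segments(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    pab = (fa * np.conj(fb)).mean(axis=0)
    paa = (np.abs(fa) ** 2).mean(axis=0)
    pbb = (np.abs(fb) ** 2).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(pab) ** 2 / (paa * pbb)


def ratio_feature(value_num: float, value_den: float) -> float:
    """Ordered band-ratio feature: numerator / denominator band value.

    Non-finite inputs or a near-zero denominator yield NaN, which the
    table assembly flags and excludes downstream.
    """
    if not (np.isfinite(value_num) and np.isfinite(value_den)):
        return float("nan")
    if abs(value_den) < 1e-12:
        return float("nan")
    return float(value_num / value_den)


@dataclass
class FeatureConfig:
    """Tunable method parameters for feature extraction."""

    tsen_k: int = TSEN_K
    tsen_q: float = TSEN_Q
    hfd_kmax: int = HFD_KMAX
    apen_m: int = APEN_M
    apen_r_factor: float = APEN_R_FACTOR
    band_power_sum: bool = False  # report band power as sum instead of mean


@dataclass
class BiomarkerTable:
    """Subjects x features biomarker matrix with group labels.

    ``values`` is a DataFrame indexed by subject id whose columns are
    :class:`FeatureId` column strings; ``groups`` maps subject id to
    group label.  ``exclusions`` records (subject, column, reason) for
    non-finite cells, which are stored as NaN.
    """

    values: pd.DataFrame
    groups: pd.Series
    meta: dict = field(default_factory=dict)
    exclusions: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise ValueError("feature columns must be unique")
        self.groups = self.groups.reindex(self.values.index)

    @property
    def feature_ids(self) -> list[FeatureId]:
        return [FeatureId.from_column(c) for c in self.values.columns]

    def subset(self, columns: list[str]) -> "BiomarkerTable":
        missing = [c for c in columns if c not in self.values.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        return BiomarkerTable(self.values[columns].copy(), self.groups.copy(),
                              dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiomarkerTable":
        df = pd.read_csv(path, index_col="subject_id")
        groups = df.pop("group")
        return cls(df, groups)


def _single_channel_value(method: str, band_sig: np.ndarray, fs: float,
                          cfg: FeatureConfig, raw_sig: np.ndarray,
                          band: str) -> float:
    if method == "APEN":
        return approximate_entropy(band_sig, cfg.apen_m,
                                   cfg.apen_r_factor * float(np.std(band_sig))
                                   if np.std(band_sig) > 0 else None)
    if method == "LZC":
        return lempel_ziv_complexity(band_sig)
    if method == "HFD":
        return higuchi_fd(band_sig, cfg.hfd_kmax)
    if method == "TSEN":
        return tsallis_entropy(band_sig, cfg.tsen_k, cfg.tsen_q)
    if method == "DPS":
        v = band_power(raw_sig, fs, band)
        if cfg.band_power_sum:
            lo, hi = BANDS[band]
            n = raw_sig.size
            freqs = np.fft.rfftfreq(n, d=1 / fs)
            v *= int(((freqs >= lo) & (freqs < hi)).sum())
        return v
    if method == "DEEGA":
        return amplitude_change_rate(band_sig, fs)
    if method == "ZCI":
        return zero_crossing_interval(band_sig, fs)
    raise ValueError(f"unknown method {method}")


def extract_record(record: EegRecord, cfg: FeatureConfig | None = None
                   ) -> dict[str, float]:
    """All biomarker values for one record, keyed by feature column name."""
    cfg = cfg or FeatureConfig()
    bank = band_filter_bank(record)
    fs = record.fs
    values: dict[str, float] = {}

    # per-channel, per-band base values for the seven single-channel methods
    base: dict[tuple[str, str, str], float] = {}
    for ci, ch in enumerate(record.channels):
        raw_sig = record.data[ci]
        for bname in BAND_NAMES:
            band_sig = bank[bname].data[ci]
            for method in SINGLE_CHANNEL_METHODS:
                try:
                    v = _single_channel_value(method, band_sig, fs, cfg,
                                              raw_sig, bname)
                except ValueError:
                    v = float("nan")
                base[(method, bname, ch)] = v
                values[FeatureId(method, bname, ch).column] = v
    for method in SINGLE_CHANNEL_METHODS:
        for num in BAND_NAMES:
            for den in BAND_NAMES:
                if num == den:
                    continue
                for ch in record.channels:
                    col = FeatureId(method, f"{num}/{den}", ch).column
                    values[col] = ratio_feature(base[(method, num, ch)],
                                                base[(method, den, ch)])

    # coherence: Welch segments once per channel, then all pairs
    if len(record.channels) >= 2 and record.n_samples >= 4 * fs:
        segs = {ch: _welch_segments(record.data[ci], fs)
                for ci, ch in enumerate(record.channels)}
        freqs = np.fft.rfftfreq(int(round(WELCH_SEG_S * fs)), d=1 / fs)
        cbase: dict[tuple[str, str], float] = {}
        for a, b in channel_pairs(tuple(record.channels)):
            msc = _msc_from_segments(segs[a], segs[b])
            loc = f"{a}-{b}"
            for bname in BAND_NAMES:
                lo, hi = BANDS[bname]
                mask = (freqs >= max(lo, freqs[1])) & (freqs < hi)
                v = float(msc[mask].mean())
                cbase[(bname, loc)] = v
                values[FeatureId(COHERENCE_METHOD, bname, loc).column] = v
            for num in BAND_NAMES:
                for den in BAND_NAMES:
                    if num == den:
                        continue
                    col = FeatureId(COHERENCE_METHOD, f"{num}/{den}", loc).column
                    values[col] = ratio_feature(cbase[(num, loc)],
                                                cbase[(den, loc)])
    return values


def extract_all(records: list[EegRecord], cfg: FeatureConfig | None = None
                ) -> BiomarkerTable:
    """Assemble the subjects x features biomarker table for a cohort.

    For ``C`` montage channels this yields ``7*25*C`` single-channel
    columns plus ``25*C*(C-1)/2`` coherence columns (7600 for the full
    19-channel montage).  Non-finite values are kept as NaN and logged in
    the table's exclusion list.
    """
    cfg = cfg or FeatureConfig()
    if not records:
        return BiomarkerTable(pd.DataFrame(), pd.Series(dtype=object),
                              {"n_records": 0})
    fs0 = records[0].fs
    chans0 = set(records[0].channels)
    for r in records[1:]:
        if r.fs != fs0 or set(r.channels) != chans0:
            raise ValueError("all records must share sampling rate and montage")
    rows = []
    exclusions: list[tuple[str, str, str]] = []
    for rec in records:
        vals = extract_record(rec, cfg)
        for col, v in vals.items():
            if not np.isfinite(v):
                exclusions.append((rec.subject_id, col, "non-finite value"))
        rows.append(pd.Series(vals, name=rec.subject_id))
    values = pd.DataFrame(rows)
    groups = pd.Series({r.subject_id: r.group for r in records})
    if exclusions:
        logger.warning("%d non-finite biomarker cells excluded", len(exclusions))
    meta = {
        "n_records": len(records),
        "fs": fs0,
        "bands": dict(BANDS),
        "feature_config": vars(cfg).copy(),
    }
    return BiomarkerTable(values, groups, meta, exclusions)
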