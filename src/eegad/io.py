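"""Reading, validation and band filtering of multichannel EEG records.

Records hold channels x samples amplitude matrices in microvolts together
with the sampling rate, montage labels and the subject's group (AD patient
or normal elderly control).  Inputs are EDF files or delimited numeric
matrices; preprocessing covers pair-average downsampling (e.g. 256 Hz to
128 Hz), trimming to a fixed analysis interval, and zero-phase
Chebyshev-II band filtering into the five classical bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import cheby2, sosfiltfilt

from .montage import BANDS, BandDef, normalize_label

logger = logging.getLogger(__name__)

GROUP_AD = "AD"
GROUP_NOLD = "NOLD"
GROUP_UNKNOWN = "UNKNOWN"
GROUPS = (GROUP_AD, GROUP_NOLD, GROUP_UNKNOWN)

#: Default artefact-avoidance analysis window, seconds.
DEFAULT_TRIM = (61.0, 240.0)

#: Chebyshev-II design: filter order and stopband attenuation in dB,
#: applied forward-backward for zero phase.
FILTER_ORDER = 8
STOPBAND_DB = 40.0
#: Stopband edges are placed this factor outside the nominal band edges so
#: that the band boundary sits in the transition rather than 40 dB down;
#: without it the filter bank notches out every band boundary.
TRANSITION_RATIO = 1.05
#: The delta band's nominal 0 Hz low edge is clamped here: DC carries no
#: neural signal and would otherwise dominate the band.
DELTA_LOW_HZ = 0.5


@dataclass
class EegRecord:
    """One subject's multichannel EEG.

    ``data`` is channels x samples in microvolts; ``channels`` are unique
    10-20 montage labels, one per row.
    """

    subject_id: str
    group: str
    fs: float
    channels: list[str]
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[1] < 2:
            raise ValueError("record must hold at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]


def read_edf(path: str | Path, group: str = GROUP_UNKNOWN,
             subject_id: str | None = None) -> EegRecord:
    """Read an EDF file into an :class:`EegRecord`.

    Channel labels are matched onto the 10-20 montage case-insensitively,
    stripping reference suffixes (``T3-A1`` style); channels outside the
    montage are dropped with a warning.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    keep_idx: list[int] = []
    labels: list[str] = []
    dropped: list[str] = []
    for i, name in enumerate(raw.ch_names):
        label = normalize_label(name)
        if label is None or label in labels:
            dropped.append(name)
        else:
            keep_idx.append(i)
            labels.append(label)
    if not labels:
        raise ValueError(f"{path}: no 10-20 montage channels among {raw.ch_names}")
    if dropped:
        logger.warning("%s: dropped non-montage channels %s", path.name, dropped)
    data = raw.get_data(picks=keep_idx) * 1e6  # volts -> microvolts
    if data.shape[1] < 2 * raw.info["sfreq"]:
        raise ValueError(f"{path}: record shorter than 2 seconds")
    return EegRecord(
        subject_id=subject_id or path.stem,
        group=group,
        fs=float(raw.info["sfreq"]),
        channels=labels,
        data=data,
        meta={"source": str(path), "format": "edf"},
    )


def read_matrix(path: str | Path, fs: float, labels: list[str],
                group: str = GROUP_UNKNOWN, subject_id: str | None = None,
                delimiter: str = ",") -> EegRecord:
    """Read a delimited channels x samples text matrix (microvolts)."""
    path = Path(path)
    try:
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix: {exc}") from exc
    if data.shape[0] != len(labels):
        raise ValueError(
            f"{path}: {data.shape[0]} rows but {len(labels)} channel labels"
        )
    if data.shape[1] < 2 * fs:
        raise ValueError(f"{path}: record shorter than 2 seconds")
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-finite value at row {r}, column {c} "
            f"({bad.shape[0]} bad cells in total)"
        )
    return EegRecord(
        subject_id=subject_id or path.stem,
        group=group,
        fs=fs,
        channels=list(labels),
        data=data,
        meta={"source": str(path), "format": "matrix"},
    )


def downsample_pair_average(record: EegRecord) -> EegRecord:
    """Halve the sampling rate by averaging consecutive sample pairs.

    Output sample ``t`` is the mean of input samples ``2t`` and ``2t+1``;
    an odd trailing sample is dropped with a warning.
    """
    n = record.n_samples
    if n % 2:
        logger.warning("%s: odd sample count %d, dropping trailing sample",
                       record.subject_id, n)
        n -= 1
    data = record.data[:, :n].reshape(record.data.shape[0], n // 2, 2).mean(axis=2)
    return replace(record, fs=record.fs / 2, data=data,
                   meta={**record.meta, "downsampled_from_hz": record.fs})


def trim_interval(record: EegRecord, start_s: float | None = None,
                  end_s: float | None = None) -> EegRecord:
    """Keep the half-open interval ``[start_s, end_s)`` seconds.

    With no arguments the default 61-240 s artefact-avoidance window is
    applied when the record is long enough; shorter records are returned
    unchanged with a note (short clinical records are analysed in full).
    """
    if start_s is None and end_s is None:
        start_s, end_s = DEFAULT_TRIM
        if record.duration < end_s:
            logger.warning(
                "%s: %.0f s record shorter than default %s s window, using full record",
                record.subject_id, record.duration, DEFAULT_TRIM,
            )
            return record
    if start_s is None or end_s is None:
        raise ValueError("give both start_s and end_s, or neither")
    if not 0 <= start_s < end_s:
        raise ValueError(f"need 0 <= start < end, got {start_s}..{end_s}")
    if end_s > record.duration + 0.5 / record.fs:
        raise ValueError(f"end {end_s}s beyond record duration {record.duration}s")
    i0 = int(round(start_s * record.fs))
    i1 = int(round(end_s * record.fs))
    return replace(record, data=record.data[:, i0:i1],
                   meta={**record.meta, "trim_s": (start_s, end_s)})


def _design_band_sos(band: BandDef, fs: float) -> np.ndarray:
    lo = max(band.lo, DELTA_LOW_HZ)
    hi = band.hi
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {fs / 2} Hz")
    ws = [lo / TRANSITION_RATIO, min(hi * TRANSITION_RATIO, 0.999 * fs / 2)]
    return cheby2(FILTER_ORDER, STOPBAND_DB, ws, btype="bandpass",
                  fs=fs, output="sos")


def band_filter(record: EegRecord, band: BandDef | str) -> EegRecord:
    """Zero-phase Chebyshev-II band-pass copy of a record."""
    if isinstance(band, str):
        lo, hi = BANDS[band]
        band = BandDef(band, lo, hi)
    sos = _design_band_sos(band, record.fs)
    data = sosfiltfilt(sos, record.data, axis=1)
    return replace(record, data=data, meta={**record.meta, "band": band.name})


def band_filter_bank(record: EegRecord) -> dict[str, EegRecord]:
    """All five band-filtered copies of a record, keyed by band name."""
    return {name: band_filter(record, name) for name in BANDS}
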