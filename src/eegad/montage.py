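"""Electrode montage, frequency bands and feature addressing.

The package works on the 19 scalp electrodes of the international 10-20
system and the five classical EEG frequency bands.  Every scalar biomarker
is addressed by a :class:`FeatureId`: the analysis method, a band
specification (a single band or an ordered band ratio such as
``theta/alpha``), and a location (one channel, or one unordered channel
pair for coherence).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterator

#: The 19 channels of the 10-20 montage, in the conventional order.
MONTAGE_19: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "FZ", "F4", "F8",
    "T3", "C3", "CZ", "C4", "T4",
    "T5", "P3", "PZ", "P4", "T6",
    "O1", "O2",
)

_MONTAGE_UPPER = {c.upper(): c for c in MONTAGE_19}

# Modern 10-10 names for the temporal electrodes map onto the classical set.
_LABEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: Band edges in Hz.  Delta nominally starts at 0 Hz; the filtering stage
#: clamps its low edge to 0.5 Hz to reject DC drift.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Analysis method codes: approximate entropy, Lempel-Ziv complexity,
#: Higuchi fractal dimension, Tsallis entropy, band power (spectral
#: slowing), amplitude change rate, zero-crossing interval, and
#: magnitude-squared coherence.
SINGLE_CHANNEL_METHODS: tuple[str, ...] = (
    "APEN", "LZC", "HFD", "TSEN", "DPS", "DEEGA", "ZCI",
)
COHERENCE_METHOD = "COH"
ALL_METHODS: tuple[str, ...] = SINGLE_CHANNEL_METHODS + (COHERENCE_METHOD,)


@dataclass(frozen=True)
class BandDef:
    """One frequency band: a name and its edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"invalid band edges {self.lo}..{self.hi}")


def band_def(name: str) -> BandDef:
    lo, hi = BANDS[name]
    return BandDef(name, lo, hi)


def band_specs() -> list[str]:
    """The 25 band specifications: 5 bands plus 20 ordered ratios.

    Ordered ratios are distinct features (``theta/alpha`` is not
    ``alpha/theta``); they are enumerated by (numerator, denominator) in
    canonical band order.
    """
    specs = list(BAND_NAMES)
    for num in BAND_NAMES:
        for den in BAND_NAMES:
            if num != den:
                specs.append(f"{num}/{den}")
    return specs


def normalize_label(raw: str) -> str | None:
    """Map an electrode label onto the 19-channel montage.

    Case-insensitive; strips an ``-A1``/``-REF`` style reference suffix and
    an ``EEG `` prefix; accepts the T7/T8/P7/P8 dialect for the temporal
    channels.  Returns ``None`` for labels outside the montage.
    """
    label = raw.strip()
    label = re.sub(r"^EEG[ _]*", "", label, flags=re.IGNORECASE)
    label = re.split(r"[-_ ]", label)[0]
    label = label.upper()
    label = _LABEL_ALIASES.get(label, label)
    if label in _MONTAGE_UPPER:
        return _MONTAGE_UPPER[label]
    # Fp1/Fp2 arrive as FP1/FP2 after upper-casing
    return None


def channel_pairs(channels: tuple[str, ...] | list[str] = MONTAGE_19) -> list[tuple[str, str]]:
    """All unordered channel pairs, in montage order (171 for 19 channels)."""
    return list(itertools.combinations(channels, 2))


@dataclass(frozen=True, order=True)
class FeatureId:
    """Address of one scalar biomarker.

    Parameters
    ----------
    method : str
        One of :data:`ALL_METHODS`.
    band_spec : str
        A band name (``"alpha"``) or an ordered ratio (``"theta/alpha"``).
    location : str
        A channel label, or ``"F4-T4"`` style pair for coherence.
    """

    method: str
    band_spec: str
    location: str

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.band_spec not in band_specs():
            raise ValueError(f"unknown band spec {self.band_spec!r}")
        is_pair = "-" in self.location
        if (self.method == COHERENCE_METHOD) != is_pair:
            raise ValueError(
                "pair locations are used exactly for coherence features: "
                f"{self.method} at {self.location!r}"
            )

    @property
    def column(self) -> str:
        """Column name, e.g. ``TSEN_theta-alpha_T6`` or ``COH_alpha_F4-T4``."""
        return f"{self.method}_{self.band_spec.replace('/', '-')}_{self.location}"

    @classmethod
    def from_column(cls, column: str) -> "FeatureId":
        method, spec, location = column.split("_", 2)
        if spec not in BAND_NAMES:
            spec = spec.replace("-", "/", 1)
        return cls(method, spec, location)

    @property
    def channels(self) -> tuple[str, ...]:
        """The channel(s) this feature is computed from."""
        return tuple(self.location.split("-"))


def iter_feature_ids(channels: list[str] | tuple[str, ...]) -> Iterator[FeatureId]:
    """Enumerate all feature ids for a montage subset, in canonical order.

    For ``C`` channels there are ``7*25*C`` single-channel features and
    ``25*C*(C-1)/2`` coherence features.
    """
    specs = band_specs()
    for method in SINGLE_CHANNEL_METHODS:
        for spec in specs:
            for ch in channels:
                yield FeatureId(method, spec, ch)
    for spec in specs:
        for a, b in channel_pairs(tuple(channels)):
            yield FeatureId(COHERENCE_METHOD, spec, f"{a}-{b}")


def feature_count(n_channels: int) -> int:
    """Closed-form feature count for a montage subset."""
    return 7 * 25 * n_channels + 25 * n_channels * (n_channels - 1) // 2
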