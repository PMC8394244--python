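"""Exhaustive enumeration of biomarker panels.

Stage 1 combines one selected band feature of one method with every
combination (sizes 1..10) of the selected channels or channel pairs;
with the default selection (11 features, 12 channels, 10 coherence
pairs) this yields 44,902 panels per single-channel method and 325,567
panels in total.  Stage 2 mixes individual biomarkers across methods
into panels of up to four features (919,310 panels from 69 biomarkers).
Enumeration is lazy and deterministic: panels stream smallest-first,
then in lexicographic item order, so compliant panels with the fewest
locations are met first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Iterator, Sequence

from .montage import COHERENCE_METHOD, FeatureId, SINGLE_CHANNEL_METHODS

STAGE1_MAX_LEN = 10
STAGE2_MAX_SIZE = 4


@dataclass(frozen=True)
class PanelSpec:
    """One biomarker panel: an ordered tuple of feature ids.

    Stage-1 panels are homogeneous in method and band spec (one feature
    over a channel combination); stage-2 panels mix arbitrary features.
    """

    features: tuple[FeatureId, ...]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("panel must contain at least one feature")
        if len(set(self.features)) != len(self.features):
            raise ValueError("panel features must be unique")

    @property
    def size(self) -> int:
        return len(self.features)

    @property
    def panel_id(self) -> str:
        return "+".join(f.column for f in self.features)

    @property
    def columns(self) -> list[str]:
        return [f.column for f in self.features]

    @classmethod
    def stage1(cls, method: str, band_spec: str,
               locations: Sequence[str]) -> "PanelSpec":
        return cls(tuple(FeatureId(method, band_spec, loc)
                         for loc in locations))


def combination_count(n_items: int, min_len: int, max_len: int) -> int:
    """Closed-form count of subsets with sizes in [min_len, max_len]."""
    max_len = min(max_len, n_items)
    if min_len > max_len:
        return 0
    return sum(comb(n_items, k) for k in range(min_len, max_len + 1))


def enumerate_combinations(items: Sequence, min_len: int = 1,
                           max_len: int = STAGE1_MAX_LEN
                           ) -> Iterator[tuple]:
    """Lazily yield subsets, smallest size first, lexicographic within size."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    max_len = min(max_len, len(items))
    for k in range(min_len, max_len + 1):
        yield from itertools.combinations(items, k)


def stage1_counts(n_features: int, n_channels: int, n_pairs: int,
                  max_len: int = STAGE1_MAX_LEN) -> dict[str, int]:
    """Closed-form stage-1 panel counts.

    Per single-channel method: features x channel combinations; for
    coherence: features x pair combinations.  The default selection
    gives 11 x 4082 = 44,902 per method and 325,567 overall.
    """
    chan_combos = combination_count(n_channels, 1, max_len)
    pair_combos = combination_count(n_pairs, 1, max_len)
    per_method = n_features * chan_combos
    coh = n_features * pair_combos
    return {
        "channel_combinations": chan_combos,
        "pair_combinations": pair_combos,
        "per_single_channel_method": per_method,
        "coherence_panels": coh,
        "total": len(SINGLE_CHANNEL_METHODS) * per_method + coh,
    }


def build_stage1_panels(selected_features: Sequence[str],
                        selected_channels: Sequence[str],
                        selected_pairs: Sequence[str] = (),
                        max_len: int = STAGE1_MAX_LEN,
                        methods: Sequence[str] = SINGLE_CHANNEL_METHODS,
                        ) -> Iterator[PanelSpec]:
    """Stream all stage-1 panels.

    Panels are ordered by channel-combination size first (fewest channels
    preferred downstream), then by method, band feature and location
    order.
    """
    for k in range(1, min(max_len, len(selected_channels)) + 1):
        for combo in itertools.combinations(selected_channels, k):
            for method in methods:
                for spec in selected_features:
                    yield PanelSpec.stage1(method, spec, combo)
    for k in range(1, min(max_len, len(selected_pairs)) + 1):
        for combo in itertools.combinations(selected_pairs, k):
            for spec in selected_features:
                yield PanelSpec.stage1(COHERENCE_METHOD, spec, combo)


def stage2_counts(n_biomarkers: int,
                  max_size: int = STAGE2_MAX_SIZE) -> dict[int | str, int]:
    """Closed-form stage-2 counts per panel size plus the total."""
    out: dict[int | str, int] = {k: comb(n_biomarkers, k)
                                 for k in range(1, max_size + 1)}
    out["total"] = sum(v for k, v in out.items() if k != "total")
    return out


def build_stage2_panels(biomarkers: Sequence[FeatureId],
                        max_size: int = STAGE2_MAX_SIZE
                        ) -> Iterator[PanelSpec]:
    """Stream all cross-method panels of size 1..max_size, smallest first."""
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    for combo in enumerate_combinations(list(biomarkers), 1, max_size):
        yield PanelSpec(tuple(combo))


def panel_audit(selected_features: Sequence[str],
                selected_channels: Sequence[str],
                selected_pairs: Sequence[str],
                stage2_biomarkers: int | None = None,
                max_len: int = STAGE1_MAX_LEN,
                max_size: int = STAGE2_MAX_SIZE) -> dict:
    """Counts audit for both enumeration stages (closed form)."""
    audit = {"stage1": stage1_counts(len(selected_features),
                                     len(selected_channels),
                                     len(selected_pairs), max_len)}
    if stage2_biomarkers is not None:
        audit["stage2"] = {str(k): v for k, v in
                           stage2_counts(stage2_biomarkers, max_size).items()}
    return audit
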