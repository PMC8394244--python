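"""Synthetic AD / control EEG cohorts with controllable disease effects.

Real dementia EEG shows three robust signatures relative to healthy
ageing: spectral slowing (power moves from alpha into theta/delta),
reduced signal complexity, and reduced inter-channel coherence.  The
generator plants each signature independently:

* every channel is a weighted sum of band-limited Gaussian noise, one
  independent component per band plus one band-limited source shared by
  all channels (which creates inter-channel coherence);
* ``slowing_effect`` moves a fraction of the AD group's alpha weight
  into theta (60%) and delta (40%);
* ``complexity_effect`` raises an order-1 autoregressive smoothing
  coefficient for AD subjects, suppressing high-frequency detail and so
  lowering Lempel-Ziv, approximate-entropy and fractal-dimension values;
* ``coherence_effect`` shrinks the AD shared-source mixing weight.

With all effects at zero the two groups are draws from the identical
distribution.  Subject streams are derived from (seed, group, index), so
cohorts are reproducible and extensible without reshuffling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter

from .io import EegRecord, GROUP_AD, GROUP_NOLD, _design_band_sos
from .montage import BANDS, BAND_NAMES, BandDef, MONTAGE_19

#: Resting-state control band weights (relative RMS amplitude per band):
#: alpha-dominant occipital-style spectrum.
DEFAULT_BAND_WEIGHTS = {
    "delta": 0.7, "theta": 0.8, "alpha": 1.5, "beta": 0.6, "gamma": 0.3,
}
#: Microvolt scale of one weight unit.
AMPLITUDE_UV = 10.0


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Effects are non-negative; all-zero effects make AD and control
    subjects exchangeable.  ``shared_weight`` is the control-group mixing
    weight of the channel-shared source (per band), relative to each
    channel's own component.
    """

    n_ad: int = 20
    n_nold: int = 20
    fs: float = 128.0
    duration: float = 60.0
    channels: tuple[str, ...] = MONTAGE_19
    band_weights: dict = field(default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS))
    slowing_effect: float = 0.3
    complexity_effect: float = 0.35
    coherence_effect: float = 0.5
    shared_weight: float = 1.0
    ar_base: float = 0.2
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.slowing_effect, self.complexity_effect,
               self.coherence_effect) < 0:
            raise ValueError("effects must be non-negative")
        if not any(v > 0 for v in self.band_weights.values()):
            raise ValueError("band weights must not be all zero")
        if any(v < 0 for v in self.band_weights.values()):
            raise ValueError("band weights must be non-negative")
        if not 0 <= self.ar_base + self.complexity_effect < 1:
            raise ValueError("AR coefficient (ar_base + complexity_effect) "
                             "must stay below 1")

    def group_band_weights(self, group: str) -> dict[str, float]:
        """Band weights for one group; AD weights embody the slowing shift."""
        w = dict(self.band_weights)
        if group == GROUP_AD and self.slowing_effect > 0:
            moved = min(self.slowing_effect, 1.0) * w["alpha"]
            w["alpha"] -= moved
            w["theta"] += 0.6 * moved
            w["delta"] += 0.4 * moved
        return w

    def group_ar(self, group: str) -> float:
        return self.ar_base + (self.complexity_effect if group == GROUP_AD
                               else 0.0)

    def group_mixing(self, group: str) -> float:
        if group == GROUP_AD:
            return self.shared_weight * max(0.0, 1.0 - self.coherence_effect)
        return self.shared_weight

    def truth(self) -> dict:
        """Planted-effect metadata for recovery tests."""
        return {
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict(self).items()},
            "expected_directions": {
                "theta_alpha_power_ratio": "AD > control" if
                    self.slowing_effect > 0 else "none",
                "complexity": "AD < control" if self.complexity_effect > 0
                    else "none",
                "coherence": "AD < control" if self.coherence_effect > 0
                    else "none",
            },
        }


def _band_noise(rng: np.random.Generator, band: str, n: int,
                fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise confined to one band."""
    lo, hi = BANDS[band]
    from scipy.signal import sosfiltfilt

    sos = _design_band_sos(BandDef(band, lo, hi), fs)
    x = sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject(spec: CohortSpec, group: str, index: int) -> EegRecord:
    """One synthetic subject, deterministic under (seed, group, index)."""
    if group not in (GROUP_AD, GROUP_NOLD):
        raise ValueError(f"group must be {GROUP_AD} or {GROUP_NOLD}")
    gcode = 0 if group == GROUP_AD else 1
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(gcode, index))
    rng = np.random.default_rng(ss)
    n = int(round(spec.duration * spec.fs))
    weights = spec.group_band_weights(group)
    mix = spec.group_mixing(group)
    a = spec.group_ar(group)

    shared = {b: _band_noise(rng, b, n, spec.fs) for b in BAND_NAMES}
    data = np.empty((len(spec.channels), n))
    for ci in range(len(spec.channels)):
        sig = np.zeros(n)
        for b in BAND_NAMES:
            own = _band_noise(rng, b, n, spec.fs)
            sig += weights[b] * AMPLITUDE_UV * (own + mix * shared[b])
        # AR(1) smoothing: y[t] = a*y[t-1] + x[t]
        sig = lfilter([1.0], [1.0, -a], sig)
        sig += spec.noise_sd * rng.standard_normal(n)
        data[ci] = sig
    return EegRecord(
        subject_id=f"{group}{index:03d}",
        group=group,
        fs=spec.fs,
        channels=list(spec.channels),
        data=data,
        meta={"synthetic": True, "seed": spec.seed, "index": index},
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[EegRecord], dict]:
    """All subjects of a cohort plus the planted-effect truth metadata."""
    records = [generate_subject(spec, GROUP_AD, i) for i in range(spec.n_ad)]
    records += [generate_subject(spec, GROUP_NOLD, i)
                for i in range(spec.n_nold)]
    return records, spec.truth()
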