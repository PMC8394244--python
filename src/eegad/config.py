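"""Run configuration: every pipeline constant with its default.

The configuration is serialised into every output directory so a run can
be reproduced bit-exactly from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import CohortSpec


@dataclass
class RunConfig:
    """All tunable parameters of the ten-step pipeline."""

    # inputs: either a synthetic cohort spec or a directory of records
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None
    input_format: str = "csv"           # csv | edf
    input_fs: float = 128.0
    input_labels: list = field(default_factory=list)

    # preprocessing
    trim: tuple[float, float] | None = None  # None = default 61-240 s rule

    # feature extraction
    tsen_k: int = 2200
    tsen_q: float = 0.5
    hfd_kmax: int = 8
    apen_m: int = 2
    apen_r_factor: float = 0.15

    # selection
    test: str = "welch"
    p_threshold: float = 0.001
    cumulative_threshold: float = 80.0

    # panels
    stage1_max_len: int = 10
    stage2_max_size: int = 4

    # modelling
    sen_min: float = 80.0
    spec_min: float = 80.0
    train_frac: float = 0.6
    folds: int = 10
    seed: int = 0

    # desk-scale runs: fraction (0, 1] of stage-1/2 panels actually screened
    scale: float = 1.0

    def feature_config(self):
        from .features import FeatureConfig

        return FeatureConfig(self.tsen_k, self.tsen_q, self.hfd_kmax,
                             self.apen_m, self.apen_r_factor)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cohort"]["channels"] = list(d["cohort"]["channels"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            if "channels" in cohort:
                cohort["channels"] = tuple(cohort["channels"])
            if "band_weights" in cohort and cohort["band_weights"] is None:
                cohort.pop("band_weights")
            try:
                cohort = CohortSpec(**cohort)
            except TypeError as exc:
                raise ValueError(f"bad cohort field: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        if "trim" in d and d["trim"] is not None:
            d["trim"] = tuple(d["trim"])
        return cls(cohort=cohort, **d)
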