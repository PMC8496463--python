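"""Pipeline configuration: explicit seeds, YAML round trip."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .constants import NPQ_EVAL_HIGH, NPQ_EVAL_LOW, WAVELENGTHS
from .errors import ValidationError


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serialisable to YAML.

    When ``raw_dir`` is unset the run is fully synthetic: a campaign is
    generated from ``seed``.  ``ek_unit`` chooses whether the K-table stage
    carries the relative or the absolute light-saturation parameter.
    """

    seed: int = 0
    n_stations: int = 19
    wavelengths: list = field(default_factory=lambda: list(WAVELENGTHS))
    ek_unit: str = "absolute"            # "relative" | "absolute"
    npq_eval_pars: list = field(default_factory=lambda: [NPQ_EVAL_LOW, NPQ_EVAL_HIGH])
    selection_alpha: float = 0.05
    selection_nperm: int = 199
    pta_scale: str = "sd"                # "sd" | "range"
    combined_candidate_pool: bool = False
    raw_dir: str | None = None           # directory of raw CSV streams
    noise_sd: dict = field(default_factory=dict)  # overrides for synthesis

    def validate(self) -> "PipelineConfig":
        if self.ek_unit not in ("relative", "absolute"):
            raise ValidationError("ek_unit must be 'relative' or 'absolute'")
        if self.pta_scale not in ("sd", "range"):
            raise ValidationError("pta_scale must be 'sd' or 'range'")
        if self.seed is None:
            raise ValidationError("seed must be explicit")
        bad = set(self.wavelengths) - set(WAVELENGTHS)
        if bad:
            raise ValidationError(f"unknown wavelengths: {sorted(bad)}")
        return self

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ValidationError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()
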