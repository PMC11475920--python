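"""Run configuration: one YAML file as the source of truth for thresholds.

The pipeline has many numeric constants (hit filters, the detection limit,
the 40% specificity threshold, the 95/70% species/genus demarcations); a
single hierarchical config keeps a run reproducible.  CLI flags override
config values; a config round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from .recruitment import FilterConfig


@dataclass
class RunConfig:
    """Every tunable of a pipeline run."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    specificity_threshold: float = 40.0
    human_cols: list[str] = field(default_factory=lambda: ["human_gut"])
    animal_cols: list[str] = field(default_factory=list)
    species_threshold: float = 95.0
    genus_threshold: float = 70.0
    seed: int = 1
    paths: dict[str, str] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("specificity_threshold", "species_threshold", "genus_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must be in (0, 100), got {v}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"]["plot_identity_window"] = list(
            d["filter"]["plot_identity_window"]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        f = dict(d.pop("filter", {}))
        if "plot_identity_window" in f:
            f["plot_identity_window"] = tuple(f["plot_identity_window"])
        return cls(filter=FilterConfig(**f), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(
                f"{path}: unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls.from_dict(data)

    def echo_lines(self) -> list[str]:
        """Human-readable threshold summary for output-table headers."""
        f = self.filter
        return [
            f"min_query_coverage={f.min_query_coverage} max_evalue={f.max_evalue}",
            f"detection_threshold={f.detection_threshold} anir_weighting={f.anir_weighting}",
            f"specificity_threshold={self.specificity_threshold} "
            f"species={self.species_threshold} genus={self.genus_threshold} seed={self.seed}",
        ]
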