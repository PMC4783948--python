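"""Run configuration: a validated, YAML-round-trippable parameter record."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with validated ranges.

    Thresholds follow the method's defaults: fold-change screening at 1.5,
    p < 0.05 on the permutation TRV p-values, t-test pruning at 0.05, one
    pooled control network, 200 label permutations.
    """

    expression: str = ""
    design: str = ""
    ppi: str = ""
    out_dir: str = "results"
    sep: str = "\t"
    ppi_dialect: str = "plain_tsv"
    organism_filter: str | None = None
    normalization_scope: str = "pooled"  # or "per_time_point", "none"
    screening_method: str = "fold_change"  # or "anova"
    screening_threshold: float = 1.5  # fold change (>1) or ANOVA p (<1)
    min_links: int = 5
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    require_fc: bool = True
    alpha: float = 0.05
    screen_alpha: float = 0.05
    order_cap: int | None = None
    allow_degenerate: bool = False
    pooled_control: bool = True
    intercept: bool = False
    permutations: int = 200
    seed: int = 0
    top_n: int = 20

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValidationError("p_threshold must be in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must be > 1")
        if self.permutations < 1:
            raise ValidationError("permutations must be >= 1")
        if self.normalization_scope not in ("pooled", "per_time_point", "none"):
            raise ValidationError(
                f"unknown normalization scope {self.normalization_scope!r}"
            )
        if self.screening_method not in ("fold_change", "anova"):
            raise ValidationError(f"unknown screening method {self.screening_method!r}")
        if not 0 < self.alpha < 1 or not 0 < self.screen_alpha < 1:
            raise ValidationError("alpha levels must be in (0, 1)")
        if self.min_links < 1:
            raise ValidationError("min_links must be >= 1")
        if self.top_n < 1:
            raise ValidationError("top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
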