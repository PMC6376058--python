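"""Run configuration: every tunable of the pipeline in one JSON-serialisable object."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .cohort import CohortSpec


@dataclass
class RunConfig:
    """Pipeline parameters.

    ``bin_width`` (signal units) controls absolute grey-level
    discretization; ``icc_threshold`` / ``ccc_threshold`` gate the
    reproducibility selection; ``spearman_cutoff`` is the redundancy
    clustering cutoff; ``b_values`` are the diffusion weightings in
    s/mm^2.  ``cohort`` holds the synthetic-cohort design.
    """

    bin_width: float = 20.0
    icc_threshold: float = 0.8
    ccc_threshold: float = 0.9
    spearman_cutoff: float = 0.9
    b_values: tuple[float, float] = (0.0, 1000.0)
    rng_seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        for name in ("icc_threshold", "ccc_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.spearman_cutoff < 1.0:
            raise ValueError(
                f"spearman_cutoff must be in (0, 1), got {self.spearman_cutoff}"
            )
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        # the cohort inherits the run seed unless it sets its own
        if self.cohort.rng_seed == 0 and self.rng_seed != 0:
            self.cohort = dataclasses.replace(self.cohort, rng_seed=self.rng_seed)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=list) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        cohort = payload.pop("cohort", {})
        for key in ("sequence_labels", "image_size", "spacing_mm", "gland_axes_range",
                    "b_values", "adc_range"):
            if key in cohort and isinstance(cohort[key], list):
                cohort[key] = tuple(cohort[key])
        if "contrasts" in cohort:
            cohort["contrasts"] = {
                k: tuple(v) for k, v in cohort["contrasts"].items()
            }
        if "b_values" in payload and isinstance(payload["b_values"], list):
            payload["b_values"] = tuple(payload["b_values"])
        return cls(cohort=CohortSpec(**cohort), **payload)
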