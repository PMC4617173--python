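"""Single-source-of-truth pipeline configuration.

Every numeric threshold of the analysis lives here with its standard default:
tag length bounds (18/30 nt), the hairpin energy ceiling (-18 kcal/mol), the
novel-miRNA copy-number floor (> 5), family-expansion and expression-counting
edit budgets (2 / 3), the target alignment-score ceiling (4), the DE p-value
and FDR cuts (1e-3, 1e-2 with a stricter 1e-3 preset for target reporting)
and the integration tier thresholds (1.5- and 2-fold).  Configurations
round-trip through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # inputs / outputs
    workdir: str = "mircms_run"
    genome: str | None = None
    known_precursors: str | None = None
    known_matures: str | None = None
    transcripts: str | None = None
    srna_counts: str | None = None
    degradome: list[str] = field(default_factory=list)
    rnaseq_counts: str | None = None
    annotation: str | None = None

    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "annotate", "novel", "de", "degradome", "integrate", "report"])
    simulate: bool = True  # run on synthetic data when no inputs are given

    # thresholds (defaults are the study-standard values)
    min_tag_len: int = 18
    max_tag_len: int = 30
    max_hairpin_energy: float = -18.0
    copy_number_min: int = 5
    family_max_edits: int = 2
    expression_max_end_edits: int = 3
    max_target_score: float = 4.0
    mirna_max_p: float = 1e-3
    mrna_max_fdr: float = 1e-2
    target_max_fdr: float = 1e-3
    target_max_p: float = 0.05
    min_abs_log2fc: float = 1.0
    tier_thresholds: tuple[float, float] = (1.5, 2.0)

    # reproducibility
    seed: int = 0
    n_shuffles: int = 100
    fold_backend: str = "auto"

    # overrides for the synthetic study (SimulationConfig fields)
    sim_params: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["tier_thresholds"] = list(data["tier_thresholds"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "tier_thresholds" in data and data["tier_thresholds"] is not None:
            data["tier_thresholds"] = tuple(data["tier_thresholds"])
        return cls(**data)
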