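"""Pipeline configuration: every numeric threshold, with lossless round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .classify import ClassifierThresholds
from .simulate import SimulationConfig


@dataclass
class PipelineConfig:
    """All tunable settings of the analysis pipeline.

    Defaults are the published operating point wherever one is printed
    (classifier cutoffs, 12.5-kb stitch distance, z > 13 motif selection,
    75% / 65-read input exclusion, 95th-percentile background); settings
    the source analysis left open carry the documented package defaults.
    """

    seed: int = 0
    simulate: bool = True
    scaffold_whitelist: list | None = None
    # external-input mode paths (unused when simulate=True)
    peaks_file: str | None = None
    counts_file: str | None = None
    tss_file: str | None = None
    # signal / filters
    background_percentile: float = 0.95
    background_n_regions: int = 10_000
    input_overlap_fraction: float = 0.75
    input_count_threshold: float = 65.0
    literal_background_mode: bool = False
    apply_input_filter: bool = True
    # differential model
    pseudocount: float = 0.5
    mark: str = "H3K4me3"
    # classification
    thresholds: ClassifierThresholds = field(default_factory=ClassifierThresholds)
    classify_genes: bool = True
    h3k4me3_gene_window: int = 250
    h3k27me3_gene_window: int = 2_500
    # enhancer clusters
    stitch_distance: int = 12_500
    # motif activity
    ridge_lambda: float = 1.0
    select_lambda_by_cv: bool = False
    z_threshold: float = 13.0
    # methylation
    hypomethylation_rule: str = "bisulfite"  # or "biocap"
    bisulfite_hypo_threshold: float = 0.2
    meth_h3k4me3_window: int = 100
    meth_h3k27me3_window: int = 2_500
    biocap_window: int = 1_000
    # regulatory domains
    great_basal_up: int = 5_000
    great_basal_down: int = 1_000
    great_max_extension: int = 1_000_000
    # chromatin states
    state_bin_size: int = 200
    # synthetic data
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self):
        if self.hypomethylation_rule not in ("bisulfite", "biocap"):
            raise ValueError("hypomethylation_rule must be bisulfite or biocap")
        if not 0 < self.background_percentile < 1:
            raise ValueError("background percentile must be in (0, 1)")

    def to_dict(self) -> dict:
        d = {}
        for key, val in self.__dict__.items():
            if key == "thresholds":
                d[key] = val.to_dict()
            elif key == "simulation":
                d[key] = val.to_dict()
            else:
                d[key] = val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            d["thresholds"] = ClassifierThresholds.from_dict(d["thresholds"])
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            try:
                d = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        d = self.to_dict()
        for key, val in kwargs.items():
            if key not in d:
                raise KeyError(f"unknown config key {key!r}")
            d[key] = val
        return PipelineConfig.from_dict(d)
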