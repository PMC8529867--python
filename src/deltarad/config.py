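"""Pipeline configuration.

Every constant the analysis prints or assumes lives here with its standard
default: minimum lesion diameter 5 mm, at most 5 target lesions, 10-fold
cross-validation, the published KM cutoffs (kurtosis 1.11 at SSF 2, 1.20 at
SSF 3, entropy percentage change 5 at SSF 4 and 6), and an LDH upper limit
of normal of 450 U/L (assay-dependent; set it to your laboratory's value).
The config is serialized into every output directory for provenance.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .aggregate import AS_PRINTED, CONVENTIONS


@dataclass
class PipelineConfig:
    # paths
    manifest: str = ""
    clinical_csv: str = ""
    output_dir: str = "deltarad_out"
    # texture extraction
    scales_mm: tuple[float, ...] = (0, 2, 3, 4, 5, 6)
    entropy_base: float = 2.0
    kurtosis_convention: str = "excess"  # or "pearson"
    bin_before_stats: bool = True
    # ROI handling
    exclusion_window_enabled: bool = False
    exclusion_low_hu: float = -100.0
    exclusion_high_hu: float = 300.0
    max_target_lesions: int = 5
    min_diameter_mm: float = 5.0
    # aggregation
    sign_convention: str = AS_PRINTED
    # survival analysis
    uln: float = 450.0
    k_folds: int = 10
    km_fixed_cutoffs: dict = field(
        default_factory=lambda: {
            "kurtosis_ssf2": 1.11,
            "kurtosis_ssf3": 1.20,
            "perc_entropy_ssf4": 5.0,
            "perc_entropy_ssf6": 5.0,
        }
    )
    report_markers_baseline: tuple[str, ...] = ("kurtosis_ssf2", "kurtosis_ssf3")
    report_markers_delta: tuple[str, ...] = ("perc_entropy_ssf4", "perc_entropy_ssf6")
    min_events: int = 5
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sign_convention not in CONVENTIONS:
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")
        if self.kurtosis_convention not in ("excess", "pearson"):
            raise ValueError(f"unknown kurtosis convention {self.kurtosis_convention!r}")
        self.scales_mm = tuple(self.scales_mm)
        self.report_markers_baseline = tuple(self.report_markers_baseline)
        self.report_markers_delta = tuple(self.report_markers_delta)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["scales_mm"] = list(self.scales_mm)
        data["report_markers_baseline"] = list(self.report_markers_baseline)
        data["report_markers_delta"] = list(self.report_markers_delta)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
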