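"""Pipeline configuration and patient manifests.

Defaults are the analysis constants of the study design: CSF probability
threshold 0.95, a 2 mm partial-volume band around the CSF border, 1.5 mm
lesion-edge erosion, Spearman rank correlation, dichotomization by the IgG
quotient.  A YAML file can override any field; the config is echoed into run
logs so a run is reproducible from its log alone.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, fields

import pandas as pd
import yaml

__all__ = ["PipelineConfig", "read_manifest", "MANIFEST_COLUMNS"]


@dataclass
class PipelineConfig:
    csf_probability_threshold: float = 0.95
    csf_band_mm: float = 2.0
    lesion_edge_mm: float = 1.5
    lesion_rule: str = "edge_erosion"          # or "csf_distance"
    correlation_method: str = "spearman"       # or "pearson"
    dichotomize_by: str = "igg_quotient"
    max_distance_mm: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.csf_probability_threshold <= 1):
            raise ValueError("csf_probability_threshold must be in (0, 1]")
        if self.csf_band_mm < 0 or self.lesion_edge_mm < 0:
            raise ValueError("exclusion bands must be non-negative")
        if self.lesion_rule not in ("edge_erosion", "csf_distance"):
            raise ValueError(f"unknown lesion_rule {self.lesion_rule!r}")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation_method {self.correlation_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


#: Required manifest columns; path columns are resolved relative to the
#: manifest's own directory.
MANIFEST_COLUMNS = ("patient_id", "group", "adc", "csf_prob", "wm_mask",
                    "irl_mask", "non_irl_mask")


def read_manifest(path) -> pd.DataFrame:
    """Load and validate a patient manifest TSV.

    Checks column presence, patient_id uniqueness and existence of every
    referenced volume file.
    """
    path = os.fspath(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing manifest column(s) {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"{path}: duplicate patient_id(s) {dupes}")
    base = os.path.dirname(os.path.abspath(path))
    for col in MANIFEST_COLUMNS[2:]:
        resolved = []
        for p in df[col]:
            full = p if os.path.isabs(p) else os.path.join(base, p)
            if not os.path.exists(full):
                raise FileNotFoundError(f"{path}: referenced file missing ({col}): {full}")
            resolved.append(full)
        df[col] = resolved
    return df
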