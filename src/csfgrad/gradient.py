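"""Voxel-wise CSF-distance analysis of diffusion-measured tissue damage.

Pipeline, per patient on one aligned grid:

1. binarize the CSF probability map (conservative default threshold 0.95 —
   lower thresholds overestimate CSF spaces);
2. subtract lesion masks from the white-matter mask to obtain
   normal-appearing white matter (NAWM);
3. Euclidean distance transform of the CSF mask in physical mm;
4. exclusion rules against partial-volume contamination: drop every voxel
   within 2 mm of the CSF border, and drop lesion voxels within 1.5 mm of
   their own lesion boundary (inward erosion);
5. tabulate surviving voxels as (patient, tissue class, distance, ADC).

On the pooled table the tissue-damage gradient is quantified per tissue class
(iron-rim lesions, non-rim lesions, NAWM) as a rank correlation between ADC
and distance-to-CSF — a negative r means more damage near the CSF — together
with an ordinary least-squares slope in mm²/s per mm.  Correlations between
patient groups (e.g. high vs low IgG quotient, split at the cohort median)
are compared with the Fisher r-to-z test, assembled into skew-symmetric
z-matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import VolumeGrid, validate_same_grid

__all__ = [
    "TISSUE_CLASSES",
    "TissueMasks",
    "PatientVolumes",
    "CorrelationResult",
    "GradientResult",
    "binarize_probability",
    "make_nawm_mask",
    "euclidean_distance_to_csf",
    "apply_exclusions",
    "build_voxel_table",
    "tissue_summary",
    "distance_correlation",
    "fisher_compare",
    "z_matrix",
    "dichotomize_by_median",
    "process_patient",
    "run_gradient_study",
]

#: Analyzed tissue classes, lesion labels taking precedence over NAWM.
TISSUE_CLASSES = ("IRL", "nonIRL", "NAWM")


@dataclass
class TissueMasks:
    """Aligned binary masks on one grid; NAWM is derived, never supplied."""

    csf: np.ndarray
    wm: np.ndarray
    irl: np.ndarray
    non_irl: np.ndarray
    gm: np.ndarray | None = None

    def __post_init__(self):
        shapes = {name: m.shape for name, m in self.named().items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        if np.any(self.irl & self.non_irl):
            raise ValueError("IRL and non-IRL lesion masks overlap; masks must be disjoint")

    def named(self) -> dict:
        out = {"csf": self.csf, "wm": self.wm, "irl": self.irl, "non_irl": self.non_irl}
        if self.gm is not None:
            out["gm"] = self.gm
        return out

    @property
    def nawm(self) -> np.ndarray:
        return make_nawm_mask(self.wm, self.irl | self.non_irl)


def binarize_probability(prob, threshold: float = 0.95) -> np.ndarray:
    """Binary mask from a tissue probability map: ``prob >= threshold``.

    The inclusive comparison at the threshold is a documented convention.
    """
    values = prob.values if isinstance(prob, VolumeGrid) else np.asarray(prob)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("probability map has values outside [0, 1]")
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return values >= threshold


def make_nawm_mask(wm: np.ndarray, lesions: np.ndarray) -> np.ndarray:
    """Normal-appearing white matter: white matter minus all lesions."""
    wm = np.asarray(wm, dtype=bool)
    lesions = np.asarray(lesions, dtype=bool)
    if wm.shape != lesions.shape:
        raise ValueError(f"shape mismatch: wm {wm.shape} vs lesions {lesions.shape}")
    return wm & ~lesions


def euclidean_distance_to_csf(csf: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Exact Euclidean distance (mm) from each voxel center to the nearest
    CSF voxel center, honouring anisotropic spacing; 0 on CSF voxels."""
    csf = np.asarray(csf, dtype=bool)
    if not csf.any():
        raise ValueError("CSF mask is empty; distance to CSF is undefined")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    return ndimage.distance_transform_edt(~csf, sampling=spacing)


def apply_exclusions(
    masks: TissueMasks,
    dist: np.ndarray,
    spacing: Sequence[float],
    csf_band_mm: float = 2.0,
    lesion_edge_mm: float = 1.5,
    lesion_rule: str = "edge_erosion",
) -> dict[str, np.ndarray]:
    """Partial-volume exclusion rules; returns filtered masks per class.

    Every analyzed voxel with distance-to-CSF strictly below ``csf_band_mm``
    is removed (voxels at exactly the band distance survive).  Lesion voxels
    are additionally filtered by one of two rules:

    - ``edge_erosion`` (default): a lesion voxel is dropped when the distance
      from its center to the nearest non-lesion voxel center is below
      ``lesion_edge_mm`` — an inward erosion in physical mm targeting
      lesion-edge partial volume.  A sphere of radius 1.4 mm on a 1 mm grid
      contributes no voxels under this rule.
    - ``csf_distance``: lesion voxels with distance-to-CSF below
      ``lesion_edge_mm`` are dropped (subsumed by the CSF band whenever
      ``csf_band_mm >= lesion_edge_mm``).
    """
    if csf_band_mm < 0 or lesion_edge_mm < 0:
        raise ValueError("exclusion bands must be non-negative")
    if lesion_rule not in ("edge_erosion", "csf_distance"):
        raise ValueError(f"unknown lesion_rule {lesion_rule!r}")
    keep_band = dist >= csf_band_mm
    out = {"NAWM": masks.nawm & keep_band}
    for cls, lesion in (("IRL", masks.irl), ("nonIRL", masks.non_irl)):
        lesion = np.asarray(lesion, dtype=bool)
        kept = lesion & keep_band
        if lesion_edge_mm > 0 and lesion.any():
            if lesion_rule == "edge_erosion":
                interior = ndimage.distance_transform_edt(lesion, sampling=spacing)
                kept &= interior >= lesion_edge_mm
            else:
                kept &= dist >= lesion_edge_mm
        out[cls] = kept
    return out


def build_voxel_table(
    adc, dist: np.ndarray, filtered: Mapping[str, np.ndarray], patient_id: str
) -> pd.DataFrame:
    """Flatten surviving voxels to records of (patient, class, distance, ADC).

    Lesion labels take precedence over NAWM; the two lesion classes must be
    disjoint.
    """
    adc_values = adc.values if isinstance(adc, VolumeGrid) else np.asarray(adc)
    if np.any(filtered.get("IRL", False) & filtered.get("nonIRL", False)):
        raise ValueError("a voxel belongs to both lesion classes; masks must be disjoint")
    lesion_any = np.zeros(adc_values.shape, dtype=bool)
    frames = []
    for cls in ("IRL", "nonIRL", "NAWM"):
        mask = filtered.get(cls)
        if mask is None:
            continue
        mask = np.asarray(mask, dtype=bool)
        if cls == "NAWM":
            mask = mask & ~lesion_any
        else:
            lesion_any |= mask
        idx = np.nonzero(mask)
        frames.append(pd.DataFrame({
            "patient_id": patient_id,
            "tissue_class": cls,
            "distance_mm": dist[idx],
            "adc_mm2_per_s": adc_values[idx].astype(float),
        }))
    if not frames:
        return pd.DataFrame(
            columns=["patient_id", "tissue_class", "distance_mm", "adc_mm2_per_s"]
        )
    return pd.concat(frames, ignore_index=True)


def tissue_summary(table: pd.DataFrame, level: str = "per_patient") -> pd.DataFrame:
    """Median and IQR of ADC per tissue class.

    ``per_patient`` first takes each patient's class median and then
    summarises those medians across patients — the unit of the paired
    within-patient comparisons; ``pooled`` summarises voxels directly.
    Absent classes are simply absent from the output, never zero rows.
    """
    if level not in ("pooled", "per_patient"):
        raise ValueError(f"unknown level {level!r}")
    rows = []
    for cls, sub in table.groupby("tissue_class", sort=True):
        if level == "per_patient":
            values = sub.groupby("patient_id")["adc_mm2_per_s"].median().to_numpy()
        else:
            values = sub["adc_mm2_per_s"].to_numpy()
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        rows.append({"tissue_class": cls, "n": len(values),
                     "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    """Distance–ADC association for one tissue class in one group."""

    r: float
    n: int
    slope: float
    intercept: float
    p: float
    method: str


def distance_correlation(
    table: pd.DataFrame,
    tissue_class: str,
    method: str = "spearman",
    max_distance_mm: float | None = None,
) -> CorrelationResult:
    """Correlation of ADC with distance-to-CSF for one tissue class.

    ``r`` follows the chosen method (rank correlation by default); the slope
    and intercept always come from ordinary least squares of ADC on distance,
    quantifying the linear gradient in mm²/s per mm regardless of method.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    sub = table[table["tissue_class"] == tissue_class]
    if max_distance_mm is not None:
        sub = sub[sub["distance_mm"] <= max_distance_mm]
    d = sub["distance_mm"].to_numpy(dtype=float)
    a = sub["adc_mm2_per_s"].to_numpy(dtype=float)
    if len(d) < 3:
        raise ValueError(f"class {tissue_class!r}: need at least 3 voxels, have {len(d)}")
    if np.ptp(d) == 0 or np.ptp(a) == 0:
        raise ValueError(
            f"class {tissue_class!r}: constant distance or ADC; correlation undefined"
        )
    if method == "spearman":
        r, p = stats.spearmanr(d, a)
    else:
        r, p = stats.pearsonr(d, a)
    fit = stats.linregress(d, a)
    return CorrelationResult(r=float(r), n=len(d), slope=float(fit.slope),
                             intercept=float(fit.intercept), p=float(p), method=method)


def fisher_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher r-to-z comparison of two correlations from independent samples.

    z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3)); two-sided p from
    the standard normal.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError(f"both sample sizes must exceed 3, got {n1}, {n2}")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def z_matrix(entries: Sequence[tuple[str, float, int]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise comparison-of-correlations matrices.

    Returns labelled (z, p) DataFrames; z is skew-symmetric with a zero
    diagonal.  Entry order fixes row/column order.
    """
    labels = [e[0] for e in entries]
    if len(labels) != len(set(labels)):
        raise ValueError(f"duplicate labels in z-matrix entries: {labels}")
    if len(entries) < 2:
        raise ValueError("need at least two entries to compare")
    zmat = pd.DataFrame(0.0, index=labels, columns=labels)
    pmat = pd.DataFrame(1.0, index=labels, columns=labels)
    for la, ra, na in entries:
        for lb, rb, nb in entries:
            if la == lb:
                continue
            z, p = fisher_compare(ra, na, rb, nb)
            zmat.loc[la, lb] = z
            pmat.loc[la, lb] = p
    return zmat, pmat


def dichotomize_by_median(values: Mapping[str, float]) -> tuple[list, list]:
    """Split patients at the median of a per-patient value.

    ``high`` holds ids strictly above the median, ``low`` the rest (ties at
    the median go to low — the deterministic tie rule).  For even n the
    median is the midpoint of the two central order statistics.
    """
    if len(values) == 0:
        raise ValueError("cannot dichotomize an empty cohort")
    if len(values) < 2:
        raise ValueError("need at least 2 patients to dichotomize")
    med = float(np.median(list(values.values())))
    high = [k for k, v in values.items() if v > med]
    low = [k for k, v in values.items() if v <= med]
    return high, low


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


@dataclass
class PatientVolumes:
    """One patient's aligned inputs: ADC plus masks or probability maps."""

    patient_id: str
    adc: VolumeGrid
    wm_mask: np.ndarray
    irl_mask: np.ndarray
    non_irl_mask: np.ndarray
    csf_prob: VolumeGrid | None = None
    csf_mask: np.ndarray | None = None
    group: str | None = None


@dataclass
class GradientResult:
    """All outputs of the gradient study on one cohort."""

    voxel_table: pd.DataFrame
    correlations: pd.DataFrame
    z_between_groups: dict            # tissue_class -> (z_df, p_df)
    z_between_classes: dict           # group -> (z_df, p_df)
    summaries: pd.DataFrame

    def z_between_groups_frame(self) -> pd.DataFrame:
        rows = []
        for cls, (zm, pm) in self.z_between_groups.items():
            for a in zm.index:
                for b in zm.columns:
                    rows.append({"tissue_class": cls, "group_a": a, "group_b": b,
                                 "z": zm.loc[a, b], "p": pm.loc[a, b]})
        return pd.DataFrame(rows)

    def z_between_classes_frame(self) -> pd.DataFrame:
        rows = []
        for grp, (zm, pm) in self.z_between_classes.items():
            for a in zm.index:
                for b in zm.columns:
                    rows.append({"group": grp, "class_a": a, "class_b": b,
                                 "z": zm.loc[a, b], "p": pm.loc[a, b]})
        return pd.DataFrame(rows)


def process_patient(pv: PatientVolumes, config=None) -> pd.DataFrame:
    """Run the per-patient stages (masks → distances → exclusions → table)."""
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    named = {"adc": pv.adc, "wm": pv.wm_mask, "irl": pv.irl_mask,
             "non_irl": pv.non_irl_mask}
    if pv.csf_prob is not None:
        named["csf_prob"] = pv.csf_prob
    if pv.csf_mask is not None:
        named["csf_mask"] = pv.csf_mask
    validate_same_grid(named)
    if pv.csf_mask is not None:
        csf = np.asarray(pv.csf_mask, dtype=bool)
    elif pv.csf_prob is not None:
        csf = binarize_probability(pv.csf_prob, cfg.csf_probability_threshold)
    else:
        raise ValueError(f"patient {pv.patient_id!r}: need a CSF mask or probability map")
    masks = TissueMasks(csf=csf, wm=np.asarray(pv.wm_mask, dtype=bool),
                        irl=np.asarray(pv.irl_mask, dtype=bool),
                        non_irl=np.asarray(pv.non_irl_mask, dtype=bool))
    dist = euclidean_distance_to_csf(masks.csf, pv.adc.spacing)
    filtered = apply_exclusions(masks, dist, pv.adc.spacing,
                                csf_band_mm=cfg.csf_band_mm,
                                lesion_edge_mm=cfg.lesion_edge_mm,
                                lesion_rule=cfg.lesion_rule)
    return build_voxel_table(pv.adc, dist, filtered, pv.patient_id)


def run_gradient_study(
    patients: Sequence[PatientVolumes],
    config=None,
    grouping: Mapping[str, str] | None = None,
) -> GradientResult:
    """Full cohort analysis: per-patient tables, per-group correlations,
    pairwise Fisher z-matrices and tissue summaries.

    ``grouping`` maps patient_id → group label; when omitted the patients'
    own ``group`` attributes are used (single group ``all`` as fallback).
    Voxels are pooled across patients within a group; the pooled voxel count
    enters the Fisher comparison, with the caveat that voxels within a
    patient are not strictly independent.  Deterministic given inputs.
    """
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    if grouping is None:
        grouping = {pv.patient_id: (pv.group or "all") for pv in patients}
    tables = []
    for pv in patients:
        try:
            tables.append(process_patient(pv, cfg))
        except Exception as exc:
            raise RuntimeError(f"patient {pv.patient_id!r}: {exc}") from exc
    table = pd.concat(tables, ignore_index=True)
    table["group"] = table["patient_id"].map(dict(grouping))
    groups = sorted(set(grouping.values()))

    corr_rows = []
    corr_lookup: dict[tuple[str, str], CorrelationResult] = {}
    for grp in groups:
        sub = table[table["group"] == grp]
        for cls in TISSUE_CLASSES:
            if (sub["tissue_class"] == cls).sum() < 4:
                continue
            res = distance_correlation(sub, cls, method=cfg.correlation_method,
                                       max_distance_mm=cfg.max_distance_mm)
            corr_lookup[(grp, cls)] = res
            corr_rows.append({"group": grp, "tissue_class": cls, "method": res.method,
                              "r": res.r, "n": res.n, "slope": res.slope,
                              "intercept": res.intercept, "p": res.p})
    correlations = pd.DataFrame(corr_rows)

    # degenerate |r| = 1 (e.g. noiseless simulations) cannot enter the
    # Fisher transform and is left out of the comparison matrices
    z_between_groups = {}
    for cls in TISSUE_CLASSES:
        entries = [(grp, corr_lookup[(grp, cls)].r, corr_lookup[(grp, cls)].n)
                   for grp in groups
                   if (grp, cls) in corr_lookup and abs(corr_lookup[(grp, cls)].r) < 1]
        if len(entries) >= 2:
            z_between_groups[cls] = z_matrix(entries)
    z_between_classes = {}
    for grp in groups:
        entries = [(cls, corr_lookup[(grp, cls)].r, corr_lookup[(grp, cls)].n)
                   for cls in TISSUE_CLASSES
                   if (grp, cls) in corr_lookup and abs(corr_lookup[(grp, cls)].r) < 1]
        if len(entries) >= 2:
            z_between_classes[grp] = z_matrix(entries)

    summaries = []
    for grp in groups:
        s = tissue_summary(table[table["group"] == grp], level="per_patient")
        s.insert(0, "group", grp)
        summaries.append(s)
    return GradientResult(
        voxel_table=table,
        correlations=correlations,
        z_between_groups=z_between_groups,
        z_between_classes=z_between_classes,
        summaries=pd.concat(summaries, ignore_index=True),
    )
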