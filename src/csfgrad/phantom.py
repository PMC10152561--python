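"""Synthetic brain phantom and CSF cohort generators.

The phantom emulates the geometry the distance analysis needs and nothing
more: an ellipsoidal ventricle (inner CSF surface) and a thin CSF shell just
inside the grid boundary (outer surface), a cortical grey-matter band inside
the shell, white matter in between, and spherical lesions labelled iron-rim
(IRL) or non-rim.  The ADC field is built from the *continuous* geometric
distance d(v) of each voxel center to the nearest CSF surface,

    ADC(v) = baseline[class(v)] − slope[class(v)] · min(d(v), range) + ε,

with Gaussian noise ε, so the discreteness of the downstream voxel-based
distance transform is part of what recovery tests measure, not baked into the
truth.  Class baselines default to 1.15 / 1.05 / 0.85 ×10⁻³ mm²/s for
IRL / non-rim / NAWM, preserving the empirical ordering of damage severity.
The distance cap keeps ADC positive deep in the white matter.

The cohort generator emits two groups of laboratory profiles (patients with
at least one iron-rim lesion vs matched patients without) in which the rim
group has the higher prevalence of intrathecal IgG synthesis.  Profiles with
synthesis are constructed by inverting the discrimination hyperbola: draw a
target fraction f and set Q_IgG = Q_lim/(1 − f/100), so the classification
round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reiber
from .volume import VolumeGrid
from .gradient import TissueMasks

__all__ = [
    "Lesion",
    "PhantomSpec",
    "PhantomOutput",
    "SyntheticCohortSpec",
    "CohortResult",
    "StudySpec",
    "InvalidSpecError",
    "default_lesions",
    "make_phantom",
    "random_lesions",
    "make_cohort",
    "simulate_study_patients",
]


class InvalidSpecError(ValueError):
    """The phantom specification is geometrically inconsistent."""


@dataclass(frozen=True)
class Lesion:
    """A spherical lesion: center (mm), radius (mm) and rim class."""

    center: tuple[float, float, float]
    radius: float
    tissue_class: str  # "IRL" or "nonIRL"

    def __post_init__(self):
        if self.tissue_class not in ("IRL", "nonIRL"):
            raise InvalidSpecError(f"lesion class must be IRL or nonIRL, got {self.tissue_class!r}")
        if self.radius <= 0:
            raise InvalidSpecError(f"lesion radius must be positive, got {self.radius}")


def default_lesions() -> list[Lesion]:
    """Five fixed spheres spanning periventricular to deep white matter."""
    return [
        Lesion((13.0, 32.0, 32.0), 4.0, "IRL"),
        Lesion((32.0, 12.0, 32.0), 4.0, "IRL"),
        Lesion((48.0, 48.0, 32.0), 4.0, "nonIRL"),
        Lesion((20.0, 48.0, 42.0), 4.0, "nonIRL"),
        Lesion((44.0, 20.0, 22.0), 4.0, "nonIRL"),
    ]


@dataclass
class PhantomSpec:
    """Geometry and signal model of one synthetic brain volume.

    Distances and coordinates are in mm relative to the grid corner; voxel
    centers sit at (i + ½)·spacing.  Baselines and slopes are in mm²/s and
    mm²/s per mm of distance-to-CSF.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    ventricle_center: tuple[float, float, float] | None = None  # grid center
    ventricle_semiaxes: tuple[float, float, float] = (10.0, 14.0, 10.0)
    outer_csf_thickness: float = 2.0
    cortex_thickness: float = 3.0
    lesions: list[Lesion] = field(default_factory=default_lesions)
    adc_baseline: dict = field(default_factory=lambda: {
        "IRL": 1.15e-3, "nonIRL": 1.05e-3, "NAWM": 0.85e-3})
    adc_csf: float = 3.0e-3
    adc_gm: float = 0.9e-3
    gradient_slope: dict = field(default_factory=lambda: {
        "IRL": 10e-6, "nonIRL": 8e-6, "NAWM": 6e-6})
    gradient_range_mm: float = 20.0
    noise_sd: float = 1.0e-4
    prob_smooth_sigma_mm: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(n < 8 for n in self.grid_shape):
            raise InvalidSpecError("grid too small; need at least 8 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise InvalidSpecError("spacing must be positive")
        if any(b <= 0 for b in self.adc_baseline.values()):
            raise InvalidSpecError("ADC baselines must be positive")
        if any(s < 0 for s in self.gradient_slope.values()):
            raise InvalidSpecError("gradient slopes must be non-negative magnitudes")
        if self.noise_sd < 0 or self.gradient_range_mm < 0:
            raise InvalidSpecError("noise_sd and gradient_range_mm must be non-negative")

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.spacing))

    def resolved_ventricle_center(self) -> tuple[float, float, float]:
        if self.ventricle_center is not None:
            return self.ventricle_center
        return tuple(e / 2 for e in self.extent)


@dataclass
class PhantomOutput:
    """Volumes, masks and the imposed ground truth of one phantom."""

    adc: VolumeGrid
    prob: dict            # "CSF" / "WM" / "GM" -> VolumeGrid
    masks: TissueMasks
    truth: dict           # imposed baselines, slopes, range, distances, counts


def _voxel_centers(spec: PhantomSpec):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(spec.grid_shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _border_distance(coords, extent):
    """Continuous distance of each voxel center to the nearest grid face."""
    d = np.full(coords[0].shape, np.inf)
    for c, e in zip(coords, extent):
        d = np.minimum(d, np.minimum(c, e - c))
    return d


def _ellipsoid_distance(coords, center, semiaxes, iters: int = 64):
    """Euclidean distance from points to an axis-aligned ellipsoid surface.

    Zero inside.  Exterior distances solve Σ aᵢ²pᵢ²/(t+aᵢ²)² = 1 for t ≥ 0 by
    bisection (the left side is strictly decreasing in t), then measure to the
    foot point xᵢ = aᵢ²pᵢ/(t+aᵢ²).  Vectorised over all exterior voxels;
    64 halvings of the bracket reach floating precision.
    """
    shape = np.broadcast(*coords).shape
    p_all = np.stack(
        [np.abs(np.broadcast_to(c, shape) - cc) for c, cc in zip(coords, center)],
        axis=-1,
    ).reshape(-1, 3)
    a = np.asarray(semiaxes, dtype=float)
    inside = np.sum((p_all / a) ** 2, axis=-1) <= 1.0
    p = p_all[~inside]
    norm = np.sqrt(np.sum(p**2, axis=-1))
    lo = np.zeros_like(norm)
    hi = np.maximum(a.max() * (norm + a.max()), 1.0)
    for _ in range(iters):
        t = 0.5 * (lo + hi)
        f = np.sum((a**2 * p**2) / (t[:, None] + a**2) ** 2, axis=-1)
        too_far = f < 1.0
        hi = np.where(too_far, t, hi)
        lo = np.where(too_far, lo, t)
    t = 0.5 * (lo + hi)
    foot = (a**2 * p) / (t[:, None] + a**2)
    out = np.zeros(p_all.shape[0])
    out[~inside] = np.sqrt(np.sum((p - foot) ** 2, axis=-1))
    return out.reshape(shape)


def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Rasterise the phantom; identical spec (incl. seed) gives identical volumes."""
    coords = _voxel_centers(spec)
    extent = spec.extent
    border = _border_distance(coords, extent)
    vcenter = spec.resolved_ventricle_center()

    outer_csf = border < spec.outer_csf_thickness
    vent_d = _ellipsoid_distance(coords, vcenter, spec.ventricle_semiaxes)
    ventricle = vent_d == 0.0
    csf = outer_csf | ventricle
    gm = ~csf & (border < spec.outer_csf_thickness + spec.cortex_thickness)
    wm = ~csf & ~gm

    irl = np.zeros(spec.grid_shape, dtype=bool)
    non_irl = np.zeros(spec.grid_shape, dtype=bool)
    for i, les in enumerate(spec.lesions):
        r2 = sum((c - cc) ** 2 for c, cc in zip(coords, les.center))
        sphere = r2 <= les.radius**2
        if np.any(sphere & csf):
            raise InvalidSpecError(f"lesion {i} ({les.tissue_class}) intersects CSF")
        if np.any(sphere & gm):
            raise InvalidSpecError(f"lesion {i} ({les.tissue_class}) extends into grey matter")
        target = irl if les.tissue_class == "IRL" else non_irl
        target |= sphere
    if np.any(irl & non_irl):
        raise InvalidSpecError("IRL and non-IRL lesions overlap")
    nawm = wm & ~(irl | non_irl)

    # continuous ground-truth distance to the nearest CSF surface
    d_outer = np.clip(border - spec.outer_csf_thickness, 0.0, None)
    d_true = np.minimum(d_outer, vent_d)
    d_true[csf] = 0.0

    d_eff = np.minimum(d_true, spec.gradient_range_mm)
    adc = np.full(spec.grid_shape, spec.adc_csf, dtype=float)
    adc[gm] = spec.adc_gm
    for cls, mask in (("NAWM", nawm), ("nonIRL", non_irl), ("IRL", irl)):
        adc[mask] = spec.adc_baseline[cls] - spec.gradient_slope[cls] * d_eff[mask]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        adc = adc + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    prob = {"CSF": csf.astype(float), "WM": (wm | irl | non_irl).astype(float),
            "GM": gm.astype(float)}
    if spec.prob_smooth_sigma_mm > 0:
        sig = [spec.prob_smooth_sigma_mm / s for s in spec.spacing]
        prob = {k: ndimage.gaussian_filter(v, sig) for k, v in prob.items()}
        total = sum(prob.values())
        total[total == 0] = 1.0
        prob = {k: v / total for k, v in prob.items()}

    spacing = spec.spacing
    masks = TissueMasks(csf=csf, wm=wm | irl | non_irl, irl=irl, non_irl=non_irl, gm=gm)
    truth = {
        "adc_baseline": dict(spec.adc_baseline),
        "gradient_slope": dict(spec.gradient_slope),
        "gradient_range_mm": spec.gradient_range_mm,
        "noise_sd": spec.noise_sd,
        "distance_mm": d_true,
        "voxel_counts": {"CSF": int(csf.sum()), "GM": int(gm.sum()),
                         "NAWM": int(nawm.sum()), "IRL": int(irl.sum()),
                         "nonIRL": int(non_irl.sum())},
    }
    return PhantomOutput(
        adc=VolumeGrid(adc, spacing),
        prob={k: VolumeGrid(v, spacing) for k, v in prob.items()},
        masks=masks,
        truth=truth,
    )


def random_lesions(
    rng: np.random.Generator,
    spec: PhantomSpec,
    n_irl: int,
    n_non_irl: int,
    radius_range: tuple[float, float] = (3.0, 5.0),
    margin_mm: float = 1.0,
    max_tries: int = 5000,
) -> list[Lesion]:
    """Sample non-overlapping spherical lesions fully inside white matter.

    Rejection sampling against the continuous geometry: each sphere must
    clear the cortical band and the ventricle by ``margin_mm`` and clear
    every previously placed sphere.
    """
    extent = spec.extent
    vcenter = spec.resolved_ventricle_center()
    inner_clear = spec.outer_csf_thickness + spec.cortex_thickness
    placed: list[Lesion] = []
    wanted = ["IRL"] * n_irl + ["nonIRL"] * n_non_irl
    for cls in wanted:
        for _ in range(max_tries):
            radius = rng.uniform(*radius_range)
            lo = inner_clear + radius + margin_mm
            if any(lo >= e - lo for e in extent):
                raise InvalidSpecError(
                    f"could not place a {cls} lesion of radius {radius:.1f} mm: "
                    "grid too small for the requested lesion load"
                )
            center = tuple(rng.uniform(lo, e - lo) for e in extent)
            grid = [np.array([c]) for c in center]
            vd = float(_ellipsoid_distance(grid, vcenter, spec.ventricle_semiaxes)[0])
            if vd < radius + margin_mm:
                continue
            if any(np.sqrt(sum((a - b) ** 2 for a, b in zip(center, l.center)))
                   < radius + l.radius + margin_mm for l in placed):
                continue
            placed.append(Lesion(center, radius, cls))
            break
        else:
            raise InvalidSpecError(
                f"could not place a {cls} lesion after {max_tries} tries; "
                "grid too small for the requested lesion load"
            )
    return placed


def recovery_phantom_spec(noise_sd: float = 0.0) -> PhantomSpec:
    """Phantom layout for slope-recovery validation.

    Voxel-center distance transforms carry a sub-voxel offset relative to the
    continuous surface whose mean differs slightly between flat and curved
    CSF surfaces (≈0.5 mm vs ≈0.42 mm on a 1 mm grid).  A narrow-span lesion
    sample mixing the two surface types therefore inherits an offset–distance
    covariance worth a few percent of the slope.  This layout controls for
    that: each lesion class is a column of spheres stacked over a wide
    distance range whose nearest CSF is the flat outer shell, so the offset
    is a constant and recovery isolates the pipeline itself.  The ventricle
    is kept small (but present, so both CSF surfaces exist).
    """
    return PhantomSpec(
        ventricle_semiaxes=(6.0, 6.0, 6.0),
        lesions=[
            Lesion((10.0, 13.0, 13.0), 4.0, "IRL"),
            Lesion((19.0, 13.0, 13.0), 4.0, "IRL"),
            Lesion((28.0, 13.0, 13.0), 4.0, "IRL"),
            Lesion((54.0, 51.0, 51.0), 4.0, "nonIRL"),
            Lesion((45.0, 51.0, 51.0), 4.0, "nonIRL"),
            Lesion((36.0, 51.0, 51.0), 4.0, "nonIRL"),
        ],
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# synthetic laboratory cohort
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohortSpec:
    """Two-group cohort of laboratory profiles.

    Group labels follow the study design: ``IRL+`` (at least one iron-rim
    lesion) vs ``IRL-`` (none).  Per-group intrathecal-IgG prevalences default
    to the observed 37/51 and 28/51.  Q_alb is log-normal around a median of
    5×10⁻³; intrathecal fractions, given synthesis, are uniform on
    [5, 65] %.  All draws flow from ``seed``.
    """

    n_per_group: int = 51
    groups: tuple[str, str] = ("IRL+", "IRL-")
    p_intrathecal: dict = field(default_factory=lambda: {"IRL+": 37 / 51, "IRL-": 28 / 51})
    fraction_range_pct: tuple[float, float] = (5.0, 65.0)
    age_mean: float = 40.0
    age_sd: float = 12.0
    age_bounds: tuple[float, float] = (18.0, 75.0)
    qalb_median: float = 5.0e-3
    qalb_log_sd: float = 0.40
    serum_albumin_g_l: tuple[float, float] = (42.0, 3.0)   # mean, sd
    serum_igg_g_l: tuple[float, float] = (10.0, 2.0)
    serum_iga_g_l: tuple[float, float] = (2.2, 0.6)
    serum_igm_g_l: tuple[float, float] = (1.0, 0.4)
    p_intrathecal_iga: float = 0.09
    p_intrathecal_igm: float = 0.28
    seed: int = 0

    def __post_init__(self):
        for g, p in self.p_intrathecal.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_intrathecal[{g!r}] must be in [0, 1], got {p}")
        lo, hi = self.fraction_range_pct
        if not (0 <= lo <= hi < 100):
            raise ValueError("fraction range must lie in [0, 100)")


@dataclass
class CohortResult:
    """Generated profiles plus the generating ground truth."""

    profiles: pd.DataFrame   # columns of reiber.CSV_COLUMNS plus "group"
    truth: pd.DataFrame      # per patient: synthesis flags and imposed fractions


def _draw_class_quotient(rng, q_lim_val, synthesis: bool, frac_range):
    if synthesis:
        f = rng.uniform(*frac_range)
        return q_lim_val / (1.0 - f / 100.0), f
    return q_lim_val * rng.uniform(0.30, 0.95), 0.0


def make_cohort(
    spec: SyntheticCohortSpec,
    constants: reiber.ReiberConstants = reiber.DEFAULT_CONSTANTS,
) -> CohortResult:
    """Generate the two-group cohort; reproducible under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    rows, truth_rows = [], []
    for group in spec.groups:
        p_syn = spec.p_intrathecal[group]
        for i in range(spec.n_per_group):
            pid = f"{'rim' if group == spec.groups[0] else 'ctl'}{i:03d}"
            age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), *spec.age_bounds))
            q_alb = spec.qalb_median * float(np.exp(rng.normal(0.0, spec.qalb_log_sd)))
            alb_serum = max(20.0, rng.normal(*spec.serum_albumin_g_l))
            alb_csf = q_alb * alb_serum * 1000.0
            synthesis = {
                "IgG": bool(rng.random() < p_syn),
                "IgA": bool(rng.random() < spec.p_intrathecal_iga),
                "IgM": bool(rng.random() < spec.p_intrathecal_igm),
            }
            serum = {
                "IgG": max(3.0, rng.normal(*spec.serum_igg_g_l)),
                "IgA": max(0.4, rng.normal(*spec.serum_iga_g_l)),
                "IgM": max(0.2, rng.normal(*spec.serum_igm_g_l)),
            }
            row = {
                "patient_id": pid, "group": group, "age": age,
                "albumin_csf_mg_l": alb_csf, "albumin_serum_g_l": alb_serum,
            }
            tr = {"patient_id": pid, "group": group}
            for cls in reiber.IG_CLASSES:
                ql = reiber.q_lim(cls, q_alb, constants)
                q_ig, f = _draw_class_quotient(rng, ql, synthesis[cls],
                                               spec.fraction_range_pct)
                tag = cls.lower()
                row[f"{tag}_csf_mg_l"] = q_ig * serum[cls] * 1000.0
                row[f"{tag}_serum_g_l"] = serum[cls]
                tr[f"has_{tag}_synthesis"] = synthesis[cls]
                tr[f"imposed_{tag}_fraction_pct"] = f
            row["leukocytes_per_ul"] = float(np.round(np.exp(rng.normal(1.2, 0.9))))
            row["ocb_positive"] = bool(synthesis["IgG"] or rng.random() < 0.6)
            rows.append(row)
            truth_rows.append(tr)
    return CohortResult(profiles=pd.DataFrame(rows), truth=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# whole-study simulation (imaging subset + laboratory cohort)
# ---------------------------------------------------------------------------


@dataclass
class StudySpec:
    """Joint imaging + laboratory study.

    A subset of each cohort group receives phantom volumes (imaging the full
    cohort is unnecessary for the gradient contrast).  Patients with
    intrathecal IgG synthesis get their decline slopes scaled by
    ``slope_scale_synthesis``, coupling humoral CNS inflammation to a steeper
    CSF-distance damage gradient.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)
    n_imaging_per_group: int = 5
    n_irl_lesions: int = 2
    n_non_irl_lesions: int = 3
    slope_scale_synthesis: float = 1.5
    seed: int = 0


def simulate_study_patients(study: StudySpec):
    """Yield (patient_id, group, resolved PhantomSpec, truth row) tuples.

    The cohort is drawn first (seeded from ``study.seed``); the first
    ``n_imaging_per_group`` patients of each group receive phantoms with
    per-patient lesion placements and noise seeds.  Patients in the no-rim
    group carry no IRL lesions.
    """
    ss = np.random.SeedSequence(study.seed)
    cohort_seed, img_seed = [int(s) for s in ss.generate_state(2) >> 1]
    cohort = make_cohort(replace(study.cohort, seed=cohort_seed))
    rng = np.random.default_rng(img_seed)
    patients = []
    for group in study.cohort.groups:
        sub = cohort.profiles[cohort.profiles["group"] == group]
        for pid in sub["patient_id"].iloc[: study.n_imaging_per_group]:
            tr = cohort.truth.set_index("patient_id").loc[pid]
            n_irl = study.n_irl_lesions if group == study.cohort.groups[0] else 0
            lesions = random_lesions(rng, study.phantom, n_irl, study.n_non_irl_lesions)
            scale = study.slope_scale_synthesis if tr["has_igg_synthesis"] else 1.0
            slopes = {k: v * scale for k, v in study.phantom.gradient_slope.items()}
            spec = replace(study.phantom, lesions=lesions, gradient_slope=slopes,
                           seed=int(rng.integers(0, 2**31 - 1)))
            patients.append((pid, group, spec))
    return cohort, patients
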