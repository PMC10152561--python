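"""Blood–CSF barrier function and intrathecal immunoglobulin synthesis.

Quantifies humoral immune activity inside the CNS from paired CSF/serum
laboratory values.  The central objects are the dimensionless CSF/serum
concentration quotients

    Q_alb = albumin_CSF / albumin_serum,   Q_Ig = Ig_CSF / Ig_serum,

computed after harmonising units (CSF values arrive in mg/L, serum values in
g/L).  Albumin is synthesised exclusively outside the CNS, so ``Q_alb`` probes
the blood–CSF barrier; its upper reference limit rises with age.  For each
immunoglobulin class the hyperbolic discrimination line

    Q_lim(Q_alb) = a · sqrt(Q_alb² + b²) − c

separates barrier-derived from intrathecally produced immunoglobulin: a
measured quotient above ``Q_lim`` indicates local synthesis, and the excess is
expressed either as the intrathecal fraction ``(1 − Q_lim/Q_Ig) · 100`` (% of
the total CSF immunoglobulin) or as the absolute locally produced CSF
concentration ``(Q_Ig − Q_lim) · Ig_serum`` in mg/L.

Quotients are stored as plain dimensionless numbers throughout; the clinical
×10⁻³ display convention is applied only when formatting reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IG_CLASSES",
    "HyperbolicConstants",
    "ReiberConstants",
    "DEFAULT_CONSTANTS",
    "CSFProfile",
    "ReiberResult",
    "MissingFieldError",
    "compute_quotient",
    "age_adjusted_qalb_limit",
    "q_lim",
    "intrathecal_fraction",
    "absolute_intrathecal_synthesis",
    "classify_profile",
    "classify_profiles",
    "reibergram_isolines",
    "read_profiles_csv",
    "results_to_frame",
    "plot_reibergram",
]

#: Immunoglobulin classes with a defined discrimination hyperbola.
IG_CLASSES = ("IgG", "IgA", "IgM")


class MissingFieldError(ValueError):
    """A mandatory laboratory value is absent from a profile."""

    def __init__(self, patient_id, field_name: str):
        self.patient_id = patient_id
        self.field_name = field_name
        super().__init__(
            f"profile {patient_id!r}: mandatory field {field_name!r} is missing"
        )


@dataclass(frozen=True)
class HyperbolicConstants:
    """Constants (a, b², c) of one class's discrimination hyperbola.

    ``slope`` is the asymptotic slope a, ``curvature`` the b² term on the
    squared-quotient scale and ``offset`` the c term on the quotient scale.
    """

    slope: float
    curvature: float
    offset: float

    def __post_init__(self):
        if not (self.slope > 0 and self.curvature > 0 and self.offset > 0):
            raise ValueError("hyperbola constants must all be positive")


@dataclass(frozen=True)
class ReiberConstants:
    """Per-class hyperbola constants; defaults are the canonical values."""

    igg: HyperbolicConstants = field(
        default_factory=lambda: HyperbolicConstants(0.93, 6e-6, 1.7e-3)
    )
    iga: HyperbolicConstants = field(
        default_factory=lambda: HyperbolicConstants(0.77, 23e-6, 3.1e-3)
    )
    igm: HyperbolicConstants = field(
        default_factory=lambda: HyperbolicConstants(0.67, 120e-6, 7.1e-3)
    )

    def for_class(self, ig_class: str) -> HyperbolicConstants:
        try:
            return {"IgG": self.igg, "IgA": self.iga, "IgM": self.igm}[ig_class]
        except KeyError:
            raise ValueError(
                f"unknown immunoglobulin class {ig_class!r}; expected one of {IG_CLASSES}"
            ) from None


DEFAULT_CONSTANTS = ReiberConstants()


def compute_quotient(csf_mg_l: float, serum_g_l: float) -> float:
    """CSF/serum concentration quotient (dimensionless).

    The CSF concentration arrives in mg/L, the serum concentration in g/L;
    the quotient is formed on a common mg/L scale.  Reports conventionally
    print the result ×10³ (a returned 0.00481 reads 4.81 clinically).
    """
    if serum_g_l <= 0:
        raise ValueError(f"serum concentration must be positive, got {serum_g_l}")
    if csf_mg_l < 0:
        raise ValueError(f"CSF concentration must be non-negative, got {csf_mg_l}")
    return csf_mg_l / (serum_g_l * 1000.0)


def age_adjusted_qalb_limit(
    age_years: float, *, intercept: float = 4e-3, slope_per_year: float = 1e-3 / 15.0
) -> float:
    """Upper reference limit of Q_alb for an intact barrier at a given age.

    Uses the standard age formula (4 + age/15) × 10⁻³; the coefficient pair is
    configurable.  Q_alb above this limit indicates blood–CSF barrier
    dysfunction.
    """
    if age_years <= 0:
        raise ValueError(f"age must be positive, got {age_years}")
    return intercept + slope_per_year * age_years


def q_lim(
    ig_class: str, q_alb, constants: ReiberConstants = DEFAULT_CONSTANTS
):
    """Discrimination limit Q_lim = a·sqrt(Q_alb² + b²) − c for one Ig class.

    Strictly increasing and convex in ``q_alb``; accepts scalars or arrays.
    """
    c = constants.for_class(ig_class)
    q_alb = np.asarray(q_alb, dtype=float)
    if np.any(q_alb < 0):
        raise ValueError("q_alb must be non-negative")
    out = c.slope * np.sqrt(q_alb**2 + c.curvature) - c.offset
    return float(out) if out.ndim == 0 else out


def intrathecal_fraction(q_ig: float, q_lim_val: float) -> float:
    """Intrathecally synthesised fraction in percent of total CSF Ig.

    ``max(0, 1 − Q_lim/Q_Ig) · 100``; zero at or below the discrimination
    limit, approaching (but never reaching) 100 for extreme quotients.
    """
    if q_lim_val <= 0:
        raise ValueError(f"q_lim must be positive, got {q_lim_val}")
    if q_ig <= 0:
        raise ValueError(f"q_ig must be positive, got {q_ig}")
    return max(0.0, 1.0 - q_lim_val / q_ig) * 100.0


def absolute_intrathecal_synthesis(
    q_ig: float, q_lim_val: float, ig_serum_g_l: float
) -> float:
    """Locally produced Ig concentration in CSF, mg/L.

    ``max(0, Q_Ig − Q_lim) · Ig_serum``, with serum in g/L converted to mg/L.
    """
    if ig_serum_g_l < 0:
        raise ValueError(f"serum concentration must be non-negative, got {ig_serum_g_l}")
    return max(0.0, q_ig - q_lim_val) * ig_serum_g_l * 1000.0


# ---------------------------------------------------------------------------
# per-patient profiles and classification
# ---------------------------------------------------------------------------

_CLASS_FIELDS = {"IgG": ("igg_csf", "igg_serum"),
                 "IgA": ("iga_csf", "iga_serum"),
                 "IgM": ("igm_csf", "igm_serum")}


@dataclass
class CSFProfile:
    """One patient's paired CSF/serum laboratory values.

    CSF concentrations in mg/L, serum concentrations in g/L, age in years.
    Albumin and age are mandatory; immunoglobulin classes, leukocyte count
    (cells/µL) and oligoclonal-band status are optional and propagate as
    absent (``None``), never as zero.
    """

    patient_id: str
    age: float
    albumin_csf: float
    albumin_serum: float
    igg_csf: float | None = None
    igg_serum: float | None = None
    iga_csf: float | None = None
    iga_serum: float | None = None
    igm_csf: float | None = None
    igm_serum: float | None = None
    leukocytes: float | None = None
    ocb_positive: bool | None = None

    def __post_init__(self):
        if self.age is None or not self.age > 0:
            raise ValueError(f"profile {self.patient_id!r}: age must be positive")
        for name in ("albumin_csf", "albumin_serum", "igg_csf", "igg_serum",
                     "iga_csf", "iga_serum", "igm_csf", "igm_serum", "leukocytes"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(
                    f"profile {self.patient_id!r}: {name} must be non-negative, got {v}"
                )

    def class_pair(self, ig_class: str) -> tuple[float, float] | None:
        """(csf mg/L, serum g/L) for one Ig class, or None if absent.

        A half-present pair (CSF without serum or vice versa) is an error.
        """
        csf_name, serum_name = _CLASS_FIELDS[ig_class]
        csf, serum = getattr(self, csf_name), getattr(self, serum_name)
        if csf is None and serum is None:
            return None
        if csf is None:
            raise MissingFieldError(self.patient_id, csf_name)
        if serum is None:
            raise MissingFieldError(self.patient_id, serum_name)
        return csf, serum


@dataclass
class ReiberResult:
    """Derived barrier status and intrathecal-synthesis quantities.

    Per-class dictionaries hold ``None`` for classes absent from the input
    profile.  Invariant: ``intrathecal[c]`` ⇔ ``fraction_pct[c] > 0`` ⇔
    ``absolute_mg_per_l[c] > 0`` ⇔ ``q_ig[c] > q_lim[c]``.
    """

    patient_id: str
    q_alb: float
    q_alb_limit: float
    barrier_dysfunction: bool
    q_ig: dict
    q_lim: dict
    intrathecal: dict
    fraction_pct: dict
    absolute_mg_per_l: dict


def classify_profile(
    profile: CSFProfile, constants: ReiberConstants = DEFAULT_CONSTANTS
) -> ReiberResult:
    """Full barrier / intrathecal-synthesis classification of one profile."""
    if profile.albumin_csf is None:
        raise MissingFieldError(profile.patient_id, "albumin_csf")
    if profile.albumin_serum is None:
        raise MissingFieldError(profile.patient_id, "albumin_serum")
    qalb = compute_quotient(profile.albumin_csf, profile.albumin_serum)
    limit = age_adjusted_qalb_limit(profile.age)
    q_ig: dict = {}
    q_lims: dict = {}
    flags: dict = {}
    fracs: dict = {}
    absolutes: dict = {}
    for cls in IG_CLASSES:
        pair = profile.class_pair(cls)
        if pair is None:
            q_ig[cls] = q_lims[cls] = flags[cls] = fracs[cls] = absolutes[cls] = None
            continue
        csf, serum = pair
        qi = compute_quotient(csf, serum)
        ql = q_lim(cls, qalb, constants)
        q_ig[cls] = qi
        q_lims[cls] = ql
        flags[cls] = qi > ql
        fracs[cls] = intrathecal_fraction(qi, ql) if qi > 0 else 0.0
        absolutes[cls] = absolute_intrathecal_synthesis(qi, ql, serum)
    return ReiberResult(
        patient_id=profile.patient_id,
        q_alb=qalb,
        q_alb_limit=limit,
        barrier_dysfunction=qalb > limit,
        q_ig=q_ig,
        q_lim=q_lims,
        intrathecal=flags,
        fraction_pct=fracs,
        absolute_mg_per_l=absolutes,
    )


def classify_profiles(
    profiles: Iterable[CSFProfile], constants: ReiberConstants = DEFAULT_CONSTANTS
) -> list[ReiberResult]:
    """Classify a batch of profiles, preserving input order."""
    return [classify_profile(p, constants) for p in profiles]


def reibergram_isolines(
    ig_class: str,
    fractions: Sequence[float] = (20.0, 40.0, 60.0, 80.0),
    q_alb_grid: np.ndarray | None = None,
    constants: ReiberConstants = DEFAULT_CONSTANTS,
) -> dict[float, tuple[np.ndarray, np.ndarray]]:
    """Isolines of constant intrathecal fraction on the quotient diagram.

    For fraction f the curve is ``Q_Ig(Q_alb) = Q_lim(Q_alb) / (1 − f/100)``,
    so evaluating :func:`intrathecal_fraction` on any emitted point recovers f.
    f = 0 yields the discrimination line itself.
    """
    if q_alb_grid is None:
        q_alb_grid = np.logspace(math.log10(1.5e-3), math.log10(0.15), 200)
    q_alb_grid = np.asarray(q_alb_grid, dtype=float)
    curves: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for f in fractions:
        if not (0.0 <= f < 100.0):
            raise ValueError(f"fraction must be in [0, 100), got {f}")
        q = q_lim(ig_class, q_alb_grid, constants) / (1.0 - f / 100.0)
        curves[float(f)] = (q_alb_grid.copy(), q)
    return curves


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

#: CSV column → CSFProfile field.  Concentration units are in the names.
CSV_COLUMNS = {
    "patient_id": "patient_id",
    "age": "age",
    "albumin_csf_mg_l": "albumin_csf",
    "albumin_serum_g_l": "albumin_serum",
    "igg_csf_mg_l": "igg_csf",
    "igg_serum_g_l": "igg_serum",
    "iga_csf_mg_l": "iga_csf",
    "iga_serum_g_l": "iga_serum",
    "igm_csf_mg_l": "igm_csf",
    "igm_serum_g_l": "igm_serum",
    "leukocytes_per_ul": "leukocytes",
    "ocb_positive": "ocb_positive",
}

_MANDATORY_COLUMNS = ("patient_id", "age", "albumin_csf_mg_l", "albumin_serum_g_l")


def read_profiles_csv(path) -> list[CSFProfile]:
    """Load per-patient profiles from a CSV with the documented column names."""
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    profiles = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, attr in CSV_COLUMNS.items():
            if col not in df.columns:
                continue
            v = row[col]
            if pd.isna(v):
                v = None
            elif attr == "ocb_positive":
                v = bool(v)
            elif attr == "patient_id":
                v = str(v)
            else:
                v = float(v)
            kwargs[attr] = v
        profiles.append(CSFProfile(**kwargs))
    return profiles


def results_to_frame(results: Iterable[ReiberResult]) -> pd.DataFrame:
    """Flatten classification results to one row per patient.

    Quotients are reported on the clinical ×10³ scale (column suffix ``_x1e3``).
    """
    rows = []
    for r in results:
        row = {
            "patient_id": r.patient_id,
            "q_alb_x1e3": r.q_alb * 1e3,
            "q_alb_limit_x1e3": r.q_alb_limit * 1e3,
            "barrier_dysfunction": r.barrier_dysfunction,
        }
        for cls in IG_CLASSES:
            tag = cls.lower()
            q = r.q_ig[cls]
            row[f"q_{tag}_x1e3"] = None if q is None else q * 1e3
            ql = r.q_lim[cls]
            row[f"q_lim_{tag}_x1e3"] = None if ql is None else ql * 1e3
            row[f"intrathecal_{tag}"] = r.intrathecal[cls]
            row[f"fraction_{tag}_pct"] = r.fraction_pct[cls]
            row[f"absolute_{tag}_mg_l"] = r.absolute_mg_per_l[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def plot_reibergram(
    results: Sequence[ReiberResult],
    ig_class: str = "IgG",
    path=None,
    constants: ReiberConstants = DEFAULT_CONSTANTS,
    groups: Mapping[str, str] | None = None,
):
    """Quotient diagram: discrimination line, fraction isolines, patients.

    Log–log axes; dashed isolines mark 20/40/60/80% intrathecal fractions.
    ``groups`` optionally maps patient_id → group label for colour coding.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    curves = reibergram_isolines(ig_class, (0.0, 20.0, 40.0, 60.0, 80.0),
                                 constants=constants)
    for f, (qa, qi) in curves.items():
        style = "-" if f == 0 else "--"
        ax.plot(qa * 1e3, qi * 1e3, style, color="0.4", lw=1)
        ax.annotate(f"{f:.0f}%" if f else "Q_lim", (qa[-1] * 1e3, qi[-1] * 1e3),
                    fontsize=7, color="0.3")
    labels = sorted({(groups or {}).get(r.patient_id, "patients") for r in results})
    colors = dict(zip(labels, plt.rcParams["axes.prop_cycle"].by_key()["color"]))
    seen = set()
    for r in results:
        if r.q_ig[ig_class] is None:
            continue
        g = (groups or {}).get(r.patient_id, "patients")
        ax.plot(r.q_alb * 1e3, r.q_ig[ig_class] * 1e3, "o", ms=3,
                color=colors[g], label=None if g in seen else g)
        seen.add(g)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$Q_{alb}\ \times 10^3$")
    ax.set_ylabel(rf"$Q_{{{ig_class}}}\ \times 10^3$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
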