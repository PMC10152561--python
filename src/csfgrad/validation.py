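"""Self-validation experiments with known ground truth.

Three experiments exercise the whole pipeline against quantities that are
known by construction:

- an exhaustive check of the distance transform against the all-pairs
  minimum over CSF voxels on small random masks (isotropic and anisotropic);
- noiseless slope recovery: a phantom with an imposed linear ADC decline is
  pushed through mask construction, distance transform, exclusions and
  regression, and the recovered per-class slope is compared with the truth;
- a two-group contrast: groups whose imposed decline slopes differ two-fold
  at equal noise must yield stronger negative correlations in the steep
  group and significant Fisher z for every tissue class.

These functions back the package's self-check script and tests; they are
ordinary library code and can be used to sanity-check any re-parametrisation.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import phantom as ph
from .config import PipelineConfig
from .gradient import (PatientVolumes, distance_correlation,
                       euclidean_distance_to_csf, fisher_compare,
                       process_patient)

__all__ = [
    "brute_force_distance",
    "distance_transform_validation",
    "slope_recovery_experiment",
    "contrast_phantom_specs",
    "contrast_experiment",
]


def brute_force_distance(csf: np.ndarray, spacing) -> np.ndarray:
    """All-pairs minimum distance oracle (O(N·M); small grids only)."""
    csf = np.asarray(csf, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    all_idx = np.argwhere(np.ones_like(csf)) * spacing
    csf_idx = np.argwhere(csf) * spacing
    d2 = ((all_idx[:, None, :] - csf_idx[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1)).reshape(csf.shape)


def distance_transform_validation(
    seed: int, n_masks: int = 20, shape=(16, 16, 16),
    spacings=((1.0, 1.0, 1.0), (1.0, 1.0, 3.0)),
) -> float:
    """Max |EDT − brute force| over seeded random masks; 0 means exact."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_masks):
        mask = rng.random(shape) < rng.uniform(0.02, 0.15)
        if not mask.any():
            mask.flat[rng.integers(mask.size)] = True
        for spacing in spacings:
            dt = euclidean_distance_to_csf(mask, spacing)
            ref = brute_force_distance(mask, spacing)
            worst = max(worst, float(np.abs(dt - ref).max()))
    return worst


def _run_phantom(spec: ph.PhantomSpec, patient_id="p0", config=None) -> pd.DataFrame:
    out = ph.make_phantom(spec)
    pv = PatientVolumes(patient_id, out.adc, out.masks.wm, out.masks.irl,
                        out.masks.non_irl, csf_prob=out.prob["CSF"])
    return process_patient(pv, config or PipelineConfig())


def slope_recovery_experiment(config: PipelineConfig | None = None) -> pd.DataFrame:
    """Recover imposed ADC decline slopes from a noiseless phantom.

    Uses :func:`csfgrad.phantom.recovery_phantom_spec` and restricts the
    regression to distances one voxel inside the gradient range, where the
    imposed relation is strictly linear.  Returns one row per tissue class
    with the imposed and recovered slope, relative error in percent, and
    both correlation coefficients.
    """
    spec = ph.recovery_phantom_spec()
    table = _run_phantom(spec, config=config)
    dmax = spec.gradient_range_mm - max(spec.spacing)
    rows = []
    for cls in ("IRL", "nonIRL", "NAWM"):
        ols = distance_correlation(table, cls, "pearson", max_distance_mm=dmax)
        rank = distance_correlation(table, cls, "spearman", max_distance_mm=dmax)
        imposed = -spec.gradient_slope[cls]
        rows.append({
            "tissue_class": cls,
            "n": ols.n,
            "imposed_slope": imposed,
            "recovered_slope": ols.slope,
            "rel_err_pct": 100.0 * abs(ols.slope - imposed) / abs(imposed),
            "pearson_r": ols.r,
            "spearman_r": rank.r,
        })
    return pd.DataFrame(rows)


def contrast_phantom_specs() -> tuple[ph.PhantomSpec, ph.PhantomSpec]:
    """(low, high) specs for the group contrast: identical geometry, the
    high group's decline slopes doubled; noise at the study default."""
    radius = 4.5
    lesions = [
        ph.Lesion((10.0, 13.0, 13.0), radius, "IRL"),
        ph.Lesion((19.0, 13.0, 13.0), radius, "IRL"),
        ph.Lesion((28.0, 13.0, 13.0), radius, "IRL"),
        ph.Lesion((54.0, 51.0, 51.0), radius, "nonIRL"),
        ph.Lesion((45.0, 51.0, 51.0), radius, "nonIRL"),
        ph.Lesion((36.0, 51.0, 51.0), radius, "nonIRL"),
    ]
    low = replace(ph.recovery_phantom_spec(), lesions=lesions)
    high = replace(low, gradient_slope={k: 2 * v for k, v in low.gradient_slope.items()})
    return low, high


def contrast_experiment(
    seed: int, n_replicates: int = 20, n_patients_per_group: int = 10
) -> pd.DataFrame:
    """Two-fold slope contrast between groups at equal noise.

    The geometry is fixed across patients and replicates (only measurement
    noise varies), so per-patient fields are the shared noiseless field plus
    fresh Gaussian noise at the study's default ADC noise level.  Per
    replicate and tissue class the pooled rank correlation of each group and
    the between-group Fisher z (on correlation magnitudes) are reported.
    """
    low_spec, high_spec = contrast_phantom_specs()
    base = {"low": _run_phantom(low_spec), "high": _run_phantom(high_spec)}
    noise_sd = ph.PhantomSpec().noise_sd
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        for cls in ("IRL", "nonIRL", "NAWM"):
            res = {}
            for grp in ("low", "high"):
                sub = base[grp][base[grp]["tissue_class"] == cls]
                d = np.tile(sub["distance_mm"].to_numpy(), n_patients_per_group)
                a = np.tile(sub["adc_mm2_per_s"].to_numpy(), n_patients_per_group)
                a = a + rng.normal(0.0, noise_sd, a.size)
                r, _ = sps.spearmanr(d, a)
                res[grp] = (float(r), d.size)
            z, p = fisher_compare(abs(res["high"][0]), res["high"][1],
                                  abs(res["low"][0]), res["low"][1])
            rows.append({"replicate": rep, "tissue_class": cls,
                         "r_low": res["low"][0], "r_high": res["high"][0],
                         "n_low": res["low"][1], "n_high": res["high"][1],
                         "z": z, "p": p,
                         "stronger_in_high": abs(res["high"][0]) > abs(res["low"][0])})
    return pd.DataFrame(rows)
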