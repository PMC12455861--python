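"""End-to-end validation routines with independent oracles.

Every routine here re-derives a quantity the package computes through an
independent route — exhaustive voxel enumeration in plain Python loops,
closed-form geometry, or Monte-Carlo simulation from known generative
parameters — and reports the agreement. The oracles deliberately avoid the
vectorized code paths they check.

These routines back both the validation test suite and the
``scripts/acceptance.py`` report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .lesion_quant import (
    LesionError,
    damage_profile,
    lesion_volume,
    project_lesion,
    tract_damage,
)
from .midsagittal import classify_lesion_type, midsagittal_slice, tissue_bridges, TissueBridges
from .phantoms import (
    CohortSpec,
    GridSpec,
    LesionSpec,
    PhantomConfig,
    lesion_spec_for_type,
    make_cohort,
    make_cord_and_atlas,
    make_lesion,
)
from .stats_models import (
    build_lateralized_table,
    fit_lateralized_prediction,
    fit_longitudinal,
)
from .volumes_io import SoftMask, VoxelGrid

__all__ = [
    "brute_force_tract_damage",
    "run_overlap_oracle",
    "run_projection_conservation",
    "run_ellipsoid_volume_check",
    "run_lesion_type_check",
    "run_longitudinal_coverage",
    "run_lateralized_recovery",
    "run_type1_error",
    "run_monotonicity",
    "run_determinism",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Oracle: exhaustive voxel enumeration for tract damage
# ---------------------------------------------------------------------------


def brute_force_tract_damage(
    lesion: np.ndarray, tract: np.ndarray, threshold: float = 0.01
) -> float | None:
    """Tract-damage percentage by plain-Python exhaustive enumeration.

    Walks every voxel; the superior–inferior span is found by scanning
    slices. Returns None when the tract has no mass within the span (the
    vectorized implementation raises in that case).
    """
    n0, n1, n2 = lesion.shape
    lo, hi = None, None
    for k in range(n2):
        found = False
        for i in range(n0):
            for j in range(n1):
                if lesion[i, j, k] > threshold:
                    found = True
                    break
            if found:
                break
        if found:
            if lo is None:
                lo = k
            hi = k
    if lo is None:
        raise LesionError("no lesion above threshold")
    num = 0.0
    den = 0.0
    for k in range(lo, hi + 1):
        for i in range(n0):
            for j in range(n1):
                t = tract[i, j, k]
                den += t
                num += min(lesion[i, j, k], 1.0) * t
    if den == 0.0:
        return None
    return 100.0 * num / den


def run_overlap_oracle(n_cases: int = 500, seed: int = 0) -> dict:
    """Random binary phantoms <= 16^3: vectorized damage vs enumeration."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        shape = tuple(int(rng.integers(4, 17)) for _ in range(3))
        spacing = tuple(float(rng.uniform(0.3, 3.0)) for _ in range(3))
        grid = VoxelGrid(shape, spacing)
        lesion_arr = (rng.random(shape) < rng.uniform(0.05, 0.5)).astype(np.float64)
        tract_arr = (rng.random(shape) < rng.uniform(0.05, 0.5)).astype(np.float64)
        if not lesion_arr.any():
            lesion_arr[tuple(int(rng.integers(0, s)) for s in shape)] = 1.0
        lesion = SoftMask(grid, lesion_arr)
        tract = SoftMask(grid, tract_arr)
        expected = brute_force_tract_damage(lesion_arr, tract_arr)
        if expected is None:
            try:
                tract_damage(lesion, tract)
            except LesionError:
                agree += 1
            continue
        got = tract_damage(lesion, tract)
        if got == expected or abs(got - expected) <= 1e-12 * max(1.0, expected):
            agree += 1
    return {"n_cases": n_cases, "agreement_rate_pct": 100.0 * agree / n_cases}


def run_projection_conservation(n_lesions: int = 100, seed: int = 0) -> dict:
    """Random soft lesions: all three projection maps integrate to the volume."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_lesions):
        shape = tuple(int(rng.integers(6, 32)) for _ in range(3))
        spacing = tuple(float(rng.uniform(0.25, 4.0)) for _ in range(3))
        grid = VoxelGrid(shape, spacing)
        vals = rng.random(shape) * (rng.random(shape) < 0.4)
        lesion = SoftMask(grid, vals)
        maps = project_lesion(lesion)
        vol = lesion_volume(lesion)
        for plane in ("axial", "coronal", "sagittal"):
            rel = abs(maps.plane_volume_mm3(plane) - vol) / max(vol, 1e-30)
            worst = max(worst, rel)
    return {"n_lesions": n_lesions, "max_relative_error": worst}


def run_ellipsoid_volume_check() -> dict:
    """Hard-edged ellipsoid on a 0.25 mm grid vs (4/3) * pi * a * b * c."""
    grid_spec = GridSpec(shape=(48, 48, 96), spacing=(0.25, 0.25, 0.25))
    radii = (2.0, 2.5, 8.0)
    config = PhantomConfig(
        grid=grid_spec,
        lesion=LesionSpec(radii_mm=radii, edge_mm=0.0),
    )
    # Large cord so the cord intersection does not truncate the ellipsoid.
    config = dataclasses.replace(config, cord=dataclasses.replace(config.cord, radius_mm=50.0))
    lesion, truth = make_lesion(config)
    analytic = truth["analytic_ellipsoid_volume_mm3"]
    measured = lesion_volume(lesion)
    return {
        "measured_mm3": measured,
        "analytic_mm3": analytic,
        "error_pct": 100.0 * abs(measured - analytic) / analytic,
    }


def run_lesion_type_check() -> dict:
    """Bridge sign-pattern truth table plus end-to-end phantom lesion types."""
    table_ok = (
        classify_lesion_type(TissueBridges(1.2, 0.8)) == "central"
        and classify_lesion_type(TissueBridges(0.0, 0.8)) == "ventral"
        and classify_lesion_type(TissueBridges(1.2, 0.0)) == "dorsal"
        and classify_lesion_type(TissueBridges(0.0, 0.0)) == "complete"
    )
    config = PhantomConfig()
    cord, atlas = make_cord_and_atlas(config)
    n_match = 0
    types = ("central", "ventral", "dorsal", "complete")
    for target in types:
        cfg = dataclasses.replace(config, lesion=lesion_spec_for_type(target, config.cord))
        lesion, _ = make_lesion(cfg, cord=cord, atlas=atlas)
        mid = midsagittal_slice(cord)
        bridges = tissue_bridges(lesion, cord, mid)
        if bridges.defined and classify_lesion_type(bridges) == target:
            n_match += 1
    return {
        "truth_table_ok": bool(table_ok),
        "phantom_type_agreement_pct": 100.0 * n_match / len(types),
    }


def run_longitudinal_coverage(n_reps: int = 200, seed: int = 0) -> dict:
    """CI coverage of the true lesion-volume slope over synthetic cohorts."""
    logging.disable(logging.WARNING)
    try:
        covered = 0
        true_slope = CohortSpec().volume_slope_per_month
        for r in range(n_reps):
            cohort, _ = make_cohort(PhantomConfig(seed=seed * 100003 + r))
            res = fit_longitudinal(cohort, "lesion_volume_mm3")
            lo, hi = res.ci95_raw
            covered += lo <= true_slope <= hi
    finally:
        logging.disable(logging.NOTSET)
    return {
        "n_reps": n_reps,
        "true_slope_mm3_per_month": true_slope,
        "ci95_coverage_pct": 100.0 * covered / n_reps,
    }


def run_lateralized_recovery(n_reps: int = 200, seed: int = 0) -> dict:
    """Sign recovery and bias of the standardized damage->recovery effect."""
    logging.disable(logging.WARNING)
    try:
        beta_true = CohortSpec().beta_motor
        est = []
        for r in range(n_reps):
            cohort, _ = make_cohort(PhantomConfig(seed=seed * 100019 + r))
            lat = build_lateralized_table(cohort, "motor_damage", "motor")
            res = fit_lateralized_prediction(lat)
            est.append(res.coef_standardized)
    finally:
        logging.disable(logging.NOTSET)
    est_arr = np.asarray(est)
    return {
        "n_reps": n_reps,
        "beta_true": beta_true,
        "sign_recovery_pct": 100.0 * float((np.sign(est_arr) == np.sign(beta_true)).mean()),
        "beta_mean": float(est_arr.mean()),
        "beta_mc_sem": float(est_arr.std(ddof=1) / np.sqrt(n_reps)),
    }


def run_type1_error(n_reps: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Empirical rejection rate when the true coupling is zero."""
    logging.disable(logging.WARNING)
    try:
        null_spec = CohortSpec(beta_motor=0.0, beta_pinprick=0.0)
        rejected = 0
        for r in range(n_reps):
            cohort, _ = make_cohort(PhantomConfig(seed=seed * 100043 + r, cohort=null_spec))
            lat = build_lateralized_table(cohort, "motor_damage", "motor")
            res = fit_lateralized_prediction(lat)
            rejected += res.p_value < alpha
    finally:
        logging.disable(logging.NOTSET)
    return {"n_reps": n_reps, "alpha": alpha, "type1_error_rate": rejected / n_reps}


def run_monotonicity(n_pairs: int = 200, seed: int = 0) -> dict:
    """Nested lesion pairs: growing a lesion never decreases damage or
    volume and never increases a bridge width."""
    rng = np.random.default_rng(seed)
    config = PhantomConfig()
    cord, atlas = make_cord_and_atlas(config)
    grid = cord.grid
    mid = midsagittal_slice(cord)
    from .atlas import group_mask

    masks = {
        "motor_left": group_mask(atlas, "motor", "left"),
        "sensory_right": group_mask(atlas, "sensory", "right"),
    }
    violations = 0
    for _ in range(n_pairs):
        small_vals = rng.random(grid.shape) * (rng.random(grid.shape) < 0.15) * cord.values
        extra = rng.random(grid.shape) * (rng.random(grid.shape) < 0.1) * cord.values
        big_vals = np.maximum(small_vals, extra)
        small = SoftMask(grid, small_vals)
        big = SoftMask(grid, big_vals)
        if small.is_empty(0.01) or big.is_empty(0.01):
            continue
        if lesion_volume(big) < lesion_volume(small) - 1e-12:
            violations += 1
            continue
        for tract in masks.values():
            # the span may widen with the lesion; compare on the same footing
            try:
                d_small = tract_damage(small, tract, restrict_to_lesion_span=False)
                d_big = tract_damage(big, tract, restrict_to_lesion_span=False)
            except LesionError:
                continue
            if d_big < d_small - 1e-9:
                violations += 1
        b_small = tissue_bridges(small, cord, mid)
        b_big = tissue_bridges(big, cord, mid)
        if b_small.defined and b_big.defined:
            if (
                b_big.ventral_mm > b_small.ventral_mm + 1e-12
                or b_big.dorsal_mm > b_small.dorsal_mm + 1e-12
            ):
                violations += 1
    return {"n_pairs": n_pairs, "violations": violations}


def _hash_tree(root: Path) -> str:
    digest = hashlib.sha256()
    for path in sorted(root.rglob("*")):
        if path.is_file():
            digest.update(path.relative_to(root).as_posix().encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()


def run_determinism(workdir: str | Path, seed: int = 0, n_patients: int = 4) -> dict:
    """Full phantom -> quantify -> fit pipeline twice; outputs must match
    byte for byte under a fixed seed."""
    from .atlas import load_atlas
    from .volumes_io import read_mask

    workdir = Path(workdir)
    hashes = []
    for run_label in ("run_a", "run_b"):
        out = workdir / run_label
        spec = dataclasses.replace(CohortSpec(), n_patients=n_patients, availability=(1.0, 1.0, 1.0))
        config = PhantomConfig(seed=seed, cohort=spec)
        cohort, _ = make_cohort(config, out_dir=out, with_volumes=True)
        atlas = load_atlas(out / "atlas", out / "atlas" / "manifest.csv")
        cord = read_mask(out / "cord.nii.gz")
        profiles = []
        for pid in sorted(cohort["patient_id"].unique()):
            for tp in cohort.loc[cohort["patient_id"] == pid, "timepoint"]:
                lesion = read_mask(out / "patients" / pid / f"lesion_{tp}.nii.gz")
                prof = damage_profile(lesion, cord, atlas, pid, tp)
                profiles.append(prof.to_dict())
        with open(out / "profiles.json", "w") as fh:
            json.dump(profiles, fh, indent=2, sort_keys=True)
        logging.disable(logging.WARNING)
        try:
            res = fit_longitudinal(cohort, "lesion_volume_mm3")
        finally:
            logging.disable(logging.NOTSET)
        with open(out / "fit.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2, sort_keys=True)
        hashes.append(_hash_tree(out))
    return {"identical": hashes[0] == hashes[1], "hash": hashes[0]}
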