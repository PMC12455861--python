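"""Synthetic phantoms: cords, tract atlases, lesions and cohorts.

The study data this package is built for (acute cervical SCI, template-space
lesion/cord segmentations plus ISNCSCI exams over three timepoints) are not
publicly deposited, so every downstream module is validated against
generated phantoms that carry their own analytically known ground truth:

* **Cord + atlas** — a straight cylindrical cord whose white-matter annulus
  is partitioned into disjoint angular sectors, one per tract, mirrored
  left/right. Sensory tracts occupy the posterior (dorsal) sectors, motor
  tracts the anterior, echoing the dorsal-column / ventrolateral layout of
  the real cord.
* **Lesion** — a soft ellipsoid (linear edge ramp, so fuzzy overlaps stay
  exactly enumerable) intersected with the cord; presets produce the four
  midsagittal lesion types (central / ventral / dorsal / complete).
* **Cohort** — per-patient trajectories with configured lesion-volume and
  damage slopes, clinical recovery slopes, and a damage->recovery coupling
  with a known standardized coefficient, enabling parameter-recovery tests
  of the statistical models.

All generation is driven by ``numpy.random.default_rng`` with an explicit
seed; a fixed seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import MOTOR_TRACTS, SENSORY_TRACTS, TractAtlas
from .volumes_io import SoftMask, VoxelGrid, write_mask

__all__ = [
    "PhantomConfig",
    "GridSpec",
    "CordSpec",
    "LesionSpec",
    "CohortSpec",
    "PhantomError",
    "make_cord_and_atlas",
    "make_lesion",
    "lesion_spec_for_type",
    "make_cohort",
    "write_atlas",
]

#: Study timepoints and their mean months post-injury (19.9 / 54.2 / 192.4
#: days after injury, in 30.4375-day months).
TIMEPOINT_MONTHS = {"baseline": 0.65, "month1": 1.78, "month6": 6.32}


class PhantomError(ValueError):
    """Invalid phantom configuration."""


@dataclass(frozen=True)
class GridSpec:
    """Template grid: 0.5 mm in-plane, thick sagittal-style S-I slices."""

    shape: tuple[int, int, int] = (40, 40, 24)
    spacing: tuple[float, float, float] = (0.5, 0.5, 2.0)

    def to_grid(self) -> VoxelGrid:
        return VoxelGrid(shape=self.shape, spacing=self.spacing)


@dataclass(frozen=True)
class CordSpec:
    """Cylindrical cord: ~8 mm diameter with a central gray-matter core."""

    radius_mm: float = 4.0
    gm_radius_mm: float = 1.6


@dataclass(frozen=True)
class LesionSpec:
    """Soft ellipsoidal lesion inside the cord.

    ``center_offset_mm`` is (right-left, posterior-anterior,
    inferior-superior) displacement from the cord axis midpoint; left and
    anterior are positive. ``edge_mm`` is the width of the linear soft-edge
    ramp (0 gives a hard binary ellipsoid).
    """

    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radii_mm: tuple[float, float, float] = (1.8, 2.0, 8.0)
    edge_mm: float = 0.0
    type_target: str = "central"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii_mm):
            raise PhantomError(f"lesion radii must be > 0, got {self.radii_mm}")
        if self.edge_mm < 0:
            raise PhantomError("soft-edge width must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic longitudinal cohort.

    Scales echo an acute cervical SCI trial cohort: n = 35, three
    timepoints, lesion volume around 380 mm^3 shrinking by ~14 mm^3/month,
    sensory/motor tract damage in the 60-70% range, motor recovery of ~5
    ISNCSCI points/month. The damage->recovery coupling is parameterized
    directly as a standardized coefficient ``beta_motor`` /
    ``beta_pinprick`` (variance components chosen to sum to 1, so the
    population standardized coefficient equals the configured beta).
    """

    n_patients: int = 35
    availability: tuple[float, float, float] = (1.0, 0.90, 0.94)  # baseline, month1, month6

    # Lesion volume trajectory (mm^3)
    volume_baseline_mean: float = 381.82
    volume_baseline_sd: float = 150.0
    volume_slope_per_month: float = -14.04
    volume_noise_sd: float = 40.0

    # Tract damage (%)
    sensory_damage_mean: float = 69.57
    sensory_damage_sd: float = 9.0
    sensory_damage_slope: float = -0.69
    motor_damage_mean: float = 63.07
    motor_damage_sd: float = 12.0
    motor_damage_slope: float = 0.02
    side_asymmetry_sd: float = 7.0
    damage_noise_sd: float = 2.5

    # Clinical scores (one-sided ISNCSCI points)
    motor_baseline_mean: float = 15.9   # ~31.8 total across sides
    lt_baseline_mean: float = 30.3
    pp_baseline_mean: float = 17.4
    score_baseline_sd: float = 8.0
    motor_slope_per_month: float = 2.475   # ~4.95 total points/month
    lt_slope_per_month: float = 1.14
    pp_slope_per_month: float = 1.03
    score_noise_sd: float = 2.0

    # Damage -> recovery coupling (standardized); variance partition
    # beta^2 + patient_var + resid_var = 1 keeps deltas unit-variance in z.
    beta_motor: float = -0.3
    beta_pinprick: float = -0.3
    beta_light_touch: float = 0.0
    delta_patient_var: float = 0.35
    delta_mean_motor: float = 11.2   # per-side points gained, month1 -> month6
    delta_mean_pinprick: float = 4.7
    delta_mean_light_touch: float = 5.2
    delta_sd_motor: float = 5.0
    delta_sd_pinprick: float = 3.5
    delta_sd_light_touch: float = 3.5
    #: Scale on the per-side delta residual (0 gives the noiseless limit).
    delta_noise_scale: float = 1.0
    #: Round emitted scores to integers (disable for noiseless-limit tests).
    round_scores: bool = True

    # Demographics
    age_mean: float = 47.5
    age_sd: float = 15.0
    p_female: float = 0.057
    centers: tuple[str, ...] = ("ZRH", "MNU", "HDG")
    center_probs: tuple[float, ...] = (0.5, 0.3, 0.2)


@dataclass(frozen=True)
class PhantomConfig:
    grid: GridSpec = field(default_factory=GridSpec)
    cord: CordSpec = field(default_factory=CordSpec)
    lesion: LesionSpec = field(default_factory=LesionSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0


def _coords_mm(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates (mm) about the grid centre, broadcastable.

    x is positive toward the left, y toward anterior, z toward superior.
    Even shapes put voxel centres off the midline, so no voxel sits at
    exactly x = 0 and left/right sector assignment is unambiguous.
    """
    n0, n1, n2 = grid.shape
    s0, s1, s2 = grid.spacing
    x = ((np.arange(n0) - (n0 - 1) / 2.0) * s0)[:, None, None]
    y = ((np.arange(n1) - (n1 - 1) / 2.0) * s1)[None, :, None]
    z = ((np.arange(n2) - (n2 - 1) / 2.0) * s2)[None, None, :]
    return x, y, z


def make_cord_and_atlas(config: PhantomConfig) -> tuple[SoftMask, TractAtlas]:
    """Straight cylindrical cord plus a sectorized tract atlas.

    The white-matter annulus (between the gray-matter core and the cord
    surface) is partitioned into one angular sector per tract and side:
    sensory tracts fill the posterior sectors, motor tracts the anterior,
    and the right side mirrors the left exactly. Sectors are disjoint, so
    tract masses sum to the annulus mass by construction.
    """
    grid = config.grid.to_grid()
    x, y, _ = _coords_mm(grid)
    r = np.sqrt(x**2 + y**2)
    cord_vals = (r <= config.cord.radius_mm).astype(np.float64)
    cord_vals = np.broadcast_to(cord_vals, grid.shape).copy()
    cord = SoftMask(grid, cord_vals, copy=False)

    annulus = (r > config.cord.gm_radius_mm) & (r <= config.cord.radius_mm)
    names = list(SENSORY_TRACTS) + list(MOTOR_TRACTS)  # posterior -> anterior order
    n_sectors = len(names)
    # Angle from the posterior direction in [0, pi]; mirror-symmetric in x.
    alpha = np.arctan2(np.abs(x), -y)
    sector = np.minimum((alpha / (np.pi / n_sectors)).astype(int), n_sectors - 1)

    tracts: dict[str, SoftMask] = {}
    group_of: dict[str, str] = {}
    side_of: dict[str, str] = {}
    for side, side_sel in (("left", x > 0), ("right", x < 0)):
        for k, name in enumerate(names):
            sel = annulus & side_sel & (sector == k)
            vals = np.broadcast_to(sel, grid.shape).astype(np.float64).copy()
            key = f"{name}_{side}"
            tracts[key] = SoftMask(grid, vals, copy=False)
            group_of[key] = "sensory" if name in SENSORY_TRACTS else "motor"
            side_of[key] = side
    return cord, TractAtlas(tracts=tracts, group_of=group_of, side_of=side_of)


def write_atlas(atlas: TractAtlas, directory: str | Path) -> Path:
    """Write all tract masks plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(atlas.tracts):
        fname = f"{name}.nii.gz"
        write_mask(atlas.tracts[name], directory / fname)
        rows.append(
            {
                "filename": fname,
                "tract_name": name,
                "group": atlas.group_of[name],
                "side": atlas.side_of[name],
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def lesion_spec_for_type(type_target: str, cord: CordSpec = CordSpec()) -> LesionSpec:
    """Preset lesion geometry producing each midsagittal lesion type."""
    R = cord.radius_mm
    if type_target == "central":
        return LesionSpec(center_offset_mm=(0.0, 0.0, 0.0), radii_mm=(1.6, 1.8, 8.0), type_target="central")
    if type_target == "ventral":
        return LesionSpec(center_offset_mm=(0.0, 0.5 * R, 0.0), radii_mm=(1.8, 0.65 * R, 8.0), type_target="ventral")
    if type_target == "dorsal":
        return LesionSpec(center_offset_mm=(0.0, -0.5 * R, 0.0), radii_mm=(1.8, 0.65 * R, 8.0), type_target="dorsal")
    if type_target == "complete":
        return LesionSpec(center_offset_mm=(0.0, 0.0, 0.0), radii_mm=(2.2, 1.5 * R, 8.0), type_target="complete")
    raise PhantomError(f"unknown lesion type target {type_target!r}")


def _ellipsoid_values(grid: VoxelGrid, spec: LesionSpec) -> np.ndarray:
    x, y, z = _coords_mm(grid)
    cx, cy, cz = spec.center_offset_mm
    rx, ry, rz = spec.radii_mm
    rho = np.sqrt(((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2)
    if spec.edge_mm == 0:
        return (rho <= 1.0).astype(np.float64)
    # Linear ramp of width edge_mm across the boundary, measured along the
    # shortest semi-axis so the ramp is at least edge_mm wide everywhere.
    r_ref = min(spec.radii_mm)
    return np.clip(0.5 + (1.0 - rho) * r_ref / spec.edge_mm, 0.0, 1.0)


def _scan_bridges(lesion2d: np.ndarray, cord2d: np.ndarray, ap_spacing: float) -> Optional[tuple[float, float]]:
    """Independent row-by-row bridge scan used for generator ground truth."""
    ventral = np.inf
    dorsal = np.inf
    seen = False
    for j in range(lesion2d.shape[1]):
        cord_idx = [i for i in range(lesion2d.shape[0]) if cord2d[i, j]]
        les_idx = [i for i in cord_idx if lesion2d[i, j]]
        if not cord_idx or not les_idx:
            continue
        seen = True
        ventral = min(ventral, sum(1 for i in cord_idx if i > max(les_idx)) * ap_spacing)
        dorsal = min(dorsal, sum(1 for i in cord_idx if i < min(les_idx)) * ap_spacing)
    if not seen:
        return None
    return float(ventral), float(dorsal)


def make_lesion(
    config: PhantomConfig,
    cord: Optional[SoftMask] = None,
    atlas: Optional[TractAtlas] = None,
    span_threshold: float = 0.01,
) -> tuple[SoftMask, dict]:
    """Build the configured lesion and its enumerated ground truth.

    The truth record holds, computed directly at generation time: the exact
    fuzzy per-tract overlap percentages (within the lesion's S-I span), the
    discretized and analytic ellipsoid volumes, midsagittal bridge widths
    from an independent row scan, and the intended lesion type.
    """
    if cord is None or atlas is None:
        cord, atlas = make_cord_and_atlas(config)
    grid = cord.grid
    spec = config.lesion

    raw = _ellipsoid_values(grid, spec)
    vals = raw * cord.values  # lesion lives inside the cord
    if not (vals > 0).any():
        raise PhantomError("configured lesion lies entirely outside the cord")
    lesion = SoftMask(grid, vals, copy=False)

    # --- enumerated truth -------------------------------------------------
    above = (vals > span_threshold).any(axis=(0, 1))
    lo, hi = int(np.flatnonzero(above)[0]), int(np.flatnonzero(above)[-1])
    sl = np.s_[:, :, lo : hi + 1]
    per_tract = {}
    for name, tract in atlas.tracts.items():
        denom = float(tract.values[sl].sum())
        per_tract[name] = (
            None if denom == 0 else 100.0 * float((vals[sl] * tract.values[sl]).sum()) / denom
        )
    by_group_side: dict[str, float] = {}
    for group in ("motor", "sensory"):
        for side in ("left", "right", "both"):
            members = atlas.members(group, side)
            num = sum(float((vals[sl] * atlas.tracts[m].values[sl]).sum()) for m in members)
            den = sum(float(atlas.tracts[m].values[sl].sum()) for m in members)
            by_group_side[f"{group}_{side}"] = 100.0 * num / den if den > 0 else 0.0

    mid_idx = int(round(float(
        (cord.values.sum(axis=(1, 2)) * np.arange(grid.shape[0])).sum() / cord.values.sum()
    )))
    scan = _scan_bridges(vals[mid_idx] >= 0.5, cord.values[mid_idx] >= 0.5, grid.spacing[1])
    if scan is None:
        bridges_truth: dict = {"defined": False}
        derived_type = None
    else:
        v_mm, d_mm = scan
        bridges_truth = {"defined": True, "ventral_mm": v_mm, "dorsal_mm": d_mm}
        derived_type = (
            "central" if v_mm > 0 and d_mm > 0
            else "ventral" if d_mm > 0
            else "dorsal" if v_mm > 0
            else "complete"
        )

    rx, ry, rz = spec.radii_mm
    truth = {
        "volume_mm3": float(vals.sum()) * grid.voxel_volume_mm3,
        "analytic_ellipsoid_volume_mm3": 4.0 / 3.0 * np.pi * rx * ry * rz,
        "si_bounds": (lo, hi),
        "per_tract_damage_pct": per_tract,
        "damage_pct": by_group_side,
        "bridges": bridges_truth,
        "lesion_type_intended": spec.type_target,
        "lesion_type_from_bridges": derived_type,
        "midsagittal_index": mid_idx,
    }
    return lesion, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _zscore_ref(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (x - mean) / sd


def make_cohort(
    config: PhantomConfig,
    out_dir: Optional[str | Path] = None,
    with_volumes: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Generate a longitudinal cohort with known recovery dynamics.

    Returns a long-format table (one row per patient x available timepoint)
    with demographic, imaging and per-side clinical columns, plus a truth
    record echoing every generative parameter. With ``out_dir`` the cohort
    CSV and truth JSON are written there; ``with_volumes`` additionally
    writes a per-patient lesion volume series, the shared cord, and the
    atlas as NIfTI files for end-to-end pipeline runs.

    The month1 -> month6 score change on each side is generated as

        delta = mean + sd * (beta * z(damage) + u_patient + eps)

    with ``var(u) + var(eps) = 1 - beta**2``, so ``beta`` *is* the
    population standardized regression coefficient of delta on damage.
    """
    spec = config.cohort
    rng = np.random.default_rng(config.seed)
    tps = list(TIMEPOINT_MONTHS)

    # Population scales of emitted per-side damage, used to z-score in the
    # delta coupling so the configured beta is exact in the population.
    motor_dmg_sd_total = float(np.sqrt(spec.motor_damage_sd**2 + spec.side_asymmetry_sd**2 + spec.damage_noise_sd**2))
    sens_dmg_sd_total = float(np.sqrt(spec.sensory_damage_sd**2 + spec.side_asymmetry_sd**2 + spec.damage_noise_sd**2))
    resid_var = 1.0 - spec.delta_patient_var - max(abs(spec.beta_motor), abs(spec.beta_pinprick)) ** 2
    if resid_var <= 0:
        raise PhantomError("delta variance partition exceeds 1; reduce beta or delta_patient_var")

    rows: list[dict] = []
    per_patient: list[dict] = []
    for i in range(spec.n_patients):
        pid = f"P{i + 1:03d}"
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18, 70))
        sex = "F" if rng.random() < spec.p_female else "M"
        center = str(rng.choice(spec.centers, p=np.asarray(spec.center_probs) / np.sum(spec.center_probs)))
        nli = str(rng.choice(["C4", "C5", "C6", "C7"]))
        ais = str(rng.choice(["A", "B", "C", "D"], p=[0.25, 0.2, 0.25, 0.3]))

        vol0 = float(np.clip(rng.normal(spec.volume_baseline_mean, spec.volume_baseline_sd), 30.0, None))
        dmg_motor0 = float(rng.normal(spec.motor_damage_mean, spec.motor_damage_sd))
        dmg_sens0 = float(rng.normal(spec.sensory_damage_mean, spec.sensory_damage_sd))
        asym_motor = float(rng.normal(0.0, spec.side_asymmetry_sd))
        asym_sens = float(rng.normal(0.0, spec.side_asymmetry_sd))
        score0 = {
            "motor": rng.normal(spec.motor_baseline_mean, spec.score_baseline_sd, size=2),
            "light_touch": rng.normal(spec.lt_baseline_mean, spec.score_baseline_sd, size=2),
            "pinprick": rng.normal(spec.pp_baseline_mean, spec.score_baseline_sd, size=2),
        }
        u_delta = {m: float(rng.normal(0.0, np.sqrt(spec.delta_patient_var))) for m in ("motor", "light_touch", "pinprick")}

        available = {tp: (rng.random() < p) for tp, p in zip(tps, spec.availability)}
        t0 = TIMEPOINT_MONTHS["baseline"]

        # Per-timepoint imaging + observed damage (with measurement noise).
        patient_rows: dict[str, dict] = {}
        for tp in tps:
            t = TIMEPOINT_MONTHS[tp]
            dt = t - t0
            vol = vol0 + spec.volume_slope_per_month * dt + float(rng.normal(0.0, spec.volume_noise_sd))
            vol = max(vol, 0.0)
            dmg = {}
            for grp, base, slope, asym in (
                ("motor", dmg_motor0, spec.motor_damage_slope, asym_motor),
                ("sensory", dmg_sens0, spec.sensory_damage_slope, asym_sens),
            ):
                mean_t = base + slope * dt
                dmg[f"{grp}_damage_left"] = float(np.clip(mean_t + asym + rng.normal(0.0, spec.damage_noise_sd), 0.0, 100.0))
                dmg[f"{grp}_damage_right"] = float(np.clip(mean_t - asym + rng.normal(0.0, spec.damage_noise_sd), 0.0, 100.0))
            patient_rows[tp] = {"months_post_injury": t, "lesion_volume_mm3": vol, **dmg}

        # Clinical trajectories: baseline -> month1 by the per-month slopes,
        # month1 -> month6 by the damage-coupled delta.
        slopes = {
            "motor": spec.motor_slope_per_month,
            "light_touch": spec.lt_slope_per_month,
            "pinprick": spec.pp_slope_per_month,
        }
        betas = {"motor": spec.beta_motor, "light_touch": spec.beta_light_touch, "pinprick": spec.beta_pinprick}
        delta_means = {"motor": spec.delta_mean_motor, "light_touch": spec.delta_mean_light_touch, "pinprick": spec.delta_mean_pinprick}
        delta_sds = {"motor": spec.delta_sd_motor, "light_touch": spec.delta_sd_light_touch, "pinprick": spec.delta_sd_pinprick}
        maxima = {"motor": 50, "light_touch": 56, "pinprick": 56}
        dmg_group_of = {"motor": "motor", "light_touch": "sensory", "pinprick": "sensory"}
        dmg_sd_of = {"motor": motor_dmg_sd_total, "light_touch": sens_dmg_sd_total, "pinprick": sens_dmg_sd_total}
        dmg_mean_of = {
            "motor": spec.motor_damage_mean + spec.motor_damage_slope * (TIMEPOINT_MONTHS["month1"] - t0),
            "light_touch": spec.sensory_damage_mean + spec.sensory_damage_slope * (TIMEPOINT_MONTHS["month1"] - t0),
            "pinprick": spec.sensory_damage_mean + spec.sensory_damage_slope * (TIMEPOINT_MONTHS["month1"] - t0),
        }

        scores: dict[str, dict[str, np.ndarray]] = {"baseline": {}, "month1": {}, "month6": {}}
        truth_deltas: dict[str, tuple[float, float]] = {}
        for mod in ("motor", "light_touch", "pinprick"):
            base = score0[mod]
            m1 = base + slopes[mod] * (TIMEPOINT_MONTHS["month1"] - t0) + rng.normal(0.0, spec.score_noise_sd, size=2)
            dmg_m1 = np.array([
                patient_rows["month1"][f"{dmg_group_of[mod]}_damage_left"],
                patient_rows["month1"][f"{dmg_group_of[mod]}_damage_right"],
            ])
            z = _zscore_ref(dmg_m1, dmg_mean_of[mod], dmg_sd_of[mod])
            resid_sd = np.sqrt(max(1.0 - spec.delta_patient_var - betas[mod] ** 2, 0.0))
            eps = spec.delta_noise_scale * rng.normal(0.0, max(resid_sd, 1e-12), size=2)
            delta = delta_means[mod] + delta_sds[mod] * (betas[mod] * z + u_delta[mod] + eps)
            m6 = m1 + delta
            rnd = np.round if spec.round_scores else (lambda a: a)
            scores["baseline"][mod] = np.clip(rnd(base), 0, maxima[mod])
            scores["month1"][mod] = np.clip(rnd(m1), 0, maxima[mod])
            scores["month6"][mod] = np.clip(rnd(m6), 0, maxima[mod])
            truth_deltas[mod] = (float(delta[0]), float(delta[1]))

        for tp in tps:
            if not available[tp]:
                continue
            row = {
                "patient_id": pid,
                "timepoint": tp,
                "age": age,
                "sex": sex,
                "center": center,
                "nli": nli,
                "ais": ais,
                **patient_rows[tp],
            }
            cast = int if spec.round_scores else float
            row.update(
                {
                    "motor_left": cast(scores[tp]["motor"][0]),
                    "motor_right": cast(scores[tp]["motor"][1]),
                    "lt_left": cast(scores[tp]["light_touch"][0]),
                    "lt_right": cast(scores[tp]["light_touch"][1]),
                    "pp_left": cast(scores[tp]["pinprick"][0]),
                    "pp_right": cast(scores[tp]["pinprick"][1]),
                }
            )
            rows.append(row)

        per_patient.append(
            {
                "patient_id": pid,
                "vol0": vol0,
                "motor_damage_base": dmg_motor0,
                "sensory_damage_base": dmg_sens0,
                "asym_motor": asym_motor,
                "asym_sensory": asym_sens,
                "delta_motor": truth_deltas["motor"],
                "delta_pinprick": truth_deltas["pinprick"],
                "available": available,
            }
        )

    cohort = pd.DataFrame(rows)
    truth = {
        "config": dataclasses.asdict(config),
        "timepoint_months": dict(TIMEPOINT_MONTHS),
        "per_patient": per_patient,
        "population": {
            "volume_slope_per_month": spec.volume_slope_per_month,
            "beta_motor_standardized": spec.beta_motor,
            "beta_pinprick_standardized": spec.beta_pinprick,
        },
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(out_dir / "cohort.csv", index=False)
        import json

        with open(out_dir / "truth.json", "w") as fh:
            json.dump(_jsonable(truth), fh, indent=2)
        if with_volumes:
            _write_cohort_volumes(config, cohort, out_dir, rng)

    return cohort, truth


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write_cohort_volumes(config: PhantomConfig, cohort: pd.DataFrame, out_dir: Path, rng: np.random.Generator) -> None:
    """Write per-patient shrinking lesion volumes plus shared cord/atlas."""
    cord, atlas = make_cord_and_atlas(config)
    write_mask(cord, out_dir / "cord.nii.gz")
    write_atlas(atlas, out_dir / "atlas")
    shrink = {"baseline": 1.0, "month1": 0.92, "month6": 0.72}
    types = ("central", "ventral", "dorsal", "complete")
    for pid, g in cohort.groupby("patient_id"):
        ltype = types[int(rng.integers(0, len(types)))]
        base = lesion_spec_for_type(ltype, config.cord)
        pdir = out_dir / "patients" / str(pid)
        pdir.mkdir(parents=True, exist_ok=True)
        for tp in g["timepoint"]:
            f = shrink[str(tp)]
            spec = dataclasses.replace(
                base, radii_mm=tuple(r * f for r in base.radii_mm)
            )
            lesion, _ = make_lesion(
                dataclasses.replace(config, lesion=spec), cord=cord, atlas=atlas
            )
            write_mask(lesion, pdir / f"lesion_{tp}.nii.gz")
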