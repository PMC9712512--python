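"""Seeded phantom legs for end-to-end pipeline testing.

Real inputs are pairs of Dixon fat/water volumes plus muscle label maps.
This module synthesizes those with the statistical structure the analysis
assumes: a leg is a bundle of disjoint elliptical muscle "tubes" inside a
subcutaneous fat shell; each muscle's voxelwise fat fraction follows a
distally-high reversed sigmoid along its own length plus Gaussian noise;
the volume is split into overlapping axial stacks like a multi-station
acquisition; follow-up scans advance each muscle's fat front with a speed
that peaks at intermediate whole-muscle fat fractions.

All randomness flows from one seeded generator; per-leg substreams are
spawned deterministically, so the same seed yields bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dixon import DixonStack, MuscleLabelMap, ValidationError
from .front import FrontParams, ProgressionConfig, eval_front, mean_ff, propagate_front


@dataclass(frozen=True)
class MuscleGeometry:
    """Elliptical cross-section tube: center/radii in mm, span in slices."""

    center_mm: tuple[float, float]
    radii_mm: tuple[float, float]
    slice_start: int
    slice_stop: int  # exclusive

    def __post_init__(self) -> None:
        if self.slice_stop - self.slice_start < 2:
            raise ValidationError("muscle must span >= 2 slices")
        if min(self.radii_mm) <= 0:
            raise ValidationError("muscle radii must be > 0")


@dataclass(frozen=True)
class SyntheticLegConfig:
    """Geometry and signal model of one phantom leg.

    Defaults mirror a typical lower-extremity protocol: 1.36 x 1.36 mm
    in-plane resolution, 5 mm slices, stacks overlapping by 9 slices
    (45 mm).  Front-parameter draws span mostly-spared through almost
    fully infiltrated muscles so every baseline-FF bin is populated.
    """

    n_muscles: int = 6
    shape_xy: tuple[int, int] = (64, 64)
    n_slices: int = 80
    voxel_spacing: tuple[float, float, float] = (1.36, 1.36, 5.0)
    noise_sd_pp: float = 2.0
    shell_ff: float = 90.0
    shell_inner_mm: float = 36.0
    shell_outer_mm: float = 41.0
    n_stacks: int = 2
    overlap_slices: int = 9  # 45 mm at 5 mm thickness
    intensity: float = 100.0
    pi_top_range: tuple[float, float] = (55.0, 90.0)
    pi_base_range: tuple[float, float] = (1.0, 8.0)
    x0_range: tuple[float, float] = (-0.4, 1.3)
    w_range: tuple[float, float] = (0.04, 0.12)
    span_start_range: tuple[int, int] = (2, 8)
    span_len_range: tuple[int, int] = (45, 70)
    seed: int = 0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Longitudinal phantom cohort.

    ``follow_up_years`` defaults to 3.67 (3 years 8 months); follow-up
    fronts advance per :class:`~fatfront.front.ProgressionConfig`, whose
    default speed peaks at 35% whole-muscle FF.  ``severity_sd`` spreads
    patients along the disease course by shifting their muscles' front
    positions.
    """

    n_patients: int = 9
    n_followup: int = 7
    sides: tuple[str, ...] = ("L", "R")
    follow_up_years: float = 3.67
    progression: ProgressionConfig = field(default_factory=ProgressionConfig)
    severity_sd: float = 0.25
    leg: SyntheticLegConfig = field(default_factory=SyntheticLegConfig)
    seed: int = 0


@dataclass(frozen=True)
class LegPhantom:
    """One rendered phantom leg: acquisition stacks, labels, and truth."""

    stacks: list[DixonStack]
    label_map: MuscleLabelMap
    truth: pd.DataFrame  # label, muscle, side, params, true mean FF
    geoms: tuple[MuscleGeometry, ...] = ()


def _muscle_layout(config: SyntheticLegConfig, rng: np.random.Generator) -> list[MuscleGeometry]:
    """Place disjoint elliptical tubes on a ring inside the fat shell."""
    nx, ny = config.shape_xy
    dx, dy, _ = config.voxel_spacing
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    ring = config.shell_inner_mm * 0.55
    geoms = []
    for m in range(config.n_muscles):
        ang = 2.0 * np.pi * m / config.n_muscles
        # radius capped so neighbours on the ring cannot touch and the
        # tube stays clear of the fat shell
        if config.n_muscles > 1:
            max_r = ring * np.sin(np.pi / config.n_muscles) * 0.85
        else:
            max_r = ring * 0.85
        max_r = min(max_r, (config.shell_inner_mm - ring) * 0.9)
        r_a = rng.uniform(0.6, 1.0) * max_r
        r_b = rng.uniform(0.6, 1.0) * max_r
        start = int(rng.integers(config.span_start_range[0], config.span_start_range[1] + 1))
        length = int(rng.integers(config.span_len_range[0], config.span_len_range[1] + 1))
        stop = min(start + length, config.n_slices)
        geoms.append(MuscleGeometry(
            center_mm=(cx + ring * np.cos(ang), cy + ring * np.sin(ang)),
            radii_mm=(r_a, r_b),
            slice_start=start,
            slice_stop=stop,
        ))
    return geoms


def _draw_params(config: SyntheticLegConfig, rng: np.random.Generator,
                 x0_shift: float = 0.0) -> FrontParams:
    return FrontParams(
        pi_top=float(rng.uniform(*config.pi_top_range)),
        pi_base=float(rng.uniform(*config.pi_base_range)),
        x0=float(np.clip(rng.uniform(*config.x0_range) + x0_shift, -0.5, 1.5)),
        w=float(rng.uniform(*config.w_range)),
    )


def _render_volume(
    config: SyntheticLegConfig,
    geoms: list[MuscleGeometry],
    params: list[FrontParams],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize (ff, labels) full volumes from geometry and front params."""
    nx, ny = config.shape_xy
    nz = config.n_slices
    dx, dy, _ = config.voxel_spacing
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    cx, cy = nx * dx / 2.0, ny * dy / 2.0
    ff = np.full((nx, ny, nz), np.nan)
    labels = np.zeros((nx, ny, nz), dtype=np.int16)

    rad = np.hypot(X - cx, Y - cy)
    shell = (rad >= config.shell_inner_mm) & (rad < config.shell_outer_mm)
    if shell.any():
        shell_vals = np.clip(
            config.shell_ff + rng.normal(0.0, config.noise_sd_pp, (int(shell.sum()), nz)),
            0.0, 100.0,
        )
        ff[shell] = shell_vals

    masks = []
    for geom in geoms:
        mx, my = geom.center_mm
        ra, rb = geom.radii_mm
        mask = ((X - mx) / ra) ** 2 + ((Y - my) / rb) ** 2 <= 1.0
        masks.append(mask)
    for i, a in enumerate(masks):
        for b in masks[i + 1:]:
            if (a & b).any():
                raise ValidationError("generated muscle cross-sections overlap")
        if (a & shell).any():
            raise ValidationError("muscle overlaps the subcutaneous fat shell")

    for label, (geom, par, mask) in enumerate(zip(geoms, params, masks), start=1):
        span = np.arange(geom.slice_start, geom.slice_stop)
        x_rel = (span - geom.slice_start) / (len(span) - 1)
        clean = eval_front(par, x_rel)
        n_inplane = int(mask.sum())
        noisy = np.clip(
            clean[None, :] + rng.normal(0.0, config.noise_sd_pp, (n_inplane, len(span))),
            0.0, 100.0,
        )
        ff[mask, geom.slice_start:geom.slice_stop] = noisy
        labels[mask, geom.slice_start:geom.slice_stop] = label
    return ff, labels


def _split_stacks(config: SyntheticLegConfig, ff: np.ndarray) -> list[DixonStack]:
    """Cut the rendered FF volume into overlapping acquisition stacks."""
    nz = ff.shape[2]
    v = config.overlap_slices
    k = config.n_stacks
    if k == 1:
        bounds = [(0, nz)]
    else:
        length = int(np.ceil((nz + (k - 1) * v) / k))
        bounds = []
        for i in range(k):
            start = i * (length - v)
            stop = min(start + length, nz)
            bounds.append((start, stop))
        bounds[-1] = (bounds[-1][0], nz)
    dz = config.voxel_spacing[2]
    stacks = []
    for start, stop in bounds:
        chunk = ff[:, :, start:stop]
        defined = np.isfinite(chunk)
        fat = np.where(defined, chunk / 100.0 * config.intensity, 0.0)
        water = np.where(defined, (100.0 - chunk) / 100.0 * config.intensity, 0.0)
        stacks.append(DixonStack(
            fat=fat, water=water, voxel_spacing=config.voxel_spacing,
            axis_offset_mm=start * dz, distal_first=True,
        ))
    return stacks


def generate_leg(
    config: SyntheticLegConfig,
    side: str = "L",
    patient: str = "P01",
    params: list[FrontParams] | None = None,
    geoms: list[MuscleGeometry] | None = None,
    x0_shift: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LegPhantom:
    """Render one phantom leg as overlapping Dixon stacks plus labels.

    ``params``/``geoms`` may be passed explicitly (e.g. to re-render the
    same leg at a later timepoint with advanced fronts); otherwise they
    are drawn from the config's distributions.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if geoms is None:
        geoms = _muscle_layout(config, rng)
    if params is None:
        params = [_draw_params(config, rng, x0_shift) for _ in geoms]
    if len(params) != len(geoms):
        raise ValidationError("one FrontParams per muscle geometry required")
    ff, labels = _render_volume(config, geoms, params, rng)
    table = {
        i + 1: {"muscle": f"muscle_{i + 1:02d}", "side": side}
        for i in range(len(geoms))
    }
    label_map = MuscleLabelMap(labels=labels, label_table=table)
    truth = pd.DataFrame([
        {
            "patient": patient, "side": side, "label": i + 1,
            "muscle": table[i + 1]["muscle"],
            "pi_top": p.pi_top, "pi_base": p.pi_base, "x0": p.x0, "w": p.w,
            "true_mean_ff": mean_ff(p),
            "slice_start": g.slice_start, "slice_stop": g.slice_stop,
        }
        for i, (p, g) in enumerate(zip(params, geoms))
    ])
    return LegPhantom(
        stacks=_split_stacks(config, ff), label_map=label_map,
        truth=truth, geoms=tuple(geoms),
    )


@dataclass(frozen=True)
class SyntheticCohort:
    """Paired baseline/follow-up phantom legs with ground truth."""

    legs: list[dict]  # patient, side, baseline: LegPhantom, followup: LegPhantom|None
    truth: pd.DataFrame
    config: SyntheticCohortConfig


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a longitudinal phantom cohort.

    The first ``n_followup`` patients get a follow-up scan rendered on the
    same geometry with fronts advanced by the progression law over
    ``follow_up_years``; noise is drawn fresh at each timepoint.  Truth
    includes each muscle's true whole-muscle FF at both timepoints and
    the implied true change per year.
    """
    if config.n_followup > config.n_patients:
        raise ValidationError("n_followup cannot exceed n_patients")
    root = np.random.SeedSequence(config.seed)
    legs = []
    truth_rows = []
    patient_seqs = root.spawn(config.n_patients)
    for p_idx, pseq in enumerate(patient_seqs):
        patient = f"P{p_idx + 1:02d}"
        severity = float(np.random.default_rng(pseq.spawn(1)[0]).normal(0.0, config.severity_sd))
        has_fu = p_idx < config.n_followup
        for s_idx, side in enumerate(config.sides):
            leg_seq = pseq.spawn(1)[0]
            rng = np.random.default_rng(leg_seq)
            base = generate_leg(
                config.leg, side=side, patient=patient,
                x0_shift=severity, rng=rng,
            )
            followup = None
            fu_params = None
            if has_fu:
                fu_params = [
                    propagate_front(
                        FrontParams(r.pi_top, r.pi_base, r.x0, r.w),
                        config.follow_up_years, config.progression,
                    )
                    for r in base.truth.itertuples()
                ]
                followup = generate_leg(
                    config.leg, side=side, patient=patient,
                    params=fu_params, geoms=list(base.geoms), rng=rng,
                )
            for i, r in base.truth.iterrows():
                row = r.to_dict()
                if fu_params is not None:
                    fp = fu_params[i]
                    row.update({
                        "x0_followup": fp.x0, "w_followup": fp.w,
                        "true_mean_ff_followup": mean_ff(fp),
                        "true_change_per_year":
                            (mean_ff(fp) - row["true_mean_ff"]) / config.follow_up_years,
                    })
                truth_rows.append(row)
            legs.append({
                "patient": patient, "side": side,
                "baseline": base, "followup": followup,
            })
    return SyntheticCohort(legs=legs, truth=pd.DataFrame(truth_rows), config=config)
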