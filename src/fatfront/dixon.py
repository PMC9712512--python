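"""Dixon fat-fraction mapping, scanner harmonization, and stack stitching.

A two-point Dixon acquisition yields co-registered fat (F) and water (W)
intensity volumes.  The voxelwise fat fraction is

    FF = 100 * F / (F + W)   [percent]

Voxels with negligible total signal (F + W <= epsilon) carry no fat/water
information and are marked missing (NaN) rather than forced to an arbitrary
value; they are excluded from every downstream mean.

A lower extremity is acquired as several overlapping axial stacks which are
stitched into a single volume spanning hip to ankle.  All volumes in this
package are normalized so that slice index 0 is the most distal slice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np


class StructuralError(ValueError):
    """Inputs are mutually inconsistent (shape/grid/identity mismatch)."""


class ValidationError(ValueError):
    """A single input violates its contract."""


@dataclass(frozen=True)
class DixonStack:
    """One acquired stack of co-registered fat and water images.

    ``axis_offset_mm`` locates the stack's first slice (index 0) along the
    leg axis, measured from an arbitrary but shared distal origin.
    """

    fat: np.ndarray
    water: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.36, 1.36, 5.0)
    axis_offset_mm: float = 0.0
    distal_first: bool = True

    def __post_init__(self) -> None:
        fat = np.asarray(self.fat, dtype=float)
        water = np.asarray(self.water, dtype=float)
        if fat.shape != water.shape:
            raise StructuralError(
                f"fat shape {fat.shape} != water shape {water.shape}"
            )
        if fat.ndim != 3:
            raise ValidationError("fat/water images must be 3-D (x, y, slice)")
        if np.nanmin(fat) < 0 or np.nanmin(water) < 0:
            raise ValidationError("fat/water intensities must be non-negative")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError(f"voxel spacing must be positive, got {self.voxel_spacing}")
        object.__setattr__(self, "fat", fat)
        object.__setattr__(self, "water", water)

    @property
    def n_slices(self) -> int:
        return self.fat.shape[2]

    @property
    def slice_thickness(self) -> float:
        return self.voxel_spacing[2]


@dataclass(frozen=True)
class FatFractionVolume:
    """Voxelwise fat fraction in percent; NaN marks missing voxels."""

    ff: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.36, 1.36, 5.0)
    axis_offset_mm: float = 0.0
    distal_first: bool = True

    def __post_init__(self) -> None:
        ff = np.asarray(self.ff, dtype=float)
        if ff.ndim != 3:
            raise ValidationError("FF volume must be 3-D (x, y, slice)")
        defined = ff[np.isfinite(ff)]
        if defined.size and (defined.min() < 0 or defined.max() > 100):
            raise ValidationError("defined FF values must lie in [0, 100]")
        object.__setattr__(self, "ff", ff)

    @property
    def n_slices(self) -> int:
        return self.ff.shape[2]

    @property
    def slice_thickness(self) -> float:
        return self.voxel_spacing[2]

    @property
    def voxel_volume_ml(self) -> float:
        dx, dy, dz = self.voxel_spacing
        return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class HarmonizationModel:
    """Linear cross-scanner correction ``FF_corrected = slope*FF + intercept``.

    The default coefficients map baseline fat fractions acquired before a
    scanner/reconstruction upgrade onto the follow-up scale; corrected
    values are clipped back into [0, 100].
    """

    slope: float = 1.1864
    intercept: float = -2.7878
    clip_low: float = 0.0
    clip_high: float = 100.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("harmonization slope must be > 0 (monotone)")

    @classmethod
    def identity(cls) -> "HarmonizationModel":
        return cls(slope=1.0, intercept=0.0)


@dataclass(frozen=True)
class MuscleLabelMap:
    """Integer label volume plus the table describing each label.

    ``label_table`` maps label id -> dict with at least ``muscle`` and
    ``side``; optional keys ``region`` (upper/lower leg) and
    ``compartment``.  ``exclusions`` lists (muscle, side, timepoint) triples
    to drop from analysis (e.g. fat-water swaps identified by eye).
    """

    labels: np.ndarray
    label_table: Mapping[int, Mapping[str, str]]
    exclusions: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValidationError("label map must be an integer array")
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValidationError(
                f"labels present in volume but absent from table: {sorted(missing)}"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "exclusions", tuple(tuple(e) for e in self.exclusions))

    def label_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})

    def is_excluded(self, label: int, timepoint: str) -> bool:
        info = self.label_table[label]
        return (info["muscle"], info.get("side", ""), timepoint) in self.exclusions


def compute_ff_map(stack: DixonStack, epsilon: float = 0.0) -> FatFractionVolume:
    """Compute the percent fat-fraction map 100*F/(F+W) from a Dixon stack.

    Voxels with total signal F+W <= ``epsilon`` become NaN (missing).
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    total = stack.fat + stack.water
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > epsilon, 100.0 * stack.fat / total, np.nan)
    return FatFractionVolume(
        ff=ff,
        voxel_spacing=stack.voxel_spacing,
        axis_offset_mm=stack.axis_offset_mm,
        distal_first=stack.distal_first,
    )


def harmonize_ff(volume: FatFractionVolume, model: HarmonizationModel) -> FatFractionVolume:
    """Apply the linear scanner-upgrade correction voxelwise.

    Defined voxels map to ``clip(slope*FF + intercept, 0, 100)``; missing
    voxels stay missing.
    """
    ff = model.slope * volume.ff + model.intercept
    ff = np.clip(ff, model.clip_low, model.clip_high)
    return replace(volume, ff=ff)


def _stack_index_range(vol: FatFractionVolume, origin_mm: float) -> tuple[int, int]:
    dz = vol.slice_thickness
    start = (vol.axis_offset_mm - origin_mm) / dz
    start_i = int(round(start))
    if abs(start - start_i) > 1e-6:
        raise StructuralError(
            f"stack offset {vol.axis_offset_mm} mm is not aligned to the "
            f"{dz} mm slice grid"
        )
    return start_i, start_i + vol.n_slices


def stitch_stacks(
    stacks: Sequence[FatFractionVolume], blend: str = "distance_to_edge"
) -> FatFractionVolume:
    """Stitch overlapping FF stacks into one distal-to-proximal volume.

    In overlap regions the default policy keeps, per output slice, the
    value from the stack in which that slice lies farther from the stack
    edge (coil sensitivity is worst at stack edges); ``blend="average"``
    averages the overlapping slices instead.  Adjacent stacks must abut or
    overlap; a gap raises :class:`ValidationError`.
    """
    if not stacks:
        raise ValidationError("at least one stack required")
    if blend not in ("distance_to_edge", "average"):
        raise ValidationError(f"unknown overlap policy {blend!r}")
    first = stacks[0]
    for s in stacks[1:]:
        if s.ff.shape[:2] != first.ff.shape[:2]:
            raise StructuralError("in-plane grids differ between stacks")
        if not np.allclose(s.voxel_spacing, first.voxel_spacing):
            raise StructuralError("voxel spacing differs between stacks")
        if s.distal_first != first.distal_first:
            raise StructuralError("mixed slice orientations between stacks")
    ordered = sorted(stacks, key=lambda s: s.axis_offset_mm)
    origin = ordered[0].axis_offset_mm
    ranges = [_stack_index_range(s, origin) for s in ordered]
    for (a0, a1), (b0, b1) in zip(ranges, ranges[1:]):
        if b0 > a1:
            raise ValidationError(
                f"gap of {b0 - a1} slice(s) between stacks "
                f"(indices {a1}..{b0} uncovered)"
            )
    n_out = max(r[1] for r in ranges)
    shape = first.ff.shape[:2] + (n_out,)
    if blend == "average":
        acc = np.zeros(shape)
        cnt = np.zeros(shape)
        for s, (i0, i1) in zip(ordered, ranges):
            defined = np.isfinite(s.ff)
            acc[:, :, i0:i1] += np.where(defined, s.ff, 0.0)
            cnt[:, :, i0:i1] += defined
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    else:
        out = np.full(shape, np.nan)
        best = np.full(n_out, -1)
        for s, (i0, i1) in zip(ordered, ranges):
            local = np.arange(i1 - i0)
            dist = np.minimum(local, (i1 - i0 - 1) - local)
            take = dist > best[i0:i1]
            idx = np.nonzero(take)[0]
            out[:, :, i0 + idx] = s.ff[:, :, idx]
            best[i0 + idx] = dist[idx]
    return FatFractionVolume(
        ff=out,
        voxel_spacing=first.voxel_spacing,
        axis_offset_mm=origin,
        distal_first=first.distal_first,
    )


def align_timepoints(
    baseline: FatFractionVolume,
    followup: FatFractionVolume,
    baseline_labels: MuscleLabelMap | None = None,
    followup_labels: MuscleLabelMap | None = None,
):
    """Crop two timepoints to their shared proximo-distal extent.

    Per-muscle analyses use each timepoint's own relative-length axis, so
    voxel registration is not required — only consistent coverage along the
    leg.  Returns the cropped (baseline, followup) volumes, with label maps
    cropped alongside when given.
    """
    if not (baseline.distal_first and followup.distal_first):
        raise ValidationError("volumes must be normalized distal-first before alignment")
    dz = baseline.slice_thickness
    b0, b1 = baseline.axis_offset_mm, baseline.axis_offset_mm + baseline.n_slices * dz
    f0, f1 = followup.axis_offset_mm, followup.axis_offset_mm + followup.n_slices * followup.slice_thickness
    lo, hi = max(b0, f0), min(b1, f1)
    if hi <= lo:
        raise ValidationError(
            f"timepoints have no shared coverage (baseline [{b0}, {b1}) mm, "
            f"follow-up [{f0}, {f1}) mm)"
        )

    def crop(vol: FatFractionVolume, labels: MuscleLabelMap | None):
        i0 = int(round((lo - vol.axis_offset_mm) / vol.slice_thickness))
        i1 = int(round((hi - vol.axis_offset_mm) / vol.slice_thickness))
        cropped = replace(vol, ff=vol.ff[:, :, i0:i1], axis_offset_mm=lo)
        if labels is None:
            return cropped, None
        lab = replace(labels, labels=labels.labels[:, :, i0:i1])
        return cropped, lab

    cb, lb = crop(baseline, baseline_labels)
    cf, lf = crop(followup, followup_labels)
    if baseline_labels is None and followup_labels is None:
        return cb, cf
    return cb, cf, lb, lf


def normalize_orientation(volume: FatFractionVolume) -> FatFractionVolume:
    """Flip the slice axis if needed so slice 0 is the most distal slice."""
    if volume.distal_first:
        return volume
    return replace(volume, ff=volume.ff[:, :, ::-1], distal_first=True)
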