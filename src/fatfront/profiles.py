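"""Per-slice muscle fat-fraction profiles along the proximo-distal axis.

Muscle length differs between muscles and subjects, so slice positions are
expressed as a percentage of muscle length: the most distal segmented slice
sits at 0% and the most proximal at 100% (slice i of N at 100*i/(N-1)).
Profiles are summarized as five equal proximo-distal segments and can be
subsampled with the two localized-sampling schemes used in practice:
``central5`` (five contiguous mid-muscle slices, 2.5 cm at 5 mm thickness)
and ``spread5`` (slices nearest 10/30/50/70/90% of muscle length).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .dixon import FatFractionVolume, MuscleLabelMap, ValidationError

logger = logging.getLogger(__name__)

SEGMENT_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)
SCHEMES = ("central5", "spread5", "whole")


@dataclass(frozen=True)
class MuscleProfile:
    """Ordered per-slice fat fractions for one muscle/side/timepoint.

    Slices run distal -> proximal.  ``relative_pos`` holds each slice's
    position in percent of muscle length; ``n_voxels`` the labeled,
    non-missing voxel count per slice used for volume weighting.
    """

    muscle: str
    side: str
    timepoint: str
    slice_indices: np.ndarray
    ff: np.ndarray
    n_voxels: np.ndarray
    relative_pos: np.ndarray

    def __post_init__(self) -> None:
        for name in ("slice_indices", "ff", "n_voxels", "relative_pos"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        n = len(self.ff)
        if n < 2:
            raise ValidationError(
                f"profile for {self.muscle}/{self.side} needs >= 2 slices, got {n}"
            )
        if len({len(self.slice_indices), n, len(self.n_voxels), len(self.relative_pos)}) != 1:
            raise ValidationError("profile field lengths differ")
        pos = self.relative_pos
        if pos[0] != 0.0 or abs(pos[-1] - 100.0) > 1e-9 or np.any(np.diff(pos) <= 0):
            raise ValidationError("relative positions must rise strictly from 0 to 100")
        if np.nanmin(self.ff) < 0 or np.nanmax(self.ff) > 100:
            raise ValidationError("per-slice FF must lie in [0, 100]")

    @property
    def n_slices(self) -> int:
        return len(self.ff)


@dataclass(frozen=True)
class SegmentProfile:
    """Five segment-mean fat fractions, distal (s=1) to proximal (s=5)."""

    muscle: str
    side: str
    timepoint: str
    means: np.ndarray
    n_voxels: np.ndarray
    n_slices: np.ndarray

    def __post_init__(self) -> None:
        for name in ("means", "n_voxels", "n_slices"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if len(self.means) != 5:
            raise ValidationError("segment profile must have exactly 5 segments")


def extract_profile(
    volume: FatFractionVolume,
    label_map: MuscleLabelMap,
    label: int,
    timepoint: str = "baseline",
) -> MuscleProfile:
    """Build the per-slice FF profile of one labeled muscle.

    Slice FF is the mean over labeled, non-missing voxels in that slice.
    Slices inside the muscle's span with no labeled voxels (segmentation
    holes) are dropped with a warning; relative positions are computed from
    the span so endpoints stay at exactly 0% and 100%.
    """
    if label_map.labels.shape != volume.ff.shape:
        raise ValidationError("label map shape differs from FF volume shape")
    info = label_map.label_table.get(label)
    if info is None:
        raise ValidationError(f"label {label} absent from label table")
    mask = label_map.labels == label
    counts = mask.sum(axis=(0, 1))
    occupied = np.nonzero(counts)[0]
    if occupied.size == 0:
        raise ValidationError(f"muscle {info['muscle']!r} (label {label}) not present")
    first, last = int(occupied[0]), int(occupied[-1])
    if last == first:
        raise ValidationError(
            f"muscle {info['muscle']!r} (label {label}) spans a single slice"
        )
    span = np.arange(first, last + 1)
    holes = [int(i) for i in span if counts[i] == 0]
    if holes:
        logger.warning(
            "muscle %s/%s: dropping %d empty slice(s) inside span: %s",
            info["muscle"], info.get("side", "?"), len(holes), holes,
        )
    kept, ffs, nvox = [], [], []
    for i in span:
        if counts[i] == 0:
            continue
        vals = volume.ff[:, :, i][mask[:, :, i]]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning(
                "muscle %s slice %d: all labeled voxels missing, dropped",
                info["muscle"], i,
            )
            continue
        kept.append(int(i))
        ffs.append(float(vals.mean()))
        nvox.append(int(vals.size))
    rel = 100.0 * (np.array(kept) - first) / (last - first)
    return MuscleProfile(
        muscle=info["muscle"],
        side=info.get("side", ""),
        timepoint=timepoint,
        slice_indices=np.array(kept),
        ff=np.array(ffs),
        n_voxels=np.array(nvox),
        relative_pos=rel,
    )


def whole_muscle_ff(profile: MuscleProfile) -> float:
    """Voxel-count-weighted mean FF over all slices.

    Equals the plain mean over all labeled, non-missing voxels of the 3-D
    mask, which is the quantity every "whole muscle" reference uses.
    """
    w = profile.n_voxels.astype(float)
    return float(np.sum(profile.ff * w) / np.sum(w))


def _segment_of(pos: float) -> int:
    """Segment index 1..5 for a relative position in [0, 100]."""
    if pos >= 100.0:
        return 5
    return int(pos // 20.0) + 1


def segment_means(profile: MuscleProfile) -> SegmentProfile:
    """Average the profile into five equal proximo-distal segments.

    Slices are binned by relative position into [0,20), [20,40), [40,60),
    [60,80), [80,100]; each segment mean is the voxel-weighted mean of its
    slices.
    """
    if profile.n_slices < 5:
        raise ValidationError(
            f"segment means need >= 5 slices, got {profile.n_slices} "
            f"({profile.muscle}/{profile.side})"
        )
    seg = np.array([_segment_of(p) for p in profile.relative_pos])
    means = np.empty(5)
    nvox = np.zeros(5, dtype=int)
    nsl = np.zeros(5, dtype=int)
    for s in range(1, 6):
        sel = seg == s
        if not sel.any():
            raise ValidationError(
                f"segment {s} of {profile.muscle}/{profile.side} is empty"
            )
        w = profile.n_voxels[sel].astype(float)
        means[s - 1] = np.sum(profile.ff[sel] * w) / np.sum(w)
        nvox[s - 1] = int(w.sum())
        nsl[s - 1] = int(sel.sum())
    return SegmentProfile(
        muscle=profile.muscle,
        side=profile.side,
        timepoint=profile.timepoint,
        means=means,
        n_voxels=nvox,
        n_slices=nsl,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def select_slices(scheme: str, n_slices: int) -> np.ndarray:
    """Slice indices realized by a subsampling scheme for an N-slice muscle.

    ``central5``: five contiguous slices starting at floor((N-5)/2).
    ``spread5``: nearest slices to 10/30/50/70/90% of muscle length,
    i.e. round-half-away-from-zero of p*(N-1); duplicates possible for
    N < 10 and retained.  ``whole``: every slice.
    """
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if n_slices < 5:
        raise ValidationError(f"subsampling needs >= 5 slices, got {n_slices}")
    if scheme == "whole":
        return np.arange(n_slices)
    if scheme == "central5":
        start = (n_slices - 5) // 2
        return np.arange(start, start + 5)
    return np.array([_round_half_away(p * (n_slices - 1)) for p in (0.1, 0.3, 0.5, 0.7, 0.9)])


def subsampled_ff(profile: MuscleProfile, scheme: str) -> float:
    """Mean FF over the slices a subsampling scheme would acquire.

    Unweighted across the selected slices (emulating a reading of five
    acquired slices without volumetric context); duplicates from spread5
    on short muscles each count once.
    """
    idx = select_slices(scheme, profile.n_slices)
    return float(profile.ff[idx].mean())


def classify_profile_shape(seg: SegmentProfile, delta: float = 5.0) -> str:
    """Heuristic shape label for a 5-segment profile.

    Evaluated in order: ``decreasing`` (distal end highest by > delta),
    ``reversed`` (proximal end highest by > delta), ``u_shape`` (interior
    minimum with both ends > delta above it), ``homogeneous`` (total range
    <= delta), else ``other``.  A convenience heuristic, not a clinical
    score.
    """
    m = seg.means
    if m[0] - m[4] > delta and m[0] == m.max():
        return "decreasing"
    if m[4] - m[0] > delta and m[4] == m.max():
        return "reversed"
    imin = int(np.argmin(m))
    if 0 < imin < 4 and m[0] - m[imin] > delta and m[4] - m[imin] > delta:
        return "u_shape"
    if m.max() - m.min() <= delta:
        return "homogeneous"
    return "other"
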