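"""Cohort-level summaries: whole-muscle records, volume-weighted composite
scores, longitudinal change, baseline-FF binning, and the segment-wise
change matrix that exposes wave-like proximo-distal progression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dixon import StructuralError, ValidationError
from .profiles import MuscleProfile, segment_means, whole_muscle_ff

logger = logging.getLogger(__name__)

MERCURI_CLASSES = ("<10", "10-30", "30-60", ">60")
#: Baseline-FF bins used for progression grouping, 10-percent increments.
BASELINE_BINS = tuple(f"{lo}-{lo + 10}" for lo in range(0, 90, 10))


def mercuri_class(ff: float) -> str:
    """Severity band for a whole-muscle FF: <10, 10-30, 30-60, >60 percent.

    Band edges are half-open [lo, hi).
    """
    if ff < 10:
        return "<10"
    if ff < 30:
        return "10-30"
    if ff < 60:
        return "30-60"
    return ">60"


def baseline_bin(ff: float) -> str:
    """10-percent baseline-FF bin, half-open [lo, hi); FF >= 90 maps to
    80-90 with a warning (fully replaced muscles are rare and saturate)."""
    if ff < 0:
        raise ValidationError(f"FF must be >= 0, got {ff}")
    if ff >= 90:
        logger.warning("baseline FF %.1f >= 90; assigned to bin 80-90", ff)
        return "80-90"
    lo = int(ff // 10) * 10
    return f"{lo}-{lo + 10}"


@dataclass(frozen=True)
class MuscleRecord:
    """Whole-muscle summary for one muscle/side/patient/timepoint."""

    muscle: str
    side: str
    patient: str
    timepoint: str
    ff_whole: float
    volume_ml: float
    n_slices: int

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValidationError(f"muscle volume must be > 0, got {self.volume_ml}")

    @property
    def mercuri(self) -> str:
        return mercuri_class(self.ff_whole)


@dataclass(frozen=True)
class CompositeScore:
    scope: str
    ff: float
    total_volume_ml: float
    n_muscles: int


@dataclass(frozen=True)
class LongitudinalRecord:
    """Paired baseline/follow-up summary for one muscle-side."""

    muscle: str
    side: str
    patient: str
    ff_baseline: float
    ff_followup: float
    interval_years: float

    def __post_init__(self) -> None:
        if self.interval_years <= 0:
            raise ValidationError(
                f"follow-up interval must be > 0 years, got {self.interval_years}"
            )

    @property
    def change(self) -> float:
        return self.ff_followup - self.ff_baseline

    @property
    def change_per_year(self) -> float:
        return self.change / self.interval_years

    @property
    def bin(self) -> str:
        return baseline_bin(self.ff_baseline)


def muscle_record(
    profile: MuscleProfile, patient: str, voxel_volume_ml: float
) -> MuscleRecord:
    """Summarize a profile into a whole-muscle record."""
    return MuscleRecord(
        muscle=profile.muscle,
        side=profile.side,
        patient=patient,
        timepoint=profile.timepoint,
        ff_whole=whole_muscle_ff(profile),
        volume_ml=float(profile.n_voxels.sum()) * voxel_volume_ml,
        n_slices=profile.n_slices,
    )


def composite_ff(records: list[MuscleRecord], scope: str = "lower extremity") -> CompositeScore:
    """Volume-weighted composite FF over a set of muscles.

    Each muscle's FF is weighted by its volume, so larger muscles dominate
    — equivalent to pooling all labeled voxels when the FFs are voxel
    means on a shared grid.
    """
    if not records:
        raise ValidationError(f"no muscles in scope {scope!r}")
    ffs = np.array([r.ff_whole for r in records])
    vols = np.array([r.volume_ml for r in records])
    return CompositeScore(
        scope=scope,
        ff=float(np.sum(ffs * vols) / np.sum(vols)),
        total_volume_ml=float(vols.sum()),
        n_muscles=len(records),
    )


def left_right_average(records: list[MuscleRecord]) -> pd.DataFrame:
    """Volume-weighted mean over sides, per muscle/patient/timepoint.

    A muscle present on only one side passes through unchanged.
    """
    rows = [
        {
            "patient": r.patient, "muscle": r.muscle, "timepoint": r.timepoint,
            "ff_whole": r.ff_whole, "volume_ml": r.volume_ml,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    def agg(g: pd.DataFrame) -> pd.Series:
        w = g["volume_ml"].to_numpy()
        return pd.Series({
            "ff_whole": float(np.sum(g["ff_whole"].to_numpy() * w) / w.sum()),
            "volume_ml": float(w.sum()),
            "n_sides": len(g),
        })
    out = (
        df.groupby(["patient", "muscle", "timepoint"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    out["n_sides"] = out["n_sides"].astype(int)
    return out


def longitudinal_change(
    baseline: MuscleRecord, followup: MuscleRecord, interval_years: float
) -> LongitudinalRecord:
    """Pair two timepoints of the same muscle into a longitudinal record."""
    if (baseline.muscle, baseline.side, baseline.patient) != (
        followup.muscle, followup.side, followup.patient
    ):
        raise StructuralError(
            f"timepoint identity mismatch: {baseline.muscle}/{baseline.side}/"
            f"{baseline.patient} vs {followup.muscle}/{followup.side}/{followup.patient}"
        )
    return LongitudinalRecord(
        muscle=baseline.muscle,
        side=baseline.side,
        patient=baseline.patient,
        ff_baseline=baseline.ff_whole,
        ff_followup=followup.ff_whole,
        interval_years=interval_years,
    )


def change_by_baseline_bin(records: list[LongitudinalRecord]) -> pd.DataFrame:
    """Per-bin mean, sample SD and n of the yearly FF change.

    Returns one row per baseline bin in distal..proximal bin order; bins
    with no muscles are flagged ``empty`` rather than reported as zero.
    """
    if not records:
        raise ValidationError("no longitudinal records")
    rows = []
    by_bin: dict[str, list[float]] = {b: [] for b in BASELINE_BINS}
    for r in records:
        by_bin[r.bin].append(r.change_per_year)
    for b in BASELINE_BINS:
        vals = np.array(by_bin[b])
        rows.append({
            "bin": b,
            "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            "empty": len(vals) == 0,
        })
    return pd.DataFrame(rows)


def segment_change_matrix(
    baseline_profiles: list[MuscleProfile],
    followup_profiles: list[MuscleProfile],
    interval_years: float,
) -> pd.DataFrame:
    """Segment-level FF change per year, grouped by baseline whole-muscle bin.

    Each muscle's five segment means are computed on each timepoint's own
    relative-length axis; the change per segment is aggregated over
    muscles within each 10% baseline-FF bin (long format: bin, segment,
    mean, sd, n).  Unpaired muscles are skipped with a warning.
    """
    if interval_years <= 0:
        raise ValidationError("interval_years must be > 0")
    fu = {(p.muscle, p.side): p for p in followup_profiles}
    cells: dict[tuple[str, int], list[float]] = {}
    for bp in baseline_profiles:
        fp = fu.get((bp.muscle, bp.side))
        if fp is None:
            logger.warning("muscle %s/%s has no follow-up; skipped", bp.muscle, bp.side)
            continue
        b = baseline_bin(whole_muscle_ff(bp))
        seg_b = segment_means(bp).means
        seg_f = segment_means(fp).means
        delta = (seg_f - seg_b) / interval_years
        for s in range(5):
            cells.setdefault((b, s + 1), []).append(float(delta[s]))
    rows = []
    for b in BASELINE_BINS:
        for s in range(1, 6):
            vals = np.array(cells.get((b, s), []))
            rows.append({
                "bin": b,
                "segment": s,
                "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "empty": len(vals) == 0,
            })
    return pd.DataFrame(rows)


def segment_table(
    profiles: list[MuscleProfile], patients: dict[tuple[str, str], str] | str
) -> pd.DataFrame:
    """Long-format (patient, muscle, side, segment, ff) table for the
    mixed-model gradient analysis.

    ``patients`` maps (muscle, side) -> patient id, or is a single patient
    id applied to every profile.
    """
    rows = []
    for p in profiles:
        pat = patients if isinstance(patients, str) else patients[(p.muscle, p.side)]
        seg = segment_means(p)
        whole = whole_muscle_ff(p)
        for s in range(1, 6):
            rows.append({
                "patient": pat, "muscle": p.muscle, "side": p.side,
                "timepoint": p.timepoint, "segment": s,
                "ff": float(seg.means[s - 1]),
                "ff_whole": whole, "mercuri": mercuri_class(whole),
            })
    return pd.DataFrame(rows)
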