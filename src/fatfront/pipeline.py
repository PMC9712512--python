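"""End-to-end convenience: stacks -> stitched FF volume -> per-muscle
profiles and records.  Thin orchestration over the stage modules; used by
the CLI and by cohort-level analyses on phantom data.
"""

from __future__ import annotations

import pandas as pd

from .bias import BiasRecord, bias_records
from .cohort import muscle_record, segment_table
from .dixon import (
    DixonStack,
    FatFractionVolume,
    HarmonizationModel,
    MuscleLabelMap,
    compute_ff_map,
    harmonize_ff,
    stitch_stacks,
)
from .profiles import MuscleProfile, extract_profile
from .synthetic import LegPhantom, SyntheticCohort


def stacks_to_volume(
    stacks: list[DixonStack],
    epsilon: float = 0.0,
    harmonization: HarmonizationModel | None = None,
    blend: str = "distance_to_edge",
) -> FatFractionVolume:
    """Fat-fraction maps per stack, optional harmonization, then stitching."""
    volumes = [compute_ff_map(s, epsilon=epsilon) for s in stacks]
    if harmonization is not None:
        volumes = [harmonize_ff(v, harmonization) for v in volumes]
    return stitch_stacks(volumes, blend=blend)


def leg_profiles(
    stacks: list[DixonStack],
    label_map: MuscleLabelMap,
    timepoint: str = "baseline",
    harmonization: HarmonizationModel | None = None,
    min_slices: int = 2,
) -> list[MuscleProfile]:
    """Profiles of every non-excluded muscle in one leg."""
    volume = stacks_to_volume(stacks, harmonization=harmonization)
    profiles = []
    for label in label_map.label_ids():
        if label_map.is_excluded(label, timepoint):
            continue
        prof = extract_profile(volume, label_map, label, timepoint=timepoint)
        if prof.n_slices >= min_slices:
            profiles.append(prof)
    return profiles


def profiles_table(profiles: list[MuscleProfile], patient: str = "") -> pd.DataFrame:
    """Tidy per-slice table with deterministic column order."""
    rows = []
    for p in profiles:
        for i in range(p.n_slices):
            rows.append({
                "patient": patient, "muscle": p.muscle, "side": p.side,
                "timepoint": p.timepoint,
                "slice_index": int(p.slice_indices[i]),
                "relative_pos": float(p.relative_pos[i]),
                "ff": float(p.ff[i]),
                "n_voxels": int(p.n_voxels[i]),
            })
    return pd.DataFrame(rows)


def cohort_analysis_inputs(cohort: SyntheticCohort):
    """Flatten a phantom cohort into the tables the analyses consume.

    Returns (baseline_profiles, followup_profiles, patient_of, records,
    voxel volume) where ``patient_of`` maps (muscle, side) keys — made
    unique per leg by prefixing the patient id into the muscle name — to
    patient ids.
    """
    baseline_profiles: list[MuscleProfile] = []
    followup_profiles: list[MuscleProfile] = []
    patient_of: dict[tuple[str, str], str] = {}
    records = []
    dx, dy, dz = cohort.config.leg.voxel_spacing
    vox_ml = dx * dy * dz / 1000.0
    for leg in cohort.legs:
        patient = leg["patient"]
        for tp, phantom in (("baseline", leg["baseline"]), ("followup", leg["followup"])):
            if phantom is None:
                continue
            profs = leg_profiles(phantom.stacks, phantom.label_map, timepoint=tp)
            for prof in profs:
                # phantom muscle names repeat across patients; qualify them
                qualified = MuscleProfile(
                    muscle=f"{patient}:{prof.muscle}", side=prof.side,
                    timepoint=tp, slice_indices=prof.slice_indices,
                    ff=prof.ff, n_voxels=prof.n_voxels,
                    relative_pos=prof.relative_pos,
                )
                patient_of[(qualified.muscle, qualified.side)] = patient
                if tp == "baseline":
                    baseline_profiles.append(qualified)
                    records.append(muscle_record(qualified, patient, vox_ml))
                else:
                    followup_profiles.append(qualified)
    return baseline_profiles, followup_profiles, patient_of, records, vox_ml


def cohort_bias_records(cohort: SyntheticCohort) -> list[BiasRecord]:
    """Sampling-bias records for a phantom cohort (both quantities)."""
    base, follow, patient_of, _, _ = cohort_analysis_inputs(cohort)
    return bias_records(
        base, patient_of, followup_profiles=follow,
        interval_years=cohort.config.follow_up_years,
    )


def cohort_segment_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Baseline 5-segment table for the gradient mixed model."""
    base, _, patient_of, _, _ = cohort_analysis_inputs(cohort)
    return segment_table(base, patient_of)
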