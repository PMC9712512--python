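"""NIfTI, config and report I/O.

Volumes travel as .nii/.nii.gz with the voxel spacing encoded in the
affine; label tables, harmonization coefficients, orientation flags and
exclusion lists come from a YAML/JSON config.  Tables are written as CSV
with fixed column order and '.' decimal separator; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dixon import DixonStack, FatFractionVolume, HarmonizationModel, MuscleLabelMap, ValidationError


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, voxel spacing in mm)."""
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asanyarray(img.dataobj), zooms


def save_volume(path: str | Path, data: np.ndarray, spacing: tuple[float, float, float]) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def save_ff_volume(path: str | Path, volume: FatFractionVolume) -> None:
    save_volume(path, volume.ff, volume.voxel_spacing)


def load_dixon_stack(
    fat_path: str | Path,
    water_path: str | Path,
    axis_offset_mm: float = 0.0,
    distal_first: bool = True,
) -> DixonStack:
    fat, spacing = load_volume(fat_path)
    water, spacing_w = load_volume(water_path)
    if not np.allclose(spacing, spacing_w):
        raise ValidationError(
            f"fat/water voxel spacings differ: {spacing} vs {spacing_w}"
        )
    stack = DixonStack(
        fat=fat.astype(float), water=water.astype(float),
        voxel_spacing=spacing, axis_offset_mm=axis_offset_mm,
        distal_first=distal_first,
    )
    if not distal_first:
        stack = DixonStack(
            fat=stack.fat[:, :, ::-1], water=stack.water[:, :, ::-1],
            voxel_spacing=spacing, axis_offset_mm=axis_offset_mm,
            distal_first=True,
        )
    return stack


def load_label_map(
    labels_path: str | Path, config: dict
) -> MuscleLabelMap:
    """Label volume + table/exclusions from a parsed config mapping."""
    labels, _ = load_volume(labels_path)
    table = {
        int(k): dict(v) for k, v in config.get("label_table", {}).items()
    }
    exclusions = tuple(
        (e["muscle"], e.get("side", ""), e.get("timepoint", ""))
        for e in config.get("exclusions", [])
    )
    return MuscleLabelMap(
        labels=np.asarray(labels).astype(np.int32),
        label_table=table,
        exclusions=exclusions,
    )


def load_config(path: str | Path) -> dict:
    """YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def harmonization_from_config(config: dict) -> HarmonizationModel | None:
    block = config.get("harmonization")
    if block is None:
        return None
    return HarmonizationModel(
        slope=float(block.get("slope", 1.1864)),
        intercept=float(block.get("intercept", -2.7878)),
    )


def write_json_report(path: str | Path, payload: dict, schema: str = "fatfront/1") -> None:
    out = {"schema": schema, **payload}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
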