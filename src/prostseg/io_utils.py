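"""Readers and writers for the on-disk formats: PNG, single-slice NIfTI, CSV.

PNG carries 8-bit grayscale (intensities are clipped to [0, 255] and rounded
on save); NIfTI carries the raw floating-point values plus the pixel spacing
in its affine.  Label masks are restricted to classes {0, 1, 2} and validated
on load.  Cohort case records round-trip through CSV with a fixed header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from prostseg.phantoms import CaseRecord

__all__ = [
    "FormatError",
    "MaskValidationError",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "save_records",
    "load_records",
    "write_manifest",
]

VALID_LABELS = frozenset({0, 1, 2})

#: palette mapping class labels to display grays in mask PNGs is not used;
#: masks are stored with raw label values 0/1/2 so round-trips are exact.


class FormatError(ValueError):
    """Unrecognized or unsupported file format."""


class MaskValidationError(ValueError):
    """A loaded mask contains labels outside {0, 1, 2}."""


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def load_image(path) -> np.ndarray:
    """Load a 2D grayscale image from PNG or single-slice NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".png":
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=np.float64)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise FormatError(f"{path} is not a single-slice volume")
        return data
    raise FormatError(f"unsupported image format: {path.suffix!r}")


def save_image(image: np.ndarray, path, pixel_spacing: float = 1.0) -> None:
    """Save a 2D image as 8-bit PNG or floating-point single-slice NIfTI."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if path.suffix.lower() == ".png":
        data = np.clip(np.rint(image), 0, 255).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path)
        return
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(image[:, :, None], affine), str(path))
        return
    raise FormatError(f"unsupported image format: {path.suffix!r}")


def save_mask(mask: np.ndarray, path, pixel_spacing: float = 1.0) -> None:
    """Save a {0,1,2} label mask as PNG (raw label values) or NIfTI."""
    mask = np.asarray(mask)
    if not set(np.unique(mask)) <= VALID_LABELS:
        raise MaskValidationError(
            f"mask contains labels outside {sorted(VALID_LABELS)}"
        )
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
        return
    if _is_nifti(path):
        import nibabel as nib

        affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
        nib.save(nib.Nifti1Image(mask.astype(np.uint8)[:, :, None], affine), str(path))
        return
    raise FormatError(f"unsupported mask format: {path.suffix!r}")


def load_mask(path) -> np.ndarray:
    """Load a label mask and validate its values are within {0, 1, 2}."""
    data = load_image(path)
    mask = data.astype(np.int64)
    if not np.array_equal(mask, data):
        raise MaskValidationError(f"{path} contains non-integer labels")
    if not set(np.unique(mask)) <= VALID_LABELS:
        raise MaskValidationError(
            f"{path} contains labels outside {sorted(VALID_LABELS)}"
        )
    return mask.astype(np.uint8)


def load_spacing(path) -> float:
    """Read the in-plane pixel spacing (mm) recorded in a NIfTI header."""
    import nibabel as nib

    img = nib.load(str(path))
    return float(img.header.get_zooms()[0])


RECORD_COLUMNS = [
    "case_id",
    "true_class",
    "gleason_primary",
    "gleason_secondary",
    "gleason_score",
    "psa",
    "clinical_stage",
]


def save_records(records: Iterable[CaseRecord], path, include_risk: bool = False) -> None:
    """Write case records to CSV with the canonical column order."""
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in RECORD_COLUMNS}
        if include_risk:
            row["risk_group"] = r.risk_group if r.risk_group is not None else ""
        rows.append(row)
    cols = RECORD_COLUMNS + (["risk_group"] if include_risk else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")


def load_records(path) -> list[CaseRecord]:
    """Read case records from CSV written by :func:`save_records`."""
    df = pd.read_csv(path)
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"records CSV missing columns: {sorted(missing)}")
    records = []
    for _, r in df.iterrows():
        risk = r.get("risk_group")
        if risk is not None and (pd.isna(risk) or risk == ""):
            risk = None
        records.append(
            CaseRecord(
                case_id=str(r["case_id"]),
                true_class=str(r["true_class"]),
                gleason_primary=int(r["gleason_primary"]),
                gleason_secondary=int(r["gleason_secondary"]),
                gleason_score=int(r["gleason_score"]),
                psa=float(r["psa"]),
                clinical_stage=str(r["clinical_stage"]),
                risk_group=risk,
            )
        )
    return records


def write_manifest(path, config: dict, seed: int | None) -> None:
    """Record next to the outputs everything needed to reproduce them."""
    import prostseg

    manifest = {
        "package": "prostseg",
        "version": prostseg.__version__,
        "numpy": np.__version__,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
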