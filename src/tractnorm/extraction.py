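"""Per-tract metric extraction from volumes and bundle masks.

Optional imaging front-end: given a subject's FA and RD scalar volumes
and one binary (or probabilistic) mask per bundle, computes the
per-tract mean that the rest of the pipeline consumes.  Volumes and
masks must share grid shape and affine (registration is upstream); no
resampling is performed here.  NaN voxels are excluded from the mean
and counted in the provenance log, and an empty mask marks the tract
missing rather than raising.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import nibabel as nib
import numpy as np

from .cohort import TableValidationError, TractMetrics
from .registry import TractRegistry, default_tract_registry

__all__ = [
    "MetricVolume",
    "TractMask",
    "GridMismatchError",
    "tract_mean",
    "extract_subject_profile",
    "ExtractionProvenance",
    "load_metric_volume",
    "load_masks_from_manifest",
]

AFFINE_TOL = 1e-4
BINARY_THRESHOLD = 0.5  # probabilistic masks used in binary mode


class GridMismatchError(ValueError):
    """Volume and mask do not share grid shape / affine."""


@dataclass
class MetricVolume:
    """A 3-D scalar map (FA or RD) with its affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")


@dataclass
class TractMask:
    """A bundle mask on the same grid; binary {0,1} or probabilistic [0,1]."""

    data: np.ndarray
    affine: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def is_binary(self) -> bool:
        vals = np.unique(self.data[np.isfinite(self.data)])
        return np.all(np.isin(vals, (0.0, 1.0)))


def _check_grids(volume: MetricVolume, mask: TractMask) -> None:
    if volume.data.shape != mask.data.shape:
        raise GridMismatchError(
            f"mask {mask.name!r}: shape {mask.data.shape} != volume "
            f"shape {volume.data.shape}"
        )
    if not np.allclose(volume.affine, mask.affine, atol=AFFINE_TOL, rtol=0.0):
        raise GridMismatchError(f"mask {mask.name!r}: affine mismatch")


def tract_mean(volume: MetricVolume, mask: TractMask,
               mode: Literal["binary", "weighted"] = "binary",
               ) -> tuple[float | None, int]:
    """Mean of the volume over the mask; ``(None, nan_count)`` if empty.

    Binary mode: unweighted mean over voxels with mask > 0 (a
    probabilistic mask is thresholded at > 0.5).  Weighted mode:
    sum(w * x) / sum(w) over positive weights.  NaN voxels are excluded
    and counted.
    """
    _check_grids(volume, mask)
    if mode == "binary":
        sel = mask.data > (0.0 if mask.is_binary else BINARY_THRESHOLD)
        weights = np.ones(np.count_nonzero(sel))
        vals = volume.data[sel]
    elif mode == "weighted":
        sel = mask.data > 0.0
        weights = mask.data[sel]
        vals = volume.data[sel]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    nan = ~np.isfinite(vals)
    n_nan = int(np.count_nonzero(nan))
    vals, weights = vals[~nan], weights[~nan]
    if vals.size == 0 or weights.sum() <= 0.0:
        return None, n_nan  # tract-missing signal
    return float(np.sum(weights * vals) / np.sum(weights)), n_nan


@dataclass
class ExtractionProvenance:
    missing: list[str] = field(default_factory=list)
    nan_voxels: dict[str, int] = field(default_factory=dict)


def extract_subject_profile(fa_volume: MetricVolume, rd_volume: MetricVolume,
                            masks: Mapping[str, TractMask],
                            registry: TractRegistry | None = None,
                            mode: Literal["binary", "weighted"] = "binary",
                            ) -> tuple[TractMetrics, ExtractionProvenance]:
    """Average FA and RD over every supplied bundle mask.

    Tracts whose mask is empty (or absent) are recorded in the
    provenance log; an FA mean outside [0, 1] raises, as it indicates
    the wrong input volume.
    """
    registry = registry or default_tract_registry()
    prov = ExtractionProvenance()
    values: dict[str, tuple[float, float]] = {}
    for desc in registry:
        mask = masks.get(desc.name)
        if mask is None:
            prov.missing.append(desc.name)
            continue
        fa, n_nan_fa = tract_mean(fa_volume, mask, mode)
        rd, n_nan_rd = tract_mean(rd_volume, mask, mode)
        n_nan = n_nan_fa + n_nan_rd
        if n_nan:
            prov.nan_voxels[desc.name] = n_nan
        if fa is None or rd is None:
            prov.missing.append(desc.name)
            continue
        if not 0.0 <= fa <= 1.0:
            raise TableValidationError(
                f"tract {desc.name!r}: mean FA {fa!r} outside [0, 1]; "
                "wrong input volume?"
            )
        values[desc.name] = (fa, rd)
    return TractMetrics(values), prov


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_metric_volume(path: str | Path) -> MetricVolume:
    img = nib.load(str(path))
    return MetricVolume(data=np.asarray(img.get_fdata(), dtype=float),
                        affine=np.asarray(img.affine, dtype=float))


def load_masks_from_manifest(manifest_path: str | Path,
                             registry: TractRegistry | None = None,
                             ) -> dict[str, TractMask]:
    """Load bundle masks from a JSON manifest mapping tract name -> path.

    Relative paths resolve against the manifest's directory; tract
    names are resolved to their canonical registry spelling.
    """
    registry = registry or default_tract_registry()
    manifest_path = Path(manifest_path)
    mapping = json.loads(manifest_path.read_text())
    masks: dict[str, TractMask] = {}
    for name, rel in mapping.items():
        canonical = registry.resolve(name)
        p = Path(rel)
        if not p.is_absolute():
            p = manifest_path.parent / p
        img = nib.load(str(p))
        masks[canonical] = TractMask(
            data=np.asarray(img.get_fdata(), dtype=float),
            affine=np.asarray(img.affine, dtype=float),
            name=canonical,
        )
    return masks
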