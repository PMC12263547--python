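"""Shared voxel-grid containers and physical constants.

All volumes carry an explicit voxel size in mm; susceptibility is in parts
per million (ppm), phase in radians. NIfTI-1 round-tripping preserves the
voxel size in the header zooms and a diagonal affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

#: Canonical analysis regions: seven hippocampal subfields plus entorhinal
#: cortex, in fixed column order used by every table in the package.
REGIONS: tuple[str, ...] = (
    "parasubiculum",
    "presubiculum",
    "subiculum",
    "CA1",
    "CA3",
    "CA4",
    "GCDG",
    "EC",
)

HEMISPHERES: tuple[str, str] = ("L", "R")

#: Lateral-ventricle CSF compartment used as the susceptibility reference.
VENTRICLE: str = "ventricle"

#: Reduced gyromagnetic ratio of the proton, Hz/T.
GAMMA_BAR_HZ_PER_T: float = 42.577e6


def ppm_to_radians(b0: float, te: float) -> float:
    """Scale factor from a susceptibility-induced field shift in ppm to
    accrued GRE phase in radians at echo time ``te`` (s) and field ``b0`` (T).
    """
    return 2.0 * np.pi * GAMMA_BAR_HZ_PER_T * b0 * te * 1e-6


def _check_voxel_size(voxel_size) -> tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3 or any(v <= 0 for v in vs):
        raise ValueError(f"voxel_size must be 3 positive floats, got {voxel_size}")
    return vs


@dataclass
class Volume:
    """A 3D scalar grid with voxel size in mm."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        self.voxel_size = _check_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class SusceptibilityMap(Volume):
    """Susceptibility volume in ppm.

    ``reference_state`` records whether the offset indeterminacy of dipole
    inversion has been resolved against a reference region.
    """

    reference_state: str = "unreferenced"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.reference_state not in ("unreferenced", "referenced"):
            raise ValueError(f"bad reference_state {self.reference_state!r}")


@dataclass
class PhaseVolume(Volume):
    """Wrapped GRE phase in radians, values in (-pi, pi]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.data)):
            raise ValueError("phase volume contains non-finite values")
        if np.any(np.abs(self.data) > np.pi + 1e-9):
            raise ValueError("phase volume not wrapped to (-pi, pi]")


@dataclass
class Mask(Volume):
    """Binary voxel mask."""

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool)

    @property
    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabeledAtlas:
    """Integer label volume plus a label table.

    ``table`` maps label id -> (region name, hemisphere), hemisphere one of
    ``L``/``R``/``NA`` (``NA`` for midline structures such as the ventricle).
    """

    labels: np.ndarray
    table: Mapping[int, tuple[str, str]]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3 or not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be a 3D integer volume")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        self.table = dict(self.table)
        for lab, (region, hemi) in self.table.items():
            if hemi not in ("L", "R", "NA"):
                raise ValueError(f"label {lab} ({region}): bad hemisphere {hemi!r}")

    def label_for(self, region: str, hemisphere: str = "NA") -> int:
        for lab, (r, h) in self.table.items():
            if r == region and h == hemisphere:
                return lab
        raise KeyError(f"no label for region {region!r} hemisphere {hemisphere!r}")

    def mask_of(self, label_id: int) -> np.ndarray:
        return self.labels == label_id

    def table_frame(self) -> pd.DataFrame:
        rows = [
            {"label_id": lab, "region": r, "hemisphere": h}
            for lab, (r, h) in sorted(self.table.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI and TSV I/O


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_nifti(volume: Volume | LabeledAtlas, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with voxel size encoded in the affine."""
    if isinstance(volume, LabeledAtlas):
        data, vs = volume.labels.astype(np.int32), volume.voxel_size
    else:
        data = volume.data.astype(np.float64)
        if isinstance(volume, Mask):
            data = volume.data.astype(np.uint8)
        vs = volume.voxel_size
    img = nib.Nifti1Image(data, _affine(vs))
    img.header.set_zooms(vs)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vs


def load_susceptibility(path: str | Path, reference_state: str = "unreferenced") -> SusceptibilityMap:
    data, vs = load_nifti(path)
    return SusceptibilityMap(data=np.asarray(data, dtype=float), voxel_size=vs,
                             reference_state=reference_state)


def load_phase(path: str | Path) -> PhaseVolume:
    data, vs = load_nifti(path)
    return PhaseVolume(data=np.asarray(data, dtype=float), voxel_size=vs)


def load_mask(path: str | Path) -> Mask:
    data, vs = load_nifti(path)
    return Mask(data=np.asarray(data) > 0, voxel_size=vs)


def load_atlas(label_path: str | Path, table_path: str | Path) -> LabeledAtlas:
    data, vs = load_nifti(label_path)
    # keep_default_na: the midline hemisphere code "NA" is a value, not NaN
    tab = pd.read_csv(table_path, sep="\t", keep_default_na=False)
    table = {
        int(row.label_id): (str(row.region), str(row.hemisphere))
        for row in tab.itertuples()
    }
    return LabeledAtlas(labels=np.asarray(data, dtype=np.int64), table=table, voxel_size=vs)


def save_atlas(atlas: LabeledAtlas, label_path: str | Path, table_path: str | Path) -> None:
    save_nifti(atlas, label_path)
    atlas.table_frame().to_csv(table_path, sep="\t", index=False)
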