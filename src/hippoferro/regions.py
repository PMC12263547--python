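"""Regional susceptibility quantification.

Turns a susceptibility map plus a labeled atlas into per-region values:
mask erosion for the reference compartment, per-label means with optional
vascular-outlier pruning, data-driven reference selection (lowest
across-subject SD), offset referencing, and bilateral averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import HEMISPHERES, REGIONS, VENTRICLE, LabeledAtlas, Mask, SusceptibilityMap
from .recon import exclude_vascular_voxels

__all__ = [
    "RegionValue",
    "ReferenceChoice",
    "erode_mask",
    "region_means",
    "select_reference",
    "reference_normalize",
    "bilateral_average",
    "extract_subject_values",
    "referenced_cohort_table",
]


@dataclass
class RegionValue:
    region: str
    hemisphere: str
    mean_chi: float
    voxel_count: int
    volume: float  # mm^3

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError(f"{self.region}/{self.hemisphere}: voxel_count must be >= 1")


@dataclass
class ReferenceChoice:
    candidate_id: str
    across_subject_sd: float
    chosen: bool
    voxel_count: int = 0


def erode_mask(mask: Mask, iterations: int = 1) -> Mask:
    """Binary erosion with the 6-connected structuring element.

    Used on the ventricle compartment so partial-volume voxels at its rim do
    not contaminate the reference mean.  Raises if the result is empty.
    """
    if not mask.data.any():
        raise ValueError("cannot erode an empty mask")
    if iterations < 1:
        return mask
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask.data, structure=structure,
                                    iterations=iterations)
    if not eroded.any():
        raise ValueError(f"mask vanished after {iterations} erosion iteration(s)")
    return Mask(data=eroded, voxel_size=mask.voxel_size)


def region_means(chi: SusceptibilityMap, atlas: LabeledAtlas,
                 exclude_vascular: bool = False) -> list[RegionValue]:
    """Mean susceptibility and volume per atlas label.

    Volumes come from voxel counts times voxel volume; with
    ``exclude_vascular`` the median/MAD outlier rule prunes voxels before the
    mean (the volume still reflects the full label extent).
    """
    if chi.shape != atlas.labels.shape:
        raise ValueError(f"grid mismatch: chi {chi.shape} vs atlas {atlas.labels.shape}")
    voxvol = float(np.prod(atlas.voxel_size))
    out = []
    for lab, (region, hemi) in sorted(atlas.table.items()):
        m = atlas.labels == lab
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"label {lab} ({region}/{hemi}) missing from the label volume")
        if exclude_vascular:
            pruned = exclude_vascular_voxels(chi, Mask(data=m, voxel_size=atlas.voxel_size))
            mean = float(chi.data[pruned.data].mean())
        else:
            mean = float(chi.data[m].mean())
        out.append(RegionValue(region=region, hemisphere=hemi, mean_chi=mean,
                               voxel_count=n, volume=n * voxvol))
    return out


def select_reference(candidates: Mapping[str, Sequence[float]],
                     voxel_counts: Mapping[str, int] | None = None) -> list[ReferenceChoice]:
    """Pick the reference region: lowest SD of its mean susceptibility across
    subjects.

    ``candidates`` maps candidate id to the per-subject mean series.  Ties in
    SD break to the larger (eroded) voxel count, then lexicographic id.
    Returns one :class:`ReferenceChoice` per candidate, exactly one chosen.
    """
    if not candidates:
        raise ValueError("no reference candidates supplied")
    counts = voxel_counts or {}
    rows = []
    for cid, series in candidates.items():
        arr = np.asarray(series, dtype=float)
        if arr.size < 2:
            raise ValueError(f"candidate {cid!r} needs >= 2 subjects, got {arr.size}")
        rows.append((cid, float(np.std(arr, ddof=1)), int(counts.get(cid, 0))))
    # sort key: SD ascending, voxel count descending, id ascending
    best = min(rows, key=lambda t: (t[1], -t[2], t[0]))[0]
    return [ReferenceChoice(candidate_id=cid, across_subject_sd=sd,
                            chosen=(cid == best), voxel_count=cnt)
            for cid, sd, cnt in rows]


def chosen_reference(choices: Iterable[ReferenceChoice]) -> ReferenceChoice:
    picked = [c for c in choices if c.chosen]
    if len(picked) != 1:
        raise ValueError("expected exactly one chosen reference")
    return picked[0]


_DIVIDE_GUARD = 1e-12


def reference_normalize(values: Iterable[RegionValue], ref_mean: float,
                        mode: str = "subtract") -> list[RegionValue]:
    """Resolve the additive offset of dipole inversion against a reference.

    ``subtract`` keeps ppm units (chi' = chi - ref); ``divide`` returns the
    dimensionless ratio chi/ref and refuses near-zero references.
    """
    values = list(values)
    if mode == "subtract":
        return [replace(v, mean_chi=v.mean_chi - ref_mean) for v in values]
    if mode == "divide":
        if abs(ref_mean) < _DIVIDE_GUARD:
            raise ValueError(
                f"reference mean {ref_mean:g} too close to zero for divide "
                "referencing; use mode='subtract'")
        return [replace(v, mean_chi=v.mean_chi / ref_mean) for v in values]
    raise ValueError(f"unknown referencing mode {mode!r}")


def bilateral_average(left: RegionValue, right: RegionValue) -> RegionValue:
    """Unweighted mean of the two hemisphere means (and volumes)."""
    if left.region != right.region:
        raise ValueError(f"region mismatch: {left.region} vs {right.region}")
    if {left.hemisphere, right.hemisphere} != {"L", "R"}:
        raise ValueError("bilateral_average needs one L and one R value")
    return RegionValue(
        region=left.region,
        hemisphere="LR",
        mean_chi=0.5 * (left.mean_chi + right.mean_chi),
        voxel_count=left.voxel_count + right.voxel_count,
        volume=0.5 * (left.volume + right.volume),
    )


def extract_subject_values(chi: SusceptibilityMap, atlas: LabeledAtlas,
                           exclude_vascular: bool = False,
                           erode_iterations: int = 1) -> tuple[list[RegionValue], float, int]:
    """Per-label raw means plus the eroded-ventricle reference mean.

    Returns ``(region_values, ventricle_mean, ventricle_voxel_count)`` where
    the ventricle mean is computed on the mask eroded ``erode_iterations``
    times (6-connectivity).
    """
    values = region_means(chi, atlas, exclude_vascular=exclude_vascular)
    vent_label = atlas.label_for(VENTRICLE, "NA")
    vent_mask = Mask(data=atlas.mask_of(vent_label), voxel_size=atlas.voxel_size)
    eroded = erode_mask(vent_mask, erode_iterations) if erode_iterations else vent_mask
    vent_mean = float(chi.data[eroded.data].mean())
    subfields = [v for v in values if v.region != VENTRICLE]
    return subfields, vent_mean, eroded.count


def referenced_cohort_table(per_subject: Mapping[str, tuple[list[RegionValue], float]],
                            mode: str = "subtract") -> pd.DataFrame:
    """Assemble the referenced bilateral per-subject table.

    ``per_subject`` maps subject id to ``(region_values, reference_mean)``
    as returned by :func:`extract_subject_values`.  Output columns are the
    canonical region names; values are referenced bilateral means.
    """
    rows = {}
    for sid, (values, ref_mean) in per_subject.items():
        refd = reference_normalize(values, ref_mean, mode=mode)
        by_region: dict[str, dict[str, RegionValue]] = {}
        for v in refd:
            by_region.setdefault(v.region, {})[v.hemisphere] = v
        row = {}
        for region in REGIONS:
            pair = by_region.get(region, {})
            if set(pair) != {"L", "R"}:
                raise ValueError(f"subject {sid}: region {region} missing a hemisphere")
            row[region] = bilateral_average(pair["L"], pair["R"]).mean_chi
        rows[sid] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(REGIONS))
    frame.index.name = "subject_id"
    return frame
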