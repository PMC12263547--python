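"""Synthetic cohorts and voxel phantoms for the hippocampal-iron pipeline.

Two generators live here:

* :func:`generate_cohort` draws subject-level tables (bilateral regional
  susceptibility in ppm and volume in mm^3, plus age/sex/group) whose group
  moments match configurable targets.  The shipped defaults
  (:data:`HC_DEFAULTS`, :data:`MCI_DEFAULTS`) encode the published group
  summaries of a 7 T study of 28 cognitively healthy controls and 12
  participants with mild cognitive impairment.
* :func:`generate_phantom` builds labeled ellipsoid phantoms (bilateral
  subfield ellipsoids plus a ventricle compartment) and
  :func:`forward_field` turns a ground-truth susceptibility map into the
  wrapped single-echo GRE phase that the reconstruction stage consumes.

Hemisphere values are drawn independently with SD scaled by sqrt(2) so that
the left-right average reproduces the requested bilateral SD, the form in
which group variability is reported.  Regions are independent given group;
between-region covariance is not modelled (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    HEMISPHERES,
    REGIONS,
    VENTRICLE,
    LabeledAtlas,
    Mask,
    PhaseVolume,
    SusceptibilityMap,
    Volume,
    ppm_to_radians,
)
from .recon import ReconParams, dipole_kernel

__all__ = [
    "GroupParams",
    "SubjectRecord",
    "Ellipsoid",
    "PhantomSpec",
    "HC_DEFAULTS",
    "MCI_DEFAULTS",
    "generate_cohort",
    "cohort_frame",
    "write_cohort",
    "read_cohort",
    "generate_phantom",
    "phantom_magnitude",
    "forward_field",
    "default_phantom_spec",
]


@dataclass
class GroupParams:
    """Target moments for one diagnostic group.

    ``region_chi_*`` are bilateral susceptibility means/SDs in ppm,
    ``region_vol_*`` bilateral volumes in mm^3, over the canonical 8-region
    set.  ``n_female`` of the ``n`` subjects are assigned female sex.
    """

    group_label: str
    n: int
    region_chi_mean: Mapping[str, float]
    region_chi_sd: Mapping[str, float]
    region_vol_mean: Mapping[str, float]
    region_vol_sd: Mapping[str, float]
    age_mean: float
    age_sd: float
    n_female: int

    def __post_init__(self) -> None:
        if self.group_label not in ("HC", "MCI"):
            raise ValueError(f"group_label must be HC or MCI, got {self.group_label!r}")
        if self.n < 2:
            raise ValueError(f"need n >= 2 subjects, got {self.n}")
        if not 0 <= self.n_female <= self.n:
            raise ValueError(f"n_female={self.n_female} outside [0, n={self.n}]")
        for name, mapping in (
            ("region_chi_mean", self.region_chi_mean),
            ("region_chi_sd", self.region_chi_sd),
            ("region_vol_mean", self.region_vol_mean),
            ("region_vol_sd", self.region_vol_sd),
        ):
            if set(mapping) != set(REGIONS):
                raise ValueError(f"{name} must cover exactly the regions {REGIONS}")
        for name, mapping in (("region_chi_sd", self.region_chi_sd),
                              ("region_vol_sd", self.region_vol_sd)):
            bad = [r for r, v in mapping.items() if v < 0]
            if bad:
                raise ValueError(f"{name} negative for {bad}")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")


@dataclass
class SubjectRecord:
    subject_id: str
    group_label: str
    age: float
    sex: str
    chi_left: Mapping[str, float]
    chi_right: Mapping[str, float]
    vol_left: Mapping[str, float]
    vol_right: Mapping[str, float]

    def bilateral_chi(self, region: str) -> float:
        return 0.5 * (self.chi_left[region] + self.chi_right[region])

    def bilateral_vol(self, region: str) -> float:
        return 0.5 * (self.vol_left[region] + self.vol_right[region])


def _regions_dict(values: Sequence[float]) -> dict[str, float]:
    return dict(zip(REGIONS, values))


#: Published group summaries for the cognitively healthy control group
#: (n = 28): susceptibility (ppm) and volume (mm^3) bilateral means/SDs per
#: region, age distribution and sex counts.
HC_DEFAULTS = GroupParams(
    group_label="HC",
    n=28,
    region_chi_mean=_regions_dict([0.004, -0.004, -0.006, -0.005, -0.003, -0.018, -0.012, -0.004]),
    region_chi_sd=_regions_dict([0.009, 0.004, 0.005, 0.005, 0.007, 0.005, 0.005, 0.003]),
    region_vol_mean=_regions_dict([46.6, 253.3, 361.6, 592.9, 184.6, 222.8, 256.1, 1642.6]),
    region_vol_sd=_regions_dict([8.7, 37.7, 48.3, 62.0, 35.8, 32.7, 37.6, 256.5]),
    age_mean=67.2,
    age_sd=6.11,
    n_female=13,
)

#: Published group summaries for the mild-cognitive-impairment group (n = 12).
MCI_DEFAULTS = GroupParams(
    group_label="MCI",
    n=12,
    region_chi_mean=_regions_dict([0.004, -0.0005, -0.001, -0.001, 0.001, -0.018, -0.013, -0.002]),
    region_chi_sd=_regions_dict([0.008, 0.003, 0.005, 0.005, 0.007, 0.004, 0.003, 0.003]),
    region_vol_mean=_regions_dict([48.6, 231.8, 323.3, 541.4, 171.2, 201.7, 228.5, 1665.8]),
    region_vol_sd=_regions_dict([11.7, 30.8, 37.8, 58.4, 28.9, 20.5, 26.4, 429.5]),
    age_mean=73.9,
    age_sd=8.30,
    n_female=3,
)

#: Minimum age admitted by the study inclusion criteria, years.
AGE_FLOOR: float = 50.0


def _draw_group(params: GroupParams, seed_seq: np.random.SeedSequence,
                id_prefix: str) -> list[SubjectRecord]:
    group_rng = np.random.default_rng(seed_seq)
    # Sex labels: exactly n_female females, order randomized at group level.
    sexes = np.array(["F"] * params.n_female + ["M"] * (params.n - params.n_female))
    group_rng.shuffle(sexes)
    # One independent child stream per subject keeps subsets reproducible.
    subject_seqs = seed_seq.spawn(params.n)
    records = []
    for i, (sex, sub_seq) in enumerate(zip(sexes, subject_seqs)):
        rng = np.random.default_rng(sub_seq)
        if params.age_sd > 0:
            a = (AGE_FLOOR - params.age_mean) / params.age_sd
            age = float(stats.truncnorm.rvs(a, np.inf, loc=params.age_mean,
                                            scale=params.age_sd, random_state=rng))
        else:
            age = max(params.age_mean, AGE_FLOOR)
        chi_l, chi_r, vol_l, vol_r = {}, {}, {}, {}
        for region in REGIONS:
            csd = params.region_chi_sd[region] * np.sqrt(2.0)
            cl, cr = rng.normal(params.region_chi_mean[region], csd, size=2)
            chi_l[region], chi_r[region] = float(cl), float(cr)
            vsd = params.region_vol_sd[region] * np.sqrt(2.0)
            vl, vr = rng.normal(params.region_vol_mean[region], vsd, size=2)
            # volumes are physical; redraw the rare non-positive sample
            tries = 0
            while (vl <= 0 or vr <= 0) and tries < 100:
                vl, vr = rng.normal(params.region_vol_mean[region], vsd, size=2)
                tries += 1
            vol_l[region] = float(abs(vl)) if vl <= 0 else float(vl)
            vol_r[region] = float(abs(vr)) if vr <= 0 else float(vr)
        records.append(SubjectRecord(
            subject_id=f"{id_prefix}{i + 1:03d}",
            group_label=params.group_label,
            age=age,
            sex=str(sex),
            chi_left=chi_l, chi_right=chi_r,
            vol_left=vol_l, vol_right=vol_r,
        ))
    return records


def generate_cohort(hc: GroupParams = HC_DEFAULTS, mci: GroupParams = MCI_DEFAULTS,
                    seed: int = 0) -> list[SubjectRecord]:
    """Draw a full two-group cohort; deterministic for a fixed seed.

    Returns ``hc.n + mci.n`` subject records, HC first.
    """
    root = np.random.SeedSequence(seed)
    hc_seq, mci_seq = root.spawn(2)
    return _draw_group(hc, hc_seq, "HC") + _draw_group(mci, mci_seq, "MCI")


def cohort_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Wide per-subject table: metadata columns then <region>_chi_L/R (ppm)
    and <region>_vol_L/R (mm^3)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "group": rec.group_label,
            "age": rec.age,
            "sex": rec.sex,
        }
        for region in REGIONS:
            row[f"{region}_chi_L"] = rec.chi_left[region]
            row[f"{region}_chi_R"] = rec.chi_right[region]
        for region in REGIONS:
            row[f"{region}_vol_L"] = rec.vol_left[region]
            row[f"{region}_vol_R"] = rec.vol_right[region]
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: Iterable[SubjectRecord], path: str | Path) -> None:
    """Write the cohort table as TSV (``.tsv``) or JSON (``.json``)."""
    frame = cohort_frame(records)
    path = Path(path)
    if path.suffix == ".json":
        frame.to_json(path, orient="records", indent=2)
    else:
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.read_json(path, orient="records")
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Voxel phantoms


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def mask(self, shape: Sequence[int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        acc = np.zeros(tuple(shape), dtype=float)
        for g, c, a in zip(grids, self.center, self.semi_axes):
            acc = acc + ((g - c) / a) ** 2
        return acc <= 1.0

    def continuous_volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c


#: Voxels of zero-susceptibility padding required at every grid face so the
#: periodic FFT convolutions of the forward/inverse model stay faithful.
PAD_VOXELS: int = 8


@dataclass
class PhantomSpec:
    """Geometry and ground truth for one labeled ellipsoid phantom."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    region_geometry: Mapping[tuple[str, str], Ellipsoid]
    ventricle_geometry: Ellipsoid
    region_chi: Mapping[str, float]
    background_chi: float = 0.0
    ventricle_chi: float = 0.0
    noise_sd_phase: float = 0.0
    B0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    seed: int = 0
    brain_geometry: Ellipsoid | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        missing = set(REGIONS) - {r for r, _ in self.region_geometry}
        if missing:
            raise ValueError(f"region_geometry missing regions: {sorted(missing)}")
        for key in self.region_chi:
            region = key[0] if isinstance(key, tuple) else key
            if region not in REGIONS and region != VENTRICLE:
                raise ValueError(f"region_chi contains unknown region {key!r}")


def _label_table() -> dict[int, tuple[str, str]]:
    table: dict[int, tuple[str, str]] = {}
    lab = 1
    for region in REGIONS:
        for hemi in HEMISPHERES:
            table[lab] = (region, hemi)
            lab += 1
    table[lab] = (VENTRICLE, "NA")
    return table


def generate_phantom(spec: PhantomSpec) -> tuple[LabeledAtlas, SusceptibilityMap]:
    """Paint the labeled atlas and exact ground-truth susceptibility map.

    Raises on overlapping geometry (naming the colliding labels) and on
    structures violating the zero-padding margin required by the periodic
    forward model.
    """
    shape = tuple(spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int64)
    chi = np.full(shape, float(spec.background_chi))
    table = _label_table()
    name_of = {lab: (f"{r}_{h}" if h != "NA" else r) for lab, (r, h) in table.items()}

    geoms: dict[int, Ellipsoid] = {}
    for lab, (region, hemi) in table.items():
        if region == VENTRICLE:
            geoms[lab] = spec.ventricle_geometry
        else:
            geoms[lab] = spec.region_geometry[(region, hemi)]

    for lab, geom in geoms.items():
        m = geom.mask(shape)
        if not m.any():
            raise ValueError(f"label {name_of[lab]} paints no voxels")
        clash = labels[m]
        clash = clash[clash != 0]
        if clash.size:
            other = name_of[int(clash[0])]
            raise ValueError(f"overlapping phantom geometry: {name_of[lab]} collides with {other}")
        idx = np.argwhere(m)
        lo, hi = idx.min(axis=0), idx.max(axis=0)
        if (lo < PAD_VOXELS).any() or (hi >= np.array(shape) - PAD_VOXELS).any():
            raise ValueError(
                f"label {name_of[lab]} violates the {PAD_VOXELS}-voxel zero-padding margin")
        labels[m] = lab
        region, hemi = table[lab]
        if region == VENTRICLE:
            chi_val = spec.ventricle_chi
        else:
            # hemisphere-specific value wins over the bilateral one
            chi_val = spec.region_chi.get((region, hemi), spec.region_chi.get(region, 0.0))
        chi[m] = chi_val

    atlas = LabeledAtlas(labels=labels, table=table, voxel_size=spec.voxel_size)
    chi_map = SusceptibilityMap(data=chi, voxel_size=spec.voxel_size)
    return atlas, chi_map


def phantom_magnitude(spec: PhantomSpec) -> Volume:
    """Synthetic GRE magnitude: 1 inside the brain envelope, 0 outside."""
    if spec.brain_geometry is None:
        raise ValueError("spec has no brain_geometry")
    return Volume(data=spec.brain_geometry.mask(spec.grid_shape).astype(float),
                  voxel_size=spec.voxel_size)


def default_phantom_spec(grid: int = 48, voxel_size=(1.0, 1.0, 1.0),
                         region_chi: Mapping[str, float] | None = None,
                         semi_axes=(3.2, 3.2, 3.2),
                         noise_sd_phase: float = 0.0,
                         seed: int = 0) -> PhantomSpec:
    """A compact bilateral phantom: 16 subfield ellipsoids and a ventricle
    on a 3 x 3 x 2 lattice inside the padding margin, brain envelope around
    them.  Region susceptibilities default to the healthy-control means.
    """
    if region_chi is None:
        region_chi = dict(HC_DEFAULTS.region_chi_mean)
    lo = PAD_VOXELS + max(semi_axes) + 1
    hi = grid - PAD_VOXELS - max(semi_axes) - 1
    if hi - lo < 2 * max(semi_axes):
        raise ValueError(f"grid {grid} too small for semi-axes {semi_axes}")
    xs = np.linspace(lo, hi, 3)
    zs = np.linspace(lo, hi, 3)
    slots = [(x, y, z) for z in zs for y in xs for x in xs]  # 27 slots
    geometry: dict[tuple[str, str], Ellipsoid] = {}
    i = 0
    for region in REGIONS:
        for hemi in HEMISPHERES:
            geometry[(region, hemi)] = Ellipsoid(center=slots[i], semi_axes=semi_axes)
            i += 1
    ventricle = Ellipsoid(center=slots[i], semi_axes=semi_axes)
    center = ((grid - 1) / 2.0,) * 3
    brain = Ellipsoid(center=center, semi_axes=((grid - 2) / 2.0,) * 3)
    return PhantomSpec(
        grid_shape=(grid, grid, grid),
        voxel_size=tuple(voxel_size),
        region_geometry=geometry,
        ventricle_geometry=ventricle,
        region_chi=dict(region_chi),
        noise_sd_phase=noise_sd_phase,
        seed=seed,
        brain_geometry=brain,
    )


def phantom_spec_for_subject(record: SubjectRecord, grid: int = 48,
                             voxel_size=(1.0, 1.0, 1.0),
                             noise_sd_phase: float = 0.0,
                             seed: int = 0,
                             semi_axes=(3.2, 3.2, 3.2)) -> PhantomSpec:
    """Phantom spec whose hemisphere ellipsoids carry the subject's own
    bilateral susceptibility values."""
    chi: dict = {}
    for region in REGIONS:
        chi[(region, "L")] = record.chi_left[region]
        chi[(region, "R")] = record.chi_right[region]
    base = default_phantom_spec(grid=grid, voxel_size=voxel_size,
                                semi_axes=semi_axes,
                                noise_sd_phase=noise_sd_phase, seed=seed)
    base.region_chi = chi
    return base


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap radians into (-pi, pi]."""
    wrapped = np.mod(phase + np.pi, 2.0 * np.pi) - np.pi
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def forward_field(chi: SusceptibilityMap, params: ReconParams,
                  noise_sd_phase: float = 0.0, seed: int | None = None) -> PhaseVolume:
    """Wrapped single-echo GRE phase induced by a susceptibility map.

    The field shift is the periodic dipole convolution evaluated in k-space;
    phase accrues linearly with echo time and is wrapped into (-pi, pi].
    Optional Gaussian phase noise is added before wrapping.
    """
    if not np.all(np.isfinite(chi.data)):
        raise ValueError("susceptibility map contains non-finite values")
    d = dipole_kernel(chi.shape, chi.voxel_size, params.B0_direction)
    field = np.fft.ifftn(d * np.fft.fftn(chi.data)).real
    phase = ppm_to_radians(params.B0, params.TE) * field
    if noise_sd_phase > 0:
        rng = np.random.default_rng(seed)
        phase = phase + rng.normal(0.0, noise_sd_phase, size=phase.shape)
    return PhaseVolume(data=wrap_phase(phase), voxel_size=chi.voxel_size)
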