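"""Configured, seedable orchestration: simulate -> recon -> extract -> stats.

A run is described by a YAML/JSON mapping (see :class:`RunConfig`); every
stage writes its artifacts under the output directory and the final
:class:`StatsReport` carries a provenance block (config hash, seed, package
version) so any reported number is traceable to a stage output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (REGIONS, Volume, load_atlas, load_nifti, load_phase,
                   load_susceptibility, save_atlas, save_nifti)
from .recon import ReconParams, make_brain_mask, tgv_invert
from .regions import extract_subject_values, referenced_cohort_table
from .stats import (KSResult, SubfieldMatrix, coherence_compare, covariate_split,
                    cv_summary, group_test_table, icc_2_1, jarque_bera)
from .synthetic import (GroupParams, HC_DEFAULTS, MCI_DEFAULTS, forward_field,
                        generate_cohort, generate_phantom, phantom_magnitude,
                        phantom_spec_for_subject, read_cohort, write_cohort)

__all__ = ["RunConfig", "StatsReport", "run_pipeline", "validate_table",
           "write_report", "build_matrix"]

STAGES = ("simulate", "recon", "extract", "stats")


def _stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the root seed (< 2**31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Validated run configuration.

    ``stages`` is an ordered subset of simulate/recon/extract/stats; stage
    dependencies (recon needs simulated phantoms, extract needs chi maps,
    stats needs a table) are checked before any work happens.
    """

    stages: tuple[str, ...]
    seed: int = 0
    out_dir: str = "run_out"
    # simulate block
    hc: GroupParams = field(default_factory=lambda: HC_DEFAULTS)
    mci: GroupParams = field(default_factory=lambda: MCI_DEFAULTS)
    phantoms: bool = False
    grid: int = 48
    noise_sd_phase: float = 0.0
    # recon block
    recon_params: ReconParams = field(default_factory=ReconParams)
    # extract block
    erode_iterations: int = 1
    exclude_vascular: bool = False
    referencing: str = "subtract"
    # stats block
    value: str = "chi"  # chi | volume
    precision: int = 2
    table_path: str | None = None  # external table for a stats-only run

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if list(self.stages) != [s for s in STAGES if s in self.stages]:
            raise ValueError(f"stages must be ordered as {STAGES}")
        if "recon" in self.stages and "simulate" not in self.stages:
            raise ValueError("recon requires the simulate stage (phantom inputs)")
        if "extract" in self.stages and "recon" not in self.stages:
            raise ValueError("extract requires the recon stage (chi maps)")
        if "stats" in self.stages and not (
                "simulate" in self.stages or "extract" in self.stages
                or self.table_path):
            raise ValueError("stats requires a table: simulate/extract stage or table_path")
        if self.value not in ("chi", "volume"):
            raise ValueError(f"value must be 'chi' or 'volume', got {self.value!r}")
        if self.referencing not in ("subtract", "divide"):
            raise ValueError(f"unknown referencing mode {self.referencing!r}")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        known_top = {"stages", "seed", "out_dir", "simulate", "recon", "extract",
                     "stats", "table_path"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {
            "stages": tuple(raw.get("stages", ("simulate", "stats"))),
            "seed": int(raw.get("seed", 0)),
            "out_dir": str(raw.get("out_dir", "run_out")),
            "table_path": raw.get("table_path"),
        }
        sim = dict(raw.get("simulate") or {})
        for grp_key, default in (("hc", HC_DEFAULTS), ("mci", MCI_DEFAULTS)):
            if grp_key in sim:
                kwargs[grp_key] = replace(default, **sim.pop(grp_key))
        for key in ("phantoms", "grid", "noise_sd_phase"):
            if key in sim:
                kwargs[key] = sim.pop(key)
        if sim:
            raise ValueError(f"unknown simulate keys: {sorted(sim)}")
        rec = dict(raw.get("recon") or {})
        if rec:
            kwargs["recon_params"] = ReconParams(**rec)
        ext = dict(raw.get("extract") or {})
        for key in ("erode_iterations", "exclude_vascular", "referencing"):
            if key in ext:
                kwargs[key] = ext.pop(key)
        if ext:
            raise ValueError(f"unknown extract keys: {sorted(ext)}")
        st = dict(raw.get("stats") or {})
        for key in ("value", "precision"):
            if key in st:
                kwargs[key] = st.pop(key)
        if st:
            raise ValueError(f"unknown stats keys: {sorted(st)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = _to_jsonable(dataclasses.asdict(self))
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class StatsReport:
    """All statistics of one run plus provenance."""

    value_kind: str
    group_tests: pd.DataFrame
    iccs: dict[str, dict[str, float]]
    ks_groups: KSResult
    cv: dict
    jarque_bera_p: dict[str, float]
    covariate_splits: dict[str, dict]
    provenance: dict[str, Any]

    def to_json_dict(self) -> dict:
        return _to_jsonable({
            "value_kind": self.value_kind,
            "group_tests": self.group_tests.reset_index().to_dict(orient="records"),
            "iccs": self.iccs,
            "ks_groups": dataclasses.asdict(self.ks_groups),
            "cv": self.cv,
            "jarque_bera_p": self.jarque_bera_p,
            "covariate_splits": self.covariate_splits,
            "provenance": self.provenance,
        })


# ---------------------------------------------------------------------------
# Table validation


def validate_table(path: str | Path) -> pd.DataFrame:
    """Schema-check a cohort table; informative errors name the offenders."""
    frame = read_cohort(path)
    problems = []
    for col in ("subject_id", "group", "age", "sex"):
        if col not in frame.columns:
            problems.append(f"missing metadata column {col!r}")
    value_cols = []
    for region in REGIONS:
        for kind in ("chi", "vol"):
            for hemi in ("L", "R"):
                col = f"{region}_{kind}_{hemi}"
                if col not in frame.columns:
                    problems.append(f"missing region column {col!r}")
                else:
                    value_cols.append(col)
    if problems:
        raise ValueError("invalid cohort table: " + "; ".join(problems))
    dup = frame["subject_id"][frame["subject_id"].duplicated()]
    if len(dup):
        problems.append(f"duplicate subject ids: {sorted(set(dup))}")
    for col in value_cols:
        bad = pd.to_numeric(frame[col], errors="coerce").isna()
        if bad.any():
            rows = frame.loc[bad, "subject_id"].tolist()
            problems.append(f"non-numeric cells in {col!r} (subjects {rows})")
    if not problems:
        for region in REGIONS:
            for hemi in ("L", "R"):
                col = f"{region}_vol_{hemi}"
                nonpos = frame[col] <= 0
                if nonpos.any():
                    rows = frame.loc[nonpos, "subject_id"].tolist()
                    problems.append(f"non-positive volume in {col!r} (subjects {rows})")
    if problems:
        raise ValueError("invalid cohort table: " + "; ".join(problems))
    return frame


def build_matrix(frame: pd.DataFrame, value: str = "chi") -> SubfieldMatrix:
    """Bilateral subjects x regions matrix from a wide cohort table."""
    kind = {"chi": "chi", "volume": "vol"}[value]
    data = {
        region: 0.5 * (frame[f"{region}_{kind}_L"] + frame[f"{region}_{kind}_R"]).to_numpy()
        for region in REGIONS
    }
    values = pd.DataFrame(data, index=pd.Index(frame["subject_id"], name="subject_id"))
    values = values[list(REGIONS)]
    return SubfieldMatrix(
        values=values,
        groups=pd.Series(frame["group"].to_numpy(), index=values.index),
        ages=pd.Series(frame["age"].to_numpy(), index=values.index),
        sexes=pd.Series(frame["sex"].to_numpy(), index=values.index),
    )


# ---------------------------------------------------------------------------
# Stats stage


def compute_report(matrix: SubfieldMatrix, value_kind: str,
                   provenance: Mapping[str, Any] | None = None) -> StatsReport:
    """Full statistics block for a subjects x regions matrix.

    Effect-size sign follows the reporting convention for each value kind:
    MCI - HC for susceptibility (positive = more iron in MCI), HC - MCI for
    volumes (positive = atrophy in MCI).
    """
    sign = "a_minus_b" if value_kind == "chi" else "b_minus_a"
    tests = group_test_table(matrix, "MCI", "HC", effect_sign=sign)
    iccs: dict[str, dict[str, float]] = {}
    all_icc = icc_2_1(matrix.values.to_numpy().T)
    iccs["all"] = {"icc": all_icc.icc, "n_subjects": matrix.n_subjects}
    per_group, ks = coherence_compare(matrix)
    for lab, res in per_group.items():
        iccs[lab] = {"icc": res.icc, "n_subjects": res.k_raters}
    # normality screen needs a minimally sized cohort
    if matrix.n_subjects >= 8:
        jb = {region: jarque_bera(matrix.values[region])[1] for region in REGIONS}
    else:
        jb = {}
    means = {r: float(matrix.values[r].mean()) for r in REGIONS}
    sds = {r: float(matrix.values[r].std(ddof=1)) for r in REGIONS}
    cv = cv_summary(means, sds) if all(m > 0 for m in means.values()) else {
        "per_region": {}, "note": "CV undefined for non-positive means"}
    splits = {}
    for cov in ("age_median", "sex"):
        try:
            cov_iccs, cov_ks = covariate_split(matrix, cov)
            splits[cov] = {
                "iccs": {k: v.icc for k, v in cov_iccs.items()},
                "ks": dataclasses.asdict(cov_ks),
            }
        except ValueError as err:
            splits[cov] = {"error": str(err)}
    return StatsReport(
        value_kind=value_kind,
        group_tests=tests,
        iccs=iccs,
        ks_groups=ks,
        cv=cv,
        jarque_bera_p=jb,
        covariate_splits=splits,
        provenance=dict(provenance or {}),
    )


def write_report(report: StatsReport, outdir: str | Path,
                 matrix: SubfieldMatrix | None = None,
                 precision: int = 2) -> dict[str, Path]:
    """Write report JSON + per-region TSV (+ long-format scatter TSV).

    Full precision is preserved (round-tripping the TSV/JSON reproduces
    every number exactly); a companion ``*_printed.tsv`` renders the table
    at reporting precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    jpath = outdir / "report.json"
    with open(jpath, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1)
    paths["json"] = jpath
    tpath = outdir / "group_tests.tsv"
    report.group_tests.reset_index().to_csv(tpath, sep="\t", index=False,
                                            float_format="%.17g")
    paths["tsv"] = tpath
    printed = report.group_tests.round(precision)
    ppath = outdir / "group_tests_printed.tsv"
    printed.reset_index().to_csv(ppath, sep="\t", index=False)
    paths["printed"] = ppath
    if matrix is not None:
        long = matrix.values.reset_index().melt(
            id_vars="subject_id", var_name="region", value_name="value")
        long["group"] = long["subject_id"].map(
            dict(zip(matrix.values.index, matrix.groups)))
        spath = outdir / "scatter.tsv"
        long[["subject_id", "group", "region", "value"]].to_csv(
            spath, sep="\t", index=False, float_format="%.17g")
        paths["scatter"] = spath
    return paths


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: RunConfig) -> StatsReport:
    """Execute the configured stages in order; deterministic per seed."""
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    records = None
    frame = None
    chi_paths: dict[str, Path] = {}
    atlas_paths: dict[str, tuple[Path, Path]] = {}

    if "simulate" in config.stages:
        seed = _stage_seed(config.seed, "simulate")
        records = generate_cohort(config.hc, config.mci, seed=seed)
        table_path = outdir / "cohort.tsv"
        write_cohort(records, table_path)
        write_cohort(records, outdir / "cohort.json")
        log("simulate", f"{len(records)} subjects -> {table_path} (seed {seed})")
        frame = validate_table(table_path)
        if config.phantoms:
            pdir = outdir / "phantoms"
            pdir.mkdir(exist_ok=True)
            for i, rec in enumerate(records):
                spec = phantom_spec_for_subject(
                    rec, grid=config.grid,
                    noise_sd_phase=config.noise_sd_phase,
                    seed=_stage_seed(config.seed, f"phantom:{rec.subject_id}"))
                atlas, chi = generate_phantom(spec)
                phase = forward_field(chi, config.recon_params,
                                      noise_sd_phase=spec.noise_sd_phase,
                                      seed=spec.seed)
                sid = rec.subject_id
                save_atlas(atlas, pdir / f"{sid}_labels.nii.gz",
                           pdir / f"{sid}_labels.tsv")
                save_nifti(phase, pdir / f"{sid}_phase.nii.gz")
                save_nifti(phantom_magnitude(spec), pdir / f"{sid}_mag.nii.gz")
                save_nifti(chi, pdir / f"{sid}_chi_true.nii.gz")
                atlas_paths[sid] = (pdir / f"{sid}_labels.nii.gz",
                                   pdir / f"{sid}_labels.tsv")
            log("simulate", f"phantoms for {len(records)} subjects -> {pdir}")

    if "recon" in config.stages:
        if not atlas_paths:
            raise ValueError("recon stage needs simulated phantoms "
                             "(set simulate.phantoms: true)")
        pdir = outdir / "phantoms"
        for sid in atlas_paths:
            phase = load_phase(pdir / f"{sid}_phase.nii.gz")
            mag_data, vs = load_nifti(pdir / f"{sid}_mag.nii.gz")
            mask = make_brain_mask(Volume(data=np.asarray(mag_data, float),
                                          voxel_size=vs), 0.1)
            res = tgv_invert(phase, mask, config.recon_params, objective_every=25)
            cpath = pdir / f"{sid}_chi.nii.gz"
            save_nifti(res.chi, cpath)
            chi_paths[sid] = cpath
            log("recon", f"{sid}: {config.recon_params.iterations} iterations, "
                         f"objective {res.objective[-1]:.4g} -> {cpath}")

    if "extract" in config.stages:
        per_subject = {}
        for sid, cpath in chi_paths.items():
            chi = load_susceptibility(cpath)
            atlas = load_atlas(*atlas_paths[sid])
            vals, vent_mean, vcnt = extract_subject_values(
                chi, atlas, exclude_vascular=config.exclude_vascular,
                erode_iterations=config.erode_iterations)
            per_subject[sid] = (vals, vent_mean)
        table = referenced_cohort_table(per_subject, mode=config.referencing)
        epath = outdir / "referenced_chi.tsv"
        table.to_csv(epath, sep="\t", float_format="%.17g")
        log("extract", f"referenced table ({config.referencing}) -> {epath}")
        # splice extracted values back into a wide frame for the stats stage
        if frame is not None:
            for region in REGIONS:
                frame[f"{region}_chi_L"] = frame["subject_id"].map(table[region])
                frame[f"{region}_chi_R"] = frame["subject_id"].map(table[region])

    report = None
    if "stats" in config.stages:
        if frame is None:
            frame = validate_table(config.table_path)
        matrix = build_matrix(frame, config.value)
        provenance = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": list(config.stages),
        }
        report = compute_report(matrix, config.value, provenance)
        paths = write_report(report, outdir / "report", matrix=matrix,
                             precision=config.precision)
        log("stats", f"report -> {paths['json']}")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    if report is None:
        raise ValueError("no stats stage configured; nothing to report")
    return report
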