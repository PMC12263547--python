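"""Shared fixtures: published summary tables as test inputs, and the two
expensive reconstruction fixtures (sphere phantom, 6-subject cohort) built
once per session."""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hippoferro.core import REGIONS, Mask, SusceptibilityMap
from hippoferro.recon import ReconParams, make_brain_mask, tgv_invert
from hippoferro.regions import extract_subject_values, referenced_cohort_table
from hippoferro.synthetic import (Ellipsoid, HC_DEFAULTS, MCI_DEFAULTS,
                                  forward_field, generate_cohort,
                                  generate_phantom, phantom_magnitude,
                                  phantom_spec_for_subject)

# ---------------------------------------------------------------------------
# Published summary tables (inputs to replication tests)

#: Demographics: (mean, SD, n) of age per group.
AGE_SUMMARY = {"MCI": (73.9, 8.30, 12), "HC": (67.2, 6.11, 28)}

#: Subfield volumes (mm^3): All / MCI / HC columns as (mean, SD).
VOLUME_TABLE = pd.DataFrame(
    {
        "all_mean": [47.2, 246.9, 350.1, 577.4, 180.6, 216.4, 247.8, 1649.6],
        "all_sd": [9.6, 36.7, 48.3, 64.8, 34.1, 30.9, 36.6, 312.6],
        "mci_mean": [48.6, 231.8, 323.3, 541.4, 171.2, 201.7, 228.5, 1665.8],
        "mci_sd": [11.7, 30.8, 37.8, 58.4, 28.9, 20.5, 26.4, 429.5],
        "hc_mean": [46.6, 253.3, 361.6, 592.9, 184.6, 222.8, 256.1, 1642.6],
        "hc_sd": [8.7, 37.7, 48.3, 62.0, 35.8, 32.7, 37.6, 256.5],
        "p_raw": [0.59, 0.07, 0.01, 0.02, 0.23, 0.02, 0.01, 0.86],
        "p_fdr": [0.67, 0.11, 0.04, 0.04, 0.30, 0.04, 0.04, 0.86],
        "cohens_d": [-0.21, 0.59, 0.82, 0.83, 0.39, 0.70, 0.78, -0.07],
    },
    index=list(REGIONS),
)

#: Referenced subfield susceptibilities (ppm): MCI / HC group means.
CHI_TABLE = pd.DataFrame(
    {
        "mci_mean": [0.004, -0.0005, -0.001, -0.001, 0.001, -0.018, -0.013, -0.002],
        "hc_mean": [0.004, -0.004, -0.006, -0.005, -0.003, -0.018, -0.012, -0.004],
    },
    index=list(REGIONS),
)


@pytest.fixture(scope="session")
def volume_table() -> pd.DataFrame:
    return VOLUME_TABLE


@pytest.fixture(scope="session")
def chi_table() -> pd.DataFrame:
    return CHI_TABLE


# ---------------------------------------------------------------------------
# Expensive reconstruction fixtures


SPHERE_CONTRAST = 0.02  # ppm; magnitude of the largest subfield-CSF contrast


@pytest.fixture(scope="session")
def sphere_recon():
    """Noiseless 48^3 sphere phantom pushed through forward model and the
    full 1000-iteration TGV inversion, with iterate snapshots."""
    grid = 48
    sphere = Ellipsoid(center=(23.5,) * 3, semi_axes=(6.0,) * 3)
    inside = sphere.mask((grid,) * 3)
    chi_true = np.where(inside, SPHERE_CONTRAST, 0.0)
    params = ReconParams(iterations=1000)
    phase = forward_field(
        SusceptibilityMap(data=chi_true, voxel_size=(1.0, 1.0, 1.0)), params)
    brain = Ellipsoid(center=(23.5,) * 3, semi_axes=(20.0,) * 3)
    mask = Mask(data=brain.mask((grid,) * 3), voxel_size=(1.0, 1.0, 1.0))
    result = tgv_invert(phase, mask, params, snapshot_at=(50, 200, 1000),
                        objective_every=1)
    return {
        "chi_true": chi_true, "inside": inside, "mask": mask.data,
        "contrast": SPHERE_CONTRAST, "result": result, "phase": phase,
    }


def sphere_rmse(snapshot: np.ndarray, fixture: dict) -> float:
    """Mean-subtracted in-sphere RMSE relative to the true contrast."""
    m, inside = fixture["mask"], fixture["inside"]
    rec = snapshot - snapshot[m].mean()
    tru = fixture["chi_true"] - fixture["chi_true"][m].mean()
    return float(np.sqrt(np.mean((rec[inside] - tru[inside]) ** 2))
                 / fixture["contrast"])


@pytest.fixture(scope="session")
def cohort_e2e():
    """Six-subject phantom cohort (3 HC + 3 MCI) through forward model,
    TGV inversion, erosion, extraction, referencing and bilateral averaging.
    """
    hc = replace(HC_DEFAULTS, n=3, n_female=1)
    mci = replace(MCI_DEFAULTS, n=3, n_female=1)
    records = generate_cohort(hc, mci, seed=11)
    params = ReconParams(iterations=500)
    per_subject, truth = {}, {}
    t0 = time.time()
    for rec in records:
        spec = phantom_spec_for_subject(rec)
        atlas, chi = generate_phantom(spec)
        phase = forward_field(chi, params)
        mask = make_brain_mask(phantom_magnitude(spec), 0.1)
        res = tgv_invert(phase, mask, params, objective_every=50)
        vals, vent_mean, _ = extract_subject_values(res.chi, atlas)
        per_subject[rec.subject_id] = (vals, vent_mean)
        truth[rec.subject_id] = {r: rec.bilateral_chi(r) for r in REGIONS}
    elapsed = time.time() - t0
    table = referenced_cohort_table(per_subject)
    truth_table = pd.DataFrame.from_dict(truth, orient="index")[list(REGIONS)]
    return {"recovered": table, "truth": truth_table, "elapsed_s": elapsed,
            "records": records}
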