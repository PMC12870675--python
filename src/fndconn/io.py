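"""NIfTI volumes, cohort tables, configuration, and truth records.

All phantom-grid volumes are written as NIfTI-1 with a unit affine; the
cohort table is a TSV with one row per subject and a documented schema
(see :data:`COHORT_COLUMNS`).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .simulate import CGI_CATEGORIES, SimulationConfig

__all__ = [
    "read_volume",
    "write_volume",
    "read_cohort_table",
    "write_cohort_table",
    "load_config",
    "save_config",
    "COHORT_COLUMNS",
]


class FormatError(ValueError):
    pass


class SchemaError(ValueError):
    pass


#: cohort-table schema: column -> (dtype kind, required for FND rows)
COHORT_COLUMNS = {
    "subject_id": ("str", True),
    "group": ("str", True),
    "age": ("float", True),
    "sex": ("binary", True),
    "ssri_snri": ("binary", True),
    "fnd_seizure": ("binary", True),
    "interval_months": ("float", True),
    "mean_fd_baseline": ("float", True),
    "mean_fd_followup": ("float", True),
    "has_followup_scan": ("bool", True),
    "soms_cd_baseline": ("float", True),
    "soms_cd_followup": ("float", False),
    "phq15_baseline": ("float", True),
    "phq15_followup": ("float", False),
    "bdi_baseline": ("float", True),
    "bdi_followup": ("float", False),
    "stai_baseline": ("float", True),
    "stai_followup": ("float", False),
    "pcl5_baseline": ("float", True),
    "ctq_abuse": ("float", True),
    "ctq_neglect": ("float", True),
    "cgi_i": ("cgi", False),
}

_SYMPTOM_FIELDS = [
    c for c in COHORT_COLUMNS
    if c.startswith(("soms", "phq", "bdi", "stai", "pcl", "ctq")) or c == "cgi_i"
]


def write_volume(data: np.ndarray, path) -> None:
    """Write a 3D map or 4D series as NIfTI-1 (unit affine)."""
    img = nib.Nifti1Image(np.asarray(data), affine=np.eye(4))
    nib.save(img, str(path))


def read_volume(path) -> np.ndarray:
    """Read a NIfTI-1 volume (.nii or .nii.gz) back to an array."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        return np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot read NIfTI volume {path.name}: {exc}") from exc


def write_cohort_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate the per-subject TSV/CSV.

    Schema violations (unknown/missing columns, bad group or CGI values,
    symptom fields on healthy-control rows, missing required FND fields)
    raise :class:`SchemaError` naming the offending row.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    tab = pd.read_csv(path, sep=sep)

    unknown = set(tab.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown column(s): {sorted(unknown)}")
    missing = set(COHORT_COLUMNS) - set(tab.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")

    for i, row in tab.iterrows():
        rowname = f"row {i} ({row['subject_id']})"
        if row["group"] not in ("FND", "HC"):
            raise SchemaError(f"{rowname}: bad group {row['group']!r}")
        cgi = row["cgi_i"]
        if pd.notna(cgi) and cgi not in CGI_CATEGORIES:
            raise SchemaError(f"{rowname}: bad CGI-I value {cgi!r}")
        if row["group"] == "HC":
            bad = [c for c in _SYMPTOM_FIELDS if pd.notna(row[c])]
            if bad:
                raise SchemaError(f"{rowname}: HC row carries symptom "
                                  f"field(s) {bad}")
        else:
            need = [c for c, (_, req) in COHORT_COLUMNS.items() if req]
            empty = [c for c in need if pd.isna(row[c])]
            if empty:
                raise SchemaError(f"{rowname}: missing required value(s) {empty}")
        for c in ("sex", "ssri_snri"):
            v = row[c]
            if pd.notna(v) and v not in (0, 1):
                raise SchemaError(f"{rowname}: {c} must be 0/1, got {v!r}")
    return tab


def save_config(config, path) -> None:
    obj = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_config(path, cls=SimulationConfig):
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    return cls.from_dict(obj) if hasattr(cls, "from_dict") else obj


def save_truth(truth: dict, path) -> None:
    """Ground-truth record as JSON (arrays become lists)."""
    enc = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in truth.items()
    }
    with open(path, "w") as fh:
        json.dump(enc, fh, indent=1)


def load_truth(path) -> dict:
    with open(path) as fh:
        truth = json.load(fh)
    for k in ("boosts", "boost_change", "planted_change", "effect_region"):
        if k in truth:
            truth[k] = np.asarray(truth[k])
    return truth
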