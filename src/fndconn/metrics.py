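"""Voxel-wise connectivity matrices and graph metrics.

Three metrics summarize each voxel's positive-correlation weights:

* weighted-degree  WD_i  = sum_j adj(i, j) over all grey-matter voxels —
  global centrality, computed on the whole-grey matrix;
* integration      INT_i = sum over voxels in *different* networks —
  between-network connectivity, isocortical matrix only;
* segregation      SEG_i = sum over voxels in the *same* network —
  within-network connectivity, isocortical matrix only.

Negative Pearson correlations are removed (set to zero, not
absolute-valued) and the diagonal is excluded, so integration +
segregation equals the isocortical row sum exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "MetricMap",
    "compute_fc_matrix",
    "weighted_degree_map",
    "integration_map",
    "segregation_map",
    "metric_change_map",
    "flag_outlier_subjects",
]

METRICS = ("weighted_degree", "integration", "segregation")
TIMEPOINTS = ("baseline", "followup", "change")


class ScopeError(ValueError):
    """Matrix scope does not match the requested operation."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric nonnegative voxel-by-voxel correlation weights.

    ``weights[i, j]`` in [0, 1] with zero diagonal; ``voxel_index`` ties
    row i to a grid coordinate; ``scope`` is ``"grey"`` (whole grey
    matter) or ``"iso"`` (isocortical only).
    """

    weights: np.ndarray
    voxel_index: np.ndarray  # (n, 3) grid coordinates
    scope: str

    def __post_init__(self):
        if self.scope not in ("grey", "iso"):
            raise ValueError(f"scope must be 'grey' or 'iso', got {self.scope!r}")

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class MetricMap:
    """One scalar per masked voxel for one metric / subject / timepoint."""

    metric: str
    values: np.ndarray  # (n_masked,) aligned with voxel_index
    voxel_index: np.ndarray
    subject_id: str
    timepoint: str

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")

    def to_volume(self, dims: tuple[int, int, int]) -> np.ndarray:
        vol = np.zeros(dims)
        idx = self.voxel_index
        vol[idx[:, 0], idx[:, 1], idx[:, 2]] = self.values
        return vol


def compute_fc_matrix(
    timeseries: np.ndarray, voxel_index: np.ndarray, scope: str
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation with negatives and diagonal zeroed.

    Parameters
    ----------
    timeseries : (T, n) array, T >= 3.
    voxel_index : (n, 3) grid coordinates of the n voxels (column order).
    scope : "grey" or "iso".

    Zero-variance voxels have undefined correlations; their rows/columns
    are set to 0 with a warning so map geometry stays stable.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 3:
        raise ValueError("timeseries must be (T >= 3, n)")
    if len(voxel_index) != ts.shape[1] or len(voxel_index) == 0:
        raise ValueError("voxel_index must match the number of series")

    sd = ts.std(axis=0)
    dead = sd == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} zero-variance voxel(s); rows/columns zeroed",
            RuntimeWarning,
            stacklevel=2,
        )
        ts = ts.copy()
        # any finite placeholder: the row/col is zeroed below
        ts[:, dead] = np.arange(ts.shape[0])[:, None]

    r = np.corrcoef(ts, rowvar=False)
    r = (r + r.T) / 2.0  # corrcoef divides row- then column-wise; exact symmetry
    np.clip(r, 0.0, 1.0, out=r)  # negative removal + fp guard
    np.fill_diagonal(r, 0.0)
    if dead.any():
        r[dead, :] = 0.0
        r[:, dead] = 0.0
    return ConnectivityMatrix(r, np.asarray(voxel_index), scope)


def weighted_degree_map(
    fc: ConnectivityMatrix, subject_id: str = "", timepoint: str = "baseline"
) -> MetricMap:
    """WD_i = sum_j adj(i, j) on the whole-grey matrix."""
    if fc.scope != "grey":
        raise ScopeError("weighted-degree requires a whole-grey matrix")
    return MetricMap(
        "weighted_degree", fc.weights.sum(axis=1), fc.voxel_index,
        subject_id, timepoint,
    )


def _labels_for(fc: ConnectivityMatrix, labels: np.ndarray) -> np.ndarray:
    idx = fc.voxel_index
    lab = labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    if np.any(lab <= 0):
        raise ValueError("matrix contains unlabeled voxels")
    return lab


def integration_map(
    fc: ConnectivityMatrix, labels: np.ndarray,
    subject_id: str = "", timepoint: str = "baseline",
) -> MetricMap:
    """INT_i = sum of adj(i, k) over voxels k with label(k) != label(i)."""
    if fc.scope != "iso":
        raise ScopeError("integration requires an isocortical matrix")
    lab = _labels_for(fc, labels)
    cross = lab[:, None] != lab[None, :]
    return MetricMap(
        "integration", (fc.weights * cross).sum(axis=1), fc.voxel_index,
        subject_id, timepoint,
    )


def segregation_map(
    fc: ConnectivityMatrix, labels: np.ndarray,
    subject_id: str = "", timepoint: str = "baseline",
) -> MetricMap:
    """SEG_i = sum of adj(i, k) over voxels k with label(k) == label(i)."""
    if fc.scope != "iso":
        raise ScopeError("segregation requires an isocortical matrix")
    lab = _labels_for(fc, labels)
    within = lab[:, None] == lab[None, :]
    return MetricMap(
        "segregation", (fc.weights * within).sum(axis=1), fc.voxel_index,
        subject_id, timepoint,
    )


def metric_change_map(followup: MetricMap, baseline: MetricMap) -> MetricMap:
    """Voxel-wise follow-up minus baseline map."""
    if followup.metric != baseline.metric:
        raise ValueError("metric mismatch between maps")
    if followup.subject_id != baseline.subject_id:
        raise ValueError("subject mismatch between maps")
    if not np.array_equal(followup.voxel_index, baseline.voxel_index):
        raise ValueError("mask mismatch between maps")
    return replace(followup, values=followup.values - baseline.values,
                   timepoint="change")


def flag_outlier_subjects(
    mean_wd_per_subject: dict[str, float] | "pd.Series", k_sd: float = 3.0
) -> set[str]:
    """Subjects whose grey-mean weighted-degree deviates from the cohort
    mean by more than ``k_sd`` standard deviations.

    The mean and SD for each subject are computed leave-one-out (excluding
    that subject), so a single gross outlier cannot mask itself by
    inflating the cohort SD.  With all-equal values nothing is flagged.
    """
    import pandas as pd

    s = pd.Series(mean_wd_per_subject, dtype=float)
    if len(s) < 3:
        raise ValueError("outlier screen needs >= 3 subjects")
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    flagged = set()
    vals = s.to_numpy()
    for i, sid in enumerate(s.index):
        rest = np.delete(vals, i)
        sd = rest.std(ddof=1)
        if sd > 0 and abs(vals[i] - rest.mean()) > k_sd * sd:
            flagged.add(sid)
    return flagged
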