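"""Raw assay matrices -> differential-modification (fold-change) matrices.

The models downstream consume per-treatment log2 fold changes versus the
vehicle control (DMSO).  This module imputes missing measurements,
collapses plate replicates, and subtracts the matched control baseline.
All arithmetic assumes log2-scale input; declare linear-scale data via
``log2_transform`` before anything else.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_gct import AnalyteMatrix

DEFAULT_IMPUTE_K = 5
DEFAULT_CONTROL = "DMSO"
#: Floor applied before log2 when transforming declared-linear input.
DEFAULT_LINEAR_EPS = 1e-6


@dataclass
class FoldChangeMatrix:
    """Analyte x treatment matrix of log2 fold changes versus control.

    ``treatment_meta`` is indexed by treatment id and carries
    ``perturbagen``, ``cell_line`` and ``timepoint_h`` per column.
    Missing values are not permitted: impute upstream.
    """

    values: np.ndarray
    analyte_ids: list[str]
    treatment_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.analyte_ids), len(self.treatment_meta)):
            raise ValueError("values shape inconsistent with analyte/treatment metadata")
        if np.isnan(self.values).any():
            raise ValueError("fold-change matrix contains missing values; impute first")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.analyte_ids, columns=self.treatment_meta.index
        )

    def column_for(self, perturbagen: str, timepoint_h: float | None = None) -> np.ndarray:
        """Fold-change vector of one perturbagen (optionally one time point)."""
        meta = self.treatment_meta
        mask = meta["perturbagen"] == perturbagen
        if timepoint_h is not None:
            mask &= meta["timepoint_h"] == timepoint_h
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError(f"no treatment column for {perturbagen!r} at t={timepoint_h}")
        if idx.size > 1:
            raise KeyError(
                f"{idx.size} treatment columns match {perturbagen!r} at t={timepoint_h}; "
                "restrict by timepoint"
            )
        return self.values[:, idx[0]]


def write_fold_change(fc: FoldChangeMatrix, path) -> None:
    """Persist a fold-change matrix as a TSV with three metadata header
    rows (perturbagen, cell_line, timepoint_h) above the analyte rows."""
    with open(path, "w") as fh:
        meta = fc.treatment_meta
        fh.write("\t".join(["id", *map(str, meta.index)]) + "\n")
        for fld in ("perturbagen", "cell_line", "timepoint_h"):
            fh.write("\t".join([f"#{fld}", *map(str, meta[fld])]) + "\n")
        for i, aid in enumerate(fc.analyte_ids):
            fh.write("\t".join([str(aid), *(repr(float(v)) for v in fc.values[i])]) + "\n")


def read_fold_change(path) -> FoldChangeMatrix:
    """Read a TSV written by :func:`write_fold_change`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        treatment_ids = header[1:]
        meta: dict[str, list] = {}
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            f = line.rstrip("\n").split("\t")
            meta[f[0][1:]] = f[1:]
            pos = fh.tell()
            line = fh.readline()
        analyte_ids, rows = [], []
        while line:
            f = line.rstrip("\n").split("\t")
            analyte_ids.append(f[0])
            rows.append([float(v) for v in f[1:]])
            line = fh.readline()
    tm = pd.DataFrame(meta, index=pd.Index(treatment_ids, name="treatment_id"))
    tm["timepoint_h"] = tm["timepoint_h"].astype(float)
    return FoldChangeMatrix(np.array(rows), analyte_ids, tm)


def log2_transform(m: AnalyteMatrix, eps: float = DEFAULT_LINEAR_EPS) -> AnalyteMatrix:
    """log2-transform a linear-scale matrix, flooring values at ``eps``."""
    out = m.copy()
    with np.errstate(invalid="ignore"):
        out.values = np.log2(np.maximum(out.values, eps))
    out.values[m.missing_mask] = np.nan
    return out


def impute_missing(m: AnalyteMatrix, k_neighbors: int = DEFAULT_IMPUTE_K) -> AnalyteMatrix:
    """Fill missing cells by correlation-weighted k-nearest-analyte averaging.

    For each analyte with holes, the ``k_neighbors`` analytes most similar
    by Pearson correlation on shared observed samples donate their observed
    values at the missing column, combined as a similarity-weighted mean.
    Deterministic and seedless.  Observed values are never altered.

    Falls back to the analyte's own observed mean when no neighbor observed
    the column (noted only in degenerate fixtures).
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    mask = m.missing_mask
    if not mask.any():
        return m.copy()
    observed = ~mask
    n_obs = observed.sum(axis=1)
    if (n_obs == 0).any():
        bad = [m.analyte_ids[i] for i in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"analytes with zero observed values: {bad}")

    X = m.values
    out = X.copy()
    n = X.shape[0]
    for i in np.flatnonzero(mask.any(axis=1)):
        sims = np.full(n, -np.inf)
        for j in range(n):
            if j == i:
                continue
            shared = observed[i] & observed[j]
            if shared.sum() < 2:
                continue
            xi, xj = X[i, shared], X[j, shared]
            sxi, sxj = xi.std(), xj.std()
            if sxi == 0 or sxj == 0:
                # flat on the shared support: degenerate correlation; treat
                # identical flats as perfect neighbors, others as unusable
                sims[j] = 1.0 if np.allclose(xi, xj) else -np.inf
                continue
            sims[j] = float(np.corrcoef(xi, xj)[0, 1])
        order = np.argsort(-sims)
        neighbors = [j for j in order if np.isfinite(sims[j])][:k_neighbors]
        own_mean = X[i, observed[i]].mean()
        for c in np.flatnonzero(mask[i]):
            donors = [j for j in neighbors if observed[j, c]]
            if not donors:
                out[i, c] = own_mean
                continue
            # shift similarities into (0, 1] so anti-correlated neighbors
            # cannot carry negative weight
            w = np.array([(sims[j] + 1.0) / 2.0 for j in donors])
            if w.sum() == 0:
                w = np.ones_like(w)
            out[i, c] = float(np.average([X[j, c] for j in donors], weights=w))
    return AnalyteMatrix(out, m.analyte_meta.copy(), m.sample_meta.copy())


def collapse_replicates(m: AnalyteMatrix) -> AnalyteMatrix:
    """Collapse replicate columns to their per-group median.

    Groups are (cell_line, perturbagen, dose, timepoint_h); the median is
    robust to single-plate outliers.  Missing values are ignored within a
    group (a group fully missing for an analyte stays missing).
    """
    meta = m.sample_meta
    keys = ["cell_line", "perturbagen", "dose", "timepoint_h"]
    for key in keys:
        if key not in meta.columns:
            raise ValueError(f"sample_meta lacks required field {key!r}")
    groups = meta.groupby(keys, sort=True, dropna=False).indices
    new_cols: list[np.ndarray] = []
    new_meta_rows: list[dict] = []
    for group_key in sorted(groups, key=lambda k: tuple(map(str, k))):
        idx = np.sort(np.asarray(groups[group_key]))
        with np.errstate(all="ignore"):
            col = np.nanmedian(m.values[:, idx], axis=1)
        cell_line, perturbagen, dose, timepoint = group_key
        first = meta.iloc[idx[0]]
        new_cols.append(col)
        new_meta_rows.append(
            {
                "sample_id": f"{cell_line}_{perturbagen}_{dose}_{timepoint}",
                "cell_line": cell_line,
                "perturbagen": perturbagen,
                "dose": dose,
                "timepoint_h": timepoint,
                "replicate": 1,
                "is_control": bool(first.get("is_control", False)),
            }
        )
    sample_meta = pd.DataFrame(new_meta_rows).set_index("sample_id")
    return AnalyteMatrix(np.column_stack(new_cols), m.analyte_meta.copy(), sample_meta)


def compute_fold_change(
    m: AnalyteMatrix, control_perturbagen: str = DEFAULT_CONTROL
) -> FoldChangeMatrix:
    """Subtract the matched vehicle-control mean from every treatment column.

    Controls are matched within (cell_line, timepoint_h); dose is ignored
    for control matching because the vehicle has none.  Input must be on
    the log2 scale, so the difference is a log2 fold change.  Control
    columns are removed from the output.
    """
    if np.isnan(m.values).any():
        raise ValueError("matrix contains missing values; impute before fold change")
    meta = m.sample_meta
    is_control = meta["perturbagen"] == control_perturbagen
    if "is_control" in meta.columns:
        is_control = is_control | meta["is_control"].astype(bool)
    if not is_control.any():
        raise ValueError(f"no control columns matching {control_perturbagen!r}")

    control_means: dict[tuple, np.ndarray] = {}
    ctrl_meta = meta[is_control]
    for stratum, idx in ctrl_meta.groupby(["cell_line", "timepoint_h"], sort=False).indices.items():
        cols = np.flatnonzero(is_control.to_numpy())[idx]
        control_means[stratum] = m.values[:, cols].mean(axis=1)

    treat_idx = np.flatnonzero(~is_control.to_numpy())
    missing_strata = []
    cols: list[np.ndarray] = []
    rows: list[dict] = []
    for j in treat_idx:
        row = meta.iloc[j]
        stratum = (row["cell_line"], row["timepoint_h"])
        if stratum not in control_means:
            missing_strata.append(stratum)
            continue
        cols.append(m.values[:, j] - control_means[stratum])
        rows.append(
            {
                "treatment_id": str(meta.index[j]),
                "perturbagen": row["perturbagen"],
                "cell_line": row["cell_line"],
                "timepoint_h": row["timepoint_h"],
            }
        )
    if missing_strata:
        raise ValueError(
            "treatment strata without matching control columns: "
            f"{sorted(set(missing_strata))}"
        )
    treatment_meta = pd.DataFrame(rows).set_index("treatment_id")
    return FoldChangeMatrix(np.column_stack(cols), m.analyte_ids, treatment_meta)
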