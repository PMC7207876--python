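"""Drug-concordance statistics across cell lines and time points.

Agreement between two drugs is quantified three ways: the Rand index on
their module (histone-signature) assignments across cell lines, the
Pearson correlation of their phosphoprotein temporal-change vectors over
a time interval, and an ordinary least-squares regression of one drug's
histone fold changes on the other's at a fixed time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import comb

from .io_gct import AnalyteMatrix
from .preprocess import FoldChangeMatrix


@dataclass
class Partition:
    """A labelling of items (e.g. drugs) into modules."""

    labels: dict[str, str]

    @property
    def items(self) -> set[str]:
        return set(self.labels)

    def __getitem__(self, item: str) -> str:
        return self.labels[item]


def rand_index(p1: Partition, p2: Partition, adjusted: bool = False) -> float:
    """Rand index between two partitions of the same item set.

    The plain RI is the fraction of item pairs on which the partitions
    agree (both together or both apart); 1 means identical clusterings.
    ``adjusted`` switches to the chance-corrected adjusted Rand index.
    """
    if p1.items != p2.items:
        only1 = sorted(p1.items - p2.items)
        only2 = sorted(p2.items - p1.items)
        raise ValueError(f"item sets differ: only in first={only1}, only in second={only2}")
    items = sorted(p1.items)
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to compare partitions")
    a = [p1[i] for i in items]
    b = [p2[i] for i in items]
    if adjusted:
        from sklearn.metrics import adjusted_rand_score

        return float(adjusted_rand_score(a, b))
    # contingency-table pair counting
    from collections import Counter

    nij = Counter(zip(a, b))
    ai = Counter(a)
    bj = Counter(b)
    sum_ij = sum(comb(c, 2, exact=True) for c in nij.values())
    sum_a = sum(comb(c, 2, exact=True) for c in ai.values())
    sum_b = sum(comb(c, 2, exact=True) for c in bj.values())
    total = comb(n, 2, exact=True)
    agreements = total + 2 * sum_ij - sum_a - sum_b
    return agreements / total


def drug_pair_concordance(
    partitions: dict[str, Partition], drug_a: str, drug_b: str
) -> tuple[dict[str, bool], float]:
    """Per-cell-line same-module flags for a drug pair plus their mean.

    Returns ({cell_line: same_module}, overall fraction)."""
    if not partitions:
        raise ValueError("no partitions given")
    flags: dict[str, bool] = {}
    for cell_line, part in partitions.items():
        for drug in (drug_a, drug_b):
            if drug not in part.items:
                raise KeyError(f"drug {drug!r} absent from partition for {cell_line!r}")
        flags[cell_line] = part[drug_a] == part[drug_b]
    overall = float(np.mean([v for v in flags.values()]))
    return flags, overall


def _drug_profile(m: AnalyteMatrix, drug: str, timepoint_h: float) -> np.ndarray:
    meta = m.sample_meta
    mask = (meta["perturbagen"] == drug) & (meta["timepoint_h"] == timepoint_h)
    idx = np.flatnonzero(mask.to_numpy())
    if idx.size == 0:
        raise KeyError(f"no samples for drug {drug!r} at t={timepoint_h} h")
    return np.nanmean(m.values[:, idx], axis=1)  # replicates averaged


def interval_response_correlation(
    m: AnalyteMatrix, drug_a: str, drug_b: str, t_start: float, t_end: float
) -> float:
    """Pearson r between two drugs' temporal-change vectors.

    For each drug, the per-analyte change value(t_end) - value(t_start) is
    computed (replicates averaged); the correlation between the two drugs'
    change vectors measures how similarly the drugs move the assay over
    the interval.
    """
    delta_a = _drug_profile(m, drug_a, t_end) - _drug_profile(m, drug_a, t_start)
    delta_b = _drug_profile(m, drug_b, t_end) - _drug_profile(m, drug_b, t_start)
    ok = ~np.isnan(delta_a) & ~np.isnan(delta_b)
    if ok.sum() < 3:
        raise ValueError("need >=3 shared analytes with observed values")
    da, db = delta_a[ok], delta_b[ok]
    if da.std() == 0 or db.std() == 0:
        raise ValueError("zero-variance change vector; correlation undefined")
    return float(stats.pearsonr(da, db).statistic)


def within_drug_interval_correlation(
    m: AnalyteMatrix, drug: str, t_start: float, t_end: float
) -> float:
    """Alternative reading of interval concordance: Pearson r between one
    drug's profiles at the two time points (profile persistence)."""
    a = _drug_profile(m, drug, t_start)
    b = _drug_profile(m, drug, t_end)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("need >=3 shared analytes with observed values")
    if a[ok].std() == 0 or b[ok].std() == 0:
        raise ValueError("zero-variance profile; correlation undefined")
    return float(stats.pearsonr(a[ok], b[ok]).statistic)


def paired_response_regression(
    fc: FoldChangeMatrix,
    drug_a: str,
    drug_b: str,
    timepoint_h: float | None = None,
) -> tuple[float, float, float]:
    """OLS of drug_b's fold changes on drug_a's, paired per analyte.

    Returns (slope, intercept, r_squared); slope 1 / intercept 0 / r2 1
    means the two treatments moved every analyte identically.
    """
    x = fc.column_for(drug_a, timepoint_h)
    y = fc.column_for(drug_b, timepoint_h)
    if len(x) < 3:
        raise ValueError("need >=3 shared analytes")
    if x.std() == 0:
        raise ValueError(f"zero variance in {drug_a!r}'s fold changes")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
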