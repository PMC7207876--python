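"""Histone signatures: NMF consensus clustering of histone fold changes.

A "histone signature" is a functional module (c1..ck) grouping histone
codes with the drugs that shift them in a shared pattern.  Signed fold
changes are split into stacked positive/negative parts (NMF needs
non-negative input), factorised with multiplicative-update NMF over many
random restarts, and the rank k is selected by the cophenetic correlation
of the restart-consensus matrix (Brunet-style consensus clustering).
Coefficient products W.H weight the drug-histone edges of the signature
network; the sign of the underlying fold change marks a histone as
elevated or reduced by the drug.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .preprocess import FoldChangeMatrix

DEFAULT_RESTARTS = 30
DEFAULT_K_RANGE = (2, 8)
NMF_MAX_ITER = 2000
NMF_TOL = 1e-6
#: Default edge-weight cutoff quantile over the nonzero W.H products.
DEFAULT_MIN_WEIGHT_QUANTILE = 0.25


@dataclass
class SignatureModel:
    """A fitted NMF signature model.

    W (stacked-analytes x k) and H (k x treatments) are the non-negative
    factors of the best restart; ``consensus`` is the treatments x
    treatments co-clustering frequency over restarts; ``cophenetic`` maps
    each evaluated rank to its consensus cophenetic correlation;
    ``modules`` maps histone and drug ids to module labels c1..ck once
    :func:`assign_modules` has run.
    """

    W: np.ndarray
    H: np.ndarray
    k: int
    restarts: int
    consensus: np.ndarray
    reconstruction_error: float
    cophenetic: dict[int, float] = field(default_factory=dict)
    dispersion: dict[int, float] = field(default_factory=dict)
    modules: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be non-negative")
        c = self.consensus
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("consensus matrix must be symmetric with unit diagonal")
        if c.min() < 0 or c.max() > 1 + 1e-12:
            raise ValueError("consensus entries must lie in [0, 1]")

    def module_label(self, index: int) -> str:
        return f"c{index + 1}"


def nonneg_transform(fc: FoldChangeMatrix | np.ndarray) -> np.ndarray:
    """Split a signed matrix into stacked positive and negative parts.

    Output rows 0..A-1 hold max(fc, 0) and rows A..2A-1 hold max(-fc, 0),
    so the original matrix is recoverable as top - bottom and both
    elevation and reduction patterns survive the non-negativity
    constraint.
    """
    values = fc.values if isinstance(fc, FoldChangeMatrix) else np.asarray(fc, float)
    if np.isnan(values).any():
        raise ValueError("fold-change matrix contains missing values")
    return np.vstack([np.maximum(values, 0.0), np.maximum(-values, 0.0)])


def _single_nmf(X: np.ndarray, k: int, rng: np.random.Generator):
    scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
    W0 = rng.uniform(0, 2 * scale, size=(X.shape[0], k))
    H0 = rng.uniform(0, 2 * scale, size=(k, X.shape[1]))
    model = NMF(
        n_components=k,
        init="custom",
        solver="mu",
        beta_loss="frobenius",
        tol=NMF_TOL,
        max_iter=NMF_MAX_ITER,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X, W=W0.copy(), H=H0.copy())
    return W, model.components_, float(model.reconstruction_err_)


def fit_nmf(
    X: np.ndarray, k: int, seed: int = 0, n_restarts: int = DEFAULT_RESTARTS
) -> SignatureModel:
    """Factorise a non-negative matrix with multi-restart NMF.

    Returns the restart with the lowest Frobenius reconstruction error;
    the consensus matrix accumulates column co-membership (argmax row of
    H) across all restarts.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if (X < 0).any():
        raise ValueError("NMF input must be non-negative")
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"rank k={k} outside [1, {min(X.shape)}]")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_restarts)]
    n_cols = X.shape[1]
    co = np.zeros((n_cols, n_cols))
    best = None
    for rng in rngs:
        W, H, err = _single_nmf(X, k, rng)
        labels = H.argmax(axis=0)
        co += labels[:, None] == labels[None, :]
        if best is None or err < best[2]:
            best = (W, H, err)
    consensus = co / n_restarts
    np.fill_diagonal(consensus, 1.0)
    W, H, err = best
    model = SignatureModel(
        W=W, H=H, k=k, restarts=n_restarts, consensus=consensus,
        reconstruction_error=err,
    )
    model.cophenetic[k] = consensus_cophenetic(consensus)
    model.dispersion[k] = consensus_dispersion(consensus)
    return model


def consensus_cophenetic(consensus: np.ndarray) -> float:
    """Cophenetic correlation between consensus distances (1 - C) and the
    average-linkage dendrogram built from them.

    A perfectly reproducible consensus (all entries 0 or 1 in clean
    blocks) gives 1; degenerate all-equal distances are defined as 1
    (the dendrogram reproduces them exactly).
    """
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if condensed.size == 0 or np.ptp(condensed) == 0:
        return 1.0
    link = average(condensed)
    c, _ = cophenet(link, condensed)
    return float(c)


def consensus_dispersion(consensus: np.ndarray) -> float:
    """Mean of 4*(C - 1/2)^2: 1 when every entry is 0 or 1."""
    return float(np.mean(4.0 * (consensus - 0.5) ** 2))


def select_rank(
    X: np.ndarray,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
) -> tuple[int, dict[int, SignatureModel]]:
    """Choose the NMF rank maximizing consensus cophenetic correlation.

    Evaluates every k in the inclusive ``k_range``, refitting
    ``n_restarts`` times per rank.  Ties (within 1e-9) go to the largest
    rank: merging clean modules is also perfectly reproducible, so the
    cophenetic correlation saturates at 1 for every rank at or below the
    true one and the finest perfectly-stable rank is the informative
    choice.  Returns the selected rank and the per-rank fitted models
    (each carrying its cophenetic correlation and dispersion
    diagnostics).
    """
    lo, hi = k_range
    if lo > hi:
        raise ValueError(f"empty k_range {k_range}")
    if lo < 2 or hi > min(X.shape) - 1:
        raise ValueError(f"k_range {k_range} outside [2, {min(X.shape) - 1}]")
    models: dict[int, SignatureModel] = {}
    for offset, k in enumerate(range(lo, hi + 1)):
        models[k] = fit_nmf(X, k, seed=seed + 10_000 * offset, n_restarts=n_restarts)
    coph = {k: m.cophenetic[k] for k, m in models.items()}
    best_k = max(sorted(coph), key=lambda k: (round(coph[k], 9), k))
    selected = models[best_k]
    selected.cophenetic = dict(sorted(coph.items()))
    selected.dispersion = {kk: models[kk].dispersion[kk] for kk in sorted(models)}
    return best_k, models


def _drug_ids(fc: FoldChangeMatrix) -> list[str]:
    perts = list(fc.treatment_meta["perturbagen"])
    if len(set(perts)) == len(perts):
        return [str(p) for p in perts]
    return [str(t) for t in fc.treatment_meta.index]


def assign_modules(model: SignatureModel, fc: FoldChangeMatrix) -> dict[str, str]:
    """Assign every drug and histone to its dominant module.

    A drug (treatment column) goes to the argmax row of its H column; a
    histone goes to the module with the largest combined loading, i.e. the
    sum of its positive-part and negative-part rows of W.  Ties break
    toward the lowest module index.  The mapping is stored on the model
    and returned.
    """
    n_analytes = len(fc.analyte_ids)
    if model.W.shape[0] != 2 * n_analytes:
        raise ValueError(
            "model W rows do not match 2x analyte count; was the model fitted "
            "on nonneg_transform of this matrix?"
        )
    if model.H.shape[1] != fc.values.shape[1]:
        raise ValueError("model H columns do not match treatment count")
    modules: dict[str, str] = {}
    for j, drug in enumerate(_drug_ids(fc)):
        modules[drug] = model.module_label(int(model.H[:, j].argmax()))
    combined = model.W[:n_analytes] + model.W[n_analytes:]
    for i, hist in enumerate(fc.analyte_ids):
        modules[str(hist)] = model.module_label(int(combined[i].argmax()))
    model.modules = modules
    return modules


@dataclass(frozen=True, order=True)
class DrugHistoneEdge:
    """A coefficient-weighted drug-histone interaction within a module."""

    drug: str
    histone: str
    weight: float
    sign: int
    module: str

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("edge weight must be non-negative")
        if self.sign not in (-1, 1):
            raise ValueError("edge sign must be +1 or -1")


def default_min_weight(model: SignatureModel, fc: FoldChangeMatrix) -> float:
    """Data-adaptive cutoff: 25th percentile of nonzero W.H products over
    same-module (histone, drug) pairs."""
    products = _module_products(model, fc)
    nonzero = products[products > 0]
    if nonzero.size == 0:
        return 0.0
    return float(np.quantile(nonzero, DEFAULT_MIN_WEIGHT_QUANTILE))


def _module_products(model: SignatureModel, fc: FoldChangeMatrix) -> np.ndarray:
    n_analytes = len(fc.analyte_ids)
    combined = model.W[:n_analytes] + model.W[n_analytes:]
    drugs = _drug_ids(fc)
    out = []
    for j, drug in enumerate(drugs):
        for i, hist in enumerate(fc.analyte_ids):
            if model.modules[drug] != model.modules[str(hist)]:
                continue
            m = int(model.modules[drug][1:]) - 1
            out.append(combined[i, m] * model.H[m, j])
    return np.asarray(out)


def build_drug_histone_edges(
    model: SignatureModel,
    fc: FoldChangeMatrix,
    min_weight: float | None = None,
) -> set[DrugHistoneEdge]:
    """Emit the drug-histone edges of the signature network.

    An edge exists iff the drug and histone share a module and the
    coefficient product (combined W loading x H coefficient) reaches
    ``min_weight`` (default: adaptive quantile cutoff).  The sign is the
    sign of the underlying fold change; a histone a drug did not move
    (fold change exactly 0) gets no edge.
    """
    if not model.modules:
        raise ValueError("assign_modules must run before building edges")
    if min_weight is None:
        min_weight = default_min_weight(model, fc)
    n_analytes = len(fc.analyte_ids)
    combined = model.W[:n_analytes] + model.W[n_analytes:]
    edges: set[DrugHistoneEdge] = set()
    for j, drug in enumerate(_drug_ids(fc)):
        module = model.modules[drug]
        m = int(module[1:]) - 1
        for i, hist in enumerate(fc.analyte_ids):
            if model.modules[str(hist)] != module:
                continue
            weight = float(combined[i, m] * model.H[m, j])
            if weight < min_weight:
                continue
            fc_val = fc.values[i, j]
            if fc_val == 0:
                continue
            edges.add(
                DrugHistoneEdge(
                    drug=drug,
                    histone=str(hist),
                    weight=weight,
                    sign=1 if fc_val > 0 else -1,
                    module=module,
                )
            )
    return edges
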