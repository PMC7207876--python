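"""Phosphoprotein -> histone PLSR model with bootstrap coefficient tests.

Each histone code is modelled as a response to the combined influence of
all phosphoproteins via partial least squares regression, the right tool
when treatments (samples) are far fewer than phosphopeptides
(predictors).  PLSR has no closed-form coefficient variance, so
significance is assessed with a row-resampling bootstrap t-test; the
surviving coefficients (p below alpha, default 1e-4) form the signed
histone-phosphoprotein network whose highest-degree nodes are the hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

DEFAULT_ALPHA = 1e-4
DEFAULT_N_BOOT = 1000
MAX_COMPONENTS = 10


@dataclass
class PlsrFit:
    """A fitted PLSR model with optional bootstrap inference attached.

    ``B`` (predictors x responses) is on the original, unstandardized
    scale so coefficients are comparable to fold changes; predictions are
    ``(X - x_center) @ B + y_center`` (centering is absorbed, scaling is
    folded into B).
    """

    B: np.ndarray
    n_components: int
    x_center: np.ndarray
    y_center: np.ndarray
    x_scale: np.ndarray
    y_scale: np.ndarray
    predictor_ids: list[str]
    response_ids: list[str]
    n_samples: int
    se: np.ndarray | None = None
    t_stat: np.ndarray | None = None
    p_value: np.ndarray | None = None
    cv_press: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p, q = self.B.shape
        if len(self.predictor_ids) != p or len(self.response_ids) != q:
            raise ValueError("coefficient matrix shape inconsistent with ids")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return (X - self.x_center) @ self.B + self.y_center

    @property
    def df_resid(self) -> int:
        """Degrees of freedom for the t reference (latent-variable
        convention: samples minus components minus intercept)."""
        return self.n_samples - self.n_components - 1


def _fit_core(X: np.ndarray, Y: np.ndarray, n_components: int) -> np.ndarray:
    """Raw PLSR coefficients (original scale) via NIPALS; no validation."""
    pls = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(X, Y)
    return pls.coef_.T  # (n_features, n_targets)


def fit_plsr(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    predictor_ids: list[str] | None = None,
    response_ids: list[str] | None = None,
) -> PlsrFit:
    """Fit Y (samples x histones) on X (samples x phosphoproteins).

    Both blocks are column-standardized internally; ``B`` is reported
    back-transformed to the original scale.  Constant predictor columns
    are dropped with a warning and given zero coefficients.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share sample rows")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("PLSR input contains missing values")
    n, p = X.shape
    q = Y.shape[1]
    max_ok = min(n - 1, p)
    if not 1 <= n_components <= max_ok:
        raise ValueError(f"n_components={n_components} outside [1, {max_ok}]")
    predictor_ids = list(predictor_ids) if predictor_ids is not None else [
        f"x{i}" for i in range(p)
    ]
    response_ids = list(response_ids) if response_ids is not None else [
        f"y{j}" for j in range(q)
    ]

    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [predictor_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant predictor columns: {dropped}", stacklevel=2)
        n_components = min(n_components, min(n - 1, int(keep.sum())))
    B_kept = _fit_core(X[:, keep], Y, n_components)
    B = np.zeros((p, q))
    B[keep] = B_kept

    return PlsrFit(
        B=B,
        n_components=n_components,
        x_center=X.mean(axis=0),
        y_center=Y.mean(axis=0),
        x_scale=np.where(keep, X.std(axis=0, ddof=1), 1.0),
        y_scale=Y.std(axis=0, ddof=1),
        predictor_ids=predictor_ids,
        response_ids=response_ids,
        n_samples=n,
    )


def select_components(
    X: np.ndarray,
    Y: np.ndarray,
    max_components: int = MAX_COMPONENTS,
    n_folds: int | None = None,
    sample_ids: list[str] | None = None,
    rel_tol: float = 0.05,
) -> tuple[int, dict[int, float]]:
    """Pick the component count by cross-validated PRESS with parsimony.

    PRESS plateaus once the informative components are in, so a strict
    argmin overfits by chasing noise along the plateau; instead the
    smallest count whose PRESS is within ``rel_tol`` of the achievable
    reduction — PRESS(c) <= min PRESS + rel_tol * (PRESS0 - min PRESS),
    where PRESS0 is the intercept-only baseline — is chosen
    (``rel_tol=0`` recovers the plain argmin, smaller model on ties).
    When no component count beats the baseline (pure-noise responses) the
    one-component model is returned.

    The fold split is deterministic: samples are ordered by sorted sample
    id (row order when ids are not given) and dealt round-robin into
    ``n_folds`` folds (default leave-one-out).  Returns (n_components,
    PRESS per component count).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if n_folds is None:
        n_folds = n  # leave-one-out
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds the {n} samples")

    order = np.arange(n)
    if sample_ids is not None:
        order = np.argsort(np.asarray(sample_ids, dtype=object))
    folds = [order[f::n_folds] for f in range(n_folds)]
    # cap so every training split can support the largest model
    min_train = n - max(len(f) for f in folds)
    max_components = min(max_components, min_train - 1, X.shape[1])

    press0 = 0.0
    press: dict[int, float] = {c: 0.0 for c in range(1, max_components + 1)}
    for hold in folds:
        train = np.setdiff1d(order, hold)
        press0 += float(((Y[hold] - Y[train].mean(axis=0)) ** 2).sum())
        for c in press:
            fit = fit_plsr(X[train], Y[train], n_components=c)
            resid = Y[hold] - fit.predict(X[hold])
            press[c] += float((resid**2).sum())
    min_press = min(press.values())
    if press0 <= min_press:
        return 1, press
    threshold = min_press + rel_tol * (press0 - min_press)
    best = min(c for c in press if press[c] <= threshold)
    return best, press


def coefficient_pvalues(
    fit: PlsrFit,
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> PlsrFit:
    """Bootstrap t-test for every PLSR coefficient.

    Sample rows are resampled with replacement ``n_boot`` times and the
    model refit each time; the bootstrap standard deviation is the
    coefficient standard error, t = B / se, and the two-sided p-value
    comes from the t distribution with n - n_components - 1 degrees of
    freedom.  A degenerate coefficient (se = 0) gets p = 1 with a warning
    rather than a division blow-up.  Fills ``se``, ``t_stat`` and
    ``p_value`` on the fit (in place) and returns it.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    keep = X.std(axis=0) > 0
    boots = np.empty((n_boot, int(keep.sum()), Y.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, Yb = X[idx][:, keep], Y[idx]
        comp = min(fit.n_components, np.linalg.matrix_rank(Xb - Xb.mean(0)))
        boots[b] = _fit_core(Xb, Yb, max(comp, 1))
    se = np.zeros_like(fit.B)
    se[keep] = boots.std(axis=0, ddof=1)

    degenerate = se == 0
    if degenerate.any() and not (fit.B[degenerate] == 0).all():
        warnings.warn(
            f"{int(degenerate.sum())} coefficients with zero bootstrap variance; "
            "their p-values are set to 1",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, fit.B / np.where(degenerate, 1.0, se))
    df = max(fit.df_resid, 1)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[degenerate] = 1.0
    fit.se, fit.t_stat, fit.p_value = se, t, np.clip(p, 0.0, 1.0)
    return fit


@dataclass(frozen=True, order=True)
class HistonePhosphoEdge:
    """A significant phosphoprotein-histone coefficient."""

    phosphoprotein: str
    histone: str
    weight: float
    sign: int
    p_value: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


def build_histone_phospho_network(
    fit: PlsrFit, alpha: float = DEFAULT_ALPHA
) -> set[HistonePhosphoEdge]:
    """Keep every coefficient with p < alpha as a signed, weighted edge."""
    if fit.p_value is None:
        raise ValueError("run coefficient_pvalues before building the network")
    edges: set[HistonePhosphoEdge] = set()
    sig = np.argwhere(fit.p_value < alpha)
    for i, j in sig:
        b = fit.B[i, j]
        if b == 0:
            continue
        edges.add(
            HistonePhosphoEdge(
                phosphoprotein=fit.predictor_ids[i],
                histone=fit.response_ids[j],
                weight=abs(float(b)),
                sign=1 if b > 0 else -1,
                p_value=float(fit.p_value[i, j]),
            )
        )
    return edges


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted q-values for an arbitrary-shape p matrix (reported for
    reference; edge retention uses raw p per the pipeline convention)."""
    from statsmodels.stats.multitest import multipletests

    flat = np.asarray(p, float).ravel()
    _, q, _, _ = multipletests(flat, method="fdr_bh")
    return q.reshape(np.shape(p))


def find_hubs(edges: set, top_n: int = 5) -> list[tuple[str, int]]:
    """Rank nodes by degree (descending, ties lexicographic).

    Works on any edge collection whose items expose two endpoint ids as
    their first two string fields (drug-histone or histone-phospho edges).
    """
    if not edges:
        raise ValueError("empty edge set has no hubs")
    degree: dict[str, int] = {}
    for e in edges:
        if hasattr(e, "phosphoprotein"):
            a, b = e.phosphoprotein, e.histone
        elif hasattr(e, "drug"):
            a, b = e.drug, e.histone
        else:
            a, b = e[0], e[1]
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]
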