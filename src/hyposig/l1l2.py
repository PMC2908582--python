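"""Sparse l1-l2 (elastic-net) feature selection with double optimization.

The selection stage minimizes

    (1/n) ||y - X beta||^2 + tau ||beta||_1 + mu ||beta||_2^2

by damped iterative soft-thresholding (proximal gradient with step
1/(2*sigma_max), where sigma_max is the largest eigenvalue of X^T X / n).
The l1 term enforces sparsity; the l2 term keeps correlated discriminant
features together.  The l2 weight is parameterized as mu = epsilon * mu0
with a data-driven baseline mu0 = 1e-3 * sigma_max, so epsilon is a
dimensionless knob for how much correlation the selection tolerates:
epsilon <= 1 behaves like the lasso (minimal lists), epsilon = 100
(the default) yields the inclusive, correlation-aware lists.

The "double optimization" is a second, unregularized-by-l1 refit: a
ridge / least-squares fit restricted to the selected support, used for
prediction only.

Model selection is fully nested: an outer leave-one-out loop holds out
one sample at a time; on each training fold the l1 weight tau is chosen
by an inner leave-one-out error curve; feature standardization happens
inside every training fold, so the held-out sample never influences
selection.  The outer loop yields one selected list per fold; features
are aggregated by a frequency score (how many of the L loops selected
them) and the signature is the set of features selected in at least a
given fraction of loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PairedDesign
from .signature import Signature

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = [
    "LabeledDataset",
    "L1L2Config",
    "SelectionFrequencyTable",
    "ConvergenceError",
    "soft_threshold",
    "l1l2_solve",
    "l1l2_objective",
    "debias_rls",
    "select_tau_loocv",
    "outer_loo_selection",
    "frequency_signature",
    "tau_grid_for",
]


class ConvergenceError(RuntimeError):
    """Iteration budget exhausted; carries the last iterate."""

    def __init__(self, message: str, last_iterate: np.ndarray):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class LabeledDataset:
    """n x p design with labels in {-1, +1} (hypoxic = +1, normoxic = -1).

    ``X`` holds raw (typically log2) values; standardization (mean 0,
    unit l2 norm per feature) is applied inside each training fold, not
    here, to keep the cross-validation loops selection-bias free.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n, p = self.X.shape
        if n < 4:
            raise ValueError("need at least 4 samples")
        if self.y.shape != (n,):
            raise ValueError("label vector length mismatch")
        if not set(np.unique(self.y)) <= {-1.0, 1.0}:
            raise ValueError("labels must be in {-1, +1}")
        if len(set(np.unique(self.y))) < 2:
            raise ValueError("both classes must be present")
        if len(self.feature_ids) != p:
            raise ValueError("feature id list length mismatch")

    @classmethod
    def from_expression(cls, E: ExpressionMatrix, design: PairedDesign) -> "LabeledDataset":
        """Hypoxic (+1) vs normoxic (-1) samples from a paired design.

        Expects a log2-scale matrix (values are used as-is).
        """
        design.validate_against(E)
        samples = design.normoxic_samples + design.hypoxic_samples
        y = np.concatenate([-np.ones(len(design.entries)), np.ones(len(design.entries))])
        X = E.data[samples].to_numpy(dtype=float).T
        return cls(X, y, E.probeset_ids)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class L1L2Config:
    """Knobs of the selection stage.

    ``epsilon`` multiplies the data-driven l2 baseline mu0; ``tau_grid``
    (descending) overrides the default rule of ``n_tau`` log-spaced
    values from tau_max = 2||X^T y||_inf / n down to
    ``tau_min_ratio * tau_max``.  ``tie_break`` resolves plateaus of the
    inner-LOO error curve: "dense" keeps the smallest tau attaining the
    minimum (the most inclusive list, matching the intent of a large
    epsilon), "sparse" the largest.
    """

    epsilon: float = 100.0
    tau_grid: np.ndarray | None = None
    n_tau: int = 30
    tau_min_ratio: float = 1e-3
    mu0_scale: float = 1e-3
    ridge_lambda: float = 0.0
    tol: float = 1e-5
    max_iter: int = 3000
    frequency_threshold: float = 0.5
    tie_break: str = "dense"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.tau_grid is not None:
            g = np.asarray(self.tau_grid, dtype=float)
            if g.size == 0 or (g <= 0).any():
                raise ValueError("tau_grid must be non-empty and positive")
            if g.size > 1 and not (np.diff(g) < 0).all():
                raise ValueError("tau_grid must be strictly descending")
            self.tau_grid = g
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("tol and max_iter must be positive")
        if not (0 < self.frequency_threshold <= 1):
            raise ValueError("frequency_threshold must be in (0, 1]")
        if self.tie_break not in ("dense", "sparse"):
            raise ValueError("tie_break must be 'dense' or 'sparse'")


@dataclass
class SelectionFrequencyTable:
    """Per-feature selection counts over the L outer LOO loops."""

    feature_ids: list[str]
    counts: np.ndarray
    L: int
    loo_error: float
    per_loop: list[list[str]]
    tau_stars: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts > self.L).any() or (self.counts < 0).any():
            raise ValueError("counts must be in [0, L]")
        if not (0.0 <= self.loo_error <= 1.0):
            raise ValueError("loo_error must be in [0, 1]")
        union = {f for lst in self.per_loop for f in lst}
        with_count = {f for f, c in zip(self.feature_ids, self.counts) if c >= 1}
        if union != with_count:
            raise ValueError("per-loop lists inconsistent with counts")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.feature_ids, "count": self.counts, "loops": self.L}
        )

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)


def soft_threshold(z, lam):
    """sign(z) * max(|z| - lam, 0), elementwise."""
    if np.any(np.asarray(lam) < 0):
        raise ValueError("threshold must be >= 0")
    z = np.asarray(z, dtype=float)
    return np.sign(z) * np.maximum(np.abs(z) - lam, 0.0)


def l1l2_objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, tau: float, mu: float) -> float:
    r = y - X @ beta
    n = X.shape[0]
    return float(r @ r / n + tau * np.abs(beta).sum() + mu * beta @ beta)


def _sigma_max(X: np.ndarray) -> float:
    """Largest eigenvalue of X^T X / n (squared top singular value of X/sqrt n)."""
    n, p = X.shape
    G = X @ X.T if n <= p else X.T @ X
    return float(np.linalg.eigvalsh(G)[-1] / n)


@njit(cache=True)
def _ista_path_jit(X, y, taus, mu, sigma, tol, max_iter):  # pragma: no cover - numba
    n, p = X.shape
    k = taus.shape[0]
    betas = np.zeros((k, p))
    iters = np.zeros(k, dtype=np.int64)
    beta = np.zeros(p)
    damp = 1.0 / (1.0 + mu / sigma)
    for ti in range(k):
        thr = taus[ti] / (2.0 * sigma)
        it = 0
        while it < max_iter:
            r = y - np.dot(X, beta)
            g = np.dot(r, X)
            delta = 0.0
            for j in range(p):
                z = beta[j] + g[j] / (n * sigma)
                az = abs(z) - thr
                if az > 0.0:
                    nb = damp * (az if z > 0.0 else -az)
                else:
                    nb = 0.0
                d = abs(nb - beta[j])
                if d > delta:
                    delta = d
                beta[j] = nb
            it += 1
            if delta < tol:
                break
        betas[ti] = beta
        iters[ti] = it
    return betas, iters


def _ista_path_numpy(X, y, taus, mu, sigma, tol, max_iter):
    n, p = X.shape
    betas = np.zeros((len(taus), p))
    iters = np.zeros(len(taus), dtype=int)
    beta = np.zeros(p)
    damp = 1.0 / (1.0 + mu / sigma)
    for ti, tau in enumerate(taus):
        thr = tau / (2.0 * sigma)
        for it in range(1, max_iter + 1):
            z = beta + (y - X @ beta) @ X / (n * sigma)
            new = damp * np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
            delta = np.max(np.abs(new - beta))
            beta = new
            if delta < tol:
                break
        betas[ti] = beta
        iters[ti] = it
    return betas, iters


def ista_path(X, y, taus, mu, sigma=None, tol=1e-5, max_iter=3000):
    """Warm-started damped-ISTA solutions along a descending tau grid."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    taus = np.ascontiguousarray(taus, dtype=float)
    if sigma is None:
        sigma = _sigma_max(X)
    fn = _ista_path_jit if _HAVE_NUMBA else _ista_path_numpy
    return fn(X, y, taus, float(mu), float(sigma), float(tol), int(max_iter))


def l1l2_solve(
    X: np.ndarray,
    y: np.ndarray,
    tau: float,
    mu: float,
    tol: float = 1e-5,
    max_iter: int = 3000,
    beta0: np.ndarray | None = None,
    return_objectives: bool = False,
):
    """Minimize (1/n)||y - X b||^2 + tau ||b||_1 + mu ||b||_2^2.

    Damped ISTA: b <- (1 + mu/sigma)^-1 * soft(b + X^T (y - X b)/(n sigma),
    tau/(2 sigma)), a proximal-gradient step whose objective decreases
    monotonically.  Raises :class:`ConvergenceError` (carrying the last
    iterate) if the maximum coefficient change does not drop below
    ``tol`` within ``max_iter`` iterations.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    sigma = _sigma_max(X)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    damp = 1.0 / (1.0 + mu / sigma)
    thr = tau / (2.0 * sigma)
    objectives = [l1l2_objective(X, y, beta, tau, mu)] if return_objectives else None
    for _ in range(max_iter):
        z = beta + (y - X @ beta) @ X / (n * sigma)
        new = damp * np.sign(z) * np.maximum(np.abs(z) - thr, 0.0)
        delta = np.max(np.abs(new - beta)) if p else 0.0
        beta = new
        if return_objectives:
            objectives.append(l1l2_objective(X, y, beta, tau, mu))
        if delta < tol:
            if return_objectives:
                return beta, objectives
            return beta
    raise ConvergenceError(
        f"l1l2_solve did not converge in {max_iter} iterations (tau={tau:g}, mu={mu:g})",
        beta,
    )


def debias_rls(
    X: np.ndarray, y: np.ndarray, support: np.ndarray, ridge_lambda: float = 0.0
) -> np.ndarray:
    """Second optimization: (ridge) least squares restricted to the support.

    Minimizes (1/n)||y - X_s b||^2 + ridge_lambda ||b||^2 on the selected
    columns; with ridge_lambda = 0 the minimum-norm least-squares solution
    is used.  Returns coefficients on the support only (prediction only;
    the support itself is unchanged).
    """
    support = np.asarray(support)
    if support.dtype == bool:
        support = np.flatnonzero(support)
    if support.size == 0:
        raise ValueError("empty support")
    Xs = np.asarray(X, dtype=float)[:, support]
    y = np.asarray(y, dtype=float)
    n, k = Xs.shape
    if ridge_lambda == 0.0:
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        return beta
    if k <= n:
        A = Xs.T @ Xs / n + ridge_lambda * np.eye(k)
        return np.linalg.solve(A, Xs.T @ y / n)
    # dual form for wide restricted designs
    A = Xs @ Xs.T / n + ridge_lambda * np.eye(n)
    return Xs.T @ np.linalg.solve(A, y) / n


def tau_grid_for(X: np.ndarray, y: np.ndarray, cfg: L1L2Config) -> np.ndarray:
    """Descending log-spaced grid from tau_max = 2||X^T y||_inf / n."""
    if cfg.tau_grid is not None:
        return cfg.tau_grid
    n = X.shape[0]
    tau_max = 2.0 * np.max(np.abs(X.T @ y)) / n
    if tau_max <= 0:
        raise ValueError("degenerate data: tau_max = 0")
    return np.geomspace(tau_max, cfg.tau_min_ratio * tau_max, cfg.n_tau)


def _standardize_fit(X: np.ndarray):
    """Per-feature center + unit-l2-norm scaling; constant features dropped."""
    mean = X.mean(axis=0)
    centered = X - mean
    norm = np.sqrt((centered**2).sum(axis=0))
    keep = norm > 1e-12
    return mean, norm, keep


def _standardize_apply(X: np.ndarray, mean, norm, keep) -> np.ndarray:
    return (X[:, keep] - mean[keep]) / norm[keep]


def _predict(x_std: np.ndarray, support: np.ndarray, beta_s: np.ndarray, intercept: float) -> float:
    score = float(x_std[support] @ beta_s + intercept)
    return 1.0 if score >= 0 else -1.0


def _fold_error_curve(
    X: np.ndarray, y: np.ndarray, taus: np.ndarray, mu_scale: float, cfg: L1L2Config
) -> np.ndarray:
    """Inner leave-one-out misclassification for each tau on (X, y)."""
    n = X.shape[0]
    errors = np.zeros((n, len(taus)))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr_raw, ytr = X[mask], y[mask]
        mean, norm, keep = _standardize_fit(Xtr_raw)
        Xtr = _standardize_apply(Xtr_raw, mean, norm, keep)
        xho = _standardize_apply(X[i : i + 1], mean, norm, keep)[0]
        sigma = _sigma_max(Xtr)
        mu = mu_scale * sigma
        betas, _ = ista_path(Xtr, ytr, taus, mu, sigma, cfg.tol, cfg.max_iter)
        ybar = float(ytr.mean())
        for ti in range(len(taus)):
            support = np.flatnonzero(betas[ti])
            if support.size == 0:
                pred = 1.0 if ybar >= 0 else -1.0
            else:
                beta_s = debias_rls(Xtr, ytr, support, cfg.ridge_lambda)
                pred = _predict(xho, support, beta_s, ybar)
            errors[i, ti] = pred != y[i]
    return errors.mean(axis=0)


def _pick_tau(taus: np.ndarray, curve: np.ndarray, tie_break: str) -> float:
    if np.allclose(curve, curve[0]):
        warnings.warn("flat inner error curve: tie-break applied to the whole grid")
        return float(taus[0]) if tie_break == "sparse" else float(taus[-1])
    best = curve.min()
    ties = np.flatnonzero(curve == best)
    idx = ties[-1] if tie_break == "dense" else ties[0]  # taus descend
    return float(taus[idx])


def select_tau_loocv(
    X: np.ndarray, y: np.ndarray, cfg: L1L2Config, taus: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Choose tau by inner leave-one-out classification error.

    Returns (tau_star, error curve over the grid).  Plateaus of the
    minimum are resolved by ``cfg.tie_break``; a completely flat curve
    falls back to the largest (most regularized) tau with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for tau selection")
    if taus is None:
        taus = tau_grid_for(X, y, cfg)
    if len(taus) == 1:
        return float(taus[0]), np.array([np.nan])
    mu_scale = cfg.epsilon * cfg.mu0_scale
    curve = _fold_error_curve(X, y, taus, mu_scale, cfg)
    return _pick_tau(taus, curve, cfg.tie_break), curve


def outer_loo_selection(D: LabeledDataset, cfg: L1L2Config | None = None) -> SelectionFrequencyTable:
    """Nested leave-one-out selection: one list per held-out sample.

    Loop i holds out sample i, selects tau on the remaining samples by
    inner LOO, fits the l1-l2 model plus the ridge refit on the full
    training fold, records the selected feature list and the held-out
    prediction.  The aggregate is a per-feature count over the L = n
    loops and the leave-one-out misclassification error.
    """
    cfg = cfg or L1L2Config()
    n = D.n
    counts = np.zeros(D.p, dtype=int)
    per_loop: list[list[str]] = []
    tau_stars: list[float] = []
    n_errors = 0
    feature_ids = np.asarray(D.feature_ids)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr_raw, ytr = D.X[mask], D.y[mask]
        mean, norm, keep = _standardize_fit(Xtr_raw)
        if not keep.all():
            warnings.warn(f"loop {i}: dropped {int((~keep).sum())} constant features")
        Xtr = _standardize_apply(Xtr_raw, mean, norm, keep)
        xho = _standardize_apply(D.X[i : i + 1], mean, norm, keep)[0]
        taus = tau_grid_for(Xtr, ytr, cfg)
        tau_star, _ = select_tau_loocv(Xtr, ytr, cfg, taus)
        sigma = _sigma_max(Xtr)
        mu = cfg.epsilon * cfg.mu0_scale * sigma
        ti = int(np.flatnonzero(np.isclose(taus, tau_star))[0])
        betas, _ = ista_path(Xtr, ytr, taus[: ti + 1], mu, sigma, cfg.tol, cfg.max_iter)
        try:
            beta = l1l2_solve(
                Xtr, ytr, tau_star, mu, cfg.tol, cfg.max_iter, beta0=betas[-1]
            )
        except ConvergenceError as exc:
            raise ConvergenceError(f"outer loop {i}: {exc}", exc.last_iterate) from exc
        support = np.flatnonzero(beta)
        kept_ids = feature_ids[keep]
        selected = list(kept_ids[support])
        per_loop.append(selected)
        tau_stars.append(tau_star)
        sel_mask = np.zeros(D.p, dtype=bool)
        sel_mask[np.flatnonzero(keep)[support]] = True
        counts += sel_mask
        ybar = float(ytr.mean())
        if support.size == 0:
            pred = 1.0 if ybar >= 0 else -1.0
        else:
            beta_s = debias_rls(Xtr, ytr, support, cfg.ridge_lambda)
            pred = _predict(xho, support, beta_s, ybar)
        n_errors += pred != D.y[i]
    return SelectionFrequencyTable(
        feature_ids=list(D.feature_ids),
        counts=counts,
        L=n,
        loo_error=n_errors / n,
        per_loop=per_loop,
        tau_stars=tau_stars,
    )


def frequency_signature(
    T: SelectionFrequencyTable, threshold: float = 0.5, name: str = "l1l2"
) -> Signature:
    """Features selected in at least ``threshold`` of the loops.

    Ordered by descending count, ties by feature id.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    chosen = [
        (int(c), f) for f, c in zip(T.feature_ids, T.counts) if c / T.L >= threshold
    ]
    chosen.sort(key=lambda t: (-t[0], t[1]))
    if not chosen:
        warnings.warn("frequency threshold selects no features")
    return Signature(name, [f for _, f in chosen])
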