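"""Exploratory factor analysis of a sensor-based feature table.

The conceptual-model stage of the pipeline: jerk measures are
log-transformed and every measure standardized (:func:`preprocess`); the
number of factors to retain comes from parallel analysis
(:func:`parallel_analysis`); the common-factor model is fitted by iterated
principal-axis factoring and varimax-rotated; measures are assigned to the
factor on which their absolute loading is largest, when it exceeds the
relevance threshold (0.5); and Thurstone regression factor scores place
each subject on each factor.

The surface follows the statsmodels convention: build a
:class:`FactorModel` from a feature table, call :meth:`FactorModel.fit`,
and read everything off the returned :class:`FactorResults`.

Notes on the estimator
----------------------
Principal-axis factoring iterates communality estimates (initialized at
squared multiple correlations) on the reduced correlation matrix.  Unlike
principal components, it models only the *common* variance, which is what
makes the cumulative-variance figure `sum of communalities / p`.  Varimax
is an orthogonal rotation, so communalities, fit and the factor scores'
orthogonality are preserved; only simplicity of the loading pattern
changes.

Parallel analysis here retains factors whose reduced-correlation-matrix
eigenvalues exceed the chosen quantile of the same eigenvalues computed on
random normal data of identical shape (the common-factor variant of
Horn's procedure).  ``method="pc"`` switches to full correlation-matrix
eigenvalues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FactorModel", "FactorResults", "preprocess", "parallel_analysis",
           "assign_measures", "factor_scores", "check_variance", "varimax",
           "is_jerk_name", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Principal-axis iteration failed to converge."""


def is_jerk_name(name: str) -> bool:
    """Heuristic jerk-measure flag from the canonical feature names."""
    return "NJS" in name or " JS " in name


def preprocess(table: pd.DataFrame,
               jerk_measures: list[str] | None = None) -> pd.DataFrame:
    """Log-transform jerk measures and standardize every column.

    Jerk scores are strictly positive and right-skewed; the natural log
    brings them near normality, which the factor model assumes.  All
    columns are then centred and scaled to unit sample SD (ddof=1).
    Rows with any missing value are dropped (listwise deletion).
    """
    table = table.dropna(axis=0)
    if jerk_measures is None:
        jerk_measures = [c for c in table.columns if is_jerk_name(c)]
    out = table.astype(float).copy()
    for col in jerk_measures:
        if col not in out.columns:
            continue
        if (out[col] <= 0).any():
            raise ValueError(f"jerk measure {col!r} has non-positive values; "
                             "cannot log-transform")
        out[col] = np.log(out[col])
    sd = out.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) after preprocessing: {constant}")
    return (out - out.mean()) / sd


def _reduced_eigvals(R: np.ndarray) -> np.ndarray:
    """Eigenvalues of R with SMC communalities on the diagonal, descending."""
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    Rs = R.copy()
    np.fill_diagonal(Rs, smc)
    return np.sort(np.linalg.eigvalsh(Rs))[::-1]


def parallel_analysis(X: np.ndarray | pd.DataFrame, n_iter: int = 100,
                      quantile: float = 0.95,
                      seed: int | np.random.Generator | None = None,
                      method: str = "fa") -> int:
    """Number of factors to retain by Horn's parallel analysis.

    Observed eigenvalues are compared position by position against the
    ``quantile`` of eigenvalues from ``n_iter`` standard-normal matrices of
    the same shape; retention stops at the first position where the
    observed eigenvalue no longer exceeds the null.  ``method="fa"``
    (default) uses reduced-correlation (common-factor) eigenvalues,
    ``method="pc"`` full correlation-matrix eigenvalues.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    eig = _reduced_eigvals if method == "fa" else (
        lambda R: np.sort(np.linalg.eigvalsh(R))[::-1])
    if method not in ("fa", "pc"):
        raise ValueError("method must be 'fa' or 'pc'")
    obs = eig(np.corrcoef(X, rowvar=False))
    rng = np.random.default_rng(seed)
    null = np.empty((n_iter, p))
    for i in range(n_iter):
        Z = rng.standard_normal((n, p))
        null[i] = eig(np.corrcoef(Z, rowvar=False))
    thresholds = np.quantile(null, quantile, axis=0)
    k = 0
    for o, thr in zip(obs, thresholds):
        if o > thr:
            k += 1
        else:
            break
    return k


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation by Kaiser's pairwise planar-rotation algorithm.

    Each sweep rotates every factor pair by the closed-form angle that
    maximizes the varimax criterion in that plane, so the algorithm cannot
    stall at the symmetric saddle points that defeat gradient methods.
    Rows are Kaiser-normalized (divided by the square-rooted communality)
    during rotation by default.  Returns the rotated loadings and the
    orthogonal rotation matrix.
    """
    L = np.asarray(loadings, float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    comm = None
    if normalize:
        comm = np.sqrt((L ** 2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]
    R = np.eye(k)
    B = L.copy()
    for _ in range(max_iter):
        total_rotation = 0.0
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = B[:, i], B[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (u * v).sum() - 2.0 * u.sum() * v.sum() / p
                den = (u ** 2 - v ** 2).sum() - (u.sum() ** 2
                                                 - v.sum() ** 2) / p
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                B[:, [i, j]] = B[:, [i, j]] @ rot
                R[:, [i, j]] = R[:, [i, j]] @ rot
                total_rotation += abs(phi)
        if total_rotation < tol:
            break
    out = B
    if normalize:
        out = out * comm[:, None]
    return out, R


def _principal_axis(R: np.ndarray, k: int, max_iter: int = 2000,
                    tol: float = 1e-8) -> tuple[np.ndarray, int]:
    """Iterated principal-axis factoring on a correlation matrix."""
    h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    L = None
    for it in range(1, max_iter + 1):
        Rs = R.copy()
        np.fill_diagonal(Rs, h2)
        w, V = np.linalg.eigh(Rs)
        order = np.argsort(w)[::-1][:k]
        lam = np.clip(w[order], 0.0, None)
        L = V[:, order] * np.sqrt(lam)
        h2_new = np.minimum((L ** 2).sum(axis=1), 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            return L, it
        h2 = h2_new
    raise ConvergenceError(
        f"principal-axis factoring did not converge in {max_iter} iterations")


def assign_measures(loadings: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Assign each measure to the factor with its largest absolute loading.

    A measure is assigned only when that maximum exceeds ``threshold``
    (in absolute value); otherwise it is left unassigned (None).  A
    measure loading above the threshold on several factors goes to the
    single factor where |loading| is largest.
    """
    absl = loadings.abs()
    best = absl.idxmax(axis=1)
    maxed = absl.max(axis=1)
    return pd.Series(np.where(maxed > threshold, best, None),
                     index=loadings.index, name="factor")


def factor_scores(X: pd.DataFrame | np.ndarray,
                  loadings: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Thurstone regression factor scores ``S = Z R^-1 L``.

    ``X`` must be the standardized data the loadings were estimated from;
    scores are least-squares predictions of each subject's position on
    each factor and have column mean zero.
    """
    Z = np.asarray(X, float)
    L = np.asarray(loadings, float)
    R = np.corrcoef(Z, rowvar=False)
    return Z @ np.linalg.solve(R, L)


def check_variance(result_or_fraction, min_fraction: float = 0.70) -> bool:
    """Is the cumulative explained-variance fraction at least ``min_fraction``?"""
    frac = getattr(result_or_fraction, "cumulative_variance", result_or_fraction)
    return bool(frac >= min_fraction)


class FactorModel:
    """Common-factor model of a subjects x measures feature table.

    Parameters
    ----------
    data : DataFrame
        Feature table.  If ``standardize`` is true (default) it is passed
        through :func:`preprocess` (log-jerk + z-scoring) first.
    jerk_measures : list of str, optional
        Columns to log-transform; by default inferred from the names.
    standardize : bool
        Set to False if the table is already preprocessed.
    """

    def __init__(self, data: pd.DataFrame,
                 jerk_measures: list[str] | None = None,
                 standardize: bool = True):
        self.endog = preprocess(data, jerk_measures) if standardize else \
            data.dropna(axis=0).astype(float)
        self.measure_names = list(self.endog.columns)
        n, p = self.endog.shape
        if n <= p:
            warnings.warn(f"only {n} subjects for {p} measures; factor "
                          "solutions may be unstable", stacklevel=2)

    @classmethod
    def from_features(cls, table: pd.DataFrame, **kwargs) -> "FactorModel":
        return cls(table, **kwargs)

    def select_n_factors(self, n_iter: int = 100, quantile: float = 0.95,
                         seed: int | np.random.Generator | None = None,
                         method: str = "fa") -> int:
        """Parallel analysis on the (preprocessed) table."""
        return parallel_analysis(self.endog.to_numpy(), n_iter=n_iter,
                                 quantile=quantile, seed=seed, method=method)

    def fit(self, n_factors: int | None = None, threshold: float = 0.5,
            min_variance: float = 0.70,
            seed: int | np.random.Generator | None = None,
            pa_iter: int = 100, pa_quantile: float = 0.95,
            max_iter: int = 2000, tol: float = 1e-8) -> "FactorResults":
        """Fit the varimax-rotated common-factor model.

        When ``n_factors`` is None it is chosen by parallel analysis
        (``seed`` drives the null replicates).  Factors are ordered by
        explained variance and sign-flipped so each factor's dominant
        loading is positive.
        """
        Z = self.endog.to_numpy()
        n, p = Z.shape
        if n_factors is None:
            n_factors = self.select_n_factors(n_iter=pa_iter,
                                              quantile=pa_quantile, seed=seed)
        if n_factors < 1:
            raise ValueError("need at least one factor to fit")
        if p < n_factors + 1:
            raise ValueError(f"cannot extract {n_factors} factors from only "
                             f"{p} measures")
        R = np.corrcoef(Z, rowvar=False)
        L, n_iter_used = _principal_axis(R, n_factors, max_iter=max_iter,
                                         tol=tol)
        L, _ = varimax(L)
        # order by explained variance, canonical sign
        ssq = (L ** 2).sum(axis=0)
        order = np.argsort(ssq)[::-1]
        L = L[:, order]
        for j in range(L.shape[1]):
            if L[np.argmax(np.abs(L[:, j])), j] < 0:
                L[:, j] = -L[:, j]
        factor_names = [f"F{j + 1}" for j in range(n_factors)]
        loadings = pd.DataFrame(L, index=self.measure_names,
                                columns=factor_names)
        scores = pd.DataFrame(factor_scores(Z, L), index=self.endog.index,
                              columns=factor_names)
        return FactorResults(model=self, loadings=loadings, scores=scores,
                             threshold=threshold, min_variance=min_variance,
                             n_iterations=n_iter_used)


@dataclass
class FactorResults:
    """Fitted conceptual model: loadings, variance accounting, assignment
    and per-subject factor scores."""

    model: FactorModel
    loadings: pd.DataFrame
    scores: pd.DataFrame
    threshold: float = 0.5
    min_variance: float = 0.70
    n_iterations: int = 0
    assignment: pd.Series = field(init=False)

    def __post_init__(self):
        self.assignment = assign_measures(self.loadings, self.threshold)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings ** 2).sum(axis=1).rename("communality")

    @property
    def uniquenesses(self) -> pd.Series:
        return (1.0 - self.communalities).rename("uniqueness")

    @property
    def variance_explained(self) -> pd.Series:
        """Per-factor explained-variance fraction (of total variance p)."""
        p = self.loadings.shape[0]
        return ((self.loadings ** 2).sum(axis=0) / p).rename("variance")

    @property
    def cumulative_variance(self) -> float:
        """Sum of communalities over the number of measures."""
        return float(self.communalities.sum() / self.loadings.shape[0])

    @property
    def n_assigned(self) -> int:
        return int(self.assignment.notna().sum())

    def meets_variance(self, min_fraction: float | None = None) -> bool:
        return check_variance(self, self.min_variance
                              if min_fraction is None else min_fraction)

    def rename_factors(self, labels: dict[str, str]) -> "FactorResults":
        """Relabel factors with configured domain names (pure relabelling)."""
        self.loadings = self.loadings.rename(columns=labels)
        self.scores = self.scores.rename(columns=labels)
        self.assignment = self.assignment.map(
            lambda f: labels.get(f, f) if f is not None else None)
        return self

    def loading_table(self) -> pd.DataFrame:
        """Loading matrix plus a cumulative-variance row (percent), mirroring
        the published table layout."""
        tab = self.loadings.copy()
        cum = (self.loadings ** 2).sum(axis=0).cumsum() / self.loadings.shape[0]
        tab.loc["CV%"] = 100.0 * cum
        return tab

    def summary(self) -> str:
        lines = [
            "Exploratory factor analysis (principal axis, varimax)",
            f"  measures: {self.loadings.shape[0]}   subjects: {self.scores.shape[0]}",
            f"  factors retained: {self.n_factors}",
            f"  cumulative variance: {100 * self.cumulative_variance:.1f}% "
            f"(threshold {100 * self.min_variance:.0f}%: "
            f"{'pass' if self.meets_variance() else 'FAIL'})",
            f"  measures assigned (|loading| > {self.threshold}): "
            f"{self.n_assigned} of {self.loadings.shape[0]}",
            "",
            "Per-factor variance and assigned measures:",
        ]
        for f in self.loadings.columns:
            members = self.assignment[self.assignment == f].index.tolist()
            lines.append(f"  {f}: {100 * self.variance_explained[f]:.1f}%  "
                         f"[{', '.join(members) if members else '-'}]")
        return "\n".join(lines)
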