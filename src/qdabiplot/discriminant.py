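"""Scatter decomposition, canonical (CVA/LDA) transformation and quadratic
discriminant scoring.

The canonical variate transformation whitens the within-class scatter and
maximizes between-class relative to within-class variation; it underlies the
classical CVA biplot.  Quadratic discriminant analysis (QDA) replaces the
pooled within-class covariance with one covariance matrix per class, so each
class j carries a quadratic score

    phi_j^2(x) = (x - xbar_j)' S_j^{-1} (x - xbar_j) + log|S_j|

and a sample is assigned to the class maximizing log(pi_j) - phi_j^2(x)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "LabeledData",
    "CanonicalModel",
    "QuadraticModel",
    "DataError",
    "NumericalError",
    "centre_and_index",
    "scatter_decomposition",
    "canonical_transform",
    "lda_classify",
    "fit_quadratic",
    "phi_squared",
    "qda_classify",
]


class DataError(ValueError):
    """Invalid or unusable input data (bad labels, missing values, tiny classes)."""


class NumericalError(RuntimeError):
    """A numerical failure: singular scatter or non-positive-definite covariance."""


@dataclass
class LabeledData:
    """Column-centred data matrix with group membership bookkeeping.

    Attributes
    ----------
    X : (n, p) ndarray
        Data matrix centred on the grand column means.
    groups : (n,) ndarray of int
        Class index per sample, 0 .. J-1, in first-appearance label order.
    G : (n, J) ndarray
        0/1 group indicator matrix; each row sums to 1.
    n_j : (J,) ndarray of int
        Per-class sample counts.
    class_labels : list
        Original labels in first-appearance order; ``class_labels[k]`` is the
        label of class index k.
    centre : (p,) ndarray
        The grand column means removed from X (needed to calibrate biplot
        axes in original units).
    variable_names : list of str
        Column names.
    raw : (n, p) ndarray
        The uncentred input values, kept so original-unit operations
        (writing, dichotomizing, pattern collapsing) are bit-exact.
    """

    X: np.ndarray
    groups: np.ndarray
    G: np.ndarray
    n_j: np.ndarray
    class_labels: list
    centre: np.ndarray
    variable_names: list
    raw: np.ndarray

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def J(self) -> int:
        return self.G.shape[1]


@dataclass
class CanonicalModel:
    """Scatter matrices and the canonical transformation.

    B, W and T are the between-class, within-class and total scatter matrices
    (T = B + W).  M solves the generalized eigenproblem B M = W M Lambda with
    M'WM = I; its columns are ordered by decreasing eigenvalue.  At most J-1
    eigenvalues are nonzero.  Mr holds the first r columns, and scores /
    class_means_canonical the sample and class-mean coordinates Z = X Mr.
    """

    B: np.ndarray
    W: np.ndarray
    T: np.ndarray
    M: np.ndarray | None = None
    Lambda: np.ndarray | None = None
    r: int | None = None
    Mr: np.ndarray | None = None
    scores: np.ndarray | None = None
    class_means_canonical: np.ndarray | None = None


@dataclass
class QuadraticModel:
    """Per-class Gaussian estimates and the standardized quadratic scores.

    ``class_covs`` are unbiased estimates (divisor n_j - 1); ``chol_factors``
    store their lower Cholesky factors, whose existence is the positive-
    definiteness check.  ``Phi`` (built separately, see
    :func:`qdabiplot.biplot.build_phi_matrix`) holds standardized phi_j^2
    scores: column j is (phi_j^2(x_i) - phi_means[j]) / phi_sds[j].
    """

    class_means: np.ndarray  # (J, p)
    class_covs: np.ndarray  # (J, p, p)
    chol_factors: np.ndarray  # (J, p, p) lower triangular
    log_dets: np.ndarray  # (J,)
    priors: np.ndarray  # (J,)
    class_labels: list
    Phi: np.ndarray | None = None
    phi_means: np.ndarray | None = None
    phi_sds: np.ndarray | None = None

    @property
    def J(self) -> int:
        return self.class_means.shape[0]

    @property
    def p(self) -> int:
        return self.class_means.shape[1]


def centre_and_index(raw_matrix, labels, variable_names=None) -> LabeledData:
    """Centre a raw data matrix and build the group indicator.

    Columns are centred on the grand mean (so ``1'X = 0``); the removed
    offset is retained for axis calibration.  Classes are indexed in
    first-appearance order of their labels.

    Raises
    ------
    DataError
        If any cell is non-numeric or missing, fewer than two classes are
        present, or any class has fewer than two samples.
    """
    raw = np.asarray(raw_matrix, dtype=float)
    if raw.ndim != 2:
        raise DataError("data matrix must be two-dimensional")
    n, p = raw.shape
    if p < 1:
        raise DataError("at least one variable is required")
    if not np.all(np.isfinite(raw)):
        i, k = np.argwhere(~np.isfinite(raw))[0]
        raise DataError(
            f"non-numeric or missing value at row {i}, column {k}"
            + (f" ({variable_names[k]!r})" if variable_names else "")
        )

    labels = list(labels)
    if len(labels) != n:
        raise DataError(f"{len(labels)} labels for {n} rows")
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise DataError("missing group label")

    class_labels: list = []
    index = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(class_labels)
            class_labels.append(lab)
    J = len(class_labels)
    if J < 2:
        raise DataError("at least two classes are required")

    groups = np.array([index[lab] for lab in labels], dtype=int)
    G = np.zeros((n, J))
    G[np.arange(n), groups] = 1.0
    n_j = G.sum(axis=0).astype(int)
    small = np.flatnonzero(n_j < 2)
    if small.size:
        raise DataError(
            f"insufficient class size: class {class_labels[small[0]]!r} has "
            f"{n_j[small[0]]} sample(s); at least 2 are needed"
        )

    centre = raw.mean(axis=0)
    X = raw - centre
    if variable_names is None:
        variable_names = [f"V{k + 1}" for k in range(p)]
    return LabeledData(
        X=X,
        groups=groups,
        G=G,
        n_j=n_j,
        class_labels=class_labels,
        centre=centre,
        variable_names=list(variable_names),
        raw=raw,
    )


def scatter_decomposition(data: LabeledData) -> CanonicalModel:
    """Decompose the total scatter T = X'X into between- and within-class parts.

    W = X'[I - G(G'G)^{-1}G']X and B = T - W, which equals the scatter of the
    class means weighted by class size.
    """
    X, G = data.X, data.G
    T = X.T @ X
    # class means, rows of (G'G)^{-1} G' X
    means = (G.T @ X) / data.n_j[:, None]
    resid = X - G @ means
    W = resid.T @ resid
    B = (means * data.n_j[:, None]).T @ means
    return CanonicalModel(B=B, W=W, T=T)


def canonical_transform(
    model: CanonicalModel, data: LabeledData, r: int = 2
) -> CanonicalModel:
    """Solve B M = W M Lambda subject to M'WM = I and attach canonical scores.

    Solved as a symmetric problem: with W = L L' (Cholesky), the eigenvectors
    V of L^{-1} B L^{-T} give M = L^{-T} V, which automatically satisfies
    M'WM = I.  Columns are ordered by decreasing eigenvalue and signed so each
    column's largest-magnitude entry is positive (reproducible plots).  Sample
    scores are Z = X M_r and class means their per-class averages.
    """
    if r < 1:
        raise ValueError("display dimension r must be >= 1")
    J = data.J
    if r > max(1, J - 1):
        import warnings

        warnings.warn(
            f"r={r} exceeds the {max(1, J - 1)} meaningful canonical "
            f"dimension(s) for J={J} classes; trailing axes carry no "
            "between-class separation",
            stacklevel=2,
        )
    try:
        L = linalg.cholesky(model.W, lower=True)
    except linalg.LinAlgError as exc:
        raise NumericalError(
            "within-class scatter singular; consider regularization or "
            "variable removal"
        ) from exc
    # symmetric whitened between-class matrix
    Linv_B = linalg.solve_triangular(L, model.B, lower=True)
    A = linalg.solve_triangular(L, Linv_B.T, lower=True).T
    A = (A + A.T) / 2.0
    evals, V = linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    V = V[:, order]
    M = linalg.solve_triangular(L, V, lower=True, trans="T")
    # sign convention: largest-magnitude entry of each column positive
    flip = np.sign(M[np.argmax(np.abs(M), axis=0), np.arange(M.shape[1])])
    flip[flip == 0] = 1.0
    M = M * flip

    r_eff = min(r, M.shape[1])
    Mr = M[:, :r_eff]
    scores = data.X @ Mr
    class_means = (data.G.T @ scores) / data.n_j[:, None]

    model.M = M
    model.Lambda = np.clip(evals, 0.0, None)
    model.r = r_eff
    model.Mr = Mr
    model.scores = scores
    model.class_means_canonical = class_means
    return model


def lda_classify(scores_u, class_means_u, priors, scale) -> int:
    """Nearest-canonical-mean rule with a log-prior adjustment.

    Returns argmax_j { log(pi_j) - (scale/2) * ||u - u_j||^2 } where
    ``scale`` is n - J (the within-class scatter in canonical coordinates is
    the identity, so the squared Euclidean distance times n - J is the
    Mahalanobis distance under the pooled covariance).  Ties go to the lowest
    class index.
    """
    u = np.asarray(scores_u, dtype=float)
    means = np.atleast_2d(np.asarray(class_means_u, dtype=float))
    priors = np.asarray(priors, dtype=float)
    d2 = np.sum((means - u) ** 2, axis=1)
    crit = np.log(priors) - 0.5 * scale * d2
    return int(np.argmax(crit))  # argmax takes the first (lowest) index on ties


def _resolve_priors(priors, n_j) -> np.ndarray:
    n_j = np.asarray(n_j)
    J = len(n_j)
    if isinstance(priors, str):
        if priors == "equal":
            return np.full(J, 1.0 / J)
        if priors == "proportional":
            return n_j / n_j.sum()
        raise ValueError(f"unknown priors mode {priors!r}")
    pi = np.asarray(priors, dtype=float)
    if pi.shape != (J,):
        raise ValueError(f"explicit priors must have length {J}")
    if np.any(pi <= 0):
        raise ValueError("priors must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError("explicit priors must sum to 1")
    return pi


def fit_quadratic(
    data: LabeledData, priors="proportional", ridge: float = 0.0
) -> QuadraticModel:
    """Estimate per-class means and covariances for quadratic discrimination.

    Covariances use the unbiased divisor n_j - 1 and must be positive
    definite; the log-determinant comes from the Cholesky factor (never an
    explicit determinant).  ``priors`` is ``"equal"`` (1/J),
    ``"proportional"`` (n_j / n) or an explicit vector summing to 1.
    ``ridge`` adds eps * I to every class covariance — off by default, an
    escape hatch for near-singular binary data.
    """
    J, p = data.J, data.p
    means = np.empty((J, p))
    covs = np.empty((J, p, p))
    chols = np.empty((J, p, p))
    log_dets = np.empty(J)
    for j in range(J):
        rows = data.X[data.groups == j]
        means[j] = rows.mean(axis=0)
        S = np.cov(rows, rowvar=False, ddof=1).reshape(p, p)
        if ridge > 0:
            S = S + ridge * np.eye(p)
        try:
            C = linalg.cholesky(S, lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalError(
                f"covariance of class {data.class_labels[j]!r} is not "
                f"positive definite (p={p} may exceed n_j-1={data.n_j[j] - 1}, "
                "or variables may be collinear); consider a ridge"
            ) from exc
        covs[j] = S
        chols[j] = C
        log_dets[j] = 2.0 * np.sum(np.log(np.diag(C)))
    return QuadraticModel(
        class_means=means,
        class_covs=covs,
        chol_factors=chols,
        log_dets=log_dets,
        priors=_resolve_priors(priors, data.n_j),
        class_labels=list(data.class_labels),
    )


def pool_covariances(model: QuadraticModel, n_j) -> QuadraticModel:
    """Replace every class covariance with the pooled estimate.

    The pooled covariance is sum_j (n_j - 1) S_j / (n - J).  With a shared
    covariance the quadratic rule collapses to the linear one, which is the
    standard cross-check between QDA and LDA.
    """
    n_j = np.asarray(n_j)
    w = (n_j - 1).astype(float)
    S = np.einsum("j,jkl->kl", w, model.class_covs) / (n_j.sum() - len(n_j))
    C = linalg.cholesky(S, lower=True)
    J = model.J
    return QuadraticModel(
        class_means=model.class_means,
        class_covs=np.repeat(S[None, :, :], J, axis=0),
        chol_factors=np.repeat(C[None, :, :], J, axis=0),
        log_dets=np.full(J, 2.0 * np.sum(np.log(np.diag(C)))),
        priors=model.priors,
        class_labels=list(model.class_labels),
    )


def phi_squared(x, model: QuadraticModel, j: int) -> float:
    """Quadratic score of class j at x: Mahalanobis part plus log|S_j|.

    Computed via the stored Cholesky factor, never an explicit inverse.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (model.p,):
        raise ValueError(f"x must have shape ({model.p},), got {x.shape}")
    d = x - model.class_means[j]
    y = linalg.solve_triangular(model.chol_factors[j], d, lower=True)
    return float(y @ y + model.log_dets[j])


def phi_squared_matrix(X, model: QuadraticModel) -> np.ndarray:
    """Raw phi_j^2 scores for every row of X against every class: (n, J)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    out = np.empty((n, model.J))
    for j in range(model.J):
        D = X - model.class_means[j]
        Y = linalg.solve_triangular(model.chol_factors[j], D.T, lower=True)
        out[:, j] = np.sum(Y * Y, axis=0) + model.log_dets[j]
    return out


def qda_classify(x, model: QuadraticModel) -> int:
    """Quadratic rule: argmax_j { log(pi_j) - phi_j^2(x) / 2 }, ties to the
    lowest class index."""
    phi = np.array([phi_squared(x, model, j) for j in range(model.J)])
    return int(np.argmax(np.log(model.priors) - 0.5 * phi))


def qda_classify_matrix(X, model: QuadraticModel) -> np.ndarray:
    """Vectorized :func:`qda_classify` over the rows of X."""
    crit = np.log(model.priors) - 0.5 * phi_squared_matrix(X, model)
    return np.argmax(crit, axis=1)
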