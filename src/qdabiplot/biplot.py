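"""QDA and CVA biplot construction.

The QDA biplot represents each sample by its J standardized quadratic scores
(the columns of Phi), projects those to two dimensions by PCA, and paints
classification regions by back-projecting every display point to approximate
raw scores phi-hat_j^2 and applying the discriminant rule.  The CVA biplot is
the classical canonical-variate display with nearest-mean regions.  Both are
decorated with calibrated variable axes fitted by the regression method, which
can be translated orthogonally out of the point cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .discriminant import (
    CanonicalModel,
    LabeledData,
    QuadraticModel,
    lda_classify,
    phi_squared_matrix,
)

__all__ = [
    "BiplotLayout",
    "CalibratedAxis",
    "RegionGrid",
    "build_phi_matrix",
    "qda_scores",
    "back_project",
    "classify_display_point",
    "classify_display_points",
    "build_region_grid",
    "two_group_plot",
    "cva_layout",
    "regression_axes",
    "translate_axes",
    "collapse_patterns",
]


@dataclass
class CalibratedAxis:
    """A biplot axis for one variable, marked in the variable's original units.

    ``direction`` is the regression direction b_k; a marker for value v sits at
    ((v - centre_k) / (b_k'b_k)) * b_k + offset, so the orthogonal projection
    of a display point onto the axis reads off its fitted value.  ``offset``
    is the orthogonal parallel translation applied (zero until translated).
    """

    variable_name: str
    direction: np.ndarray  # (2,)
    markers: list  # [(value, (2,) position), ...]
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    centre_value: float = 0.0


@dataclass
class RegionGrid:
    """A regular lattice over the display window with one class label per point."""

    x: np.ndarray  # (res_x,)
    y: np.ndarray  # (res_y,)
    labels: np.ndarray  # (res_y, res_x) int class indices


@dataclass
class BiplotLayout:
    """2-D display coordinates plus everything needed to classify the plane.

    ``layout_kind`` is "qda" (PCA of Phi), "two_group" (direct phi_2^2 vs
    phi_1^2 scatter) or "cva" (canonical scores).  For the phi-based kinds,
    ``loadings``/``phi_scale``/``phi_offset`` define the linear back-map from
    a display point z to raw scores:  phi_hat = (loadings @ z) * scale +
    offset.  For CVA the plane is classified by the nearest-canonical-mean
    rule instead (``class_means_display``, ``lda_scale``).
    """

    scores: np.ndarray  # (n, 2)
    layout_kind: str
    loadings: np.ndarray | None = None  # (J, 2)
    centre_offset: np.ndarray | None = None
    phi_scale: np.ndarray | None = None  # (J,)
    phi_offset: np.ndarray | None = None  # (J,)
    priors: np.ndarray | None = None
    class_means_display: np.ndarray | None = None  # (J, 2) for cva
    lda_scale: float | None = None  # n - J, for cva
    class_labels: list | None = None
    axes: list = field(default_factory=list)
    region_grid: RegionGrid | None = None
    aspect: float = 1.0


def build_phi_matrix(data: LabeledData, model: QuadraticModel) -> QuadraticModel:
    """Attach the standardized score matrix Phi to a fitted quadratic model.

    Raw scores phi_j^2(x_i) are computed for every sample and class; each
    column is then centred by its mean and scaled to unit standard deviation
    (divisor n - 1), creating the J 'new' variables whose PCA yields the QDA
    biplot.
    """
    raw = phi_squared_matrix(data.X, model)
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    dead = np.flatnonzero(sds <= 0)
    if dead.size:
        raise ValueError(
            f"phi column for class {model.class_labels[dead[0]]!r} has zero "
            "variance: every sample is equally far from that class, so the "
            "standardized score is undefined"
        )
    model.Phi = (raw - means) / sds
    model.phi_means = means
    model.phi_sds = sds
    return model


def _fix_signs(scores: np.ndarray, loadings: np.ndarray):
    """Flip components so each loading column's largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    flip = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    return scores * flip, loadings * flip


def qda_scores(model: QuadraticModel, r: int = 2) -> BiplotLayout:
    """PCA of Phi: sample scores on the first r principal components.

    Phi's columns are mean zero by construction, so no re-centring is applied.
    When J = 2 the r = 2 representation is exact (Phi has rank at most 2).
    """
    if model.Phi is None:
        raise ValueError("Phi not built; call build_phi_matrix first")
    J = model.J
    if r > J:
        raise ValueError(f"cannot extract r={r} components from {J} phi columns")
    U, s, Vt = np.linalg.svd(model.Phi, full_matrices=False)
    scores = U[:, :r] * s[:r]
    loadings = Vt[:r].T  # (J, r)
    scores, loadings = _fix_signs(scores, loadings)
    return BiplotLayout(
        scores=scores,
        layout_kind="qda",
        loadings=loadings,
        centre_offset=np.zeros(J),
        phi_scale=model.phi_sds.copy(),
        phi_offset=model.phi_means.copy(),
        priors=model.priors.copy(),
        class_labels=list(model.class_labels),
    )


def two_group_plot(
    data: LabeledData, model: QuadraticModel, scaled: bool = True
) -> BiplotLayout:
    """Direct two-group display: phi_2^2 against phi_1^2.

    Unscaled, the equal-prior classification boundary is literally the line
    y = x (class 1 above it, since small phi_1^2 favours class 1).  Scaled,
    each coordinate is divided by its standard deviation for a better spread;
    regions are still decided on the raw scores.
    """
    if model.J != 2:
        raise ValueError(
            f"two_group_plot requires exactly 2 classes, got {model.J}; "
            "use qda_scores for the general PCA display"
        )
    raw = phi_squared_matrix(data.X, model)
    sds = raw.std(axis=0, ddof=1)
    if scaled:
        scores = raw / sds
        scale = sds.copy()
    else:
        scores = raw.copy()
        scale = np.ones(2)
    return BiplotLayout(
        scores=scores,
        layout_kind="two_group",
        loadings=np.eye(2),
        centre_offset=np.zeros(2),
        phi_scale=scale,
        phi_offset=np.zeros(2),
        priors=model.priors.copy(),
        class_labels=list(model.class_labels),
    )


def back_project(z, layout: BiplotLayout, model: QuadraticModel | None = None):
    """Map a display point back to the J-vector of raw phi-hat_j^2 scores.

    The standardized reconstruction is loadings @ z (the PCA inverse map on
    the retained subspace; Phi columns have mean zero, so no centring term);
    raw scores are recovered by undoing the per-column standardization.
    Exact when r equals the number of classes (two-group case).
    """
    if layout.loadings is None:
        raise ValueError(f"back projection undefined for {layout.layout_kind} layouts")
    z = np.asarray(z, dtype=float)
    std = layout.loadings @ z
    return std * layout.phi_scale + layout.phi_offset


def _back_project_many(Z, layout: BiplotLayout) -> np.ndarray:
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return Z @ layout.loadings.T * layout.phi_scale + layout.phi_offset


def classify_display_points(Z, layout: BiplotLayout, model: QuadraticModel | None = None):
    """Vectorized classification of display points (rows of Z)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if layout.layout_kind == "cva":
        d2 = np.sum(
            (Z[:, None, :] - layout.class_means_display[None, :, :]) ** 2, axis=2
        )
        crit = np.log(layout.priors) - 0.5 * layout.lda_scale * d2
    else:
        phi_hat = _back_project_many(Z, layout)
        crit = np.log(layout.priors) - 0.5 * phi_hat
    return np.argmax(crit, axis=1)


def classify_display_point(z, layout: BiplotLayout, model: QuadraticModel | None = None) -> int:
    """Classify one display point.

    Phi-based layouts use argmax_j { log(pi_j) - phi-hat_j^2(z) / 2 } on the
    back-projected raw scores, which with equal priors is the smallest-phi
    rule; CVA layouts use the nearest-canonical-mean rule with the log-prior
    adjustment.  Ties go to the lowest class index.
    """
    return int(classify_display_points(np.asarray(z)[None, :], layout, model)[0])


def build_region_grid(
    layout: BiplotLayout,
    model: QuadraticModel | None = None,
    resolution: int = 400,
    margin: float = 0.1,
) -> RegionGrid:
    """Label a regular lattice covering the score range plus a margin.

    The lattice spans [min - m, max + m] per display dimension, where m is
    ``margin`` times that dimension's score range; every point is classified
    with :func:`classify_display_point`'s rule.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    lo = layout.scores.min(axis=0)
    hi = layout.scores.max(axis=0)
    extent = hi - lo
    extent[extent <= 0] = 1.0  # degenerate (rank-1) display dimension
    lo = lo - margin * extent
    hi = hi + margin * extent
    x = np.linspace(lo[0], hi[0], resolution)
    y = np.linspace(lo[1], hi[1], resolution)
    XX, YY = np.meshgrid(x, y)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    labels = classify_display_points(pts, layout, model).reshape(resolution, resolution)
    grid = RegionGrid(x=x, y=y, labels=labels)
    layout.region_grid = grid
    return grid


def cva_layout(canonical: CanonicalModel, data: LabeledData, priors="proportional") -> BiplotLayout:
    """Classical canonical-variate display: Z = X M_r with nearest-mean regions.

    With J = 2 classes only one canonical dimension separates the groups; the
    rank-1 scores are then plotted on the horizontal axis (vertical
    coordinate zero) with a warning.
    """
    from .discriminant import _resolve_priors

    if canonical.scores is None:
        raise ValueError("canonical transform not fitted; call canonical_transform")
    scores = canonical.scores
    means = canonical.class_means_canonical
    if scores.shape[1] < 2:
        scores = np.column_stack([scores[:, 0], np.zeros(len(scores))])
        means = np.column_stack([means[:, 0], np.zeros(len(means))])
    elif data.J == 2:
        warnings.warn(
            "two classes span a single canonical dimension; the vertical "
            "axis carries no between-class separation — plotting rank-1 "
            "scores on the horizontal axis",
            stacklevel=2,
        )
        scores = np.column_stack([scores[:, 0], np.zeros(len(scores))])
        means = np.column_stack([means[:, 0], np.zeros(len(means))])
    return BiplotLayout(
        scores=scores[:, :2],
        layout_kind="cva",
        priors=_resolve_priors(priors, data.n_j),
        class_means_display=means[:, :2],
        lda_scale=float(data.n - data.J),
        class_labels=list(data.class_labels),
    )


def _nice_marker_values(vmin: float, vmax: float, target: int = 6) -> np.ndarray:
    """Round marker values on a 1-2-5 ladder spanning [vmin, vmax]."""
    from matplotlib.ticker import MaxNLocator

    if vmax <= vmin:
        return np.array([vmin])
    loc = MaxNLocator(nbins=target, steps=[1, 2, 5, 10])
    ticks = loc.tick_values(vmin, vmax)
    return ticks[(ticks >= vmin - 1e-12) & (ticks <= vmax + 1e-12)]


def regression_axes(
    layout: BiplotLayout, data: LabeledData, which_variables=None
) -> list[CalibratedAxis]:
    """Fit calibrated variable axes to the display by the regression method.

    For variable k the direction is the least-squares coefficient
    b_k = (Z'Z)^{-1} Z' x_k of the centred variable on the display scores Z.
    Markers at nice round values v (1-2-5 ladder over the observed range; for
    binary variables just 0 and 1) sit at ((v - centre_k)/(b_k'b_k)) b_k, so
    orthogonally projecting a score onto the axis reads off the fitted value
    z'b_k + centre_k.  Near-zero directions are skipped with a warning.
    """
    Z = layout.scores
    ZtZ = Z.T @ Z
    if which_variables is None:
        which = list(range(data.p))
    else:
        which = [
            data.variable_names.index(v) if isinstance(v, str) else int(v)
            for v in which_variables
        ]
    axes = []
    for k in which:
        xk = data.X[:, k]
        b = np.linalg.solve(ZtZ, Z.T @ xk)
        if np.linalg.norm(b) < 1e-12:
            warnings.warn(
                f"variable {data.variable_names[k]!r} has a degenerate axis "
                "direction; omitted",
                stacklevel=2,
            )
            continue
        centre_k = float(data.centre[k])
        orig = xk + centre_k
        vals = np.unique(orig)
        if vals.size <= 2 and np.all(np.isin(vals, (0.0, 1.0))):
            marker_values = np.array([0.0, 1.0])
        else:
            marker_values = _nice_marker_values(orig.min(), orig.max())
        bb = float(b @ b)
        markers = [
            (float(v), (v - centre_k) / bb * b) for v in marker_values
        ]
        axes.append(
            CalibratedAxis(
                variable_name=data.variable_names[k],
                direction=b,
                markers=markers,
                centre_value=centre_k,
            )
        )
    layout.axes = axes
    return axes


def translate_axes(
    axes: list[CalibratedAxis], layout: BiplotLayout, strategy: str = "hull-clear"
) -> list[CalibratedAxis]:
    """Shift each axis orthogonally to its direction, clear of the samples.

    "hull-clear" (default) moves the axis just beyond the extreme projection
    of the scores onto the axis normal, on whichever side is closer;
    projections onto the axis direction — hence read-off values — are
    unchanged.  "none" resets all offsets to zero.
    """
    if strategy not in ("hull-clear", "none"):
        raise ValueError(f"unknown translation strategy {strategy!r}")
    Z = layout.scores
    pad = 0.05 * float(np.max(Z.max(axis=0) - Z.min(axis=0)) or 1.0)
    for ax in axes:
        if strategy == "none":
            offset = np.zeros(2)
        else:
            d = ax.direction / np.linalg.norm(ax.direction)
            normal = np.array([-d[1], d[0]])
            proj = Z @ normal
            lo, hi = proj.min(), proj.max()
            c = hi + pad if abs(hi) <= abs(lo) else lo - pad
            offset = c * normal
        shift = offset - ax.offset
        ax.markers = [(v, pos + shift) for v, pos in ax.markers]
        ax.offset = offset
    return axes


def collapse_patterns(data: LabeledData):
    """Collapse identical binary response patterns into single glyphs.

    Identical 0/1 patterns land on the same biplot point; each unique pattern
    gets per-class counts, a total multiplicity (for glyph sizing), and a
    displayed class chosen by majority vote (ties to the lowest class index).
    Returns a DataFrame with one row per distinct pattern.
    """
    import pandas as pd

    orig = data.raw
    if not np.all(np.isin(np.round(orig, 9), (0.0, 1.0))):
        raise ValueError("collapse_patterns requires binary 0/1 data")
    patterns = np.round(orig).astype(int)
    uniq, inverse = np.unique(patterns, axis=0, return_inverse=True)
    J = data.J
    counts = np.zeros((len(uniq), J), dtype=int)
    np.add.at(counts, (inverse, data.groups), 1)
    majority = np.argmax(counts, axis=1)  # first max wins ties
    df = pd.DataFrame(
        uniq, columns=data.variable_names
    )
    for j, lab in enumerate(data.class_labels):
        df[f"count_{lab}"] = counts[:, j]
    df["multiplicity"] = counts.sum(axis=1)
    df["display_class"] = [data.class_labels[j] for j in majority]
    return df
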