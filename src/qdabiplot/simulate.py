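"""Synthetic data generators: the three-group Gaussian benchmark, its
median-dichotomized indicator version, and generic binary presence/absence
panels for two-group discrimination experiments."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discriminant import LabeledData, centre_and_index

__all__ = [
    "SimulationSpec",
    "three_group_spec",
    "simulate_normal",
    "dichotomize_at_median",
    "pathogen_panel",
]


@dataclass
class SimulationSpec:
    """Parameters of a multivariate-normal mixture: one mean vector and one
    covariance matrix per group, the per-group sample sizes, and a seed."""

    group_means: np.ndarray  # (J, p)
    group_covs: np.ndarray  # (J, p, p)
    sizes: np.ndarray  # (J,)
    seed: int = 0

    def __post_init__(self):
        self.group_means = np.asarray(self.group_means, dtype=float)
        self.group_covs = np.asarray(self.group_covs, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        J, p = self.group_means.shape
        if self.group_covs.shape != (J, p, p):
            raise ValueError("group_covs must be (J, p, p)")
        if np.any(self.sizes < 2):
            raise ValueError("every group needs at least 2 samples")
        for j in range(J):
            S = self.group_covs[j]
            if not np.allclose(S, S.T):
                raise ValueError(f"covariance {j} not symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError(f"covariance {j} not positive definite")


def three_group_spec(seed: int = 0) -> SimulationSpec:
    """The standard three-group benchmark with unequal covariance structures.

    Three four-variate normal groups of 50 samples each:
    mu_1 = (1,1,1,1) with Sigma_1 = I; mu_2 = (-1,2,3,4) with Sigma_2 = 2I;
    mu_3 = (1,1,5,5) with Sigma_3 compound-symmetric (unit variance,
    correlation 0.7).  Group 2 is the most dispersed and lies between groups
    1 and 3 on variables 3 and 4.
    """
    p = 4
    means = np.array(
        [
            [1.0, 1.0, 1.0, 1.0],
            [-1.0, 2.0, 3.0, 4.0],
            [1.0, 1.0, 5.0, 5.0],
        ]
    )
    covs = np.stack(
        [
            np.eye(p),
            2.0 * np.eye(p),
            0.3 * np.eye(p) + 0.7 * np.ones((p, p)),
        ]
    )
    return SimulationSpec(group_means=means, group_covs=covs, sizes=[50, 50, 50], seed=seed)


def simulate_normal(spec: SimulationSpec) -> LabeledData:
    """Draw multivariate-normal samples per group (deterministic for a seed).

    Draws use a Cholesky factor of each covariance with numpy's PCG64
    generator.  Group labels are "G1", "G2", ... in group order.
    """
    rng = np.random.default_rng(spec.seed)
    J, p = spec.group_means.shape
    blocks, labels = [], []
    for j in range(J):
        L = np.linalg.cholesky(spec.group_covs[j])
        z = rng.standard_normal((spec.sizes[j], p))
        blocks.append(z @ L.T + spec.group_means[j])
        labels.extend([f"G{j + 1}"] * spec.sizes[j])
    raw = np.vstack(blocks)
    return centre_and_index(raw, labels)


def dichotomize_at_median(data: LabeledData) -> LabeledData:
    """Convert to indicator variables by thresholding at the pooled median.

    Per variable, the median is taken across all samples (all groups pooled);
    values below the median become 0 and values at or above it become 1.  A
    constant column therefore becomes all ones (with a warning).
    """
    import warnings

    orig = data.raw
    med = np.median(orig, axis=0)
    binary = (orig >= med).astype(float)
    const = np.flatnonzero(orig.max(axis=0) == orig.min(axis=0))
    for k in const:
        warnings.warn(
            f"variable {data.variable_names[k]!r} is constant; dichotomized "
            "to all ones",
            stacklevel=2,
        )
    labels = [data.class_labels[g] for g in data.groups]
    return centre_and_index(binary, labels, variable_names=data.variable_names)


def pathogen_panel(
    n_per_group,
    p: int,
    presence_probs,
    seed: int = 0,
    group_labels=None,
) -> LabeledData:
    """Binary presence/absence panel: independent Bernoulli draws per class.

    ``presence_probs`` is a (J, p) array (or nested list) of per-class,
    per-variable presence probabilities in (0, 1) — e.g. a 15-pathogen panel
    for two patient groups.  Variables are named P1..Pp.
    """
    probs = np.atleast_2d(np.asarray(presence_probs, dtype=float))
    J = probs.shape[0]
    if probs.shape[1] != p:
        raise ValueError(f"presence_probs must have {p} columns")
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("presence probabilities must lie strictly in (0, 1)")
    sizes = np.broadcast_to(np.asarray(n_per_group, dtype=int), (J,))
    if group_labels is None:
        group_labels = [f"G{j + 1}" for j in range(J)]
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for j in range(J):
        blocks.append((rng.random((sizes[j], p)) < probs[j]).astype(float))
        labels.extend([group_labels[j]] * sizes[j])
    raw = np.vstack(blocks)
    names = [f"P{k + 1}" for k in range(p)]
    return centre_and_index(raw, labels, variable_names=names)
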