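"""Self-contained statistics: partial Spearman association, permutation
group contrasts, and the Mapper resolution/gain perturbation sweep."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotate import annotate_and_score
from .mapper import FilterEmbedding, geodesic_filter, mapper_from_embedding


@dataclass
class AssociationResult:
    rho: float
    n: int
    covariates: int
    p_value: float
    n_perm: int


def _residualize(x: np.ndarray, cov: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), cov]) if cov.size else np.ones((len(x), 1))
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> AssociationResult:
    """Rank correlation of x and y after removing covariate effects.

    Both variables are rank-transformed (average ranks on ties), residualised
    on the covariates by least squares, and correlated; covariates equal to
    none (or constant) reduce this to a plain Spearman correlation.  The
    p-value is two-sided, from ``n_perm`` seeded permutations of the pairing
    between the two residual vectors, with add-one correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    cov = np.empty((len(x), 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.size and cov.shape[0] != len(x):
        cov = cov.T
    if cov.size and cov.shape[0] != len(x):
        raise ValueError("covariates are not aligned with x and y")
    if len(x) <= cov.shape[1] + 2:
        raise ValueError("too few observations for the requested covariates")

    rx = rankdata(x)
    ry = rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant input after ranking")
    ex = _residualize(rx, cov)
    ey = _residualize(ry, cov)

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    rho = corr(ex, ey)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(corr(ex, ey[rng.permutation(len(ey))])) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return AssociationResult(rho=rho, n=len(x), covariates=cov.shape[1],
                             p_value=p, n_perm=n_perm)


@dataclass
class GroupTestResult:
    statistic: float  # difference in group means (first - second)
    p_value: float
    groups: tuple[str, str]
    n: tuple[int, int]
    n_perm: int


def permutation_group_test(
    values: Sequence[float],
    groups: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> GroupTestResult:
    """Two-sided permutation test on the difference in group means.

    Group labels are permuted ``n_perm`` times; the p-value is the add-one
    corrected fraction of permutations with ``|stat| >= |observed|``.
    Deterministic given the seed and invariant to the input ordering of the
    (value, label) pairs up to the permutation stream.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    in_a = labels == names[0]
    n_a, n_b = int(in_a.sum()), int((~in_a).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 observations")

    def stat(mask: np.ndarray) -> float:
        return float(values[mask].mean() - values[~mask].mean())

    obs = stat(in_a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(in_a)
        if abs(stat(perm)) >= abs(obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return GroupTestResult(statistic=obs, p_value=p, groups=(names[0], names[1]),
                           n=(n_a, n_b), n_perm=n_perm)


@dataclass
class PreparedSubject:
    """A subject readied for resolution/gain sweeps: the geodesic embedding
    is computed once (it does not depend on r or g)."""

    subject_id: str
    group: str
    X: np.ndarray  # cleaned frames x parcels
    labels: pd.DataFrame  # retained-frame labels
    embedding: FilterEmbedding


def prepare_for_sweep(
    subject_id: str,
    group: str,
    X: np.ndarray,
    labels: pd.DataFrame,
    k: int | None = None,
    d: int = 2,
    metric: str = "euclidean",
) -> PreparedSubject:
    emb = geodesic_filter(X, k=k, d=d, metric=metric)
    return PreparedSubject(subject_id=subject_id, group=group, X=X,
                           labels=labels, embedding=emb)


def subject_mean_pc(
    prepared: PreparedSubject,
    r: int,
    g: float,
    axis: str = "load",
    metric: str = "euclidean",
    aggregate: str = "mean",
) -> float:
    graph = mapper_from_embedding(prepared.embedding, prepared.X, r=r, g=g, metric=metric)
    result = annotate_and_score(graph, prepared.labels, axis=axis, aggregate=aggregate)
    return result.mean_pc


def perturbation_sweep(
    prepared_subjects: Sequence[PreparedSubject],
    r_values: Sequence[int] = (14, 16, 18, 20, 22),
    g_values: Sequence[float] = (0.6, 0.7, 0.8),
    axis: str = "load",
    metric: str = "euclidean",
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Mapper + annotation + PC over a (resolution, gain) grid.

    One row per grid cell: per-group mean PC (averaged over subjects), their
    difference (first group name alphabetically minus second) and its sign —
    the robustness check that the direction of the group contrast does not
    hinge on the choice of r and g.
    """
    if not len(prepared_subjects):
        raise ValueError("no subjects to sweep")
    if not len(r_values) or not len(g_values):
        raise ValueError("r_values and g_values must be non-empty")
    names = sorted({p.group for p in prepared_subjects})
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    rows = []
    for r in r_values:
        for g in g_values:
            per_subject = {
                p.subject_id: (p.group, subject_mean_pc(p, r, g, axis, metric, aggregate))
                for p in prepared_subjects
            }
            means = {
                name: float(np.mean([v for grp, v in per_subject.values() if grp == name]))
                for name in names
            }
            diff = means[names[0]] - means[names[1]]
            rows.append({
                "r": int(r),
                "g": float(g),
                "axis": axis,
                f"mean_pc_{names[0]}": means[names[0]],
                f"mean_pc_{names[1]}": means[names[1]],
                "difference": diff,
                "sign": int(np.sign(diff)),
            })
    return pd.DataFrame(rows)
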