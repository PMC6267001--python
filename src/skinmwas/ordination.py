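"""Bray-Curtis ordination and constrained analysis with permutation tests.

Canonical analysis of principal coordinates is realized as distance-based
redundancy analysis: principal coordinates are computed from the Bray-Curtis
dissimilarity matrix, the axes with positive eigenvalues are regressed on the
constraint design matrix (odor intensity as a numeric column; age group,
timepoint and sex as indicators), and the fitted values are eigen-analyzed.
Significance of the constraint set comes from a permutation test on the
pseudo-F statistic (constrained vs. residual inertia), permuting rows of the
constraint matrix; p has resolution 1/(n_permutations + 1).  Negative PCoA
eigenvalues are reported but not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import skbio

from ._rng import stage_rng
from .errors import DegenerateDistanceError

#: default permutation count; p-value floor is 1 / (n_perm + 1)
DEFAULT_N_PERM = 999


def bray_curtis(abundances: pd.DataFrame) -> skbio.DistanceMatrix:
    """Bray-Curtis dissimilarity between the rows (samples) of a
    sample x taxon abundance table: d = 1 - 2 * sum(min) / sum(u + v)."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = x.sum(axis=1) == 0
    if zero.any():
        bad = list(np.asarray(abundances.index)[zero][:5])
        raise DegenerateDistanceError(
            f"Bray-Curtis undefined for all-zero sample(s): {bad}")
    condensed = scipy.spatial.distance.pdist(x, metric="braycurtis")
    return skbio.DistanceMatrix(scipy.spatial.distance.squareform(condensed),
                                ids=[str(i) for i in abundances.index])


def pcoa(dm: skbio.DistanceMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Principal-coordinates analysis of a distance matrix.

    Returns (eigenvalues, coordinates); coordinates are eigenvectors scaled
    by sqrt(eigenvalue) for positive eigenvalues (zero columns otherwise).
    Negative eigenvalues are reported as-is.
    """
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    axes = [f"PC{i + 1}" for i in range(n)]
    return (pd.Series(eigvals, index=axes, name="eigenvalue"),
            pd.DataFrame(coords, index=list(dm.ids), columns=axes))


def build_constraints(meta: pd.DataFrame, terms=("odor", "age", "time", "sex"),
                      ) -> pd.DataFrame:
    """Constraint design matrix: odor numeric; age/time/sex as indicators."""
    cols = {}
    for term in terms:
        if term == "odor":
            cols["odor_intensity"] = meta["odor_intensity"].to_numpy(float)
        elif term == "age":
            cols["age_teens"] = (meta["age_group"] == "teens").to_numpy(float)
        elif term == "time":
            tps = list(dict.fromkeys(meta["timepoint"]))
            cols[f"time_{tps[-1]}"] = (meta["timepoint"] == tps[-1]).to_numpy(float)
        elif term == "sex":
            cols["sex_M"] = (meta["sex"] == "M").to_numpy(float)
        else:
            raise ValueError(f"unknown constraint term {term!r}")
    return pd.DataFrame(cols, index=meta["sample_id"])


@dataclass
class CapResult:
    """Constrained-ordination summary."""

    eigenvalues: pd.Series        # constrained axes, non-increasing
    sample_scores: pd.DataFrame   # samples x constrained axes
    biplot_scores: pd.DataFrame   # constraints x constrained axes (correlations)
    pseudo_f: float
    p_value: float
    n_permutations: int
    total_inertia: float
    constrained_inertia: float
    dropped_constraints: list


def _drop_collinear(x: np.ndarray, names: list) -> tuple[np.ndarray, list, list]:
    """Greedily drop columns that do not increase the rank of the centered
    design; returns (reduced matrix, kept names, dropped names)."""
    kept_idx: list[int] = []
    dropped: list[str] = []
    for j in range(x.shape[1]):
        trial = x[:, kept_idx + [j]]
        if np.linalg.matrix_rank(trial) > len(kept_idx):
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        warnings.warn(f"dropping collinear constraint column(s): {dropped}",
                      stacklevel=3)
    return x[:, kept_idx], [names[j] for j in kept_idx], dropped


def cap(dm: skbio.DistanceMatrix, constraints: pd.DataFrame,
        n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> CapResult:
    """Constrained analysis of principal coordinates (distance-based RDA).

    ``constraints`` rows must align with ``dm.ids``.  The permutation p-value
    is (1 + #{F_perm >= F_obs}) / (1 + n_perm) under row permutation of the
    constraint matrix; deterministic given ``seed``.
    """
    if list(map(str, constraints.index)) != list(dm.ids):
        raise ValueError("constraint rows are not aligned with distance-matrix ids")
    if n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")
    eigvals, coords = pcoa(dm)
    pos = eigvals > max(1e-10 * abs(eigvals.iloc[0]), 0)
    y = coords.loc[:, pos.to_numpy()].to_numpy()
    n = y.shape[0]

    x = constraints.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    x, kept, dropped = _drop_collinear(x, list(constraints.columns))
    q = x.shape[1]
    if q == 0:
        raise ValueError("constraint matrix has rank 0 after centering")

    def _fit(xmat):
        beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
        return xmat @ beta

    fitted = _fit(x)
    total = float((y ** 2).sum())
    constrained = float((fitted ** 2).sum())
    resid = total - constrained
    df_resid = n - q - 1
    f_obs = (constrained / q) / (resid / df_resid)

    rng = stage_rng(seed, "cap_permutation")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        fp = _fit(x[perm])
        cp = float((fp ** 2).sum())
        f_perm = (cp / q) / ((total - cp) / df_resid)
        if f_perm >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)

    # eigen-analysis of the fitted values -> constrained axes
    u, s, _ = np.linalg.svd(fitted, full_matrices=False)
    lam = s ** 2
    n_axes = int(min(q, (lam > 1e-10 * max(lam[0], 1e-30)).sum()))
    axes = [f"CAP{i + 1}" for i in range(n_axes)]
    scores = pd.DataFrame((u[:, :n_axes] * s[:n_axes]), index=list(dm.ids),
                          columns=axes)
    biplot = pd.DataFrame(
        np.array([[_safe_corr(x[:, j], scores[a].to_numpy()) for a in axes]
                  for j in range(q)]),
        index=kept, columns=axes)
    return CapResult(
        eigenvalues=pd.Series(lam[:n_axes], index=axes, name="eigenvalue"),
        sample_scores=scores,
        biplot_scores=biplot,
        pseudo_f=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        total_inertia=total,
        constrained_inertia=constrained,
        dropped_constraints=dropped,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
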