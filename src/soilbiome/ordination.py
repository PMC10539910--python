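"""Constrained ordination: RDA, forward-selected conditional term effects, VPA.

Redundancy analysis regresses the (Hellinger-transformed, by default)
community matrix on z-scored environmental predictors and eigen-decomposes
the fitted values.  Conditional term effects enter predictors by forward
selection -- at each step the candidate adding the most explained variance --
and test the added variance with a permutation pseudo-F over residuals of the
reduced model.  Variation partitioning splits the community variance among
predictor sets via adjusted R^2 (Ezekiel) and inclusion-exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ValidationError

logger = logging.getLogger(__name__)


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Square root of row-wise relative abundances."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValidationError("Hellinger transform: sample with zero total")
    return np.sqrt(counts / totals)


def transform_community(counts: np.ndarray, how: str = "hellinger") -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if how == "hellinger":
        return hellinger(counts)
    if how == "log1p":
        return np.log1p(counts)
    if how == "none":
        return counts
    raise ValueError(f"unknown community transform {how!r}")


def _zscore(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError("zero-variance predictor column")
    return (X - X.mean(axis=0)) / sd


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns that are numerically linear combinations of earlier ones."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-10) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear predictor %r", names[j])
    return X[:, keep], [names[j] for j in keep]


def _fitted_ss(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """Sum of squares of fitted values of the regression of Yc on Xc (centred)."""
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    return float((fitted**2).sum())


@dataclass
class RdaResult:
    eigenvalues: np.ndarray
    explained_proportion: float
    site_scores: pd.DataFrame | None = None
    term_effects: pd.DataFrame | None = None


def rda(
    Y,
    X,
    community_transform: str = "hellinger",
    sample_ids: Sequence[str] | None = None,
) -> RdaResult:
    """Redundancy analysis of community matrix Y on predictors X."""
    Yt = transform_community(np.asarray(Y, dtype=float), community_transform)
    n = Yt.shape[0]
    if n < 3:
        raise ValidationError("RDA needs >= 3 samples")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xz = _zscore(np.asarray(X, dtype=float))
    Xz, _ = _drop_collinear(Xz, names)
    Yc = Yt - Yt.mean(axis=0)
    total_ss = float((Yc**2).sum())
    beta, *_ = np.linalg.lstsq(Xz, Yc, rcond=None)
    fitted = Xz @ beta
    # eigenvalues of the fitted covariance = squared singular values / (n-1)
    sv = np.linalg.svd(fitted, compute_uv=False)
    eig = (sv**2) / (n - 1)
    eig = eig[eig > 1e-12 * max(eig.max(), 1.0)]
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    k = len(eig)
    scores = pd.DataFrame(
        (u[:, :k] * s[:k]),
        index=list(sample_ids) if sample_ids is not None else range(n),
        columns=[f"RDA{i+1}" for i in range(k)],
    )
    return RdaResult(eig, float((fitted**2).sum()) / total_ss, scores)


def conditional_term_effects(
    Y,
    X: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    community_transform: str = "hellinger",
) -> pd.DataFrame:
    """Forward-selection conditional effects of each predictor.

    Returns one row per predictor in entry order with the conditional
    (added) explained variance as % of total community variance, the
    pseudo-F at entry, and its permutation p-value.  Ties in added variance
    break by column order for determinism.
    """
    rng = np.random.default_rng(seed)
    Yt = transform_community(np.asarray(Y, dtype=float), community_transform)
    Yc = Yt - Yt.mean(axis=0)
    n, q = Yc.shape
    names = list(X.columns)
    Xz = _zscore(np.asarray(X, dtype=float))
    Xz, names = _drop_collinear(Xz, list(names))
    total_ss = float((Yc**2).sum())

    selected: list[int] = []
    rows = []
    remaining = list(range(Xz.shape[1]))
    R = Yc.copy()  # residuals of Y on the selected predictors
    Xres = Xz.copy()  # candidates residualised on the selected predictors
    while remaining:
        # added SS for each remaining candidate given current residuals
        added = {}
        for j in remaining:
            xj = Xres[:, j]
            norm = float(xj @ xj)
            if norm < 1e-12:
                added[j] = 0.0
                continue
            s = xj @ R
            added[j] = float((s**2).sum()) / norm
        best = max(remaining, key=lambda j: (added[j], -j))
        xj = Xres[:, best]
        norm = float(xj @ xj)
        added_ss = added[best]
        df_res = n - 1 - (len(selected) + 1)
        rss_new = float((R**2).sum()) - added_ss
        f_obs = (added_ss / 1.0) / (rss_new / df_res) if df_res > 0 else np.inf

        # permutation of reduced-model residuals, vectorised over replicates
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        xp = xj[perms]  # (n_perm, n): permuting residual rows == permuting x
        S = xp @ R  # (n_perm, q)
        added_perm = (S**2).sum(axis=1) / norm if norm > 0 else np.zeros(n_perm)
        rss_perm = float((R**2).sum()) - added_perm
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = added_perm / (rss_perm / df_res)
        p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_perm)

        rows.append(
            {
                "term": names[best],
                "explains_pct": 100.0 * added_ss / total_ss,
                "pseudo_F": f_obs,
                "p": p,
            }
        )
        # update residuals: project out the entered candidate
        if norm > 0:
            proj = np.outer(xj, xj @ R) / norm
            R = R - proj
            coef = (xj @ Xres) / norm
            Xres = Xres - np.outer(xj, coef)
        selected.append(best)
        remaining.remove(best)
    return pd.DataFrame(rows).set_index("term")


def adjusted_r2(r2: float, n: int, n_pred: int) -> float:
    """Ezekiel's adjusted R^2; may be negative."""
    if n - n_pred - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_pred - 1)


def _set_r2(Yc: np.ndarray, Xz: np.ndarray, cols: Sequence[int], total_ss: float) -> tuple[float, int]:
    if not cols:  # empty predictor set explains nothing
        return 0.0, 0
    X = Xz[:, list(cols)]
    X, kept = _drop_collinear(X, [str(c) for c in cols])
    return _fitted_ss(Yc, X) / total_ss, X.shape[1]


@dataclass
class VpaResult:
    """Adjusted-R^2 variance partition over three predictor sets a, b, c."""

    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def residual(self) -> float:
        return self.fractions["residual"]

    def total(self) -> float:
        return sum(v for k, v in self.fractions.items() if k != "residual")


def vpa(
    Y,
    X: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    community_transform: str = "hellinger",
) -> VpaResult:
    """Three-set variation partitioning by inclusion-exclusion of adjusted R^2.

    ``sets`` maps set names (e.g. pH / macronutrient / micronutrient) to
    disjoint lists of predictor columns.  Fractions: unique(a), unique(b),
    unique(c), the three pairwise overlaps, the three-way overlap, and the
    residual; they sum to 1 exactly (identity of the decomposition).
    """
    if len(sets) != 3:
        raise ValidationError("vpa expects exactly three predictor sets")
    keys = list(sets)
    cols = {k: list(v) for k, v in sets.items()}
    flat = [c for v in cols.values() for c in v]
    if len(flat) != len(set(flat)):
        raise ValidationError("predictor sets overlap")
    Yt = transform_community(np.asarray(Y, dtype=float), community_transform)
    Yc = Yt - Yt.mean(axis=0)
    n = Yc.shape[0]
    total_ss = float((Yc**2).sum())
    Xz = _zscore(np.asarray(X[flat], dtype=float))
    index = {c: j for j, c in enumerate(flat)}

    def adj(union_keys: Sequence[str]) -> float:
        cset = [index[c] for k in union_keys for c in cols[k]]
        r2, npred = _set_r2(Yc, Xz, cset, total_ss)
        return adjusted_r2(r2, n, npred)

    a, b, c = keys
    A, B, C = adj([a]), adj([b]), adj([c])
    AB, AC, BC = adj([a, b]), adj([a, c]), adj([b, c])
    ABC = adj([a, b, c])
    # inclusion-exclusion for three sets
    ab = A + B - AB  # variance jointly in a and b (incl. triple)
    ac = A + C - AC
    bc = B + C - BC
    abc = A + B + C - AB - AC - BC + ABC
    f = {
        f"unique_{a}": ABC - BC,
        f"unique_{b}": ABC - AC,
        f"unique_{c}": ABC - AB,
        f"shared_{a}_{b}": ab - abc,
        f"shared_{a}_{c}": ac - abc,
        f"shared_{b}_{c}": bc - abc,
        f"shared_{a}_{b}_{c}": abc,
        "residual": 1.0 - ABC,
    }
    return VpaResult(f)
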