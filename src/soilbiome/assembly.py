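"""Community assembly inference: Sloan's neutral model and the null-model
(betaNTI / Raup-Crick) process classification.

Sloan's neutral community model (NCM) predicts a taxon's occurrence frequency
across local communities from its mean relative abundance p in the
metacommunity: at stationarity the local relative abundance of the taxon
follows Beta(Nm*p, Nm*(1-p)), where N is the local community size and m the
immigration probability, so the expected frequency of detection above a limit
d is 1 - BetaCDF(d; Nm*p, Nm*(1-p)).  The single free parameter Nm is fitted
by least squares to the observed frequency-abundance cloud.

The null-model route computes, per community pair, the abundance-weighted
beta mean-nearest-taxon distance (betaMNTD) and standardises it against a
taxa-label-shuffling null to give betaNTI, plus the Bray-Curtis Raup-Crick
metric (RCbray) against richness- and abundance-constrained random
assemblies.  Pairs are then classified: |betaNTI| > 2 -> selection
(heterogeneous if positive, homogeneous if negative); otherwise RCbray > 0.95
-> dispersal limitation, RCbray < -0.95 -> homogenizing dispersal, else
undominated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.proportion import proportion_confint

from .io_formats import OtuTable, ValidationError

logger = logging.getLogger(__name__)

BETANTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95

PROCESSES = [
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
]


# ---------------------------------------------------------------- Sloan NCM


def ncm_predict(p, Nm: float, d: float):
    """Expected detection frequency 1 - BetaCDF(d; Nm*p, Nm*(1-p)).

    Vectorised over metacommunity relative abundance ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValidationError("ncm_predict requires 0 < p < 1")
    if Nm <= 0 or not 0 < d < 1:
        raise ValidationError("require Nm > 0 and 0 < d < 1")
    out = stats.beta.sf(d, Nm * p, Nm * (1.0 - p))
    return float(out) if out.ndim == 0 else out


@dataclass
class NcmFit:
    Nm: float
    m: float
    N: float
    d: float
    r_squared: float
    per_otu: pd.DataFrame  # p, freq_obs, freq_pred, lower, upper, partition

    def summary(self) -> dict:
        part = self.per_otu["partition"].value_counts()
        return {
            "Nm": self.Nm,
            "m": self.m,
            "N": self.N,
            "detection_limit": self.d,
            "r_squared": self.r_squared,
            "n_otus_fit": int(len(self.per_otu)),
            "within_pct": 100.0 * int(part.get("within", 0)) / len(self.per_otu),
        }


def fit_occurrence_frequencies(p, freq, d: float) -> float:
    """Least-squares Nm for observed occurrence frequencies vs abundance.

    Single free parameter on [1, 1e7]: coarse log-spaced grid, then bounded
    local refinement around the grid optimum.
    """
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)

    def sse(log_nm: float) -> float:
        pred = stats.beta.sf(d, np.exp(log_nm) * p, np.exp(log_nm) * (1 - p))
        return float(((freq - pred) ** 2).sum())

    grid = np.log(np.logspace(0, 7, 49))
    best = min(grid, key=sse)
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        sse,
        bounds=(max(best - 2 * step, grid[0]), min(best + 2 * step, grid[-1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def ncm_fit(table: OtuTable, ci_alpha: float = 0.05) -> NcmFit:
    """Fit Sloan's NCM to an OTU table.

    N is the mean sample total count; the detection limit d = 1/N.  Nm is
    found on [1, 1e7] by a log-spaced grid search followed by bounded local
    refinement, minimising untransformed squared error between observed and
    predicted occurrence frequencies.
    """
    if table.n_samples < 10:
        raise ValidationError("NCM fit needs >= 10 samples")
    rel = table.relative_abundances()
    n_samples = table.n_samples
    N = float(table.counts.sum(axis=1).mean())
    d = 1.0 / N
    p = rel.mean(axis=0)
    freq = (table.counts > 0).mean(axis=0)
    ok = (p > 0) & (p < 1)
    if ok.sum() < 5:
        raise ValidationError("fewer than 5 OTUs with 0 < p < 1")
    p_fit, f_fit = p[ok], freq[ok]
    nm = fit_occurrence_frequencies(p_fit, f_fit, d)
    pred = ncm_predict(p_fit, nm, d)
    sst = float(((f_fit - f_fit.mean()) ** 2).sum())
    r2 = 1.0 - float(((f_fit - pred) ** 2).sum()) / sst if sst > 0 else float("nan")
    # binomial sampling envelope around the predicted frequency at n_samples
    lower, upper = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=ci_alpha, method="wilson"
    )
    partition = np.where(
        f_fit > upper, "above", np.where(f_fit < lower, "below", "within")
    )
    per_otu = pd.DataFrame(
        {
            "p": p_fit,
            "freq_obs": f_fit,
            "freq_pred": pred,
            "lower": lower,
            "upper": upper,
            "partition": partition,
        },
        index=[o for o, k in zip(table.otu_ids, ok) if k],
    )
    return NcmFit(nm, nm / N, N, d, r2, per_otu)


# ------------------------------------------------------- betaMNTD / betaNTI


def _patristic_matrix(tree: TreeNode, otu_ids: list[str]) -> np.ndarray:
    tips = {t.name for t in tree.tips()}
    missing = [o for o in otu_ids if o not in tips]
    if missing:
        raise ValidationError(f"OTUs absent from tree: {missing[:5]}")
    dm = tree.tip_tip_distances(endpoints=otu_ids)
    return np.asarray(dm.filter(otu_ids).data)


def _comdistnt(rel: np.ndarray, D: np.ndarray, weighted: bool) -> np.ndarray:
    """All-pairs betaMNTD given relative abundances and a patristic matrix."""
    present = rel > 0
    n = rel.shape[0]
    # dmin[s, i] = distance from taxon i to its nearest taxon present in sample s
    dmin = np.empty((n, rel.shape[1]))
    for s in range(n):
        dmin[s] = D[:, present[s]].min(axis=1)
    if weighted:
        F = rel
    else:
        F = present / present.sum(axis=1, keepdims=True)
    M = F @ dmin.T  # M[a, b] = mean distance from a's taxa to nearest in b
    return (M + M.T) / 2.0


def beta_mntd(
    table: OtuTable, tree: TreeNode, abundance_weighted: bool = True
) -> DistanceMatrix:
    """Abundance-weighted beta mean-nearest-taxon distance between samples."""
    D = _patristic_matrix(tree, list(table.otu_ids))
    rel = table.relative_abundances()
    M = _comdistnt(rel, D, abundance_weighted)
    np.fill_diagonal(M, 0.0)
    return DistanceMatrix(M, ids=table.sample_ids)


def beta_nti(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """betaNTI: z-score of observed betaMNTD against a taxa-shuffling null.

    The null shuffles taxa labels across the tree tips (equivalently,
    permutes rows/columns of the patristic matrix) and recomputes betaMNTD;
    pairs whose null distribution has zero spread get NaN and a warning.
    """
    rng = np.random.default_rng(seed)
    D = _patristic_matrix(tree, list(table.otu_ids))
    rel = table.relative_abundances()
    obs = _comdistnt(rel, D, abundance_weighted)
    n_otus = rel.shape[1]
    nulls = np.empty((n_null,) + obs.shape)
    for b in range(n_null):
        perm = rng.permutation(n_otus)
        nulls[b] = _comdistnt(rel, D[np.ix_(perm, perm)], abundance_weighted)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = (sd == 0) & ~np.eye(obs.shape[0], dtype=bool)
    if degenerate.any():
        logger.warning("betaNTI undefined for %d pairs (sd_null = 0)",
                       int(degenerate.sum()) // 2)
        z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    return DistanceMatrix(z, ids=table.sample_ids, validate=False)


# ------------------------------------------------------------- Raup-Crick


def _bray_curtis_counts(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.sum(), b.sum()
    if sa == 0 or sb == 0:
        raise ValidationError("Bray-Curtis undefined for an empty sample")
    return 1.0 - 2.0 * np.minimum(a, b).sum() / (sa + sb)


def raup_crick_bray(
    table: OtuTable, n_null: int = 999, seed: int = 0
) -> DistanceMatrix:
    """Raup-Crick metric with Bray-Curtis, rescaled to [-1, 1].

    Each null replicate rebuilds every sample with its observed richness
    (species drawn without replacement, probability proportional to occupancy
    across the analysed samples) and observed total abundance (individuals
    allocated multinomially, probability proportional to summed relative
    abundance), then the replicate's Bray-Curtis matrix is computed on
    counts.  RC = 2 * (P(BC_null < BC_obs) + 0.5 P(=) - 0.5) per pair.
    """
    rng = np.random.default_rng(seed)
    counts = table.counts
    n, m = counts.shape
    if n < 2:
        raise ValidationError("Raup-Crick needs >= 2 samples")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("sample with zero total count")
    richness = (counts > 0).sum(axis=1)
    occupancy = (counts > 0).sum(axis=0).astype(float)
    abund = table.relative_abundances().sum(axis=0)
    occ_p = occupancy / occupancy.sum()
    obs = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        obs[i, j] = obs[j, i] = _bray_curtis_counts(counts[i], counts[j])
    lt = np.zeros((n, n))
    eq = np.zeros((n, n))
    taxa = np.arange(m)
    for _ in range(n_null):
        null = np.zeros((n, m))
        for s in range(n):
            chosen = rng.choice(taxa, size=richness[s], replace=False, p=occ_p)
            w = abund[chosen]
            alloc = rng.multinomial(totals[s] - richness[s], w / w.sum())
            null[s, chosen] = 1 + alloc  # each drawn species keeps >= 1 individual
        for i, j in itertools.combinations(range(n), 2):
            bc = _bray_curtis_counts(null[i], null[j])
            if bc < obs[i, j] - 1e-12:
                lt[i, j] += 1
            elif abs(bc - obs[i, j]) <= 1e-12:
                eq[i, j] += 1
    rc = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    rc[iu] = ((lt[iu] + 0.5 * eq[iu]) / n_null - 0.5) * 2.0
    rc = rc + rc.T
    np.fill_diagonal(rc, 0.0)
    return DistanceMatrix(rc, ids=table.sample_ids, validate=False)


# ------------------------------------------------------ process classification


def classify_pair(bnti: float, rc: float) -> str:
    if np.isnan(bnti) or np.isnan(rc):
        return "unclassified"
    if bnti > BETANTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti < -BETANTI_THRESHOLD:
        return "homogeneous_selection"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


@dataclass
class AssemblyResult:
    pairs: pd.DataFrame  # sample_a, sample_b, group, betaNTI, RCbray, process
    fractions: pd.DataFrame  # per group: fraction of each process

    def stochastic_fraction(self, group: str) -> float:
        """Share of pairs not attributed to selection (|betaNTI| <= 2)."""
        sub = self.pairs[self.pairs["group"] == group]
        return float((sub["betaNTI"].abs() <= BETANTI_THRESHOLD).mean())


def classify_assembly(
    bnti: DistanceMatrix,
    rc: DistanceMatrix,
    groups: pd.Series,
    bc: DistanceMatrix | None = None,
    bmntd: DistanceMatrix | None = None,
) -> AssemblyResult:
    """Classify within-group sample pairs into the five assembly processes."""
    ids = list(bnti.ids)
    if set(ids) != set(rc.ids):
        raise ValidationError("betaNTI and RCbray sample ids differ")
    rc = rc.filter(ids)
    rows = []
    excluded = 0
    for a, b in itertools.combinations(ids, 2):
        ga, gb = groups.get(a), groups.get(b)
        if ga is None or gb is None or ga != gb:
            continue
        z = float(bnti[a, b])
        r = float(rc[a, b])
        proc = classify_pair(z, r)
        if proc == "unclassified":
            excluded += 1
        row = {"sample_a": a, "sample_b": b, "group": ga,
               "betaNTI": z, "RCbray": r, "process": proc}
        if bmntd is not None:
            row["betaMNTD"] = float(bmntd[a, b])
        if bc is not None:
            row["BC"] = float(bc[a, b])
        rows.append(row)
    if excluded:
        logger.warning("%d pairs excluded (undefined betaNTI or RCbray)", excluded)
    pairs = pd.DataFrame(rows)
    fr = {}
    for g, sub in pairs[pairs["process"] != "unclassified"].groupby("group"):
        counts = sub["process"].value_counts()
        fr[g] = {p: float(counts.get(p, 0)) / len(sub) for p in PROCESSES}
    fractions = pd.DataFrame.from_dict(fr, orient="index").fillna(0.0)
    return AssemblyResult(pairs, fractions)
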