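"""Alpha diversity, dissimilarity, NMDS, group tests and distance decay.

Counts are used raw for alpha diversity (Shannon in nats, bias-corrected
Chao1); Bray-Curtis works on relative abundances.  An optional rarefaction
helper subsamples without replacement for users who want equal depths.
Permutation tests (ANOSIM, Mantel) use the (1+b)/(1+m) p-value estimator so
p is never exactly zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import shannon as _shannon
from skbio.stats.distance import anosim as _anosim
from skbio.stats.distance import mantel as _mantel
from sklearn.manifold import MDS

from .io_formats import ChemistryTable, OtuTable, ValidationError

logger = logging.getLogger(__name__)


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValidationError("Shannon undefined for an all-zero sample")
    return float(_shannon(counts, base=np.e))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValidationError("Chao1 undefined for an all-zero sample")
    return float(_chao1(counts, bias_corrected=True))


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon (nats) and bias-corrected Chao1."""
    rows = {
        s: {"shannon": shannon(row), "chao1": chao1(row)}
        for s, row in zip(table.sample_ids, table.counts)
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    Samples shallower than ``depth`` are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    keep, rows = [], []
    for s, row in zip(table.sample_ids, table.counts):
        total = int(row.sum())
        if total < depth:
            logger.warning("dropping sample %s: depth %d < %d", s, total, depth)
            continue
        pool = np.repeat(np.arange(table.n_otus), row)
        chosen = rng.choice(pool, size=depth, replace=False)
        rows.append(np.bincount(chosen, minlength=table.n_otus))
        keep.append(s)
    if not keep:
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    return OtuTable(keep, list(table.otu_ids), np.array(rows), table.taxonomy)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on relative abundances."""
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs at least 2 samples")
    rel = table.relative_abundances()
    return beta_diversity("braycurtis", rel, ids=table.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centred
    stress: float  # Kruskal stress-1
    converged: bool
    n_restarts: int


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS of a distance matrix; best of ``n_restarts`` starts."""
    n = dm.shape[0]
    if k > n - 1:
        raise ValidationError(f"k={k} must be <= n-1 = {n - 1}")
    model = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        n_init=n_restarts,
        init="random",
        max_iter=max_iter,
        eps=tol,
        normalized_stress=True,
        random_state=seed % (2**32),
    )
    coords = model.fit_transform(np.asarray(dm.data))
    coords = coords - coords.mean(axis=0)
    converged = model.n_iter_ < max_iter
    if not converged:
        logger.warning("NMDS did not converge in %d iterations", max_iter)
    return OrdinationResult(
        pd.DataFrame(
            coords, index=list(dm.ids), columns=[f"NMDS{i+1}" for i in range(k)]
        ),
        float(model.stress_),  # normalized_stress=True -> already stress-1
        bool(converged),
        n_restarts,
    )


def anosim(
    dm: DistanceMatrix, groups: Sequence[str], n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """ANOSIM R and its permutation p-value."""
    groups = list(groups)
    counts = pd.Series(groups).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValidationError("ANOSIM needs >= 2 groups with >= 2 members each")
    res = _anosim(dm, groups, permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with matched ids."""
    if set(d1.ids) != set(d2.ids):
        raise ValidationError("Mantel requires matching sample ids")
    d2 = d2.filter(d1.ids)
    r, p, _ = _mantel(d1, d2, method=method, permutations=n_perm, seed=seed)
    return float(r), float(p)


def env_distance(
    chem: ChemistryTable, variables: Sequence[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance on z-scored chemistry variables."""
    df = chem.indicators(variables) if variables else chem.data.select_dtypes("number")
    if len(df) < 2:
        raise ValidationError("environmental distance needs >= 2 samples")
    sd = df.std(ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        logger.warning("dropping zero-variance variables: %s", list(constant))
        df = df.drop(columns=constant)
        sd = sd.drop(index=constant)
    z = (df - df.mean()) / sd
    from scipy.spatial.distance import pdist, squareform

    return DistanceMatrix(squareform(pdist(z.to_numpy())), ids=[str(i) for i in df.index])


def distance_decay(
    d_comm: DistanceMatrix,
    d_env: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group slope of community dissimilarity against environmental distance.

    The slope comes from least squares over within-group pairs; significance
    from a Mantel test on the group's submatrices.
    """
    out = {}
    for g in sorted(groups.unique()):
        ids = [str(s) for s in groups.index[groups == g]]
        if len(ids) < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 samples")
        sub_c = d_comm.filter(ids)
        sub_e = d_env.filter(ids)
        x = sub_e.condensed_form()
        y = sub_c.condensed_form()
        fit = stats.linregress(x, y)
        r, p = mantel(sub_c, sub_e, method="pearson", n_perm=n_perm, seed=seed)
        out[g] = {"slope": fit.slope, "intercept": fit.intercept, "r": r, "p": p,
                  "n_pairs": len(x)}
    return pd.DataFrame.from_dict(out, orient="index")


def group_compare_lsd(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA with Fisher's LSD pairwise tests and a letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    Letters are the maximal cliques of the "not significantly different"
    graph, ordered by descending group mean.
    """
    groups = groups.loc[values.index]
    names = sorted(groups.unique())
    if len(names) < 2:
        raise ValidationError("need >= 2 groups")
    samples = {g: values[groups == g].to_numpy(dtype=float) for g in names}
    sizes = {g: len(v) for g, v in samples.items()}
    if min(sizes.values()) < 2:
        small = min(sizes, key=sizes.get)
        raise ValidationError(f"group {small!r} has fewer than 2 members")
    f_stat, anova_p = stats.f_oneway(*samples.values())
    # pooled error variance for LSD t-tests
    n_total = sum(sizes.values())
    df_err = n_total - len(names)
    mse = sum(((v - v.mean()) ** 2).sum() for v in samples.values()) / df_err
    pmat = pd.DataFrame(1.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(mse * (1 / sizes[a] + 1 / sizes[b]))
        t = (samples[a].mean() - samples[b].mean()) / se if se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), df_err) if se > 0 else 1.0
        pmat.loc[a, b] = pmat.loc[b, a] = p
    # letter display via maximal cliques of the non-significance graph
    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        if pmat.loc[a, b] >= alpha:
            g.add_edge(a, b)
    means = {name: samples[name].mean() for name in names}
    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(g)),
        key=lambda c: -max(means[m] for m in c),
    )
    letters = {name: "" for name in names}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for member in clique:
            letters[member] += letter
    return pd.DataFrame(
        {
            "mean": [means[g_] for g_ in names],
            "n": [sizes[g_] for g_ in names],
            "letters": [letters[g_] for g_ in names],
            "anova_F": f_stat,
            "anova_p": anova_p,
        },
        index=names,
    )
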