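"""Synthetic study generator: chemistry, phylogeny and OTU tables with known
fertility structure and known assembly regime.

The chemistry generator draws per-sample values around group profiles
(defaults follow the observed LF/MF/HF means and standard errors of a
123-field soil survey, SE converted to per-sample SD at the default group
size).  The phylogeny is a pure-birth tree scaled to height 1 with per-tip
environmental optima evolved by Brownian motion, so selection on the
environment leaves a phylogenetic signal.  Communities are assembled under
one of three regimes:

* ``neutral`` -- Sloan's stationary approximation: each sample's composition
  is Dirichlet(N*m*p) around the metacommunity p, then N individuals are
  drawn multinomially;
* ``selection`` -- sampling weights p_i * exp(-(env_s - optimum_i)^2 /
  (2 sigma^2)), renormalised, then multinomial N;
* ``dispersal_limited`` -- each sample draws from a spatially autocorrelated
  local metacommunity (log-Gaussian field per OTU with an exponential
  spatial kernel), so community similarity decays with distance.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .io_formats import (
    ChemistryTable,
    OtuTable,
    ValidationError,
    write_chemistry,
    write_otu_table,
    write_tree,
)

#: LF/MF/HF chemistry profiles: (mean, standard error) per variable
GROUP_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "LF": {
        "SOM": (22.9, 2.24), "pH": (6.19, 0.17), "TN": (1.29, 0.12),
        "AN": (85.57, 9.09), "AP": (28.59, 4.13), "AK": (206.54, 16.49),
        "WSCa": (66.26, 9.53), "WSMg": (21.63, 2.57), "WSCl": (0.15, 0.01),
        "ACu": (2.26, 0.4), "AZn": (1.98, 0.24), "AFe": (65.14, 16.11),
        "AMn": (36.12, 4.81),
    },
    "MF": {
        "SOM": (21.82, 0.96), "pH": (6.43, 0.17), "TN": (1.23, 0.04),
        "AN": (81.09, 3.74), "AP": (36.06, 3.86), "AK": (272.59, 20.31),
        "WSCa": (102.46, 10.2), "WSMg": (24.16, 1.91), "WSCl": (0.13, 0.01),
        "ACu": (1.62, 0.18), "AZn": (1.95, 0.23), "AFe": (37.41, 4.58),
        "AMn": (42.5, 4.78),
    },
    "HF": {
        "SOM": (23.97, 0.82), "pH": (6.82, 0.16), "TN": (1.25, 0.04),
        "AN": (75.26, 1.75), "AP": (57.59, 4.85), "AK": (303.85, 25.04),
        "WSCa": (78.24, 9.84), "WSMg": (25.97, 3.12), "WSCl": (0.15, 0.04),
        "ACu": (1.62, 0.14), "AZn": (2.39, 0.33), "AFe": (30.45, 3.07),
        "AMn": (32.1, 3.67),
    },
}

#: group size used to convert a profile SE into a per-sample SD (123/3)
DEFAULT_GROUP_N = 41

#: target metacommunity abundance shares per phylum (dominant three > 60%)
PHYLUM_SHARES = {
    "Proteobacteria": 0.30,
    "Acidobacteria": 0.20,
    "Actinobacteria": 0.15,
    "Chloroflexi": 0.10,
    "Bacteroidetes": 0.08,
    "Firmicutes": 0.07,
    "Gemmatimonadetes": 0.05,
    "Verrucomicrobia": 0.05,
}


@dataclass
class MetaCommunity:
    otu_ids: list[str]
    p: np.ndarray  # relative abundances, sum 1
    optima: np.ndarray  # per-OTU environmental optimum

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValidationError("metacommunity abundances must sum to 1")
        if (self.p <= 0).any():
            raise ValidationError("metacommunity abundances must be positive")


@dataclass
class ScenarioConfig:
    n_samples: int = 30
    n_otus: int = 150
    N: int = 10_000  # local community size (individuals)
    m: float = 0.5  # immigration probability per birth
    regime: str = "neutral"  # neutral | selection | dispersal_limited
    sigma: float = 0.5  # environmental-filter width (selection)
    decay_length: float = 0.2  # spatial decay length (dispersal_limited)
    field_sd: float = 1.5  # log-scale amplitude of the spatial field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if not 0 < self.m <= 1:
            raise ValidationError("m must lie in (0, 1]")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")
        if self.regime not in {"neutral", "selection", "dispersal_limited"}:
            raise ValidationError(f"unknown regime {self.regime!r}")


def simulate_chemistry(
    n_samples: int,
    group_profiles: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    group_n_for_sd: int = DEFAULT_GROUP_N,
) -> ChemistryTable:
    """Draw per-sample chemistry around group profiles.

    Profiles are (mean, SE) per variable; per-sample SD = SE * sqrt(n_group).
    Samples are split as evenly as possible across the profiles, draws are
    truncated at 0 and pH is clipped into (0, 14); the group label is kept.
    """
    if n_samples <= 0:
        raise ValidationError("n_samples must be positive")
    profiles = group_profiles or GROUP_PROFILES
    rng = np.random.default_rng(seed)
    names = list(profiles)
    sizes = [n_samples // len(names)] * len(names)
    for i in range(n_samples - sum(sizes)):
        sizes[i] += 1
    rows, labels, ids = [], [], []
    k = 0
    for gname, size in zip(names, sizes):
        prof = profiles[gname]
        for _ in range(size):
            row = {}
            for var, (mean, se) in prof.items():
                sd = se * np.sqrt(group_n_for_sd)
                x = rng.normal(mean, sd)
                if var == "pH":
                    x = float(np.clip(x, 1e-6, 14 - 1e-6))
                else:
                    x = max(x, 0.0)
                row[var] = x
            rows.append(row)
            labels.append(gname)
            ids.append(f"S{k:03d}")
            k += 1
    df = pd.DataFrame(rows, index=ids)
    return ChemistryTable(df, group=pd.Series(labels, index=ids, name="group"))


def simulate_tree(
    n_otus: int, seed: int = 0, brownian_sd: float = 1.0
) -> tuple[TreeNode, pd.Series]:
    """Pure-birth tree (height 1) plus Brownian per-tip environmental optima.

    The optimum starts at 0 at the root and accumulates N(0, sd^2 * t) along
    branches, so closely related OTUs share similar optima (phylogenetic
    signal, the precondition for selection to register on betaNTI).
    """
    if n_otus < 2:
        raise ValidationError("need at least 2 OTUs")
    dtree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_otus,
        rng=random.Random(seed),
    )
    dtree.seed_node.edge.length = 0.0
    # scale to height 1 (pure-birth trees on extant tips are ultrametric)
    depths = dtree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= height
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i:04d}"
    rng = np.random.default_rng(seed + 1)
    optima: dict[str, float] = {}
    values = {dtree.seed_node: 0.0}
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        t = node.edge.length or 0.0
        values[node] = values[node.parent_node] + rng.normal(0, brownian_sd * np.sqrt(t))
        if node.is_leaf():
            optima[node.taxon.label] = values[node]
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    opt = pd.Series(optima, name="optimum").sort_index()
    return tree, opt


def lognormal_metacommunity(
    otu_ids: list[str], optima: pd.Series, seed: int = 0, sigma_log: float = 1.5
) -> MetaCommunity:
    """Ranked lognormal species-abundance distribution over the OTUs."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=sigma_log, size=len(otu_ids))
    p = raw / raw.sum()
    return MetaCommunity(list(otu_ids), p, optima.loc[list(otu_ids)].to_numpy())


def assign_phyla(
    tree: TreeNode, meta: MetaCommunity, shares: dict[str, float] | None = None
) -> dict[str, str]:
    """Assign phylum labels to tip clades so the dominant phyla dominate.

    Tips in tree (post-order) traversal order are cut into contiguous blocks
    whose cumulative metacommunity abundance matches the target shares;
    contiguity in traversal order keeps phyla phylogenetically coherent.
    """
    shares = shares or PHYLUM_SHARES
    order = [t.name for t in tree.tips()]
    p = pd.Series(meta.p, index=meta.otu_ids).loc[order].to_numpy()
    cum = np.cumsum(p)
    bounds = np.cumsum(list(shares.values()))
    names = list(shares)
    taxonomy = {}
    for otu, c in zip(order, cum):
        idx = int(np.searchsorted(bounds, min(c, bounds[-1]) - 1e-12))
        taxonomy[otu] = names[min(idx, len(names) - 1)]
    return taxonomy


def simulate_communities(
    meta: MetaCommunity,
    cfg: ScenarioConfig,
    env: pd.Series | None = None,
    coords: pd.DataFrame | None = None,
    sample_ids: list[str] | None = None,
) -> OtuTable:
    """Assemble local communities under the configured regime."""
    rng = np.random.default_rng(cfg.seed)
    n, m_otus = cfg.n_samples, len(meta.otu_ids)
    ids = sample_ids or [f"S{i:03d}" for i in range(n)]
    counts = np.zeros((n, m_otus), dtype=np.int64)
    if cfg.regime == "neutral":
        alpha = cfg.N * cfg.m * meta.p
        for s in range(n):
            comp = rng.dirichlet(alpha)
            counts[s] = rng.multinomial(cfg.N, comp)
    elif cfg.regime == "selection":
        if env is None:
            raise ValidationError("selection regime needs per-sample env values")
        env_vals = np.asarray(env, dtype=float)[:n]
        for s in range(n):
            w = meta.p * np.exp(
                -((env_vals[s] - meta.optima) ** 2) / (2 * cfg.sigma**2)
            )
            total = w.sum()
            if total <= 0:
                raise ValidationError("selection weights vanished; widen sigma")
            counts[s] = rng.multinomial(cfg.N, w / total)
    else:  # dispersal_limited
        if coords is None:
            raise ValidationError("dispersal_limited regime needs coordinates")
        xy = np.asarray(coords, dtype=float)[:n]
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        K = np.exp(-d / cfg.decay_length)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        z = L @ rng.standard_normal((n, m_otus))  # correlated field per OTU
        w = meta.p[None, :] * np.exp(cfg.field_sd * z)
        w /= w.sum(axis=1, keepdims=True)
        for s in range(n):
            counts[s] = rng.multinomial(cfg.N, w[s])
    return OtuTable(ids, list(meta.otu_ids), counts)


def random_coords(n: int, seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.uniform(0, 1, size=(n, 2)),
        index=[f"S{i:03d}" for i in range(n)],
        columns=["x", "y"],
    )


@dataclass
class Scenario:
    """A complete generated input set plus its ground truth."""

    chemistry: ChemistryTable
    tree: TreeNode
    optima: pd.Series
    table: OtuTable
    coords: pd.DataFrame
    truth: dict = field(default_factory=dict)


def simulate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Generate chemistry, tree, metacommunity and communities in one go.

    The selection regime's environmental axis is the z-scored simulated pH.
    """
    chem = simulate_chemistry(cfg.n_samples, seed=cfg.seed)
    tree, optima = simulate_tree(cfg.n_otus, seed=cfg.seed + 10)
    meta = lognormal_metacommunity(
        [t.name for t in tree.tips()], optima, seed=cfg.seed + 20
    )
    taxonomy = assign_phyla(tree, meta)
    coords = random_coords(cfg.n_samples, seed=cfg.seed + 30)
    env = None
    if cfg.regime == "selection":
        ph = chem.data["pH"]
        z = (ph - ph.mean()) / ph.std(ddof=1)
        # spread optima scale onto the z-scored axis
        env = pd.Series(
            np.asarray(z) * np.std(meta.optima), index=chem.sample_ids
        )
    table = simulate_communities(
        meta, cfg, env=env, coords=coords, sample_ids=chem.sample_ids
    )
    table.taxonomy = taxonomy
    truth = {
        "regime": cfg.regime,
        "n_samples": cfg.n_samples,
        "n_otus": cfg.n_otus,
        "N": cfg.N,
        "m": cfg.m,
        "Nm": cfg.N * cfg.m,
        "sigma": cfg.sigma,
        "decay_length": cfg.decay_length,
        "seed": cfg.seed,
    }
    return Scenario(chem, tree, optima, table, coords, truth)


FIXTURES: dict[str, ScenarioConfig] = {
    "tiny": ScenarioConfig(n_samples=6, n_otus=10, N=200, m=0.5,
                           regime="neutral", seed=7),
    "neutral_demo": ScenarioConfig(n_samples=30, n_otus=150, N=10_000, m=0.5,
                                   regime="neutral", seed=11),
    "selection_demo": ScenarioConfig(n_samples=30, n_otus=150, N=10_000, m=0.5,
                                     regime="selection", sigma=0.5, seed=11),
    "dispersal_demo": ScenarioConfig(n_samples=30, n_otus=150, N=10_000, m=0.5,
                                     regime="dispersal_limited",
                                     decay_length=0.2, seed=11),
}


def make_fixture(name: str, out_dir: str | Path) -> Path:
    """Write a complete small input set (chemistry, tree, OTU table, coords,
    taxonomy, truth JSON) for one named scenario."""
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {list(FIXTURES)}")
    cfg = FIXTURES[name]
    sc = simulate_scenario(cfg)
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    write_chemistry(sc.chemistry, out / "chemistry.tsv")
    write_tree(sc.tree, out / "tree.nwk")
    write_otu_table(sc.table, out / "otu_table.tsv")
    sc.coords.rename_axis("sample_id").to_csv(out / "coords.tsv", sep="\t")
    tax = pd.Series(sc.table.taxonomy, name="phylum").rename_axis("otu_id")
    tax.to_csv(out / "taxonomy.tsv", sep="\t")
    (out / "truth.json").write_text(json.dumps(sc.truth, indent=2, sort_keys=True))
    return out
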