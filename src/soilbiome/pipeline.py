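"""End-to-end orchestration: fertility scoring -> grouping -> per-group
diversity, ordination, networks and assembly inference, from one config.

A single global seed deterministically derives per-stage seeds by hashing the
stage name, so any stage can be rerun in isolation and reproduce the full
run's numbers.
"""

from __future__ import annotations

import json
import logging
import tomllib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, diversity, fertility, network, ordination
from .io_formats import (
    ChemistryTable,
    OtuTable,
    read_chemistry,
    read_otu_table,
    read_tree,
    write_results,
)

logger = logging.getLogger(__name__)

MACRO_SET = ["SOM", "TN", "AN", "AP", "AK", "WSCa", "WSMg"]
MICRO_SET = ["WSCl", "ACu", "AZn", "AFe", "AMn"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (global_seed ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    otu_table: str
    chemistry: str
    tree: str | None = None
    taxonomy: str | None = None
    coords: str | None = None
    orientation: str = "otus_as_rows"
    lf_cutoff: float = 0.55
    hf_cutoff: float = 0.75
    rho_min: float = 0.6
    p_max: float = 0.001
    min_prevalence: float = 1 / 3
    n_null: int = 999
    n_perm: int = 999
    rarefy_depth: int | None = None
    seed: int = 0
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        if not 0 < self.lf_cutoff < self.hf_cutoff < 1:
            raise ValueError("fertility cutoffs must satisfy 0 < LF < HF < 1")
        if not 0 < self.rho_min < 1 or not 0 < self.p_max < 1:
            raise ValueError("network thresholds out of range")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        raw = tomllib.loads(Path(path).read_text())
        flat: dict = {}
        for section in ("inputs", "thresholds", "nulls"):
            flat.update(raw.get(section, {}))
        flat.update({k: v for k, v in raw.items() if not isinstance(v, dict)})
        return cls(**flat)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns (and writes) the summary bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "load"
    try:
        table = read_otu_table(
            config.otu_table, orientation=config.orientation,
            taxonomy_path=config.taxonomy,
        )
        chem = read_chemistry(config.chemistry)
        tree = read_tree(config.tree, require_lengths=True) if config.tree else None
        shared = [s for s in chem.sample_ids if s in table.sample_ids]
        if len(shared) < len(chem.sample_ids) or len(shared) < table.n_samples:
            logger.warning("restricting to %d shared samples", len(shared))
        table = table.select_samples(shared)
        chem = ChemistryTable(chem.data.loc[shared], group=None)
        if config.rarefy_depth:
            stage = "rarefy"
            table = diversity.rarefy(
                table, config.rarefy_depth, stage_seed(config.seed, "rarefy")
            )
            chem = ChemistryTable(chem.data.loc[table.sample_ids], group=None)

        stage = "fertility"
        fert = fertility.score_chemistry(chem)
        groups = fert.classes
        write_results(
            {
                "fertility": fert.to_frame(),
                "weights": fert.weights,
                "ifi_range": [float(fert.ifi.min()), float(fert.ifi.max())],
                "class_boundaries": {"LF_below": config.lf_cutoff,
                                     "HF_at_or_above": config.hf_cutoff},
            },
            out / "fertility", seed=config.seed,
        )
        summary["fertility"] = {
            "ifi_min": float(fert.ifi.min()),
            "ifi_max": float(fert.ifi.max()),
            "class_counts": groups.value_counts().to_dict(),
        }
        usable = [g for g, c in groups.value_counts().items() if c >= 3]

        stage = "diversity"
        alpha = diversity.alpha_diversity(table)
        bc = diversity.bray_curtis(table)
        seed_div = stage_seed(config.seed, "diversity")
        results_div: dict = {"alpha": alpha}
        lsd = {}
        if len(usable) >= 2:
            for metric in ("shannon", "chao1"):
                lsd[metric] = diversity.group_compare_lsd(
                    alpha[metric], groups.loc[alpha.index]
                )
            nm = diversity.nmds(bc, seed=seed_div)
            r, p = diversity.anosim(
                bc, list(groups.loc[list(bc.ids)]), n_perm=config.n_perm,
                seed=seed_div,
            )
            summary["anosim"] = {"R": r, "p": p}
            summary["nmds_stress"] = nm.stress
            results_div["nmds"] = nm.coordinates
            results_div["lsd_shannon"] = lsd["shannon"]
            results_div["lsd_chao1"] = lsd["chao1"]
            results_div["anosim"] = summary["anosim"]
        d_env = diversity.env_distance(chem)
        decay = diversity.distance_decay(
            bc, d_env, groups, n_perm=config.n_perm, seed=seed_div
        ) if all(groups.value_counts() >= 3) else None
        if decay is not None:
            results_div["distance_decay"] = decay
            summary["distance_decay"] = decay.to_dict(orient="index")
        results_div["bray_curtis"] = bc.to_data_frame()
        write_results(results_div, out / "diversity", seed=seed_div)

        stage = "ordination"
        seed_ord = stage_seed(config.seed, "ordination")
        env_cols = [c for c in chem.data.columns
                    if c in ["pH"] + MACRO_SET + MICRO_SET]
        X = chem.data[env_cols].astype(float)
        effects = ordination.conditional_term_effects(
            table.counts, X, n_perm=config.n_perm, seed=seed_ord
        )
        summary["rda_conditional_effects"] = effects.to_dict(orient="index")
        vpa_results = {}
        sets = {"pH": ["pH"],
                "macro": [c for c in MACRO_SET if c in env_cols],
                "micro": [c for c in MICRO_SET if c in env_cols]}
        for g in usable:
            ids = list(groups.index[groups == g])
            if len(ids) < len(env_cols) + 3:
                logger.warning(
                    "VPA skipped for group %s: %d samples < %d predictors + 3",
                    g, len(ids), len(env_cols),
                )
                continue
            vr = ordination.vpa(
                table.select_samples(ids).counts, X.loc[ids], sets
            )
            vpa_results[g] = vr.fractions
        summary["vpa"] = vpa_results
        write_results(
            {"conditional_effects": effects, "vpa": vpa_results},
            out / "ordination", seed=seed_ord,
        )

        stage = "network"
        seed_net = stage_seed(config.seed, "network")
        summary["network"] = {}
        for g in usable:
            ids = list(groups.index[groups == g])
            sub = table.select_samples(ids)
            try:
                net, roles, props = network.build_network(
                    sub, min_prevalence=config.min_prevalence,
                    rho_min=config.rho_min, p_max=config.p_max, seed=seed_net,
                )
            except Exception as exc:  # a group may be too sparse to network
                logger.warning("network skipped for group %s: %s", g, exc)
                continue
            summary["network"][g] = props
            write_results(
                {"edges": net.edge_table(), "roles": roles, "properties": props},
                out / "network" / g, seed=seed_net,
            )

        stage = "assembly"
        seed_asm = stage_seed(config.seed, "assembly")
        summary["ncm"] = {}
        for g in usable:
            ids = list(groups.index[groups == g])
            sub = table.select_samples(ids)
            if sub.n_samples >= 10:
                fit = assembly.ncm_fit(sub)
                summary["ncm"][g] = fit.summary()
                write_results(
                    {"ncm_per_otu": fit.per_otu, "ncm": fit.summary()},
                    out / "assembly" / g, seed=seed_asm,
                )
        if tree is not None:
            bnti = assembly.beta_nti(
                table, tree, n_null=config.n_null, seed=seed_asm
            )
            rc = assembly.raup_crick_bray(
                table, n_null=config.n_null, seed=seed_asm + 1
            )
            res = assembly.classify_assembly(bnti, rc, groups, bc=bc)
            summary["assembly_fractions"] = res.fractions.to_dict(orient="index")
            write_results(
                {"pairs": res.pairs, "fractions": res.fractions},
                out / "assembly", seed=seed_asm,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str)
    )
    return summary
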