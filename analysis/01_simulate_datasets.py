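#!/usr/bin/env python
"""Generate the synthetic datasets every later analysis step consumes.

Writes three complete input sets under results/data/:

* ``survey``  -- 60 fields, 150 OTUs, environmental selection on pH: the
  stand-in for a regional soil survey with fertility structure.
* ``neutral`` -- 30 samples assembled purely by drift and immigration.
* ``dispersal`` -- 30 samples with spatially limited dispersal.

Each directory holds chemistry.tsv, tree.nwk, otu_table.tsv, coords.tsv,
taxonomy.tsv and truth.json (the generating parameters).
"""

import json
from pathlib import Path

import pandas as pd

from soilbiome.io_formats import write_chemistry, write_otu_table, write_tree
from soilbiome.synthetic_data import ScenarioConfig, simulate_scenario

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

CONFIGS = {
    "survey": ScenarioConfig(n_samples=60, n_otus=150, N=10_000, m=0.5,
                             regime="selection", sigma=0.5, seed=17),
    "neutral": ScenarioConfig(n_samples=30, n_otus=150, N=10_000, m=0.5,
                              regime="neutral", seed=11),
    "dispersal": ScenarioConfig(n_samples=30, n_otus=150, N=10_000, m=0.5,
                                regime="dispersal_limited", decay_length=0.2,
                                seed=11),
}


def main() -> None:
    for name, cfg in CONFIGS.items():
        sc = simulate_scenario(cfg)
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        write_chemistry(sc.chemistry, d / "chemistry.tsv")
        write_tree(sc.tree, d / "tree.nwk")
        write_otu_table(sc.table, d / "otu_table.tsv")
        sc.coords.rename_axis("sample_id").to_csv(d / "coords.tsv", sep="\t")
        pd.Series(sc.table.taxonomy, name="phylum").rename_axis("otu_id").to_csv(
            d / "taxonomy.tsv", sep="\t"
        )
        (d / "truth.json").write_text(json.dumps(sc.truth, indent=2, sort_keys=True))
        print(f"{name}: {cfg.n_samples} samples x {cfg.n_otus} OTUs, "
              f"regime={cfg.regime} -> {d}")


if __name__ == "__main__":
    main()
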