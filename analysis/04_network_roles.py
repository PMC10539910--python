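#!/usr/bin/env python
"""Per-fertility-class co-occurrence networks, modules and Zi-Pi roles.

Builds a Spearman network (|rho| > 0.6, p < 0.001, prevalence >= 1/3) for
every fertility class of the survey, detects modules, assigns node roles
and prints the summary property table.
"""

from pathlib import Path

import pandas as pd

from soilbiome import network
from soilbiome.fertility import score_chemistry
from soilbiome.io_formats import read_chemistry, read_otu_table, write_results

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data" / "survey"
    table = read_otu_table(data / "otu_table.tsv",
                           taxonomy_path=data / "taxonomy.tsv")
    chem = read_chemistry(data / "chemistry.tsv")
    table = table.select_samples(chem.sample_ids)
    groups = score_chemistry(chem).classes

    all_props = {}
    for g in sorted(groups.unique()):
        sub = table.select_samples(list(groups.index[groups == g]))
        net, roles, props = network.build_network(sub)
        all_props[g] = props
        write_results(
            {"edges": net.edge_table(), "roles": roles, "properties": props},
            ROOT / "network" / g,
        )
    summary = pd.DataFrame(all_props)
    keep = ["nodes", "links", "average_degree", "average_path_distance",
            "modules", "modularity", "positive_pct", "negative_pct",
            "peripheral", "module_hub", "connector", "network_hub"]
    print("co-occurrence network properties by fertility class:")
    print(summary.loc[keep].round(3).to_string())


if __name__ == "__main__":
    main()
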