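# soilbiome

Soil bacterial communities respond to the overall fertility of the soil they
live in, and disentangling *why* communities differ — deterministic
environmental selection versus stochastic drift and dispersal — requires a
chain of analyses that is usually scattered across half a dozen tools.
`soilbiome` packages that chain end to end for soil survey data:

1. **Fertility scoring.** Six indicators (SOM, pH, TN, AN, AP, AK) are mapped
   to fuzzy membership values `N_i ∈ [0.1, 1.0]` by piecewise-linear S-type or
   parabola-type functions, weighted by PCA-derived weights `W_i` (Σ W_i = 1),
   and combined into an integrated fertility index `IFI = Σ W_i N_i`. Fields
   are classed LF (IFI < 0.55), MF ([0.55, 0.75)) or HF (≥ 0.75).
2. **Diversity & ordination.** Shannon (nats) and bias-corrected Chao1,
   Bray–Curtis dissimilarity, non-metric MDS, ANOSIM, Mantel tests, one-way
   ANOVA with LSD letter displays, and distance–decay regressions.
3. **Constrained ordination.** RDA on Hellinger-transformed abundances with
   forward-selected conditional term effects (permutation pseudo-F), and
   variance partitioning into pH / macronutrient / micronutrient sets via
   adjusted R² and inclusion–exclusion.
4. **Co-occurrence networks.** Spearman correlation networks (|ρ| > 0.6,
   p < 0.001), greedy modularity modules, and Zi–Pi node roles (module hubs,
   connectors, network hubs, peripherals at Zi = 2.5, Pi = 0.62).
5. **Community assembly.** Sloan's neutral community model — the occurrence
   frequency of a taxon with metacommunity relative abundance *p* is
   `1 − BetaCDF(d; Nm·p, Nm(1−p))` with detection limit `d = 1/N` — fitted by
   least squares for the dispersal parameter `Nm`; abundance-weighted
   betaMNTD/betaNTI phylogenetic null models; Raup–Crick with Bray–Curtis
   (RCbray); and the five-process classification (|betaNTI| > 2 → selection,
   RCbray beyond ±0.95 → dispersal processes, otherwise undominated).

Because real surveys rarely come with ground truth, the package also ships a
first-class synthetic generator (`soilbiome.synthetic_data`): soil chemistry
drawn around LF/MF/HF group profiles, a pure-birth phylogeny with Brownian
trait evolution, and OTU tables assembled under *neutral*, *selection* or
*dispersal-limited* regimes — so every estimator can be validated against the
regime that generated the data.

Intended users: microbial ecologists and agronomy researchers analysing
OTU/ASV tables against soil chemistry, and method developers who need a
tested reference implementation of the assembly-inference stack.

## Worked example

```bash
soilbiome simulate --regime neutral --n-samples 30 --n-otus 150 --seed 11 --out demo
soilbiome assembly --otu-table demo/otu_table.tsv --tree demo/tree.nwk \
    --chemistry demo/chemistry.tsv --n-null 199 --seed 23 --out demo_assembly
```

The `analysis/` directory runs the same workflow as a numbered narrative
(`01_simulate_datasets.py` … `05_assembly_processes.py`). On the bundled
neutral scenario, step 05 prints:

```
[neutral] NCM: m=0.668, Nm=6680, R2=0.864
[neutral] process fractions: heterogeneous_selection=7.1%, undominated=92.9%
[neutral] stochastic (|betaNTI| <= 2) share: 92.9%
[neutral] distance decay: slope=-0.001, p=0.675
```

i.e. the neutral model explains 86% of the frequency–abundance relationship
and 92.9% of sample pairs are classified as stochastic — the generator's
truth. The dispersal-limited scenario instead yields 94.7% dispersal
limitation and a significant positive distance decay (slope 0.169, p=0.005),
and the selection-driven survey puts pH first in the RDA table (60.8%
conditional variance, p=0.001).

## Layout

```
src/soilbiome/      io_formats, synthetic_data, fertility, diversity,
                    ordination, network, assembly, pipeline, cli
analysis/           numbered narrative drivers writing under results/
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     models, assumptions, parameter choices, limitations
```
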