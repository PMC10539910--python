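#!/usr/bin/env python
"""Score soil fertility for the simulated survey.

Computes fuzzy memberships of the six indicators (SOM, pH, TN, AN, AP, AK),
PCA-derived weights, the integrated fertility index (IFI) and the LF/MF/HF
class of every field; writes results/fertility/ and prints the headline
numbers.
"""

from pathlib import Path

from soilbiome.fertility import score_chemistry
from soilbiome.io_formats import read_chemistry, write_results

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    chem = read_chemistry(ROOT / "data" / "survey" / "chemistry.tsv")
    res = score_chemistry(chem)
    write_results(
        {"fertility": res.to_frame(), "weights": res.weights},
        ROOT / "fertility",
    )
    counts = res.classes.value_counts().to_dict()
    print(f"IFI range: {res.ifi.min():.4f} - {res.ifi.max():.4f}")
    print(f"class counts: {counts}")
    print("indicator weights:")
    print(res.weights.round(4).to_string())


if __name__ == "__main__":
    main()
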