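"""Readers, writers and validated containers for the pipeline's external formats.

Tables travel as TSV (UTF-8, '.' decimal; CSV via ``sep=','``), trees as newick,
scalar results and run metadata as JSON.  Validation is strict and failures name
the offending row, column or id.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: chemistry columns every fertility analysis needs, in canonical order
MANDATORY_CHEMISTRY = ["SOM", "pH", "TN", "AN", "AP", "AK"]

#: full micronutrient/macronutrient panel the study design measures
FULL_CHEMISTRY = MANDATORY_CHEMISTRY + [
    "WSCa", "WSMg", "WSCl", "ACu", "AZn", "AFe", "AMn",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Sample x OTU count matrix with optional OTU -> phylum taxonomy."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # (n_samples, n_otus) non-negative integers
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            bad = np.nonzero(~np.isclose(counts, rounded, atol=1e-9) | np.isnan(counts))
            if bad[0].size:
                r, c = bad[0][0], bad[1][0]
                raise ValidationError(
                    f"non-integer count {counts[r, c]!r} at sample "
                    f"{self.sample_ids[r]!r}, OTU {self.otu_ids[c]!r}"
                )
            counts = rounded.astype(np.int64)
        neg = np.nonzero(counts < 0)
        if neg[0].size:
            r, c = neg[0][0], neg[1][0]
            raise ValidationError(
                f"negative count {counts[r, c]} at sample "
                f"{self.sample_ids[r]!r}, OTU {self.otu_ids[c]!r}"
            )
        self.counts = counts.astype(np.int64)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise ValidationError(
                    f"taxonomy refers to unknown OTU ids: {sorted(unknown)[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalised counts; rows with zero total raise."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = self.sample_ids[int(np.argmax(totals == 0))]
            raise ValidationError(f"sample {empty!r} has zero total count")
        return self.counts / totals[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            list(sample_ids), list(self.otu_ids), self.counts[idx], self.taxonomy
        )

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx], tax)


@dataclass
class ChemistryTable:
    """Per-sample soil abiotic measurements.

    Units: SOM and TN in g/kg, pH unitless, all remaining columns mg/kg.
    """

    data: pd.DataFrame = field(repr=False)
    group: pd.Series | None = None  # optional fertility-class label per sample

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(list(df.index.astype(str)), "sample")
        missing = [c for c in MANDATORY_CHEMISTRY if c not in df.columns]
        if missing:
            raise ValidationError(f"missing mandatory chemistry columns: {missing}")
        # drop (never impute) samples with any missing mandatory indicator
        incomplete = df[MANDATORY_CHEMISTRY].isna().any(axis=1)
        if incomplete.any():
            dropped = list(df.index[incomplete])
            logger.warning(
                "dropping %d samples with missing mandatory chemistry: %s",
                len(dropped), dropped,
            )
            df = df.loc[~incomplete]
            if self.group is not None:
                self.group = self.group.loc[df.index]
        ph = df["pH"]
        bad_ph = (ph <= 0) | (ph >= 14)
        if bad_ph.any():
            s = df.index[bad_ph][0]
            raise ValidationError(f"pH {ph.loc[s]} outside (0, 14) for sample {s!r}")
        conc = df.drop(columns=["pH"]).select_dtypes(include=[np.number])
        neg = conc < 0
        if neg.any().any():
            col = neg.any()[neg.any()].index[0]
            s = conc.index[neg[col]][0]
            raise ValidationError(
                f"negative concentration {conc.loc[s, col]} in column {col!r}, "
                f"sample {s!r}"
            )
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def indicators(self, columns: Sequence[str] | None = None) -> pd.DataFrame:
        return self.data[list(columns or MANDATORY_CHEMISTRY)].astype(float)


def read_otu_table(
    path: str | Path,
    orientation: str = "otus_as_rows",
    sep: str = "\t",
    taxonomy_path: str | Path | None = None,
) -> OtuTable:
    """Read a count table; ``orientation`` declares which axis the rows are."""
    if orientation not in {"otus_as_rows", "samples_as_rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "otus_as_rows":
        df = df.T
    taxonomy = None
    if taxonomy_path is not None:
        tax = pd.read_csv(taxonomy_path, sep=sep, index_col=0)
        taxonomy = tax.iloc[:, 0].astype(str).to_dict()
    return OtuTable(
        [str(s) for s in df.index],
        [str(o) for o in df.columns],
        df.to_numpy(),
        taxonomy,
    )


def write_otu_table(
    table: OtuTable, path: str | Path, orientation: str = "otus_as_rows",
    sep: str = "\t",
) -> None:
    df = table.to_dataframe()
    if orientation == "otus_as_rows":
        df = df.T
        df.index.name = "otu_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_chemistry(path: str | Path, sep: str = "\t") -> ChemistryTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    group = None
    if "group" in df.columns:
        group = df.pop("group").astype(str)
    return ChemistryTable(df, group=group)


def write_chemistry(chem: ChemistryTable, path: str | Path, sep: str = "\t") -> None:
    df = chem.data.copy()
    if chem.group is not None:
        df["group"] = chem.group
    df.index.name = "sample_id"
    df.to_csv(path, sep=sep)


def read_tree(path: str | Path, require_lengths: bool = False) -> TreeNode:
    """Read a rooted newick tree; unlabeled internal nodes are tolerated."""
    tree = TreeNode.read(str(path), format="newick")
    tips = list(tree.tips())
    names = [t.name for t in tips]
    _check_unique(names, "tip")
    if require_lengths:
        check_branch_lengths(tree)
    return tree


def check_branch_lengths(tree: TreeNode) -> None:
    """Raise unless every non-root branch has a non-negative length."""
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"branch length missing above node {node.name or '<internal>'!r}; "
                "phylogenetic null models need branch lengths"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    results: Mapping[str, object],
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> list[Path]:
    """Write a stage's result bundle.

    DataFrames become TSV (deterministic column order as given), everything
    JSON-serialisable goes into a single ``<name>.json``; run metadata (seed,
    config hash, package versions) is always emitted as ``metadata.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    scalars: dict[str, object] = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out / f"{name}.tsv"
            obj.to_csv(p, sep="\t")
            written.append(p)
        elif isinstance(obj, pd.Series):
            p = out / f"{name}.tsv"
            obj.to_frame(name).to_csv(p, sep="\t")
            written.append(p)
        else:
            scalars[name] = obj
    if scalars:
        p = out / "summary.json"
        p.write_text(json.dumps(scalars, indent=2, sort_keys=True, default=str))
        written.append(p)
    meta = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-bio": skbio.__version__,
        },
    }
    if config is not None:
        meta["config"] = dict(config)
    mp = out / "metadata.json"
    mp.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written.append(mp)
    return written
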