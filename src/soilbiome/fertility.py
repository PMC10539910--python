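"""Integrated fertility index (IFI) from fuzzy memberships and PCA weights.

Six indicators (SOM, pH, TN, AN, AP, AK) are mapped to membership values in
[0.1, 1.0] by piecewise-linear fuzzy functions: S-type (monotone, for nutrients
where more is better up to sufficiency) or parabola-type (an optimal plateau
[O1, O2] flanked by linear ramps, for indicators like pH with a sweet spot).
Indicator weights come from a principal-component analysis of the z-scored
indicators, and IFI = sum_i W_i * N_i with W the weights (sum 1) and N the
memberships.  Samples are classed LF (< 0.55), MF ([0.55, 0.75)) or
HF (>= 0.75).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ChemistryTable, ValidationError

logger = logging.getLogger(__name__)

LF_CUTOFF = 0.55
HF_CUTOFF = 0.75

#: membership floor/ceiling of the fuzzy transform
_FLOOR, _CEIL = 0.1, 1.0


@dataclass(frozen=True)
class MembershipSpec:
    """Limits of one indicator's piecewise-linear membership function."""

    kind: str  # "s_type" | "parabola"
    L: float
    U: float
    O1: float | None = None
    O2: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "s_type":
            if not self.L < self.U:
                raise ValidationError(f"s_type requires L < U, got {self.L}, {self.U}")
        elif self.kind == "parabola":
            if self.O1 is None or self.O2 is None:
                raise ValidationError("parabola requires O1 and O2")
            if not (self.L < self.O1 <= self.O2 < self.U):
                raise ValidationError(
                    f"parabola requires L < O1 <= O2 < U, got "
                    f"{self.L}, {self.O1}, {self.O2}, {self.U}"
                )
        else:
            raise ValidationError(f"unknown membership kind {self.kind!r}")


#: standard limit values for the six fertility indicators on their native scales
DEFAULT_SPECS: dict[str, MembershipSpec] = {
    "pH": MembershipSpec("parabola", L=5.0, U=7.5, O1=5.5, O2=7.0),
    "SOM": MembershipSpec("parabola", L=15.0, U=45.0, O1=25.0, O2=35.0),
    "AN": MembershipSpec("parabola", L=30.0, U=100.0, O1=50.0, O2=70.0),
    "TN": MembershipSpec("parabola", L=0.9, U=3.5, O1=1.4, O2=2.5),
    "AP": MembershipSpec("s_type", L=20.0, U=40.0),
    "AK": MembershipSpec("s_type", L=100.0, U=150.0),
}

INDICATORS = list(DEFAULT_SPECS)


def membership(x, spec: MembershipSpec):
    """Fuzzy membership of indicator value(s) ``x`` in [0.1, 1.0].

    Vectorised over ``x``; scalars in, scalar out.
    """
    x = np.asarray(x, dtype=float)
    if spec.kind == "s_type":
        y = _FLOOR + 0.9 * (x - spec.L) / (spec.U - spec.L)
        y = np.clip(y, _FLOOR, _CEIL)
    else:
        y = np.full_like(x, _FLOOR)
        rising = (x > spec.L) & (x < spec.O1)
        y = np.where(rising, _FLOOR + 0.9 * (x - spec.L) / (spec.O1 - spec.L), y)
        plateau = (x >= spec.O1) & (x <= spec.O2)
        y = np.where(plateau, _CEIL, y)
        falling = (x > spec.O2) & (x < spec.U)
        y = np.where(falling, _CEIL - 0.9 * (x - spec.O2) / (spec.U - spec.O2), y)
    return float(y) if y.ndim == 0 else y


def membership_table(
    chem: ChemistryTable,
    specs: Mapping[str, MembershipSpec] = DEFAULT_SPECS,
) -> pd.DataFrame:
    """Per-sample membership values for every indicator in ``specs``."""
    df = chem.indicators(list(specs))
    out = {name: membership(df[name].to_numpy(), spec) for name, spec in specs.items()}
    return pd.DataFrame(out, index=df.index)


def pca_weights(
    chem: ChemistryTable,
    indicators: Sequence[str] = tuple(INDICATORS),
    variant: str = "communality",
) -> pd.Series:
    """Indicator weights from PCA of the z-scored indicator matrix.

    ``communality`` (default): each indicator's summed squared loadings over the
    components with eigenvalue > 1, normalised to sum 1.  ``first_component``:
    the share of absolute loadings on the first component.
    """
    df = chem.indicators(indicators)
    if len(df) < 7:
        raise ValidationError(f"PCA weights need >= 7 samples, got {len(df)}")
    sd = df.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValidationError(f"indicator {bad!r} has zero variance")
    z = (df - df.mean()) / sd
    corr = np.asarray(z.corr())  # correlation matrix of z-scores
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    loadings = eigvec * np.sqrt(np.clip(eigval, 0, None))
    if variant == "communality":
        keep = eigval > 1.0
        if not keep.any():  # degenerate: fall back to the leading component
            keep = np.zeros_like(keep)
            keep[0] = True
        comm = (loadings[:, keep] ** 2).sum(axis=1)
    elif variant == "first_component":
        comm = np.abs(loadings[:, 0])
    else:
        raise ValueError(f"unknown weight variant {variant!r}")
    w = comm / comm.sum()
    return pd.Series(w, index=list(indicators), name="weight")


def compute_ifi(memberships: pd.DataFrame, weights: pd.Series) -> pd.Series:
    """IFI = sum_i W_i N_i per sample; bounded in [0.1, 1.0]."""
    if set(memberships.columns) != set(weights.index):
        raise ValidationError(
            f"indicator sets differ: memberships {sorted(memberships.columns)} "
            f"vs weights {sorted(weights.index)}"
        )
    aligned = memberships[weights.index]
    return (aligned * weights).sum(axis=1).rename("IFI")


def classify_fertility(ifi) -> pd.Series | str:
    """LF below 0.55, MF in [0.55, 0.75), HF at or above 0.75."""
    arr = np.atleast_1d(np.asarray(ifi, dtype=float))
    labels = np.select([arr < LF_CUTOFF, arr < HF_CUTOFF], ["LF", "MF"], default="HF")
    if np.isscalar(ifi) or np.ndim(ifi) == 0:
        return str(labels[0])
    index = ifi.index if isinstance(ifi, pd.Series) else None
    return pd.Series(labels, index=index, name="class")


@dataclass
class FertilityResult:
    memberships: pd.DataFrame
    weights: pd.Series
    ifi: pd.Series
    classes: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.memberships.copy()
        out["IFI"] = self.ifi
        out["class"] = self.classes
        return out


def score_chemistry(
    chem: ChemistryTable,
    specs: Mapping[str, MembershipSpec] = DEFAULT_SPECS,
    weight_variant: str = "communality",
) -> FertilityResult:
    """Full fertility scoring: memberships -> PCA weights -> IFI -> class.

    PCA weights need at least 7 samples; below that, equal weights are used
    with a warning (a defensible degenerate choice for toy inputs).
    """
    members = membership_table(chem, specs)
    if len(members) >= 7:
        weights = pca_weights(chem, list(specs), variant=weight_variant)
    else:
        logger.warning(
            "only %d samples: falling back to equal indicator weights",
            len(members),
        )
        weights = pd.Series(1.0 / len(specs), index=list(specs), name="weight")
    ifi = compute_ifi(members, weights)
    return FertilityResult(members, weights, ifi, classify_fertility(ifi))
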