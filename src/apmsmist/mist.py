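"""MiST (Mass spectrometry Interaction STatistics) scoring of bait-prey pairs.

MiST summarizes a prey's quantitative behaviour in an AP-MS experiment with
three components, each in [0, 1]:

* **Reproducibility (R)** - normalized Shannon entropy of the prey's
  abundance fractions across one bait's biological replicates. A prey seen
  at equal levels in every replicate scores 1; a prey seen in a single
  replicate scores 0. The log base is the replicate count, so R is
  normalized for any replicate number.
* **Abundance (A)** - the mean of the prey's per-column abundance fractions
  over the bait's replicates. Missing observations contribute 0 (absence of
  evidence of binding).
* **Specificity (S)** - the share of the prey's summed abundance that is
  attributable to the bait, relative to every bait in the scoring group
  (including the IgG mock control, which receives its own score).

The composite is the weighted sum ``w_R*R + w_A*A + w_S*S`` with
nonnegative weights summing to 1. The defaults are the published
MiST-trained weights, renormalized.

Scoring groups
--------------
``score_dataset`` scores all baits jointly by default, so a prey's
specificity sums to 1 across every bait in the experiment. Passing
``baits=[bait, control]`` instead scores one pull-down against its mock
control in isolation - the appropriate grouping when two baits sharing
biology are each compared to the same IgG control, since joint specificity
would split a genuinely shared partner's specificity between the baits and
make it uncallable at any useful threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_quant import CollapsedMatrix


class MistError(ValueError):
    pass


@dataclass(frozen=True)
class MistWeights:
    """Composite weights (reproducibility, abundance, specificity).

    Renormalized to sum to 1 at construction; all must be nonnegative and
    not all zero.
    """

    w_R: float
    w_A: float
    w_S: float

    def __post_init__(self) -> None:
        if min(self.w_R, self.w_A, self.w_S) < 0:
            raise MistError("MiST weights must be nonnegative")
        total = self.w_R + self.w_A + self.w_S
        if total <= 0:
            raise MistError("MiST weights must not all be zero")
        object.__setattr__(self, "w_R", self.w_R / total)
        object.__setattr__(self, "w_A", self.w_A / total)
        object.__setattr__(self, "w_S", self.w_S / total)


#: Published MiST-trained component weights (renormalized to sum to 1).
DEFAULT_WEIGHTS = MistWeights(w_R=0.30853, w_A=0.00596, w_S=0.68551)


@dataclass
class AbundanceMatrix:
    """Per-column normalized abundance fractions (preys x (bait, bio_rep)).

    Each column sums to 1; missing observations are 0.
    """

    fractions: pd.DataFrame
    control: str
    baits: list[str]


def normalize_runs(matrix: CollapsedMatrix, baits: Sequence[str] | None = None) -> AbundanceMatrix:
    """De-log the collapsed matrix and normalize each column to fractions.

    Missing cells contribute 0 abundance. A column with zero total
    intensity is an error (that pull-down quantified nothing).
    """
    baits = list(baits) if baits is not None else list(matrix.baits)
    unknown = [b for b in baits if b not in matrix.baits]
    if unknown:
        raise MistError(f"unknown bait(s): {unknown}")
    values = matrix.values[baits]
    linear = np.exp2(values).fillna(0.0)
    totals = linear.sum(axis=0)
    dead = totals[totals <= 0]
    if not dead.empty:
        cells = ", ".join(f"({b}, bio_rep {rep})" for b, rep in dead.index)
        raise MistError(f"column(s) with zero total intensity: {cells}")
    return AbundanceMatrix(fractions=linear / totals, control=matrix.control, baits=baits)


def reproducibility(fractions: Sequence[float]) -> float:
    """Normalized Shannon entropy of a prey's fractions across replicates.

    With n replicates and fractions a_i, let T = sum a_i. If T == 0 the
    prey was never observed and R = 0. Otherwise p_i = a_i / T and
    R = -sum p_i * log_n(p_i), with 0*log(0) := 0.
    """
    a = np.asarray(fractions, dtype=float)
    n = a.size
    if n < 2:
        raise MistError("reproducibility needs at least 2 replicates")
    if (a < 0).any():
        raise MistError("fractions must be nonnegative")
    total = a.sum()
    if total == 0:
        return 0.0
    p = a / total
    nz = p[p > 0]
    r = float(-(nz * np.log(nz)).sum() / math.log(n))
    return min(max(r, 0.0), 1.0)


def abundance(fractions: Sequence[float]) -> float:
    """Mean abundance fraction across a bait's replicates (missing -> 0)."""
    a = np.asarray(fractions, dtype=float)
    if ((a < 0) | (a > 1)).any():
        raise MistError("fractions must lie in [0, 1]")
    return float(a.mean())

def specificity(abundance_by_bait: dict[str, float]) -> dict[str, float]:
    """Share of a prey's total abundance attributable to each bait.

    S(bait) = A(bait) / sum over baits of A; all-zero abundances give
    S = 0 everywhere.
    """
    if len(abundance_by_bait) < 2:
        raise MistError("specificity needs at least 2 baits")
    if min(abundance_by_bait.values()) < 0:
        raise MistError("abundances must be nonnegative")
    total = sum(abundance_by_bait.values())
    if total == 0:
        return {b: 0.0 for b in abundance_by_bait}
    return {b: a / total for b, a in abundance_by_bait.items()}


def _entropy_rows(sub: np.ndarray) -> np.ndarray:
    """Row-wise normalized entropy of a preys x replicates fraction block."""
    n = sub.shape[1]
    totals = sub.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals[:, None] > 0, sub / np.where(totals[:, None] > 0, totals[:, None], 1.0), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    r = -plogp.sum(axis=1) / math.log(n)
    r[totals == 0] = 0.0
    return np.clip(r, 0.0, 1.0)


def score_dataset(
    matrix: CollapsedMatrix,
    weights: MistWeights = DEFAULT_WEIGHTS,
    baits: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Compute MiST records for every (bait, prey) pair in the scoring group.

    Returns a tidy DataFrame with columns
    ``bait, prey, gene, R, A, S, score``, sorted by bait (design order)
    then prey id. ``baits`` restricts the scoring group (e.g. one test bait
    plus the control); by default all baits are scored jointly.
    """
    am = normalize_runs(matrix, baits=baits)
    preys = am.fractions.index
    r_cols: dict[str, np.ndarray] = {}
    a_cols: dict[str, np.ndarray] = {}
    for bait in am.baits:
        block = am.fractions[bait].to_numpy()
        if block.shape[1] < 2:
            raise MistError(f"bait {bait!r} has fewer than 2 biological replicates")
        r_cols[bait] = _entropy_rows(block)
        a_cols[bait] = block.mean(axis=1)
    a_df = pd.DataFrame(a_cols, index=preys)
    totals = a_df.sum(axis=1)
    s_df = a_df.div(totals.where(totals > 0, 1.0), axis=0)
    s_df[totals == 0] = 0.0
    r_df = pd.DataFrame(r_cols, index=preys)
    score_df = weights.w_R * r_df + weights.w_A * a_df + weights.w_S * s_df

    records = []
    for bait in am.baits:
        records.append(
            pd.DataFrame(
                {
                    "bait": bait,
                    "prey": preys,
                    "gene": matrix.gene_names.reindex(preys).fillna("").values,
                    "R": r_df[bait].values,
                    "A": a_df[bait].values,
                    "S": s_df[bait].values,
                    "score": score_df[bait].values,
                }
            )
        )
    out = pd.concat(records, ignore_index=True)
    out = out.sort_values(
        ["bait", "prey"],
        key=lambda c: c.map({b: i for i, b in enumerate(am.baits)}) if c.name == "bait" else c,
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
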