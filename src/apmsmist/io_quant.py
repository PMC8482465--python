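"""Reading and preprocessing of MaxQuant protein-group quantification tables.

This module handles the upstream half of an AP-MS (affinity purification /
mass spectrometry) analysis: parsing a ``proteinGroups.txt``-dialect table
of label-free quantification (LFQ) intensities, removing the standard
quality-flagged rows (potential contaminants, reverse decoy hits, proteins
identified only by modification site), log2-transforming, collapsing
technical replicates to their median, and applying the valid-value filter
("at least k valid values in at least one bait group").

Conventions
-----------
* A stored intensity of 0 means "not quantified" and is represented as NaN
  throughout (the MaxQuant convention; a zero LFQ value carries no abundance
  information).
* Flag columns use MaxQuant's ``"+"`` text convention; any other non-empty
  value is rejected as a dialect error.
* Technical-replicate medians are computed over valid (non-missing) values
  only; a (bait, biological replicate) cell with no valid technical
  replicate is missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: MaxQuant column names for the three row-level quality flags.
FLAG_COLUMNS: dict[str, str] = {
    "contaminant": "Potential contaminant",
    "reverse": "Reverse",
    "only_by_site": "Only identified by site",
}

ID_COLUMN = "Protein IDs"
GENE_COLUMN = "Gene names"
INTENSITY_PATTERN = "LFQ intensity {run_id}"


class DesignError(ValueError):
    """The experimental design table violates an invariant."""


class QuantTableError(ValueError):
    """The protein-group table cannot be parsed under the strict dialect."""


@dataclass(frozen=True)
class RunDesign:
    """One MS run: which bait was pulled down, and its replicate indices."""

    run_id: str
    bait: str
    bio_rep: int
    tech_rep: int
    is_control: bool = False


def validate_design(design: Sequence[RunDesign]) -> str:
    """Check design invariants and return the control bait label.

    Requires unique run ids, replicate indices >= 1, and exactly one bait
    flagged as the control, flagged consistently across all its runs.
    """
    if not design:
        raise DesignError("experimental design is empty")
    run_ids = [r.run_id for r in design]
    if len(set(run_ids)) != len(run_ids):
        dupes = sorted({r for r in run_ids if run_ids.count(r) > 1})
        raise DesignError(f"duplicate run_id(s) in design: {dupes}")
    for r in design:
        if r.bio_rep < 1 or r.tech_rep < 1:
            raise DesignError(f"run {r.run_id!r}: replicate indices must be >= 1")
    control_flags: dict[str, set[bool]] = {}
    for r in design:
        control_flags.setdefault(r.bait, set()).add(r.is_control)
    for bait, flags in control_flags.items():
        if len(flags) > 1:
            raise DesignError(f"bait {bait!r} has inconsistent is_control flags")
    controls = [b for b, f in control_flags.items() if True in f]
    if len(controls) != 1:
        raise DesignError(
            f"exactly one control bait required, found {len(controls)}: {controls}"
        )
    return controls[0]


def bait_order(design: Sequence[RunDesign]) -> list[str]:
    """Baits in order of first appearance in the design."""
    seen: list[str] = []
    for r in design:
        if r.bait not in seen:
            seen.append(r.bait)
    return seen


def read_design(path: str | Path) -> list[RunDesign]:
    """Read a design TSV with columns run_id, bait, bio_rep, tech_rep, is_control."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"run_id", "bait", "bio_rep", "tech_rep", "is_control"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"design file {path} lacks columns: {sorted(missing)}")
    truthy = {"true", "1", "yes"}
    design = [
        RunDesign(
            run_id=row.run_id,
            bait=row.bait,
            bio_rep=int(row.bio_rep),
            tech_rep=int(row.tech_rep),
            is_control=str(row.is_control).strip().lower() in truthy,
        )
        for row in df.itertuples()
    ]
    validate_design(design)
    return design


def write_design(design: Sequence[RunDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "run_id": [r.run_id for r in design],
            "bait": [r.bait for r in design],
            "bio_rep": [r.bio_rep for r in design],
            "tech_rep": [r.tech_rep for r in design],
            "is_control": [str(r.is_control).lower() for r in design],
        }
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass
class QuantTable:
    """Protein groups x runs intensity matrix with row flags and run design.

    ``intensities`` is indexed by protein-group id with one column per
    run_id; missing values are NaN. ``flags`` holds the three boolean
    quality flags per row; ``gene_names`` maps group id to the (possibly
    ``;``-separated) gene symbol string.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    gene_names: pd.Series
    design: list[RunDesign] = field(default_factory=list)

    @property
    def control_bait(self) -> str:
        return validate_design(self.design)

    @property
    def n_rows(self) -> int:
        return len(self.intensities)


@dataclass
class CollapsedMatrix:
    """Protein groups x (bait, biological replicate) log2-intensity matrix.

    Columns are a two-level MultiIndex (bait, bio_rep); missing cells are NaN.
    """

    values: pd.DataFrame
    control: str
    gene_names: pd.Series
    baits: list[str]

    @property
    def test_baits(self) -> list[str]:
        return [b for b in self.baits if b != self.control]

    def bio_columns(self, bait: str) -> pd.DataFrame:
        """The sub-matrix of this bait's biological-replicate columns."""
        return self.values[bait]


def _parse_flag_column(series: pd.Series, column: str) -> pd.Series:
    filled = series.fillna("").astype(str).str.strip()
    bad = sorted(set(filled[~filled.isin(["", "+"])]))
    if bad:
        raise QuantTableError(
            f"flag column {column!r} contains values other than '+'/empty: {bad}"
        )
    return filled == "+"


def read_protein_groups(
    path: str | Path,
    design: Sequence[RunDesign],
    column_map: Mapping[str, str] | None = None,
    id_column: str = ID_COLUMN,
    gene_column: str = GENE_COLUMN,
) -> QuantTable:
    """Read a proteinGroups.txt-dialect TSV into a :class:`QuantTable`.

    Each design run resolves to the column ``"LFQ intensity <run_id>"``
    unless ``column_map`` supplies an explicit column name for that run.
    Zeros are converted to NaN (not quantified). Flag columns absent from
    the file are treated as all-false with a logged warning.
    """
    control = validate_design(design)  # noqa: F841 - invariant check
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column not in df.columns:
        raise QuantTableError(f"table lacks the id column {id_column!r}")
    group_ids = df[id_column]
    dup = group_ids[group_ids.duplicated()]
    if not dup.empty:
        raise QuantTableError(f"duplicate protein-group id(s): {sorted(set(dup))}")

    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    missing_runs: list[str] = []
    for r in design:
        col = column_map.get(r.run_id, INTENSITY_PATTERN.format(run_id=r.run_id))
        if col not in df.columns:
            missing_runs.append(r.run_id)
        else:
            resolved[r.run_id] = col
    if missing_runs:
        raise QuantTableError(
            "no intensity column found for design run(s): " + ", ".join(missing_runs)
        )

    intensities = pd.DataFrame(
        {rid: pd.to_numeric(df[col], errors="raise").to_numpy() for rid, col in resolved.items()},
        index=group_ids.values,
    ).astype(float)
    if (intensities.fillna(0) < 0).any().any():
        raise QuantTableError("negative intensity values are not permitted")
    intensities = intensities.replace(0.0, np.nan)
    intensities.index.name = "group_id"

    flags = pd.DataFrame(index=intensities.index)
    for key, column in FLAG_COLUMNS.items():
        if column in df.columns:
            flags[key] = _parse_flag_column(df[column], column).values
        else:
            logger.warning("flag column %r absent; treating all rows as unflagged", column)
            flags[key] = False

    if gene_column in df.columns:
        genes = pd.Series(df[gene_column].fillna("").values, index=intensities.index)
    else:
        genes = pd.Series("", index=intensities.index)
    genes.name = "gene_names"

    return QuantTable(
        intensities=intensities, flags=flags, gene_names=genes, design=list(design)
    )


def write_protein_groups(table: QuantTable, path: str | Path) -> None:
    """Write a QuantTable back out in the proteinGroups.txt dialect.

    NaN cells are stored as 0 (MaxQuant's "not quantified"); flags use the
    ``"+"`` convention. Reading the file back with the same design recovers
    a value-identical table.
    """
    out = pd.DataFrame({ID_COLUMN: table.intensities.index})
    out[GENE_COLUMN] = table.gene_names.values
    for rid in table.intensities.columns:
        out[INTENSITY_PATTERN.format(run_id=rid)] = table.intensities[rid].fillna(0.0).values
    for key, column in FLAG_COLUMNS.items():
        out[column] = np.where(table.flags[key].values, "+", "")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def drop_flagged_rows(table: QuantTable) -> QuantTable:
    """Remove rows flagged as contaminant, reverse hit, or only-by-site.

    A row carrying any of the three flags is removed once (set semantics).
    Per-flag removal counts are logged at INFO.
    """
    flags = table.flags
    for key in FLAG_COLUMNS:
        logger.info("rows flagged %s: %d", key, int(flags[key].sum()))
    keep = ~flags.any(axis=1)
    logger.info("drop_flagged_rows: %d -> %d rows", len(flags), int(keep.sum()))
    return QuantTable(
        intensities=table.intensities.loc[keep],
        flags=flags.loc[keep],
        gene_names=table.gene_names.loc[keep],
        design=list(table.design),
    )


def log2_collapse(table: QuantTable) -> CollapsedMatrix:
    """Log2-transform and take the median over technical replicates.

    Each output cell is the median of log2(intensity) over that
    (bait, bio_rep)'s technical replicates, computed over valid values
    only; a cell whose technical replicates are all missing stays missing.
    """
    if not table.design:
        raise DesignError("QuantTable has no attached design")
    control = validate_design(table.design)
    order = bait_order(table.design)
    log2 = np.log2(table.intensities)

    key = {r.run_id: (r.bait, r.bio_rep) for r in table.design}
    groups: dict[tuple[str, int], list[str]] = {}
    for r in table.design:
        groups.setdefault(key[r.run_id], []).append(r.run_id)

    cells = sorted(groups, key=lambda bb: (order.index(bb[0]), bb[1]))
    collapsed = pd.DataFrame(
        {bb: log2[groups[bb]].median(axis=1, skipna=True) for bb in cells},
        index=log2.index,
    )
    collapsed.columns = pd.MultiIndex.from_tuples(cells, names=["bait", "bio_rep"])
    return CollapsedMatrix(
        values=collapsed, control=control, gene_names=table.gene_names, baits=order
    )


def filter_min_valid(matrix: CollapsedMatrix, k: int = 3) -> CollapsedMatrix:
    """Keep rows with at least ``k`` valid values in at least one bait group.

    Groups are baits (after technical-replicate collapse), counted over
    biological replicates; ``k=0`` retains every row.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    counts = matrix.values.notna().T.groupby(level="bait").sum().T
    max_per_bait = max(
        (matrix.values[b].shape[1] for b in matrix.baits), default=0
    )
    if k > max_per_bait:
        raise ValueError(
            f"k={k} exceeds the number of biological replicates ({max_per_bait})"
        )
    keep = counts.max(axis=1) >= k if k > 0 else pd.Series(True, index=matrix.values.index)
    logger.info("filter_min_valid(k=%d): %d -> %d rows", k, len(keep), int(keep.sum()))
    return replace(
        matrix,
        values=matrix.values.loc[keep],
        gene_names=matrix.gene_names.loc[keep],
    )


def write_collapsed(matrix: CollapsedMatrix, path: str | Path) -> None:
    """Write the collapsed matrix as TSV with ``bait.bio_rep`` column names."""
    flat = matrix.values.copy()
    flat.columns = [f"{b}.{rep}" for b, rep in flat.columns]
    flat.insert(0, "gene_names", matrix.gene_names)
    flat.to_csv(path, sep="\t", na_rep="NA", index_label="group_id", lineterminator="\n")
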