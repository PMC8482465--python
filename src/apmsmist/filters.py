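"""Interactor calling: MiST dual thresholds and contaminant-frequency filter.

A prey is called an interactor of a test bait when its MiST score for that
bait is >= tau_bait AND its MiST score for the IgG mock control is
<= tau_igg (both inequalities non-strict, as printed). Called preys are
then screened against a contaminant repository - a catalogue of how often
each protein was detected in control IP experiments - and retained only if
that detection frequency is strictly below ``f_max`` (default 40%).
Finally, calls are ranked by their log2 enrichment over the control.

Every surviving call carries full provenance: the bait and control scores,
the repository frequency, and the ranking statistic; each filter appends a
before/after record to the call set's provenance log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_quant import CollapsedMatrix

logger = logging.getLogger(__name__)


class FilterError(ValueError):
    pass


class RepositoryError(ValueError):
    pass


@dataclass
class ContaminantRepository:
    """Detection counts of preys across a panel of control IP experiments."""

    total_experiments: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_experiments <= 0:
            raise RepositoryError("total_experiments must be > 0")
        bad = {p: c for p, c in self.counts.items() if c < 0 or c > self.total_experiments}
        if bad:
            raise RepositoryError(
                f"counts outside [0, {self.total_experiments}]: {sorted(bad)}"
            )

    def frequency(self, prey: str) -> float:
        """Detection frequency in [0, 1]; preys never catalogued have 0."""
        return self.counts.get(prey, 0) / self.total_experiments


@dataclass
class InteractorCallSet:
    """One bait's called interactors with per-call filter provenance.

    ``calls`` is indexed by prey id with columns score, igg_score,
    repo_frequency (NaN until the frequency filter runs) and rank_stat
    (NaN until ranking). ``provenance`` records every filter applied, in
    order, with its parameters and before/after counts.
    """

    bait: str
    control: str
    calls: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def preys(self) -> frozenset[str]:
        return frozenset(self.calls.index)

    def _log(self, name: str, params: dict, n_before: int) -> None:
        self.provenance.append(
            {"filter": name, "params": params, "n_before": n_before, "n_after": len(self.calls)}
        )


def call_interactors(
    records: pd.DataFrame,
    tau_bait: float = 0.75,
    tau_igg: float = 0.75,
    control: str = "IgG",
) -> dict[str, InteractorCallSet]:
    """Apply the dual MiST thresholds to a record table.

    A prey is called for test bait B iff score(B, prey) >= tau_bait and
    score(control, prey) <= tau_igg; both comparisons are non-strict, so a
    prey at exactly (0.75, 0.75) passes. Returns one call set per test bait.
    """
    for tau, name in ((tau_bait, "tau_bait"), (tau_igg, "tau_igg")):
        if not 0.0 <= tau <= 1.0:
            raise FilterError(f"{name} must lie in [0, 1], got {tau}")
    baits = list(dict.fromkeys(records["bait"]))
    if control not in baits:
        raise FilterError(f"records contain no control bait {control!r}")
    scores = records.pivot(index="prey", columns="bait", values="score")
    igg = scores[control]
    out: dict[str, InteractorCallSet] = {}
    for bait in baits:
        if bait == control:
            continue
        mask = (scores[bait] >= tau_bait) & (igg <= tau_igg)
        calls = pd.DataFrame(
            {
                "score": scores.loc[mask, bait],
                "igg_score": igg[mask],
                "repo_frequency": np.nan,
                "rank_stat": np.nan,
            }
        ).sort_index(kind="mergesort")
        calls.index.name = "prey"
        cs = InteractorCallSet(bait=bait, control=control, calls=calls)
        cs._log(
            "mist_thresholds",
            {"tau_bait": tau_bait, "tau_igg": tau_igg},
            n_before=int(scores[bait].notna().sum()),
        )
        logger.info("%s: %d preys pass MiST thresholds", bait, len(cs))
        out[bait] = cs
    return out


def load_contaminant_repository(
    path: str | Path, total_experiments: int | None = None
) -> ContaminantRepository:
    """Load a repository TSV (columns prey_id, n_detected).

    The panel size comes from a ``#total=<int>`` header line or the
    ``total_experiments`` argument (the argument wins if both are given).
    An empty table is a valid repository: every query has frequency 0.
    """
    header_total: int | None = None
    rows: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#total="):
                header_total = int(line.strip().split("=", 1)[1])
            elif line.strip():
                rows.append(line)
    total = total_experiments if total_experiments is not None else header_total
    if total is None:
        raise RepositoryError(
            f"{path}: panel size unknown (no '#total=' header and no argument)"
        )
    if not rows or (len(rows) == 1 and rows[0].startswith("prey_id")):
        return ContaminantRepository(total_experiments=total)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t")
    if not {"prey_id", "n_detected"} <= set(df.columns):
        raise RepositoryError(f"{path}: expected columns prey_id, n_detected")
    dup = df["prey_id"][df["prey_id"].duplicated()]
    if not dup.empty:
        raise RepositoryError(f"{path}: duplicate prey_id(s): {sorted(set(dup))}")
    counts = dict(zip(df["prey_id"].astype(str), df["n_detected"].astype(int)))
    return ContaminantRepository(total_experiments=total, counts=counts)


def write_contaminant_repository(repo: ContaminantRepository, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#total={repo.total_experiments}\n")
        fh.write("prey_id\tn_detected\n")
        for prey in sorted(repo.counts):
            fh.write(f"{prey}\t{repo.counts[prey]}\n")


def frequency_filter(
    calls: InteractorCallSet, repo: ContaminantRepository, f_max: float = 0.40
) -> InteractorCallSet:
    """Retain calls whose control-IP detection frequency is strictly < f_max.

    Preys absent from the repository have frequency 0 and are retained.
    """
    if not 0.0 < f_max <= 1.0:
        raise FilterError(f"f_max must lie in (0, 1], got {f_max}")
    n_before = len(calls)
    freq = pd.Series(
        [repo.frequency(p) for p in calls.calls.index], index=calls.calls.index, dtype=float
    )
    kept = calls.calls.copy()
    kept["repo_frequency"] = freq
    kept = kept[freq < f_max]
    out = InteractorCallSet(
        bait=calls.bait, control=calls.control, calls=kept,
        provenance=list(calls.provenance),
    )
    out._log(
        "contaminant_frequency",
        {"f_max": f_max, "total_experiments": repo.total_experiments},
        n_before=n_before,
    )
    logger.info(
        "%s: frequency filter %d -> %d calls", calls.bait, n_before, len(out)
    )
    return out


def rank_by_enrichment(calls: InteractorCallSet, matrix: CollapsedMatrix) -> InteractorCallSet:
    """Rank calls by mean log2 enrichment of the bait IP over the control IP.

    The statistic is the mean of valid log2 intensities in the bait's
    biological replicates minus the same mean in the control's; a prey
    undetected in the control contributes a control mean of 0, which places
    control-absent preys at the top. Sort is descending with lexicographic
    prey-id tie-breaking, so the ranking is deterministic.
    """
    preys = calls.calls.index
    bait_vals = matrix.bio_columns(calls.bait).reindex(preys)
    ctrl_vals = matrix.bio_columns(calls.control).reindex(preys)
    bait_mean = bait_vals.mean(axis=1, skipna=True)
    ctrl_mean = ctrl_vals.mean(axis=1, skipna=True).fillna(0.0)
    stat = (bait_mean - ctrl_mean).fillna(-np.inf)
    ranked = calls.calls.copy()
    ranked["rank_stat"] = stat
    ranked = ranked.sort_index(kind="mergesort").sort_values(
        "rank_stat", ascending=False, kind="mergesort"
    )
    out = InteractorCallSet(
        bait=calls.bait, control=calls.control, calls=ranked,
        provenance=list(calls.provenance),
    )
    out._log("rank_by_enrichment", {}, n_before=len(calls))
    return out


def write_calls(calls: InteractorCallSet, path: str | Path) -> None:
    out = calls.calls.copy()
    out.insert(0, "bait", calls.bait)
    out.to_csv(path, sep="\t", float_format="%.10g", index_label="prey", lineterminator="\n")
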