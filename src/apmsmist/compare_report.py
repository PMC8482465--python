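"""Interactome comparison, export artifacts, and over-representation analysis.

Compares two baits' interactor call sets (shared vs unique partners),
exports simple network files (SIF plus node attributes) and heatmap-ready
log2-intensity matrices, and runs a plain hypergeometric over-representation
analysis (ORA) on user-supplied GMT annotation sets with Holm (Bonferroni
step-down) multiple-testing correction.

All exports are deterministically ordered, UTF-8, LF line endings, so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .filters import InteractorCallSet
from .io_quant import CollapsedMatrix


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class SharedUniqueResult:
    """Shared and unique interactors of two baits."""

    bait_a: str
    bait_b: str
    shared: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        """(|shared|, |unique_a|, |unique_b|)."""
        return len(self.shared), len(self.unique_a), len(self.unique_b)


def compare_baits(a: InteractorCallSet, b: InteractorCallSet) -> SharedUniqueResult:
    """Exact set intersection/differences of two baits' called preys."""
    sa, sb = a.preys, b.preys
    return SharedUniqueResult(
        bait_a=a.bait,
        bait_b=b.bait,
        shared=frozenset(sa & sb),
        unique_a=frozenset(sa - sb),
        unique_b=frozenset(sb - sa),
    )


def export_network(result: SharedUniqueResult, directory: str | Path) -> dict[str, Path]:
    """Write bait->prey edges as SIF plus a node-attribute table.

    The SIF uses edge type ``interacts``; the node attributes flag each
    prey as shared / unique_<bait>. Both files are sorted for byte
    stability. Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sif_path = directory / "network.sif"
    attr_path = directory / "node_attributes.tsv"

    edges: list[tuple[str, str]] = []
    for prey in result.shared | result.unique_a:
        edges.append((result.bait_a, prey))
    for prey in result.shared | result.unique_b:
        edges.append((result.bait_b, prey))
    with open(sif_path, "w", encoding="utf-8", newline="\n") as fh:
        for bait, prey in sorted(edges):
            fh.write(f"{bait}\tinteracts\t{prey}\n")

    with open(attr_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tclass\n")
        rows = (
            [(p, "shared") for p in result.shared]
            + [(p, f"unique_{result.bait_a}") for p in result.unique_a]
            + [(p, f"unique_{result.bait_b}") for p in result.unique_b]
        )
        for node, cls in sorted(rows):
            fh.write(f"{node}\t{cls}\n")
    return {"sif": sif_path, "node_attributes": attr_path}


def heatmap_matrix(
    matrix: CollapsedMatrix, calls: InteractorCallSet, top_n: int
) -> pd.DataFrame:
    """Log2 intensities of the top-ranked calls, pull-down vs control.

    Rows are the first ``top_n`` calls in rank order; columns are the
    bait's and the control's biological replicates. Missing cells stay NaN
    and are written as "NA" by :func:`write_heatmap` (rendered gray in a
    heatmap viewer).
    """
    if top_n < 0:
        raise CompareError("top_n must be >= 0")
    if top_n > len(calls):
        raise CompareError(f"top_n={top_n} exceeds the {len(calls)} available calls")
    preys = list(calls.calls.index[:top_n])
    blocks = []
    for bait in (calls.bait, calls.control):
        sub = matrix.bio_columns(bait).reindex(preys)
        sub.columns = [f"{bait}.{rep}" for rep in sub.columns]
        blocks.append(sub)
    out = pd.concat(blocks, axis=1)
    out.index.name = "prey"
    return out


def write_heatmap(heatmap: pd.DataFrame, path: str | Path) -> None:
    heatmap.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g", lineterminator="\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read GMT annotation sets: term -> (description, member set)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            term, description, members = parts[0], parts[1], parts[2:]
            if term in sets:
                raise CompareError(f"duplicate GMT term {term!r}")
            sets[term] = (description, frozenset(m for m in members if m))
    return sets


def overrepresentation(
    query: set[str],
    annotations: dict[str, tuple[str, frozenset[str]]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric ORA of annotation terms in a query set.

    For each term, membership is intersected with the universe (size N);
    with K members, a query of size n and overlap k, the raw p-value is the
    upper tail P(X >= k) of Hypergeometric(N, K, n). P-values are adjusted
    across all tested terms with the Holm step-down procedure; terms with
    adjusted p <= alpha are flagged significant.

    Returns every tested term, sorted by (p_raw, term).
    """
    if not universe:
        raise CompareError("universe is empty")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise CompareError(f"query contains ids outside the universe, e.g. {extra}")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term in sorted(annotations):
        description, members = annotations[term]
        in_universe = members & universe
        big_k = len(in_universe)
        k = len(in_universe & query)
        p_raw = float(hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {
                "term": term,
                "description": description,
                "k": k,
                "K": big_k,
                "n": n_query,
                "N": n_universe,
                "p_raw": min(p_raw, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "description", "k", "K", "n", "N", "p_raw", "p_adj", "significant"]
        )
    df = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(df["p_raw"], method="holm")
    df["p_adj"] = np.minimum(p_adj, 1.0)
    df["significant"] = df["p_adj"] <= alpha
    return df.sort_values(["p_raw", "term"], kind="mergesort").reset_index(drop=True)


def write_enrichment(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
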