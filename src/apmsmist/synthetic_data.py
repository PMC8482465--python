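"""Synthetic AP-MS datasets with known ground truth.

Emulates the study design this pipeline targets: two test baits and an IgG
mock control, three biological by three technical replicates, label-free
quantification intensities that are log-normal on the raw scale, and
intensity-dependent (missing-not-at-random) dropout. Ground truth planted
into each dataset:

* bait-specific interactors, enriched by ``enrich_log2`` log2 units only in
  their bait's runs (a subset shared between both test baits);
* frequent background binders, present in every pull-down including IgG,
  each with a per-bait log2 affinity offset (sticky proteins often show
  antibody preference) and a contaminant-repository count of at least
  ceil(0.40 * repo_total) - so the 40% frequency filter must remove them
  even when their bait bias pushes them past the MiST thresholds;
* rare background: everything else, present at background level everywhere.

Randomness comes from a single seed fanned out into named streams, so
adding a new draw to one stream never perturbs the others and every output
is byte-reproducible from the config.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .filters import ContaminantRepository, InteractorCallSet, write_contaminant_repository
from .io_quant import QuantTable, RunDesign, write_design, write_protein_groups


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration; defaults emulate the target study design.

    Intensity parameters are on the log2 scale. ``dropout_mid`` is the
    log2 intensity at which a cell has a 50% chance of being missing;
    ``dropout_slope`` controls how sharply dropout falls off with
    intensity (0 disables dropout entirely).
    """

    n_preys: int = 1000
    n_true_per_bait: int = 50
    n_shared_true: int = 20
    n_frequent_background: int = 100
    baits: tuple[str, ...] = ("FOSL1", "FOSL2", "IgG")
    control: str = "IgG"
    n_bio: int = 3
    n_tech: int = 3
    mu_log2: float = 24.0
    sigma_log2: float = 0.5
    enrich_log2: float = 6.0
    bio_sigma: float = 0.25
    tech_sigma: float = 0.1
    bg_affinity_sigma: float = 2.0
    dropout_mid: float = 22.0
    dropout_slope: float = 1.0
    repo_total: int = 126
    n_flagged: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.control not in self.baits:
            raise SynthError(f"control {self.control!r} not among baits {self.baits}")
        if len(set(self.baits)) != len(self.baits):
            raise SynthError("bait labels must be distinct")
        if len(self.baits) < 2:
            raise SynthError("need at least one test bait plus the control")
        for name in ("n_preys", "n_true_per_bait", "n_shared_true",
                     "n_frequent_background", "n_flagged"):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")
        if self.n_shared_true > self.n_true_per_bait:
            raise SynthError("n_shared_true cannot exceed n_true_per_bait")
        n_test = len(self.baits) - 1
        n_planted = self.n_shared_true + n_test * (self.n_true_per_bait - self.n_shared_true)
        if n_planted + self.n_frequent_background > self.n_preys:
            raise SynthError("planted interactors plus frequent background exceed n_preys")
        if self.n_bio < 1 or self.n_tech < 1:
            raise SynthError("replicate counts must be >= 1")
        if self.repo_total <= 0:
            raise SynthError("repo_total must be > 0")

    @property
    def test_baits(self) -> tuple[str, ...]:
        return tuple(b for b in self.baits if b != self.control)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted labels: which preys truly bind which bait, and which are sticky."""

    interactors: Mapping[str, frozenset[str]]
    shared: frozenset[str]
    frequent_background: frozenset[str]

    def true_interactor_of(self, prey: str) -> frozenset[str]:
        return frozenset(b for b, s in self.interactors.items() if prey in s)


@dataclass
class SyntheticDataset:
    quant: QuantTable
    design: list[RunDesign]
    repository: ContaminantRepository
    truth: SyntheticTruth
    config: SynthConfig


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for a named stream of one dataset's randomness."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(name.encode()),))
    )


def generate_apms_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate a quantification table, design, repository, and truth labels."""
    n_test = len(cfg.test_baits)
    n_unique = cfg.n_true_per_bait - cfg.n_shared_true

    prey_ids = [f"PREY{i + 1:05d}" for i in range(cfg.n_preys)]
    genes = pd.Series([f"GENE{i + 1:05d}" for i in range(cfg.n_preys)], index=prey_ids)

    # deterministic truth layout: shared block, then one unique block per
    # test bait, then frequent background, remainder rare background
    pos = 0
    shared = frozenset(prey_ids[pos:pos + cfg.n_shared_true])
    pos += cfg.n_shared_true
    interactors: dict[str, set[str]] = {b: set(shared) for b in cfg.test_baits}
    for bait in cfg.test_baits:
        interactors[bait].update(prey_ids[pos:pos + n_unique])
        pos += n_unique
    frequent = frozenset(prey_ids[pos:pos + cfg.n_frequent_background])
    pos += cfg.n_frequent_background

    design: list[RunDesign] = []
    for bait in cfg.baits:
        for j in range(1, cfg.n_bio + 1):
            for t in range(1, cfg.n_tech + 1):
                design.append(
                    RunDesign(
                        run_id=f"{bait}_B{j}_T{t}",
                        bait=bait,
                        bio_rep=j,
                        tech_rep=t,
                        is_control=bait == cfg.control,
                    )
                )

    base = _stream(cfg.seed, "base").normal(cfg.mu_log2, cfg.sigma_log2, cfg.n_preys)
    affinity = _stream(cfg.seed, "bg_affinity").normal(
        0.0, cfg.bg_affinity_sigma, (cfg.n_preys, len(cfg.baits))
    )
    bio_eff = _stream(cfg.seed, "bio").normal(
        0.0, cfg.bio_sigma, (cfg.n_preys, len(cfg.baits), cfg.n_bio)
    )
    tech_rng = _stream(cfg.seed, "tech")
    drop_rng = _stream(cfg.seed, "dropout")

    is_freq = np.array([p in frequent for p in prey_ids])
    enrich = np.zeros((cfg.n_preys, len(cfg.baits)))
    for bi, bait in enumerate(cfg.baits):
        if bait in interactors:
            member = np.array([p in interactors[bait] for p in prey_ids])
            enrich[member, bi] = cfg.enrich_log2
        enrich[is_freq, bi] += affinity[is_freq, bi]

    columns: dict[str, np.ndarray] = {}
    for r in design:
        bi = cfg.baits.index(r.bait)
        x = (
            base
            + enrich[:, bi]
            + bio_eff[:, bi, r.bio_rep - 1]
            + tech_rng.normal(0.0, cfg.tech_sigma, cfg.n_preys)
        )
        if cfg.dropout_slope > 0:
            p_drop = expit((cfg.dropout_mid - x) * cfg.dropout_slope)
            x = np.where(drop_rng.random(cfg.n_preys) < p_drop, np.nan, x)
        columns[r.run_id] = np.exp2(x)

    intensities = pd.DataFrame(columns, index=prey_ids)
    flags = pd.DataFrame(
        {"contaminant": False, "reverse": False, "only_by_site": False}, index=prey_ids
    )

    # decoy rows exercising the flag filter: background-level intensities,
    # flags cycling through the three classes
    if cfg.n_flagged:
        flag_rng = _stream(cfg.seed, "flagged")
        fids = [f"FLAG{i + 1:03d}" for i in range(cfg.n_flagged)]
        fvals = pd.DataFrame(
            np.exp2(flag_rng.normal(cfg.mu_log2, cfg.sigma_log2, (cfg.n_flagged, len(design)))),
            index=fids,
            columns=[r.run_id for r in design],
        )
        intensities = pd.concat([intensities, fvals])
        fflags = pd.DataFrame(False, index=fids, columns=flags.columns)
        for i, key in enumerate(fids):
            fflags.loc[key, flags.columns[i % 3]] = True
        flags = pd.concat([flags, fflags])
        genes = pd.concat([genes, pd.Series([f"DECOY{i + 1:03d}" for i in range(cfg.n_flagged)], index=fids)])

    intensities.index.name = "group_id"
    flags.index.name = "group_id"
    quant = QuantTable(intensities=intensities, flags=flags, gene_names=genes, design=design)

    repo_rng = _stream(cfg.seed, "repo")
    floor = int(np.ceil(0.40 * cfg.repo_total))
    counts: dict[str, int] = {}
    for prey in prey_ids:
        if prey in frequent:
            counts[prey] = int(repo_rng.integers(floor, cfg.repo_total + 1))
        else:
            c = int(repo_rng.binomial(cfg.repo_total, 0.03))
            counts[prey] = min(c, floor - 1)
    repository = ContaminantRepository(total_experiments=cfg.repo_total, counts=counts)

    truth = SyntheticTruth(
        interactors={b: frozenset(s) for b, s in interactors.items()},
        shared=shared,
        frequent_background=frequent,
    )
    return SyntheticDataset(
        quant=quant, design=design, repository=repository, truth=truth, config=cfg
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the same dialects the pipeline consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "protein_groups": directory / "proteinGroups.txt",
        "design": directory / "design.tsv",
        "repository": directory / "contaminant_repository.tsv",
        "truth": directory / "truth.tsv",
    }
    write_protein_groups(dataset.quant, paths["protein_groups"])
    write_design(dataset.design, paths["design"])
    write_contaminant_repository(dataset.repository, paths["repository"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("prey\ttrue_interactor_of\tbackground_class\n")
        for prey in dataset.quant.intensities.index:
            baits = ";".join(sorted(dataset.truth.true_interactor_of(prey)))
            cls = "frequent" if prey in dataset.truth.frequent_background else "rare"
            fh.write(f"{prey}\t{baits}\t{cls}\n")
    return paths


def evaluate_recovery(
    calls: Mapping[str, InteractorCallSet], truth: SyntheticTruth
) -> dict:
    """Precision/recall/F1 of interactor calls against the planted truth.

    An empty call set has recall 0 and precision reported as NaN (no calls
    to be right or wrong about). ``shared_recall`` is the fraction of
    planted shared preys called for *every* bait they were planted in.
    """
    metrics: dict = {"per_bait": {}}
    for bait, truth_set in truth.interactors.items():
        called = calls[bait].preys if bait in calls else frozenset()
        tp = len(called & truth_set)
        precision = tp / len(called) if called else float("nan")
        recall = tp / len(truth_set) if truth_set else float("nan")
        if called and truth_set and (precision + recall) > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = 0.0 if called or truth_set else float("nan")
        metrics["per_bait"][bait] = {
            "n_called": len(called),
            "n_true": len(truth_set),
            "tp": tp,
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    if truth.shared:
        recovered = sum(
            1
            for prey in truth.shared
            if all(prey in calls[b].preys for b in truth.interactors if b in calls)
            and len(calls) == len(truth.interactors)
        )
        metrics["shared_recall"] = recovered / len(truth.shared)
    else:
        metrics["shared_recall"] = float("nan")
    all_called = frozenset().union(*(c.preys for c in calls.values())) if calls else frozenset()
    metrics["frequent_background_called"] = len(all_called & truth.frequent_background)
    return metrics
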