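"""End-to-end AP-MS analysis orchestration from a single YAML config.

Stage order: read protein groups -> drop flagged rows -> log2 transform and
collapse technical replicates -> valid-value filter -> MiST scoring ->
dual-threshold interactor calling -> contaminant-frequency filter ->
enrichment ranking -> bait comparison -> exports. Every parameter defaults
to the published procedure's value (k_valid=3, tau_bait=tau_igg=0.75,
f_max=0.40), so a bare config reproduces it.

``run_pipeline`` writes all artifacts plus a machine-readable JSON report
with per-stage survivor counts, the parameters used, and SHA-256 digests of
every output file; identical inputs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import compare_report, filters, io_quant, mist

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run."""

    protein_groups: str
    design: str
    repository: str
    outdir: str
    gmt: str | None = None
    universe: str | None = None
    k_valid: int = 3
    tau_bait: float = 0.75
    tau_igg: float = 0.75
    f_max: float = 0.40
    weights: dict[str, float] = field(
        default_factory=lambda: {"w_R": mist.DEFAULT_WEIGHTS.w_R,
                                 "w_A": mist.DEFAULT_WEIGHTS.w_A,
                                 "w_S": mist.DEFAULT_WEIGHTS.w_S}
    )
    top_n: int = 20
    alpha: float = 0.05
    scoring: str = "per_control_pair"

    def __post_init__(self) -> None:
        for name in ("tau_bait", "tau_igg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.f_max <= 1.0:
            raise ConfigError(f"f_max must lie in (0, 1], got {self.f_max}")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.k_valid < 0:
            raise ConfigError("k_valid must be >= 0")
        if self.top_n < 0:
            raise ConfigError("top_n must be >= 0")
        if self.scoring not in ("per_control_pair", "joint"):
            raise ConfigError(
                f"scoring must be 'per_control_pair' or 'joint', got {self.scoring!r}"
            )
        if (self.gmt is None) != (self.universe is None):
            raise ConfigError("gmt and universe must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def mist_weights(self) -> mist.MistWeights:
        return mist.MistWeights(**self.weights)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorate


@dataclass
class AnalysisResult:
    """In-memory result of the core analysis (no file I/O)."""

    matrix: io_quant.CollapsedMatrix
    records: Any
    call_sets: dict[str, filters.InteractorCallSet]
    comparison: compare_report.SharedUniqueResult | None
    stage_counts: dict[str, Any]


def analyze(
    quant: io_quant.QuantTable,
    repo: filters.ContaminantRepository,
    cfg: PipelineConfig,
) -> AnalysisResult:
    """Run the analysis stages on in-memory inputs."""
    counts: dict[str, Any] = {"input_rows": quant.n_rows}

    clean = _stage("drop_flagged_rows")(io_quant.drop_flagged_rows)(quant)
    counts["after_flag_filter"] = clean.n_rows

    collapsed = _stage("log2_collapse")(io_quant.log2_collapse)(clean)
    matrix = _stage("filter_min_valid")(io_quant.filter_min_valid)(collapsed, cfg.k_valid)
    counts["after_min_valid"] = len(matrix.values)

    weights = cfg.mist_weights()
    control = matrix.control
    score = _stage("score_dataset")(mist.score_dataset)
    call = _stage("call_interactors")(filters.call_interactors)
    if cfg.scoring == "joint":
        records = score(matrix, weights)
        call_sets = call(records, cfg.tau_bait, cfg.tau_igg, control=control)
    else:
        import pandas as pd

        frames = []
        call_sets = {}
        for bait in matrix.test_baits:
            rec = score(matrix, weights, baits=[bait, control])
            rec = rec.assign(scoring_group=f"{bait}|{control}")
            frames.append(rec)
            call_sets[bait] = call(
                rec.drop(columns="scoring_group"), cfg.tau_bait, cfg.tau_igg, control=control
            )[bait]
        records = pd.concat(frames, ignore_index=True)

    counts["called"] = {b: len(cs) for b, cs in call_sets.items()}

    freq = _stage("frequency_filter")(filters.frequency_filter)
    rank = _stage("rank_by_enrichment")(filters.rank_by_enrichment)
    for bait in list(call_sets):
        call_sets[bait] = rank(freq(call_sets[bait], repo, cfg.f_max), matrix)
    counts["after_frequency_filter"] = {b: len(cs) for b, cs in call_sets.items()}

    comparison = None
    test_baits = matrix.test_baits
    if len(test_baits) >= 2:
        comparison = _stage("compare_baits")(compare_report.compare_baits)(
            call_sets[test_baits[0]], call_sets[test_baits[1]]
        )
        shared, ua, ub = comparison.counts
        counts["comparison"] = {
            "baits": [comparison.bait_a, comparison.bait_b],
            "shared": shared,
            f"unique_{comparison.bait_a}": ua,
            f"unique_{comparison.bait_b}": ub,
        }
    return AnalysisResult(
        matrix=matrix, records=records, call_sets=call_sets,
        comparison=comparison, stage_counts=counts,
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline from files to artifacts; return the JSON report."""
    for name in ("protein_groups", "design", "repository", "gmt", "universe"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{name} path does not exist: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    design = _stage("read_design")(io_quant.read_design)(cfg.design)
    quant = _stage("read_protein_groups")(io_quant.read_protein_groups)(
        cfg.protein_groups, design
    )
    repo = _stage("load_contaminant_repository")(filters.load_contaminant_repository)(
        cfg.repository
    )
    result = analyze(quant, repo, cfg)
    matrix, call_sets = result.matrix, result.call_sets

    written: dict[str, Path] = {}
    io_quant.write_collapsed(matrix, outdir / "collapsed_matrix.tsv")
    written["collapsed_matrix"] = outdir / "collapsed_matrix.tsv"
    mist.write_records(result.records, outdir / "mist_records.tsv")
    written["mist_records"] = outdir / "mist_records.tsv"
    for bait, cs in call_sets.items():
        p = outdir / f"calls_{bait}.tsv"
        filters.write_calls(cs, p)
        written[f"calls_{bait}"] = p
        hm = compare_report.heatmap_matrix(matrix, cs, min(cfg.top_n, len(cs)))
        hp = outdir / f"heatmap_{bait}.tsv"
        compare_report.write_heatmap(hm, hp)
        written[f"heatmap_{bait}"] = hp
    if result.comparison is not None:
        net = _stage("export_network")(compare_report.export_network)(
            result.comparison, outdir
        )
        written["network_sif"] = net["sif"]
        written["node_attributes"] = net["node_attributes"]

    if cfg.gmt is not None:
        annotations = compare_report.read_gmt(cfg.gmt)
        universe = {
            line.strip()
            for line in Path(cfg.universe).read_text(encoding="utf-8").splitlines()
            if line.strip()
        }
        for bait, cs in call_sets.items():
            query = set(cs.preys) & universe
            enr = _stage("overrepresentation")(compare_report.overrepresentation)(
                query, annotations, universe, cfg.alpha
            )
            p = outdir / f"enrichment_{bait}.tsv"
            compare_report.write_enrichment(enr, p)
            written[f"enrichment_{bait}"] = p

    report = {
        "parameters": asdict(cfg),
        "stage_counts": result.stage_counts,
        "provenance": {b: cs.provenance for b, cs in call_sets.items()},
        "outputs": {k: str(p) for k, p in written.items()},
        "digests": {k: _sha256(p) for k, p in sorted(written.items())},
    }
    report_path = outdir / "report.json"
    report_path.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    logger.info("pipeline complete: report at %s", report_path)
    return report
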