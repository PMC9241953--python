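"""End-to-end orchestration: read -> normalize -> merge -> fit -> classify -> write.

`run_pipeline` executes the stage chain on a counts file plus a lengths
file, writes the ranked calls table and a machine-readable run record
(parameters, seed, observation bookkeeping, fit summary, exclusion log),
and returns the calls.  Identical configuration and seed reproduce
byte-identical outputs; ``replay`` re-runs a pipeline from nothing but its
run record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import gmm, scoring
from .errors import PipelineStageError, ValidationError
from .io_tables import (
    CountTable,
    InteractorCall,
    read_count_table,
    read_de_table,
    read_lengths,
    read_phase_annotation,
    write_calls,
)

__all__ = ["RunConfig", "run_pipeline", "replay", "run_phase_sort"]

logger = logging.getLogger(__name__)

RUN_RECORD_NAME = "run_record.json"
CALLS_NAME = "calls.tsv"
FIT_SUMMARY_NAME = "fit_summary.txt"
EXCLUSIONS_NAME = "exclusions.tsv"


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one scoring run."""

    counts_path: str
    lengths_path: str
    bait_id: str
    dialect: str = "long"
    fit: gmm.FitConfig = field(default_factory=gmm.FitConfig)
    posterior_threshold: float = 0.5
    count_threshold: int = 5
    count_mode: str = "total"
    pseudocount: float = 0.0
    min_observations: int = 10
    out_dir: str = "pullcall_out"

    def __post_init__(self) -> None:
        if not self.bait_id:
            raise ValidationError("bait_id must be non-empty")
        if not (0.0 < self.posterior_threshold < 1.0):
            raise ValidationError("posterior_threshold must lie in (0, 1)")
        if self.count_threshold < 0:
            raise ValidationError("count_threshold must be >= 0")


def _stage(name: str):
    """Decorator-free helper: run fn(), re-raising with the stage name attached."""

    class _Ctx:
        def __init__(self, stage_name: str):
            self.name = stage_name

        def __enter__(self):
            logger.info("stage: %s", self.name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(self.name, exc) from exc
            return False

    return _Ctx(name)


def run_pipeline(config: RunConfig) -> list[InteractorCall]:
    """Execute the full scoring chain and write artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        table = read_count_table(config.counts_path, config.dialect, config.bait_id)
        table = table.attach_lengths(read_lengths(config.lengths_path))
    with _stage("length_normalize"):
        values = scoring.length_normalize(table, pseudocount=config.pseudocount)
    with _stage("bait_normalize"):
        values = scoring.bait_normalize(values, config.bait_id)
    with _stage("merge_and_log2"):
        obs = scoring.merge_and_log2(
            values, config.bait_id, min_observations=config.min_observations
        )
    with _stage("fit_gmm"):
        fit = gmm.fit_gmm(obs.values, config.fit)
    with _stage("classify"):
        calls = scoring.classify(
            obs,
            fit,
            table,
            posterior_threshold=config.posterior_threshold,
            count_threshold=config.count_threshold,
            count_mode=config.count_mode,
        )
    with _stage("write"):
        write_calls(out / CALLS_NAME, calls)
        (out / FIT_SUMMARY_NAME).write_text(fit.summary(), encoding="utf-8")
        _write_exclusions(out / EXCLUSIONS_NAME, obs)
        _write_run_record(out / RUN_RECORD_NAME, config, table, obs, fit)
    return calls


def _write_exclusions(path: Path, obs: scoring.ObservationSet) -> None:
    lines = ["protein_id\tassay_id\treason"]
    lines += [f"{p}\t{a}\t{r}" for p, a, r in obs.excluded]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _write_run_record(
    path: Path,
    config: RunConfig,
    table: CountTable,
    obs: scoring.ObservationSet,
    fit: gmm.MixtureFit,
) -> None:
    record = {
        "config": asdict(config),
        "data": {
            "n_proteins": len(table.proteins),
            "n_assays": len(table.assays),
            "n_observations": int(len(obs.entries)),
            "n_excluded_bait": sum(1 for _, _, r in obs.excluded if r == "bait"),
            "n_excluded_zero": sum(1 for _, _, r in obs.excluded if r == "zero-count"),
        },
        "fit": {
            "k": fit.k,
            "weights": list(fit.weights),
            "means": list(fit.means),
            "variances": list(fit.variances),
            "log_likelihood": fit.log_likelihood,
            "n_iter": fit.n_iter,
            "converged": fit.converged,
            "seed": fit.seed,
        },
    }
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def replay(record_path: str | Path, out_dir: str | Path | None = None) -> list[InteractorCall]:
    """Re-run a pipeline from its run record alone.

    The record carries every parameter including the seed, so the replay
    reproduces the original calls file byte for byte (inputs unchanged).
    """
    record = json.loads(Path(record_path).read_text(encoding="utf-8"))
    cfg_dict = dict(record["config"])
    cfg_dict["fit"] = gmm.FitConfig(**cfg_dict["fit"])
    if out_dir is not None:
        cfg_dict["out_dir"] = str(out_dir)
    return run_pipeline(RunConfig(**cfg_dict))


def run_phase_sort(
    de_path: str | Path,
    annotation_path: str | Path,
    out_path: str | Path,
    lfc_threshold: float = 1.5,
    padj_threshold: float | None = 0.1,
) -> dict[str, list[str]]:
    """Filter a DE table, partition by peak phase, write a grouped summary.

    The summary is three-column tab-separated (transcript_id, group,
    log2_change) with a trailing per-group count block as comments.
    """
    de = read_de_table(de_path)
    annotation = read_phase_annotation(annotation_path)
    groups = scoring.phase_sort(
        de, annotation, lfc_threshold=lfc_threshold, padj_threshold=padj_threshold
    )
    lfc = de.frame.set_index("transcript_id")["log2_change"]
    lines = ["transcript_id\tgroup\tlog2_change"]
    for group, members in groups.items():
        for tid in sorted(members):
            lines.append(f"{tid}\t{group}\t{lfc[tid]:.6g}")
    for group, members in groups.items():
        lines.append(f"# {group}\t{len(members)}")
    Path(out_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return groups
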