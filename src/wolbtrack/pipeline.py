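"""End-to-end pipeline: estimate clade frequencies, test drift, infer selection, call infection.

The pipeline mirrors the analysis of a two-timepoint evolve-and-resequence
design: pooled counts from the starting populations and from the evolved
populations are reduced to per-replicate clade frequencies, the focal
clade's frequency change is tested against the Wright–Fisher drift null,
its selection coefficient is inferred under both haploid formulations, and
(optionally) individually sequenced flies are classified as infected or
not and summarised by relative titer.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

import wolbtrack
from wolbtrack.clades import (
    CladeSNPTable,
    cumulative_frequency_check,
    estimate_clade_frequencies,
    estimates_to_frame,
)
from wolbtrack.drift import DriftTestConfig, drift_test, estimate_selection
from wolbtrack.infection import (
    call_infection,
    group_coverage_stats,
    relative_titer,
    summaries_from_frame,
)
from wolbtrack.sync_io import read_clade_table, read_coverage_table, read_sync

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Pipeline configuration; field names mirror the YAML/JSON config keys.

    Target coverage defaults to 50x, the standard downsampling depth for
    the symbiont genome (use 100 for mtDNA panels).
    """

    sync_start: str
    sync_end: str
    clade_table: str
    output_dir: str
    focal_clade: str
    coverage_table: str | None = None
    target_coverage: int = 50
    effective_size: int = 75
    generations: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_coverage < 1:
            raise ValueError("target_coverage must be >= 1")
        if self.effective_size < 1:
            raise ValueError("effective_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a key-value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("sync_start", "sync_end", "clade_table", "coverage_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")


def _stage(name: str):
    """Decorator wrapping stage errors with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return inner

    return wrap


def _pseudo_clip(freq: float, coverage: int) -> float:
    """Clip a frequency away from 0/1 by half a read at the working coverage,
    so odds stay defined for selection inference."""
    eps = 1.0 / (2.0 * coverage)
    return min(max(freq, eps), 1.0 - eps)


@_stage("estimate")
def _estimate(config: PipelineConfig, table: CladeSNPTable, seed_seq) -> tuple:
    start_records = read_sync(config.sync_start)
    end_records = read_sync(config.sync_end)
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(2)]
    start_est = estimate_clade_frequencies(
        start_records, table, config.target_coverage, rngs[0]
    )
    end_est = estimate_clade_frequencies(
        end_records, table, config.target_coverage, rngs[1]
    )
    return start_est, end_est


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle under ``config.output_dir``.

    Outputs: ``clade_frequencies.tsv`` (both timepoints),
    ``cumulative_check.tsv``, ``drift_selection.tsv`` (per-replicate p and
    s plus combined values), optional ``infection_calls.tsv`` and
    ``coverage_group_stats.tsv``, a ``summary.json``, and ``run_log.txt``
    recording seed and versions. Returns the summary dict. Any stage error
    raises :class:`PipelineStageError` naming the stage.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(config.seed)

    table = CladeSNPTable.from_frame(read_clade_table(config.clade_table))

    start_est, end_est = _estimate(config, table, seed_seq)
    freq_frames = []
    for label, est in (("start", start_est), ("end", end_est)):
        df = estimates_to_frame(est)
        df.insert(0, "timepoint", label)
        freq_frames.append(df)
    freq_df = pd.concat(freq_frames, ignore_index=True)
    freq_df.to_csv(outdir / "clade_frequencies.tsv", sep="\t", index=False)

    # cumulative check on both timepoints
    check_frames = []
    for label, est in (("start", start_est), ("end", end_est)):
        chk = cumulative_frequency_check(est)
        chk.insert(0, "timepoint", label)
        check_frames.append(chk)
    check_df = pd.concat(check_frames, ignore_index=True)
    check_df.to_csv(outdir / "cumulative_check.tsv", sep="\t", index=False)

    # drift + selection on the focal clade
    try:
        start_by_rep = {
            e.replicate: e for e in start_est if e.clade == config.focal_clade
        }
        end_by_rep = {e.replicate: e for e in end_est if e.clade == config.focal_clade}
        if not start_by_rep or not end_by_rep:
            raise ValueError(f"focal clade {config.focal_clade!r} not in estimates")
        reps = [r for r in start_by_rep if r in end_by_rep]
        pairs = []
        for r in reps:
            s_e, e_e = start_by_rep[r], end_by_rep[r]
            if s_e.is_missing or e_e.is_missing:
                raise ValueError(f"missing focal-clade estimate in replicate {r}")
            pairs.append((s_e.median_frequency, e_e.median_frequency))
        result = drift_test(
            DriftTestConfig(config.effective_size, config.generations, pairs)
        )
        rows = []
        for r, (p0, pt), p in zip(reps, pairs, result.per_replicate_p):
            row = {
                "replicate": r,
                "start_frequency": p0,
                "end_frequency": pt,
                "p_drift": p,
            }
            if config.generations >= 1:
                c0 = _pseudo_clip(p0, config.target_coverage)
                ct = _pseudo_clip(pt, config.target_coverage)
                row["s_discrete"] = estimate_selection(c0, ct, config.generations, "discrete")
                row["s_logit"] = estimate_selection(c0, ct, config.generations, "logit")
            rows.append(row)
        drift_df = pd.DataFrame(rows)
        drift_df.to_csv(outdir / "drift_selection.tsv", sep="\t", index=False)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("drift-test", str(exc)) from exc

    summary: dict = {
        "seed": config.seed,
        "focal_clade": config.focal_clade,
        "effective_size": config.effective_size,
        "generations": config.generations,
        "combined_p": result.combined_p,
        "fisher_p": result.fisher_p,
        "per_replicate_p": result.per_replicate_p,
        "cumulative_check": check_df.to_dict(orient="records"),
    }
    if config.generations >= 1:
        summary["s_discrete"] = [r["s_discrete"] for r in rows]
        summary["s_logit"] = [r["s_logit"] for r in rows]

    if config.coverage_table is not None:
        try:
            summaries = summaries_from_frame(read_coverage_table(config.coverage_table))
            calls = [call_infection(s) for s in summaries]
            calls_df = pd.DataFrame(
                [
                    {
                        "sample_id": c.sample_id,
                        "infected": c.infected,
                        "wolbachia_nuclear_ratio": c.ratio,
                        "wolbachia_breadth": c.breadth,
                        "mtdna_nuclear_ratio": relative_titer(s, "mtdna"),
                    }
                    for c, s in zip(calls, summaries)
                ]
            )
            calls_df.to_csv(outdir / "infection_calls.tsv", sep="\t", index=False)
            grouping = {
                c.sample_id: "infected" if c.infected else "uninfected" for c in calls
            }
            stats = pd.concat(
                [
                    group_coverage_stats(summaries, grouping, genome)
                    for genome in ("nuclear", "wolbachia", "mtdna")
                ],
                ignore_index=True,
            )
            stats.to_csv(outdir / "coverage_group_stats.tsv", sep="\t", index=False)
            summary["n_infected"] = int(sum(c.infected for c in calls))
            summary["n_samples"] = len(calls)
        except Exception as exc:
            raise PipelineStageError("infection", str(exc)) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(
            f"wolbtrack {wolbtrack.__version__}\n"
            f"python {platform.python_version()}\n"
            f"numpy {np.__version__}\npandas {pd.__version__}\n"
            f"seed {config.seed}\n"
            f"config {json.dumps(asdict(config))}\n"
        )
    return summary
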