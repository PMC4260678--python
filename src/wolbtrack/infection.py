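"""Sequencing-based Wolbachia infection calling and relative titer estimation.

An individually sequenced fly is called infected when its reads cover more
than 95% of the Wolbachia reference genome AND its Wolbachia/nuclear mean
depth ratio exceeds one (both strict). Uninfected flies still show traces
of Wolbachia-like coverage (homologous bacterial reads, index hopping), but
at ratios far below one, so the two rules cleanly separate the classes.

Relative titer — symbiont or mtDNA copy number per host cell — is proxied
by the ratio of mean sequencing depth on the target genome to mean depth on
the host nuclear genome, which cancels library size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CoverageSummary",
    "InfectionCall",
    "call_infection",
    "relative_titer",
    "group_coverage_stats",
    "load_base_population_coverage",
    "round_half_away",
    "BREADTH_THRESHOLD",
    "RATIO_THRESHOLD",
]

#: Minimum fraction of the Wolbachia genome that must be covered >=1x (strict).
BREADTH_THRESHOLD = 0.95
#: Minimum Wolbachia/nuclear depth ratio (strict).
RATIO_THRESHOLD = 1.0


@dataclass(frozen=True)
class CoverageSummary:
    """Per-sample mean depths and Wolbachia breadth of coverage."""

    sample_id: str
    mean_depth_nuclear: float
    mean_depth_wolbachia: float
    mean_depth_mtdna: float
    wolbachia_breadth: float

    def __post_init__(self) -> None:
        for name in ("mean_depth_nuclear", "mean_depth_wolbachia", "mean_depth_mtdna"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.wolbachia_breadth <= 1.0:
            raise ValueError("wolbachia_breadth must be in [0, 1]")


@dataclass(frozen=True)
class InfectionCall:
    sample_id: str
    infected: bool
    ratio: float
    breadth: float


def relative_titer(summary: CoverageSummary, target: str = "wolbachia") -> float:
    """Target-genome depth normalised by nuclear depth.

    ``target`` selects the Wolbachia or mtDNA genome. Scale-invariant:
    multiplying all depths by a constant (more sequencing) leaves the
    ratio unchanged.
    """
    if summary.mean_depth_nuclear <= 0:
        raise ZeroDivisionError(
            f"{summary.sample_id}: nuclear depth is 0, titer ratio undefined"
        )
    if target == "wolbachia":
        return summary.mean_depth_wolbachia / summary.mean_depth_nuclear
    if target == "mtdna":
        return summary.mean_depth_mtdna / summary.mean_depth_nuclear
    raise ValueError(f"unknown target {target!r}; use 'wolbachia' or 'mtdna'")


def call_infection(summary: CoverageSummary) -> InfectionCall:
    """Apply the two-rule infection criterion (breadth > 0.95 and ratio > 1)."""
    ratio = relative_titer(summary, "wolbachia")
    infected = (summary.wolbachia_breadth > BREADTH_THRESHOLD) and (
        ratio > RATIO_THRESHOLD
    )
    return InfectionCall(summary.sample_id, infected, ratio, summary.wolbachia_breadth)


def group_coverage_stats(
    summaries: Sequence[CoverageSummary],
    grouping: Mapping[str, str],
    genome: str = "nuclear",
) -> pd.DataFrame:
    """Mean and sample (n-1) standard deviation of depth per group.

    ``genome`` is one of nuclear / wolbachia / mtdna. Groups of size 1
    report the mean with a missing SD (NaN).
    """
    attr = {
        "nuclear": "mean_depth_nuclear",
        "wolbachia": "mean_depth_wolbachia",
        "mtdna": "mean_depth_mtdna",
    }.get(genome)
    if attr is None:
        raise ValueError(f"unknown genome {genome!r}")
    by_group: dict[str, list[float]] = {}
    for s in summaries:
        if s.sample_id not in grouping:
            raise KeyError(f"sample {s.sample_id!r} has no group assignment")
        by_group.setdefault(grouping[s.sample_id], []).append(getattr(s, attr))
    rows = []
    for group in sorted(by_group):
        vals = np.asarray(by_group[group], dtype=float)
        if vals.size == 0:
            raise ValueError(f"group {group!r} is empty")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
        rows.append(
            {"group": group, "genome": genome, "n": vals.size, "mean": float(vals.mean()), "sd": sd}
        )
    return pd.DataFrame(rows, columns=["group", "genome", "n", "mean", "sd"])


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (12.295 -> 12.30), as in tabulated output."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def summaries_from_frame(df: pd.DataFrame) -> list[CoverageSummary]:
    """Build :class:`CoverageSummary` objects from a coverage TSV frame."""
    return [
        CoverageSummary(
            str(r.sample_id),
            float(r.mean_depth_nuclear),
            float(r.mean_depth_wolbachia),
            float(r.mean_depth_mtdna),
            float(r.wolbachia_breadth),
        )
        for r in df.itertuples()
    ]


def load_base_population_coverage() -> pd.DataFrame:
    """Load the packaged 12-fly base-population coverage fixture.

    Wolbachia and nuclear mean depths are the published per-individual
    values for the 12 base-population females; the per-sample mtDNA depths
    and Wolbachia breadth values are synthetic stand-ins (plausible values
    consistent with each fly's infection status), since those were never
    reported per individual.
    """
    ref = resources.files("wolbtrack.data") / "base_population_coverage.synthetic.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
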