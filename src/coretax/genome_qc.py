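"""Genome quality control from SCG copy counts.

Completeness = fraction of SCGs present in the genome (>= 1 copy);
redundancy = fraction of SCGs with two or more copies. Genomes pass QC when
completeness is strictly above the minimum and redundancy strictly below the
maximum (the published thresholds are >90% and <10%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualityRecord:
    genome_id: str
    completeness: float
    redundancy: float
    passed: bool
    reason: str = ""


def compute_genome_quality(matrix: pd.DataFrame, genome_id: str,
                           completeness_min: float = 0.90,
                           redundancy_max: float = 0.10) -> QualityRecord:
    """Quality record for one genome from the (final-SCG) copy matrix."""
    if matrix.shape[1] == 0:
        raise ValueError("copy matrix has zero SCGs")
    if genome_id not in matrix.index:
        raise KeyError(f"genome {genome_id!r} not in copy matrix")
    row = matrix.loc[genome_id]
    completeness = float((row >= 1).mean())
    redundancy = float((row >= 2).mean())
    passed = completeness > completeness_min and redundancy < redundancy_max
    reasons = []
    if completeness <= completeness_min:
        reasons.append(f"completeness {completeness:.4f} <= {completeness_min}")
    if redundancy >= redundancy_max:
        reasons.append(f"redundancy {redundancy:.4f} >= {redundancy_max}")
    return QualityRecord(genome_id=genome_id, completeness=completeness,
                         redundancy=redundancy, passed=passed,
                         reason="; ".join(reasons))


def assess_all_genomes(matrix: pd.DataFrame, completeness_min: float = 0.90,
                       redundancy_max: float = 0.10) -> list[QualityRecord]:
    return [compute_genome_quality(matrix, g, completeness_min, redundancy_max)
            for g in matrix.index]


def filter_genomes(records: list[QualityRecord]) -> list[str]:
    """Ids of quality-passing genomes; rejections are logged with reasons."""
    passing = []
    for r in records:
        if r.passed:
            passing.append(r.genome_id)
        else:
            logger.info("genome %s rejected: %s", r.genome_id, r.reason)
    return passing


def quality_frame(records: list[QualityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.genome_id, r.completeness, r.redundancy, r.passed, r.reason)
         for r in records],
        columns=["genome_id", "completeness", "redundancy", "passed", "reason"])
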