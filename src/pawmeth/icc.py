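"""Immunocytochemistry H-scores from per-field nucleus staining grades.

Each leukocyte nucleus is graded 0 (negative), 1 (weak), 2 (medium) or
3 (strong) for anti-5-methylcytosine immunostaining. The H-score of a sample
is the classic 0-300 statistic

    H = sum_{g=1..3} g * (100 * n_g / N)

where n_g is the number of nuclei at grade g and N the total number graded.
Fields of a sample are aggregated by pooling counts, which weights each field
by the number of nuclei it contributed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GRADE_COLUMNS

GRADES = np.arange(4)


@dataclass
class HScore:
    sample: str
    h_score: float
    grade_percent: np.ndarray  # percentage of nuclei at grades 0..3
    n_cells: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.h_score <= 300.0 + 1e-9:
            raise ValueError("H-score must lie in [0, 300]")
        if abs(float(np.sum(self.grade_percent)) - 100.0) > 1e-6:
            raise ValueError("grade percentages must sum to 100")


def h_score(counts, sample: str = "") -> HScore:
    """H-score from pooled per-grade nucleus counts ``(n0, n1, n2, n3)``."""
    c = np.asarray(counts, dtype=float)
    if c.shape != (4,):
        raise ValueError("counts must be a length-4 vector for grades 0..3")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("zero total cell count")
    pct = 100.0 * c / total
    return HScore(sample, float(np.dot(GRADES, pct)), pct, int(total))


def sample_h_score(fields: pd.DataFrame) -> HScore:
    """Pool all fields of one sample, then score the pooled counts.

    ``fields`` follows the cell-grade table layout: one row per microscopic
    field with columns ``sample``, ``field``, ``grade0..grade3``. All rows
    must belong to the same sample.
    """
    samples = fields["sample"].unique()
    if len(samples) != 1:
        raise ValueError(f"mixed sample ids in field table: {sorted(map(str, samples))}")
    if len(fields) < 1:
        raise ValueError("at least one field is required")
    pooled = fields[GRADE_COLUMNS].to_numpy(float).sum(axis=0)
    return h_score(pooled, sample=str(samples[0]))


def score_table(grades: pd.DataFrame) -> pd.DataFrame:
    """Score every sample in a cell-grade table into a tidy frame."""
    rows = []
    for sample, sub in grades.groupby("sample", sort=True):
        hs = sample_h_score(sub)
        rows.append(
            {
                "sample": sample,
                "h_score": hs.h_score,
                "n_cells": hs.n_cells,
                "pct_grade0": hs.grade_percent[0],
                "pct_grade1": hs.grade_percent[1],
                "pct_grade2": hs.grade_percent[2],
                "pct_grade3": hs.grade_percent[3],
            }
        )
    return pd.DataFrame(rows)
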