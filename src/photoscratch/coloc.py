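"""Puncta-threshold positivity calling and marker colocalization counting.

Input is tabular FISH quantification: one row per DAPI-stained nucleus with
an integer puncta count per probe channel (puncta not overlying a nucleus are
assumed filtered out upstream).  A cell is positive for a channel when its
puncta count reaches the threshold (≥ 5 by default, the cFos rule).  Overlap
between two markers is reported bidirectionally: % of A-positive cells that
are also B-positive, and vice versa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DEFAULT_MIN_PUNCTA = 5


@dataclass
class CellTable:
    """Per-nucleus puncta counts, one column per channel, optional positivity calls.

    ``data`` columns: ``cell_id``, optional ``section_id``, ``<channel>_puncta``
    (nonnegative integers) and, after :func:`call_positive`,
    ``<channel>_positive`` booleans.
    """

    data: pd.DataFrame
    thresholds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if "cell_id" not in self.data.columns:
            raise ConfigurationError("cell table needs a cell_id column")
        for col in self.puncta_columns():
            counts = self.data[col]
            if (counts < 0).any() or not np.allclose(counts, counts.astype(int)):
                raise ConfigurationError(f"{col} must hold nonnegative integers")

    def puncta_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.endswith("_puncta")]

    @property
    def channels(self) -> list[str]:
        return [c[: -len("_puncta")] for c in self.puncta_columns()]

    def __len__(self) -> int:
        return len(self.data)

    def positivity(self, channel: str) -> pd.Series:
        col = f"{channel}_positive"
        if col not in self.data.columns:
            raise ConfigurationError(
                f"channel {channel!r} has not been called; run call_positive first"
            )
        return self.data[col]


def call_positive(
    table: CellTable, channel: str, min_puncta: int = DEFAULT_MIN_PUNCTA
) -> CellTable:
    """Mark cells with ≥ ``min_puncta`` puncta in ``channel`` as positive.

    Returns a new table; counts are unchanged.
    """
    if min_puncta < 0:
        raise ConfigurationError("min_puncta must be nonnegative")
    col = f"{channel}_puncta"
    if col not in table.data.columns:
        raise ConfigurationError(f"channel {channel!r} not present in the table")
    data = table.data.copy()
    data[f"{channel}_positive"] = data[col] >= min_puncta
    return CellTable(data=data, thresholds={**table.thresholds, channel: min_puncta})


class OverlapResult(NamedTuple):
    """Bidirectional colocalization percentages with the underlying counts."""

    pct_a_pos_that_are_b: float  # 100·|A⁺∩B⁺|/|A⁺|; NaN when |A⁺| = 0
    pct_b_pos_that_are_a: float  # 100·|A⁺∩B⁺|/|B⁺|; NaN when |B⁺| = 0
    n_a: int
    n_b: int
    n_both: int


def overlap_percentages(table: CellTable, channel_a: str, channel_b: str) -> OverlapResult:
    """Percentage of A-positive cells that are B-positive, and vice versa.

    An empty denominator yields NaN (undefined), never 0; the raw counts are
    always reported.
    """
    a = table.positivity(channel_a).to_numpy()
    b = table.positivity(channel_b).to_numpy()
    n_a, n_b, n_both = int(a.sum()), int(b.sum()), int((a & b).sum())
    return OverlapResult(
        pct_a_pos_that_are_b=100.0 * n_both / n_a if n_a else math.nan,
        pct_b_pos_that_are_a=100.0 * n_both / n_b if n_b else math.nan,
        n_a=n_a,
        n_b=n_b,
        n_both=n_both,
    )


class PooledOverlap(NamedTuple):
    pooled: OverlapResult
    per_section: list[OverlapResult]
    mean_of_percentages: tuple[float, float]


def aggregate_sections(results: list[OverlapResult]) -> PooledOverlap:
    """Pool overlap counts across sections, then take percentages.

    Pooled counts (not a mean of per-section percentages) are the primary
    summary; the per-section values and their naive mean are retained for
    reporting.
    """
    if not results:
        raise ConfigurationError("need at least one section")
    n_a = sum(r.n_a for r in results)
    n_b = sum(r.n_b for r in results)
    n_both = sum(r.n_both for r in results)
    pooled = OverlapResult(
        pct_a_pos_that_are_b=100.0 * n_both / n_a if n_a else math.nan,
        pct_b_pos_that_are_a=100.0 * n_both / n_b if n_b else math.nan,
        n_a=n_a,
        n_b=n_b,
        n_both=n_both,
    )
    mean_ab = float(np.nanmean([r.pct_a_pos_that_are_b for r in results]))
    mean_ba = float(np.nanmean([r.pct_b_pos_that_are_a for r in results]))
    return PooledOverlap(pooled=pooled, per_section=results, mean_of_percentages=(mean_ab, mean_ba))
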