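"""Descriptive and inferential battery for the categorical and Likert data.

Covers the survey's §-style analyses: McNemar-Bowker symmetry tests of
paired 4-category preference tables, paired and pooled two-sample t-tests
of Likert willingness, thresholded willingness shares ("likely" means a
response above the scale midpoint 4), and the eight-cell partition of
participants by which mandated algorithms they would accept.

Conventions pinned here (they matter for matching published degrees of
freedom): the Bowker statistic counts only informative category pairs
(pair-sum > 0) toward its df — a full 4x4 table gives df 6; the
two-sample test is the pooled-variance Student t (df n1+n2-2), not
Welch; percentages are rounded half-up to one decimal place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import Condition, Frame, LikertResponse, PreferenceResponse

__all__ = [
    "PairedTable",
    "TestResult",
    "WillingnessSummary",
    "build_paired_table",
    "bowker_test",
    "paired_t_test",
    "two_sample_t_test",
    "willingness_summary",
    "overlap_partition",
    "round_percent",
]

logger = logging.getLogger(__name__)

#: Mandate conditions in the fixed order of the overlap partition.
MANDATES = (Condition.MANDATE_MOST, Condition.MANDATE_PED, Condition.MANDATE_OCC)


def round_percent(x: float) -> float:
    """Half-up rounding to one decimal place, on the percent scale."""
    return float(np.floor(x * 10 + 0.5) / 10)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    n: int


@dataclass(frozen=True)
class PairedTable:
    """k x k counts of (response under frame 1, response under frame 2)."""

    counts: np.ndarray
    labels: tuple[str, ...]
    n_excluded: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("paired table must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("labels must match table dimension")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(np.asarray(self.counts).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def build_paired_table(
    responses: list[PreferenceResponse],
    frame1: Frame,
    frame2: Frame,
    labels: tuple[str, ...] | None = None,
) -> PairedTable:
    """Cross-tabulate each participant's responses under two framings.

    Participants missing either framing are excluded (their count is
    logged and kept on the table).  RANDOM stays a category of its own.
    """
    by_frame: dict[Frame, dict[str, str]] = {frame1: {}, frame2: {}}
    for r in responses:
        if r.frame in by_frame:
            by_frame[r.frame][r.participant_id] = r.choice.value
    if labels is None:
        labels = ("MOST", "OCCUPANTS", "PEDESTRIANS", "RANDOM")
    index = {lab: i for i, lab in enumerate(labels)}
    complete = sorted(set(by_frame[frame1]) & set(by_frame[frame2]))
    n_excluded = len(set(by_frame[frame1]) | set(by_frame[frame2])) - len(complete)
    if n_excluded:
        logger.warning(
            "build_paired_table: excluded %d participant(s) missing %s or %s",
            n_excluded,
            frame1.value,
            frame2.value,
        )
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for pid in complete:
        counts[index[by_frame[frame1][pid]], index[by_frame[frame2][pid]]] += 1
    return PairedTable(counts=counts, labels=tuple(labels), n_excluded=n_excluded)


def bowker_test(table: PairedTable) -> TestResult:
    """McNemar-Bowker chi-square test of table symmetry.

    statistic = sum over informative pairs (i<j, n_ij + n_ji > 0) of
    (n_ij - n_ji)^2 / (n_ij + n_ji); df counts the informative pairs.
    On a 2x2 this is the uncorrected McNemar statistic.
    """
    c = np.asarray(table.counts, dtype=float)
    k = c.shape[0]
    statistic = 0.0
    df = 0
    for i in range(k):
        for j in range(i + 1, k):
            pair_sum = c[i, j] + c[j, i]
            if pair_sum > 0:
                statistic += (c[i, j] - c[j, i]) ** 2 / pair_sum
                df += 1
    if df == 0:
        raise ValueError("degenerate table: all off-diagonal pairs are empty")
    p = float(sps.chi2.sf(statistic, df))
    return TestResult(statistic=float(statistic), df=df, p_value=p, n=table.n)


def paired_t_test(before, after) -> TestResult:
    """Two-sided paired Student t-test (df = n - 1)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    n = before.size
    diff = before - after
    if np.all(diff == diff[0]) and diff[0] == 0:
        return TestResult(statistic=0.0, df=n - 1, p_value=1.0, n=n)
    res = sps.ttest_rel(before, after)
    return TestResult(statistic=float(res.statistic), df=n - 1, p_value=float(res.pvalue), n=n)


def two_sample_t_test(x, y) -> TestResult:
    """Two-sided pooled-variance Student t-test (df = n1 + n2 - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample must have length >= 2")
    res = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(
        statistic=float(res.statistic),
        df=x.size + y.size - 2,
        p_value=float(res.pvalue),
        n=x.size + y.size,
    )


@dataclass(frozen=True)
class WillingnessSummary:
    """Summary of one Likert condition; shares on the percent scale,
    rounded half-up to one decimal."""

    mean: float
    se: float
    median: float
    share_likely: float
    share_neither: float
    n: int


def willingness_summary(
    likert: list[LikertResponse], condition: Condition
) -> WillingnessSummary:
    """Mean/SE/median plus likely (>4) and neither (=4) shares."""
    values = np.array([r.response for r in likert if r.condition is condition], dtype=float)
    if values.size == 0:
        raise ValueError(f"no responses for condition {condition.value}")
    return WillingnessSummary(
        mean=float(values.mean()),
        se=float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0,
        median=float(np.median(values)),
        share_likely=round_percent(100.0 * (values > 4).mean()),
        share_neither=round_percent(100.0 * (values == 4).mean()),
        n=values.size,
    )


def overlap_partition(likert: list[LikertResponse]) -> pd.DataFrame:
    """Partition participants by which mandated algorithms they accept.

    A participant is "likely" to buy under a mandate when the response
    exceeds 4.  Each participant with all three mandate responses lands
    in exactly one of the 2^3 cells; incomplete participants are
    excluded with a logged count.  Returns one row per cell with boolean
    columns per mandate, the count, and the percent share (half-up, one
    decimal); shares sum to 100 up to rounding.
    """
    by_pid: dict[str, dict[Condition, int]] = {}
    for r in likert:
        if r.condition in MANDATES:
            by_pid.setdefault(r.participant_id, {})[r.condition] = r.response
    complete = {pid: v for pid, v in by_pid.items() if len(v) == len(MANDATES)}
    n_excluded = len(by_pid) - len(complete)
    if n_excluded:
        logger.warning("overlap_partition: excluded %d incomplete participant(s)", n_excluded)
    if not complete:
        raise ValueError("no participant has all three mandate responses")
    cells: dict[tuple[bool, bool, bool], int] = {}
    for v in complete.values():
        key = tuple(v[m] > 4 for m in MANDATES)
        cells[key] = cells.get(key, 0) + 1
    n = len(complete)
    rows = []
    for key in sorted(cells, reverse=True):
        rows.append(
            {
                **{m.value: k for m, k in zip(MANDATES, key)},
                "count": cells[key],
                "percent": round_percent(100.0 * cells[key] / n),
            }
        )
    # include empty cells so the partition is always exhaustive
    for a in (True, False):
        for b in (True, False):
            for c in (True, False):
                if (a, b, c) not in cells:
                    rows.append(
                        {
                            **{m.value: k for m, k in zip(MANDATES, (a, b, c))},
                            "count": 0,
                            "percent": 0.0,
                        }
                    )
    out = pd.DataFrame(rows)
    out.attrs["n"] = n
    out.attrs["n_excluded"] = n_excluded
    return out
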