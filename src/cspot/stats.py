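"""Bespoke inferential statistics for the block-design experiments.

Two study-specific procedures are implemented here:

* a randomization test based on the F statistic for the effect of a
  systemic drug on baseline striatal responding, comparing the pre-drug
  period (blocks 1-4) with the post-drug baseline period (blocks 5-12).
  Channels are treated as blocks of a two-way additive layout
  (period + channel); the period F statistic is referred to its
  permutation distribution obtained by shuffling period labels among
  blocks independently within each channel;
* the Pearson chi-square comparison of proportions of potentiated
  channels between treatment groups (2x2, df = 1, no continuity
  correction by default).

Standard tests used around these (Mann-Whitney, Wilcoxon, Kruskal-Wallis,
repeated-measures ANOVA) are deliberately left to scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PeriodComparison",
    "RandomizationFResult",
    "randomization_f_test",
    "proportion_chi_square",
    "group_timecourse",
]


@dataclass
class PeriodComparison:
    """Per-channel per-block response values split into periods A and B.

    ``table`` has columns channel_id, block, period ('A' or 'B'), value;
    every (channel, block) belongs to exactly one period and every channel
    contributes the same block layout.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel_id", "block", "period", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"PeriodComparison table lacks columns {sorted(missing)}")
        dup = self.table.duplicated(subset=["channel_id", "block"])
        if dup.any():
            raise ValueError("a (channel, block) value is assigned to both periods")

    @classmethod
    def from_arrays(
        cls,
        values_a: np.ndarray,
        values_b: np.ndarray,
        channel_ids: Optional[Sequence[int]] = None,
    ) -> "PeriodComparison":
        """Build from (channels x blocks) arrays of period A and B values."""
        values_a = np.atleast_2d(np.asarray(values_a, dtype=float))
        values_b = np.atleast_2d(np.asarray(values_b, dtype=float))
        if values_a.shape[0] != values_b.shape[0]:
            raise ValueError("period arrays must share the channel dimension")
        channels = list(channel_ids) if channel_ids is not None else list(
            range(values_a.shape[0])
        )
        rows = []
        for i, ch in enumerate(channels):
            for b, v in enumerate(values_a[i]):
                rows.append({"channel_id": ch, "block": b, "period": "A", "value": v})
            for b, v in enumerate(values_b[i]):
                rows.append(
                    {
                        "channel_id": ch,
                        "block": values_a.shape[1] + b,
                        "period": "B",
                        "value": v,
                    }
                )
        return cls(pd.DataFrame(rows))

    def as_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(channels x blocks value matrix, per-block boolean 'is period B').

        Requires every channel to share the same block/period layout.
        """
        pivot = self.table.pivot(index="channel_id", columns="block", values="value")
        if pivot.isna().any().any():
            raise ValueError("unbalanced layout: channels differ in blocks")
        labels = (
            self.table.drop_duplicates("block").set_index("block")["period"].sort_index()
        )
        per_block = self.table.pivot(index="channel_id", columns="block", values="period")
        if not (per_block.nunique() == 1).all():
            raise ValueError("channels disagree on block period assignment")
        return pivot.to_numpy(dtype=float), (labels.to_numpy() == "B")


@dataclass(frozen=True)
class RandomizationFResult:
    F: float
    p: float
    n_permutations: int
    df_period: int
    df_residual: int
    degenerate: bool = False


def _period_f(y: np.ndarray, is_b: np.ndarray) -> tuple[float, float]:
    """Period and residual sums of squares of the additive two-way layout.

    Valid for proportional layouts (every channel has the same number of
    A and B blocks), where the period and channel effects are orthogonal.
    """
    n_channels, n_blocks = y.shape
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_channel = float(n_blocks * ((y.mean(axis=1) - grand) ** 2).sum())
    n_b = int(is_b.sum())
    n_a = n_blocks - n_b
    mean_b = y[:, is_b].mean()
    mean_a = y[:, ~is_b].mean()
    ss_period = float(
        n_channels * n_a * (mean_a - grand) ** 2
        + n_channels * n_b * (mean_b - grand) ** 2
    )
    ss_resid = ss_total - ss_channel - ss_period
    return ss_period, ss_resid


def randomization_f_test(
    data: PeriodComparison,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> RandomizationFResult:
    """Randomization test of the period effect based on the F statistic.

    F is the between-period mean square over the residual mean square of
    the additive period + channel decomposition. The p-value counts
    permutations (period labels shuffled among blocks independently within
    each channel) whose F is at least the observed one, with the observed
    statistic included (add-one rule), so p is never zero.
    """
    y, is_b = data.as_matrix()
    n_channels, n_blocks = y.shape
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if not (is_b.any() and (~is_b).any()):
        raise ValueError("both periods must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    df_period = 1
    df_resid = n_channels * n_blocks - n_channels - 1

    ss_period, ss_resid = _period_f(y, is_b)
    if ss_resid <= 1e-12 * max(1.0, abs(ss_period)):
        return RandomizationFResult(
            F=float("inf") if ss_period > 0 else 0.0,
            p=1.0 / (1.0 + n_permutations),
            n_permutations=n_permutations,
            df_period=df_period,
            df_residual=df_resid,
            degenerate=True,
        )
    f_obs = (ss_period / df_period) / (ss_resid / df_resid)

    # Permute period labels within each channel. The channel SS is
    # invariant under within-channel shuffles, so only SS_period (hence
    # SS_resid = SS_total - SS_channel - SS_period) changes.
    n_b = int(is_b.sum())
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_channel = float(n_blocks * ((y.mean(axis=1) - grand) ** 2).sum())
    count = 0
    # vectorised over permutations in manageable chunks
    chunk = 250
    done = 0
    n_a = n_blocks - n_b
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        # for each (perm, channel) draw a random subset of n_b blocks as B
        order = np.argsort(rng.random((m, n_channels, n_blocks)), axis=-1)
        sel_b = order[..., :n_b]  # (m, C, n_b) indices of period-B blocks
        sum_b = np.take_along_axis(
            np.broadcast_to(y, (m, n_channels, n_blocks)), sel_b, axis=-1
        ).sum(axis=(1, 2))
        total_sum = y.sum()
        mean_b = sum_b / (n_channels * n_b)
        mean_a = (total_sum - sum_b) / (n_channels * n_a)
        ss_period_perm = n_channels * n_a * (mean_a - grand) ** 2 + n_channels * n_b * (
            mean_b - grand
        ) ** 2
        ss_resid_perm = ss_total - ss_channel - ss_period_perm
        f_perm = (ss_period_perm / df_period) / (ss_resid_perm / df_resid)
        count += int((f_perm >= f_obs).sum())
        done += m

    p = (1.0 + count) / (1.0 + n_permutations)
    return RandomizationFResult(
        F=float(f_obs),
        p=float(p),
        n_permutations=n_permutations,
        df_period=df_period,
        df_residual=df_resid,
    )


def proportion_chi_square(
    a_pot: int, a_tot: int, b_pot: int, b_tot: int, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 potentiated/total table (df = 1).

    No continuity correction by default. Raises on a zero margin
    (no potentiated channels anywhere, or none un-potentiated).
    """
    if a_tot <= 0 or b_tot <= 0:
        raise ValueError("group totals must be positive")
    if a_pot > a_tot or b_pot > b_tot or min(a_pot, b_pot) < 0:
        raise ValueError("potentiated counts must lie in [0, total]")
    table = np.array(
        [[a_pot, a_tot - a_pot], [b_pot, b_tot - b_pot]], dtype=float
    )
    if (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate 2x2 table: a column margin is zero")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def group_timecourse(
    series: pd.DataFrame,
    value_col: str = "normalized_pct",
    subject_col: str = "subject",
    block_col: str = "block",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Per-(condition, block) mean and SEM across subjects.

    SEM uses the sample SD over subjects and is 0 for a single subject.
    """
    def _sem(x: pd.Series) -> float:
        if len(x) < 2:
            return 0.0
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    g = series.groupby([condition_col, block_col])[value_col]
    out = g.agg(mean="mean", sem=_sem, n="count").reset_index()
    return out
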