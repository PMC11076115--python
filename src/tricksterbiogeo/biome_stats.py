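"""Contingency comparisons of biome fractions and co-occurrence probabilities.

Two questions, two tools. (1) Do two groups of grid cells (e.g. the cells
where a real animal occurs vs the terrestrial background) distribute
differently across biome classes? — Pearson chi-squared on a 2xK table,
Benjamini-Hochberg FDR across the family of animal categories. (2) Is a
real animal present wherever its folklore counterpart is? — the
conditional probability P(real | trickster) = |trickster AND real| /
|trickster| with a Wilson score interval, which stays well behaved at
the proportions near 1 this analysis produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .gridding import CellId, ValidationError


@dataclass(frozen=True)
class ContingencyTable2xK:
    """Aligned biome-class counts for two groups."""

    labels: Tuple[str, ...]
    row_a: Tuple[int, ...]
    row_b: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.row_a) == len(self.row_b)):
            raise ValidationError("labels and both rows must have equal length")
        if any(x < 0 for x in self.row_a + self.row_b):
            raise ValidationError("counts must be non-negative")

    @classmethod
    def from_count_dicts(
        cls, counts_a: Dict[str, int], counts_b: Dict[str, int]
    ) -> "ContingencyTable2xK":
        labels = tuple(sorted(set(counts_a) | set(counts_b)))
        return cls(
            labels=labels,
            row_a=tuple(int(counts_a.get(l, 0)) for l in labels),
            row_b=tuple(int(counts_b.get(l, 0)) for l in labels),
        )


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    df: int
    p: float
    n_dropped_columns: int


@dataclass(frozen=True)
class CondProbResult:
    n_trickster_cells: int
    n_joint_cells: int
    p_hat: float
    ci_low: float
    ci_high: float


def chisq_2xk(t: ContingencyTable2xK, simulate_p: bool = False, n_sim: int = 9999,
              seed: int | None = None) -> ChiSqResult:
    """Pearson chi-squared test on a 2xK table, no continuity correction.

    Columns that are zero in both rows are dropped first (they carry no
    information and would corrupt the df convention); df = K' - 1 for
    the K' retained columns. ``simulate_p`` switches to a Monte-Carlo
    p-value (random multinomial tables under the margins), for the
    small-expected-count regime where the asymptotic p is unreliable.
    """
    a = np.asarray(t.row_a, dtype=float)
    b = np.asarray(t.row_b, dtype=float)
    keep = (a + b) > 0
    n_dropped = int(np.sum(~keep))
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValidationError(
            f"need >= 2 biome classes with counts; got {a.size} after dropping empty columns"
        )
    if a.sum() == 0 or b.sum() == 0:
        raise ValidationError("each row must have a positive total")
    table = np.vstack([a, b])
    stat, p, df, expected = chi2_contingency(table, correction=False)
    if simulate_p:
        p = _simulated_p(table, float(stat), n_sim=n_sim, seed=seed)
    return ChiSqResult(statistic=float(stat), df=int(df), p=float(p), n_dropped_columns=n_dropped)


def _simulated_p(table: np.ndarray, observed_stat: float, n_sim: int, seed: int | None) -> float:
    """Monte-Carlo p: resample tables with fixed row totals and the pooled
    column distribution, recompute Pearson's statistic."""
    rng = np.random.default_rng(seed)
    col_p = table.sum(axis=0) / table.sum()
    row_totals = table.sum(axis=1).astype(int)
    count = 0
    for _ in range(n_sim):
        sim = np.vstack([rng.multinomial(n, col_p) for n in row_totals]).astype(float)
        expected = np.outer(sim.sum(axis=1), sim.sum(axis=0)) / sim.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(expected > 0, (sim - expected) ** 2 / expected, 0.0)
        if contrib.sum() >= observed_stat - 1e-12:
            count += 1
    return (count + 1) / (n_sim + 1)


def fdr_bh(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adjusted]


def conditional_probability(
    trickster_cells: Set[CellId],
    real_cells: Set[CellId],
    conf: float = 0.95,
) -> CondProbResult:
    """P(real present | trickster present) over grid cells, Wilson CI.

    The estimate is the fraction of trickster-presence cells that also
    hold the corresponding real animal. Values near 1 mean the real
    animal's presence is (almost) a necessary condition for the
    folklore's presence.
    """
    if not trickster_cells:
        raise ValidationError("conditional probability undefined: no trickster cells")
    if not (0.0 < conf < 1.0):
        raise ValidationError(f"confidence level must be in (0, 1), got {conf}")
    n = len(trickster_cells)
    k = len(trickster_cells & real_cells)
    low, high = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    return CondProbResult(
        n_trickster_cells=n,
        n_joint_cells=k,
        p_hat=k / n,
        ci_low=float(low),
        ci_high=float(high),
    )
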