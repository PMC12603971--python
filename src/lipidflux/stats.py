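"""Summary statistics and approximate permutation testing for endpoint data.

The permutation test follows the common "approximate" scheme: the observed
statistic is the absolute difference of group means, the null distribution
is built from random relabelings of the pooled values at the original group
sizes, and the two-sided p-value uses the add-one correction
``p = (1 + #{null >= observed}) / (n_rounds + 1)``, which guarantees
``p >= 1/(n_rounds+1)`` and validity at finite rounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import COMPARTMENTS

__all__ = [
    "PermutationResult",
    "permutation_test",
    "summarize",
    "significance_stars",
]


@dataclass(frozen=True)
class PermutationResult:
    observed_stat: float
    p_value: float
    n_rounds: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")
        if self.p_value < 1.0 / (self.n_rounds + 1) - 1e-12:
            raise ValueError("p_value below the attainable minimum 1/(n_rounds+1)")


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_rounds: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided approximate permutation test on the difference of means."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(pooled, (n_rounds, pooled.size)), axis=1)
    null = np.abs(perms[:, : a.size].mean(axis=1) - perms[:, a.size:].mean(axis=1))
    p = (1.0 + int((null >= observed).sum())) / (n_rounds + 1.0)
    return PermutationResult(
        observed_stat=float(observed), p_value=float(p), n_rounds=n_rounds, seed=seed
    )


def summarize(
    fractions: pd.DataFrame,
    group_cols: Sequence[str] = ("probe", "time_min"),
    value_cols: Sequence[str] = COMPARTMENTS,
) -> pd.DataFrame:
    """Per-(probe, time, compartment) mean, SD, SE and replicate count.

    SD uses ddof=1; SE = SD/sqrt(n).  Both are reported as missing (NaN) for
    single-field groups.  Rows are sorted by (group columns, compartment), so
    the table does not depend on the input row order.
    """
    if fractions.empty:
        raise ValueError("fraction table is empty")
    long = fractions.melt(
        id_vars=list(group_cols),
        value_vars=list(value_cols),
        var_name="compartment",
        value_name="fraction",
    )
    out = (
        long.groupby([*group_cols, "compartment"], sort=False)["fraction"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_fields="size")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n_fields"])
    out = out[[*group_cols, "compartment", "mean", "sd", "se", "n_fields"]]
    return out.sort_values(
        [*group_cols, "compartment"], kind="stable"
    ).reset_index(drop=True)


def significance_stars(p: float) -> str:
    """Conventional star annotation: n.s. >0.05, * <=0.05 ... **** <=0.0001."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."
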