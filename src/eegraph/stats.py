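"""Permutation-based group comparison of graph measures with FDR control,
plus Pearson correlations against cognitive scores.

Every measure × band is compared between the two groups by a two-sided
permutation test on the difference of group means: the pooled subjects are
randomly relabelled ``n_perm`` times and

    p = (1 + #{ |null diff| >= |observed diff| }) / (n_perm + 1),

the add-one convention guaranteeing p in (0, 1].  When the number of
distinct relabelings C(n_A + n_B, n_A) is small (<= 10,000) the test
switches to exhaustive enumeration and the p-value is exact.  The family of
all measure × band tests is then adjusted with the Benjamini–Hochberg
step-up procedure.

Correlation p-values are reported unadjusted, matching the common
"(P < 0.05)" screening usage for post-hoc score correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import (
    CovariateTable,
    MEASURE_NAMES,
    PipelineConfig,
    UndefinedCorrelationError,
)

__all__ = [
    "GroupComparisonResult",
    "CorrelationResult",
    "permutation_test",
    "fdr_adjust",
    "compare_groups",
    "correlate",
    "demographics_summary",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class GroupComparisonResult:
    measure: str
    band: str
    mean_A: float
    mean_B: float
    observed_diff: float
    p_perm: float
    p_fdr: float
    significant: bool


@dataclass
class CorrelationResult:
    measure: str
    band: str
    score_name: str
    r: float
    p: float


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 5000,
    rng: np.random.Generator | int | None = None,
    exhaustive: bool | None = None,
) -> tuple[float, float]:
    """Two-sided permutation test on the difference of group means.

    Returns ``(observed_diff, p)`` with ``observed_diff = mean(A) - mean(B)``.
    ``exhaustive=None`` (default) enumerates all relabelings whenever
    C(n_A + n_B, n_A) <= 10,000, making the p-value exact; otherwise
    ``n_perm`` random relabelings are drawn (not necessarily distinct) and
    the add-one estimator is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.concatenate([a, b])
    na, n = a.size, a.size + b.size
    observed = float(a.mean() - b.mean())
    # relative tolerance so float round-off cannot drop tied null values
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    if exhaustive is None:
        exhaustive = comb(n, na) <= EXHAUSTIVE_LIMIT
    if exhaustive:
        total = comb(n, na)
        if total > EXHAUSTIVE_LIMIT * 10:
            raise ValueError(f"exhaustive enumeration infeasible: C({n},{na}) = {total}")
        s = pooled.sum()
        count = 0
        for idx in combinations(range(n), na):
            sa = pooled[list(idx)].sum()
            null = sa / na - (s - sa) / (n - na)
            if abs(null) >= abs(observed) - tol:
                count += 1
        return observed, count / total
    rng = np.random.default_rng(rng)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    sel = np.take(pooled, order[:, :na])
    sa = sel.sum(axis=1)
    null = sa / na - (pooled.sum() - sa) / (n - na)
    count = int((np.abs(null) >= abs(observed) - tol).sum())
    return observed, (1 + count) / (n_perm + 1)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("cannot FDR-adjust an empty p-value list")
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def compare_groups(
    metrics: pd.DataFrame,
    covariates: CovariateTable,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation test for every measure × band, FDR over the full family.

    ``metrics`` is the long-format (subject_id, band, measure, value) table.
    Group A is the first level appearing in the covariate table, group B the
    second; ``observed_diff = mean_A - mean_B``.  Returns one row per
    measure × band with columns mirroring :class:`GroupComparisonResult`
    plus the group labels.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    level_a, level_b = covariates.require_two_groups()
    groups = covariates.frame.set_index("subject_id")["group"]
    missing = set(metrics["subject_id"]) - set(groups.index)
    if missing:
        raise ValueError(f"metric rows for subjects without covariates: {sorted(missing)[:5]}")
    wide = metrics.pivot_table(
        index="subject_id", columns=["measure", "band"], values="value"
    )
    bands = list(pd.unique(metrics["band"]))
    measures = [m for m in MEASURE_NAMES if m in set(metrics["measure"])]
    ids_a = groups.index[(groups == level_a) & groups.index.isin(wide.index)]
    ids_b = groups.index[(groups == level_b) & groups.index.isin(wide.index)]
    rows = []
    ss = np.random.SeedSequence([int(seed) % (2**31), 2])
    children = ss.spawn(len(measures) * len(bands))
    i = 0
    for measure in measures:
        for band in bands:
            if (measure, band) not in wide.columns:
                raise ValueError(f"missing metric rows for {measure!r} × {band!r}")
            col = wide[(measure, band)]
            va, vb = col.loc[ids_a].to_numpy(), col.loc[ids_b].to_numpy()
            obs, p = permutation_test(
                va, vb, n_perm=config.n_permutations,
                rng=np.random.default_rng(children[i]),
            )
            rows.append(
                {
                    "measure": measure,
                    "band": band,
                    "group_A": level_a,
                    "group_B": level_b,
                    "mean_A": float(va.mean()),
                    "mean_B": float(vb.mean()),
                    "observed_diff": obs,
                    "p_perm": p,
                }
            )
            i += 1
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p_perm"].to_numpy())
    out["significant"] = out["p_fdr"] < config.fdr_level
    return out


def correlate(
    metrics: pd.DataFrame,
    covariates: CovariateTable,
    pairs: Sequence[tuple[str, str]] | None = None,
    scores: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between graph measures and cognitive scores.

    ``pairs`` selects (measure, band) combinations — default: every
    measure × band present in ``metrics``.  ``scores`` selects covariate
    score columns — default: all of them.  Constant vectors raise
    :class:`UndefinedCorrelationError`.  p-values are two-sided and
    unadjusted.
    """
    if scores is None:
        scores = covariates.score_columns
    wide = metrics.pivot_table(
        index="subject_id", columns=["measure", "band"], values="value"
    )
    cov = covariates.frame.set_index("subject_id").loc[wide.index]
    if pairs is None:
        pairs = list(wide.columns)
    rows = []
    for measure, band in pairs:
        if (measure, band) not in wide.columns:
            raise ValueError(f"no metric values for {measure!r} × {band!r}")
        x = wide[(measure, band)].to_numpy(float)
        for score in scores:
            if score not in cov.columns:
                raise ValueError(f"no covariate score column {score!r}")
            y = cov[score].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise UndefinedCorrelationError(
                    f"constant vector in ({measure}, {band}) vs {score}"
                )
            r, p = sps.pearsonr(x, y)
            rows.append(
                {"measure": measure, "band": band, "score_name": score,
                 "r": float(r), "p": float(p)}
            )
    return pd.DataFrame(rows)


def demographics_summary(covariates: CovariateTable) -> pd.DataFrame:
    """Convenience group summary: mean ± SD and Welch t-test per numeric
    covariate (demographics reporting, not part of the network analysis)."""
    level_a, level_b = covariates.require_two_groups()
    frame = covariates.frame
    numeric = ["mmse", *covariates.score_columns]
    rows = []
    for col in numeric:
        xa = frame.loc[frame["group"] == level_a, col].to_numpy(float)
        xb = frame.loc[frame["group"] == level_b, col].to_numpy(float)
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append(
            {
                "variable": col,
                f"mean_{level_a}": xa.mean(), f"sd_{level_a}": xa.std(ddof=1),
                f"mean_{level_b}": xb.mean(), f"sd_{level_b}": xb.std(ddof=1),
                "t": float(t), "p": float(p),
            }
        )
    return pd.DataFrame(rows)
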