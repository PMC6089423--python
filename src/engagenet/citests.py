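"""Discrete (conditional) independence tests and descriptive statistics.

The structure learner's association test is the G² (log-likelihood
ratio / mutual-information) test on stratified contingency tables, the
canonical discrete default for constraint-based skeleton discovery;
Pearson's X² is available as an alternative. Both are referred to a
chi-square distribution with (|X|-1)(|Y|-1)·Π|Z| degrees of freedom by
default; an adjusted-df mode drops structurally empty rows/columns per
stratum. Descriptive comparisons (Spearman rank correlation, one-way
ANOVA) mirror what is conventionally reported alongside such networks;
significance is two-tailed at alpha = 0.05 throughout.

G² = 2·Σ O·ln(O/E) summed within each conditioning stratum, which
equals 2·N times the conditional mutual information in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metadata import VariableMeta, meta_index
from .sentinels import INELIGIBLE, MISSING


class TestError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """Counts indexed by (z configuration, x level, y level)."""

    counts: np.ndarray  # shape (n_z_configs, kx, ky)
    x: str
    y: str
    z: tuple[str, ...]
    x_levels: tuple[str, ...]
    y_levels: tuple[str, ...]

    @property
    def n_used(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    test_name: str
    n_used: int


def contingency(table: pd.DataFrame, x: str, y: str,
                z: Sequence[str] = (),
                meta: Sequence[VariableMeta] | None = None,
                ineligible_as_level: bool = False) -> ContingencyTable:
    """Cross-tabulate x by y within configurations of z.

    Rows are used if complete on {x, y} ∪ z after sentinel deletion
    (available-case analysis); cells for unobserved level combinations
    are explicit zeros. With ``ineligible_as_level`` the INELIGIBLE
    sentinel is promoted to an ordinary level instead of being deleted.
    """
    cols = [x, y, *z]
    for c in cols:
        if c not in table.columns:
            raise TestError(f"unknown variable {c!r}")
    index = meta_index(meta) if meta is not None else {}

    def _codes(col: str) -> tuple[np.ndarray, tuple[str, ...]]:
        values = table[col].to_numpy()
        if col in index:
            levels = list(index[col].levels)
        else:
            drop = {MISSING} | (set() if ineligible_as_level else {INELIGIBLE})
            levels = sorted({v for v in values.tolist() if v not in drop})
        if ineligible_as_level and INELIGIBLE in values:
            if INELIGIBLE not in levels:
                levels = levels + [INELIGIBLE]
        lookup = {lv: i for i, lv in enumerate(levels)}
        codes = np.array([lookup.get(v, -1) for v in values.tolist()],
                         dtype=np.int64)
        return codes, tuple(levels)

    coded = {c: _codes(c) for c in cols}
    valid = np.ones(len(table), dtype=bool)
    for c in cols:
        valid &= coded[c][0] >= 0
    if not valid.any():
        raise TestError(f"no jointly observed rows for {cols}")

    dims = [len(coded[c][1]) for c in cols]
    flat = np.zeros(int(valid.sum()), dtype=np.int64)
    for c, k in zip(cols, dims):
        flat = flat * k + coded[c][0][valid]
    counts = np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)
    kx, ky = dims[0], dims[1]
    # reorder to (z-config, x, y)
    counts = np.moveaxis(counts.reshape(kx, ky, -1), 2, 0)
    return ContingencyTable(counts=counts, x=x, y=y, z=tuple(z),
                            x_levels=coded[x][1], y_levels=coded[y][1])


# ---------------------------------------------------------------------
# Statistics on stratified counts
# ---------------------------------------------------------------------


def _expected(stratum: np.ndarray) -> np.ndarray:
    n = stratum.sum()
    if n == 0:
        return np.zeros_like(stratum, dtype=float)
    return np.outer(stratum.sum(axis=1), stratum.sum(axis=0)) / n


def g2_statistic(counts: np.ndarray) -> float:
    """2·Σ O·ln(O/E) per stratum (0·ln0 := 0, and 0·ln(0/0) := 0)."""
    stat = 0.0
    for stratum in counts:
        expected = _expected(stratum)
        observed = stratum.astype(float)
        mask = observed > 0
        stat += 2.0 * float(
            (observed[mask] * np.log(observed[mask] / expected[mask])).sum()
        )
    return stat


def x2_statistic(counts: np.ndarray) -> float:
    """Pearson Σ (O-E)²/E per stratum; cells with E = 0 contribute 0."""
    stat = 0.0
    for stratum in counts:
        expected = _expected(stratum)
        observed = stratum.astype(float)
        mask = expected > 0
        stat += float(
            ((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        )
    return stat


def _df(counts: np.ndarray, adjust: bool) -> float:
    if not adjust:
        kz, kx, ky = counts.shape
        return float((kx - 1) * (ky - 1) * kz)
    df = 0.0
    for stratum in counts:
        kx = int((stratum.sum(axis=1) > 0).sum())
        ky = int((stratum.sum(axis=0) > 0).sum())
        df += max(kx - 1, 0) * max(ky - 1, 0)
    return float(df)


def _finish(ct: ContingencyTable, stat: float, name: str,
            adjust_df: bool) -> TestResult:
    if ct.counts.sum() == 0:
        raise TestError("all-zero contingency table")
    if ct.counts.shape[1] < 2 or ct.counts.shape[2] < 2:
        raise TestError("test requires >= 2 levels on each of x and y")
    df = _df(ct.counts, adjust_df)
    if df <= 0:
        raise TestError("non-positive degrees of freedom")
    p = float(sps.chi2.sf(stat, df))
    return TestResult(statistic=float(stat), df=df, p_value=p,
                      test_name=name, n_used=ct.n_used)


def g2_test(ct: ContingencyTable, adjust_df: bool = False) -> TestResult:
    """Conditional G² test; equals 2·N·(conditional MI in nats)."""
    return _finish(ct, g2_statistic(ct.counts), "g2", adjust_df)


def x2_test(ct: ContingencyTable, adjust_df: bool = False) -> TestResult:
    """Conditional Pearson chi-square test."""
    return _finish(ct, x2_statistic(ct.counts), "x2", adjust_df)


# ---------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------


def ordinal_codes(table: pd.DataFrame, var: str,
                  meta: Sequence[VariableMeta]) -> np.ndarray:
    """Map a column to numeric ranks (NaN for sentinels/unranked levels)."""
    m = meta_index(meta)[var]
    if not m.ordinal or not m.ordinal_ranks:
        raise TestError(f"{var} is not ordinal")
    ranks = m.ordinal_ranks
    return np.array(
        [float(ranks[v]) if v in ranks else np.nan
         for v in table[var].to_numpy().tolist()]
    )


def spearman(table: pd.DataFrame, x: str, y: str,
             meta: Sequence[VariableMeta]) -> TestResult:
    """Spearman rank correlation on pairwise-complete ordinal codes.

    ρ is the Pearson correlation of mid-ranks (average ranks for ties);
    the two-tailed p-value uses the t approximation with n-2 df.
    """
    xv = ordinal_codes(table, x, meta)
    yv = ordinal_codes(table, y, meta)
    ok = ~np.isnan(xv) & ~np.isnan(yv)
    n = int(ok.sum())
    if n < 3:
        raise TestError(f"fewer than 3 pairwise-complete rows for ({x}, {y})")
    if np.unique(xv[ok]).size < 2 or np.unique(yv[ok]).size < 2:
        raise TestError("zero variance in a rank vector")
    rho, p = sps.spearmanr(xv[ok], yv[ok])
    return TestResult(statistic=float(rho), df=float(n - 2),
                      p_value=float(p), test_name="spearman", n_used=n)


def anova_oneway(values: np.ndarray, groups: np.ndarray) -> TestResult:
    """One-way ANOVA of a numeric vector across categorical groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    labels = np.unique(groups)
    if labels.size < 2:
        raise TestError("ANOVA requires >= 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) < 1 for s in samples) or len(values) <= labels.size:
        raise TestError("ANOVA requires n > number of groups")
    k, n = labels.size, len(values)
    if all(np.allclose(s, s[0]) for s in samples) and not np.allclose(
            values, values[0]):
        # zero within-group variance but group means differ
        return TestResult(statistic=float("inf"), df=float(k - 1),
                          p_value=0.0, test_name="anova", n_used=n)
    f, p = sps.f_oneway(*samples)
    return TestResult(statistic=float(f), df=float(k - 1),
                      p_value=float(p), test_name="anova", n_used=n)
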