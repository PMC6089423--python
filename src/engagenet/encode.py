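"""Integer encoding of a cleaned survey table for fast repeated counting.

Structure learning evaluates tens of thousands of contingency tables
and local scores per run, so the string table is encoded once into an
integer code matrix (sentinel cells = -1) and all counting happens with
``np.bincount`` over flattened indices. Available-case analysis falls
out naturally: a test or family score uses the rows whose codes are
non-negative on exactly the columns involved.

Test results are memoised per table: the G² test of (x, y | S) is
symmetric in x and y, so the cache key orders the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaincc

from .metadata import VariableMeta, meta_index
from .sentinels import INELIGIBLE, MISSING


@njit(cache=True)
def _joint_counts(codesT: np.ndarray, cols: np.ndarray, cards: np.ndarray):
    """Counts over the flattened level grid of ``cols`` (complete rows).

    ``codesT`` is the (variables x rows) transpose so each scanned
    column is a contiguous stream; callers order ``cols`` rarest-first
    so the scan bails out of mostly-unobserved rows after one read.
    """
    n = codesT.shape[1]
    k = cols.size
    size = 1
    for i in range(k):
        size *= cards[i]
    counts = np.zeros(size, dtype=np.int64)
    n_used = 0
    for r in range(n):
        idx = 0
        ok = True
        for i in range(k):
            c = codesT[cols[i], r]
            if c < 0:
                ok = False
                break
            idx = idx * cards[i] + c
        if ok:
            counts[idx] += 1
            n_used += 1
    return counts, n_used


@njit(cache=True)
def _stratified_stat(counts: np.ndarray, kz: int, kx: int, ky: int,
                     pearson: bool) -> float:
    """G² (or Pearson X²) summed over conditioning strata."""
    stat = 0.0
    for z in range(kz):
        base = z * kx * ky
        nz = 0.0
        for i in range(kx * ky):
            nz += counts[base + i]
        if nz == 0.0:
            continue
        for i in range(kx):
            row = 0.0
            for j in range(ky):
                row += counts[base + i * ky + j]
            if row == 0.0:
                continue
            for j in range(ky):
                col = 0.0
                for ii in range(kx):
                    col += counts[base + ii * ky + j]
                if col == 0.0:
                    continue
                e = row * col / nz
                o = counts[base + i * ky + j]
                if pearson:
                    stat += (o - e) * (o - e) / e
                elif o > 0:
                    stat += 2.0 * o * np.log(o / e)
    return stat


@dataclass
class EncodedTable:
    names: list[str]
    codes: np.ndarray          # (n, p) int8, -1 = unobserved
    levels: list[tuple[str, ...]]
    index: dict[str, int] = field(init=False)
    _cache: dict = field(init=False, default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.index = {name: i for i, name in enumerate(self.names)}
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int8)
        self._codesT = np.ascontiguousarray(self.codes.T)
        self._observed = (self.codes >= 0).sum(axis=0)

    @property
    def n_rows(self) -> int:
        return self.codes.shape[0]

    @property
    def n_vars(self) -> int:
        return self.codes.shape[1]

    def card(self, i: int) -> int:
        return len(self.levels[i])

    @classmethod
    def from_frame(cls, table: pd.DataFrame,
                   meta: Sequence[VariableMeta],
                   ineligible_as_level: bool = False) -> "EncodedTable":
        """Encode the analysis columns of a cleaned table.

        Sentinels become -1 (unobserved); with ``ineligible_as_level``
        INELIGIBLE is appended to each gated variable's level set
        instead.
        """
        index = meta_index(meta)
        names = [c for c in table.columns if c in index]
        codes = np.empty((len(table), len(names)), dtype=np.int8)
        levels: list[tuple[str, ...]] = []
        for j, name in enumerate(names):
            lv = list(index[name].levels)
            values = table[name].to_numpy()
            if ineligible_as_level and (values == INELIGIBLE).any():
                lv = lv + [INELIGIBLE]
            lookup = {level: k for k, level in enumerate(lv)}
            codes[:, j] = np.array(
                [lookup.get(v, -1) for v in values.tolist()], dtype=np.int8
            )
            levels.append(tuple(lv))
        return cls(names=names, codes=codes, levels=levels)

    def resample(self, row_idx: np.ndarray) -> "EncodedTable":
        """Nonparametric bootstrap replicate (rows drawn with replacement)."""
        return EncodedTable(names=list(self.names),
                            codes=self.codes[row_idx],
                            levels=list(self.levels))

    # -- counting ------------------------------------------------------
    def _counts(self, cols: tuple[int, ...]) -> tuple[np.ndarray, int]:
        """Joint counts over ``cols`` in the given axis order."""
        # scan rarest-observed column first for the early bail-out, then
        # restore the caller's axis order on the (small) counts array
        order = sorted(range(len(cols)), key=lambda i: self._observed[cols[i]])
        scan_cols = np.asarray([cols[i] for i in order], dtype=np.int64)
        cards = np.asarray([self.card(c) for c in scan_cols], dtype=np.int64)
        counts, n_used = _joint_counts(self._codesT, scan_cols, cards)
        if order != sorted(order):
            inverse = np.argsort(order)
            counts = np.ascontiguousarray(
                counts.reshape(tuple(cards)).transpose(tuple(inverse))
            )
        return counts.ravel(), int(n_used)

    def family_counts(self, child: int, parents: tuple[int, ...]
                      ) -> tuple[np.ndarray, int]:
        """Counts over (parent configs, child levels) on complete rows."""
        counts, n_used = self._counts((*parents, child))
        return counts.reshape(-1, self.card(child)), n_used

    def ctab(self, x: int, y: int, zs: tuple[int, ...]
             ) -> tuple[np.ndarray, int]:
        """Counts shaped (z configs, |x|, |y|) on complete rows."""
        counts, n_used = self._counts((*zs, x, y))
        return counts.reshape(-1, self.card(x), self.card(y)), n_used

    # -- cached conditional independence test --------------------------
    def ci_test(self, x: int, y: int, zs: tuple[int, ...],
                test: str = "g2") -> tuple[float, float, float, int]:
        """(statistic, df, p, n_used) for x ⟂ y | zs.

        Untestable combinations (no jointly observed rows) are reported
        as maximally independent: statistic 0, p = 1, n_used = 0.
        """
        a, b = (x, y) if x < y else (y, x)
        key = (a, b, tuple(sorted(zs)), test)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        counts, n_used = self._counts((*key[2], a, b))
        if n_used == 0:
            result = (0.0, 0.0, 1.0, 0)
        else:
            ka, kb = self.card(a), self.card(b)
            kz = counts.size // (ka * kb)
            stat = _stratified_stat(counts.astype(np.float64), kz, ka, kb,
                                    test == "x2")
            df = (ka - 1) * (kb - 1) * kz
            # chi-square survival function via the regularized upper
            # incomplete gamma (avoids scipy's frozen-distribution cost)
            p = float(gammaincc(df / 2.0, stat / 2.0)) if df > 0 else 1.0
            result = (float(stat), float(df), p, n_used)
        self._cache[key] = result
        return result
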