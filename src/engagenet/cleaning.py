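"""Survey-table cleaning: missing recode, eligibility, exclusion ledger.

The raw table arrives as strings. Cleaning recodes refusal-type answers
to MISSING, applies questionnaire skip patterns (gate predicates) to
mark structurally unasked cells INELIGIBLE, reports per-variable data
quality, and drops variables flagged by the expert-exclusion ledger.

Missing-data policy downstream is available-case (test-wise) deletion:
each contingency table or local score uses the rows complete on exactly
the variables involved. INELIGIBLE is treated like MISSING for analysis
by default (single-country items can only join networks via
available-case analysis); promoting it to an explicit level is a config
option on the encoding step.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .metadata import VariableMeta, meta_index
from .sentinels import DEFAULT_MISSING_CODES, INELIGIBLE, MISSING


class CleaningError(ValueError):
    pass


def recode_missing(raw: pd.DataFrame,
                   missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
                   ) -> pd.DataFrame:
    """Recode refusal-type answer categories to MISSING.

    Matching is case-insensitive; all other cells pass through
    unchanged (valid levels are never mapped onto other valid levels).
    """
    codes = {str(c).casefold() for c in missing_codes}
    if not codes:
        return raw.copy()

    def _recode(column: pd.Series) -> pd.Series:
        values = column.to_numpy(copy=True)
        lowered = np.array([str(v).casefold() for v in values.tolist()])
        hit = np.isin(lowered, sorted(codes))
        values[hit] = MISSING
        return pd.Series(values, index=column.index, name=column.name)

    return raw.apply(_recode)


def apply_eligibility(table: pd.DataFrame,
                      meta: Sequence[VariableMeta]) -> pd.DataFrame:
    """Mark gated cells INELIGIBLE where their gate predicate fails.

    For each gated variable: rows whose gate evaluates false become
    INELIGIBLE regardless of content; rows where a gate input is
    MISSING become MISSING for the gated variable (eligibility cannot
    be determined, so the cell is treated as unobserved rather than
    structurally absent).
    """
    out = table.copy()
    index = meta_index(meta)
    for m in meta:
        if m.gate is None or m.name not in out.columns:
            continue
        absent = m.gate.variables - set(out.columns)
        if absent and all(
            ref in index and index[ref].excluded for ref in absent
        ):
            # gate inputs were legitimately dropped by variable selection;
            # the column already carries its sentinel coding
            continue
        passed, undetermined = m.gate.evaluate(out)
        col = out[m.name].to_numpy(copy=True)
        col[~passed & ~undetermined] = INELIGIBLE
        col[undetermined] = MISSING
        out[m.name] = col
    return out


def variable_report(table: pd.DataFrame,
                    meta: Sequence[VariableMeta] | None = None) -> pd.DataFrame:
    """Per-variable data quality: ineligibility, missingness, frequencies.

    The MISSING proportion is computed over non-INELIGIBLE rows
    (skip-pattern absence and refusals are reported separately).  A
    column that is entirely INELIGIBLE has an undefined missingness
    denominator; it is reported as 0 with ``vacuous_missing=True``.
    """
    rows = []
    n = len(table)
    for name in table.columns:
        values = table[name].to_numpy()
        inel = values == INELIGIBLE
        miss = values == MISSING
        eligible = int(n - inel.sum())
        vacuous = eligible == 0
        prop_missing = 0.0 if vacuous else float(miss.sum() / eligible)
        valid = values[~inel & ~miss]
        levels, counts = np.unique(valid, return_counts=True)
        freqs = {
            lv: float(c / len(valid)) if len(valid) else 0.0
            for lv, c in zip(levels.tolist(), counts.tolist())
        }
        rows.append({
            "variable": name,
            "n": n,
            "prop_ineligible": float(inel.sum() / n) if n else 0.0,
            "prop_missing": prop_missing,
            "vacuous_missing": vacuous,
            "level_frequencies": freqs,
        })
    return pd.DataFrame(rows).set_index("variable")


def select_variables(table: pd.DataFrame,
                     meta: Sequence[VariableMeta]) -> pd.DataFrame:
    """Drop variables flagged by the expert-exclusion ledger."""
    index = meta_index(meta)
    keep = [c for c in table.columns if not (c in index and index[c].excluded)]
    if len(keep) < 2:
        raise CleaningError(
            f"fewer than 2 variables remain after exclusion ({len(keep)})"
        )
    return table[keep].copy()


def clean(raw: pd.DataFrame, meta: Sequence[VariableMeta],
          missing_codes: Iterable[str] = DEFAULT_MISSING_CODES,
          ) -> pd.DataFrame:
    """Full cleaning chain: recode -> eligibility -> select.

    The chain is idempotent: applying it twice equals applying it once.
    """
    return select_variables(
        apply_eligibility(recode_missing(raw, missing_codes), meta), meta
    )
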