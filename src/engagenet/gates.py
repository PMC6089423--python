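"""Eligibility-gate predicates.

A gate is a small boolean expression over other survey columns deciding
whether a respondent was ever asked a question, e.g.::

    saw_specialist == 'Yes'
    Country == 'Netherlands' and saw_specialist == 'Yes'

Supported syntax: string equality/inequality comparisons, membership
tests (``x in ('a', 'b')``), ``and`` / ``or`` / ``not`` and parentheses.
Expressions are parsed with :mod:`ast` and evaluated against table
columns; nothing is ever passed to ``eval``.

Evaluation is three-valued: if any referenced cell is MISSING the gate is
*undetermined* for that row (the cleaned cell becomes MISSING rather than
INELIGIBLE). A referenced INELIGIBLE cell is treated as an ordinary
(never-matching) value, so gates chained through other gated items
propagate ineligibility.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sentinels import MISSING


class GateError(ValueError):
    """Malformed gate expression or reference to an unknown column."""


@dataclass(frozen=True)
class Gate:
    """Compiled eligibility predicate.

    Parameters
    ----------
    expression:
        Source text of the predicate (kept verbatim for serialization).
    """

    expression: str
    _tree: ast.expr = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        try:
            tree = ast.parse(self.expression, mode="eval").body
        except SyntaxError as exc:  # pragma: no cover - message detail
            raise GateError(f"cannot parse gate {self.expression!r}: {exc}") from exc
        _validate(tree)
        object.__setattr__(self, "_tree", tree)

    @property
    def variables(self) -> frozenset[str]:
        """Columns referenced by the predicate."""
        names: set[str] = set()
        for node in ast.walk(self._tree):
            if isinstance(node, ast.Name):
                names.add(node.id)
        return frozenset(names)

    def evaluate(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised evaluation.

        Returns
        -------
        passed, undetermined:
            Boolean arrays of length ``len(table)``. ``undetermined`` is
            True where a referenced cell is MISSING; ``passed`` is only
            meaningful where ``undetermined`` is False.
        """
        missing = self.variables
        unknown = missing - set(table.columns)
        if unknown:
            raise GateError(
                f"gate {self.expression!r} references unknown column(s) "
                f"{sorted(unknown)}"
            )
        undetermined = np.zeros(len(table), dtype=bool)
        for name in self.variables:
            undetermined |= table[name].to_numpy() == MISSING
        passed = _eval(self._tree, table)
        return passed, undetermined

    def __call__(self, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return self.evaluate(table)


_ALLOWED = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Compare,
    ast.Eq,
    ast.NotEq,
    ast.In,
    ast.NotIn,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.Tuple,
    ast.List,
)


def _validate(tree: ast.expr) -> None:
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED):
            raise GateError(
                f"unsupported syntax {type(node).__name__!r} in gate expression"
            )
        if isinstance(node, ast.Constant) and not isinstance(node.value, str):
            raise GateError("gate constants must be strings")
        if isinstance(node, ast.Compare) and len(node.ops) != 1:
            raise GateError("chained comparisons are not supported in gates")


def _eval(node: ast.expr, table: pd.DataFrame) -> np.ndarray:
    if isinstance(node, ast.BoolOp):
        parts = [_eval(v, table) for v in node.values]
        out = parts[0]
        for part in parts[1:]:
            out = (out & part) if isinstance(node.op, ast.And) else (out | part)
        return out
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.Not):
        return ~_eval(node.operand, table)
    if isinstance(node, ast.Compare):
        left, op, right = node.left, node.ops[0], node.comparators[0]
        if not isinstance(left, ast.Name):
            raise GateError("comparison left-hand side must be a column name")
        col = table[left.id].to_numpy()
        if isinstance(op, (ast.In, ast.NotIn)):
            values = {elt.value for elt in right.elts}  # type: ignore[attr-defined]
            out = np.isin(col, sorted(values))
            return ~out if isinstance(op, ast.NotIn) else out
        value = right.value  # type: ignore[attr-defined]
        out = col == value
        return ~out if isinstance(op, ast.NotEq) else out
    raise GateError(f"unsupported gate node {type(node).__name__!r}")
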