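"""Per-variable survey metadata.

Each analysis column carries the information the pipeline needs beyond
its raw codes: the declared level set, whether the levels are ordered
(and with what ranks, for rank correlations), the causal *layer*
(1 = socio-demographic / health-system characteristics that may never
receive arcs, 2 = everything else), an optional eligibility gate, an
exclusion flag with the expert panel's reason, and an optional patient
engagement classification with its display colour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .gates import Gate

ENGAGEMENT_CLASSES = (
    "shared decision-making",
    "self-care and autonomy",
    "critical self-knowledge",
    "mixed",
)


class MetadataError(ValueError):
    pass


@dataclass
class VariableMeta:
    """Declared properties of one survey variable."""

    name: str
    levels: tuple[str, ...]
    layer: int = 2
    ordinal: bool = False
    #: level -> integer rank; may cover only a subset of levels (levels
    #: without a rank, e.g. "Not applicable" on a frequency scale, are
    #: dropped from rank correlations).
    ordinal_ranks: dict[str, int] | None = None
    gate: Gate | None = None
    excluded: bool = False
    reason: str | None = None
    engagement_class: str | None = None
    color: str | None = None
    short_name: str | None = None

    def __post_init__(self) -> None:
        self.levels = tuple(self.levels)
        if len(set(self.levels)) != len(self.levels) or not self.levels:
            raise MetadataError(f"{self.name}: levels must be non-empty and unique")
        if self.layer not in (1, 2):
            raise MetadataError(f"{self.name}: layer must be 1 or 2")
        if isinstance(self.gate, str):
            self.gate = Gate(self.gate)
        if self.gate is not None and self.layer != 2:
            raise MetadataError(f"{self.name}: gated variables must be layer 2")
        if self.ordinal:
            if self.ordinal_ranks is None:
                self.ordinal_ranks = {lv: i for i, lv in enumerate(self.levels)}
            unknown = set(self.ordinal_ranks) - set(self.levels)
            if unknown:
                raise MetadataError(f"{self.name}: ranks for unknown levels {unknown}")
            ranked = [lv for lv in self.levels if lv in self.ordinal_ranks]
            ranks = [self.ordinal_ranks[lv] for lv in ranked]
            if any(b <= a for a, b in zip(ranks, ranks[1:])):
                raise MetadataError(
                    f"{self.name}: ordinal ranks must strictly increase over "
                    "the listed level order"
                )
        if self.engagement_class is not None and (
            self.engagement_class not in ENGAGEMENT_CLASSES
        ):
            raise MetadataError(
                f"{self.name}: unknown engagement class {self.engagement_class!r}"
            )

    def to_dict(self) -> dict:
        out: dict = {"name": self.name, "levels": list(self.levels), "layer": self.layer}
        if self.ordinal:
            out["ordinal"] = True
            out["ordinal_ranks"] = dict(self.ordinal_ranks or {})
        if self.gate is not None:
            out["gate"] = self.gate.expression
        if self.excluded:
            out["excluded"] = True
            out["reason"] = self.reason
        for key in ("engagement_class", "color", "short_name"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "VariableMeta":
        return cls(
            name=data["name"],
            levels=tuple(data["levels"]),
            layer=int(data.get("layer", 2)),
            ordinal=bool(data.get("ordinal", False)),
            ordinal_ranks=(
                {k: int(v) for k, v in data["ordinal_ranks"].items()}
                if data.get("ordinal_ranks")
                else None
            ),
            gate=Gate(data["gate"]) if data.get("gate") else None,
            excluded=bool(data.get("excluded", False)),
            reason=data.get("reason"),
            engagement_class=data.get("engagement_class"),
            color=data.get("color"),
            short_name=data.get("short_name"),
        )


def meta_index(meta: Iterable[VariableMeta]) -> dict[str, VariableMeta]:
    index = {m.name: m for m in meta}
    return index


def analysis_variables(meta: Sequence[VariableMeta]) -> list[VariableMeta]:
    """Variables the expert-exclusion ledger lets through to modelling."""
    return [m for m in meta if not m.excluded]


def save_metadata(meta: Sequence[VariableMeta], path: str | Path) -> None:
    path = Path(path)
    payload = {"variables": [m.to_dict() for m in meta]}
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1))


def load_metadata(path: str | Path) -> list[VariableMeta]:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return [VariableMeta.from_dict(d) for d in payload["variables"]]
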