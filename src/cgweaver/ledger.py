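"""Typed, selectively ignorable diagnostics.

Every pipeline stage records problems in a :class:`WarningLedger` instead of
printing ad hoc messages.  At the end of a run the ledger decides whether
output files may be written at all: corrupted inputs must never propagate
silently into downstream simulation workflows.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Any, Iterable

#: The closed warning taxonomy.  Categories can be ignored selectively from
#: the command line; anything not ignored blocks output.
CATEGORIES = frozenset(
    {
        "unrecognized-residue",
        "unexpected-atoms",
        "missing-atoms",
        "missing-coordinates",
        "ss-failure",
        "empty-selection",
        "io",
    }
)


@dataclasses.dataclass(frozen=True)
class WarningEntry:
    category: str
    message: str
    context: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown warning category: {self.category!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "category": self.category,
            "message": self.message,
            "context": self.context,
        }


class WarningLedger:
    """Ordered collection of :class:`WarningEntry` with an ignore policy.

    Parameters
    ----------
    ignored_categories:
        Categories whose entries do not count against ``max_warnings``.
    max_warnings:
        Number of unignored warnings tolerated before output is blocked.
        The default, 0, means any unignored warning blocks output.
    """

    def __init__(
        self,
        ignored_categories: Iterable[str] = (),
        max_warnings: int = 0,
    ) -> None:
        self.entries: list[WarningEntry] = []
        self.ignored_categories = set(ignored_categories)
        unknown = self.ignored_categories - CATEGORIES
        if unknown:
            raise ValueError(f"unknown warning categories: {sorted(unknown)}")
        self.max_warnings = int(max_warnings)

    def warn(self, category: str, message: str, **context: Any) -> WarningEntry:
        entry = WarningEntry(category, message, context)
        self.entries.append(entry)
        return entry

    def extend(self, other: "WarningLedger") -> None:
        self.entries.extend(other.entries)

    @property
    def blocking_entries(self) -> list[WarningEntry]:
        return [e for e in self.entries if e.category not in self.ignored_categories]

    @property
    def output_allowed(self) -> bool:
        return len(self.blocking_entries) <= self.max_warnings

    def categories_seen(self) -> set[str]:
        return {e.category for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def format_human(self) -> str:
        lines = []
        for e in self.entries:
            ctx = " ".join(f"{k}={v}" for k, v in sorted(e.context.items()))
            flag = " (ignored)" if e.category in self.ignored_categories else ""
            lines.append(f"[{e.category}]{flag} {e.message}" + (f" [{ctx}]" if ctx else ""))
        return "\n".join(lines)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(e.to_dict(), sort_keys=True) for e in self.entries)
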