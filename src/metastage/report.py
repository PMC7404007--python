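"""Shared anomaly log and run report containers.

Every stage of the pipeline records non-fatal events (padding, truncation,
rejected rows, conflicts, on-the-fly catalog expansion) in one
:class:`AnomalyLog`. The log serializes as JSON lines so a run leaves a
machine-readable trail of everything that was tolerated rather than fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator


@dataclass
class Anomaly:
    stage: str
    kind: str
    message: str
    severity: str = "warning"  # "info" | "warning" | "error"
    context: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "stage": self.stage,
            "kind": self.kind,
            "severity": self.severity,
            "message": self.message,
            **({"context": self.context} if self.context else {}),
        }


@dataclass
class AnomalyLog:
    entries: list[Anomaly] = field(default_factory=list)

    def add(
        self,
        stage: str,
        kind: str,
        message: str,
        severity: str = "warning",
        **context: Any,
    ) -> None:
        self.entries.append(Anomaly(stage, kind, message, severity, context))

    def __iter__(self) -> Iterator[Anomaly]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def count(self, kind: str | None = None, stage: str | None = None) -> int:
        return sum(
            1
            for a in self.entries
            if (kind is None or a.kind == kind) and (stage is None or a.stage == stage)
        )

    def warnings(self) -> list[Anomaly]:
        return [a for a in self.entries if a.severity == "warning"]

    def to_jsonl(self) -> str:
        return "".join(json.dumps(a.to_dict(), sort_keys=True) + "\n" for a in self.entries)
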