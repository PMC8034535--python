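"""In-memory run log collected across pipeline stages.

Every warning and note emitted during a run ends up here and is flushed
verbatim into the run's log file, so output is deterministic (no
timestamps).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


@dataclass
class RunLog:
    events: list[tuple[str, str]] = field(default_factory=list)
    counters: Counter = field(default_factory=Counter)

    def note(self, message: str) -> None:
        self.events.append(("INFO", message))

    def warn(self, message: str, count_key: str | None = None) -> None:
        self.events.append(("WARNING", message))
        if count_key is not None:
            self.counters[count_key] += 1

    def count(self, key: str, n: int = 1) -> None:
        self.counters[key] += n

    def lines(self) -> list[str]:
        out = [f"{level}\t{msg}" for level, msg in self.events]
        for key in sorted(self.counters):
            out.append(f"COUNT\t{key}={self.counters[key]}")
        return out
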