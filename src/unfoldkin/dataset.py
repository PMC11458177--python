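"""A collection of time-courses plus the manifest describing them."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

from .timecourse import TimeCourse


@dataclass
class Dataset:
    """Traces from one experiment series and their manifest.

    The manifest records the substrate registry, delay times, replicate
    count and — for synthetic data — every generating parameter and the
    seed, so parameter-recovery tests can compare against the truth.
    """

    traces: list[TimeCourse] = field(default_factory=list)
    manifest: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def select(self, substrate: str | None = None, dt1: float | None = None,
               replicate: int | None = None) -> list[TimeCourse]:
        """Traces matching all given criteria, in stored order."""
        out: Iterable[TimeCourse] = self.traces
        if substrate is not None:
            out = (tc for tc in out if tc.substrate == substrate)
        if dt1 is not None:
            out = (tc for tc in out if tc.dt1 == dt1)
        if replicate is not None:
            out = (tc for tc in out if tc.replicate == replicate)
        return list(out)

    @property
    def substrates(self) -> list[str]:
        seen: dict[str, None] = {}
        for tc in self.traces:
            seen.setdefault(tc.substrate)
        return list(seen)

    @property
    def dt1_values(self) -> list[float]:
        seen: dict[float, None] = {}
        for tc in self.traces:
            seen.setdefault(tc.dt1)
        return list(seen)
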