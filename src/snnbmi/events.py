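"""Spike event streams.

An :class:`EventStream` is an ordered sequence of ``(time_ms, address)`` pairs,
the abstract form of address-event (AER) spike traffic.  It is used for
recorded spikes, network input lines, teacher lines and network output alike;
only the meaning of the address differs (recording channel, input synapse
line, ensemble index, output neuron index).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventStream"]


@dataclass(frozen=True)
class EventStream:
    """Ordered spike events: parallel arrays of times (ms) and integer addresses.

    Events are kept sorted by time (stable with respect to address order for
    simultaneous events).  Streams are immutable; all operations return new
    instances.
    """

    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    addresses: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.addresses, dtype=np.int64)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and addresses must be 1-D arrays of equal length")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError("event times must be finite")
        if t.size and np.any(np.diff(t) < 0):
            order = np.argsort(t, kind="stable")
            t, a = t[order], a[order]
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "addresses", a)

    def __len__(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_lines(cls, lines: list[np.ndarray] | dict[int, np.ndarray]) -> "EventStream":
        """Build a stream from per-address spike-time lists."""
        items = lines.items() if isinstance(lines, dict) else enumerate(lines)
        ts, ads = [], []
        for addr, tt in items:
            tt = np.asarray(tt, dtype=float)
            ts.append(tt)
            ads.append(np.full(tt.size, addr, dtype=np.int64))
        if not ts:
            return cls()
        return cls(np.concatenate(ts), np.concatenate(ads))

    def to_lines(self, n_lines: int) -> list[np.ndarray]:
        """Split into per-address sorted time arrays (length ``n_lines``)."""
        if len(self) and (self.addresses.min() < 0 or self.addresses.max() >= n_lines):
            raise ValueError("address out of range")
        return [self.times[self.addresses == i] for i in range(n_lines)]

    def restricted(self, t_max: float) -> "EventStream":
        """Events with time strictly below ``t_max``."""
        keep = self.times < t_max
        return EventStream(self.times[keep], self.addresses[keep])

    # -- plain-text serialization (two tab-separated columns) -----------------

    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write("time_ms\tline_id\n")
        for t, a in zip(self.times, self.addresses):
            buf.write(f"{float(t)!r}\t{int(a)}\n")
        return buf.getvalue()

    @classmethod
    def loads(cls, text: str) -> "EventStream":
        lines = text.strip().splitlines()
        ts, ads = [], []
        for row in lines[1:]:
            t, a = row.split("\t")
            ts.append(float(t))
            ads.append(int(a))
        return cls(np.asarray(ts, dtype=float), np.asarray(ads, dtype=np.int64))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def load(cls, path) -> "EventStream":
        with open(path) as fh:
            return cls.loads(fh.read())
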