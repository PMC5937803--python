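"""Time-block token-injection schedules.

Token inputs are parameterised with the notation ``a-b,c;d-e,f``: during time
blocks *a* through *b* (inclusive on both ends) ``c`` tokens are added per
block, during blocks *d*–*e* ``f`` tokens, and so on.  In the steroidogenesis
models the amounts encode enzyme activities in pmol/minute/million cells, one
token unit per pmol/min/10^6 cells.  Amounts are non-negative reals; blocks not
covered by any segment receive zero tokens, which is also how an in-silico
knockout (schedule removal) behaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Segment",
    "InjectionSchedule",
    "ScheduleError",
    "parse_schedule",
    "format_schedule",
    "amount_at",
    "load_schedules",
    "save_schedules",
]

# the printed notation uses en-dashes; accept those plus plain hyphens
_DASHES = ("–", "—", "−")


class ScheduleError(ValueError):
    """Raised for malformed or inconsistent schedule notation."""


@dataclass(frozen=True)
class Segment:
    """One clause ``start-end,amount`` of a schedule (inclusive bounds)."""

    start: int
    end: int
    amount: float

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ScheduleError(f"segment start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ScheduleError(
                f"end before start in segment {self.start}-{self.end}"
            )
        amount = float(self.amount)
        if not amount >= 0.0 or amount != amount or amount == float("inf"):
            raise ScheduleError(f"amount must be finite and >= 0, got {self.amount}")
        object.__setattr__(self, "amount", amount)


@dataclass(frozen=True)
class InjectionSchedule:
    """An ordered, non-overlapping list of injection segments for one node."""

    segments: tuple[Segment, ...] = ()
    target: str | None = None

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ScheduleError(
                    f"overlapping segments {a.start}-{a.end} and {b.start}-{b.end}"
                )
        object.__setattr__(self, "segments", segs)

    def with_target(self, target: str | None) -> "InjectionSchedule":
        return replace(self, target=target)

    def amount_at(self, block: int) -> float:
        return amount_at(self, block)

    @property
    def notation(self) -> str:
        return format_schedule(self)


def _parse_clause(clause: str) -> Segment:
    text = clause.strip()
    for dash in _DASHES:
        text = text.replace(dash, "-")
    try:
        bounds, amount_text = text.rsplit(",", 1)
        start_text, end_text = bounds.split("-", 1)
        start = int(start_text.strip())
        end = int(end_text.strip())
        amount = float(amount_text.strip())
    except (ValueError, TypeError) as exc:
        raise ScheduleError(f"malformed schedule clause {clause!r}") from exc
    return Segment(start, end, amount)


def parse_schedule(text: str, target: str | None = None) -> InjectionSchedule:
    """Parse ``a-b,c;d-e,f`` notation into an :class:`InjectionSchedule`.

    Both hyphen-minus and en-dash are accepted as the block-range separator.
    An empty string denotes the empty schedule (zero input at every block).
    """
    if text is None:
        raise ScheduleError("schedule text is None")
    stripped = text.strip()
    if not stripped:
        return InjectionSchedule((), target)
    segments = tuple(
        _parse_clause(clause) for clause in stripped.split(";") if clause.strip()
    )
    return InjectionSchedule(segments, target)


def _format_amount(amount: float) -> str:
    if float(amount).is_integer() and abs(amount) < 1e15:
        return str(int(amount))
    return repr(float(amount))


def format_schedule(schedule: InjectionSchedule) -> str:
    """Canonical notation string: sorted segments, hyphen-separated bounds."""
    return ";".join(
        f"{s.start}-{s.end},{_format_amount(s.amount)}" for s in schedule.segments
    )


def amount_at(schedule: InjectionSchedule, block: int) -> float:
    """Tokens injected at *block* (1-based); 0 outside all segments."""
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    for seg in schedule.segments:
        if seg.start <= block <= seg.end:
            return seg.amount
    return 0.0


def load_schedules(path: str | Path) -> dict[str, InjectionSchedule]:
    """Read a two-column delimited file of (node id, notation string).

    Columns are separated by a tab, or by the first run of whitespace when the
    line contains no tab (notation strings never contain whitespace).  Blank
    lines and ``#`` comments are ignored.
    """
    schedules: dict[str, InjectionSchedule] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            node, _, notation = line.partition("\t")
        else:
            parts = line.split(None, 1)
            node, notation = parts[0], (parts[1] if len(parts) > 1 else "")
        node = node.strip()
        if not node:
            raise ScheduleError(f"{path}:{lineno}: missing node id")
        schedules[node] = parse_schedule(notation.strip(), target=node)
    return schedules


def save_schedules(
    schedules: Mapping[str, InjectionSchedule], path: str | Path
) -> None:
    lines: Iterable[str] = (
        f"{node}\t{format_schedule(sched)}" for node, sched in schedules.items()
    )
    Path(path).write_text("\n".join(lines) + "\n")
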