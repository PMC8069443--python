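"""Test-day recording protocols and schedule subsampling.

The reference protocol A records every 15 days from DIM 15 to 210 (14
test days).  The reduced protocols keep one monthly record: B uses
months 1-4, C months 1, 2, 4 and 6.  Month m maps to DIM 30*m, which
matches the ~30-day ICAR recording interval and puts every monthly
record on the 15-day grid, so B and C are exact subsets of A.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "RecordingProtocol",
    "schedule_full",
    "schedule_monthly",
    "protocol_a",
    "protocol_b",
    "protocol_c",
    "standard_protocols",
    "subsample",
]

FULL_GRID_STEP = 15
FULL_GRID_FIRST = 15
HORIZON_DAYS = 210
DAYS_PER_MONTH = 30


@dataclass(frozen=True)
class RecordingProtocol:
    """An ordered set of scheduled test days (DIM)."""

    name: str
    dims: tuple

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        if len(dims) == 0:
            raise ValueError("a protocol needs at least one scheduled DIM")
        if any(d < 1 for d in dims):
            raise ValueError("scheduled DIMs must be >= 1")
        if any(b <= a for a, b in zip(dims, dims[1:])):
            raise ValueError("scheduled DIMs must be strictly increasing")
        object.__setattr__(self, "dims", dims)

    def __len__(self) -> int:
        return len(self.dims)


def schedule_full() -> RecordingProtocol:
    """Protocol A: all 14 fortnightly test days, DIM 15, 30, ..., 210."""
    return RecordingProtocol(
        "A", tuple(range(FULL_GRID_FIRST, HORIZON_DAYS + 1, FULL_GRID_STEP))
    )


def schedule_monthly(months, name: str = "custom") -> RecordingProtocol:
    """Protocol from month indices: month m -> DIM 30*m.

    Months must be strictly increasing and within 1..7 (the 210-day
    horizon).
    """
    months = list(months)
    if any(not (1 <= m <= HORIZON_DAYS // DAYS_PER_MONTH) for m in months):
        raise ValueError("months must lie in 1..7 (210-day horizon)")
    if any(b <= a for a, b in zip(months, months[1:])):
        raise ValueError("months must be strictly increasing")
    return RecordingProtocol(name, tuple(DAYS_PER_MONTH * m for m in months))


def protocol_a() -> RecordingProtocol:
    return schedule_full()


def protocol_b() -> RecordingProtocol:
    """Monthly records of months 1-4: DIM {30, 60, 90, 120}."""
    return schedule_monthly([1, 2, 3, 4], name="B")


def protocol_c() -> RecordingProtocol:
    """Monthly records of months 1, 2, 4, 6: DIM {30, 60, 120, 180}."""
    return schedule_monthly([1, 2, 4, 6], name="C")


def standard_protocols() -> dict:
    return {"A": protocol_a(), "B": protocol_b(), "C": protocol_c()}


def subsample(
    records: pd.DataFrame,
    protocol: RecordingProtocol,
    mode: str = "strict",
    tolerance_days: int = 7,
) -> pd.DataFrame:
    """Reduce a test-day dataset to the protocol's scheduled DIMs.

    ``records`` must carry columns ``animal_id`` and ``dim``.  In strict
    mode (the default; synthetic data are complete) every animal must
    have a record at every scheduled DIM or a ValueError is raised.  In
    tolerant mode a missing scheduled DIM is substituted by the nearest
    available record within ``tolerance_days``; animals with no record
    in range for some scheduled day simply lack that row.
    Row order of the input is preserved.
    """
    if mode not in ("strict", "tolerant"):
        raise ValueError(f"unknown subsample mode {mode!r}")
    wanted = set(protocol.dims)
    if mode == "strict":
        missing = (
            records.groupby("animal_id")["dim"]
            .apply(lambda d: sorted(wanted - set(d)))
            .loc[lambda s: s.str.len() > 0]
        )
        if len(missing):
            aid, dims = missing.index[0], missing.iloc[0]
            raise ValueError(
                f"animal {aid!r} lacks scheduled DIM(s) {dims} for protocol "
                f"{protocol.name} (strict mode; {len(missing)} animals affected)"
            )
        return records[records["dim"].isin(wanted)]

    keep_idx = []
    for _, grp in records.groupby("animal_id", sort=False):
        dims = grp["dim"].to_numpy()
        for sched in protocol.dims:
            dist = abs(dims - sched)
            j = int(dist.argmin())
            if dist[j] <= tolerance_days:
                keep_idx.append(grp.index[j])
    return records.loc[sorted(set(keep_idx))]
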