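"""Event data model and tab-separated event-table I/O.

An *event* is one inelastic interaction (ionization or electronic
excitation) of an electron in liquid water: a 3-D position in nm, a kind
token and the energy it deposits in eV.  An :class:`EventSet` is the
column-oriented container for a whole track (or a batch of tracks) and
carries the two aggregate quantities the yield model consumes: the event
count ``n_event`` and the total deposited energy ``e_dep_keV``.

The on-disk format is a plain TSV with a fixed header
(``track_id  x_nm  y_nm  z_nm  kind  edep_eV``); ``kind`` is ``ION`` or
``EXC``.  Events depositing less than the 1 eV electron transport
cut-off are rejected at parse time.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Event",
    "EventSet",
    "EventTableError",
    "read_events",
    "write_events",
    "EDEP_CUTOFF_EV",
    "EVENT_TABLE_COLUMNS",
]

#: electron transport cut-off: events depositing less than this are invalid
EDEP_CUTOFF_EV = 1.0

EVENT_TABLE_COLUMNS = ("track_id", "x_nm", "y_nm", "z_nm", "kind", "edep_eV")

ION = "ION"
EXC = "EXC"
_KINDS = (ION, EXC)


class EventTableError(ValueError):
    """Raised when an event table fails parsing or validation."""


@dataclass(frozen=True)
class Event:
    """One inelastic interaction.

    Parameters
    ----------
    track_id : int
        Label of the primary track the event belongs to.
    x, y, z : float
        Position in nm; must be finite.
    kind : str
        ``"ION"`` (ionization) or ``"EXC"`` (electronic excitation).
        Both kinds count equally in every event/cluster statistic.
    edep : float
        Deposited energy in eV; must be at least the 1 eV cut-off.
    """

    track_id: int
    x: float
    y: float
    z: float
    kind: str
    edep: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)):
            raise EventTableError("event coordinates must be finite")
        if not np.isfinite(self.edep) or self.edep < EDEP_CUTOFF_EV:
            raise EventTableError(
                f"edep must be >= {EDEP_CUTOFF_EV} eV (transport cut-off), got {self.edep!r}"
            )
        if self.kind not in _KINDS:
            raise EventTableError(f"unknown event kind {self.kind!r}; expected ION or EXC")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


class EventSet:
    """Column-oriented collection of events.

    Stores track ids, an ``(n, 3)`` coordinate array in nm, kind tokens
    and per-event deposited energies in eV.  Equality is element-wise
    and order-sensitive; the derived aggregates ``n_event`` and
    ``e_dep_keV`` are invariant under row reordering.
    """

    __slots__ = ("track_id", "coords", "kind", "edep_eV")

    def __init__(
        self,
        track_id: np.ndarray | Sequence[int],
        coords: np.ndarray,
        kind: np.ndarray | Sequence[str],
        edep_eV: np.ndarray | Sequence[float],
    ) -> None:
        self.track_id = np.asarray(track_id, dtype=np.int64)
        self.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
        self.kind = np.asarray(kind, dtype="U3")
        self.edep_eV = np.asarray(edep_eV, dtype=np.float64)
        n = len(self.coords)
        if not (len(self.track_id) == len(self.kind) == len(self.edep_eV) == n):
            raise EventTableError("EventSet columns have mismatched lengths")
        if n:
            if not np.all(np.isfinite(self.coords)):
                raise EventTableError("event coordinates must be finite")
            if not np.all(np.isfinite(self.edep_eV)) or np.any(self.edep_eV < EDEP_CUTOFF_EV):
                raise EventTableError(
                    f"all edep values must be >= {EDEP_CUTOFF_EV} eV (transport cut-off)"
                )
            bad = ~np.isin(self.kind, _KINDS)
            if bad.any():
                raise EventTableError(
                    f"unknown event kind {self.kind[bad][0]!r}; expected ION or EXC"
                )

    @classmethod
    def empty(cls) -> "EventSet":
        return cls(
            np.empty(0, dtype=np.int64),
            np.empty((0, 3)),
            np.empty(0, dtype="U3"),
            np.empty(0),
        )

    @classmethod
    def from_events(cls, events: Sequence[Event]) -> "EventSet":
        if not events:
            return cls.empty()
        return cls(
            [e.track_id for e in events],
            np.array([[e.x, e.y, e.z] for e in events], dtype=float),
            [e.kind for e in events],
            [e.edep for e in events],
        )

    # -- derived aggregates -------------------------------------------------

    @property
    def n_event(self) -> int:
        """Total number of events, N_event (ionizations + excitations)."""
        return len(self.coords)

    @property
    def e_dep_keV(self) -> float:
        """Total deposited energy E_dep in keV."""
        return float(self.edep_eV.sum()) / 1000.0

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return self.n_event

    def __getitem__(self, i: int) -> Event:
        return Event(
            int(self.track_id[i]),
            float(self.coords[i, 0]),
            float(self.coords[i, 1]),
            float(self.coords[i, 2]),
            str(self.kind[i]),
            float(self.edep_eV[i]),
        )

    def __iter__(self) -> Iterator[Event]:
        for i in range(len(self)):
            yield self[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventSet):
            return NotImplemented
        return (
            np.array_equal(self.track_id, other.track_id)
            and np.array_equal(self.coords, other.coords)
            and np.array_equal(self.kind, other.kind)
            and np.array_equal(self.edep_eV, other.edep_eV)
        )

    def __repr__(self) -> str:
        return f"EventSet(n_event={self.n_event}, e_dep_keV={self.e_dep_keV:.6g})"


def read_events(path: str | os.PathLike, dialect: str = "tsv") -> EventSet:
    """Read an event table into an :class:`EventSet`.

    Parameters
    ----------
    path : path-like
        TSV file with the fixed header ``track_id x_nm y_nm z_nm kind edep_eV``.
    dialect : str
        Format name; only ``"tsv"`` is defined.

    Raises
    ------
    EventTableError
        On a wrong header, a malformed row (with its 1-based line
        number), an unknown kind token, or an ``edep`` below the 1 eV
        transport cut-off.
    """
    if dialect != "tsv":
        raise EventTableError(f"unknown event-table dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EventTableError(f"{path}: empty file (missing header)") from None
    if tuple(df.columns) != EVENT_TABLE_COLUMNS:
        raise EventTableError(
            f"{path}: bad header {tuple(df.columns)!r}; expected {EVENT_TABLE_COLUMNS!r}"
        )
    if df.empty:
        return EventSet.empty()

    def _numeric(col: str, as_int: bool = False) -> np.ndarray:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise EventTableError(
                f"{path}: line {line}: malformed {col} value {df[col][bad.idxmax()]!r}"
            )
        # numpy's strtod parse is bit-exact on repr output; pandas' fast
        # parser is not, and round-trip identity is part of the contract
        values = df[col].to_numpy(dtype="U32").astype(np.float64)
        return values.astype(np.int64) if as_int else values

    track_id = _numeric("track_id", as_int=True)
    coords = np.column_stack([_numeric(c) for c in ("x_nm", "y_nm", "z_nm")])
    edep = _numeric("edep_eV")
    kind = df["kind"].to_numpy(dtype="U3")

    bad_kind = ~np.isin(kind, _KINDS)
    if bad_kind.any():
        i = int(np.argmax(bad_kind))
        raise EventTableError(
            f"{path}: line {i + 2}: unknown kind {df['kind'].iloc[i]!r}; expected ION or EXC"
        )
    low = edep < EDEP_CUTOFF_EV
    if low.any():
        i = int(np.argmax(low))
        raise EventTableError(
            f"{path}: line {i + 2}: edep {edep[i]!r} eV below the "
            f"{EDEP_CUTOFF_EV} eV transport cut-off"
        )
    if not np.all(np.isfinite(coords)):
        i = int(np.argmax(~np.isfinite(coords).all(axis=1)))
        raise EventTableError(f"{path}: line {i + 2}: non-finite coordinate")
    return EventSet(track_id, coords, kind, edep)


def write_events(es: EventSet, path: str | os.PathLike) -> None:
    """Write an :class:`EventSet` as a TSV event table.

    Floats are written with full ``repr`` precision so that
    ``read_events(write_events(es)) == es`` bit-exactly.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EVENT_TABLE_COLUMNS) + "\n")
        for i in range(len(es)):
            x, y, z = es.coords[i]
            fh.write(
                f"{es.track_id[i]}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}"
                f"\t{es.kind[i]}\t{float(es.edep_eV[i])!r}\n"
            )
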