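"""Domain types and I/O for WHO cone-bioassay data on insecticidal nets.

A long-lasting insecticidal net (LLIN) is evaluated by pressing standard WHO
cones onto netting pieces cut from the net's top and four lateral sides.  Each
of the 5 pieces receives 4 cones of 5 susceptible female mosquitoes (100
mosquitoes per net in total).  Knock-down is scored 60 minutes after the
3-minute exposure and mortality after 24 hours; the two endpoints are scored
on different schedules, so no ordering between them is assumed or enforced.

A net is *valid* under the WHOPES rule if its average mortality is >= 80% or
its average knock-down is >= 95%; the two thresholds may also be applied
singly.  This module holds the per-cone record type, the per-net assay
container, the validity classifiers, and a flat CSV round trip.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Side",
    "OutcomeKind",
    "ConeRecord",
    "NetAssay",
    "ValidityOutcome",
    "ConeSelection",
    "DatasetError",
    "MORTALITY",
    "KD",
    "MIXED",
    "pooled_rates",
    "classify_net",
    "read_dataset",
    "write_dataset",
    "nets_to_frame",
]

N_SIDES = 5
N_CONES = 4
DEFAULT_N_PER_CONE = 5


class Side(enum.Enum):
    """One of the five netting pieces cut from a net (top + four sides)."""

    TOP = "top"
    SIDE1 = "side1"
    SIDE2 = "side2"
    SIDE3 = "side3"
    SIDE4 = "side4"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SIDES: tuple[Side, ...] = tuple(Side)


class OutcomeKind(enum.Enum):
    MORTALITY = "mortality"
    KD = "kd"
    MIXED = "mixed"


class DatasetError(ValueError):
    """Structural or validation failure in a cone-bioassay dataset."""


@dataclass(frozen=True)
class ConeRecord:
    """Counts from a single cone: mosquitoes exposed, knocked down, dead."""

    net_id: str
    side: Side
    cone_index: int
    n_exposed: int = DEFAULT_N_PER_CONE
    n_kd_60: int = 0
    n_dead_24: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.cone_index <= N_CONES:
            raise ValueError(f"cone_index must be in 1..{N_CONES}, got {self.cone_index}")
        if self.n_exposed <= 0:
            raise ValueError("n_exposed must be positive")
        if not 0 <= self.n_kd_60 <= self.n_exposed:
            raise ValueError(
                f"n_kd_60={self.n_kd_60} outside 0..n_exposed={self.n_exposed}"
            )
        if not 0 <= self.n_dead_24 <= self.n_exposed:
            raise ValueError(
                f"n_dead_24={self.n_dead_24} outside 0..n_exposed={self.n_exposed}"
            )


@dataclass(frozen=True)
class NetAssay:
    """One net's complete assay: exactly one record per (side, cone) pair."""

    net_id: str
    brand: str
    age_months: int
    cones: tuple[ConeRecord, ...]

    def __post_init__(self) -> None:
        if self.age_months < 0:
            raise ValueError("age_months must be >= 0")
        if len(self.cones) != N_SIDES * N_CONES:
            raise DatasetError(
                f"net {self.net_id}: expected {N_SIDES * N_CONES} cone records, "
                f"got {len(self.cones)}"
            )
        seen: set[tuple[Side, int]] = set()
        for rec in self.cones:
            if rec.net_id != self.net_id:
                raise DatasetError(
                    f"net {self.net_id}: record with foreign net_id {rec.net_id!r}"
                )
            key = (rec.side, rec.cone_index)
            if key in seen:
                raise DatasetError(
                    f"net {self.net_id}: duplicate cone ({rec.side.value}, {rec.cone_index})"
                )
            seen.add(key)

    def record(self, side: Side, cone_index: int) -> ConeRecord:
        for rec in self.cones:
            if rec.side is side and rec.cone_index == cone_index:
                return rec
        raise DatasetError(
            f"net {self.net_id}: missing cone ({side.value}, {cone_index})"
        )

    @classmethod
    def from_records(
        cls, net_id: str, brand: str, age_months: int, records: Iterable[ConeRecord]
    ) -> "NetAssay":
        ordered = sorted(records, key=lambda r: (SIDES.index(r.side), r.cone_index))
        return cls(net_id, brand, age_months, tuple(ordered))


@dataclass(frozen=True)
class ValidityOutcome:
    """A validity rule: mortality-only, knock-down-only, or their disjunction."""

    kind: OutcomeKind
    mortality_cutoff: float = 0.80
    kd_cutoff: float = 0.95

    def __post_init__(self) -> None:
        for name in ("mortality_cutoff", "kd_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


MORTALITY = ValidityOutcome(OutcomeKind.MORTALITY)
KD = ValidityOutcome(OutcomeKind.KD)
MIXED = ValidityOutcome(OutcomeKind.MIXED)


@dataclass(frozen=True)
class ConeSelection:
    """Which cones are read on each side; the same number k on every side."""

    by_side: Mapping[Side, tuple[int, ...]]

    def __post_init__(self) -> None:
        chosen = dict(self.by_side)
        if set(chosen) != set(SIDES):
            missing = sorted(s.value for s in set(SIDES) - set(chosen))
            raise ValueError(f"selection must cover all five sides; missing {missing}")
        ks = {len(v) for v in chosen.values()}
        if len(ks) != 1:
            raise ValueError("selection must use the same number of cones per side")
        (k,) = ks
        if not 1 <= k <= N_CONES:
            raise ValueError(f"cones per side must be in 1..{N_CONES}, got {k}")
        for side, idx in chosen.items():
            if len(set(idx)) != len(idx) or not all(1 <= i <= N_CONES for i in idx):
                raise ValueError(
                    f"side {side.value}: cone indices must be distinct and in 1..{N_CONES}"
                )
        object.__setattr__(self, "by_side", {s: tuple(sorted(chosen[s])) for s in SIDES})

    @property
    def k_cones(self) -> int:
        return len(next(iter(self.by_side.values())))

    @classmethod
    def full(cls) -> "ConeSelection":
        return cls({s: tuple(range(1, N_CONES + 1)) for s in SIDES})


def pooled_rates(net: NetAssay, sel: ConeSelection) -> tuple[float, float]:
    """Mortality and knock-down rates pooled over the selected cones.

    Rates are total events over total mosquitoes exposed across the selected
    cones.  With the standard design (equal exposure in every cone) this
    coincides with the unweighted mean of per-cone proportions; pooling keeps
    the estimate well defined if exposures ever differ.
    """
    dead = kd = exposed = 0
    for side, indices in sel.by_side.items():
        for i in indices:
            rec = net.record(side, i)
            dead += rec.n_dead_24
            kd += rec.n_kd_60
            exposed += rec.n_exposed
    return dead / exposed, kd / exposed


def classify_net(net: NetAssay, sel: ConeSelection, outcome: ValidityOutcome) -> bool:
    """Apply a validity rule to the pooled rates; thresholds are inclusive."""
    mort, kd = pooled_rates(net, sel)
    passes_mort = mort >= outcome.mortality_cutoff
    passes_kd = kd >= outcome.kd_cutoff
    if outcome.kind is OutcomeKind.MORTALITY:
        return passes_mort
    if outcome.kind is OutcomeKind.KD:
        return passes_kd
    return passes_mort or passes_kd


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "net_id",
    "brand",
    "age_months",
    "side",
    "cone",
    "n_exposed",
    "n_kd_60",
    "n_dead_24",
]

_SIDE_BY_NAME = {s.value: s for s in Side}


def nets_to_frame(nets: Sequence[NetAssay]) -> pd.DataFrame:
    """Flatten assays to one row per cone, in deterministic order."""
    rows = []
    for net in sorted(nets, key=lambda n: n.net_id):
        for side in SIDES:
            for cone in range(1, N_CONES + 1):
                rec = net.record(side, cone)
                rows.append(
                    (
                        net.net_id,
                        net.brand,
                        net.age_months,
                        side.value,
                        cone,
                        rec.n_exposed,
                        rec.n_kd_60,
                        rec.n_dead_24,
                    )
                )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_dataset(nets: Sequence[NetAssay], path: str | Path) -> None:
    nets_to_frame(nets).to_csv(path, index=False)


def _frame_to_nets(df: pd.DataFrame) -> list[NetAssay]:
    problems: list[str] = []
    records: dict[str, list[ConeRecord]] = {}
    meta: dict[str, tuple[str, int]] = {}
    seen_keys: set[tuple[str, str, int]] = set()

    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is row 1
        try:
            side = _SIDE_BY_NAME[str(row.side)]
            key = (str(row.net_id), side.value, int(row.cone))
            if key in seen_keys:
                raise ValueError(f"duplicate cone {key}")
            rec = ConeRecord(
                net_id=str(row.net_id),
                side=side,
                cone_index=int(row.cone),
                n_exposed=int(row.n_exposed),
                n_kd_60=int(row.n_kd_60),
                n_dead_24=int(row.n_dead_24),
            )
        except (KeyError, ValueError, TypeError) as exc:
            problems.append(f"row {pos}: {exc}")
            continue
        seen_keys.add(key)
        records.setdefault(rec.net_id, []).append(rec)
        meta.setdefault(rec.net_id, (str(row.brand), int(row.age_months)))

    if problems:
        raise DatasetError("invalid rows:\n" + "\n".join(problems))

    nets: list[NetAssay] = []
    incomplete: list[tuple[str, str, int]] = []
    for net_id in sorted(records):
        have = {(r.side, r.cone_index) for r in records[net_id]}
        missing = [
            (net_id, s.value, c)
            for s in SIDES
            for c in range(1, N_CONES + 1)
            if (s, c) not in have
        ]
        if missing:
            incomplete.extend(missing)
            continue
        brand, age = meta[net_id]
        nets.append(NetAssay.from_records(net_id, brand, age, records[net_id]))
    if incomplete:
        raise DatasetError(
            "incomplete nets; missing (net_id, side, cone): "
            + ", ".join(map(str, incomplete))
        )
    return nets


def read_dataset(path: str | Path) -> list[NetAssay]:
    """Read a cone-level CSV into validated :class:`NetAssay` objects.

    Raises :class:`DatasetError` listing the offending row numbers for
    malformed rows, counts exceeding exposure, duplicate cones, or nets with
    missing (side, cone) pairs.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetError(f"missing columns: {missing_cols}")
    return _frame_to_nets(df[CSV_COLUMNS])
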