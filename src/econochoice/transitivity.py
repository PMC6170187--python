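"""Transitivity of revealed preferences across pellet triplets.

For three goods A, B, C labeled in decreasing preference order, internally
consistent valuation implies log IP(A:C) = log IP(A:B) + log IP(B:C).  A
triplet's transitivity statistic is the departure from that identity,

    T = ln IP_AC - ln IP_AB - ln IP_BC,

zero under perfect consistency.  In the transitivity plane, each triplet x
condition is the point (x, y) = (ln IP_AB + ln IP_BC, ln IP_AC): points on
the identity line are exactly the T = 0 triplets, and y - x = T everywhere.
Laser effects on the stability of the value space are probed through the
Euclidean distances between a triplet's laser-on and laser-off points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.distributions.empirical_distribution import ECDF

from .errors import InputError
from .session_io import CONDITIONS

__all__ = [
    "TripletRecord",
    "order_triplet",
    "transitivity_stat",
    "transitivity_coords",
    "pair_distance",
    "distance_ecdf",
    "read_triplet_table",
    "write_triplet_table",
]


@dataclass
class TripletRecord:
    """Ordered IPs for one pellet triplet under the four conditions.

    ``flavors`` lists (A, B, C) in decreasing preference; ``ips`` maps each
    condition to the oriented (ip_AC, ip_AB, ip_BC) tuple.
    """

    triplet_id: str
    flavors: tuple[str, str, str]
    ips: dict[str, tuple[float, float, float]]

    def condition(self, cond: str) -> tuple[float, float, float]:
        return self.ips[cond]


def _orient(pair_ips: Mapping[tuple[str, str], float]) -> dict[frozenset, tuple]:
    """Normalize {(a, b): ip} so each unordered pair maps to (a, b, ip >= orientation)."""
    out = {}
    for (a, b), ip in pair_ips.items():
        if ip <= 0:
            raise InputError(f"IP for pair ({a}, {b}) must be > 0")
        key = frozenset((a, b))
        if key in out:
            raise InputError(f"duplicate pair ({a}, {b})")
        out[key] = (a, b, float(ip))
    return out


def order_triplet(
    pair_ips: Mapping[tuple[str, str], float],
    triplet_id: str = "triplet",
    all_condition_ips: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
) -> TripletRecord:
    """Label three flavors A, B, C so the A:C pair carries the greatest IP.

    ``pair_ips`` maps flavor pairs ``(a, b)`` to IP_{a:b}, the pair's
    indifference ratio with ``a`` listed as the preferred good (IP_{a:b} >= 1
    when ``a`` really is preferred; a value below 1 just means the stated
    orientation was backwards and is inverted during labeling, since
    IP_{b:a} = 1 / IP_{a:b}).  The pair with the largest oriented IP defines
    (A, C); the leftover flavor is B.  When ``all_condition_ips`` supplies
    per-condition IP tables the labeling derived from ``pair_ips`` (the
    reference condition) is held fixed and applied to each condition;
    intransitive-looking samples are labeled, never rejected.
    """
    oriented = _orient(pair_ips)
    flavors = set()
    for key in oriented:
        flavors |= key
    if len(flavors) != 3 or len(oriented) != 3:
        raise InputError("need exactly 3 pairwise IPs over exactly 3 flavors")

    # orient every pair as (preferred, nonpreferred, ip >= 1)
    pref = {}
    for a, b, ip in oriented.values():
        if ip >= 1:
            pref[frozenset((a, b))] = (a, b, ip)
        else:
            pref[frozenset((a, b))] = (b, a, 1.0 / ip)
    (A, C, _) = max(pref.values(), key=lambda t: t[2])
    (B,) = flavors - {A, C}

    def ip_of(u: str, v: str, table) -> float:
        """IP_{u:v} (u preferred) from a table keyed by either orientation."""
        key = frozenset((u, v))
        for (a, b), ip in table.items():
            if frozenset((a, b)) == key:
                return float(ip) if a == u else 1.0 / float(ip)
        raise InputError(f"pair ({u}, {v}) missing")

    conditions = all_condition_ips or {"ref": pair_ips}
    ips = {
        cond: (
            ip_of(A, C, table),
            ip_of(A, B, table),
            ip_of(B, C, table),
        )
        for cond, table in conditions.items()
    }
    return TripletRecord(triplet_id, (A, B, C), ips)


def transitivity_stat(trip: TripletRecord, condition: str) -> float:
    """T = ln IP_AC - ln IP_AB - ln IP_BC for one condition (0 = consistent)."""
    ip_ac, ip_ab, ip_bc = trip.condition(condition)
    return math.log(ip_ac) - math.log(ip_ab) - math.log(ip_bc)


def transitivity_coords(trip: TripletRecord, condition: str) -> tuple[float, float]:
    """Point in the transitivity plane: (ln IP_AB + ln IP_BC, ln IP_AC)."""
    ip_ac, ip_ab, ip_bc = trip.condition(condition)
    return (math.log(ip_ab) + math.log(ip_bc), math.log(ip_ac))


def pair_distance(
    coords_on: tuple[float, float], coords_off: tuple[float, float]
) -> float:
    """Euclidean distance between laser-on and laser-off transitivity points."""
    return math.hypot(coords_on[0] - coords_off[0], coords_on[1] - coords_off[1])


def distance_ecdf(distances_by_fiber: Mapping[str, Sequence[float]]) -> dict[str, ECDF]:
    """Right-continuous empirical CDF of on/off distances, one per fiber."""
    out = {}
    for fiber, d in distances_by_fiber.items():
        arr = np.asarray(d, dtype=float)
        if arr.size == 0:
            raise InputError(f"no distances for fiber {fiber!r}")
        out[fiber] = ECDF(arr)
    return out


# ---------------------------------------------------------------------------
# triplet tables: one row per triplet x condition with the three ordered IPs
# ---------------------------------------------------------------------------

_TRIPLET_COLUMNS = ("triplet", "condition", "ip_AC", "ip_AB", "ip_BC")


def write_triplet_table(records: Sequence[TripletRecord], target) -> None:
    from .session_io import _open

    stream, should_close = _open(target, "w")
    try:
        stream.write("\t".join(_TRIPLET_COLUMNS) + "\n")
        for rec in records:
            for cond in rec.ips:
                ac, ab, bc = rec.ips[cond]
                stream.write(
                    f"{rec.triplet_id}\t{cond}\t{ac:.6g}\t{ab:.6g}\t{bc:.6g}\n"
                )
    finally:
        if should_close:
            stream.close()


def read_triplet_table(source) -> list[TripletRecord]:
    """Read a triplet IP table (one row per triplet x condition)."""
    from .errors import FormatError
    from .session_io import _open

    stream, should_close = _open(source)
    try:
        by_id: dict[str, TripletRecord] = {}
        header_seen = False
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if tuple(parts) != _TRIPLET_COLUMNS:
                    raise FormatError(
                        f"line {lineno}: expected header {'/'.join(_TRIPLET_COLUMNS)}"
                    )
                header_seen = True
                continue
            if len(parts) != 5:
                raise FormatError(f"line {lineno}: expected 5 fields, got {len(parts)}")
            tid, cond = parts[0], parts[1]
            try:
                ips = tuple(float(v) for v in parts[2:])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric IP") from None
            rec = by_id.setdefault(tid, TripletRecord(tid, ("A", "B", "C"), {}))
            rec.ips[cond] = ips  # type: ignore[assignment]
        if not header_seen:
            raise FormatError("no header row found")
        return list(by_id.values())
    finally:
        if should_close:
            stream.close()
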