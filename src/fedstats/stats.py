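"""Aggregate-only secure statistics over private columns.

Mirrors the restricted evaluation vocabulary of the federated study session:
``freq``, ``mean``, ``median``/``quantile``/``min``/``max``, ``length``,
masked variants of the counting statistics, and per-month survival tables.
Every operation touches only shares and opens nothing but the final
aggregates; each opening is gated by statistical disclosure control (SDC),
which refuses any result computed over a non-empty selection smaller than a
configured threshold ``k``.

Order statistics use an oblivious bitonic sorting network (compare-and-swap
from a secure comparison plus one Beaver multiplication), so no comparison
outcome is ever revealed; the five-number summary interpolates *on shares*
with public weights and reconstructs exactly five values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import ring as R
from .ring import (BIT, FIXED, INT, DEFAULT_RING, Ring, SharedValue,
                   TripleStore, equals_public, less_than, mul, mul_public,
                   reconstruct, sub, truncate)
from .table import (CATEGORICAL, METRIC, PrivateColumn, SelectionMask,
                    SchemaMismatchError)

logger = logging.getLogger("fedstats.sdc")

ALLOWED = "allowed"
REFUSED = "refused"


@dataclass(frozen=True)
class QuantileSummary:
    """Five-number summary (min, lower quartile, median, upper quartile, max)."""

    min: float
    q1: float
    median: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        vals = (self.min, self.q1, self.median, self.q3, self.max)
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("quantile summary must be nondecreasing")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.min, self.q1, self.median, self.q3, self.max)


@dataclass
class SurvivalTableAgg:
    """Per-month life table: events d_m, censorings c_m, derived at-risk n_m.

    The conservation invariants tie the table to the cohort it came from:
    ``n_0`` equals the selection size, ``n_{m+1} = n_m - d_m - c_m ≥ 0`` and
    all subjects are accounted for.  This is the only aggregate species whose
    length grows with follow-up (by month, never by patient).
    """

    events: list[int]
    censored: list[int]

    def __post_init__(self) -> None:
        if len(self.events) != len(self.censored):
            raise ValueError("events and censored must cover the same months")
        if any(d < 0 for d in self.events) or any(c < 0 for c in self.censored):
            raise ValueError("negative counts in survival table")

    @property
    def months(self) -> list[int]:
        return list(range(len(self.events)))

    @property
    def n_total(self) -> int:
        return sum(self.events) + sum(self.censored)

    @property
    def at_risk(self) -> list[int]:
        out, n = [], self.n_total
        for d, c in zip(self.events, self.censored):
            out.append(n)
            n -= d + c
        return out

    def validate(self) -> None:
        n = self.n_total
        for d, c in zip(self.events, self.censored):
            if d + c > n:
                raise ValueError("at-risk count would go negative")
            n -= d + c
        if n != 0:
            raise ValueError("survival table does not conserve the cohort")

    def to_csv(self) -> str:
        lines = ["month,events,censored,at_risk"]
        for m, d, c, n in zip(self.months, self.events, self.censored, self.at_risk):
            lines.append(f"{m},{d},{c},{n}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_csv(cls, text: str) -> "SurvivalTableAgg":
        rows = [ln.split(",") for ln in text.strip().splitlines()[1:]]
        events = [int(r[1]) for r in rows]
        censored = [int(r[2]) for r in rows]
        return cls(events=events, censored=censored)

    def to_dict(self) -> dict:
        return {"months": self.months, "events": self.events,
                "censored": self.censored, "at_risk": self.at_risk}


@dataclass
class AggregateResult:
    """The only public output species of the secure layer."""

    statistic: str
    payload: object | None
    sdc_status: str
    reason: str = ""
    provenance: dict = field(default_factory=dict)

    @property
    def allowed(self) -> bool:
        return self.sdc_status == ALLOWED

    def unwrap(self):
        if not self.allowed:
            raise PermissionError(
                f"{self.statistic}: result refused ({self.reason})"
            )
        return self.payload

    def to_dict(self) -> dict:
        payload = self.payload
        if isinstance(payload, QuantileSummary):
            payload = list(payload.as_tuple())
        elif isinstance(payload, SurvivalTableAgg):
            payload = payload.to_dict()
        return {
            "statistic": self.statistic,
            "payload": payload,
            "sdc_status": self.sdc_status,
            **({"reason": self.reason} if self.reason else {}),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def sdc_guard(selection_size: int, k: int) -> str:
    """Refuse aggregates over small non-empty groups.

    ``k = 0`` disables the control (the printed-session reproduction mode,
    which reports cells of size 1); production deployments are expected to
    run with ``k`` around 5.  The check applies to the *selection* size, not
    to individual output cells.
    """
    if k < 0:
        raise ValueError("SDC threshold must be non-negative")
    return REFUSED if 0 < selection_size < k else ALLOWED


def _sum_shares(sv: SharedValue) -> SharedValue:
    r = sv.ring
    return SharedValue(
        r, INT if sv.kind == BIT else sv.kind,
        tuple(np.atleast_1d(r._reduce(s.sum(dtype=np.uint64))) for s in sv.shares),
    )


# ---------------------------------------------------------------------------
# oblivious sorting network
# ---------------------------------------------------------------------------

def _bitonic_layers(n: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Compare-exchange layers of a bitonic sorting network for 2^m lanes.

    Each layer is a pair of index arrays (lo, hi): after the layer,
    value[lo] <= value[hi] elementwise.  Pairs within a layer are disjoint,
    so a whole layer runs as one vectorised secure comparison.
    """
    layers = []
    k = 2
    while k <= n:
        j = k >> 1
        while j >= 1:
            lo, hi = [], []
            for i in range(n):
                l = i ^ j
                if l > i:
                    if i & k == 0:
                        lo.append(i); hi.append(l)
                    else:
                        lo.append(l); hi.append(i)
            layers.append((np.array(lo), np.array(hi)))
            j >>= 1
        k <<= 1
    return layers


def oblivious_sort(sv: SharedValue, store: TripleStore) -> SharedValue:
    """Sort shared values ascending without revealing any comparison.

    The input is padded to a power of two with a public "+infinity" sentinel
    (far above any representable clinical value), run through the bitonic
    network, and the first ``n`` lanes are returned.  Cost: O(n log^2 n)
    compare-and-swap gates, each one comparison and one multiplication.
    """
    n = len(sv)
    if n <= 1:
        return sv
    N = 1 << (n - 1).bit_length()
    ring = sv.ring
    sentinel = 1 << (ring.bits - 3)  # ring units; decoded ~2^(bits-f-3)
    shares = [s.copy() for s in sv.shares]
    if N > n:
        pad0 = np.full(N - n, sentinel, dtype=np.uint64)
        padz = np.zeros(N - n, dtype=np.uint64)
        shares = [
            np.concatenate([shares[0], pad0]),
            np.concatenate([shares[1], padz]),
            np.concatenate([shares[2], padz.copy()]),
        ]
    v = SharedValue(ring, sv.kind, tuple(shares))
    for lo, hi in _bitonic_layers(N):
        a, b = v[lo], v[hi]
        swap = less_than(b, a, store)          # 1 iff out of order
        delta = mul(swap, sub(a, b).with_kind(a.kind), store)
        new_lo = sub(a, delta).with_kind(a.kind)
        new_hi = (b + delta).with_kind(a.kind)
        for p in range(3):
            v.shares[p][lo] = new_lo.shares[p]
            v.shares[p][hi] = new_hi.shares[p]
    return v[np.arange(n)]


def _oblivious_max(sv: SharedValue, store: TripleStore) -> SharedValue:
    """Tournament maximum (log-depth), returned as a shared scalar."""
    v = sv
    while len(v) > 1:
        m = len(v)
        half = m // 2
        a, b = v[np.arange(half)], v[np.arange(half, 2 * half)]
        t = less_than(a, b, store)                     # 1 iff b larger
        mx = (a + mul(t, sub(b, a).with_kind(a.kind), store)).with_kind(a.kind)
        if m % 2:
            shares = tuple(
                np.concatenate([ms, vs[-1:]]) for ms, vs in zip(mx.shares, v.shares)
            )
            mx = SharedValue(v.ring, a.kind, shares)
        v = mx
    return v


# ---------------------------------------------------------------------------
# the statistics engine
# ---------------------------------------------------------------------------

class SecureStats:
    """Statistics engine bound to a triple store and an SDC threshold."""

    #: supported quantile conventions; "inclusive" is h = (n-1)p + 1 with
    #: linear interpolation (the common statistical default, pinned to the
    #: printed session output by the conformance tests)
    QUANTILE_CONVENTIONS = ("inclusive",)

    def __init__(self, store: TripleStore, sdc_threshold: int = 0,
                 quantile_convention: str = "inclusive") -> None:
        if quantile_convention not in self.QUANTILE_CONVENTIONS:
            raise ValueError(f"unknown quantile convention {quantile_convention!r}")
        self.store = store
        self.k = int(sdc_threshold)
        self.quantile_convention = quantile_convention

    # -- plumbing ------------------------------------------------------------

    def _selection_size(self, col: PrivateColumn,
                        mask: SelectionMask | None) -> int:
        if mask is None:
            return len(col)
        if len(mask) != len(col):
            raise SchemaMismatchError("mask length does not match column length")
        return int(col.values.ring.signed(reconstruct(_sum_shares(mask.bits)))[0])

    def _provenance(self, expr: str, col: PrivateColumn,
                    mask: SelectionMask | None) -> dict:
        return {
            "expression": expr,
            "column": col.spec.name,
            "mask": mask.description if mask is not None else None,
        }

    def _refuse(self, statistic: str, reason: str, prov: dict) -> AggregateResult:
        logger.info("SDC refusal: %s (%s) provenance=%s", statistic, reason, prov)
        return AggregateResult(statistic=statistic, payload=None,
                               sdc_status=REFUSED, reason=reason, provenance=prov)

    def _guarded(self, statistic: str, size: int, prov: dict,
                 require_nonempty: bool = False):
        if require_nonempty and size == 0:
            return self._refuse(statistic, "empty selection — undefined", prov)
        if sdc_guard(size, self.k) == REFUSED:
            return self._refuse(
                statistic, f"selection of size {size} below SDC threshold {self.k}",
                prov)
        return None

    # -- statistics ----------------------------------------------------------

    def length(self, col: PrivateColumn,
               mask: SelectionMask | None = None) -> AggregateResult:
        size = self._selection_size(col, mask)
        prov = self._provenance(f"length({col.spec.name})", col, mask)
        return AggregateResult("length", size, ALLOWED, provenance=prov)

    def freq(self, col: PrivateColumn,
             mask: SelectionMask | None = None) -> AggregateResult:
        """Frequency table over every dictionary category (zero counts kept)."""
        if col.kind != CATEGORICAL:
            raise SchemaMismatchError(
                f"freq needs a categorical column, got {col.spec.name!r} "
                f"({col.kind})")
        size = self._selection_size(col, mask)
        prov = self._provenance(f"freq({col.spec.name})", col, mask)
        refusal = self._guarded("freq", size, prov)
        if refusal is not None:
            return refusal
        counts: dict[str, int] = {}
        for code, label in enumerate(col.spec.categories):
            bits = equals_public(col.values, code, self.store)
            if mask is not None:
                bits = mul(bits, mask.bits, self.store)
            total = reconstruct(_sum_shares(bits))[0]
            counts[label] = int(col.values.ring.signed(np.atleast_1d(total))[0])
        return AggregateResult("freq", counts, ALLOWED, provenance=prov)

    def mean(self, col: PrivateColumn,
             mask: SelectionMask | None = None) -> AggregateResult:
        """Masked mean: the aggregate sum and count are the only openings."""
        if col.kind != METRIC:
            raise SchemaMismatchError(f"mean needs a metric column, got {col.kind}")
        size = self._selection_size(col, mask)
        prov = self._provenance(f"mean({col.spec.name})", col, mask)
        refusal = self._guarded("mean", size, prov, require_nonempty=True)
        if refusal is not None:
            return refusal
        vals = col.values
        if mask is not None:
            vals = mul(mask.bits, vals, self.store)   # bit x fixed, exact
        total_enc = reconstruct(_sum_shares(vals))
        total = float(vals.ring.decode_fixed(total_enc)[0])
        return AggregateResult("mean", total / size, ALLOWED, provenance=prov)

    def _interpolated_order_stat(self, sorted_sv: SharedValue, n: int,
                                 p: float) -> SharedValue:
        """Order statistic at h = (n-1)p + 1 interpolated on shares."""
        h = (n - 1) * p + 1.0
        lo = int(math.floor(h))
        frac = h - lo
        ring = sorted_sv.ring
        if frac == 0.0 or lo >= n:
            return sorted_sv[np.array([lo - 1])]
        x_lo = sorted_sv[np.array([lo - 1])]
        x_hi = sorted_sv[np.array([lo])]
        w = int(round(frac * ring.scale))
        scaled = mul_public(sub(x_hi, x_lo).with_kind(FIXED), w)
        return (x_lo + truncate(scaled, self.store)).with_kind(FIXED)

    def quantile(self, col: PrivateColumn,
                 mask: SelectionMask | None = None) -> AggregateResult:
        """Five-number summary; only the five aggregate values are opened."""
        if col.kind != METRIC:
            raise SchemaMismatchError(f"quantile needs a metric column, got {col.kind}")
        if mask is not None:
            raise SchemaMismatchError("masked quantiles are not part of the "
                                      "agreed statistics vocabulary")
        n = len(col)
        prov = self._provenance(f"quantile({col.spec.name})", col, None)
        refusal = self._guarded("quantile", n, prov, require_nonempty=True)
        if refusal is not None:
            return refusal
        sorted_sv = oblivious_sort(col.values, self.store)
        out = []
        for p in (0.0, 0.25, 0.5, 0.75, 1.0):
            q = self._interpolated_order_stat(sorted_sv, n, p)
            out.append(float(q.ring.decode_fixed(reconstruct(q))[0]))
        summary = QuantileSummary(*out)
        return AggregateResult("quantile", summary, ALLOWED, provenance=prov)

    def median(self, col: PrivateColumn) -> AggregateResult:
        res = self.quantile(col)
        if not res.allowed:
            res.statistic = "median"
            return res
        return AggregateResult("median", res.payload.median, ALLOWED,
                               provenance=self._provenance(
                                   f"median({col.spec.name})", col, None))

    def minimum(self, col: PrivateColumn) -> AggregateResult:
        res = self.quantile(col)
        if not res.allowed:
            res.statistic = "min"
            return res
        return AggregateResult("min", res.payload.min, ALLOWED,
                               provenance=res.provenance)

    def maximum(self, col: PrivateColumn) -> AggregateResult:
        res = self.quantile(col)
        if not res.allowed:
            res.statistic = "max"
            return res
        return AggregateResult("max", res.payload.max, ALLOWED,
                               provenance=res.provenance)

    def survival_table(self, time_col: PrivateColumn, event_col: PrivateColumn,
                       mask: SelectionMask | None = None,
                       max_month: int | None = None) -> AggregateResult:
        """Life table by counting events and censorings per follow-up month.

        Months are floor-binned from the fractional follow-up time on shares;
        per month m, the event count d_m and censoring count c_m are opened
        as aggregate sums.  The at-risk series is derived publicly from the
        conservation invariant.  ``max_month`` defaults to the (aggregate)
        oblivious maximum of the binned months.
        """
        if time_col.kind != METRIC:
            raise SchemaMismatchError("survival_table needs a metric time column")
        if event_col.kind != CATEGORICAL or tuple(event_col.spec.categories) not in (
                ("0", "1"),):
            raise SchemaMismatchError(
                "event column must be categorical with categories ('0', '1')")
        if len(time_col) != len(event_col):
            raise SchemaMismatchError("time and event columns differ in length")
        size = self._selection_size(time_col, mask)
        prov = {
            "expression": f"survival_table({time_col.spec.name}, "
                          f"{event_col.spec.name})",
            "column": [time_col.spec.name, event_col.spec.name],
            "mask": mask.description if mask is not None else None,
        }
        refusal = self._guarded("survival_table", size, prov, require_nonempty=True)
        if refusal is not None:
            return refusal
        months = truncate(time_col.values, self.store, out_kind=INT)
        event_bits = event_col.values.with_kind(BIT)
        if mask is not None:
            event_bits = mul(event_bits, mask.bits, self.store)
            in_sel = mask.bits
        else:
            in_sel = R.public_share(np.ones(len(time_col), dtype=np.int64),
                                    ring=time_col.values.ring, kind=BIT)
        censor_bits = sub(in_sel, event_bits).with_kind(BIT)
        if max_month is None:
            mm = _oblivious_max(months, self.store)
            max_month = int(months.ring.signed(reconstruct(mm))[0])
        events, censored = [], []
        for m in range(max_month + 1):
            eq = equals_public(months, m, self.store)
            d = reconstruct(_sum_shares(mul(eq, event_bits, self.store)))[0]
            c = reconstruct(_sum_shares(mul(eq, censor_bits, self.store)))[0]
            ringo = months.ring
            events.append(int(ringo.signed(np.atleast_1d(d))[0]))
            censored.append(int(ringo.signed(np.atleast_1d(c))[0]))
        table = SurvivalTableAgg(events=events, censored=censored)
        table.validate()
        return AggregateResult("survival_table", table, ALLOWED, provenance=prov)
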