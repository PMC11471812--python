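"""Three-party additive secret sharing over a power-of-two ring.

Every private value in the system lives here: a real (or categorical code)
is fixed-point encoded into ``Z_{2^k}`` and split into three uniformly random
ring elements, one per compute party, that sum to the encoding.  Any single
share is marginally uniform, so a party on its own learns nothing; all
statistics downstream are built from the linear homomorphism of the shares
plus the dealer-assisted protocols below.

Adversary model: semi-honest parties, honest majority (no two of the three
compute parties collude), and a trusted dealer that distributes correlated
randomness (Beaver triples and random values with bit shares) but never sees
data.  This matches a passively secure outsourced-computation setting.

Protocols
---------
* addition / subtraction / public scaling: local, no communication
* multiplication: Beaver triples (only the uniformly masked differences
  ``x - a`` and ``y - b`` are ever opened)
* fixed-point truncation after a product: exact floor truncation through a
  masked opening of ``x + r`` where the dealer shared ``r`` together with its
  bit decomposition; the borrow of ``(c - r)`` is evaluated as a chain of
  Beaver AND gates with public per-lane coefficients
* comparison (signed less-than) = most significant bit of the difference,
  extracted through the same masked-opening borrow chain
* equality against a public constant: bitwise agreement product

All share vectors are ``numpy.uint64`` arrays; arithmetic wraps modulo
``2^64`` natively and is masked down for reduced rings (used by the
statistical privacy tests, which run on ``Z_256``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Ring",
    "SharedValue",
    "TripleStore",
    "TripleExhaustedError",
    "KindMismatchError",
    "RangeError",
    "share",
    "reconstruct",
    "public_share",
    "add",
    "sub",
    "mul_public",
    "mul",
    "truncate",
    "msb",
    "less_than",
    "equals_public",
    "bit_not",
]

FIXED = "fixed"
INT = "integer"
BIT = "bit"

_U64 = np.uint64


class KindMismatchError(TypeError):
    """Operands of a share-level operation have incompatible kinds."""


class RangeError(ValueError):
    """Plaintext outside the representable fixed-point range."""


class TripleExhaustedError(RuntimeError):
    """The correlated-randomness queue has no unused triples left."""


@dataclass(frozen=True)
class Ring:
    """Modular ring ``Z_{2^bits}`` with fixed-point scale ``2^frac_bits``.

    The default (``bits=64, frac_bits=16``) gives native word arithmetic and
    a ``2^-16`` grid — ample for ages, months, Gy and cm^3 at clinical
    precision.  Reduced rings (e.g. ``bits=8``) make share distributions
    exhaustively testable.
    """

    bits: int = 64
    frac_bits: int = 16

    def __post_init__(self) -> None:
        if not 1 <= self.bits <= 64:
            raise ValueError("ring width must be between 1 and 64 bits")
        if not 0 <= self.frac_bits < self.bits:
            raise ValueError("frac_bits must fit inside the ring")

    @property
    def modulus(self) -> int:
        return 1 << self.bits

    @property
    def mask(self) -> int:
        return (1 << self.bits) - 1

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    # largest magnitude a fixed-point value may take: one bit is the sign,
    # and dealer-assisted truncation needs one more bit of headroom.
    @property
    def max_abs(self) -> float:
        return float(1 << (self.bits - self.frac_bits - 1))

    def _reduce(self, a: np.ndarray) -> np.ndarray:
        if self.bits == 64:
            return a
        return a & _U64(self.mask)

    # -- fixed-point codec ---------------------------------------------------

    def encode_fixed(self, x) -> np.ndarray:
        """Encode reals on the ``2^-frac_bits`` grid, round-half-even.

        Scaling by a power of two is exact in binary floating point, so any
        representable grid value round-trips exactly; off-grid values land on
        the nearest grid point (ties to even).
        """
        xs = np.asarray(x, dtype=np.float64)
        if np.any(~np.isfinite(xs)):
            raise RangeError("non-finite value cannot be encoded")
        if np.any(np.abs(xs) >= self.max_abs):
            raise RangeError(
                f"|x| must be < 2^{self.bits - self.frac_bits - 1} "
                f"for a {self.bits}-bit ring with f={self.frac_bits}"
            )
        scaled = np.rint(xs * float(self.scale))
        out = self._reduce(scaled.astype(np.int64).astype(_U64))
        return out

    def encode_int(self, x) -> np.ndarray:
        xs = np.asarray(x)
        return self._reduce(np.asarray(xs, dtype=np.int64).astype(_U64))

    def signed(self, u: np.ndarray) -> np.ndarray:
        """Two's-complement (signed) integer interpretation of ring elements."""
        u = np.ascontiguousarray(u, dtype=_U64)
        if self.bits == 64:
            return u.view(np.int64)
        s = u.astype(np.int64)
        half = 1 << (self.bits - 1)
        return np.where(s >= half, s - (1 << self.bits), s)

    def decode_fixed(self, u: np.ndarray) -> np.ndarray:
        return self.signed(u) / float(self.scale)

    def decode_fixed_exact(self, u: int) -> Fraction:
        """Exact rational decode of a single ring element."""
        s = int(u) & self.mask
        if s >= 1 << (self.bits - 1):
            s -= self.modulus
        return Fraction(s, self.scale)

    def random_elements(self, rng: np.random.Generator, shape) -> np.ndarray:
        if self.bits == 64:
            return rng.integers(0, 2**64, size=shape, dtype=_U64)
        return rng.integers(0, self.modulus, size=shape, dtype=_U64)


DEFAULT_RING = Ring()


@dataclass
class SharedValue:
    """A (vector of) secret value(s) held as three additive shares.

    ``shares`` are three equal-shape ``uint64`` arrays, one per party; their
    elementwise sum modulo the ring is the plaintext encoding.  ``kind``
    records the plaintext semantics: ``fixed`` (scale ``2^f``), ``integer``
    (scale 1) or ``bit`` (plaintext in {0, 1}).
    """

    ring: Ring
    kind: str
    shares: tuple[np.ndarray, np.ndarray, np.ndarray]

    def __post_init__(self) -> None:
        if self.kind not in (FIXED, INT, BIT):
            raise KindMismatchError(f"unknown kind {self.kind!r}")

    @property
    def shape(self):
        return self.shares[0].shape

    def __len__(self) -> int:
        return self.shares[0].shape[0]

    def __getitem__(self, idx) -> "SharedValue":
        return SharedValue(self.ring, self.kind, tuple(s[idx] for s in self.shares))

    def party_share(self, p: int) -> np.ndarray:
        """Share array as seen by party ``p`` — used by privacy inspections."""
        return self.shares[p]

    def with_kind(self, kind: str) -> "SharedValue":
        return SharedValue(self.ring, kind, self.shares)

    def copy(self) -> "SharedValue":
        return SharedValue(self.ring, self.kind, tuple(s.copy() for s in self.shares))

    # operator sugar delegating to the module-level protocol functions
    def __add__(self, other: "SharedValue") -> "SharedValue":
        return add(self, other)

    def __sub__(self, other: "SharedValue") -> "SharedValue":
        return sub(self, other)

    def __neg__(self) -> "SharedValue":
        return mul_public(self, -1)


def _check_compatible(a: SharedValue, b: SharedValue) -> str:
    if a.ring != b.ring:
        raise KindMismatchError("operands live in different rings")
    if a.kind != b.kind:
        raise KindMismatchError(f"kind mismatch: {a.kind} vs {b.kind}")
    return a.kind


def share(
    value,
    rng: np.random.Generator | None = None,
    *,
    ring: Ring = DEFAULT_RING,
    kind: str = INT,
    encoded: bool = False,
) -> SharedValue:
    """Split plaintext(s) into three additive shares.

    Two shares are independent uniform ring elements; the third is the
    difference to the encoding, so the triple sums to the plaintext while any
    single share is marginally uniform on ``[0, 2^bits)``.
    """
    if rng is None:
        rng = np.random.default_rng()  # OS entropy
    if encoded:
        enc = np.asarray(value, dtype=_U64)
    elif kind == FIXED:
        enc = ring.encode_fixed(value)
    else:
        enc = ring.encode_int(value)
    enc = np.atleast_1d(enc)
    s1 = ring.random_elements(rng, enc.shape)
    s2 = ring.random_elements(rng, enc.shape)
    s3 = ring._reduce(enc - s1 - s2)
    return SharedValue(ring, kind, (s1, s2, s3))


def reconstruct(sv: SharedValue) -> np.ndarray:
    """Sum the three shares modulo the ring (an *opening* — aggregate-only
    callers must apply this exclusively to values that are safe to publish)."""
    return sv.ring._reduce(sv.shares[0] + sv.shares[1] + sv.shares[2])


def reconstruct_fixed(sv: SharedValue) -> np.ndarray:
    return sv.ring.decode_fixed(reconstruct(sv))


def reconstruct_signed(sv: SharedValue) -> np.ndarray:
    return sv.ring.signed(reconstruct(sv))


def public_share(value, *, ring: Ring = DEFAULT_RING, kind: str = INT,
                 shape=None, encoded: bool = False) -> SharedValue:
    """A public constant represented in share form (held by party 0)."""
    if encoded:
        enc = np.asarray(value, dtype=_U64)
    elif kind == FIXED:
        enc = ring.encode_fixed(value)
    else:
        enc = ring.encode_int(value)
    enc = np.atleast_1d(enc)
    if shape is not None:
        enc = np.broadcast_to(enc, shape).copy()
    zero = np.zeros(enc.shape, dtype=_U64)
    return SharedValue(ring, kind, (enc, zero.copy(), zero))


def add(a: SharedValue, b: SharedValue) -> SharedValue:
    kind = _check_compatible(a, b)
    r = a.ring
    out_kind = INT if kind == BIT else kind  # bit + bit may carry out of {0,1}
    return SharedValue(r, out_kind, tuple(r._reduce(x + y) for x, y in zip(a.shares, b.shares)))


def sub(a: SharedValue, b: SharedValue) -> SharedValue:
    kind = _check_compatible(a, b)
    r = a.ring
    out_kind = INT if kind == BIT else kind
    return SharedValue(r, out_kind, tuple(r._reduce(x - y) for x, y in zip(a.shares, b.shares)))


def mul_public(a: SharedValue, k) -> SharedValue:
    """Scale by a public integer (or per-lane integer array) — local."""
    r = a.ring
    kf = np.asarray(np.asarray(k, dtype=np.int64)).astype(_U64)
    out_kind = a.kind if not (a.kind == BIT) else INT
    return SharedValue(r, out_kind, tuple(r._reduce(s * kf) for s in a.shares))


def _add_public_lane(a: SharedValue, c: np.ndarray, kind: str | None = None) -> SharedValue:
    r = a.ring
    s0 = r._reduce(a.shares[0] + np.asarray(c, dtype=_U64))
    return SharedValue(r, kind or a.kind, (s0, a.shares[1], a.shares[2]))


def _mul_public_lane(a: SharedValue, c: np.ndarray) -> SharedValue:
    r = a.ring
    cf = np.asarray(c, dtype=_U64)
    return SharedValue(r, a.kind, tuple(r._reduce(s * cf) for s in a.shares))


def bit_not(b: SharedValue) -> SharedValue:
    """1 - b for a shared bit."""
    if b.kind != BIT:
        raise KindMismatchError("bit_not needs a shared bit")
    r = b.ring
    one = np.ones(b.shape, dtype=_U64)
    return SharedValue(
        r, BIT,
        (r._reduce(one - b.shares[0]), r._reduce(-b.shares[1]), r._reduce(-b.shares[2])),
    )


class TripleStore:
    """Queue of dealer-issued correlated randomness.

    The dealer is a logical component trusted not to collude with any
    compute party: it samples Beaver triples ``(a, b, c=ab)`` and random ring
    elements with bit decompositions ("edabits"), secret-shares them, and
    hands the shares out.  Each unit is consumed exactly once.  With
    ``capacity=None`` the dealer stays online and deals on demand; a finite
    capacity models a pre-dealt queue and raises :class:`TripleExhaustedError`
    when it runs dry.
    """

    def __init__(self, ring: Ring = DEFAULT_RING, seed: int | None = None,
                 capacity: int | None = None) -> None:
        self.ring = ring
        self.rng = np.random.default_rng(seed)
        self.capacity = capacity
        self.triples_used = 0
        self.edabits_used = 0

    def _charge(self, n: int) -> None:
        if self.capacity is not None and self.triples_used + n > self.capacity:
            raise TripleExhaustedError(
                f"triple queue exhausted ({self.triples_used} used, "
                f"{n} requested, capacity {self.capacity})"
            )

    def take_triples(self, shape) -> tuple[SharedValue, SharedValue, SharedValue]:
        n = int(np.prod(shape)) if not np.isscalar(shape) else int(shape)
        self._charge(n)
        self.triples_used += n
        r = self.ring
        a = r.random_elements(self.rng, shape)
        b = r.random_elements(self.rng, shape)
        c = r._reduce(a * b)
        return (
            share(a, self.rng, ring=r, kind=INT, encoded=True),
            share(b, self.rng, ring=r, kind=INT, encoded=True),
            share(c, self.rng, ring=r, kind=INT, encoded=True),
        )

    def take_edabits(self, shape) -> tuple[SharedValue, SharedValue]:
        """Random ``r`` (shape ``shape``) plus bit shares (shape ``(bits,) + shape``)."""
        self.edabits_used += int(np.prod(shape)) if not np.isscalar(shape) else int(shape)
        r = self.ring
        val = r.random_elements(self.rng, shape)
        bits = np.stack([(val >> _U64(i)) & _U64(1) for i in range(r.bits)])
        return (
            share(val, self.rng, ring=r, kind=INT, encoded=True),
            share(bits, self.rng, ring=r, kind=BIT, encoded=True),
        )


def mul(a: SharedValue, b: SharedValue, store: TripleStore) -> SharedValue:
    """Beaver-triple multiplication.

    Only the masked differences ``x - a`` and ``y - b`` are opened; both are
    uniform, so nothing about the operands leaks.  Fixed-point x fixed-point
    products are re-truncated to scale ``2^f``; a bit factor never changes
    the other operand's scale.
    """
    if a.ring != b.ring:
        raise KindMismatchError("operands live in different rings")
    if (a.kind == FIXED) != (b.kind == FIXED) and not (a.kind == BIT or b.kind == BIT):
        raise KindMismatchError(f"cannot multiply {a.kind} by {b.kind}")
    ta, tb, tc = store.take_triples(np.broadcast_shapes(a.shape, b.shape))
    d = reconstruct(sub(a.with_kind(INT), ta))
    e = reconstruct(sub(b.with_kind(INT), tb))
    z = add(tc, _mul_public_lane(tb, d))
    z = add(z, _mul_public_lane(ta, e))
    z = _add_public_lane(z, a.ring._reduce(d * e))

    if a.kind == FIXED and b.kind == FIXED:
        return truncate(z.with_kind(FIXED), store)
    if BIT in (a.kind, b.kind):
        other = a.kind if b.kind == BIT else b.kind
        return z.with_kind(other)
    return z.with_kind(INT)


def _borrow_chain(c_pub: np.ndarray, rbits: SharedValue, store: TripleStore,
                  collect: Iterable[int]) -> dict[int, SharedValue]:
    """Borrow bits of the subtraction ``c - r`` with ``c`` public.

    Returns, for each requested index ``j``, the borrow *into* bit position
    ``j`` (``j = bits`` gives the final borrow, i.e. the bit ``c < r``).
    Costs one Beaver AND per ring bit; lanes are processed in parallel.
    """
    ring = store.ring
    want = set(collect)
    out: dict[int, SharedValue] = {}
    lanes = c_pub.shape
    borrow = SharedValue(
        ring, BIT, tuple(np.zeros(lanes, dtype=_U64) for _ in range(3))
    )
    for i in range(ring.bits):
        if i in want:
            out[i] = borrow
        ci = ((c_pub >> _U64(i)) & _U64(1)).astype(_U64)
        ri = rbits[i]
        t = mul(ri, borrow, store)  # r_i AND borrow
        # c_i = 0: borrow' = r_i + b - t (OR);  c_i = 1: borrow' = t (AND)
        lin = add(ri, borrow).with_kind(BIT)
        borrow = add(
            _mul_public_lane(sub(lin.with_kind(INT), t.with_kind(INT)).with_kind(BIT),
                             (1 - ci)),
            _mul_public_lane(t, ci),
        ).with_kind(BIT)
    if ring.bits in want:
        out[ring.bits] = borrow
    return out


def _masked_open(x: SharedValue, store: TripleStore) -> tuple[np.ndarray, SharedValue]:
    r, rbits = store.take_edabits(x.shape)
    c = reconstruct(add(x.with_kind(INT), r))
    return c, rbits


def truncate(y: SharedValue, store: TripleStore, shift: int | None = None,
             out_kind: str = FIXED) -> SharedValue:
    """Exact floor division of the signed plaintext by ``2^shift``.

    Used to rescale after fixed-point products (``shift = f``) and to bin
    fractional months into integers.  Requires ``|plaintext encoding| <
    2^(bits-2)`` so the positivity offset does not overflow.
    """
    ring = y.ring
    f = ring.frac_bits if shift is None else shift
    offset = 1 << (ring.bits - 2)
    u = _add_public_lane(y, np.full(y.shape, offset, dtype=_U64))
    c, rbits = _masked_open(u, store)
    borrows = _borrow_chain(c, rbits, store, collect=(f, ring.bits))
    b_f, wrap = borrows[f], borrows[ring.bits]
    # r >> f, linearly from the dealt bit shares
    weights = np.array([1 << (i - f) for i in range(f, ring.bits)], dtype=_U64)
    hi_shares = tuple(
        ring._reduce((s[f:].T * weights).T.sum(axis=0, dtype=_U64))
        for s in rbits.shares
    )
    r_hi = SharedValue(ring, INT, hi_shares)
    res = _add_public_lane(
        add(
            sub(public_share(c >> _U64(f), ring=ring, kind=INT, encoded=True), r_hi),
            sub(mul_public(wrap, 1 << (ring.bits - f)).with_kind(INT),
                b_f.with_kind(INT)),
        ),
        np.full(y.shape, ring.modulus - (offset >> f), dtype=_U64),
    )
    return res.with_kind(out_kind)


def msb(x: SharedValue, store: TripleStore) -> SharedValue:
    """Most significant (sign) bit of the two's-complement plaintext."""
    ring = x.ring
    c, rbits = _masked_open(x, store)
    borrows = _borrow_chain(c, rbits, store, collect=(ring.bits - 1, ring.bits))
    b_hi, wrap = borrows[ring.bits - 1], borrows[ring.bits]
    c_hi = (c >> _U64(ring.bits - 1)) & _U64(1)
    res = add(
        mul_public(wrap, 2).with_kind(INT),
        sub(
            _add_public_lane(mul_public(rbits[ring.bits - 1], -1).with_kind(INT), c_hi),
            b_hi.with_kind(INT),
        ),
    )
    return res.with_kind(BIT)


def less_than(a: SharedValue, b: SharedValue, store: TripleStore) -> SharedValue:
    """Shared bit ``[a < b]`` on the signed plaintexts.

    Sound while ``|a - b| < 2^(bits-1)`` (always true for clinical-scale
    fixed-point data in the 64-bit ring).
    """
    if a.kind != b.kind:
        raise KindMismatchError(f"kind mismatch: {a.kind} vs {b.kind}")
    return msb(sub(a, b).with_kind(a.kind), store)


def equals_public(a: SharedValue, const, store: TripleStore) -> SharedValue:
    """Shared bit ``[a == const]`` for a public constant (scalar or per-lane)."""
    ring = a.ring
    if a.kind == FIXED:
        enc = ring.encode_fixed(const)
    else:
        enc = ring.encode_int(const)
    z = sub(a, public_share(enc, ring=ring, kind=a.kind, shape=a.shape, encoded=True))
    c, rbits = _masked_open(z, store)
    # z == 0  iff  c == r bitwise: multiply the per-bit agreement indicators
    acc: SharedValue | None = None
    for i in range(ring.bits):
        ci = ((c >> _U64(i)) & _U64(1)).astype(_U64)
        ri = rbits[i]
        # agreement m_i = r_i if c_i else (1 - r_i)
        m = add(
            _mul_public_lane(ri, (2 * ci - 1)),
            public_share((1 - ci), ring=ring, kind=BIT, encoded=True),
        ).with_kind(BIT)
        acc = m if acc is None else mul(acc, m, store)
    assert acc is not None
    return acc
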