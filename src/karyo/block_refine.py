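"""Reduce two comparable arm sequences to a signed permutation of common blocks.

Both sequences are first canonicalised (whole-arm flips normalised away), then
the band-level description of ``b`` is rewritten in ``a``'s coordinates and
condensed into maximal runs that are contiguous and co-oriented in *both*
sequences.  Virtual end markers frame the arm so that terminal segments only
merge when they abut the same end in both sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

from .band_model import ArmSequence, Band, check_same_band_set, _maximal_runs
from .errors import ValidationError


@dataclass(frozen=True)
class SignedPermutation:
    """Ordered signed integers whose absolute values are a permutation of 1..n."""

    elements: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(abs(v) for v in self.elements) != list(range(1, len(self.elements) + 1)):
            raise ValidationError([f"not a signed permutation: {self.elements}"])
        if any(v == 0 for v in self.elements):
            raise ValidationError(["signed permutation elements must be nonzero"])

    @property
    def n(self) -> int:
        return len(self.elements)

    @property
    def is_identity(self) -> bool:
        return self.elements == tuple(range(1, self.n + 1))

    def inverse(self) -> "SignedPermutation":
        inv = [0] * self.n
        for pos, v in enumerate(self.elements, start=1):
            inv[abs(v) - 1] = pos if v > 0 else -pos
        return SignedPermutation(tuple(inv))

    def reversed_segment(self, i: int, j: int) -> "SignedPermutation":
        if not (0 <= i <= j < self.n):
            raise ValidationError([f"reversal ({i}, {j}) out of range for n={self.n}"])
        e = list(self.elements)
        e[i : j + 1] = [-v for v in reversed(e[i : j + 1])]
        return SignedPermutation(tuple(e))

    def __str__(self) -> str:
        return "(" + ", ".join(f"{v:+d}" for v in self.elements) + ")"


def identity_permutation(n: int) -> SignedPermutation:
    return SignedPermutation(tuple(range(1, n + 1)))


@dataclass(frozen=True)
class CommonBlock:
    """A maximal segment shared by both sequences.

    ``band_run`` lists the bands in ``a``'s reading order; blocks are numbered
    1..n in that order, so ``orientation_in_a`` is always forward and
    ``orientation_in_b`` carries the relative orientation.
    """

    id: int
    band_run: tuple[Band, ...]
    orientation_in_b: str  # forward | inverted

    orientation_in_a: str = "forward"


def _b_in_a_coordinates(a_order: tuple[int, ...], b_order: tuple[int, ...]) -> list[int]:
    """Express b's signed band list in a's position coordinates."""
    pos_in_a = {}
    sign_in_a = {}
    for pos, v in enumerate(a_order, start=1):
        pos_in_a[abs(v)] = pos
        sign_in_a[abs(v)] = 1 if v > 0 else -1
    out = []
    for v in b_order:
        s = (1 if v > 0 else -1) * sign_in_a[abs(v)]
        out.append(s * pos_in_a[abs(v)])
    return out


def flip_order(order: tuple[int, ...]) -> tuple[int, ...]:
    """The same arm read from the other end (reverse and negate)."""
    return tuple(-v for v in reversed(order))


def permutation_from_orders(
    a_order: tuple[int, ...], b_order: tuple[int, ...]
) -> SignedPermutation:
    """Block permutation of two raw signed band orders (no canonicalisation)."""
    m = len(a_order)
    framed = [0] + _b_in_a_coordinates(a_order, b_order) + [m + 1]
    runs = []
    for i, j in _maximal_runs(framed):
        vals = [v for v in framed[i : j + 1] if 0 < abs(v) <= m]
        if vals:
            runs.append((min(abs(v) for v in vals), 1 if vals[0] > 0 else -1))
    by_a = sorted(lo for lo, _ in runs)
    ids = {lo: rank + 1 for rank, lo in enumerate(by_a)}
    return SignedPermutation(tuple(sign * ids[lo] for lo, sign in runs))


def refine_to_blocks(a: ArmSequence, b: ArmSequence) -> list[CommonBlock]:
    """Coarsest common oriented-block refinement of two comparable sequences."""
    check_same_band_set(a, b)
    a = a.canonical()
    b = b.canonical()
    m = len(a.order)
    framed = [0] + _b_in_a_coordinates(a.order, b.order) + [m + 1]
    blocks: list[tuple[int, int, int]] = []  # (a_start_pos, a_end_pos, sign) 1-based
    for i, j in _maximal_runs(framed):
        vals = framed[i : j + 1]
        vals = [v for v in vals if 0 < abs(v) <= m]  # strip frame markers
        if not vals:
            continue
        sign = 1 if vals[0] > 0 else -1
        lo, hi = min(abs(v) for v in vals), max(abs(v) for v in vals)
        blocks.append((lo, hi, sign))
    # number blocks 1..n by position in a
    order = sorted(range(len(blocks)), key=lambda t: blocks[t][0])
    ids = {t: rank + 1 for rank, t in enumerate(order)}
    out = []
    for t in order:
        lo, hi, sign = blocks[t]
        band_run = tuple(a.reference[abs(a.order[p - 1]) - 1] for p in range(lo, hi + 1))
        out.append(
            CommonBlock(
                id=ids[t],
                band_run=band_run,
                orientation_in_b="forward" if sign > 0 else "inverted",
            )
        )
    return out


def to_signed_permutation(a: ArmSequence, b: ArmSequence) -> SignedPermutation:
    """b's block order with orientations relative to a (identity iff a == b)."""
    check_same_band_set(a, b)
    return permutation_from_orders(a.canonical().order, b.canonical().order)


def apply_permutation(a: ArmSequence, blocks: list[CommonBlock], p: SignedPermutation) -> tuple[int, ...]:
    """Rearrange a's band list according to block permutation ``p``.

    Returns a signed band order (in a's *canonical* coordinates); used to check
    that the permutation reconstructs ``b``.
    """
    a = a.canonical()
    if len(blocks) != p.n:
        raise ValidationError([f"{len(blocks)} blocks but permutation of length {p.n}"])
    # block id -> signed slice of a.order
    spans: dict[int, list[int]] = {}
    pos = 1
    for blk in sorted(blocks, key=lambda x: x.id):
        run = a.order[pos - 1 : pos - 1 + len(blk.band_run)]
        spans[blk.id] = list(run)
        pos += len(blk.band_run)
    out: list[int] = []
    for v in p.elements:
        seg = spans[abs(v)]
        if v > 0:
            out.extend(seg)
        else:
            out.extend(-x for x in reversed(seg))
    return tuple(out)


def blocks_to_tsv(blocks: list[CommonBlock]) -> str:
    """Debug dump of a block table."""
    lines = ["id\tn_bands\tband_run\torientation_in_a\torientation_in_b"]
    for b in blocks:
        run = " ".join(x.label for x in b.band_run)
        lines.append(f"{b.id}\t{len(b.band_run)}\t{run}\t{b.orientation_in_a}\t{b.orientation_in_b}")
    return "\n".join(lines) + "\n"
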