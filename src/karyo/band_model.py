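"""Domain types for polytene-chromosome banding sequences and karyotypes.

A chromosome arm is modelled as a linear order of *bands*; each band has a
major number and an optional lowercase subband letter (Keyl-style labels such
as ``"17"`` or ``"17b"``).  A banding sequence for an arm of a species is a
signed rearrangement of the arm's *reference* band order, written in interval
notation: whitespace-separated tokens ``"3"``, ``"1-7"`` or ``"15-12"``, where
a descending token denotes an inverted (reversed) block.

Karyotype records bundle the per-arm sequence pools of one species together
with its haploid number and whole-arm combination, and round-trip through a
small JSON dialect (see :func:`read_karyotype` / :func:`write_karyotype`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import BandParseError, IncomparableArmsError, ValidationError

ARMS = ("A", "B", "C", "D", "E", "F", "G")

ANNOTATION_FEATURES = frozenset({"nucleolus", "balbiani_ring", "puff", "centromere"})

_BAND_RE = re.compile(r"^([0-9]+)([a-z]+)?$")
_CODE_RE = re.compile(r"^[a-z]{3}([A-G])")


@dataclass(frozen=True, order=True)
class Band:
    """A single polytene band: major number plus optional subband letters."""

    major: int
    sub: str = ""

    def __post_init__(self) -> None:
        if self.major < 1:
            raise ValidationError([f"band major must be >= 1, got {self.major}"])
        if self.sub and not self.sub.islower():
            raise ValidationError([f"subband letters must be lowercase, got {self.sub!r}"])

    @property
    def label(self) -> str:
        return f"{self.major}{self.sub}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_band_label(text: str) -> Band:
    m = _BAND_RE.match(text)
    if not m:
        raise BandParseError(f"malformed band label {text!r}", token=text)
    return Band(int(m.group(1)), m.group(2) or "")


def make_reference(labels: Iterable[str]) -> tuple[Band, ...]:
    """Build a reference band order from labels, enforcing the (major, sub) order."""
    bands = tuple(parse_band_label(x) for x in labels)
    problems = []
    for prev, cur in zip(bands, bands[1:]):
        if not (prev < cur):
            problems.append(f"reference order violates (major, sub) order at {prev}..{cur}")
    if len(set(bands)) != len(bands):
        problems.append("reference order contains duplicate bands")
    if problems:
        raise ValidationError(problems)
    return bands


@dataclass(frozen=True)
class OrientedInterval:
    """A contiguous run of reference bands read forward or inverted."""

    start: Band
    end: Band

    @property
    def inverted(self) -> bool:
        return self.end < self.start

    @property
    def orientation(self) -> str:
        return "inverted" if self.inverted else "forward"

    def __str__(self) -> str:
        if self.start == self.end:
            return self.start.label
        return f"{self.start.label}-{self.end.label}"


def _maximal_runs(order: Sequence[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive signed values (``next == cur + 1``)."""
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and order[j + 1] == order[j] + 1:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


@dataclass(frozen=True)
class ArmSequence:
    """One banding sequence of one chromosome arm.

    ``order`` holds signed 1-based reference indices in reading position
    order; an empty ``order`` means "not mapped" (the sequence has a code but
    no usable formula).  Isolated single bands are normalised to forward
    orientation because a one-band inversion is not observable at band
    granularity.
    """

    code: str
    arm: str
    reference: tuple[Band, ...]
    order: tuple[int, ...] = ()
    annotations: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        problems: list[str] = []
        if self.arm not in ARMS:
            problems.append(f"unknown arm {self.arm!r}")
        m = _CODE_RE.match(self.code)
        if m and m.group(1) != self.arm:
            problems.append(
                f"code {self.code!r} names arm {m.group(1)} but sequence is on arm {self.arm}"
            )
        for feature, _pos in self.annotations:
            if feature not in ANNOTATION_FEATURES:
                problems.append(f"unknown annotation feature {feature!r}")
        if self.order:
            n = len(self.reference)
            covered = sorted(abs(v) for v in self.order)
            if covered != list(range(1, n + 1)):
                seen: set[int] = set()
                for v in self.order:
                    if abs(v) in seen:
                        problems.append(
                            f"band {self.reference[abs(v) - 1].label} covered more than once"
                        )
                    seen.add(abs(v))
                for idx in set(range(1, n + 1)) - {abs(v) for v in self.order}:
                    problems.append(f"band {self.reference[idx - 1].label} missing from sequence")
        if problems:
            raise ValidationError(problems)
        # normalise isolated negatives to forward
        if self.order:
            order = list(self.order)
            for i, j in _maximal_runs(order):
                if i == j and order[i] < 0:
                    order[i] = -order[i]
            object.__setattr__(self, "order", tuple(order))
        object.__setattr__(self, "annotations", tuple(tuple(a) for a in self.annotations))

    @property
    def is_mapped(self) -> bool:
        return bool(self.order)

    @property
    def n_bands(self) -> int:
        return len(self.reference)

    @property
    def intervals(self) -> tuple[OrientedInterval, ...]:
        """Maximal oriented intervals of the formula, derived from ``order``."""
        out = []
        for i, j in _maximal_runs(self.order):
            out.append(
                OrientedInterval(
                    self.reference[abs(self.order[i]) - 1],
                    self.reference[abs(self.order[j]) - 1],
                )
            )
        return tuple(out)

    @property
    def formula(self) -> str | None:
        if not self.is_mapped:
            return None
        return format_band_sequence(self)

    def canonical(self) -> "ArmSequence":
        """Normalise away a whole-arm flip.

        An arm read in the opposite direction is the same cytological object;
        the canonical representative is the one whose first band is smaller in
        the reference order.
        """
        if not self.is_mapped:
            return self
        rev = tuple(-v for v in reversed(self.order))
        if (abs(rev[0]), rev) < (abs(self.order[0]), self.order):
            return replace(self, order=rev)
        return self

    def reversed_segment(self, i: int, j: int) -> "ArmSequence":
        """Return a copy with reading positions ``i..j`` (inclusive) reversed."""
        if not (0 <= i <= j < len(self.order)):
            raise ValidationError([f"reversal ({i}, {j}) out of range for {len(self.order)} bands"])
        order = list(self.order)
        order[i : j + 1] = [-v for v in reversed(order[i : j + 1])]
        return replace(self, order=tuple(order))


def identity_sequence(code: str, arm: str, reference: tuple[Band, ...], annotations=()) -> ArmSequence:
    return ArmSequence(code, arm, reference, tuple(range(1, len(reference) + 1)), tuple(annotations))


def parse_band_sequence(
    text: str,
    arm: str,
    reference_order: Sequence[Band] | Sequence[str],
    code: str = "seq?",
    annotations: Iterable[tuple[str, str]] = (),
) -> ArmSequence:
    """Parse a Keyl-notation formula into an :class:`ArmSequence`.

    Tokens are ``"X"`` or ``"X-Y"`` with band labels like ``"3"`` or ``"17b"``;
    a descending token (``"15-12"``) is an inverted block.  The parsed
    intervals must cover the reference band set exactly once.
    """
    reference = tuple(
        b if isinstance(b, Band) else parse_band_label(b) for b in reference_order
    )
    index = {b.label: k + 1 for k, b in enumerate(reference)}
    order: list[int] = []
    problems: list[str] = []
    for pos, token in enumerate(text.split()):
        parts = token.split("-")
        if len(parts) > 2 or not all(parts):
            raise BandParseError(
                f"malformed token {token!r} at position {pos}", token=token, position=pos
            )
        try:
            lo = parse_band_label(parts[0])
            hi = parse_band_label(parts[-1])
        except BandParseError as e:
            raise BandParseError(
                f"malformed token {token!r} at position {pos}: {e}", token=token, position=pos
            ) from e
        for b in {lo.label, hi.label}:
            if b not in index:
                problems.append(f"unknown band {b!r} in token {token!r}")
        if problems:
            continue
        i, j = index[lo.label], index[hi.label]
        if i <= j:
            order.extend(range(i, j + 1))
        else:
            order.extend(-v for v in range(i, j - 1, -1))
    if problems:
        raise ValidationError(problems)
    return ArmSequence(code, arm, reference, tuple(order), tuple(annotations))


def format_band_sequence(seq: ArmSequence) -> str:
    """Format a sequence back to Keyl notation with maximal intervals.

    Inverse of :func:`parse_band_sequence`: parsing the result reproduces
    ``seq`` exactly.
    """
    if not seq.is_mapped:
        raise ValidationError([f"sequence {seq.code} is not mapped, nothing to format"])
    return " ".join(str(iv) for iv in seq.intervals)


# ---------------------------------------------------------------------------
# arm combinations


def parse_combination(text: str) -> tuple[tuple[str, ...], ...]:
    """Parse ``"AE CD BF G"`` into ordered groups, validating the arm partition."""
    groups = tuple(tuple(g) for g in text.split())
    validate_combination(groups)
    return groups


def validate_combination(groups: Sequence[Sequence[str]]) -> None:
    problems = []
    seen: list[str] = []
    for g in groups:
        for a in g:
            if a not in ARMS:
                problems.append(f"unknown arm {a!r}")
            seen.append(a)
    for a in ARMS:
        c = seen.count(a)
        if c == 0:
            problems.append(f"arm {a} missing from combination")
        elif c > 1:
            problems.append(f"arm {a} appears in more than one group")
    if problems:
        raise ValidationError(problems)


def format_combination(groups: Sequence[Sequence[str]]) -> str:
    return " ".join("".join(g) for g in groups)


# ---------------------------------------------------------------------------
# karyotype records


@dataclass
class Karyotype:
    """Species record: haploid number, whole-arm combination, per-arm pools."""

    species: str
    haploid_n: int
    arm_combination: tuple[tuple[str, ...], ...]
    pool: dict[str, list[ArmSequence]] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        try:
            validate_combination(self.arm_combination)
        except ValidationError as e:
            problems.extend(e.problems)
        if len(self.arm_combination) != self.haploid_n:
            problems.append(
                f"haploid_n={self.haploid_n} but combination has "
                f"{len(self.arm_combination)} groups"
            )
        in_combination = {a for g in self.arm_combination for a in g}
        for arm, seqs in self.pool.items():
            if arm not in ARMS:
                problems.append(f"pool keyed by unknown arm {arm!r}")
                continue
            for s in seqs:
                if s.arm != arm:
                    problems.append(f"sequence {s.code} (arm {s.arm}) filed under arm {arm}")
                if s.arm not in in_combination:
                    problems.append(f"sequence {s.code} on arm {s.arm} absent from combination")
        codes = [s.code for seqs in self.pool.values() for s in seqs]
        for c in set(codes):
            if codes.count(c) > 1:
                problems.append(f"duplicate sequence code {c!r}")
        if problems:
            raise ValidationError(problems)

    @property
    def polymorphic_arms(self) -> frozenset[str]:
        return frozenset(a for a, seqs in self.pool.items() if len(seqs) >= 2)

    def sequences(self, arm: str | None = None) -> list[ArmSequence]:
        if arm is not None:
            return list(self.pool.get(arm, []))
        return [s for a in ARMS for s in self.pool.get(a, [])]

    def find(self, code: str) -> ArmSequence:
        for s in self.sequences():
            if s.code == code:
                return s
        raise KeyError(code)


# ---------------------------------------------------------------------------
# JSON dialect


def _karyotype_to_obj(k: Karyotype) -> dict:
    references: dict[str, str] = {}
    arms: dict[str, list[dict]] = {}
    for arm in ARMS:
        seqs = k.pool.get(arm, [])
        if not seqs:
            continue
        entries = []
        for s in seqs:
            if s.is_mapped:
                ref = " ".join(b.label for b in s.reference)
                if arm in references and references[arm] != ref:
                    raise ValidationError(
                        [f"arm {arm} has sequences over different reference orders"]
                    )
                references[arm] = ref
            entries.append(
                {
                    "code": s.code,
                    "formula": s.formula,
                    "annotations": [list(a) for a in s.annotations],
                }
            )
        arms[arm] = entries
    return {
        "species": k.species,
        "haploid_n": k.haploid_n,
        "arm_combination": format_combination(k.arm_combination),
        "references": references,
        "arms": arms,
        "notes": k.notes,
    }


def _karyotype_from_obj(obj: Mapping) -> Karyotype:
    problems: list[str] = []
    for key in ("species", "haploid_n", "arm_combination"):
        if key not in obj:
            problems.append(f"missing required field {key!r}")
    if problems:
        raise ValidationError(problems)
    references: dict[str, tuple[Band, ...]] = {}
    for arm, labels in obj.get("references", {}).items():
        try:
            references[arm] = make_reference(labels.split())
        except (ValidationError, BandParseError) as e:
            problems.append(f"bad reference order for arm {arm}: {e}")
    pool: dict[str, list[ArmSequence]] = {}
    for arm, entries in obj.get("arms", {}).items():
        pool[arm] = []
        for entry in entries:
            code = entry.get("code", "seq?")
            formula = entry.get("formula")
            annotations = tuple(tuple(a) for a in entry.get("annotations", []))
            try:
                if formula is None:
                    seq = ArmSequence(code, arm, references.get(arm, ()), (), annotations)
                else:
                    if arm not in references:
                        problems.append(
                            f"sequence {code} has a formula but arm {arm} has no reference order"
                        )
                        continue
                    seq = parse_band_sequence(
                        formula, arm, references[arm], code=code, annotations=annotations
                    )
            except (ValidationError, BandParseError) as e:
                problems.append(f"sequence {code}: {e}")
                continue
            pool[arm].append(seq)
    try:
        combination = parse_combination(obj["arm_combination"])
    except ValidationError as e:
        problems.extend(e.problems)
        combination = ()
    if problems:
        raise ValidationError(problems)
    return Karyotype(
        species=obj["species"],
        haploid_n=obj["haploid_n"],
        arm_combination=combination,
        pool=pool,
        notes=obj.get("notes", ""),
    )


def write_karyotype(k: Karyotype, path: str | Path) -> None:
    """Write a karyotype record as JSON (deterministic, idempotent)."""
    Path(path).write_text(json.dumps(_karyotype_to_obj(k), indent=2) + "\n")


def read_karyotype(path: str | Path) -> Karyotype:
    """Read and fully validate a karyotype record; reports *all* violations."""
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValidationError([f"not valid JSON: {e}"]) from e
    return _karyotype_from_obj(obj)


def karyotypes_to_tsv(records: Iterable[Karyotype]) -> str:
    """Flat TSV export: one row per sequence (unmapped arms included)."""
    lines = ["species\thaploid_n\tarm_combination\tarm\tcode\tformula\tannotations"]
    for k in records:
        combo = format_combination(k.arm_combination)
        for arm in ARMS:
            seqs = k.pool.get(arm, [])
            if not seqs:
                lines.append(f"{k.species}\t{k.haploid_n}\t{combo}\t{arm}\t\t\t")
                continue
            for s in seqs:
                ann = ";".join(f"{f}@{p}" for f, p in s.annotations)
                lines.append(
                    f"{k.species}\t{k.haploid_n}\t{combo}\t{arm}\t{s.code}\t{s.formula or ''}\t{ann}"
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# registry of basic / standard sequences


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    arm: str
    sequence: ArmSequence
    scope: str  # cosmopolitan_basic | reference_standard

    def __post_init__(self) -> None:
        problems = []
        if self.scope not in ("cosmopolitan_basic", "reference_standard"):
            problems.append(f"unknown registry scope {self.scope!r}")
        if self.sequence.arm != self.arm:
            problems.append(
                f"registry entry {self.name} declares arm {self.arm} but its "
                f"sequence is on arm {self.sequence.arm}"
            )
        if problems:
            raise ValidationError(problems)


@dataclass
class BasicRegistry:
    """Named basic/standard sequences used to classify species sequences."""

    entries: list[RegistryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError([f"duplicate registry name {n!r}" for n in sorted(dupes)])

    def for_arm(self, arm: str, scope: str | None = None) -> list[RegistryEntry]:
        return [
            e
            for e in self.entries
            if e.arm == arm and (scope is None or e.scope == scope) and e.sequence.is_mapped
        ]

    def get(self, name: str) -> RegistryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def write_registry(reg: BasicRegistry, path: str | Path) -> None:
    obj = {
        "entries": [
            {
                "name": e.name,
                "arm": e.arm,
                "scope": e.scope,
                "reference": " ".join(b.label for b in e.sequence.reference),
                "formula": e.sequence.formula,
                "code": e.sequence.code,
            }
            for e in reg.entries
        ]
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_registry(path: str | Path) -> BasicRegistry:
    obj = json.loads(Path(path).read_text())
    entries = []
    problems: list[str] = []
    for raw in obj.get("entries", []):
        try:
            reference = make_reference(raw["reference"].split()) if raw.get("reference") else ()
            code = raw.get("code", raw["name"])
            if raw.get("formula"):
                seq = parse_band_sequence(raw["formula"], raw["arm"], reference, code=code)
            else:
                seq = ArmSequence(code, raw["arm"], reference, ())
            entries.append(RegistryEntry(raw["name"], raw["arm"], seq, raw["scope"]))
        except (ValidationError, BandParseError, KeyError) as e:
            problems.append(f"registry entry {raw.get('name', '?')}: {e}")
    if problems:
        raise ValidationError(problems)
    return BasicRegistry(entries)


def check_same_band_set(a: ArmSequence, b: ArmSequence) -> None:
    """Raise :class:`IncomparableArmsError` unless a and b cover the same bands."""
    if not a.is_mapped or not b.is_mapped:
        unmapped = [s.code for s in (a, b) if not s.is_mapped]
        raise IncomparableArmsError(f"unmapped sequence(s): {', '.join(unmapped)}")
    if a.arm != b.arm:
        raise IncomparableArmsError(f"different arms: {a.code} on {a.arm}, {b.code} on {b.arm}")
    if a.reference != b.reference:
        sa = {x.label for x in a.reference}
        sb = {x.label for x in b.reference}
        diff = sorted(sa ^ sb) or ["<same bands, different order>"]
        raise IncomparableArmsError(
            f"incomparable arms {a.code} vs {b.code}; band-set difference: {', '.join(diff)}"
        )
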