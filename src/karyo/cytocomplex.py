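"""Whole-arm combination logic: cytocomplex calls and translocation distance.

A cytocomplex groups species sharing a whole-arm combination (the partition of
arms A-G over chromosomes).  The registry is data-driven; it ships with the
three complexes observed in the Afrotropical study plus the fused-variant rule
("modified <name>": one chromosome fusion away from a registered complex).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

from .band_model import ARMS, parse_combination, validate_combination
from .errors import ValidationError

#: canonical combination string -> complex name
DEFAULT_COMPLEXES: dict[str, str] = {
    "AE BF CD G": "pseudothummi",
    "AB CD EF G": "thummi",
    "AC BF DE G": "parathummi",
}


@dataclass(frozen=True)
class CytocomplexCall:
    name: str  # e.g. "thummi", "modified thummi", "unrecognized"
    matched_reference: str  # canonical form of the classified combination
    haploid_n: int
    base: str | None = None  # registered complex a modified call derives from

    @property
    def is_modified(self) -> bool:
        return self.base is not None and self.name != self.base


def _as_groups(combination) -> tuple[tuple[str, ...], ...]:
    if isinstance(combination, str):
        return parse_combination(combination)
    groups = tuple(tuple(g) for g in combination)
    validate_combination(groups)
    return groups


def canonicalize_combination(combination) -> str:
    """Sort arms within groups and groups by first arm: "EA DC" == "AC DE"."""
    groups = _as_groups(combination)
    canon = sorted("".join(sorted(g)) for g in groups)
    return " ".join(canon)


def haploid_number(combination) -> int:
    """Number of linkage groups (chromosomes) in the combination."""
    return len(_as_groups(combination))


def load_complex_registry(path: str | Path | None = None) -> dict[str, str]:
    """Complex registry, canonicalised; default ships the three known entries."""
    raw: Mapping[str, str]
    if path is None:
        raw = DEFAULT_COMPLEXES
    else:
        raw = json.loads(Path(path).read_text())
    return {canonicalize_combination(k): v for k, v in raw.items()}


def write_complex_registry(registry: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(registry), indent=2) + "\n")


def classify_cytocomplex(
    combination, registry: Mapping[str, str] | None = None
) -> CytocomplexCall:
    """Match a combination against the registry, allowing one-fusion variants.

    A combination whose split (of any one group into two) reproduces a
    registered complex is reported as "modified <name>" with its reduced
    haploid number.  Unmatched input yields the name "unrecognized".
    """
    registry = load_complex_registry() if registry is None else registry
    groups = _as_groups(combination)
    canon = canonicalize_combination(groups)
    n = len(groups)
    if canon in registry:
        return CytocomplexCall(registry[canon], canon, n, base=registry[canon])
    hits = []
    for gi, g in enumerate(groups):
        if len(g) < 2:
            continue
        for r in range(1, len(g) // 2 + 1):
            for left in combinations(g, r):
                right = tuple(x for x in g if x not in left)
                split = groups[:gi] + (left, right) + groups[gi + 1 :]
                c = canonicalize_combination(split)
                if c in registry:
                    hits.append(registry[c])
    if hits:
        base = sorted(set(hits))[0]
        return CytocomplexCall(f"modified {base}", canon, n, base=base)
    return CytocomplexCall("unrecognized", canon, n)


# ---------------------------------------------------------------------------
# whole-arm rearrangement distance


def _state(groups) -> frozenset[frozenset[str]]:
    return frozenset(frozenset(g) for g in groups)


def _moves(state: frozenset[frozenset[str]]):
    groups = sorted(state, key=lambda g: sorted(g))
    # reciprocal whole-arm exchange between two chromosomes
    for g1, g2 in combinations(groups, 2):
        for a in g1:
            for b in g2:
                yield state - {g1, g2} | {
                    frozenset(g1 - {a} | {b}),
                    frozenset(g2 - {b} | {a}),
                }
    # fusion
    for g1, g2 in combinations(groups, 2):
        yield state - {g1, g2} | {g1 | g2}
    # fission
    for g in groups:
        if len(g) < 2:
            continue
        members = sorted(g)
        for r in range(1, len(members) // 2 + 1):
            for left in combinations(members, r):
                yield state - {g} | {frozenset(left), g - set(left)}


def translocation_distance(c1, c2) -> int:
    """Minimal whole-arm moves (exchange / fusion / fission) from c1 to c2.

    Exhaustive breadth-first search over arm partitions; the state space is
    tiny (Bell(7) = 877 partitions of seven arms).
    """
    s1 = _state(_as_groups(c1))
    s2 = _state(_as_groups(c2))
    if s1 == s2:
        return 0
    seen = {s1}
    queue = deque([(s1, 0)])
    while queue:
        state, d = queue.popleft()
        for nxt in _moves(state):
            if nxt == s2:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    raise ValidationError(["translocation distance search exhausted (should not happen)"])


def combination_of_call(call: CytocomplexCall) -> tuple[tuple[str, ...], ...]:
    return parse_combination(call.matched_reference)


def all_arms_present(combination) -> bool:
    groups = _as_groups(combination)
    return sorted(a for g in groups for a in g) == list(ARMS)
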