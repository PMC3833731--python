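"""Sequence-pool statistics: pool sizes, polymorphic arms, basic/endemic split.

Counting rule: every arm contributes ``max(1, number of named sequences)`` to
the species total, so an unmapped monomorphic arm still counts once.  A
sequence is *basic* iff it is zero inversion steps from a registry entry of
scope ``cosmopolitan_basic`` on the same arm; everything else (including
unmapped arms) is endemic.  Sequences one or two steps from a basic entry are
additionally reported as derived-from, but still count as endemic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .band_model import ARMS, BasicRegistry, Karyotype, format_combination
from .cytocomplex import CytocomplexCall, classify_cytocomplex
from .errors import IncomparableArmsError
from .reversal import arm_distance

NEAR_BASIC_MAX_STEPS = 2


@dataclass
class PoolSummary:
    species: str
    per_arm_counts: dict[str, int]
    total_sequences: int
    polymorphic_arms: frozenset[str]
    basic_count: int
    endemic_count: int
    basic_codes: tuple[str, ...] = ()
    #: endemic sequences close to a basic one: code -> (registry name, steps)
    derived_from: dict[str, tuple[str, int]] = field(default_factory=dict)


def _nearest_basic(seq, reg: BasicRegistry) -> tuple[str, int] | None:
    best: tuple[str, int] | None = None
    for entry in reg.for_arm(seq.arm, scope="cosmopolitan_basic"):
        try:
            d = arm_distance(seq, entry.sequence).distance
        except IncomparableArmsError:
            continue
        if best is None or (d, entry.name) < (best[1], best[0]):
            best = (entry.name, d)
    return best


def pool_summary(k: Karyotype, reg: BasicRegistry) -> PoolSummary:
    per_arm: dict[str, int] = {}
    basic_codes: list[str] = []
    derived: dict[str, tuple[str, int]] = {}
    endemic = 0
    for arm in ARMS:
        named = k.pool.get(arm, [])
        per_arm[arm] = max(1, len(named))
        if not named:
            endemic += 1  # unmapped monomorphic arm counts once, endemic by default
            continue
        for seq in named:
            hit = _nearest_basic(seq, reg) if seq.is_mapped else None
            if hit is not None and hit[1] == 0:
                basic_codes.append(seq.code)
            else:
                endemic += 1
                if hit is not None and hit[1] <= NEAR_BASIC_MAX_STEPS:
                    derived[seq.code] = hit
    total = sum(per_arm.values())
    return PoolSummary(
        species=k.species,
        per_arm_counts=per_arm,
        total_sequences=total,
        polymorphic_arms=k.polymorphic_arms,
        basic_count=len(basic_codes),
        endemic_count=endemic,
        basic_codes=tuple(basic_codes),
        derived_from=derived,
    )


def polymorphic_arms(k: Karyotype) -> frozenset[str]:
    """Arms carrying two or more named sequences."""
    return k.polymorphic_arms


def study_summary(
    records: list[Karyotype], reg: BasicRegistry, complexes=None
) -> tuple[pd.DataFrame, dict]:
    """Per-species table plus study-level aggregates.

    Aggregates count modified complexes under their base name (a fused
    "modified thummi" karyotype is a thummi-complex species).
    """
    if not records:
        raise ValueError("study_summary requires at least one record")
    rows = []
    calls: list[CytocomplexCall] = []
    for k in records:
        call = classify_cytocomplex(k.arm_combination, registry=complexes)
        summary = pool_summary(k, reg)
        calls.append(call)
        rows.append(
            {
                "species": k.species,
                "cytocomplex": call.name,
                "arm_combination": format_combination(k.arm_combination),
                "haploid_n": k.haploid_n,
                "pool_size": summary.total_sequences,
                "polymorphic_arms": ",".join(sorted(summary.polymorphic_arms)),
                "basic": summary.basic_count,
                "endemic": summary.endemic_count,
                "basic_codes": ",".join(summary.basic_codes),
            }
        )
    df = pd.DataFrame(rows)
    by_base: dict[str, int] = {}
    for call in calls:
        key = call.base if call.base is not None else call.name
        by_base[key] = by_base.get(key, 0) + 1
    aggregates = {
        "n_species": len(records),
        "species_per_complex": dict(sorted(by_base.items())),
        "distinct_complexes": len(by_base),
        "total_sequences": int(df["pool_size"].sum()),
    }
    return df, aggregates
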