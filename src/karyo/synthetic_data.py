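"""Synthetic banding sequences, species, and whole studies with ground truth.

The real study's band formulas exist only as photomap figures, so everything
here stands in for them: ancestors are identity sequences over generated
reference band lists, derived sequences are produced by known numbers of
random paracentric inversions, and whole studies come with a truth ledger
recording every step count, basic/endemic flag and cytocomplex so that the
full pipeline can be checked against it.

All randomness flows through a single integer-seeded generator; identical
seeds give byte-identical studies.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .band_model import (
    ArmSequence,
    Band,
    BasicRegistry,
    Karyotype,
    RegistryEntry,
    identity_sequence,
    write_karyotype,
)
from .cytocomplex import load_complex_registry
from .errors import ValidationError
from .reversal import arm_distance

MIN_BANDS, MAX_BANDS = 10, 30


@dataclass(frozen=True)
class EvolutionLog:
    """Replayable record of reversals applied to an ancestor sequence."""

    ancestor: ArmSequence
    steps: tuple[tuple[int, int], ...]  # 0-based inclusive reading-position intervals
    derived: ArmSequence
    seed: int

    def replay(self) -> ArmSequence:
        cur = self.ancestor
        for i, j in self.steps:
            cur = cur.reversed_segment(i, j)
        return cur


def generate_ancestor(
    n_bands: int,
    subband_rate: float,
    seed: int,
    arm: str = "A",
    code: str | None = None,
) -> ArmSequence:
    """Identity-order sequence over a generated reference band list.

    Each major band independently carries 2-3 lettered subbands with
    probability ``subband_rate``.
    """
    if not (MIN_BANDS <= n_bands <= MAX_BANDS):
        raise ValidationError([f"n_bands must be in [{MIN_BANDS}, {MAX_BANDS}], got {n_bands}"])
    if not (0.0 <= subband_rate <= 1.0):
        raise ValidationError([f"subband_rate must be a probability, got {subband_rate}"])
    rng = np.random.default_rng(seed)
    bands: list[Band] = []
    for major in range(1, n_bands + 1):
        if rng.random() < subband_rate:
            for letter in string.ascii_lowercase[: 2 + int(rng.integers(0, 2))]:
                bands.append(Band(major, letter))
        else:
            bands.append(Band(major))
    return identity_sequence(code or f"anc{arm}1", arm, tuple(bands))


def evolve(seq: ArmSequence, k: int, seed: int, code: str | None = None) -> EvolutionLog:
    """Apply ``k`` random paracentric inversions, logging every interval.

    Intervals are uniform over band-position pairs i < j.  Degenerate
    proposals are rejected and resampled: one-band reversals (invisible at
    band granularity) and reversals whose breakpoints strand an isolated
    inverted band, which Keyl notation cannot record (a single-band token is
    always read as forward).  Every accepted step is therefore an exact
    reversal between representable states, so the inversion distance between
    ancestor and derived sequence never exceeds ``k``.
    """
    if k < 0:
        raise ValidationError([f"reversal count must be >= 0, got {k}"])
    if not seq.is_mapped:
        raise ValidationError([f"cannot evolve unmapped sequence {seq.code}"])
    m = len(seq.order)
    if m < 2 and k > 0:
        raise ValidationError(["sequence too short to invert"])
    rng = np.random.default_rng(seed)
    cur = seq
    steps = []
    for _ in range(k):
        for _attempt in range(10_000):
            i, j = sorted(int(x) for x in rng.choice(m, size=2, replace=False))
            if i == 0 and j == m - 1:
                continue  # whole-arm reversal == flipped reading, observationally a no-op
            nxt = cur.reversed_segment(i, j)
            raw = list(cur.order)
            raw[i : j + 1] = [-v for v in reversed(raw[i : j + 1])]
            if nxt.order == tuple(raw):
                break
        else:  # pragma: no cover - cannot happen for m >= 2
            raise ValidationError(["could not sample a representable reversal"])
        steps.append((i, j))
        cur = nxt
    if code is not None:
        cur = ArmSequence(code, cur.arm, cur.reference, cur.order, cur.annotations)
    return EvolutionLog(ancestor=seq, steps=tuple(steps), derived=cur, seed=seed)


def recovery_table(
    n_bands: int = 20,
    ks: tuple[int, ...] = (1, 2, 3, 4),
    n_seeds: int = 200,
    seed: int = 0,
    subband_rate: float = 0.0,
) -> pd.DataFrame:
    """Fraction of replicates where the inferred distance recovers true k.

    For each k, ``n_seeds`` independent evolutions from a fresh identity
    ancestor; reports the fraction with distance <= k (always 1) and == k.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        le = eq = 0
        for _ in range(n_seeds):
            s = int(rng.integers(0, 2**31))
            anc = generate_ancestor(n_bands, subband_rate, seed=s)
            log = evolve(anc, k, seed=s + 1)
            d = arm_distance(log.ancestor, log.derived).distance
            le += d <= k
            eq += d == k
        rows.append(
            {
                "n_bands": n_bands,
                "k": k,
                "replicates": n_seeds,
                "frac_le_k": le / n_seeds,
                "frac_eq_k": eq / n_seeds,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole studies

_ARM_SIZES = {"A": 19, "B": 16, "C": 22, "D": 18, "E": 15, "F": 20, "G": 12}


def _species_tag(i: int) -> str:
    letters = string.ascii_lowercase
    return "s" + letters[i // 26] + letters[i % 26]


def generate_study(
    n_species: int,
    complex_mix: dict[str, int],
    polymorphism_rate: float,
    step_range: tuple[int, int],
    seed: int,
    subband_rate: float = 0.15,
    complexes: dict[str, str] | None = None,
) -> tuple[list[Karyotype], pd.DataFrame, BasicRegistry]:
    """Generate a study of karyotypes with a ground-truth ledger.

    Each species draws its arm combination from ``complex_mix`` (complex name
    -> species count), and per-arm pools of 1-3 sequences derived from shared
    per-arm basic ancestors by ``k`` reversals, k uniform in ``step_range``
    (k = 0 reproduces the ancestor, i.e. a basic sequence).  Returns the
    records, the truth ledger, and a registry holding the ancestors.
    """
    complexes = load_complex_registry() if complexes is None else complexes
    by_name = {v: k for k, v in complexes.items()}
    problems = []
    for name in complex_mix:
        if name not in by_name:
            problems.append(f"unknown cytocomplex {name!r} in mix")
    if sum(complex_mix.values()) != n_species:
        problems.append(
            f"complex mix totals {sum(complex_mix.values())} but n_species={n_species}"
        )
    if not (0.0 <= polymorphism_rate <= 1.0):
        problems.append(f"polymorphism_rate must be a probability, got {polymorphism_rate}")
    lo, hi = step_range
    if not (0 <= lo <= hi):
        problems.append(f"invalid step_range {step_range}")
    if problems:
        raise ValidationError(problems)

    rng = np.random.default_rng(seed)
    ancestors = {
        arm: generate_ancestor(
            _ARM_SIZES[arm], subband_rate, seed=int(rng.integers(0, 2**31)), arm=arm,
            code=f"bas{arm}1",
        )
        for arm in _ARM_SIZES
    }
    registry = BasicRegistry(
        [
            RegistryEntry(f"bas{arm}1", arm, ancestors[arm], "cosmopolitan_basic")
            for arm in sorted(ancestors)
        ]
    )

    assignment = [name for name in sorted(complex_mix) for _ in range(complex_mix[name])]
    records: list[Karyotype] = []
    truth_rows = []
    for si in range(n_species):
        tag = _species_tag(si)
        complex_name = assignment[si]
        combo_str = by_name[complex_name]
        groups = tuple(tuple(g) for g in combo_str.split())
        pool: dict[str, list[ArmSequence]] = {}
        for arm in sorted(_ARM_SIZES):
            n_seq = 1
            if rng.random() < polymorphism_rate:
                n_seq += 1 + int(rng.integers(0, 2))
            pool[arm] = []
            for serial in range(1, n_seq + 1):
                k = int(rng.integers(lo, hi + 1))
                code = f"{tag}{arm}{serial}"
                log = evolve(
                    ancestors[arm], k, seed=int(rng.integers(0, 2**31)), code=code
                )
                pool[arm].append(log.derived)
                truth_rows.append(
                    {
                        "species": f"Species {tag}",
                        "cytocomplex": complex_name,
                        "arm": arm,
                        "code": code,
                        "true_steps": k,
                        "is_basic": k == 0,
                    }
                )
        records.append(
            Karyotype(
                species=f"Species {tag}",
                haploid_n=len(groups),
                arm_combination=groups,
                pool=pool,
                notes=f"synthetic study member (seed {seed})",
            )
        )
    truth = pd.DataFrame(truth_rows)
    return records, truth, registry


def write_study(
    records: list[Karyotype],
    truth: pd.DataFrame,
    outdir: str | Path,
    registry: BasicRegistry | None = None,
) -> list[Path]:
    """Write one karyotype JSON per species plus a truth.tsv ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for k in records:
        name = k.species.lower().replace(" ", "_") + ".json"
        path = outdir / name
        write_karyotype(k, path)
        written.append(path)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    written.append(truth_path)
    if registry is not None:
        from .band_model import write_registry

        reg_path = outdir / "basic.json"
        write_registry(registry, reg_path)
        written.append(reg_path)
    return written
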