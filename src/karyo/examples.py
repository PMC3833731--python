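"""Bundled example study: six Afrotropical Chironomus karyotype records.

Species names, haploid numbers, whole-arm combinations, sequence-code lists,
polymorphism and basic/endemic status are transcribed from the published
species descriptions.  The band formulas themselves are NOT published in
machine-readable form (they exist only as photomap figures), so the formulas
here are synthetic placeholders: each mapped endemic sequence is generated
from the relevant standard by the reported number of random inversion steps.
Counts, combinations and basic/endemic calls are therefore faithful; the
concrete band orders are not.
"""

from __future__ import annotations

from .band_model import (
    ArmSequence,
    Band,
    BasicRegistry,
    Karyotype,
    RegistryEntry,
    identity_sequence,
    parse_combination,
)
from .synthetic_data import evolve

_ARM_SIZES = {"A": 19, "B": 16, "C": 22, "D": 18, "E": 15, "F": 20, "G": 12}


def reference_orders() -> dict[str, tuple[Band, ...]]:
    """Placeholder reference band orders (plain majors, one arm with subbands)."""
    refs = {}
    for arm, n in _ARM_SIZES.items():
        if arm == "G":
            bands: list[Band] = []
            for major in range(1, n + 1):
                if major in (1, 5):  # a couple of subdivided regions
                    bands.extend([Band(major, "a"), Band(major, "b")])
                else:
                    bands.append(Band(major))
            refs[arm] = tuple(bands)
        else:
            refs[arm] = tuple(Band(m) for m in range(1, n + 1))
    return refs


def _standards(refs) -> dict[str, ArmSequence]:
    return {arm: identity_sequence(f"pig{arm}1", arm, refs[arm]) for arm in _ARM_SIZES}


def basic_registry(seed: int = 20260905) -> BasicRegistry:
    """Standard and cosmopolitan-basic sequences used by the example study.

    pigST is carried per arm: cosmopolitan basic on arms E and F (where the
    study's species match it exactly), reference standard elsewhere.  holA1,
    lonC1, lonE1, aciE1 and aprE1 are further basic sequences; formulas for
    the lon/aci/apr entries are placeholders a few steps off the standard.
    """
    refs = reference_orders()
    pig = _standards(refs)
    entries = [
        RegistryEntry("pigST_A", "A", pig["A"], "reference_standard"),
        RegistryEntry("pigST_C", "C", pig["C"], "reference_standard"),
        RegistryEntry("pigST_D", "D", pig["D"], "reference_standard"),
        RegistryEntry("pigST_E", "E", pig["E"], "cosmopolitan_basic"),
        RegistryEntry("pigST_F", "F", pig["F"], "cosmopolitan_basic"),
        # basic sequence of arm A shared by many species; identical to the
        # standard in this placeholder geometry
        RegistryEntry("holA1", "A", identity_sequence("holA1", "A", refs["A"]), "cosmopolitan_basic"),
        RegistryEntry(
            "lonC1", "C", evolve(pig["C"], 3, seed=seed + 1, code="lonC1").derived,
            "cosmopolitan_basic",
        ),
        RegistryEntry(
            "lonE1", "E", evolve(pig["E"], 2, seed=seed + 2, code="lonE1").derived,
            "cosmopolitan_basic",
        ),
        RegistryEntry(
            "aciE1", "E", evolve(pig["E"], 3, seed=seed + 3, code="aciE1").derived,
            "cosmopolitan_basic",
        ),
        RegistryEntry(
            "aprE1", "E", evolve(pig["E"], 1, seed=seed + 4, code="aprE1").derived,
            "cosmopolitan_basic",
        ),
    ]
    return BasicRegistry(entries)


def african_study(seed: int = 20260905) -> list[Karyotype]:
    """The six example karyotype records (placeholder formulas, see module doc)."""
    refs = reference_orders()
    pig = _standards(refs)
    reg = basic_registry(seed)

    def derived(base: ArmSequence, k: int, code: str, salt: int) -> ArmSequence:
        return evolve(base, k, seed=seed + salt, code=code).derived

    def unmapped(code: str, arm: str) -> ArmSequence:
        return ArmSequence(code, arm, refs[arm], ())

    lonC1 = reg.get("lonC1").sequence
    aciE1 = reg.get("aciE1").sequence
    lonE1 = reg.get("lonE1").sequence
    aprE1 = reg.get("aprE1").sequence

    # --- species 1: pseudothummi complex, polymorphic in arms C and G
    allC1 = derived(pig["C"], 7, "allC1", 101)
    alluaudi = Karyotype(
        species="Chironomus alluaudi",
        haploid_n=4,
        arm_combination=parse_combination("AE CD BF G"),
        pool={
            "A": [identity_sequence("allA1", "A", refs["A"])],
            "E": [identity_sequence("allE1", "E", refs["E"])],
            "C": [allC1, evolve(allC1, 1, seed=seed + 102, code="allC2").derived],
            "D": [derived(pig["D"], 1, "allD1", 103)],
            "B": [],  # not mapped, monomorphic
            "F": [
                identity_sequence(
                    "allF1", "F", refs["F"], annotations=(("balbiani_ring", "3"),)
                )
            ],
            "G": [unmapped("allG1", "G"), unmapped("allG2", "G")],
        },
        notes="placeholder formulas; pool and combination transcribed from the literature",
    )

    # --- species 2: pseudothummi complex, all sequences endemic
    trvC1 = derived(lonC1, 4, "trvC1", 201)
    transvaalensis = Karyotype(
        species="Chironomus transvaalensis",
        haploid_n=4,
        arm_combination=parse_combination("AE CD BF G"),
        pool={
            "A": [derived(reg.get("holA1").sequence, 1, "trvA1", 202)],
            "E": [derived(aciE1, 1, "trvE1", 203)],
            "C": [trvC1, evolve(trvC1, 1, seed=seed + 204, code="trvC2").derived],
            "D": [derived(pig["D"], 4, "trvD1", 205)],
            "B": [],
            "F": [derived(pig["F"], 3, "trvF1", 206)],
            "G": [unmapped("trvG1", "G"), unmapped("trvG2", "G"), unmapped("trvG3", "G")],
        },
        notes="placeholder formulas; trvG2/trvG3 recorded only as heterozygotes",
    )

    # --- species 3: pseudothummi complex, no polymorphism
    nakuru = Karyotype(
        species="Chironomus sp. Nakuru",
        haploid_n=4,
        arm_combination=parse_combination("AE CD BF G"),
        pool={
            "A": [identity_sequence("nakA1", "A", refs["A"])],
            "E": [derived(lonE1, 2, "nakE1", 301)],
            "C": [derived(lonC1, 4, "nakC1", 302)],
            "D": [derived(pig["D"], 3, "nakD1", 303)],
            "B": [],
            "F": [derived(pig["F"], 4, "nakF1", 304)],
            "G": [unmapped("nakG1", "G")],
        },
        notes="placeholder formulas",
    )

    # --- species 4: thummi complex; only arm E could be mapped
    formosipennis = Karyotype(
        species="Chironomus formosipennis",
        haploid_n=4,
        arm_combination=parse_combination("AB CD EF G"),
        pool={
            "E": [
                ArmSequence("frmE1", "E", aprE1.reference, aprE1.order)
            ],  # identical with basic aprE1
        },
        notes="fragmentarily mapped; only arm E determined",
    )

    # --- species 5: modified thummi complex (E and G fused), n=3
    pulcher = Karyotype(
        species="Chironomus prope pulcher",
        haploid_n=3,
        arm_combination=parse_combination("AB CD FEG"),
        pool={
            "A": [derived(pig["A"], 4, "pulA1", 501)],
            "B": [unmapped("pulB1", "B")],
            "C": [unmapped("pulC1", "C"), unmapped("pulC2", "C")],
            "D": [derived(pig["D"], 5, "pulD1", 502)],
            "E": [derived(pig["E"], 3, "pulE1", 503)],
            "F": [
                derived(pig["F"], 1, "pulF1", 504)
            ],
            "G": [],
        },
        notes="placeholder formulas; arm G joined with arm E",
    )

    # --- species 6: parathummi complex
    kisumu = Karyotype(
        species="Chironomus sp. Kisumu",
        haploid_n=4,
        arm_combination=parse_combination("AC BF DE G"),
        pool={
            "A": [derived(pig["A"], 3, "kisA1", 601)],
            "C": [derived(pig["C"], 8, "kisC1", 602)],
            "D": [derived(pig["D"], 6, "kisD1", 603)],
            "E": [derived(pig["E"], 2, "kisE1", 604)],
            "B": [unmapped("kisB1", "B")],
            "F": [unmapped("kisF1", "F")],
            "G": [],
        },
        notes="placeholder formulas; arm F mapped only fragmentarily",
    )

    return [alluaudi, transvaalensis, nakuru, formosipennis, pulcher, kisumu]
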