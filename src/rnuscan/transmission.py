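"""Allele transmission in dual-carrier trios vs Mendelian expectation.

In a family where both parents each carry one rare heterozygous variant at
the locus, the offspring receives both alleles with Mendelian probability
1/4, exactly one with probability 1/2 and neither with probability 1/4 —
regardless of whether the parents carry the same variant (offspring
homozygous) or different variants (offspring compound heterozygous in
trans, by construction of inheritance).  In a cohort ascertained for a
recessive condition, affected offspring are expected to show
over-transmission of both alleles.  A chi-squared goodness-of-fit test
compares the observed both/one/neither tallies to the (1/4, 1/2, 1/4)
ratios, per stratum and pooled.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

from .enrichment_stats import GofResult, chisq_goodness_of_fit
from .genotype_model import Cohort, GenotypeCall

__all__ = [
    "TrioRecord",
    "TransmissionCounts",
    "MendelianInconsistencyError",
    "MENDELIAN_PROBABILITIES",
    "mendelian_transmission_probabilities",
    "find_dual_carrier_trios",
    "classify_transmission",
    "count_transmissions",
    "transmission_test",
]

#: Expected (both, one, neither) transmission probabilities.
MENDELIAN_PROBABILITIES = (0.25, 0.5, 0.25)


class MendelianInconsistencyError(ValueError):
    """Offspring genotype is impossible given the parental genotypes."""


@dataclass(frozen=True)
class TrioRecord:
    """A trio whose parents each carry exactly one rare heterozygous variant."""

    family: str
    proband: str
    father: str
    mother: str
    father_variant: str
    mother_variant: str
    proband_group: str = "unknown"

    @property
    def same_variant(self) -> bool:
        return self.father_variant == self.mother_variant

    @property
    def stratum(self) -> str:
        return "same_variant" if self.same_variant else "different_variant"


@dataclass(frozen=True)
class TransmissionCounts:
    both: int
    one: int
    neither: int
    expected_probabilities: tuple = MENDELIAN_PROBABILITIES

    def __post_init__(self) -> None:
        if min(self.both, self.one, self.neither) < 0:
            raise ValueError("transmission counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.both + self.one + self.neither

    @property
    def counts(self) -> tuple:
        return (self.both, self.one, self.neither)


def mendelian_transmission_probabilities() -> dict:
    """Both/one/neither transmission probabilities by gamete enumeration.

    Enumerates the four equally likely parental gamete combinations (each
    carrier parent transmits its variant-bearing haplotype or not).  The
    result is exact (Fractions): both 1/4, one 1/2, neither 1/4, identical
    in the same-variant and different-variant strata.
    """
    tally = {"both": Fraction(0), "one": Fraction(0), "neither": Fraction(0)}
    combos = list(itertools.product([True, False], repeat=2))
    weight = Fraction(1, len(combos))
    for father_transmits, mother_transmits in combos:
        n = father_transmits + mother_transmits
        outcome = {2: "both", 1: "one", 0: "neither"}[n]
        tally[outcome] += weight
    return tally


def find_dual_carrier_trios(
    cohort: Cohort,
    rare_calls: Mapping[str, Sequence[GenotypeCall]],
) -> list:
    """Identify trios in which both parents carry one rare heterozygote each.

    ``rare_calls`` maps samples to their rare-variant genotype calls (after
    frequency filtering).  Parents heterozygous for zero or more than one
    rare variant, or homozygous, are excluded; trios with a parent entirely
    absent from the genotype data are skipped with a warning.
    """
    records = []
    for trio in cohort.trios:
        missing = [
            who
            for who in (trio.father, trio.mother)
            if who not in cohort.calls and who not in rare_calls
        ]
        if missing:
            warnings.warn(
                f"family {trio.family}: no genotype data for {missing}; "
                "trio skipped",
                stacklevel=2,
            )
            continue
        parent_variants = []
        ok = True
        for parent in (trio.father, trio.mother):
            hets = [
                c for c in rare_calls.get(parent, ()) if c.zygosity == "het"
            ]
            homs = [
                c for c in rare_calls.get(parent, ()) if c.zygosity == "hom_alt"
            ]
            if len(hets) != 1 or homs:
                ok = False
                break
            parent_variants.append(hets[0].variant_id)
        if not ok:
            continue
        group = (
            cohort.assignments[trio.child].group
            if trio.child in cohort.assignments
            else "unknown"
        )
        records.append(
            TrioRecord(
                family=trio.family,
                proband=trio.child,
                father=trio.father,
                mother=trio.mother,
                father_variant=parent_variants[0],
                mother_variant=parent_variants[1],
                proband_group=group,
            )
        )
    return records


def classify_transmission(
    trio: TrioRecord,
    offspring_calls: Iterable[GenotypeCall],
) -> str:
    """Classify a trio's transmission outcome as both/one/neither.

    Same-variant parents: a homozygous-alt offspring received both alleles,
    a heterozygote one, a reference-homozygote neither.  Different-variant
    parents: carrying both parental variants means both (compound
    heterozygous in trans by inheritance), one means one, none means
    neither.  Offspring genotypes impossible under the parental genotypes
    raise :class:`MendelianInconsistencyError`.
    """
    calls = {c.variant_id: c for c in offspring_calls}
    vf, vm = trio.father_variant, trio.mother_variant
    if trio.same_variant:
        call = calls.get(vf)
        if call is None:
            return "neither"
        return "both" if call.zygosity == "hom_alt" else "one"
    n_carried = 0
    for variant in (vf, vm):
        call = calls.get(variant)
        if call is None:
            continue
        if call.zygosity == "hom_alt":
            raise MendelianInconsistencyError(
                f"family {trio.family}: offspring homozygous for {variant} "
                "but only one parent carries it"
            )
        n_carried += 1
    return {2: "both", 1: "one", 0: "neither"}[n_carried]


def count_transmissions(
    trios: Iterable[TrioRecord],
    calls_by_sample: Mapping[str, Sequence[GenotypeCall]],
    group: str | None = None,
) -> dict:
    """Tally transmission outcomes per stratum and pooled.

    Trios with Mendelian-inconsistent offspring are excluded (with a
    warning) rather than counted as "neither".  ``group`` restricts the
    tally to trios whose proband belongs to that cohort group.
    """
    tallies = {
        "same_variant": {"both": 0, "one": 0, "neither": 0},
        "different_variant": {"both": 0, "one": 0, "neither": 0},
    }
    for trio in trios:
        if group is not None and trio.proband_group != group:
            continue
        try:
            outcome = classify_transmission(
                trio, calls_by_sample.get(trio.proband, ())
            )
        except MendelianInconsistencyError as exc:
            warnings.warn(f"excluded: {exc}", stacklevel=2)
            continue
        tallies[trio.stratum][outcome] += 1
    out = {}
    pooled = {"both": 0, "one": 0, "neither": 0}
    for stratum, tally in tallies.items():
        out[stratum] = TransmissionCounts(**tally)
        for key in pooled:
            pooled[key] += tally[key]
    out["pooled"] = TransmissionCounts(**pooled)
    return out


def transmission_test(counts: TransmissionCounts) -> GofResult:
    """Chi-squared goodness of fit of transmission counts to (1/4, 1/2, 1/4)."""
    if counts.total < 1:
        raise ValueError("at least one trio required")
    return chisq_goodness_of_fit(counts.counts, counts.expected_probabilities)
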