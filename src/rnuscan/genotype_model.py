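"""Cohort ingestion, variant filters and biallelic-genotype enumeration.

A recessive candidate genotype at a small non-coding locus is either a rare
homozygous variant or a pair of rare heterozygous variants on opposite
haplotypes (compound heterozygous, "in trans").  This module reads a cohort
(VCF + PED + group table), applies the variant-level filters used in the
discovery analysis (FILTER=PASS, population allele frequency < 0.001) and
enumerates candidate biallelic genotypes, keeping phase bookkeeping explicit
so that read-backed evidence can later override statistical phasing.

Coordinates throughout are 1-based transcript positions on the single-exon
locus (default full transcript n.1-n.191).  Indels are anchored at their
most 5' coordinate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneRegion",
    "Variant",
    "GenotypeCall",
    "BiallelicGenotype",
    "CohortAssignment",
    "Trio",
    "Cohort",
    "ParseError",
    "ReferentialError",
    "RNU2_2_TRANSCRIPT",
    "CONSTRAINED_5P",
    "SM_SITE",
    "load_cohort",
    "read_ped",
    "read_groups",
    "read_af_table",
    "read_regions",
    "filter_rare_variants",
    "statistical_pair_phase",
    "enumerate_biallelic_genotypes",
    "filter_by_control_combinations",
    "apply_region_constraint",
    "eligible_for_distribution_analysis",
    "count_biallelic_carriers",
]

_BASES = frozenset("ACGT")


class ParseError(ValueError):
    """An input file could not be parsed; the message names file and line."""


class ReferentialError(KeyError):
    """A record references a sample or variant that does not exist."""


@dataclass(frozen=True)
class GeneRegion:
    """A named 1-based inclusive interval in transcript coordinates."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"region {self.name!r}: need 1 <= start <= end, got "
                f"[{self.start}, {self.end}]"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Full transcript of the 191-nt single-exon U2-2 locus.
RNU2_2_TRANSCRIPT = GeneRegion("transcript", 1, 191)
#: 5' constrained region (stem I, branchpoint recognition sequence, stem IIa).
CONSTRAINED_5P = GeneRegion("5p_constrained", 1, 67)
#: Sm protein binding site.
SM_SITE = GeneRegion("sm_site", 97, 107)


@dataclass(frozen=True)
class Variant:
    """A normalized variant with its anchor (most 5') transcript position."""

    variant_id: str
    gene: str
    position: int
    ref: str
    alt: str
    af: float | None = None
    filter_status: str = "PASS"

    def __post_init__(self) -> None:
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - _BASES:
                raise ValueError(
                    f"variant {self.variant_id}: {label} allele {allele!r} must "
                    "be non-empty uppercase ACGT"
                )
        if self.position < 1:
            raise ValueError(f"variant {self.variant_id}: position must be >= 1")
        if self.af is not None and not (0.0 <= self.af <= 1.0):
            raise ValueError(
                f"variant {self.variant_id}: AF {self.af} outside [0, 1]"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def indel_length(self) -> int:
        """Net length change |len(ref) - len(alt)|; 0 for SNVs and MNVs."""
        return abs(len(self.ref) - len(self.alt))

    @property
    def ref_end(self) -> int:
        """Last transcript position covered by the reference allele."""
        return self.position + len(self.ref) - 1


@dataclass(frozen=True)
class GenotypeCall:
    """One non-reference genotype for one sample at one variant.

    ``haplotype`` is the 0/1 index of the phased haplotype carrying the
    alternate allele (heterozygous, phased calls only); ``phase_set`` tags
    calls whose statistical phase is mutually comparable.
    """

    sample: str
    variant_id: str
    zygosity: str  # "het" | "hom_alt"
    phased: bool = False
    haplotype: int | None = None
    phase_set: str | None = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom_alt"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class BiallelicGenotype:
    """A candidate recessive genotype: homozygous or a trans variant pair.

    ``phase`` is "na" for homozygotes; compound candidates carry
    "trans"/"cis"/"unknown".  Only homozygotes and trans pairs count as
    biallelic ("confident").  The unordered variant set is the combination
    key used for cross-cohort filtering.
    """

    sample: str
    genotype_class: str  # "homozygous" | "compound_het"
    variants: frozenset
    phase: str = "na"  # "na" | "trans" | "cis" | "unknown"
    evidence: str = "statistical"  # "statistical" | "read_backed" | "trio"

    def __post_init__(self) -> None:
        if self.genotype_class == "homozygous":
            if len(self.variants) != 1:
                raise ValueError("homozygous genotype must have exactly 1 variant")
        elif self.genotype_class == "compound_het":
            if len(self.variants) != 2:
                raise ValueError(
                    "compound het genotype must have exactly 2 distinct variants"
                )
        else:
            raise ValueError(f"unknown genotype class {self.genotype_class!r}")

    @property
    def combination_key(self) -> frozenset:
        return self.variants

    @property
    def is_confident(self) -> bool:
        return self.genotype_class == "homozygous" or self.phase == "trans"


@dataclass(frozen=True)
class CohortAssignment:
    sample: str
    group: str  # "unsolved_NDD" | "control"
    family: str


@dataclass(frozen=True)
class Trio:
    family: str
    child: str
    father: str
    mother: str


@dataclass
class Cohort:
    """Parsed cohort: variants, per-sample calls, groups and trio structure."""

    variants: dict = field(default_factory=dict)  # variant_id -> Variant
    calls: dict = field(default_factory=dict)  # sample -> {variant_id: GenotypeCall}
    assignments: dict = field(default_factory=dict)  # sample -> CohortAssignment
    trios: list = field(default_factory=list)

    @property
    def samples(self) -> list:
        return sorted(self.assignments)

    def calls_for(self, sample: str) -> list:
        return list(self.calls.get(sample, {}).values())

    def samples_in_group(self, group: str) -> list:
        return sorted(
            s for s, a in self.assignments.items() if a.group == group
        )


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_ped(path) -> list:
    """Read a 6-column whitespace-delimited PED file into Trio records.

    Rows whose father and mother are both "0" describe singletons and
    produce no trio.
    """
    trios = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected 6 PED columns, "
                    f"got {len(fields)}"
                )
            fam, child, father, mother = fields[:4]
            if father != "0" and mother != "0":
                trios.append(Trio(fam, child, father, mother))
    return trios


def read_groups(path) -> dict:
    """Read the sample->cohort-group TSV (sample_id, group, family_id)."""
    assignments = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "group", "family_id"]:
            raise ParseError(
                f"{path}: line 1: expected header sample_id/group/family_id, "
                f"got {header}"
            )
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(fields)}"
                )
            sample, group, family = fields[:3]
            assignments[sample] = CohortAssignment(sample, group, family)
    return assignments


def read_af_table(path) -> dict:
    """Read a variant_id -> allele frequency TSV."""
    table = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["variant_id", "af"]:
            raise ParseError(f"{path}: line 1: expected header variant_id/af")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            vid, af_str = line.split("\t")[:2]
            try:
                af = float(af_str)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad AF {af_str!r}") from exc
            table[vid] = af
    return table


def read_regions(path) -> dict:
    """Read a name/start/end region TSV (1-based inclusive)."""
    regions = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["name", "start", "end"]:
            raise ParseError(f"{path}: line 1: expected header name/start/end")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            name, start, end = line.split("\t")[:3]
            try:
                regions[name] = GeneRegion(name, int(start), int(end))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return regions


def load_cohort(vcf_path, ped_path, groups_path) -> Cohort:
    """Load genotype calls, group assignments and trios for a cohort.

    Only PASS variants produce calls.  Phased genotype separators ("|") are
    preserved as statistical phase: the haplotype index carrying the
    alternate allele and a per-variant phase-set tag (the PS FORMAT field
    when present, otherwise a whole-sample default) are stored on each call.

    Raises
    ------
    ParseError
        If the VCF or PED cannot be parsed.
    ReferentialError
        If the PED or group table references a sample absent from the VCF.
    """
    from cyvcf2 import VCF

    assignments = read_groups(groups_path)
    trios = read_ped(ped_path)

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare Exception subclasses
        raise ParseError(f"{vcf_path}: could not parse VCF: {exc}") from exc

    vcf_samples = list(vcf.samples)
    sample_set = set(vcf_samples)
    for trio in trios:
        for member in (trio.child, trio.father, trio.mother):
            if member not in sample_set:
                raise ReferentialError(
                    f"{ped_path}: sample {member!r} (family {trio.family}) "
                    "absent from VCF"
                )
    for sample in assignments:
        if sample not in sample_set:
            raise ReferentialError(
                f"{groups_path}: sample {sample!r} absent from VCF"
            )

    cohort = Cohort(assignments=assignments, trios=trios)
    for record in vcf:
        if record.FILTER is not None:  # cyvcf2: None means PASS
            continue
        gene = record.INFO.get("GENE") or record.CHROM
        af = record.INFO.get("AF")
        alts = record.ALT
        for alt_index, alt in enumerate(alts, start=1):
            vid = record.ID if (record.ID and len(alts) == 1) else (
                f"{gene}:{record.POS}:{record.REF}>{alt}"
            )
            variant = Variant(
                variant_id=vid,
                gene=gene,
                position=record.POS,
                ref=record.REF,
                alt=alt,
                af=float(af) if af is not None else None,
            )
            cohort.variants[vid] = variant
            try:
                phase_sets = record.format("PS")
            except KeyError:
                phase_sets = None
            for si, gt in enumerate(record.genotypes):
                a0, a1, phased = gt[0], gt[1], bool(gt[2])
                n_alt = (a0 == alt_index) + (a1 == alt_index)
                if n_alt == 0:
                    continue
                sample = vcf_samples[si]
                zyg = "hom_alt" if n_alt == 2 else "het"
                hap = None
                ps = None
                if phased and zyg == "het":
                    hap = 0 if a0 == alt_index else 1
                    ps = (
                        str(phase_sets[si][0])
                        if phase_sets is not None
                        else f"{sample}:default"
                    )
                call = GenotypeCall(
                    sample=sample,
                    variant_id=vid,
                    zygosity=zyg,
                    phased=phased and zyg == "het",
                    haplotype=hap,
                    phase_set=ps,
                )
                cohort.calls.setdefault(sample, {})[vid] = call
    return cohort


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_rare_variants(
    calls: Iterable[GenotypeCall],
    af_table: Mapping[str, float],
    max_af: float = 0.001,
    inclusive: bool = False,
    missing_af: str = "error",
) -> list:
    """Keep calls at rare variants only.

    The default predicate is strict (AF < ``max_af``; a variant at exactly
    the threshold is removed); ``inclusive=True`` retains AF == max_af.
    Missing AFs raise by default; ``missing_af="zero"`` treats them as 0
    with a warning.
    """
    if missing_af not in ("error", "zero"):
        raise ValueError(f"unknown missing-AF policy {missing_af!r}")
    kept = []
    for call in calls:
        af = af_table.get(call.variant_id)
        if af is None:
            if missing_af == "error":
                raise ReferentialError(
                    f"variant {call.variant_id} has no allele frequency"
                )
            warnings.warn(
                f"variant {call.variant_id} missing AF; treated as 0",
                stacklevel=2,
            )
            af = 0.0
        if not (0.0 <= af <= 1.0):
            raise ValueError(f"variant {call.variant_id}: AF {af} outside [0, 1]")
        if (af <= max_af) if inclusive else (af < max_af):
            kept.append(call)
    return kept


# ---------------------------------------------------------------------------
# Biallelic genotype enumeration
# ---------------------------------------------------------------------------

def statistical_pair_phase(call_a: GenotypeCall, call_b: GenotypeCall) -> str:
    """Phase of a het pair from statistical (VCF "|") phasing.

    Returns "cis"/"trans" when both calls are phased heterozygotes in the
    same phase set, "unknown" otherwise.
    """
    if (
        call_a.phased
        and call_b.phased
        and call_a.phase_set is not None
        and call_a.phase_set == call_b.phase_set
    ):
        return "cis" if call_a.haplotype == call_b.haplotype else "trans"
    return "unknown"


def pair_key(sample: str, variant_a: str, variant_b: str) -> tuple:
    """Canonical (sample, unordered variant pair) key."""
    return (sample, frozenset((variant_a, variant_b)))


def enumerate_biallelic_genotypes(
    sample_calls: Mapping[str, Sequence[GenotypeCall]],
    phase_assessments: Mapping[tuple, object] | None = None,
) -> list:
    """Enumerate candidate biallelic genotypes from per-sample rare calls.

    Homozygous-alt calls yield homozygous genotypes.  Every unordered pair of
    heterozygous calls yields a compound-het candidate whose phase comes from
    ``phase_assessments`` when the pair key ``(sample, frozenset(pair))`` is
    present (values are ``(phase, evidence)`` tuples or bare phase strings),
    and from the calls' statistical phasing otherwise.  Cis and unknown pairs
    are emitted with their phase so callers can report them, but only
    homozygotes and trans pairs are confident biallelic genotypes.
    """
    phase_assessments = phase_assessments or {}
    out = []
    for sample in sorted(sample_calls):
        calls = sample_calls[sample]
        hets = sorted(
            (c for c in calls if c.zygosity == "het"), key=lambda c: c.variant_id
        )
        for call in calls:
            if call.zygosity == "hom_alt":
                out.append(
                    BiallelicGenotype(
                        sample=sample,
                        genotype_class="homozygous",
                        variants=frozenset((call.variant_id,)),
                        phase="na",
                        evidence="statistical",
                    )
                )
        for ca, cb in itertools.combinations(hets, 2):
            key = pair_key(sample, ca.variant_id, cb.variant_id)
            if key in phase_assessments:
                assessed = phase_assessments[key]
                if isinstance(assessed, str):
                    phase, evidence = assessed, "statistical"
                else:
                    phase, evidence = assessed
            else:
                phase, evidence = statistical_pair_phase(ca, cb), "statistical"
            out.append(
                BiallelicGenotype(
                    sample=sample,
                    genotype_class="compound_het",
                    variants=frozenset((ca.variant_id, cb.variant_id)),
                    phase=phase,
                    evidence=evidence,
                )
            )
    return out


def filter_by_control_combinations(
    case_genotypes: Iterable[BiallelicGenotype],
    control_genotypes: Iterable[BiallelicGenotype] = (),
    external_combinations: Iterable[frozenset] = (),
) -> list:
    """Drop case genotypes whose variant combination occurs in any control.

    A case genotype is removed iff its unordered variant set (or its single
    homozygous variant) appears as a biallelic genotype in the control
    cohort or in ``external_combinations`` (pre-computed combination keys
    from other control sources).  Heterozygous-only carriage of a variant in
    controls does not remove a homozygous case genotype.
    """
    seen = {g.combination_key for g in control_genotypes}
    seen.update(frozenset(c) for c in external_combinations)
    return [g for g in case_genotypes if g.combination_key not in seen]


def apply_region_constraint(
    genotypes: Iterable[BiallelicGenotype],
    variants: Mapping[str, Variant],
    regions: Sequence[GeneRegion] = (CONSTRAINED_5P, SM_SITE),
    include_homozygous: bool = False,
    transcript: GeneRegion | None = None,
) -> list:
    """Keep genotypes with >= 1 variant anchored in a constrained region.

    Region membership is decided on each variant's most 5' (anchor)
    coordinate.  By default the constraint applies to compound heterozygotes
    only, with homozygous genotypes passing unconditionally;
    ``include_homozygous=True`` subjects them to the same rule.  When a
    ``transcript`` region is given, anchor positions outside it raise.
    """
    kept = []
    for genotype in genotypes:
        positions = []
        for vid in genotype.variants:
            if vid not in variants:
                raise ReferentialError(f"variant {vid!r} not in variant table")
            pos = variants[vid].position
            if transcript is not None and pos not in transcript:
                raise ValueError(
                    f"variant {vid}: anchor position {pos} outside transcript "
                    f"[{transcript.start}, {transcript.end}]"
                )
            positions.append(pos)
        if genotype.genotype_class == "homozygous" and not include_homozygous:
            kept.append(genotype)
        elif any(pos in region for pos in positions for region in regions):
            kept.append(genotype)
    return kept


def eligible_for_distribution_analysis(
    genotype: BiallelicGenotype,
    variants: Mapping[str, Variant],
    transcript: GeneRegion = RNU2_2_TRANSCRIPT,
    max_indel_nt: int = 2,
) -> bool:
    """Whether a genotype enters the variant-position distribution analysis.

    Eligible iff every allele lies entirely within the transcript bounds and
    each variant is an SNV or an indel whose net length change is at most
    ``max_indel_nt`` nucleotides.
    """
    for vid in genotype.variants:
        if vid not in variants:
            raise ReferentialError(f"variant {vid!r} not in variant table")
        variant = variants[vid]
        if variant.position < transcript.start or variant.ref_end > transcript.end:
            return False
        if not variant.is_snv and variant.indel_length > max_indel_nt:
            return False
    return True


def count_biallelic_carriers(
    genotypes: Iterable[BiallelicGenotype], confident_only: bool = True
) -> int:
    """Number of distinct samples carrying >= 1 (confident) biallelic genotype."""
    return len(
        {
            g.sample
            for g in genotypes
            if g.is_confident or not confident_only
        }
    )
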