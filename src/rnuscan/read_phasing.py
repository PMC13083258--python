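"""Read-backed phase classification and phase-switch error detection.

Statistical (population) phasing of two rare heterozygous variants in the
same individual occasionally assigns them to the wrong haplotype
configuration — a phase-switch error.  At a compact single-exon locus the
configuration is directly observable from sequencing reads: two variants
are in trans if their alternate alleles occur on mutually exclusive reads
(with at least one read traversing both positions), and in cis if they
occur on the same reads.  This module automates that read-level call and
reconciles it against the statistical phase, overriding where read evidence
is decisive and counting the discordances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "AlignedReadObservation",
    "PhaseAssessment",
    "ReconcileResult",
    "read_observations_tsv",
    "filter_reads",
    "classify_variant_pair_phase",
    "reconcile_phase",
]


@dataclass(frozen=True)
class AlignedReadObservation:
    """Allele observations from one sequencing fragment.

    ``alleles`` maps covered variant sites to "ref" or "alt"; uncovered
    sites are simply absent.  Paired-end mates sharing a fragment are merged
    into one observation, so a fragment whose two mates jointly cover both
    sites spans the pair.
    """

    read_id: str
    mapq: int
    alleles: Mapping[object, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError(f"read {self.read_id}: negative mapping quality")
        bad = {a for a in self.alleles.values() if a not in ("ref", "alt")}
        if bad:
            raise ValueError(f"read {self.read_id}: bad allele calls {bad}")

    def covers(self, site) -> bool:
        return site in self.alleles

    def spans(self, site_a, site_b) -> bool:
        return self.covers(site_a) and self.covers(site_b)


@dataclass(frozen=True)
class PhaseAssessment:
    """Statistical vs read-backed phase for one two-variant carrier."""

    pair_id: object
    statistical_phase: str
    read_backed_phase: str
    spanning_reads: int = 0
    discordant: bool = False
    final_phase: str = "unknown"
    confirmed: bool = False

    def __post_init__(self) -> None:
        if self.discordant and (
            "unknown" in (self.statistical_phase, self.read_backed_phase)
            or self.statistical_phase == self.read_backed_phase
        ):
            raise ValueError(
                "discordant requires both phases known and unequal"
            )


def read_observations_tsv(path) -> list:
    """Read observations from a (read_id, mapq, site, allele) TSV.

    Rows sharing a read_id are merged into one fragment observation; the
    fragment's mapq is the minimum over its rows.
    """
    rows: dict = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["read_id", "mapq", "site", "allele"]:
            raise ValueError(
                f"{path}: expected header read_id/mapq/site/allele"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            read_id, mapq, site, allele = line.split("\t")[:4]
            entry = rows.setdefault(read_id, {"mapq": int(mapq), "alleles": {}})
            entry["mapq"] = min(entry["mapq"], int(mapq))
            entry["alleles"][site] = allele
    return [
        AlignedReadObservation(rid, entry["mapq"], entry["alleles"])
        for rid, entry in rows.items()
    ]


def filter_reads(
    reads: Iterable[AlignedReadObservation], min_mapq: int = 30
) -> list:
    """Keep reads with mapping quality strictly above ``min_mapq``."""
    kept = []
    for read in reads:
        if read.mapq < 0:
            raise ValueError(f"read {read.read_id}: negative mapping quality")
        if read.mapq > min_mapq:
            kept.append(read)
    return kept


def classify_variant_pair_phase(
    reads: Iterable[AlignedReadObservation],
    site_a,
    site_b,
    min_spanning: int = 1,
    max_conflict_fraction: float = 0.0,
) -> str:
    """Classify a heterozygous variant pair as cis/trans/unknown from reads.

    Cis requires >= ``min_spanning`` spanning reads carrying the alternate
    allele at both sites; trans requires the alternate alleles to occur only
    on mutually exclusive reads, each observed at least once, with
    >= ``min_spanning`` reads traversing both positions.  Spanning reads
    contradicting the candidate configuration are tolerated up to
    ``max_conflict_fraction`` of the informative spanning reads (default 0:
    any conflict yields unknown).

    ``reads`` are assumed pre-filtered by mapping quality.
    """
    if site_a == site_b:
        raise ValueError("site_a and site_b must differ")
    alt_alt = alt_ref = ref_alt = 0
    n_spanning = 0
    alt_a_seen = alt_b_seen = False
    for read in reads:
        alt_a_seen = alt_a_seen or read.alleles.get(site_a) == "alt"
        alt_b_seen = alt_b_seen or read.alleles.get(site_b) == "alt"
        if not read.spans(site_a, site_b):
            continue
        n_spanning += 1
        a, b = read.alleles[site_a], read.alleles[site_b]
        if a == "alt" and b == "alt":
            alt_alt += 1
        elif a == "alt":
            alt_ref += 1
        elif b == "alt":
            ref_alt += 1
    informative = alt_alt + alt_ref + ref_alt
    if n_spanning < min_spanning or informative == 0:
        return "unknown"
    exclusive = alt_ref + ref_alt
    if alt_alt >= min_spanning and exclusive / informative <= max_conflict_fraction:
        return "cis"
    if (
        exclusive >= min_spanning
        and alt_alt / informative <= max_conflict_fraction
        and alt_a_seen
        and alt_b_seen
    ):
        return "trans"
    return "unknown"


@dataclass
class ReconcileResult:
    """Outcome of reconciling statistical and read-backed phase."""

    assessments: list
    corrected_counts: Counter
    original_counts: Counter
    n_errors: int

    @property
    def n_confident_trans(self) -> int:
        return self.corrected_counts.get("trans", 0)


def reconcile_phase(
    statistical: Mapping[object, str],
    read_backed: Mapping[object, object],
) -> ReconcileResult:
    """Override statistical phase with read evidence and count switch errors.

    ``statistical`` maps pair ids to their statistical phase labels.
    ``read_backed`` maps pair ids to a read-derived phase, optionally as a
    ``(phase, spanning_read_count)`` tuple; pairs absent from it keep their
    statistical phase, unconfirmed.  Where both phases are known the read
    phase wins; a disagreement is one phase-switch error.  Relabelling
    conserves the total pair count.

    Raises
    ------
    KeyError
        If a pair appears in ``read_backed`` but not in ``statistical``.
    """
    missing = set(read_backed) - set(statistical)
    if missing:
        raise KeyError(
            f"pairs in read evidence absent from statistical ledger: "
            f"{sorted(map(str, missing))[:5]}"
        )
    assessments = []
    for pid in statistical:
        stat_phase = statistical[pid]
        entry = read_backed.get(pid)
        if entry is None:
            read_phase, spanning = "unknown", 0
        elif isinstance(entry, str):
            read_phase, spanning = entry, 0
        else:
            read_phase, spanning = entry
        if read_phase == "unknown":
            final, confirmed, discordant = stat_phase, False, False
        else:
            final = read_phase
            confirmed = True
            discordant = stat_phase != "unknown" and stat_phase != read_phase
        assessments.append(
            PhaseAssessment(
                pair_id=pid,
                statistical_phase=stat_phase,
                read_backed_phase=read_phase,
                spanning_reads=spanning,
                discordant=discordant,
                final_phase=final,
                confirmed=confirmed,
            )
        )
    original = Counter(statistical.values())
    corrected = Counter(a.final_phase for a in assessments)
    n_errors = sum(a.discordant for a in assessments)
    return ReconcileResult(
        assessments=assessments,
        corrected_counts=corrected,
        original_counts=original,
        n_errors=n_errors,
    )
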