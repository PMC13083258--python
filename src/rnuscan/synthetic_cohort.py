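"""Synthetic cohort generator with a truth ledger.

The real discovery cohorts live in protected research environments, so the
pipeline is exercised end to end on generated data that reproduce the
statistical structure every stage assumes: rare-variant genotypes at a
191-nt single-exon locus with a log-uniform allele-frequency spectrum
(spanning both sides of the 0.001 rarity threshold), case-enriched
homozygous and compound-heterozygous genotypes, statistically phased
haplotypes with injected phase-switch errors plus read-level evidence,
dual-carrier trios with configurable both-allele transmission probability,
case-clustered phenotype term profiles on a generated toy ontology, and
negative-binomial paralog expression with a calibrated inter-gene
correlation and case-specific U2-2 depletion.  Every generator is
deterministic under the configured seed, and a truth ledger records the
injected state so recovery can be verified exactly.
"""

from __future__ import annotations

import itertools
import json
import math
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotype_model import (
    CohortAssignment,
    GenotypeCall,
    Trio,
    Variant,
)
from .phenotype_ontology import OntologyDAG, build_ontology
from .read_phasing import AlignedReadObservation

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "SimulatedCohort",
    "simulate_locus_cohort",
    "simulate_reads_for_pair",
    "simulate_ontology",
    "simulate_hpo_profiles",
    "simulate_expression",
    "simulate_gene_carrier_counts",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with defaults matching the
    conditions the pipeline is meant to operate under."""

    seed: int = 0
    # locus cohort
    n_cases: int = 500
    n_controls: int = 2000
    n_trios: int = 50
    locus_length: int = 191
    gene_name: str = "RNU2-2"
    n_variants: int = 40
    af_min: float = 1e-5
    af_max: float = 1e-2
    indel_fraction: float = 0.15
    max_indel_length: int = 4
    fail_filter_fraction: float = 0.05
    base_biallelic_prevalence: float = 0.02
    case_enrichment_factor: float = 5.0
    compound_het_fraction: float = 0.69  # of injected biallelic genotypes
    cis_pair_prevalence: float = 0.02  # dual-het cis (non-biallelic) carriers
    phase_switch_error_rate: float = 0.08
    both_transmission_probability: float = 0.25
    same_variant_parent_fraction: float = 0.5
    # read simulation
    read_depth: int = 20
    spanning_probability: float = 1.0
    base_error_rate: float = 0.0
    read_mapq: int = 60
    # phenotype ontology
    hpo_n_terms: int = 50
    hpo_max_parents: int = 2
    hpo_n_cases: int = 31
    hpo_n_controls: int = 150
    hpo_profile_size: tuple = (3, 6)
    hpo_n_cluster_terms: int = 8
    hpo_cluster_weight: float = 0.8
    # expression
    expr_n_cases: int = 9
    expr_n_controls: int = 300
    u2_2_mean_count: float = 1514.0
    u2_1_mean_count: float = 1456.0
    chr11_total: float = 2_000_000.0
    chr17_total: float = 2_000_000.0
    chromosome_total_cv: float = 0.05
    nb_dispersion: float = 25.0
    paralog_correlation: float = 0.83
    case_depletion_factor: float = 0.5

    def validate(self) -> None:
        fractions = {
            "indel_fraction": self.indel_fraction,
            "fail_filter_fraction": self.fail_filter_fraction,
            "base_biallelic_prevalence": self.base_biallelic_prevalence,
            "compound_het_fraction": self.compound_het_fraction,
            "cis_pair_prevalence": self.cis_pair_prevalence,
            "phase_switch_error_rate": self.phase_switch_error_rate,
            "both_transmission_probability": self.both_transmission_probability,
            "same_variant_parent_fraction": self.same_variant_parent_fraction,
            "spanning_probability": self.spanning_probability,
            "base_error_rate": self.base_error_rate,
            "hpo_cluster_weight": self.hpo_cluster_weight,
            "case_depletion_factor": self.case_depletion_factor,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.case_enrichment_factor < 1:
            raise ValueError("case_enrichment_factor must be >= 1")
        if self.base_biallelic_prevalence * self.case_enrichment_factor > 1:
            raise ValueError(
                "infeasible config: case biallelic prevalence would exceed 1"
            )
        if not (0 < self.af_min <= self.af_max <= 1):
            raise ValueError("need 0 < af_min <= af_max <= 1")
        if self.n_variants > self.locus_length:
            raise ValueError("more variants than locus positions")
        if self.u2_2_mean_count <= 0 or self.u2_1_mean_count <= 0:
            raise ValueError("expression means must be positive")
        if not (0 < self.paralog_correlation < self.nb_dispersion
                / (self.nb_dispersion + 1)):
            raise ValueError(
                "paralog_correlation unreachable at this NB dispersion"
            )
        lo, hi = self.hpo_profile_size
        if not (1 <= lo <= hi):
            raise ValueError("hpo_profile_size bounds must satisfy 1 <= lo <= hi")


@dataclass
class TruthLedger:
    """Injected ground truth, keyed the same way the pipeline keys its calls."""

    group: dict = field(default_factory=dict)  # sample -> group
    genotype_class: dict = field(default_factory=dict)  # sample -> class
    true_phase: dict = field(default_factory=dict)  # (sample, fs pair) -> phase
    statistical_phase: dict = field(default_factory=dict)
    switch_error_pairs: set = field(default_factory=set)
    trio_outcome: dict = field(default_factory=dict)  # family -> both/one/neither
    expression_depleted: dict = field(default_factory=dict)  # sample -> bool

    def to_json(self) -> str:
        def pair_key(key):
            sample, pair = key
            return f"{sample}|{','.join(sorted(pair))}"

        payload = {
            "group": self.group,
            "genotype_class": self.genotype_class,
            "true_phase": {pair_key(k): v for k, v in self.true_phase.items()},
            "statistical_phase": {
                pair_key(k): v for k, v in self.statistical_phase.items()
            },
            "switch_error_pairs": sorted(
                pair_key(k) for k in self.switch_error_pairs
            ),
            "trio_outcome": self.trio_outcome,
            "expression_depleted": self.expression_depleted,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _haplotype_pairs(rare_ids: set, h0: set, h1: set) -> dict:
    """Phase of every rare het pair implied by a pair of haplotypes."""
    hom = (h0 & h1) & rare_ids
    only0 = sorted((h0 - h1) & rare_ids)
    only1 = sorted((h1 - h0) & rare_ids)
    phases = {}
    for va, vb in itertools.product(only0, only1):
        phases[frozenset((va, vb))] = "trans"
    for side in (only0, only1):
        for va, vb in itertools.combinations(side, 2):
            phases[frozenset((va, vb))] = "cis"
    return phases, hom


def _classify_sample(rare_ids: set, h0: set, h1: set) -> str:
    phases, hom = _haplotype_pairs(rare_ids, h0, h1)
    if hom:
        return "homozygous"
    if any(p == "trans" for p in phases.values()):
        return "compound_het"
    if any(p == "cis" for p in phases.values()):
        return "cis_pair"
    return "het_carrier" if (h0 | h1) & rare_ids else "none"


@dataclass
class SimulatedCohort:
    """In-memory synthetic cohort plus its truth ledger and file writers."""

    config: SimulationConfig
    variants: dict  # variant_id -> Variant
    af_table: dict
    assignments: dict  # sample -> CohortAssignment
    trios: list
    true_haplotypes: dict  # sample -> (set, set)
    emitted_haplotypes: dict  # statistical phasing, switch errors included
    ledger: TruthLedger
    sample_order: list

    @property
    def rare_variant_ids(self) -> set:
        return {
            vid
            for vid, v in self.variants.items()
            if v.filter_status == "PASS" and v.af is not None and v.af < 0.001
        }

    def to_calls(self) -> dict:
        """Per-sample genotype calls as the cohort loader would produce them
        (PASS variants only, '|'-phased statistical haplotypes)."""
        calls: dict = {}
        for sample in self.sample_order:
            h0, h1 = self.emitted_haplotypes[sample]
            sample_calls = {}
            for vid in sorted(h0 | h1):
                if self.variants[vid].filter_status != "PASS":
                    continue
                if vid in h0 and vid in h1:
                    sample_calls[vid] = GenotypeCall(
                        sample, vid, "hom_alt", phased=False
                    )
                else:
                    sample_calls[vid] = GenotypeCall(
                        sample,
                        vid,
                        "het",
                        phased=True,
                        haplotype=0 if vid in h0 else 1,
                        phase_set=f"{sample}:1",
                    )
            if sample_calls:
                calls[sample] = sample_calls
        return calls

    # ------------------------------------------------------------------
    # File emission
    # ------------------------------------------------------------------

    def vcf_text(self) -> str:
        cfg = self.config
        lines = [
            "##fileformat=VCFv4.2",
            f"##contig=<ID={cfg.gene_name},length={cfg.locus_length}>",
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
            '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">',
            '##FILTER=<ID=LowQual,Description="Low quality">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.sample_order),
        ]
        for vid in sorted(self.variants, key=lambda v: self.variants[v].position):
            var = self.variants[vid]
            gts = []
            for sample in self.sample_order:
                h0, h1 = self.emitted_haplotypes[sample]
                gts.append(f"{int(vid in h0)}|{int(vid in h1)}")
            lines.append(
                "\t".join(
                    [
                        cfg.gene_name,
                        str(var.position),
                        vid,
                        var.ref,
                        var.alt,
                        ".",
                        var.filter_status,
                        f"AF={var.af:.6g};GENE={cfg.gene_name}",
                        "GT",
                    ]
                    + gts
                )
            )
        return "\n".join(lines) + "\n"

    def ped_text(self) -> str:
        rows = []
        in_trio = set()
        for trio in self.trios:
            rows.append(
                f"{trio.family}\t{trio.child}\t{trio.father}\t{trio.mother}\t0\t2"
            )
            rows.append(f"{trio.family}\t{trio.father}\t0\t0\t1\t1")
            rows.append(f"{trio.family}\t{trio.mother}\t0\t0\t2\t1")
            in_trio |= {trio.child, trio.father, trio.mother}
        for sample in self.sample_order:
            if sample not in in_trio:
                fam = self.assignments[sample].family
                rows.append(f"{fam}\t{sample}\t0\t0\t0\t0")
        return "\n".join(rows) + "\n"

    def groups_text(self) -> str:
        rows = ["sample_id\tgroup\tfamily_id"]
        for sample in self.sample_order:
            a = self.assignments[sample]
            rows.append(f"{a.sample}\t{a.group}\t{a.family}")
        return "\n".join(rows) + "\n"

    def af_text(self) -> str:
        rows = ["variant_id\taf"]
        for vid in sorted(self.af_table):
            rows.append(f"{vid}\t{self.af_table[vid]:.6g}")
        return "\n".join(rows) + "\n"

    def write(self, out_dir) -> dict:
        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for name, text in (
            ("cohort.vcf", self.vcf_text()),
            ("cohort.ped", self.ped_text()),
            ("groups.tsv", self.groups_text()),
            ("af.tsv", self.af_text()),
            ("truth.json", self.ledger.to_json()),
        ):
            path = os.path.join(out_dir, name)
            with open(path, "w") as fh:
                fh.write(text)
            paths[name] = path
        return paths


def _draw_variants(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    positions = np.sort(
        rng.choice(np.arange(1, cfg.locus_length + 1), cfg.n_variants, replace=False)
    )
    log_af = rng.uniform(math.log(cfg.af_min), math.log(cfg.af_max), cfg.n_variants)
    afs = np.exp(log_af)
    variants = {}
    for i, pos in enumerate(positions):
        vid = f"v{i + 1:03d}"
        is_indel = rng.random() < cfg.indel_fraction
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        if is_indel:
            length = int(rng.integers(1, cfg.max_indel_length + 1))
            extra = "".join(rng.choice(_BASES, length))
            if rng.random() < 0.5 and pos + length <= cfg.locus_length:
                ref, alt = ref + extra, ref  # deletion kept inside the locus
            else:
                ref, alt = ref, ref + extra  # insertion
        status = "LowQual" if rng.random() < cfg.fail_filter_fraction else "PASS"
        variants[vid] = Variant(
            variant_id=vid,
            gene=cfg.gene_name,
            position=int(pos),
            ref=ref,
            alt=alt,
            af=float(afs[i]),
            filter_status=status,
        )
    return variants


def simulate_locus_cohort(
    config: SimulationConfig | None = None, out_dir=None
) -> SimulatedCohort:
    """Generate a full case/control/trio cohort at the synthetic locus.

    Haplotypes carry background variants at their allele frequencies, plus
    injected biallelic genotypes (homozygous or trans compound-het) at a
    prevalence of ``base_biallelic_prevalence`` in controls and
    ``case_enrichment_factor`` times that in cases, and dual-het cis pairs
    that are carriers but not biallelic.  Statistical phase labels are the
    true haplotype assignments corrupted at ``phase_switch_error_rate`` per
    dual-het sample.  Trio offspring genotypes come from explicit gamete
    draws with per-parent transmission probability
    sqrt(both_transmission_probability), so (1/4, 1/2, 1/4) at the
    Mendelian default.  The truth ledger is derived from the realized
    haplotypes, so it agrees exactly with the emitted genotypes.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    variants = _draw_variants(cfg, rng)
    af_table = {vid: v.af for vid, v in variants.items()}
    all_ids = sorted(variants)
    afs = np.array([variants[v].af for v in all_ids])
    rare_pool = sorted(
        v
        for v in all_ids
        if variants[v].filter_status == "PASS" and variants[v].af < 0.001
    )
    if len(rare_pool) < 2:
        raise ValueError("AF spectrum produced fewer than 2 rare PASS variants")
    rare_ids = set(rare_pool)

    assignments: dict = {}
    true_haps: dict = {}
    sample_order: list = []

    def background_haplotype() -> set:
        mask = rng.random(len(all_ids)) < afs
        return {all_ids[i] for i in np.nonzero(mask)[0]}

    def add_sample(sample: str, group: str, family: str, inject: bool) -> None:
        h0, h1 = background_haplotype(), background_haplotype()
        if inject:
            p_biallelic = cfg.base_biallelic_prevalence * (
                cfg.case_enrichment_factor if group == "unsolved_NDD" else 1.0
            )
            u = rng.random()
            if u < p_biallelic:
                if rng.random() < cfg.compound_het_fraction:
                    va, vb = rng.choice(rare_pool, 2, replace=False)
                    h0.add(str(va))
                    h1.add(str(vb))
                else:
                    v = str(rng.choice(rare_pool))
                    h0.add(v)
                    h1.add(v)
            elif u < p_biallelic + cfg.cis_pair_prevalence:
                va, vb = rng.choice(rare_pool, 2, replace=False)
                h0.update((str(va), str(vb)))
        assignments[sample] = CohortAssignment(sample, group, family)
        true_haps[sample] = (h0, h1)
        sample_order.append(sample)

    for i in range(cfg.n_cases):
        add_sample(f"CASE{i + 1:05d}", "unsolved_NDD", f"FC{i + 1:05d}", True)
    for i in range(cfg.n_controls):
        add_sample(f"CTRL{i + 1:05d}", "control", f"FK{i + 1:05d}", True)

    # dual-carrier trios: clean single-het parents, gamete-draw offspring
    trios = []
    ledger = TruthLedger()
    q = math.sqrt(cfg.both_transmission_probability)
    for i in range(cfg.n_trios):
        fam = f"TRIO{i + 1:04d}"
        father, mother, child = f"{fam}_F", f"{fam}_M", f"{fam}_C"
        if rng.random() < cfg.same_variant_parent_fraction:
            vf = vm = str(rng.choice(rare_pool))
        else:
            vf, vm = (str(v) for v in rng.choice(rare_pool, 2, replace=False))
        f_transmits = rng.random() < q
        m_transmits = rng.random() < q
        child_h0 = {vf} if f_transmits else set()
        child_h1 = {vm} if m_transmits else set()
        for sample, group, haps in (
            (father, "control", ({vf}, set())),
            (mother, "control", ({vm}, set())),
            (child, "unsolved_NDD", (child_h0, child_h1)),
        ):
            assignments[sample] = CohortAssignment(sample, group, fam)
            true_haps[sample] = haps
            sample_order.append(sample)
        trios.append(Trio(fam, child, father, mother))
        n_transmitted = f_transmits + m_transmits
        ledger.trio_outcome[fam] = {2: "both", 1: "one", 0: "neither"}[
            n_transmitted
        ]

    # emitted statistical phasing: corrupt dual-het samples at the switch rate
    emitted: dict = {}
    for sample in sample_order:
        h0, h1 = true_haps[sample]
        e0, e1 = set(h0), set(h1)
        rare_hets = sorted((h0 ^ h1) & rare_ids)
        if len(rare_hets) >= 2 and rng.random() < cfg.phase_switch_error_rate:
            flip = str(rng.choice(rare_hets))
            if flip in e0:
                e0.discard(flip)
                e1.add(flip)
            else:
                e1.discard(flip)
                e0.add(flip)
        emitted[sample] = (e0, e1)

    # truth ledger from realized haplotypes
    for sample in sample_order:
        h0, h1 = true_haps[sample]
        ledger.group[sample] = assignments[sample].group
        ledger.genotype_class[sample] = _classify_sample(rare_ids, h0, h1)
        phases, _hom = _haplotype_pairs(rare_ids, h0, h1)
        stat_phases, _ = _haplotype_pairs(rare_ids, *emitted[sample])
        for pair, phase in phases.items():
            key = (sample, pair)
            ledger.true_phase[key] = phase
            ledger.statistical_phase[key] = stat_phases.get(pair, "unknown")
            if ledger.statistical_phase[key] != phase:
                ledger.switch_error_pairs.add(key)

    cohort = SimulatedCohort(
        config=cfg,
        variants=variants,
        af_table=af_table,
        assignments=assignments,
        trios=trios,
        true_haplotypes=true_haps,
        emitted_haplotypes=emitted,
        ledger=ledger,
        sample_order=sample_order,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def simulate_reads_for_pair(
    true_phase: str,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    site_a="site_a",
    site_b="site_b",
) -> list:
    """Generate aligned-read observations for a two-variant het carrier.

    Reads alternate between the two haplotypes (both are covered whenever
    depth >= 2, as manual inspection of a well-covered short locus would
    see); under trans the haplotypes are alt/ref and ref/alt, under cis
    alt/alt and ref/ref.  Each read spans both sites with probability
    ``spanning_probability`` (default 1: a short-read fragment virtually
    always traverses both positions of a 191-nt locus; lower it to emulate
    partial coverage), and allele calls flip with ``base_error_rate``.
    """
    if true_phase not in ("cis", "trans"):
        raise ValueError("true_phase must be 'cis' or 'trans'")
    cfg = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if true_phase == "trans":
        haplotypes = ({site_a: "alt", site_b: "ref"}, {site_a: "ref", site_b: "alt"})
    else:
        haplotypes = ({site_a: "alt", site_b: "alt"}, {site_a: "ref", site_b: "ref"})
    reads = []
    for i in range(cfg.read_depth):
        hap = haplotypes[i % 2]
        if rng.random() < cfg.spanning_probability:
            sites = (site_a, site_b)
        else:
            sites = (site_a,) if rng.random() < 0.5 else (site_b,)
        alleles = {}
        for site in sites:
            call = hap[site]
            if rng.random() < cfg.base_error_rate:
                call = "alt" if call == "ref" else "ref"
            alleles[site] = call
        reads.append(
            AlignedReadObservation(f"read{i + 1:04d}", cfg.read_mapq, alleles)
        )
    return reads


def simulate_ontology(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> OntologyDAG:
    """Generate a toy rooted DAG: each new term gets 1-2 existing parents."""
    cfg = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    terms = ["T000"]
    edges = []
    for i in range(1, cfg.hpo_n_terms):
        term = f"T{i:03d}"
        n_parents = int(rng.integers(1, cfg.hpo_max_parents + 1))
        n_parents = min(n_parents, len(terms))
        parents = rng.choice(terms, n_parents, replace=False)
        for parent in parents:
            edges.append((term, str(parent)))
        terms.append(term)
    return build_ontology(edges)


def simulate_hpo_profiles(
    config: SimulationConfig | None = None,
    ontology: OntologyDAG | None = None,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Generate case-clustered and background term profiles.

    Returns ``(profiles, case_ids)``.  Cases draw a ``hpo_cluster_weight``
    fraction of their terms from a fixed cluster of leaf terms; controls
    draw uniformly from all non-root terms.  With cluster weight 1.0 every
    case term is a cluster term, making the case group maximally homogeneous.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if ontology is None:
        ontology = simulate_ontology(cfg, rng)
    leaves = sorted(t for t in ontology.terms if not ontology.children(t))
    n_cluster = min(cfg.hpo_n_cluster_terms, len(leaves))
    cluster = sorted(str(t) for t in rng.choice(leaves, n_cluster, replace=False))
    if not cluster:
        raise ValueError("ontology has no leaf terms for the case cluster")
    background = sorted(t for t in ontology.terms if t != ontology.root)
    lo, hi = cfg.hpo_profile_size
    profiles: dict = {}
    case_ids = []

    def draw_profile(is_case: bool) -> set:
        k = int(rng.integers(lo, hi + 1))
        if is_case:
            n_clust = min(
                len(cluster), int(round(k * cfg.hpo_cluster_weight))
            )
            if cfg.hpo_cluster_weight >= 1.0:
                k = min(k, len(cluster))
                n_clust = k
            chosen = set(
                str(t) for t in rng.choice(cluster, n_clust, replace=False)
            )
            rest_pool = [t for t in background if t not in chosen]
            n_rest = min(k - n_clust, len(rest_pool))
            if n_rest > 0:
                chosen |= {
                    str(t) for t in rng.choice(rest_pool, n_rest, replace=False)
                }
            return chosen
        return {str(t) for t in rng.choice(background, min(k, len(background)),
                                           replace=False)}

    for i in range(cfg.hpo_n_cases):
        sample = f"PCASE{i + 1:04d}"
        profiles[sample] = draw_profile(True)
        case_ids.append(sample)
    for i in range(cfg.hpo_n_controls):
        profiles[f"PCTRL{i + 1:04d}"] = draw_profile(False)
    return profiles, case_ids


def _solve_latent_sigma(cfg: SimulationConfig) -> float:
    """Latent log-normal scale achieving the target count correlation.

    With a shared latent factor L = exp(sigma Z - sigma^2/2) multiplying
    both negative-binomial means (m1, m2) and dispersion theta, the count
    correlation is m1 m2 (e^{s}-1) / sqrt(prod_i m_i + m_i^2((1+1/theta)
    e^{s}-1)) with s = sigma^2; solved for s by bisection.
    """
    m1, m2 = cfg.u2_1_mean_count, cfg.u2_2_mean_count
    theta = cfg.nb_dispersion
    target = cfg.paralog_correlation

    def corr(s: float) -> float:
        es = math.exp(s)
        cov = m1 * m2 * (es - 1.0)
        v1 = m1 + m1 * m1 * ((1 + 1 / theta) * es - 1.0)
        v2 = m2 + m2 * m2 * ((1 + 1 / theta) * es - 1.0)
        return cov / math.sqrt(v1 * v2)

    s = brentq(lambda s: corr(s) - target, 1e-8, 25.0)
    return math.sqrt(s)


def simulate_expression(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple:
    """Generate paralog expression counts with a shared latent factor.

    Returns ``(counts, depleted)``: a long-format DataFrame (sample_id,
    gene_id, count, chromosome, chromosome_total) and a sample -> bool map
    of injected U2-2 depletion.  Counts are negative-binomial around
    latent-scaled means; flagged cases have their U2-2 mean multiplied by
    ``case_depletion_factor``.  The latent scale is calibrated so that the
    U2-2/U2-1 count correlation matches ``paralog_correlation``.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sigma = _solve_latent_sigma(cfg)
    theta = cfg.nb_dispersion
    samples = [f"ECASE{i + 1:04d}" for i in range(cfg.expr_n_cases)] + [
        f"ECTRL{i + 1:04d}" for i in range(cfg.expr_n_controls)
    ]
    depleted = {s: s.startswith("ECASE") for s in samples}
    rows = []
    cv = cfg.chromosome_total_cv
    for sample in samples:
        z = rng.standard_normal()
        latent = math.exp(sigma * z - sigma * sigma / 2.0)
        factor = cfg.case_depletion_factor if depleted[sample] else 1.0
        for gene, base_mean, chrom, chrom_total in (
            ("RNU2-2", cfg.u2_2_mean_count * factor, "chr11", cfg.chr11_total),
            ("RNU2-1", cfg.u2_1_mean_count, "chr17", cfg.chr17_total),
        ):
            mean = base_mean * latent
            lam = rng.gamma(shape=theta, scale=mean / theta)
            count = int(rng.poisson(lam))
            total = chrom_total * math.exp(
                cv * rng.standard_normal() - cv * cv / 2.0
            )
            rows.append(
                {
                    "sample_id": sample,
                    "gene_id": gene,
                    "count": count,
                    "chromosome": chrom,
                    "chromosome_total": round(total),
                }
            )
    return pd.DataFrame(rows), depleted


def simulate_gene_carrier_counts(
    n_genes: int,
    n_cases: int,
    n_controls: int,
    enrichment_factor: float = 1.0,
    prevalence_range: tuple = (2e-4, 5e-3),
    rng: np.random.Generator | None = None,
) -> tuple:
    """Per-gene biallelic carrier counts for enrichment-scan calibration.

    Each gene draws a baseline carrier prevalence log-uniformly from
    ``prevalence_range``; control carriers are Binomial(n_controls, p) and
    case carriers Binomial(n_cases, p * enrichment_factor).  Returns
    (case_counts, control_counts) dicts keyed by gene.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = prevalence_range
    prevalence = np.exp(rng.uniform(math.log(lo), math.log(hi), n_genes))
    case_p = np.minimum(prevalence * enrichment_factor, 1.0)
    case_counts = rng.binomial(n_cases, case_p)
    control_counts = rng.binomial(n_controls, prevalence)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    return (
        dict(zip(genes, map(int, case_counts))),
        dict(zip(genes, map(int, control_counts))),
    )
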