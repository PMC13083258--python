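"""Shared fixtures: a tiny hand-written cohort and a toy ontology."""

import pytest

import rnuscan as r

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=RNU2-2,length=191>
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene name">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path, samples, rows):
    """Write a small VCF: rows are (pos, vid, ref, alt, filt, af, gts)."""
    lines = [VCF_HEADER.rstrip("\n")]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for pos, vid, ref, alt, filt, af, gts in rows:
        lines.append(
            f"RNU2-2\t{pos}\t{vid}\t{ref}\t{alt}\t.\t{filt}\t"
            f"AF={af};GENE=RNU2-2\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_groups(path, assignments):
    lines = ["sample_id\tgroup\tfamily_id"]
    for sample, group, family in assignments:
        lines.append(f"{sample}\t{group}\t{family}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_ped(path, rows):
    path.write_text("\n".join("\t".join(map(str, row)) for row in rows) + "\n")
    return path


@pytest.fixture
def tiny_cohort_files(tmp_path):
    """Two unrelated carriers of a PASS het variant plus a LowQual variant."""
    vcf = write_vcf(
        tmp_path / "tiny.vcf",
        ["S1", "S2"],
        [
            (35, "v1", "A", "G", "PASS", 0.0005, ["0|1", "1|0"]),
            (80, "v2", "C", "T", "LowQual", 0.0005, ["0/1", "0/0"]),
        ],
    )
    ped = write_ped(
        tmp_path / "tiny.ped",
        [("F1", "S1", 0, 0, 1, 2), ("F2", "S2", 0, 0, 2, 1)],
    )
    groups = write_groups(
        tmp_path / "tiny.groups.tsv",
        [("S1", "unsolved_NDD", "F1"), ("S2", "control", "F2")],
    )
    return vcf, ped, groups


# 7-term toy DAG used for the brute-force similarity oracle:
#       root
#       /  \
#      a    b
#     / \  / \
#    c   d    e
#    |___f (two parents: c and b)
TOY_EDGES = [
    ("a", "root"),
    ("b", "root"),
    ("c", "a"),
    ("d", "a"),
    ("d", "b"),
    ("e", "b"),
    ("f", "c"),
    ("f", "b"),
]


@pytest.fixture(scope="session")
def toy_ontology():
    return r.build_ontology(TOY_EDGES)


@pytest.fixture(scope="session")
def toy_profiles():
    return {
        "p1": {"c", "e"},
        "p2": {"c", "d"},
        "p3": {"f"},
        "p4": {"d", "e"},
        "p5": {"a", "e"},
        "p6": {"f", "d"},
    }


def make_variant(vid, pos, ref="A", alt="G", af=0.0001, filt="PASS"):
    return r.Variant(vid, "RNU2-2", pos, ref, alt, af, filt)


def het(sample, vid, hap=None, ps=None):
    phased = hap is not None
    return r.GenotypeCall(
        sample, vid, "het", phased=phased, haplotype=hap,
        phase_set=ps if ps is not None else (f"{sample}:1" if phased else None),
    )


def hom(sample, vid):
    return r.GenotypeCall(sample, vid, "hom_alt")
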