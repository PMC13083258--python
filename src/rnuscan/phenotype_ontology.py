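"""Ontology-based phenotype similarity, enrichment and PCA.

Patient phenotypes are sets of terms from a directed acyclic ontology
(HPO-like).  Term specificity is measured by information content,
IC(t) = -ln(fraction of reference profiles annotated with t after ancestor
propagation), so the root has IC 0 and rarer terms are more informative.
Profile similarity is the symmetric best-match average (BMA) of Resnik term
similarity — the IC of the most informative common ancestor — and a group's
phenotypic homogeneity is the mean pairwise similarity over its members.
Whether a case group is more homogeneous than chance is assessed with a
Monte Carlo permutation test against random same-size groups.  Per-term
enrichment between two cohorts uses Fisher's exact test on non-redundant
terms with Benjamini-Hochberg FDR control, and phenotype matrices can be
compared by PCA on Boolean encodings (missing coded as absent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment_stats import bh_adjust, fisher_exact_2x2, TwoByTwoTable

__all__ = [
    "OntologyDAG",
    "ICTable",
    "SimilarityResult",
    "PCAResult",
    "build_ontology",
    "load_ontology",
    "propagate_profile",
    "propagate_and_ic",
    "resnik_similarity",
    "profile_similarity",
    "group_similarity",
    "monte_carlo_similarity_p",
    "remove_redundant_terms",
    "hpo_enrichment",
    "phenotype_pca",
]


class OntologyDAG:
    """A rooted DAG of terms with a precomputed ancestor closure.

    Each term's ancestor set includes the term itself.  Construction
    verifies acyclicity and that every term reaches the single root.
    """

    def __init__(self, graph: nx.DiGraph):
        # graph edges point child -> parent
        if not nx.is_directed_acyclic_graph(graph):
            raise ValueError("ontology contains a cycle")
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(
                f"ontology must have exactly one root; found {sorted(roots)}"
            )
        self.root = roots[0]
        self.graph = graph
        self.ancestors: dict = {}
        for term in graph.nodes:
            closure = nx.descendants(graph, term) | {term}
            self.ancestors[term] = frozenset(closure)
        # all terms must reach the root
        orphans = [t for t, anc in self.ancestors.items() if self.root not in anc]
        if orphans:
            raise ValueError(f"terms with no path to root: {sorted(orphans)}")

    def __contains__(self, term) -> bool:
        return term in self.ancestors

    def __len__(self) -> int:
        return len(self.ancestors)

    @property
    def terms(self) -> list:
        return sorted(self.ancestors)

    def parents(self, term) -> set:
        return set(self.graph.successors(term))

    def children(self, term) -> set:
        return set(self.graph.predecessors(term))

    def is_ancestor(self, candidate, term) -> bool:
        """True if ``candidate`` is an ancestor of ``term`` (or the term itself)."""
        return candidate in self.ancestors[term]


def build_ontology(edges: Iterable[tuple]) -> OntologyDAG:
    """Build an ontology from (child, parent) edges."""
    graph = nx.DiGraph()
    for child, parent in edges:
        graph.add_edge(child, parent)
    if graph.number_of_nodes() == 0:
        raise ValueError("no edges given")
    return OntologyDAG(graph)


def load_ontology(path) -> OntologyDAG:
    """Load an ontology from an OBO file (id/is_a stanzas) or a two-column
    child-parent TSV."""
    path = str(path)
    if path.endswith(".obo"):
        import obonet

        graph = obonet.read_obo(path)
        edges = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        ]
        return build_ontology(edges)
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected child<TAB>parent"
                )
            edges.append((fields[0], fields[1]))
    return build_ontology(edges)


def propagate_profile(terms: Iterable, ontology: OntologyDAG) -> frozenset:
    """Extend a term set to its full ancestor closure."""
    closure: set = set()
    for term in terms:
        if term not in ontology:
            raise KeyError(f"term {term!r} absent from ontology")
        closure |= ontology.ancestors[term]
    return frozenset(closure)


@dataclass(frozen=True)
class ICTable:
    """Information content per term, in nats, from a reference population."""

    ic: Mapping
    n_profiles: int

    def __getitem__(self, term) -> float:
        return self.ic[term]

    def get(self, term, default: float = 0.0) -> float:
        return self.ic.get(term, default)


def propagate_and_ic(
    profiles: Mapping[str, Iterable], ontology: OntologyDAG
) -> ICTable:
    """IC(t) = -ln(annotation frequency of t) over ancestor-propagated profiles.

    The reference population is the given profiles; terms annotated in every
    profile (including the root) get IC 0.  Terms never annotated are absent
    from the table (``ICTable.get`` returns 0 for them).
    """
    if not profiles:
        raise ValueError("at least one profile required")
    counts: dict = {}
    for sample in profiles:
        for term in propagate_profile(profiles[sample], ontology):
            counts[term] = counts.get(term, 0) + 1
    n = len(profiles)
    ic = {term: -np.log(count / n) for term, count in counts.items()}
    return ICTable(ic=ic, n_profiles=n)


def resnik_similarity(term_a, term_b, ontology: OntologyDAG, ic: ICTable) -> float:
    """IC of the most informative common ancestor of two terms."""
    common = ontology.ancestors[term_a] & ontology.ancestors[term_b]
    return max((ic.get(t, 0.0) for t in common), default=0.0)


def profile_similarity(
    profile_a: Iterable,
    profile_b: Iterable,
    ontology: OntologyDAG,
    ic: ICTable,
) -> float:
    """Symmetric best-match-average Resnik similarity of two term profiles."""
    a, b = sorted(set(profile_a)), sorted(set(profile_b))
    if not a or not b:
        raise ValueError("profiles must be nonempty")
    sim = np.array(
        [[resnik_similarity(ta, tb, ontology, ic) for tb in b] for ta in a]
    )
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


def _pairwise_matrix(
    profiles: Mapping[str, Iterable],
    samples: Sequence[str],
    ontology: OntologyDAG,
    ic: ICTable,
) -> np.ndarray:
    """All-pairs profile similarity over ``samples`` (vectorized via a
    term-pair Resnik lookup)."""
    terms = sorted({t for s in samples for t in profiles[s]})
    index = {t: i for i, t in enumerate(terms)}
    k = len(terms)
    term_sim = np.zeros((k, k))
    for i, ta in enumerate(terms):
        for j, tb in enumerate(terms[i:], start=i):
            term_sim[i, j] = term_sim[j, i] = resnik_similarity(
                ta, tb, ontology, ic
            )
    idx = []
    for s in samples:
        prof = sorted(set(profiles[s]))
        if not prof:
            raise ValueError(f"profile for {s!r} is empty")
        idx.append(np.array([index[t] for t in prof]))
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            block = term_sim[np.ix_(idx[i], idx[j])]
            out[i, j] = out[j, i] = (
                block.max(axis=1).mean() + block.max(axis=0).mean()
            ) / 2.0
    return out


def group_similarity(
    profiles: Mapping[str, Iterable],
    group_ids: Sequence[str],
    ontology: OntologyDAG,
    ic: ICTable,
) -> float:
    """Mean pairwise BMA similarity over all unordered pairs in a group."""
    ids = list(group_ids)
    if len(ids) < 2:
        raise ValueError("group size must be >= 2")
    matrix = _pairwise_matrix(profiles, ids, ontology, ic)
    upper = matrix[np.triu_indices(len(ids), k=1)]
    return float(upper.mean())


@dataclass(frozen=True)
class SimilarityResult:
    observed: float
    null: np.ndarray
    n_perm: int
    seed: object
    p_two_sided: float
    p_high: float
    p_low: float


def monte_carlo_similarity_p(
    profiles: Mapping[str, Iterable],
    group_ids: Sequence[str],
    ontology: OntologyDAG,
    ic: ICTable | None = None,
    n_perm: int = 1000,
    seed=None,
) -> SimilarityResult:
    """Permutation test of a group's phenotypic homogeneity.

    The null distribution is the group-similarity statistic of ``n_perm``
    random same-size subsets of the whole profile population.  Tail p values
    use the add-one convention, p_high = (1 + #{null >= observed}) /
    (n_perm + 1) (p_low analogous), and the two-sided p doubles the smaller
    tail, capped at 1 — so p can never fall below 2/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    population = sorted(profiles)
    ids = list(group_ids)
    if len(ids) > len(population):
        raise ValueError("group larger than population")
    if ic is None:
        ic = propagate_and_ic(profiles, ontology)
    rng = np.random.default_rng(seed)
    # one similarity matrix over the whole population; permutations just index it
    sample_index = {s: i for i, s in enumerate(population)}
    matrix = _pairwise_matrix(profiles, population, ontology, ic)

    def stat(members: Sequence[str]) -> float:
        locs = np.array([sample_index[s] for s in members])
        sub = matrix[np.ix_(locs, locs)]
        return float(sub[np.triu_indices(len(locs), k=1)].mean())

    observed = stat(ids)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(population, size=len(ids), replace=False)
        null[i] = stat(list(draw))
    p_high = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    p_low = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    p_two = min(1.0, 2.0 * min(p_high, p_low))
    return SimilarityResult(
        observed=observed,
        null=null,
        n_perm=n_perm,
        seed=seed,
        p_two_sided=p_two,
        p_high=p_high,
        p_low=p_low,
    )


def remove_redundant_terms(term_set: Iterable, ontology: OntologyDAG) -> set:
    """Drop every term that is a proper ancestor of another term in the set.

    The result is an antichain: no remaining term is an ancestor of any
    other.
    """
    terms = set(term_set)
    for term in terms:
        if term not in ontology:
            raise KeyError(f"term {term!r} absent from ontology")
    redundant = set()
    for term in terms:
        for other in terms:
            if other != term and ontology.is_ancestor(term, other):
                redundant.add(term)
                break
    return terms - redundant


def hpo_enrichment(
    profiles_a: Mapping[str, Iterable],
    profiles_b: Mapping[str, Iterable],
    ontology: OntologyDAG,
    min_count: int = 0,
) -> pd.DataFrame:
    """Per-term enrichment between two cohorts on non-redundant terms.

    Term presence is evaluated on ancestor-propagated profiles; the tested
    term set is the antichain obtained by redundancy removal from the union
    of annotated terms across both cohorts.  Each term gets a 2x2 Fisher
    test (cross-product OR) and a Benjamini-Hochberg adjusted p value.
    Terms observed in neither cohort are skipped; ``min_count`` additionally
    requires a term to reach that count in at least one cohort.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("both cohorts must be nonempty")
    closures_a = {s: propagate_profile(p, ontology) for s, p in profiles_a.items()}
    closures_b = {s: propagate_profile(p, ontology) for s, p in profiles_b.items()}
    universe = {t for p in profiles_a.values() for t in p}
    universe |= {t for p in profiles_b.values() for t in p}
    tested = sorted(remove_redundant_terms(universe, ontology))
    n_a, n_b = len(closures_a), len(closures_b)
    rows = []
    for term in tested:
        k_a = sum(term in c for c in closures_a.values())
        k_b = sum(term in c for c in closures_b.values())
        if k_a == 0 and k_b == 0:
            continue
        if k_a == n_a and k_b == n_b:
            continue  # universal term: degenerate table, uninformative
        if min_count and max(k_a, k_b) < min_count:
            continue
        res = fisher_exact_2x2(TwoByTwoTable(k_a, n_a - k_a, k_b, n_b - k_b))
        rows.append(
            {
                "term": term,
                "count_a": k_a,
                "count_b": k_b,
                "n_a": n_a,
                "n_b": n_b,
                "odds_ratio": res.odds_ratio,
                "p": res.p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term", "count_a", "count_b", "n_a", "n_b", "odds_ratio", "p"]
    )
    df["p_adjusted"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


@dataclass
class PCAResult:
    scores: pd.DataFrame
    variance_explained: np.ndarray
    features: list


def phenotype_pca(
    boolean_feature_matrix,
    scale: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of a samples x features Boolean phenotype matrix.

    Missing values are coded as absent (0) before decomposition; constant
    columns are dropped; columns are centered and (by default)
    unit-variance scaled.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    df = pd.DataFrame(boolean_feature_matrix).fillna(0).astype(float)
    variable = df.columns[df.nunique() > 1]
    df = df[variable]
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise ValueError(
            "need >= 2 samples and >= 1 non-constant feature for PCA"
        )
    X = StandardScaler(with_mean=True, with_std=scale).fit_transform(df.to_numpy())
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    score_df = pd.DataFrame(
        scores,
        index=df.index,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return PCAResult(
        scores=score_df,
        variance_explained=pca.explained_variance_ratio_,
        features=list(df.columns),
    )
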