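"""Ontology construction, IC, similarity (vs brute force) and enrichment."""

import itertools
import math

import numpy as np
import pytest

import rnuscan as r

from conftest import TOY_EDGES


# ---------------------------------------------------------------------------
# independent brute-force oracle (own ancestor computation, nested loops)
# ---------------------------------------------------------------------------

def oracle_ancestors(edges):
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
        parents.setdefault(parent, set())
    def climb(term):
        out = {term}
        for p in parents[term]:
            out |= climb(p)
        return out
    return {t: climb(t) for t in parents}


def oracle_ic(profiles, ancestors):
    n = len(profiles)
    counts = {}
    for terms in profiles.values():
        closed = set()
        for t in terms:
            closed |= ancestors[t]
        for t in closed:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(c / n) for t, c in counts.items()}


def oracle_bma(p1, p2, ancestors, ic):
    def resnik(t1, t2):
        return max((ic.get(t, 0.0) for t in ancestors[t1] & ancestors[t2]),
                   default=0.0)
    def one_way(src, dst):
        return sum(max(resnik(s, d) for d in dst) for s in src) / len(src)
    return (one_way(p1, p2) + one_way(p2, p1)) / 2.0


class TestBuildOntology:
    def test_chain_ancestors(self):
        ont = r.build_ontology([("a", "root"), ("b", "a")])
        assert ont.ancestors["b"] == {"b", "a", "root"}

    def test_multi_parent_union(self, toy_ontology):
        assert toy_ontology.ancestors["d"] == {"d", "a", "b", "root"}

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            r.build_ontology([("a", "b"), ("b", "a")])

    def test_two_roots_rejected(self):
        with pytest.raises(ValueError, match="root"):
            r.build_ontology([("a", "r1"), ("b", "r2")])

    def test_tsv_and_obo_loaders(self, tmp_path, toy_ontology):
        tsv = tmp_path / "edges.tsv"
        tsv.write_text("".join(f"{c}\t{p}\n" for c, p in TOY_EDGES))
        assert r.load_ontology(tsv).ancestors == toy_ontology.ancestors
        obo = tmp_path / "toy.obo"
        stanzas = ["format-version: 1.2\n"]
        terms = {t for e in TOY_EDGES for t in e}
        for term in sorted(terms):
            stanzas.append(f"\n[Term]\nid: {term}\nname: {term}\n")
            for child, parent in TOY_EDGES:
                if child == term:
                    stanzas.append(f"is_a: {parent} ! {parent}\n")
        obo.write_text("".join(stanzas))
        assert r.load_ontology(obo).ancestors == toy_ontology.ancestors


class TestInformationContent:
    def test_matches_formula_and_root_is_zero(self, toy_ontology):
        profiles = {f"s{i}": {"e"} for i in range(9)}
        profiles["s9"] = {"f"}
        ic = r.propagate_and_ic(profiles, toy_ontology)
        assert ic["f"] == pytest.approx(-math.log(0.1))
        assert ic["root"] == 0.0
        # term present in every profile after propagation
        assert ic["b"] == 0.0

    def test_ancestor_never_more_informative(self, toy_ontology, toy_profiles):
        ic = r.propagate_and_ic(toy_profiles, toy_ontology)
        for term, value in ic.ic.items():
            for anc in toy_ontology.ancestors[term]:
                assert ic.get(anc) <= value + 1e-12

    def test_unknown_term_raises(self, toy_ontology):
        with pytest.raises(KeyError, match="zzz"):
            r.propagate_and_ic({"s": {"zzz"}}, toy_ontology)


class TestGroupSimilarity:
    def test_matches_brute_force_on_all_small_groups(
        self, toy_ontology, toy_profiles
    ):
        ancestors = oracle_ancestors(TOY_EDGES)
        ic_oracle = oracle_ic(toy_profiles, ancestors)
        ic = r.propagate_and_ic(toy_profiles, toy_ontology)
        samples = sorted(toy_profiles)
        for size in (2, 3, 4):
            for group in itertools.combinations(samples, size):
                expected = np.mean(
                    [
                        oracle_bma(
                            toy_profiles[x], toy_profiles[y], ancestors, ic_oracle
                        )
                        for x, y in itertools.combinations(group, 2)
                    ]
                )
                got = r.group_similarity(toy_profiles, group, toy_ontology, ic)
                assert got == pytest.approx(expected)

    def test_member_order_invariant(self, toy_ontology, toy_profiles):
        ic = r.propagate_and_ic(toy_profiles, toy_ontology)
        a = r.group_similarity(toy_profiles, ["p1", "p2", "p3"], toy_ontology, ic)
        b = r.group_similarity(toy_profiles, ["p3", "p1", "p2"], toy_ontology, ic)
        assert a == pytest.approx(b)

    def test_profiles_sharing_only_root_have_zero_similarity(self):
        ont = r.build_ontology([("a", "root"), ("b", "root")])
        profiles = {"s1": {"a"}, "s2": {"b"}}
        ic = r.propagate_and_ic(profiles, ont)
        assert r.group_similarity(profiles, ["s1", "s2"], ont, ic) == 0.0

    def test_identical_maximally_specific_profiles_score_highest(
        self, toy_ontology, toy_profiles
    ):
        profiles = dict(toy_profiles)
        profiles["t1"] = {"f"}
        profiles["t2"] = {"f"}
        ic = r.propagate_and_ic(profiles, toy_ontology)
        twin = r.group_similarity(profiles, ["t1", "t2"], toy_ontology, ic)
        assert twin == pytest.approx(ic["f"])
        others = [
            r.group_similarity(profiles, pair, toy_ontology, ic)
            for pair in itertools.combinations(sorted(toy_profiles), 2)
        ]
        assert twin >= max(others)

    def test_small_group_rejected(self, toy_ontology, toy_profiles):
        ic = r.propagate_and_ic(toy_profiles, toy_ontology)
        with pytest.raises(ValueError):
            r.group_similarity(toy_profiles, ["p1"], toy_ontology, ic)


class TestMonteCarlo:
    def test_floor_when_observed_beats_every_draw(self, toy_ontology):
        profiles = {f"case{i}": {"f"} for i in range(3)}
        profiles.update({f"ctrl{i}": {"e" if i % 2 else "d"} for i in range(30)})
        res = r.monte_carlo_similarity_p(
            profiles, ["case0", "case1", "case2"], toy_ontology,
            n_perm=1000, seed=4,
        )
        assert res.p_two_sided == pytest.approx(2 / 1001)
        assert res.p_high == pytest.approx(1 / 1001)

    def test_reproducible_under_fixed_seed(self, toy_ontology, toy_profiles):
        kwargs = dict(n_perm=200, seed=11)
        a = r.monte_carlo_similarity_p(
            toy_profiles, ["p1", "p2"], toy_ontology, **kwargs
        )
        b = r.monte_carlo_similarity_p(
            toy_profiles, ["p1", "p2"], toy_ontology, **kwargs
        )
        assert a.p_two_sided == b.p_two_sided
        assert np.array_equal(a.null, b.null)

    def test_p_never_below_floor(self, toy_ontology, toy_profiles):
        res = r.monte_carlo_similarity_p(
            toy_profiles, ["p1", "p2"], toy_ontology, n_perm=50, seed=0
        )
        assert res.p_two_sided >= 2 / 51

    def test_invalid_arguments(self, toy_ontology, toy_profiles):
        with pytest.raises(ValueError):
            r.monte_carlo_similarity_p(
                toy_profiles, ["p1", "p2"], toy_ontology, n_perm=0
            )
        with pytest.raises(ValueError):
            r.monte_carlo_similarity_p(
                toy_profiles, list(toy_profiles) + ["extra"], toy_ontology
            )

    def test_null_group_p_roughly_uniform(self):
        cfg = r.SimulationConfig(
            seed=31, hpo_cluster_weight=0.0, hpo_n_cases=0, hpo_n_controls=60
        )
        ont = r.simulate_ontology(cfg)
        profiles, _ = r.simulate_hpo_profiles(cfg, ont)
        ic = r.propagate_and_ic(profiles, ont)
        rng = np.random.default_rng(1)
        population = sorted(profiles)
        ps = [
            r.monte_carlo_similarity_p(
                profiles,
                list(rng.choice(population, 8, replace=False)),
                ont, ic=ic, n_perm=99, seed=rep,
            ).p_two_sided
            for rep in range(60)
        ]
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps <= 0.05).mean() <= 0.12


class TestRedundancyAndEnrichment:
    def test_proper_ancestor_removed(self, toy_ontology):
        assert r.remove_redundant_terms({"f", "c"}, toy_ontology) == {"f"}

    def test_antichain_unchanged(self, toy_ontology):
        assert r.remove_redundant_terms({"c", "d", "e"}, toy_ontology) == {
            "c", "d", "e",
        }

    def test_root_alone_kept(self, toy_ontology):
        assert r.remove_redundant_terms({"root"}, toy_ontology) == {"root"}

    def test_output_is_always_an_antichain(self, toy_ontology):
        out = r.remove_redundant_terms(
            {"root", "a", "b", "c", "d", "e", "f"}, toy_ontology
        )
        for x in out:
            for y in out:
                assert x == y or not toy_ontology.is_ancestor(x, y)

    def test_enrichment_cross_product_or(self, toy_ontology):
        profiles_a = {f"a{i}": ({"f"} if i < 8 else {"e"}) for i in range(10)}
        profiles_b = {f"b{i}": ({"f"} if i < 2 else {"e"}) for i in range(10)}
        df = r.hpo_enrichment(profiles_a, profiles_b, toy_ontology)
        row = df.set_index("term").loc["f"]
        assert row["odds_ratio"] == pytest.approx(16.0)
        assert row["p_adjusted"] >= row["p"]

    def test_unobserved_and_universal_terms_not_tested(self, toy_ontology):
        profiles_a = {"a1": {"e"}, "a2": {"c"}}
        profiles_b = {"b1": {"c"}, "b2": {"c"}}
        df = r.hpo_enrichment(profiles_a, profiles_b, toy_ontology)
        # "f" is observed nowhere; "root" would be universal after
        # propagation; only the annotated antichain terms are tested
        assert set(df["term"]) == {"c", "e"}


class TestPhenotypePCA:
    def test_single_varying_feature_explains_everything(self):
        matrix = [[0, 1, 1], [1, 1, 1], [0, 1, 1], [1, 1, 1]]
        res = r.phenotype_pca(matrix)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_duplicated_samples_get_identical_scores(self):
        matrix = [[0, 1, 0], [0, 1, 0], [1, 0, 1], [1, 0, 0]]
        res = r.phenotype_pca(matrix)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[1])

    def test_missing_coded_as_absent(self):
        import pandas as pd

        with_nan = pd.DataFrame([[np.nan, 1, 0], [1, 0, 1], [0, 1, 1]])
        explicit = pd.DataFrame([[0, 1, 0], [1, 0, 1], [0, 1, 1]])
        a = r.phenotype_pca(with_nan)
        b = r.phenotype_pca(explicit)
        assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            r.phenotype_pca([[1, 1], [1, 1], [1, 1]])
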