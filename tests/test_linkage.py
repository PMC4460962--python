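import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from modrep.linkage import (
    DrugDiseaseLink,
    export_network,
    hypergeom_overlap,
    link_drugs,
    rank_by_signature,
    rank_drugs,
)
from modrep.sensitivity import SensitivityModule


def _sm(drug, genes, compound=""):
    return SensitivityModule(drug=drug, compound=compound, genes=tuple(genes),
                             stats=None)


def draw_enumeration_oracle(M, N, m, n):
    """Exact tail probability by enumerating every m-subset of an M-universe
    containing N marked items (rational arithmetic)."""
    marked = set(range(N))
    hits = sum(
        1 for draw in itertools.combinations(range(M), m)
        if len(marked & set(draw)) >= n
    )
    return Fraction(hits, comb(M, m))


class TestHypergeomOverlap:
    def test_zero_overlap_full_tail(self):
        assert hypergeom_overlap(1000, 30, 50, 0) == 1.0

    def test_direct_combinatorial_values(self):
        assert hypergeom_overlap(10, 5, 5, 5) == pytest.approx(1 / 252)
        assert hypergeom_overlap(4, 2, 2, 1) == pytest.approx(5 / 6)

    def test_matches_draw_enumeration_small_universes(self):
        for M in range(1, 9):
            for N in range(M + 1):
                for m in range(M + 1):
                    for n in range(min(N, m) + 1):
                        exact = draw_enumeration_oracle(M, N, m, n)
                        assert hypergeom_overlap(M, N, m, n) == pytest.approx(
                            float(exact), abs=1e-12
                        ), (M, N, m, n)

    def test_complement_identity_large(self, rng):
        from scipy import stats

        for _ in range(500):
            M = int(rng.integers(2, 20001))
            N = int(rng.integers(0, M + 1))
            m = int(rng.integers(0, M + 1))
            n = int(rng.integers(0, min(N, m) + 1))
            upper = hypergeom_overlap(M, N, m, n)
            lower = stats.hypergeom.cdf(n - 1, M, N, m)
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("args", [(10, 11, 5, 0), (10, 5, 5, 6), (0, 0, 0, 0)])
    def test_invalid_inputs(self, args):
        with pytest.raises(ValueError):
            hypergeom_overlap(*args)


class TestLinkDrugs:
    def test_identical_sets_strongly_significant(self):
        genes = [f"G{i}" for i in range(10)]
        universe = [f"G{i}" for i in range(1000)]
        links = link_drugs({"mod": genes}, [_sm("d1", genes)], universe)
        (ln,) = links
        assert ln.overlap_n == 10
        assert ln.p < 1e-12
        assert ln.significant

    def test_disjoint_sets_p_one(self):
        universe = [f"G{i}" for i in range(100)]
        links = link_drugs({"mod": universe[:10]}, [_sm("d1", universe[50:60])],
                           universe)
        assert links[0].overlap_n == 0
        assert links[0].p == 1.0
        assert not links[0].significant

    def test_empty_sensitivity_module(self):
        universe = [f"G{i}" for i in range(100)]
        links = link_drugs({"mod": universe[:10]}, [_sm("d1", [])], universe)
        assert links[0].overlap_n == 0
        assert links[0].p == 1.0

    def test_empty_prognostic_selection_error(self):
        with pytest.raises(ValueError, match="empty prognostic"):
            link_drugs({}, [_sm("d1", ["G1"])], ["G1"])

    def test_sets_intersected_with_universe(self):
        universe = [f"G{i}" for i in range(50)]
        links = link_drugs({"mod": universe[:5] + ["ALIEN1"]},
                           [_sm("d1", universe[:5] + ["ALIEN2"])], universe)
        assert links[0].module_N == 5
        assert links[0].sens_m == 5
        assert links[0].overlap_n == 5


class TestRankDrugs:
    def _links(self, spec):
        """spec: drug -> (n_significant, best_p)"""
        links = []
        for drug, (k, best_p) in spec.items():
            for i in range(k):
                links.append(DrugDiseaseLink(
                    drug=drug, compound=f"c{drug}", module=f"m{i}", overlap_n=5,
                    module_N=10, sens_m=10, universe_M=100,
                    p=best_p if i == 0 else best_p * 2, significant=True))
            links.append(DrugDiseaseLink(
                drug=drug, compound=f"c{drug}", module="null", overlap_n=0,
                module_N=10, sens_m=10, universe_M=100, p=1.0, significant=False))
        return links

    def test_effect_score_from_published_ranking(self):
        # 18 significant links against 30 prognostic modules -> 18/15 = 1.2
        ranking = rank_drugs(self._links({"pac": (18, 1e-8)}), 30)
        row = ranking.rows.iloc[0]
        assert row["n_linked_modules"] == 18
        assert row["effect_score"] == pytest.approx(1.2)

    def test_zero_link_drug_ranked_last(self):
        ranking = rank_drugs(self._links({"a": (3, 1e-4), "z": (0, 1.0)}), 10)
        assert list(ranking.rows["drug"]) == ["a", "z"]
        assert ranking.rows.iloc[1]["effect_score"] == 0.0

    def test_tie_broken_by_best_p(self):
        ranking = rank_drugs(self._links({"x": (2, 1e-3), "y": (2, 1e-6)}), 10)
        assert list(ranking.rows["drug"]) == ["y", "x"]

    def test_invariant_to_link_order(self):
        links = self._links({"a": (2, 1e-3), "b": (5, 1e-5), "c": (5, 1e-2)})
        fwd = rank_drugs(links, 10).rows
        rev = rank_drugs(links[::-1], 10).rows
        assert list(fwd["drug"]) == list(rev["drug"])

    def test_full_linkage_scores_two(self):
        ranking = rank_drugs(self._links({"d": (12, 1e-9)}), 12)
        assert ranking.rows.iloc[0]["effect_score"] == pytest.approx(2.0)

    def test_no_modules_error(self):
        with pytest.raises(ValueError):
            rank_drugs(self._links({"a": (1, 0.01)}), 0)


class TestRankBySignature:
    def test_overlap_count_ordering(self):
        universe = [f"G{i}" for i in range(200)]
        sig = universe[:20]
        mods = [_sm("d1", sig[:5]), _sm("d2", sig[:2]), _sm("d3", sig[:7])]
        ranked = rank_by_signature(sig, mods, universe)
        assert list(ranked["drug"]) == ["d3", "d1", "d2"]
        assert list(ranked["n_overlap"]) == [7, 5, 2]

    def test_identical_module_ranks_first(self):
        universe = [f"G{i}" for i in range(100)]
        sig = universe[:10]
        mods = [_sm("noise", universe[50:55]), _sm("match", sig)]
        ranked = rank_by_signature(sig, mods, universe)
        assert ranked.iloc[0]["drug"] == "match"
        assert ranked.iloc[0]["p"] < 1e-10

    def test_disjoint_signature_all_p_one(self):
        universe = [f"G{i}" for i in range(100)]
        ranked = rank_by_signature(universe[:10], [_sm("d", universe[90:])],
                                   universe)
        assert (ranked["n_overlap"] == 0).all()
        assert (ranked["p"] == 1.0).all()

    def test_empty_signature_error(self):
        with pytest.raises(ValueError, match="empty signature"):
            rank_by_signature(["ALIEN"], [_sm("d", ["G1"])], ["G1", "G2"])


class TestExportNetwork:
    def _link(self, drug, module, significant, p=0.01):
        return DrugDiseaseLink(drug=drug, compound=f"name-{drug}", module=module,
                               overlap_n=3, module_N=10, sens_m=10,
                               universe_M=100, p=p, significant=significant)

    def test_significant_links_exported(self, tmp_path):
        path = tmp_path / "net.tsv"
        export_network([self._link("d1", "m1", True),
                        self._link("d2", "m1", False)], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("source\t")
        assert len(lines) == 2
        assert "name-d1" in lines[1]

    def test_empty_network_header_only(self, tmp_path):
        path = tmp_path / "net.tsv"
        export_network([], path)
        assert path.read_text().splitlines() == [
            "source\ttarget\tsource_type\ttarget_type\toverlap_n\tp"]

    def test_tab_in_name_quoted(self, tmp_path):
        path = tmp_path / "net.tsv"
        link = DrugDiseaseLink(drug="d1", compound="", module="mod\twith tab",
                               overlap_n=1, module_N=5, sens_m=5,
                               universe_M=50, p=0.001, significant=True)
        export_network([link], path)
        body = path.read_text().splitlines()[1]
        assert '"mod\twith tab"' in body
        import csv

        with open(path) as fh:
            rows = list(csv.reader(fh, delimiter="\t"))
        assert rows[1][1] == "mod\twith tab"
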