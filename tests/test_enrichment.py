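"""Fisher machinery, opposing enrichment and the overlap network."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from tximbalance import DegenerateDataError, ParameterError
from tximbalance import enrichment as enr
from tximbalance import synthdata as sd
from tximbalance.ioformats import GeneSetCollection


def gene_frame(lengths):
    lengths = np.asarray(lengths, dtype=float)
    return pd.DataFrame(
        {
            "transcript_length": lengths,
            "gene_length": lengths * 2,
            "cds_length": np.maximum(lengths / 2, 1),
            "gc_content": 0.5,
            "n_exons": 2,
        },
        index=pd.Index([f"g{i:03d}" for i in range(len(lengths))], name="gene_id"),
    )


class TestLengthExtremes:
    def test_distinct_lengths(self):
        genes = gene_frame(np.arange(1, 101) * 10)
        short, long_ = enr.length_extremes(genes, q=0.05)
        assert short == frozenset(genes.index[:5])
        assert long_ == frozenset(genes.index[-5:])

    def test_quarter_on_eight(self):
        genes = gene_frame([10, 20, 30, 40, 50, 60, 70, 80])
        short, long_ = enr.length_extremes(genes, q=0.25)
        assert len(short) == len(long_) == 2
        assert short == frozenset(["g000", "g001"])

    def test_ties_resolved_deterministically_exact_size(self):
        # all lengths tied across the 5% boundary
        genes = gene_frame([100] * 40 + [500] * 20 + [900] * 40)
        short, long_ = enr.length_extremes(genes, q=0.05)
        assert len(short) == len(long_) == 5
        again_short, again_long = enr.length_extremes(genes, q=0.05)
        assert short == again_short and long_ == again_long
        assert not short & long_

    def test_too_small_q(self):
        genes = gene_frame([10, 20, 30])
        with pytest.raises(ParameterError):
            enr.length_extremes(genes, q=0.05)


class TestFisher:
    def test_term_equals_background(self):
        bg = {f"g{i}" for i in range(40)}
        query = {f"g{i}" for i in range(10)}
        res = enr.fisher_enrichment(query, bg, bg)
        assert res.n_obs == 10
        assert res.e_exp == pytest.approx(10.0)
        assert res.fold == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_complete_depletion_sentinel(self):
        bg = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(80, 100)}
        res = enr.fisher_enrichment(query, term, bg)
        assert res.n_obs == 0 and res.e_exp == pytest.approx(4.0)
        assert res.fold == float("-inf") and res.direction == "depleted"
        table = enr.enrichment_table([res])
        assert table.loc[0, "fold"] == "complete_depletion"

    def test_disjoint_term_background_rejected(self):
        with pytest.raises(DegenerateDataError):
            enr.fisher_enrichment({"a"}, {"z"}, {"a", "b"})

    def test_brute_force_oracle_small_margins(self):
        """p equals enumeration from binomial coefficients for margins <= 12."""
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(300):
            r1 = int(rng.integers(1, 13))  # query size
            r2 = int(rng.integers(0, 13))  # rest of background
            N = r1 + r2
            T = int(rng.integers(1, N + 1))  # term size
            lo, hi = max(0, r1 + T - N), min(r1, T)
            a = int(rng.integers(lo, hi + 1))
            p_obs = (
                math.comb(T, a) * math.comb(N - T, r1 - a) / math.comb(N, r1)
            )
            p_expected = sum(
                math.comb(T, x) * math.comb(N - T, r1 - x) / math.comb(N, r1)
                for x in range(lo, hi + 1)
                if math.comb(T, x) * math.comb(N - T, r1 - x) / math.comb(N, r1)
                <= p_obs * (1 + 1e-7)
            )
            assert enr._fisher_two_sided(a, r1, T, N) == pytest.approx(
                min(1.0, p_expected), abs=1e-9
            )
            checked += 1
        assert checked == 300


class TestLongevity:
    def test_planted_directions(self):
        spec = sd.SyntheticSpec(n_genes=4000, seed=0)
        genes = sd.generate_gene_table(spec)
        coll = sd.plant_annotations(genes, spec)
        res = enr.longevity_enrichment(genes, coll)
        assert res[("short", "pro_longevity")].direction == "depleted"
        assert res[("long", "pro_longevity")].direction == "enriched"
        assert res[("short", "anti_longevity")].direction == "enriched"
        assert res[("long", "anti_longevity")].direction == "depleted"

    def test_background_mode_changes_expectation_per_formula(self):
        spec = sd.SyntheticSpec(n_genes=2000, seed=2)
        genes = sd.generate_gene_table(spec)
        coll = sd.plant_annotations(genes, spec)
        res_ann = enr.longevity_enrichment(genes, coll, background_mode="annotated_only")
        res_all = enr.longevity_enrichment(genes, coll, background_mode="all_genes")
        for key, r in res_all.items():
            assert r.e_exp == pytest.approx(r.n_query * r.n_term / r.n_background)
        # annotated-only background is smaller, so expectations differ
        key = ("short", "pro_longevity")
        assert res_ann[key].n_background <= res_all[key].n_background

    def test_random_labels_rarely_significant(self):
        hits = 0
        for seed in range(12):
            spec = sd.SyntheticSpec(
                n_genes=2000, seed=seed,
                annotations=sd.AnnotationSpec(
                    pro_longevity_bias=0.0, anti_longevity_bias=0.0
                ),
            )
            genes = sd.generate_gene_table(spec)
            coll = sd.plant_annotations(genes, spec)
            res = enr.longevity_enrichment(genes, coll)
            n_sig = sum(r.p < 0.05 for r in res.values())
            hits += n_sig <= 1
        assert hits >= 10


class TestOpposing:
    def _setup(self, seed=0, bias=0.0, n_genes=2000):
        spec = sd.SyntheticSpec(
            n_genes=n_genes, seed=seed,
            annotations=sd.AnnotationSpec(
                n_terms=80, term_size_min=15, term_size_max=60, length_bias=bias
            ),
        )
        genes = sd.generate_gene_table(spec)
        coll = sd.plant_annotations(genes, spec)
        bg = coll.annotated_genes() & frozenset(genes.index)
        short, long_ = enr.length_extremes(genes, q=0.05)
        return genes, coll, bg, short, long_

    def test_planted_short_biased_term_qualifies(self):
        genes, coll, bg, short, long_ = self._setup(seed=1, n_genes=4000)
        # plant one strongly short-biased term from background genes, large
        # enough that zero overlap with the long extreme is itself
        # BH-significant depletion (expected overlap ~ 10)
        ordered = [g for g in genes.sort_values("transcript_length").index if g in bg]
        mid = len(ordered) // 2
        members = ordered[:100] + ordered[mid : mid + 100]
        coll.add("planted", "planted short-biased term", members)
        hits = enr.opposing_enrichment(short, long_, coll, bg)
        assert "planted" in {t.term_id for t in hits}
        hit = next(t for t in hits if t.term_id == "planted")
        assert hit.enriched_in == "short"
        assert hit.long.direction == "depleted"

    def test_uniform_collection_produces_nothing(self):
        genes, coll, bg, short, long_ = self._setup(seed=2)
        assert enr.opposing_enrichment(short, long_, coll, bg) == []

    def test_swap_symmetry(self):
        genes, coll, bg, short, long_ = self._setup(seed=3, bias=0.8)
        fwd = enr.opposing_enrichment(short, long_, coll, bg)
        rev = enr.opposing_enrichment(long_, short, coll, bg)
        fwd_short = {t.term_id for t in fwd if t.enriched_in == "short"}
        rev_long = {t.term_id for t in rev if t.enriched_in == "long"}
        assert fwd_short == rev_long

    def test_randomization_fpr_reproducible(self):
        genes, coll, bg, short, long_ = self._setup(seed=4)
        a = enr.randomization_fpr(genes, coll, (len(short), len(long_)), n_rand=5, seed=1)
        b = enr.randomization_fpr(genes, coll, (len(short), len(long_)), n_rand=5, seed=1)
        assert (a.counts == b.counts).all()
        assert (a.counts >= 0).all()


class TestNetwork:
    def _collection(self, sets: dict[str, set[str]]) -> GeneSetCollection:
        coll = GeneSetCollection()
        for t, members in sets.items():
            coll.add(t, t, members)
        return coll

    def test_edges_match_brute_force(self):
        sets = {
            "A": {"g1", "g2", "g3"},
            "B": {"g3", "g4"},
            "C": {"g5"},
            "D": {"g1", "g4", "g6"},
            "E": {"g6", "g7"},
        }
        coll = self._collection(sets)
        universe = set().union(*sets.values())
        net = enr.build_annotation_network(list(sets), coll, universe)
        expected = {
            frozenset((u, v)): len(sets[u] & sets[v])
            for u, v in itertools.combinations(sets, 2)
            if sets[u] & sets[v]
        }
        got = {
            frozenset((u, v)): d["weight"] for u, v, d in net.graph.edges(data=True)
        }
        assert got == expected

    def test_two_disjoint_terms_no_edges(self):
        coll = self._collection({"A": {"g1"}, "B": {"g2"}})
        net = enr.build_annotation_network(["A", "B"], coll, {"g1", "g2"})
        assert net.graph.number_of_edges() == 0
        simplified = enr.simplify_network(net)
        assert simplified.kept_edges == frozenset()

    def test_two_nodes_one_edge(self):
        coll = self._collection({"A": {"g1", "g2"}, "B": {"g2"}})
        net = enr.build_annotation_network(["A", "B"], coll, {"g1", "g2"})
        simplified = enr.simplify_network(net)
        assert simplified.kept_edges == {frozenset(("A", "B"))}

    def test_star_graph_manual_trace(self):
        """C shares 3 genes with A and 1 with B; A and B are disjoint."""
        sets = {
            "A": {"g1", "g2", "g3", "g4"},
            "B": {"g5", "g6"},
            "C": {"g1", "g2", "g3", "g5"},
        }
        coll = self._collection(sets)
        net = enr.build_annotation_network(list(sets), coll, set().union(*sets.values()))
        simplified = enr.simplify_network(net)
        assert simplified.kept_edges == {
            frozenset(("A", "C")),
            frozenset(("B", "C")),
        }

    def test_rule2_tie_prefers_fewest_attached(self):
        """Equal intersections: keep the edge to the smaller neighbor."""
        sets = {
            "X": {"a", "b", "c"},
            "Y": {"a", "d"},
            "Z": {"b", "e", "f"},
        }
        coll = self._collection(sets)
        net = enr.build_annotation_network(list(sets), coll, set().union(*sets.values()))
        simplified = enr.simplify_network(net)
        # manual trace: Y->X, X->(tie w=1; |Y|=2 < |Z|=3)->Y, Z->X
        assert simplified.kept_edges == {
            frozenset(("X", "Y")),
            frozenset(("X", "Z")),
        }

    def test_rule3_tie_uses_universe_wide_counts(self):
        """Residual tie resolved by counts including out-of-analysis genes."""
        sets = {
            "X": {"a", "b"},
            "Y": {"a", "c", "w1", "o1", "o2"},  # 2 genes outside the universe
            "Z": {"b", "d", "w2"},
            "W": {"w1", "w2", "c", "d"},
        }
        universe = {"a", "b", "c", "d", "w1", "w2"}
        coll = self._collection(sets)
        net = enr.build_annotation_network(list(sets), coll, universe)
        assert net.graph.nodes["Y"]["n_analysis"] == 3
        assert net.graph.nodes["Y"]["n_total"] == 5
        simplified = enr.simplify_network(net)
        # manual trace: X ties Y/Z at w=1 and n_analysis=3 -> rule 3: |Z|=3 < |Y|=5
        # Y->W (w=2), Z->W (w=2), W ties Y/Z -> rule 3 -> Z
        assert simplified.kept_edges == {
            frozenset(("X", "Z")),
            frozenset(("Y", "W")),
            frozenset(("Z", "W")),
        }

    def test_idempotent_and_never_grows(self):
        spec = sd.SyntheticSpec(n_genes=500, seed=6)
        genes = sd.generate_gene_table(spec)
        coll = sd.plant_annotations(genes, spec)
        terms = coll.term_ids()[:12]
        net = enr.build_annotation_network(terms, coll, set(genes.index))
        once = enr.simplify_network(net)
        twice = enr.simplify_network(once)
        assert once.kept_edges == twice.kept_edges
        assert len(once.kept_edges) <= net.graph.number_of_edges()
        non_isolated = sum(1 for n in net.graph if net.graph.degree(n) > 0)
        assert len(once.kept_edges) <= non_isolated

    def test_write_network(self, tmp_path):
        coll = self._collection({"A": {"g1", "g2"}, "B": {"g2"}})
        net = enr.simplify_network(
            enr.build_annotation_network(["A", "B"], coll, {"g1", "g2"})
        )
        enr.write_network(net, tmp_path / "net")
        edges = pd.read_csv(tmp_path / "net.edges.tsv", sep="\t")
        assert edges.loc[0, "kept"]
        assert (tmp_path / "net.graphml").exists()
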