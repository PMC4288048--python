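"""Arrangement calling, the lux conservation law, and topology typing."""

import itertools
from functools import lru_cache

import numpy as np
import pytest

from luxcart import ProximityPolicy, call_arrangements, type_topology
from luxcart.circuit_classification import (
    CANONICAL_PAIR,
    DOUBLE,
    LUXI_SOLO,
    LUXR_SOLO,
    TopologyPattern,
    annotate_topologies,
    load_synonym_map,
    load_topology_catalog,
)
from luxcart.io_layer import LuxcartInputError

from conftest import make_gene

R, I, TRUNC = "AUTHENTIC_LUXR", "AUTHENTIC_LUXI", "LUXR_LIKE_INCOMPLETE"


def lay_out(roles_strands, contig="ctg1", gap=150, length=600, start=100, prefix="g"):
    """Place genes left to right; roles_strands = [(verdict or None, strand), ...]."""
    genes, verdicts = [], {}
    pos = start
    for idx, (verdict, strand) in enumerate(roles_strands):
        gid = f"{prefix}{idx}"
        genes.append(make_gene(gid, pos, pos + length - 1, strand, contig))
        verdicts[gid] = verdict or "NONE"
        pos += length + gap
    return genes, verdicts


def categories(calls):
    return sorted(c.category for c in calls)


class TestCallArrangements:
    def test_convergent_adjacent_pair_is_canonical(self):
        genes, verdicts = lay_out([(I, "+"), (R, "-")])
        (call,) = call_arrangements(genes, verdicts)
        assert call.category == CANONICAL_PAIR
        assert call.relations == ("convergent",)
        assert call.roles == ("luxI", "luxR")

    def test_lone_luxr_is_solo(self):
        genes, verdicts = lay_out([(None, "+"), (R, "+"), (None, "-")])
        (call,) = call_arrangements(genes, verdicts)
        assert call.category == LUXR_SOLO

    def test_partners_on_different_contigs_stay_solos(self):
        g1, v1 = lay_out([(I, "+")], contig="ctgA", prefix="a")
        g2, v2 = lay_out([(R, "+")], contig="ctgB", prefix="b")
        calls = call_arrangements(g1 + g2, {**v1, **v2})
        assert categories(calls) == [LUXI_SOLO, LUXR_SOLO]

    def test_tandem_luxr_pair_with_luxi_is_double(self):
        genes, verdicts = lay_out([(R, "+"), (R, "+"), (I, "-")])
        (call,) = call_arrangements(genes, verdicts)
        assert call.category == DOUBLE
        assert call.relations == ("tandem", "convergent")

    def test_luxi_with_adjacent_truncated_luxr_is_flagged_solo(self):
        genes, verdicts = lay_out([(TRUNC, "+"), (I, "-")])
        (call,) = call_arrangements(genes, verdicts)
        assert call.category == LUXI_SOLO
        assert call.adjacent_truncated_luxR

    def test_luxr_four_genes_from_a_pair_stays_solo(self):
        # a distant luxR beyond the intervening-gene limit keeps solo status
        genes, verdicts = lay_out(
            [(I, "+"), (R, "-")]
            + [(None, "+")] * 4
            + [(R, "+")]
        )
        calls = call_arrangements(genes, verdicts)
        assert categories(calls) == [CANONICAL_PAIR, LUXR_SOLO]

    def test_gap_limit_blocks_distant_pairing(self):
        genes, verdicts = lay_out([(I, "+"), (R, "-")], gap=6000)
        calls = call_arrangements(genes, verdicts)
        assert categories(calls) == [LUXI_SOLO, LUXR_SOLO]

    def test_upstream_intergenic_distance_reported_for_luxi_solo(self):
        genes = [
            make_gene("gUp", 100, 700, "+"),
            make_gene("gI", 2700, 3300, "+"),
        ]
        (call,) = call_arrangements(genes, {"gUp": "NONE", "gI": I})
        assert call.category == LUXI_SOLO
        assert call.upstream_intergenic_bp == 2700 - 700 - 1

    def test_unknown_gene_in_verdicts_rejected(self):
        genes, verdicts = lay_out([(R, "+")])
        verdicts["ghost"] = R
        with pytest.raises(LuxcartInputError, match="ghost"):
            call_arrangements(genes, verdicts)

    def test_input_order_does_not_matter(self):
        genes, verdicts = lay_out([(R, "+"), (R, "+"), (I, "-"), (None, "+"), (I, "+")])
        ref = call_arrangements(genes, verdicts)
        for perm in itertools.islice(itertools.permutations(genes), 0, 24, 5):
            assert call_arrangements(list(perm), verdicts) == ref


# ---------------------------------------------------------------------------
# randomized properties


def random_instance(rng):
    n = int(rng.integers(4, 9))
    genes, verdicts = [], {}
    pos = 100
    for idx in range(n):
        length = int(rng.integers(300, 900))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{idx}"
        genes.append(make_gene(gid, pos, pos + length - 1, strand))
        u = rng.random()
        verdicts[gid] = R if u < 0.3 else I if u < 0.6 else "NONE"
        pos += length + int(rng.integers(50, 3000))
    return genes, verdicts


def oracle_best_counts(genes, verdicts, policy):
    """Exhaustive lexicographic maximization of (doubles, pairs)."""
    order = sorted(genes, key=lambda g: g.start)
    index = {g.gene_id: i for i, g in enumerate(order)}

    def within(a, b):
        inter = abs(index[a.gene_id] - index[b.gene_id]) - 1
        first, second = (a, b) if a.start <= b.start else (b, a)
        gap = max(0, second.start - first.end - 1)
        return inter <= policy.max_intervening_genes and gap <= policy.max_gap_bp

    rs = [g for g in order if verdicts[g.gene_id] == R]
    is_ = [g for g in order if verdicts[g.gene_id] == I]
    trios = [
        (a, b, x)
        for a, b in itertools.combinations(rs, 2)
        if a.strand == b.strand and within(a, b)
        for x in is_
        if within(a, x) or within(b, x)
    ]
    pairs = [(r, x) for r in rs for x in is_ if within(r, x)]

    @lru_cache(maxsize=None)
    def best(used: frozenset):
        result = (0, 0)
        for a, b, x in trios:
            ids = {a.gene_id, b.gene_id, x.gene_id}
            if ids & used:
                continue
            d, p = best(used | ids)
            result = max(result, (d + 1, p))
        for r, x in pairs:
            ids = {r.gene_id, x.gene_id}
            if ids & used:
                continue
            d, p = best(used | ids)
            result = max(result, (d, p + 1))
        return result

    return best(frozenset())


def reverse_contig(genes):
    total = max(g.end for g in genes) + 100
    return [
        make_gene(
            g.gene_id,
            total - g.end + 1,
            total - g.start + 1,
            "+" if g.strand == "-" else "-",
            g.contig_id,
        )
        for g in genes
    ]


class TestProperties:
    def test_matches_exhaustive_search_on_small_instances(self):
        policy = ProximityPolicy()
        rng = np.random.default_rng(7)
        for _ in range(120):
            genes, verdicts = random_instance(rng)
            calls = call_arrangements(genes, verdicts, policy)
            got = (
                sum(c.category == DOUBLE for c in calls),
                sum(c.category == CANONICAL_PAIR for c in calls),
            )
            assert got == oracle_best_counts(genes, verdicts, policy)

    def test_conservation_law_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            genes, verdicts = random_instance(rng)
            calls = call_arrangements(genes, verdicts)
            n_r = sum(v == R for v in verdicts.values())
            n_i = sum(v == I for v in verdicts.values())
            d = sum(c.category == DOUBLE for c in calls)
            p = sum(c.category == CANONICAL_PAIR for c in calls)
            assert n_r == 2 * d + p + sum(c.category == LUXR_SOLO for c in calls)
            assert n_i == d + p + sum(c.category == LUXI_SOLO for c in calls)

    def test_contig_reversal_preserves_category_multiset(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            genes, verdicts = random_instance(rng)
            fwd = categories(call_arrangements(genes, verdicts))
            rev = categories(call_arrangements(reverse_contig(genes), verdicts))
            assert fwd == rev


# ---------------------------------------------------------------------------
# topology typing


def double_with_neighborhood(products):
    roles = [(R, "+"), (R, "+"), (I, "-")] + [(None, "-")] * len(products)
    genes, verdicts = lay_out(roles)
    for gene, product in zip(genes[3:], products):
        genes[genes.index(gene)] = make_gene(
            gene.gene_id, gene.start, gene.end, gene.strand, product=product
        )
    calls = call_arrangements(genes, verdicts)
    (double,) = [c for c in calls if c.category == DOUBLE]
    return double, genes


class TestTypeTopology:
    def test_full_topology_T_matches(self):
        call, genes = double_with_neighborhood(
            ["phytanoyl dioxygenase", "hypothetical protein", "virB1", "virB2", "virB3"]
        )
        assert type_topology(call, genes) == "T"

    def test_unrelated_neighborhood_untyped(self):
        call, genes = double_with_neighborhood(["unrelated", "unrelated"])
        assert type_topology(call, genes) == "UNTYPED"

    def test_non_double_returns_na(self):
        genes, verdicts = lay_out([(I, "+"), (R, "-")])
        (call,) = call_arrangements(genes, verdicts)
        assert type_topology(call, genes) == "N/A"

    def test_custom_catalog_pattern(self):
        catalog = [TopologyPattern("custom1", ("metB", "lcmT"))]
        call, genes = double_with_neighborhood(
            ["cystathionine gamma-synthase", "isoprenylcysteine carboxyl methyltransferase"]
        )
        assert type_topology(call, genes, catalog=catalog) == "custom1"

    def test_longest_pattern_wins(self):
        catalog = [
            TopologyPattern("short", ("phyH",)),
            TopologyPattern("long", ("phyH", "X")),
        ]
        call, genes = double_with_neighborhood(
            ["phytanoyl dioxygenase", "hypothetical protein"]
        )
        assert type_topology(call, genes, catalog=catalog) == "long"

    def test_annotate_topologies_fills_doubles_only(self):
        call, genes = double_with_neighborhood(
            ["phytanoyl dioxygenase", "hypothetical protein", "virB1", "virB2", "virB3"]
        )
        (annotated,) = annotate_topologies([call], genes)
        assert annotated.topology_label == "T"

    def test_packaged_catalog_and_synonyms_load(self):
        catalog = load_topology_catalog()
        assert [p.label for p in catalog] == ["T"]
        synonyms = load_synonym_map()
        assert "phytanoyl dioxygenase" in synonyms["phyH"]
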