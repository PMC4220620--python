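"""Formal Concept Analysis: derivation, lattice, measures, filtering, export."""

from __future__ import annotations

import numpy as np
import pytest

from trajmine.fca import (
    FormalConcept,
    FormalContext,
    build_lattice,
    derive_attributes,
    derive_objects,
    export_lattice,
    filter_concepts,
    lattice_from_json,
    lattice_to_dot,
    lattice_to_json,
    own_objects,
    own_proportion,
    support,
)

from conftest import TABLE1_CONCEPTS, brute_force_concepts, random_context


def as_pairs(lattice):
    return {(frozenset(c.extent), frozenset(c.intent)) for c in lattice}


class TestDerivation:
    def test_shared_attributes_of_object_pair(self, table1_ctx):
        assert set(derive_attributes(table1_ctx, [3, 8])) == {"b", "d"}

    def test_empty_object_set_derives_all_attributes(self, table1_ctx):
        assert set(derive_attributes(table1_ctx, [])) == {"a", "b", "c", "d"}

    def test_objects_with_nothing_in_common(self, table1_ctx):
        assert derive_attributes(table1_ctx, [1, 2]) == ()

    def test_objects_of_attribute(self, table1_ctx):
        assert set(derive_objects(table1_ctx, ["c"])) == {2, 4, 6, 7}

    def test_empty_attribute_set_derives_all_objects(self, table1_ctx):
        assert set(derive_objects(table1_ctx, [])) == set(range(1, 9))

    def test_incompatible_attributes_give_empty_extent(self, table1_ctx):
        assert derive_objects(table1_ctx, ["a", "d"]) == ()

    def test_unknown_object_or_attribute_is_error(self, table1_ctx):
        with pytest.raises(ValueError):
            derive_attributes(table1_ctx, [99])
        with pytest.raises(ValueError):
            derive_objects(table1_ctx, ["z"])


class TestWorkedExampleLattice:
    def test_exactly_the_eight_concepts(self, table1_ctx):
        assert as_pairs(build_lattice(table1_ctx)) == TABLE1_CONCEPTS

    def test_intent_c_concept(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        c = lattice.find_by_intent(["c"])
        assert set(c.extent) == {2, 4, 6, 7}
        assert support(c) == 4
        assert own_objects(table1_ctx, c) == (7,)
        assert own_proportion(table1_ctx, c) == pytest.approx(0.25)

    def test_intent_b_concept_has_no_own_object(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        c = lattice.find_by_intent(["b"])
        assert set(c.extent) == {2, 3, 4, 6, 8}
        assert own_objects(table1_ctx, c) == ()
        assert own_proportion(table1_ctx, c) == 0.0

    def test_top_and_bottom(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        assert support(lattice.top) == 8
        assert lattice.top.intent == ()
        assert lattice.bottom.extent == ()
        assert support(lattice.bottom) == 0

    def test_cover_edges_are_transitive_reduction(self, table1_ctx):
        """Line-diagram edges must match networkx's transitive reduction."""
        import networkx as nx

        lattice = build_lattice(table1_ctx)
        order = nx.DiGraph()
        order.add_nodes_from(range(len(lattice.concepts)))
        for i, ci in enumerate(lattice.concepts):
            for j, cj in enumerate(lattice.concepts):
                if i != j and set(ci.extent) < set(cj.extent):
                    order.add_edge(i, j)
        expected = set(nx.transitive_reduction(order).edges())
        assert set(lattice.cover_edges) == expected


class TestDegenerateContexts:
    def test_single_object_single_attribute_full_incidence(self):
        ctx = FormalContext(["g"], ["m"], [("g", "m")])
        lattice = build_lattice(ctx)
        assert len(lattice) == 1
        assert lattice.top == lattice.bottom == FormalConcept(("g",), ("m",))

    def test_empty_incidence(self):
        ctx = FormalContext(["g1", "g2"], ["m1", "m2"], [])
        assert as_pairs(build_lattice(ctx)) == {
            (frozenset({"g1", "g2"}), frozenset()),
            (frozenset(), frozenset({"m1", "m2"})),
        }

    def test_no_objects(self):
        ctx = FormalContext([], ["m1"], [])
        lattice = build_lattice(ctx)
        assert len(lattice) == 1
        assert lattice.top.intent == ("m1",)

    def test_no_attributes(self):
        ctx = FormalContext(["g1"], [], [])
        assert len(build_lattice(ctx)) == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            FormalContext(["g", "g"], ["m"], [])
        with pytest.raises(ValueError):
            FormalContext(["g"], ["m", "m"], [])


class TestOracleEquivalence:
    """Close-by-One against exhaustive closure of all attribute subsets."""

    def test_matches_brute_force_on_random_contexts(self):
        rng = np.random.default_rng(0)
        for k in range(200):
            density = 0.1 + 0.8 * (k % 9) / 8
            ctx = random_context(
                rng, int(rng.integers(1, 11)), int(rng.integers(1, 9)), density
            )
            assert as_pairs(build_lattice(ctx)) == brute_force_concepts(ctx)

    def test_galois_properties_on_sampled_subsets(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            ctx = random_context(rng, 8, 6, float(rng.uniform(0.1, 0.9)))
            objs, attrs = ctx.objects, ctx.attributes
            for _ in range(5):
                X1 = {g for g in objs if rng.random() < 0.4}
                X2 = X1 | {g for g in objs if rng.random() < 0.3}
                # extensivity of closure: X ⊆ X''
                closure = set(derive_objects(ctx, derive_attributes(ctx, X1)))
                assert X1 <= closure
                # antitonicity: X1 ⊆ X2 ⇒ X2' ⊆ X1'
                assert set(derive_attributes(ctx, X2)) <= set(
                    derive_attributes(ctx, X1)
                )
                # idempotence: X' = X'''
                once = derive_attributes(ctx, X1)
                thrice = derive_attributes(
                    ctx, derive_objects(ctx, derive_attributes(ctx, X1))
                )
                assert set(once) == set(thrice)
                # dual properties on attributes
                Y1 = {m for m in attrs if rng.random() < 0.4}
                Y2 = Y1 | {m for m in attrs if rng.random() < 0.3}
                y_closure = set(derive_attributes(ctx, derive_objects(ctx, Y1)))
                assert Y1 <= y_closure
                assert set(derive_objects(ctx, Y2)) <= set(derive_objects(ctx, Y1))

    def test_concept_count_invariant_under_permutation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            ctx = random_context(rng, 7, 6, float(rng.uniform(0.2, 0.8)))
            pairs = [
                (g, m)
                for g in ctx.objects
                for m in ctx.attributes
                if ctx.obj_intents[ctx.objects.index(g)]
                >> ctx.attributes.index(m)
                & 1
            ]
            perm_objects = list(rng.permutation(ctx.objects))
            perm_attrs = [str(a) for a in rng.permutation(ctx.attributes)]
            permuted = FormalContext(perm_objects, perm_attrs, pairs)
            assert len(build_lattice(permuted)) == len(build_lattice(ctx))


class TestOwnObjectPartition:
    def test_every_object_owned_by_exactly_one_concept(self):
        """g is an own object precisely of the concept ({g}'', {g}')."""
        rng = np.random.default_rng(3)
        for _ in range(60):
            ctx = random_context(
                rng, int(rng.integers(1, 11)), int(rng.integers(1, 9)),
                float(rng.uniform(0.1, 0.9)),
            )
            lattice = build_lattice(ctx)
            counts = {g: 0 for g in ctx.objects}
            total_own = 0
            for c in lattice:
                own = own_objects(ctx, c)
                total_own += len(own)
                for g in own:
                    counts[g] += 1
            assert all(v == 1 for v in counts.values())
            assert total_own == len(ctx.objects)

    def test_antitone_extent_intent_sizes(self):
        rng = np.random.default_rng(4)
        ctx = random_context(rng, 9, 7, 0.5)
        lattice = build_lattice(ctx)
        for i, j in lattice.cover_edges:
            sub, sup = lattice.concepts[i], lattice.concepts[j]
            assert set(sub.extent) < set(sup.extent)
            assert set(sup.intent) < set(sub.intent)


class TestFiltering:
    def test_worked_example_thresholds(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        kept = filter_concepts(lattice, table1_ctx, min_support=2, min_own_prop=0.3)
        expected = {
            (frozenset({1, 2, 3, 4, 5, 6, 7, 8}), frozenset()),  # top kept
            (frozenset({1, 5, 6}), frozenset({"a"})),
            (frozenset({2, 4, 6}), frozenset({"b", "c"})),
            (frozenset({3, 8}), frozenset({"b", "d"})),
        }
        assert {(frozenset(c.extent), frozenset(c.intent)) for c in kept} == expected

    def test_no_op_filter_keeps_everything(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        assert len(filter_concepts(lattice, min_support=0, min_own_prop=0.0)) == 8

    def test_unreachable_support_leaves_only_top(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        assert filter_concepts(lattice, min_support=99) == [lattice.top]
        assert filter_concepts(lattice, min_support=99, keep_top=False) == []

    def test_output_sorted_by_support_descending(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        kept = filter_concepts(lattice, min_support=0, min_own_prop=0.0)
        supports = [support(c) for c in kept]
        assert supports == sorted(supports, reverse=True)


class TestExport:
    def test_json_round_trip(self, table1_ctx, tmp_path):
        lattice = build_lattice(table1_ctx)
        restored = lattice_from_json(lattice_to_json(lattice))
        assert as_pairs(restored) == as_pairs(lattice)
        assert set(restored.cover_edges) == set(lattice.cover_edges)
        # the reconstructed context supports the same measures
        c = restored.find_by_intent(["c"])
        assert own_objects(restored.context, c) == (7,)

    def test_dot_has_all_nodes_and_cover_edges(self, table1_ctx):
        lattice = build_lattice(table1_ctx)
        dot = lattice_to_dot(lattice)
        assert dot.count("[label=") == 8
        assert dot.count("->") == len(lattice.cover_edges)

    def test_unknown_format_is_error(self, table1_ctx, tmp_path):
        lattice = build_lattice(table1_ctx)
        with pytest.raises(ValueError):
            export_lattice(lattice, tmp_path / "x", format="xml")

    def test_export_files(self, table1_ctx, tmp_path):
        lattice = build_lattice(table1_ctx)
        export_lattice(lattice, tmp_path / "l.json", "json")
        export_lattice(lattice, tmp_path / "l.dot", "dot")
        restored = lattice_from_json((tmp_path / "l.json").read_text())
        assert len(restored) == 8
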