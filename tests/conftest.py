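"""Shared fixtures: the worked-example context, stay factories, oracles."""

from __future__ import annotations

from datetime import date
from itertools import combinations

import pytest

from trajmine.claims_io import StayRecord
from trajmine.fca import FormalContext, derive_attributes, derive_objects

#: the 8-object / 4-attribute incidence of the worked example
TABLE1 = {
    1: ["a"],
    2: ["b", "c"],
    3: ["b", "d"],
    4: ["b", "c"],
    5: ["a"],
    6: ["a", "b", "c"],
    7: ["c"],
    8: ["b", "d"],
}

#: all 8 concepts of that context, computed by the brute-force oracle below
TABLE1_CONCEPTS = {
    (frozenset({1, 2, 3, 4, 5, 6, 7, 8}), frozenset()),
    (frozenset({1, 5, 6}), frozenset({"a"})),
    (frozenset({2, 3, 4, 6, 8}), frozenset({"b"})),
    (frozenset({2, 4, 6, 7}), frozenset({"c"})),
    (frozenset({2, 4, 6}), frozenset({"b", "c"})),
    (frozenset({3, 8}), frozenset({"b", "d"})),
    (frozenset({6}), frozenset({"a", "b", "c"})),
    (frozenset(), frozenset({"a", "b", "c", "d"})),
}


@pytest.fixture
def table1_ctx() -> FormalContext:
    return FormalContext.from_dict(TABLE1)


def brute_force_concepts(ctx: FormalContext) -> set[tuple[frozenset, frozenset]]:
    """Independent lattice oracle: close every attribute subset.

    Enumerates all 2^|M| attribute subsets, derives each subset's extent
    and closes it back; the distinct (extent, closure) pairs are exactly
    the formal concepts. Exponential — test-scale contexts only.
    """
    concepts = set()
    for r in range(len(ctx.attributes) + 1):
        for Y in combinations(ctx.attributes, r):
            extent = derive_objects(ctx, Y)
            intent = derive_attributes(ctx, extent)
            concepts.add((frozenset(extent), frozenset(intent)))
    return concepts


def random_context(rng, n_objects: int, n_attributes: int, density: float) -> FormalContext:
    objects = list(range(n_objects))
    attributes = [f"m{j}" for j in range(n_attributes)]
    pairs = [
        (g, m) for g in objects for m in attributes if rng.random() < density
    ]
    return FormalContext(objects, attributes, pairs)


@pytest.fixture
def make_stay():
    """Factory for StayRecord with sensible defaults, overridable per field."""

    counter = {"n": 0}

    def _make(**overrides) -> StayRecord:
        counter["n"] += 1
        fields = dict(
            patient_id="P1",
            hospital_id="H001",
            stay_index=f"S{counter['n']:04d}",
            age=56,
            gender="F",
            admission_date=date(2009, 3, 10),
            stay_duration=3,
            discharge_status="home",
            principal_dx="C504",
            cost=1000.0,
        )
        fields.update(overrides)
        return StayRecord(**fields)

    return _make
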