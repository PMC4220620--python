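"""Formal Concept Analysis: contexts, derivation, lattice construction, filtering.

A formal context is a triple (G, M, I) of objects, attributes and a binary
incidence relation; here objects are patients and attributes are coarsened
diagnosis codes. The two derivation operators

    X' = {m in M | every g in X has m}      for X a set of objects
    Y' = {g in G | g has every m in Y}      for Y a set of attributes

form a Galois connection, and a formal concept is a pair (A, B) with
A' = B and B' = A: a maximal rectangle of the incidence table. The set of
all concepts ordered by extent inclusion is a complete lattice. Each
concept intent reads as a morbidity profile — a set of diagnosis codes
co-occurring in the trajectories of all patients of the extent.

Two interest measures tame the lattice: the *support* of a concept is the
size of its extent, and its *own objects* are the extent members whose full
attribute set equals the intent exactly. A low own-object proportion marks
a concept whose members mostly carry more specific descriptions (a symptom
of noise); filtering on support and own-object proportion keeps the
frequent, cohesive profiles.

Concepts are enumerated with Close-by-One over attribute closures, with
extents held as integer bitmasks over the object list; a brute-force
powerset enumeration would be intractable at realistic attribute counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class FormalContext:
    """Binary incidence between an ordered object list and attribute list.

    Parameters
    ----------
    objects : ordered unique object identifiers
    attributes : ordered unique attribute labels
    incidence : iterable of (object, attribute) pairs
    """

    def __init__(
        self,
        objects: Sequence,
        attributes: Sequence[str],
        incidence: Iterable[tuple],
    ) -> None:
        self.objects = list(objects)
        self.attributes = list(attributes)
        if len(set(self.objects)) != len(self.objects):
            raise ValueError("duplicate object ids in context")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("duplicate attribute labels in context")
        self._obj_index = {g: i for i, g in enumerate(self.objects)}
        self._attr_index = {m: j for j, m in enumerate(self.attributes)}
        # column masks: bit i of attr_extents[j] set iff object i has attribute j
        self.attr_extents = [0] * len(self.attributes)
        self.obj_intents = [0] * len(self.objects)
        for g, m in incidence:
            i = self._obj_index.get(g)
            j = self._attr_index.get(m)
            if i is None:
                raise ValueError(f"unknown object in incidence: {g!r}")
            if j is None:
                raise ValueError(f"unknown attribute in incidence: {m!r}")
            self.attr_extents[j] |= 1 << i
            self.obj_intents[i] |= 1 << j

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dict(cls, description: dict) -> "FormalContext":
        """Build from a mapping object -> iterable of attributes."""
        objects = list(description)
        attributes = sorted({m for attrs in description.values() for m in attrs})
        pairs = [(g, m) for g, attrs in description.items() for m in attrs]
        return cls(objects, attributes, pairs)

    @classmethod
    def from_pairs_csv(cls, path, delimiter: str = ",") -> "FormalContext":
        """Read a sparse two-column (object_id, attribute) file."""
        import csv

        objects: list = []
        seen = set()
        pairs = []
        with open(path, newline="", encoding="utf-8") as handle:
            reader = csv.reader(handle, delimiter=delimiter)
            header = next(reader, None)
            if header and header[:2] != ["object_id", "attribute"]:
                # no header: treat the first line as data
                pairs.append((header[0], header[1]))
                if header[0] not in seen:
                    seen.add(header[0])
                    objects.append(header[0])
            for row in reader:
                if not row:
                    continue
                g, m = row[0], row[1]
                pairs.append((g, m))
                if g not in seen:
                    seen.add(g)
                    objects.append(g)
        attributes = sorted({m for _, m in pairs})
        return cls(objects, attributes, set(pairs))

    # -- bitmask helpers ---------------------------------------------------

    @property
    def full_extent_mask(self) -> int:
        return (1 << len(self.objects)) - 1

    @property
    def full_intent_mask(self) -> int:
        return (1 << len(self.attributes)) - 1

    def objects_to_mask(self, X: Iterable) -> int:
        mask = 0
        for g in X:
            try:
                mask |= 1 << self._obj_index[g]
            except KeyError:
                raise ValueError(f"object not in context: {g!r}") from None
        return mask

    def attributes_to_mask(self, Y: Iterable[str]) -> int:
        mask = 0
        for m in Y:
            try:
                mask |= 1 << self._attr_index[m]
            except KeyError:
                raise ValueError(f"attribute not in context: {m!r}") from None
        return mask

    def mask_to_objects(self, mask: int) -> tuple:
        return tuple(g for i, g in enumerate(self.objects) if mask >> i & 1)

    def mask_to_attributes(self, mask: int) -> tuple[str, ...]:
        return tuple(m for j, m in enumerate(self.attributes) if mask >> j & 1)

    def extent_prime(self, extent_mask: int) -> int:
        """Attributes common to all objects of the mask (M when empty)."""
        intent = self.full_intent_mask
        rest = extent_mask
        while rest:
            low = rest & -rest
            intent &= self.obj_intents[low.bit_length() - 1]
            rest ^= low
        return intent

    def intent_prime(self, intent_mask: int) -> int:
        """Objects having every attribute of the mask (G when empty)."""
        extent = self.full_extent_mask
        rest = intent_mask
        while rest:
            low = rest & -rest
            extent &= self.attr_extents[low.bit_length() - 1]
            rest ^= low
        return extent


@dataclass(frozen=True)
class FormalConcept:
    """An (extent, intent) pair closed under the derivation operators."""

    extent: tuple
    intent: tuple[str, ...]

    def __str__(self) -> str:
        ext = "{" + ",".join(map(str, self.extent)) + "}"
        int_ = "{" + ",".join(self.intent) + "}" if self.intent else "∅"
        return f"({ext}, {int_})"


@dataclass
class ConceptLattice:
    """All formal concepts of a context with their subconcept order."""

    context: FormalContext
    concepts: list[FormalConcept]
    cover_edges: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    @property
    def top(self) -> FormalConcept:
        """Concept with the largest extent (all objects)."""
        return self.concepts[-1]

    @property
    def bottom(self) -> FormalConcept:
        """Concept with the smallest extent."""
        return self.concepts[0]

    def leq(self, c1: FormalConcept, c2: FormalConcept) -> bool:
        """Subconcept order: extent inclusion."""
        m1 = self.context.objects_to_mask(c1.extent)
        m2 = self.context.objects_to_mask(c2.extent)
        return m1 & m2 == m1

    def find_by_intent(self, intent: Iterable[str]) -> FormalConcept | None:
        key = frozenset(intent)
        for c in self.concepts:
            if frozenset(c.intent) == key:
                return c
        return None


# -- derivation operators (public API) ------------------------------------


def derive_attributes(ctx: FormalContext, X: Iterable) -> tuple[str, ...]:
    """X' — attributes shared by all objects of X (all of M when X is empty)."""
    return ctx.mask_to_attributes(ctx.extent_prime(ctx.objects_to_mask(X)))


def derive_objects(ctx: FormalContext, Y: Iterable[str]) -> tuple:
    """Y' — objects having every attribute of Y (all of G when Y is empty)."""
    return ctx.mask_to_objects(ctx.intent_prime(ctx.attributes_to_mask(Y)))


# -- lattice construction --------------------------------------------------


def _enumerate_concepts(ctx: FormalContext) -> list[tuple[int, int]]:
    """Close-by-One over attributes: all (extent_mask, intent_mask) pairs.

    The canonicity test guarantees each closed intent is produced exactly
    once: a closure extending the current intent with an attribute below
    the current branching attribute has been (or will be) generated on
    another branch and is skipped.
    """
    n_attr = len(ctx.attributes)
    out: list[tuple[int, int]] = []

    def closure_of_extent(extent: int) -> int:
        return ctx.extent_prime(extent)

    def recurse(extent: int, intent: int, start: int) -> None:
        out.append((extent, intent))
        for j in range(start, n_attr):
            if intent >> j & 1:
                continue
            new_extent = extent & ctx.attr_extents[j]
            new_intent = closure_of_extent(new_extent)
            # canonicity: no attribute below j may be newly acquired
            if new_intent & ~intent & ((1 << j) - 1):
                continue
            recurse(new_extent, new_intent, j + 1)

    top_extent = ctx.full_extent_mask
    recurse(top_extent, closure_of_extent(top_extent), 0)
    return out


def _extent_sort_key(ctx: FormalContext, extent_mask: int):
    members = tuple(i for i in range(len(ctx.objects)) if extent_mask >> i & 1)
    return (bin(extent_mask).count("1"), members)


def build_lattice(ctx: FormalContext) -> ConceptLattice:
    """Enumerate all formal concepts and the cover edges of their order.

    Concepts are listed by extent size ascending (ties by position of the
    extent members in the context's object order), so the bottom concept
    comes first and the top concept last. Cover edges (i, j) link concept
    i to an immediate superconcept j (the transitive reduction of extent
    inclusion).
    """
    pairs = _enumerate_concepts(ctx)
    pairs.sort(key=lambda p: _extent_sort_key(ctx, p[0]))
    concepts = [
        FormalConcept(ctx.mask_to_objects(ext), ctx.mask_to_attributes(int_))
        for ext, int_ in pairs
    ]
    masks = [ext for ext, _ in pairs]
    sizes = [bin(m).count("1") for m in masks]
    edges: list[tuple[int, int]] = []
    for i, mi in enumerate(masks):
        # upper covers of i: minimal strict supersets
        covers: list[int] = []
        for j in range(i + 1, len(masks)):
            mj = masks[j]
            if sizes[j] <= sizes[i] or mi & mj != mi or mi == mj:
                continue
            if any(masks[k] & mj == masks[k] for k in covers):
                continue
            covers.append(j)
        edges.extend((i, j) for j in covers)
    return ConceptLattice(ctx, concepts, edges)


# -- interest measures -----------------------------------------------------


def support(c: FormalConcept) -> int:
    """Number of objects in the extent."""
    return len(c.extent)


def own_objects(ctx: FormalContext, c: FormalConcept) -> tuple:
    """Extent members whose full attribute set equals the intent exactly."""
    intent_mask = ctx.attributes_to_mask(c.intent)
    return tuple(
        g for g in c.extent if ctx.obj_intents[ctx._obj_index[g]] == intent_mask
    )


def own_proportion(ctx: FormalContext, c: FormalConcept) -> float:
    """|own objects| / support, 0.0 for an empty extent."""
    n = support(c)
    if n == 0:
        return 0.0
    return len(own_objects(ctx, c)) / n


def filter_concepts(
    lattice: ConceptLattice,
    ctx: FormalContext | None = None,
    min_support: int = 0,
    min_own_prop: float = 0.0,
    keep_top: bool = True,
) -> list[FormalConcept]:
    """Keep frequent, cohesive concepts: support and own-object proportion
    above thresholds.

    With ``keep_top`` the top concept (empty-intent profile, the whole
    cohort) is always retained as a baseline even though its own-object
    proportion is typically 0. Output is ordered by support descending,
    ties by intent.
    """
    ctx = ctx or lattice.context
    if min_support < 0 or min_own_prop < 0:
        raise ValueError("thresholds must be >= 0")
    top = lattice.top
    kept = [
        c
        for c in lattice.concepts
        if support(c) >= min_support and own_proportion(ctx, c) >= min_own_prop
    ]
    if keep_top and top not in kept:
        kept.append(top)
    kept.sort(key=lambda c: (-support(c), c.intent))
    return kept


# -- export / import -------------------------------------------------------


def lattice_to_json(lattice: ConceptLattice) -> str:
    ctx = lattice.context
    payload = {
        "objects": list(ctx.objects),
        "attributes": list(ctx.attributes),
        "concepts": [
            {
                "extent": list(c.extent),
                "intent": list(c.intent),
                "support": support(c),
                "own_objects": list(own_objects(ctx, c)),
            }
            for c in lattice.concepts
        ],
        "cover_edges": [list(e) for e in lattice.cover_edges],
    }
    return json.dumps(payload, indent=1)


def lattice_from_json(text: str) -> ConceptLattice:
    payload = json.loads(text)
    pairs = [
        (g, m)
        for c in payload["concepts"]
        for g in c["extent"]
        for m in c["intent"]
    ]
    # incidence is recoverable from the concepts: each object's description
    # is the intent of the most specific concept containing it
    ctx = FormalContext(payload["objects"], payload["attributes"], set(pairs))
    concepts = [
        FormalConcept(tuple(c["extent"]), tuple(c["intent"]))
        for c in payload["concepts"]
    ]
    edges = [tuple(e) for e in payload["cover_edges"]]
    return ConceptLattice(ctx, concepts, edges)


def lattice_to_dot(lattice: ConceptLattice) -> str:
    """Line diagram in DOT: nodes labelled intent/support, drawn top-down."""
    ctx = lattice.context
    lines = ["digraph lattice {", "  rankdir=TB;", "  node [shape=box];"]
    for i, c in enumerate(lattice.concepts):
        intent = ",".join(c.intent) if c.intent else "∅"
        lines.append(f'  n{i} [label="{{{intent}}}\\nn={support(c)}"];')
    for i, j in lattice.cover_edges:
        lines.append(f"  n{j} -> n{i};")  # superconcept above subconcept
    lines.append("}")
    return "\n".join(lines)


def export_lattice(lattice: ConceptLattice, path, format: str = "json") -> None:
    """Write the lattice to ``path`` as ``json`` or ``dot``."""
    if format == "json":
        text = lattice_to_json(lattice)
    elif format == "dot":
        text = lattice_to_dot(lattice)
    else:
        raise ValueError(f"unknown export format: {format!r}")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(text)


__all__ = [
    "FormalContext",
    "FormalConcept",
    "ConceptLattice",
    "derive_attributes",
    "derive_objects",
    "build_lattice",
    "support",
    "own_objects",
    "own_proportion",
    "filter_concepts",
    "export_lattice",
    "lattice_to_json",
    "lattice_from_json",
    "lattice_to_dot",
]
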