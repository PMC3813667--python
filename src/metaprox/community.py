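"""The layered biofilm model and colonization-order enumeration/scoring.

A layered model (after Kolenbrander's coaggregation map of the dental
biofilm) groups organisms into ordered layers L_1 … L_m: layer-1 organisms
bind salivary-pellicle anchor points, each later layer binds the one
beneath it.  A colonization order consistent with the model is any
concatenation of within-layer permutations, giving ∏_x |L_x|! orders —
864 for the packaged 11-organism map with layer sizes (3, 3, 1, 4) —
against n! unconstrained permutations.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml

from .metrics import (
    PrevalenceTable,
    added_information,
    jaccard_distance,
    prevalence,
)
from .profiles import ProfileCollection

__all__ = [
    "BiofilmModel",
    "OrderScore",
    "read_model",
    "write_model",
    "enumerate_layer_orders",
    "count_layer_orders",
    "count_unconstrained_orders",
    "score_order",
    "reverse",
]

#: A colonization order is a plain tuple of organism ids — a permutation of
#: the community.
ColonizationOrder = tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class BiofilmModel:
    """Ordered layers of organisms plus the adhesion topology.

    ``layers`` are disjoint, non-empty, ordered inner-to-outer; ``anchors``
    are surface receptor sites (e.g. salivary pellicle components);
    ``adhesion_edges`` are unordered organism–organism or organism–anchor
    binding pairs.  Every layer-1 organism must bind at least one anchor.
    The edges document the experimentally mapped binding interactions; the
    canonical order enumeration uses only the layer blocks.
    """

    layers: tuple[frozenset[str], ...]
    adhesion_edges: frozenset[frozenset[str]] = frozenset()
    anchors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "layers", tuple(frozenset(layer) for layer in self.layers)
        )
        object.__setattr__(self, "anchors", frozenset(self.anchors))
        object.__setattr__(
            self,
            "adhesion_edges",
            frozenset(frozenset(e) for e in self.adhesion_edges),
        )
        if not self.layers:
            raise ValueError("a biofilm model needs at least one layer")
        seen: set[str] = set()
        for i, layer in enumerate(self.layers, start=1):
            if not layer:
                raise ValueError(f"layer {i} is empty")
            overlap = layer & seen
            if overlap:
                raise ValueError(f"organisms in multiple layers: {sorted(overlap)}")
            seen |= layer
        if seen & self.anchors:
            raise ValueError("anchor ids collide with organism ids")
        known = seen | self.anchors
        for edge in self.adhesion_edges:
            if len(edge) != 2:
                raise ValueError(f"adhesion edge must join two nodes: {sorted(edge)}")
            unknown = edge - known
            if unknown:
                raise ValueError(f"adhesion edge references unknown node: {sorted(unknown)}")
        if self.adhesion_edges:
            for org in self.layers[0]:
                if not any(org in e and e & self.anchors for e in self.adhesion_edges):
                    raise ValueError(
                        f"layer-1 organism {org!r} has no edge to an anchor point"
                    )

    @property
    def organisms(self) -> tuple[str, ...]:
        """All organisms, inner layer first, sorted within each layer."""
        return tuple(
            org for layer in self.layers for org in sorted(layer)
        )

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(len(layer) for layer in self.layers)

    def layer_of(self, organism_id: str) -> int:
        """1-based layer index of an organism."""
        for i, layer in enumerate(self.layers, start=1):
            if organism_id in layer:
                return i
        raise KeyError(organism_id)


@dataclasses.dataclass(frozen=True)
class OrderScore:
    """Scores of one colonization order.

    ``mean_adjacent_J`` is the arithmetic mean of the n-1 adjacent-pair
    Jaccard distances along the order; ``total_added_info`` is the sum of
    the n-1 ordered adjacent ΔI values (earlier colonizer first), in nats.
    """

    order: ColonizationOrder
    mean_adjacent_J: float
    total_added_info: float


def read_model(path: str | Path) -> BiofilmModel:
    """Read a biofilm model from a YAML file with keys ``layers`` (ordered
    list of organism-id lists), ``anchors`` (list) and ``edges`` (list of
    2-element lists)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "layers" not in doc:
        raise ValueError(f"{path}: model file must be a mapping with a 'layers' key")
    return BiofilmModel(
        layers=tuple(frozenset(layer) for layer in doc["layers"]),
        anchors=frozenset(doc.get("anchors", [])),
        adhesion_edges=frozenset(frozenset(e) for e in doc.get("edges", [])),
    )


def write_model(model: BiofilmModel, path: str | Path) -> None:
    """Serialize a model to the YAML format read by :func:`read_model`."""
    doc = {
        "layers": [sorted(layer) for layer in model.layers],
        "anchors": sorted(model.anchors),
        "edges": sorted(sorted(e) for e in model.adhesion_edges),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def enumerate_layer_orders(model: BiofilmModel) -> Iterator[ColonizationOrder]:
    """Yield every colonization order consistent with the layer blocks.

    Each order is the concatenation of a within-layer permutation of L_1,
    then of L_2, and so on; exactly ∏_x |L_x|! orders are yielded, in
    lexicographic order of the per-layer permutations.
    """
    per_layer = [itertools.permutations(sorted(layer)) for layer in model.layers]
    for combo in itertools.product(*per_layer):
        yield tuple(itertools.chain.from_iterable(combo))


def count_layer_orders(model: BiofilmModel) -> int:
    """∏_x |L_x|! without enumeration."""
    return math.prod(math.factorial(s) for s in model.layer_sizes)


def count_unconstrained_orders(model_or_n: BiofilmModel | int) -> int:
    """Number of orders disregarding the layer structure: n! for n
    organisms (39,916,800 for the 11-organism community)."""
    if isinstance(model_or_n, BiofilmModel):
        n = sum(model_or_n.layer_sizes)
    else:
        n = int(model_or_n)
    return math.factorial(n)


def score_order(
    order: Sequence[str],
    collection: ProfileCollection,
    prev: PrevalenceTable | None = None,
) -> OrderScore:
    """Score a colonization order by its adjacent-pair metrics.

    ``mean_adjacent_J`` = (1/(n-1)) Σ_i J(order_i, order_{i+1});
    ``total_added_info`` = Σ_i ΔI(order_i, order_{i+1}) with the earlier
    colonizer as the reference organism of each ordered pair.
    """
    order = tuple(order)
    if len(order) < 2:
        raise ValueError("an order must contain at least two organisms")
    missing = [o for o in order if o not in collection]
    if missing:
        raise KeyError(f"no profile for organisms: {missing}")
    if prev is None:
        prev = prevalence(collection)
    pairs = list(zip(order[:-1], order[1:]))
    mean_j = sum(
        jaccard_distance(collection[a], collection[b]) for a, b in pairs
    ) / len(pairs)
    total_info = sum(
        added_information(collection[a], collection[b], prev) for a, b in pairs
    )
    return OrderScore(order=order, mean_adjacent_J=mean_j, total_added_info=total_info)


def reverse(order: Sequence[str]) -> ColonizationOrder:
    """The order walked from the outer layer back down to the surface.

    ``mean_adjacent_J`` is invariant under reversal (J is symmetric);
    ``total_added_info`` generally is not — ΔI is directional.
    """
    return tuple(reversed(tuple(order)))
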