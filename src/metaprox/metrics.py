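"""Pairwise distance and information metrics between enzyme profiles.

Two complementary metrics drive the colonization-order analysis:

* the Jaccard distance ``J(A,B) = 1 - |A∩B| / |A∪B|`` on binary enzyme
  sets — symmetric, a true metric;
* the added information ``ΔI(A,B) = Σ_{k ∈ K(A,B)} -ln P_k`` (nats), the
  Shannon information content of the enzymes B contributes on top of A,
  weighted by community-wide enzyme prevalence ``P_k`` — asymmetric, so it
  can distinguish a colonization order from its reverse.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .profiles import EnzymeProfile, ProfileCollection

__all__ = [
    "PrevalenceTable",
    "jaccard_distance",
    "jaccard_coefficient",
    "prevalence",
    "added_information",
    "pairwise_jaccard_matrix",
    "pairwise_added_information_matrix",
]


class UndefinedDistanceError(ValueError):
    """Raised when a distance is requested between two empty profiles."""


@dataclasses.dataclass(frozen=True)
class PrevalenceTable:
    """Per-feature carrier counts and prevalences over a community.

    ``counts[k]`` is N_k, the number of organisms carrying feature k
    (1 ≤ N_k ≤ n_organisms); ``prevalence[k] = N_k / n_organisms`` lies in
    (0, 1].  The table covers exactly the community universe: features
    absent from every organism do not appear.
    """

    counts: dict[str, int]
    n_organisms: int

    @property
    def prevalence(self) -> dict[str, float]:
        return {k: n / self.n_organisms for k, n in self.counts.items()}

    def information(self, feature: str) -> float:
        """-ln P_k in nats; the self-information of observing feature k."""
        return -math.log(self.counts[feature] / self.n_organisms)


def jaccard_distance(a: EnzymeProfile, b: EnzymeProfile) -> float:
    """Jaccard distance between two feature sets; 0 for identical sets,
    1 for disjoint ones.  Undefined (raises) when both sets are empty,
    which cannot occur for real genomes and signals upstream data loss."""
    union = len(a.features | b.features)
    if union == 0:
        raise UndefinedDistanceError(
            f"Jaccard distance undefined: {a.organism_id} and {b.organism_id} "
            "both have empty feature sets"
        )
    return 1.0 - len(a.features & b.features) / union


def jaccard_coefficient(a: EnzymeProfile, b: EnzymeProfile) -> float:
    """Jaccard similarity coefficient, ``Jc = 1 - J``."""
    return 1.0 - jaccard_distance(a, b)


def prevalence(collection: ProfileCollection) -> PrevalenceTable:
    """Carrier counts N_k and prevalences P_k = N_k / n over a community."""
    counts: dict[str, int] = {}
    for p in collection:
        for f in p.features:
            counts[f] = counts.get(f, 0) + 1
    return PrevalenceTable(counts=counts, n_organisms=len(collection))


def added_information(
    a: EnzymeProfile, b: EnzymeProfile, prev: PrevalenceTable
) -> float:
    """Shannon information (nats) added by organism ``b`` colonizing on top
    of organism ``a``: the summed self-information of the features of b
    that a lacks.  Asymmetric; features with prevalence 1 contribute 0.

    The prevalence table must come from the community that contains ``b``
    (every feature of b must be tabulated).
    """
    added = b.features - a.features
    missing = added - prev.counts.keys()
    if missing:
        raise KeyError(
            f"features of {b.organism_id} absent from the prevalence table: "
            f"{sorted(missing)[:5]}"
        )
    return sum(prev.information(k) for k in added)


def pairwise_jaccard_matrix(collection: ProfileCollection) -> np.ndarray:
    """Dense n × n Jaccard distance matrix in profile order.

    Vectorized equivalent of calling :func:`jaccard_distance` on every
    pair; used by the order-scoring and null-model machinery where n²
    pair distances are reused across many thousands of orders.
    """
    mat = collection.to_matrix()
    sizes = mat.sum(axis=1)
    inter = (mat.astype(np.int64) @ mat.T.astype(np.int64)).astype(float)
    union = sizes[:, None] + sizes[None, :] - inter
    if np.any(union == 0):
        raise UndefinedDistanceError("a pair of empty profiles has no defined distance")
    return 1.0 - inter / union


def pairwise_added_information_matrix(
    collection: ProfileCollection, prev: PrevalenceTable | None = None
) -> np.ndarray:
    """Dense n × n matrix D with D[i, j] = ΔI(organism_i, organism_j)."""
    if prev is None:
        prev = prevalence(collection)
    mat = collection.to_matrix()
    info = np.array(
        [prev.information(f) for f in collection.universe], dtype=float
    )
    # ΔI(i,j) = Σ_k info_k · [not present in i] · [present in j]
    return (~mat).astype(float) @ (mat.astype(float) * info[None, :]).T
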