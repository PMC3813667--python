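"""Synthetic-data generators with the statistical structure the analysis
assumes, so every pipeline stage runs without any database download.

The community generator plants a metabolic gradient across layers: each
layer has an archetype enzyme set, consecutive archetypes share a tunable
fraction of features, and organisms are noisy copies of their layer's
archetype.  With a positive gradient, adjacent-layer organisms are
metabolically closer than distant-layer ones — the structure the layered
colonization orders are expected to detect.  A background-pool generator
stands in for randomly chosen prokaryote genomes, a pathway-map generator
supports enrichment calibration and recovery tests, and a random
stoichiometric-network generator emulates the hub-skewed metabolite
degree distribution of real metabolic networks.
"""

from __future__ import annotations

import dataclasses
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .community import BiofilmModel
from .enrichment import PathwayMap
from .profiles import EnzymeProfile, ProfileCollection
from .stoich import StoichNetwork

__all__ = [
    "CommunitySpec",
    "make_community",
    "make_background_pool",
    "make_pathway_map",
    "make_random_metabolic_network",
    "kolenbrander_fixture",
]


@dataclasses.dataclass(frozen=True)
class CommunitySpec:
    """Parameters of the planted-gradient community generator.

    ``p0`` sets the archetype size (round(p0 · universe_size) features per
    layer archetype); ``noise`` is the per-feature flip rate that turns an
    archetype into an organism profile (small noise = high within-layer
    similarity); ``gradient`` is the fraction of archetype features
    resampled between consecutive layers (0 = identical archetypes, layer
    structure uninformative).
    """

    layer_sizes: tuple[int, ...] = (3, 3, 1, 4)
    universe_size: int = 600
    p0: float = 0.3
    noise: float = 0.05
    gradient: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be >= 1")
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie in (0, 1)")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")
        if self.gradient < 0:
            raise ValueError("gradient must be >= 0")


def _feature_universe(size: int) -> list[str]:
    return [f"E{i:05d}" for i in range(size)]


def make_community(
    spec: CommunitySpec, model: BiofilmModel | None = None
) -> tuple[ProfileCollection, BiofilmModel]:
    """Generate a layered community with a planted metabolic gradient.

    Layer archetypes are built along a chain: the first is a random
    feature subset of size round(p0 · U); each next archetype keeps a
    fraction 1 - gradient of its predecessor and resamples the rest from
    outside it.  Organism profiles are noisy archetype copies (archetype
    features dropped with probability ``noise``; background features
    gained at a rate matched to keep the expected profile size constant).

    When ``model`` is given, its layers supply the organism names and the
    same model is returned; otherwise organisms are named L<x>O<i> and a
    bare layer-block model is built.
    """
    if model is not None:
        if model.layer_sizes != tuple(spec.layer_sizes):
            raise ValueError(
                f"model layer sizes {model.layer_sizes} do not match the "
                f"requested {tuple(spec.layer_sizes)}"
            )
        names = [sorted(layer) for layer in model.layers]
    else:
        names = [
            [f"L{x + 1}O{i + 1}" for i in range(size)]
            for x, size in enumerate(spec.layer_sizes)
        ]
        model = BiofilmModel(layers=tuple(frozenset(ns) for ns in names))

    u = spec.universe_size
    k = int(round(spec.p0 * u))
    min_needed = k + int(np.ceil(min(1.0, spec.gradient) * k))
    if u < min_needed or k < 1:
        raise ValueError(
            f"universe of {u} features is too small for archetypes of {k} "
            "features with the requested gradient"
        )
    rng = np.random.default_rng(spec.seed)
    universe = np.array(_feature_universe(u), dtype=object)

    archetypes: list[set[str]] = []
    current = set(rng.choice(universe, size=k, replace=False))
    archetypes.append(current)
    n_swap = int(round(min(1.0, spec.gradient) * k))
    for _ in spec.layer_sizes[1:]:
        kept = set(
            rng.choice(np.array(sorted(current), dtype=object), size=k - n_swap, replace=False)
        )
        outside = np.array(sorted(set(universe) - current), dtype=object)
        gained = set(rng.choice(outside, size=n_swap, replace=False))
        current = kept | gained
        archetypes.append(current)

    gain_rate = spec.noise * k / max(u - k, 1)
    profiles = []
    for layer_names, archetype in zip(names, archetypes):
        arch_mask = np.isin(universe, sorted(archetype))
        for org in layer_names:
            drop = rng.random(u) < spec.noise
            gain = rng.random(u) < gain_rate
            present = (arch_mask & ~drop) | (~arch_mask & gain)
            feats = frozenset(universe[present])
            if not feats:  # keep profiles non-empty for distance definitions
                feats = frozenset(rng.choice(sorted(archetype), size=1))
            profiles.append(EnzymeProfile(org, feats))
    return ProfileCollection(profiles), model


def make_background_pool(
    n_organisms: int,
    universe_size: int = 600,
    p0: float = 0.3,
    dispersion: float = 0.2,
    seed: int = 0,
) -> ProfileCollection:
    """A pool of independent genomes with heterogeneous feature prevalence.

    Per-feature prevalences are Beta-distributed with mean ``p0`` and
    concentration 1/``dispersion`` (``dispersion`` 0 makes every feature's
    prevalence exactly p0); profiles are independent Bernoulli draws.
    Stands in for a list of sequenced prokaryotes from which random groups
    are sampled.
    """
    if n_organisms < 1:
        raise ValueError("n_organisms must be >= 1")
    if not 0 < p0 <= 1:
        raise ValueError("p0 must lie in (0, 1]")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    universe = np.array(_feature_universe(universe_size), dtype=object)
    if dispersion == 0:
        pi = np.full(universe_size, p0)
    else:
        nu = 1.0 / dispersion
        pi = rng.beta(p0 * nu, (1 - p0) * nu, size=universe_size)
    profiles = []
    for i in range(n_organisms):
        present = rng.random(universe_size) < pi
        feats = frozenset(universe[present])
        if not feats:
            feats = frozenset(rng.choice(universe, size=1))
        profiles.append(EnzymeProfile(f"P{i + 1:04d}", feats))
    return ProfileCollection(profiles)


def make_pathway_map(
    universe: Sequence[str],
    n_pathways: int,
    planted: Mapping[str, int] | None = None,
    model: BiofilmModel | None = None,
    collection: ProfileCollection | None = None,
    seed: int = 0,
    size_range: tuple[int, int] = (5, 20),
    planted_purity: float = 0.8,
) -> PathwayMap:
    """Random enzyme-to-pathway assignments, optionally with planted
    layer-specific pathways.

    Unplanted pathways draw their enzymes uniformly from the universe.  A
    planted pathway (``planted`` maps pathway id → target layer index)
    draws a fraction ``planted_purity`` of its enzymes from the features
    private to that layer's organisms (carried inside the layer, absent
    everywhere else), which requires ``model`` and ``collection``.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    planted = dict(planted or {})
    if planted and (model is None or collection is None):
        raise ValueError("planting pathways requires the model and the collection")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    pathways: dict[str, set[str]] = {}
    for j in range(n_pathways):
        pid = f"PW{j + 1:03d}"
        m = int(rng.integers(size_range[0], size_range[1] + 1))
        members = set(rng.choice(np.array(universe, dtype=object), size=m, replace=False))
        if pid in planted:
            x = planted[pid]
            inside: set[str] = set()
            outside: set[str] = set()
            for org in collection.organism_ids:
                feats = collection[org].features
                if org in model.layers[x - 1]:
                    inside |= feats
                else:
                    outside |= feats
            private = sorted((inside - outside))
            n_private = min(int(round(planted_purity * m)), len(private))
            chosen = set(
                rng.choice(np.array(private, dtype=object), size=n_private, replace=False)
            )
            filler = sorted(set(universe) - chosen)
            chosen |= set(
                rng.choice(np.array(filler, dtype=object), size=m - n_private, replace=False)
            )
            members = chosen
        pathways[pid] = members
    return PathwayMap(pathways)


def make_random_metabolic_network(
    n_metabolites: int = 25,
    n_reactions: int = 25,
    mean_degree: float = 6.0,
    hub_fraction: float = 0.2,
    reversible_fraction: float = 0.1,
    exchange_fraction: float = 0.2,
    seed: int = 0,
) -> StoichNetwork:
    """A random stoichiometric network with metabolic-like topology.

    A linear backbone chain through non-hub metabolites guarantees a
    connected core (its dead-end termini act as exchange points under the
    single-use external rule).  An ``exchange_fraction`` of the remaining
    reactions are single-metabolite uptake/secretion steps — genome-scale
    models are open systems, and without boundary fluxes a random network
    rarely supports any steady-state mode.  The other reactions each
    consume 1–2 and produce 1–2 metabolites, with a ``hub_fraction`` of
    designated currency-like metabolites sampled ``mean_degree`` times
    more often than the rest, yielding a right-skewed metabolite degree
    distribution.  Coefficients are 1 with an occasional 2.
    """
    if n_metabolites < 4 or n_reactions < 3:
        raise ValueError("need at least 4 metabolites and 3 reactions")
    rng = np.random.default_rng(seed)
    mets = [f"M{i:03d}" for i in range(n_metabolites)]
    n_hubs = int(round(hub_fraction * n_metabolites))
    hubs = mets[:n_hubs]
    chain_mets = mets[n_hubs:]
    weights = np.array(
        [mean_degree if m in hubs else 1.0 for m in mets], dtype=float
    )
    weights /= weights.sum()

    reactions: list[str] = []
    coeffs: list[dict[str, Fraction]] = []
    chain_len = min(len(chain_mets) - 1, max(2, n_reactions // 3))
    for i in range(chain_len):
        reactions.append(f"R{len(reactions):03d}")
        coeffs.append(
            {chain_mets[i]: Fraction(-1), chain_mets[i + 1]: Fraction(1)}
        )
    while len(reactions) < n_reactions:
        if rng.random() < exchange_fraction:
            idx = int(rng.choice(n_metabolites, p=weights))
            sign = Fraction(1) if rng.random() < 0.5 else Fraction(-1)
            cmap = {mets[idx]: sign}
        else:
            n_sub = int(rng.integers(1, 3))
            n_prod = int(rng.integers(1, 3))
            picked = rng.choice(
                n_metabolites, size=n_sub + n_prod, replace=False, p=weights
            )
            cmap = {}
            for idx in picked[:n_sub]:
                cmap[mets[idx]] = Fraction(-1 if rng.random() > 0.1 else -2)
            for idx in picked[n_sub:]:
                cmap[mets[idx]] = Fraction(1 if rng.random() > 0.1 else 2)
        reactions.append(f"R{len(reactions):03d}")
        coeffs.append(cmap)
    reversible = tuple(bool(rng.random() < reversible_fraction) for _ in reactions)
    used: set[str] = set()
    for cmap in coeffs:
        used |= set(cmap)
    return StoichNetwork(
        metabolites=tuple(m for m in mets if m in used),
        reactions=tuple(reactions),
        coefficients=tuple(coeffs),
        reversible=reversible,
    )


def kolenbrander_fixture() -> BiofilmModel:
    """The packaged 11-organism, 4-layer dental-biofilm adhesion model.

    Layer memberships and the six salivary-pellicle anchor points follow
    the classic coaggregation map of the dental biofilm (streptococci
    binding pellicle receptors first; Fusobacterium nucleatum bridging
    early and late colonizers; periodontal pathogens outermost).  The
    adhesion edge list is a reconstruction from the coaggregation
    literature; the layered-order enumeration uses only the layer blocks,
    so analyses do not depend on individual edges.
    """
    layers = (
        frozenset({"SM", "SS", "SG"}),
        frozenset({"CO", "VS", "PA"}),
        frozenset({"FN"}),
        frozenset({"AA", "TD", "ES", "PG"}),
    )
    anchors = frozenset({"SMU", "BCF", "PRP", "SA", "S", "AAM"})
    edges = frozenset(
        frozenset(e)
        for e in [
            # first colonizers -> salivary pellicle receptors
            ("SM", "SMU"), ("SM", "BCF"),
            ("SS", "PRP"), ("SS", "SA"), ("SS", "S"),
            ("SG", "PRP"), ("SG", "SA"), ("SG", "S"), ("SG", "AAM"),
            # second layer binds the streptococci
            ("CO", "SG"), ("CO", "SS"),
            ("VS", "SM"), ("VS", "SS"), ("VS", "SG"),
            ("PA", "SG"), ("PA", "SS"),
            # F. nucleatum bridges early colonizers ...
            ("FN", "SM"), ("FN", "SS"), ("FN", "SG"),
            ("FN", "CO"), ("FN", "VS"), ("FN", "PA"),
            # ... and the late colonizers
            ("AA", "FN"), ("TD", "FN"), ("ES", "FN"), ("PG", "FN"),
            ("PG", "SG"), ("TD", "PG"),
        ]
    )
    return BiofilmModel(layers=layers, adhesion_edges=edges, anchors=anchors)
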