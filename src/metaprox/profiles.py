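"""Binary enzyme/gene presence-absence profiles and their I/O.

An organism's metabolic potential is reduced to the set of enzymatic
functions (EC numbers) annotated in its genome; abundance and stoichiometry
are deliberately ignored.  The same container serves non-metabolic gene
profiles (KO identifiers) — feature identifiers are opaque strings.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "EnzymeProfile",
    "ProfileCollection",
    "read_profiles",
    "write_profiles",
    "subsample_features",
]


@dataclasses.dataclass(frozen=True)
class EnzymeProfile:
    """One organism's binary presence/absence profile.

    Parameters
    ----------
    organism_id :
        Unique organism identifier (e.g. a KEGG organism code).
    features :
        The set of feature identifiers (EC numbers or KO identifiers)
        present in the organism's genome.
    """

    organism_id: str
    features: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", frozenset(self.features))
        if not self.organism_id:
            raise ValueError("organism_id must be a non-empty string")
        if any(not f for f in self.features):
            raise ValueError("feature identifiers must be non-empty strings")

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature: str) -> bool:
        return feature in self.features


class ProfileCollection:
    """An ordered collection of profiles sharing one feature universe.

    The universe is the exact union of all member feature sets, sorted
    lexicographically so that vector layouts are reproducible across runs.
    """

    def __init__(self, profiles: Iterable[EnzymeProfile]):
        profiles = list(profiles)
        if not profiles:
            raise ValueError("a ProfileCollection needs at least one profile")
        ids = [p.organism_id for p in profiles]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate organism ids: {dup}")
        self._profiles: tuple[EnzymeProfile, ...] = tuple(profiles)
        self._by_id = {p.organism_id: p for p in profiles}
        universe: set[str] = set()
        for p in profiles:
            universe |= p.features
        self.universe: tuple[str, ...] = tuple(sorted(universe))

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[EnzymeProfile]:
        return iter(self._profiles)

    def __getitem__(self, organism_id: str) -> EnzymeProfile:
        return self._by_id[organism_id]

    def __contains__(self, organism_id: str) -> bool:
        return organism_id in self._by_id

    @property
    def organism_ids(self) -> tuple[str, ...]:
        return tuple(p.organism_id for p in self._profiles)

    def to_matrix(self) -> np.ndarray:
        """Boolean organisms × universe presence matrix (row order =
        profile order, column order = sorted universe)."""
        index = {f: j for j, f in enumerate(self.universe)}
        mat = np.zeros((len(self._profiles), len(self.universe)), dtype=bool)
        for i, p in enumerate(self._profiles):
            for f in p.features:
                mat[i, index[f]] = True
        return mat

    def subset(self, organism_ids: Iterable[str]) -> "ProfileCollection":
        """Collection restricted to the named organisms (given order)."""
        missing = [o for o in organism_ids if o not in self._by_id]
        if missing:
            raise KeyError(f"unknown organism ids: {missing}")
        return ProfileCollection(self._by_id[o] for o in organism_ids)


def read_profiles(path: str | Path, feature_kind: str = "enzyme") -> ProfileCollection:
    """Read a two-column TSV of (organism_id, feature_id) rows.

    Lines starting with ``#`` are comments; blank lines are skipped; LF and
    CRLF line endings are both accepted.  Duplicate (organism, feature) rows
    collapse — presence is binary.  ``feature_kind`` is a label only
    ("enzyme" for EC numbers, "gene" for KO identifiers); features are
    treated as opaque strings either way.
    """
    if feature_kind not in ("enzyme", "gene"):
        raise ValueError(f"feature_kind must be 'enzyme' or 'gene', got {feature_kind!r}")
    path = Path(path)
    features: dict[str, set[str]] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'organism_id<TAB>feature_id', got {line!r}"
                )
            features.setdefault(parts[0], set()).add(parts[1])
    if not features:
        raise ValueError(f"{path}: no profile rows found")
    return ProfileCollection(
        EnzymeProfile(org, frozenset(feats)) for org, feats in features.items()
    )


def write_profiles(collection: ProfileCollection, path: str | Path) -> None:
    """Write a collection in the two-column TSV format read by
    :func:`read_profiles` (rows sorted for byte-reproducibility)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# organism_id\tfeature_id\n")
        for p in collection:
            for f in sorted(p.features):
                fh.write(f"{p.organism_id}\t{f}\n")


def subsample_features(
    collection: ProfileCollection, remove_fraction: float, seed: int
) -> ProfileCollection:
    """Delete a random fraction of the shared feature universe.

    A uniformly random subset of ``floor(remove_fraction * |universe|)``
    universe features is removed from every profile simultaneously — the
    removal acts on the dataset, not independently per organism.  Used for
    sensitivity analysis of order-discrimination under annotation loss.
    """
    if not 0 <= remove_fraction < 1:
        raise ValueError(f"remove_fraction must be in [0, 1), got {remove_fraction}")
    if remove_fraction == 0:
        return collection
    rng = np.random.default_rng(seed)
    universe = np.asarray(collection.universe, dtype=object)
    n_remove = int(np.floor(remove_fraction * len(universe)))
    removed = set(rng.choice(universe, size=n_remove, replace=False))
    return ProfileCollection(
        EnzymeProfile(p.organism_id, p.features - removed) for p in collection
    )
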