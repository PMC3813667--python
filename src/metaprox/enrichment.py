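"""Layer profiles and pathway enrichment per biofilm layer.

Each layer x gets a profile B^(x): for every enzyme in the community
universe, the fraction of layer-x organisms that carry it (an exact
rational with denominator |L_x|).  Enzymes are then ranked, per layer, by
the layer-specificity statistic B^(x)_i - mean_{y != x} B^(y)_i, and a
weighted running-sum (GSEA-style) enrichment score is computed for every
pathway against that ranking.  Nominal p-values come from enzyme-label
permutations (random same-size enzyme sets); FDR q-values from
Benjamini–Hochberg over all pathway × layer tests.
"""

from __future__ import annotations

import dataclasses
import warnings
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import BiofilmModel
from .profiles import ProfileCollection

__all__ = [
    "LayerProfile",
    "PathwayMap",
    "EnrichmentResult",
    "read_pathway_map",
    "write_pathway_map",
    "layer_profile",
    "gsea_layer_enrichment",
]

#: Default significance thresholds: nominal p <= 0.05 and FDR q < 0.25.
P_THRESHOLD = 0.05
Q_THRESHOLD = 0.25


@dataclasses.dataclass(frozen=True)
class LayerProfile:
    """Per-enzyme carriage fraction within one biofilm layer.

    ``values[i]`` is the exact fraction of layer-``layer_index`` organisms
    carrying enzyme i, defined over the full community universe (0 for
    enzymes no layer member carries).
    """

    layer_index: int
    values: Mapping[str, Fraction]
    layer_size: int

    def as_array(self, universe: Sequence[str]) -> np.ndarray:
        return np.array([float(self.values[f]) for f in universe])


class PathwayMap:
    """Mapping from pathway ids to enzyme-id sets (a binary
    enzyme-by-pathway membership matrix stored sparsely)."""

    def __init__(self, pathways: Mapping[str, Sequence[str] | frozenset[str]]):
        self._pathways = {
            pid: frozenset(enzymes) for pid, enzymes in pathways.items()
        }
        for pid, enzymes in self._pathways.items():
            if not enzymes:
                raise ValueError(f"pathway {pid!r} has no enzymes")

    def __len__(self) -> int:
        return len(self._pathways)

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self._pathways[pathway_id]

    def __iter__(self):
        return iter(sorted(self._pathways))

    def items(self):
        return sorted(self._pathways.items())


def read_pathway_map(path: str | Path) -> PathwayMap:
    """Read pathway membership from a two-column TSV of
    (pathway_id, enzyme_id) rows ('#' comments allowed)."""
    pathways: dict[str, set[str]] = {}
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 'pathway_id<TAB>enzyme_id', got {line!r}"
                )
            pathways.setdefault(parts[0], set()).add(parts[1])
    if not pathways:
        raise ValueError(f"{path}: no pathway rows found")
    return PathwayMap(pathways)


def write_pathway_map(pmap: PathwayMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pathway_id\tenzyme_id\n")
        for pid, enzymes in pmap.items():
            for e in sorted(enzymes):
                fh.write(f"{pid}\t{e}\n")


@dataclasses.dataclass
class EnrichmentResult:
    """Per (pathway, layer) enrichment scores and significance calls.

    ``table`` has columns pathway, layer, es, pvalue, qvalue, flag;
    ``params`` records the ranking statistic, weighting, permutation
    scheme, seed and thresholds used.
    """

    table: pd.DataFrame
    params: dict

    def pass_matrix(self) -> pd.DataFrame:
        """Pathways × layers 0/1 grid of significance flags."""
        return (
            self.table.pivot(index="pathway", columns="layer", values="flag")
            .fillna(False)
            .astype(int)
        )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def layer_profile(
    model: BiofilmModel, collection: ProfileCollection, x: int
) -> LayerProfile:
    """B^(x): exact per-enzyme carriage fractions for layer x (1-based)."""
    if not 1 <= x <= len(model.layers):
        raise KeyError(f"model has layers 1..{len(model.layers)}, got {x}")
    members = sorted(model.layers[x - 1])
    missing = [o for o in members if o not in collection]
    if missing:
        raise KeyError(f"no profile for layer-{x} organisms: {missing}")
    size = len(members)
    counts: dict[str, int] = {f: 0 for f in collection.universe}
    for org in members:
        for f in collection[org].features:
            counts[f] += 1
    values = {f: Fraction(c, size) for f, c in counts.items()}
    return LayerProfile(layer_index=x, values=values, layer_size=size)


def _running_sum_es(
    order_weights: np.ndarray, hit_mask: np.ndarray
) -> float | np.ndarray:
    """Maximum of the GSEA running sum for hit masks over a ranked list.

    ``order_weights`` holds |r_j|^w in ranked order; ``hit_mask`` is a
    boolean (…, N) array marking pathway members.  Hits step up by their
    normalized weight, misses step down by 1/(N - N_hits).
    """
    n = order_weights.shape[-1]
    n_hits = hit_mask.sum(axis=-1)
    w_hit = np.where(hit_mask, order_weights, 0.0)
    n_r = w_hit.sum(axis=-1, keepdims=True)
    # degenerate case: all hit weights zero -> fall back to uniform steps
    uniform = np.broadcast_to(hit_mask / np.maximum(n_hits, 1)[..., None], w_hit.shape)
    hit_steps = np.where(n_r > 0, w_hit / np.where(n_r > 0, n_r, 1.0), uniform)
    miss_steps = (~hit_mask) / (n - n_hits)[..., None]
    running = np.cumsum(hit_steps - miss_steps, axis=-1)
    return running.max(axis=-1)


def gsea_layer_enrichment(
    profiles: Sequence[LayerProfile],
    pathway_map: PathwayMap,
    n_perm: int = 1000,
    seed: int = 0,
    universe: Sequence[str] | None = None,
    weight: float = 1.0,
    min_pathway_size: int = 3,
) -> EnrichmentResult:
    """Pathway × layer enrichment against layer-specificity rankings.

    For each layer x, enzymes are ranked by B^(x)_i - mean_{y != x}
    B^(y)_i (descending; ties broken by enzyme id for determinism).  A
    pathway's enrichment score is the maximum of the weighted running sum
    over that ranking; its nominal p-value is the fraction of random
    same-size enzyme sets scoring at least as high (enzyme-label
    permutation null — only a handful of layers exist, too few for sample
    permutation).  FDR is Benjamini–Hochberg over every pathway × layer
    test; a test is flagged when p <= 0.05 and q < 0.25.

    Pathways with fewer than ``min_pathway_size`` enzymes in the universe
    are excluded with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two layer profiles to rank specificity")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for usable p-values")
    if universe is None:
        universe = sorted(profiles[0].values.keys())
    universe = list(universe)
    n = len(universe)
    b = np.stack([p.as_array(universe) for p in profiles])  # layers × enzymes

    kept: list[tuple[str, np.ndarray]] = []
    for pid, enzymes in pathway_map.items():
        members = np.array([f in enzymes for f in universe])
        if members.sum() < min_pathway_size:
            warnings.warn(
                f"pathway {pid!r}: fewer than {min_pathway_size} enzymes in the "
                "universe; excluded",
                stacklevel=2,
            )
            continue
        kept.append((pid, members))
    if not kept:
        raise ValueError("no pathway has enough enzymes in the universe")

    rng = np.random.default_rng(seed)
    rows = []
    for i, profile in enumerate(profiles):
        x = profile.layer_index
        others = np.delete(b, i, axis=0)
        rank_stat = b[i] - others.mean(axis=0)
        if np.allclose(rank_stat, rank_stat[0]):
            raise ValueError(
                f"layer {x}: ranking statistic is constant across enzymes "
                "(no discrimination)"
            )
        # descending by statistic, ties broken lexicographically by enzyme id
        order = np.lexsort((universe, -rank_stat))
        order_weights = np.abs(rank_stat[order]) ** weight

        null_cache: dict[int, np.ndarray] = {}
        for pid, members in kept:
            hit = members[order]
            es = float(_running_sum_es(order_weights, hit))
            m = int(members.sum())
            if m not in null_cache:
                null_hits = np.zeros((n_perm, n), dtype=bool)
                for k in range(n_perm):
                    null_hits[k, rng.choice(n, size=m, replace=False)] = True
                null_cache[m] = np.asarray(
                    _running_sum_es(order_weights, null_hits)
                )
            null = null_cache[m]
            p = (1 + int((null >= es).sum())) / (n_perm + 1)
            rows.append({"pathway": pid, "layer": x, "es": es, "pvalue": p})

    table = pd.DataFrame(rows)
    table["qvalue"] = stats.false_discovery_control(table["pvalue"], method="bh")
    table["flag"] = (table["pvalue"] <= P_THRESHOLD) & (table["qvalue"] < Q_THRESHOLD)
    params = {
        "ranking": "layer specificity B(x) - mean of other layers",
        "weight_exponent": weight,
        "null": "enzyme-label permutation (random same-size sets)",
        "n_perm": n_perm,
        "seed": seed,
        "min_pathway_size": min_pathway_size,
        "p_threshold": P_THRESHOLD,
        "q_threshold": Q_THRESHOLD,
    }
    return EnrichmentResult(table=table, params=params)
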