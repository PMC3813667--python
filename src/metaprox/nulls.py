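"""Randomized baselines and score-distribution comparisons.

Three kinds of baseline are compared against the layered colonization
orders: uniformly random permutations of the same community (order
randomization), random groups drawn from a large prokaryote background
pool (community randomization), and feature-subsampled re-analyses
(annotation-loss sensitivity).  Distributions are compared with the
two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import BiofilmModel, enumerate_layer_orders
from .metrics import (
    pairwise_added_information_matrix,
    pairwise_jaccard_matrix,
)
from .profiles import ProfileCollection, subsample_features

__all__ = [
    "ScoreDistribution",
    "layered_order_distribution",
    "random_order_distribution",
    "random_group_distribution",
    "ks_two_sample",
    "sensitivity_analysis",
    "exclude_organisms",
]


@dataclasses.dataclass
class ScoreDistribution:
    """A labelled sample of per-order (or per-group) scores."""

    label: str
    values: np.ndarray
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("a score distribution cannot be empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return self.values.size

    def to_tsv(self, path: str | Path) -> None:
        """Single-column TSV with the metadata in '#'-prefixed header lines."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# label: {self.label}\n")
            for k, v in sorted(self.metadata.items()):
                fh.write(f"# {k}: {v}\n")
            fh.write("score\n")
            for v in self.values:
                fh.write(f"{v!r}\n")


def _orders_to_indices(
    orders: Iterable[Sequence[str]], collection: ProfileCollection
) -> np.ndarray:
    pos = {org: i for i, org in enumerate(collection.organism_ids)}
    return np.array([[pos[o] for o in order] for order in orders], dtype=np.intp)


def _score_index_orders(
    idx: np.ndarray, pair_matrix: np.ndarray, reduce: str
) -> np.ndarray:
    """Score orders given as index rows against a precomputed n×n pair
    matrix; 'mean' for <J>, 'sum' for the added-information total."""
    vals = pair_matrix[idx[:, :-1], idx[:, 1:]]
    return vals.mean(axis=1) if reduce == "mean" else vals.sum(axis=1)


def _pair_matrix(collection: ProfileCollection, metric: str) -> tuple[np.ndarray, str]:
    if metric == "jaccard":
        return pairwise_jaccard_matrix(collection), "mean"
    if metric == "added_info":
        return pairwise_added_information_matrix(collection), "sum"
    raise ValueError(f"metric must be 'jaccard' or 'added_info', got {metric!r}")


def layered_order_distribution(
    collection: ProfileCollection,
    model: BiofilmModel,
    metric: str = "jaccard",
    reverse_orders: bool = False,
) -> ScoreDistribution:
    """Scores of every colonization order consistent with the layer blocks.

    With ``metric='jaccard'`` each order contributes its mean adjacent
    Jaccard distance <J>; with ``'added_info'`` its summed added
    information (nats).  ``reverse_orders`` walks each order from the
    outer layer down to the surface — it changes added-information scores
    but not <J>.
    """
    orders = enumerate_layer_orders(model)
    if reverse_orders:
        orders = (tuple(reversed(o)) for o in orders)
    idx = _orders_to_indices(orders, collection)
    matrix, reduce = _pair_matrix(collection, metric)
    values = _score_index_orders(idx, matrix, reduce)
    return ScoreDistribution(
        label=("layered" if not reverse_orders else "layered-reversed"),
        values=values,
        metadata={
            "metric": metric,
            "n_orders": len(values),
            "layer_sizes": model.layer_sizes,
        },
    )


def random_order_distribution(
    collection: ProfileCollection,
    n_samples: int,
    seed: int,
    metric: str = "jaccard",
) -> ScoreDistribution:
    """Scores of uniformly random permutations of the whole community."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = len(collection)
    if n < 2:
        raise ValueError("need at least two organisms to score an order")
    rng = np.random.default_rng(seed)
    idx = np.array([rng.permutation(n) for _ in range(n_samples)], dtype=np.intp)
    matrix, reduce = _pair_matrix(collection, metric)
    values = _score_index_orders(idx, matrix, reduce)
    return ScoreDistribution(
        label="random-orders",
        values=values,
        metadata={"metric": metric, "n_samples": n_samples, "seed": seed},
    )


def random_group_distribution(
    pool: ProfileCollection,
    group_size: int = 11,
    n_groups: int = 1000,
    seed: int = 0,
) -> ScoreDistribution:
    """Permutation-averaged adjacent-distance sums for random groups drawn
    from a background pool.

    For each group the reported score is the average over all group_size!
    colonization orders of the summed adjacent Jaccard distances.  By
    linearity of expectation each adjacent slot of a uniformly random
    permutation is a uniformly random unordered pair, so this average
    equals ``(group_size - 1) × (mean pairwise J within the group)``
    exactly — no permutation iteration is needed.  Scores are on the sum
    scale; divide by ``group_size - 1`` for the per-pair-mean scale of the
    order distributions.
    """
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    if len(pool) < group_size:
        raise ValueError(
            f"pool of {len(pool)} organisms cannot supply groups of {group_size}"
        )
    rng = np.random.default_rng(seed)
    matrix = pairwise_jaccard_matrix(pool)
    iu = np.triu_indices(group_size, k=1)
    values = np.empty(n_groups)
    for g in range(n_groups):
        members = rng.choice(len(pool), size=group_size, replace=False)
        sub = matrix[np.ix_(members, members)]
        values[g] = (group_size - 1) * sub[iu].mean()
    return ScoreDistribution(
        label="random-groups",
        values=values,
        metadata={
            "group_size": group_size,
            "n_groups": n_groups,
            "seed": seed,
            "scale": "sum",
        },
    )


def ks_two_sample(
    x: ScoreDistribution | np.ndarray, y: ScoreDistribution | np.ndarray
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic D and p-value.

    The exact small-sample p-value is used when both samples have at most
    25 values, the asymptotic one otherwise.
    """
    xv = x.values if isinstance(x, ScoreDistribution) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, ScoreDistribution) else np.asarray(y, dtype=float)
    if xv.size == 0 or yv.size == 0:
        raise ValueError("cannot compare empty samples")
    method = "exact" if (xv.size <= 25 and yv.size <= 25) else "asymp"
    res = stats.ks_2samp(xv, yv, method=method)
    return float(res.statistic), float(res.pvalue)


def sensitivity_analysis(
    collection: ProfileCollection,
    model: BiofilmModel,
    fractions: Sequence[float],
    reps: int,
    seed: int,
    n_random: int = 1000,
    metric: str = "jaccard",
) -> pd.DataFrame:
    """Order-discrimination significance under random enzyme removal.

    For each removal fraction and replicate: delete that fraction of the
    shared feature universe, recompute the layered-order and random-order
    score distributions, and record the KS comparison.  Returns a tidy
    frame with columns fraction, replicate, statistic, pvalue; a fraction
    of 0 uses the unperturbed data (one deterministic replicate suffices
    but all requested replicates are reported).
    """
    if any(not 0 <= f <= 0.8 for f in fractions):
        raise ValueError("removal fractions must lie in [0, 0.8]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for fraction in fractions:
        for rep in range(reps):
            sub_seed = int(rng.integers(2**31))
            sub = subsample_features(collection, fraction, seed=sub_seed)
            layered = layered_order_distribution(sub, model, metric=metric)
            random_ = random_order_distribution(
                sub, n_samples=n_random, seed=sub_seed + 1, metric=metric
            )
            d, p = ks_two_sample(layered, random_)
            rows.append(
                {"fraction": fraction, "replicate": rep, "statistic": d, "pvalue": p}
            )
    return pd.DataFrame(rows)


def exclude_organisms(
    collection: ProfileCollection, model: BiofilmModel, ids: Iterable[str]
) -> tuple[ProfileCollection, BiofilmModel]:
    """Remove named organisms from the community and the model.

    A layer emptied entirely is dropped.  The reduced model carries only
    the layer blocks: the binding topology of a pruned community is not
    re-derived, so adhesion edges and anchors are omitted from it.  Used
    e.g. to test whether near-identical early colonizers (the
    streptococci) drive the order-discrimination signal on their own.
    """
    ids = set(ids)
    known = set(collection.organism_ids)
    unknown = ids - known
    if unknown:
        raise KeyError(f"unknown organism ids: {sorted(unknown)}")
    if not ids:
        return collection, model
    new_layers = tuple(
        frozenset(layer - ids) for layer in model.layers if layer - ids
    )
    if not new_layers:
        raise ValueError("excluding these organisms empties the whole model")
    reduced_model = BiofilmModel(layers=new_layers)
    keep = [o for o in collection.organism_ids if o not in ids]
    return collection.subset(keep), reduced_model
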