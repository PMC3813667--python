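"""Elementary flux mode enumeration and the metabolic synergy score.

An elementary flux mode (EFM) is a steady-state flux vector (S·v = 0 over
internal metabolites, v respecting irreversibility) whose support is
minimal: no other steady-state vector uses a strict subset of its
reactions.  The number of EFMs gauges a network's pathway versatility;
the synergy score compares the EFM count of a joint two-species network
against the counts of its constituents.

Enumeration is a double-description sweep over the steady-state
constraints with exact integer arithmetic: reversible reactions are split
into forward/backward halves, the nonnegative orthant's extreme rays are
intersected with one metabolite balance at a time, and candidate rays are
kept only when support-minimal.  An independent exponential brute-force
enumerator (every support subset tested for a one-dimensional,
sign-feasible nullspace) serves as a cross-check at small sizes.
"""

from __future__ import annotations

import dataclasses
import math
from fractions import Fraction
from typing import Sequence

import numpy as np
import sympy

from .stoich import StoichNetwork, build_paired_networks, sample_source_network

__all__ = [
    "EFMCapError",
    "enumerate_efms",
    "brute_force_efms",
    "count_efms",
    "synergy_score",
    "SynergyPoint",
    "synergy_curve",
]

#: An EFM is reported as a tuple of exact fluxes aligned with
#: ``net.reactions``, scaled so the first nonzero flux has magnitude 1.
FluxMode = tuple[Fraction, ...]


class EFMCapError(RuntimeError):
    """Raised when a network exceeds the enumeration size/work caps."""


def _integer_columns(
    net: StoichNetwork, auto_external: bool
) -> tuple[tuple[str, ...], list[dict[int, int]], list[Fraction]]:
    """Internal-metabolite rows and integer-scaled reaction columns.

    Each reaction column is scaled by the LCM of its coefficient
    denominators; the per-column scale is returned so solutions can be
    mapped back to fluxes of the original network.
    """
    internal = net.internal_metabolites(auto_external=auto_external)
    met_idx = {m: i for i, m in enumerate(internal)}
    cols: list[dict[int, int]] = []
    scales: list[Fraction] = []
    for cmap in net.coefficients:
        denom = math.lcm(*(c.denominator for c in cmap.values()))
        col = {
            met_idx[m]: int(c * denom) for m, c in cmap.items() if m in met_idx
        }
        cols.append(col)
        scales.append(Fraction(denom))
    return internal, cols, scales


def _canonical(
    flux: Sequence[Fraction], reversible: Sequence[bool]
) -> FluxMode | None:
    """Scale so the first nonzero flux has magnitude 1; orient modes whose
    support is fully reversible so their first nonzero is positive.
    Returns None for the zero vector."""
    first = next((v for v in flux if v != 0), None)
    if first is None:
        return None
    scaled = tuple(v / abs(first) for v in flux)
    if all(reversible[j] for j, v in enumerate(scaled) if v != 0) and first < 0:
        scaled = tuple(-v for v in scaled)
    return scaled


def enumerate_efms(
    net: StoichNetwork,
    cap: int = 32,
    auto_external: bool = True,
    max_rays: int = 200_000,
) -> list[FluxMode]:
    """All elementary flux modes of a network, exactly.

    Reversible reactions are split; the spurious two-cycles the split
    introduces are discarded; a mode whose support is entirely reversible
    is reported once (canonical orientation).  Every returned vector
    satisfies the internal-metabolite balances exactly.  Networks with
    more than ``cap`` columns after splitting, or intermediate ray counts
    above ``max_rays``, raise :class:`EFMCapError`.

    With no internal metabolite every reaction is unconstrained and each
    is its own mode.
    """
    internal, int_cols, scales = _integer_columns(net, auto_external)
    n = net.n_reactions

    if not internal:
        modes = []
        for k in range(n):
            flux = [Fraction(0)] * n
            flux[k] = Fraction(1)
            modes.append(tuple(flux))
        return modes

    # split columns: (reaction index, direction, integer column)
    split: list[tuple[int, int, dict[int, int]]] = []
    for k in range(n):
        split.append((k, +1, int_cols[k]))
        if net.reversible[k]:
            split.append((k, -1, {i: -v for i, v in int_cols[k].items()}))
    n_cols = len(split)
    if n_cols > cap:
        raise EFMCapError(
            f"{n_cols} columns after reversible splitting exceeds the cap of "
            f"{cap}; enumerate a smaller network or raise the cap"
        )

    # rows of the integer constraint matrix
    rows = []
    for i in range(len(internal)):
        row = np.zeros(n_cols, dtype=object)
        for j, (_, _, col) in enumerate(split):
            if i in col:
                row[j] = col[i]
        if np.any(row != 0):
            rows.append(row)

    # double description: start from the extreme rays of the orthant
    rays: list[np.ndarray] = [
        np.array([1 if j == c else 0 for j in range(n_cols)], dtype=object)
        for c in range(n_cols)
    ]
    supports: list[int] = [1 << c for c in range(n_cols)]

    remaining = list(range(len(rows)))
    while remaining:
        # cheapest-row-first heuristic: fewest positive x negative pairs
        best, best_cost, best_dots = None, None, None
        for ri in remaining:
            dots = [int(rows[ri] @ r) for r in rays]
            npos = sum(d > 0 for d in dots)
            nneg = sum(d < 0 for d in dots)
            cost = npos * nneg
            if best_cost is None or cost < best_cost:
                best, best_cost, best_dots = ri, cost, dots
        remaining.remove(best)
        dots = best_dots

        zero = [(rays[j], supports[j]) for j, d in enumerate(dots) if d == 0]
        pos = [(rays[j], supports[j], d) for j, d in enumerate(dots) if d > 0]
        neg = [(rays[j], supports[j], d) for j, d in enumerate(dots) if d < 0]

        new: dict[tuple, tuple[np.ndarray, int]] = {}
        all_supports = supports
        for rp, sp, dp in pos:
            for rn, sn, dn in neg:
                s = sp | sn
                # adjacency via support minimality: no third ray's support
                # may fit inside the union
                adjacent = True
                for other in all_supports:
                    if other != sp and other != sn and (other | s) == s:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                combo = dp * rn - dn * rp  # both terms nonnegative
                g = math.gcd(*(int(v) for v in combo))
                if g > 1:
                    combo = combo // g
                new[tuple(combo)] = (combo, s)
        rays = [r for r, _ in zero] + [r for r, _ in new.values()]
        supports = [s for _, s in zero] + [s for _, s in new.values()]
        if len(rays) > max_rays:
            raise EFMCapError(
                f"intermediate ray count {len(rays)} exceeds max_rays={max_rays}"
            )

    # map split-space rays back to net fluxes of the original reactions
    modes: dict[FluxMode, None] = {}
    for ray in rays:
        flux = [Fraction(0)] * n
        for j, (k, direction, _) in enumerate(split):
            if ray[j]:
                flux[k] += direction * int(ray[j]) * scales[k]
        canon = _canonical(flux, net.reversible)
        if canon is not None:  # zero vector = futile two-cycle from the split
            modes[canon] = None
    return sorted(modes.keys())


def brute_force_efms(
    net: StoichNetwork, auto_external: bool = True, max_reactions: int = 14
) -> list[FluxMode]:
    """Independent EFM enumeration by exhaustive support testing.

    Every nonempty reaction subset is tested: a subset supports an
    elementary mode iff the stoichiometric submatrix over internal
    metabolites has a one-dimensional nullspace whose generator has full
    support and can be oriented to respect irreversibility; minimal
    supports among the feasible candidates are the EFMs.  Exponential in
    the reaction count — a cross-check for small networks only.
    """
    n = net.n_reactions
    if n > max_reactions:
        raise EFMCapError(f"brute force is limited to {max_reactions} reactions")
    internal = net.internal_metabolites(auto_external=auto_external)
    met_idx = {m: i for i, m in enumerate(internal)}
    columns = []
    for cmap in net.coefficients:
        col = [sympy.Rational(0)] * len(internal)
        for m, c in cmap.items():
            if m in met_idx:
                col[met_idx[m]] = sympy.Rational(c.numerator, c.denominator)
        columns.append(col)

    candidates: list[tuple[int, FluxMode]] = []
    for mask in range(1, 1 << n):
        members = [k for k in range(n) if mask >> k & 1]
        if internal:
            sub = sympy.Matrix([[columns[k][i] for k in members] for i in range(len(internal))])
            null = sub.nullspace()
            if len(null) != 1:
                continue
            vec = null[0]
        else:
            if len(members) != 1:
                continue
            vec = sympy.Matrix([1])
        vals = [sympy.Rational(v) for v in vec]
        if any(v == 0 for v in vals):
            continue  # actual support is smaller; found at its own subset
        irrev_signs = {
            sympy.sign(vals[i]) for i, k in enumerate(members) if not net.reversible[k]
        }
        if irrev_signs == {1, -1} or irrev_signs == {-1, 1}:
            continue
        if -1 in irrev_signs:
            vals = [-v for v in vals]
        flux = [Fraction(0)] * n
        for i, k in enumerate(members):
            flux[k] = Fraction(int(vals[i].p), int(vals[i].q))
        canon = _canonical(flux, net.reversible)
        if canon is not None:
            candidates.append((mask, canon))

    modes = []
    for mask, canon in candidates:
        if not any(
            other != mask and (other | mask) == mask for other, _ in candidates
        ):
            modes.append(canon)
    return sorted(set(modes))


def count_efms(net: StoichNetwork, **kwargs) -> int:
    """Number of elementary flux modes (see :func:`enumerate_efms`)."""
    return len(enumerate_efms(net, **kwargs))


def synergy_score(
    efm1: int, efm2: int, efm12: int, mode: str = "ratio"
) -> float:
    """Normalized gain in flux-mode count from conjoining two networks.

    ``"ratio"`` (default): EFM(1,2) / (EFM(1) + EFM(2)) — exactly 1 for a
    fully disjoint pair (the joint modes are the union of the parts) and
    0.5 for an identical pair.  ``"relative_increase"``:
    (EFM(1,2) - EFM(1) - EFM(2)) / (EFM(1) + EFM(2)), the same quantity
    shifted by 1.
    """
    if efm1 < 0 or efm2 < 0 or efm12 < 0:
        raise ValueError("EFM counts must be nonnegative")
    denom = efm1 + efm2
    if denom == 0:
        raise ValueError("synergy score undefined: both constituent networks have 0 EFMs")
    if mode == "ratio":
        return efm12 / denom
    if mode == "relative_increase":
        return (efm12 - denom) / denom
    raise ValueError(f"mode must be 'ratio' or 'relative_increase', got {mode!r}")


@dataclasses.dataclass
class SynergyPoint:
    """Replicate synergy scores at one target Jaccard coefficient."""

    target_jc: float
    scores: list[float]
    counts: list[tuple[int, int, int]]  # (EFM1, EFM2, EFM12) per replicate
    n_skipped: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sem(self) -> float:
        """Standard error of the mean over replicates."""
        if len(self.scores) < 2:
            return float("nan")
        return float(np.std(self.scores, ddof=1) / math.sqrt(len(self.scores)))


def synergy_curve(
    main: StoichNetwork,
    jc_grid: Sequence[float],
    n_pairs: int,
    P: float = 0.8,
    seed: int = 0,
    mode: str = "ratio",
    cap: int = 32,
) -> list[SynergyPoint]:
    """Mean ± SEM synergy score across a grid of target overlaps.

    For each grid value, ``n_pairs`` independent replicates are drawn:
    sample a source network covering fraction P of the main network,
    build a paired network set at the target Jc, enumerate EFMs of the
    two components and the joint network, and score.  Replicates whose
    enumeration exceeds the cap — or whose constituents have no flux mode
    at all — are recorded as skipped; a grid point with every replicate
    skipped raises.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    points = []
    for jc in jc_grid:
        scores: list[float] = []
        counts: list[tuple[int, int, int]] = []
        skipped = 0
        for _ in range(n_pairs):
            s1, s2 = (int(x) for x in rng.integers(2**31, size=2))
            try:
                source = sample_source_network(main, P, seed=s1)
                pair = build_paired_networks(source, jc, seed=s2)
                e1 = count_efms(pair.c1, cap=cap)
                e2 = count_efms(pair.c2, cap=cap)
                e12 = count_efms(pair.c12, cap=cap)
                if e1 + e2 == 0:
                    skipped += 1
                    continue
                scores.append(synergy_score(e1, e2, e12, mode=mode))
                counts.append((e1, e2, e12))
            except EFMCapError:
                skipped += 1
        if not scores:
            raise RuntimeError(
                f"every replicate at Jc={jc} was skipped (cap or zero-mode draws)"
            )
        points.append(
            SynergyPoint(target_jc=float(jc), scores=scores, counts=counts, n_skipped=skipped)
        )
    return points
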