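"""Stoichiometric networks and randomized paired-network construction.

A network is a metabolites × reactions coefficient matrix (exact rational
coefficients, consumed negative / produced positive) with a reversibility
flag per reaction and a set of external metabolites exempt from the
steady-state constraint.

Paired networks model two interacting species with a prescribed enzyme
overlap: from a source network of R_s reactions, R_int = round(Jc · R_s)
shared reactions and two disjoint private sets of (R_s - R_int)/2
reactions each are drawn, so the two component networks have Jaccard
coefficient R_int / R_s.  In the joint network, private metabolites not
touched by any shared reaction are renamed per side so that no overlap
beyond the chosen shared reactions sneaks in through common metabolite
names.
"""

from __future__ import annotations

import dataclasses
import re
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "StoichNetwork",
    "PairedNetworkSet",
    "read_network",
    "write_network",
    "sample_source_network",
    "build_paired_networks",
]


@dataclasses.dataclass(frozen=True)
class StoichNetwork:
    """An exact-arithmetic stoichiometric network.

    ``coefficients[k]`` maps metabolite ids to rational coefficients for
    reaction ``reactions[k]`` (consumed negative, produced positive);
    ``reversible[k]`` flags reversibility; ``externals`` lists metabolites
    exempt from steady state (environment exchange species).
    """

    metabolites: tuple[str, ...]
    reactions: tuple[str, ...]
    coefficients: tuple[Mapping[str, Fraction], ...]
    reversible: tuple[bool, ...]
    externals: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.reactions)) != len(self.reactions):
            dup = sorted({r for r in self.reactions if self.reactions.count(r) > 1})
            raise ValueError(f"duplicate reaction ids: {dup}")
        if len(self.coefficients) != len(self.reactions) or len(self.reversible) != len(
            self.reactions
        ):
            raise ValueError("coefficients/reversible must align with reactions")
        met_set = set(self.metabolites)
        coeffs = []
        for rid, cmap in zip(self.reactions, self.coefficients):
            cmap = {m: Fraction(c) for m, c in cmap.items() if c != 0}
            if not cmap:
                raise ValueError(f"reaction {rid!r} has no nonzero coefficient")
            undeclared = set(cmap) - met_set
            if undeclared:
                raise ValueError(
                    f"reaction {rid!r} references undeclared metabolites: "
                    f"{sorted(undeclared)}"
                )
            coeffs.append(cmap)
        object.__setattr__(self, "coefficients", tuple(coeffs))
        bad_ext = self.externals - met_set
        if bad_ext:
            raise ValueError(f"unknown external metabolites: {sorted(bad_ext)}")

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite_degree(self) -> dict[str, int]:
        """Number of reactions each metabolite participates in."""
        deg = {m: 0 for m in self.metabolites}
        for cmap in self.coefficients:
            for m in cmap:
                deg[m] += 1
        return deg

    def internal_metabolites(self, auto_external: bool = True) -> tuple[str, ...]:
        """Metabolites subject to the steady-state constraint.

        Declared externals are always exempt; with ``auto_external`` a
        metabolite participating in exactly one reaction (a dead end, as
        random subnetworks are riddled with) is treated as external too.
        """
        deg = self.metabolite_degree()
        internal = []
        for m in self.metabolites:
            if m in self.externals:
                continue
            if auto_external and deg[m] <= 1:
                continue
            internal.append(m)
        return tuple(internal)

    def subnetwork(self, reaction_ids: Sequence[str]) -> "StoichNetwork":
        """Restriction to the named reactions; metabolites no longer
        referenced are dropped, external status is inherited."""
        index = {r: k for k, r in enumerate(self.reactions)}
        missing = [r for r in reaction_ids if r not in index]
        if missing:
            raise KeyError(f"unknown reactions: {missing}")
        ks = [index[r] for r in reaction_ids]
        used: set[str] = set()
        for k in ks:
            used |= set(self.coefficients[k])
        mets = tuple(m for m in self.metabolites if m in used)
        return StoichNetwork(
            metabolites=mets,
            reactions=tuple(self.reactions[k] for k in ks),
            coefficients=tuple(self.coefficients[k] for k in ks),
            reversible=tuple(self.reversible[k] for k in ks),
            externals=self.externals & used,
        )


_TERM_RE = re.compile(r"^\s*(?:(\d+(?:/\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, rid: str, lineno: int) -> dict[str, Fraction]:
    terms: dict[str, Fraction] = {}
    side = side.strip()
    if not side:
        return terms
    for term in side.split("+"):
        m = _TERM_RE.match(term)
        if m is None:
            raise ValueError(f"line {lineno}: cannot parse term {term!r} in {rid!r}")
        coeff = Fraction(m.group(1)) if m.group(1) else Fraction(1)
        met = m.group(2)
        terms[met] = terms.get(met, Fraction(0)) + coeff
    return terms


def read_network(path: str | Path) -> StoichNetwork:
    """Read a reaction-list file.

    One reaction per line, ``id : c1 M1 + c2 M2 -> c3 M3`` with ``<->``
    marking reversibility and rational coefficients allowed (``1/2 M``).
    Optional header lines ``external: M1 M2 ...`` declare external
    metabolites; other metabolites are declared implicitly by use, unless
    an optional ``metabolites: ...`` header fixes the allowed set.
    ``#`` starts a comment.
    """
    path = Path(path)
    declared: list[str] | None = None
    externals: set[str] = set()
    rows: list[tuple[str, dict[str, Fraction], bool]] = []
    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("external:"):
                externals.update(line[len("external:"):].split())
                continue
            if line.startswith("metabolites:"):
                declared = line[len("metabolites:"):].split()
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'id : reaction', got {line!r}")
            rid, body = (s.strip() for s in line.split(":", 1))
            if "<->" in body:
                lhs, rhs = body.split("<->", 1)
                rev = True
            elif "->" in body:
                lhs, rhs = body.split("->", 1)
                rev = False
            else:
                raise ValueError(f"{path}:{lineno}: reaction {rid!r} has no arrow")
            cmap: dict[str, Fraction] = {}
            for met, c in _parse_side(lhs, rid, lineno).items():
                cmap[met] = cmap.get(met, Fraction(0)) - c
            for met, c in _parse_side(rhs, rid, lineno).items():
                cmap[met] = cmap.get(met, Fraction(0)) + c
            cmap = {m: c for m, c in cmap.items() if c != 0}
            if not cmap:
                raise ValueError(f"{path}:{lineno}: reaction {rid!r} is empty")
            rows.append((rid, cmap, rev))
    if not rows:
        raise ValueError(f"{path}: no reactions found")
    if declared is None:
        used: set[str] = set(externals)
        for _, cmap, _ in rows:
            used |= set(cmap)
        metabolites = tuple(sorted(used))
    else:
        metabolites = tuple(declared)
    return StoichNetwork(
        metabolites=metabolites,
        reactions=tuple(r for r, _, _ in rows),
        coefficients=tuple(c for _, c, _ in rows),
        reversible=tuple(v for _, _, v in rows),
        externals=frozenset(externals),
    )


def write_network(net: StoichNetwork, path: str | Path) -> None:
    """Serialize in the reaction-list format read by :func:`read_network`."""

    def fmt_side(terms: list[tuple[str, Fraction]]) -> str:
        return " + ".join(
            (f"{c} {m}" if c != 1 else m) for m, c in terms
        )

    with open(path, "w", encoding="utf-8") as fh:
        if net.externals:
            fh.write("external: " + " ".join(sorted(net.externals)) + "\n")
        for rid, cmap, rev in zip(net.reactions, net.coefficients, net.reversible):
            lhs = [(m, -c) for m, c in sorted(cmap.items()) if c < 0]
            rhs = [(m, c) for m, c in sorted(cmap.items()) if c > 0]
            arrow = "<->" if rev else "->"
            fh.write(f"{rid} : {fmt_side(lhs)} {arrow} {fmt_side(rhs)}\n")


def sample_source_network(
    main: StoichNetwork, P: float, seed: int
) -> StoichNetwork:
    """A uniformly random reaction subset covering fraction P of the main
    network (size round(P · R_TOT)); P = 0.8 is the working default that
    keeps flux-mode enumeration tractable."""
    if not 0 < P <= 1:
        raise ValueError(f"coverage P must be in (0, 1], got {P}")
    if P == 1:
        return main
    n = int(round(P * main.n_reactions))
    if n < 2:
        raise ValueError(f"source of {n} reactions is too small")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(main.n_reactions, size=n, replace=False)
    chosen.sort()
    return main.subnetwork([main.reactions[k] for k in chosen])


@dataclasses.dataclass(frozen=True)
class PairedNetworkSet:
    """Two random component networks with a prescribed reaction overlap
    plus their joint network."""

    shared: tuple[str, ...]  # N^int reaction ids
    private_1: tuple[str, ...]  # N^1
    private_2: tuple[str, ...]  # N^2
    c1: StoichNetwork
    c2: StoichNetwork
    c12: StoichNetwork
    target_jc: float

    @property
    def realized_jc(self) -> Fraction:
        """|C1 ∩ C2| / |C1 ∪ C2| = R_int / R_s as an exact rational."""
        r_int = len(self.shared)
        r_s = r_int + len(self.private_1) + len(self.private_2)
        return Fraction(r_int, r_s)

    @property
    def per_network_overlap(self) -> Fraction:
        """Fraction of each component's reactions that are shared,
        R_int / |C1| = 2·Jc / (1 + Jc) at the target overlap."""
        return Fraction(len(self.shared), len(self.shared) + len(self.private_1))


def _rename_private(
    net: StoichNetwork, protected: set[str], suffix: str
) -> StoichNetwork:
    """Rename every metabolite not in ``protected`` with a per-network
    suffix (externals keep their status under the new name)."""
    mapping = {
        m: (m if m in protected else f"{m}{suffix}") for m in net.metabolites
    }
    return StoichNetwork(
        metabolites=tuple(mapping[m] for m in net.metabolites),
        reactions=net.reactions,
        coefficients=tuple(
            {mapping[m]: c for m, c in cmap.items()} for cmap in net.coefficients
        ),
        reversible=net.reversible,
        externals=frozenset(mapping[m] for m in net.externals),
    )


def build_paired_networks(
    source: StoichNetwork, jc: float, seed: int
) -> PairedNetworkSet:
    """Draw a random network pair with target Jaccard coefficient ``jc``.

    R_int = round(jc · R_s), decremented by one when R_s - R_int is odd
    (incremented instead if that would make it negative) so the two
    private sets have equal integral size.  In the joint network, private
    metabolites absent from every shared reaction are renamed per side —
    in particular a metabolite used by both private sets but by no shared
    reaction becomes two distinct species — so the realized overlap is
    exactly the chosen reaction set.
    """
    if not 0 <= jc <= 1:
        raise ValueError(f"target Jaccard coefficient must be in [0, 1], got {jc}")
    r_s = source.n_reactions
    if r_s < 4:
        raise ValueError(f"source network of {r_s} reactions is too small to pair")
    r_int = int(round(jc * r_s))
    if (r_s - r_int) % 2:
        r_int = r_int - 1 if r_int >= 1 else r_int + 1
    if r_int < 0 or r_int > r_s or (r_s - r_int) % 2:
        raise ValueError(f"infeasible sizing: R_s={r_s}, R_int={r_int}")
    n_private = (r_s - r_int) // 2

    rng = np.random.default_rng(seed)
    perm = rng.permutation(r_s)
    shared = tuple(sorted(source.reactions[k] for k in perm[:r_int]))
    priv1 = tuple(
        sorted(source.reactions[k] for k in perm[r_int : r_int + n_private])
    )
    priv2 = tuple(sorted(source.reactions[k] for k in perm[r_int + n_private :]))

    c1 = source.subnetwork(shared + priv1)
    c2 = source.subnetwork(shared + priv2)

    shared_mets: set[str] = set()
    if shared:
        shared_mets = set(source.subnetwork(shared).metabolites)
    part1 = _rename_private(source.subnetwork(priv1), shared_mets, "|1") if priv1 else None
    part2 = _rename_private(source.subnetwork(priv2), shared_mets, "|2") if priv2 else None

    pieces = [p for p in (source.subnetwork(shared) if shared else None, part1, part2) if p]
    mets: list[str] = []
    seen: set[str] = set()
    reactions: list[str] = []
    coeffs: list[Mapping[str, Fraction]] = []
    rev: list[bool] = []
    ext: set[str] = set()
    for piece in pieces:
        for m in piece.metabolites:
            if m not in seen:
                seen.add(m)
                mets.append(m)
        reactions.extend(piece.reactions)
        coeffs.extend(piece.coefficients)
        rev.extend(piece.reversible)
        ext |= piece.externals
    c12 = StoichNetwork(
        metabolites=tuple(mets),
        reactions=tuple(reactions),
        coefficients=tuple(coeffs),
        reversible=tuple(rev),
        externals=frozenset(ext),
    )
    return PairedNetworkSet(
        shared=shared,
        private_1=priv1,
        private_2=priv2,
        c1=c1,
        c2=c2,
        c12=c12,
        target_jc=float(jc),
    )
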