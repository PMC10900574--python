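"""Anomaly-zone detection from coalescent branch lengths.

For a rooted species tree, an internal branch of coalescent length x with a
descendant internal branch of length y produces *anomalous gene trees*
(gene-tree topologies more probable than the one matching the species tree)
whenever y < a(x), with the boundary function

    a(x) = log[ 2/3 + (3 e^{2x} - 2) / (18 (e^{3x} - e^{2x})) ]

a(x) decreases from +inf at x -> 0+ to log(2/3) < 0 as x -> inf, crossing
zero at x* ~ 0.2655; no descendant branch can be anomalous below a parent
branch longer than x*.  The scanner reports every adjacent pair of internal
branches; a simulation-based verifier tabulates gene-tree topologies and
asks whether the species-tree topology is modal.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .msc_sim import SpeciesTree, branch_id, simulate_gene_trees
from .trees import Tree, TreeError, canonical_topology

__all__ = [
    "a_of_x",
    "anomaly_threshold_x",
    "AnomalyPair",
    "scan_anomaly_zone",
    "AnomalySimReport",
    "verify_anomaly_by_simulation",
]


def a_of_x(x: float) -> float:
    """Anomaly-zone boundary a(x) for a parent internal branch of length x
    (coalescent units, e^(-tau) convention)."""
    if x <= 0:
        raise ValueError(f"x must be positive, got {x}")
    e2x = math.exp(2.0 * x)
    e3x = math.exp(3.0 * x)
    return math.log(2.0 / 3.0 + (3.0 * e2x - 2.0) / (18.0 * (e3x - e2x)))


def anomaly_threshold_x(tol: float = 1e-12) -> float:
    """The unique root x* of a(x) = 0 (~0.2655), by bisection.

    Equivalent to the root of 6 e^{3x} - 9 e^{2x} + 2 = 0.
    """
    lo, hi = 1e-9, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if a_of_x(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class AnomalyPair:
    """An adjacent (parent x, child y) internal-branch pair."""

    parent_id: str
    child_id: str
    x: float
    y: float
    a_of_x: float
    in_zone: bool


def _coal_lengths(sp, conversion: float):
    """(tree, node -> coalescent length) for a SpeciesTree or a plain Tree
    whose branch lengths are already in coalescent units."""
    if isinstance(sp, SpeciesTree):
        tree = sp.tree

        def coal(node):
            return sp.coal_len(node) * conversion

    elif isinstance(sp, Tree):
        tree = sp

        def coal(node):
            if node.length is None:
                raise TreeError(
                    f"internal branch {branch_id(node)!r} has no coalescent length"
                )
            return node.length * conversion

    else:
        raise TypeError("expected SpeciesTree or Tree")
    return tree, coal


def scan_anomaly_zone(sp, conversion: float = 1.0) -> list[AnomalyPair]:
    """Flag every adjacent internal-branch pair with y < a(x).

    ``conversion`` rescales input branch lengths into e^(-tau) coalescent
    units for trees estimated under a different unit convention.  Zero-length
    child branches are always flagged.  Pairs are reported in preorder.
    """
    tree, coal = _coal_lengths(sp, conversion)
    pairs = []
    for node in tree.preorder():
        if node.is_tip or node.parent is None:
            continue
        internal_children = [c for c in node.children if not c.is_tip]
        if not internal_children:
            continue
        x = coal(node)
        if x < 0:
            raise TreeError(
                f"internal branch {branch_id(node)!r} has negative "
                f"coalescent length {x}"
            )
        # x = 0 is degenerate: a(x) -> +inf as x -> 0+, so any child is in zone
        ax = math.inf if x == 0 else a_of_x(x)
        for child in internal_children:
            y = coal(child)
            pairs.append(
                AnomalyPair(
                    parent_id=branch_id(node),
                    child_id=branch_id(child),
                    x=x,
                    y=y,
                    a_of_x=ax,
                    in_zone=bool(y < ax or y == 0.0),
                )
            )
    return pairs


@dataclass
class AnomalySimReport:
    """Gene-tree topology tabulation from MSC simulation."""

    n_loci: int
    frequencies: dict  # canonical rooted TopologyID -> fraction
    modal_topology: str
    species_topology: str
    matches_species_tree: bool


def verify_anomaly_by_simulation(
    sp: SpeciesTree, n_loci: int, rng_seed: int | None = None
) -> AnomalySimReport:
    """Simulate gene trees and ask whether the species-tree topology is modal."""
    if n_loci < 1000:
        raise ValueError("n_loci must be >= 1000 for a stable modal call")
    gts = simulate_gene_trees(sp, n_loci, rng_seed=rng_seed)
    counts = Counter(canonical_topology(g) for g in gts)
    modal, _ = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    species_id = canonical_topology(sp.tree)
    return AnomalySimReport(
        n_loci=n_loci,
        frequencies={k: v / n_loci for k, v in sorted(counts.items())},
        modal_topology=modal,
        species_topology=species_id,
        matches_species_tree=modal == species_id,
    )
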