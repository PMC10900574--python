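"""Multispecies-coalescent gene-tree simulation with per-branch theta.

Time runs backward from the present in *mutational units* (expected
substitutions per site).  Within a species-tree branch carrying population
mutation parameter theta = 4*Ne*mu, every pair of lineages coalesces at rate
2/theta per unit of mutational time, so a branch of coalescent length
tau = 2*mut_len/theta leaves two lineages uncoalesced with probability
e^(-tau).  Lineages surviving a branch enter the parent branch; the branch
above the root extends until a single lineage remains.

Pulse admixture is supported: at an event time, every lineage currently in
the recipient branch independently jumps to the donor branch with
probability m before coalescence resumes — a discrete gene-flow pulse used
by the synthetic-study generator to plant introgression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import Node, Tree, TreeError, parse_newick

__all__ = [
    "SpeciesTree",
    "AdmixtureEvent",
    "theta_from_lengths",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "simulate_with_admixture",
    "branch_id",
]


def theta_from_lengths(mut_len: float, coal_len: float) -> float:
    """theta = 2*mut_len/coal_len under tau = T/(2Ne), theta = 4*Ne*mu.

    A branch spanning T generations has mut_len = mu*T and coal_len
    tau = T/(2Ne); their ratio fixes theta = 4*Ne*mu = 2*mut_len/tau.
    """
    if coal_len <= 0:
        raise ValueError(f"coal_len must be positive, got {coal_len}")
    if mut_len < 0:
        raise ValueError(f"mut_len must be non-negative, got {mut_len}")
    return 2.0 * mut_len / coal_len


def branch_id(node: Node) -> str:
    """Stable identifier for the branch above ``node``: its sorted tip set."""
    if node.is_tip:
        return node.label
    tips = sorted(t.label for t in node.postorder() if t.is_tip)
    return "+".join(tips)


@dataclass(frozen=True)
class AdmixtureEvent:
    """A gene-flow pulse: lineages in ``recipient`` jump to ``donor``.

    ``time`` is in mutational units before the present and must fall within
    the lifespan of both branches; ``m`` is the per-lineage migration
    probability.
    """

    time: float
    donor: str
    recipient: str
    m: float
    movers: tuple | None = None

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise ValueError(f"m must be in [0, 1], got {self.m}")
        if self.time < 0:
            raise ValueError("event time must be non-negative")

    def with_movers(self, movers) -> "AdmixtureEvent":
        """Pin the event to a fixed set of sample labels: lineages all of
        whose descendant samples are in ``movers`` jump deterministically.
        Used to make introgressed tracts coherent across nearby loci."""
        return AdmixtureEvent(self.time, self.donor, self.recipient, self.m, tuple(sorted(movers)))


class SpeciesTree:
    """A rooted species tree with dual-unit branch lengths and per-branch theta.

    Branch lengths on the wrapped :class:`~phylodisc.trees.Tree` are in
    mutational units (mu*T); per-branch annotations may carry ``tau``
    (coalescent units) and ``theta``.  Missing thetas are filled where
    derivable (theta = 2*mut_len/tau); branches with no usable theta
    (typically terminals, whose coalescent lengths species-tree methods do
    not estimate) default to the mean internal-branch theta, overridable
    via ``default_theta``.
    """

    def __init__(self, tree: Tree, default_theta: float | None = None):
        self.tree = tree
        self._theta: dict[int, float] = {}
        self._ids: dict[str, Node] = {}
        for node in tree.preorder():
            self._ids[branch_id(node)] = node
        internal_thetas = []
        for node in tree.preorder():
            th = node.annotations.get("theta")
            tau = node.annotations.get("tau")
            if th is None and tau is not None and tau > 0 and node.length is not None:
                th = theta_from_lengths(node.length, tau)
                node.annotations["theta"] = th
            if th is not None:
                self._theta[id(node)] = float(th)
                if not node.is_tip:
                    internal_thetas.append(float(th))
        if default_theta is None:
            default_theta = float(np.mean(internal_thetas)) if internal_thetas else None
        self.default_theta = default_theta
        self._ages = self._compute_ages()

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, default_theta: float | None = None) -> "SpeciesTree":
        return cls(parse_newick(text), default_theta=default_theta)

    @classmethod
    def from_coalescent(cls, tree: Tree, theta: float) -> "SpeciesTree":
        """Reinterpret a tree with coalescent-unit branch lengths under a uniform theta.

        Branch lengths are converted to mutational units (mut = theta*tau/2)
        and every branch is annotated with the given theta.
        """
        t = tree.copy()
        for node in t.preorder():
            if node.length is not None:
                node.annotations["tau"] = node.length
                node.length = node.length * theta / 2.0
            node.annotations["theta"] = theta
        return cls(t, default_theta=theta)

    # -- bookkeeping --------------------------------------------------------
    def _compute_ages(self) -> dict[int, float]:
        ages: dict[int, float] = {}
        for node in self.tree.postorder():
            if node.is_tip:
                ages[id(node)] = 0.0
            else:
                ages[id(node)] = max(
                    ages[id(c)] + (c.length or 0.0) for c in node.children
                )
        return ages

    def age(self, node: Node) -> float:
        return self._ages[id(node)]

    def node(self, bid: str) -> Node:
        try:
            return self._ids[bid]
        except KeyError:
            raise TreeError(f"no branch with id {bid!r}") from None

    def theta(self, node: Node) -> float:
        th = self._theta.get(id(node), self.default_theta)
        if th is None or th <= 0:
            raise ValueError(
                f"branch {branch_id(node)!r} has no positive theta and no default"
            )
        return th

    def coal_len(self, node: Node) -> float:
        """Coalescent length of the branch above ``node`` (tau = 2*mut_len/theta)."""
        tau = node.annotations.get("tau")
        if tau is not None:
            return float(tau)
        if node.length is None:
            raise TreeError(f"branch {branch_id(node)!r} has no length")
        return 2.0 * node.length / self.theta(node)

    def branch_span(self, node: Node) -> tuple[float, float]:
        """Backward-time interval [bottom, top) occupied by the branch above ``node``."""
        bottom = self.age(node)
        top = self.age(node.parent) if node.parent is not None else math.inf
        return bottom, top

    def with_theta(self, theta: float) -> "SpeciesTree":
        """Copy with every branch's theta replaced by a uniform value."""
        t = self.tree.copy()
        for node in t.preorder():
            node.annotations["theta"] = theta
        return SpeciesTree(t, default_theta=theta)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _normalize_samples(sp: SpeciesTree, samples_per_species) -> dict[str, int]:
    labels = sorted(sp.tree.tip_labels)
    if samples_per_species is None:
        return {l: 1 for l in labels}
    if isinstance(samples_per_species, int):
        return {l: samples_per_species for l in labels}
    out = {l: int(samples_per_species.get(l, 1)) for l in labels}
    if any(v < 1 for v in out.values()):
        raise ValueError("samples_per_species must be >= 1 for every species")
    return out


def sample_label(species: str, index: int, count: int) -> str:
    return species if count == 1 else f"{species}_{index + 1}"


def species_of_sample(label: str) -> str:
    """Inverse of :func:`sample_label` for multi-sample tips."""
    base, _, idx = label.rpartition("_")
    if base and idx.isdigit():
        return base
    return label


def _coalesce_in_branch(lineages, heights, t, t_end, theta, rng):
    """Exponential-waiting-time coalescent among ``lineages`` until ``t_end``."""
    k = len(lineages)
    while k >= 2:
        rate = k * (k - 1) / theta  # C(k,2) pairs x 2/theta
        t = t + rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        parent = Node()
        heights[id(parent)] = t
        parent.add_child(lineages[i])
        parent.add_child(lineages[j])
        lineages[i] = parent
        lineages.pop(j)
        k -= 1
    return lineages


def _validate_events(sp: SpeciesTree, events) -> list[AdmixtureEvent]:
    out = []
    for ev in events:
        if (ev.movers is None and ev.m == 0.0) or ev.movers == ():
            continue  # no-op pulse: keep the random stream identical to no-event runs
        dnode, rnode = sp.node(ev.donor), sp.node(ev.recipient)
        for nm, node in (("donor", dnode), ("recipient", rnode)):
            lo, hi = sp.branch_span(node)
            if not (lo <= ev.time < hi):
                raise TreeError(
                    f"event time {ev.time} outside {nm} branch "
                    f"{branch_id(node)!r} span [{lo}, {hi})"
                )
        out.append(ev)
    return out


def simulate_gene_tree(
    sp: SpeciesTree,
    samples_per_species=None,
    rng=None,
    events: tuple = (),
) -> Tree:
    """Simulate one gene tree under the MSC (optionally with pulse admixture).

    Returns an ultrametric :class:`Tree` with branch lengths in mutational
    units; tip labels are the species labels (suffixed ``_i`` when a species
    contributes several samples).
    """
    rng = np.random.default_rng(rng)
    samples = _normalize_samples(sp, samples_per_species)
    events = _validate_events(sp, events)

    heights: dict[int, float] = {}
    pools: dict[int, list[Node]] = {}
    for tip in sp.tree.tips():
        lin = []
        for i in range(samples[tip.label]):
            node = Node(sample_label(tip.label, i, samples[tip.label]))
            heights[id(node)] = 0.0
            lin.append(node)
        pools[id(tip)] = lin

    # Schedule: admixture pulses first at ties, then speciation merges;
    # tied merges (zero-length branches) run deepest-first so child pools
    # are populated before the parent collects them.
    depth: dict[int, int] = {id(sp.tree.root): 0}
    for node in sp.tree.preorder():
        for c in node.children:
            depth[id(c)] = depth[id(node)] + 1
    sched: list = []
    for node in sp.tree.internal_nodes(include_root=True):
        sched.append((sp.age(node), 1, -depth[id(node)], "merge", node))
    for ev in events:
        sched.append((ev.time, 0, 0, "pulse", ev))
    sched.sort(key=lambda x: (x[0], x[1], x[2]))

    t_prev: dict[int, float] = {id(n): sp.age(n) for n in sp.tree.preorder()}

    def advance(node: Node, t_to: float):
        lin = pools.get(id(node))
        if lin and len(lin) >= 2:
            pools[id(node)] = _coalesce_in_branch(
                lin, heights, t_prev[id(node)], t_to, sp.theta(node), rng
            )
        t_prev[id(node)] = t_to

    for t_ev, _, _, kind, payload in sched:
        if kind == "pulse":
            ev = payload
            rnode, dnode = sp.node(ev.recipient), sp.node(ev.donor)
            advance(rnode, t_ev)
            advance(dnode, t_ev)
            stay, move = [], []
            for x in pools.get(id(rnode), []):
                if ev.movers is not None:
                    jumps = all(
                        t.label in ev.movers for t in x.postorder() if t.is_tip
                    )
                else:
                    jumps = rng.random() < ev.m
                (move if jumps else stay).append(x)
            pools[id(rnode)] = stay
            pools.setdefault(id(dnode), []).extend(move)
        else:
            node = payload
            merged: list[Node] = list(pools.get(id(node), []))
            for c in node.children:
                advance(c, t_ev)
                merged.extend(pools.pop(id(c), []))
            pools[id(node)] = merged
            t_prev[id(node)] = t_ev

    # Above the root: a single open-ended branch with the root's theta.
    root = sp.tree.root
    lin = pools[id(root)]
    if len(lin) > 1:
        lin = _coalesce_in_branch(
            lin, heights, t_prev[id(root)], math.inf, sp.theta(root), rng
        )
    (g_root,) = lin
    for node in g_root.preorder():
        for c in node.children:
            c.length = heights[id(node)] - heights[id(c)]
    g_root.length = None
    return Tree(g_root)


def simulate_gene_trees(
    sp: SpeciesTree,
    n: int,
    theta_override: float | None = None,
    rng_seed: int | None = None,
    samples_per_species=None,
    events: tuple = (),
) -> list[Tree]:
    """Simulate ``n`` independent gene trees.

    ``theta_override`` replaces every branch's theta by a uniform value
    while keeping mutational branch lengths — the low/high-ILS regimes use
    0.001 and 0.1.  Per-locus generators are seeded ``rng_seed + locus`` for
    reproducible parallelism.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if theta_override is not None:
        sp = sp.with_theta(theta_override)
    base = 0 if rng_seed is None else int(rng_seed)
    return [
        simulate_gene_tree(
            sp,
            samples_per_species=samples_per_species,
            rng=np.random.default_rng(base + i),
            events=events,
        )
        for i in range(n)
    ]


def simulate_with_admixture(
    sp: SpeciesTree,
    events,
    samples_per_species=None,
    rng=None,
) -> Tree:
    """:func:`simulate_gene_tree` with a mandatory event list."""
    return simulate_gene_tree(
        sp, samples_per_species=samples_per_species, rng=rng, events=tuple(events)
    )
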