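"""TWISST-style topology weighting in genomic windows.

For a window tree whose tips belong to taxon groups, the weight of a
candidate group topology is the fraction of one-tip-per-group subtrees
(including one outgroup tip, used only to root) that induce it.  With four
ingroup groups the candidate space is the 15 rooted leaf-labelled
topologies.  Windows can then be stratified by a covariate (e.g. a
recombination rate) into upper/lower percentile sets and the per-topology
weights compared between strata with rank-sum tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import seqevolve
from .trees import Tree, TreeError, canonical_topology, enumerate_rooted_topologies, restrict, root_with_outgroup

__all__ = [
    "TopologyWeightRecord",
    "StratifiedWindows",
    "enumerate_group_topologies",
    "topology_weights",
    "windows_pipeline",
    "stratify_and_compare",
    "summarize_weights",
]

EXACT_COMBINATION_LIMIT = 10_000_000


@dataclass
class TopologyWeightRecord:
    chrom: str | None
    start: int | None
    end: int | None
    weights: dict | None  # TopologyID -> weight; None when the window is masked
    n_subtrees: int = 0

    @property
    def masked(self) -> bool:
        return self.weights is None

    @property
    def modal(self) -> str | None:
        """Modal topology; ties broken by lexicographically smallest ID."""
        if self.weights is None:
            return None
        best = max(self.weights.values())
        return min(k for k, v in self.weights.items() if v == best)


def enumerate_group_topologies(groups: list[str]) -> list[str]:
    """Canonical IDs of all rooted topologies over the ingroup group labels."""
    return sorted(canonical_topology(t) for t in enumerate_rooted_topologies(sorted(groups)))


def _induced_group_topology(tree: Tree, combo: dict, outgroup_tip: str) -> str:
    """Topology ID of the group-relabelled subtree spanned by one tip per
    group, rooted with the outgroup tip."""
    sub = restrict(tree, list(combo.values()) + [outgroup_tip])
    rooted = root_with_outgroup(sub, outgroup_tip)
    (out_child, ingroup_root) = rooted.root.children
    if out_child.label != outgroup_tip:
        out_child, ingroup_root = ingroup_root, out_child
    tip_to_group = {tip: grp for grp, tip in combo.items()}
    for node in ingroup_root.preorder():
        if node.is_tip:
            node.label = tip_to_group[node.label]
        node.length = None
    ingroup_root.parent = None
    return canonical_topology(Tree(ingroup_root))


def topology_weights(
    window_tree: Tree,
    groups: dict,
    outgroup_group: str,
    mode: str = "exact",
    n_samples: int = 10_000,
    rng_seed=None,
) -> TopologyWeightRecord:
    """Topology weights of one window tree.

    ``groups`` maps every tip label to its group; ``outgroup_group`` names
    the group used for rooting (it does not appear in the topology IDs).
    Exact mode iterates all one-tip-per-group combinations; sample mode
    draws ``n_samples`` uniformly.
    """
    tips = window_tree.tip_labels
    missing = tips - set(groups)
    if missing:
        raise TreeError(f"tips without a group assignment: {sorted(missing)}")
    members: dict[str, list] = {}
    for tip, grp in groups.items():
        if tip in tips:
            members.setdefault(grp, []).append(tip)
    for grp in members:
        members[grp].sort()
    if outgroup_group not in members:
        raise TreeError(f"no tips in outgroup group {outgroup_group!r}")
    ingroups = sorted(g for g in members if g != outgroup_group)
    if len(ingroups) < 3:
        raise TreeError("need at least 3 ingroup groups")
    space = enumerate_group_topologies(ingroups)
    counts = dict.fromkeys(space, 0)

    n_comb = int(np.prod([len(members[g]) for g in ingroups + [outgroup_group]]))
    if mode == "exact":
        if n_comb > EXACT_COMBINATION_LIMIT:
            raise ValueError(
                f"{n_comb} combinations exceed the exact-mode limit; use mode='sample'"
            )
        total = 0
        for combo_tips in itertools.product(*(members[g] for g in ingroups)):
            combo = dict(zip(ingroups, combo_tips))
            for out_tip in members[outgroup_group]:
                tid = _induced_group_topology(window_tree, combo, out_tip)
                counts[tid] += 1
                total += 1
    elif mode == "sample":
        rng = np.random.default_rng(rng_seed)
        total = n_samples
        for _ in range(n_samples):
            combo = {g: members[g][rng.integers(len(members[g]))] for g in ingroups}
            out_tip = members[outgroup_group][rng.integers(len(members[outgroup_group]))]
            tid = _induced_group_topology(window_tree, combo, out_tip)
            counts[tid] += 1
    else:
        raise ValueError("mode must be 'exact' or 'sample'")
    weights = {k: v / total for k, v in counts.items()}
    return TopologyWeightRecord(None, None, None, weights, n_subtrees=total)


def windows_pipeline(
    windows,
    groups: dict,
    outgroup_group: str,
    min_sites: int = 50,
    mode: str = "exact",
    n_samples: int = 10_000,
    rng_seed=None,
) -> list[TopologyWeightRecord]:
    """Weights per genomic window.

    ``windows`` is an iterable of ``(chrom, start, end, payload)`` where the
    payload is a window :class:`~phylodisc.seqevolve.Alignment` (a
    neighbor-joining window tree is estimated) or an already-built
    :class:`~phylodisc.trees.Tree`, or None.  Windows with no payload or
    fewer than ``min_sites`` sites are masked.
    """
    out = []
    for chrom, start, end, payload in windows:
        tree = None
        if isinstance(payload, Tree):
            tree = payload
            grouped = tree.tip_labels & set(groups)
            if len(grouped) < len(tree.tip_labels):
                tree = restrict(tree, grouped) if len(grouped) >= 2 else None
        elif payload is not None and payload.n_sites >= min_sites:
            # estimate from the grouped taxa only: unassigned taxa would only
            # add placement noise to a tree used for group weights
            rows = [i for i, t in enumerate(payload.taxa) if t in groups]
            if len(rows) >= 3:
                sub = seqevolve.Alignment(
                    [payload.taxa[i] for i in rows], payload.matrix[rows]
                )
                tree = seqevolve.estimate_gene_tree(sub)
        if tree is None:
            out.append(TopologyWeightRecord(chrom, start, end, None))
            continue
        rec = topology_weights(
            tree, groups, outgroup_group, mode=mode, n_samples=n_samples, rng_seed=rng_seed
        )
        rec.chrom, rec.start, rec.end = chrom, start, end
        out.append(rec)
    return out


def cherry_weight(record: TopologyWeightRecord, group_a: str, group_b: str) -> float | None:
    """Summed weight of all topologies in which ``group_a`` and ``group_b``
    are sisters.  The natural response for a planted gene-flow signal: an
    introgression pulse makes the recipient sister to the donor, while the
    arrangement of the remaining groups stays ILS-distributed, so the
    signal spreads over every topology containing that cherry."""
    if record.masked:
        return None
    key = "(" + ",".join(sorted((group_a, group_b))) + ")"
    return sum(v for k, v in record.weights.items() if key in k)


def summarize_weights(records) -> dict:
    """Both window-level summaries: share of windows whose *modal* topology
    is each candidate, and the mean weight per candidate."""
    live = [r for r in records if not r.masked]
    if not live:
        return {"n_windows": 0, "modal_share": {}, "mean_weight": {}}
    space = sorted(live[0].weights)
    modal = {t: 0 for t in space}
    for r in live:
        modal[r.modal] += 1
    return {
        "n_windows": len(live),
        "modal_share": {t: modal[t] / len(live) for t in space},
        "mean_weight": {
            t: float(np.mean([r.weights[t] for r in live])) for t in space
        },
    }


@dataclass
class StratifiedWindows:
    covariate: str
    upper: list  # (chrom, start) keys
    lower: list
    upper_mean_weights: dict
    lower_mean_weights: dict
    statistics: dict  # topology -> (U, p, p_adjusted)


def stratify_and_compare(
    records,
    covariates: dict,
    percentile: float = 10.0,
    response: str = "weights",
    fd_values: dict | None = None,
    cherry_groups: tuple | None = None,
    covariate_name: str = "covariate",
    min_windows: int = 10,
) -> StratifiedWindows:
    """Compare responses between upper- and lower-percentile covariate windows.

    ``covariates`` maps ``(chrom, start)`` to the covariate value and must
    cover every unmasked window.  Windows are ranked by covariate (ties
    broken by coordinate, so a constant covariate still yields deterministic
    complementary strata); the top and bottom ``percentile`` % form the two
    sets.  ``response='weights'`` compares per-topology weights with
    two-sided Mann-Whitney rank-sum tests (BH-adjusted);
    ``response='fd'`` compares the ``fd_values`` of the windows instead.
    """
    live = [r for r in records if not r.masked]
    missing = [(r.chrom, r.start) for r in live if (r.chrom, r.start) not in covariates]
    if missing:
        raise ValueError(f"covariate missing for windows: {missing[:5]} ...")
    ranked = sorted(live, key=lambda r: (covariates[(r.chrom, r.start)], r.chrom, r.start))
    n = len(ranked)
    k = int(round(n * percentile / 100.0))
    k = max(k, 1)
    if k < min_windows:
        raise ValueError(
            f"{k} windows per stratum (< {min_windows}); not enough for a comparison"
        )
    lower, upper = ranked[:k], ranked[-k:]

    def mean_weights(rs):
        space = sorted(rs[0].weights)
        return {t: float(np.mean([r.weights[t] for r in rs])) for t in space}

    stats = {}
    if response == "weights":
        space = sorted(live[0].weights)
        pvals, keys = [], []
        for t in space:
            u_vals = [r.weights[t] for r in upper]
            l_vals = [r.weights[t] for r in lower]
            if np.ptp(u_vals + l_vals) == 0:
                stats[t] = (float("nan"), 1.0, None)
                continue
            u, p = mannwhitneyu(u_vals, l_vals, alternative="two-sided")
            stats[t] = (float(u), float(p), None)
            pvals.append(p)
            keys.append(t)
        if pvals:
            adj = multipletests(pvals, method="fdr_bh")[1]
            for t, a in zip(keys, adj):
                stats[t] = (stats[t][0], stats[t][1], float(a))
    elif response == "cherry":
        if not cherry_groups:
            raise ValueError("cherry_groups required for response='cherry'")
        a, b = cherry_groups
        u_vals = [cherry_weight(r, a, b) for r in upper]
        l_vals = [cherry_weight(r, a, b) for r in lower]
        u, p = mannwhitneyu(u_vals, l_vals, alternative="two-sided")
        stats["cherry"] = (float(u), float(p), float(p))
    elif response == "fd":
        if fd_values is None:
            raise ValueError("fd_values required for response='fd'")
        u_vals = [fd_values.get((r.chrom, r.start)) for r in upper]
        l_vals = [fd_values.get((r.chrom, r.start)) for r in lower]
        u_vals = [v for v in u_vals if v is not None]
        l_vals = [v for v in l_vals if v is not None]
        u, p = mannwhitneyu(u_vals, l_vals, alternative="two-sided")
        stats["fd"] = (float(u), float(p), float(p))
    else:
        raise ValueError("response must be 'weights' or 'fd'")

    return StratifiedWindows(
        covariate=covariate_name,
        upper=[(r.chrom, r.start) for r in upper],
        lower=[(r.chrom, r.start) for r in lower],
        upper_mean_weights=mean_weights(upper),
        lower_mean_weights=mean_weights(lower),
        statistics=stats,
    )
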