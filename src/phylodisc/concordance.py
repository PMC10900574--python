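"""Gene concordance factors, the quartet polytomy test, and the
discordance-explained ratio.

Every internal species-tree branch splits the taxa into four groups: the
two child clades (A, B), the sister clade(s) (C) and everything else (D).
A gene tree is *decisive* for the branch when it contains at least one
taxon from each group.  Among decisive gene trees,

* gCF  — % containing the species-tree split  A+B | C+D,
* gDF1 — % containing the first  alternative  A+C | B+D,
* gDF2 — % containing the second alternative  A+D | B+C,
* gDFp — % resolving none of the three (non-monophyletic groups),

so the four percentages sum to 100 per branch.  The polytomy test asks, per
branch, whether the three resolved counts are compatible with the equal
1/3:1/3:1/3 expectation a hard polytomy would produce (chi-square, 2 df).

The discordance-explained ratio compares mean gene-tree/species-tree
distances of simulated gene trees (optionally passed through sequence
simulation and re-estimation to add gene-tree estimation error) against the
mean distance of empirically estimated gene trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from . import seqevolve
from .msc_sim import SpeciesTree, branch_id, simulate_gene_trees
from .trees import (
    Tree,
    TreeError,
    clades,
    matching_cluster_distance,
    restrict,
    rf_cluster_distance,
    root_with_outgroup,
)

__all__ = [
    "ConcordanceRecord",
    "PolytomyTestRecord",
    "SimulationRegime",
    "RegimeResult",
    "DiscordanceReport",
    "branch_groups",
    "concordance_factors",
    "polytomy_test",
    "discordance_ratio",
]


@dataclass
class ConcordanceRecord:
    branch_id: str
    n_decisive: int
    gcf: float
    gdf1: float
    gdf2: float
    gdfp: float
    counts: tuple = (0, 0, 0, 0)  # concordant, alt1, alt2, paraphyletic


@dataclass
class PolytomyTestRecord:
    branch_id: str
    n1: int
    n2: int
    n3: int
    chi2: float | None
    p_value: float | None
    rejected: bool | None

    @property
    def n_decisive(self) -> int:
        return self.n1 + self.n2 + self.n3


def branch_groups(sp_tree: Tree) -> list[tuple[str, tuple]]:
    """Per internal non-root branch: (branch_id, (A, B, C, D) tip-label sets).

    A and B are the child clades (A holds the lexicographically smallest
    tip), C the sister group, D the remainder.  Branches without four
    non-empty groups (a child of a bifurcating root) are skipped.
    """
    cm: dict = {}
    for node in sp_tree.postorder():
        cm[id(node)] = (
            frozenset([node.label])
            if node.is_tip
            else frozenset().union(*(cm[id(c)] for c in node.children))
        )
    full = cm[id(sp_tree.root)]
    out = []
    for node in sp_tree.preorder():
        if node.is_tip or node.parent is None:
            continue
        if len(node.children) != 2:
            continue  # concordance factors are defined on bifurcations
        a, b = (cm[id(c)] for c in node.children)
        if min(a) > min(b):
            a, b = b, a
        c = frozenset().union(
            *(cm[id(s)] for s in node.parent.children if s is not node)
        )
        d = full - a - b - c
        if not d:
            continue
        out.append((branch_id(node), (a, b, c, d)))
    return out


def _classify_splits(gene_tree: Tree, groups: tuple) -> int | None:
    """0 = concordant, 1/2 = alternatives, 3 = resolves none, None = not decisive."""
    present = gene_tree.tip_labels
    pa, pb, pc, pd = (g & present for g in groups)
    if not (pa and pb and pc and pd):
        return None
    rg = restrict(gene_tree, pa | pb | pc | pd)
    cl = clades(rg)
    for idx, (left, right) in enumerate(
        ((pa | pb, pc | pd), (pa | pc, pb | pd), (pa | pd, pb | pc))
    ):
        if left in cl or right in cl:
            return idx
    return 3


def concordance_factors(sp: SpeciesTree | Tree, gene_trees) -> list[ConcordanceRecord]:
    """Per-branch gCF/gDF1/gDF2/gDFp percentages over decisive gene trees."""
    sp_tree = sp.tree if isinstance(sp, SpeciesTree) else sp
    records = []
    for bid, groups in branch_groups(sp_tree):
        counts = [0, 0, 0, 0]
        for gt in gene_trees:
            cls = _classify_splits(gt, groups)
            if cls is not None:
                counts[cls] += 1
        n = sum(counts)
        pct = [100.0 * c / n if n else float("nan") for c in counts]
        records.append(
            ConcordanceRecord(
                branch_id=bid,
                n_decisive=n,
                gcf=pct[0],
                gdf1=pct[1],
                gdf2=pct[2],
                gdfp=pct[3],
                counts=tuple(counts),
            )
        )
    return records


def _majority_quartet(gene_tree: Tree, groups: tuple, max_combinations: int = 200000):
    """Tree-level resolution: majority vote over one-tip-per-group quartets.

    Returns 0/1/2 for the three resolutions, or None on a tie.
    """
    from itertools import product

    present = gene_tree.tip_labels
    sets = [sorted(g & present) for g in groups]
    if any(not s for s in sets):
        return None
    n_comb = np.prod([len(s) for s in sets])
    if n_comb > max_combinations:
        raise ValueError(
            f"{n_comb} quartet combinations; too many for exact majority vote"
        )
    tally = [0, 0, 0]
    for a, b, c, d in product(*sets):
        rq = restrict(gene_tree, (a, b, c, d))
        cl = clades(rq)
        res = 3
        for idx, (l, r) in enumerate(
            ((frozenset((a, b)), frozenset((c, d))),
             (frozenset((a, c)), frozenset((b, d))),
             (frozenset((a, d)), frozenset((b, c)))),
        ):
            if l in cl or r in cl:
                res = idx
                break
        if res < 3:
            tally[res] += 1
    best = max(tally)
    if best == 0 or tally.count(best) > 1:
        return None
    return tally.index(best)


def polytomy_test(sp: SpeciesTree | Tree, gene_trees, alpha: float = 0.05):
    """Chi-square test of the three quartet-resolution counts against 1:1:1.

    One count per decisive gene tree, by majority of its induced quartets
    around the branch; p < alpha rejects the polytomy null for that branch.
    """
    sp_tree = sp.tree if isinstance(sp, SpeciesTree) else sp
    records = []
    for bid, groups in branch_groups(sp_tree):
        counts = [0, 0, 0]
        for gt in gene_trees:
            res = _majority_quartet(gt, groups)
            if res is not None:
                counts[res] += 1
        n = sum(counts)
        if n == 0:
            records.append(
                PolytomyTestRecord(bid, 0, 0, 0, None, None, None)
            )
            continue
        expected = n / 3.0
        stat = sum((c - expected) ** 2 / expected for c in counts)
        p = float(chi2.sf(stat, df=2))
        records.append(
            PolytomyTestRecord(bid, *counts, chi2=stat, p_value=p, rejected=p < alpha)
        )
    return records


# ---------------------------------------------------------------------------
# Discordance-explained ratio
# ---------------------------------------------------------------------------

@dataclass
class SimulationRegime:
    """One simulation arm: a uniform theta, optionally with the
    sequence-simulation + re-estimation step that adds estimation error."""

    theta: float
    label: str = ""
    estimation_error: bool = False
    seq_length: int = seqevolve.INTRON_LENGTH
    model: seqevolve.SubstitutionModel = field(
        default_factory=seqevolve.SubstitutionModel
    )
    n_trees: int = 1500

    def __post_init__(self):
        if not self.label:
            err = "+err" if self.estimation_error else ""
            self.label = f"theta={self.theta:g}{err}"


@dataclass
class RegimeResult:
    label: str
    theta: float
    estimation_error: bool
    mean: float
    ci: tuple
    explained_ratio: float  # NaN when the empirical mean is 0
    flagged: bool


@dataclass
class DiscordanceReport:
    metric: str
    empirical_mean: float
    empirical_ci: tuple
    regimes: list


_METRICS = {"rf": rf_cluster_distance, "mc": matching_cluster_distance}


def _mean_ci(values: np.ndarray) -> tuple[float, tuple]:
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return mean, (mean - 1.96 * se, mean + 1.96 * se)


def discordance_ratio(
    empirical_trees,
    sp: SpeciesTree,
    regimes,
    metric: str = "rf",
    rng_seed: int | None = None,
    outgroup: str | None = None,
) -> DiscordanceReport:
    """Mean simulated distance to the species tree / mean empirical distance.

    A ratio of 1 means the regime (ILS at the given theta, plus estimation
    error when enabled) fully accounts for the observed heterogeneity.
    When the estimation arm is on, each simulated gene tree is passed
    through sequence simulation and neighbor-joining re-estimation, then
    rooted with ``outgroup`` before the rooted-cluster distance.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if len(empirical_trees) < 2:
        raise ValueError("need at least 2 empirical gene trees")
    dist = _METRICS[metric]
    sp_topo = sp.tree

    emp = np.array([dist(t, sp_topo) for t in empirical_trees], dtype=float)
    emp_mean, emp_ci = _mean_ci(emp)

    base = 0 if rng_seed is None else int(rng_seed)
    results = []
    for k, regime in enumerate(regimes):
        gts = simulate_gene_trees(
            sp, regime.n_trees, theta_override=regime.theta,
            rng_seed=base + 100_000 * (k + 1),
        )
        if regime.estimation_error:
            if outgroup is None:
                raise ValueError("outgroup required for the estimation-error arm")
            est = []
            for i, gt in enumerate(gts):
                aln = seqevolve.simulate_alignment(
                    gt, regime.model, regime.seq_length,
                    rng_seed=base + 100_000 * (k + 1) + i + 1,
                )
                est.append(root_with_outgroup(seqevolve.estimate_gene_tree(aln), outgroup))
            gts = est
        d = np.array([dist(t, sp_topo) for t in gts], dtype=float)
        mean, ci = _mean_ci(d)
        flagged = emp_mean == 0.0
        ratio = float("nan") if flagged else mean / emp_mean
        results.append(
            RegimeResult(
                label=regime.label,
                theta=regime.theta,
                estimation_error=regime.estimation_error,
                mean=mean,
                ci=ci,
                explained_ratio=ratio,
                flagged=flagged,
            )
        )
    return DiscordanceReport(
        metric=metric, empirical_mean=emp_mean, empirical_ci=emp_ci, regimes=results
    )
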