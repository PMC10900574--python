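"""Seeded generator of a synthetic accentor-like phylogenomic study.

The generator emulates the statistical structure the analyses assume,
without any real data: a two-clade species tree of 9 ingroup taxa plus an
outgroup, whose focal subclade of four lineages is joined by three
successive short internal branches (0.05 coalescent units each — inside
the anomaly zone); per-branch theta; a gene-flow pulse among the focal
lineages; exon-like (500 bp) and intron-like (1000 bp) loci packed in
clusters of six per 50-kb window (the rest of each window invariant) so
genomic windows and jackknife blocks are meaningful; a per-window
recombination-like covariate with gene flow applied only to loci in
windows above a covariate quantile; and a "Z-like" chromosome with a low
covariate and no gene flow.

Two output paths share the same coalescent machinery:

* :func:`simulate_genotypes` — fast infinite-sites mutation dropping on
  simulated gene trees, returning a :class:`GenotypeMatrix` directly;
* :func:`simulate_study` — the full pipeline (GTR+I+G sequence simulation,
  FASTA alignments, text VCF, popmap, window table, truth ledger), fully
  deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from . import seqevolve
from .anomaly import scan_anomaly_zone
from .introgression import GenotypeMatrix
from .msc_sim import (
    AdmixtureEvent,
    SpeciesTree,
    sample_label,
    simulate_gene_tree,
)
from .trees import Tree, parse_newick

__all__ = [
    "StudyConfig",
    "StudyBundle",
    "make_species_tree",
    "simulate_study",
    "simulate_genotypes",
    "scale",
    "DEFAULT_THETA",
    "FOCAL_LINEAGES",
    "OUTGROUP",
]

DEFAULT_THETA = 0.02
OUTGROUP = "out"
# The four focal lineages joined by the three successive short branches.
FOCAL_LINEAGES = ("mod", "mon", "ful", "ocu")


def _prunella_like(theta: float, short_tau: float) -> SpeciesTree:
    # Ultrametric node ages in coalescent units; theta converts to mutational.
    ages = {
        "fo": 0.5,  # (ful, ocu)
        "mfo": 0.5 + short_tau,
        "S": 0.5 + 2 * short_tau,   # focal subclade crown
        "p3": 0.5 + 3 * short_tau,  # pru3 joins: top of the short ladder
        "p2": 1.65,
        "p1": 2.65,
        "lai": 2.0,
        "in": 4.0,
        "root": 8.0,
    }

    nwk = (
        f"({OUTGROUP}:{ages['root']},"
        f"((lai1:{ages['lai']},lai2:{ages['lai']}):{ages['in'] - ages['lai']},"
        f"(pru1:{ages['p1']},(pru2:{ages['p2']},(pru3:{ages['p3']},"
        f"(mod:{ages['S']},(mon:{ages['mfo']},(ful:{ages['fo']},ocu:{ages['fo']})"
        f":{short_tau}):{short_tau}):{short_tau}):{ages['p2'] - ages['p3']})"
        f":{ages['p1'] - ages['p2']}):{ages['in'] - ages['p1']})"
        f":{ages['root'] - ages['in']});"
    )
    return SpeciesTree.from_coalescent(parse_newick(nwk), theta=theta)


def _caterpillar(theta: float, internal_taus: tuple) -> SpeciesTree:
    y1, y2 = internal_taus
    a_ab = 0.5
    a1 = a_ab + y1
    a2 = a1 + y2
    a_root = a2 + 2.0
    nwk = (
        f"((((A:{a_ab},B:{a_ab}):{y1},C:{a1}):{y2},D:{a2}):{a_root - a2},E:{a_root});"
    )
    return SpeciesTree.from_coalescent(parse_newick(nwk), theta=theta)


def make_species_tree(
    preset: str = "prunella-like",
    theta: float = DEFAULT_THETA,
    short_tau: float = 0.05,
    internal_taus: tuple = (0.05, 0.05),
) -> SpeciesTree:
    """Species-tree presets.

    ``"prunella-like"``: 9 ingroup tips + outgroup, focal 4-lineage
    subclade joined by three successive internal branches of
    ``short_tau`` coalescent units (0.05 by default — inside the anomaly
    zone since a(0.05) ~ 0.671); all other internals >= 1.
    ``"caterpillar"``: 5 taxa with two stacked internal branches
    ``internal_taus`` above a (A,B) cherry.  Anything containing ``(`` is
    parsed as a custom annotated Newick string.
    """
    if preset == "prunella-like":
        return _prunella_like(theta, short_tau)
    if preset == "caterpillar":
        return _caterpillar(theta, internal_taus)
    if "(" in preset:
        tree = parse_newick(preset)
        if any("theta" in n.annotations for n in tree.preorder()):
            return SpeciesTree(tree)
        # Bare branch lengths are read as coalescent units under a uniform theta.
        return SpeciesTree.from_coalescent(tree, theta=theta)
    raise ValueError(f"unknown preset {preset!r}")


def default_events(theta: float = DEFAULT_THETA, m: float = 0.9) -> list[AdmixtureEvent]:
    """The default planted pulse: forward-time gene flow mod => ful, 0.05
    coalescent units before present (recipient lineages jump into the donor
    branch backward in time).  m is the per-haplotype introgression
    probability *within gene-flow windows*; with the default 10% window
    coupling the genome-wide admixture fraction is ~m/10."""
    t_mut = 0.05 * theta / 2.0
    return [AdmixtureEvent(time=t_mut, donor="mod", recipient="ful", m=m)]


@dataclass
class StudyConfig:
    """Design constants of the synthetic study (defaults = study conditions)."""

    preset: str = "prunella-like"
    theta: float = DEFAULT_THETA
    short_tau: float = 0.05
    n_exon_loci: int = 2373
    exon_length: int = seqevolve.EXON_LENGTH
    n_intron_loci: int = 6879
    intron_length: int = seqevolve.INTRON_LENGTH
    model: seqevolve.SubstitutionModel = field(
        default_factory=lambda: seqevolve.SubstitutionModel(
            freqs=(0.30, 0.20, 0.20, 0.30),
            rates=(1.0, 3.0, 1.0, 1.0, 3.0, 1.0),
            p_inv=0.2,
            alpha=1.0,
        )
    )
    events: list | None = None  # None -> default_events(theta); [] -> no gene flow
    samples_per_species: dict = field(
        default_factory=lambda: {
            **{sp: 2 for sp in ("lai1", "lai2", "pru1", "pru2", "pru3", OUTGROUP)},
            **{sp: 4 for sp in FOCAL_LINEAGES},
        }
    )
    outgroup: str = OUTGROUP
    n_autosomes: int = 9
    z_chromosome: bool = True
    # Loci are packed in clusters of loci_per_window at the start of each
    # 50-kb window (locus_gap bp of invariant sequence between loci, the
    # rest of the window invariant), so every covered window carries a
    # comparable amount of aligned sequence.
    loci_per_window: int = 6
    locus_gap: int = 600
    window_span: int = 50_000
    couple_to_covariate: bool = True
    coupling_quantile: float = 0.9
    # "tract": per gene-flow window, each recipient haplotype is introgressed
    # (with probability m) for the WHOLE window, emulating coherent
    # introgressed tracts; "lineage": independent per-locus, per-lineage
    # jumps (the bare pulse semantics of the simulator).
    admixture_mode: str = "tract"
    covariate_mean: float = 2.0       # cM/Mb-like scale
    covariate_sigma: float = 0.7      # lognormal sigma
    z_covariate_factor: float = 0.25  # Z-like chromosome shift
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_exon_loci < 0 or self.n_intron_loci < 0:
            problems.append("locus counts must be non-negative")
        if self.n_exon_loci + self.n_intron_loci == 0:
            problems.append("at least one locus required")
        if self.exon_length < 1 or self.intron_length < 1:
            problems.append("locus lengths must be positive")
        if not 0 < self.coupling_quantile < 1:
            problems.append("coupling_quantile must be in (0, 1)")
        if self.locus_gap < 0:
            problems.append("locus_gap must be non-negative")
        if self.window_span < 1:
            problems.append("window_span must be positive")
        if any(v % 2 for v in self.samples_per_species.values()):
            problems.append("samples_per_species must be even (diploid individuals)")
        if problems:
            raise ValueError("invalid StudyConfig: " + "; ".join(problems))

    def resolved_events(self) -> list:
        if self.events is None:
            return default_events(self.theta)
        return list(self.events)

    def species_tree(self) -> SpeciesTree:
        return make_species_tree(self.preset, theta=self.theta, short_tau=self.short_tau)


def scale(cfg: StudyConfig, factor: float) -> StudyConfig:
    """Scale locus counts down by ``factor`` (structure preserved)."""
    if not 0 < factor <= 1:
        raise ValueError(f"factor must be in (0, 1], got {factor}")
    return replace(
        cfg,
        n_exon_loci=int(cfg.n_exon_loci * factor),
        n_intron_loci=int(cfg.n_intron_loci * factor),
    )


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    index: int
    chrom: str
    start: int
    length: int
    kind: str          # "exon" | "intron"
    admixed: bool = False

    @property
    def end(self) -> int:
        return self.start + self.length


def _layout(cfg: StudyConfig, rng: np.random.Generator):
    """Assign loci to chromosomes end-to-end and draw window covariates.

    Returns (loci, windows) where windows is a list of dicts with the
    per-window covariate and gene-flow eligibility flag.
    """
    chroms = [f"chr{i + 1}" for i in range(cfg.n_autosomes)]
    if cfg.z_chromosome:
        chroms.append("chrZ")
    kinds = ["exon"] * cfg.n_exon_loci + ["intron"] * cfg.n_intron_loci
    lengths = [cfg.exon_length] * cfg.n_exon_loci + [cfg.intron_length] * cfg.n_intron_loci
    order = rng.permutation(len(kinds))

    # Pack loci_per_window loci at the start of each window; windows are
    # dealt round-robin across chromosomes.
    loci: list[Locus] = []
    windows_used = {c: 0 for c in chroms}
    for li, oi in enumerate(order):
        wi = li // cfg.loci_per_window
        chrom = chroms[wi % len(chroms)]
        within = li % cfg.loci_per_window
        if within == 0:
            windows_used[chrom] += 1
        wstart = (windows_used[chrom] - 1) * cfg.window_span
        offset = wstart + sum(
            lengths[order[li - k - 1]] + cfg.locus_gap for k in range(within)
        )
        if offset + lengths[oi] > wstart + cfg.window_span:
            raise ValueError(
                "loci_per_window x (locus length + gap) exceeds the window span"
            )
        loci.append(Locus(li, chrom, offset, lengths[oi], kinds[oi]))

    chrom_lengths = {
        c: max(windows_used[c], 1) * cfg.window_span for c in chroms
    }

    windows = []
    for c in chroms:
        n_win = chrom_lengths[c] // cfg.window_span
        mu = cfg.covariate_mean * (cfg.z_covariate_factor if c == "chrZ" else 1.0)
        vals = mu * rng.lognormal(
            -cfg.covariate_sigma**2 / 2.0, cfg.covariate_sigma, n_win
        )
        for w in range(n_win):
            windows.append(
                {
                    "chrom": c,
                    "start": w * cfg.window_span,
                    "end": (w + 1) * cfg.window_span,
                    "covariate": float(vals[w]),
                }
            )

    # Gene flow allowed only in autosomal windows above the covariate quantile
    # (or in every autosomal window when coupling is disabled).
    auto_vals = [w["covariate"] for w in windows if w["chrom"] != "chrZ"]
    cutoff = float(np.quantile(auto_vals, cfg.coupling_quantile))
    win_index = {}
    for w in windows:
        eligible = w["covariate"] >= cutoff or not cfg.couple_to_covariate
        w["gene_flow"] = bool(w["chrom"] != "chrZ" and eligible)
        win_index[(w["chrom"], w["start"])] = w
    for locus in loci:
        wstart = (locus.start // cfg.window_span) * cfg.window_span
        locus.admixed = win_index[(locus.chrom, wstart)]["gene_flow"]
    return loci, windows, chrom_lengths


def _window_events(cfg: StudyConfig, windows, names, seed: int) -> dict:
    """Per-window event tuples.  In tract mode, each gene-flow window fixes
    which recipient haplotypes are introgressed (each with probability m),
    shared by all loci of the window; recipients that are not tip species
    (ancestral branches) keep the per-lineage pulse."""
    win_events: dict = {}
    rng = np.random.default_rng(seed + 800_000)
    events = cfg.resolved_events()
    for w in windows:
        if not w["gene_flow"] or not events:
            continue
        evs = []
        movers_log = {}
        for ev in events:
            if cfg.admixture_mode == "tract" and ev.recipient in names:
                haps = names[ev.recipient]
                k = max(1, round(ev.m * len(haps)))
                movers = sorted(rng.choice(haps, size=k, replace=False))
                evs.append(ev.with_movers(movers))
                movers_log[f"{ev.donor}=>{ev.recipient}"] = movers
            else:
                evs.append(ev)
        w["movers"] = movers_log
        win_events[(w["chrom"], w["start"])] = tuple(evs)
    return win_events


def _sample_names(cfg: StudyConfig, sp: SpeciesTree):
    """Haplotype tip labels per species, in a stable order."""
    out = {}
    for label in sorted(sp.tree.tip_labels):
        k = cfg.samples_per_species.get(label, 2)
        out[label] = [sample_label(label, i, k) for i in range(k)]
    return out


# ---------------------------------------------------------------------------
# Fast path: infinite-sites genotypes
# ---------------------------------------------------------------------------

def _drop_mutations(gene_tree: Tree, length: int, rng: np.random.Generator):
    """Infinite-sites mutations: per branch, Poisson(branch_len * length)
    mutations in total, each creating one biallelic site carried by the
    tips below the branch.

    Returns (positions, carriers, tip_labels): ``carriers`` is an
    (n_mut, n_tips) boolean matrix over ``tip_labels``.
    """
    tips = gene_tree.tips()
    tip_labels = [t.label for t in tips]
    tip_index = {id(t): i for i, t in enumerate(tips)}
    masks: dict[int, np.ndarray] = {}
    nodes, weights = [], []
    for node in gene_tree.root.postorder():
        if node.is_tip:
            m = np.zeros(len(tips), dtype=bool)
            m[tip_index[id(node)]] = True
        else:
            m = np.zeros(len(tips), dtype=bool)
            for c in node.children:
                m |= masks[id(c)]
        masks[id(node)] = m
        if node.parent is not None and node.length:
            nodes.append(m)
            weights.append(node.length)
    if not nodes:
        return np.empty(0, dtype=np.int64), np.empty((0, len(tips)), dtype=bool), tip_labels
    weights = np.asarray(weights)
    n_mut = min(int(rng.poisson(weights.sum() * length)), length)
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.empty((0, len(tips)), dtype=bool), tip_labels
    which = rng.choice(len(nodes), size=n_mut, p=weights / weights.sum())
    positions = np.sort(rng.choice(length, size=n_mut, replace=False))
    carriers = np.stack([nodes[k] for k in which])
    return positions, carriers, tip_labels


def simulate_genotypes(
    cfg: StudyConfig | None = None,
    seed: int | None = None,
    events: list | None = None,
) -> tuple[GenotypeMatrix, "StudyBundle"]:
    """Fast synthetic genotypes: MSC gene trees + infinite-sites mutations.

    Shares the study's layout, coupling rule and sampling design but skips
    sequence simulation; sites where any outgroup haplotype carries the
    derived allele are excluded (strict polarization).  Returns the
    genotype matrix and a lightweight bundle (trees are not retained).
    """
    cfg = cfg or StudyConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    sp = cfg.species_tree()
    rng_layout = np.random.default_rng(seed + 900_000)
    loci, windows, chrom_lengths = _layout(cfg, rng_layout)
    names = _sample_names(cfg, sp)
    pops = sorted(names)
    hap_cols = {p: len(names[p]) for p in pops}
    if events is None:
        win_events = _window_events(cfg, windows, names, seed)
    else:
        win_events = None  # caller-supplied per-locus events, bare semantics

    chroms, poss, rows = [], [], []
    hap_data = {p: [] for p in pops}
    for locus in loci:
        rng = np.random.default_rng(seed + locus.index)
        if not locus.admixed:
            locus_events = ()
        elif win_events is None:
            locus_events = tuple(events)
        else:
            wstart = (locus.start // cfg.window_span) * cfg.window_span
            locus_events = win_events.get((locus.chrom, wstart), ())
        gt = simulate_gene_tree(
            sp,
            samples_per_species=cfg.samples_per_species,
            rng=rng,
            events=locus_events,
        )
        positions, carriers, tip_labels = _drop_mutations(gt, locus.length, rng)
        if len(positions) == 0:
            continue
        col = {lbl: i for i, lbl in enumerate(tip_labels)}
        pop_cols = {p: [col[h] for h in names[p]] for p in pops}
        out_any = carriers[:, pop_cols[cfg.outgroup]].any(axis=1)
        fixed = carriers.all(axis=1)
        keep = ~(out_any | fixed)  # strict polarization; drop invariant-derived
        if not keep.any():
            continue
        carriers = carriers[keep]
        chroms.extend([locus.chrom] * len(carriers))
        poss.extend((locus.start + positions[keep]).tolist())
        row_block = np.empty((len(carriers), len(pops)))
        for j, p in enumerate(pops):
            sub = carriers[:, pop_cols[p]].astype(np.int8)
            hap_data[p].append(sub)
            row_block[:, j] = sub.mean(axis=1)
        rows.append(row_block)
    g = GenotypeMatrix(
        np.array(chroms),
        np.array(poss, dtype=np.int64),
        np.vstack(rows) if rows else np.empty((0, len(pops))),
        pops,
        sample_sizes=hap_cols,
        haplotypes={
            p: np.vstack(hap_data[p]) if hap_data[p] else np.empty((0, hap_cols[p]), dtype=np.int8)
            for p in pops
        },
        chrom_lengths=chrom_lengths,
    )
    bundle = StudyBundle(
        config=cfg, seed=seed, species_tree=sp, loci=loci, windows=windows,
        chrom_lengths=chrom_lengths, genotypes=g, popmap=_popmap(names),
    )
    return g, bundle


def _popmap(names: dict) -> dict:
    """Diploid individual -> species (haplotypes paired in order)."""
    out = {}
    for spp, haps in names.items():
        for j in range(len(haps) // 2):
            out[f"{spp}_ind{j + 1}"] = spp
    return out


# ---------------------------------------------------------------------------
# Full pipeline: sequences, VCF, truth ledger
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything a downstream analysis needs, plus the truth ledger."""

    config: StudyConfig
    seed: int
    species_tree: SpeciesTree
    loci: list
    windows: list
    chrom_lengths: dict
    genotypes: GenotypeMatrix | None = None
    popmap: dict = field(default_factory=dict)
    gene_trees: list = field(default_factory=list)
    alignments: list = field(default_factory=list)  # aligned with self.loci

    # -- truth --------------------------------------------------------------
    def truth(self) -> dict:
        sp = self.species_tree
        pairs = scan_anomaly_zone(sp)
        return {
            "seed": self.seed,
            "species_tree": sp.tree.newick(annotations=True),
            "events": [
                {"time": e.time, "donor": e.donor, "recipient": e.recipient, "m": e.m}
                for e in self.config.resolved_events()
            ],
            "anomaly_pairs": [
                {"parent": p.parent_id, "child": p.child_id, "x": p.x, "y": p.y,
                 "a_of_x": p.a_of_x, "in_zone": p.in_zone}
                for p in pairs
            ],
            "windows": self.windows,
            "loci": [
                {"index": l.index, "chrom": l.chrom, "start": l.start,
                 "end": l.end, "kind": l.kind, "admixed": l.admixed}
                for l in self.loci
            ],
        }

    # -- window access ------------------------------------------------------
    def window_alignment(self, chrom: str, start: int) -> seqevolve.Alignment | None:
        """Concatenation of the locus alignments inside one window
        (species-collapsed columns are NOT merged; taxa are haplotypes)."""
        end = start + self.config.window_span
        parts = [
            self.alignments[l.index]
            for l in self.loci
            if l.chrom == chrom and l.start >= start and l.start < end
        ]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        taxa = parts[0].taxa
        mats = [p.matrix[[p.taxa.index(t) for t in taxa]] for p in parts]
        return seqevolve.Alignment(taxa, np.concatenate(mats, axis=1))

    # -- serialization ------------------------------------------------------
    def write(self, outdir) -> dict:
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        trees_dir = os.path.join(outdir, "trees")
        aln_dir = os.path.join(outdir, "alignments")
        os.makedirs(trees_dir, exist_ok=True)
        paths["species_tree"] = os.path.join(trees_dir, "species.nwk")
        with open(paths["species_tree"], "w") as fh:
            fh.write(self.species_tree.tree.newick(annotations=True) + "\n")
        if self.gene_trees:
            paths["gene_trees"] = os.path.join(trees_dir, "gene_trees.nwk")
            with open(paths["gene_trees"], "w") as fh:
                for gt in self.gene_trees:
                    fh.write(gt.newick() + "\n")
        if self.alignments:
            os.makedirs(aln_dir, exist_ok=True)
            for locus, aln in zip(self.loci, self.alignments):
                if aln is not None:
                    aln.to_fasta(os.path.join(aln_dir, f"locus_{locus.index:05d}.fasta"))
            paths["alignments"] = aln_dir
        if self.genotypes is not None:
            paths["vcf"] = os.path.join(outdir, "variants.vcf")
            write_vcf(self.genotypes, self.popmap, paths["vcf"])
        paths["popmap"] = os.path.join(outdir, "popmap.tsv")
        with open(paths["popmap"], "w") as fh:
            for ind, spp in sorted(self.popmap.items()):
                fh.write(f"{ind}\t{spp}\n")
        paths["windows"] = os.path.join(outdir, "windows.tsv")
        with open(paths["windows"], "w") as fh:
            fh.write("chrom\tstart\tend\tcovariate\tgene_flow\n")
            for w in self.windows:
                fh.write(
                    f"{w['chrom']}\t{w['start']}\t{w['end']}"
                    f"\t{w['covariate']:.6g}\t{int(w['gene_flow'])}\n"
                )
        paths["truth"] = os.path.join(outdir, "truth.json")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth(), fh, indent=1)
        manifest = {
            "seed": self.seed,
            "outputs": {
                k: v for k, v in paths.items()
            },
            "checksums": {
                k: _sha256(v) for k, v in paths.items() if os.path.isfile(v)
            },
        }
        paths["manifest"] = os.path.join(outdir, "manifest.json")
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1)
        return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def simulate_study(cfg: StudyConfig | None = None, seed: int | None = None) -> StudyBundle:
    """Run the full generator: gene trees, alignments, genotypes, truth.

    Deterministic given ``seed``: the locus with index i uses generator
    seed ``seed + i`` for its gene tree, mutation placement and sequence
    evolution.
    """
    cfg = cfg or StudyConfig()
    cfg.validate()
    if seed is None:
        seed = cfg.seed
    sp = cfg.species_tree()
    rng_layout = np.random.default_rng(seed + 900_000)
    loci, windows, chrom_lengths = _layout(cfg, rng_layout)
    names = _sample_names(cfg, sp)
    pops = sorted(names)
    win_events = _window_events(cfg, windows, names, seed)

    gene_trees, alignments = [], []
    chroms, poss, rows = [], [], []
    hap_data = {p: [] for p in pops}
    for locus in loci:
        rng = np.random.default_rng(seed + locus.index)
        if locus.admixed:
            wstart = (locus.start // cfg.window_span) * cfg.window_span
            locus_events = win_events.get((locus.chrom, wstart), ())
        else:
            locus_events = ()
        gt = simulate_gene_tree(
            sp,
            samples_per_species=cfg.samples_per_species,
            rng=rng,
            events=locus_events,
        )
        gene_trees.append(gt)
        aln = seqevolve.simulate_alignment(
            gt, cfg.model, locus.length, rng_seed=rng
        )
        alignments.append(aln)
        for off, row, haps in _biallelic_sites(aln, names, pops, cfg.outgroup):
            chroms.append(locus.chrom)
            poss.append(locus.start + off)
            rows.append(row)
            for p in pops:
                hap_data[p].append(haps[p])

    genotypes = GenotypeMatrix(
        np.array(chroms),
        np.array(poss, dtype=np.int64),
        np.array(rows) if rows else np.empty((0, len(pops))),
        pops,
        sample_sizes={p: len(names[p]) for p in pops},
        haplotypes={
            p: np.array(hap_data[p]) if hap_data[p] else np.empty((0, len(names[p])), dtype=np.int8)
            for p in pops
        },
        chrom_lengths=chrom_lengths,
    )
    return StudyBundle(
        config=cfg, seed=seed, species_tree=sp, loci=loci, windows=windows,
        chrom_lengths=chrom_lengths, genotypes=genotypes, popmap=_popmap(names),
        gene_trees=gene_trees, alignments=alignments,
    )


def _biallelic_sites(aln: seqevolve.Alignment, names: dict, pops: list, outgroup: str = OUTGROUP):
    """Yield (offset, per-pop derived freq row, per-pop hap arrays) for every
    biallelic site with a monomorphic-ancestral outgroup."""
    idx = {t: i for i, t in enumerate(aln.taxa)}
    out_rows = [idx[h] for h in names[outgroup]]
    mat = aln.matrix
    out_mono = np.all(mat[out_rows] == mat[out_rows[0]], axis=0)
    for s in np.flatnonzero(out_mono):
        col = mat[:, s]
        alleles = np.unique(col)
        if len(alleles) != 2:
            continue
        anc = mat[out_rows[0], s]
        derived = alleles[alleles != anc]
        if len(derived) != 1:
            continue  # outgroup carries the derived allele only -> unpolarizable
        d = derived[0]
        row, haps = [], {}
        for p in pops:
            hap = (col[[idx[h] for h in names[p]]] == d).astype(np.int8)
            haps[p] = hap
            row.append(hap.mean())
        yield int(s), row, haps


# ---------------------------------------------------------------------------
# Plain-text VCF output
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=phylodisc-synthdata
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(g: GenotypeMatrix, popmap: dict, path) -> None:
    """Write biallelic sites as an uncompressed VCF (REF=A ancestral, ALT=T
    derived placeholders when no sequence context is available)."""
    inds = sorted(popmap)
    by_pop: dict[str, list[str]] = {}
    for ind in inds:
        by_pop.setdefault(popmap[ind], []).append(ind)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c, ln in sorted(g.chrom_lengths.items()):
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(inds) + "\n")
        hap_index: dict[str, int] = {}
        for s in range(g.n_sites):
            fields = [str(g.chrom[s]), str(int(g.pos[s]) + 1), ".", "A", "T", ".", "PASS", ".", "GT"]
            for ind in inds:
                p = popmap[ind]
                j = by_pop[p].index(ind)
                hap = g.haplotypes[p][s]
                a, b = hap[2 * j], hap[2 * j + 1]
                fields.append(f"{a}|{b}")
            fh.write("\t".join(fields) + "\n")
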