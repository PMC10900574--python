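"""Site-pattern introgression statistics over population allele frequencies.

All statistics run on a :class:`GenotypeMatrix` of derived-allele
frequencies per population (polarized against an outgroup) with genomic
coordinates, and use frequency-weighted site-pattern sums: for the ordered
taxa (P1, P2, P3, O),

    ABBA = sum (1-p1) p2 p3 (1-pO)
    BABA = sum p1 (1-p2) p3 (1-pO)
    BBAA = sum p1 p2 (1-p3) (1-pO)

Implemented: Patterson's D with delete-one 1-Mb block jackknife and
Benjamini-Hochberg FDR over all trios; the f4-ratio admixture-proportion
estimator (with a seeded haplotype split of P3); the f-branch statistic
f_b(P3) = median_A[min_B[f4-ratio(A, B; P3, O)]] over a guide tree; the
five-taxon D_FOIL system with signature-based classification of (possibly
ancestral) introgression; and the windowed f_d statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .msc_sim import branch_id
from .trees import Tree

__all__ = [
    "GenotypeMatrix",
    "TrioResult",
    "pattern_sums",
    "d_statistic",
    "all_trios",
    "f4_ratio",
    "FBranchResult",
    "f_branch",
    "DfoilResult",
    "dfoil",
    "DFOIL_PATTERNS",
    "WindowFd",
    "fd_windows",
]


class GenotypeMatrix:
    """Biallelic sites x populations derived-allele-frequency matrix.

    ``freqs[i, j]`` is the derived-allele frequency of population ``j`` at
    site ``i``; rows are ordered by (chromosome, position) with strictly
    increasing positions within a chromosome.  ``haplotypes`` optionally
    maps a population to its per-haplotype 0/1 matrix (needed by the
    f4-ratio's within-P3 split).  Sites at which the outgroup carries the
    derived allele are excluded at load time (strict polarization).
    """

    def __init__(
        self,
        chrom,
        pos,
        freqs,
        populations,
        sample_sizes=None,
        haplotypes=None,
        chrom_lengths=None,
    ):
        self.chrom = np.asarray(chrom)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.freqs = np.asarray(freqs, dtype=float)
        self.populations = list(populations)
        self.sample_sizes = dict(sample_sizes or {})
        self.haplotypes = {k: np.asarray(v, dtype=np.int8) for k, v in (haplotypes or {}).items()}
        self.chrom_lengths = dict(chrom_lengths or {})
        if self.freqs.shape != (len(self.pos), len(self.populations)):
            raise ValueError("freqs must be (n_sites, n_populations)")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if (np.diff(p) <= 0).any():
                raise ValueError(f"positions not strictly increasing on {c}")
        self._index = {p: i for i, p in enumerate(self.populations)}

    # -- construction -------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, outgroup=None) -> "GenotypeMatrix":
        """Read a per-site frequency table (columns: chrom, pos, one per population)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        pops = [c for c in df.columns if c not in ("chrom", "pos")]
        g = cls(df["chrom"].astype(str), df["pos"], df[pops].to_numpy(), pops)
        if outgroup is not None:
            g = g.polarize(outgroup)
        return g

    @classmethod
    def from_vcf(cls, path, popmap, outgroup=None) -> "GenotypeMatrix":
        """Load biallelic SNPs from a VCF; ``popmap`` maps sample -> population.

        Derived-allele frequencies are ALT frequencies; sites where the
        outgroup carries any ALT allele are dropped when ``outgroup`` is
        given (strict polarization).  Per-haplotype matrices are retained
        for every population.
        """
        from cyvcf2 import VCF

        if not isinstance(popmap, dict):
            import pandas as pd

            pm = pd.read_csv(popmap, sep="\t", header=None, names=["sample", "population"])
            popmap = dict(zip(pm["sample"], pm["population"]))

        vcf = VCF(str(path))
        samples = vcf.samples
        pops = sorted(set(popmap.values()))
        cols = {p: [i for i, s in enumerate(samples) if popmap.get(s) == p] for p in pops}
        chroms, poss, rows = [], [], []
        hap_rows: dict[str, list] = {p: [] for p in pops}
        for var in vcf:
            if len(var.ALT) != 1 or not var.is_snp:
                continue
            gt = np.array(var.genotype.array())[:, :2]  # (n_samples, 2)
            if (gt < 0).any():
                continue  # skip sites with missing genotypes
            chroms.append(var.CHROM)
            poss.append(var.POS - 1)  # 0-based internally
            row = []
            for p in pops:
                haps = gt[cols[p]].reshape(-1)
                hap_rows[p].append(haps)
                row.append(haps.mean() if haps.size else np.nan)
            rows.append(row)
        sizes = {p: 2 * len(cols[p]) for p in pops}
        g = cls(
            np.array(chroms),
            np.array(poss),
            np.array(rows),
            pops,
            sample_sizes=sizes,
            haplotypes={p: np.array(hap_rows[p]) for p in pops if hap_rows[p]},
        )
        if outgroup is not None:
            g = g.polarize(outgroup)
        return g

    def polarize(self, outgroup: str) -> "GenotypeMatrix":
        """Drop sites where the outgroup carries any derived allele."""
        keep = self.freqs[:, self.index(outgroup)] == 0.0
        return self.subset(keep)

    def subset(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[mask],
            self.pos[mask],
            self.freqs[mask],
            self.populations,
            sample_sizes=self.sample_sizes,
            haplotypes={k: v[mask] for k, v in self.haplotypes.items()},
            chrom_lengths=self.chrom_lengths,
        )

    # -- accessors ----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def index(self, population: str) -> int:
        try:
            return self._index[population]
        except KeyError:
            raise ValueError(f"unknown population {population!r}") from None

    def freq(self, population: str) -> np.ndarray:
        return self.freqs[:, self.index(population)]

    def block_ids(self, block_size: int) -> np.ndarray:
        """Contiguous genomic jackknife block per site (final partial block kept)."""
        labels = np.empty(self.n_sites, dtype=object)
        for c in np.unique(self.chrom):
            m = self.chrom == c
            labels[m] = [f"{c}:{b}" for b in self.pos[m] // int(block_size)]
        return labels


# ---------------------------------------------------------------------------
# Patterson's D
# ---------------------------------------------------------------------------

def _site_patterns(g: GenotypeMatrix, p1, p2, p3, o):
    if len({p1, p2, p3, o}) != 4:
        raise ValueError("the four populations must be distinct")
    f1, f2, f3, fo = (g.freq(p) for p in (p1, p2, p3, o))
    abba = (1 - f1) * f2 * f3 * (1 - fo)
    baba = f1 * (1 - f2) * f3 * (1 - fo)
    bbaa = f1 * f2 * (1 - f3) * (1 - fo)
    return abba, baba, bbaa


def pattern_sums(g: GenotypeMatrix, p1, p2, p3, o):
    """Frequency-weighted (ABBA, BABA, BBAA) sums for the ordered quartet."""
    abba, baba, bbaa = _site_patterns(g, p1, p2, p3, o)
    return float(abba.sum()), float(baba.sum()), float(bbaa.sum())


@dataclass
class TrioResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    abba: float
    baba: float
    bbaa: float
    d: float | None
    se: float | None
    z: float | None
    p_value: float | None
    p_adjusted: float | None = None
    n_blocks: int = 0
    flagged: str = ""


def _jackknife_ratio(num: np.ndarray, den: np.ndarray):
    """Delete-one-block SE for a ratio statistic from per-block sums."""
    n = len(num)
    total_n, total_d = num.sum(), den.sum()
    loo = (total_n - num) / (total_d - den)
    mean = loo.mean()
    var = (n - 1) / n * ((loo - mean) ** 2).sum()
    return float(np.sqrt(var))


def d_statistic(g: GenotypeMatrix, p1, p2, p3, o, block_size: int = 1_000_000) -> TrioResult:
    """Patterson's D with a delete-one genomic block jackknife.

    D = (ABBA - BABA) / (ABBA + BABA); Z = D/SE with SE from contiguous
    blocks of ``block_size`` bp (default 1 Mb); two-sided normal p-value.
    """
    abba, baba, bbaa = _site_patterns(g, p1, p2, p3, o)
    A, B, C = float(abba.sum()), float(baba.sum()), float(bbaa.sum())
    res = TrioResult(p1, p2, p3, o, A, B, C, None, None, None, None)
    if A + B == 0:
        res.flagged = "no informative sites (ABBA + BABA = 0)"
        return res
    res.d = (A - B) / (A + B)
    blocks = g.block_ids(block_size)
    uniq = np.unique(blocks)
    res.n_blocks = len(uniq)
    nonempty = [b for b in uniq if (abba[blocks == b].sum() + baba[blocks == b].sum()) > 0]
    if len(nonempty) < 2:
        res.flagged = "fewer than 2 non-empty jackknife blocks; SE undefined"
        return res
    num = np.array([(abba - baba)[blocks == b].sum() for b in uniq])
    den = np.array([(abba + baba)[blocks == b].sum() for b in uniq])
    res.se = _jackknife_ratio(num, den)
    if res.se == 0:
        res.flagged = "zero jackknife SE"
        return res
    res.z = res.d / res.se
    res.p_value = float(2 * norm.sf(abs(res.z)))
    return res


def all_trios(
    g: GenotypeMatrix,
    taxa=None,
    outgroup: str | None = None,
    block_size: int = 1_000_000,
) -> list[TrioResult]:
    """Every ingroup trio, roles assigned without a prior topology.

    Within each trio, P3 is chosen so the BBAA sum is the largest of the
    three arrangements, then P1/P2 are ordered so D >= 0; p-values are
    Benjamini-Hochberg adjusted across trios.
    """
    if outgroup is None:
        raise ValueError("outgroup is required")
    if taxa is None:
        taxa = [p for p in g.populations if p != outgroup]
    if len(taxa) < 3:
        raise ValueError("need at least 3 ingroup taxa")
    results = []
    for trio in itertools.combinations(sorted(taxa), 3):
        best, best_bbaa = None, -np.inf
        for k in range(3):
            p3 = trio[k]
            p1, p2 = (t for i, t in enumerate(trio) if i != k)
            _, _, bbaa = pattern_sums(g, p1, p2, p3, outgroup)
            if bbaa > best_bbaa:
                best, best_bbaa = (p1, p2, p3), bbaa
        p1, p2, p3 = best
        abba, baba, _ = pattern_sums(g, p1, p2, p3, outgroup)
        if baba > abba:
            p1, p2 = p2, p1
        results.append(d_statistic(g, p1, p2, p3, outgroup, block_size=block_size))
    pvals = [r.p_value for r in results if r.p_value is not None]
    if pvals:
        adj = multipletests(pvals, method="fdr_bh")[1]
        it = iter(adj)
        for r in results:
            if r.p_value is not None:
                r.p_adjusted = float(next(it))
    return results


# ---------------------------------------------------------------------------
# f4-ratio and f-branch
# ---------------------------------------------------------------------------

def _split_p3(g: GenotypeMatrix, p3: str, rng) -> tuple[np.ndarray, np.ndarray]:
    hap = g.haplotypes.get(p3)
    if hap is None or hap.shape[1] < 2:
        raise ValueError(
            f"f4-ratio requires >= 2 haplotypes for P3 ({p3!r}); "
            "load data with per-haplotype genotypes"
        )
    cols = rng.permutation(hap.shape[1])
    half = hap.shape[1] // 2
    a, b = cols[:half], cols[half:]
    return hap[:, a].mean(axis=1), hap[:, b].mean(axis=1)


def _f4_terms(g, a, b, p3a, p3b, o):
    fa, fb, fo = g.freq(a), g.freq(b), g.freq(o)
    num = (fb - fa) * (p3a - fo)
    den = (p3b - fa) * (p3a - fo)
    return num, den


def f4_ratio(
    g: GenotypeMatrix, a, b, p3, o, rng_seed=None, n_splits: int = 1
) -> float | None:
    """Admixture-proportion estimate f4(A,B;P3a,O) / f4(A,P3b;P3a,O).

    P3's haplotypes are split into two halves at random (seeded) — averaged
    over ``n_splits`` splits — and the ratio is clamped to [0, 1].
    Returns None (masked) when the denominator is not positive.
    """
    rng = np.random.default_rng(rng_seed)
    vals = []
    for _ in range(n_splits):
        p3a, p3b = _split_p3(g, p3, rng)
        num, den = _f4_terms(g, a, b, p3a, p3b, o)
        d = den.sum()
        if d <= 0:
            continue
        vals.append(num.sum() / d)
    if not vals:
        return None
    return float(np.clip(np.mean(vals), 0.0, 1.0))


@dataclass
class FBranchResult:
    """f-branch matrix: rows = guide-tree branches, columns = P3 taxa."""

    branches: list
    taxa: list
    values: np.ndarray  # NaN where masked
    z: np.ndarray
    p_adjusted: np.ndarray

    def cell(self, branch: str, taxon: str):
        return self.values[self.branches.index(branch), self.taxa.index(taxon)]


def f_branch(
    g: GenotypeMatrix,
    guide_tree: Tree,
    outgroup: str,
    block_size: int = 1_000_000,
    rng_seed=None,
    n_splits: int = 4,
) -> FBranchResult:
    """f_b(P3) = median over A (sister descendants) of min over B (branch
    descendants) of the positive f4-ratios, per guide-tree branch.

    Cells where P3 descends from the branch or its sister are masked (NaN);
    Z-scores come from a delete-one block jackknife of the whole statistic,
    and p-values are BH-adjusted across unmasked cells.
    """
    rng = np.random.default_rng(rng_seed)
    ingroup = [t for t in g.populations if t != outgroup]
    blocks = g.block_ids(block_size)
    uniq_blocks = list(np.unique(blocks))
    nb = len(uniq_blocks)
    block_idx = {b: np.flatnonzero(blocks == b) for b in uniq_blocks}

    splits = {
        p3: [_split_p3(g, p3, rng) for _ in range(n_splits)]
        for p3 in ingroup
        if p3 in g.haplotypes
    }

    # Per (A, B, P3): per-block numerator/denominator sums, averaged over
    # the haplotype splits of P3 (one split is noisy for small samples).
    def block_sums(a, b, p3):
        ns = np.zeros(nb)
        ds = np.zeros(nb)
        for p3a, p3b in splits[p3]:
            num, den = _f4_terms(g, a, b, p3a, p3b, outgroup)
            ns += np.array([num[block_idx[k]].sum() for k in uniq_blocks])
            ds += np.array([den[block_idx[k]].sum() for k in uniq_blocks])
        return ns / len(splits[p3]), ds / len(splits[p3])

    def fb_from(nums, dens, drop=None):
        # nums/dens: dict A -> list over B of per-block arrays
        per_a = []
        for a, pairs in nums.items():
            ratios = []
            for ns, ds in pairs:
                if drop is not None:
                    n_, d_ = ns.sum() - ns[drop], ds.sum() - ds[drop]
                else:
                    n_, d_ = ns.sum(), ds.sum()
                if d_ > 0:
                    r = n_ / d_
                    if r > 0:
                        ratios.append(min(r, 1.0))
            if ratios:
                per_a.append(min(ratios))
        if not per_a:
            return np.nan
        return float(np.median(per_a))

    # Guide-tree branches (every non-root node with a sister).
    clades_of: dict[int, set] = {}
    for node in guide_tree.postorder():
        clades_of[id(node)] = (
            {node.label} if node.is_tip else set().union(*(clades_of[id(c)] for c in node.children))
        )
    rows, row_ids = [], []
    for node in guide_tree.preorder():
        if node.parent is None:
            continue
        sisters = [c for c in node.parent.children if c is not node]
        b_taxa = sorted(clades_of[id(node)] - {outgroup})
        a_taxa = sorted(set().union(*(clades_of[id(s)] for s in sisters)) - {outgroup})
        if not b_taxa or not a_taxa:
            continue
        rows.append((b_taxa, a_taxa))
        row_ids.append(branch_id(node))

    values = np.full((len(rows), len(ingroup)), np.nan)
    zmat = np.full_like(values, np.nan)
    pvals = np.full_like(values, np.nan)
    for i, (b_taxa, a_taxa) in enumerate(rows):
        excluded = set(b_taxa) | set(a_taxa)
        for j, p3 in enumerate(ingroup):
            if p3 in excluded or p3 not in splits:
                continue
            nums = {
                a: [block_sums(a, b, p3) for b in b_taxa if b != p3]
                for a in a_taxa
                if a != p3
            }
            fb = fb_from(nums, None)
            if np.isnan(fb):
                continue
            loo = np.array([fb_from(nums, None, drop=k) for k in range(nb)])
            loo = loo[~np.isnan(loo)]
            if len(loo) >= 2:
                var = (len(loo) - 1) / len(loo) * ((loo - loo.mean()) ** 2).sum()
                se = np.sqrt(var)
                if se > 0:
                    zmat[i, j] = fb / se
                    pvals[i, j] = 2 * norm.sf(abs(zmat[i, j]))
            values[i, j] = fb
    mask = ~np.isnan(pvals)
    padj = np.full_like(pvals, np.nan)
    if mask.any():
        padj[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return FBranchResult(row_ids, ingroup, values, zmat, padj)


# ---------------------------------------------------------------------------
# D_FOIL
# ---------------------------------------------------------------------------

# The four FOIL contrasts over (P1, P2, P3, P4) site patterns (outgroup
# ancestral).  Each left/right set is the mirror of the other under the
# relevant taxon swap (P3<->P4 for FO/IL, P1<->P2 for FI/OL), so every
# statistic has expectation 0 without introgression; singleton patterns
# polarize donor vs recipient.
DFOIL_PATTERNS = {
    "DFO": (("BABAA", "BBBAA", "ABABA", "AAABA"), ("BAABA", "BBABA", "ABBAA", "AABAA")),
    "DIL": (("ABBAA", "BBBAA", "BAABA", "AAABA"), ("ABABA", "BBABA", "BABAA", "AABAA")),
    "DFI": (("BABAA", "BABBA", "ABABA", "ABAAA"), ("ABBAA", "ABBBA", "BAABA", "BAAAA")),
    "DOL": (("BAABA", "BABBA", "ABBAA", "ABAAA"), ("ABABA", "ABBBA", "BABAA", "BAAAA")),
}

# Sign signature (DFO, DIL, DFI, DOL) -> introgression class, in forward-flow
# "donor => recipient" notation.  The FO/IL pair carries the P3-vs-P4 sign and
# the FI/OL pair the P1-vs-P2 sign; which member of each pair responds
# identifies the recipient, so direction is polarized for terminal taxa.
# Ancestral flow involving the (P1,P2) stem leaves FI/OL null and its
# direction is not identifiable from the signature.
DFOIL_SIGNATURES = {
    ("0", "0", "0", "0"): "none",
    ("+", "0", "+", "+"): "P3 => P1",
    ("0", "+", "-", "-"): "P3 => P2",
    ("-", "0", "+", "+"): "P4 => P1",
    ("0", "-", "-", "-"): "P4 => P2",
    ("+", "+", "+", "0"): "P1 => P3",
    ("+", "+", "-", "0"): "P2 => P3",
    ("-", "-", "0", "+"): "P1 => P4",
    ("-", "-", "0", "-"): "P2 => P4",
    ("+", "+", "0", "0"): "P3 <=> ancestor(P1,P2)",
    ("-", "-", "0", "0"): "P4 <=> ancestor(P1,P2)",
}


@dataclass
class DfoilResult:
    taxa: tuple
    statistics: dict  # name -> value (None when L+R = 0)
    chi2: dict
    p_values: dict
    signature: str
    introgression_class: str
    flagged: list = field(default_factory=list)


def _pattern_sum(freqs: list[np.ndarray], pattern: str) -> float:
    acc = np.ones_like(freqs[0])
    for f, ch in zip(freqs, pattern):
        acc = acc * (f if ch == "B" else 1.0 - f)
    return float(acc.sum())


def dfoil(g: GenotypeMatrix, p1, p2, p3, p4, o, alpha: float = 0.001) -> DfoilResult:
    """Five-taxon D_FOIL on the symmetric topology ((P1,P2),(P3,P4)) with the
    (P1,P2) split the younger (caller-asserted).

    Each statistic is (L-R)/(L+R) over its pattern groups, tested with a
    chi-square goodness-of-fit of (L, R) against equality; the sign
    signature at threshold ``alpha`` is looked up in the published
    signature table (ancestral classes included).
    """
    freqs = [g.freq(p) for p in (p1, p2, p3, p4, o)]
    stats, chis, ps, signature, flagged = {}, {}, {}, [], []
    for name, (left, right) in DFOIL_PATTERNS.items():
        lsum = sum(_pattern_sum(freqs, pat) for pat in left)
        rsum = sum(_pattern_sum(freqs, pat) for pat in right)
        tot = lsum + rsum
        if tot == 0:
            stats[name], chis[name], ps[name] = None, None, None
            signature.append("0")
            flagged.append(f"{name}: no informative sites")
            continue
        stats[name] = (lsum - rsum) / tot
        stat = (lsum - rsum) ** 2 / tot  # 1-df goodness of fit vs 50:50
        chis[name] = stat
        ps[name] = float(chi2_dist.sf(stat, df=1))
        if ps[name] < alpha:
            signature.append("+" if stats[name] > 0 else "-")
        else:
            signature.append("0")
    sig = tuple(signature)
    cls = DFOIL_SIGNATURES.get(sig, "other/complex")
    return DfoilResult(
        taxa=(p1, p2, p3, p4, o),
        statistics=stats,
        chi2=chis,
        p_values=ps,
        signature="".join(sig),
        introgression_class=cls,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Windowed f_d
# ---------------------------------------------------------------------------

@dataclass
class WindowFd:
    chrom: str
    start: int
    end: int
    fd: float | None
    n_informative: int
    d: float | None = None


def fd_windows(
    g: GenotypeMatrix,
    p1,
    p2,
    p3,
    o,
    window_span: int = 50_000,
    min_sites: int = 1,
) -> list[WindowFd]:
    """f_d in non-overlapping windows anchored at position 0.

    f_d = (ABBA - BABA) / (ABBA_D - BABA_D), the denominator substituting
    at each site the donor population PD = argmax(p2, p3) into both the P2
    and P3 slots; masked where the window D < 0 or informative sites are
    fewer than ``min_sites``.
    """
    f1, f2, f3, fo = (g.freq(p) for p in (p1, p2, p3, o))
    abba = (1 - f1) * f2 * f3 * (1 - fo)
    baba = f1 * (1 - f2) * f3 * (1 - fo)
    pd_ = np.maximum(f2, f3)
    abba_d = (1 - f1) * pd_ * pd_ * (1 - fo)
    baba_d = f1 * (1 - pd_) * pd_ * (1 - fo)
    informative = (abba + baba) > 0

    out = []
    for c in dict.fromkeys(np.asarray(g.chrom, dtype=str)):  # preserve order
        m = g.chrom == c
        pos = g.pos[m]
        length = g.chrom_lengths.get(c, int(pos.max()) + 1)
        for start in range(0, int(length), window_span):
            end = start + window_span
            if end > length:
                break  # only full windows
            w = m & (g.pos >= start) & (g.pos < end)
            n_inf = int(informative[w].sum())
            num = abba[w].sum() - baba[w].sum()
            den_tot = abba[w].sum() + baba[w].sum()
            d_win = None if den_tot == 0 else float(num / den_tot)
            fd = None
            if n_inf >= min_sites and num >= 0:
                den = abba_d[w].sum() - baba_d[w].sum()
                if den > 0:
                    fd = float(num / den)
            out.append(WindowFd(str(c), start, end, fd, n_inf, d_win))
    return out
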