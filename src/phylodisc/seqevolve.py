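"""GTR+I+G sequence simulation along gene trees, and a distance-based
gene-tree estimator.

The estimator (neighbor-joining on Jukes-Cantor or LogDet distances) stands
in for likelihood-based gene-tree inference: it is fast, deterministic and
exhibits the qualitative property the estimation-error analyses need —
topological error that shrinks as alignments grow.  Externally estimated
gene trees (Newick) can be supplied anywhere a gene tree is consumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import Tree, parse_newick

__all__ = [
    "SubstitutionModel",
    "Alignment",
    "simulate_alignment",
    "estimate_gene_tree",
    "jc_distance_matrix",
    "logdet_distance_matrix",
    "EXON_LENGTH",
    "INTRON_LENGTH",
]

# Mean lengths of the exon-like and intron-like locus classes (bp).
EXON_LENGTH = 500
INTRON_LENGTH = 1000

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# Exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class SubstitutionModel:
    """GTR+I+G nucleotide substitution model.

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG, CT, GT
    (scale-free); ``p_inv`` is the invariant-site proportion and ``alpha``
    the gamma shape for among-site rate variation (``None`` disables it).
    The rate matrix is normalised so the expected substitution rate is one
    per unit branch length after averaging over invariant sites and gamma
    categories.
    """

    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    p_inv: float = 0.0
    alpha: float | None = None
    n_categories: int = 4

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or abs(f.sum() - 1.0) > 1e-8 or (f <= 0).any():
            raise ValueError("base frequencies must be 4 positive values summing to 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be positive")
        if len(self.rates) != 6 or any(r < 0 for r in self.rates):
            raise ValueError("need 6 non-negative exchangeability rates")

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        return cls()

    def q_matrix(self) -> np.ndarray:
        """Normalised GTR rate matrix (rows sum to 0, mean rate 1)."""
        f = np.asarray(self.freqs, dtype=float)
        q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _PAIRS):
            q[i, j] = r * f[j]
            q[j, i] = r * f[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(f * np.diag(q)).sum()
        return q / mu

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean 1), Yang's equal-probability
        quantile slices with the slice mean as representative rate."""
        if self.alpha is None:
            return np.array([1.0])
        k = self.n_categories
        a = self.alpha
        # Gamma(shape a, rate a) has mean 1; slice means via the shape a+1 CDF.
        bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        upper = gammainc(a + 1, bounds[1:] * a)
        lower = gammainc(a + 1, bounds[:-1] * a)
        return k * (upper - lower)

    def site_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, probabilities) of the full site-rate mixture including
        invariant sites; conditional rates are inflated by 1/(1-p_inv) so
        the mixture mean is exactly 1."""
        cats = self.category_rates() / (1.0 - self.p_inv)
        probs = np.full(len(cats), (1.0 - self.p_inv) / len(cats))
        if self.p_inv > 0:
            cats = np.concatenate([[0.0], cats])
            probs = np.concatenate([[self.p_inv], probs])
        return cats, probs


class Alignment:
    """Taxa x sites nucleotide matrix over {A, C, G, T}."""

    def __init__(self, taxa: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=np.uint8)
        if matrix.ndim != 2 or matrix.shape[0] != len(taxa):
            raise ValueError("matrix must be (n_taxa, n_sites)")
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon names")
        self.taxa = list(taxa)
        self.matrix = matrix

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, taxon: str) -> str:
        row = self.matrix[self.taxa.index(taxon)]
        return "".join(BASES[i] for i in row)

    def to_fasta(self, handle) -> None:
        close = False
        if isinstance(handle, (str, bytes)):
            handle, close = open(handle, "w"), True
        try:
            for taxon in self.taxa:
                handle.write(f">{taxon}\n")
                seq = self.sequence(taxon)
                for i in range(0, len(seq), 80):
                    handle.write(seq[i : i + 80] + "\n")
        finally:
            if close:
                handle.close()

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append([_BASE_INDEX[c] for c in str(rec.seq).upper()])
        return cls(taxa, np.array(rows, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _transition_matrices(model: SubstitutionModel, rates: np.ndarray, length: float):
    """P(t) = expm(Q * r * t) for every rate class, via the reversible
    eigendecomposition (B = D^(1/2) Q D^(-1/2) is symmetric under GTR)."""
    q = model.q_matrix()
    f = np.asarray(model.freqs)
    sq = np.sqrt(f)
    b = (q * sq[:, None]) / sq[None, :]
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    left = v / sq[:, None]
    right = v * sq[:, None]
    out = []
    for r in rates:
        p = (left * np.exp(w * r * length)) @ right.T
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=1, keepdims=True)
        out.append(p)
    return out


def simulate_alignment(
    gene_tree: Tree,
    model: SubstitutionModel,
    length: int,
    rng_seed=None,
) -> Alignment:
    """Evolve ``length`` sites down ``gene_tree`` under GTR+I+G.

    Root states are drawn from the stationary frequencies; each site is
    invariant with probability p_inv, otherwise it gets a discrete-gamma
    category rate, and states evolve by the matrix exponential of
    (rate x branch_length x Q) along every branch.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rates, probs = model.site_rates()
    site_cat = rng.choice(len(rates), size=length, p=probs)
    f = np.asarray(model.freqs)

    states: dict[int, np.ndarray] = {
        id(gene_tree.root): rng.choice(4, size=length, p=f).astype(np.uint8)
    }
    taxa, rows = [], []
    for node in gene_tree.preorder():
        if node.parent is not None:
            parent_states = states[id(node.parent)]
            child = parent_states.copy()
            blen = node.length or 0.0
            if blen > 0:
                pmats = _transition_matrices(model, rates, blen)
                for ci, p in enumerate(pmats):
                    if rates[ci] == 0.0:
                        continue
                    idx = np.flatnonzero(site_cat == ci)
                    if idx.size == 0:
                        continue
                    cum = np.cumsum(p, axis=1)
                    u = rng.random(idx.size)
                    child[idx] = (
                        u[:, None] > cum[parent_states[idx]]
                    ).sum(axis=1).astype(np.uint8)
            states[id(node)] = child
        if node.is_tip:
            taxa.append(node.label)
            rows.append(states[id(node)])
    return Alignment(taxa, np.array(rows, dtype=np.uint8))


# ---------------------------------------------------------------------------
# Distance-based estimation
# ---------------------------------------------------------------------------

JC_SATURATION_CAP = 5.0


def _mismatch_fractions(aln: Alignment) -> np.ndarray:
    m = aln.matrix
    n = len(aln.taxa)
    p = np.zeros((n, n))
    for i in range(n):
        diff = (m[i + 1 :] != m[i]).mean(axis=1)
        p[i, i + 1 :] = diff
        p[i + 1 :, i] = diff
    return p


def jc_distance_matrix(aln: Alignment, cap: float = JC_SATURATION_CAP) -> np.ndarray:
    """Jukes-Cantor distances d = -3/4 ln(1 - 4p/3), capped when saturated."""
    p = _mismatch_fractions(aln)
    arg = 1.0 - 4.0 * p / 3.0
    saturated = arg <= np.exp(-4.0 * cap / 3.0)
    if saturated.any():
        warnings.warn(
            f"{int(saturated.sum() // 2)} saturated pairwise distances capped at {cap}",
            stacklevel=2,
        )
    d = np.where(saturated, cap, -0.75 * np.log(np.where(saturated, 1.0, arg)))
    np.fill_diagonal(d, 0.0)
    return d


def logdet_distance_matrix(aln: Alignment, cap: float = JC_SATURATION_CAP) -> np.ndarray:
    """LogDet/paralinear distances, robust to base-composition drift."""
    m = aln.matrix
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fmat = np.zeros((4, 4))
            np.add.at(fmat, (m[i], m[j]), 1.0)
            fmat /= fmat.sum()
            det = np.linalg.det(fmat)
            fx = fmat.sum(axis=1)
            fy = fmat.sum(axis=0)
            if det <= 0 or (fx <= 0).any() or (fy <= 0).any():
                dist = cap
            else:
                dist = -0.25 * (np.log(det) - 0.5 * (np.log(fx).sum() + np.log(fy).sum()))
                dist = min(max(dist, 0.0), cap)
            d[i, j] = d[j, i] = dist
    return d


def estimate_gene_tree(aln: Alignment, distance: str = "jc", cap: float = JC_SATURATION_CAP) -> Tree:
    """Neighbor-joining tree from JC (default) or LogDet distances.

    Returns an unrooted binary tree (trifurcating root) over the
    alignment's taxa; deterministic given the input.
    """
    if len(aln.taxa) < 3:
        raise ValueError("need at least 3 taxa")
    if distance == "jc":
        dmat = jc_distance_matrix(aln, cap=cap)
    elif distance == "logdet":
        dmat = logdet_distance_matrix(aln, cap=cap)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return nj_tree(dmat, aln.taxa)


def nj_tree(dmat: np.ndarray, taxa: list[str]) -> Tree:
    """Neighbor joining via scikit-bio, negative branch lengths clamped to 0."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    # Order rows by taxon name so the result is invariant to input row order.
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    dmat = dmat[np.ix_(order, order)]
    names = [taxa[i] for i in order]
    sk = nj(DistanceMatrix(dmat, names))
    tree = parse_newick(str(sk).strip())
    for node in tree.preorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree
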