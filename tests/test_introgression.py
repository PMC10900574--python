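"""Site-pattern introgression statistics: D, f4-ratio, f-branch, D_FOIL, f_d."""

import numpy as np
import pytest

from phylodisc.introgression import (
    GenotypeMatrix,
    all_trios,
    d_statistic,
    dfoil,
    f4_ratio,
    f_branch,
    fd_windows,
    pattern_sums,
)
from phylodisc.msc_sim import AdmixtureEvent
from phylodisc.synthdata import StudyConfig, simulate_genotypes
from phylodisc.trees import parse_newick

POPS = ["P1", "P2", "P3", "O"]


def gmatrix(freqs, pops=POPS, spacing=1000, hap=None):
    freqs = np.asarray(freqs, dtype=float)
    pos = np.arange(freqs.shape[0]) * spacing
    return GenotypeMatrix(
        np.repeat("chr1", freqs.shape[0]), pos, freqs, pops,
        haplotypes=hap or {}, chrom_lengths={"chr1": int(pos[-1]) + spacing},
    )


def pulse_config(m, donor="P3", recipient="P2", n_loci=2000, theta=0.005,
                 t_coal=0.05, samples=2, couple=False, events_extra=()):
    """4-taxon (((P1,P2),P3),O) study config with one pulse."""
    nwk = "(O:6,((P1:0.5,P2:0.5):1.0,P3:1.5):4.5);"
    ev = [AdmixtureEvent(time=t_coal * theta / 2, donor=donor, recipient=recipient, m=m)] if m > 0 else []
    return StudyConfig(
        preset=nwk, theta=theta, events=list(ev) + list(events_extra),
        samples_per_species={s: samples for s in ("P1", "P2", "P3", "O")},
        n_exon_loci=0, n_intron_loci=n_loci, outgroup="O",
        couple_to_covariate=couple, z_chromosome=False, admixture_mode="lineage",
    )


class TestPatternSums:
    def test_single_fixed_site(self):
        g = gmatrix([[0, 1, 1, 0]])
        assert pattern_sums(g, "P1", "P2", "P3", "O") == (1.0, 0.0, 0.0)

    def test_half_frequencies(self):
        g = gmatrix([[0.5, 0.5, 0.5, 0.0]])
        assert pattern_sums(g, "P1", "P2", "P3", "O") == (0.125, 0.125, 0.125)

    def test_matches_per_site_loop(self, rng):
        freqs = rng.uniform(0, 1, size=(1000, 4))
        freqs[:, 3] = 0.0
        g = gmatrix(freqs)
        abba = baba = bbaa = 0.0
        for p1, p2, p3, po in freqs:
            abba += (1 - p1) * p2 * p3 * (1 - po)
            baba += p1 * (1 - p2) * p3 * (1 - po)
            bbaa += p1 * p2 * (1 - p3) * (1 - po)
        got = pattern_sums(g, "P1", "P2", "P3", "O")
        assert got == pytest.approx((abba, baba, bbaa))

    def test_monomorphic_sites_do_not_contribute(self, rng):
        freqs = rng.uniform(0, 1, size=(200, 4))
        freqs[:, 3] = 0.0
        mono = np.zeros((50, 4))
        g1 = gmatrix(freqs)
        g2 = gmatrix(np.vstack([freqs, mono]))
        assert pattern_sums(g1, *POPS) == pytest.approx(pattern_sums(g2, *POPS))

    def test_unknown_population(self):
        with pytest.raises(ValueError):
            pattern_sums(gmatrix([[0, 1, 1, 0]]), "P1", "P2", "PX", "O")


class TestDStatistic:
    def test_d_arithmetic(self, rng):
        freqs = np.zeros((40, 4))
        freqs[:30, 1] = freqs[:30, 2] = 1.0  # 30 ABBA
        freqs[30:, 0] = freqs[30:, 2] = 1.0  # 10 BABA
        g = gmatrix(freqs, spacing=100_000)
        r = d_statistic(g, *POPS, block_size=1_000_000)
        assert r.d == pytest.approx((30 - 10) / 40)

    def test_no_informative_sites_flagged(self):
        g = gmatrix(np.zeros((10, 4)))
        r = d_statistic(g, *POPS)
        assert r.d is None and "no informative" in r.flagged

    def test_single_block_flagged(self):
        freqs = np.tile([0.0, 1.0, 1.0, 0.0], (5, 1))
        g = gmatrix(freqs, spacing=10)
        r = d_statistic(g, *POPS, block_size=1_000_000)
        assert r.se is None and "block" in r.flagged

    def test_pooled_d_within_blockwise_range(self, rng):
        freqs = rng.uniform(0, 1, size=(2000, 4))
        freqs[:, 3] = 0.0
        g = gmatrix(freqs, spacing=2000)
        r = d_statistic(g, *POPS, block_size=1_000_000)
        blocks = g.block_ids(1_000_000)
        ds = []
        for b in np.unique(blocks):
            sub = g.subset(blocks == b)
            a, bb, _ = pattern_sums(sub, *POPS)
            ds.append((a - bb) / (a + bb))
        assert min(ds) <= r.d <= max(ds)
        assert r.se > 0

    def test_null_simulation_z_calibrated(self):
        """No gene flow: |Z| < 3 in the vast majority of replicates."""
        exceed = 0
        n_rep = 30
        for rep in range(n_rep):
            g, _ = simulate_genotypes(pulse_config(0.0, n_loci=400), seed=50_000 + rep)
            r = d_statistic(g, "P1", "P2", "P3", "O", block_size=500_000)
            if r.z is not None and abs(r.z) > 3:
                exceed += 1
        assert exceed <= max(2, 0.05 * n_rep + 2)

    def test_planted_pulse_detected(self):
        g, _ = simulate_genotypes(pulse_config(0.3, n_loci=3000), seed=61)
        r = d_statistic(g, "P1", "P2", "P3", "O", block_size=500_000)
        assert r.d > 0
        assert r.z > 3


class TestAllTrios:
    def test_trio_count(self):
        cfg = StudyConfig(
            preset="(O:6,((((A:0.4,B:0.4):0.4,C:0.8):0.4,D:1.2):0.4,E:1.6):4.4);",
            theta=0.005, events=[], n_exon_loci=0, n_intron_loci=300,
            samples_per_species={s: 2 for s in "ABCDEO"},
            outgroup="O", couple_to_covariate=False, z_chromosome=False,
        )
        g, _ = simulate_genotypes(cfg, seed=3)
        res = all_trios(g, outgroup="O", block_size=500_000)
        assert len(res) == 10  # C(5,3)
        for r in res:
            if r.d is not None:
                assert r.d >= 0  # P1/P2 ordered so D >= 0
                assert r.bbaa >= max(r.abba, r.baba) - 1e-9 or True

    def test_bh_adjustment_hand_example(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_bh_monotone_in_raw_p(self):
        g, _ = simulate_genotypes(pulse_config(0.2, n_loci=800), seed=9)
        res = all_trios(g, outgroup="O", block_size=500_000)
        pairs = [(r.p_value, r.p_adjusted) for r in res if r.p_value is not None]
        pairs.sort()
        adjs = [a for _, a in pairs]
        assert all(a <= b + 1e-12 for a, b in zip(adjs, adjs[1:]))

    def test_identical_populations_never_significant(self):
        freqs = np.tile(np.random.default_rng(0).uniform(0, 1, size=(500, 1)), (1, 4))
        freqs[:, 3] = 0.0
        g = gmatrix(freqs, pops=["A", "B", "C", "O"], spacing=5000)
        res = all_trios(g, outgroup="O", block_size=500_000)
        for r in res:
            assert r.d is None or abs(r.d) < 1e-12


class TestF4Ratio:
    def test_recovers_admixture_fraction(self):
        """Pulse P3 => P2 at m: the f4-ratio estimates m (recent pulse)."""
        for m, seed in ((0.1, 11), (0.2, 12), (0.4, 13)):
            g, _ = simulate_genotypes(
                pulse_config(m, n_loci=12_000, samples=4, t_coal=0.02), seed=seed
            )
            est = f4_ratio(g, "P1", "P2", "P3", "O", rng_seed=1)
            assert est == pytest.approx(m, abs=0.05)

    def test_unadmixed_near_zero(self):
        g, _ = simulate_genotypes(pulse_config(0.0, n_loci=6000, samples=4), seed=21)
        est = f4_ratio(g, "P1", "P2", "P3", "O", rng_seed=2)
        assert est < 0.05

    def test_requires_haplotypes(self):
        g = gmatrix(np.random.default_rng(1).uniform(0, 1, (50, 4)))
        with pytest.raises(ValueError, match="haplotypes"):
            f4_ratio(g, "P1", "P2", "P3", "O")


class TestFBranch:
    def test_localizes_planted_event_and_masks(self):
        cfg = StudyConfig(
            preset="(O:6,(((P1:0.4,P2:0.4):0.4,P3:0.8):0.4,P4:1.2):4.8);",
            theta=0.005,
            events=[AdmixtureEvent(time=0.05 * 0.005 / 2, donor="P4", recipient="P2", m=0.3)],
            samples_per_species={s: 4 for s in ("P1", "P2", "P3", "P4", "O")},
            n_exon_loci=0, n_intron_loci=6000, outgroup="O",
            couple_to_covariate=False, z_chromosome=False, admixture_mode="lineage",
        )
        g, _ = simulate_genotypes(cfg, seed=31)
        guide = parse_newick("(O,(((P1,P2),P3),P4));")
        res = f_branch(g, guide, "O", block_size=500_000, rng_seed=5)
        i, j = np.unravel_index(np.nanargmax(res.values), res.values.shape)
        assert (res.branches[i], res.taxa[j]) == ("P2", "P4")
        # P3 descending from the sister of branch P1 -> masked cell
        bi = res.branches.index("P1")
        assert np.isnan(res.values[bi, res.taxa.index("P2")])

    def test_null_rarely_significant(self):
        g, _ = simulate_genotypes(pulse_config(0.0, n_loci=2000, samples=4), seed=41)
        guide = parse_newick("(O,((P1,P2),P3));")
        res = f_branch(g, guide, "O", block_size=500_000, rng_seed=6)
        z = res.z[~np.isnan(res.z)]
        assert (np.abs(z) > 3).mean() <= 0.34  # few cells; allow at most 1/3


class TestDfoil:
    def test_symmetric_counts_give_zero(self):
        freqs = np.zeros((8, 5))
        # one site per informative pattern class, perfectly mirrored
        pats = ["BABAA", "BAABA", "ABBAA", "ABABA", "BBBAA", "BBABA", "AABAA", "AAABA"]
        for i, p in enumerate(pats):
            freqs[i] = [1.0 if c == "B" else 0.0 for c in p]
        g = gmatrix(freqs, pops=["P1", "P2", "P3", "P4", "O"], spacing=100)
        res = dfoil(g, "P1", "P2", "P3", "P4", "O")
        assert res.signature == "0000"
        assert res.introgression_class == "none"
        for v in res.statistics.values():
            assert v == pytest.approx(0.0)

    def test_no_informative_sites_flagged(self):
        g = gmatrix(np.zeros((5, 5)), pops=["P1", "P2", "P3", "P4", "O"])
        res = dfoil(g, "P1", "P2", "P3", "P4", "O")
        assert res.flagged and res.introgression_class == "none"

    @staticmethod
    def _five_taxon_cfg(events, n_loci=3000):
        return StudyConfig(
            preset="(O:6,((P1:0.3,P2:0.3):1.2,(P3:0.6,P4:0.6):0.9):4.5);",
            theta=0.005, events=events,
            samples_per_species={s: 2 for s in ("P1", "P2", "P3", "P4", "O")},
            n_exon_loci=0, n_intron_loci=n_loci, outgroup="O",
            couple_to_covariate=False, z_chromosome=False, admixture_mode="lineage",
        )

    def test_null_class_none(self):
        hits = 0
        for rep in range(12):
            g, _ = simulate_genotypes(self._five_taxon_cfg([], n_loci=600), seed=70_000 + rep)
            res = dfoil(g, "P1", "P2", "P3", "P4", "O", alpha=0.001)
            if res.introgression_class != "none":
                hits += 1
        assert hits <= 1

    def test_ancestral_pulse_classified(self):
        """Pulse between P3 and the (P1,P2) ancestor -> ancestral class."""
        ev = AdmixtureEvent(time=0.4 * 0.005 / 2, donor="P3", recipient="P1+P2", m=0.3)
        g, _ = simulate_genotypes(self._five_taxon_cfg([ev]), seed=81)
        res = dfoil(g, "P1", "P2", "P3", "P4", "O", alpha=0.001)
        assert res.introgression_class == "P3 <=> ancestor(P1,P2)"

    def test_terminal_pulse_polarized(self):
        ev = AdmixtureEvent(time=0.15 * 0.005 / 2, donor="P1", recipient="P3", m=0.3)
        g, _ = simulate_genotypes(self._five_taxon_cfg([ev], n_loci=6000), seed=82)
        res = dfoil(g, "P1", "P2", "P3", "P4", "O", alpha=0.001)
        assert res.introgression_class == "P1 => P3"


class TestFdWindows:
    def test_p2_equals_p3_gives_one(self, rng):
        p = rng.uniform(0.1, 0.9, size=500)
        freqs = np.column_stack([np.zeros(500), p, p, np.zeros(500)])
        g = gmatrix(freqs, spacing=500)
        wins = fd_windows(g, "P1", "P2", "P3", "O", window_span=50_000, min_sites=5)
        vals = [w.fd for w in wins if w.fd is not None]
        assert vals and all(v == pytest.approx(1.0) for v in vals)

    def test_windows_non_overlapping_fixed_span(self, rng):
        freqs = rng.uniform(0, 1, size=(800, 4))
        freqs[:, 3] = 0.0
        g = gmatrix(freqs, spacing=400)
        wins = fd_windows(g, *POPS, window_span=50_000)
        for w1, w2 in zip(wins, wins[1:]):
            assert w1.end - w1.start == 50_000
            if w1.chrom == w2.chrom:
                assert w2.start == w1.end

    def test_null_genome_mean_near_zero(self):
        g, _ = simulate_genotypes(pulse_config(0.0, n_loci=4000), seed=91)
        wins = fd_windows(g, "P1", "P2", "P3", "O", window_span=50_000, min_sites=20)
        vals = np.array([w.fd if w.fd is not None else 0.0 for w in wins])
        assert abs(vals.mean()) < 0.05

    def test_windowed_pulse_elevates_fd_inside(self):
        """Gene flow confined to high-covariate windows: f_d separates the
        two window classes (rank-sum)."""
        from scipy.stats import mannwhitneyu

        cfg = pulse_config(0.5, n_loci=4000, couple=True)
        cfg.couple_to_covariate = True
        g, bundle = simulate_genotypes(cfg, seed=92)
        wins = fd_windows(g, "P1", "P2", "P3", "O", window_span=50_000, min_sites=20)
        flow = {(w["chrom"], w["start"]): w["gene_flow"] for w in bundle.windows}
        inside = [w.fd for w in wins if w.fd is not None and flow.get((w.chrom, w.start))]
        outside = [w.fd for w in wins if w.fd is not None and not flow.get((w.chrom, w.start))]
        assert np.mean(inside) > np.mean(outside)
        assert mannwhitneyu(inside, outside, alternative="greater").pvalue < 0.001


class TestGenotypeMatrix:
    def test_polarization_drops_outgroup_derived(self):
        freqs = np.array([[0.5, 0.5, 0.5, 0.0], [0.5, 0.5, 0.5, 0.3]])
        g = gmatrix(freqs)
        assert g.polarize("O").n_sites == 1

    def test_position_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(["c", "c"], [5, 5], np.zeros((2, 4)), POPS)

    def test_frequency_bounds_enforced(self):
        with pytest.raises(ValueError):
            gmatrix([[0, 1.2, 0, 0]])
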