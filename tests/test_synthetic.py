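"""Simulator contracts: determinism, geometry of the planted effect, and
distributional oracles (log-normal tail, Poisson coverage, NB limits)."""

import numpy as np
import pytest
from scipy import stats

import broaddomain as bd


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


class TestGenome:
    def test_zero_genes(self):
        assert bd.simulate_genome(bd.SynthConfig(seed=1, n_genes=0)) == []

    def test_determinism(self):
        cfg = bd.SynthConfig(seed=5, n_genes=2)
        assert bd.simulate_genome(cfg) == bd.simulate_genome(cfg)

    def test_no_pairwise_overlap_and_min_gaps(self):
        genes = bd.simulate_genome(bd.SynthConfig(seed=2, n_genes=200))
        # brute-force all-pairs overlap check
        n_overlaps = sum(
            1
            for i, a in enumerate(genes)
            for b in genes[i + 1 :]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end
        )
        assert n_overlaps == 0
        by_chrom: dict[str, list[bd.GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.start)
            assert all(b.start - a.end >= 10_000 for a, b in zip(glist, glist[1:]))

    def test_too_small_genome_rejected(self):
        cfg = bd.SynthConfig(seed=1, n_genes=50, chrom_length_bp=200_000)
        with pytest.raises(ValueError, match="too small"):
            bd.simulate_genome(cfg)

    def test_strands_alternate(self):
        genes = bd.simulate_genome(bd.SynthConfig(seed=3, n_genes=40))
        by_id = sorted(genes, key=lambda g: g.gene_id)
        strands = {g.strand for g in by_id}
        assert strands == {"+", "-"}
        assert all(a.strand != b.strand for a, b in zip(by_id, by_id[1:]))


# ---------------------------------------------------------------------------
# Peaks + truth
# ---------------------------------------------------------------------------


class TestPeaks:
    def test_null_effect_gives_identical_peak_sets(self):
        cfg = bd.SynthConfig(seed=4, n_genes=100, planted_fraction=0.0)
        genes = bd.simulate_genome(cfg)
        control, mutant, truth = bd.simulate_peaks(genes, cfg)
        assert control == mutant
        assert not truth["is_planted"].any()
        assert (truth["true_breadth_control"] == truth["true_breadth_mutant"]).all()
        assert (truth["true_log2fc_expression"] == 0).all()

    def test_shrink_arithmetic_tes_proximal(self, sim):
        """With breadth_reduction_factor=0.5 and body_bias=1.0 the mutant
        domain keeps its TSS edge and loses the whole span from the TES side."""
        cfg, genes = sim["cfg"], sim["genes"]
        truth = sim["truth"]
        ctrl = {p.name: p for p in sim["peaks_control"]}
        mut = {p.name: p for p in sim["peaks_mutant"]}
        by_id = {g.gene_id: g for g in genes}
        planted = truth.index[truth["is_planted"]]
        assert len(planted) > 0
        for gid in planted:
            pc, pm, g = ctrl[f"{gid}:pk1"], mut[f"{gid}:pk1"], by_id[gid]
            loss = truth.loc[gid, "true_breadth_control"] - truth.loc[gid, "true_breadth_mutant"]
            assert truth.loc[gid, "true_breadth_mutant"] == round(
                truth.loc[gid, "true_breadth_control"] * cfg.breadth_reduction_factor
            )
            if g.strand == "+":
                assert pm.start == pc.start and pm.end == pc.end - loss
            else:
                assert pm.end == pc.end and pm.start == pc.start + loss

    def test_planted_implies_identity(self, sim):
        truth = sim["truth"]
        assert (truth.loc[truth["is_planted"], "is_identity"]).all()
        nonplanted = truth.loc[~truth["is_planted"]]
        assert (nonplanted["true_breadth_control"] == nonplanted["true_breadth_mutant"]).all()
        assert (nonplanted["true_log2fc_expression"] == 0).all()

    def test_domains_anchored_at_tss(self, sim):
        by_id = {g.gene_id: g for g in sim["genes"]}
        for p in sim["peaks_control"]:
            g = by_id[p.name.split(":")[0]]
            anchor = p.start if g.strand == "+" else p.end
            assert anchor == g.tss

    def test_lognormal_tail_above_40kb(self):
        """Fraction of identity genes drawn broader than 40 kb must sit inside
        binomial 99% bounds of the tail probability implied by the log-normal."""
        cfg = bd.SynthConfig(seed=6, n_genes=500)
        genes = bd.simulate_genome(cfg)
        _, _, truth = bd.simulate_peaks(genes, cfg)
        ident = truth.loc[truth["is_identity"], "drawn_breadth"]
        p_tail = 1.0 - stats.norm.cdf(
            (np.log(40_000) - cfg.breadth_lognormal_mu_broad) / cfg.breadth_lognormal_sigma_broad
        )
        assert p_tail >= 0.05  # defaults guarantee a >=5% super-broad tail
        k = int((ident > 40_000).sum())
        lo, hi = stats.binom.interval(0.99, len(ident), p_tail)
        assert lo <= k <= hi

    def test_determinism(self, sim):
        cfg = sim["cfg"]
        control, mutant, truth = bd.simulate_peaks(sim["genes"], cfg)
        assert control == sim["peaks_control"] and mutant == sim["peaks_mutant"]
        assert truth.equals(sim["truth"])

    def test_fragmented_mode_counts_and_gaps(self):
        cfg = bd.SynthConfig(seed=9, n_genes=80, fragment_domains=True)
        genes = bd.simulate_genome(cfg)
        control, _, truth = bd.simulate_peaks(genes, cfg)
        per_gene: dict[str, int] = {}
        for p in control:
            gid = p.name.split(":")[0]
            per_gene[gid] = per_gene.get(gid, 0) + 1
        assert per_gene == truth["n_fragments"].to_dict()
        assert truth["n_fragments"].max() == 3 and truth["n_fragments"].max() <= 3


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


class TestCoverage:
    def test_poisson_reads_oracle(self):
        """One 1,000 bp peak at depth 10/bin with 50 bp bins: expected reads
        10 * (1000/50) = 200; the sampled total must land within 4 sigma."""
        cfg = bd.SynthConfig(seed=7, coverage_depth=10.0, background_fraction=0.0, read_length=50)
        peaks = bd.PeakSet([bd.Peak("chr1", 1000, 2000, "p1")])
        track = bd.simulate_coverage(peaks, cfg)
        expected = 10.0 * (1000 / 50)
        assert abs(track.total_mapped_reads - expected) <= 4 * np.sqrt(expected)
        # all mass lies inside the peak when background is off
        inside = track.values_array("chr1", 1000, 2000).sum()
        assert inside == pytest.approx(track.total_mass())

    def test_determinism(self):
        cfg = bd.SynthConfig(seed=8)
        peaks = bd.PeakSet([bd.Peak("chr1", 0, 5000, "p1"), bd.Peak("chr2", 100, 900, "p2")])
        assert bd.simulate_coverage(peaks, cfg) == bd.simulate_coverage(peaks, cfg)

    def test_background_level(self):
        cfg = bd.SynthConfig(seed=10, coverage_depth=10.0, background_fraction=0.1)
        peaks = bd.PeakSet([bd.Peak("chr1", 0, 1000, "p1")])
        track = bd.simulate_coverage(peaks, cfg)
        bg = track.values_array("chr1", 2000, 10_000)
        # per-base value equals its bin's read count: 160 bins at lambda = 1
        assert abs(bg.reshape(-1, 50)[:, 0].mean() - 1.0) < 5 / np.sqrt(160)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


class TestCounts:
    def test_flat_coupling_shares_base_mean(self, sim):
        cfg = bd.SynthConfig(seed=11, n_genes=400, expression_coupling_slope=0.0, planted_fraction=0.0)
        genes = bd.simulate_genome(cfg)
        _, _, truth = bd.simulate_peaks(genes, cfg)
        cm = bd.simulate_counts(truth, cfg)
        grand_mean = cm.counts.to_numpy().mean()
        se = cm.counts.to_numpy().std() / np.sqrt(cm.counts.size)
        assert abs(grand_mean - cfg.base_mean_count) < 5 * se

    def test_poisson_limit_of_nb(self):
        """theta -> infinity: variance approaches the mean (10^4 draws)."""
        cfg = bd.SynthConfig(
            seed=12,
            nb_dispersion=1e6,
            n_replicates_per_condition=5000,
            expression_coupling_slope=0.0,
            planted_fraction=0.0,
            n_genes=1,
        )
        genes = bd.simulate_genome(cfg)
        _, _, truth = bd.simulate_peaks(genes, cfg)
        cm = bd.simulate_counts(truth, cfg)
        draws = cm.counts.to_numpy().ravel()
        assert draws.size == 10_000
        assert draws.var() / draws.mean() == pytest.approx(1.0, rel=0.1)

    def test_planted_fold_change_law_of_large_numbers(self):
        cfg = bd.SynthConfig(seed=13, n_genes=60, n_replicates_per_condition=50, planted_fraction=1.0)
        genes = bd.simulate_genome(cfg)
        _, _, truth = bd.simulate_peaks(genes, cfg)
        cm = bd.simulate_counts(truth, cfg)
        planted = truth.index[truth["is_planted"]]
        ctrl = cm.counts.loc[planted, cm.samples_of("control")].mean(axis=1)
        mut = cm.counts.loc[planted, cm.samples_of("mutant")].mean(axis=1)
        ratio = (mut / ctrl).to_numpy()
        # per-gene sampling error of the ratio at n=50, theta=60 is ~3%
        assert np.allclose(ratio, 0.5, rtol=0.15)
        assert abs(ratio.mean() - 0.5) < 0.02

    def test_bit_reproducibility(self, sim, sim_counts):
        again = bd.simulate_counts(sim["truth"], sim["cfg"])
        assert again.counts.equals(sim_counts.counts)

    def test_peak_counts_track_breadth_ratio(self, sim):
        cfg, truth = sim["cfg"], sim["truth"]
        pc = bd.simulate_peak_counts(truth, sim["peaks_control"], cfg)
        planted = truth.index[truth["is_planted"]]
        names = [f"{gid}:pk1" for gid in planted]
        ctrl = pc.counts.loc[names, pc.samples_of("control")].to_numpy().mean()
        mut = pc.counts.loc[names, pc.samples_of("mutant")].to_numpy().mean()
        assert mut / ctrl == pytest.approx(cfg.breadth_reduction_factor, rel=0.05)

    def test_invalid_dispersion_rejected(self, sim):
        cfg = bd.SynthConfig(seed=1, nb_dispersion=-1.0)
        with pytest.raises(ValueError, match="nb_dispersion"):
            bd.simulate_counts(sim["truth"], cfg)
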