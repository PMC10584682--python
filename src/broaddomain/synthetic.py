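"""Synthetic genomes, H3K4me3 peak sets, coverage tracks and count matrices.

The simulator emulates the statistical structure the downstream analysis
assumes: a toy genome of non-overlapping stranded genes; one H3K4me3 domain
per gene anchored at the TSS and extending into the gene body, with breadth
drawn from a class-specific log-normal (a designated "identity" subset carries
broad domains, a tail of which exceed 40 kb); expression monotonically coupled
to breadth via negative-binomial counts; and a mutant condition in which a
planted subset of identity genes loses a fixed fraction of its domain breadth
from the gene-body (TES-proximal) side, together with a planted expression
log2 fold change.

All randomness flows from ``SynthConfig.seed``; each operation derives its own
stream with a fixed offset, so identical configs are bit-reproducible and the
operations can be re-run independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .formats import CountMatrix, CoverageTrack, GeneModel, Peak, PeakSet

__all__ = [
    "SynthConfig",
    "simulate_genome",
    "simulate_peaks",
    "simulate_coverage",
    "simulate_counts",
    "simulate_peak_counts",
]

# per-operation rng stream offsets (spawned as default_rng([seed, offset]))
_RNG_GENOME, _RNG_PEAKS, _RNG_COVERAGE, _RNG_COUNTS, _RNG_PEAK_COUNTS = 1, 2, 3, 4, 5


@dataclass
class SynthConfig:
    """All simulation parameters.

    Breadth is log-normal per class: identity genes use
    ``(mu_broad, sigma_broad)`` — defaults give a median domain of 20 kb with
    roughly 8% of draws beyond 40 kb — and the remaining genes use
    ``(mu_narrow, sigma_narrow)`` (median 2 kb).  Expression couples to breadth
    through ``expression_coupling_slope`` = d(log2 mean count)/d(log10 breadth),
    referenced to ``base_mean_count`` at 1 kb.  Counts are NB(mu, theta) with
    variance mu + mu^2/theta.  Coverage is Poisson per ``read_length``-sized
    bin with expectation ``coverage_depth`` inside peaks and
    ``background_fraction * coverage_depth`` outside.
    """

    seed: int = 0
    n_genes: int = 600
    n_chroms: int = 4
    gene_length_range: tuple[int, int] = (5_000, 60_000)
    intergenic_gap_range: tuple[int, int] = (50_000, 80_000)
    chrom_length_bp: int | None = None
    identity_fraction: float = 0.25
    breadth_lognormal_mu_broad: float = math.log(20_000.0)
    breadth_lognormal_sigma_broad: float = 0.5
    breadth_lognormal_mu_narrow: float = math.log(2_000.0)
    breadth_lognormal_sigma_narrow: float = 0.6
    downstream_extension_bp: int = 30_000
    expression_coupling_slope: float = 2.0
    base_mean_count: float = 150.0
    nb_dispersion: float = 60.0
    n_replicates_per_condition: int = 3
    planted_fraction: float = 0.5
    breadth_reduction_factor: float = 0.5
    body_bias: float = 1.0
    expression_reduction_log2fc: float = -1.0
    coverage_depth: float = 10.0
    background_fraction: float = 0.02
    read_length: int = 50
    fragment_domains: bool = False
    fragment_gap_bp: int = 200

    def validate(self) -> None:
        for name in ("identity_fraction", "planted_fraction", "body_bias", "background_fraction"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {x}")
        if not (0.0 < self.breadth_reduction_factor < 1.0):
            raise ValueError("breadth_reduction_factor must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.coverage_depth <= 0:
            raise ValueError("coverage_depth must be > 0")
        if self.n_genes < 0 or self.n_chroms < 1:
            raise ValueError("n_genes must be >= 0 and n_chroms >= 1")
        if self.gene_length_range[0] < 1 or self.gene_length_range[0] > self.gene_length_range[1]:
            raise ValueError("invalid gene_length_range")
        if self.intergenic_gap_range[0] < 10_000:
            raise ValueError("intergenic gaps must be >= 10 kb")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_length_range"] = list(d["gene_length_range"])
        d["intergenic_gap_range"] = list(d["intergenic_gap_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("gene_length_range", "intergenic_gap_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SynthConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), offset])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SynthConfig) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping stranded genes across ``n_chroms``
    with intergenic gaps drawn from ``intergenic_gap_range`` (>= 10 kb).

    Strands alternate deterministically (the starting strand is drawn from the
    seed).  Raises if ``chrom_length_bp`` is set and the genes do not fit.
    """
    config.validate()
    rng = _rng(config, _RNG_GENOME)
    n = config.n_genes
    genes: list[GeneModel] = []
    if n == 0:
        return genes
    lo, hi = config.gene_length_range
    glo, ghi = config.intergenic_gap_range
    lengths = rng.integers(lo, hi + 1, size=n)
    gaps = rng.integers(glo, ghi + 1, size=n)
    first_strand = "+" if rng.integers(0, 2) == 0 else "-"
    per_chrom = np.array_split(np.arange(n), config.n_chroms)
    width = len(str(n))
    for ci, idx in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = 0
        for k, i in enumerate(idx):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            if config.chrom_length_bp is not None and end + glo > config.chrom_length_bp:
                raise ValueError(
                    f"genome too small: gene {i} does not fit on {chrom} "
                    f"within chrom_length_bp={config.chrom_length_bp}"
                )
            strand = first_strand if (int(i) % 2 == 0) else ("-" if first_strand == "+" else "+")
            genes.append(
                GeneModel(
                    gene_id=f"g{int(i) + 1:0{width}d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
            pos = end
    return genes


# ---------------------------------------------------------------------------
# Peaks + truth
# ---------------------------------------------------------------------------


def _fragment(start: int, end: int, gap: int) -> list[tuple[int, int]]:
    """Split the span into <=3 equal fragments separated by internal gaps of
    ``gap`` bp carved out of the left-hand fragment ends."""
    span = end - start
    n_frag = 3 if span >= 6_000 else (2 if span >= 2_000 else 1)
    if n_frag == 1:
        return [(start, end)]
    edges = [start + round(span * k / n_frag) for k in range(n_frag + 1)]
    return [
        (edges[k], edges[k + 1] - (gap if k < n_frag - 1 else 0))
        for k in range(n_frag)
    ]


def simulate_peaks(
    genes: list[GeneModel], config: SynthConfig
) -> tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Draw one H3K4me3 domain per gene and return control peaks, mutant peaks
    and the truth table.

    The domain is anchored at the TSS and extends into the gene body; draws
    longer than gene length + ``downstream_extension_bp`` are truncated and
    flagged.  For planted genes the mutant domain shrinks by
    ``breadth_reduction_factor``, with ``body_bias`` of the lost span removed
    from the TES-proximal end (the remainder from the TSS side).  The truth
    table records, per gene: identity/planted flags, the drawn (pre-truncation)
    breadth, realized control/mutant breadths, the truncation flag, the planted
    expression log2FC and the fragment count.
    """
    config.validate()
    rng = _rng(config, _RNG_PEAKS)
    n = len(genes)
    is_identity = np.zeros(n, dtype=bool)
    n_id = int(math.floor(config.identity_fraction * n))
    if n_id > 0:
        is_identity[rng.choice(n, size=n_id, replace=False)] = True
    mu = np.where(is_identity, config.breadth_lognormal_mu_broad, config.breadth_lognormal_mu_narrow)
    sigma = np.where(
        is_identity, config.breadth_lognormal_sigma_broad, config.breadth_lognormal_sigma_narrow
    )
    drawn = np.exp(rng.normal(mu, sigma)).round().astype(np.int64)
    drawn = np.maximum(drawn, 200)  # a domain narrower than a nucleosome pair is not a peak

    is_planted = np.zeros(n, dtype=bool)
    id_idx = np.flatnonzero(is_identity)
    n_planted = int(math.floor(config.planted_fraction * len(id_idx)))
    if n_planted > 0:
        is_planted[rng.choice(id_idx, size=n_planted, replace=False)] = True

    rows = []
    control: list[Peak] = []
    mutant: list[Peak] = []
    for i, g in enumerate(genes):
        allowed = g.length + config.downstream_extension_bp
        b_ctrl = int(min(drawn[i], allowed))
        truncated = bool(drawn[i] > allowed)
        if g.strand == "+":
            c_start, c_end = g.start, g.start + b_ctrl
        else:
            c_start, c_end = g.end - b_ctrl, g.end
            c_start = max(c_start, 0)
            b_ctrl = c_end - c_start
        if is_planted[i]:
            b_mut = int(round(b_ctrl * config.breadth_reduction_factor))
            loss = b_ctrl - b_mut
            tes_trim = int(round(config.body_bias * loss))
            tss_trim = loss - tes_trim
            if g.strand == "+":
                m_start, m_end = c_start + tss_trim, c_end - tes_trim
            else:
                m_start, m_end = c_start + tes_trim, c_end - tss_trim
            log2fc = config.expression_reduction_log2fc
        else:
            b_mut, (m_start, m_end) = b_ctrl, (c_start, c_end)
            log2fc = 0.0

        for tag, (s, e), dest in (("ctrl", (c_start, c_end), control), ("mut", (m_start, m_end), mutant)):
            spans = (
                _fragment(s, e, config.fragment_gap_bp)
                if config.fragment_domains
                else [(s, e)]
            )
            for k, (fs, fe) in enumerate(spans):
                dest.append(Peak(chrom=g.chrom, start=fs, end=fe, name=f"{g.gene_id}:pk{k + 1}"))
        n_fragments = (
            len(_fragment(c_start, c_end, config.fragment_gap_bp)) if config.fragment_domains else 1
        )
        rows.append(
            {
                "gene_id": g.gene_id,
                "is_identity": bool(is_identity[i]),
                "is_planted": bool(is_planted[i]),
                "drawn_breadth": int(drawn[i]),
                "true_breadth_control": b_ctrl,
                "true_breadth_mutant": b_mut,
                "truncated": truncated,
                "true_log2fc_expression": log2fc,
                "n_fragments": n_fragments,
            }
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    return PeakSet(control), PeakSet(mutant), truth


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


def simulate_coverage(peaks: PeakSet, config: SynthConfig) -> CoverageTrack:
    """Poisson-sample a coverage track from a peak set.

    The genome is tiled in ``read_length``-sized bins; a bin's expected read
    count interpolates between ``coverage_depth`` (fully inside a peak) and
    ``background_fraction * coverage_depth`` (fully outside) by its covered
    fraction.  The per-base signal equals the reads sampled in its bin, and
    ``total_mapped_reads`` is the genome-wide sum of sampled reads.
    """
    config.validate()
    rng = _rng(config, _RNG_COVERAGE)
    L = config.read_length
    depth, bg = config.coverage_depth, config.background_fraction * config.coverage_depth
    track = CoverageTrack(total_mapped_reads=1)
    total_reads = 0
    by_chrom = peaks.by_chrom()
    for chrom in sorted(by_chrom):
        plist = by_chrom[chrom]
        chrom_len = max(p.end for p in plist) + 10_000
        n_bins = -(-chrom_len // L)
        covered = np.zeros(n_bins)
        # merged peak intervals -> covered bp per bin
        ivs = sorted((p.start, p.end) for p in plist)
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            b0, b1 = s // L, (e - 1) // L
            if b0 == b1:
                covered[b0] += e - s
            else:
                covered[b0] += (b0 + 1) * L - s
                covered[b1] += e - b1 * L
                covered[b0 + 1 : b1] += L
        frac = covered / L
        lam = bg + (depth - bg) * frac
        reads = rng.poisson(lam)
        total_reads += int(reads.sum())
        starts = np.arange(n_bins, dtype=np.int64) * L
        ends = np.minimum(starts + L, chrom_len)
        track._set_chrom(chrom, starts, ends, reads.astype(float))
    track.total_mapped_reads = max(total_reads, 1)
    return track


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float, size: tuple) -> np.ndarray:
    # numpy's negative_binomial(n, p): mean n(1-p)/p; set n=theta, p=theta/(theta+mu)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def _sample_labels(config: SynthConfig) -> tuple[list[str], dict[str, str]]:
    r = config.n_replicates_per_condition
    samples = [f"ctrl_{k + 1}" for k in range(r)] + [f"mut_{k + 1}" for k in range(r)]
    cond = {s: ("control" if s.startswith("ctrl") else "mutant") for s in samples}
    return samples, cond


def simulate_counts(truth: pd.DataFrame, config: SynthConfig) -> CountMatrix:
    """Draw the gene x sample RNA count matrix from the truth table.

    Control mean: ``base_mean_count * 2**(slope * log10(breadth_control/1000))``;
    mutant mean additionally scaled by ``2**true_log2fc_expression``.  Counts
    are NB(mu, theta) per replicate.
    """
    config.validate()
    rng = _rng(config, _RNG_COUNTS)
    r = config.n_replicates_per_condition
    b = truth["true_breadth_control"].to_numpy(dtype=float)
    mu_ctrl = config.base_mean_count * 2.0 ** (
        config.expression_coupling_slope * np.log10(b / 1_000.0)
    )
    mu_mut = mu_ctrl * 2.0 ** truth["true_log2fc_expression"].to_numpy(dtype=float)
    n = len(truth)
    ctrl = _nb_sample(rng, mu_ctrl[:, None], config.nb_dispersion, (n, r))
    mut = _nb_sample(rng, mu_mut[:, None], config.nb_dispersion, (n, r))
    samples, cond = _sample_labels(config)
    df = pd.DataFrame(np.hstack([ctrl, mut]), index=truth.index, columns=samples)
    return CountMatrix(counts=df, sample_condition=cond)


def simulate_peak_counts(
    truth: pd.DataFrame, peaks_control: PeakSet, config: SynthConfig
) -> CountMatrix:
    """Draw the peak x sample ChIP-signal count matrix.

    A domain's expected read count is ``coverage_depth * breadth / read_length``
    under its own condition's breadth, split across fragments proportionally to
    fragment width, NB-dispersed across replicates.  Features are the control
    peak names, so the matrix joins directly against a peak-to-gene assignment
    built from the control peak set.
    """
    config.validate()
    rng = _rng(config, _RNG_PEAK_COUNTS)
    r = config.n_replicates_per_condition
    widths: dict[str, list[tuple[str, int]]] = {}
    for p in peaks_control:
        gene_id = p.name.rsplit(":", 1)[0]
        widths.setdefault(gene_id, []).append((p.name, p.width))
    names: list[str] = []
    mu_ctrl_list: list[float] = []
    mu_mut_list: list[float] = []
    scale = config.coverage_depth / config.read_length
    for gene_id, frags in widths.items():
        b_ctrl = float(truth.loc[gene_id, "true_breadth_control"])
        b_mut = float(truth.loc[gene_id, "true_breadth_mutant"])
        total_w = sum(w for _, w in frags)
        for name, w in frags:
            share = w / total_w
            names.append(name)
            mu_ctrl_list.append(scale * b_ctrl * share)
            mu_mut_list.append(scale * b_mut * share)
    mu_ctrl = np.asarray(mu_ctrl_list)
    mu_mut = np.asarray(mu_mut_list)
    n = len(names)
    ctrl = _nb_sample(rng, mu_ctrl[:, None], config.nb_dispersion, (n, r))
    mut = _nb_sample(rng, mu_mut[:, None], config.nb_dispersion, (n, r))
    samples, cond = _sample_labels(config)
    df = pd.DataFrame(np.hstack([ctrl, mut]), index=pd.Index(names, name="peak"), columns=samples)
    return CountMatrix(counts=df, sample_condition=cond)
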