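"""RPM-normalized, strand-oriented, length-scaled TSS->TES metagene profiles.

Each gene contributes a vector of bin means: fixed-width upstream flank bins,
``n_body_bins`` equal fractional-width bins over the gene body (fractional
bases weighted proportionally, so the per-base oracle is exact), and
fixed-width downstream flank bins.  Minus-strand genes are reported 5'->3'.
Group curves are unweighted means of gene vectors, so profiles are comparable
across gene lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breadth import AnalysisConfig
from .formats import CoverageTrack, GeneModel

__all__ = ["Metaprofile", "rpm_scale", "gene_profile", "group_metaprofile", "bin_labels"]


@dataclass
class Metaprofile:
    """Per-group mean RPM per bin, with group sizes."""

    bin_labels: list[str]
    curves: dict[str, np.ndarray]
    n_genes: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for group, curve in self.curves.items():
            for label, value in zip(self.bin_labels, curve):
                rows.append(
                    {"bin": label, "group": group, "mean_rpm": value, "n_genes": self.n_genes[group]}
                )
        return pd.DataFrame(rows)


def bin_labels(config: AnalysisConfig) -> list[str]:
    """Bin labels from -flank through TSS..TES to +flank."""
    n_flank = config.flank_bp // config.flank_bin_bp
    up = [f"{-config.flank_bp + i * config.flank_bin_bp}" for i in range(n_flank)]
    body = [f"body_{i:03d}" for i in range(config.n_body_bins)]
    down = [f"+{i * config.flank_bin_bp}" for i in range(n_flank)]
    return up + body + down


def rpm_scale(track: CoverageTrack) -> CoverageTrack:
    """Scale every step value by 1e6 / total_mapped_reads (reads per million)."""
    if track.total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0 for RPM scaling")
    return track.scaled(1e6 / track.total_mapped_reads)


def _flank_bins(values: np.ndarray, valid: np.ndarray, bin_bp: int) -> np.ndarray:
    """Fixed-width flank bins; bins truncated by the chromosome edge are
    averaged over their available bases (all-invalid bins read 0)."""
    n = len(values) // bin_bp
    v = values[: n * bin_bp].reshape(n, bin_bp)
    m = valid[: n * bin_bp].reshape(n, bin_bp)
    avail = m.sum(axis=1)
    out = np.zeros(n)
    nz = avail > 0
    out[nz] = (v * m).sum(axis=1)[nz] / avail[nz]
    return out


def _body_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal fractional-width bins via the exact prefix-integral of the
    per-base step function."""
    L = len(values)
    csum = np.concatenate(([0.0], np.cumsum(values)))

    def integral(x: np.ndarray) -> np.ndarray:
        i = np.floor(x).astype(int)
        i = np.clip(i, 0, L)
        frac = x - i
        base = csum[i]
        inner = np.clip(i, 0, L - 1)
        return base + np.where(i < L, frac * values[inner], 0.0)

    edges = np.linspace(0.0, float(L), n_bins + 1)
    mass = np.diff(integral(edges))
    widths = np.diff(edges)
    return mass / widths


def gene_profile(
    gene: GeneModel, track: CoverageTrack, config: AnalysisConfig | None = None
) -> np.ndarray:
    """Binned signal vector for one gene: upstream flank, scaled body,
    downstream flank, oriented 5'->3'."""
    config = config or AnalysisConfig()
    config.validate()
    flank = config.flank_bp
    left = gene.start - flank
    vals = track.values_array(gene.chrom, left, gene.end + flank)
    valid = np.ones(len(vals), dtype=bool)
    if left < 0:  # flank runs off the chromosome start
        valid[: -left] = False
    body = vals[flank : flank + gene.length]
    up = _flank_bins(vals[:flank], valid[:flank], config.flank_bin_bp)
    down = _flank_bins(vals[flank + gene.length :], valid[flank + gene.length :], config.flank_bin_bp)
    body_binned = _body_bins(body, config.n_body_bins)
    profile = np.concatenate([up, body_binned, down])
    if gene.strand == "-":
        profile = profile[::-1]
    return profile


def group_metaprofile(
    genes: list[GeneModel],
    groups: pd.DataFrame,
    track: CoverageTrack,
    config: AnalysisConfig | None = None,
) -> Metaprofile:
    """Unweighted per-group mean of gene profiles.

    ``groups`` is a classified breadth table (indexed by gene_id with a
    ``group`` column); every profiled gene must be classified, and every group
    present in the table must be non-empty among the supplied genes.
    """
    config = config or AnalysisConfig()
    config.validate()
    by_group: dict[str, list[np.ndarray]] = {}
    group_of = groups["group"].astype(str).to_dict()
    for g in genes:
        if g.gene_id not in group_of:
            raise ValueError(f"gene {g.gene_id} is not classified")
        by_group.setdefault(group_of[g.gene_id], []).append(gene_profile(g, track, config))
    curves: dict[str, np.ndarray] = {}
    n_genes: dict[str, int] = {}
    for group in sorted(set(group_of.values())):
        profiles = by_group.get(group, [])
        if not profiles:
            raise ValueError(f"group {group!r} is empty")
        curves[group] = np.mean(profiles, axis=0)
        n_genes[group] = len(profiles)
    return Metaprofile(bin_labels=bin_labels(config), curves=curves, n_genes=n_genes)


def plot_metaprofile(profile: Metaprofile, path: str) -> None:
    """Write a simple per-group curve plot (optional convenience output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(profile.bin_labels))
    for group, curve in profile.curves.items():
        ax.plot(x, curve, label=f"{group} (n={profile.n_genes[group]})")
    n_flank = sum(1 for b in profile.bin_labels if b.startswith("-"))
    ax.axvline(n_flank, color="grey", lw=0.5)
    ax.axvline(len(profile.bin_labels) - n_flank - 1, color="grey", lw=0.5)
    ax.set_xlabel("bin (-flank .. TSS .. TES .. +flank)")
    ax.set_ylabel("mean RPM")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
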