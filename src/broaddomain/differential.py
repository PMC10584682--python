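"""Count normalization and differential testing between control and mutant.

Normalization is the median-of-ratios scheme: sample j's size factor is the
median, over features with a positive geometric mean across samples, of
count_gj / geomean_g.  Significance comes from a two-sided pooled-variance
two-sample t-test on log2(normalized + 1) per feature (the two conditions
share a dispersion model, and at n = 3 replicates the pooled test is
correctly calibrated where the unpooled Welch variant is conservative); the effect size is
log2((mean_mutant + 0.5) / (mean_control + 0.5)) on normalized counts.  A
feature is called ``down`` when p < alpha and log2FC < 0, ``up`` when
p < alpha and log2FC > 0, otherwise ``unchanged``.  This is deliberately a
self-contained engine implementing the published thresholding rule (P < 0.05,
no multiple-testing correction by default; a Benjamini-Hochberg switch is
available) — it does not claim numeric equivalence with NB-GLM tools.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .breadth import AnalysisConfig
from .formats import CountMatrix, Peak

logger = logging.getLogger("broaddomain")

__all__ = ["size_factors", "normalize", "de_test", "peak_signal_change"]


def size_factors(matrix: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to unit geometric
    mean (only factor ratios are identified by the scheme; the rescale makes
    it exactly idempotent).

    Requires at least one feature with nonzero counts in every sample (those
    are the features with a positive geometric mean).  Accepts a raw
    DataFrame as well, so the scheme can be re-applied to already-normalized
    (non-integer) matrices.
    """
    table = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    counts = table.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    finite = np.all(np.isfinite(logc), axis=1)
    if not finite.any():
        raise ValueError("no feature has nonzero counts in all samples; cannot compute size factors")
    geomean = np.exp(logc[finite].mean(axis=1))
    ratios = counts[finite] / geomean[:, None]
    factors = np.median(ratios, axis=0)
    # rescale to unit geometric mean: only factor *ratios* are identified, and
    # this normalization makes the scheme exactly idempotent (re-running on a
    # normalized matrix returns factors of 1)
    factors = factors / np.exp(np.log(factors).mean())
    return pd.Series(factors, index=table.columns, name="size_factor")


def normalize(matrix: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    factors = factors.reindex(matrix.counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("size factors must be present and > 0 for every sample")
    return matrix.counts / factors


def _ttest_log(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided pooled-variance t-test p-values per row of log-transformed data.

    Degenerate rows (zero variance in both groups) get p = 1 when the group
    means agree and p = 0 when they differ.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        same = np.isclose(a[bad].mean(axis=1), b[bad].mean(axis=1))
        p[bad] = np.where(same, 1.0, 0.0)
    return p


def de_test(matrix: CountMatrix, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-feature differential test, mutant vs control.

    Returns a DataFrame indexed by feature id with columns ``mean_control``,
    ``mean_mutant``, ``log2fc``, ``p_value`` (and ``q_value`` when
    ``fdr_mode='bh'``) and ``call`` in {up, down, unchanged}.  Requires >= 2
    replicates per condition.
    """
    config = config or AnalysisConfig()
    config.validate()
    ctrl_samples = matrix.samples_of("control")
    mut_samples = matrix.samples_of("mutant")
    if len(ctrl_samples) < 2 or len(mut_samples) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition, got {len(ctrl_samples)} control "
            f"and {len(mut_samples)} mutant"
        )
    norm = normalize(matrix, size_factors(matrix))
    ctrl = norm[ctrl_samples].to_numpy()
    mut = norm[mut_samples].to_numpy()
    mean_ctrl = ctrl.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    log2fc = np.log2((mean_mut + 0.5) / (mean_ctrl + 0.5))
    p = _ttest_log(np.log2(mut + 1.0), np.log2(ctrl + 1.0))
    out = pd.DataFrame(
        {
            "mean_control": mean_ctrl,
            "mean_mutant": mean_mut,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=matrix.counts.index,
    )
    p_eff = p
    if config.fdr_mode == "bh":
        out["q_value"] = stats.false_discovery_control(p, method="bh")
        p_eff = out["q_value"].to_numpy()
    sig = p_eff < config.de_alpha
    call = np.where(sig & (log2fc < 0), "down", np.where(sig & (log2fc > 0), "up", "unchanged"))
    out["call"] = call
    return out


def peak_signal_change(
    peak_counts: CountMatrix,
    assignment: dict[str, list[Peak]],
    config: AnalysisConfig | None = None,
) -> pd.Series:
    """Per-gene H3K4me3 direction from peak-level differential calls.

    Runs :func:`de_test` on the peak count matrix, maps each tested peak to
    its assigned gene, and calls a gene ``reduced`` if >= 1 of its peaks is
    down and none up, ``increased`` if >= 1 up and none down, else
    ``unchanged`` (genes with conflicting peaks are counted and logged).
    Peaks present in the counts but absent from the assignment are logged and
    skipped.
    """
    config = config or AnalysisConfig()
    de = de_test(peak_counts, config)
    peak_to_gene = {p.name: gid for gid, plist in assignment.items() for p in plist}
    calls_by_gene: dict[str, set[str]] = {gid: set() for gid in assignment}
    n_unmapped = 0
    for peak_name, row in de.iterrows():
        gid = peak_to_gene.get(peak_name)
        if gid is None:
            n_unmapped += 1
            continue
        calls_by_gene[gid].add(row["call"])
    if n_unmapped:
        logger.info("peak_signal_change: %d peaks in counts not in assignment; skipped", n_unmapped)
    direction = {}
    n_conflicts = 0
    for gid, calls in calls_by_gene.items():
        has_up, has_down = "up" in calls, "down" in calls
        if has_up and has_down:
            direction[gid] = "unchanged"
            n_conflicts += 1
        elif has_down:
            direction[gid] = "reduced"
        elif has_up:
            direction[gid] = "increased"
        else:
            direction[gid] = "unchanged"
    if n_conflicts:
        logger.info("peak_signal_change: %d genes with conflicting peak calls", n_conflicts)
    return pd.Series(direction, name="direction").rename_axis("gene_id").sort_index()
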