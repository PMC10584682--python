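"""Integration of the differential-expression and differential-H3K4me3 gene
sets (Venn counts, overlap percentage, breadth-group composition), plus two
small self-contained utilities: volcano-style metabolite classification and
qPCR delta-delta-Ct relative quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .breadth import GROUPS, AnalysisConfig

__all__ = ["IntegrationSummary", "overlap_summary", "volcano_classify", "delta_delta_ct"]


@dataclass
class IntegrationSummary:
    """Venn counts and composition of the "reduced H3K4me3 and reduced
    expression" overlap.

    ``pct_overlap_of_reduced_peaks`` is rounded to 1 decimal and the
    per-group composition percents to 2 decimals, matching the precision the
    quantities are conventionally reported at.
    """

    n_reduced_peaks: int
    n_reduced_expression: int
    n_overlap: int
    pct_overlap_of_reduced_peaks: float
    composition_counts: dict[str, int] = field(default_factory=dict)
    composition_pcts: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_summary(
    reduced_peak_genes: set[str],
    reduced_expr_genes: set[str],
    groups: pd.DataFrame,
) -> IntegrationSummary:
    """Intersect the two reduced gene sets and report counts, the overlap as a
    percentage of the reduced-H3K4me3 set, and the broad/medium/narrow
    composition of the overlap.

    Every overlap gene must appear in the classified breadth table; an empty
    reduced-H3K4me3 set makes the percentage undefined and raises.
    """
    reduced_peak_genes = set(reduced_peak_genes)
    reduced_expr_genes = set(reduced_expr_genes)
    if not reduced_peak_genes:
        raise ValueError("n_reduced_peaks = 0: overlap percentage undefined")
    overlap = reduced_peak_genes & reduced_expr_genes
    missing = overlap - set(groups.index)
    if missing:
        raise ValueError(f"overlap genes missing from breadth table: {sorted(missing)[:5]}")
    group_of = groups["group"].astype(str)
    counts = {g: 0 for g in GROUPS}
    for gid in overlap:
        counts[group_of[gid]] += 1
    n_overlap = len(overlap)
    pcts = {
        g: (round(100.0 * c / n_overlap, 2) if n_overlap else 0.0) for g, c in counts.items()
    }
    return IntegrationSummary(
        n_reduced_peaks=len(reduced_peak_genes),
        n_reduced_expression=len(reduced_expr_genes),
        n_overlap=n_overlap,
        pct_overlap_of_reduced_peaks=round(100.0 * n_overlap / len(reduced_peak_genes), 1),
        composition_counts=counts,
        composition_pcts=pcts,
    )


def volcano_classify(
    metabolites: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.Series:
    """Classify features from a (fold_change, p_value) table.

    ``increased`` iff fold_change > fc_up and p < alpha; ``decreased`` iff
    fold_change < fc_down and p < alpha; otherwise ``unchanged``.  The
    fold-change comparisons are strict, so a feature sitting exactly on a
    threshold is ``unchanged``.  Non-positive fold changes are rejected.
    """
    config = config or AnalysisConfig()
    config.validate()
    fc = metabolites["fold_change"].to_numpy(dtype=float)
    p = metabolites["p_value"].to_numpy(dtype=float)
    if (fc <= 0).any():
        raise ValueError("fold changes must be > 0")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must be in [0, 1]")
    sig = p < config.de_alpha
    label = np.where(
        sig & (fc > config.fc_up),
        "increased",
        np.where(sig & (fc < config.fc_down), "decreased", "unchanged"),
    )
    return pd.Series(label, index=metabolites.index, name="label")


def delta_delta_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    """qPCR relative quantification.

    Per sample, ``delta_ct = ct_reference - ct_target`` and relative
    expression ``2**delta_ct`` scaled so the control-group mean equals 1.
    Requires columns ``sample``, ``condition``, ``ct_target``,
    ``ct_reference`` and at least one control sample; missing Ct values are
    rejected.
    """
    required = {"sample", "condition", "ct_target", "ct_reference"}
    missing_cols = required - set(ct_table.columns)
    if missing_cols:
        raise ValueError(f"ct table missing columns: {sorted(missing_cols)}")
    if ct_table[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct value")
    out = ct_table.copy()
    out["delta_ct"] = out["ct_reference"] - out["ct_target"]
    expr = 2.0 ** out["delta_ct"]
    is_control = out["condition"] == "control"
    if not is_control.any():
        raise ValueError("need >= 1 control sample")
    out["relative_expression"] = expr / expr[is_control].mean()
    return out
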