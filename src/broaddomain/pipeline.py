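"""Pipeline orchestration: simulate -> breadth -> profile -> diff -> integrate.

A single config file (YAML or TOML) carries three sections — ``synthetic``
(the simulator), ``analysis`` (assignment/classification/DE/profile tunables)
and ``io``/``inputs`` — and one run writes every stage's outputs under
``outdir/{simulate,breadth,profile,diff,integrate}/`` plus a manifest with the
config hash, seed, tool version and a checksum for every file written.  When
``inputs`` supplies real files the simulate stage is skipped.  Stages
communicate through their serialized outputs, so a stage re-run from an
existing outdir equals the in-process run, and identical configs reproduce
byte-identical TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .breadth import (
    AnalysisConfig,
    assign_peaks_to_genes,
    classify_breadth,
    gene_breadth,
)
from .differential import de_test, peak_signal_change
from .formats import (
    CountMatrix,
    read_bedgraph,
    read_counts,
    read_gff3,
    read_peaks,
    write_bedgraph,
    write_condition_map,
    write_counts,
    write_gff3,
    write_peaks,
)
from .integration import overlap_summary
from .metaprofile import group_metaprofile, rpm_scale
from .synthetic import (
    SynthConfig,
    simulate_counts,
    simulate_coverage,
    simulate_genome,
    simulate_peak_counts,
    simulate_peaks,
)

logger = logging.getLogger("broaddomain")

STAGES = ("simulate", "breadth", "profile", "diff", "integrate")

__all__ = ["RunManifest", "load_config", "run_pipeline", "STAGES"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict[str, str]] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix in (".toml", ".tml"):
        import tomllib

        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _parse_config(cfg: dict) -> tuple[SynthConfig, AnalysisConfig, dict, dict]:
    synth = SynthConfig.from_dict(cfg.get("synthetic", {}))
    analysis = AnalysisConfig(**cfg.get("analysis", {}))
    synth.validate()
    analysis.validate()
    return synth, analysis, cfg.get("io", {}), cfg.get("inputs", {})


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


class _Run:
    """Mutable state for one pipeline run; stages populate in-memory objects
    and serialize them, or lazily re-load them from a previous stage's files."""

    def __init__(self, synth: SynthConfig, analysis: AnalysisConfig, outdir: Path, inputs: dict):
        self.synth = synth
        self.analysis = analysis
        self.outdir = outdir
        self.inputs = inputs
        self.files: dict[str, dict[str, str]] = {}
        self._cache: dict[str, object] = {}

    def path(self, stage: str, name: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d / name

    def record(self, stage: str, path: Path) -> None:
        self.files.setdefault(stage, {})[path.name] = _sha256(path)

    # --- lazy intermediate loading -------------------------------------
    def genes(self):
        if "genes" not in self._cache:
            src = self.inputs.get("gff3") or self.path("simulate", "genes.gff3")
            self._cache["genes"] = read_gff3(src)
        return self._cache["genes"]

    def peaks(self, condition: str):
        key = f"peaks_{condition}"
        if key not in self._cache:
            src = self.inputs.get(key) or self.path("simulate", f"{key}.bed")
            self._cache[key] = read_peaks(src, self.inputs.get("peaks_dialect", "bed6"))
        return self._cache[key]

    def coverage(self, condition: str):
        key = f"coverage_{condition}"
        if key not in self._cache:
            if key in self.inputs:
                src, reads = self.inputs[key], int(self.inputs[f"{key}_reads"])
            else:
                src = self.path("simulate", f"{key}.bedgraph")
                sidecar = json.loads(self.path("simulate", "coverage_reads.json").read_text())
                reads = int(sidecar[condition])
            self._cache[key] = read_bedgraph(src, reads)
        return self._cache[key]

    def counts(self, kind: str) -> CountMatrix:
        key = f"{kind}_counts"
        if key not in self._cache:
            src = self.inputs.get(key) or self.path("simulate", f"{key}.tsv")
            cmap = self.inputs.get(f"{kind}_condition_map") or self.path(
                "simulate", "condition_map.tsv"
            )
            self._cache[key] = read_counts(src, cmap)
        return self._cache[key]

    def assignment(self):
        if "assignment" not in self._cache:
            self._cache["assignment"] = assign_peaks_to_genes(
                self.peaks("control"), self.genes(), self.analysis
            )
        return self._cache["assignment"]

    def breadth_table(self) -> pd.DataFrame:
        if "breadth_table" not in self._cache:
            p = self.path("breadth", "breadth.tsv")
            if not p.exists():
                raise FileNotFoundError("breadth stage output missing; run the breadth stage first")
            self._cache["breadth_table"] = pd.read_csv(p, sep="\t", index_col=0)
        return self._cache["breadth_table"]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_simulate(run: _Run) -> None:
    cfg = run.synth
    genes = simulate_genome(cfg)
    write_gff3(genes, run.path("simulate", "genes.gff3"))
    ctrl_peaks, mut_peaks, truth = simulate_peaks(genes, cfg)
    write_peaks(ctrl_peaks, run.path("simulate", "peaks_control.bed"))
    write_peaks(mut_peaks, run.path("simulate", "peaks_mutant.bed"))
    _write_tsv(truth, run.path("simulate", "truth.tsv"))
    reads = {}
    for cond, pk in (("control", ctrl_peaks), ("mutant", mut_peaks)):
        track = simulate_coverage(pk, cfg)
        write_bedgraph(track, run.path("simulate", f"coverage_{cond}.bedgraph"))
        reads[cond] = track.total_mapped_reads
        run._cache[f"coverage_{cond}"] = track
    run.path("simulate", "coverage_reads.json").write_text(json.dumps(reads, sort_keys=True))
    gene_counts = simulate_counts(truth, cfg)
    write_counts(gene_counts, run.path("simulate", "gene_counts.tsv"), "gene_id")
    peak_counts = simulate_peak_counts(truth, ctrl_peaks, cfg)
    write_counts(peak_counts, run.path("simulate", "peak_counts.tsv"), "peak")
    write_condition_map(gene_counts.sample_condition, run.path("simulate", "condition_map.tsv"))
    run._cache.update(
        genes=genes, peaks_control=ctrl_peaks, peaks_mutant=mut_peaks,
        gene_counts=gene_counts, peak_counts=peak_counts,
    )
    for name in (
        "genes.gff3", "peaks_control.bed", "peaks_mutant.bed", "truth.tsv",
        "coverage_control.bedgraph", "coverage_mutant.bedgraph", "coverage_reads.json",
        "gene_counts.tsv", "peak_counts.tsv", "condition_map.tsv",
    ):
        run.record("simulate", run.outdir / "simulate" / name)


def _stage_breadth(run: _Run) -> None:
    table = gene_breadth(run.assignment())
    n_zero = int((table["breadth"] == 0).sum())
    if n_zero:
        logger.info("breadth: %d genes without assigned peaks", n_zero)
    classified = classify_breadth(table, run.analysis)
    p = run.path("breadth", "breadth.tsv")
    _write_tsv(classified, p)
    run._cache["breadth_table"] = classified
    run.record("breadth", p)


def _stage_profile(run: _Run) -> None:
    groups = run.breadth_table()
    genes = [g for g in run.genes() if g.gene_id in groups.index]
    for cond in ("control", "mutant"):
        track = rpm_scale(run.coverage(cond))
        profile = group_metaprofile(genes, groups, track, run.analysis)
        p = run.path("profile", f"metaprofile_{cond}.tsv")
        profile.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6g")
        run.record("profile", p)


def _stage_diff(run: _Run) -> None:
    de_genes = de_test(run.counts("gene"), run.analysis)
    p = run.path("diff", "de_genes.tsv")
    _write_tsv(de_genes, p)
    run.record("diff", p)
    direction = peak_signal_change(run.counts("peak"), run.assignment(), run.analysis)
    p2 = run.path("diff", "peak_direction.tsv")
    direction.to_frame().to_csv(p2, sep="\t")
    run.record("diff", p2)
    run._cache["de_genes"] = de_genes
    run._cache["peak_direction"] = direction


def _stage_integrate(run: _Run) -> None:
    de_genes = run._cache.get("de_genes")
    if de_genes is None:
        de_genes = pd.read_csv(run.path("diff", "de_genes.tsv"), sep="\t", index_col=0)
    direction = run._cache.get("peak_direction")
    if direction is None:
        direction = pd.read_csv(run.path("diff", "peak_direction.tsv"), sep="\t", index_col=0)[
            "direction"
        ]
    reduced_expr = set(de_genes.index[de_genes["call"] == "down"])
    reduced_peaks = set(direction.index[direction == "reduced"])
    groups = run.breadth_table()
    try:
        summary = overlap_summary(reduced_peaks, reduced_expr, groups).to_dict()
    except ValueError:
        logger.info("integrate: no reduced-H3K4me3 genes; overlap percentage undefined")
        summary = {
            "n_reduced_peaks": 0,
            "n_reduced_expression": len(reduced_expr),
            "n_overlap": 0,
            "pct_overlap_of_reduced_peaks": None,
            "composition_counts": None,
            "composition_pcts": None,
        }
    p = run.path("integrate", "integration.json")
    p.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    run.record("integrate", p)
    overlap_genes = sorted(reduced_peaks & reduced_expr)
    tab = groups.loc[[g for g in overlap_genes if g in groups.index], ["breadth", "group"]]
    p2 = run.path("integrate", "overlap_genes.tsv")
    _write_tsv(tab, p2)
    run.record("integrate", p2)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "breadth": _stage_breadth,
    "profile": _stage_profile,
    "diff": _stage_diff,
    "integrate": _stage_integrate,
}


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_pipeline(
    config: str | Path | dict,
    outdir: str | Path | None = None,
    seed: int | None = None,
    stages: list[str] | None = None,
) -> RunManifest:
    """Execute the pipeline (or a subset of stages) from a config.

    ``config`` is a YAML/TOML path or an equivalent dict; ``outdir`` and
    ``seed`` override the config.  When the config has an ``inputs`` section
    the simulate stage is skipped and real files are used.  Any stage error
    aborts with the stage name attached.  Returns the manifest (also written
    to ``outdir/manifest.json``).
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    synth, analysis, io_cfg, inputs = _parse_config(cfg)
    if seed is not None:
        synth.seed = int(seed)
    out = Path(outdir or io_cfg.get("outdir") or "broaddomain_run")
    out.mkdir(parents=True, exist_ok=True)

    todo = list(stages) if stages is not None else list(STAGES)
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if inputs and "simulate" in todo:
        logger.info("run_pipeline: real inputs supplied; skipping simulate stage")
        todo = [s for s in todo if s != "simulate"]

    run = _Run(synth, analysis, out, inputs)
    for stage in STAGES:
        if stage not in todo:
            continue
        logger.info("stage %s: start", stage)
        try:
            _STAGE_FN[stage](run)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s: done", stage)

    canonical = {
        "synthetic": synth.to_dict(),
        "analysis": dataclasses.asdict(analysis),
        "inputs": {k: str(v) for k, v in inputs.items()},
    }
    config_hash = hashlib.sha256(
        json.dumps(canonical, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        seed=synth.seed,
        version=__version__,
        stages=run.files,
        inputs={k: _sha256(Path(v)) for k, v in inputs.items() if Path(str(v)).is_file()},
    )
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    return manifest
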