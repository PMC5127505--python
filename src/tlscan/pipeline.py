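"""Configuration, orchestration and provenance for the five pipeline stages.

``run_pipeline`` executes simulate -> call -> score -> qc -> cluster, each
stage reading its inputs from and writing its outputs to the configured
output directory, and records a manifest (parameters hash, per-stage seeds,
output checksums, read/variant tallies).  Stages can be re-run individually
against untouched upstream outputs.

A single global seed deterministically derives per-stage seeds by hashing
the stage name, so any stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landscape, qc, quant, readproc, synthetic_data
from .quant import FilterConfig
from .readproc import AlleleCountTable, ScoringScheme
from .synthetic_data import WT_ID, AmpliconReference, ExpectedVariantSet, SpikeIn

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "SimulateParams",
    "CallParams",
    "ScoreParams",
    "ClusterParams",
    "validate_config",
    "run_pipeline",
    "stage_seed",
    "write_reference_fasta",
    "read_reference_fasta",
    "write_whitelist",
    "read_whitelist",
    "write_counts",
    "read_counts",
]

STAGES = ("simulate", "call", "score", "qc", "cluster")


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message lists every problem."""


@dataclass
class SimulateParams:
    n_variants: int = 412
    depth: int = 100_000
    n_replicates: int = 3
    wt_fraction: float = 0.10
    spike_fraction: float = 0.005
    error_rate: float = 0.001
    template_switch_rate: float = 0.01
    pcr_mode: str = "emulsion"
    empcr_suppression: float = 2.5
    noise_sd: float = 0.3
    reads_format: str = "collapsed"  # or "fastq"


@dataclass
class CallParams:
    scheme: tuple[int, int, int] = (1, -1, -2)
    band: int = 9
    flank_len: int = 15


@dataclass
class ScoreParams:
    min_pool_reads: int = 200
    min_condition_reads: int = 50
    pool_condition: str = "SC-Leu"
    require_both_below: bool = True
    log_base: float = 2.0
    pseudocount: float = 0.5


@dataclass
class ClusterParams:
    linkage: str = "average"
    k_min: int = 2
    k_max: int = 8


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "tlscan_out"
    simulate: SimulateParams = field(default_factory=SimulateParams)
    call: CallParams = field(default_factory=CallParams)
    score: ScoreParams = field(default_factory=ScoreParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["call"]["scheme"] = list(d["call"]["scheme"])
        return d


_BLOCKS = {
    "simulate": SimulateParams,
    "call": CallParams,
    "score": ScoreParams,
    "cluster": ClusterParams,
}


def _check_params(block: str, obj, errors: list[str]) -> None:
    def bad(key, msg):
        errors.append(f"{block}.{key}: {msg}")

    for f in fields(obj):
        v = getattr(obj, f.name)
        if f.name in ("depth", "n_replicates", "n_variants") and v is not None and v <= 0:
            bad(f.name, f"must be positive (got {v})")
        if f.name in ("wt_fraction",) and not 0 < v < 1:
            bad(f.name, f"must lie in (0, 1) (got {v})")
        if f.name in ("error_rate", "template_switch_rate", "spike_fraction") and not 0 <= v <= 1:
            bad(f.name, f"must lie in [0, 1] (got {v})")
        if f.name == "pcr_mode" and v not in ("regular", "emulsion"):
            bad(f.name, f"must be 'regular' or 'emulsion' (got {v!r})")
        if f.name == "reads_format" and v not in ("collapsed", "fastq"):
            bad(f.name, f"must be 'collapsed' or 'fastq' (got {v!r})")
        if f.name in ("min_pool_reads", "min_condition_reads") and v < 0:
            bad(f.name, f"must be >= 0 (got {v})")
        if f.name == "log_base" and v <= 1:
            bad(f.name, f"must exceed 1 (got {v})")
        if f.name == "linkage" and v not in ("average", "complete", "single"):
            bad(f.name, f"unsupported linkage (got {v!r})")
        if f.name in ("band", "flank_len") and v <= 0:
            bad(f.name, f"must be positive (got {v})")
    if block == "call":
        m, mm, ind = obj.scheme
        if m <= 0 or mm >= 0 or ind >= 0:
            bad("scheme", "needs match > 0 and mismatch, indel < 0")
    if block == "cluster" and obj.k_min >= obj.k_max:
        bad("k_min", "must be below k_max")


def _config_from_dict(data: dict) -> tuple[PipelineConfig, list[str]]:
    errors: list[str] = []
    cfg = PipelineConfig()
    known_top = {"seed", "outdir"} | set(_BLOCKS)
    for key in data:
        if key not in known_top:
            errors.append(f"unknown key {key!r}")
    if "seed" in data:
        if not isinstance(data["seed"], int):
            errors.append(f"seed: must be an integer (got {data['seed']!r})")
        else:
            cfg.seed = data["seed"]
    if "outdir" in data:
        cfg.outdir = str(data["outdir"])
    for block, cls in _BLOCKS.items():
        sub = data.get(block, {}) or {}
        if not isinstance(sub, dict):
            errors.append(f"{block}: must be a mapping")
            continue
        valid = {f.name for f in fields(cls)}
        for key in sub:
            if key not in valid:
                errors.append(f"unknown key {block}.{key!r}")
        kwargs = {k: v for k, v in sub.items() if k in valid}
        if "scheme" in kwargs:
            kwargs["scheme"] = tuple(kwargs["scheme"])
        try:
            setattr(cfg, block, cls(**kwargs))
        except (TypeError, ValueError) as exc:
            errors.append(f"{block}: {exc}")
    for block in _BLOCKS:
        _check_params(block, getattr(cfg, block), errors)
    return cfg, errors


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline config, filling defaults.

    All problems are collected and reported together in the raised
    :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    cfg, errors = _config_from_dict(data)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage-name hashing."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# --------------------------------------------------------------------------
# File formats
# --------------------------------------------------------------------------


def write_reference_fasta(ref: AmpliconReference, path) -> None:
    header = (
        f">amplicon coding_start={len(ref.upstream_flank)} "
        f"coding_length={len(ref.coding_sequence)} "
        f"first_residue={ref.first_residue_number}"
    )
    Path(path).write_text(f"{header}\n{ref.amplicon}\n")


def read_reference_fasta(path) -> AmpliconReference:
    lines = Path(path).read_text().splitlines()
    header, seq = lines[0], "".join(lines[1:])
    meta = dict(
        kv.split("=") for kv in header.split() if "=" in kv
    )
    start = int(meta["coding_start"])
    length = int(meta["coding_length"])
    return AmpliconReference(
        coding_sequence=seq[start : start + length],
        upstream_flank=seq[:start],
        downstream_flank=seq[start + length :],
        first_residue_number=int(meta["first_residue"]),
    )


def write_whitelist(evs: ExpectedVariantSet, path) -> None:
    rows = []
    for ci, codon in sorted(evs.programmed):
        rows.append(
            {"codon_index": ci, "mutant_codon": codon,
             "variant_id": evs.variant_id(ci, codon),
             "spike_in": False, "fraction": ""}
        )
    for s in evs.spike_ins:
        rows.append(
            {"codon_index": s.codon_index, "mutant_codon": s.codon,
             "variant_id": evs.variant_id(s.codon_index, s.codon),
             "spike_in": True, "fraction": s.fraction}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_whitelist(path, ref: AmpliconReference) -> ExpectedVariantSet:
    df = pd.read_csv(path, sep="\t")
    programmed = frozenset(
        (int(r.codon_index), str(r.mutant_codon))
        for r in df[~df.spike_in].itertuples()
    )
    spikes = tuple(
        SpikeIn(int(r.codon_index), str(r.mutant_codon), float(r.fraction))
        for r in df[df.spike_in].itertuples()
    )
    return ExpectedVariantSet(reference=ref, programmed=programmed, spike_ins=spikes)


def write_counts(table: AlleleCountTable, counts_path, rejects_path) -> None:
    long = (
        table.counts.rename_axis("variant_id")
        .reset_index()
        .melt(id_vars="variant_id", var_name="sample", value_name="count")
    )
    meta = table.samples[["condition", "replicate", "role"]]
    long = long.join(meta, on="sample")
    long[["variant_id", "condition", "replicate", "role", "count"]].to_csv(
        counts_path, sep="\t", index=False
    )
    rej = (
        table.rejected.rename_axis("reason")
        .reset_index()
        .melt(id_vars="reason", var_name="sample", value_name="count")
        .join(meta, on="sample")
    )
    rej[["reason", "condition", "replicate", "role", "count"]].to_csv(
        rejects_path, sep="\t", index=False
    )


def read_counts(counts_path, rejects_path=None) -> AlleleCountTable:
    long = pd.read_csv(counts_path, sep="\t")
    long["sample"] = (
        long["condition"].astype(str) + "_rep" + long["replicate"].astype(str)
    )
    counts = (
        long.pivot_table(index="variant_id", columns="sample", values="count",
                         aggfunc="sum", fill_value=0)
        .astype(int)
    )
    counts.columns.name = None
    sheet = (
        long[["sample", "condition", "replicate", "role"]]
        .drop_duplicates()
        .set_index("sample", drop=False)
    )
    if rejects_path is not None and Path(rejects_path).exists():
        rej_long = pd.read_csv(rejects_path, sep="\t")
        rej_long["sample"] = (
            rej_long["condition"].astype(str) + "_rep"
            + rej_long["replicate"].astype(str)
        )
        rejected = (
            rej_long.pivot_table(index="reason", columns="sample",
                                 values="count", aggfunc="sum", fill_value=0)
            .astype(int)
        )
        rejected.columns.name = None
    else:
        rejected = pd.DataFrame(index=pd.Index([], name="reason"),
                                columns=counts.columns).fillna(0)
    return AlleleCountTable(counts=counts.sort_index(), rejected=rejected,
                            samples=sheet)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    p = cfg.simulate
    sim = synthetic_data.simulate_screen(
        n_variants=p.n_variants,
        depth=p.depth,
        n_replicates=p.n_replicates,
        wt_fraction=p.wt_fraction,
        spike_fraction=p.spike_fraction,
        error_rate=p.error_rate,
        template_switch_rate=p.template_switch_rate,
        pcr_mode=p.pcr_mode,
        empcr_suppression=p.empcr_suppression,
        profile=synthetic_data.ClassProfileConfig(noise_sd=p.noise_sd),
        pool_condition=cfg.score.pool_condition,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    write_reference_fasta(sim.reference, outdir / "reference.fasta")
    write_whitelist(sim.variant_set, outdir / "whitelist.tsv")
    sim.true_effects.rename_axis("variant_id").to_csv(
        outdir / "truth_effects.tsv", sep="\t"
    )
    sim.true_labels.rename_axis("variant_id").to_csv(
        outdir / "truth_labels.tsv", sep="\t"
    )
    sheet = sim.sample_sheet.copy()
    n_reads = 0
    if p.reads_format == "fastq":
        reads_dir = outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        f1s, f2s = [], []
        for sample in sheet.index:
            f1 = reads_dir / f"{sample}_R1.fastq"
            f2 = reads_dir / f"{sample}_R2.fastq"
            n_reads += synthetic_data.write_fastq(sim.readsets[sample], f1, f2,
                                                  prefix=sample)
            f1s.append(str(f1.relative_to(outdir)))
            f2s.append(str(f2.relative_to(outdir)))
        sheet["fastq1"], sheet["fastq2"] = f1s, f2s
    else:
        rows = []
        for sample in sheet.index:
            for seq, count in sorted(sim.readsets[sample].items()):
                rows.append((sample, seq, synthetic_data.reverse_complement(seq),
                             count))
                n_reads += count
        pd.DataFrame(rows, columns=["sample", "read1", "read2", "count"]).to_csv(
            outdir / "reads_collapsed.tsv", sep="\t", index=False
        )
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    outputs = ["reference.fasta", "whitelist.tsv", "truth_effects.tsv",
               "truth_labels.tsv", "sample_sheet.tsv"]
    if p.reads_format == "collapsed":
        outputs.append("reads_collapsed.tsv")
    return {"outputs": outputs, "tallies": {"reads": int(n_reads),
                                            "samples": int(len(sheet))}}


def _stage_call(cfg: PipelineConfig, outdir: Path) -> dict:
    ref = read_reference_fasta(outdir / "reference.fasta")
    evs = read_whitelist(outdir / "whitelist.tsv", ref)
    sheet = pd.read_csv(outdir / "sample_sheet.tsv", sep="\t").set_index(
        "sample", drop=False
    )
    scheme = ScoringScheme(*cfg.call.scheme)
    cache = readproc._CoreCallCache(ref, evs, scheme, cfg.call.band)
    per_sample: dict[str, tuple[Counter, Counter]] = {}
    collapsed = outdir / "reads_collapsed.tsv"
    if collapsed.exists():
        reads = pd.read_csv(collapsed, sep="\t")
        for sample, grp in reads.groupby("sample", sort=True):
            pairs = (
                (f"{sample}:{i}", r.read1, r.read2, int(r.count))
                for i, r in enumerate(grp.itertuples())
            )
            per_sample[str(sample)] = readproc._tally(
                pairs, ref, evs, scheme, cfg.call.band,
                cfg.call.flank_len, 10, cache,
            )
    else:
        for sample in sheet.index:
            per_sample[str(sample)] = readproc.call_fastq_pair(
                outdir / sheet.loc[sample, "fastq1"],
                outdir / sheet.loc[sample, "fastq2"],
                ref, evs, scheme, cfg.call.band, cfg.call.flank_len,
                cache=cache,
            )
    table = readproc.count_alleles(per_sample, sheet)
    write_counts(table, outdir / "counts.tsv", outdir / "rejects.tsv")
    return {
        "outputs": ["counts.tsv", "rejects.tsv"],
        "tallies": {
            "accepted_reads": int(table.counts.to_numpy().sum()),
            "rejected_reads": int(table.rejected.to_numpy().sum()),
            "variants": int((table.counts.index != WT_ID).sum()),
        },
    }


def _stage_score(cfg: PipelineConfig, outdir: Path) -> dict:
    table = read_counts(outdir / "counts.tsv", outdir / "rejects.tsv")
    p = cfg.score
    fc = FilterConfig(
        min_pool_reads=p.min_pool_reads,
        min_condition_reads=p.min_condition_reads,
        pool_condition=p.pool_condition,
        require_both_below=p.require_both_below,
    )
    matrix = quant.score_screen(table, fc, p.pseudocount, p.log_base)
    matrix.scores.rename_axis("variant_id").to_csv(
        outdir / "scores.tsv", sep="\t", na_rep="NA"
    )
    matrix.mask.rename_axis("variant_id").to_csv(
        outdir / "score_mask.tsv", sep="\t"
    )
    return {
        "outputs": ["scores.tsv", "score_mask.tsv"],
        "tallies": {
            "scored_variants": int(len(matrix.scores)),
            "measured_cells": int((matrix.mask == "measured").to_numpy().sum()),
        },
    }


def _stage_qc(cfg: PipelineConfig, outdir: Path) -> dict:
    table = read_counts(outdir / "counts.tsv", outdir / "rejects.tsv")
    ref = read_reference_fasta(outdir / "reference.fasta")
    evs = read_whitelist(outdir / "whitelist.tsv", ref)
    freq = quant.frequencies(table)
    pool = cfg.score.pool_condition
    pool_samples = [
        s for s in table.samples.index
        if table.samples.loc[s, "condition"] == pool
    ]
    reports = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in pool_samples:
            reports[s] = qc.template_switch_ratio(freq, evs.spike_ids, s)
    corr = qc.replicate_correlation(freq, pool_samples)
    summary = {
        "mean_switch_ratio": {
            s: (None if np.isnan(r.mean_ratio) else r.mean_ratio)
            for s, r in reports.items()
        },
        "replicate_pearson_r": corr.round(6).to_dict(),
    }
    (outdir / "qc_summary.json").write_text(json.dumps(summary, indent=2))
    pd.concat(
        [r.per_pair.assign(sample=s) for s, r in reports.items()],
        ignore_index=True,
    ).to_csv(outdir / "qc_template_switch.tsv", sep="\t", index=False)
    return {"outputs": ["qc_summary.json", "qc_template_switch.tsv"],
            "tallies": {"pool_samples": len(pool_samples)}}


def _stage_cluster(cfg: PipelineConfig, outdir: Path) -> dict:
    scores = pd.read_csv(outdir / "scores.tsv", sep="\t", index_col="variant_id",
                         na_values="NA")
    singles = scores.loc[[v for v in scores.index
                          if v != WT_ID and "," not in v]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = landscape.hier_cluster(singles, linkage=cfg.cluster.linkage)
        assignment = landscape.assign_classes(
            result, k_range=range(cfg.cluster.k_min, cfg.cluster.k_max + 1)
        )
    assignment.labels.rename_axis("variant_id").to_csv(
        outdir / "classes.tsv", sep="\t"
    )
    (outdir / "dendrogram.nwk").write_text(
        landscape.dendrogram_to_newick(result.linkage_matrix, result.ids)
    )
    singles.loc[result.ids].rename_axis("variant_id").to_csv(
        outdir / "clustered_scores.tsv", sep="\t", na_rep="NA"
    )
    return {
        "outputs": ["classes.tsv", "dendrogram.nwk", "clustered_scores.tsv"],
        "tallies": {"clustered_variants": len(result.ids),
                    "k": assignment.k},
    }


def analyze_simulation(
    sim: synthetic_data.ScreenSimulation,
    call_params: CallParams | None = None,
    score_params: ScoreParams | None = None,
    cluster_params: ClusterParams | None = None,
    cluster: bool = True,
):
    """In-memory end-to-end analysis of a simulated screen.

    Runs call -> count -> score (-> cluster) on ``sim.readsets`` and
    returns ``(table, matrix, assignment)``; ``assignment`` is None when
    ``cluster`` is False.  This is the same path the file-based pipeline
    takes, without the serialisation round-trip.
    """
    cp = call_params or CallParams()
    sp = score_params or ScoreParams()
    kp = cluster_params or ClusterParams()
    if sim.readsets is None:
        raise ValueError("simulation was run with make_reads=False")
    scheme = ScoringScheme(*cp.scheme)
    cache = readproc._CoreCallCache(sim.reference, sim.variant_set, scheme, cp.band)
    per_sample = {
        sample: readproc.call_readset(
            sim.readsets[sample], sim.reference, sim.variant_set,
            scheme, cp.band, cp.flank_len, cache=cache,
        )
        for sample in sim.sample_sheet.index
    }
    table = readproc.count_alleles(per_sample, sim.sample_sheet)
    fc = FilterConfig(sp.min_pool_reads, sp.min_condition_reads,
                      sp.pool_condition, sp.require_both_below)
    matrix = quant.score_screen(table, fc, sp.pseudocount, sp.log_base)
    assignment = None
    if cluster:
        singles = matrix.scores.loc[
            [v for v in matrix.scores.index if v != WT_ID and "," not in v]
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = landscape.hier_cluster(singles, linkage=kp.linkage)
            assignment = landscape.assign_classes(
                result, k_range=range(kp.k_min, kp.k_max + 1)
            )
    return table, matrix, assignment


_STAGE_FN = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "score": _stage_score,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
}


def run_pipeline(cfg: PipelineConfig, stages=None) -> dict:
    """Run the requested stages in order and write ``manifest.json``.

    A stage failure aborts the run with the failing stage named; the
    manifest records, per completed stage, its derived seed, outputs with
    sha256 checksums, and tallies.
    """
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        try:
            old = json.loads(manifest_path.read_text())
            if old.get("config_sha256") == manifest["config_sha256"]:
                manifest["stages"] = old.get("stages", {})
        except json.JSONDecodeError:
            pass
    for stage in stages:
        try:
            info = _STAGE_FN[stage](cfg, outdir)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest_path.write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        info["status"] = "ok"
        info["seed"] = stage_seed(cfg.seed, stage)
        info["checksums"] = {
            out: _sha256(outdir / out) for out in info["outputs"]
        }
        manifest["stages"][stage] = info
        manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
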