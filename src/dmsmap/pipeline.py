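"""End-to-end orchestration: simulate a dataset to disk, analyze a dataset
from disk, with a YAML run configuration and a plain-text run log.

Randomness lives only in simulation; analysis of identical inputs is fully
deterministic. Replicates are analyzed independently; region metrics are
reported per replicate and summarized as the across-replicate mean per
condition.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import metrics as dmetrics
from . import sd as dsd
from .folding import FoldConfig, guided_fold, pairs_to_arcs
from .reactivity import ReactivityParams, exclusion_counts, reactivity_pipeline
from .simulate import (SimulationConfig, assign_true_rates, derive_seeds,
                       release_footprint, simulate_counts)


@dataclass
class RunConfig:
    """Validated run configuration (see docs/methods.md for the YAML shape)."""

    fasta: str = ""
    annotation: str = ""
    masks: str = ""
    structure_ct: str = ""
    accessibility: str = ""
    counts: dict = field(default_factory=dict)  # condition -> [tsv, ...]
    params: ReactivityParams = field(default_factory=ReactivityParams)
    gini_form: str = "population"
    temperature_K: float = dsd.DEFAULT_TEMPERATURE_K
    fold: FoldConfig = field(default_factory=FoldConfig)
    simulation: SimulationConfig | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "params" in kwargs:
            kwargs["params"] = ReactivityParams(**kwargs["params"])
        if "fold" in kwargs:
            kwargs["fold"] = FoldConfig(**kwargs["fold"])
        if "simulation" in kwargs and kwargs["simulation"] is not None:
            kwargs["simulation"] = SimulationConfig(**kwargs["simulation"])
        cfg = cls(**kwargs)
        base = Path(path).parent
        for attr in ("fasta", "annotation", "masks", "structure_ct", "accessibility"):
            p = getattr(cfg, attr)
            if p:
                p = str(base / p) if not Path(p).is_absolute() else p
                if not Path(p).exists():
                    raise FileNotFoundError(f"{attr}: {p}")
                setattr(cfg, attr, p)
        cfg.counts = {
            cond: [str(base / f) if not Path(f).is_absolute() else f for f in files]
            for cond, files in cfg.counts.items()
        }
        for files in cfg.counts.values():
            for f in files:
                if not Path(f).exists():
                    raise FileNotFoundError(f"counts file {f}")
        return cfg


def run_simulate(transcript, structure, annotation, config: SimulationConfig,
                 outdir, *, conditions=("in_vivo", "in_vitro"),
                 footprint_range=None, n_replicates: int = 2,
                 primer_ranges=(), editing_sites=(), overwrite: bool = False) -> dict:
    """Write a complete synthetic dataset (FASTA, CT, accessibility, masks,
    annotation, per-condition/replicate counts, manifest with all seeds)."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} is not empty (pass overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    if transcript.length == 0:
        raise ValueError("zero-length transcript")

    dio.write_fasta([transcript], outdir / "transcripts.fasta")
    dio.write_ct(structure, transcript.sequence, outdir / f"{transcript.id}.ct")
    dio.write_accessibility(structure.solvent_accessible, outdir / "accessibility.tsv")
    masks = dio.MaskSet(primer_ranges=list(primer_ranges),
                        editing_sites=list(editing_sites))
    dio.write_masks({transcript.id: masks}, outdir / "masks.tsv")
    dio.write_annotation([annotation], outdir / "annotation.tsv")

    structures = {"in_vitro": structure}
    structures["in_vivo"] = (
        release_footprint(structure, footprint_range) if footprint_range
        else structure
    )
    seeds = derive_seeds(config.seed, len(conditions) * n_replicates)
    manifest = {"seed": config.seed, "config": asdict(config), "counts": {},
                "footprint_range": list(footprint_range) if footprint_range else None}
    k = 0
    for cond in conditions:
        track = assign_true_rates(transcript, structures.get(cond, structure),
                                  config, tuple(editing_sites))
        manifest["counts"][cond] = []
        for rep in range(1, n_replicates + 1):
            counts = simulate_counts(track, config, seeds[k],
                                     tuple(primer_ranges))
            k += 1
            fname = f"counts_{cond}_rep{rep}.tsv"
            dio.write_counts_table(counts, outdir / fname)
            manifest["counts"][cond].append({"file": fname, "seed": seeds[k - 1]})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest


def run_analyze(config: RunConfig, outdir) -> dict:
    """Analyze a dataset per the run configuration; returns a result bundle
    and writes reactivity/region/ROC/SD/constraint/arc tables plus run.log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"parameters: {asdict(config.params)}",
                      f"gini_form: {config.gini_form}",
                      f"temperature_K: {config.temperature_K}"]

    transcripts = {t.id: t for t in dio.read_fasta(config.fasta)}
    annotations = dio.read_annotation(config.annotation) if config.annotation else []
    masks = dio.read_masks(config.masks) if config.masks else {}
    structure = None
    if config.structure_ct:
        structure = dio.read_structure(config.structure_ct, "ct")
        if config.accessibility:
            n = structure.length
            structure.solvent_accessible = dio.read_accessibility(
                config.accessibility, n)

    profiles: dict[str, dict[str, pd.DataFrame]] = {}
    for cond, files in config.counts.items():
        profiles[cond] = {}
        for fpath in files:
            counts = dio.read_counts_table(fpath)
            profile = reactivity_pipeline(counts, masks, config.params)
            rep = Path(fpath).stem
            profiles[cond][rep] = profile
            dio.write_reactivity(profile, outdir / f"reactivity_{cond}_{rep}.tsv")
            excl = exclusion_counts(profile)
            log.append(f"{cond}/{rep} exclusions: {excl} (total {sum(excl.values())})")
            for t in transcripts.values():
                sub = profile[profile["transcript_id"] == t.id]
                if sub.empty or sub["normalized"].isna().all():
                    continue
                dio.write_constraints(
                    profile, t, outdir / f"constraints_{cond}_{rep}_{t.id}.txt")

    results: dict = {"profiles": profiles, "log": log}

    # region metrics per condition pair (first two conditions compared)
    region_tables = []
    conds = list(profiles)
    if annotations and len(conds) >= 2:
        a_cond, b_cond = conds[0], conds[1]
        for rep_a, prof_a in profiles[a_cond].items():
            for rep_b, prof_b in profiles[b_cond].items():
                for ann in annotations:
                    t = transcripts[ann.transcript_id]
                    regions = dmetrics.resolve_regions(ann, t)
                    table = dmetrics.compare_conditions(
                        prof_a, prof_b, regions, config.gini_form, t.id)
                    table.insert(0, "rep_pair", f"{rep_a}|{rep_b}")
                    region_tables.append(table)
        if region_tables:
            region_table = pd.concat(region_tables, ignore_index=True)
            region_table.to_csv(outdir / "region_metrics.tsv", sep="\t", index=False)
            summary = (
                region_table.groupby(["gene", "region"], sort=True)
                [["mean_vivo", "mean_vitro", "gini_vivo", "gini_vitro"]]
                .mean().reset_index()
            )
            summary.to_csv(outdir / "region_metrics_summary.tsv", sep="\t",
                           index=False)
            results["region_metrics"] = region_table
            results["region_summary"] = summary

    # replicate correlation per condition
    corr_rows = []
    for cond, reps in profiles.items():
        names = list(reps)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                merged = reps[names[a]].merge(
                    reps[names[b]], on=["transcript_id", "pos"],
                    suffixes=("_a", "_b"))
                ok = merged["normalized_a"].notna() & merged["normalized_b"].notna()
                if ok.sum() >= 3:
                    r = float(np.corrcoef(merged.loc[ok, "normalized_a"],
                                          merged.loc[ok, "normalized_b"])[0, 1])
                    corr_rows.append({"condition": cond, "rep_a": names[a],
                                      "rep_b": names[b], "pearson_r": r,
                                      "n": int(ok.sum())})
    if corr_rows:
        corr = pd.DataFrame(corr_rows)
        corr.to_csv(outdir / "replicate_correlation.tsv", sep="\t", index=False)
        results["replicate_correlation"] = corr

    # ROC against the reference structure, when one is provided
    if structure is not None:
        labels = dmetrics.accessibility_labels(structure)
        roc_rows, curve_frames = [], []
        for cond, reps in profiles.items():
            for rep, profile in reps.items():
                for channel in ("AC", "GU"):
                    try:
                        roc = dmetrics.roc_auc(profile, labels, channel,
                                               structure.transcript_id)
                    except ValueError:
                        continue
                    roc_rows.append({"condition": cond, "rep": rep,
                                     "channel": channel, "auc": roc.auc,
                                     "n_pos": roc.n_pos, "n_neg": roc.n_neg})
                    curve_frames.append(pd.DataFrame(
                        {"condition": cond, "rep": rep, "channel": channel,
                         "fpr": roc.fpr, "tpr": roc.tpr}))
        if roc_rows:
            auc_table = pd.DataFrame(roc_rows)
            auc_table.to_csv(outdir / "roc_auc.tsv", sep="\t", index=False)
            pd.concat(curve_frames, ignore_index=True).to_csv(
                outdir / "roc_curves.tsv", sep="\t", index=False)
            results["roc"] = auc_table
    else:
        log.append("no reference structure given: ROC section skipped")

    # SD classification
    if annotations:
        sd_table, fractions = dsd.classify_plastome(
            annotations, transcripts, temperature_K=config.temperature_K)
        sd_table.to_csv(outdir / "sd_classes.tsv", sep="\t", index=False)
        results["sd_table"] = sd_table
        results["sd_fractions"] = fractions
        log.append(f"sd class fractions: {fractions}")

    # guided folds and arc tables (first condition, first replicate)
    if conds:
        first = profiles[conds[0]]
        rep0 = next(iter(first))
        profile = first[rep0]
        for t in transcripts.values():
            sub = profile[profile["transcript_id"] == t.id]
            if sub.empty or sub["normalized"].isna().all() or t.length > 400:
                continue  # the stand-in DP is cubic; long RNAs go to an external engine
            fold = guided_fold(t.sequence, profile, config.fold, t.id)
            react = np.full(t.length, np.nan)
            ok = (sub["mask_reason"] == "none") & sub["normalized"].notna()
            react[sub.loc[ok, "pos"].to_numpy(dtype=int) - 1] = (
                sub.loc[ok, "normalized"])
            pairs_to_arcs(fold, outdir / f"arcs_{conds[0]}_{t.id}.tsv", react)

    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return results
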