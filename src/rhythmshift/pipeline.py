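"""End-to-end orchestration of the night-shift rhythm analysis.

``run_full_pipeline`` wires the stages in the order the analysis is meant to
be read: preprocessing -> group rhythmicity per condition -> rhythmic-set
overlap -> circadian/behavioural classification (when circadian time is
available) -> overall level change -> individual analysis -> class
enrichments. It returns (and optionally writes) a JSON-able manifest holding
every headline quantity plus the configuration hash and seed, so a rerun with
the same inputs and seed reproduces the manifest byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, circstats, enrichment, group, individual
from .io_preprocess import ConcentrationMatrix, filter_lod, load_dataset


@dataclass
class PipelineConfig:
    """Inputs and thresholds for the full analysis."""

    samples_path: str = ""
    metabolites_path: str = ""
    concentrations_path: str = ""
    already_log2: bool = False
    fdr: float = 0.05
    raw_p: float = 0.05
    n_perm: int = 1000
    seed: int = 0
    max_below_frac: float = 0.10
    overlap_method: str = "jaccard"          # or "min"
    permutation_scheme: str = "pooled"       # or "per_metabolite"
    fisher_alternative: str = "greater"      # or "two-sided"
    out_dir: str | None = None

    def __post_init__(self):
        for name in ("fdr", "raw_p", "max_below_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_full_pipeline(config: PipelineConfig,
                      samples: pd.DataFrame | None = None,
                      matrix: ConcentrationMatrix | None = None) -> dict:
    """Run every stage and return the manifest.

    Either the three table paths in ``config`` or an in-memory
    ``(samples, matrix)`` pair must be provided. Stage failures raise
    :class:`StageError` naming the stage; results computed so far are written
    (when ``out_dir`` is set) alongside a FAILED marker.
    """
    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            if out_dir:
                (out_dir / "FAILED").write_text(f"{name}: {exc}\n")
                _write_manifest(manifest, out_dir)
            raise StageError(name, exc) from exc
        _log(name, f"done in {time.perf_counter() - t0:.2f}s")
        return result

    # --- preprocess ---------------------------------------------------------
    def _pre():
        nonlocal samples, matrix
        if samples is None or matrix is None:
            samples, matrix = load_dataset(
                config.samples_path, config.metabolites_path,
                config.concentrations_path, already_log2=config.already_log2)
        filtered = filter_lod(matrix, config.max_below_frac)
        return samples, filtered

    samples, matrix = run_stage("preprocess", _pre)
    manifest["stages"]["preprocess"] = {
        "n_samples": int(len(samples)),
        "n_metabolites": int(len(matrix.metabolites)),
        "filter_report": {k: v for k, v in matrix.filter_report.items()
                          if k != "imputed"} | {
            "n_imputed_cells": int(sum(matrix.filter_report.get("imputed", {}).values()))},
    }

    # --- group rhythmicity --------------------------------------------------
    def _group():
        fits = {c: group.run_group_rhythmicity(samples, matrix, c, fdr=config.fdr)
                for c in ("baseline", "nightshift")}
        return fits

    fits = run_stage("group_rhythmicity", _group)
    ov = group.overlap_test(fits["baseline"], fits["nightshift"])
    common = ov["overlap"]
    manifest["stages"]["group_rhythmicity"] = {
        "n_rhythmic_baseline": int(fits["baseline"]["rhythmic"].sum()),
        "n_rhythmic_nightshift": int(fits["nightshift"]["rhythmic"].sum()),
        "n_rhythmic_both": ov["n_overlap"],
        "overlap_p": ov["p"],
    }
    phase_summaries = {}
    for c in ("baseline", "nightshift"):
        try:
            s = group.summarize_phase_distribution(fits[c], seed=config.seed)
            phase_summaries[c] = {"rao_U": s["rao_U"], "p": s["p"]}
        except circstats.InsufficientDataError:
            phase_summaries[c] = None
    manifest["stages"]["phase_distribution"] = phase_summaries

    # --- classification -----------------------------------------------------
    classification = None
    if samples["circadian_time_h"].notna().all() and common:
        def _classify():
            return group.classify_circadian_behavioural(samples, matrix, common,
                                                        alpha=config.fdr)
        classification = run_stage("classification", _classify)
        labels = classification["label"].value_counts().to_dict()
        shifts = group.group_phase_shifts(fits["baseline"], fits["nightshift"], common)
        cls_summary = {"labels": {k: int(v) for k, v in labels.items()}}
        behav = classification.index[classification["label"] == "behavioural"]
        if len(behav) >= 3:
            cls_summary["behavioural_shift"] = group.group_phase_shift_summary(
                shifts.loc[behav, "delta_phi_h"].to_numpy())
        circ = classification.index[classification["label"] == "circadian"]
        if len(circ) >= 3:
            cls_summary["circadian_shift"] = group.group_phase_shift_summary(
                shifts.loc[circ, "delta_phi_h"].to_numpy())
        cls_summary["amplitude_comparison"] = group.compare_amplitudes(
            fits["baseline"], fits["nightshift"], common)
        manifest["stages"]["classification"] = cls_summary
    else:
        manifest["stages"]["classification"] = None
        _log("classification", "skipped (no circadian time or no common rhythmic set)")

    # --- level change -------------------------------------------------------
    def _levels():
        return group.run_level_change(samples, matrix, fdr=config.fdr)

    levels = run_stage("level_change", _levels)
    manifest["stages"]["level_change"] = {
        "n_significant": int((levels["q"] < config.fdr).sum()),
        "n_up": int((levels["direction"] == "up").sum()),
        "n_down": int((levels["direction"] == "down").sum()),
    }

    # --- individual ---------------------------------------------------------
    def _indiv():
        res = individual.run_individual_rhythmicity(
            samples, matrix, n_perm=config.n_perm, seed=config.seed,
            scheme=config.permutation_scheme)
        return res

    indiv = run_stage("individual", _indiv)
    indiv_summary = {}
    for c in ("baseline", "nightshift"):
        sets = individual.rhythmic_sets(indiv, c, corrected_p=config.raw_p)
        counts = [len(s) for s in sets.values()]
        overlap = individual.pairwise_overlap(indiv, c, corrected_p=config.raw_p,
                                              method=config.overlap_method)
        tri = overlap.where(np.triu(np.ones(overlap.shape, dtype=bool), k=1))
        indiv_summary[c] = {
            "median_rhythmic_per_subject": float(np.median(counts)) if counts else None,
            "range_rhythmic_per_subject": [int(min(counts)), int(max(counts))]
            if counts else None,
            "median_pairwise_overlap_pct": float(np.nanmedian(tri.to_numpy()))
            if counts else None,
        }
    shifts = individual.per_subject_phase_shifts(indiv, raw_p=config.raw_p)
    indiv_summary["phase_shifts"] = {
        "per_subject_mean_shift_h": {
            s: v["mean_shift_h"] for s, v in shifts["per_subject"].items()},
        "across_subject": shifts["summary"],
    }
    manifest["stages"]["individual"] = indiv_summary

    # --- enrichment ---------------------------------------------------------
    def _enrich():
        base_set = set(fits["baseline"].index[fits["baseline"]["rhythmic"]])
        night_set = set(fits["nightshift"].index[fits["nightshift"]["rhythmic"]])
        lists = {
            "lost_rhythm": sorted(base_set - night_set),
            "gained_rhythm": sorted(night_set - base_set),
            "level_up": sorted(levels.index[levels["direction"] == "up"]),
            "level_down": sorted(levels.index[levels["direction"] == "down"]),
        }
        if classification is not None:
            lists["behaviour_influenced"] = sorted(
                classification.index[classification["label"] == "behavioural"])
        out = {}
        for name, hit_list in lists.items():
            table = enrichment.class_overrepresentation(
                hit_list, matrix, alternative=config.fisher_alternative)
            out[name] = {
                "n_hits": len(hit_list),
                "significant_classes": table.index[table["significant"]].tolist(),
            }
        return out

    manifest["stages"]["enrichment"] = run_stage("enrichment", _enrich)

    if out_dir:
        fits["baseline"].to_csv(out_dir / "rhythmicity_baseline.tsv", sep="\t")
        fits["nightshift"].to_csv(out_dir / "rhythmicity_nightshift.tsv", sep="\t")
        if classification is not None:
            classification.to_csv(out_dir / "classification.tsv", sep="\t")
        levels.to_csv(out_dir / "level_change.tsv", sep="\t")
        indiv.to_csv(out_dir / "individual_rhythmicity.tsv", sep="\t", index=False)
        _write_manifest(manifest, out_dir)
    return manifest


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (Path(out_dir) / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default) + "\n")
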