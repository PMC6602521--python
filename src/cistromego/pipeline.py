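"""End-to-end solo and ensemble runs.

Solo mode (peaks only): classify the cistrome and pick the decay distance,
compute adjusted RP scores and the binding-derived gene ranking, then run
mHG enrichment per gene-set collection.  Ensemble mode (peaks + DGE table)
additionally derives the expression ranking, combines the two by rank
product, runs enrichment on the combined ranking (solo-ranking tables are
written too, for comparison), and emits ROC/PR diagnostics of adjusted RP
against DE-defined labels.

Runs are fully deterministic: identical config and input bytes produce
byte-identical output tables.  Floats are printed with 6 significant
digits.  On failure every output file created by the run is removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .classify import classify
from .enrichment import (DEFAULT_FDR_CUTOFF, dedup_by_jaccard, enrichment_frame,
                         filter_term_sets, run_enrichment)
from .integration import (binding_expression_curves, ensemble_ranking,
                          rank_by_de, rank_product)
from .ranking import RankedGeneList
from .rp import (DecayConfig, adjust_rp, baseline_series, compute_baseline,
                 rank_by_adjusted_rp, raw_rp_all, rp_table, scale_rp)

logger = logging.getLogger("cistromego")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    peaks: str
    annotation: str
    gmts: Sequence[str]
    outdir: str
    dge: Optional[str] = None
    baseline: Optional[str] = None
    mode: Optional[str] = None  # None = auto: ensemble iff a DGE file is given
    d0_override: Optional[float] = None
    window_multiple: float = 15.0
    direction: str = "all"
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF
    classify_threshold: float = 0.20
    de_label_cutoff: float = 0.05
    peak_dialect: str = "bed"

    def resolved_mode(self) -> str:
        if self.mode is not None:
            return self.mode
        return "ensemble" if self.dge else "solo"

    def validate(self) -> None:
        mode = self.resolved_mode()
        if mode not in ("solo", "ensemble"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if mode == "ensemble" and not self.dge:
            raise ValueError("ensemble mode requires a DGE file")
        if mode == "solo" and self.direction != "all":
            raise ValueError("solo mode does not accept a direction filter")
        if not self.gmts:
            raise ValueError("at least one GMT file is required")
        for p in [self.peaks, self.annotation, *self.gmts]:
            if not Path(p).exists():
                raise FileNotFoundError(p)


class _OutputBundle:
    """Tracks files written by a run so they can be removed on failure."""

    def __init__(self, outdir):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.files.append(p)
        return p

    def cleanup(self) -> None:
        for p in self.files:
            p.unlink(missing_ok=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _enrich_and_write(ranking: RankedGeneList, gmt_paths, bundle, suffix, fdr_cutoff,
                      log):
    """Filter/dedup/test each collection against a ranking; write the full
    and FDR-restricted tables.  Returns {collection: results}."""
    all_results = {}
    for gmt_path in gmt_paths:
        collection = Path(gmt_path).stem
        sets, report = gio.read_gmt(gmt_path, with_report=True)
        filtered = filter_term_sets(sets, ranking.gene_ids)
        deduped = dedup_by_jaccard(filtered)
        results = run_enrichment(ranking, deduped, fdr_cutoff)
        frame = enrichment_frame(results)
        _write_tsv(frame, bundle.path(f"enrichment_{collection}{suffix}.tsv"))
        _write_tsv(frame[frame["fdr"] < fdr_cutoff],
                   bundle.path(f"enrichment_{collection}{suffix}.reported.tsv"))
        log.setdefault("gene_sets", {})[f"{collection}{suffix}"] = {
            "parsed": report.kept,
            "dropped_at_parse": report.n_dropped,
            "after_size_filter": len(filtered),
            "after_jaccard_dedup": len(deduped),
            "reported_fdr_lt_cutoff": int((frame["fdr"] < fdr_cutoff).sum()),
        }
        all_results[collection] = results
    return all_results


def _solo_stages(config: RunConfig, bundle: _OutputBundle, log: dict):
    peaks, peak_report = gio.read_peaks(config.peaks, config.peak_dialect,
                                        with_report=True)
    genes = gio.read_annotation(config.annotation)
    gio.check_chromosome_overlap(peaks, genes)

    report = classify(peaks, genes, config.classify_threshold,
                      d0_override=config.d0_override)
    with open(bundle.path("classification.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)

    decay = DecayConfig(report.chosen_d0, config.window_multiple)
    baseline_table = gio.read_baseline(config.baseline) if config.baseline else None
    raw = raw_rp_all(genes, peaks, decay)
    scaled = scale_rp(raw)
    base = baseline_series(scaled, baseline_table)
    adjusted = adjust_rp(scaled, baseline_table)
    ranking = rank_by_adjusted_rp(adjusted)
    _write_tsv(rp_table(raw, scaled, base, adjusted, ranking),
               bundle.path("rp_ranks.tsv"))

    log["peaks"] = {"kept": peak_report.kept, "dropped": peak_report.dropped}
    log["n_genes"] = int(adjusted.index.nunique())
    log["classification"] = report.to_dict()
    log["d0"] = decay.d0
    log["window_bp"] = decay.window
    return peaks, genes, adjusted, ranking


def run_solo(config: RunConfig) -> dict:
    """Solo-mode run; returns a summary dict (also written to run_log.json)."""
    config.validate()
    bundle = _OutputBundle(config.outdir)
    log: dict = {"mode": "solo", "config": _config_dict(config)}
    try:
        _, _, _, ranking = _solo_stages(config, bundle, log)
        results = _enrich_and_write(ranking, config.gmts, bundle, "",
                                    config.fdr_cutoff, log)
        log["top_terms"] = _top_terms(results)
        with open(bundle.path("run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True, default=str)
    except Exception:
        bundle.cleanup()
        raise
    return log


def run_ensemble(config: RunConfig) -> dict:
    """Ensemble-mode run: solo stages + DE ranking, rank product, combined
    enrichment and ROC/PR diagnostics."""
    config.validate()
    if not Path(config.dge).exists():
        raise FileNotFoundError(config.dge)
    bundle = _OutputBundle(config.outdir)
    log: dict = {"mode": "ensemble", "config": _config_dict(config)}
    try:
        _, _, adjusted, rp_ranking = _solo_stages(config, bundle, log)
        dge, dge_report = gio.read_dge(config.dge, with_report=True)
        log["dge"] = {"kept": dge_report.kept, "dropped": dge_report.dropped}

        de_ranking = rank_by_de(dge, config.direction)
        combined = rank_product(rp_ranking, de_ranking)
        _write_tsv(combined, bundle.path("ensemble_ranks.tsv"))
        log["rank_product"] = {
            "n_common": len(combined),
            "n_binding_only": len(rp_ranking) - len(combined),
            "n_expression_only": len(de_ranking) - len(combined),
        }

        ens_ranking = ensemble_ranking(combined)
        results = _enrich_and_write(ens_ranking, config.gmts, bundle, "",
                                    config.fdr_cutoff, log)
        _enrich_and_write(rp_ranking, config.gmts, bundle, ".solo",
                          config.fdr_cutoff, log)
        log["top_terms"] = _top_terms(results)

        roc, pr = binding_expression_curves(
            adjusted.to_dict(), dge, config.de_label_cutoff, config.direction
        )
        _write_tsv(pd.DataFrame({"fpr": roc.x, "tpr": roc.y}), bundle.path("roc.tsv"))
        _write_tsv(pd.DataFrame({"recall": pr.x, "precision": pr.y}),
                   bundle.path("pr.tsv"))
        log["auroc"] = round(roc.auc, 6)
        log["aupr"] = round(pr.auc, 6)
        with open(bundle.path("summary.json"), "w") as fh:
            json.dump({"auroc": log["auroc"], "aupr": log["aupr"]}, fh, indent=2)
        with open(bundle.path("run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True, default=str)
    except Exception:
        bundle.cleanup()
        raise
    return log


def analyze(
    genes,
    peaks,
    gene_sets,
    dge=None,
    baseline=None,
    d0: Optional[float] = None,
    direction: str = "all",
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    de_label_cutoff: float = 0.05,
    classify_threshold: float = 0.20,
    window_multiple: float = 15.0,
) -> dict:
    """In-memory analysis on already-parsed objects; no files touched.

    Runs classification, RP scoring and solo enrichment; with a DGE record
    list it additionally computes the expression ranking, the rank-product
    ensemble ranking, ensemble enrichment and ROC/PR diagnostics.  Returns a
    dict with keys ``classification``, ``adjusted_rp``, ``rp_ranking``,
    ``solo_enrichment`` and, in ensemble mode, ``ensemble_table``,
    ``ensemble_enrichment``, ``roc`` and ``pr``.
    """
    report = classify(peaks, genes, classify_threshold, d0_override=d0)
    decay = DecayConfig(report.chosen_d0, window_multiple)
    scaled = scale_rp(raw_rp_all(genes, peaks, decay))
    adjusted = adjust_rp(scaled, baseline)
    rp_ranking = rank_by_adjusted_rp(adjusted)

    def _enrich(ranking):
        filtered = filter_term_sets(gene_sets, ranking.gene_ids)
        return run_enrichment(ranking, dedup_by_jaccard(filtered), fdr_cutoff)

    out = {
        "classification": report,
        "adjusted_rp": adjusted,
        "rp_ranking": rp_ranking,
        "solo_enrichment": _enrich(rp_ranking),
    }
    if dge is not None:
        de_ranking = rank_by_de(dge, direction)
        combined = rank_product(rp_ranking, de_ranking)
        ens_ranking = ensemble_ranking(combined)
        out["de_ranking"] = de_ranking
        out["ensemble_table"] = combined
        out["ensemble_enrichment"] = _enrich(ens_ranking)
        roc, pr = binding_expression_curves(
            adjusted.to_dict(), dge, de_label_cutoff, direction
        )
        out["roc"], out["pr"] = roc, pr
    return out


def run(config: RunConfig) -> dict:
    return run_ensemble(config) if config.resolved_mode() == "ensemble" else run_solo(config)


def baseline_from_files(peak_paths: Sequence[str], annotation_path: str,
                        d0: float = 1000.0, window_multiple: float = 15.0) -> dict:
    """Compute a baseline table from a panel of peak files (fixture-scale
    counterpart of the precomputed reference baselines)."""
    if not peak_paths:
        raise ValueError("need at least one peak file")
    genes = gio.read_annotation(annotation_path)
    peak_sets = [gio.read_peaks(p) for p in peak_paths]
    return compute_baseline(peak_sets, genes, DecayConfig(d0, window_multiple))


def _config_dict(config: RunConfig) -> dict:
    d = dict(config.__dict__)
    d["gmts"] = list(d["gmts"])
    d["resolved_mode"] = config.resolved_mode()
    return d


def _top_terms(results_by_collection: dict) -> dict:
    out = {}
    for collection, results in results_by_collection.items():
        out[collection] = [
            {"set_id": r.set_id, "pvalue": float(r.pvalue), "fdr": float(r.fdr)}
            for r in results[:3]
        ]
    return out
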