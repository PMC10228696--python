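"""End-to-end bootstrap workflow.

Point-estimate inference on the original data, bootstrap replicate
generation, per-replicate clone inference, consensus clones with
bootstrap support, per-replicate migration histories (each tumor sample
is treated as one tumor site), a consensus migration history, and an
optional driver-mutation comparison — plus a manifest making the run
reproducible byte for byte under the same seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bootstrap import make_replicate_set
from .consensus import consensus_clones
from .datatypes import GenotypeMatrix, MigrationHistory, ReadCountTable, RunConfig
from .inference import ClonePrediction, deconvolve_clones
from .io import write_genotypes_fasta, write_migration, write_outputs
from .migration import (AnnotatedPath, SiteLabeling, consensus_history,
                        infer_history, map_mutations_to_paths)
from .trees import build_tree

logger = logging.getLogger("cloneboot")


@dataclass
class PipelineResult:
    point: ClonePrediction
    replicate_predictions: list[ClonePrediction]
    consensus_genotypes: GenotypeMatrix
    consensus_support: dict[str, float]
    point_history: MigrationHistory | None = None
    replicate_histories: list[MigrationHistory] | None = None
    consensus_migration: MigrationHistory | None = None
    replicate_annotations: list[list[AnnotatedPath]] | None = None
    manifest: dict = field(default_factory=dict)


def reported_occupancy(pred: ClonePrediction, report_freq: float) -> dict[str, set[str]]:
    """Sites (samples) where each clone exceeds the reporting threshold."""
    occ: dict[str, set[str]] = {}
    f = pred.frequencies
    for k, cid in enumerate(f.clone_ids):
        sites = {f.sample_ids[i] for i in range(len(f.sample_ids))
                 if f.values[i, k] > report_freq}
        if sites:
            occ[cid] = sites
    return occ


def history_for_prediction(pred: ClonePrediction, primary: str,
                           report_freq: float):
    """Migration history of one prediction's reportable clones.

    Clones above the reporting frequency in no sample are excluded; the
    tree is rebuilt on the remaining clones. Returns
    ``(history, labeling, tree, occupancy)``; the history is empty when no
    clone qualifies.
    """
    occ = reported_occupancy(pred, report_freq)
    if not occ:
        logger.warning("no clone exceeds the %.0f%% reporting threshold",
                       100 * report_freq)
        return MigrationHistory([]), None, None, occ
    g = pred.genotypes
    keep = [i for i, c in enumerate(g.clone_ids) if c in occ]
    sub = GenotypeMatrix([g.clone_ids[i] for i in keep], g.snv_ids,
                         g.state[keep])
    if sub.n_clones >= 2:
        tree = build_tree(sub)
    else:
        from .inference import _single_clone_tree
        tree = _single_clone_tree(sub)
    history, labeling = infer_history(tree, occ, primary)
    return history, labeling, tree, occ


def run_pipeline(counts: ReadCountTable, config: RunConfig | None = None,
                 primary: str | None = None,
                 driver_flags: dict[str, bool] | None = None,
                 out_dir=None) -> PipelineResult:
    """Run the full bootstrap workflow on one multi-tumor dataset.

    ``primary`` (a sample id) turns on migration inference, treating each
    sample as a tumor site. All randomness derives from
    ``config.rng_seed``.
    """
    config = config or RunConfig()
    counts = counts.drop_uncovered_snvs()
    if primary is not None and primary not in counts.sample_ids:
        raise ValueError(f"primary site {primary!r} is not a sample id")

    logger.info("point-estimate inference on %d samples x %d SNVs",
                counts.n_samples, counts.n_snvs)
    point = deconvolve_clones(counts, config)

    reps = make_replicate_set(counts, config.n_replicates, config.rng_seed)
    rep_preds = []
    for r, table in enumerate(reps):
        logger.info("replicate %d/%d", r + 1, len(reps))
        rep_preds.append(deconvolve_clones(table, config))

    cons_geno, cons_support = consensus_clones(
        [p.genotypes for p in rep_preds],
        cutoff=config.group_cutoff, base_threshold=config.base_threshold)

    result = PipelineResult(point, rep_preds, cons_geno, cons_support)

    if primary is not None:
        result.point_history, _, _, _ = history_for_prediction(
            point, primary, config.report_freq)
        histories, annotations = [], []
        for p in rep_preds:
            h, lab, tree, occ = history_for_prediction(p, primary,
                                                       config.report_freq)
            histories.append(h)
            if lab is not None:
                annotations.append(
                    map_mutations_to_paths(tree, lab, occ, driver_flags))
            else:
                annotations.append([])
        result.replicate_histories = histories
        result.replicate_annotations = annotations
        result.consensus_migration = consensus_history(
            histories, config.support_threshold_paths, primary)

    result.manifest = {
        "version": __version__,
        "config": dict(sorted(config.__dict__.items())),
        "replicate_seeds": reps.seeds,
        "primary": primary,
    }
    if out_dir is not None:
        result.manifest["files"] = _write_all(result, out_dir)
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return result


def _write_all(result: PipelineResult, out_dir) -> dict[str, str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_outputs(result.point, out_dir / "point",
                          history=result.point_history)
    files = {f"point/{k}": str(v) for k, v in paths.items()}

    cons_fasta = out_dir / "consensus_clones.fasta"
    write_genotypes_fasta(result.consensus_genotypes, cons_fasta)
    files["consensus_fasta"] = str(cons_fasta)
    support_tsv = out_dir / "consensus_support.tsv"
    with open(support_tsv, "w") as fh:
        fh.write("clone_id\tsupport_percent\n")
        for cid in result.consensus_genotypes.clone_ids:
            fh.write(f"{cid}\t{result.consensus_support[cid]:.10g}\n")
    files["consensus_support"] = str(support_tsv)

    if result.consensus_migration is not None:
        mig_tsv = out_dir / "consensus_migration.tsv"
        write_migration(result.consensus_migration, mig_tsv)
        files["consensus_migration"] = str(mig_tsv)

    return {k: _sha256(v) for k, v in files.items()}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
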