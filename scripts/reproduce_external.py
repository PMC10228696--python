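#!/usr/bin/env python
"""Optional driver: run the bootstrap workflow over external datasets.

Applies the identical analysis to every dataset in a directory tree that
the user has obtained and converted to the package's read-count format.
Expected layout, one sub-directory per patient/dataset:

    <data-dir>/<name>/counts.tsv          required (paired-column dialect)
    <data-dir>/<name>/primary.txt         optional: primary site (sample id)
    <data-dir>/<name>/drivers.txt         optional: one driver SNV id per line
    <data-dir>/<name>/true_clones.fasta   optional: truth genotypes (0->A, 1->T)
    <data-dir>/<name>/true_migration.tsv  optional: truth migration paths

For each dataset the script runs 30-replicate bootstrap inference, writes
consensus clones with supports and (when a primary is given) the
consensus migration history, and — when truth files exist — genotype
error and path-classification summaries. Expect hours of compute for
large collections; datasets run independently, so shard the directory to
parallelise.
"""

from __future__ import annotations

import argparse
import json
import logging
from pathlib import Path

import numpy as np

from cloneboot import (RunConfig, classify_paths, nearest_true_ge,
                       path_supports, run_pipeline)
from cloneboot.io import read_counts, read_genotypes_fasta, read_migration


def analyse_dataset(ds_dir: Path, out_dir: Path, seed: int) -> dict:
    counts = read_counts(ds_dir / "counts.tsv")
    primary = None
    if (ds_dir / "primary.txt").exists():
        primary = (ds_dir / "primary.txt").read_text().strip()
    drivers = None
    if (ds_dir / "drivers.txt").exists():
        flagged = set((ds_dir / "drivers.txt").read_text().split())
        drivers = {s: s in flagged for s in counts.snv_ids}

    cfg = RunConfig(rng_seed=seed)
    res = run_pipeline(counts, cfg, primary=primary, driver_flags=drivers,
                       out_dir=out_dir)
    summary: dict = {
        "n_consensus_clones": res.consensus_genotypes.n_clones,
        "low_support_clone_percent": 100.0 * float(np.mean(
            [s <= 10.0 for s in res.consensus_support.values()])),
    }

    if (ds_dir / "true_clones.fasta").exists():
        truth = read_genotypes_fasta(ds_dir / "true_clones.fasta",
                                     counts.snv_ids)
        ge = nearest_true_ge(res.consensus_genotypes, truth,
                             ambiguity="ignore")
        hi = [ge[c] for c, s in res.consensus_support.items() if s > 50.0]
        if hi:
            summary["median_ge_high_support"] = float(np.median(hi))

    if primary and (ds_dir / "true_migration.tsv").exists():
        true_hist = read_migration(ds_dir / "true_migration.tsv")
        summary["path_classification"] = classify_paths(
            true_hist, res.consensus_migration)
        sups = path_supports(res.replicate_histories)
        tp = [s for p, s in sups.items() if p in true_hist.path_set()]
        fp = [s for p, s in sups.items() if p not in true_hist.path_set()]
        if tp:
            summary["tp_path_support_median"] = float(np.median(tp))
        if fp:
            summary["fp_path_support_median"] = float(np.median(fp))
    return summary


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out-dir", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    logging.basicConfig(level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")

    results = {}
    for ds_dir in sorted(p for p in args.data_dir.iterdir() if p.is_dir()):
        logging.info("dataset %s", ds_dir.name)
        results[ds_dir.name] = analyse_dataset(
            ds_dir, args.out_dir / ds_dir.name, args.seed)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    with open(args.out_dir / "summary.json", "w") as fh:
        json.dump(results, fh, indent=2)
    print(json.dumps(results, indent=2))


if __name__ == "__main__":
    main()
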