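"""Readers and writers for the package's on-disk formats.

Formats (all plain text):

* read counts — one TSV with an ``snv_id`` column and, per sample, paired
  ``<sample>:ref`` / ``<sample>:alt`` columns (canonical dialect), or two
  matrix TSVs (reference counts and variant counts) behind the ``two-file``
  dialect;
* clone genotypes — TSV with states ``0``/``1``/``?`` and FASTA with the
  0->A, 1->T, ambiguous->N base encoding (interoperable with tree
  software);
* clone frequencies — samples x clones TSV;
* clone phylogeny — Newick;
* migration paths — TSV with columns source, destination, support_percent,
  status.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import AMBIGUOUS, FrequencyMatrix, GenotypeMatrix, MigrationHistory, ReadCountTable

logger = logging.getLogger("cloneboot")

_STATE_TO_CHAR = {0: "0", 1: "1", AMBIGUOUS: "?"}
_CHAR_TO_STATE = {v: k for k, v in _STATE_TO_CHAR.items()}
_STATE_TO_BASE = {0: "A", 1: "T", AMBIGUOUS: "N"}
_BASE_TO_STATE = {v: k for k, v in _STATE_TO_BASE.items()}


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def read_counts(path, dialect: str = "paired", alt_path=None) -> ReadCountTable:
    """Read a read-count table.

    ``dialect='paired'`` expects one TSV whose header names the SNV id
    column first, then ``<sample>:ref`` / ``<sample>:alt`` column pairs.
    ``dialect='two-file'`` expects ``path`` to be a reference-count matrix
    (rows SNVs, columns samples) and ``alt_path`` the matching variant-count
    matrix. SNVs with zero total coverage everywhere are dropped with a
    warning.
    """
    if dialect == "paired":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        snv_col = df.columns[0]
        samples: list[str] = []
        for col in df.columns[1:]:
            if ":" not in col:
                raise ValueError(
                    f"malformed header column {col!r}: expected '<sample>:ref' or '<sample>:alt'"
                )
            name, kind = col.rsplit(":", 1)
            if kind not in ("ref", "alt"):
                raise ValueError(f"malformed header column {col!r}")
            if name not in samples:
                samples.append(name)
        for s in samples:
            for kind in ("ref", "alt"):
                if f"{s}:{kind}" not in df.columns:
                    raise ValueError(f"sample {s!r} is missing its {kind} column")
        snv_ids = df[snv_col].astype(str).tolist()
        if len(set(snv_ids)) != len(snv_ids):
            dup = sorted({s for s in snv_ids if snv_ids.count(s) > 1})
            raise ValueError(f"duplicate SNV ids: {dup}")
        ref = df[[f"{s}:ref" for s in samples]].to_numpy().T
        alt = df[[f"{s}:alt" for s in samples]].to_numpy().T
        neg = np.argwhere((ref < 0) | (alt < 0))
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count for SNV {snv_ids[j]!r} in sample {samples[i]!r}"
            )
        table = ReadCountTable(samples, snv_ids, ref, alt)
    elif dialect == "two-file":
        if alt_path is None:
            raise ValueError("two-file dialect requires alt_path")
        ref_df = pd.read_csv(path, sep="\t", index_col=0)
        alt_df = pd.read_csv(alt_path, sep="\t", index_col=0)
        if list(ref_df.index) != list(alt_df.index) or list(ref_df.columns) != list(alt_df.columns):
            raise ValueError("ref and alt matrices must share row and column labels")
        table = ReadCountTable(
            [str(c) for c in ref_df.columns],
            [str(i) for i in ref_df.index],
            ref_df.to_numpy().T,
            alt_df.to_numpy().T,
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return table.drop_uncovered_snvs()


def write_counts(table: ReadCountTable, path) -> None:
    cols = {"snv_id": table.snv_ids}
    for i, s in enumerate(table.sample_ids):
        cols[f"{s}:ref"] = table.ref[i]
        cols[f"{s}:alt"] = table.alt[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        [[_STATE_TO_CHAR[int(x)] for x in row] for row in genotypes.state],
        index=genotypes.clone_ids,
        columns=genotypes.snv_ids,
    )
    df.to_csv(path, sep="\t", index_label="clone_id")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    state = np.array([[_CHAR_TO_STATE[x] for x in row] for row in df.to_numpy()],
                     dtype=np.int8)
    return GenotypeMatrix([str(i) for i in df.index],
                          [str(c) for c in df.columns], state)


def write_genotypes_fasta(genotypes: GenotypeMatrix, path) -> None:
    """Clone sequences with the 0->A, 1->T, ambiguous->N base encoding."""
    records = [
        SeqRecord(Seq("".join(_STATE_TO_BASE[int(x)] for x in row)),
                  id=cid, description="")
        for cid, row in zip(genotypes.clone_ids, genotypes.state)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genotypes_fasta(path, snv_ids: list[str] | None = None) -> GenotypeMatrix:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    state = np.array(
        [[_BASE_TO_STATE[c] for c in str(r.seq)] for r in records], dtype=np.int8
    )
    if snv_ids is None:
        snv_ids = [f"s{j}" for j in range(state.shape[1])]
    return GenotypeMatrix([r.id for r in records], snv_ids, state)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

def write_frequencies(freqs: FrequencyMatrix, path) -> None:
    pd.DataFrame(freqs.values, index=freqs.sample_ids,
                 columns=freqs.clone_ids).to_csv(
        path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_frequencies(path) -> FrequencyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FrequencyMatrix([str(i) for i in df.index],
                           [str(c) for c in df.columns], df.to_numpy())


# ---------------------------------------------------------------------------
# migration paths
# ---------------------------------------------------------------------------

def write_migration(history: MigrationHistory, path) -> None:
    rows = []
    for src, dst in history.paths:
        rows.append({
            "source": src,
            "destination": dst,
            "support_percent": history.support.get((src, dst), ""),
            "status": "tentative" if (src, dst) in history.tentative else "solid",
        })
    pd.DataFrame(rows, columns=["source", "destination", "support_percent", "status"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_migration(path) -> MigrationHistory:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "destination": str})
    paths = [(r.source, r.destination) for r in df.itertuples()]
    support = {}
    tentative = set()
    for r in df.itertuples():
        key = (r.source, r.destination)
        if pd.notna(r.support_percent) and r.support_percent != "":
            support[key] = float(r.support_percent)
        if getattr(r, "status", "solid") == "tentative":
            tentative.add(key)
    return MigrationHistory(paths, support, tentative)


# ---------------------------------------------------------------------------
# prediction bundles
# ---------------------------------------------------------------------------

def write_outputs(prediction, out_dir, history: MigrationHistory | None = None) -> dict:
    """Write a clone prediction (genotypes, frequencies, tree) to ``out_dir``.

    Returns a mapping of artefact name to file path. Raises on any
    dimension mismatch between the parts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g, f = prediction.genotypes, prediction.frequencies
    if g.clone_ids != f.clone_ids:
        raise ValueError("genotype and frequency clone axes disagree")
    paths = {
        "genotypes_tsv": out_dir / "clone_genotypes.tsv",
        "genotypes_fasta": out_dir / "clone_sequences.fasta",
        "frequencies_tsv": out_dir / "clone_frequencies.tsv",
        "tree_newick": out_dir / "clone_tree.nwk",
    }
    write_genotypes_tsv(g, paths["genotypes_tsv"])
    write_genotypes_fasta(g, paths["genotypes_fasta"])
    write_frequencies(f, paths["frequencies_tsv"])
    with open(paths["tree_newick"], "w") as fh:
        fh.write(prediction.tree.to_newick() + "\n")
    if history is not None:
        paths["migration_tsv"] = out_dir / "migration_paths.tsv"
        write_migration(history, paths["migration_tsv"])
    return paths
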