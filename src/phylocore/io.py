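"""Readers and writers for the package's on-disk formats.

TSV abundance tables (taxa rows x sample columns, integer counts), FASTA
sequences, newick trees with branch lengths, trait tables, truth-label
sidecars and YAML run configuration. Readers validate and reject rather
than silently coerce; writers emit stable, deterministic orderings.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import PipelineConfig
from .containers import AbundanceTable, SequenceSet, TraitTable, ValidationError
from .simulate import TruthLabels
from .tree import LabeledTree


class FormatError(ValidationError):
    """Raised when an input file does not parse or validate."""


# -- abundance tables --------------------------------------------------------

def read_abundance_tsv(path) -> AbundanceTable:
    """Read a taxa x samples TSV: header row, first column taxon ids."""
    rows: dict[str, list[int]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        samples = header[1:]
        if not samples:
            raise FormatError(f"{path}: header has no sample columns")
        if len(samples) != len(set(samples)):
            raise FormatError(f"{path}: duplicate sample ids in header")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            taxon = row[0]
            if taxon in rows:
                raise FormatError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
            vals = []
            for cell in row[1:]:
                try:
                    v = int(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer count {cell!r} for taxon {taxon!r}"
                    ) from None
                if v < 0:
                    raise FormatError(
                        f"{path}:{lineno}: negative count for taxon {taxon!r}"
                    )
                vals.append(v)
            rows[taxon] = vals
    if not rows:
        raise FormatError(f"{path}: no taxon rows")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return AbundanceTable(df)


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    table.df.to_csv(path, sep="\t", index_label="taxon")


# -- sequences ----------------------------------------------------------------

def read_fasta(path) -> SequenceSet:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return SequenceSet(seqs)


def write_fasta(seqs: SequenceSet, path) -> None:
    records = [SeqRecord(Seq(seqs[sid]), id=sid, description="") for sid in seqs.ids]
    SeqIO.write(records, str(path), "fasta")


# -- trees --------------------------------------------------------------------

def read_newick(path) -> LabeledTree:
    text = Path(path).read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty newick file")
    return LabeledTree.from_newick(text)


def write_newick(tree: LabeledTree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# -- traits -------------------------------------------------------------------

def read_traits_tsv(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TraitTable(df)


def write_traits_tsv(traits: TraitTable, path) -> None:
    traits.df.to_csv(path, sep="\t", index=False)


# -- truth labels -------------------------------------------------------------

def write_truth_json(truth: TruthLabels, path) -> None:
    d = dataclasses.asdict(truth)
    d["departing_taxa"] = list(d["departing_taxa"])
    d["eligible"] = list(d["eligible"])
    if d["expected_pcgs"] is not None:
        d["expected_pcgs"] = [sorted(s) for s in d["expected_pcgs"]]
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def read_truth_json(path) -> TruthLabels:
    d = json.loads(Path(path).read_text())
    if d.get("expected_pcgs") is not None:
        d["expected_pcgs"] = tuple(frozenset(s) for s in d["expected_pcgs"])
    d["departing_taxa"] = tuple(d.get("departing_taxa", ()))
    d["eligible"] = tuple(d.get("eligible", ()))
    return TruthLabels(**d)


# -- run configuration --------------------------------------------------------

def read_config_yaml(path) -> PipelineConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise FormatError(f"{path}: unknown config keys: {unknown}")
    if "thresholds" in raw:
        raw["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise FormatError(f"{path}: invalid config: {exc}") from None
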