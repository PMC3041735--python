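"""Readers and writers for the flat-file formats the pipeline touches.

Sequences travel as FASTA (alignments as aligned FASTA), gene models as
tab-separated tables, qPCR wells as comma-separated tables, trees as
Newick with integer bootstrap supports stored as internal-node labels.
All genomic coordinates are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from . import __version__ as _pkg_version
from .qpcr import WellRecord
from .sequtils import validate_alphabet

logger = logging.getLogger(__name__)


class FastaFormatError(ValueError):
    pass


class TableFormatError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or DNA sequence (possibly gapped, uppercase)."""

    id: str
    sequence: str
    alphabet: str = "protein"
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        bad = validate_alphabet(self.sequence, self.alphabet)
        if bad:
            pos, char = bad[0]
            raise FastaFormatError(
                f"record {self.id!r}: character {char!r} at position {pos} "
                f"not allowed in {self.alphabet} alphabet"
            )

    def ungapped(self) -> "SequenceRecord":
        return dataclasses.replace(self, sequence=self.sequence.replace("-", ""))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneRow:
    """One gene model: chromosome placement plus an ordered exon list."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.start > self.end:
            raise TableFormatError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise TableFormatError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s > e:
                raise TableFormatError(f"gene {self.gene_id!r}: exon start {s} > end {e}")
            if s < self.start or e > self.end:
                raise TableFormatError(
                    f"gene {self.gene_id!r}: exon {s}-{e} outside gene bounds"
                )
            if prev_end is not None and s <= prev_end:
                raise TableFormatError(f"gene {self.gene_id!r}: overlapping exons")
            prev_end = e

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, uppercasing sequences.

    Raises on duplicate ids and on characters outside the declared
    alphabet (gap '-' and the ambiguity codes X/N are allowed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                alphabet=alphabet,
                description=desc,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_gene_table(path) -> list[GeneRow]:
    """Read a tab-separated gene table.

    Expected header: gene_id, chromosome, start, end, strand, exons with
    exons encoded "s1-e1;s2-e2;...". Exons are re-sorted ascending; '#'
    lines are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["gene_id", "chromosome", "start", "end", "strand", "exons"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"gene table missing columns: {missing}")
    rows = []
    for _, row in df.iterrows():
        exons = []
        cell = row["exons"]
        if isinstance(cell, str) and cell.strip():
            for part in cell.split(";"):
                s, _, e = part.partition("-")
                exons.append((int(s), int(e)))
        rows.append(
            GeneRow(
                gene_id=row["gene_id"],
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                exons=tuple(exons),
            )
        )
    return rows


def write_gene_table(genes: Sequence[GeneRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchromosome\tstart\tend\tstrand\texons\n")
        for g in genes:
            exons = ";".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.start}\t{g.end}\t{g.strand}\t{exons}\n")


def read_ct_table(path) -> list[WellRecord]:
    """Read a comma-separated qPCR well table (gene, sample, replicate, ct
    and optional efficiency); '#' lines are skipped."""
    df = pd.read_csv(path, comment="#", dtype=str)
    required = ["gene", "sample", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"ct table missing columns: {missing}")
    wells = []
    for i, row in df.iterrows():
        try:
            ct = float(row["ct"])
        except (TypeError, ValueError):
            raise TableFormatError(f"row {i + 2}: non-numeric ct {row['ct']!r}") from None
        if ct < 0:
            raise TableFormatError(f"row {i + 2}: negative ct {ct}")
        eff = None
        if "efficiency" in df.columns and pd.notna(row.get("efficiency")):
            eff = float(row["efficiency"])
        wells.append(
            WellRecord(
                gene=row["gene"],
                sample=row["sample"],
                replicate=int(row["replicate"]),
                ct=ct,
                efficiency=eff,
            )
        )
    if not wells:
        logger.warning("ct table %s contains a header but no wells", path)
    return wells


def group_wells(wells: Iterable[WellRecord]) -> dict[tuple[str, str], list[WellRecord]]:
    groups: dict[tuple[str, str], list[WellRecord]] = {}
    for w in wells:
        groups.setdefault((w.gene, w.sample), []).append(w)
    return groups


def read_newick(path):
    """Parse a Newick tree file via dendropy (supports as node labels)."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Pipeline configuration; every field has a usable default so a config
    file only needs to override what it cares about."""

    seed: int = 0
    family: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)
    phylo: dict = field(default_factory=dict)
    comparative: dict = field(default_factory=dict)
    promoters: dict = field(default_factory=dict)
    qpcr: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# reporting


def emit_report(results: dict, outdir, config: RunConfig | None = None) -> dict:
    """Write per-stage result tables plus a JSON manifest.

    ``results`` maps stage names to pandas DataFrames (written as TSV) or,
    for the "tree" key, an object with a ``to_newick`` method. Returns the
    manifest dict. Re-running with the same config and seed produces
    byte-identical outputs except for the manifest timestamp.
    """
    if not results:
        raise ValueError("no stage results to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for name in sorted(results):
        obj = results[name]
        if obj is None:
            continue
        if hasattr(obj, "to_newick"):
            fname = f"{name}.nwk"
            (outdir / fname).write_text(obj.to_newick() + "\n")
        elif isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            obj.to_csv(outdir / fname, sep="\t", index=False)
        else:
            fname = f"{name}.json"
            (outdir / fname).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        files.append(fname)
    manifest = {
        "config": config.to_dict() if config is not None else None,
        "seed": config.seed if config is not None else None,
        "files": files,
        "version": _pkg_version,
        "timestamp": datetime.datetime.now().isoformat(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
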