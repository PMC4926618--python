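"""File readers and writers: FASTA with key=value metadata, lineage TSV.

Survey metadata travels inside the FASTA description line as ``key=value``
tokens (``marker=``, ``event=``, ``morph=``), so that one file fully specifies
a survey.  Lineage tables are tab-separated with a header row naming the ranks
in most-inclusive to least-inclusive order and the sequence id in column 1.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import DataError, ParseError
from .records import Lineage, SequenceRecord

_META_KEYS = {"marker": "marker", "event": "event_id", "morph": "morphospecies"}


def read_fasta(path) -> list[SequenceRecord]:
    """Read barcode sequences; the header token before the first whitespace is
    the id, the rest is scanned for ``marker=``, ``event=`` and ``morph=``
    tokens."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise DataError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        meta = _parse_description(bio.description, bio.id)
        records.append(SequenceRecord(id=bio.id, bases=str(bio.seq), **meta))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    return records


def _parse_description(description: str, rec_id: str) -> dict:
    meta: dict = {}
    for token in description.split()[1:]:
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key in _META_KEYS:
            meta[_META_KEYS[key]] = value
    return meta


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio_records = []
    for rec in records:
        parts = []
        if rec.marker:
            parts.append(f"marker={rec.marker}")
        if rec.event_id is not None:
            parts.append(f"event={rec.event_id}")
        if rec.morphospecies is not None:
            parts.append(f"morph={rec.morphospecies}")
        bio_records.append(
            BioSeqRecord(Seq(rec.bases), id=rec.id, description=" ".join(parts))
        )
    SeqIO.write(bio_records, str(path), "fasta")


def read_lineage_table(path) -> dict[str, Lineage]:
    """Tab-separated lineage table: header names the ranks, column 1 is the
    sequence id.  Empty trailing cells truncate the lineage; an empty cell
    followed by a filled one is an error (no rank gaps)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"lineage table not found: {path}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"empty lineage table {path}")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: header must name the id column and >=1 rank")
    rank_names = header[1:]
    out: dict[str, Lineage] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {lineno} has {len(cells)} fields, "
                f"expected {len(header)}"
            )
        rec_id = cells[0].strip()
        if not rec_id:
            raise ParseError(f"{path}: line {lineno} has an empty id")
        if rec_id in out:
            raise DataError(f"{path}: duplicate id {rec_id!r} at line {lineno}")
        taxa = [c.strip() for c in cells[1:]]
        ranks = []
        for rank, taxon in zip(rank_names, taxa):
            if not taxon:
                break
            ranks.append((rank, taxon))
        trailing = taxa[len(ranks):]
        if any(t for t in trailing):
            raise ParseError(
                f"{path}: line {lineno} has a rank gap (empty cell before a "
                f"filled one)"
            )
        out[rec_id] = Lineage(tuple(ranks))
    return out


def write_lineage_table(lineages: dict[str, Lineage], path) -> None:
    rank_names: list[str] = []
    for lin in lineages.values():
        for rank in lin.rank_names:
            if rank not in rank_names:
                rank_names.append(rank)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(rank_names) + "\n")
        for rec_id in sorted(lineages):
            row = dict(lineages[rec_id].ranks)
            fh.write(
                rec_id + "\t"
                + "\t".join(row.get(r, "") for r in rank_names) + "\n"
            )
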