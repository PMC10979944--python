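"""Data model and I/O for genomes, genes, proteins and taxonomy.

Coordinates are 1-based and inclusive throughout (the GFF3 convention);
no half-open intervals are used internally.  Gene order within a contig
(the ``index`` field) is defined by start coordinate regardless of strand:
neighborhood windows are genomic, not transcriptional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping
from urllib.parse import unquote

from Bio import SeqIO

__all__ = [
    "Gene",
    "Protein",
    "TaxonomyRecord",
    "GeneTable",
    "GeneTableError",
    "read_gene_table",
    "write_gene_table",
    "read_fasta",
    "write_fasta",
    "read_taxonomy",
    "write_taxonomy",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

TSV_HEADER = ["gene_id", "genome_id", "contig_id", "start", "end", "strand"]

GTDB_RANK_PREFIXES = ["d__", "p__", "c__", "o__", "f__", "g__", "s__"]


class GeneTableError(ValueError):
    """Raised for malformed gene tables (bad row, duplicate id, bad coords)."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 1-based inclusive genomic coordinates.

    ``index`` is the 0-based rank of the gene by start coordinate within its
    contig; it is the coordinate the neighborhood window operates on.
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    index: int = -1
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GeneTableError(f"gene {self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise GeneTableError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.strand not in {"+", "-"}:
            raise GeneTableError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class Protein:
    """An amino-acid sequence keyed by the identifier of its encoding gene."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TaxonomyRecord:
    """A GTDB-style 7-rank taxonomy string attached to a genome."""

    genome_id: str
    taxonomy: str
    ranks: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        fields = self.taxonomy.split(";")
        if len(fields) != 7:
            raise ValueError(
                f"genome {self.genome_id}: taxonomy must have 7 ranks, got {len(fields)}"
            )
        stripped = []
        for prefix, rank in zip(GTDB_RANK_PREFIXES, fields):
            rank = rank.strip()
            if not rank.startswith(prefix):
                raise ValueError(
                    f"genome {self.genome_id}: rank field {rank!r} lacks prefix {prefix!r}"
                )
            stripped.append(rank[len(prefix):])
        object.__setattr__(self, "ranks", tuple(stripped))

    @property
    def domain(self) -> str:
        return self.ranks[0]

    @property
    def phylum(self) -> str:
        return self.ranks[1]


#: Genes grouped by (genome_id, contig_id), sorted by start with 0-based index.
GeneTable = dict[tuple[str, str], list[Gene]]


def _finalize_table(genes: Iterable[Gene]) -> GeneTable:
    """Group by contig, sort by start, assign 0..n-1 indices, check id uniqueness."""
    table: GeneTable = {}
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise GeneTableError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        table.setdefault((g.genome_id, g.contig_id), []).append(g)
    out: GeneTable = {}
    for key in sorted(table):
        ordered = sorted(table[key], key=lambda g: (g.start, g.end, g.gene_id))
        out[key] = [replace(g, index=i) for i, g in enumerate(ordered)]
    return out


def _iter_data_lines(path: Path):
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            yield lineno, line


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in attr_field.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[unquote(key)] = unquote(value)
    return attrs


def read_gene_table(path: str | Path, format: str = "tsv", genome_id: str | None = None) -> GeneTable:
    """Read genes from a TSV gene table or a GFF3 file (CDS features only).

    Parameters
    ----------
    path:
        Input file.  TSV must carry the header ``gene_id genome_id contig_id
        start end strand``; GFF3 rows of type CDS must carry an ID attribute.
    format:
        ``"tsv"`` or ``"gff3"``.
    genome_id:
        Genome identifier used for GFF3 input (which has no genome column);
        defaults to the file stem.  Ignored for TSV.

    Returns
    -------
    GeneTable
        Genes grouped by (genome_id, contig_id), sorted by start, with
        ``index`` assigned 0..n-1 within each contig.
    """
    path = Path(path)
    if format not in {"tsv", "gff3"}:
        raise ValueError(f"unknown gene table format {format!r}")
    genes: list[Gene] = []
    if format == "tsv":
        lines = _iter_data_lines(path)
        try:
            _, header = next(lines)
        except StopIteration:
            return {}
        cols = header.split("\t")
        if cols[: len(TSV_HEADER)] != TSV_HEADER:
            raise GeneTableError(
                f"{path}:1: expected header {TSV_HEADER}, got {cols}"
            )
        has_label = "label" in cols
        for lineno, line in lines:
            fields = line.split("\t")
            if len(fields) < len(TSV_HEADER):
                raise GeneTableError(f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GeneTableError(f"{path}:{lineno}: non-integer coordinate: {exc}") from None
            label = fields[cols.index("label")] or None if has_label else None
            try:
                genes.append(
                    Gene(fields[0], fields[1], fields[2], start, end, fields[5], label=label)
                )
            except GeneTableError as exc:
                raise GeneTableError(f"{path}:{lineno}: {exc}") from None
    else:
        gid = genome_id if genome_id is not None else path.stem
        for lineno, line in _iter_data_lines(path):
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GeneTableError(f"{path}:{lineno}: GFF3 row has {len(fields)} columns, need 9")
            if fields[2] != "CDS":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GeneTableError(f"{path}:{lineno}: non-integer coordinate") from None
            attrs = _parse_gff3_attributes(fields[8])
            if "ID" not in attrs:
                raise GeneTableError(f"{path}:{lineno}: CDS row lacks an ID attribute")
            try:
                genes.append(
                    Gene(attrs["ID"], gid, fields[0], start, end, fields[6],
                         label=attrs.get("product"))
                )
            except GeneTableError as exc:
                raise GeneTableError(f"{path}:{lineno}: {exc}") from None
    return _finalize_table(genes)


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    """Write a gene table as TSV (inverse of :func:`read_gene_table`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_HEADER + ["label"]) + "\n")
        for key in sorted(table):
            for g in table[key]:
                fh.write(
                    f"{g.gene_id}\t{g.genome_id}\t{g.contig_id}\t{g.start}\t{g.end}"
                    f"\t{g.strand}\t{g.label or ''}\n"
                )


def read_fasta(path: str | Path) -> dict[str, Protein]:
    """Read proteins from FASTA, keyed by identifier, preserving file order.

    Sequences are uppercased and terminal stop characters (``*``) stripped.
    Duplicate identifiers and empty sequences are errors.
    """
    proteins: dict[str, Protein] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        pid = record.id
        if pid in proteins:
            raise ValueError(f"{path}: duplicate FASTA identifier {pid!r}")
        seq = str(record.seq).upper().rstrip("*")
        if not seq:
            raise ValueError(f"{path}: empty sequence for {pid!r}")
        proteins[pid] = Protein(pid, seq)
    return proteins


def write_fasta(proteins: Mapping[str, Protein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins.values():
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyRecord]:
    """Read a two-column TSV (genome_id, GTDB 7-rank taxonomy string)."""
    records: dict[str, TaxonomyRecord] = {}
    for lineno, line in _iter_data_lines(Path(path)):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        gid, tax = fields[0], fields[1]
        try:
            records[gid] = TaxonomyRecord(gid, tax)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_taxonomy(records: Mapping[str, TaxonomyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records.values():
            fh.write(f"{rec.genome_id}\t{rec.taxonomy}\n")
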