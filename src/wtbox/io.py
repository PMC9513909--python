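"""Sequence and annotation I/O plus upstream-window extraction.

Reads the standard formats the pipeline touches (FASTA, GFF3, plain-text gene
lists) into light domain containers, and derives gene-oriented upstream windows
from a genome plus annotation.  Coordinates are 1-based inclusive throughout;
the upstream window of a gene is the ``window`` nucleotides strictly 5' of its
transcription start site (the TSS itself excluded), reverse-complemented for
minus-strand genes so every window reads 5'->3' of the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: residue alphabet after normalisation
ALPHABET = frozenset("ACGTN")

#: IUPAC ambiguity codes collapsed to N on input (real genome FASTA contains
#: them; an unknown/ambiguous subject base never matches a pattern position)
_AMBIGUOUS = set("RYSWKMBDHVU")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceIOError(ValueError):
    """Malformed sequence input (missing/empty file, duplicate ids, ...)."""


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceIOError("sequence record with empty identifier")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceIOError(
                f"record {self.id!r}: residues outside ACGTN: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of uniquely named sequences for one region.

    ``total_nt`` counts only A/C/G/T residues; N is excluded, matching the
    convention that unknown bases contribute neither to composition nor to the
    nucleotide denominator of frequency estimates.
    """

    records: list[SequenceRecord] = field(default_factory=list)
    region_label: str = "genome"
    window_length: int | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceIOError(f"duplicate sequence identifier {rec.id!r}")
            seen.add(rec.id)

    @property
    def total_nt(self) -> int:
        return sum(
            rec.length - rec.residues.count("N") for rec in self.records
        )

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)


@dataclass(frozen=True)
class GeneModel:
    """A gene's location: contig, strand, 1-based TSS, genomic compartment."""

    gene_id: str
    contig_id: str
    strand: str
    tss: int
    compartment: str = "nuclear"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise SequenceIOError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 1:
            raise SequenceIOError(f"gene {self.gene_id!r}: tss must be >= 1")


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Upper-case and collapse non-ACGTN IUPAC codes to N (logged)."""
    up = raw.upper()
    if set(up) <= ALPHABET:
        return up
    n_ambiguous = 0
    out = []
    for ch in up:
        if ch in ALPHABET:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("N")
            n_ambiguous += 1
        else:
            raise SequenceIOError(
                f"record {record_id!r}: invalid residue {ch!r}"
            )
    logger.warning(
        "record %r: %d ambiguous IUPAC residue(s) normalized to N",
        record_id,
        n_ambiguous,
    )
    return "".join(out)


def read_fasta(path: str | Path, region_label: str | None = None) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`, order preserved."""
    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(bio.seq), bio.id)
        if not residues:
            raise SequenceIOError(f"record {bio.id!r} has zero residues")
        records.append(
            SequenceRecord(id=bio.id, residues=residues, description=bio.description)
        )
    if not records:
        raise SequenceIOError(f"no FASTA records in {path}")
    return SequenceSet(records=records, region_label=region_label or path.stem)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    bio_records = [
        _BioSeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
        for rec in seqs.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)


def read_gene_annotation(
    path: str | Path,
    organellar_contigs: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Parse gene features from GFF3 into :class:`GeneModel` objects.

    The TSS is the feature start for plus-strand genes and the feature end for
    minus-strand genes.  ``organellar_contigs`` maps contig ids to a
    compartment label ("plastid"/"mitochondrial"); unmapped contigs are
    nuclear.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"GFF3 file not found: {path}")
    organellar_contigs = dict(organellar_contigs or {})
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises bare ValueError on bad lines
        raise SequenceIOError(f"failed to parse GFF3 {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if not gene_id:
            raise SequenceIOError(f"gene feature without ID at line {feat.start}")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                contig_id=feat.seqid,
                strand=feat.strand,
                tss=feat.start if feat.strand == "+" else feat.end,
                compartment=organellar_contigs.get(feat.seqid, "nuclear"),
            )
        )
    return genes


def filter_nuclear(genes: Iterable[GeneModel]) -> list[GeneModel]:
    """Drop organellar (plastid/mitochondrial) genes, preserving order."""
    genes = list(genes)
    kept = [g for g in genes if g.compartment == "nuclear"]
    removed = len(genes) - len(kept)
    if removed:
        logger.info("filter_nuclear: removed %d organellar gene(s)", removed)
    return kept


def extract_upstream(
    genome: SequenceSet,
    genes: Sequence[GeneModel],
    window: int,
) -> SequenceSet:
    """Extract the ``window`` nt immediately 5' of each gene's TSS.

    Plus strand: genomic interval [tss-window, tss-1].  Minus strand:
    [tss+1, tss+window] reverse-complemented.  Windows are clipped at contig
    ends, so records may be shorter than ``window``.
    """
    if window < 1:
        raise SequenceIOError(f"window must be >= 1, got {window}")
    contigs = {rec.id: rec.residues for rec in genome.records}
    out: list[SequenceRecord] = []
    for gene in genes:
        if gene.contig_id not in contigs:
            raise SequenceIOError(
                f"gene {gene.gene_id!r}: unknown contig {gene.contig_id!r}"
            )
        contig = contigs[gene.contig_id]
        if gene.strand == "+":
            lo = max(1, gene.tss - window)
            hi = gene.tss - 1
            segment = contig[lo - 1 : hi]
        else:
            lo = gene.tss + 1
            hi = min(len(contig), gene.tss + window)
            segment = reverse_complement(contig[lo - 1 : hi])
        out.append(
            SequenceRecord(
                id=gene.gene_id,
                residues=segment,
                description=f"{gene.contig_id}:{lo}-{hi}({gene.strand})",
            )
        )
    return SequenceSet(
        records=out, region_label=f"upstream{window}", window_length=window
    )


def read_gene_list(path: str | Path, label: str | None = None):
    """Read a one-identifier-per-line gene list into a GeneSet.

    Identifiers are upper-cased and de-duplicated (AGI locus codes are
    case-insensitive in practice); blank lines are ignored.
    """
    from .genesets import GeneSet

    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"gene list not found: {path}")
    seen: set[str] = set()
    members: list[str] = []
    n_dup = 0
    for line in path.read_text().splitlines():
        ident = line.strip().upper()
        if not ident:
            continue
        if ident in seen:
            n_dup += 1
            continue
        seen.add(ident)
        members.append(ident)
    if not members:
        raise SequenceIOError(f"gene list {path} is empty after filtering")
    if n_dup:
        logger.info("read_gene_list(%s): %d duplicate identifier(s)", path, n_dup)
    return GeneSet(label=label or path.stem, members=frozenset(members))
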