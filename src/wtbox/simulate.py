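"""Seeded synthetic genomes, annotations, and planted-motif sequences.

Backgrounds are drawn iid at a chosen GC fraction, P(G)=P(C)=gc/2 and
P(A)=P(T)=(1-gc)/2, matching the independent-base null model the enrichment
statistics assume, so a null simulation is exactly null.  Motif copies are
planted at uniform non-overlapping positions over the background; the
returned ground truth lists the planted positions.  Planted copies may still
create incidental extra matches at their boundaries with background bases,
so exact-count assertions should use motifs whose boundaries cannot extend a
match (see :func:`is_non_self_overlapping`).

All generators consume a single ``numpy`` Generator seeded from the config,
in documented order (sequences first, then per-sequence planting), so a seed
fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import GeneModel, SequenceRecord, SequenceSet, reverse_complement
from .motifs import Occurrence

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic run; the seed is recorded in every output."""

    seed: int
    n_sequences: int = 1
    sequence_length: int = 1000
    gc_fraction: float = 0.3262
    planted_motif: str | None = None
    copies_per_sequence: int | None = None
    planting_rate: float | None = None  # expected planted copies per sequence
    n_genes: int = 0
    n_organellar_contigs: int = 0
    genes_per_organellar_contig: int = 2
    window_clearance: int = 500
    region_label: str = "simulated"

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0,1)")
        for name in ("n_sequences", "sequence_length", "n_genes",
                     "n_organellar_contigs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw_residues(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    cum = np.array([at, at + gc / 2.0, at + gc, 1.0])
    idx = np.searchsorted(cum, rng.random(length), side="right")
    return _BASES[idx].tobytes().decode("ascii")


def simulate_sequences(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> SequenceSet:
    """Draw ``n_sequences`` iid background sequences at the config's GC."""
    rng = cfg.rng() if rng is None else rng
    records = [
        SequenceRecord(
            id=f"sim{i + 1}",
            residues=_draw_residues(rng, cfg.sequence_length, cfg.gc_fraction),
            description=f"seed={cfg.seed} gc={cfg.gc_fraction}",
        )
        for i in range(cfg.n_sequences)
    ]
    return SequenceSet(records=records, region_label=cfg.region_label)


def plant_motifs(
    seqs: SequenceSet,
    motif: str,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SequenceSet, list[Occurrence]]:
    """Overwrite background with motif copies at uniform non-overlapping starts.

    The number of copies per sequence is ``cfg.copies_per_sequence`` if set,
    otherwise Poisson with mean ``cfg.planting_rate``.  Raises if the
    requested copies cannot be placed without overlap.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("planted motif must be concrete bases ACGT")
    rng = cfg.rng() if rng is None else rng
    k = len(motif)
    out_records: list[SequenceRecord] = []
    truth: list[Occurrence] = []
    for rec in seqs:
        if k > rec.length:
            raise ValueError(
                f"motif longer than sequence {rec.id!r} ({k} > {rec.length})"
            )
        if cfg.copies_per_sequence is not None:
            n_copies = cfg.copies_per_sequence
        elif cfg.planting_rate is not None:
            n_copies = int(rng.poisson(cfg.planting_rate))
        else:
            raise ValueError("set copies_per_sequence or planting_rate")
        starts = _place_nonoverlapping(rng, rec.length, k, n_copies, rec.id)
        residues = rec.residues
        for s0 in starts:
            residues = residues[:s0] + motif + residues[s0 + k:]
            truth.append(
                Occurrence(
                    sequence_id=rec.id, start=s0 + 1, strand="+",
                    matched_text=motif,
                )
            )
        out_records.append(
            SequenceRecord(id=rec.id, residues=residues,
                           description=rec.description)
        )
    planted = SequenceSet(
        records=out_records,
        region_label=seqs.region_label,
        window_length=seqs.window_length,
    )
    truth.sort(key=lambda o: (o.sequence_id, o.start))
    return planted, truth


def _place_nonoverlapping(
    rng: np.random.Generator, length: int, k: int, n_copies: int, seq_id: str
) -> list[int]:
    """Uniform 0-based starts for n_copies length-k intervals, no overlap."""
    if n_copies == 0:
        return []
    if n_copies * k > length:
        raise ValueError(
            f"cannot place {n_copies} non-overlapping copies of a {k}-mer "
            f"in sequence {seq_id!r} of length {length}"
        )
    placed: list[int] = []
    attempts = 0
    max_attempts = 1000 * n_copies
    while len(placed) < n_copies:
        cand = int(rng.integers(0, length - k + 1))
        if all(abs(cand - p) >= k for p in placed):
            placed.append(cand)
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"failed to place {n_copies} copies without overlap in "
                f"sequence {seq_id!r} after {max_attempts} attempts"
            )
    return sorted(placed)


def is_non_self_overlapping(motif: str) -> bool:
    """True when no proper prefix of the motif equals a suffix.

    For such motifs planted copies cannot chain into extra overlapping
    matches, so count-based ground truth is exact up to incidental
    background hits.
    """
    return not any(motif[:l] == motif[-l:] for l in range(1, len(motif)))


def simulate_genome_with_annotation(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_contigs: int = 1,
) -> tuple[SequenceSet, list[GeneModel]]:
    """Multi-contig genome with genes on both strands plus organellar contigs.

    Nuclear genes are spread evenly over ``n_contigs`` contigs of
    ``cfg.sequence_length`` nt, with at least ``cfg.window_clearance`` nt of
    contig on the upstream side of every TSS; strands alternate +/- in gene
    order.  ``cfg.n_organellar_contigs`` extra contigs carry
    ``cfg.genes_per_organellar_contig`` genes each, compartment alternating
    plastid / mitochondrial by contig.
    """
    rng = cfg.rng() if rng is None else rng
    clearance = cfg.window_clearance
    L = cfg.sequence_length
    if cfg.n_genes > 0:
        per_contig = -(-cfg.n_genes // n_contigs)  # ceil
        needed = 2 * clearance * per_contig
        if needed > L:
            raise ValueError(
                f"contig length {L} cannot host {per_contig} genes with "
                f"window clearance {clearance}"
            )
    records: list[SequenceRecord] = []
    genes: list[GeneModel] = []
    for c in range(n_contigs):
        cid = f"chr{c + 1}"
        records.append(
            SequenceRecord(
                id=cid,
                residues=_draw_residues(rng, L, cfg.gc_fraction),
                description=f"seed={cfg.seed}",
            )
        )
    gi = 0
    for c in range(n_contigs):
        cid = f"chr{c + 1}"
        n_here = min(cfg.n_genes - gi, -(-cfg.n_genes // n_contigs))
        if n_here <= 0:
            continue
        # TSSs evenly spaced, clearance on both sides regardless of strand
        step = (L - 2 * clearance) // max(n_here - 1, 1) if n_here > 1 else 0
        for j in range(n_here):
            tss = clearance + 1 + j * step if n_here > 1 else L // 2
            tss = min(tss, L - clearance)
            strand = "+" if gi % 2 == 0 else "-"
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gi:04d}", contig_id=cid,
                    strand=strand, tss=tss, compartment="nuclear",
                )
            )
    for o in range(cfg.n_organellar_contigs):
        comp = "plastid" if o % 2 == 0 else "mitochondrial"
        cid = f"{comp[:2]}org{o + 1}"
        org_len = max(L, 2 * clearance * max(cfg.genes_per_organellar_contig, 1))
        records.append(
            SequenceRecord(
                id=cid,
                residues=_draw_residues(rng, org_len, cfg.gc_fraction),
                description=f"seed={cfg.seed} compartment={comp}",
            )
        )
        for j in range(cfg.genes_per_organellar_contig):
            gi += 1
            tss = clearance + 1 + j * clearance
            genes.append(
                GeneModel(
                    gene_id=f"ORG{gi:04d}", contig_id=cid,
                    strand="+" if j % 2 == 0 else "-",
                    tss=min(tss, org_len - clearance),
                    compartment=comp,
                )
            )
    genome = SequenceSet(records=records, region_label="simulated_genome")
    return genome, genes


def plant_in_upstream_windows(
    genome: SequenceSet,
    genes: Sequence[GeneModel],
    motif: str,
    offset: int,
) -> SequenceSet:
    """Write a motif on each gene's strand, ``offset`` nt 5' of its TSS.

    Returns a new genome.  ``offset`` is the distance from the TSS to the
    motif's gene-proximal end (so the motif occupies positions
    [-offset-len+1 .. -offset] of the upstream window in gene coordinates).
    """
    motif = motif.upper()
    k = len(motif)
    if offset < 1:
        raise ValueError("offset must be >= 1")
    contigs = {rec.id: rec.residues for rec in genome.records}
    for gene in genes:
        seq = contigs[gene.contig_id]
        if gene.strand == "+":
            end = gene.tss - offset          # 1-based end of motif
            start = end - k + 1
            insert = motif
        else:
            start = gene.tss + offset        # 1-based start of motif (genomic)
            end = start + k - 1
            insert = reverse_complement(motif)
        if start < 1 or end > len(seq):
            raise ValueError(
                f"motif does not fit upstream of gene {gene.gene_id!r}"
            )
        contigs[gene.contig_id] = seq[: start - 1] + insert + seq[end:]
    records = [
        SequenceRecord(id=r.id, residues=contigs[r.id], description=r.description)
        for r in genome.records
    ]
    return SequenceSet(records=records, region_label=genome.region_label)


def write_gff3(
    genes: Sequence[GeneModel],
    contig_lengths: dict[str, int],
    path: str | Path,
    gene_length: int = 100,
) -> None:
    """Write gene features as GFF3 (synthetic fixed-length gene bodies)."""
    lines = ["##gff-version 3"]
    for cid, clen in contig_lengths.items():
        lines.append(f"##sequence-region {cid} 1 {clen}")
    for g in genes:
        if g.strand == "+":
            start, end = g.tss, min(g.tss + gene_length - 1,
                                    contig_lengths[g.contig_id])
        else:
            start, end = max(g.tss - gene_length + 1, 1), g.tss
        lines.append(
            "\t".join(
                [
                    g.contig_id, "wtbox_sim", "gene", str(start), str(end),
                    ".", g.strand, ".", f"ID={g.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
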