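"""Reference parsing: gene models from GTF, intron models with reading-frame
context, and an exact-match self-peptide index built from a proteome FASTA.

Internal coordinates are 0-based half-open throughout; the GTF boundary
converts from 1-based inclusive. "Upstream"/"downstream" always mean 5'/3'
in transcription order, so on the minus strand they are swapped in genomic
coordinates and sequence extraction reverse-complements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
PEPTIDE_LENGTHS = range(8, 12)


@dataclass
class GeneModel:
    """One transcript of one gene.

    exons are genomic intervals (start, end), 0-based half-open, sorted by
    genomic coordinate and non-overlapping. cds intervals are (start, end,
    frame) where frame is the GTF phase of the piece (nt to skip to reach the
    next codon boundary). cds may be empty for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class IntronModel:
    """One intron of one transcript with its flanking exons.

    frame_at_intron_start is the number of leftover coding nucleotides at the
    exon/intron junction (cumulative CDS length 5' of the junction, mod 3), or
    None when the upstream exon's CDS does not reach the junction. upstream_cds
    is the CDS piece inside the upstream exon (genomic coordinates) and
    upstream_cds_entry_phase the cumulative CDS length mod 3 at its 5' end;
    both are None when frame_at_intron_start is None.
    """

    event_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    intron: tuple[int, int]
    upstream_exon: tuple[int, int]
    downstream_exon: tuple[int, int]
    frame_at_intron_start: Optional[int] = None
    upstream_cds: Optional[tuple[int, int]] = None
    upstream_cds_entry_phase: Optional[int] = None

    @property
    def interval_key(self) -> str:
        """Genomic-interval identity used to deduplicate events across transcripts."""
        s, e = self.intron
        return f"{self.chrom}:{s}-{e}:{self.strand}"

    @property
    def length(self) -> int:
        return self.intron[1] - self.intron[0]


def make_event_id(chrom: str, start: int, end: int, strand: str, transcript_id: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}:{transcript_id}"


def interval_key_of(event_id: str) -> str:
    """Strip the transcript qualifier from an event id, leaving chrom:start-end:strand."""
    return event_id.rsplit(":", 1)[0]


def load_annotation(gtf_path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Parse a GTF (Ensembl/Gencode dialect) into per-transcript GeneModels.

    Coordinates are converted from GTF 1-based inclusive to 0-based half-open.
    A missing contig in the FASTA is a hard error; a transcript whose CDS is
    not nested in its exons is skipped with a warning.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = Fasta(str(fasta_path))
    contigs = set(genome.keys())

    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx = feat.attributes.get("transcript_id", [None])[0]
        if tx is None:
            continue
        rec = by_tx.setdefault(
            tx,
            {
                "gene_id": feat.attributes.get("gene_id", [tx])[0],
                "chrom": feat.seqid,
                "strand": feat.strand,
                "exons": [],
                "cds": [],
            },
        )
        start0, end0 = feat.start - 1, feat.end  # GTF 1-based inclusive -> half-open
        if feat.featuretype == "exon":
            rec["exons"].append((start0, end0))
        else:
            frame = int(feat.frame) if feat.frame in ("0", "1", "2") else 0
            rec["cds"].append((start0, end0, frame))

    models: list[GeneModel] = []
    for tx, rec in by_tx.items():
        if not rec["exons"]:
            continue
        if rec["chrom"] not in contigs:
            raise ValueError(f"contig {rec['chrom']!r} referenced by {tx} is absent from FASTA")
        exons = sorted(rec["exons"])
        cds = sorted(rec["cds"])
        nested = all(any(s >= es and e <= ee for es, ee in exons) for s, e, _ in cds)
        if not nested:
            logger.warning("transcript %s has CDS not nested in exons; skipped", tx)
            continue
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tx,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exons,
                cds=cds,
            )
        )
    return models


def extract_introns(gene: GeneModel) -> list[IntronModel]:
    """Return the (n_exons - 1) introns of a transcript in transcription order.

    Adjacent exons with zero gap are skipped with a warning. Reading-frame
    context is attached whenever the upstream (5') exon is coding through the
    junction.
    """
    exons_tx = list(gene.exons) if gene.strand == "+" else list(reversed(gene.exons))
    # CDS pieces in transcription order with cumulative coding length before each
    cds_tx = list(gene.cds) if gene.strand == "+" else list(reversed(gene.cds))
    cum_before: list[int] = []
    cum = 0
    for s, e, _ in cds_tx:
        cum_before.append(cum)
        cum += e - s

    introns: list[IntronModel] = []
    for i in range(len(exons_tx) - 1):
        up, down = exons_tx[i], exons_tx[i + 1]
        if gene.strand == "+":
            gap = (up[1], down[0])
        else:
            gap = (down[1], up[0])
        if gap[1] - gap[0] < 1:
            logger.warning(
                "zero-length gap between exons %s/%s of %s; junction skipped",
                up, down, gene.transcript_id,
            )
            continue

        frame = None
        up_cds = None
        up_phase = None
        for j, (cs, ce, _) in enumerate(cds_tx):
            if cs >= up[0] and ce <= up[1]:
                # CDS must run through the exon's 3' (transcription) end to
                # anchor the extension at the junction
                junction_ok = (ce == up[1]) if gene.strand == "+" else (cs == up[0])
                if junction_ok:
                    up_cds = (cs, ce)
                    up_phase = cum_before[j] % 3
                    frame = (cum_before[j] + (ce - cs)) % 3
                break

        start, end = gap
        introns.append(
            IntronModel(
                event_id=make_event_id(gene.chrom, start, end, gene.strand, gene.transcript_id),
                gene_id=gene.gene_id,
                transcript_id=gene.transcript_id,
                chrom=gene.chrom,
                strand=gene.strand,
                intron=gap,
                upstream_exon=up,
                downstream_exon=down,
                frame_at_intron_start=frame,
                upstream_cds=up_cds,
                upstream_cds_entry_phase=up_phase,
            )
        )
    return introns


def write_intron_bed(introns: Iterable[IntronModel], path: str | Path) -> None:
    """BED6 dump of intron models for inspection (0-based half-open, as BED)."""
    with open(path, "w") as fh:
        for m in introns:
            s, e = m.intron
            fh.write(f"{m.chrom}\t{s}\t{e}\t{m.event_id}\t0\t{m.strand}\n")


@dataclass
class ProteomeIndex:
    """Exact-match membership index of every 8-11-mer in a proteome.

    Windows containing non-standard residues (B, Z, X, U, *, ...) are not
    indexed; queries are case-insensitive over the 20-letter alphabet.
    """

    kmer_sets: dict[int, set[str]]

    def __contains__(self, peptide: str) -> bool:
        pep = peptide.upper()
        return pep in self.kmer_sets.get(len(pep), set())


def build_proteome_index(proteome_fasta: str | Path) -> ProteomeIndex:
    """Index all 8-11-mers over the 20 standard residues from a protein FASTA."""
    kmer_sets: dict[int, set[str]] = {k: set() for k in PEPTIDE_LENGTHS}
    n_records = 0
    for rec in SeqIO.parse(str(proteome_fasta), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        for k in PEPTIDE_LENGTHS:
            for i in range(len(seq) - k + 1):
                window = seq[i : i + k]
                if set(window) <= STANDARD_AA:
                    kmer_sets[k].add(window)
    if n_records == 0:
        raise ValueError(f"no sequences in proteome FASTA {proteome_fasta}")
    return ProteomeIndex(kmer_sets=kmer_sets)
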