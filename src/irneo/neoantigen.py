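"""Neoantigen calling from retained introns.

A retained intron is translated by extending the open reading frame of its
upstream exon through the exon/intron junction with the standard codon table,
stopping at the first in-frame stop codon (or the last complete codon inside
the intron). The translation is segmented into 8-11-mers containing at least
one intron-encoded residue, exact matches to the normal proteome are removed,
and the survivors are scored against the patient's HLA class-I alleles; a
percentile rank score < 2 calls a binder. Per-sample load is the number of
unique binder peptides; the expression-weighted load multiplies each source
event's RPKM by its unique-binder count.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence

import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from pyfaidx import Fasta

from .detection import IRQuantRecord
from .reference import IntronModel, ProteomeIndex, interval_key_of

logger = logging.getLogger(__name__)

_TABLE = unambiguous_dna_by_id[1]  # standard codon table
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = set(_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

MAX_FLANK_AA = 10  # k_max - 1: every junction-spanning 8-11-mer stays reachable
DEFAULT_RANK_CUTOFF = 2.0


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_allele(allele: str) -> str:
    """Canonical 2-field HLA notation: 'HLA-A*02:01' <-> 'A02:01' -> 'HLA-A*02:01'."""
    a = allele.strip().upper().replace("HLA-", "").replace("*", "")
    gene, sep, rest = a.partition(":")
    if not sep:
        raise ValueError(f"cannot parse HLA allele {allele!r}")
    locus = gene.rstrip("0123456789")
    group = gene[len(locus):]
    fields = rest.split(":")
    return f"HLA-{locus}*{int(group):02d}:{int(fields[0]):02d}"


@dataclass
class ExtendedTranslation:
    """Junction-anchored translation of one retained intron.

    exon_flank_aa: up to 10 residues immediately 5' of the junction, in frame,
    encoded entirely by exonic sequence. intron_aa: residues whose codon uses
    >= 1 intronic nucleotide, up to (and excluding) the first in-frame stop.
    """

    event_id: str
    exon_flank_aa: str
    intron_aa: str
    terminated_by_stop: bool


@dataclass(frozen=True)
class NeoPeptide:
    peptide: str
    event_id: str
    n_intronic_residues: int
    is_self: bool = False

    def __post_init__(self) -> None:
        if not (8 <= len(self.peptide) <= 11):
            raise ValueError("peptide length must be 8-11")
        if self.n_intronic_residues < 1:
            raise ValueError("neo-peptide needs >= 1 intron-encoded residue")


@dataclass(frozen=True)
class BindingCall:
    peptide: str
    allele: str
    rank_score: float
    is_binder: bool


@dataclass
class SampleLoad:
    sample_id: str
    neoag_load: int
    weighted_load: float


def _transcription_order_seq(genome: Fasta, chrom: str, start: int, end: int, strand: str) -> str:
    seq = str(genome[chrom][start:end]).upper()
    return seq if strand == "+" else revcomp(seq)


def translate_extension(intron: IntronModel, genome: Fasta) -> Optional[ExtendedTranslation]:
    """ORF-extension translation of a retained intron.

    Returns None (with a log line) when the upstream exon is non-coding, i.e.
    no reading frame anchors the junction. Translation is truncated at the
    first codon containing an ambiguous base.
    """
    if intron.frame_at_intron_start is None or intron.upstream_cds is None:
        logger.info("event %s skipped: non-coding upstream flank", intron.event_id)
        return None

    cds_seq = _transcription_order_seq(
        genome, intron.chrom, intron.upstream_cds[0], intron.upstream_cds[1], intron.strand
    )
    intron_seq = _transcription_order_seq(
        genome, intron.chrom, intron.intron[0], intron.intron[1], intron.strand
    )

    q = intron.upstream_cds_entry_phase or 0
    lc = len(cds_seq)
    p = intron.frame_at_intron_start  # leftover coding nt at the junction
    skip = (3 - q) % 3  # nt of a codon begun in the previous exon
    complete = cds_seq[skip : lc - p]  # codon-aligned, fully exonic

    flank_codons = [complete[i : i + 3] for i in range(0, len(complete), 3)]
    flank_aa = []
    for codon in flank_codons[-MAX_FLANK_AA:]:
        if codon in STOP_CODONS or codon not in CODON_TO_AA:
            flank_aa = []  # annotation anomaly; restart flank after it
            continue
        flank_aa.append(CODON_TO_AA[codon])
    exon_flank_aa = "".join(flank_aa[-MAX_FLANK_AA:])

    ext = cds_seq[lc - p :] + intron_seq
    intron_aa = []
    terminated = False
    for i in range(0, len(ext) - 2, 3):
        codon = ext[i : i + 3]
        if codon in STOP_CODONS:
            terminated = True
            break
        aa = CODON_TO_AA.get(codon)
        if aa is None:  # ambiguous base
            logger.info("event %s: ambiguous codon %s; translation truncated", intron.event_id, codon)
            break
        intron_aa.append(aa)
    return ExtendedTranslation(
        event_id=intron.event_id,
        exon_flank_aa=exon_flank_aa,
        intron_aa="".join(intron_aa),
        terminated_by_stop=terminated,
    )


def enumerate_peptides(
    t: ExtendedTranslation, k_range: Iterable[int] = range(8, 12)
) -> list[NeoPeptide]:
    """All k-mers of flank+intron translation with >= 1 intron-encoded residue,
    deduplicated by (peptide, event)."""
    full = t.exon_flank_aa + t.intron_aa
    f = len(t.exon_flank_aa)
    seen: dict[tuple[str, str], NeoPeptide] = {}
    for k in k_range:
        for i in range(0, len(full) - k + 1):
            n_intronic = max(0, (i + k) - max(i, f))
            if n_intronic < 1:
                continue
            pep = full[i : i + k]
            key = (pep, t.event_id)
            if key not in seen:
                seen[key] = NeoPeptide(pep, t.event_id, n_intronic)
    return list(seen.values())


def filter_self(peptides: Sequence[NeoPeptide], index: ProteomeIndex) -> list[NeoPeptide]:
    """Drop peptides also derivable from the normal proteome (exact match)."""
    out = []
    for p in peptides:
        is_self = p.peptide in index
        if not is_self:
            out.append(replace(p, is_self=False))
    return out


class BindingPredictor(Protocol):
    def rank(self, peptide: str, allele: str) -> float: ...


class SurrogatePredictor:
    """Deterministic stand-in scorer mapping (peptide, allele) to a uniform
    percentile rank in [0, 100) via a seeded cryptographic hash.

    Gives a controlled 2% binder rate at the default cutoff; identical inputs
    always produce identical ranks. Synthetic by construction; it models no
    binding biology.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def rank(self, peptide: str, allele: str) -> float:
        key = f"{self.seed}:{peptide}:{normalize_allele(allele)}".encode()
        digest = hashlib.sha256(key).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64
        return 100.0 * u


class NetMHCpanFileAdapter:
    """Rank lookup backed by NetMHCpan-4.1-style tabular output.

    Expects a tab- or whitespace-separated file with columns containing the
    peptide, allele and EL_Rank (case-insensitive header match). Every
    requested (peptide, allele) pair must be present.
    """

    def __init__(self, path: str | Path):
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower(): c for c in df.columns}
        try:
            pep_c = next(cols[c] for c in cols if "peptide" in c)
            alle_c = next(cols[c] for c in cols if "allele" in c or c == "mhc")
            rank_c = next(cols[c] for c in cols if "el_rank" in c or c == "rank" or "%rank" in c)
        except StopIteration as exc:
            raise ValueError(f"cannot locate peptide/allele/EL_Rank columns in {path}") from exc
        self._ranks: dict[tuple[str, str], float] = {}
        for row in df.itertuples(index=False):
            pep = str(getattr(row, pep_c))
            allele = normalize_allele(str(getattr(row, alle_c)))
            self._ranks[(pep, allele)] = float(getattr(row, rank_c))

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self._ranks)

    def rank(self, peptide: str, allele: str) -> float:
        key = (peptide, normalize_allele(allele))
        if key not in self._ranks:
            raise KeyError(f"no prediction for pair {key}")
        return self._ranks[key]


def predict_binding(
    peptides: Sequence[NeoPeptide],
    alleles: Sequence[str],
    predictor: BindingPredictor,
    rank_cutoff: float = DEFAULT_RANK_CUTOFF,
) -> list[BindingCall]:
    """One call per (unique peptide, allele); binder iff rank < cutoff (strict)."""
    unique_peps = sorted({p.peptide for p in peptides})
    norm_alleles = sorted({normalize_allele(a) for a in alleles})
    missing: list[tuple[str, str]] = []
    calls: list[BindingCall] = []
    for pep in unique_peps:
        for allele in norm_alleles:
            try:
                r = predictor.rank(pep, allele)
            except KeyError:
                missing.append((pep, allele))
                continue
            calls.append(BindingCall(pep, allele, r, r < rank_cutoff))
    if missing:
        raise ValueError(f"missing predictions for {len(missing)} pairs, e.g. {missing[:3]}")
    return calls


def compute_sample_load(
    calls: Sequence[BindingCall],
    quants: Sequence[IRQuantRecord],
    peptides: Sequence[NeoPeptide],
    sample_id: str,
    load_unit: str = "peptide",
    weight_mode: str = "rpkm_x_count",
) -> SampleLoad:
    """Count-based and RPKM-weighted neoantigen load for one sample.

    neoag_load counts unique binder peptides (load_unit='peptide'; the
    'peptide-allele' alternative counts pairs). weighted_load sums, over
    events producing >= 1 binder, RPKM * unique-binder-count
    (weight_mode='rpkm_x_count') or RPKM once per event ('rpkm_per_event').
    A peptide produced by several events contributes to each event's term.
    """
    if load_unit not in ("peptide", "peptide-allele"):
        raise ValueError("load_unit must be 'peptide' or 'peptide-allele'")
    if weight_mode not in ("rpkm_x_count", "rpkm_per_event"):
        raise ValueError("unknown weight_mode")

    binder_peps = {c.peptide for c in calls if c.is_binder}
    if load_unit == "peptide":
        load = len(binder_peps)
    else:
        load = len({(c.peptide, c.allele) for c in calls if c.is_binder})

    pep_to_events: dict[str, set[str]] = {}
    for p in peptides:
        pep_to_events.setdefault(p.peptide, set()).add(interval_key_of(p.event_id))
    rpkm_by_event: dict[str, float] = {}
    for q in quants:
        if q.passes_filters:
            key = interval_key_of(q.event_id)
            rpkm_by_event[key] = max(rpkm_by_event.get(key, 0.0), q.intron_rpkm)

    event_binders: dict[str, set[str]] = {}
    for pep in binder_peps:
        events = pep_to_events.get(pep)
        if not events:
            raise ValueError(f"binder peptide {pep} has no source event (pipeline order violation)")
        for ev in events:
            if ev not in rpkm_by_event:
                raise ValueError(f"binder peptide {pep} traces to unquantified event {ev}")
            event_binders.setdefault(ev, set()).add(pep)

    if weight_mode == "rpkm_x_count":
        weighted = sum(rpkm_by_event[ev] * len(peps) for ev, peps in event_binders.items())
    else:
        weighted = sum(rpkm_by_event[ev] for ev in event_binders)
    return SampleLoad(sample_id=sample_id, neoag_load=load, weighted_load=float(weighted))


def cohort_allele_summary(
    all_calls: Mapping[str, Sequence[BindingCall]],
    genotypes: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per-allele carrier frequency and number of unique presented peptides
    (cohort-wide, unique across carrier samples)."""
    n_samples = len(genotypes)
    carriers: dict[str, set[str]] = {}
    for sample, alleles in genotypes.items():
        for a in alleles:
            carriers.setdefault(normalize_allele(a), set()).add(sample)
    presented: dict[str, set[str]] = {a: set() for a in carriers}
    for sample, calls in all_calls.items():
        for c in calls:
            if c.is_binder and sample in carriers.get(c.allele, set()):
                presented[c.allele].add(c.peptide)
    rows = [
        (a, len(carriers[a]) / n_samples, len(presented[a]))
        for a in sorted(carriers)
    ]
    return pd.DataFrame(rows, columns=["allele", "carrier_frequency", "n_presented_peptides"])


def shared_peptide_frequency(
    per_sample_binders: Sequence[set[str]], threshold: float = 0.05
) -> pd.DataFrame:
    """Fraction of samples carrying each binder peptide; shared iff fraction
    strictly exceeds the threshold."""
    if not per_sample_binders:
        raise ValueError("need >= 1 sample")
    n = len(per_sample_binders)
    tally: dict[str, int] = {}
    for binders in per_sample_binders:
        for pep in binders:
            tally[pep] = tally.get(pep, 0) + 1
    rows = [(pep, cnt / n, cnt / n > threshold) for pep, cnt in sorted(tally.items())]
    return pd.DataFrame(rows, columns=["peptide", "sample_fraction", "shared_flag"])


def read_genotypes(path: str | Path) -> dict[str, list[str]]:
    """Genotype TSV: sample_id <tab> comma-separated allele list."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "alleles"} <= set(df.columns):
        raise ValueError(f"genotype table {path} needs sample_id and alleles columns")
    return {
        str(r.sample_id): [normalize_allele(a) for a in str(r.alleles).split(",")]
        for r in df.itertuples(index=False)
    }
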