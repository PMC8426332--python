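"""Self-contained synthetic cohort generator.

Emulates everything the retention pipeline consumes: a toy genome and GTF
with known reading frames and controlled stop-codon placement inside introns,
a proteome of the annotated CDS translations (so intron-derived peptides are
non-self by construction, except for planted self decoys), per-sample region
counts with planted retained introns and single-clause decoys, a disjointly
planted normal panel, HLA genotypes, and survival times whose hazard depends
on the (future) load group.

Counts model: flanking-exon counts are negative-binomial around base_depth
(clipped below at 12 reads so planted events never fail the exon-count clause
through noise alone); intron counts are then derived deterministically from
the realised flank rates to hit a target TPM ratio, which makes planted /
decoy classification exact. Same seed => byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .detection import RegionCount, write_count_table
from .neoantigen import CODON_TO_AA, STOP_CODONS, SampleLoad, revcomp
from .reference import GeneModel, IntronModel, extract_introns

NON_STOP_CODONS = sorted(set(CODON_TO_AA) - STOP_CODONS)
STOP_LIST = sorted(STOP_CODONS)

DEFAULT_ALLELE_POOL = [
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01", "HLA-A*11:01", "HLA-A*24:02",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01", "HLA-B*40:01", "HLA-B*44:02",
    "HLA-C*03:04", "HLA-C*04:01", "HLA-C*05:01", "HLA-C*07:01", "HLA-C*07:02",
]


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the package's reference
    conditions (20 genes, 50 tumor + 5 normal samples)."""

    seed: int = 0
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_length: tuple[int, int] = (90, 150)  # CDS nt, forced to multiples of 3
    intron_length: tuple[int, int] = (90, 180)
    n_tumor_samples: int = 50
    n_normal_samples: int = 5
    planted_event_fraction: float = 0.3  # mean per-sample fraction of introns retained
    planted_ratio: tuple[float, float] = (0.1, 0.4)
    decoy_ratio: float = 0.01  # unretained introns sit far below the low cutoff
    base_depth: float = 200.0  # mean reads per flanking exon
    nb_dispersion: float = 0.05
    panel_fraction: float = 0.2  # introns planted in the normal panel
    allele_pool: Sequence[str] = field(default_factory=lambda: list(DEFAULT_ALLELE_POOL))
    alleles_per_sample: int = 6
    true_log_hr: float = math.log(2.0)
    censoring_rate: float = 0.3
    baseline_hazard: float = 1.0 / 60.0  # per month
    n_self_decoys: int = 3
    # mix of intron stop-codon placements: immediate stop / short ORF / no stop
    category_weights: tuple[float, float, float] = (0.2, 0.6, 0.2)

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.exons_per_gene < 2:
            raise ValueError("need >= 1 gene with >= 2 exons")
        lo, hi = self.planted_ratio
        if not (0.05 < lo < hi < 0.5):
            raise ValueError("planted_ratio must sit strictly inside (0.05, 0.5)")


@dataclass
class SimReference:
    genome_fasta: Path
    gtf: Path
    proteome_fasta: Path
    genes: list[GeneModel]
    introns: list[IntronModel]
    intron_category: dict[str, str]  # event_id -> immediate | orf | nostop
    self_decoy_peptides: list[str]
    self_decoy_sources: list[tuple[str, str]]  # (event_id, peptide)


@dataclass
class SimCounts:
    tumor_counts: Path
    normal_counts: Path
    genotypes: Path
    genotype_map: dict[str, list[str]]
    planted_by_tumor: dict[str, set[str]]  # sample -> planted interval keys
    panel_truth: set[str]  # interval keys planted in >= 1 normal
    tumor_specific_truth: set[str]
    decoy_clauses: dict[str, str]  # interval key -> violated clause (sample TUM00)


def _random_codons(rng: np.random.Generator, n: int, pool: Sequence[str]) -> str:
    return "".join(rng.choice(pool) for _ in range(n))


def _intron_seq(rng: np.random.Generator, length: int, category: str) -> str:
    n_codons, rem = divmod(length, 3)
    codons: list[str] = []
    if category == "immediate":
        codons.append(str(rng.choice(STOP_LIST)))
        codons.extend(rng.choice(NON_STOP_CODONS) for _ in range(n_codons - 1))
    elif category == "orf":
        k_orf = int(rng.integers(6, min(13, n_codons - 1)))
        codons.extend(rng.choice(NON_STOP_CODONS) for _ in range(k_orf))
        codons.append(str(rng.choice(STOP_LIST)))
        codons.extend(rng.choice(NON_STOP_CODONS) for _ in range(n_codons - k_orf - 1))
    elif category == "nostop":
        codons.extend(rng.choice(NON_STOP_CODONS) for _ in range(n_codons))
    else:
        raise ValueError(category)
    tail = "".join(rng.choice(list("ACGT")) for _ in range(rem))
    return "".join(codons) + tail


def _translate_cds(seq: str) -> str:
    return "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


def make_reference(cfg: SimConfig, out_dir: str | Path) -> SimReference:
    """Write genome FASTA, GTF and proteome FASTA; return models plus truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chrom = "chrS"
    spacer = 200

    genome_parts: list[str] = []
    offset = 0
    genes: list[GeneModel] = []
    intron_category: dict[str, str] = {}
    gtf_lines: list[str] = []

    for g in range(cfg.n_genes):
        gid, tid = f"GENE{g:03d}", f"TX{g:03d}"
        strand = "+" if g % 2 == 0 else "-"
        n_ex = cfg.exons_per_gene
        exon_lens = [
            3 * int(rng.integers(cfg.exon_length[0] // 3, cfg.exon_length[1] // 3 + 1))
            for _ in range(n_ex)
        ]
        intron_lens = [
            int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
            for _ in range(n_ex - 1)
        ]
        cats = [str(rng.choice(["immediate", "orf", "nostop"], p=list(cfg.category_weights)))
                for _ in range(n_ex - 1)]

        # transcription-order sequences; CDS covers every exon, no in-frame stops
        exon_seqs = []
        for i, ln in enumerate(exon_lens):
            seq = _random_codons(rng, ln // 3, NON_STOP_CODONS)
            if i == 0:
                seq = "ATG" + seq[3:]
            exon_seqs.append(seq)
        intron_seqs = [_intron_seq(rng, intron_lens[i], cats[i]) for i in range(n_ex - 1)]

        tx_parts = []
        for i in range(n_ex):
            tx_parts.append(("exon", exon_seqs[i]))
            if i < n_ex - 1:
                tx_parts.append(("intron", intron_seqs[i]))
        tx_seq = "".join(s for _, s in tx_parts)
        gseq = tx_seq if strand == "+" else revcomp(tx_seq)

        spacer_seq = "".join(rng.choice(list("ACGT")) for _ in range(spacer))
        genome_parts.append(spacer_seq)
        offset += spacer
        gene_start = offset
        genome_parts.append(gseq)
        offset += len(gseq)

        # genomic part order: as transcribed on +, reversed on -
        parts_genomic = tx_parts if strand == "+" else list(reversed(tx_parts))
        pos = gene_start
        exon_ivs: list[tuple[int, int]] = []
        intron_ivs: list[tuple[int, int]] = []
        for kind, s in parts_genomic:
            iv = (pos, pos + len(s))
            (exon_ivs if kind == "exon" else intron_ivs).append(iv)
            pos += len(s)
        exon_ivs.sort()

        cds = [(s, e, 0) for s, e in exon_ivs]  # phase 0 everywhere (lengths % 3 == 0)
        gene = GeneModel(gene_id=gid, transcript_id=tid, chrom=chrom, strand=strand,
                         exons=exon_ivs, cds=cds)
        genes.append(gene)
        for iv in exon_ivs:
            gtf_lines.append(
                f"{chrom}\tsim\texon\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t"
                f'gene_id "{gid}"; transcript_id "{tid}";'
            )
            gtf_lines.append(
                f"{chrom}\tsim\tCDS\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t0\t"
                f'gene_id "{gid}"; transcript_id "{tid}";'
            )

        for m, cat in zip(extract_introns(gene), cats):
            intron_category[m.event_id] = cat

    genome_seq = "".join(genome_parts)
    genome_fasta = out / "genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 70):
            fh.write(genome_seq[i : i + 70] + "\n")

    gtf = out / "annotation.gtf"
    gtf.write_text("\n".join(gtf_lines) + "\n")

    introns: list[IntronModel] = []
    for gene in genes:
        introns.extend(extract_introns(gene))

    # proteome = annotated CDS translations (+ optional planted self decoys)
    proteome_records: list[tuple[str, str]] = []
    tx_cds = {}
    for gene in genes:
        exons_tx = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
        seqs = []
        for s, e in exons_tx:
            sub = genome_seq[s:e]
            seqs.append(sub if gene.strand == "+" else revcomp(sub))
        cds_seq = "".join(seqs)
        tx_cds[gene.transcript_id] = cds_seq
        proteome_records.append((f"PROT_{gene.transcript_id}", _translate_cds(cds_seq)))

    decoy_peptides: list[str] = []
    decoy_sources: list[tuple[str, str]] = []
    # pick self decoys from junction translations with enough intronic residues
    from .neoantigen import translate_extension
    if cfg.n_self_decoys > 0:
        genome_acc = _InMemoryGenome({chrom: genome_seq})
        candidates = []
        for m in introns:
            t = translate_extension(m, genome_acc)
            if t is not None and len(t.intron_aa) >= 4 and len(t.exon_flank_aa) >= 5:
                full = t.exon_flank_aa + t.intron_aa
                f = len(t.exon_flank_aa)
                candidates.append((m.event_id, full[f - 5 : f + 4]))  # 9-mer, 4 intronic
        idx = rng.choice(len(candidates), size=min(cfg.n_self_decoys, len(candidates)),
                         replace=False)
        for j, i in enumerate(sorted(int(v) for v in idx)):
            event_id, pep = candidates[i]
            decoy_peptides.append(pep)
            decoy_sources.append((event_id, pep))
            proteome_records.append((f"SELF_DECOY_{j}", pep))

    proteome_fasta = out / "proteome.fa"
    with open(proteome_fasta, "w") as fh:
        for name, seq in proteome_records:
            fh.write(f">{name}\n{seq}\n")

    return SimReference(
        genome_fasta=genome_fasta,
        gtf=gtf,
        proteome_fasta=proteome_fasta,
        genes=genes,
        introns=introns,
        intron_category=intron_category,
        self_decoy_peptides=decoy_peptides,
        self_decoy_sources=decoy_sources,
    )


class _InMemoryGenome:
    """Minimal pyfaidx-compatible accessor over in-memory contig strings."""

    def __init__(self, contigs: dict[str, str]):
        self._contigs = contigs

    def __getitem__(self, chrom: str):
        return _Contig(self._contigs[chrom])

    def keys(self):
        return self._contigs.keys()


class _Contig:
    def __init__(self, seq: str):
        self._seq = seq

    def __getitem__(self, sl):
        return self._seq[sl]


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _sample_counts(
    cfg: SimConfig,
    rng: np.random.Generator,
    introns: Sequence[IntronModel],
    planted: set[str],
    decoys: dict[str, str] | None = None,
) -> list[RegionCount]:
    decoys = decoys or {}
    rows = []
    for m in introns:
        li = m.length
        lu = m.upstream_exon[1] - m.upstream_exon[0]
        ld = m.downstream_exon[1] - m.downstream_exon[0]
        cu = max(_nb_draw(rng, cfg.base_depth, cfg.nb_dispersion), 12)
        cd = max(_nb_draw(rng, cfg.base_depth, cfg.nb_dispersion), 12)
        key = m.interval_key
        clause = decoys.get(key)
        if clause == "count":
            # TPM ratio in range but intron count exactly at the (failing) boundary
            mfr = 50.0 / li
            cu, cd = max(11, round(mfr * lu)), max(11, round(mfr * ld))
            ci = 10
        elif clause == "ratio_low":
            mfr = 400.0 / li
            cu, cd = round(mfr * lu), round(mfr * ld)
            ci = 16  # > 10, ratio ~= 0.04
        elif clause == "ratio_high":
            mfr = (cu / lu + cd / ld) / 2
            ci = round(0.7 * mfr * li)
        elif key in planted:
            mfr = (cu / lu + cd / ld) / 2
            lo = int(math.floor(0.06 * mfr * li))
            hi = int(math.ceil(0.45 * mfr * li))
            if hi <= 11:  # flank coverage too shallow to plant; force the mean depth
                cu = cd = int(round(cfg.base_depth))
                mfr = (cu / lu + cd / ld) / 2
                lo, hi = int(math.floor(0.06 * mfr * li)), int(math.ceil(0.45 * mfr * li))
            target = rng.uniform(*cfg.planted_ratio)
            ci = int(np.clip(round(target * mfr * li), max(11, lo), hi))
        else:
            mfr = (cu / lu + cd / ld) / 2
            ci = round(cfg.decoy_ratio * mfr * li)
        rows.append((m.event_id, int(ci), int(cu), int(cd)))
    lib = sum(ci + cu + cd for _, ci, cu, cd in rows)
    return [
        RegionCount(event_id=e, intron_count=ci, upstream_exon_count=cu,
                    downstream_exon_count=cd, library_size=lib)
        for e, ci, cu, cd in rows
    ]


def make_counts(cfg: SimConfig, reference: SimReference, out_dir: str | Path) -> SimCounts:
    """Per-sample region counts for tumors and normals, plus HLA genotypes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    introns = reference.introns
    keys = [m.interval_key for m in introns]
    n_int = len(keys)

    n_panel = max(1, round(cfg.panel_fraction * n_int))
    panel_keys = set(rng.choice(keys, size=n_panel, replace=False).tolist())

    # each panel event is planted in >= 1 normal sample
    normal_planted: list[set[str]] = [set() for _ in range(cfg.n_normal_samples)]
    for key in sorted(panel_keys):
        members = [i for i in range(cfg.n_normal_samples) if rng.random() < 0.6]
        if not members:
            members = [int(rng.integers(cfg.n_normal_samples))]
        for i in members:
            normal_planted[i].add(key)

    # tumor planting: per-sample retention propensity varies widely so that
    # event counts (and hence loads) spread across the cohort
    planted_by_tumor: dict[str, set[str]] = {}
    decoy_clauses: dict[str, str] = {}
    tumor_counts: dict[str, list[RegionCount]] = {}
    for s in range(cfg.n_tumor_samples):
        sid = f"TUM{s:02d}"
        u = rng.uniform(0.05, 2 * cfg.planted_event_fraction)
        mask = rng.random(n_int) < u
        planted = {keys[i] for i in range(n_int) if mask[i]}
        if not planted:
            planted = {keys[int(rng.integers(n_int))]}
        decoys = {}
        if s == 0:
            free = [k for k in keys if k not in planted and k not in panel_keys]
            if len(free) >= 3:
                decoys = {free[0]: "count", free[1]: "ratio_low", free[2]: "ratio_high"}
                decoy_clauses = dict(decoys)
        planted_by_tumor[sid] = planted
        tumor_counts[sid] = _sample_counts(cfg, rng, introns, planted, decoys)

    normal_counts: dict[str, list[RegionCount]] = {}
    for i in range(cfg.n_normal_samples):
        sid = f"NRM{i:02d}"
        normal_counts[sid] = _sample_counts(cfg, rng, introns, normal_planted[i])

    tumor_tsv = out / "tumor_counts.tsv"
    normal_tsv = out / "normal_counts.tsv"
    write_count_table(tumor_counts, tumor_tsv)
    write_count_table(normal_counts, normal_tsv)

    # HLA genotypes: two alleles per locus drawn with replacement
    by_locus: dict[str, list[str]] = {}
    for a in cfg.allele_pool:
        by_locus.setdefault(a.split("*")[0], []).append(a)
    genotype_map: dict[str, list[str]] = {}
    per_locus = max(1, cfg.alleles_per_sample // max(1, len(by_locus)))
    for sid in tumor_counts:
        alleles: list[str] = []
        for locus in sorted(by_locus):
            alleles.extend(rng.choice(by_locus[locus], size=per_locus, replace=True).tolist())
        genotype_map[sid] = alleles
    genotypes = out / "genotypes.tsv"
    pd.DataFrame(
        {"sample_id": list(genotype_map), "alleles": [",".join(v) for v in genotype_map.values()]}
    ).to_csv(genotypes, sep="\t", index=False)

    tumor_specific = set().union(*planted_by_tumor.values()) - panel_keys
    return SimCounts(
        tumor_counts=tumor_tsv,
        normal_counts=normal_tsv,
        genotypes=genotypes,
        genotype_map=genotype_map,
        planted_by_tumor=planted_by_tumor,
        panel_truth=panel_keys,
        tumor_specific_truth=tumor_specific,
        decoy_clauses=decoy_clauses,
    )


def make_cohort(
    cfg: SimConfig, loads: Sequence[SampleLoad], out_path: str | Path
) -> pd.DataFrame:
    """Clinical table with survival driven by the load group.

    Event times are exponential with hazard h0 * exp(true_log_hr * I(load >
    cohort median)); censoring is an independent exponential calibrated so
    roughly censoring_rate of baseline subjects are censored. Age and sex are
    independent nuisance covariates.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    values = np.array([s.neoag_load for s in loads], dtype=float)
    med = float(np.median(values))
    rows = []
    for s, v in zip(loads, values):
        high = v > med
        rate = cfg.baseline_hazard * math.exp(cfg.true_log_hr if high else 0.0)
        t_event = rng.exponential(1.0 / rate)
        if cfg.censoring_rate > 0:
            c_rate = cfg.baseline_hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
            t_cens = rng.exponential(1.0 / c_rate)
        else:
            t_cens = math.inf
        time = max(min(t_event, t_cens), 0.01)
        event = int(t_event <= t_cens)
        age = float(np.round(rng.normal(65, 8), 1))
        sex = "M" if rng.random() < 0.55 else "F"
        rows.append((s.sample_id, round(time, 3), event, age, sex))
    df = pd.DataFrame(rows, columns=["sample_id", "os_months", "os_event", "age", "sex"])
    df.to_csv(out_path, sep="\t", index=False)
    return df
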