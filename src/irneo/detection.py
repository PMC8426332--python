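"""Intron-retention event detection from region-level read support.

For every intron we track read counts over three regions — the intron itself
and its two flanking exons — then normalise to region-level TPM over the
universe of all intron and flanking-exon regions, and call an intron retained
in a sample when

  * intron, upstream-exon and downstream-exon counts are all > 10 (strict), and
  * the TPM ratio intron / flanking-exons lies strictly between 0.05 and 0.5.

Events seen in any healthy control sample under the same filters form the
normal panel and are subtracted to leave tumor-specific events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .reference import IntronModel, interval_key_of

logger = logging.getLogger(__name__)


@dataclass
class RegionCount:
    """Raw read counts for one intron event in one sample."""

    event_id: str
    intron_count: int
    upstream_exon_count: int
    downstream_exon_count: int
    library_size: int

    def __post_init__(self) -> None:
        for c in (self.intron_count, self.upstream_exon_count, self.downstream_exon_count):
            if c < 0:
                raise ValueError("region counts must be non-negative")


@dataclass
class IRQuantRecord:
    """Per-sample, per-intron normalised quantities and filter verdict."""

    event_id: str
    sample_id: str
    intron_tpm: float
    flank_tpm: float
    tpm_ratio: float  # NaN when flank_tpm == 0
    intron_rpkm: float
    passes_filters: bool = False


@dataclass
class FilterConfig:
    """Retention-call thresholds; all inequalities are strict."""

    min_region_count: int = 10
    ratio_low: float = 0.05
    ratio_high: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.ratio_low < self.ratio_high):
            raise ValueError("require 0 <= ratio_low < ratio_high")


def count_regions(
    bam_path: str | Path,
    introns: Sequence[IntronModel],
    mapq_unique: int = 255,
) -> list[RegionCount]:
    """Count uniquely-mapped reads overlapping each intron and flanking exon.

    A read contributes to a region when any aligned block (CIGAR M/=/X)
    overlaps it by >= 1 bp, so a spliced read whose N gap spans the whole
    intron does not count toward that intron. Uniqueness is MAPQ >=
    mapq_unique, or NH:i:1 when the NH tag is present. library_size is the
    number of unique reads that contributed to at least one region.
    """
    bam = pysam.AlignmentFile(str(bam_path), "rb")
    if not bam.has_index():
        raise ValueError(f"BAM {bam_path} is not indexed")
    bam_contigs = set(bam.references)
    needed = {m.chrom for m in introns}
    missing = sorted(needed - bam_contigs)
    if missing:
        raise ValueError(f"contigs in annotation absent from BAM: {missing}")

    # region id -> running count; regions keyed (event_id, role)
    counts: dict[tuple[str, str], int] = {}
    trees: dict[str, IntervalTree] = {}
    for m in introns:
        for role, (s, e) in (
            ("intron", m.intron),
            ("up", m.upstream_exon),
            ("down", m.downstream_exon),
        ):
            counts[(m.event_id, role)] = 0
            trees.setdefault(m.chrom, IntervalTree()).addi(s, e, (m.event_id, role))

    library_size = 0
    for read in bam.fetch(until_eof=True):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        unique = read.mapping_quality >= mapq_unique
        if read.has_tag("NH"):
            unique = read.get_tag("NH") == 1
        if not unique:
            continue
        tree = trees.get(read.reference_name)
        if tree is None:
            continue
        hit_regions: set[tuple[str, str]] = set()
        for bs, be in read.get_blocks():
            for iv in tree.overlap(bs, be):
                hit_regions.add(iv.data)
        if hit_regions:
            library_size += 1
            for key in hit_regions:
                counts[key] += 1
    bam.close()

    return [
        RegionCount(
            event_id=m.event_id,
            intron_count=counts[(m.event_id, "intron")],
            upstream_exon_count=counts[(m.event_id, "up")],
            downstream_exon_count=counts[(m.event_id, "down")],
            library_size=library_size,
        )
        for m in introns
    ]


def region_lengths_of(introns: Iterable[IntronModel]) -> dict[str, tuple[int, int, int]]:
    """event_id -> (intron, upstream-exon, downstream-exon) lengths in bp."""
    out = {}
    for m in introns:
        out[m.event_id] = (
            m.intron[1] - m.intron[0],
            m.upstream_exon[1] - m.upstream_exon[0],
            m.downstream_exon[1] - m.downstream_exon[0],
        )
    return out


def compute_region_tpm(
    counts: Sequence[RegionCount],
    region_lengths: Mapping[str, tuple[int, int, int]],
    sample_id: str,
    flank_agg: str = "mean",
) -> list[IRQuantRecord]:
    """Region-level TPM over the intron + flanking-exon universe, plus RPKM.

    rate_r = count_r / length_r for every region; TPM_r = rate_r / sum(rates)
    * 1e6. flank_tpm aggregates the two flanking-exon TPMs by ``mean``
    (default) or ``min``. intron_rpkm = count / (len_kb * library_size / 1e6).
    A sample with zero total rate yields NaN TPMs and failing records.
    """
    if flank_agg not in ("mean", "min"):
        raise ValueError("flank_agg must be 'mean' or 'min'")
    rates = []
    for rc in counts:
        li, lu, ld = region_lengths[rc.event_id]
        for c, ln in ((rc.intron_count, li), (rc.upstream_exon_count, lu), (rc.downstream_exon_count, ld)):
            if ln <= 0:
                raise ValueError(f"non-positive region length for {rc.event_id}")
            rates.append(c / ln)
    total_rate = float(np.sum(rates))
    if total_rate == 0:
        logger.warning("sample %s has zero counts over the region universe", sample_id)

    records = []
    for rc in counts:
        li, lu, ld = region_lengths[rc.event_id]
        if total_rate == 0:
            records.append(
                IRQuantRecord(rc.event_id, sample_id, np.nan, np.nan, np.nan, 0.0, False)
            )
            continue
        tpm_i = rc.intron_count / li / total_rate * 1e6
        tpm_u = rc.upstream_exon_count / lu / total_rate * 1e6
        tpm_d = rc.downstream_exon_count / ld / total_rate * 1e6
        flank = (tpm_u + tpm_d) / 2 if flank_agg == "mean" else min(tpm_u, tpm_d)
        ratio = tpm_i / flank if flank > 0 else np.nan
        rpkm = (
            rc.intron_count / ((li / 1e3) * (rc.library_size / 1e6))
            if rc.library_size > 0
            else 0.0
        )
        records.append(IRQuantRecord(rc.event_id, sample_id, tpm_i, flank, ratio, rpkm))
    return records


def apply_ir_filters(
    record: IRQuantRecord, raw: RegionCount, cfg: FilterConfig | None = None
) -> IRQuantRecord:
    """Set passes_filters per the strict count and TPM-ratio clauses."""
    cfg = cfg or FilterConfig()
    counts_ok = (
        raw.intron_count > cfg.min_region_count
        and raw.upstream_exon_count > cfg.min_region_count
        and raw.downstream_exon_count > cfg.min_region_count
    )
    ratio_ok = (
        np.isfinite(record.tpm_ratio)
        and cfg.ratio_low < record.tpm_ratio < cfg.ratio_high
    )
    return replace(record, passes_filters=bool(counts_ok and ratio_ok))


def quantify_and_filter(
    counts: Sequence[RegionCount],
    region_lengths: Mapping[str, tuple[int, int, int]],
    sample_id: str,
    cfg: FilterConfig | None = None,
    flank_agg: str = "mean",
) -> list[IRQuantRecord]:
    """Convenience: TPM/RPKM then filters, in one pass."""
    recs = compute_region_tpm(counts, region_lengths, sample_id, flank_agg=flank_agg)
    return [apply_ir_filters(r, rc, cfg) for r, rc in zip(recs, counts)]


def call_sample_events(records: Sequence[IRQuantRecord], dedupe: bool = True) -> set[str]:
    """Event set of one sample: ids passing filters, deduplicated by genomic
    interval when dedupe is set (returns interval keys then, event ids otherwise)."""
    passing = [r.event_id for r in records if r.passes_filters]
    if dedupe:
        return {interval_key_of(e) for e in passing}
    return set(passing)


def build_normal_panel(
    normal_samples: Sequence[Sequence[IRQuantRecord]], dedupe: bool = True
) -> set[str]:
    """Union of passing event sets over healthy control samples (membership in
    at least one control puts an event in the panel)."""
    if not normal_samples:
        logger.warning("building normal panel from zero samples: empty panel")
        return set()
    panel: set[str] = set()
    for records in normal_samples:
        panel |= call_sample_events(records, dedupe=dedupe)
    return panel


def subtract_normal(tumor_events: set[str], panel: set[str]) -> set[str]:
    """Tumor-specific events: set difference against the normal panel."""
    return set(tumor_events) - set(panel)


# ---------------------------------------------------------------------------
# Count-table I/O: a TSV path into the pipeline that bypasses BAM counting.

COUNT_COLUMNS = [
    "sample_id",
    "event_id",
    "intron_count",
    "upstream_exon_count",
    "downstream_exon_count",
    "library_size",
]


def write_count_table(counts_by_sample: Mapping[str, Sequence[RegionCount]], path: str | Path) -> None:
    rows = []
    for sample_id, counts in counts_by_sample.items():
        for rc in counts:
            rows.append(
                (sample_id, rc.event_id, rc.intron_count, rc.upstream_exon_count,
                 rc.downstream_exon_count, rc.library_size)
            )
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> dict[str, list[RegionCount]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} missing columns: {sorted(missing)}")
    out: dict[str, list[RegionCount]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample_id), []).append(
            RegionCount(
                event_id=row.event_id,
                intron_count=int(row.intron_count),
                upstream_exon_count=int(row.upstream_exon_count),
                downstream_exon_count=int(row.downstream_exon_count),
                library_size=int(row.library_size),
            )
        )
    return out


def quant_table(records: Sequence[IRQuantRecord]) -> pd.DataFrame:
    """Flatten quant records for TSV export."""
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in records],
            "sample_id": [r.sample_id for r in records],
            "intron_tpm": [r.intron_tpm for r in records],
            "flank_tpm": [r.flank_tpm for r in records],
            "tpm_ratio": [r.tpm_ratio for r in records],
            "intron_rpkm": [r.intron_rpkm for r in records],
            "passes_filters": [r.passes_filters for r in records],
        }
    )
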