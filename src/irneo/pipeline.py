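"""End-to-end orchestration: detect -> subtract -> translate -> enumerate ->
self-filter -> bind -> load -> stats, with a provenance manifest.

The pipeline is a plain function over a validated config so the CLI stays a
thin wrapper and every stage remains individually importable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .detection import (
    FilterConfig,
    build_normal_panel,
    call_sample_events,
    quant_table,
    quantify_and_filter,
    read_count_table,
    region_lengths_of,
    subtract_normal,
)
from .neoantigen import (
    NetMHCpanFileAdapter,
    SampleLoad,
    SurrogatePredictor,
    compute_sample_load,
    enumerate_peptides,
    filter_self,
    predict_binding,
    read_genotypes,
    translate_extension,
)
from .reference import build_proteome_index, extract_introns, interval_key_of, load_annotation
from .survival import (
    cox_fit,
    dichotomize_load,
    km_estimate,
    logrank_test,
    read_clinical_table,
)

logger = logging.getLogger(__name__)

STAGES = ["detect", "subtract", "translate", "enumerate", "self_filter", "bind", "load", "stats"]


@dataclass
class PipelineConfig:
    annotation: Path
    genome: Path
    proteome: Path
    tumor_counts: Path
    genotypes: Path
    normal_counts: Optional[Path] = None
    clinical: Optional[Path] = None
    predictor: str = "surrogate:0"  # or netmhcpan-file:<path>
    filters: FilterConfig = field(default_factory=FilterConfig)
    rank_cutoff: float = 2.0
    load_unit: str = "peptide"
    weight_mode: str = "rpkm_x_count"
    flank_agg: str = "mean"
    dedupe: bool = True
    seed: int = 0
    out_dir: Path = Path("irneo_out")
    cox_covariates: tuple[str, ...] = ("age", "sex")

    def __post_init__(self) -> None:
        for name in ("annotation", "genome", "proteome", "tumor_counts", "genotypes",
                     "normal_counts", "clinical", "out_dir"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    def validate(self) -> None:
        for name in ("annotation", "genome", "proteome", "tumor_counts", "genotypes",
                     "normal_counts", "clinical"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if not (self.predictor.startswith("surrogate:")
                or self.predictor.startswith("netmhcpan-file:")):
            raise ValueError(f"unknown predictor spec {self.predictor!r}")

    def parameter_hash(self) -> str:
        d = dataclasses.asdict(self)
        d = {k: str(v) for k, v in sorted(d.items())}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _make_predictor(spec: str, seed: int):
    kind, _, arg = spec.partition(":")
    if kind == "surrogate":
        return SurrogatePredictor(seed=int(arg) if arg else seed)
    if kind == "netmhcpan-file":
        return NetMHCpanFileAdapter(arg)
    raise ValueError(f"unknown predictor spec {spec!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; write per-stage outputs and return the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameter_hash": cfg.parameter_hash(),
        "inputs": {k: str(getattr(cfg, k)) for k in
                   ("annotation", "genome", "proteome", "tumor_counts", "normal_counts",
                    "genotypes", "clinical")},
        "stages": {},
    }

    genes = load_annotation(cfg.annotation, cfg.genome)
    introns = [m for g in genes for m in extract_introns(g)]
    lengths = region_lengths_of(introns)
    genome = Fasta(str(cfg.genome))
    genotypes = read_genotypes(cfg.genotypes)

    # ---- detect: quantify + filter every sample -----------------------------
    tumor_counts = read_count_table(cfg.tumor_counts)
    tumor_quants = {
        sid: quantify_and_filter(counts, lengths, sid, cfg.filters, cfg.flank_agg)
        for sid, counts in tumor_counts.items()
    }
    pd.concat([quant_table(v) for v in tumor_quants.values()]).to_csv(
        out / "ir_quant.tsv", sep="\t", index=False
    )
    tumor_events = {sid: call_sample_events(q, dedupe=cfg.dedupe) for sid, q in tumor_quants.items()}
    manifest["stages"]["detect"] = sum(len(v) for v in tumor_events.values())
    logger.info("detect: %d passing events across %d tumor samples",
                manifest["stages"]["detect"], len(tumor_events))

    # ---- subtract: normal panel ---------------------------------------------
    if cfg.normal_counts is not None:
        normal_counts = read_count_table(cfg.normal_counts)
        normal_quants = [
            quantify_and_filter(counts, lengths, sid, cfg.filters, cfg.flank_agg)
            for sid, counts in normal_counts.items()
        ]
        panel = build_normal_panel(normal_quants, dedupe=cfg.dedupe)
    else:
        panel = set()
    specific = {sid: subtract_normal(ev, panel) for sid, ev in tumor_events.items()}
    manifest["stages"]["subtract"] = sum(len(v) for v in specific.values())
    with open(out / "events.json", "w") as fh:
        json.dump({sid: sorted(ev) for sid, ev in specific.items()}, fh, indent=1)

    # ---- translate + enumerate + self-filter (once per unique event) --------
    needed = set().union(*specific.values()) if specific else set()
    by_key: dict[str, list] = {}
    for m in introns:
        if m.interval_key in needed:
            by_key.setdefault(m.interval_key, []).append(m)
    translations = {}
    for key, models in sorted(by_key.items()):
        t = translate_extension(models[0], genome)
        if t is not None:
            translations[key] = t
    manifest["stages"]["translate"] = len(translations)

    peptides_by_key = {key: enumerate_peptides(t) for key, t in translations.items()}
    manifest["stages"]["enumerate"] = sum(len(v) for v in peptides_by_key.values())

    index = build_proteome_index(cfg.proteome)
    nonself_by_key = {key: filter_self(p, index) for key, p in peptides_by_key.items()}
    manifest["stages"]["self_filter"] = sum(len(v) for v in nonself_by_key.values())

    # ---- bind + load per sample ----------------------------------------------
    predictor = _make_predictor(cfg.predictor, cfg.seed)
    loads: list[SampleLoad] = []
    neo_rows = []
    all_calls = {}
    n_binder_calls = 0
    for sid in sorted(tumor_counts):
        sample_keys = specific[sid]
        sample_peps = [p for key in sample_keys for p in nonself_by_key.get(key, [])]
        alleles = genotypes.get(sid, [])
        if sample_peps and alleles:
            calls = predict_binding(sample_peps, alleles, predictor, cfg.rank_cutoff)
        else:
            calls = []
        all_calls[sid] = calls
        n_binder_calls += sum(c.is_binder for c in calls)
        load = compute_sample_load(
            calls, tumor_quants[sid], sample_peps, sid,
            load_unit=cfg.load_unit, weight_mode=cfg.weight_mode,
        )
        loads.append(load)
        pep_events = {}
        for p in sample_peps:
            pep_events.setdefault(p.peptide, interval_key_of(p.event_id))
        for c in calls:
            if c.is_binder:
                neo_rows.append((sid, c.peptide, pep_events[c.peptide], c.allele, c.rank_score))
    manifest["stages"]["bind"] = n_binder_calls
    pd.DataFrame(
        neo_rows, columns=["sample_id", "peptide", "event", "allele", "rank_score"]
    ).to_csv(out / "neoantigens.tsv", sep="\t", index=False)
    loads_df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in loads],
            "neoag_load": [s.neoag_load for s in loads],
            "weighted_load": [s.weighted_load for s in loads],
        }
    )
    loads_df.to_csv(out / "loads.tsv", sep="\t", index=False)
    manifest["stages"]["load"] = len(loads)

    # ---- stats ----------------------------------------------------------------
    stats_out: dict = {}
    if cfg.clinical is not None:
        records = read_clinical_table(cfg.clinical)
        by_id = {s.sample_id: s for s in loads}
        records = [r for r in records if r.sample_id in by_id]
        for field_name, tag in (("neoag_load", "count"), ("weighted_load", "weighted")):
            groups = dichotomize_load([by_id[r.sample_id] for r in records], field_name)
            for r in records:
                r.load_group = groups[r.sample_id]
            high = [r for r in records if r.load_group == "high"]
            low = [r for r in records if r.load_group == "low"]
            chi2, p = logrank_test(high, low)
            km_estimate(high).to_csv(out / f"km_high_{tag}.tsv", sep="\t", index=False)
            km_estimate(low).to_csv(out / f"km_low_{tag}.tsv", sep="\t", index=False)
            uni = cox_fit(records, ["load_group"])
            stats_out[tag] = {
                "logrank_chi2": chi2,
                "logrank_p": p,
                "cox_univariate": uni.coefficients["load_group[high]"],
            }
            if tag == "count":
                covs = ["load_group"] + [
                    c for c in cfg.cox_covariates if c in records[0].covariates
                ]
                if len(covs) > 1:
                    multi = cox_fit(records, covs)
                    stats_out["cox_multivariate"] = multi.coefficients
        with open(out / "stats.json", "w") as fh:
            json.dump(stats_out, fh, indent=1, default=float)
    manifest["stages"]["stats"] = len(stats_out)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def simulate_study(cfg, out_dir: str | Path):
    """Generate a full synthetic study: reference, counts, genotypes, and a
    clinical table whose hazard follows the realised load groups.

    Returns (SimReference, SimCounts, clinical_path, loads_df, manifest).
    """
    from .simulate import SimConfig, make_cohort, make_counts, make_reference

    out = Path(out_dir)
    ref = make_reference(cfg, out)
    counts = make_counts(cfg, ref, out)
    pcfg = PipelineConfig(
        annotation=ref.gtf,
        genome=ref.genome_fasta,
        proteome=ref.proteome_fasta,
        tumor_counts=counts.tumor_counts,
        normal_counts=counts.normal_counts,
        genotypes=counts.genotypes,
        clinical=None,
        predictor=f"surrogate:{cfg.seed}",
        seed=cfg.seed,
        out_dir=out / "pipeline",
    )
    run_pipeline(pcfg)
    loads_df = pd.read_csv(out / "pipeline" / "loads.tsv", sep="\t")
    loads = [
        SampleLoad(r.sample_id, int(r.neoag_load), float(r.weighted_load))
        for r in loads_df.itertuples(index=False)
    ]
    clinical = out / "clinical.tsv"
    make_cohort(cfg, loads, clinical)
    pcfg.clinical = clinical
    manifest = run_pipeline(pcfg)
    return ref, counts, clinical, loads_df, manifest
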