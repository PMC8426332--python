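"""ORF-extension translation, peptide enumeration, self-filter, binding, loads."""

import numpy as np
import pytest

from irneo.detection import IRQuantRecord
from irneo.neoantigen import (
    ExtendedTranslation,
    NeoPeptide,
    NetMHCpanFileAdapter,
    SurrogatePredictor,
    cohort_allele_summary,
    compute_sample_load,
    enumerate_peptides,
    filter_self,
    normalize_allele,
    predict_binding,
    shared_peptide_frequency,
    translate_extension,
)
from irneo.reference import GeneModel, ProteomeIndex, extract_introns
from irneo.simulate import _InMemoryGenome


def gene_and_genome(exon1, intron, exon2, strand="+"):
    """Build a two-exon gene whose full exons are CDS, plus its genome."""
    tx = exon1 + intron + exon2
    if strand == "+":
        seq = tx
        e1 = (0, len(exon1))
        iv = (len(exon1), len(exon1) + len(intron))
        e2 = (iv[1], iv[1] + len(exon2))
    else:
        from irneo.neoantigen import revcomp
        seq = revcomp(tx)
        n = len(tx)
        e1 = (n - len(exon1), n)
        iv = (n - len(exon1) - len(intron), n - len(exon1))
        e2 = (0, iv[0])
    exons = sorted([e1, e2])
    cds = [(s, e, 0) for s, e in exons]
    g = GeneModel("g", "t", "c", strand, exons=exons, cds=cds)
    return extract_introns(g)[0], _InMemoryGenome({"c": seq})


class TestTranslateExtension:
    def test_standard_code_through_junction(self):
        # CDS ends ...GCT AAG; intron begins GGG TGA ...
        m, genome = gene_and_genome("ATGGCTAAG", "GGGTGACCC", "ATGATGATG")
        t = translate_extension(m, genome)
        assert t.exon_flank_aa.endswith("AK")
        assert t.intron_aa == "G"
        assert t.terminated_by_stop is True

    def test_minus_strand_matches_plus(self):
        plus, gplus = gene_and_genome("ATGGCTAAG", "GGGTGACCC", "ATGATGATG", "+")
        minus, gminus = gene_and_genome("ATGGCTAAG", "GGGTGACCC", "ATGATGATG", "-")
        tp = translate_extension(plus, gplus)
        tm = translate_extension(minus, gminus)
        assert (tp.exon_flank_aa, tp.intron_aa, tp.terminated_by_stop) == (
            tm.exon_flank_aa, tm.intron_aa, tm.terminated_by_stop
        )

    def test_immediate_stop_gives_empty_extension(self):
        m, genome = gene_and_genome("ATGGCTAAG", "TAACCCGGG", "ATGATGATG")
        t = translate_extension(m, genome)
        assert t.intron_aa == ""
        assert t.terminated_by_stop is True

    def test_no_stop_translates_floor_length_over_three(self):
        # 10 nt intron, no stop codon in frame: 3 residues, not terminated
        m, genome = gene_and_genome("ATGGCTAAG", "GGGCCCAAAG", "ATGATGATG")
        t = translate_extension(m, genome)
        assert len(t.intron_aa) == 3
        assert t.terminated_by_stop is False

    def test_nonzero_junction_phase_spans_exon_intron(self):
        # CDS length 10: leftover C joins the first two intron nt (C+GG = Arg)
        m, genome = gene_and_genome("ATGGCTAAGC", "GGTGACCCGG", "ATGATGATG")
        assert m.frame_at_intron_start == 1
        t = translate_extension(m, genome)
        assert t.exon_flank_aa == "MAK"  # only complete exonic codons
        assert t.intron_aa[0] == "R"  # junction codon counts as intron-encoded
        assert t.terminated_by_stop is True  # TGA right after

    def test_noncoding_flank_skipped(self):
        g = GeneModel("g", "t", "c", "+", exons=[(0, 9), (18, 27)])
        m = extract_introns(g)[0]
        genome = _InMemoryGenome({"c": "A" * 27})
        assert translate_extension(m, genome) is None

    def test_ambiguous_base_truncates(self):
        m, genome = gene_and_genome("ATGGCTAAG", "GGGNCCAAAG", "ATGATGATG")
        t = translate_extension(m, genome)
        assert t.intron_aa == "G"  # stops before the N codon
        assert t.terminated_by_stop is False

    def test_flank_capped_at_ten_residues(self):
        exon = "ATG" + "GCT" * 20  # 21 codons
        m, genome = gene_and_genome(exon, "GGGTGACCC", "ATGATGATG")
        t = translate_extension(m, genome)
        assert len(t.exon_flank_aa) == 10


def brute_force_windows(t, k_range=range(8, 12)):
    full = t.exon_flank_aa + t.intron_aa
    f = len(t.exon_flank_aa)
    out = set()
    for k in k_range:
        for i in range(len(full) - k + 1):
            if any(j >= f for j in range(i, i + k)):
                out.add(full[i : i + k])
    return out


def closed_form_total(f, m):
    return sum(max(0, f + m - k + 1) - max(0, f - k + 1) for k in range(8, 12))


class TestEnumerate:
    def test_worked_case_flank10_intron5_yields_20(self):
        t = ExtendedTranslation("e", "ACDEFGHIKL", "MNPQR", True)
        peps = enumerate_peptides(t)
        assert len(peps) == 20
        assert {len(p.peptide) for p in peps} == {8, 9, 10, 11}
        assert all(p.n_intronic_residues >= 1 for p in peps)

    def test_no_intronic_residue_yields_nothing(self):
        t = ExtendedTranslation("e", "ACDEFGHIKL", "", False)
        assert enumerate_peptides(t) == []

    def test_pure_intronic_eightmer_single_window(self):
        t = ExtendedTranslation("e", "", "ACDEFGHI", False)
        peps = enumerate_peptides(t)
        assert len(peps) == 1
        assert peps[0].peptide == "ACDEFGHI"
        assert peps[0].n_intronic_residues == 8

    def test_matches_bruteforce_and_closed_form_on_random_translations(self):
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(200):
            f = int(rng.integers(0, 11))
            m = int(rng.integers(0, 31))
            # distinct-ish random residues; duplicates possible and fine for set compare
            flank = "".join(rng.choice(aas, size=f))
            intro = "".join(rng.choice(aas, size=m))
            t = ExtendedTranslation("e", flank, intro, True)
            peps = {p.peptide for p in enumerate_peptides(t)}
            assert peps == brute_force_windows(t)
            # closed form counts windows (positions), matching when all windows distinct
            n_windows = sum(
                1
                for k in range(8, 12)
                for i in range(len(flank + intro) - k + 1)
                if i + k > f
            )
            assert n_windows == closed_form_total(f, m)


class TestSelfFilter:
    INDEX = ProteomeIndex(kmer_sets={8: {"ACDEFGHI"}, 9: set(), 10: set(), 11: set()})

    def test_exact_hit_removed_near_miss_kept(self):
        peps = [
            NeoPeptide("ACDEFGHI", "e", 2),
            NeoPeptide("ACDEFGHK", "e", 2),  # one residue off
        ]
        kept = filter_self(peps, self.INDEX)
        assert [p.peptide for p in kept] == ["ACDEFGHK"]

    def test_idempotent_and_order_independent(self):
        peps = [NeoPeptide("ACDEFGHI", "e", 1), NeoPeptide("MNPQRSTV", "e", 1)]
        once = filter_self(peps, self.INDEX)
        assert filter_self(once, self.INDEX) == once
        assert filter_self(list(reversed(peps)), self.INDEX) == list(reversed(once))

    def test_empty_input(self):
        assert filter_self([], self.INDEX) == []


class TestBinding:
    def test_surrogate_deterministic(self):
        p = SurrogatePredictor(seed=3)
        r1 = p.rank("ACDEFGHI", "HLA-A*02:01")
        r2 = p.rank("ACDEFGHI", "A02:01")  # allele normalisation
        assert r1 == r2
        assert SurrogatePredictor(seed=4).rank("ACDEFGHI", "A02:01") != r1

    def test_rank_cutoff_strict(self, tmp_path):
        path = tmp_path / "pred.tsv"
        path.write_text(
            "peptide\tallele\tEL_Rank\n"
            "ACDEFGHI\tHLA-A*02:01\t1.5\n"
            "ACDEFGHK\tHLA-A*02:01\t2.0\n"
        )
        adapter = NetMHCpanFileAdapter(path)
        peps = [NeoPeptide("ACDEFGHI", "e", 1), NeoPeptide("ACDEFGHK", "e", 1)]
        calls = {c.peptide: c for c in predict_binding(peps, ["A02:01"], adapter)}
        assert calls["ACDEFGHI"].is_binder is True
        assert calls["ACDEFGHK"].is_binder is False  # rank 2.0 is not < 2

    def test_missing_pair_errors(self, tmp_path):
        path = tmp_path / "pred.tsv"
        path.write_text("peptide\tallele\tEL_Rank\nACDEFGHI\tHLA-A*02:01\t1.5\n")
        adapter = NetMHCpanFileAdapter(path)
        peps = [NeoPeptide("ACDEFGHI", "e", 1), NeoPeptide("MNPQRSTV", "e", 1)]
        with pytest.raises(ValueError, match="missing predictions"):
            predict_binding(peps, ["A02:01"], adapter)

    def test_allele_normalisation(self):
        assert normalize_allele("HLA-A*02:01") == "HLA-A*02:01"
        assert normalize_allele("A02:01") == "HLA-A*02:01"
        assert normalize_allele("b07:02") == "HLA-B*07:02"


def quant(event, rpkm, passing=True):
    return IRQuantRecord(event, "s", 1.0, 1.0, 0.2, rpkm, passing)


class TestSampleLoad:
    def test_load_dedupes_across_alleles(self):
        peps = [NeoPeptide("ACDEFGHI", "c:1-2:+:t", 1), NeoPeptide("MNPQRSTV", "c:1-2:+:t", 1),
                NeoPeptide("WYACDEFG", "c:1-2:+:t", 1)]
        calls = []
        from irneo.neoantigen import BindingCall
        for p in peps:
            calls.append(BindingCall(p.peptide, "HLA-A*02:01", 1.0, True))
        calls.append(BindingCall("ACDEFGHI", "HLA-B*07:02", 0.5, True))  # same peptide, 2nd allele
        load = compute_sample_load(calls, [quant("c:1-2:+:t", 4.0)], peps, "s")
        assert load.neoag_load == 3
        assert load.weighted_load == pytest.approx(4.0 * 3)

    def test_duplicated_calls_do_not_inflate(self):
        from irneo.neoantigen import BindingCall
        peps = [NeoPeptide("ACDEFGHI", "c:1-2:+:t", 1)]
        call = BindingCall("ACDEFGHI", "HLA-A*02:01", 1.0, True)
        load = compute_sample_load([call, call], [quant("c:1-2:+:t", 2.0)], peps, "s")
        assert load.neoag_load == 1
        assert load.weighted_load == pytest.approx(2.0)

    def test_no_binders_zero_loads(self):
        load = compute_sample_load([], [quant("c:1-2:+:t", 4.0)], [], "s")
        assert (load.neoag_load, load.weighted_load) == (0, 0.0)

    def test_binder_without_source_event_errors(self):
        from irneo.neoantigen import BindingCall
        call = BindingCall("ACDEFGHI", "HLA-A*02:01", 1.0, True)
        with pytest.raises(ValueError, match="no source event"):
            compute_sample_load([call], [], [], "s")

    def test_adding_allele_never_decreases_load(self):
        rng = np.random.default_rng(9)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        peps = [NeoPeptide("".join(rng.choice(aas, size=9)), "c:1-2:+:t", 1) for _ in range(40)]
        quants = [quant("c:1-2:+:t", 1.0)]
        pred = SurrogatePredictor(seed=0)
        pool = ["A01:01", "A02:01", "B07:02", "B08:01"]
        prev = 0
        for n in range(1, len(pool) + 1):
            calls = predict_binding(peps, pool[:n], pred, rank_cutoff=30.0)
            load = compute_sample_load(calls, quants, peps, "s").neoag_load
            assert load >= prev
            prev = load


class TestCohortSummaries:
    def test_allele_carrier_frequency_and_counts(self):
        from irneo.neoantigen import BindingCall
        genotypes = {f"s{i}": ["HLA-A*02:01"] for i in range(2)}
        genotypes.update({f"s{i}": ["HLA-B*07:02"] for i in range(2, 10)})
        calls = {s: [] for s in genotypes}
        calls["s0"] = [BindingCall("ACDEFGHI", "HLA-A*02:01", 1.0, True)]
        df = cohort_allele_summary(calls, genotypes).set_index("allele")
        assert df.loc["HLA-A*02:01", "carrier_frequency"] == pytest.approx(0.2)
        assert df.loc["HLA-A*02:01", "n_presented_peptides"] == 1
        assert df.loc["HLA-B*07:02", "n_presented_peptides"] == 0

    def test_shifted_allele_tops_presentation(self):
        """An allele whose ranks are shifted low presents the most peptides."""
        from irneo.neoantigen import BindingCall

        class Shifted:
            def __init__(self, favored):
                self.base = SurrogatePredictor(seed=0)
                self.favored = favored

            def rank(self, pep, allele):
                r = self.base.rank(pep, allele)
                return r * 0.05 if allele == self.favored else r

        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        peps = [NeoPeptide("".join(rng.choice(aas, size=9)), "c:1-2:+:t", 1) for _ in range(300)]
        alleles = ["HLA-A*02:01", "HLA-B*07:02", "HLA-C*07:01"]
        pred = Shifted("HLA-B*07:02")
        genotypes = {"s0": alleles}
        calls = {"s0": predict_binding(peps, alleles, pred)}
        df = cohort_allele_summary(calls, genotypes).set_index("allele")
        counts = df["n_presented_peptides"]
        assert counts.idxmax() == "HLA-B*07:02"

    @pytest.mark.parametrize(
        "n_carriers,n_samples,expected_shared",
        [(6, 100, True), (5, 100, False), (100, 100, True)],
    )
    def test_shared_fraction_strict_threshold(self, n_carriers, n_samples, expected_shared):
        per_sample = [({"ACDEFGHI"} if i < n_carriers else set()) for i in range(n_samples)]
        df = shared_peptide_frequency(per_sample)
        row = df.set_index("peptide").loc["ACDEFGHI"]
        assert row["sample_fraction"] == pytest.approx(n_carriers / n_samples)
        assert bool(row["shared_flag"]) is expected_shared
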