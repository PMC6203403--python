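"""Open-reading-frame-state annotation: routes, criteria, verdicts."""

import numpy as np
import pytest

from varsync.core_io import SampleVariantSet, VariantCall, revcomp
from varsync.orfs import (
    CandidateAnnotation,
    OrfsCall,
    annotate_by_liftover,
    annotate_by_spliced_alignment,
    annotate_gene_sample,
    annotate_population,
    call_orfs,
    evaluate_criteria,
    extract_gene_haplotype,
    flag_trustable,
    reference_gene_data,
    translate,
)
from tests.conftest import varset_of
from varsync import simulate as sim


@pytest.fixture(scope="module")
def toy(toy_gene):
    genome, model = toy_gene
    cds_seq, protein, pairs = reference_gene_data(genome, model)
    return genome, model, cds_seq, protein, pairs


class TestExtractGeneHaplotype:
    def test_reference_sample_equals_reference(self, toy):
        genome, model, *_ = toy
        hap = extract_gene_haplotype(genome, SampleVariantSet("r"), model, flank=30)
        span = genome.sequences["chr1"][model.start - 30 : model.end + 30]
        assert hap.seq == span

    def test_intron_deletion_shifts_exons(self, toy):
        genome, model, *_ = toy
        c = model.coords
        vs = varset_of(
            genome, "s",
            ("chr1", c["e1"] + 8, genome.sequences["chr1"][c["e1"] + 8 : c["e1"] + 10], ""),
        )
        hap = extract_gene_haplotype(genome, vs, model, flank=30)
        assert len(hap.seq) == (model.end - model.start + 60) - 2
        # exon 2 start moves left by 2 through the map
        ls, _ = hap.local_interval(c["s2"], c["e2"])
        assert ls == (c["s2"] - (model.start - 30)) - 2

    def test_minus_strand_is_reverse_complement(self, toy):
        genome, model, *_ = toy
        import dataclasses

        minus = dataclasses.replace(model, strand="-")
        hap_p = extract_gene_haplotype(genome, SampleVariantSet("r"), model, flank=30)
        hap_m = extract_gene_haplotype(genome, SampleVariantSet("r"), minus, flank=30)
        assert hap_m.seq == revcomp(hap_p.seq)


class TestLiftoverFrameArithmetic:
    @pytest.mark.parametrize("length", range(1, 10))
    @pytest.mark.parametrize("is_insertion", [False, True])
    def test_single_cds_indel_frame(self, toy, length, is_insertion):
        """For any single INDEL of length L wholly inside a CDS exon, the
        lifted model's frame is intact iff L is a multiple of 3."""
        genome, model, cds_seq, protein, pairs = toy
        c = model.coords
        pos = c["s2"] + 7
        seq = genome.sequences["chr1"]
        if is_insertion:
            vs = varset_of(genome, "s", ("chr1", pos, "", "A" * length))
        else:
            vs = varset_of(genome, "s", ("chr1", pos, seq[pos : pos + length], ""))
        hap = extract_gene_haplotype(genome, vs, model, flank=30)
        flags = evaluate_criteria(annotate_by_liftover(hap, model), hap, pairs)
        assert flags["frame_ok"] == (length % 3 == 0)


class TestSpliceWhitelist:
    WHITELIST = [("GT", "AG"), ("GC", "AG"), ("GG", "AG"), ("GT", "TG"), ("GT", "CG"), ("CT", "AG")]

    @pytest.mark.parametrize("donor,acceptor", WHITELIST)
    def test_whitelisted_pairs_accepted(self, toy, donor, acceptor):
        genome, model, cds_seq, protein, pairs = toy
        c = model.coords
        seq = genome.sequences["chr1"]
        calls = []
        for off, new in ((0, donor[0]), (1, donor[1])):
            if seq[c["e1"] + off] != new:
                calls.append(("chr1", c["e1"] + off, seq[c["e1"] + off], new))
        for off, new in ((-2, acceptor[0]), (-1, acceptor[1])):
            p = c["s2"] + off
            if seq[p] != new:
                calls.append(("chr1", p, seq[p], new))
        vs = varset_of(genome, "s", *calls)
        hap = extract_gene_haplotype(genome, vs, model, flank=30)
        flags = evaluate_criteria(annotate_by_liftover(hap, model), hap, pairs)
        assert flags["splice_intact"] is True

    @pytest.mark.parametrize("donor,acceptor", [("AT", "AG"), ("GT", "AA"), ("CC", "GG")])
    def test_non_whitelisted_pairs_rejected(self, toy, donor, acceptor):
        genome, model, cds_seq, protein, pairs = toy
        c = model.coords
        seq = genome.sequences["chr1"]
        calls = []
        for off, new in ((0, donor[0]), (1, donor[1])):
            if seq[c["e1"] + off] != new:
                calls.append(("chr1", c["e1"] + off, seq[c["e1"] + off], new))
        for off, new in ((-2, acceptor[0]), (-1, acceptor[1])):
            p = c["s2"] + off
            if seq[p] != new:
                calls.append(("chr1", p, seq[p], new))
        vs = varset_of(genome, "s", *calls)
        hap = extract_gene_haplotype(genome, vs, model, flank=30)
        flags = evaluate_criteria(annotate_by_liftover(hap, model), hap, pairs)
        assert flags["splice_intact"] is False

    def test_reference_pair_accepted_even_if_unusual(self, toy):
        """A pair matching the reference's own (index-matched) intron pair
        counts as intact even outside the whitelist."""
        genome, model, *_ = toy
        hap = extract_gene_haplotype(genome, SampleVariantSet("r"), model, flank=30)
        ann = annotate_by_liftover(hap, model)
        odd_pairs = [("AA", "CC"), ("GT", "AG")]
        flags = evaluate_criteria(ann, hap, odd_pairs)
        # intron 1 of the annotation is GT..AG: whitelisted anyway; intron 2
        # must fall back to the reference pair comparison
        assert flags["splice_intact"] is True


class TestSplicedAlignment:
    def test_reference_reproduces_exon_structure(self, toy):
        genome, model, cds_seq, protein, pairs = toy
        hap = extract_gene_haplotype(genome, SampleVariantSet("r"), model, flank=30)
        ann = annotate_by_spliced_alignment(hap, cds_seq, mode="cds")
        expect = [hap.local_interval(s, e) for s, e in model.exons]
        assert ann.exons == expect

    def test_protein_route_covers_stop_codon(self, toy):
        genome, model, cds_seq, protein, pairs = toy
        hap = extract_gene_haplotype(genome, SampleVariantSet("r"), model, flank=30)
        ann = annotate_by_spliced_alignment(hap, protein, mode="protein")
        assert ann.exons[-1][1] == hap.local_interval(*model.exons[-1])[1]
        flags = evaluate_criteria(ann, hap, pairs)
        assert all(flags.values())

    def test_intronic_snp_reduces_score_only(self, toy):
        genome, model, cds_seq, protein, pairs = toy
        c = model.coords
        seq = genome.sequences["chr1"]
        mid = c["e1"] + 8  # deep inside intron 1
        alt = "A" if seq[mid] != "A" else "C"
        vs = varset_of(genome, "s", ("chr1", mid, seq[mid], alt))
        hap_ref = extract_gene_haplotype(genome, SampleVariantSet("r"), model, flank=30)
        hap_mut = extract_gene_haplotype(genome, vs, model, flank=30)
        a_ref = annotate_by_spliced_alignment(hap_ref, cds_seq, mode="cds")
        a_mut = annotate_by_spliced_alignment(hap_mut, cds_seq, mode="cds")
        assert a_mut.exons == a_ref.exons
        assert a_mut.score <= a_ref.score

    def test_low_score_route_unevaluable(self):
        assert annotate_by_spliced_alignment("ACGT" * 10, "TTTTTTTTTTTT", mode="cds") is None


class TestVerdicts:
    def test_one_passing_route_conserves(self):
        fail = {"start_stop_intact": True, "frame_ok": False,
                "no_premature_stop": True, "splice_intact": True}
        ok = {k: True for k in fail}
        call = call_orfs("g", "s", {"liftover": fail, "cds_align": ok, "protein_align": fail})
        assert call.state == "conserved"

    def test_all_routes_failing_interrupts(self):
        fail = {"start_stop_intact": True, "frame_ok": False,
                "no_premature_stop": True, "splice_intact": True}
        call = call_orfs("g", "s", {"liftover": fail, "cds_align": dict(fail),
                                    "protein_align": dict(fail)})
        assert call.state == "interrupted"

    def test_unevaluable_routes_excluded_from_conjunction(self):
        fail = {"start_stop_intact": False, "frame_ok": True,
                "no_premature_stop": True, "splice_intact": True}
        call = call_orfs("g", "s", {"liftover": fail, "cds_align": None,
                                    "protein_align": None})
        assert call.state == "interrupted"
        call = call_orfs("g", "s", {"liftover": None, "cds_align": None,
                                    "protein_align": None})
        assert call.state == "missing"

    def test_monotone_conservativeness(self):
        """Adding an evaluable passing route can flip interrupted to
        conserved, never the reverse."""
        fail = {"start_stop_intact": True, "frame_ok": False,
                "no_premature_stop": True, "splice_intact": True}
        ok = {k: True for k in fail}
        base = call_orfs("g", "s", {"liftover": fail})
        more = call_orfs("g", "s", {"liftover": fail, "cds_align": ok})
        assert base.state == "interrupted" and more.state == "conserved"
        base2 = call_orfs("g", "s", {"liftover": ok})
        more2 = call_orfs("g", "s", {"liftover": ok, "cds_align": fail})
        assert base2.state == more2.state == "conserved"


class TestTrustable:
    def test_full_coverage_and_confirmed_indels(self, toy):
        genome, model, *_ = toy
        call = OrfsCall("toy", "s", "conserved")
        cov = np.ones(genome.length("chr1"))
        vs = varset_of(genome, "s", ("chr1", model.coords["s2"] + 3,
                                     genome.sequences["chr1"][model.coords["s2"] + 3], ""))
        confirmed = {("chr1", model.coords["s2"] + 3,
                      genome.sequences["chr1"][model.coords["s2"] + 3], ""): True}
        assert flag_trustable(call, model, cov, confirmed, vs) is True

    def test_zero_coverage_base_untrustable(self, toy):
        genome, model, *_ = toy
        cov = np.ones(genome.length("chr1"))
        cov[model.coords["s2"] + 5] = 0
        assert flag_trustable(OrfsCall("toy", "s", "conserved"), model, cov) is False

    def test_absent_inputs_default_trustable(self, toy):
        genome, model, *_ = toy
        assert flag_trustable(OrfsCall("toy", "s", "conserved"), model) is True


class TestPopulationAnnotation:
    def test_reference_self_conserved_for_all_generated_genes(self, synth_ref):
        cfg, ref = synth_ref
        for gid, model in ref.models.items():
            call = annotate_gene_sample(ref.genome, SampleVariantSet("r"), model, flank=200)
            assert call.state == "conserved", (gid, call.route_flags)

    def test_orfs_concordance_on_synthetic_truth(self, synth_ref):
        """Planted frame-shifting INDELs come out interrupted and in-frame or
        intronic edits conserved for at least 99% of 500 gene x sample
        pairs."""
        cfg, ref = synth_ref
        cache = {gid: reference_gene_data(ref.genome, m) for gid, m in ref.models.items()}
        total = ok = 0
        for batch_seed in (101, 202, 303):
            cases = sim.gen_orfs_cases(ref, 170, np.random.default_rng(batch_seed))
            for vs, gid, expected in cases:
                call = annotate_gene_sample(
                    ref.genome, vs, ref.models[gid], flank=1000, ref_data=cache[gid]
                )
                total += 1
                ok += call.state == expected
        assert total >= 500
        assert ok / total >= 0.99, f"{ok}/{total}"

    def test_alt_reference_for_broken_reference_copy(self, toy):
        """When the reference copy of a gene is non-functional (broken start
        codon), the query CDS/protein can come from an accession carrying a
        working allele: functional carriers are conserved, reference-like
        samples interrupted."""
        from varsync.core_io import ReferenceGenome

        genome, model, *_ = toy
        c = model.coords
        seq = genome.sequences["chr1"]
        broken = seq[: c["s1"]] + "TTG" + seq[c["s1"] + 3 :]  # ATG -> TTG
        broken_genome = ReferenceGenome(["chr1"], {"chr1": broken})
        vs_alt = varset_of(broken_genome, "alt", ("chr1", c["s1"], "T", "A"))
        vs_plain = SampleVariantSet("plain")
        vs_plain.sort_and_validate(broken_genome)
        matrix, calls = annotate_population(
            broken_genome, [vs_alt, vs_plain], {"toy": model},
            flank=30, alt_reference={"toy": "alt"},
        )
        assert matrix.loc["toy", "alt"] == 0  # functional allele conserved
        assert matrix.loc["toy", "plain"] == 1  # reference-like allele LoF


def test_translate_matches_biopython():
    from Bio.Seq import Seq

    rng = np.random.default_rng(3)
    for _ in range(20):
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)])
        ours = translate(s).replace("*", "*")
        theirs = str(Seq(s).translate())
        assert ours == theirs
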