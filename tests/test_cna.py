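"""CNA locus identity, Venn partitioning, unique fractions, recurrence."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remodelprint.io import Group
from remodelprint.cna import (
    CnaComparison,
    comparative_segments,
    count_cna_comparative,
    count_cna_global,
    gene_cna_sets,
    group_gene_set,
    locus_key,
    recurrent_cna_genes,
    unique_fraction,
    venn,
)
from remodelprint.io import Morphology
from remodelprint.variants import ComparativeMode

from conftest import (
    brute_cna_counts,
    brute_comparative_segments,
    brute_venn_sizes,
    make_cohort,
    seg,
)


class TestLocusIdentity:
    def test_exact_coordinates_required(self):
        a = seg("chr1", 100, 200)
        b = seg("chr1", 100, 201)
        assert locus_key(a) != locus_key(b)
        assert locus_key(a) == locus_key(seg("chr1", 100, 200, state="LOSS"))

    def test_state_matters_only_in_strict_mode(self):
        a = seg("chr1", 100, 200, state="GAIN")
        b = seg("chr1", 100, 200, state="LOSS")
        assert locus_key(a) == locus_key(b)
        assert locus_key(a, with_state=True) != locus_key(b, with_state=True)

    def test_strict_mode_keeps_state_mismatched_loci(self):
        cohort = make_cohort(
            {"P1": Group.COPD},
            cna={"P1-N": [seg("chr1", 100, 200, state="GAIN")],
                 "P1-R": [seg("chr1", 100, 200, state="LOSS")]},
        )
        default = comparative_segments(cohort)
        strict = comparative_segments(cohort, with_state=True)
        assert default["P1-R"] == []  # same locus, state ignored
        assert len(strict["P1-R"]) == 1  # states differ -> not the same event

    def test_reciprocal_overlap_mode(self):
        cohort = make_cohort(
            {"P1": Group.COPD},
            cna={"P1-N": [seg("chr1", 100, 200)], "P1-R": [seg("chr1", 110, 210)]},
        )
        exact = comparative_segments(cohort, match="exact")
        loose = comparative_segments(cohort, match="overlap", overlap_frac=0.5)
        assert len(exact["P1-R"]) == 1  # coordinates differ
        assert loose["P1-R"] == []  # 90% reciprocal overlap


class TestCounts:
    def test_empty_sample_zero(self):
        cohort = make_cohort({"P1": Group.COPD, "P2": Group.NON_COPD})
        per_sample, _ = count_cna_global(cohort)
        assert (per_sample.n_loci == 0).all() and (per_sample.n_genes == 0).all()

    def test_identical_pair_comparative_zero(self):
        segs = [seg("chr1", 100, 200, genes=["G1"]), seg("chr1", 300, 400, genes=["G2"])]
        cohort = make_cohort(
            {"P1": Group.COPD},
            cna={"P1-N": [seg(s.chrom, s.start, s.end, s.copy_state, s.genes) for s in segs],
                 "P1-R": segs},
        )
        per_sample, _ = count_cna_comparative(cohort)
        assert (per_sample.n_loci == 0).all()

    def test_matches_brute_force_oracle(self, small_cohort):
        cohort = small_cohort.to_cohort()
        per_sample, _ = count_cna_global(cohort)
        for row in per_sample.itertuples(index=False):
            assert (row.n_loci, row.n_genes) == brute_cna_counts(cohort.cna[row.sample_id])
        comp, _ = count_cna_comparative(cohort)
        for row in comp.itertuples(index=False):
            partner = cohort.paired(cohort.sample(row.patient_id, Morphology(row.morphology)))
            survivors = brute_comparative_segments(
                cohort.cna[row.sample_id], cohort.cna[partner.sample_id]
            )
            assert (row.n_loci, row.n_genes) == brute_cna_counts(survivors)

    def test_conservation_identity(self, small_cohort):
        cohort = small_cohort.to_cohort()
        for mode in ComparativeMode:
            surviving = comparative_segments(cohort, mode)
            for s in cohort.samples:
                total = len(cohort.cna[s.sample_id])
                kept = len(surviving[s.sample_id])
                removed = total - kept
                assert removed >= 0 and kept + removed == total


class TestVenn:
    def test_identical_sets(self):
        part = venn({"A", "B"}, {"A", "B"})
        assert (len(part.only_a), len(part.shared), len(part.only_b)) == (0, 2, 0)

    def test_hand_partition(self):
        a = {"G1", "G2", "G3", "G4", "G5"}
        b = {"G4", "G5", "G6", "G7"}
        part = venn(a, b)
        assert (len(part.only_a), len(part.shared), len(part.only_b)) == (3, 2, 2)
        assert len(a | b) == sum((len(part.only_a), len(part.shared), len(part.only_b)))

    def test_disjoint_sets(self):
        part = venn({"A"}, {"B", "C"})
        assert (part.only_a, part.shared, part.only_b) == ({"A"}, set(), {"B", "C"})

    def test_group_level_matches_brute_force(self, small_cohort):
        cohort = small_cohort.to_cohort()
        for group in cohort.groups:
            r = group_gene_set(cohort, group, Morphology.R)
            n = group_gene_set(cohort, group, Morphology.N)
            part = venn(r, n)
            assert (len(part.only_a), len(part.shared), len(part.only_b)) == \
                brute_venn_sizes(sorted(r), sorted(n))


class TestUniqueFraction:
    def test_subset_zero(self):
        assert unique_fraction({"A", "B"}, {"A", "B", "C"}) == 0.0

    def test_disjoint_hundred(self):
        assert unique_fraction({"A", "B"}, {"C"}) == 100.0

    def test_hand_seventy(self):
        target = {f"G{i}" for i in range(10)}
        reference = {"G0", "G1", "G2", "X"}
        assert unique_fraction(target, reference) == 70.0

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError):
            unique_fraction(set(), {"A"})

    def test_self_and_empty_reference(self):
        s = {"A", "B", "C"}
        assert unique_fraction(s, s) == 0.0
        assert unique_fraction(s, set()) == 100.0

    @settings(derandomize=True, max_examples=50)
    @given(
        target=st.sets(st.integers(0, 30), min_size=1, max_size=20),
        ref=st.sets(st.integers(0, 30), max_size=20),
        extra=st.sets(st.integers(0, 30), max_size=10),
    )
    def test_enlarging_reference_never_increases(self, target, ref, extra):
        assert unique_fraction(target, ref | extra) <= unique_fraction(target, ref)


class TestRecurrentCnaGenes:
    def _cohort(self, extra_r=None):
        # gene GPL appears as R-unique CNA in 2 COPD patients
        cna = {
            "B1-N": [seg("chr1", 0, 100, genes=["GBG1"])],
            "B1-R": [seg("chr1", 0, 100, genes=["GBG1"]), seg("chr1", 500, 600, genes=["GPL"])],
            "B2-N": [],
            "B2-R": [seg("chr1", 700, 800, genes=["GPL"])],
            "B3-N": [],
            "B3-R": [],
            "A1-N": [],
            "A1-R": [],
        }
        if extra_r:
            for sid, segs in extra_r.items():
                cna.setdefault(sid, []).extend(segs)
        return make_cohort(
            {"B1": Group.COPD, "B2": Group.COPD, "B3": Group.COPD, "A1": Group.NON_COPD},
            cna=cna,
        )

    def test_two_sample_support_recovered(self):
        goi = recurrent_cna_genes(self._cohort())
        by_comp = {}
        for g in goi:
            by_comp.setdefault(g.comparison, set()).add(g.gene)
        assert by_comp[CnaComparison.COPD_R_VS_COPD_N] == {"GPL"}
        assert by_comp[CnaComparison.COPD_R_VS_NONCOPD_R] == {"GPL"}
        assert not any(g.bold for g in goi)

    def test_single_sample_excluded(self):
        cohort = self._cohort()
        cohort.cna["B2-R"] = []
        assert recurrent_cna_genes(cohort) == []

    def test_three_sample_support_bold(self):
        goi = recurrent_cna_genes(self._cohort({"B3-R": [seg("chr2", 0, 50, genes=["GPL"])]}))
        assert all(g.bold for g in goi if g.gene == "GPL")

    def test_gene_in_noncopd_r_removed_from_cross_group_comparison(self):
        goi = recurrent_cna_genes(self._cohort({"A1-R": [seg("chr2", 90, 95, genes=["GPL"])]}))
        by_comp = {}
        for g in goi:
            by_comp.setdefault(g.comparison, set()).add(g.gene)
        assert by_comp.get(CnaComparison.COPD_R_VS_NONCOPD_R, set()) == set()
        assert by_comp[CnaComparison.COPD_R_VS_COPD_N] == {"GPL"}

    def test_planted_truth_recovered_exactly(self, small_cohort):
        cohort = small_cohort.to_cohort()
        truth = set(small_cohort.truth.copd_r_unique_cna_genes)
        bold_truth = {
            g for g, supp in small_cohort.truth.copd_r_unique_cna_genes.items()
            if len(supp) >= 3
        }
        for comp in CnaComparison:
            got = {g.gene for g in recurrent_cna_genes(cohort) if g.comparison == comp}
            bold = {g.gene for g in recurrent_cna_genes(cohort)
                    if g.comparison == comp and g.bold}
            assert got == truth
            assert bold == bold_truth
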