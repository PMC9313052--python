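"""Variant normalization, annotation, counting and gene-of-interest filters."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from remodelprint.io import GeneModel, Group, Impact, Morphology, build_gene_index
from remodelprint.variants import (
    ComparativeMode,
    GOICategory,
    annotate_genes,
    build_variant_sets,
    classify_impact,
    comparative_key_sets,
    count_comparative,
    count_global,
    group_exclusive_recurrent_genes,
    normalize_variant,
    remodelled_only_genes,
)

from conftest import (
    brute_comparative_calls,
    brute_unique_keys,
    brute_variant_counts,
    make_cohort,
    vc,
)


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            (("chr1", 100, "GCA", "GCC"), ("chr1", 102, "A", "C")),  # prefix GC
            (("chr1", 100, "A", "T"), ("chr1", 100, "A", "T")),  # already minimal
            (("chr1", 100, "ATT", "AT"), ("chr1", 100, "AT", "A")),  # suffix then stop
            (("chr1", 100, "CAG", "CTG"), ("chr1", 101, "A", "T")),  # suffix G, prefix C
        ],
    )
    def test_trimming(self, raw, expected):
        key = normalize_variant(*raw)
        assert (key.chrom, key.pos, key.ref, key.alt) == expected

    def test_non_variant_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant("chr1", 100, "ACG", "ACG")

    @settings(derandomize=True, max_examples=100)
    @given(
        pos=st.integers(min_value=1, max_value=10**6),
        ref=st.text(alphabet="ACGT", min_size=1, max_size=5),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=5),
    )
    def test_idempotent(self, pos, ref, alt):
        if ref == alt:
            return
        k = normalize_variant("chr1", pos, ref, alt)
        k2 = normalize_variant(k.chrom, k.pos, k.ref, k.alt)
        assert k2 == k


class TestAnnotation:
    GENES = [
        GeneModel("GENEA", "chr1", 100, 200),
        GeneModel("GENEB", "chr1", 150, 300),  # overlaps GENEA
        GeneModel("GENEC", "chr2", 0, 100),
    ]

    def test_snv_in_one_gene(self):
        index = build_gene_index(self.GENES)
        (call,) = annotate_genes([vc("chr1", 120, "A", "T")], index)
        assert call.genes == {"GENEA"}

    def test_deletion_spanning_two_genes(self):
        index = build_gene_index(self.GENES)
        # ref covers [149, 155): last base of GENEA-only region into GENEB
        (call,) = annotate_genes([vc("chr1", 150, "ACGTAC", "A")], index)
        assert call.genes == {"GENEA", "GENEB"}

    def test_intergenic_empty(self):
        index = build_gene_index(self.GENES)
        (call,) = annotate_genes([vc("chr1", 500, "A", "T")], index)
        assert call.genes == set()


class TestImpactClassification:
    def test_default_table(self):
        assert classify_impact("stop_gained") is Impact.HIGH
        assert classify_impact("synonymous_variant") is Impact.LOW
        assert classify_impact("missense_variant") is Impact.MODERATE

    def test_unknown_term_falls_back(self, caplog):
        with caplog.at_level("WARNING"):
            assert classify_impact("weird_term") is Impact.MODIFIER
        assert "weird_term" in caplog.text

    def test_custom_table(self):
        assert classify_impact("x", {"x": Impact.HIGH}) is Impact.HIGH


class TestCounting:
    def test_empty_sample_counts_zero(self):
        cohort = make_cohort({"P1": Group.COPD, "P2": Group.NON_COPD})
        vs = build_variant_sets(cohort)
        per_sample, _ = count_global(vs)
        assert (per_sample.n_positions == 0).all()
        assert (per_sample.n_genes == 0).all()

    def test_identical_samples_in_stratum_sem_zero(self):
        calls = [vc("chr1", 10, "A", "T", gene="G1"), vc("chr1", 20, "C", "G", gene="G2")]
        cohort = make_cohort(
            {"P1": Group.COPD, "P2": Group.COPD, "P3": Group.NON_COPD},
            variants={sid: list(calls) for sid in
                      ("P1-N", "P1-R", "P2-N", "P2-R", "P3-N", "P3-R")},
        )
        _, summary = count_global(build_variant_sets(cohort))
        assert (summary["sem"] == 0).all()

    def test_hand_set_difference(self):
        k1 = vc("chr1", 10, "A", "T")
        k2 = vc("chr1", 20, "C", "G")
        k3 = vc("chr1", 30, "G", "A")
        cohort = make_cohort(
            {"P1": Group.COPD},
            variants={"P1-N": [k1, k2], "P1-R": [k2, k3]},
        )
        vs = build_variant_sets(cohort)
        surv = comparative_key_sets(vs, cohort, ComparativeMode.WITHIN_PATIENT)
        assert {(k.pos) for k in surv["P1-N"]} == {10}
        assert {(k.pos) for k in surv["P1-R"]} == {30}

    def test_identical_pair_comparative_zero(self):
        calls = [vc("chr1", 10, "A", "T"), vc("chr1", 20, "C", "G")]
        cohort = make_cohort({"P1": Group.COPD},
                             variants={"P1-N": list(calls), "P1-R": list(calls)})
        per_sample, _ = count_comparative(build_variant_sets(cohort), cohort)
        assert (per_sample.n_positions == 0).all()

    def test_conservation_identity(self, small_cohort):
        """global = comparative + shared-with-reference, per sample."""
        cohort = small_cohort.to_cohort()
        vs = build_variant_sets(cohort)
        for mode in ComparativeMode:
            surv = comparative_key_sets(vs, cohort, mode)
            for sid, s in vs.items():
                shared = s.keys - surv[sid]
                assert len(s.keys) == len(surv[sid]) + len(shared)

    def test_label_swap_exchanges_comparative_sets(self):
        a = [vc("chr1", 10, "A", "T"), vc("chr1", 20, "C", "G")]
        b = [vc("chr1", 20, "C", "G"), vc("chr1", 30, "G", "A")]
        direct = make_cohort({"P1": Group.COPD}, variants={"P1-N": a, "P1-R": b})
        swapped = make_cohort({"P1": Group.COPD}, variants={"P1-N": b, "P1-R": a})
        sd = comparative_key_sets(build_variant_sets(direct), direct)
        ss = comparative_key_sets(build_variant_sets(swapped), swapped)
        assert sd["P1-N"] == ss["P1-R"]
        assert sd["P1-R"] == ss["P1-N"]

    def test_matches_brute_force_oracle(self, small_cohort):
        cohort = small_cohort.to_cohort()
        vs = build_variant_sets(cohort)
        per_sample, _ = count_global(vs)
        for row in per_sample.itertuples(index=False):
            n_pos, n_genes = brute_variant_counts(cohort.variants[row.sample_id])
            assert (row.n_positions, row.n_genes) == (n_pos, n_genes)
        comp, _ = count_comparative(vs, cohort)
        for row in comp.itertuples(index=False):
            partner = cohort.paired(cohort.sample(row.patient_id, Morphology(row.morphology)))
            survivors = brute_comparative_calls(
                cohort.variants[row.sample_id], cohort.variants[partner.sample_id]
            )
            assert row.n_positions == len(brute_unique_keys(survivors))


def _remodelled_fixture(extra=None):
    """Two COPD + one non-COPD patients; k_som private to B1-R."""
    k_germ = lambda: vc("chr1", 10, "A", "T", gene="GSHARED")
    k_som = vc("chr1", 50, "C", "G", gene="GSOM")
    variants = {
        "B1-N": [k_germ()],
        "B1-R": [k_germ(), k_som],
        "B2-N": [k_germ()],
        "B2-R": [k_germ()],
        "A1-N": [],
        "A1-R": [],
    }
    if extra:
        for sid, calls in extra.items():
            variants.setdefault(sid, []).extend(calls)
    return make_cohort(
        {"B1": Group.COPD, "B2": Group.COPD, "A1": Group.NON_COPD}, variants=variants
    )


class TestRemodelledOnly:
    def test_private_r_key_recovered(self):
        goi = remodelled_only_genes(_remodelled_fixture())
        assert [(g.gene, g.group) for g in goi] == [("GSOM", Group.COPD)]
        assert goi[0].category is GOICategory.REMODELLED_ONLY

    def test_key_in_two_r_samples_excluded(self):
        # same key appears in B1-R and B2-R: violates the single-R rule
        dup = vc("chr1", 50, "C", "G", gene="GSOM")
        goi = remodelled_only_genes(_remodelled_fixture(extra={"B2-R": [dup]}))
        assert [g.gene for g in goi] == []

    def test_key_also_in_paired_n_excluded(self):
        dup = vc("chr1", 50, "C", "G", gene="GSOM")
        goi = remodelled_only_genes(_remodelled_fixture(extra={"B1-N": [dup]}))
        assert [g.gene for g in goi] == []

    def test_r1_scope_cohort_vs_group(self):
        # key in B1-R (COPD) and A1-R (non-COPD): unique within each
        # group, not unique cohort-wide
        dup = vc("chr1", 50, "C", "G", gene="GSOM")
        cohort = _remodelled_fixture(extra={"A1-R": [dup]})
        within_group = remodelled_only_genes(cohort, r1_scope="group")
        assert {(g.gene, g.group) for g in within_group} == {
            ("GSOM", Group.COPD), ("GSOM", Group.NON_COPD)
        }
        assert remodelled_only_genes(cohort, r1_scope="cohort") == []

    def test_high_impact_flagged_underline(self):
        k = vc("chr2", 99, "G", "T", gene="GHI", impact=Impact.HIGH)
        cohort = _remodelled_fixture(extra={"B1-R": [k]})
        flags = {g.gene: g.underline for g in remodelled_only_genes(cohort)}
        assert flags == {"GSOM": False, "GHI": True}

    def test_planted_truth_recovered_exactly(self, small_cohort):
        cohort = small_cohort.to_cohort()
        goi = remodelled_only_genes(cohort)
        recovered = {}
        for g in goi:
            recovered.setdefault(g.group, set()).add(g.gene)
        truth = small_cohort.truth.remodelled_only_by_group(small_cohort.samples)
        assert recovered == truth


class TestGroupExclusiveRecurrent:
    def _cohort(self, extra=None):
        shared = lambda: vc("chr1", 77, "T", "C", gene="GREC")
        variants = {
            "B1-N": [shared()], "B1-R": [shared()],
            "B2-N": [shared()], "B2-R": [shared()],
            "B3-N": [], "B3-R": [],
            "A1-N": [], "A1-R": [],
        }
        if extra:
            for sid, calls in extra.items():
                variants.setdefault(sid, []).extend(calls)
        return make_cohort(
            {"B1": Group.COPD, "B2": Group.COPD, "B3": Group.COPD, "A1": Group.NON_COPD},
            variants=variants,
        )

    def test_two_patient_support_included_not_bold(self):
        goi = group_exclusive_recurrent_genes(self._cohort())
        assert [(g.gene, g.group, g.bold) for g in goi] == [("GREC", Group.COPD, False)]

    def test_three_patient_support_bold(self):
        extra = {"B3-N": [vc("chr1", 77, "T", "C", gene="GREC")],
                 "B3-R": [vc("chr1", 77, "T", "C", gene="GREC")]}
        goi = group_exclusive_recurrent_genes(self._cohort(extra))
        assert [(g.gene, g.bold) for g in goi] == [("GREC", True)]

    def test_presence_in_other_group_excludes(self):
        extra = {"A1-N": [vc("chr1", 77, "T", "C", gene="GREC")]}
        assert group_exclusive_recurrent_genes(self._cohort(extra)) == []

    def test_single_patient_not_recurrent(self):
        cohort = self._cohort()
        cohort.variants["B2-N"] = []
        cohort.variants["B2-R"] = []
        assert group_exclusive_recurrent_genes(cohort) == []

    def test_planted_truth_recovered_exactly(self, small_cohort):
        cohort = small_cohort.to_cohort()
        goi = group_exclusive_recurrent_genes(cohort)
        recovered = {}
        for g in goi:
            recovered.setdefault(g.group, set()).add(g.gene)
        truth = {
            grp: set(d)
            for grp, d in small_cohort.truth.group_exclusive_recurrent_genes.items()
            if d
        }
        assert recovered == truth
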