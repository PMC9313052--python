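"""CNA locus/gene comparisons, Venn partitioning and recurrence filters.

Locus identity is *exact*: two segments are the same locus iff they
share chromosome, start and end coordinates (copy state is ignored by
default, since the identity rule is purely positional; a strict mode
requiring matching state is available).  A reciprocal-overlap matcher is
provided for robustness studies but is deliberately not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Set

import pandas as pd

from .io import CNASegment, Cohort, Group, Morphology
from .stats import round_half_up, stratum_summary
from .variants import ComparativeMode

__all__ = [
    "LocusKey",
    "CnaComparison",
    "CnaGOI",
    "VennPartition",
    "annotate_segment_genes",
    "locus_key",
    "count_cna_global",
    "count_cna_comparative",
    "comparative_segments",
    "gene_cna_sets",
    "group_gene_set",
    "venn",
    "unique_fraction",
    "recurrent_cna_genes",
]


class LocusKey(NamedTuple):
    chrom: str
    start: int
    end: int


def locus_key(seg: CNASegment, with_state: bool = False):
    if with_state:
        return (seg.chrom, seg.start, seg.end, seg.copy_state)
    return LocusKey(seg.chrom, seg.start, seg.end)


def annotate_segment_genes(segments: Iterable[CNASegment], gene_index: Mapping) -> list:
    """Fill each segment's ``genes`` with all overlapping gene models."""
    segments = list(segments)
    for seg in segments:
        tree = gene_index.get(seg.chrom)
        seg.genes = {iv.data for iv in tree.overlap(seg.start, seg.end)} if tree else set()
    return segments


def _reciprocal_overlap(a: CNASegment, b: CNASegment) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def _matches_reference(
    seg: CNASegment,
    reference: List[CNASegment],
    match: str,
    overlap_frac: float,
    with_state: bool,
) -> bool:
    if match == "exact":
        key = locus_key(seg, with_state)
        return any(locus_key(r, with_state) == key for r in reference)
    for r in reference:
        if with_state and r.copy_state != seg.copy_state:
            continue
        if _reciprocal_overlap(seg, r) >= overlap_frac:
            return True
    return False


def _per_sample_counts(rows: list) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "group", "morphology", "n_loci", "n_genes"]
    )


def count_cna_global(cohort: Cohort) -> tuple:
    """Per-sample (n loci, n genes with CNA) plus stratum mean +/- SEM."""
    rows = []
    for s in cohort.samples:
        segs = cohort.cna.get(s.sample_id, [])
        genes: Set[str] = set().union(*(seg.genes for seg in segs)) if segs else set()
        rows.append([s.sample_id, s.patient_id, s.group.value, s.morphology.value,
                     len(segs), len(genes)])
    per_sample = _per_sample_counts(rows)
    summary = stratum_summary(per_sample, ["n_loci", "n_genes"])
    return per_sample, summary


def comparative_segments(
    cohort: Cohort,
    mode: ComparativeMode = ComparativeMode.WITHIN_PATIENT,
    match: str = "exact",
    overlap_frac: float = 0.5,
    with_state: bool = False,
) -> Dict[str, List[CNASegment]]:
    """Segments surviving comparative removal, per sample.

    WITHIN_PATIENT removes a sample's segments whose locus matches a
    segment of the patient's paired sample; CROSS_GROUP removes loci
    matched anywhere in the other clinical group.
    """
    if match not in ("exact", "overlap"):
        raise ValueError(f"match must be 'exact' or 'overlap', got {match!r}")
    out: Dict[str, List[CNASegment]] = {}
    for s in cohort.samples:
        segs = cohort.cna.get(s.sample_id, [])
        if mode is ComparativeMode.WITHIN_PATIENT:
            try:
                partner = cohort.paired(s)
            except KeyError as exc:
                raise ValueError(
                    f"comparative WITHIN_PATIENT requires paired samples; "
                    f"patient {s.patient_id} is unpaired"
                ) from exc
            reference = cohort.cna.get(partner.sample_id, [])
        else:
            reference = [
                seg
                for other in cohort.samples
                if other.group != s.group
                for seg in cohort.cna.get(other.sample_id, [])
            ]
        out[s.sample_id] = [
            seg
            for seg in segs
            if not _matches_reference(seg, reference, match, overlap_frac, with_state)
        ]
    return out


def count_cna_comparative(
    cohort: Cohort,
    mode: ComparativeMode = ComparativeMode.WITHIN_PATIENT,
    match: str = "exact",
    overlap_frac: float = 0.5,
    with_state: bool = False,
) -> tuple:
    surviving = comparative_segments(cohort, mode, match, overlap_frac, with_state)
    rows = []
    for s in cohort.samples:
        segs = surviving[s.sample_id]
        genes: Set[str] = set().union(*(seg.genes for seg in segs)) if segs else set()
        rows.append([s.sample_id, s.patient_id, s.group.value, s.morphology.value,
                     len(segs), len(genes)])
    per_sample = _per_sample_counts(rows)
    summary = stratum_summary(per_sample, ["n_loci", "n_genes"])
    return per_sample, summary


def gene_cna_sets(cohort: Cohort) -> Dict[str, Set[str]]:
    """Per-sample set of genes overlapped by at least one CNA segment."""
    out = {}
    for s in cohort.samples:
        segs = cohort.cna.get(s.sample_id, [])
        out[s.sample_id] = set().union(*(seg.genes for seg in segs)) if segs else set()
    return out


def group_gene_set(cohort: Cohort, group: Group, morphology: Morphology) -> Set[str]:
    """Union of CNA gene sets over a group's samples of one morphology."""
    sets = gene_cna_sets(cohort)
    out: Set[str] = set()
    for s in cohort.of(group=group, morphology=morphology):
        out |= sets[s.sample_id]
    return out


class VennPartition(NamedTuple):
    only_a: Set[str]
    shared: Set[str]
    only_b: Set[str]


def venn(set_a: Set[str], set_b: Set[str]) -> VennPartition:
    """Two-way partition; |A u B| = |only A| + |shared| + |only B|."""
    return VennPartition(set_a - set_b, set_a & set_b, set_b - set_a)


def unique_fraction(target_set: Set[str], reference_set: Set[str]) -> float:
    """100 x |target \\ reference| / |target|, one decimal (half-up)."""
    if not target_set:
        raise ValueError("unique_fraction: empty target set")
    return round_half_up(100.0 * len(target_set - reference_set) / len(target_set), 1)


class CnaComparison(str, Enum):
    COPD_R_VS_COPD_N = "COPD_R_vs_COPD_N"
    COPD_R_VS_NONCOPD_R = "COPD_R_vs_NONCOPD_R"


@dataclass
class CnaGOI:
    gene: str
    comparison: CnaComparison
    supporting_samples: Set[str]
    bold: bool = False  # CNA in all 3 COPD samples


def recurrent_cna_genes(
    cohort: Cohort,
    min_samples: int = 2,
    bold_at: int = 3,
    target_group: Group = Group.COPD,
) -> List[CnaGOI]:
    """Genes carrying CNA in >= ``min_samples`` target-group R samples
    after comparative removal against the named reference.

    Comparison 1 (R vs paired N) removes exact-coordinate loci present
    in the same patient's N sample; comparison 2 (target R vs other-group
    R) removes genes carrying CNA in any other-group R sample.
    """
    other_groups = [g for g in cohort.groups if g != target_group]
    results: List[CnaGOI] = []

    # comparison 1: per-patient locus removal against paired N
    support1: Dict[str, Set[str]] = {}
    for s in cohort.of(group=target_group, morphology=Morphology.R):
        n_loci = {locus_key(seg) for seg in cohort.cna.get(cohort.paired(s).sample_id, [])}
        retained = [seg for seg in cohort.cna.get(s.sample_id, []) if locus_key(seg) not in n_loci]
        for seg in retained:
            for gene in seg.genes:
                support1.setdefault(gene, set()).add(s.patient_id)

    # comparison 2: gene removal against the other group's R samples
    ref_genes: Set[str] = set()
    for g in other_groups:
        ref_genes |= group_gene_set(cohort, g, Morphology.R)
    support2: Dict[str, Set[str]] = {}
    sets = gene_cna_sets(cohort)
    for s in cohort.of(group=target_group, morphology=Morphology.R):
        for gene in sets[s.sample_id] - ref_genes:
            support2.setdefault(gene, set()).add(s.patient_id)

    for comparison, support in (
        (CnaComparison.COPD_R_VS_COPD_N, support1),
        (CnaComparison.COPD_R_VS_NONCOPD_R, support2),
    ):
        for gene in sorted(support):
            supp = support[gene]
            if len(supp) >= min_samples:
                results.append(
                    CnaGOI(
                        gene=gene,
                        comparison=comparison,
                        supporting_samples=supp,
                        bold=len(supp) >= bold_at,
                    )
                )
    return results
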