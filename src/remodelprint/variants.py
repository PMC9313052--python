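"""Variant-level global/comparative analyses and gene-of-interest filters.

Two sets of calls are compared through *variant keys*: the normalized
(chrom, pos, ref, alt) quadruple.  Identity deliberately includes the
alleles, not the position alone, so two different substitutions at the
same site stay distinct.

The two gene-of-interest filters mirror the comparative exome design on
paired non-remodelled (N) / remodelled (R) epithelia:

* *remodelled-only*: a gene carries a key found in exactly one R sample
  of a group and absent from that patient's paired N sample — a
  candidate somatic print of remodelling.
* *group-exclusive recurrent*: a key present in both N and R of at
  least ``min_samples`` patients of one group and in no sample of the
  other group — a candidate susceptibility (germline-like) variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Set

import pandas as pd

from .io import (
    Cohort,
    Group,
    Impact,
    IMPACT_RANK,
    Morphology,
    SampleMeta,
    VariantCall,
    VType,
)
from .stats import stratum_summary

log = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "SampleVariantSet",
    "VariantGOI",
    "ComparativeMode",
    "normalize_variant",
    "classify_vtype",
    "classify_impact",
    "DEFAULT_IMPACT_TIERS",
    "annotate_genes",
    "build_variant_sets",
    "count_global",
    "count_comparative",
    "comparative_key_sets",
    "remodelled_only_genes",
    "group_exclusive_recurrent_genes",
]


class VariantKey(NamedTuple):
    chrom: str
    pos: int  # 1-based, normalized
    ref: str
    alt: str


class ComparativeMode(str, Enum):
    #: remove keys shared between a patient's own N and R samples
    WITHIN_PATIENT = "within_patient"
    #: remove keys present in any sample of the other clinical group
    CROSS_GROUP = "cross_group"


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Minimal allele representation: trim common suffix, then common
    prefix (advancing ``pos``), keeping at least one base on each side.

    Raises ``ValueError`` for a non-variant (ref == alt).
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt or not ref.isalpha() or not alt.isalpha():
        raise ValueError(f"normalize_variant: bad alleles {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError(f"normalize_variant: ref == alt at {chrom}:{pos}")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt)


def classify_vtype(ref: str, alt: str) -> VType:
    """SNV for substitutions, INS/DEL by allele-length difference."""
    if len(ref) == len(alt):
        return VType.SNV
    return VType.INS if len(alt) > len(ref) else VType.DEL


#: default consequence-term -> severity tier table (editable; the tier
#: vocabulary follows the Sequence Ontology terms annotation tools emit)
DEFAULT_IMPACT_TIERS: Dict[str, Impact] = {
    "transcript_ablation": Impact.HIGH,
    "splice_acceptor_variant": Impact.HIGH,
    "splice_donor_variant": Impact.HIGH,
    "stop_gained": Impact.HIGH,
    "frameshift_variant": Impact.HIGH,
    "stop_lost": Impact.HIGH,
    "start_lost": Impact.HIGH,
    "inframe_insertion": Impact.MODERATE,
    "inframe_deletion": Impact.MODERATE,
    "missense_variant": Impact.MODERATE,
    "protein_altering_variant": Impact.MODERATE,
    "splice_region_variant": Impact.LOW,
    "synonymous_variant": Impact.LOW,
    "stop_retained_variant": Impact.LOW,
    "start_retained_variant": Impact.LOW,
    "5_prime_UTR_variant": Impact.MODIFIER,
    "3_prime_UTR_variant": Impact.MODIFIER,
    "intron_variant": Impact.MODIFIER,
    "upstream_gene_variant": Impact.MODIFIER,
    "downstream_gene_variant": Impact.MODIFIER,
    "intergenic_variant": Impact.MODIFIER,
}


def classify_impact(
    consequence_term: str, tier_table: Optional[Mapping[str, Impact]] = None
) -> Impact:
    """Deterministic tier lookup; unknown terms fall back to MODIFIER."""
    table = DEFAULT_IMPACT_TIERS if tier_table is None else tier_table
    tier = table.get(consequence_term)
    if tier is None:
        log.warning("unknown consequence term %r; classified as MODIFIER", consequence_term)
        return Impact.MODIFIER
    return tier


def annotate_genes(calls: Iterable[VariantCall], gene_index: Mapping) -> list:
    """Fill ``genes`` with every gene model overlapping the ref-allele
    interval [pos-1, pos-1+len(ref)); an empty set means intergenic."""
    calls = list(calls)
    for call in calls:
        tree = gene_index.get(call.chrom)
        if tree is None:
            call.genes = set()
            continue
        start, end = call.interval
        call.genes = {iv.data for iv in tree.overlap(start, end)}
    return calls


@dataclass
class SampleVariantSet:
    """A sample's calls indexed by normalized variant key."""

    sample: SampleMeta
    calls: Dict[VariantKey, VariantCall]

    @classmethod
    def from_calls(cls, sample: SampleMeta, calls: Iterable[VariantCall]) -> "SampleVariantSet":
        index: Dict[VariantKey, VariantCall] = {}
        for c in calls:
            key = VariantKey(c.chrom, c.pos, c.ref, c.alt)
            if key not in index:  # duplicate records collapse to one key
                index[key] = c
        return cls(sample=sample, calls=index)

    @property
    def keys(self) -> Set[VariantKey]:
        return set(self.calls)

    def genes_of(self, keys: Iterable[VariantKey]) -> Set[str]:
        out: Set[str] = set()
        for k in keys:
            out |= self.calls[k].genes
        return out


def build_variant_sets(cohort: Cohort) -> Dict[str, SampleVariantSet]:
    return {
        s.sample_id: SampleVariantSet.from_calls(s, cohort.variants.get(s.sample_id, []))
        for s in cohort.samples
    }


def _per_sample_counts(rows: list) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "group", "morphology",
                       "n_positions", "n_genes"]
    )


def count_global(variant_sets: Mapping[str, SampleVariantSet]) -> tuple:
    """Per-sample (n positions, n altered genes) plus stratum mean +/- SEM.

    A gene counts once per sample regardless of how many of its variants
    are present.
    """
    rows = []
    for sid, vs in variant_sets.items():
        s = vs.sample
        rows.append(
            [sid, s.patient_id, s.group.value, s.morphology.value,
             len(vs.keys), len(vs.genes_of(vs.keys))]
        )
    per_sample = _per_sample_counts(rows)
    summary = stratum_summary(per_sample, ["n_positions", "n_genes"])
    return per_sample, summary


def comparative_key_sets(
    variant_sets: Mapping[str, SampleVariantSet],
    cohort: Cohort,
    mode: ComparativeMode = ComparativeMode.WITHIN_PATIENT,
) -> Dict[str, Set[VariantKey]]:
    """Keys surviving comparative removal, per sample.

    WITHIN_PATIENT removes keys shared with the patient's paired sample
    of the other morphology; CROSS_GROUP removes keys present anywhere
    in the other clinical group.
    """
    out: Dict[str, Set[VariantKey]] = {}
    if mode is ComparativeMode.CROSS_GROUP:
        group_keys: Dict[Group, Set[VariantKey]] = {}
        for vs in variant_sets.values():
            group_keys.setdefault(vs.sample.group, set()).update(vs.keys)
    for sid, vs in variant_sets.items():
        s = vs.sample
        if mode is ComparativeMode.WITHIN_PATIENT:
            try:
                partner = cohort.paired(s)
            except KeyError as exc:
                raise ValueError(
                    f"comparative WITHIN_PATIENT requires paired samples; "
                    f"patient {s.patient_id} is unpaired"
                ) from exc
            reference = variant_sets[partner.sample_id].keys
        else:
            other = [g for g in group_keys if g != s.group]
            reference = set().union(*(group_keys[g] for g in other)) if other else set()
        out[sid] = vs.keys - reference
    return out


def count_comparative(
    variant_sets: Mapping[str, SampleVariantSet],
    cohort: Cohort,
    mode: ComparativeMode = ComparativeMode.WITHIN_PATIENT,
) -> tuple:
    """Per-sample counts of keys/genes surviving comparative removal."""
    surviving = comparative_key_sets(variant_sets, cohort, mode)
    rows = []
    for sid, vs in variant_sets.items():
        s = vs.sample
        keys = surviving[sid]
        rows.append(
            [sid, s.patient_id, s.group.value, s.morphology.value,
             len(keys), len(vs.genes_of(keys))]
        )
    per_sample = _per_sample_counts(rows)
    summary = stratum_summary(per_sample, ["n_positions", "n_genes"])
    return per_sample, summary


class GOICategory(str, Enum):
    REMODELLED_ONLY = "REMODELLED_ONLY"
    GROUP_EXCLUSIVE_RECURRENT = "GROUP_EXCLUSIVE_RECURRENT"


@dataclass
class VariantGOI:
    """A gene surviving a variant uniqueness/recurrence filter."""

    gene: str
    category: GOICategory
    group: Group
    supporting_samples: Set[str]
    keys: tuple
    max_impact: Impact
    bold: bool = False  # recurrence in 3 samples
    underline: bool = False  # carries a HIGH-impact key


def _max_impact(impacts: Iterable[Impact]) -> Impact:
    return max(impacts, key=lambda i: IMPACT_RANK[i], default=Impact.MODIFIER)


def remodelled_only_genes(
    cohort: Cohort,
    variant_sets: Optional[Mapping[str, SampleVariantSet]] = None,
    r1_scope: str = "group",
) -> List[VariantGOI]:
    """Genes with a variant key in exactly one R sample and absent from
    the paired N sample at the same key.

    The "exactly one R" restriction is applied within the clinical group
    by default (``r1_scope='group'``) or over all R samples of the
    cohort (``r1_scope='cohort'``).  Entries carrying a HIGH-impact key
    get ``underline=True`` (rendered underlined in reports).
    """
    if r1_scope not in ("group", "cohort"):
        raise ValueError(f"r1_scope must be 'group' or 'cohort', got {r1_scope!r}")
    vs = build_variant_sets(cohort) if variant_sets is None else variant_sets
    all_r = cohort.of(morphology=Morphology.R)

    def r_count(key: VariantKey, scope_samples) -> int:
        return sum(1 for s in scope_samples if key in vs[s.sample_id].calls)

    results: Dict[tuple, dict] = {}
    for group in cohort.groups:
        r_samples = cohort.of(group=group, morphology=Morphology.R)
        scope = r_samples if r1_scope == "group" else all_r
        for r in r_samples:
            n_keys = vs[cohort.paired(r).sample_id].keys
            for key, call in vs[r.sample_id].calls.items():
                if key in n_keys or r_count(key, scope) != 1:
                    continue
                for gene in call.genes:
                    rec = results.setdefault(
                        (group, gene),
                        {"samples": set(), "keys": [], "impacts": []},
                    )
                    rec["samples"].add(r.sample_id)
                    rec["keys"].append(key)
                    rec["impacts"].append(call.impact)
    out = []
    for (group, gene), rec in sorted(results.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        mi = _max_impact(rec["impacts"])
        out.append(
            VariantGOI(
                gene=gene,
                category=GOICategory.REMODELLED_ONLY,
                group=group,
                supporting_samples=rec["samples"],
                keys=tuple(sorted(rec["keys"])),
                max_impact=mi,
                underline=mi is Impact.HIGH,
            )
        )
    return out


def group_exclusive_recurrent_genes(
    cohort: Cohort,
    variant_sets: Optional[Mapping[str, SampleVariantSet]] = None,
    min_samples: int = 2,
    bold_at: int = 3,
) -> List[VariantGOI]:
    """Genes with a key identical in both N and R of >= ``min_samples``
    patients of one group and absent from every sample of the other
    group; bold when supported by ``bold_at`` patients."""
    vs = build_variant_sets(cohort) if variant_sets is None else variant_sets
    results: Dict[tuple, dict] = {}
    for group in cohort.groups:
        other_keys: Set[VariantKey] = set()
        for s in cohort.samples:
            if s.group != group:
                other_keys |= vs[s.sample_id].keys
        support: Dict[VariantKey, Set[str]] = {}
        patients = sorted({s.patient_id for s in cohort.of(group=group)})
        for p in patients:
            shared = (
                vs[cohort.sample(p, Morphology.N).sample_id].keys
                & vs[cohort.sample(p, Morphology.R).sample_id].keys
            )
            for key in shared:
                support.setdefault(key, set()).add(p)
        for key, supp in support.items():
            if len(supp) < min_samples or key in other_keys:
                continue
            any_patient = next(iter(supp))
            call = vs[cohort.sample(any_patient, Morphology.R).sample_id].calls[key]
            for gene in call.genes:
                rec = results.setdefault(
                    (group, gene), {"samples": set(), "keys": [], "impacts": []}
                )
                rec["samples"] |= supp
                rec["keys"].append(key)
                rec["impacts"].append(call.impact)
    out = []
    for (group, gene), rec in sorted(results.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        mi = _max_impact(rec["impacts"])
        out.append(
            VariantGOI(
                gene=gene,
                category=GOICategory.GROUP_EXCLUSIVE_RECURRENT,
                group=group,
                supporting_samples=rec["samples"],
                keys=tuple(sorted(rec["keys"])),
                max_impact=mi,
                bold=len(rec["samples"]) >= bold_at,
                underline=mi is Impact.HIGH,
            )
        )
    return out
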