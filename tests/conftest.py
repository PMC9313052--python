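"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's set machinery: they walk
raw per-sample record lists with nested loops so that equality against
the implementation is a genuine cross-check.
"""

from __future__ import annotations

from functools import lru_cache

import pytest

from remodelprint.io import (
    CNASegment,
    Cohort,
    Group,
    Impact,
    Morphology,
    SampleMeta,
    VariantCall,
)
from remodelprint.simulate import SimConfig, generate_cohort
from remodelprint.variants import classify_vtype


# ---------------------------------------------------------------------------
# hand-built cohort helpers


def vc(chrom, pos, ref, alt, gene=None, impact=Impact.MODERATE, consequence=None):
    call = VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, vtype=classify_vtype(ref, alt),
        consequence=consequence, impact=impact,
    )
    if gene is not None:
        call.genes = {gene} if isinstance(gene, str) else set(gene)
    return call


def seg(chrom, start, end, state="GAIN", genes=()):
    return CNASegment(chrom=chrom, start=start, end=end, copy_state=state,
                      genes=set(genes))


def make_cohort(groups, variants=None, cna=None):
    """Build a paired cohort from ``groups``: dict patient_id -> Group.

    ``variants`` / ``cna`` map sample ids like ``"P1-N"`` to record
    lists; missing samples get empty lists.
    """
    samples = []
    for pid, group in groups.items():
        for m in (Morphology.N, Morphology.R):
            samples.append(SampleMeta(sample_id=f"{pid}-{m.value}", patient_id=pid,
                                      group=group, morphology=m))
    variants = variants or {}
    cna = cna or {}
    return Cohort(
        samples=samples,
        gene_models=[],
        variants={s.sample_id: list(variants.get(s.sample_id, [])) for s in samples},
        cna={s.sample_id: list(cna.get(s.sample_id, [])) for s in samples},
    )


# ---------------------------------------------------------------------------
# brute-force oracles (nested loops over raw records)


def _vkey(call):
    return (call.chrom, call.pos, call.ref, call.alt)


def brute_unique_keys(calls):
    out = []
    for c in calls:
        k = _vkey(c)
        if not any(k == e for e in out):
            out.append(k)
    return out


def brute_variant_counts(calls):
    """(n distinct positions/keys, n distinct genes) by nested loops."""
    keys = brute_unique_keys(calls)
    genes = []
    for c in calls:
        for g in c.genes:
            if not any(g == e for e in genes):
                genes.append(g)
    return len(keys), len(genes)


def brute_comparative_calls(calls, reference_calls):
    """Calls whose key does not appear in the reference record list."""
    ref_keys = [_vkey(c) for c in reference_calls]
    survivors = []
    for c in calls:
        if not any(_vkey(c) == rk for rk in ref_keys):
            survivors.append(c)
    return survivors


def _lkey(s):
    return (s.chrom, s.start, s.end)


def brute_cna_counts(segments):
    loci = []
    for s in segments:
        if not any(_lkey(s) == e for e in loci):
            loci.append(_lkey(s))
    genes = []
    for s in segments:
        for g in s.genes:
            if not any(g == e for e in genes):
                genes.append(g)
    return len(loci), len(genes)


def brute_comparative_segments(segments, reference_segments):
    survivors = []
    for s in segments:
        if not any(_lkey(s) == _lkey(r) for r in reference_segments):
            survivors.append(s)
    return survivors


def brute_venn_sizes(genes_a, genes_b):
    """(only A, shared, only B) sizes from two gene iterables."""
    a = list(dict.fromkeys(genes_a))
    b = list(dict.fromkeys(genes_b))
    shared = [g for g in a if any(g == h for h in b)]
    only_a = [g for g in a if not any(g == h for h in b)]
    only_b = [g for g in b if not any(g == h for h in a)]
    return len(only_a), len(shared), len(only_b)


# ---------------------------------------------------------------------------
# synthetic cohorts


SMALL_OVERRIDES = dict(
    n_genes=400,
    genome=(("chr1", 5_000_000), ("chr2", 5_000_000)),
    germline_shared_per_patient=60,
    private_variants_per_sample=10,
    remodelled_only_planted_copd=4,
    remodelled_only_planted_non_copd=2,
    group_exclusive_recurrent_per_group=3,
    cna_background_per_sample=12,
    cna_unique_per_sample=10,
    cna_recurrent_planted_two=3,
    cna_recurrent_planted_three=2,
    expr_samples_per_group=5,
    expr_de_genes=10,
)


def small_config(seed=0, **overrides):
    """<= 100 variants and <= 50 CNA segments per sample."""
    kw = dict(SMALL_OVERRIDES)
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


@lru_cache(maxsize=16)
def cached_small_cohort(seed=0):
    return generate_cohort(small_config(seed))


@lru_cache(maxsize=16)
def cached_default_cohort(seed=0):
    return generate_cohort(SimConfig(seed=seed))


@pytest.fixture(scope="session")
def small_cohort():
    return cached_small_cohort(0)


@pytest.fixture(scope="session")
def default_cohort():
    return cached_default_cohort(0)
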