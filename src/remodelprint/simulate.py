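"""Synthetic paired-morphology exome cohort with planted truth tables.

The generator emulates the statistical structure of a laser-microdissected
paired cohort: for each patient, the non-remodelled (N) and remodelled (R)
samples share a large germline variant background (identical keys), each
sample carries a minority of private calls, and extra "somatic" variants
are planted in R samples only.  CNA segments are shared with exact
coordinates between a patient's N and R (locus identity is coordinate
exact), with sample-unique segments whose count is inflated in COPD R by
a configurable excess factor.  A whole-lung style expression matrix with
planted log2 fold changes and a small gene-set annotation round out the
inputs every downstream stage needs.

Design choices that make planted truth exactly recoverable:

* variant positions are globally distinct across the cohort unless
  sharing is intended (germline within a patient, planted recurrence),
  so no accidental key coincidence can create recurrence;
* every CNA segment covers exactly one gene, and background segments
  draw their genes without replacement cohort-wide, so gene-level CNA
  recurrence arises only from planted recurrent genes;
* R-private background variants themselves satisfy the remodelled-only
  filter (present in one R, absent from the paired N), so the truth
  table records them alongside the explicitly planted events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .io import (
    CNASegment,
    Cohort,
    ExpressionMatrix,
    GeneModel,
    Group,
    Impact,
    Morphology,
    SampleMeta,
    VariantCall,
    write_expression,
    write_gmt,
    write_manifest,
    write_seg,
    write_vcf,
)
from .variants import DEFAULT_IMPACT_TIERS, classify_impact, classify_vtype

__all__ = ["SimConfig", "TruthTables", "SyntheticCohort",
           "generate_gene_models", "generate_cohort", "write_cohort"]

_BASES = "ACGT"

# consequence pools per severity tier, drawn from the default tier table
_HIGH_TERMS = sorted(t for t, i in DEFAULT_IMPACT_TIERS.items() if i is Impact.HIGH)
_MODERATE_TERMS = sorted(t for t, i in DEFAULT_IMPACT_TIERS.items() if i is Impact.MODERATE)
_LOW_TERMS = sorted(t for t, i in DEFAULT_IMPACT_TIERS.items() if i is Impact.LOW)
_MODIFIER_TERMS = sorted(t for t, i in DEFAULT_IMPACT_TIERS.items() if i is Impact.MODIFIER)


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: 4 non-COPD + 3 COPD patients, ~500 variants
    and ~100-250 CNA loci per sample, COPD-R CNA excess 2.4."""

    seed: int = 0
    n_patients_non_copd: int = 4
    n_patients_copd: int = 3
    n_genes: int = 3000
    genome: Tuple[Tuple[str, int], ...] = (("chr1", 25_000_000), ("chr2", 25_000_000))
    # variants
    germline_shared_per_patient: int = 430
    private_variants_per_sample: int = 25
    remodelled_only_planted_copd: int = 8
    remodelled_only_planted_non_copd: int = 4
    group_exclusive_recurrent_per_group: int = 5
    high_impact_prob: float = 0.2
    intergenic_rate: float = 0.0
    # CNA
    cna_background_per_sample: int = 60  # shared N/R, exact coordinates
    cna_unique_per_sample: int = 50
    copd_r_unique_cna_excess: float = 2.4
    cna_recurrent_planted_two: int = 6  # planted COPD-R genes in 2 patients
    cna_recurrent_planted_three: int = 4  # ... in 3 patients (bold)
    # expression
    expr_samples_per_group: int = 20
    expr_de_genes: int = 30
    expr_log2fc_effect: float = 1.0
    expr_noise_sd: float = 0.2

    def validate(self) -> None:
        counts = [
            self.n_patients_non_copd, self.n_patients_copd, self.n_genes,
            self.germline_shared_per_patient, self.private_variants_per_sample,
            self.remodelled_only_planted_copd, self.remodelled_only_planted_non_copd,
            self.group_exclusive_recurrent_per_group, self.cna_background_per_sample,
            self.cna_unique_per_sample, self.cna_recurrent_planted_two,
            self.cna_recurrent_planted_three, self.expr_samples_per_group,
            self.expr_de_genes,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("SimConfig: all counts must be >= 0")
        if self.copd_r_unique_cna_excess < 1.0:
            raise ValueError("SimConfig: copd_r_unique_cna_excess must be >= 1")
        if not 0.0 <= self.high_impact_prob <= 1.0:
            raise ValueError("SimConfig: high_impact_prob must be in [0, 1]")
        if self.expr_noise_sd < 0:
            raise ValueError("SimConfig: expr_noise_sd must be >= 0")
        if self._cna_genes_needed() > self.n_genes:
            raise ValueError(
                f"SimConfig: CNA gene budget {self._cna_genes_needed()} exceeds "
                f"n_genes={self.n_genes}"
            )

    def _cna_genes_needed(self) -> int:
        n_pat = self.n_patients_non_copd + self.n_patients_copd
        r_unique_copd = int(round(self.cna_unique_per_sample * self.copd_r_unique_cna_excess))
        return (
            n_pat * self.cna_background_per_sample
            + n_pat * self.cna_unique_per_sample  # N-unique
            + self.n_patients_non_copd * self.cna_unique_per_sample  # non-COPD R
            + self.n_patients_copd * r_unique_copd  # COPD R
            + self.cna_recurrent_planted_two
            + self.cna_recurrent_planted_three
        )


@dataclass
class TruthTables:
    """Planted ground truth for recovery tests.

    ``remodelled_only_genes`` maps patient id -> genes whose R-only keys
    (planted or private) make them recoverable by the remodelled-only
    filter.  ``group_exclusive_recurrent_genes`` maps group -> gene ->
    supporting patient ids.  ``copd_r_unique_cna_genes`` maps gene ->
    supporting COPD patient ids.  ``de_genes`` maps gene -> signed log2FC.
    """

    remodelled_only_genes: Dict[str, Set[str]] = field(default_factory=dict)
    group_exclusive_recurrent_genes: Dict[Group, Dict[str, Set[str]]] = field(default_factory=dict)
    copd_r_unique_cna_genes: Dict[str, Set[str]] = field(default_factory=dict)
    de_genes: Dict[str, float] = field(default_factory=dict)

    def remodelled_only_by_group(self, samples: List[SampleMeta]) -> Dict[Group, Set[str]]:
        out: Dict[Group, Set[str]] = {}
        by_patient = {s.patient_id: s.group for s in samples}
        for patient, genes in self.remodelled_only_genes.items():
            out.setdefault(by_patient[patient], set()).update(genes)
        return out


@dataclass
class SyntheticCohort:
    config: SimConfig
    samples: List[SampleMeta]
    gene_models: List[GeneModel]
    variants: Dict[str, List[VariantCall]]
    cna: Dict[str, List[CNASegment]]
    expression: ExpressionMatrix
    gene_sets: Dict[str, Set[str]]
    cilia_reference: Set[str]
    truth: TruthTables

    def to_cohort(self) -> Cohort:
        """In-memory view for the downstream analysis stages."""
        return Cohort(
            samples=self.samples,
            gene_models=self.gene_models,
            variants=self.variants,
            cna=self.cna,
        )


def generate_gene_models(config: SimConfig) -> List[GeneModel]:
    """Place ``n_genes`` disjoint gene bodies left to right with random
    lengths (1.5-3 kb) and gaps (0.2-2 kb); deterministic given seed."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    models: List[GeneModel] = []
    remaining = config.n_genes
    idx = 0
    for chrom, length in config.genome:
        pos = 0
        while remaining > 0:
            gap = int(rng.integers(200, 2001))
            glen = int(rng.integers(1500, 3001))
            start = pos + gap
            end = start + glen
            if end > length:
                break
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(GeneModel(gene=f"GENE{idx:05d}", chrom=chrom,
                                    start=start, end=end, strand=strand))
            pos = end
            remaining -= 1
        if remaining == 0:
            break
    if remaining > 0:
        raise ValueError(
            f"genome too small: placed {config.n_genes - remaining} of {config.n_genes} genes"
        )
    return models


class _VariantFactory:
    """Draws variants at globally distinct positions inside gene bodies."""

    def __init__(self, rng: np.random.Generator, genes: List[GeneModel],
                 high_impact_prob: float) -> None:
        self.rng = rng
        self.genes = genes
        self.p_high = high_impact_prob
        self._used: Set[Tuple[str, int]] = set()

    def _consequence(self) -> str:
        r = self.rng.random()
        if r < self.p_high:
            pool = _HIGH_TERMS
        elif r < self.p_high + 0.3:
            pool = _MODERATE_TERMS
        elif r < self.p_high + 0.55:
            pool = _LOW_TERMS
        else:
            pool = _MODIFIER_TERMS
        return pool[int(self.rng.integers(0, len(pool)))]

    def new_call(self, gene: Optional[GeneModel] = None) -> VariantCall:
        rng = self.rng
        if gene is None:
            gene = self.genes[int(rng.integers(0, len(self.genes)))]
        for _ in range(1000):
            # keep the full ref allele (up to 4 bases) inside the gene body
            pos = int(rng.integers(gene.start + 1, gene.end - 4))  # 1-based
            if (gene.chrom, pos) not in self._used:
                break
        else:  # pragma: no cover - gene bodies are far from saturated
            raise RuntimeError("variant position space exhausted")
        self._used.add((gene.chrom, pos))
        kind = rng.choice(["SNV", "INS", "DEL"], p=[0.8, 0.1, 0.1])
        base = _BASES[int(rng.integers(0, 4))]
        if kind == "SNV":
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == base:
                alt = _BASES[int(rng.integers(0, 4))]
            ref = base
        elif kind == "INS":
            ref = base
            alt = base + "".join(
                _BASES[int(rng.integers(0, 4))] for _ in range(int(rng.integers(1, 4)))
            )
        else:
            ref = base + "".join(
                _BASES[int(rng.integers(0, 4))] for _ in range(int(rng.integers(1, 4)))
            )
            alt = base
        csq = self._consequence()
        return VariantCall(
            chrom=gene.chrom, pos=pos, ref=ref, alt=alt,
            vtype=classify_vtype(ref, alt), consequence=csq,
            impact=classify_impact(csq), genes={gene.gene},
        )


def _copy_call(call: VariantCall) -> VariantCall:
    return replace(call, genes=set(call.genes))


def _sorted_calls(calls: List[VariantCall]) -> List[VariantCall]:
    return sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))


def _make_segment(rng: np.random.Generator, gene: GeneModel) -> CNASegment:
    # pads stay below half the minimum inter-gene gap, so segments on
    # neighbouring genes can never touch
    pad_l = int(rng.integers(0, 80))
    pad_r = int(rng.integers(0, 80))
    state = "GAIN" if rng.random() < 0.5 else "LOSS"
    return CNASegment(chrom=gene.chrom, start=gene.start - pad_l,
                      end=gene.end + pad_r, copy_state=state, genes={gene.gene})


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Build the full synthetic cohort in memory, with truth tables."""
    config.validate()
    gene_models = generate_gene_models(config)
    rng = np.random.default_rng([config.seed, 1])
    truth = TruthTables()

    patients: List[Tuple[str, Group]] = []
    noncopd_ids = ["A1", "A3", "A4", "A5", "A6", "A7", "A8", "A9"]
    copd_ids = ["B2", "B3", "B4", "B5", "B6", "B7", "B8", "B9"]
    for i in range(config.n_patients_non_copd):
        pid = noncopd_ids[i] if i < len(noncopd_ids) else f"A{i + 10}"
        patients.append((pid, Group.NON_COPD))
    for i in range(config.n_patients_copd):
        pid = copd_ids[i] if i < len(copd_ids) else f"B{i + 10}"
        patients.append((pid, Group.COPD))

    samples: List[SampleMeta] = []
    for pid, group in patients:
        for morph in (Morphology.N, Morphology.R):
            samples.append(SampleMeta(sample_id=f"{pid}-{morph.value}", patient_id=pid,
                                      group=group, morphology=morph))

    factory = _VariantFactory(rng, gene_models, config.high_impact_prob)
    variants: Dict[str, List[VariantCall]] = {s.sample_id: [] for s in samples}

    # germline background + per-sample private + planted remodelled-only
    for pid, group in patients:
        germline = [factory.new_call() for _ in range(config.germline_shared_per_patient)]
        for morph in (Morphology.N, Morphology.R):
            sid = f"{pid}-{morph.value}"
            variants[sid].extend(_copy_call(c) for c in germline)
            variants[sid].extend(
                factory.new_call() for _ in range(config.private_variants_per_sample)
            )
        n_planted = (
            config.remodelled_only_planted_copd
            if group is Group.COPD
            else config.remodelled_only_planted_non_copd
        )
        variants[f"{pid}-R"].extend(factory.new_call() for _ in range(n_planted))

    # truth: every R-exclusive key (private background or planted) makes
    # its gene remodelled-only for that patient
    for pid, _group in patients:
        r_calls = variants[f"{pid}-R"]
        n_shared = config.germline_shared_per_patient
        r_only = r_calls[n_shared:]  # private + planted, appended after germline
        truth.remodelled_only_genes[pid] = set().union(*(c.genes for c in r_only)) if r_only else set()

    # planted group-exclusive recurrent variants (in N and R of >= 2 patients)
    for group in (Group.NON_COPD, Group.COPD):
        group_pids = [pid for pid, g in patients if g is group]
        truth.group_exclusive_recurrent_genes[group] = {}
        if len(group_pids) < 2:
            continue
        for i in range(config.group_exclusive_recurrent_per_group):
            size = 3 if (i % 2 == 0 and len(group_pids) >= 3) else 2
            chosen = [str(p) for p in rng.choice(group_pids, size=size, replace=False)]
            call = factory.new_call()
            for pid in chosen:
                variants[f"{pid}-N"].append(_copy_call(call))
                variants[f"{pid}-R"].append(_copy_call(call))
            for gene in call.genes:
                truth.group_exclusive_recurrent_genes[group].setdefault(gene, set()).update(chosen)

    variants = {sid: _sorted_calls(calls) for sid, calls in variants.items()}

    # ----- CNA: gene-disjoint background, planted COPD-R recurrence -----
    cna: Dict[str, List[CNASegment]] = {s.sample_id: [] for s in samples}
    order = rng.permutation(len(gene_models))
    pool = iter(order)

    def take_gene() -> GeneModel:
        return gene_models[int(next(pool))]

    copd_pids = [pid for pid, g in patients if g is Group.COPD]
    planted_cna: List[Tuple[GeneModel, int]] = []
    for _ in range(config.cna_recurrent_planted_three):
        planted_cna.append((take_gene(), 3))
    for _ in range(config.cna_recurrent_planted_two):
        planted_cna.append((take_gene(), 2))

    r_unique_copd = int(round(config.cna_unique_per_sample * config.copd_r_unique_cna_excess))
    for pid, group in patients:
        shared = [_make_segment(rng, take_gene()) for _ in range(config.cna_background_per_sample)]
        for morph in (Morphology.N, Morphology.R):
            sid = f"{pid}-{morph.value}"
            cna[sid].extend(
                CNASegment(chrom=s.chrom, start=s.start, end=s.end,
                           copy_state=s.copy_state, genes=set(s.genes))
                for s in shared
            )
        cna[f"{pid}-N"].extend(
            _make_segment(rng, take_gene()) for _ in range(config.cna_unique_per_sample)
        )
        n_r_unique = r_unique_copd if group is Group.COPD else config.cna_unique_per_sample
        cna[f"{pid}-R"].extend(_make_segment(rng, take_gene()) for _ in range(n_r_unique))

    for gene, support in planted_cna:
        if len(copd_pids) < support:
            continue
        chosen = [str(p) for p in rng.choice(copd_pids, size=support, replace=False)]
        for pid in chosen:
            cna[f"{pid}-R"].append(_make_segment(rng, gene))
        truth.copd_r_unique_cna_genes[gene.gene] = set(chosen)

    cna = {sid: sorted(segs, key=lambda s: (s.chrom, s.start)) for sid, segs in cna.items()}

    # ----- expression: planted log2FC on truth-linked genes -----
    expr_rng = np.random.default_rng([config.seed, 2])
    all_symbols = [g.gene for g in gene_models]
    truth_pool = sorted(
        set().union(*truth.remodelled_only_genes.values(), truth.copd_r_unique_cna_genes)
        if truth.remodelled_only_genes or truth.copd_r_unique_cna_genes
        else set()
    )
    de_genes: List[str] = [
        str(g)
        for g in expr_rng.choice(
            truth_pool, size=min(config.expr_de_genes, len(truth_pool)), replace=False
        )
    ] if truth_pool else []
    if len(de_genes) < config.expr_de_genes:
        others = [g for g in all_symbols if g not in set(de_genes)]
        extra = expr_rng.choice(others, size=config.expr_de_genes - len(de_genes), replace=False)
        de_genes.extend(str(g) for g in extra)
    n_per = config.expr_samples_per_group
    expr_samples = [f"CTRL{i + 1:03d}" for i in range(n_per)] + [
        f"COPD{i + 1:03d}" for i in range(n_per)
    ]
    group_map = {
        s: (Group.NON_COPD if s.startswith("CTRL") else Group.COPD) for s in expr_samples
    }
    baseline = expr_rng.normal(7.0, 1.0, size=len(all_symbols))
    values = baseline[:, None] + expr_rng.normal(
        0.0, config.expr_noise_sd, size=(len(all_symbols), 2 * n_per)
    )
    row_of = {g: i for i, g in enumerate(all_symbols)}
    for j, gene in enumerate(de_genes):
        sign = 1.0 if j % 2 == 0 else -1.0
        values[row_of[gene], n_per:] += sign * config.expr_log2fc_effect
        truth.de_genes[gene] = sign * config.expr_log2fc_effect
    expression = ExpressionMatrix(
        genes=list(all_symbols), samples=expr_samples, values=values, group_map=group_map
    )

    # ----- gene sets + cilia reference (planted enrichment surface) -----
    gmt_rng = np.random.default_rng([config.seed, 3])
    gene_sets: Dict[str, Set[str]] = {}
    planted_term_genes: Set[str] = set()
    if truth_pool:
        k = min(30, len(truth_pool))
        planted_term_genes = {str(g) for g in gmt_rng.choice(truth_pool, size=k, replace=False)}
    filler = gmt_rng.choice(all_symbols, size=min(30, len(all_symbols)), replace=False)
    gene_sets["CILIUM_MOVEMENT"] = planted_term_genes | {str(g) for g in filler}
    for t in range(8):
        members = gmt_rng.choice(all_symbols, size=min(50, len(all_symbols)), replace=False)
        gene_sets[f"RANDOM_TERM_{t + 1:02d}"] = {str(g) for g in members}
    cilia_extra = gmt_rng.choice(all_symbols, size=min(80, len(all_symbols)), replace=False)
    cilia_reference = planted_term_genes | {str(g) for g in cilia_extra}

    return SyntheticCohort(
        config=config, samples=samples, gene_models=gene_models, variants=variants,
        cna=cna, expression=expression, gene_sets=gene_sets,
        cilia_reference=cilia_reference, truth=truth,
    )


def write_cohort(sc: SyntheticCohort, out_dir) -> Path:
    """Write the cohort to disk (manifest, BED, VCFs, SEGs, expression,
    GMT, cilia list, truth tables); returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = dict(sc.config.genome)

    with open(out / "genes.bed", "w") as fh:
        for gm in sc.gene_models:
            fh.write(f"{gm.chrom}\t{gm.start}\t{gm.end}\t{gm.gene}\t0\t{gm.strand}\n")

    located: List[SampleMeta] = []
    for s in sc.samples:
        vcf_name = f"{s.sample_id}.vcf"
        seg_name = f"{s.sample_id}.seg"
        write_vcf(out / vcf_name, sc.variants[s.sample_id], contigs=contigs)
        write_seg(out / seg_name, sc.cna[s.sample_id], sample=s.sample_id)
        located.append(replace(s, variant_path=out / vcf_name, cna_path=out / seg_name))
    sc.samples = located
    write_manifest(located, out / "manifest.tsv")

    write_expression(out / "expression.tsv", out / "expression_groups.tsv", sc.expression)
    write_gmt(out / "genesets.gmt", sc.gene_sets)
    (out / "cilia_reference.txt").write_text(
        "\n".join(sorted(sc.cilia_reference)) + "\n"
    )

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    rows = [
        {"patient_id": pid, "gene": g}
        for pid in sorted(sc.truth.remodelled_only_genes)
        for g in sorted(sc.truth.remodelled_only_genes[pid])
    ]
    pd.DataFrame(rows, columns=["patient_id", "gene"]).to_csv(
        truth_dir / "remodelled_only_genes.tsv", sep="\t", index=False
    )
    rows = [
        {"group": grp.value, "gene": g, "supporting_patients": ",".join(sorted(supp))}
        for grp in sorted(sc.truth.group_exclusive_recurrent_genes, key=lambda g: g.value)
        for g, supp in sorted(sc.truth.group_exclusive_recurrent_genes[grp].items())
    ]
    pd.DataFrame(rows, columns=["group", "gene", "supporting_patients"]).to_csv(
        truth_dir / "group_exclusive_recurrent_genes.tsv", sep="\t", index=False
    )
    rows = [
        {"gene": g, "supporting_patients": ",".join(sorted(supp))}
        for g, supp in sorted(sc.truth.copd_r_unique_cna_genes.items())
    ]
    pd.DataFrame(rows, columns=["gene", "supporting_patients"]).to_csv(
        truth_dir / "copd_r_unique_cna_genes.tsv", sep="\t", index=False
    )
    rows = [
        {"gene": g, "log2fc": f"{v:+.4f}"} for g, v in sorted(sc.truth.de_genes.items())
    ]
    pd.DataFrame(rows, columns=["gene", "log2fc"]).to_csv(
        truth_dir / "de_genes.tsv", sep="\t", index=False
    )
    return out / "manifest.tsv"
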