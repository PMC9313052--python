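"""File formats, domain types and coordinate conventions.

Every genomic interval is held internally as 0-based half-open
``[start, end)``.  External conventions are converted exactly once, on
read, and converted back on write:

* VCF positions are 1-based (``pos`` on :class:`VariantCall` keeps the
  1-based VCF position; the *interval* covered by its reference allele
  is ``[pos - 1, pos - 1 + len(ref))``).
* SEG rows are 1-based inclusive, i.e. external ``(start, end)`` maps to
  internal ``(start - 1, end)``.
* BED is already 0-based half-open and is taken verbatim.

Gene symbols are the join key across variants, CNA segments, gene sets
and expression data; they are upper-cased on read everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ValidationError",
    "Group",
    "Morphology",
    "Impact",
    "VType",
    "SampleMeta",
    "GeneModel",
    "VariantCall",
    "CNASegment",
    "ExpressionMatrix",
    "Cohort",
    "read_manifest",
    "write_manifest",
    "read_vcf",
    "write_vcf",
    "read_seg",
    "write_seg",
    "read_gene_bed",
    "read_gmt",
    "read_gene_list",
    "read_expression",
    "write_expression",
    "build_gene_index",
    "seg_to_internal",
    "seg_to_external",
    "load_cohort",
]


class ParseError(ValueError):
    """A file could not be parsed under its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class Group(str, Enum):
    NON_COPD = "non-COPD"
    COPD = "COPD"

    @classmethod
    def parse(cls, token: str) -> "Group":
        t = str(token).strip().upper().replace("-", "_")
        if t in ("NON_COPD", "NONCOPD"):
            return cls.NON_COPD
        if t == "COPD":
            return cls.COPD
        raise ParseError(f"unknown group token: {token!r}")


class Morphology(str, Enum):
    N = "N"  # non-remodelled epithelium
    R = "R"  # remodelled epithelium

    @classmethod
    def parse(cls, token: str) -> "Morphology":
        t = str(token).strip().upper()
        if t in ("N", "R"):
            return cls(t)
        raise ParseError(f"unknown morphology token: {token!r}")

    @property
    def other(self) -> "Morphology":
        return Morphology.R if self is Morphology.N else Morphology.N


class Impact(str, Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    LOW = "LOW"
    MODIFIER = "MODIFIER"


#: severity rank used when taking the maximum impact over several keys
IMPACT_RANK = {Impact.HIGH: 3, Impact.MODERATE: 2, Impact.LOW: 1, Impact.MODIFIER: 0}


class VType(str, Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class SampleMeta:
    """One microdissected sample of a patient's bronchial epithelium."""

    sample_id: str
    patient_id: str
    group: Group
    morphology: Morphology
    variant_path: Optional[Path] = None
    cna_path: Optional[Path] = None


@dataclass(frozen=True)
class GeneModel:
    """A gene body interval; strand is carried but ignored by analyses."""

    gene: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene}: start must be < end ({self.start} >= {self.end})"
            )


@dataclass
class VariantCall:
    """A normalized small variant (single alt allele) with annotation.

    ``pos`` is the 1-based VCF position of the normalized allele pair.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: VType
    consequence: Optional[str] = None
    impact: Impact = Impact.MODIFIER
    genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos} ref == alt ({self.ref})")

    @property
    def interval(self) -> tuple:
        """0-based half-open interval covered by the reference allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


CopyState = Union[str, int]


@dataclass
class CNASegment:
    """A copy-number-altered interval (0-based half-open) with gene overlap."""

    chrom: str
    start: int
    end: int
    copy_state: CopyState
    genes: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"CNA segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )


@dataclass
class ExpressionMatrix:
    """Gene-by-sample log2 expression with a sample-to-group map."""

    genes: list
    samples: list
    values: np.ndarray
    group_map: dict

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        missing = [s for s in self.samples if s not in self.group_map]
        if missing:
            raise ValidationError(f"samples missing from group map: {missing[:5]}")

    def gene_values(self, gene: str, group: Group) -> np.ndarray:
        idx = self.genes.index(gene)
        cols = [j for j, s in enumerate(self.samples) if self.group_map[s] == group]
        return self.values[idx, cols]


# ---------------------------------------------------------------------------
# coordinate conversion (SEG dialect: 1-based inclusive)


def seg_to_internal(start: int, end: int) -> tuple:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def seg_to_external(start: int, end: int) -> tuple:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# manifest

MANIFEST_COLUMNS = ["sample_id", "patient_id", "group", "morphology", "variant_path", "cna_path"]


def read_manifest(path, require_paired: bool = True) -> list:
    """Read the cohort manifest TSV into validated :class:`SampleMeta` rows.

    Checks that (patient, morphology) is unique and, when
    ``require_paired``, that every patient carries exactly one N and one
    R sample.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    samples = []
    base = path.parent
    for row in df.itertuples(index=False):
        vp = getattr(row, "variant_path")
        cp = getattr(row, "cna_path")
        samples.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                patient_id=str(row.patient_id),
                group=Group.parse(row.group),
                morphology=Morphology.parse(row.morphology),
                variant_path=None if pd.isna(vp) else (base / str(vp)),
                cna_path=None if pd.isna(cp) else (base / str(cp)),
            )
        )
    seen = set()
    for s in samples:
        k = (s.patient_id, s.morphology)
        if k in seen:
            raise ValidationError(
                f"{path}: duplicate sample for patient {s.patient_id} morphology {s.morphology.value}"
            )
        seen.add(k)
    if require_paired:
        patients = {s.patient_id for s in samples}
        for p in sorted(patients):
            morphs = {s.morphology for s in samples if s.patient_id == p}
            if morphs != {Morphology.N, Morphology.R}:
                raise ValidationError(
                    f"{path}: patient {p} must have exactly one N and one R sample"
                )
    return samples


def write_manifest(samples: Iterable[SampleMeta], path) -> None:
    path = Path(path)
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "group": s.group.value,
                "morphology": s.morphology.value,
                "variant_path": "" if s.variant_path is None else Path(s.variant_path).name,
                "cna_path": "" if s.cna_path is None else Path(s.cna_path).name,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF

_SYMBOLIC = ("<", ">", "[", "]", ".", "*")


def read_vcf(path) -> list:
    """Read a VCF 4.2 file into normalized :class:`VariantCall` records.

    Multi-allelic records are split into one call per alt allele;
    symbolic/breakend alleles are skipped with a warning.  Alleles are
    normalized (suffix then prefix trimming) on read.  ``genes`` is left
    empty; use :func:`remodelprint.variants.annotate_genes` to fill it.
    """
    from .variants import classify_impact, classify_vtype, normalize_variant

    calls = []
    idx = 0
    try:
        with pysam.VariantFile(str(path)) as vf:
            for idx, rec in enumerate(vf, 1):
                csq = rec.info.get("CSQ") if "CSQ" in rec.info else None
                if isinstance(csq, tuple):
                    csq = csq[0]
                for alt in rec.alts or ():
                    if alt is None or any(c in alt for c in _SYMBOLIC) or not alt.isalpha():
                        log.warning(
                            "%s: skipping symbolic/non-sequence alt %r at %s:%s",
                            path, alt, rec.chrom, rec.pos,
                        )
                        continue
                    key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt)
                    impact = (
                        classify_impact(csq) if csq is not None else Impact.MODIFIER
                    )
                    calls.append(
                        VariantCall(
                            chrom=key.chrom,
                            pos=key.pos,
                            ref=key.ref,
                            alt=key.alt,
                            vtype=classify_vtype(key.ref, key.alt),
                            consequence=csq,
                            impact=impact,
                        )
                    )
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: malformed VCF near record {idx + 1}: {exc}") from exc
    return calls


def write_vcf(path, calls: Iterable[VariantCall], contigs: Optional[Mapping[str, int]] = None) -> None:
    """Write calls as a minimal, deterministic VCF 4.2 text file."""
    lines = ["##fileformat=VCFv4.2"]
    lines.append('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence term">')
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in calls:
        info = f"CSQ={c.consequence}" if c.consequence else "."
        lines.append(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SEG

SEG_COLUMNS = ["sample", "chrom", "start", "end", "copy_state"]


def _parse_copy_state(token) -> CopyState:
    s = str(token).strip()
    try:
        return int(s)
    except ValueError:
        pass
    u = s.upper()
    if u in ("GAIN", "LOSS"):
        return u
    raise ParseError(f"unknown copy_state token: {token!r}")


def read_seg(path) -> list:
    """Read a SEG-like TSV (1-based inclusive) into internal segments.

    Segments are returned sorted by (chrom, start); per-sample
    non-overlap on each chromosome is validated.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: SEG file missing columns {missing}")
    segments = []
    by_key = {}
    for row in df.itertuples(index=False):
        ext_start, ext_end = int(row.start), int(row.end)
        if ext_start >= ext_end:
            raise ParseError(
                f"{path}: segment {row.chrom}:{ext_start}-{ext_end} has start >= end"
            )
        start, end = seg_to_internal(ext_start, ext_end)
        seg = CNASegment(
            chrom=str(row.chrom), start=start, end=end, copy_state=_parse_copy_state(row.copy_state)
        )
        segments.append(seg)
        by_key.setdefault((str(row.sample), str(row.chrom)), []).append(seg)
    for (sample, chrom), segs in by_key.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{path}: overlapping segments in sample {sample} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    segments.sort(key=lambda s: (s.chrom, s.start, s.end))
    return segments


def write_seg(path, segments: Iterable[CNASegment], sample: str) -> None:
    rows = []
    for seg in segments:
        ext_start, ext_end = seg_to_external(seg.start, seg.end)
        rows.append(
            {"sample": sample, "chrom": seg.chrom, "start": ext_start, "end": ext_end,
             "copy_state": seg.copy_state}
        )
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / GMT / gene list / expression


def read_gene_bed(path) -> list:
    """Read a BED4(+strand) gene model; symbols upper-cased."""
    models = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln}: BED needs >= 4 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3].upper()
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            if start >= end:
                raise ParseError(f"{path}:{ln}: start >= end ({start} >= {end})")
            key = (name, chrom)
            if key in seen:
                raise ValidationError(f"{path}:{ln}: duplicate gene symbol {name} on {chrom}")
            seen.add(key)
            models.append(GeneModel(gene=name, chrom=chrom, start=start, end=end, strand=strand))
    return models


def read_gmt(path) -> dict:
    """Read GMT gene sets (term, description, genes...); empty terms dropped."""
    gene_sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: GMT line needs term and description")
            term = parts[0]
            genes = {g.upper() for g in parts[2:] if g}
            if not genes:
                log.warning("%s:%d: term %s has zero genes; dropped", path, ln, term)
                continue
            gene_sets[term] = genes
    return gene_sets


def write_gmt(path, gene_sets: Mapping[str, set]) -> None:
    with open(path, "w") as fh:
        for term in gene_sets:
            genes = "\t".join(sorted(gene_sets[term]))
            fh.write(f"{term}\tsynthetic\t{genes}\n")


def read_gene_list(path) -> set:
    """Read a one-symbol-per-line gene list (e.g. a cilia reference list)."""
    out = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip().upper()
            if g:
                out.add(g)
    return out


def read_expression(path, group_map_path) -> ExpressionMatrix:
    """Read a gene x sample TSV matrix plus a sample-to-group map TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    gm = pd.read_csv(group_map_path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(gm.columns):
        raise ParseError(f"{group_map_path}: group map needs sample_id and group columns")
    group_map = {str(r.sample_id): Group.parse(r.group) for r in gm.itertuples(index=False)}
    return ExpressionMatrix(
        genes=[str(g).upper() for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        group_map=group_map,
    )


def write_expression(path, group_map_path, matrix: ExpressionMatrix) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.genes, columns=matrix.samples)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.4f")
    pd.DataFrame(
        {"sample_id": matrix.samples,
         "group": [matrix.group_map[s].value for s in matrix.samples]}
    ).to_csv(group_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene interval index and cohort container


def build_gene_index(gene_models: Iterable[GeneModel]) -> dict:
    """Per-chromosome interval trees keyed by gene symbol."""
    trees: dict = {}
    for gm in gene_models:
        trees.setdefault(gm.chrom, IntervalTree()).addi(gm.start, gm.end, gm.gene)
    return trees


@dataclass
class Cohort:
    """Loaded study: samples, gene model and per-sample calls/segments."""

    samples: list
    gene_models: list
    variants: dict  # sample_id -> list[VariantCall]
    cna: dict  # sample_id -> list[CNASegment]

    def sample(self, patient_id: str, morphology: Morphology) -> SampleMeta:
        for s in self.samples:
            if s.patient_id == patient_id and s.morphology == morphology:
                return s
        raise KeyError(f"no sample for patient {patient_id} morphology {morphology.value}")

    def paired(self, sample: SampleMeta) -> SampleMeta:
        return self.sample(sample.patient_id, sample.morphology.other)

    def of(self, group: Optional[Group] = None, morphology: Optional[Morphology] = None) -> list:
        return [
            s
            for s in self.samples
            if (group is None or s.group == group)
            and (morphology is None or s.morphology == morphology)
        ]

    @property
    def groups(self) -> list:
        out = []
        for s in self.samples:
            if s.group not in out:
                out.append(s.group)
        return out


def load_cohort(manifest_path, genes_bed_path) -> Cohort:
    """Read manifest + gene BED + all per-sample VCF/SEG files and annotate genes."""
    from .cna import annotate_segment_genes
    from .variants import annotate_genes

    samples = read_manifest(manifest_path)
    gene_models = read_gene_bed(genes_bed_path)
    index = build_gene_index(gene_models)
    variants = {}
    cna = {}
    for s in samples:
        calls = read_vcf(s.variant_path) if s.variant_path else []
        annotate_genes(calls, index)
        variants[s.sample_id] = calls
        segs = read_seg(s.cna_path) if s.cna_path else []
        annotate_segment_genes(segs, index)
        cna[s.sample_id] = segs
    return Cohort(samples=samples, gene_models=gene_models, variants=variants, cna=cna)
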