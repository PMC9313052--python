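"""Stage orchestration: simulate -> compare-variants -> compare-cna ->
integrate -> report, driven by a single YAML config and one seed.

Each stage is a plain function writing TSV outputs into a run directory,
so stages compose from the CLI or directly from Python.  All randomness
flows from the config seed; rerunning into a clean directory reproduces
byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Set

import pandas as pd
import yaml

from . import cna as cna_mod
from . import integrate as integ
from . import stats as stats_mod
from . import variants as var_mod
from .io import Cohort, Group, Morphology, load_cohort, read_expression, read_gene_list, read_gmt
from .simulate import SimConfig, generate_cohort, write_cohort
from .variants import ComparativeMode

log = logging.getLogger(__name__)

__all__ = [
    "stage_simulate",
    "stage_compare_variants",
    "stage_compare_cna",
    "stage_integrate",
    "stage_report",
    "run_all",
]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def stage_simulate(sim_config: SimConfig, out_dir) -> Path:
    sc = generate_cohort(sim_config)
    manifest = write_cohort(sc, out_dir)
    log.info("simulated cohort written to %s", out_dir)
    return manifest


def stage_compare_variants(
    cohort: Cohort,
    out_dir,
    mode: ComparativeMode = ComparativeMode.WITHIN_PATIENT,
    min_samples: int = 2,
) -> Dict[str, pd.DataFrame]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vsets = var_mod.build_variant_sets(cohort)
    glob_ps, glob_sum = var_mod.count_global(vsets)
    comp_ps, comp_sum = var_mod.count_comparative(vsets, cohort, mode)
    glob_ps = glob_ps.assign(analysis="global")
    comp_ps = comp_ps.assign(analysis="comparative")
    per_sample = pd.concat([glob_ps, comp_ps], ignore_index=True)
    summary = pd.concat(
        [glob_sum.assign(analysis="global"), comp_sum.assign(analysis="comparative")],
        ignore_index=True,
    )
    goi = var_mod.remodelled_only_genes(cohort, vsets) + var_mod.group_exclusive_recurrent_genes(
        cohort, vsets, min_samples=min_samples
    )
    goi_df = pd.DataFrame(
        [
            {
                "gene": g.gene,
                "category": g.category.value,
                "group": g.group.value,
                "supporting_samples": ",".join(sorted(g.supporting_samples)),
                "keys": ";".join(f"{k.chrom}:{k.pos}:{k.ref}>{k.alt}" for k in g.keys),
                "max_impact": g.max_impact.value,
                "bold": g.bold,
                "underline": g.underline,
            }
            for g in goi
        ],
        columns=["gene", "category", "group", "supporting_samples", "keys",
                 "max_impact", "bold", "underline"],
    )
    _write(per_sample, out / "variant_counts_per_sample.tsv")
    _write(summary, out / "variant_counts_summary.tsv")
    _write(goi_df, out / "goi_variants.tsv")
    return {"per_sample": per_sample, "summary": summary, "goi": goi_df}


def stage_compare_cna(
    cohort: Cohort,
    out_dir,
    mode: ComparativeMode = ComparativeMode.WITHIN_PATIENT,
    min_samples: int = 2,
    match: str = "exact",
    overlap_frac: float = 0.5,
) -> Dict[str, pd.DataFrame]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    glob_ps, glob_sum = cna_mod.count_cna_global(cohort)
    comp_ps, comp_sum = cna_mod.count_cna_comparative(
        cohort, mode, match=match, overlap_frac=overlap_frac
    )
    per_sample = pd.concat(
        [glob_ps.assign(analysis="global"), comp_ps.assign(analysis="comparative")],
        ignore_index=True,
    )
    summary = pd.concat(
        [glob_sum.assign(analysis="global"), comp_sum.assign(analysis="comparative")],
        ignore_index=True,
    )

    venn_rows, uniq_rows = [], []
    for group in cohort.groups:
        r_set = cna_mod.group_gene_set(cohort, group, Morphology.R)
        n_set = cna_mod.group_gene_set(cohort, group, Morphology.N)
        part = cna_mod.venn(r_set, n_set)
        venn_rows.append(
            {"comparison": f"{group.value} R vs {group.value} N",
             "only_a": len(part.only_a), "shared": len(part.shared),
             "only_b": len(part.only_b)}
        )
        if r_set:
            uniq_rows.append(
                {"comparison": f"{group.value} R vs {group.value} N",
                 "unique_pct": cna_mod.unique_fraction(r_set, n_set)}
            )
    goi = cna_mod.recurrent_cna_genes(cohort, min_samples=min_samples)
    goi_df = pd.DataFrame(
        [
            {
                "gene": g.gene,
                "comparison": g.comparison.value,
                "supporting_samples": ",".join(sorted(g.supporting_samples)),
                "bold": g.bold,
            }
            for g in goi
        ],
        columns=["gene", "comparison", "supporting_samples", "bold"],
    )
    _write(per_sample, out / "cna_counts_per_sample.tsv")
    _write(summary, out / "cna_counts_summary.tsv")
    _write(pd.DataFrame(venn_rows), out / "venn.tsv")
    _write(pd.DataFrame(uniq_rows), out / "unique_fractions.tsv")
    _write(goi_df, out / "goi_cna.tsv")
    return {"per_sample": per_sample, "summary": summary, "goi": goi_df,
            "venn": pd.DataFrame(venn_rows), "unique_fractions": pd.DataFrame(uniq_rows)}


def stage_integrate(
    cohort: Cohort,
    variant_goi_genes: Set[str],
    cna_goi_genes: Set[str],
    out_dir,
    gmt_path=None,
    cilia_path=None,
    expression_path=None,
    expression_groups_path=None,
    test_mode: str = "welch",
    fdr_threshold: float = 0.05,
) -> Dict[str, pd.DataFrame]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, pd.DataFrame] = {}

    inter, union = integ.joint_genes(variant_goi_genes, cna_goi_genes)
    joint_df = pd.DataFrame(
        sorted(
            [{"gene": g, "in_variants": g in variant_goi_genes,
              "in_cna": g in cna_goi_genes, "joint": g in inter} for g in union],
            key=lambda r: r["gene"],
        ),
        columns=["gene", "in_variants", "in_cna", "joint"],
    )
    _write(joint_df, out / "joint_genes.tsv")
    results["joint"] = joint_df

    background = {gm.gene for gm in cohort.gene_models}
    if gmt_path is not None:
        annotations = read_gmt(gmt_path)
        enr = integ.enrich(union, annotations, background)
        enr_df = pd.DataFrame(
            [{"term": e.term, "observed": e.observed, "expected": e.expected,
              "strength": e.strength, "p": e.p, "fdr": e.fdr} for e in enr],
            columns=["term", "observed", "expected", "strength", "p", "fdr"],
        )
        _write(enr_df, out / "enrichment.tsv")
        results["enrichment"] = enr_df
    else:
        log.warning("no GMT supplied; enrichment stage skipped")

    if cilia_path is not None and union:
        reference = read_gene_list(cilia_path)
        overlap, pct = integ.list_overlap(union, reference)
        ov_df = pd.DataFrame(
            {"gene": sorted(union), "in_reference": [g in overlap for g in sorted(union)]}
        )
        ov_df.attrs["overlap_pct"] = pct
        _write(ov_df, out / "overlap.tsv")
        pd.DataFrame(
            [{"n_query": len(union), "n_overlap": len(overlap), "overlap_pct": pct}]
        ).to_csv(out / "overlap_summary.tsv", sep="\t", index=False)
        results["overlap"] = ov_df
    elif cilia_path is None:
        log.warning("no reference gene list supplied; overlap stage skipped")

    if expression_path is not None and expression_groups_path is not None:
        matrix = read_expression(expression_path, expression_groups_path)
        xr, n_detected, n_dereg = integ.expression_crossref(
            union, matrix, test_mode=test_mode, fdr_threshold=fdr_threshold
        )
        xr_df = pd.DataFrame(
            [{"gene": r.gene, "log2fc": r.log2fc, "p": r.p, "fdr": r.fdr,
              "deregulated": r.deregulated} for r in xr],
            columns=["gene", "log2fc", "p", "fdr", "deregulated"],
        )
        xr_df.attrs["n_detected"] = n_detected
        xr_df.attrs["n_deregulated"] = n_dereg
        _write(xr_df, out / "expression_crossref.tsv")
        results["expression"] = xr_df
    else:
        log.warning("no expression matrix supplied; cross-reference stage skipped")
    return results


_CONTRASTS = [
    ("COPD N vs non-COPD N", Group.COPD, Morphology.N, Group.NON_COPD, Morphology.N),
    ("COPD R vs non-COPD N", Group.COPD, Morphology.R, Group.NON_COPD, Morphology.N),
    ("COPD R vs non-COPD R", Group.COPD, Morphology.R, Group.NON_COPD, Morphology.R),
    ("COPD R vs COPD N", Group.COPD, Morphology.R, Group.COPD, Morphology.N),
    ("non-COPD R vs non-COPD N", Group.NON_COPD, Morphology.R, Group.NON_COPD, Morphology.N),
]


def stage_report(run_dir) -> Dict[str, pd.DataFrame]:
    """Join stage outputs into summary.tsv and tests.tsv.

    Per-stratum t-tests and fold changes are computed on the comparative
    per-sample counts (variants and CNA loci) for the standard contrasts.
    """
    run = Path(run_dir)
    frames = []
    for stem, metric_cols in [
        ("variant_counts_per_sample", ["n_positions", "n_genes"]),
        ("cna_counts_per_sample", ["n_loci", "n_genes"]),
    ]:
        path = run / f"{stem}.tsv"
        if path.exists():
            frames.append((stem, pd.read_csv(path, sep="\t"), metric_cols))
    summary_rows, test_rows = [], []
    for stem, df, metric_cols in frames:
        kind = "variants" if stem.startswith("variant") else "cna"
        for analysis in df["analysis"].unique():
            sub = df[df["analysis"] == analysis]
            summ = stats_mod.stratum_summary(sub, metric_cols)
            summ = summ.assign(dataset=kind, analysis=analysis)
            summary_rows.append(summ)
            if analysis != "comparative":
                continue
            metric = metric_cols[0]  # positions / loci
            for label, g1, m1, g2, m2 in _CONTRASTS:
                a = sub[(sub["group"] == g1.value) & (sub["morphology"] == m1.value)][metric]
                b = sub[(sub["group"] == g2.value) & (sub["morphology"] == m2.value)][metric]
                if len(a) < 2 or len(b) < 2:
                    continue
                res = stats_mod.two_sample_t(a, b, equal_var=True, contrast=label)
                fc = (
                    stats_mod.fold_change(a.mean(), b.mean()) if b.mean() > 0 else float("nan")
                )
                test_rows.append(
                    {"dataset": kind, "metric": metric, "contrast": label,
                     "t": res.t, "p": res.p, "star": stats_mod.significance_star(res.p),
                     "fold_change": fc}
                )
    summary = pd.concat(summary_rows, ignore_index=True) if summary_rows else pd.DataFrame()
    tests = pd.DataFrame(
        test_rows, columns=["dataset", "metric", "contrast", "t", "p", "star", "fold_change"]
    )
    _write(summary, run / "summary.tsv")
    _write(tests, run / "tests.tsv")
    return {"summary": summary, "tests": tests}


def run_all(config: dict, out_dir) -> Path:
    """Run every stage under ``out_dir`` from a config mapping.

    The config either carries a ``simulate`` section (possibly empty:
    defaults apply) or a ``paths`` section naming manifest, genes_bed
    and the optional GMT / cilia list / expression inputs.  The config
    is snapshotted into the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    mode = ComparativeMode(config.get("mode", "within_patient"))
    thresholds = config.get("thresholds", {}) or {}
    min_samples = int(thresholds.get("min_samples", 2))
    fdr_threshold = float(thresholds.get("fdr", 0.05))

    with open(out / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    if "paths" in config and config["paths"]:
        paths = {k: Path(v) for k, v in config["paths"].items()}
    else:
        overrides = dict(config.get("simulate", {}) or {})
        overrides["seed"] = seed
        sim_cfg = SimConfig(**overrides)
        data_dir = out / "data"
        stage_simulate(sim_cfg, data_dir)
        paths = {
            "manifest": data_dir / "manifest.tsv",
            "genes_bed": data_dir / "genes.bed",
            "gmt": data_dir / "genesets.gmt",
            "cilia_list": data_dir / "cilia_reference.txt",
            "expression": data_dir / "expression.tsv",
            "expression_groups": data_dir / "expression_groups.tsv",
        }
    for key in ("manifest", "genes_bed"):
        if key not in paths or not Path(paths[key]).exists():
            raise FileNotFoundError(f"run_all: required input '{key}' missing")

    cohort = load_cohort(paths["manifest"], paths["genes_bed"])
    var_out = stage_compare_variants(cohort, out, mode=mode, min_samples=min_samples)
    cna_out = stage_compare_cna(cohort, out, mode=mode, min_samples=min_samples)
    variant_goi = set(var_out["goi"]["gene"])
    cna_goi = set(cna_out["goi"]["gene"])

    def optional(key):
        p = paths.get(key)
        return p if (p is not None and Path(p).exists()) else None

    stage_integrate(
        cohort, variant_goi, cna_goi, out,
        gmt_path=optional("gmt"),
        cilia_path=optional("cilia_list"),
        expression_path=optional("expression"),
        expression_groups_path=optional("expression_groups"),
        fdr_threshold=fdr_threshold,
    )
    stage_report(out)
    log.info("run complete: %s", out)
    return out
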