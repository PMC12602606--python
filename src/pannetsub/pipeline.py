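"""End-to-end orchestration of the two-level subtyping analysis.

Level 1 (methylation): filter probes, select the 2000 most variable by
MAD, consensus-cluster at k = 2, name the clusters by DAXX/ATRX-loss
enrichment (the enriched cluster is ADM, the other alpha-like), then
run differential methylation, chromatin-state over-representation and
structural-region statistics between the two.

Level 2 (expression, ADM samples only): consensus-cluster the 2000 most
variable genes, exclude clusters below ``min_cluster_size`` from
testing, run one-vs-rest NB differential expression, gene-set
enrichment, signature scoring, and the promoter
methylation-expression anti-correlation screen per subtype.

Every output is a TSV/JSON file in the run directory; all randomness
flows from the single config seed, so identical configs give
byte-identical run directories.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .consensus import cdf_and_delta_area, consensus_cluster
from .diffexpr import filter_low_counts, nb_test_one_vs_rest, size_factors, vst_like
from .diffmeth import (
    chromatin_state_ora,
    define_structural_regions,
    dmp_test,
    region_group_test,
    region_medians,
)
from .integration import anticorrelation_screen, promoter_probe_pairs
from .methylation import beta_to_m, filter_probes, select_top_mad
from .signatures import gsea_preranked, signature_score
from .survival import chisq_simulated, dichotomize_size, km_estimate, logrank_test
from .synthetic import ALPHA_LIKE, ToyGenome, read_genome

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the two-level analysis."""

    manifest: str = "manifest.tsv"
    beta: str = "beta.tsv"
    counts: str = "counts.tsv"
    sample_sheet: str = "sample_sheet.tsv"
    genome: str = "genome.tsv"
    gene_sets: str | None = None  # GMT for enrichment
    signature_sets: str | None = None  # GMT of signatures to score
    out_dir: str = "run"
    seed: int = 0

    top_n: int = 2000
    reps: int = 1000
    p_item: float = 0.8
    p_feature: float = 1.0
    max_k_methylation: int = 6
    max_k_expression: int = 8
    k_methylation: int = 2
    k_expression: int = 4
    min_cluster_size: int = 3

    dmp_p_adj: float = 0.001
    dmp_min_delta_beta: float = 0.2
    deg_log2fc: float = 1.0
    deg_p_adj: float = 0.05
    rho_threshold: float = -0.6
    assoc_p_adj: float = 0.05
    tel_window_bp: int = 2_000_000
    cen_window_bp: int = 2_000_000
    epsilon: float = 0.001
    size_threshold_cm: float = 2.5
    gsea_n_perm: int = 1000

    def __post_init__(self):
        if not 0 < self.p_item <= 1:
            raise ValueError("p_item must lie in (0, 1]")
        for name in ("dmp_p_adj", "deg_p_adj", "assoc_p_adj"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not -1 < self.rho_threshold < 0:
            raise ValueError("rho_threshold must lie in (-1, 0)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep="NA", float_format=FLOAT_FMT, index=index,
              lineterminator="\n")


def name_methylation_clusters(
    assignments: pd.Series, sheet: pd.DataFrame
) -> pd.Series:
    """Map the k=2 cluster indices to alpha-like / ADM names.

    The cluster with the higher fraction of DAXX/ATRX-lost samples is
    ADM; cluster indices are arbitrary, so naming is marker-driven. If
    the marker column is absent the clusters stay unnamed
    (``cluster_1``/``cluster_2``) with a warning.
    """
    if "daxx_atrx_lost" not in sheet.columns:
        warnings.warn("daxx_atrx_lost missing; emitting unnamed clusters")
        return assignments.map(lambda c: f"cluster_{c}")
    marker = sheet["daxx_atrx_lost"].reindex(assignments.index)
    frac = marker.groupby(assignments).mean().sort_values(ascending=False)
    adm_cluster = frac.index[0]
    return assignments.map(
        lambda c: "ADM" if c == adm_cluster else ALPHA_LIKE
    )


def run_methylation_level(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    genome: ToyGenome,
    config: PipelineConfig,
    fail_mask: pd.DataFrame | None = None,
) -> dict:
    """Methylation-level clustering, DMPs, state ORA, region statistics."""
    beta_f, removal = filter_probes(beta, manifest, fail_mask=fail_mask)
    top = select_top_mad(beta_f, min(config.top_n, beta_f.shape[0]))
    result = consensus_cluster(
        beta_f.loc[top],
        k_range=range(2, config.max_k_methylation + 1),
        reps=config.reps,
        p_item=config.p_item,
        p_feature=config.p_feature,
        seed=config.seed,
    )
    curves = cdf_and_delta_area(result)
    labels = name_methylation_clusters(
        result.assignments[config.k_methylation], sheet
    )
    labels.name = "epigenetic_subtype"

    named = set(labels.unique()) == {ALPHA_LIKE, "ADM"}
    dmp = region_tests = state_ora = medians = None
    if named:
        dmp = dmp_test(
            beta_f, labels, reference=ALPHA_LIKE,
            p_adj_threshold=config.dmp_p_adj,
            min_delta_beta=config.dmp_min_delta_beta,
        )
        manifest_f = manifest[manifest["probe_id"].isin(beta_f.index)]
        state_ora = chromatin_state_ora(
            set(dmp.index[dmp["significant"]]), manifest_f
        )
        region_map = define_structural_regions(
            genome, config.tel_window_bp, config.cen_window_bp,
            manifest=manifest_f,
        )
        medians = region_medians(beta_f, region_map)
        region_tests = region_group_test(medians, labels, reference=ALPHA_LIKE)
    return {
        "filtered_beta": beta_f,
        "removed_probes": removal,
        "consensus": result,
        "curves": curves,
        "labels": labels,
        "dmp": dmp,
        "state_ora": state_ora,
        "region_medians": medians,
        "region_tests": region_tests,
    }


def run_expression_level(
    counts: pd.DataFrame,
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    adm_samples: list,
    config: PipelineConfig,
    gene_sets=None,
    signature_sets=None,
) -> dict:
    """Expression-level clustering, DE, enrichment, signatures, integration.

    Alpha-like samples are excluded up front; transcriptomic clusters
    smaller than ``min_cluster_size`` are flagged and excluded from
    one-vs-rest testing (they remain in the "rest" pool).
    """
    cols = [s for s in counts.columns if s in set(adm_samples)]
    if len(cols) < config.min_cluster_size * 2:
        raise ValueError(f"only {len(cols)} ADM samples with expression data")
    counts = counts[cols]
    counts_f = filter_low_counts(counts)
    factors = size_factors(counts_f)
    expr = vst_like(counts_f, factors)
    top = select_top_mad(expr, min(config.top_n, expr.shape[0]))
    result = consensus_cluster(
        expr.loc[top],
        k_range=range(2, config.max_k_expression + 1),
        reps=config.reps,
        p_item=config.p_item,
        p_feature=config.p_feature,
        seed=config.seed + 1,
    )
    curves = cdf_and_delta_area(result)
    clusters = result.assignments[config.k_expression]
    labels = clusters.map(lambda c: f"E{c}")
    labels.name = "transcriptomic_subtype"

    sizes = labels.value_counts()
    usable = sorted(sizes.index[sizes >= config.min_cluster_size])
    excluded = sorted(sizes.index[sizes < config.min_cluster_size])
    if excluded:
        warnings.warn(
            f"clusters below min size {config.min_cluster_size} excluded "
            f"from testing: {excluded}"
        )
    if len(usable) < 2:
        raise RuntimeError("fewer than two usable transcriptomic clusters")

    m_values = beta_to_m(beta[cols], epsilon=config.epsilon)
    deg_tables, gsea_tables, assoc_tables = {}, {}, {}
    for st in usable:
        deg = nb_test_one_vs_rest(
            counts_f, labels, st, factors=factors,
            log2fc_threshold=config.deg_log2fc,
            p_adj_threshold=config.deg_p_adj,
        )
        deg_tables[st] = deg
        if gene_sets is not None and len(gene_sets):
            ranked = deg["wald_statistic"].dropna()
            gsea_tables[st] = gsea_preranked(
                ranked, gene_sets, n_perm=config.gsea_n_perm,
                seed=config.seed + 2,
            )
        pairs = promoter_probe_pairs(manifest, deg)
        assoc_tables[st] = anticorrelation_screen(
            m_values, expr, pairs, deg_table=deg,
            rho_threshold=config.rho_threshold,
            p_adj_threshold=config.assoc_p_adj,
        )

    scores = None
    if signature_sets is not None and len(signature_sets):
        frames = [
            signature_score(expr, signature_sets.members(name), name=name)
            for name in sorted(signature_sets)
        ]
        scores = pd.concat(frames, ignore_index=True)
        scores["transcriptomic_subtype"] = labels.reindex(
            scores["sample_id"]
        ).to_numpy()
    return {
        "expr": expr,
        "factors": factors,
        "consensus": result,
        "curves": curves,
        "labels": labels,
        "excluded_clusters": excluded,
        "deg": deg_tables,
        "gsea": gsea_tables,
        "associations": assoc_tables,
        "signature_scores": scores,
    }


def run_survival_level(sheet: pd.DataFrame, labels: pd.Series,
                       config: PipelineConfig) -> dict:
    """KM curves and log-rank across subtypes; size association test."""
    sub = sheet.loc[labels.index]
    out: dict = {}
    if {"dfs_time", "dfs_event"} <= set(sub.columns):
        times = sub["dfs_time"].to_numpy(dtype=float)
        events = sub["dfs_event"].to_numpy(dtype=int)
        out["km"] = km_estimate(times, events, labels.to_numpy())
        stat, df, p = logrank_test(times, events, labels.to_numpy())
        out["logrank"] = pd.DataFrame(
            [{"chi_square": stat, "df": df, "p_value": p}]
        )
    if "tumor_size_cm" in sub.columns:
        size_cat = dichotomize_size(
            sub["tumor_size_cm"], threshold=config.size_threshold_cm
        )
        tab = pd.crosstab(labels, size_cat)
        if tab.shape[0] >= 2 and tab.shape[1] >= 2:
            stat, p = chisq_simulated(tab.to_numpy(), n_sim=2000,
                                      seed=config.seed + 3)
            out["size_table"] = tab
            out["size_test"] = pd.DataFrame(
                [{"chi_square": stat, "p_simulated": p,
                  "threshold_cm": config.size_threshold_cm}]
            )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full two-level analysis from files named in ``config``.

    Returns the run directory path. Intermediate tables are written as
    stages complete, so a failed stage leaves earlier outputs behind.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = pio.read_manifest(config.manifest)
    beta = pio.read_matrix(config.beta, "beta")
    counts = pio.read_matrix(config.counts, "counts")
    sheet = pio.read_sample_sheet(config.sample_sheet)
    genome = read_genome(config.genome)
    gene_sets = pio.read_gmt(config.gene_sets) if config.gene_sets else None
    signature_sets = (
        pio.read_gmt(config.signature_sets) if config.signature_sets else None
    )

    meth_samples = [s for s in beta.columns if s in set(sheet.index)]
    beta_m = beta[meth_samples]
    sheet_m = sheet.loc[meth_samples]

    meth = run_methylation_level(beta_m, manifest, sheet_m, genome, config)
    mdir = out / "methylation"
    _write(meth["labels"].to_frame(), mdir / "epigenetic_subtypes.tsv")
    _write(meth["curves"], mdir / "cdf_delta_area.tsv", index=False)
    _write(meth["removed_probes"], mdir / "removed_probes.tsv", index=False)
    _write(meth["consensus"].consensus_frame(config.k_methylation),
           mdir / f"consensus_k{config.k_methylation}.tsv")
    if meth["dmp"] is not None:
        _write(meth["dmp"], mdir / "dmp_table.tsv")
        _write(meth["state_ora"], mdir / "state_ora.tsv", index=False)
        _write(meth["region_medians"], mdir / "region_medians.tsv", index=False)
        _write(meth["region_tests"], mdir / "region_tests.tsv", index=False)

    labels = meth["labels"]
    adm = sorted(labels.index[labels == "ADM"])
    expr_res = None
    if adm and len(set(adm) & set(counts.columns)) >= config.min_cluster_size * 2:
        expr_res = run_expression_level(
            counts, beta_m, manifest, sheet_m, adm, config,
            gene_sets=gene_sets, signature_sets=signature_sets,
        )
        edir = out / "expression"
        _write(expr_res["labels"].to_frame(), edir / "transcriptomic_subtypes.tsv")
        _write(expr_res["curves"], edir / "cdf_delta_area.tsv", index=False)
        _write(expr_res["consensus"].consensus_frame(config.k_expression),
               edir / f"consensus_k{config.k_expression}.tsv")
        for st, deg in expr_res["deg"].items():
            _write(deg, edir / f"deg_{st}.tsv")
        for st, g in expr_res["gsea"].items():
            _write(g, edir / f"gsea_{st}.tsv", index=False)
        for st, a in expr_res["associations"].items():
            _write(a, edir / f"associations_{st}.tsv", index=False)
        if expr_res["signature_scores"] is not None:
            _write(expr_res["signature_scores"],
                   edir / "signature_scores.tsv", index=False)

        surv = run_survival_level(sheet_m, expr_res["labels"], config)
        sdir = out / "survival"
        for name, table in surv.items():
            _write(table, sdir / f"{name}.tsv",
                   index=name in {"size_table"})

    report(out, config)
    return out


def report(run_dir, config: PipelineConfig) -> dict:
    """Write the provenance file (config echo, seed, input hashes)."""
    run_dir = Path(run_dir)
    if not run_dir.exists() or not any(run_dir.iterdir()):
        raise ValueError(f"empty or missing run directory {run_dir}")
    hashes = {}
    for key in ("manifest", "beta", "counts", "sample_sheet", "genome",
                "gene_sets", "signature_sets"):
        path = getattr(config, key)
        if path and Path(path).exists():
            hashes[key] = _sha256(Path(path))
    stages = sorted(
        str(p.relative_to(run_dir))
        for p in run_dir.rglob("*.tsv")
    )
    prov = {
        "config": config.to_dict(),
        "input_sha256": hashes,
        "outputs": stages,
    }
    (run_dir / "provenance.json").write_text(
        json.dumps(prov, indent=1, sort_keys=True) + "\n"
    )
    return prov
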