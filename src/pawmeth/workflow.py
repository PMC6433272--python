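"""End-to-end orchestration of both analysis stages from one config.

Stage 1 takes a cohort table (optionally recomputing %5MeCyt from
chromatogram TSVs and H-scores from a cell-grade TSV) and runs the full
statistical battery. Stage 2 runs the array workflow: probe filter ->
common-probe subset -> QC -> M-values -> eBayes -> MVPs -> cross-species
gene mapping -> direction census -> enrichment. Every intermediate is
written to the output directory, and all counts are logged at each filter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dm, enrichment, hplc, icc, io, stats, xspecies

log = logging.getLogger("pawmeth")


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for a pipeline run.

    Thresholds default to the study's stated values: detection p 0.05,
    minimum 3 beads, 5% bad-sample tolerance, MVP threshold p < 0.05.
    """

    out_dir: str = "pawmeth_out"
    seed: int = 0
    # stage 1 inputs
    cohort_csv: str | None = None
    chromatogram_dir: str | None = None
    grades_tsv: str | None = None
    # stage 2 inputs
    beta_tsv: str | None = None
    detp_tsv: str | None = None
    beads_tsv: str | None = None
    samples_csv: str | None = None
    manifest_tsv: str | None = None
    orthologs_tsv: str | None = None
    gmt: str | None = None
    # thresholds
    p_max: float = 0.05
    min_beads: int = 3
    max_bad_frac: float = 0.05
    p_threshold: float = 0.05
    epsilon: float = 1e-6
    quantile_normalize: bool = False
    mds_top_k: int = 1000
    plots: bool = False
    stages: tuple = ("stage1", "stage2")

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1 or not 0 < self.p_threshold < 1:
            raise ValueError("p thresholds must lie in (0, 1)")
        if not 0 < self.max_bad_frac <= 1:
            raise ValueError("max_bad_frac must lie in (0, 1]")
        if self.min_beads < 0 or self.epsilon <= 0 or self.epsilon >= 0.5:
            raise ValueError("invalid min_beads or epsilon")
        for name in ("cohort_csv", "chromatogram_dir", "grades_tsv", "beta_tsv",
                     "detp_tsv", "beads_tsv", "samples_csv", "manifest_tsv",
                     "orthologs_tsv", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


# --------------------------------------------------------------------- stage 1

def run_stage1(config: RunConfig) -> dict:
    """Global-methylation stage: quantification, H-scores, statistics."""
    out = _outdir(config)
    if config.cohort_csv is None:
        raise FileNotFoundError("stage1 requires a cohort CSV (cohort_csv)")
    cohort = io.read_cohort_csv(config.cohort_csv)

    if config.chromatogram_dir is not None:
        chroms = {}
        for path in sorted(Path(config.chromatogram_dir).glob("*.tsv")):
            t, y = io.read_chromatogram_tsv(path)
            chroms[path.stem] = hplc.Chromatogram(t, y)
        quant = hplc.quantify_batch(chroms)
        io.write_cohort_csv(out / "hplc_quant.csv", quant)
        cohort = cohort.drop(columns=["percent_5me"], errors="ignore").merge(
            quant[["sample", "percent_5me"]].rename(columns={"sample": "id"}), on="id"
        )
        log.info("stage1: quantified %d chromatograms", len(quant))

    if config.grades_tsv is not None:
        grades = io.read_cell_grades_tsv(config.grades_tsv)
        scores = icc.score_table(grades)
        io.write_cohort_csv(out / "icc_scores.csv", scores)
        cohort = cohort.drop(columns=["h_score"], errors="ignore").merge(
            scores[["sample", "h_score"]].rename(columns={"sample": "id"}), on="id"
        )
        log.info("stage1: scored %d ICC samples", len(scores))

    if "age_bin" not in cohort.columns and "age" in cohort.columns:
        cohort["age_bin"] = np.where(cohort["age"] <= 10.0, "<=10", ">10")
    io.write_cohort_csv(out / "cohort_used.csv", cohort)

    groups = sorted(cohort["group"].unique())
    results: list[dict] = []
    skipped: list[str] = []

    def add(test: str, variables: str, res: stats.TestResult) -> None:
        results.append(
            {
                "test": test,
                "variables": variables,
                "statistic": res.statistic,
                "df": res.df if not isinstance(res.df, tuple) else str(res.df),
                "p_value": res.p_value,
                "estimate": res.estimate,
            }
        )

    for var in ("percent_5me", "h_score"):
        if var not in cohort.columns:
            continue
        add("ks_normality", var, stats.ks_normality(cohort[var]))

    if len(groups) < 2:
        skipped.append("between-group tests skipped: only one group present")
        log.warning("stage1: %s", skipped[-1])
    else:
        ctrl = cohort[cohort["group"] == "control"]
        case = cohort[cohort["group"] == "lymphoma"]
        for var in ("percent_5me", "h_score"):
            if var not in cohort.columns:
                continue
            add("t_pooled", f"{var} lymphoma-vs-control",
                stats.t_test_pooled(case[var], ctrl[var]))
            for covar in ("sex", "age_bin"):
                if cohort[covar].nunique() < 2:
                    skipped.append(f"anova {var}~group+{covar} skipped: constant {covar}")
                    continue
                table = stats.two_way_anova(cohort, var, "group", covar)
                for _, row in table.iterrows():
                    results.append(
                        {
                            "test": f"anova[{var}~group+{covar}]",
                            "variables": row["factor"],
                            "statistic": row["F"],
                            "df": f"({row['df']:.0f}, {row['resid_df']:.0f})",
                            "p_value": row["p_value"],
                            "estimate": None,
                        }
                    )
        if "lymphocytes" in cohort.columns:
            add("mann_whitney", "lymphocytes lymphoma-vs-control",
                stats.mann_whitney(case["lymphocytes"], ctrl["lymphocytes"]))

    if {"percent_5me", "h_score"} <= set(cohort.columns):
        add("pearson", "percent_5me~h_score",
            stats.pearson(cohort["percent_5me"], cohort["h_score"]))
    if "lymphocytes" in cohort.columns:
        for var in ("percent_5me", "h_score"):
            if var in cohort.columns:
                add("spearman", f"lymphocytes~{var}",
                    stats.spearman(cohort["lymphocytes"], cohort[var]))

    res_df = pd.DataFrame(results)
    res_df.to_csv(out / "stage1_results.csv", index=False)
    fragment = {
        "stage": "stage1",
        "n_animals": int(len(cohort)),
        "groups": {g: int((cohort["group"] == g).sum()) for g in groups},
        "results_csv": str(out / "stage1_results.csv"),
        "skipped": skipped,
    }
    log.info("stage1: %d tests written", len(res_df))
    return fragment


# --------------------------------------------------------------------- stage 2

def run_stage2(config: RunConfig, exp: dm.BetaExperiment | None = None,
               manifest: pd.DataFrame | None = None) -> dict:
    """Array stage: filter, QC, moderated testing, mapping, enrichment."""
    out = _outdir(config)
    if exp is None:
        needed = (config.beta_tsv, config.detp_tsv, config.beads_tsv, config.samples_csv)
        if any(p is None for p in needed):
            raise FileNotFoundError(
                "stage2 requires beta_tsv, detp_tsv, beads_tsv and samples_csv"
            )
        exp = dm.BetaExperiment(
            beta=io.read_matrix_tsv(config.beta_tsv),
            detection_p=io.read_matrix_tsv(config.detp_tsv),
            bead_count=io.read_matrix_tsv(config.beads_tsv),
            samples=io.read_cohort_csv(config.samples_csv),
        )
    if manifest is None and config.manifest_tsv is not None:
        manifest = io.read_manifest_tsv(config.manifest_tsv)

    n_start = exp.beta.shape[0]
    if config.quantile_normalize:
        exp.beta = dm.quantile_normalize(exp.beta)
        log.info("stage2: between-sample quantile normalization applied")

    retained, removal_log = dm.filter_probes(
        exp, config.p_max, config.min_beads, config.max_bad_frac
    )
    removal_log.to_csv(out / "removed_probes.tsv", sep="\t", index=False)
    log.info("stage2: filter %d -> %d probes", n_start, len(retained))

    common = dm.subset_common(exp, retained, config.p_max)
    log.info("stage2: common-in-all-samples subset %d -> %d probes",
             len(retained), len(common))
    if len(common) == 0:
        raise ValueError("no probe is detected in every sample")

    qc = dm.beta_density_qc(exp, common) if len(common) >= 100 else None
    if qc is not None and len(qc["flagged"]) == len(exp.beta.columns):
        raise RuntimeError("QC hard fail: every sample flagged by beta-density check")

    M = dm.beta_to_m(exp.beta.loc[common], epsilon=config.epsilon)
    mds = dm.mds_qc(M, top_k=min(config.mds_top_k, M.shape[0]))
    qc_payload = {
        "flagged_samples": qc["flagged"] if qc else [],
        "density_mode": qc["mode"] if qc else {},
        "mds": {s: [round(float(v), 6) for v in mds.loc[s]] for s in mds.index},
    }
    with open(out / "qc.json", "w") as fh:
        json.dump(qc_payload, fh, indent=2, sort_keys=True)
    if config.plots and qc is not None:
        _qc_plots(out, qc, mds)

    fit = dm.fit_two_group(M, exp.groups())
    results = dm.ebayes_moderate(fit)
    if manifest is not None:
        genes = manifest.set_index("probe_id")["gene"]
        results["gene"] = genes.reindex(results.index)
    results.sort_index().to_csv(out / "dm_results.csv")
    mvps = dm.mvp_table(results, config.p_threshold)
    mvps.to_csv(out / "mvp.csv")
    log.info("stage2: %d MVPs at p < %g (prior df %.3g)",
             len(mvps), config.p_threshold, fit.d0)

    fragment = {
        "stage": "stage2",
        "counts": {
            "input_probes": int(n_start),
            "after_filter": int(len(retained)),
            "common_all_samples": int(len(common)),
            "mvps": int(len(mvps)),
        },
        "prior_df": float(fit.d0),
        "prior_var": float(fit.s02),
        "flagged_samples": qc_payload["flagged_samples"],
    }

    if config.orthologs_tsv is not None and "gene" in mvps.columns:
        ortho = io.read_ortholog_tsv(config.orthologs_tsv)
        summaries, unmapped = xspecies.map_genes(mvps, ortho)
        summaries.to_csv(out / "gene_summaries.csv", index=False)
        unmapped.to_csv(out / "unmapped_genes.tsv", sep="\t", index=False)
        n_hyper, n_hypo = xspecies.direction_census(summaries)
        fragment["gene_census"] = {
            "mapped": int(len(summaries)),
            "unmapped": int(len(unmapped)),
            "hyper": n_hyper,
            "hypo": n_hypo,
        }
        log.info("stage2: %d genes mapped (%d hyper / %d hypo)",
                 len(summaries), n_hyper, n_hypo)

        if config.gmt is not None and len(summaries):
            sets = io.read_gmt(config.gmt)
            universe = summaries["human_gene"].tolist()
            hyper = summaries.loc[summaries["direction"] == "hyper", "human_gene"]
            if len(hyper):
                enr = enrichment.enrich(hyper, universe, sets)
                enr.to_csv(out / "enrichment_hyper.csv", index=False)
                fragment["top_terms"] = enr.head(10)["term"].tolist()

    with open(out / "stage2_report.json", "w") as fh:
        json.dump(fragment, fh, indent=2, sort_keys=True)
    return fragment


def _qc_plots(out: Path, qc: dict, mds: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for sample, dens in qc["density"].items():
        axes[0].plot(qc["grid"], dens, label=sample)
    axes[0].set_xlabel("beta")
    axes[0].set_ylabel("density")
    axes[0].legend(fontsize=6)
    axes[1].scatter(mds["dim1"], mds["dim2"])
    for s in mds.index:
        axes[1].annotate(s, mds.loc[s], fontsize=6)
    axes[1].set_xlabel("dim1")
    axes[1].set_ylabel("dim2")
    fig.tight_layout()
    fig.savefig(out / "qc.png", dpi=120)
    plt.close(fig)


def run(config: RunConfig) -> dict:
    """Run the configured stages and write a consolidated report."""
    out = _outdir(config)
    report: dict = {"config_digest": config.digest(), "seed": config.seed}
    if "stage1" in config.stages and config.cohort_csv is not None:
        report["stage1"] = run_stage1(config)
    if "stage2" in config.stages and config.beta_tsv is not None:
        report["stage2"] = run_stage2(config)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
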