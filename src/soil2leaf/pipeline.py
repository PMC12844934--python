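"""End-to-end orchestration: stages, artifacts, manifest, report rendering.

A run executes summaries -> BAF -> ANOVA/post hoc -> correlations -> PCA ->
HCA -> LDA (on the HCA clusters) -> PLSR -> Monte Carlo, writing each stage's
CSV/JSON artifact into the output directory plus a manifest with the config
hash and per-file SHA-256.  Artifacts contain no timestamps, so a rerun with
the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baf import baf_grand_stats, baf_site_summaries, compute_baf
from .core import (
    MeasurementTable,
    ThresholdConfig,
    grand_summary,
    load_measurements,
    star_code,
    summarize_sites,
)
from .mcs import exceedance_closed_form, fit_lognormal, run_simulation
from .multivariate import hca_ward, lda_stepwise, pca_fit
from .pls import plsr_fit, plsr_predict
from .stats import correlation_matrix, games_howell, welch_anova
from .synthetic import OrchardSimConfig, generate_orchard_dataset

log = logging.getLogger("soil2leaf")

ALL_STAGES = (
    "summaries",
    "baf",
    "stats",
    "correlations",
    "pca",
    "hca",
    "lda",
    "plsr",
    "mcs",
)

DEFAULT_THRESHOLDS = (
    ThresholdConfig("Cd", 0.1, "FAO/WHO leafy tissue"),
    ThresholdConfig("Pb", 0.3, "FAO/WHO leafy tissue"),
)
ALT_THRESHOLDS = (
    ThresholdConfig("Cd", 0.2, "FAO/WHO upper permissible"),
    ThresholdConfig("Pb", 2.0, "FAO/WHO general"),
)


@dataclass
class PipelineConfig:
    input_path: str | None = None
    layout: str = "long"
    synthetic: bool = True
    sim: OrchardSimConfig = field(default_factory=OrchardSimConfig)
    seed: int = 0
    outdir: str = "results"
    stages: tuple[str, ...] = ALL_STAGES
    analytes: tuple[str, ...] | None = None  # None = all leaf analytes
    baf_elements: tuple[str, ...] | None = None
    posthoc_analytes: tuple[str, ...] = ("Cd", "Pb")
    correlation_method: str = "pearson"
    standardize: bool = True
    n_components: int = 2
    k_clusters: int = 4
    alpha_enter: float = 0.05
    plsr_predictors: tuple[str, ...] = ("Cd", "Pb", "Zn", "Ni")
    plsr_responses: tuple[str, ...] = (
        "N", "P", "K", "Ca", "Mg", "Cd", "Pb", "SPAD", "chlorophyll_a",
    )
    mcs_n_iter: int = 10_000
    mcs_granularity: str = "site_means"
    thresholds: tuple[ThresholdConfig, ...] = DEFAULT_THRESHOLDS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw:
            raw["sim"] = OrchardSimConfig(**raw["sim"])
        if "thresholds" in raw:
            raw["thresholds"] = tuple(ThresholdConfig(**t) for t in raw["thresholds"])
        for key in ("stages", "analytes", "baf_elements", "posthoc_analytes",
                    "plsr_predictors", "plsr_responses"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # where results land is not part of the analysis identity
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic fan-out of the global seed to one 64-bit seed per stage."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "big")])
    return int(ss.generate_state(1, dtype=np.uint64)[0])


def _site_means(table: MeasurementTable, analyte: str, compartment: str) -> pd.Series:
    return (
        table.select(analyte, compartment)
        .dropna(subset=["value"])
        .groupby("site_id")["value"]
        .mean()
    )


def site_feature_matrix(
    table: MeasurementTable,
    analytes: Sequence[str],
    baf_elements: Sequence[str] = (),
) -> pd.DataFrame:
    """Sites x variables matrix of site means (leaf analytes + BAF columns)."""
    cols = {}
    for a in analytes:
        cols[f"leaf_{a}"] = _site_means(table, a, "leaf")
    for el in baf_elements:
        recs = compute_baf(table, el)
        cols[f"BAF_{el}"] = pd.Series(
            {
                s.site_id: s.mean
                for s in baf_site_summaries(recs)
            }
        )
    df = pd.DataFrame(cols).dropna()
    df.index.name = "site_id"
    return df


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the in-memory bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config, "outdir": outdir}
    stage = "load"
    try:
        if config.synthetic:
            sim = dataclasses.replace(config.sim, seed=_stage_seed(config.seed, "simulate"))
            table = generate_orchard_dataset(sim)
            table.to_csv(outdir / "dataset.csv")
        else:
            if config.input_path is None:
                raise ValueError("input_path required when synthetic=false")
            table = load_measurements(config.input_path, layout=config.layout)
        bundle["table"] = table

        leaf_analytes = config.analytes or tuple(
            sorted(table.select(compartment="leaf")["analyte"].unique())
        )
        soil_elements = sorted(table.select(compartment="soil")["analyte"].unique())
        baf_elements = config.baf_elements or tuple(
            el for el in soil_elements if el in leaf_analytes
        )

        if "summaries" in config.stages:
            stage = "summaries"
            rows, grand_rows = [], []
            for a in leaf_analytes:
                summaries = summarize_sites(table, a, "leaf")
                rows += [dataclasses.asdict(s) for s in summaries]
                g = grand_summary(summaries)
                grand_rows.append(
                    {
                        "analyte": g.analyte,
                        "grand_mean": g.grand_mean,
                        "min_site": g.min_site[0],
                        "min_value": g.min_site[1],
                        "max_site": g.max_site[0],
                        "max_value": g.max_site[1],
                        "n_sites": g.n_sites,
                    }
                )
            bundle["site_summaries"] = pd.DataFrame(rows)
            bundle["grand_summaries"] = pd.DataFrame(grand_rows)
            _write_csv(bundle["site_summaries"], outdir / "site_summaries.csv", index=False)
            _write_csv(bundle["grand_summaries"], outdir / "grand_summaries.csv", index=False)
            log.info("summaries: %d analytes", len(leaf_analytes))

        if "baf" in config.stages and baf_elements:
            stage = "baf"
            rec_rows, sum_rows, grand_rows = [], [], []
            for el in baf_elements:
                recs = compute_baf(table, el)
                rec_rows += [dataclasses.asdict(r) for r in recs]
                sums = baf_site_summaries(recs)
                sum_rows += [dataclasses.asdict(s) for s in sums]
                g = baf_grand_stats(sums)
                grand_rows.append(
                    {"element": el, "grand_mean": g.grand_mean,
                     "min_site": g.min_site[0], "min_value": g.min_site[1],
                     "max_site": g.max_site[0], "max_value": g.max_site[1]}
                )
            bundle["baf_records"] = pd.DataFrame(rec_rows)
            bundle["baf_site_summaries"] = pd.DataFrame(sum_rows)
            bundle["baf_grand"] = pd.DataFrame(grand_rows)
            _write_csv(bundle["baf_records"], outdir / "baf_records.csv", index=False)
            _write_csv(bundle["baf_site_summaries"], outdir / "baf_site_summaries.csv", index=False)
            _write_csv(bundle["baf_grand"], outdir / "baf_grand.csv", index=False)
            log.info("baf: %d elements", len(baf_elements))

        if "stats" in config.stages:
            stage = "stats"
            anova_rows, gh_rows = [], []
            for a in leaf_analytes:
                vals = table.select(a, "leaf").dropna(subset=["value"])
                groups = [g["value"].to_numpy() for _, g in vals.groupby("site_id", sort=True)]
                labels = sorted(vals["site_id"].unique())
                if len(groups) < 2 or any(len(g) < 2 or np.var(g, ddof=1) == 0 for g in groups):
                    continue
                res = welch_anova(groups)
                anova_rows.append(
                    {"analyte": a, "f_stat": res.f_stat, "df1": res.df1,
                     "df2": res.df2, "p": res.p, "sig": star_code(res.p)}
                )
                if a in config.posthoc_analytes:
                    for c in games_howell(groups, labels):
                        gh_rows.append({"analyte": a, **dataclasses.asdict(c)})
            bundle["welch_anova"] = pd.DataFrame(anova_rows)
            bundle["games_howell"] = pd.DataFrame(gh_rows)
            _write_csv(bundle["welch_anova"], outdir / "welch_anova.csv", index=False)
            _write_csv(bundle["games_howell"], outdir / "games_howell.csv", index=False)
            log.info("stats: %d analytes tested", len(anova_rows))

        features = site_feature_matrix(table, leaf_analytes, baf_elements)
        bundle["features"] = features
        _write_csv(features, outdir / "site_features.csv")

        if "correlations" in config.stages:
            stage = "correlations"
            cm = correlation_matrix(features, method=config.correlation_method)
            bundle["correlations"] = cm
            _write_csv(pd.DataFrame(cm.r, index=cm.variables, columns=cm.variables),
                       outdir / "correlation_r.csv")
            _write_csv(pd.DataFrame(cm.p, index=cm.variables, columns=cm.variables),
                       outdir / "correlation_p.csv")
            pd.DataFrame(cm.stars(), index=cm.variables, columns=cm.variables).to_csv(
                outdir / "correlation_stars.csv")
            log.info("correlations: %d variables (%s)", len(cm.variables), cm.method)

        if "pca" in config.stages:
            stage = "pca"
            pca = pca_fit(features, standardize=config.standardize,
                          rotate="varimax", n_components=config.n_components)
            bundle["pca"] = pca
            comp_names = [f"PC{i + 1}" for i in range(pca.loadings.shape[1])]
            _write_csv(pd.DataFrame(pca.loadings, index=features.columns, columns=comp_names),
                       outdir / "pca_loadings.csv")
            _write_csv(pd.DataFrame(pca.scores, index=features.index, columns=comp_names),
                       outdir / "pca_scores.csv")
            _write_csv(pd.DataFrame(
                {"eigenvalue": pca.eigenvalues, "explained_pct": pca.explained_pct}),
                outdir / "pca_eigenvalues.csv", index=False)
            log.info("pca: top-%d explained %.1f%%", config.n_components,
                     pca.explained_pct[: config.n_components].sum())

        if "hca" in config.stages:
            stage = "hca"
            hca = hca_ward(features, standardize=config.standardize,
                           labels=list(features.index))
            bundle["hca"] = hca
            _write_csv(pd.DataFrame(hca.merge_history,
                                    columns=["a", "b", "height", "size"]),
                       outdir / "hca_merges.csv", index=False)
            k = min(config.k_clusters, len(features))
            clusters = hca.labels_at(k)
            bundle["clusters"] = pd.Series(clusters, index=features.index, name="cluster")
            _write_csv(bundle["clusters"].to_frame(), outdir / "hca_clusters.csv")
            log.info("hca: cut at k=%d", k)

        if "lda" in config.stages and "clusters" in bundle:
            stage = "lda"
            groups = bundle["clusters"].to_numpy()
            if len(np.unique(groups)) >= 2 and min(np.bincount(groups)) >= 2:
                lda = lda_stepwise(features, groups, alpha_enter=config.alpha_enter,
                                   standardize=config.standardize)
                bundle["lda"] = lda
                sel = [features.columns[i] for i in lda.selected_vars]
                _write_json(
                    {"selected_vars": sel,
                     "wilks_lambda_path": lda.wilks_lambda_path,
                     "status": lda.status},
                    outdir / "lda_selection.json")
                if sel:
                    fn = [f"LD{i + 1}" for i in range(lda.scores.shape[1])]
                    _write_csv(pd.DataFrame(lda.discriminant_axes, index=sel, columns=fn),
                               outdir / "lda_axes.csv")
                    _write_csv(pd.DataFrame(lda.loadings, index=sel, columns=fn),
                               outdir / "lda_structure.csv")
                    _write_csv(pd.DataFrame(lda.scores, index=features.index, columns=fn),
                               outdir / "lda_scores.csv")
                log.info("lda: selected %s", sel)
            else:
                log.info("lda: skipped (degenerate clusters)")

        if "plsr" in config.stages:
            stage = "plsr"
            predictors = [p for p in config.plsr_predictors
                          if p in soil_elements]
            responses = [r for r in config.plsr_responses if r in leaf_analytes]
            if predictors and responses:
                xcols = {f"soil_{p}": _site_means(table, p, "soil") for p in predictors}
                ycols = {f"leaf_{r}": _site_means(table, r, "leaf") for r in responses}
                xy = pd.DataFrame({**xcols, **ycols}).dropna()
                xmat = xy[list(xcols)]
                ymat = xy[list(ycols)]
                model = plsr_fit(xmat, ymat, n_components=config.n_components)
                bundle["plsr"] = model
                _write_json(
                    {"n_components": model.n_components,
                     "predictors": model.predictor_names,
                     "responses": model.response_names,
                     "coefficients": model.coefficients.tolist(),
                     "intercept": model.intercept.tolist(),
                     "r2_per_response": model.r2_fitted},
                    outdir / "plsr_model.json")
                pred = plsr_predict(model, xmat)
                for j, r in enumerate(model.response_names):
                    _write_csv(pd.DataFrame(
                        {"measured": ymat.iloc[:, j], "predicted": pred[:, j]},
                        index=xy.index), outdir / f"plsr_measured_vs_predicted_{r}.csv")
                log.info("plsr: R2 %s", {k: round(v, 3) for k, v in model.r2_fitted.items()})

        if "mcs" in config.stages:
            stage = "mcs"
            mcs_rows = []
            variables: dict[str, np.ndarray] = {}
            if config.mcs_granularity == "site_means":
                for el in ("Cd", "Pb"):
                    if el in baf_elements:
                        sums = baf_site_summaries(compute_baf(table, el))
                        variables[f"BAF_{el}"] = np.array([s.mean for s in sums])
                for a in ("Cd", "Pb", "SPAD", "chlorophyll_a"):
                    if a in leaf_analytes:
                        variables[f"leaf_{a}" if a in ("Cd", "Pb") else a] = (
                            _site_means(table, a, "leaf").to_numpy())
            else:
                for el in ("Cd", "Pb"):
                    if el in baf_elements:
                        variables[f"BAF_{el}"] = np.array(
                            [r.baf for r in compute_baf(table, el)])
                for a in ("Cd", "Pb", "SPAD", "chlorophyll_a"):
                    if a in leaf_analytes:
                        variables[f"leaf_{a}" if a in ("Cd", "Pb") else a] = (
                            table.select(a, "leaf")["value"].dropna().to_numpy())
            for name, vals in variables.items():
                vals = vals[vals > 0]
                if vals.size < 2:
                    continue
                fit = fit_lognormal(vals, variable=name,
                                    granularity=config.mcs_granularity)
                ths = [t for t in config.thresholds
                       if name in (f"leaf_{t.element}", t.element)]
                summary = run_simulation(
                    fit, n_iter=config.mcs_n_iter,
                    seed=_stage_seed(config.seed, f"mcs:{name}"), thresholds=ths)
                row = {"variable": name, "mu_ln": fit.mu_ln, "sigma_ln": fit.sigma_ln,
                       "n_fit": fit.n, "n_iter": summary.n_iter, "seed": summary.seed,
                       "mean": summary.mean, "sd": summary.sd}
                row.update({f"p{p}": v for p, v in summary.percentiles.items()})
                for label, prob in summary.exceedance.items():
                    row[f"P({label})"] = prob
                for t in ths:
                    row[f"P_closed_form({t.element}>{t.limit:g})"] = (
                        exceedance_closed_form(fit, t.limit))
                mcs_rows.append(row)
            bundle["mcs"] = pd.DataFrame(mcs_rows)
            _write_csv(bundle["mcs"], outdir / "mcs_summary.csv", index=False)
            log.info("mcs: %d variables simulated", len(mcs_rows))

        _write_manifest(bundle, outdir, partial=False)
        return bundle
    except Exception:
        _write_manifest(bundle, outdir, partial=True, failed_stage=stage)
        raise RuntimeError(f"pipeline stage {stage!r} failed") from None


def _write_manifest(bundle: dict, outdir: Path, partial: bool,
                    failed_stage: str | None = None) -> None:
    config: PipelineConfig = bundle["config"]
    files = sorted(
        p.name for p in outdir.iterdir()
        if p.is_file() and p.name not in ("manifest.json", "report.md")
        and not p.name.endswith(".png")
    )
    hashes = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        for name in files
    }
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(config.stages),
        "partial": partial,
        "failed_stage": failed_stage,
        "files": hashes,
    }
    _write_json(manifest, outdir / "manifest.json")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def write_report(bundle: dict, figures: bool = True) -> Path:
    """Render a markdown report (and figures) from a pipeline bundle."""
    outdir: Path = bundle["outdir"]
    lines = ["# Soil-to-leaf transfer analysis report", ""]

    def section(title: str, key: str, renderer) -> None:
        lines.append(f"## {title}")
        if key in bundle:
            renderer()
        else:
            lines.append("*not run*")
        lines.append("")

    def _table(df: pd.DataFrame) -> None:
        lines.append("```")
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
        lines.append("```")

    section("Site summaries", "grand_summaries",
            lambda: _table(bundle["grand_summaries"]))
    section("Bioaccumulation factors", "baf_grand",
            lambda: _table(bundle["baf_grand"]))
    section("Welch ANOVA across sites", "welch_anova",
            lambda: _table(bundle["welch_anova"]))
    section("Monte Carlo risk", "mcs", lambda: _table(bundle["mcs"]))
    if "plsr" in bundle:
        lines.append("## PLSR per-response R^2")
        for k, v in bundle["plsr"].r2_fitted.items():
            lines.append(f"- {k}: {v:.3f}")
        lines.append("")
    else:
        lines.extend(["## PLSR per-response R^2", "*not run*", ""])

    if figures:
        _render_figures(bundle, outdir)
        lines.append("## Figures")
        for png in sorted(outdir.glob("*.png")):
            lines.append(f"![{png.stem}]({png.name})")
        lines.append("")

    path = outdir / "report.md"
    path.write_text("\n".join(lines))
    return path


def _render_figures(bundle: dict, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    meta = {"Software": None}
    if "correlations" in bundle:
        cm = bundle["correlations"]
        fig, ax = plt.subplots(figsize=(9, 8))
        im = ax.imshow(cm.r, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_xticks(range(len(cm.variables)), cm.variables, rotation=90, fontsize=6)
        ax.set_yticks(range(len(cm.variables)), cm.variables, fontsize=6)
        fig.colorbar(im, ax=ax, label="r")
        fig.tight_layout()
        fig.savefig(outdir / "fig_correlation_heatmap.png", dpi=120, metadata=meta)
        plt.close(fig)
    if "pca" in bundle:
        pca = bundle["pca"]
        if pca.loadings.shape[1] >= 2:
            fig, ax = plt.subplots(figsize=(7, 6))
            ax.scatter(pca.scores[:, 0], pca.scores[:, 1], s=18)
            feats = bundle["features"]
            for i, name in enumerate(feats.index):
                ax.annotate(str(name), pca.scores[i, :2], fontsize=7)
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            ax.axhline(0, lw=0.5, color="grey")
            ax.axvline(0, lw=0.5, color="grey")
            fig.tight_layout()
            fig.savefig(outdir / "fig_pca_scores.png", dpi=120, metadata=meta)
            plt.close(fig)
    if "hca" in bundle:
        hca = bundle["hca"]
        fig, ax = plt.subplots(figsize=(8, 4))
        heights = [m[2] for m in hca.merge_history]
        ax.plot(range(1, len(heights) + 1), heights, marker="o", ms=3)
        ax.set_xlabel("merge step")
        ax.set_ylabel("Ward height")
        fig.tight_layout()
        fig.savefig(outdir / "fig_hca_heights.png", dpi=120, metadata=meta)
        plt.close(fig)
    if "mcs" in bundle and not bundle["mcs"].empty:
        df = bundle["mcs"]
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(df["variable"], df["p95"])
        ax.set_ylabel("95th percentile")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(outdir / "fig_mcs_p95.png", dpi=120, metadata=meta)
        plt.close(fig)
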