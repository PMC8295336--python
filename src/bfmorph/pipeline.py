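"""End-to-end experiment orchestration.

One seeded configuration drives the whole chain: synthetic image
generation for a genotype panel, nucleus detection and cropping, 296-
feature quantification, wild-type-referenced preprocessing, per-mutant
L1-logistic discrimination with nested CV, and coefficient-profile
clustering. Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discrim, features, prep, profiles, segment, synth

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "write_report"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a full synthetic run needs; the seed is mandatory."""

    seed: int
    n_cells: int = 700
    cells_per_field: int = 27
    geometry_scale: float = 1.0
    expand_frac: float = 0.5
    min_clump_area: int = 5
    cutoff: float = 3.0
    policy: str = "drop_cell"
    outer_folds: int = 10
    inner_folds: int = 10
    n_lambda: int = 100
    lambda_decades: float = 4.0
    selection_rule: str = "min"
    profile_mode: str = "bagged"  # "bagged" or "refit"
    n_boot: int = 24
    compute_roc: bool = True
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in blob:
            raise ValueError("config must name a seed")
        return cls(**blob)

    def geometry(self) -> synth.FieldGeometry:
        g = synth.FieldGeometry()
        return g if self.geometry_scale == 1.0 else g.scaled(self.geometry_scale)

    def feature_config(self) -> features.FeatureConfig:
        return features.FeatureConfig(min_clump_area=self.min_clump_area)

    def cv_config(self, seed: int) -> discrim.CVConfig:
        return discrim.CVConfig(
            outer_folds=self.outer_folds,
            inner_folds=self.inner_folds,
            n_lambda=self.n_lambda,
            lambda_decades=self.lambda_decades,
            seed=seed,
            selection_rule=self.selection_rule,
        )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    tables: dict[str, pd.DataFrame]          # standardized, outlier-handled
    summary: pd.DataFrame                    # genotype, mean_auc, sd_auc, n_selected
    models: dict[str, discrim.DiscriminativeModel]
    roc: dict[str, discrim.ROCResult]
    profile_matrix: profiles.ProfileMatrix
    similarity: pd.DataFrame
    dendrogram: profiles.Dendrogram
    manifest: dict


def _population_table(params, config, geometry, fconfig, seed) -> pd.DataFrame:
    """Images -> detected crops -> feature rows for one genotype."""
    fields = synth.generate_population(
        params, config.n_cells, config.cells_per_field, seed, geometry
    )
    min_area = max(10, int(2 * geometry.nucleus_sigma**2))
    rows = []
    for f in fields:
        boxes = segment.detect_nuclei(f.nuclear, min_area=min_area)
        crops = segment.crop_cells(f.bf, boxes, config.expand_frac, f.field_id)
        centers = [t.cell_center for t in f.truth]
        kept_boxes = [c.box for c in crops]
        match = segment.match_to_truth(
            kept_boxes, centers, max_dist=4 * geometry.nucleus_sigma
        )
        matched = dict(match.assignment)
        for i, crop in enumerate(crops):
            if i not in matched:
                continue  # spurious detection: no known cell
            t = f.truth[matched[i]]
            vec = features.extract_features(crop, fconfig)
            rows.append(
                {
                    "cell_id": crop.cell_id,
                    "genotype": t.genotype,
                    "clone": t.clone,
                    **dict(zip(synth.feature_columns(), vec.values)),
                }
            )
    return pd.DataFrame(rows)


def run_experiment(
    config: ExperimentConfig,
    panel: list[synth.GenotypeParams] | None = None,
) -> ExperimentResult:
    """Run the full synthetic experiment described by ``config``."""
    t0 = time.time()
    panel = panel or synth.default_genotype_panel()
    geometry = config.geometry()
    fconfig = config.feature_config()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(panel))
    timings: dict[str, float] = {}

    raw: dict[str, pd.DataFrame] = {}
    for params, child in zip(panel, children):
        raw[params.name] = _population_table(params, config, geometry, fconfig, child)
    timings["images_and_features"] = time.time() - t0

    wt_name = panel[0].name
    ref = prep.wt_reference_stats(raw[wt_name])
    tables: dict[str, pd.DataFrame] = {}
    for name, table in raw.items():
        z = prep.standardize(table, ref)
        clean, _log = prep.remove_outliers(z, config.cutoff, config.policy)
        if name != wt_name:
            by_clone = [
                clean[clean.clone == c].reset_index(drop=True) for c in (0, 1)
            ]
            clean = prep.pool_clones(*by_clone)
        tables[name] = clean
    timings["prep"] = time.time() - t0 - timings["images_and_features"]

    models: dict[str, discrim.DiscriminativeModel] = {}
    roc: dict[str, discrim.ROCResult] = {}
    profile_rows: dict[str, np.ndarray] = {}
    summary_rows = []
    mutants = [p.name for p in panel[1:]]
    for gi, name in enumerate(mutants):
        dataset = prep.build_dataset(tables[wt_name], tables[name])
        cfg = config.cv_config(seed=config.seed + 17 * (gi + 1))
        if config.profile_mode == "bagged":
            bagged, model = discrim.bagged_coefficients(
                dataset, cfg, n_boot=config.n_boot
            )
            profile_rows[name] = bagged
        else:
            model, _cv = discrim.fit_cv(dataset, cfg)
            profile_rows[name] = model.beta
        if model.selected.size == 0 and cfg.selection_rule == "1se":
            # a morphological profile needs at least one selected feature;
            # fall back to the deviance-minimizing penalty for this genotype
            model, _cv = discrim.fit_cv(
                dataset, dataclasses.replace(cfg, selection_rule="min")
            )
            model.fit_meta["rule"] = "min (1se fallback)"
            if config.profile_mode != "bagged":
                profile_rows[name] = model.beta
        model.fit_meta["schema_hash"] = fconfig.schema_hash
        model.fit_meta["genotype"] = name
        models[name] = model
        row = {
            "genotype": name,
            "n_wt": int(np.sum(dataset.y == 0)),
            "n_mut": int(np.sum(dataset.y == 1)),
            "n_selected": int(model.selected.size),
            "lambda": model.lam,
        }
        if config.compute_roc:
            res = discrim.nested_cv(dataset, cfg)
            roc[name] = res
            row["mean_auc"] = res.mean_auc
            row["sd_auc"] = res.sd_auc
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    timings["discrimination"] = time.time() - t0 - sum(timings.values())

    pm = profiles.ProfileMatrix(
        mutants,
        list(fconfig.feature_schema),
        np.vstack([profile_rows[name] for name in mutants]),
    )
    sim = profiles.profile_similarity(pm)
    dend = profiles.cluster_profiles(1.0 - sim)
    timings["profiles"] = time.time() - t0 - sum(timings.values())

    summary_csv = summary.to_csv(index=False)
    manifest = {
        "config": dataclasses.asdict(config),
        "schema_hash": fconfig.schema_hash,
        "genotypes": [p.name for p in panel],
        "n_cells_after_prep": {k: int(len(v)) for k, v in tables.items()},
        "summary_sha256": hashlib.sha256(summary_csv.encode()).hexdigest(),
        "newick": dend.to_newick(),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
    }
    result = ExperimentResult(
        config, tables, summary, models, roc, pm, sim, dend, manifest
    )
    if config.outdir:
        _write_bundle(result, Path(config.outdir))
    return result


def _write_bundle(result: ExperimentResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(outdir / "summary.csv", index=False)
    (outdir / "models").mkdir(exist_ok=True)
    for name, model in result.models.items():
        model.to_json(outdir / "models" / f"{name}.json")
    result.profile_matrix.to_frame().to_csv(outdir / "profiles.csv")
    result.similarity.to_csv(outdir / "similarity.csv")
    (outdir / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    for name, table in result.tables.items():
        table.to_csv(outdir / f"features_{name}.csv", index=False)


def write_report(result: ExperimentResult, outdir: str | Path) -> list[Path]:
    """Render summary figures (ROC curves, score distributions, heatmap)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not result.models:
        raise ValueError("empty result bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if result.roc:
        ncols = min(4, len(result.roc))
        nrows = -(-len(result.roc) // ncols)
        fig, axes = plt.subplots(
            nrows, ncols, figsize=(3 * ncols, 3 * nrows), squeeze=False
        )
        for ax, (name, res) in zip(axes.ravel(), result.roc.items()):
            for fpr, tpr in res.fold_curves:
                ax.plot(fpr, tpr, color="C0", alpha=0.4, lw=0.8)
            ax.plot([0, 1], [0, 1], "k--", lw=0.6)
            ax.set_title(f"{name}  AUC={res.mean_auc:.3f}±{res.sd_auc:.3f}", fontsize=9)
            ax.set_xlabel("FPR")
            ax.set_ylabel("TPR")
        for ax in axes.ravel()[len(result.roc):]:
            ax.axis("off")
        fig.tight_layout()
        p = outdir / "roc_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        # linear predictors + sigmoid for the first genotype
        name = next(iter(result.models))
        model = result.models[name]
        wt_name = [g for g in result.tables if g not in result.models][0]
        cols = prep.feature_columns_of(result.tables[wt_name])
        eta_wt = model.decision(result.tables[wt_name][cols].to_numpy(float))
        eta_mut = model.decision(result.tables[name][cols].to_numpy(float))
        fig, axes = plt.subplots(3, 1, figsize=(5, 7), sharex=True)
        axes[0].hist(eta_wt, bins=40, color="red", alpha=0.7)
        axes[0].set_ylabel("wild type")
        axes[1].hist(eta_mut, bins=40, color="blue", alpha=0.7)
        axes[1].set_ylabel(name)
        grid = np.linspace(
            min(eta_wt.min(), eta_mut.min()), max(eta_wt.max(), eta_mut.max()), 200
        )
        axes[2].plot(grid, discrim.sigmoid(grid))
        axes[2].set_ylabel("posterior")
        axes[2].set_xlabel("linear predictor")
        fig.tight_layout()
        p = outdir / f"linear_predictor_{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

        # top-coefficient feature histograms with one-sided U-test p
        top = np.argsort(-np.abs(model.beta))[:3]
        fig, axes = plt.subplots(1, 3, figsize=(11, 3))
        for ax, j in zip(axes, top):
            col = cols[j]
            wt_v = result.tables[wt_name][col].to_numpy(float)
            mu_v = result.tables[name][col].to_numpy(float)
            alt = "greater" if model.beta[j] > 0 else "less"
            _, pval = discrim.feature_u_test(mu_v, wt_v, alternative=alt)
            ax.hist(wt_v, bins=30, color="red", alpha=0.6, density=True)
            ax.hist(mu_v, bins=30, color="blue", alpha=0.6, density=True)
            ax.set_title(f"{col}\nP={pval:.2e}, RC={model.beta[j]:+.3f}", fontsize=8)
        fig.tight_layout()
        p = outdir / f"top_features_{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    # profile heatmap ordered by the dendrogram
    order = result.dendrogram.leaf_order()
    M = result.profile_matrix.to_frame().loc[order]
    nz = M.columns[(M != 0).any(axis=0)]
    fig, ax = plt.subplots(figsize=(10, 3))
    vmax = np.abs(M[nz].to_numpy()).max() or 1.0
    ax.imshow(M[nz].to_numpy(), aspect="auto", cmap="bwr", vmin=-vmax, vmax=vmax)
    counts = result.profile_matrix.selected_counts
    ax.set_yticks(range(len(order)), [f"{g} ({counts[g]})" for g in order], fontsize=8)
    ax.set_xlabel(f"{len(nz)} selected features")
    fig.tight_layout()
    p = outdir / "profile_heatmap.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
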