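"""End-to-end orchestration: outlines -> coefficients -> morphospace -> statistics.

One run performs, in order: curve resampling and outline assembly, elliptic
Fourier decomposition, harmonic selection by cumulative power, coefficient
normalization, a single global PCA, and then — per grouping variable (order,
period) — convex hulls, centroid distances, mean shapes, SoV/SoR disparity
with bootstrap, pairwise disparity t-tests, MANOVA (overall and pairwise) and
the LDA leave-one-out table; finally per-period k-means scans on the global
scores plus a whole-dataset scan.  Period-level subsets are always views of
the single global morphospace, never refits, so per-period results are
positioned in the common coordinate system.

No specimen is silently dropped: outline ids missing from the metadata (or
invalid records) abort the run with the offending ids listed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from trilomorph import classify, disparity, efa, io_tps, morphospace, outline, synthetic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Exactly one of (``tps_path`` + ``metadata_path``) or ``preset`` must be
    set.  ``harmonic_threshold`` selects N by cumulative power unless
    ``n_harmonics`` pins it.
    """

    tps_path: str | None = None
    metadata_path: str | None = None
    preset: str | None = None
    harmonic_threshold: float = 0.999
    n_harmonics: int | None = None
    n_harmonics_max: int = 64
    retained_dims: int = 2
    bootstrap_replicates: int = 500
    kmeans_k_min: int = 1
    kmeans_k_max: int = 10
    kmeans_restarts: int = 25
    seed: int = 0
    groupings: tuple[str, ...] = ("order", "period")
    out_dir: str | None = None
    overwrite: bool = False
    metadata_columns: dict = field(default_factory=dict)

    def validate(self) -> None:
        from_files = self.tps_path is not None and self.metadata_path is not None
        from_preset = self.preset is not None
        if from_files == from_preset:
            raise ValueError("set exactly one of (tps_path + metadata_path) or preset")
        if from_preset and self.preset not in synthetic.PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(synthetic.PRESETS)}"
            )
        if not 0 < self.harmonic_threshold <= 1:
            raise ValueError("harmonic_threshold must be in (0, 1]")
        if self.retained_dims < 1:
            raise ValueError("retained_dims must be >= 1")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        unknown = set(self.groupings) - {"order", "period"}
        if unknown:
            raise ValueError(f"unknown grouping variables: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class PipelineResult:
    config: RunConfig
    metadata: pd.DataFrame
    outlines: list[outline.ClosedOutline]
    n_harmonics: int
    coefficient_sets: list[efa.CoefficientSet]
    model: morphospace.MorphospaceModel
    tables: dict[str, pd.DataFrame]
    manifest: io_tps.ResultManifest | None = None


def _load_specimens(config: RunConfig):
    if config.preset is not None:
        specs = synthetic.PRESETS[config.preset]()
        records, metadata, outlines = synthetic.generate_dataset(specs, seed=config.seed)
        return records, metadata, outlines
    records = io_tps.read_tps(config.tps_path)
    metadata = io_tps.read_metadata(config.metadata_path, columns=config.metadata_columns)
    invalid = [r.id for r in records if not r.valid]
    if invalid:
        raise ValueError(f"records without exactly two curves: {invalid}")
    meta_ids = {m.id for m in metadata}
    missing = [r.id for r in records if r.id not in meta_ids]
    if missing:
        raise ValueError(f"specimens missing from metadata: {missing}")
    by_id = {m.id: m for m in metadata}
    metadata = [by_id[r.id] for r in records]
    outlines = [
        outline.assemble_outline(
            outline.resample_curve(r.curves[0], outline.SEMILANDMARKS_PER_CURVE),
            outline.resample_curve(r.curves[1], outline.SEMILANDMARKS_PER_CURVE),
        )
        for r in records
    ]
    return records, metadata, outlines


def _shape_table(shapes: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for label, poly in shapes.items():
        for i, (x, y) in enumerate(poly):
            rows.append({"group": label, "point": i, "x": x, "y": y})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``."""
    config.validate()
    seed = config.seed

    logger.info("loading specimens")
    records, metadata_list, outlines = _load_specimens(config)
    meta = pd.DataFrame(
        {
            "id": [m.id for m in metadata_list],
            "species": [m.species for m in metadata_list],
            "order": [m.order_label for m in metadata_list],
            "period": [m.period_label for m in metadata_list],
        }
    ).set_index("id")
    n = len(outlines)
    logger.info("processing %d specimens", n)

    raw_sets = [
        efa.efa_forward(o, config.n_harmonics_max) for o in outlines
    ]
    for rs, m in zip(raw_sets, metadata_list):
        rs.specimen_id = m.id

    if config.n_harmonics is not None:
        N = config.n_harmonics
    else:
        N = efa.select_harmonics(raw_sets, threshold=config.harmonic_threshold)
    logger.info("selected %d harmonics at threshold %.4g", N, config.harmonic_threshold)

    coeff_sets = [efa.normalize_coefficients(rs.truncated(N)) for rs in raw_sets]
    matrix = efa.coefficient_matrix(coeff_sets)

    model = morphospace.fit_pca(matrix, retained_dims=config.retained_dims)
    scores = model.retained_scores
    logger.info(
        "PCA: retained %d axes, variance fractions %s",
        config.retained_dims,
        np.round(model.variance_fractions[: config.retained_dims], 4),
    )

    tables: dict[str, pd.DataFrame] = {
        "scores": model.scores.join(meta[["order", "period"]]),
        "coefficients": matrix,
        "pca_variance": pd.DataFrame(
            {
                "eigenvalue": model.eigenvalues,
                "variance_fraction": model.variance_fractions,
            },
            index=[f"PC{i + 1}" for i in range(len(model.eigenvalues))],
        ),
    }

    rng_seeds = np.random.SeedSequence(seed).generate_state(64).tolist()
    seed_iter = iter(rng_seeds)

    for grouping in config.groupings:
        labels = meta[grouping]
        geoms = morphospace.group_geometry(scores, labels)
        tables[f"hulls_{grouping}"] = pd.DataFrame(
            [
                {
                    "group": g.group_label,
                    "n": g.n,
                    "hull_area": g.hull_area,
                    "centroid_pc1": g.centroid[0],
                    "centroid_pc2": g.centroid[1] if len(g.centroid) > 1 else np.nan,
                    "degenerate": g.degenerate,
                }
                for g in geoms
            ]
        ).set_index("group")

        group_pts = {
            g: scores.loc[labels == g].to_numpy() for g in labels.unique()
        }
        tables[f"centroid_distances_{grouping}"] = morphospace.centroid_distances(group_pts)

        shapes = {}
        for g in labels.unique():
            members = [c for c, lab in zip(coeff_sets, labels) if lab == g]
            shapes[g] = efa.mean_shape(members)
        tables[f"mean_shapes_{grouping}"] = _shape_table(shapes)

        disp = [
            disparity.bootstrap_disparity(
                group_pts[g],
                replicates=config.bootstrap_replicates,
                seed=int(next(seed_iter)),
                group_label=str(g),
            )
            for g in labels.unique()
            if len(group_pts[g]) >= 2
        ]
        tables[f"disparity_{grouping}"] = disparity.disparity_table(disp)
        if len(disp) >= 2:
            tables[f"disparity_tests_sov_{grouping}"] = disparity.pairwise_disparity_tests(
                disp, metric="sov"
            )
            tables[f"disparity_tests_sor_{grouping}"] = disparity.pairwise_disparity_tests(
                disp, metric="sor"
            )

        if labels.nunique() >= 2:
            overall = disparity.manova_test(scores, labels)
            tables[f"manova_{grouping}"] = pd.DataFrame(
                [
                    {
                        "statistic": overall.statistic_name,
                        "F": overall.statistic_value,
                        "p_value": overall.p_value,
                        "df1": overall.df[0],
                        "df2": overall.df[1],
                    }
                ]
            )
            tables[f"manova_pairwise_{grouping}"] = disparity.manova_test(
                scores, labels, pairwise=True
            )
            cv = classify.lda_loo_table(scores, labels)
            tables[f"lda_cv_{grouping}"] = cv.proportions
        else:
            logger.warning(
                "grouping %r has a single level; MANOVA/LDA skipped", grouping
            )

    # per-period order hulls: a filter-then-summarize pass over the single
    # global morphospace (never a refit)
    per_period_rows = []
    for period in meta["period"].unique():
        mask = meta["period"] == period
        for g in morphospace.group_geometry(scores.loc[mask], meta.loc[mask, "order"]):
            per_period_rows.append(
                {
                    "period": period,
                    "order": g.group_label,
                    "n": g.n,
                    "hull_area": g.hull_area,
                    "centroid_pc1": g.centroid[0],
                    "centroid_pc2": g.centroid[1] if len(g.centroid) > 1 else np.nan,
                }
            )
    tables["hulls_order_within_period"] = pd.DataFrame(per_period_rows)

    # k-means: whole dataset plus per-period scans, all on global scores
    kmeans_rows = []
    assign_frames = []
    km_seed = int(next(seed_iter))
    scan_all = classify.kmeans_scan(
        scores,
        k_min=config.kmeans_k_min,
        k_max=min(config.kmeans_k_max, n),
        restarts=config.kmeans_restarts,
        seed=km_seed,
    )
    kmeans_rows.extend(
        {"subset": "all", "k": int(k), "wcss": float(w), "chosen_k": scan_all.chosen_k}
        for k, w in zip(scan_all.k_values, scan_all.wcss)
    )
    assign_frames.append(
        pd.DataFrame(
            {"subset": "all", "id": scores.index, "cluster": scan_all.assignments}
        )
    )
    for period in meta["period"].unique():
        sub = scores.loc[meta["period"] == period]
        k_max = min(config.kmeans_k_max, len(sub))
        if k_max < config.kmeans_k_min:
            continue
        scan = classify.kmeans_scan(
            sub,
            k_min=config.kmeans_k_min,
            k_max=k_max,
            restarts=config.kmeans_restarts,
            seed=km_seed,
        )
        kmeans_rows.extend(
            {"subset": period, "k": int(k), "wcss": float(w), "chosen_k": scan.chosen_k}
            for k, w in zip(scan.k_values, scan.wcss)
        )
        assign_frames.append(
            pd.DataFrame({"subset": period, "id": sub.index, "cluster": scan.assignments})
        )
    tables["kmeans_elbow"] = pd.DataFrame(kmeans_rows)
    tables["kmeans_assignments"] = pd.concat(assign_frames, ignore_index=True)
    cluster_shapes = classify.cluster_mean_shapes(scan_all, coeff_sets)
    tables["kmeans_cluster_mean_shapes"] = _shape_table(
        {f"cluster_{c}": poly for c, poly in cluster_shapes.items()}
    )

    result = PipelineResult(
        config=config,
        metadata=meta,
        outlines=outlines,
        n_harmonics=N,
        coefficient_sets=coeff_sets,
        model=model,
        tables=tables,
    )

    if config.out_dir is not None:
        manifest_config = config.to_dict()
        manifest_config.update(
            {
                "selected_harmonics": N,
                "variance_fractions": model.variance_fractions[
                    : config.retained_dims
                ].tolist(),
                "n_specimens": n,
            }
        )
        result.manifest = io_tps.write_results(
            tables,
            Path(config.out_dir),
            config=manifest_config,
            seed=seed,
            overwrite=config.overwrite,
        )
        logger.info("wrote %d tables to %s", len(tables), config.out_dir)
    return result
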