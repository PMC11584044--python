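"""End-to-end orchestration: simulate a dataset, run every analysis stage.

The pipeline stages run in a fixed order — outline reading, descriptor
measurement, landmarking, generalized Procrustes analysis, morphospace,
archetype classification, climate modeling — with every intermediate
written to the output directory, and a manifest recording seeds, parameter
values, and a hash of the configuration so two runs with the same inputs
are bit-for-bit comparable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, climate
from .archetypes import IANNETTA_COARSE, classify_all, type_frequency_table
from .errors import LeafmorphError
from .landmarking import configurations_to_csv, find_tip_base, landmark_outline
from .morphospace import fit_pca, morphospace_grid, plot_morphospace
from .outline_io import measure_descriptors, read_outline, write_outline
from .procrustes import distance_matrix, gpa
from .regions import REGIONS
from .synthetic import (
    EffectSpec,
    LeafPriors,
    WeatherConfig,
    generate_archetypes,
    generate_leaf,
    generate_specimens,
    generate_weather,
    link_shape_to_climate,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_all"]


@dataclass
class PipelineConfig:
    """Configuration shared by every pipeline stage."""

    landmarks_per_side: int = 100
    tip_rule: str = "arc"
    gpa_tolerance: float = 1e-6
    gpa_max_iter: int = 100
    allow_reflection: bool = False
    n_components: int | None = None
    grid_ncols: int = 5
    grid_nrows: int = 5
    min_coverage: float = 0.5
    seed: int = 0
    n_specimens: int = 60
    date_range: tuple[str, str] = ("1990-01-01", "1995-12-31")
    regions: tuple[str, ...] = REGIONS
    render: bool = True

    def __post_init__(self) -> None:
        if self.landmarks_per_side < 1:
            raise ValueError("landmarks_per_side must be >= 1")
        if self.gpa_tolerance <= 0 or self.gpa_max_iter < 1:
            raise ValueError("invalid GPA settings")
        if self.grid_ncols < 1 or self.grid_nrows < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must be in [0, 1]")
        if self.tip_rule not in ("arc", "euclidean"):
            raise ValueError(f"unknown tip_rule {self.tip_rule!r}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_simulate(
    outdir: str | Path,
    config: PipelineConfig = PipelineConfig(),
    effect: EffectSpec = EffectSpec(),
    priors: LeafPriors = LeafPriors(),
    weather_config: WeatherConfig = WeatherConfig(),
) -> Path:
    """Generate a full synthetic dataset on disk.

    Writes one outline text file per specimen plus specimens.csv,
    weather.csv, truth.csv (the planted ground truth), and manifest.json.
    """
    outdir = Path(outdir)
    (outdir / "outlines").mkdir(parents=True, exist_ok=True)
    specimens = generate_specimens(
        config.n_specimens, config.date_range, config.regions, seed=config.seed
    )
    weather = generate_weather(specimens, seed=config.seed + 1, config=weather_config)
    params, truth = link_shape_to_climate(
        specimens, weather, effect=effect, seed=config.seed + 2, priors=priors
    )
    for sid, p in params.items():
        write_outline(generate_leaf(p, id=sid), outdir / "outlines" / f"{sid}.txt")
    specimens.to_csv(outdir / "specimens.csv", index=False)
    weather.to_csv(outdir / "weather.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "effect": dataclasses.asdict(effect),
        "priors": dataclasses.asdict(priors),
        "weather_config": dataclasses.asdict(weather_config),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("simulated %d specimens into %s", len(specimens), outdir)
    return outdir


def run_all(
    indir: str | Path,
    outdir: str | Path,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Run every analysis stage on a dataset directory.

    ``indir`` must hold outlines/<id>.txt, specimens.csv, and weather.csv
    (as produced by :func:`run_simulate` or assembled by hand).  Raises at
    the first failing stage, naming the stage and offending record.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    specimens = pd.read_csv(indir / "specimens.csv", parse_dates=["collection_date"])
    weather = pd.read_csv(indir / "weather.csv", parse_dates=["date"])
    stage = "outline_io"
    try:
        outlines = []
        for sid in specimens["id"]:
            path = indir / "outlines" / f"{sid}.txt"
            if not path.exists():
                raise LeafmorphError(f"missing outline file for specimen {sid!r}: {path}")
            outlines.append(read_outline(path, id=sid))

        stage = "descriptors"
        desc_rows = []
        for o in outlines:
            tip, base = find_tip_base(o, tip_rule=config.tip_rule)
            d = measure_descriptors(o, tip, base)
            desc_rows.append(dataclasses.asdict(d))
        descriptors = pd.DataFrame(desc_rows)
        descriptors.rename(
            columns={"circularity": "circ", "aspect_ratio": "ar"}
        ).to_csv(outdir / "descriptors.csv", index=False)

        stage = "landmarking"
        configs = [
            landmark_outline(o, S=config.landmarks_per_side, tip_rule=config.tip_rule)
            for o in outlines
        ]
        configurations_to_csv(configs, outdir / "landmarks.csv")

        stage = "procrustes"
        aligned = gpa(
            configs,
            tolerance=config.gpa_tolerance,
            max_iter=config.gpa_max_iter,
            allow_reflection=config.allow_reflection,
        )
        aligned.save(outdir / "procrustes_distances.csv", outdir / "gpa.json")
        distance_matrix(aligned).to_csv(outdir / "distance_matrix.csv")

        stage = "morphospace"
        space = fit_pca(aligned, n_components=config.n_components)
        space.scores_frame().to_csv(outdir / "pc_scores.csv")
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(space.n_components)],
                "explained_variance_ratio": space.explained_variance_ratio,
            }
        ).to_csv(outdir / "explained_variance.csv", index=False)
        grid = morphospace_grid(space, ncols=config.grid_ncols, nrows=config.grid_nrows)
        grid_json = {
            "pc1_values": grid.pc1_values.tolist(),
            "pc2_values": grid.pc2_values.tolist(),
            "leaves": [[leaf.points.tolist() for leaf in row] for row in grid.leaves],
        }
        (outdir / "morphospace_grid.json").write_text(json.dumps(grid_json))
        if config.render:
            plot_morphospace(space, grid, str(outdir / "morphospace.svg"))

        stage = "archetypes"
        sets = generate_archetypes(S=config.landmarks_per_side)
        regions = specimens.set_index("id")["climate_region"]
        freq_tables = {}
        for scheme, aset in sets.items():
            assignments = classify_all(configs, aset)
            assignments.to_csv(outdir / f"assignments_{scheme}.csv", index=False)
            coarse = IANNETTA_COARSE if scheme == "iannetta" else None
            table = type_frequency_table(assignments, regions, coarse=coarse)
            table.to_csv(outdir / f"type_frequency_{scheme}.csv")
            freq_tables[scheme] = table

        stage = "climate"
        summaries = climate.summarize_windows(
            weather, specimens, min_coverage=config.min_coverage
        )
        summaries.to_csv(outdir / "window_summaries.csv", index=False)
        fits = climate.fit_models(descriptors, summaries, regions=regions)
        comparisons = {
            resp: climate.compare_aic([f for f in fits if f.response == resp])
            for resp in ("circularity", "aspect_ratio")
        }
        for resp, table in comparisons.items():
            table.to_csv(outdir / f"aic_{resp}.csv", index=False)
        desc_reg = descriptors.merge(
            specimens[["id", "climate_region", "year"]].rename(
                columns={"climate_region": "region"}
            ),
            on="id",
        )
        report = climate.region_tests(desc_reg, type_table=freq_tables["shull"])
        trends = climate.trend(desc_reg)
        trends.to_csv(outdir / "trends.csv", index=False)

        run_log = {
            "version": __version__,
            "config_hash": config.hash(),
            "config": dataclasses.asdict(config),
            "n_leaves": len(outlines),
            "gpa_iterations": aligned.iterations,
            "gpa_converged": bool(aligned.converged),
            "explained_variance_ratio": space.explained_variance_ratio[:5].tolist(),
            "chi2": report.get("chi2"),
        }
        (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    except LeafmorphError as exc:
        raise LeafmorphError(f"stage {stage!r}: {exc}") from exc
    return {
        "descriptors": descriptors,
        "aligned": aligned,
        "space": space,
        "fits": fits,
        "comparisons": comparisons,
        "report": report,
        "trends": trends,
    }
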