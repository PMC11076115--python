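"""End-to-end orchestration: occurrence files in, report tables out.

``run_pipeline`` chains the stages — read and clean occurrences, reduce
to presence cells, assign climate and biomes, contingency tests with
FDR, conditional probabilities, spatial permutation tests — and writes
one TSV per report plus run metadata. Every random draw flows from the
single config seed, so a rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .biome_stats import (
    ContingencyTable2xK,
    chisq_2xk,
    conditional_probability,
    fdr_bh,
)
from .climate_biome import (
    ClimateSurface,
    background_cells,
    biome_counts,
    build_cell_climate,
    load_biome_polygons,
)
from .gridding import Role, ValidationError, build_presence, get_backend, write_presence_tsv
from .occurrences import clean_coordinates, read_exclusion_points, read_occurrences
from .spatial_permutation import fdr_over_categories, permutation_test


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


@dataclass
class PipelineConfig:
    occurrences: str = ""
    climate_surface: str = ""
    polygon_asset: Optional[str] = None
    exclusion_points: Optional[str] = None
    exclusion_radius_km: float = 0.0
    resolution: int = 1
    backend: str = "fibonacci"
    B: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    fdr_family: str = "per_family"  # or "pooled" across the three chi-squared columns
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.resolution < 0:
            raise ValidationError("resolution must be >= 0")
        if self.B < 99:
            raise ValidationError("B must be >= 99")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")
        if self.fdr_family not in ("per_family", "pooled"):
            raise ValidationError("fdr_family must be 'per_family' or 'pooled'")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


@dataclass
class ReportBundle:
    out_dir: str
    paths: Dict[str, str] = field(default_factory=dict)

    def frame(self, name: str) -> pd.DataFrame:
        return pd.read_csv(self.paths[name], sep="\t")


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else repr(float(x))


def run_pipeline(config: PipelineConfig, out_dir: str) -> ReportBundle:
    """Run the full analysis; writes all report files into ``out_dir``.

    On any stage failure the partially written outputs are removed and a
    :class:`StageError` naming the stage is raised.
    """
    os.makedirs(out_dir, exist_ok=True)
    bundle = ReportBundle(out_dir=out_dir)
    created: List[str] = []

    def _register(name: str, filename: str) -> str:
        path = os.path.join(out_dir, filename)
        bundle.paths[name] = path
        created.append(path)
        return path

    stage = "read"
    try:
        records = read_occurrences(config.occurrences)
        exclusion = (
            read_exclusion_points(config.exclusion_points) if config.exclusion_points else []
        )
        records, cleaning = clean_coordinates(
            records, exclusion_points=exclusion, exclusion_radius_km=config.exclusion_radius_km
        )
        cleaning.to_json(_register("cleaning_report", "cleaning_report.json"))

        stage = "grid"
        backend = get_backend(config.backend)
        presence = build_presence(records, config.resolution, backend=backend)
        write_presence_tsv(presence, _register("presence", "presence.tsv"))
        background = background_cells(presence)
        categories = sorted(
            set(presence.categories(Role.REAL)) | set(presence.categories(Role.TRICKSTER))
        )

        stage = "climate"
        surface = ClimateSurface.from_csv(config.climate_surface)
        polygons = (
            load_biome_polygons(config.polygon_asset) if config.polygon_asset else load_biome_polygons()
        )
        trickster_union = set()
        for cat in categories:
            trickster_union |= presence.get(cat, Role.TRICKSTER)
        real_records = [r for r in records if r.role == Role.REAL]
        climate = build_cell_climate(
            sorted(background | trickster_union, key=lambda c: c.id),
            surface,
            fallback_records=real_records,
            backend=backend,
        )
        from .climate_biome import write_climate_tsv

        write_climate_tsv(climate, _register("climate", "cell_climate.tsv"), polygons)
        climate_pairs = {c: v[0] for c, v in climate.items()}

        stage = "biomes"
        null_counts, _ = biome_counts(background, climate_pairs, polygons)
        raw: Dict[str, Dict[str, float]] = {}
        for cat in categories:
            row: Dict[str, float] = {}
            real_counts, _ = biome_counts(presence.get(cat, Role.REAL), climate_pairs, polygons)
            trick_counts, _ = biome_counts(
                presence.get(cat, Role.TRICKSTER), climate_pairs, polygons
            )
            for name, counts_a, counts_b in (
                ("real_vs_null", real_counts, null_counts),
                ("trickster_vs_null", trick_counts, null_counts),
                ("real_vs_trickster", real_counts, trick_counts),
            ):
                try:
                    res = chisq_2xk(ContingencyTable2xK.from_count_dicts(counts_a, counts_b))
                    row[name] = res.p
                except ValidationError:
                    row[name] = float("nan")
            raw[cat] = row
        biome_table = _biome_report(categories, raw, config)
        biome_table.to_csv(_register("biome_tests", "biome_tests.tsv"), sep="\t", index=False)

        stage = "condprob"
        cp_rows = []
        for cat in categories:
            trick = presence.get(cat, Role.TRICKSTER)
            if not trick:
                continue
            res = conditional_probability(trick, presence.get(cat, Role.REAL), conf=config.ci_level)
            cp_rows.append(
                {
                    "category": cat,
                    "n_trickster_cells": res.n_trickster_cells,
                    "n_joint_cells": res.n_joint_cells,
                    "p_hat": res.p_hat,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            )
        pd.DataFrame(
            cp_rows,
            columns=["category", "n_trickster_cells", "n_joint_cells", "p_hat", "ci_low", "ci_high"],
        ).to_csv(_register("cond_prob", "conditional_probabilities.tsv"), sep="\t", index=False)

        stage = "permtest"
        perm_results = []
        skipped: List[Tuple[str, str]] = []
        for cat in categories:
            trick = presence.get(cat, Role.TRICKSTER)
            real = presence.get(cat, Role.REAL)
            if len(trick) < 2:
                skipped.append((cat, f"only {len(trick)} trickster cell(s); statistic undefined"))
                continue
            if len(trick) > len(real):
                skipped.append((cat, "more trickster cells than real cells; null undefined"))
                continue
            perm_results.append(
                permutation_test(
                    trick, real, B=config.B, seed=config.seed, category=cat, backend=backend
                )
            )
        adj = fdr_over_categories(perm_results) if perm_results else []
        perm_rows = [
            {
                "category": r.category,
                "n_cells": r.n_cells,
                "observed_median_km": r.observed_median_km,
                "p_empirical": r.p_empirical,
                "p_gaussian": r.p_gaussian,
                "p_fdr": a,
                "significant": a < config.alpha,
            }
            for r, a in zip(perm_results, adj)
        ]
        pd.DataFrame(
            perm_rows,
            columns=[
                "category",
                "n_cells",
                "observed_median_km",
                "p_empirical",
                "p_gaussian",
                "p_fdr",
                "significant",
            ],
        ).to_csv(_register("permutation", "permutation_tests.tsv"), sep="\t", index=False)

        stage = "metadata"
        meta = {
            "package_version": __version__,
            "config": dataclasses.asdict(config),
            "n_records_clean": len(records),
            "n_categories": len(categories),
            "n_background_cells": len(background),
            "permutation_skipped": {cat: why for cat, why in skipped},
        }
        with open(_register("metadata", "run_metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
    except Exception as exc:
        for path in created:
            if os.path.exists(path):
                os.remove(path)
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def _biome_report(categories, raw, config: PipelineConfig) -> pd.DataFrame:
    """Assemble the chi-squared report with FDR within each comparison family
    (or pooled over all three, if configured)."""
    cols = ("real_vs_null", "trickster_vs_null", "real_vs_trickster")
    adjusted: Dict[str, Dict[str, float]] = {c: {} for c in cols}
    if config.fdr_family == "per_family":
        for col in cols:
            cats = [c for c in categories if not math.isnan(raw[c][col])]
            adj = fdr_bh([raw[c][col] for c in cats])
            for cat, a in zip(cats, adj):
                adjusted[col][cat] = a
    else:
        flat = [
            (col, cat)
            for col in cols
            for cat in categories
            if not math.isnan(raw[cat][col])
        ]
        adj = fdr_bh([raw[cat][col] for col, cat in flat])
        for (col, cat), a in zip(flat, adj):
            adjusted[col][cat] = a
    rows = []
    for cat in categories:
        row = {"category": cat}
        for col in cols:
            row[f"p_{col}"] = raw[cat][col]
            row[f"p_{col}_fdr"] = adjusted[col].get(cat, float("nan"))
            row[f"sig_{col}"] = adjusted[col].get(cat, float("nan")) < config.alpha
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(bundle: ReportBundle, constrained_threshold: float = 0.8, alpha: float = 0.05) -> str:
    """One verdict line per category from the written reports.

    A category is *constrained* when P(real | trickster) is at or above
    the threshold, and *clustered* when its FDR-adjusted permutation
    p-value is below alpha.
    """
    for key in ("cond_prob", "permutation"):
        if key not in bundle.paths or not os.path.exists(bundle.paths[key]):
            raise StageError(f"bundle is missing the {key} report")
    cp = bundle.frame("cond_prob").set_index("category")
    perm = bundle.frame("permutation").set_index("category")
    lines = []
    for cat in sorted(set(cp.index) | set(perm.index)):
        constrained = cat in cp.index and cp.loc[cat, "p_hat"] >= constrained_threshold
        clustered = cat in perm.index and bool(perm.loc[cat, "p_fdr"] < alpha)
        if constrained and clustered:
            verdict = "constrained by real presence; spatially clustered"
        elif constrained:
            verdict = "constrained by real presence; not clustered beyond the null"
        elif clustered:
            verdict = "not constrained by real presence; spatially clustered"
        else:
            verdict = "not constrained by real presence"
        lines.append(f"{cat}: {verdict}")
    return "\n".join(lines)
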