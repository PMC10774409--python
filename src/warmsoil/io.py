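"""Readers and writers for the on-disk formats.

Formats are deliberately plain text: sample metadata and feature tables are
TSV, measurements are CSV with a leading units comment line, scalar summaries
are JSON. Everything written here is re-readable by this module
(round-trip identity is tested).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from warmsoil.datamodel import (
    MANAGEMENTS,
    WARMING_LEVELS,
    FeatureTable,
    Lineage,
    MeasurementTable,
    SampleMetadata,
    StudyDesign,
    TaxonomyMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ["sample-id", "plot", "block", "management", "warming", "year"]


def read_design(metadata_path: str | os.PathLike) -> StudyDesign:
    """Read a TSV sample-metadata table into a validated StudyDesign.

    Labels are normalized to canonical lowercase. Duplicate sample ids and
    unknown management/warming labels raise :class:`ValidationError`.
    """
    df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"metadata {metadata_path} missing columns {missing}; "
            f"expected header {DESIGN_COLUMNS}"
        )
    samples = []
    for _, row in df.iterrows():
        management = str(row["management"]).strip().lower()
        warming = str(row["warming"]).strip().lower()
        if management not in MANAGEMENTS:
            raise ValidationError(
                f"unknown management {row['management']!r}; "
                f"allowed: {list(MANAGEMENTS)}"
            )
        if warming not in WARMING_LEVELS:
            raise ValidationError(
                f"unknown warming level {row['warming']!r}; "
                f"allowed: {list(WARMING_LEVELS)}"
            )
        samples.append(
            SampleMetadata(
                sample_id=str(row["sample-id"]).strip(),
                plot_id=str(row["plot"]).strip(),
                block=int(row["block"]),
                management=management,
                warming=warming,
                year=int(row["year"]),
            )
        )
    return StudyDesign(samples=samples)


def write_design(design: StudyDesign, path: str | os.PathLike) -> Path:
    path = Path(path)
    design.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(
    table_path: str | os.PathLike, taxonomy_path: str | os.PathLike
) -> tuple[FeatureTable, TaxonomyMap]:
    """Read a taxa x samples TSV count table and its taxonomy TSV.

    Taxonomy rows are ``taxon-id<TAB>d__...;p__...`` lines. Taxa present in
    the table but absent from the taxonomy are reported in a warning log;
    negative or non-integer cells raise with their row/column address.
    """
    df = pd.read_csv(table_path, sep="\t", index_col=0)
    counts = df.to_numpy()
    for (t, s) in np.argwhere(~np.isfinite(counts) | (counts < 0)):
        raise ValidationError(
            f"invalid count {counts[t, s]!r} at taxon {df.index[t]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if not np.allclose(counts, np.round(counts)):
        t, s = np.argwhere(counts != np.round(counts))[0]
        raise ValidationError(
            f"non-integer count {counts[t, s]!r} at taxon {df.index[t]!r}, "
            f"sample {df.columns[s]!r}"
        )
    table = FeatureTable(
        [str(t) for t in df.index],
        [str(c) for c in df.columns],
        counts.astype(np.int64),
    )
    taxonomy = read_taxonomy(taxonomy_path)
    uncovered = taxonomy.uncovered(table)
    if uncovered:
        logger.warning(
            "taxonomy does not cover %d taxa: %s", len(uncovered), uncovered
        )
    return table, taxonomy


def read_taxonomy(path: str | os.PathLike) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["taxon-id", "lineage"])
    return TaxonomyMap(
        {
            str(row["taxon-id"]): Lineage.from_string(str(row["lineage"]))
            for _, row in df.iterrows()
        }
    )


def write_feature_table(table: FeatureTable, path: str | os.PathLike) -> Path:
    path = Path(path)
    df = table.to_frame()
    df.index.name = "taxon-id"
    df.to_csv(path, sep="\t")
    return path


def write_taxonomy(taxonomy: TaxonomyMap, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for taxon_id, lineage in taxonomy.items():
            fh.write(f"{taxon_id}\t{lineage.to_string()}\n")
    return path


UNITS_PREFIX = "# units:"


def write_measurements(table: MeasurementTable, path: str | os.PathLike) -> Path:
    """CSV with a leading ``# units:`` comment line; NaN written as empty."""
    path = Path(path)
    units = ";".join(f"{c}={table.units[c]}" for c in table.columns)
    with open(path, "w") as fh:
        fh.write(f"{UNITS_PREFIX} {units}\n")
        table.data.to_csv(fh, float_format="%.10g")
    return path


def read_measurements(path: str | os.PathLike) -> MeasurementTable:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(UNITS_PREFIX):
            raise ValidationError(
                f"{path}: expected first line to start with {UNITS_PREFIX!r}"
            )
        units: dict[str, str] = {}
        for item in first[len(UNITS_PREFIX):].strip().split(";"):
            if item:
                key, _, value = item.partition("=")
                units[key.strip()] = value.strip()
        df = pd.read_csv(fh, index_col=0)
    return MeasurementTable(df, units)


INCUBATION_COLUMNS = [
    "sample_id",
    "soil_dry_mass",
    "dna_total_o",
    "dna_atpct_labeled",
    "dna_atpct_control",
    "co2_delta_ppm",
    "headspace_volume",
    "headspace_temp",
    "headspace_pressure",
    "incubation_hours",
    "water_label_atpct",
]


def write_incubations(incubations, path: str | os.PathLike) -> Path:
    """One CSV row per incubation; f_co is configuration, not data, and is
    deliberately not serialized."""
    path = Path(path)
    rows = [
        {c: getattr(inc, c) for c in INCUBATION_COLUMNS} for inc in incubations
    ]
    pd.DataFrame(rows, columns=INCUBATION_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )
    return path


def read_incubations(path: str | os.PathLike, f_co: float | None = None):
    from warmsoil.physiology import IsotopeIncubation

    df = pd.read_csv(path)
    missing = [c for c in INCUBATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"incubation CSV {path} missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in INCUBATION_COLUMNS}
        kwargs["sample_id"] = str(kwargs["sample_id"])
        out.append(IsotopeIncubation(f_co=f_co, **kwargs))
    return out


AMINO_COLUMNS = [
    "sample_id",
    "glucosamine",
    "galactosamine",
    "muramic_acid_mass",
    "muramic_acid_mmol",
]


def write_amino_profiles(profiles, path: str | os.PathLike) -> Path:
    path = Path(path)
    rows = [{c: getattr(p, c) for c in AMINO_COLUMNS} for p in profiles]
    pd.DataFrame(rows, columns=AMINO_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )
    return path


def read_amino_profiles(path: str | os.PathLike):
    from warmsoil.necromass import AminoSugarProfile

    df = pd.read_csv(path)
    missing = [c for c in AMINO_COLUMNS if c not in df.columns and c != "muramic_acid_mmol"]
    if missing:
        raise ValidationError(f"amino-sugar CSV {path} missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            AminoSugarProfile(
                sample_id=str(row["sample_id"]),
                glucosamine=float(row["glucosamine"]),
                galactosamine=float(row["galactosamine"]),
                muramic_acid_mass=float(row["muramic_acid_mass"])
                if "muramic_acid_mass" in df.columns
                else None,
                muramic_acid_mmol=float(row["muramic_acid_mmol"])
                if "muramic_acid_mmol" in df.columns
                else None,
            )
        )
    return out


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_json(payload: Any, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_to_jsonable(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_results(result: Any, out_dir: str | os.PathLike) -> list[Path]:
    """Write a pipeline result (or list of results) under ``out_dir``.

    Tabular results become TSV, scalar summaries become ``summary.json``.
    Returns the paths written.
    """
    from warmsoil.community import DivergenceSeries, TDRResult
    from warmsoil.effects import EffectSizeSeries

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []

    items = result if isinstance(result, (list, tuple)) else [result]
    tdrs = [r for r in items if isinstance(r, TDRResult)]
    divs = [r for r in items if isinstance(r, DivergenceSeries)]
    effs = [r for r in items if isinstance(r, EffectSizeSeries)]
    others = [r for r in items if not isinstance(r, (TDRResult, DivergenceSeries, EffectSizeSeries))]

    if tdrs or (not items and result == []):
        fits = pd.DataFrame(
            [
                {
                    "treatment": r.treatment,
                    "slope_w": r.slope_w,
                    "turnover_v": r.turnover_v,
                    "intercept": r.intercept,
                    "r2_adjusted": r.r2_adjusted,
                    "p_value": r.p_value,
                    "n_pairs": r.n_pairs,
                }
                for r in tdrs
            ],
            columns=[
                "treatment",
                "slope_w",
                "turnover_v",
                "intercept",
                "r2_adjusted",
                "p_value",
                "n_pairs",
            ],
        )
        p = out_dir / "tdr_fits.tsv"
        fits.to_csv(p, sep="\t", index=False)
        paths.append(p)
        pairs_rows = [
            {
                "treatment": r.treatment,
                "plot": pr.plot_id,
                "lag_years": pr.lag_years,
                "similarity": pr.similarity,
            }
            for r in tdrs
            for pr in r.pairs
        ]
        p = out_dir / "tdr_pairs.tsv"
        pd.DataFrame(
            pairs_rows, columns=["treatment", "plot", "lag_years", "similarity"]
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        paths.append(
            write_json(
                {r.treatment: {"turnover_v": r.turnover_v, "r2_adjusted": r.r2_adjusted, "p_value": r.p_value} for r in tdrs},
                out_dir / "summary.json",
            )
        )
    if divs:
        rows = [
            {
                "management": r.management,
                "year": year,
                "block": block,
                "dissimilarity": value,
            }
            for r in divs
            for year, pairs in sorted(r.values.items())
            for block, value in sorted(pairs.items())
        ]
        p = out_dir / "divergence.tsv"
        pd.DataFrame(
            rows, columns=["management", "year", "block", "dissimilarity"]
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        paths.append(
            write_json(
                {
                    r.management: {
                        "trend_slope": r.trend_slope,
                        "trend_r2": r.trend_r2,
                        "trend_p": r.trend_p,
                    }
                    for r in divs
                },
                out_dir / "divergence_summary.json",
            )
        )
    if effs:
        rows = [
            {
                "variable": r.variable,
                "management": r.management,
                "year": year,
                "d": r.d_by_year[year],
                "n_treated": r.group_sizes[year][0],
                "n_control": r.group_sizes[year][1],
            }
            for r in effs
            for year in sorted(r.d_by_year)
        ]
        p = out_dir / "effect_sizes.tsv"
        pd.DataFrame(
            rows,
            columns=["variable", "management", "year", "d", "n_treated", "n_control"],
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        trend_rows = [
            {
                "variable": r.variable,
                "management": r.management,
                "trend_slope": r.trend_slope,
                "trend_slope_sma": r.trend_slope_sma,
                "trend_r2_adjusted": r.trend_r2_adjusted,
                "trend_p": r.trend_p,
            }
            for r in effs
        ]
        p = out_dir / "trends.tsv"
        pd.DataFrame(
            trend_rows,
            columns=[
                "variable",
                "management",
                "trend_slope",
                "trend_slope_sma",
                "trend_r2_adjusted",
                "trend_p",
            ],
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
    for r in others:
        if isinstance(r, MeasurementTable):
            paths.append(write_measurements(r, out_dir / "measurements.csv"))
        elif isinstance(r, FeatureTable):
            paths.append(write_feature_table(r, out_dir / "feature_table.tsv"))
        elif isinstance(r, StudyDesign):
            paths.append(write_design(r, out_dir / "metadata.tsv"))
        elif isinstance(r, dict):
            paths.append(write_json(r, out_dir / "summary.json"))
        else:
            raise TypeError(f"cannot serialize result of type {type(r)!r}")
    if not items:
        # degenerate input: still emit valid headed files
        p = out_dir / "tdr_fits.tsv"
        pd.DataFrame(
            columns=[
                "treatment",
                "slope_w",
                "turnover_v",
                "intercept",
                "r2_adjusted",
                "p_value",
                "n_pairs",
            ]
        ).to_csv(p, sep="\t", index=False)
        paths.append(p)
        paths.append(write_json({}, out_dir / "summary.json"))
    return paths
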