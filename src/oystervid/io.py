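"""CSV/XLSX/YAML interchange for survey tables.

Long (tidy) CSV is the single interchange format: one row per reading, per
section, or per matched oyster, with columns named exactly as the record
fields. Readers validate row-by-row and report the offending row number.
An XLSX path with an explicit, user-supplied column mapping supports
ingesting spreadsheet exports of field/video data.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .design import GeneratorConfig, SurveyDesign, VarianceComponents
from .simulate import OYSTER_COLUMNS, READING_COLUMNS, TRUTH_COLUMNS

__all__ = [
    "ParseError",
    "reference_config_path",
    "read_readings",
    "read_truth",
    "read_oysters",
    "read_s1_table",
    "write_table",
    "load_run_config",
    "design_from_dict",
    "generator_config_from_dict",
]


class ParseError(ValueError):
    """Malformed input table; message carries the 1-based data row number."""


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, col: str, path, integer: bool) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ParseError(f"{path}: non-numeric {col} at data row {row}")
    if (s < 0).any():
        row = int((s < 0).idxmax()) + 1
        raise ParseError(f"{path}: negative {col} at data row {row}")
    if integer and not (s == s.round()).all():
        row = int((s != s.round()).idxmax()) + 1
        raise ParseError(f"{path}: non-integer {col} at data row {row}")
    return s


def _validate_readings(df: pd.DataFrame, path) -> pd.DataFrame:
    _check_columns(df, READING_COLUMNS, path)
    for col in ("site", "transect", "section", "observer", "reading"):
        df[col] = _check_numeric(df, col, path, integer=True).astype(int)
    # gaussian-model readings may carry non-integer values; counts must
    # still be non-negative numbers
    for col in ("count_probably_living", "count_possibly_living", "count_dead"):
        df[col] = _check_numeric(df, col, path, integer=False).astype(float)
    return df[READING_COLUMNS]


def _validate_truth(df: pd.DataFrame, path) -> pd.DataFrame:
    _check_columns(df, [c for c in TRUTH_COLUMNS if c != "vegetation_cover"], path)
    for col in ("site", "transect", "section", "true_living", "true_dead"):
        df[col] = _check_numeric(df, col, path, integer=True).astype(int)
    if "vegetation_cover" in df.columns:
        cover = _check_numeric(df, "vegetation_cover", path, integer=False)
        if (cover > 1).any():
            row = int((cover > 1).idxmax()) + 1
            raise ParseError(f"{path}: vegetation_cover > 1 at data row {row}")
        df["vegetation_cover"] = cover.astype(float)
        return df[TRUTH_COLUMNS]
    return df[[c for c in TRUTH_COLUMNS if c != "vegetation_cover"]]


def _validate_oysters(df: pd.DataFrame, path) -> pd.DataFrame:
    _check_columns(df, OYSTER_COLUMNS, path)
    for col in ("field_status", "video_status"):
        bad = ~df[col].isin(["living", "dead"])
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path}: unknown status {df[col].iloc[row - 1]!r} in {col} "
                f"at data row {row}"
            )
    if df["oyster_id"].duplicated().any():
        row = int(df["oyster_id"].duplicated().idxmax()) + 1
        raise ParseError(f"{path}: duplicate oyster_id at data row {row}")
    return df[OYSTER_COLUMNS]


_VALIDATORS = {
    "readings": _validate_readings,
    "truth": _validate_truth,
    "oysters": _validate_oysters,
}


def read_readings(path) -> pd.DataFrame:
    """Read and validate a reading-record CSV."""
    return _validate_readings(pd.read_csv(path), path)


def read_truth(path) -> pd.DataFrame:
    """Read and validate a section-truth CSV."""
    return _validate_truth(pd.read_csv(path), path)


def read_oysters(path) -> pd.DataFrame:
    """Read and validate a matched-oyster CSV."""
    return _validate_oysters(pd.read_csv(path), path)


def read_s1_table(
    path,
    column_mapping: dict[str, str],
    kind: str = "readings",
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Ingest an XLSX export via an explicit column mapping.

    ``column_mapping`` maps the spreadsheet's column headers to this
    package's field names (e.g. ``{"Site": "site", ...}``); the layout of
    such exports is not standardised, so no mapping is assumed. The mapped
    table passes through the same validation as the CSV readers.
    """
    if kind not in _VALIDATORS:
        raise ValueError(f"kind must be one of {sorted(_VALIDATORS)}")
    raw = pd.read_excel(path, sheet_name=sheet)
    missing = [c for c in column_mapping if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: mapped column(s) absent from sheet: {missing}")
    df = raw[list(column_mapping)].rename(columns=column_mapping)
    return _VALIDATORS[kind](df, path)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a table as CSV with the fixed header, no index."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def reference_config_path() -> Path:
    """Path of the bundled study-emulation YAML preset."""
    return Path(__file__).parent / "presets" / "reference_survey.yaml"


def design_from_dict(d: dict) -> SurveyDesign:
    return SurveyDesign(
        n_sites=d.get("n_sites", 3),
        transects_per_site=tuple(d.get("transects_per_site", (5, 3, 5))),
        sections_per_transect=d.get("sections_per_transect", 5),
        observers=d.get("observers", 2),
        readings_per_observer=d.get("readings_per_observer", 2),
        section_length=d.get("section_length", 4.0),
        section_width=d.get("section_width", 0.8),
    )


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "vc" in d:
        d["vc"] = VarianceComponents(**d["vc"])
    if "dead_vc" in d and d["dead_vc"] is not None:
        d["dead_vc"] = VarianceComponents(**d["dead_vc"])
    for key in ("site_effects", "dead_site_effects"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def load_run_config(path) -> dict:
    """Load a YAML run configuration.

    Recognised blocks: ``design``, ``generator``, ``precision``, plus
    ``seed`` and ``out_dir``. Returns the raw dict with ``design`` and
    ``generator`` replaced by constructed objects.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    out = dict(cfg)
    out["design"] = design_from_dict(cfg.get("design", {}))
    gen = dict(cfg.get("generator", {}))
    if "seed" not in gen and "seed" in cfg:
        gen["seed"] = cfg["seed"]
    out["generator"] = generator_config_from_dict(gen)
    return out


def dump_config(design: SurveyDesign, config: GeneratorConfig, path) -> None:
    """Write a YAML config reproducing a design and generator setup."""
    payload = {
        "design": {
            "n_sites": design.n_sites,
            "transects_per_site": list(design.transects_per_site),
            "sections_per_transect": design.sections_per_transect,
            "observers": design.observers,
            "readings_per_observer": design.readings_per_observer,
            "section_length": design.section_length,
            "section_width": design.section_width,
        },
        "generator": {
            **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()
                if k not in ("vc", "dead_vc")
            },
            "vc": asdict(config.vc),
            "dead_vc": asdict(config.dead_vc) if config.dead_vc else None,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
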