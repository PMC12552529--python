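"""Reading and writing the package's tabular formats.

Weight data travel as CSV with header ``age_days,weight_g,sex`` (sex in
{female, male}); posterior draws as ``chain,iteration,A,B,K,sigma`` CSV;
run configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import SEXES, WeightSeries
from .sampler import PosteriorDraws

WEIGHT_COLUMNS = ("age_days", "weight_g", "sex")


class WeightCsvError(ValueError):
    """Malformed weight CSV (missing columns, bad cells, duplicates)."""


def read_weights(path) -> dict[str, WeightSeries]:
    """Load a weight-age CSV into one :class:`WeightSeries` per sex.

    Rejects missing columns, non-numeric cells, unknown sex labels and
    duplicated (age, sex) rows, reporting 1-based data row numbers.
    """
    table = pd.read_csv(path)
    missing = [c for c in WEIGHT_COLUMNS if c not in table.columns]
    if missing:
        raise WeightCsvError(f"{path}: missing column(s) {missing}")
    for col in ("age_days", "weight_g"):
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna()].tolist()
        if bad:
            rows = [i + 1 for i in bad]
            raise WeightCsvError(f"{path}: non-numeric {col!r} at data row(s) {rows}")
        table[col] = vals
    bad_sex = table.index[~table["sex"].isin(SEXES)].tolist()
    if bad_sex:
        rows = [i + 1 for i in bad_sex]
        raise WeightCsvError(f"{path}: unknown sex label at data row(s) {rows}")
    dup = table.duplicated(subset=["age_days", "sex"], keep=False)
    if dup.any():
        rows = [i + 1 for i in table.index[dup].tolist()]
        raise WeightCsvError(f"{path}: duplicated (age, sex) at data row(s) {rows}")
    out = {}
    for sex, grp in table.groupby("sex"):
        grp = grp.sort_values("age_days")
        out[str(sex)] = WeightSeries(
            ages=grp["age_days"].to_numpy(dtype=float),
            weights=grp["weight_g"].to_numpy(dtype=float),
            sex=str(sex),
        )
    return out


def write_weights(series_by_sex: dict[str, WeightSeries], path) -> None:
    """Write one or more weight series to the standard CSV layout."""
    frames = []
    for sex, series in series_by_sex.items():
        frames.append(
            pd.DataFrame(
                {
                    "age_days": series.ages,
                    "weight_g": series.weights,
                    "sex": sex,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_draws(draws: PosteriorDraws, path) -> None:
    """Persist post-warmup draws as ``chain,iteration,<params>`` CSV."""
    draws.to_frame().to_csv(path, index=False)


def read_draws(path) -> PosteriorDraws:
    return PosteriorDraws.from_frame(pd.read_csv(path))


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def write_config_yaml(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
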