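"""Survey CSV and config round-tripping.

Surveys are plain UTF-8 CSV, one child per row, header row, missing values
as empty cells.  Categorical responses are stored as their category labels,
so a written file re-reads to an identical dataset.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codebook import Codebook
from .simulate import SurveyDataset

_NUMERIC = [
    "child_id",
    "age_years",
    "height_cm",
    "weight_kg",
    "head_circumference_cm",
    "chest_circumference_cm",
    "bll",
]


class SurveyParseError(ValueError):
    pass


def write_survey_csv(dataset: SurveyDataset, path: str | Path) -> None:
    dataset.data.to_csv(path, index=False, encoding="utf-8")


def read_survey_csv(path: str | Path, codebook: Codebook) -> SurveyDataset:
    """Parse and validate a survey CSV against a codebook.

    Raises :class:`SurveyParseError` naming row and field for an unknown
    column, an illegal category, or a non-numeric BLL.
    """
    df = pd.read_csv(path, dtype=object, keep_default_na=False, encoding="utf-8")
    expected = set(_NUMERIC) | {"area"} | set(codebook.names)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SurveyParseError(f"unknown columns {unknown}")
    needed = {"child_id", "area", "bll"}
    lacking = needed - set(df.columns)
    if lacking:
        raise SurveyParseError(f"missing required columns {sorted(lacking)}")

    out = {}
    for col in df.columns:
        vals = df[col].replace("", None)
        if col in _NUMERIC:
            try:
                out[col] = pd.to_numeric(vals)
            except (ValueError, TypeError) as e:
                bad = next(
                    i for i, v in vals.items()
                    if v is not None and not _is_number(v)
                )
                raise SurveyParseError(
                    f"row {bad}: non-numeric value {vals[bad]!r} in column {col!r}"
                ) from e
        else:
            out[col] = vals
    parsed = pd.DataFrame(out)
    if parsed["child_id"].isna().any():
        raise SurveyParseError("child_id may not be missing")
    parsed["child_id"] = parsed["child_id"].astype(int)

    bad_area = parsed["area"].notna() & ~parsed["area"].isin(["exposed", "reference"])
    if bad_area.any():
        i = int(np.flatnonzero(bad_area)[0])
        raise SurveyParseError(f"row {i}: illegal area {parsed['area'][i]!r}")
    for entry in codebook:
        if entry.kind == "continuous" or entry.name not in parsed.columns:
            continue
        vals = parsed[entry.name]
        bad = vals.notna() & ~vals.isin(entry.categories)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SurveyParseError(
                f"row {i}: illegal category {vals[i]!r} for field {entry.name!r}"
            )
    ds = SurveyDataset(parsed, codebook)
    ds.validate()
    return ds


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def dump_yaml(obj: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
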