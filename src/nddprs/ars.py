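"""Antipsychotic responsiveness score (ARS) from antemortem clinical timelines.

For each DIBS subscale s in {positive, negative, general psychopathology}:

    change_rate(s) = (S_max(s) - S_pre(s)) / S_max(s)
    ARS(s)         = change_rate(s) / D

where S_max(s) is the subscale score at its most severe point, S_pre(s)
the score three months before death, and D the daily chlorpromazine-
equivalent antipsychotic dose (mg/day) at that time.  The change rate is
a dimensionless improvement fraction in (-inf, 1]; the ARS is improvement
per mg/day of antipsychotic.  A subscale with S_max = 0 or a patient with
D = 0 yields an undefined ARS — the record is flagged (with a reason) and
excluded from correlation analyses rather than imputed, and a change rate
below zero (worsening after the recorded maximum) is retained and
flagged, never clipped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

SUBSCALES = ("pos", "neg", "gen")

REQUIRED_COLUMNS = ["id", "cpeq_3mo"] + [
    f"dibs_{s}_{t}" for s in SUBSCALES for t in ("max", "3mo")]


def change_rate(s_max: float, s_pre: float) -> float:
    """Fractional improvement from the most severe subscale score."""
    if s_max <= 0:
        raise ValidationError("change rate undefined for S_max <= 0")
    return (s_max - s_pre) / s_max


def ars(change: float, daily_cpeq: float) -> float:
    """Responsiveness per mg/day: change rate over daily CP-eq dose."""
    if daily_cpeq <= 0:
        raise ValidationError("ARS undefined for non-positive daily CP-eq")
    return change / daily_cpeq


def build_ars_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient, per-subscale change rates and ARS with exclusion flags.

    ``records`` must carry ``id``, ``cpeq_3mo`` and, for each subscale,
    ``dibs_<s>_max`` and ``dibs_<s>_3mo`` columns.  The output has one
    row per patient with ``change_<s>``, ``ars_<s>`` (NaN when undefined)
    and ``flag_<s>`` (empty string, 'smax_zero', 'cpeq_zero', or
    'worsened').  An empty input yields an empty table, not an error.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns {missing}")
    out = {"id": records["id"].to_numpy()}
    n = len(records)
    if n:
        for col in REQUIRED_COLUMNS[1:]:
            bad = records[records[col].isna()]
            if len(bad):
                raise ValidationError(
                    f"patient {bad['id'].iloc[0]!r}: missing value in {col!r}")
    d = records["cpeq_3mo"].to_numpy(dtype=float) if n else np.array([])
    for s in SUBSCALES:
        smax = records[f"dibs_{s}_max"].to_numpy(dtype=float) if n else np.array([])
        spre = records[f"dibs_{s}_3mo"].to_numpy(dtype=float) if n else np.array([])
        if n and (smax < 0).any():
            raise ValidationError(f"negative dibs_{s}_max score")
        with np.errstate(invalid="ignore", divide="ignore"):
            cr = np.where(smax > 0, (smax - spre) / np.where(smax > 0, smax, 1.0), np.nan)
            a = np.where((smax > 0) & (d > 0), cr / np.where(d > 0, d, 1.0), np.nan)
        flags = np.full(n, "", dtype=object)
        flags[smax <= 0] = "smax_zero"
        flags[(smax > 0) & (d <= 0)] = "cpeq_zero"
        flags[(smax > 0) & (cr < 0)] = "worsened"
        out[f"change_{s}"] = cr
        out[f"ars_{s}"] = a
        out[f"flag_{s}"] = flags
    table = pd.DataFrame(out)
    table.attrs["n_evaluable"] = {
        s: int(table[f"ars_{s}"].notna().sum()) for s in SUBSCALES}
    return table


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValidationError("clinical TSV must carry an 'id' column")
    return df
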