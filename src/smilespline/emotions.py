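"""Perceived-emotion percentage tables from multi-select responses."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic import EMOTIONS

__all__ = ["emotion_percentages", "top_nonhappy"]


def _emotion_indicators(data: pd.DataFrame) -> pd.DataFrame:
    emo = data["emotions"]
    if emo.map(lambda v: isinstance(v, str)).all():
        sets = emo.map(lambda s: set(s.split("|")) if s else set())
    else:
        sets = emo.map(lambda v: set(v) if v is not None else set())
    unknown = set().union(*sets) - set(EMOTIONS) - {""}
    if unknown:
        raise ValueError(f"unknown emotion labels: {sorted(unknown)}")
    out = pd.DataFrame({e: sets.map(lambda s, e=e: e in s) for e in EMOTIONS},
                       index=data.index, dtype=float)
    return out


def emotion_percentages(data: pd.DataFrame) -> pd.DataFrame:
    """7 x 27 table: percent of raters of each symmetric smile selecting each
    emotion (multi-select, so columns need not sum to 100).

    Duplicate views of one smile by the same participant are averaged per
    participant before aggregating, so each rater counts once.
    """
    sym = data.loc[data["stimulus_kind"] == "symmetric"].copy()
    ind = _emotion_indicators(sym)
    ind["smile_index"] = sym["smile_index"].to_numpy()
    ind["participant_id"] = sym["participant_id"].to_numpy()
    per_rater = ind.groupby(["smile_index", "participant_id"]).mean()
    pct = per_rater.groupby("smile_index").mean() * 100.0
    table = pct.T.reindex(columns=range(1, 28))
    table.index.name = "emotion"
    if table.isna().any().any():
        missing = [c for c in table.columns if table[c].isna().any()]
        warnings.warn(f"smiles with zero raters: {missing}; cells undefined",
                      UserWarning)
    return table


def top_nonhappy(table: pd.DataFrame) -> str:
    """The non-Happiness emotion with the largest mean percentage across
    smiles; ties broken by the canonical emotion order."""
    means = table.drop(index="Happiness").mean(axis=1)
    means = means.reindex([e for e in EMOTIONS if e != "Happiness"])
    if np.nanmax(means.to_numpy()) <= 0:
        warnings.warn("no non-happy emotion ever selected; degenerate table",
                      UserWarning)
    return str(means.idxmax()) if means.notna().any() else "Anger"
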