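"""End-to-end orchestration: I/O, the full symmetric and asymmetric analyses,
and the study's summary tables (information-criteria grid, fit-information
table, effect grids with 90% intervals, emotion percentages)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import effects as eff
from .design import LEVELS
from .model import (
    MixedSSANOVA,
    ModelSpec,
    RESPONSES,
    enumerate_smile_models,
    estimate_random_intercept,
    information_criteria,
    select_model,
)
from .synthetic import EMOTIONS

logger = logging.getLogger("smilespline")

__all__ = [
    "COLUMNS",
    "read_ratings",
    "write_ratings",
    "read_mapped_csv",
    "run_symmetric_analysis",
    "run_asymmetric_analysis",
    "SymmetricReport",
    "AsymmetricReport",
]

COLUMNS = [
    "participant_id", "age", "gender", "drinks", "stimulus_kind",
    "smile_index", "angle_level", "extent_level", "dental_level",
    "delay_ms", "effective", "genuine", "pleasant", "emotions",
]

EFFECTIVE_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
VALID_DELAYS = (0.0, 25.0, 50.0, 100.0, 150.0, 200.0)


class SchemaError(ValueError):
    pass


class ValidationError(ValueError):
    pass


def write_ratings(data: pd.DataFrame, path) -> None:
    """Write the canonical long-format CSV."""
    data.to_csv(path, index=False, columns=COLUMNS)


def read_ratings(path) -> pd.DataFrame:
    """Read and validate a canonical long-format rating CSV.

    Level strings are case-insensitive; malformed rows are reported with
    their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "emotions": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    df = df[COLUMNS]
    if df.empty:
        warnings.warn("rating file contains a header but no rows", UserWarning)
        return df
    problems: list[str] = []

    def complain(mask, msg):
        for i in df.index[np.asarray(mask)][:20]:
            problems.append(f"line {i + 2}: {msg}")

    for col in ("angle_level", "extent_level", "dental_level"):
        lv = df[col].astype("string").str.lower()
        df[col] = lv
        complain(lv.notna() & ~lv.isin(LEVELS), f"{col} not in {LEVELS}")
    df["gender"] = df["gender"].astype("string").str.upper()
    complain(df["gender"].notna() & ~df["gender"].isin(("F", "M")),
             "gender must be F or M")
    complain(df["age"].notna() & ~df["age"].between(18, 82),
             "age outside 18..82")
    complain(df["drinks"].notna() & (df["drinks"] < 0), "negative drinks")
    e = df["effective"]
    on_grid = e.isna() | np.isclose(
        e.to_numpy(float)[:, None], np.array(EFFECTIVE_GRID)[None, :]
    ).any(axis=1)
    complain(~on_grid,
             f"effective must lie on the 5-point grid {EFFECTIVE_GRID}")
    for col in ("genuine", "pleasant"):
        v = df[col]
        complain(v.notna() & ~v.between(0, 1), f"{col} outside [0, 1]")
    d = df["delay_ms"]
    complain(d.notna() & ~d.isin(VALID_DELAYS),
             f"delay_ms not in {VALID_DELAYS}")
    kind = df["stimulus_kind"].astype("string").str.lower()
    df["stimulus_kind"] = kind
    complain(~kind.isin(("symmetric", "asymmetric")),
             "stimulus_kind must be symmetric or asymmetric")
    complain((kind == "symmetric") & d.notna(),
             "symmetric records must not carry a delay")
    complain((kind == "asymmetric")
             & (d.isna() | (df["smile_index"] != 22)),
             "asymmetric records need delay_ms and smile_index 22")
    if problems:
        raise ValidationError("invalid rating rows:\n" + "\n".join(problems))
    df["emotions"] = df["emotions"].fillna("")
    return df


def read_mapped_csv(path, mapping_path) -> pd.DataFrame:
    """Adapter for external layouts (e.g. a published supplementary dataset):
    a YAML file maps external column names / level labels onto the canonical
    schema, then the table is validated as usual."""
    with open(mapping_path) as fh:
        mapping = yaml.safe_load(fh)
    df = pd.read_csv(path)
    df = df.rename(columns=mapping.get("columns", {}))
    for col, lut in mapping.get("levels", {}).items():
        df[col] = df[col].map(lambda v: lut.get(v, v))
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    import io
    buf = io.StringIO()
    df[COLUMNS].to_csv(buf, index=False)
    buf.seek(0)
    return read_ratings(buf)


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

@dataclass
class SymmetricReport:
    """Nine-model lattice results for the spatial (symmetric) smiles."""

    ic_table: pd.DataFrame          # 9 rows x (AIC, BIC) per response
    best: dict                      # response -> winning SSANOVAResults
    best_label: dict                # response -> Table-1 model number
    bic_agrees: dict
    fit_info: pd.DataFrame          # R2, R*2, sigma2, theta2, rho per response
    predictions: pd.DataFrame       # 27 smiles x responses with 90% bounds
    successful: pd.DataFrame        # per-smile success flag

    def save(self, out_dir):
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.ic_table.to_csv(out / "symmetric_information_criteria.csv")
        self.fit_info.to_csv(out / "symmetric_fit_info.csv")
        self.predictions.to_csv(out / "smile_predictions.csv", index=False)
        self.successful.to_csv(out / "successful_smiles.csv", index=False)


@dataclass
class AsymmetricReport:
    """Delay-asymmetry results for the six variants of smile 22."""

    fit_info: pd.DataFrame
    delay_curves: dict              # response -> EffectEstimate frame
    zero_crossing: dict             # response -> ms
    effect_sizes: pd.DataFrame      # d, d_star per response
    fits: dict = field(default_factory=dict)

    def save(self, out_dir):
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.fit_info.to_csv(out / "asymmetric_fit_info.csv")
        self.effect_sizes.to_csv(out / "asymmetric_effect_sizes.csv")
        for resp, frame in self.delay_curves.items():
            frame.to_csv(out / f"delay_curve_{resp}.csv", index=False)


def _fit_info_frame(fits: dict) -> pd.DataFrame:
    rows = {}
    for resp, f in fits.items():
        rows[resp] = {"R2": f.r2, "R2_star": f.r2_star, "sigma2": f.sigma2,
                      "theta2": f.theta2, "rho": f.rho, "edf": f.edf}
    return pd.DataFrame(rows)


def run_symmetric_analysis(data: pd.DataFrame, responses=RESPONSES,
                           offset: float = 900.0,
                           maxfev: int | None = None) -> SymmetricReport:
    """Fit the nine candidate smile-effect models for each response, score
    them by AIC/BIC (shifted by ``offset`` as in the published table), select
    the winner, and predict all 27 smiles with 90% Bayesian intervals."""
    sym = data.loc[data["stimulus_kind"] == "symmetric"]
    present = set(sym["smile_index"].dropna().astype(int))
    missing = sorted(set(range(1, 28)) - present)
    if missing:
        raise ValueError(f"symmetric analysis needs all 27 smiles; missing {missing}")

    ic_rows = []
    best, best_label, bic_agrees, fits_best = {}, {}, {}, {}
    from .synthetic import smile_factor_table
    grid = smile_factor_table()[["smile_index", "angle_level", "extent_level",
                                 "dental_level"]]
    preds = []
    for resp in responses:
        logger.info("symmetric analysis: response=%s", resp)
        theta2, sigma2 = estimate_random_intercept(
            sym, ModelSpec(resp, "symmetric"))
        fits = []
        for spec in enumerate_smile_models(resp):
            m = MixedSSANOVA(sym, spec)
            fits.append(m.fit(theta2=theta2, sigma2=sigma2, maxfev=maxfev))
            logger.debug("model %s: AIC=%.2f BIC=%.2f",
                         spec.label, fits[-1].aic, fits[-1].bic)
        for f in fits:
            a, b = information_criteria(f, offset=offset)
            ic_rows.append({"model": int(f.spec.label), "response": resp,
                            "AIC": a, "BIC": b})
        win = select_model(fits)
        best[resp] = win
        best_label[resp] = int(win.spec.label)
        bic_agrees[resp] = bool(win.bic_agrees)
        est = win.predict_effect("smile", grid, include_intercept=True)
        frame = est.to_frame()
        frame["response"] = resp
        preds.append(frame)

    ic_table = (pd.DataFrame(ic_rows)
                .pivot(index="model", columns="response", values=["AIC", "BIC"])
                .swaplevel(axis=1).sort_index(axis=1))
    predictions = pd.concat(preds, ignore_index=True)
    wide = predictions.pivot(index="smile_index", columns="response",
                             values="estimate")
    ok = pd.DataFrame({"smile_index": wide.index})
    if set(RESPONSES) <= set(wide.columns):
        ok["successful"] = [
            eff.successful(wide.loc[i, "effective"], wide.loc[i, "genuine"],
                           wide.loc[i, "pleasant"]) for i in wide.index
        ]
    return SymmetricReport(ic_table=ic_table, best=best, best_label=best_label,
                           bic_agrees=bic_agrees,
                           fit_info=_fit_info_frame(best),
                           predictions=predictions, successful=ok)


def asymmetric_subset(data: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the delay-asymmetry analysis: asymmetric records plus
    symmetric views of smile 22 pooled as delay 0."""
    asym = data.loc[data["stimulus_kind"] == "asymmetric"].copy()
    zero = data.loc[(data["stimulus_kind"] == "symmetric")
                    & (data["smile_index"] == 22)].copy()
    zero["delay_ms"] = 0.0
    return pd.concat([asym, zero], ignore_index=True)


def run_asymmetric_analysis(data: pd.DataFrame, responses=RESPONSES,
                            maxfev: int | None = None) -> AsymmetricReport:
    """Fit the delay-asymmetry model per response; report the fitted eta_T
    curve with 90% intervals, its zero crossing, and effect sizes d, d*."""
    sub = asymmetric_subset(data)
    delays = sorted(sub["delay_ms"].dropna().unique())
    if len(delays) < 4:
        raise ValueError(
            f"cubic delay spline underdetermined: only {len(delays)} distinct "
            f"delays {delays}; need >= 4")

    fits, curves, crossing, es_rows = {}, {}, {}, []
    t_grid = np.arange(0.0, 201.0, 5.0)
    for resp in responses:
        logger.info("asymmetric analysis: response=%s", resp)
        spec = ModelSpec(resp, "asymmetric")
        theta2, sigma2 = estimate_random_intercept(sub, spec)
        f = MixedSSANOVA(sub, spec).fit(theta2=theta2, sigma2=sigma2,
                                        maxfev=maxfev)
        fits[resp] = f
        curves[resp] = f.predict_effect("delay", t_grid).to_frame()
        crossing[resp] = eff.delay_zero_crossing(f)
        sizes = f.effect_sizes()
        es_rows.append({"response": resp, "d": sizes.d, "d_star": sizes.d_star})
    return AsymmetricReport(fit_info=_fit_info_frame(fits),
                            delay_curves=curves, zero_crossing=crossing,
                            effect_sizes=pd.DataFrame(es_rows).set_index("response"),
                            fits=fits)
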