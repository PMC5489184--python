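"""Synthetic rating-study generator.

Emulates the design and statistical structure of the smile-perception rating
study: 802 participants (510 female, 292 male) with a bimodal age
distribution peaking near 20 and 50 years, each rating 15 animations sampled
without replacement from the 33-animation universe (27 factorial symmetric
smiles — angle x extent x dental show at three levels — plus delay-asymmetry
variants of smile 22 at {0, 25, 50, 100, 150, 200} ms, where the 0 ms variant
is smile 22 itself, so 32 distinct animations).  Responses follow the
random-intercept model y = mu(stimulus, covariates) + b_i + eps with Gaussian
b_i and eps; Effective is discretized to the 5-point grid
{0, .25, .5, .75, 1}, Genuine and Pleasant are clipped to [0, 1].

The generative ground truth (:class:`SyntheticTruth`) mirrors the study's
qualitative findings: a smile surface whose dental-show effect switches sign
across angle-extent combinations (a genuine three-way interaction), a delay
curve with a positive bump at 25-100 ms, a zero crossing at 125 ms and a
-0.09 deficit at 200 ms, and emotion probabilities with Happiness dominant
and Contempt elevated for low-angle/low-extent smiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator

from .design import LEVELS

__all__ = [
    "EMOTIONS",
    "DELAYS",
    "StudyConfig",
    "SyntheticTruth",
    "default_truth",
    "smile_index",
    "smile_factor_table",
    "sample_participants",
    "generate_ratings",
    "apply_exclusions",
]

EMOTIONS = ("Anger", "Contempt", "Disgust", "Fear",
            "Happiness", "Sadness", "Surprise")
DELAYS = (0, 25, 50, 100, 150, 200)

#: Fig-1-style numbering: angle varies slowest, then dental show, then extent
#: (fixed by the published descriptions of smiles 21/22/24/27).
DEFAULT_SMILE_ORDER = ("angle", "dental", "extent")


@dataclass
class StudyConfig:
    """Design parameters of a (synthetic) rating study.

    Defaults reproduce the real study's composition; ``n_excess_drinkers``
    and ``n_incomplete`` inject extra participants that the exclusion rules
    should remove (defaults 0, so the default output is the final sample).
    """

    n_participants: int = 802
    n_female: int = 510
    n_male: int = 292
    age_means: tuple = (20.0, 50.0)
    age_sds: tuple = (4.0, 12.0)
    age_weights: tuple = (0.5, 0.5)
    age_range: tuple = (18, 82)
    drinks_probs: tuple = (0.55, 0.20, 0.12, 0.07, 0.04, 0.02)
    n_ratings: int = 15
    theta2: float = 0.011
    sigma2: float = 0.042
    n_excess_drinkers: int = 0
    n_incomplete: int = 0
    smile_order: tuple = DEFAULT_SMILE_ORDER

    def __post_init__(self):
        if self.n_female + self.n_male != self.n_participants:
            raise ValueError("n_female + n_male must equal n_participants")
        if not (self.theta2 >= 0 and self.sigma2 >= 0):
            raise ValueError("variances must be non-negative")
        if abs(sum(self.drinks_probs) - 1.0) > 1e-9:
            raise ValueError("drinks_probs must sum to 1")
        if sorted(self.smile_order) != ["angle", "dental", "extent"]:
            raise ValueError("smile_order must permute (angle, extent, dental)")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        return cls(**raw)


def smile_index(angle: int, extent: int, dental: int,
                order: tuple = DEFAULT_SMILE_ORDER) -> int:
    """Map 0-based factor levels to the 1..27 smile number."""
    lv = {"angle": angle, "extent": extent, "dental": dental}
    return 9 * lv[order[0]] + 3 * lv[order[1]] + lv[order[2]] + 1


def smile_factor_table(order: tuple = DEFAULT_SMILE_ORDER) -> pd.DataFrame:
    """The 27 factorial smiles: index plus level labels and 0-based codes."""
    rows = []
    for a in range(3):
        for e in range(3):
            for d in range(3):
                rows.append({
                    "smile_index": smile_index(a, e, d, order),
                    "angle_level": LEVELS[a], "extent_level": LEVELS[e],
                    "dental_level": LEVELS[d],
                    "angle": a, "extent": e, "dental": d,
                })
    return (pd.DataFrame(rows).sort_values("smile_index")
            .reset_index(drop=True))


@dataclass
class SyntheticTruth:
    """Generative ground truth used for recovery testing.

    ``smile_surface`` holds the 27 true mean ratings per response;
    ``delay_knots`` the true delay-curve offsets (added to smile 22's mean);
    covariate effects are small functions of age (quadratic) and zero for
    gender and drinks by default.
    """

    smile_surface: pd.DataFrame
    delay_knots: dict = field(default_factory=dict)
    theta2: float = 0.011
    sigma2: float = 0.042
    age_amplitude: float = 0.03
    emotion_probs: pd.DataFrame = None

    def __post_init__(self):
        t = np.array(sorted(self.delay_knots))
        v = np.array([self.delay_knots[k] for k in t])
        self._delay_spline = PchipInterpolator(t, v)

    def delay_curve(self, t_ms):
        """True delay-asymmetry offset relative to a symmetric smile."""
        return self._delay_spline(np.asarray(t_ms, dtype=float))

    def age_effect(self, age):
        a = np.asarray(age, dtype=float)
        return self.age_amplitude * (0.3 - ((a - 47.0) / 35.0) ** 2)

    def gender_effect(self, gender):
        return np.zeros(np.shape(gender))

    def drinks_effect(self, drinks):
        return np.zeros(np.shape(drinks))


# per-response intercepts and amplitude multipliers of the shared surface shape
_BASE = {"effective": 0.52, "genuine": 0.50, "pleasant": 0.51}
_AMP = {"effective": 1.0, "genuine": 0.9, "pleasant": 1.1}

# centered ANOVA components on level codes c = level - 1 in {-1, 0, 1}
_MAIN = {
    "angle": np.array([-0.07, 0.03, 0.04]),
    "extent": np.array([0.03, 0.02, -0.05]),
    "dental": np.array([0.01, 0.00, -0.01]),
}
_C_AE = -0.05   # angle x extent: sweet spot at high angle with low extent
_C_AD = 0.02    # angle x dental
_C_ED = 0.02    # extent x dental
_C_AED = -0.05  # three-way: dental-show effect switches sign across angle-extent

_DELAY_KNOTS = {0: 0.0, 25: 0.03, 50: 0.04, 75: 0.035,
                100: 0.02, 125: 0.0, 150: -0.035, 200: -0.09}


def default_truth(config: StudyConfig | None = None) -> SyntheticTruth:
    """The package's standard ground truth (see module docstring)."""
    config = config or StudyConfig()
    tab = smile_factor_table(config.smile_order)
    a_c = tab["angle"].to_numpy() - 1
    e_c = tab["extent"].to_numpy() - 1
    d_c = tab["dental"].to_numpy() - 1
    shape = (
        _MAIN["angle"][tab["angle"]] + _MAIN["extent"][tab["extent"]]
        + _MAIN["dental"][tab["dental"]]
        + _C_AE * a_c * e_c + _C_AD * a_c * d_c + _C_ED * e_c * d_c
        + _C_AED * a_c * e_c * d_c
    )
    surface = tab[["smile_index", "angle_level", "extent_level",
                   "dental_level"]].copy()
    for resp in ("effective", "genuine", "pleasant"):
        surface[resp] = np.clip(_BASE[resp] + _AMP[resp] * shape, 0.05, 0.95)

    # emotion probabilities: Happiness tracks smile quality; Contempt is the
    # leading non-happy emotion, strongest for low angle + low extent
    quality = surface["effective"].to_numpy() - _BASE["effective"]
    p = pd.DataFrame(index=surface["smile_index"], columns=list(EMOTIONS),
                     dtype=float)
    p["Happiness"] = np.clip(0.62 + 1.8 * quality, 0.15, 0.95)
    p["Contempt"] = np.clip(0.06 + 0.18 * np.maximum(0.0, -(a_c + e_c) / 2.0),
                            0.0, 1.0)
    p["Anger"] = 0.03
    p["Disgust"] = 0.04
    p["Fear"] = 0.03
    p["Sadness"] = 0.04
    p["Surprise"] = 0.05
    return SyntheticTruth(smile_surface=surface, delay_knots=dict(_DELAY_KNOTS),
                          theta2=config.theta2, sigma2=config.sigma2,
                          emotion_probs=p)


def additive_truth(config: StudyConfig | None = None) -> SyntheticTruth:
    """Ground truth whose smile surface has main effects only (no
    interactions) — the null condition for model-selection studies."""
    truth = default_truth(config)
    tab = smile_factor_table((config or StudyConfig()).smile_order)
    shape = (_MAIN["angle"][tab["angle"]] + _MAIN["extent"][tab["extent"]]
             + _MAIN["dental"][tab["dental"]])
    surface = truth.smile_surface
    for resp in ("effective", "genuine", "pleasant"):
        surface[resp] = np.clip(_BASE[resp] + _AMP[resp] * shape, 0.05, 0.95)
    return truth


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _sample_participants(config: StudyConfig, rng: np.random.Generator
                         ) -> pd.DataFrame:
    n = config.n_participants
    gender = np.array(["F"] * config.n_female + ["M"] * config.n_male)
    lo, hi = config.age_range
    comp = rng.choice(len(config.age_weights), size=n, p=config.age_weights)
    age = np.empty(n)
    for i in range(n):
        while True:
            a = rng.normal(config.age_means[comp[i]], config.age_sds[comp[i]])
            if lo - 0.5 <= a <= hi + 0.49:
                age[i] = np.clip(round(a), lo, hi)
                break
    drinks = rng.choice(len(config.drinks_probs), size=n,
                        p=config.drinks_probs)
    df = pd.DataFrame({
        "participant_id": [f"P{i + 1:04d}" for i in range(n)],
        "age": age.astype(int), "gender": gender, "drinks": drinks.astype(int),
    })
    # injected participants that the exclusion rules should remove
    extra = []
    k = n
    for _ in range(config.n_excess_drinkers):
        k += 1
        extra.append({"participant_id": f"P{k:04d}",
                      "age": int(rng.integers(lo, hi + 1)),
                      "gender": "F" if rng.random() < 0.5 else "M",
                      "drinks": int(rng.integers(6, 10))})
    for _ in range(config.n_incomplete):
        k += 1
        extra.append({"participant_id": f"P{k:04d}",
                      "age": int(rng.integers(lo, hi + 1)),
                      "gender": "F" if rng.random() < 0.5 else "M",
                      "drinks": int(rng.integers(0, 6))})
    if extra:
        df = pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
    df["_incomplete"] = False
    if config.n_incomplete:
        df.loc[len(df) - config.n_incomplete:, "_incomplete"] = True
    return df


def sample_participants(config: StudyConfig, seed: int) -> pd.DataFrame:
    """Demographics table: id, age (integer years), gender, drinks."""
    rng = np.random.default_rng(seed)
    return _sample_participants(config, rng).drop(columns="_incomplete")


def _stimulus_universe(config: StudyConfig, truth: SyntheticTruth
                       ) -> pd.DataFrame:
    tab = truth.smile_surface
    sym = tab.copy()
    sym["stimulus_kind"] = "symmetric"
    sym["delay_ms"] = np.nan
    s22 = tab.loc[tab["smile_index"] == 22]
    if len(s22) != 1:
        raise ValueError("truth surface must contain smile 22 exactly once")
    asym = []
    for t in DELAYS[1:]:
        row = s22.iloc[0].to_dict()
        row["stimulus_kind"] = "asymmetric"
        row["delay_ms"] = float(t)
        for resp in ("effective", "genuine", "pleasant"):
            row[resp] = float(np.clip(row[resp] + truth.delay_curve(t), 0, 1))
        asym.append(row)
    return pd.concat([sym, pd.DataFrame(asym)], ignore_index=True)


def generate_ratings(config: StudyConfig, truth: SyntheticTruth,
                     seed: int) -> pd.DataFrame:
    """Generate a long-format rating table under the random-intercept model.

    Each participant rates ``config.n_ratings`` animations sampled without
    replacement from the 32 distinct stimuli.  Deterministic given
    (config, truth, seed).
    """
    if not set(truth.smile_surface["smile_index"]) == set(range(1, 28)):
        raise ValueError("truth surface must cover smiles 1..27")
    rng = np.random.default_rng(seed)
    participants = _sample_participants(config, rng)
    universe = _stimulus_universe(config, truth)
    n_stim = len(universe)
    if config.n_ratings > n_stim:
        raise ValueError(f"n_ratings > {n_stim} distinct stimuli")

    n_part = len(participants)
    picks = np.stack([
        rng.choice(n_stim, size=config.n_ratings, replace=False)
        for _ in range(n_part)
    ])
    b = rng.normal(0.0, np.sqrt(truth.theta2), size=(n_part, 3))

    rows = universe.iloc[picks.ravel()].reset_index(drop=True)
    rep = np.repeat(np.arange(n_part), config.n_ratings)
    for col in ("participant_id", "age", "gender", "drinks"):
        rows[col] = participants[col].to_numpy()[rep]

    cov = (truth.age_effect(rows["age"])
           + truth.gender_effect(rows["gender"])
           + truth.drinks_effect(rows["drinks"]))
    for k, resp in enumerate(("effective", "genuine", "pleasant")):
        mu = rows[resp].to_numpy(float) + cov
        eps = rng.normal(0.0, np.sqrt(truth.sigma2), size=len(rows))
        y = mu + b[rep, k] + eps
        if resp == "effective":
            rows[resp] = np.clip(np.round(y * 4.0) / 4.0, 0.0, 1.0)
        else:
            rows[resp] = np.clip(y, 0.0, 1.0)

    # multi-select emotions per stimulus view
    probs = truth.emotion_probs.loc[rows["smile_index"]].to_numpy(float)
    draws = rng.random(probs.shape) < probs
    none = ~draws.any(axis=1)
    draws[none, int(np.argmax(truth.emotion_probs.columns == "Happiness"))] = True
    rows["emotions"] = [
        "|".join(np.array(EMOTIONS)[d]) for d in draws
    ]

    # incomplete participants: blank one slider in one of their rows
    inc_ids = participants.loc[participants["_incomplete"], "participant_id"]
    for pid in inc_ids:
        idx = rows.index[rows["participant_id"] == pid]
        j = idx[rng.integers(0, len(idx))]
        rows.loc[j, rng.choice(["genuine", "pleasant"])] = np.nan

    cols = ["participant_id", "age", "gender", "drinks", "stimulus_kind",
            "smile_index", "angle_level", "extent_level", "dental_level",
            "delay_ms", "effective", "genuine", "pleasant", "emotions"]
    return rows[cols].reset_index(drop=True)


def apply_exclusions(raw: pd.DataFrame) -> pd.DataFrame:
    """Participant-level exclusions: six or more drinks, or any missing
    response anywhere in the participant's survey."""
    bad_drinks = set(raw.loc[raw["drinks"] >= 6, "participant_id"])
    resp = raw[["effective", "genuine", "pleasant"]].isna().any(axis=1)
    bad_missing = set(raw.loc[resp, "participant_id"])
    bad = bad_drinks | bad_missing
    return raw.loc[~raw["participant_id"].isin(bad)].reset_index(drop=True)
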