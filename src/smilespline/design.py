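"""Penalized design construction for the rating models.

Each model term (a main effect or a tensor-product interaction) contributes a
block of columns to the regression design: an unpenalized null-space block
(intercept-free polynomial part, e.g. the linear trend of a cubic spline) and
a penalized block of reproducing-kernel sections evaluated at the term's
knots.  At this study's scale every distinct covariate value serves as a knot,
so the representer solution is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (
    MarginalDomain,
    cubic_gram,
    nominal_gram,
    ordinal_gram,
    _ordinal_gram_cached,
)

LEVELS = ("low", "medium", "high")

#: canonical covariate domains of the rating study
DOMAINS = {
    "age": MarginalDomain("continuous", lo=18.0, hi=82.0),
    "drinks": MarginalDomain("continuous", lo=0.0, hi=5.0),
    "delay": MarginalDomain("continuous", lo=0.0, hi=200.0),
    "gender": MarginalDomain("nominal", levels=("F", "M")),
    "angle": MarginalDomain("ordinal", levels=LEVELS),
    "extent": MarginalDomain("ordinal", levels=LEVELS),
    "dental": MarginalDomain("ordinal", levels=LEVELS),
}

#: data-frame column backing each term variable
VAR_COLUMNS = {
    "age": "age",
    "drinks": "drinks",
    "delay": "delay_ms",
    "gender": "gender",
    "angle": "angle_level",
    "extent": "extent_level",
    "dental": "dental_level",
}


class Term:
    """One functional-ANOVA term: knows how to build its basis columns."""

    name: str

    def null_basis(self, df: pd.DataFrame) -> np.ndarray | None:
        return None

    def pen_basis(self, df: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def penalty(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def variables(self) -> tuple[str, ...]:
        raise NotImplementedError


@dataclass
class CubicTerm(Term):
    """Cubic smoothing spline on a continuous covariate rescaled to [0,1].

    The unpenalized part is the centered linear trend; the penalized part is
    the kernel evaluated at the training knots (all distinct values).
    """

    name: str
    knots: np.ndarray = field(default=None)

    @property
    def variables(self):
        return (self.name,)

    @property
    def domain(self):
        return DOMAINS[self.name]

    def set_knots(self, df):
        x = self.domain.rescale(df[VAR_COLUMNS[self.name]].to_numpy(float))
        self.knots = np.unique(x)
        if self.knots.size < 2:
            raise ValueError(f"term {self.name!r}: need >= 2 distinct values")

    def null_basis(self, df):
        x = self.domain.rescale(df[VAR_COLUMNS[self.name]].to_numpy(float))
        return (x - 0.5)[:, None]

    def pen_basis(self, df):
        x = self.domain.rescale(df[VAR_COLUMNS[self.name]].to_numpy(float))
        return cubic_gram(x, self.knots)

    def penalty(self):
        return cubic_gram(self.knots, self.knots)


@dataclass
class NominalTerm(Term):
    """Shrinkage (nominal smoothing spline) effect of an unordered factor."""

    name: str

    @property
    def variables(self):
        return (self.name,)

    @property
    def domain(self):
        return DOMAINS[self.name]

    def set_knots(self, df):
        pass

    def pen_basis(self, df):
        idx = self.domain.level_index(df[VAR_COLUMNS[self.name]].to_numpy(object))
        return nominal_gram(idx, self.domain.n_levels)

    def penalty(self):
        K = self.domain.n_levels
        lv = np.arange(K)
        return nominal_gram(lv, K)


@dataclass
class OrdinalTerm(Term):
    """Ordinal smoothing-spline effect of an ordered factor."""

    name: str

    @property
    def variables(self):
        return (self.name,)

    @property
    def domain(self):
        return DOMAINS[self.name]

    def set_knots(self, df):
        pass

    def _indices(self, df):
        return self.domain.level_index(df[VAR_COLUMNS[self.name]].to_numpy(object))

    def pen_basis(self, df):
        return ordinal_gram(self._indices(df), self.domain.n_levels)

    def penalty(self):
        return _ordinal_gram_cached(self.domain.n_levels)


@dataclass
class TensorTerm(Term):
    """Tensor-product interaction of ordinal marginals.

    Basis columns run over the full product grid of marginal levels with the
    first factor slowest; the penalty is the Kronecker product of the marginal
    Gram matrices, i.e. the reproducing kernel of the product space.
    """

    factors: tuple[OrdinalTerm, ...]

    @property
    def name(self):
        return ":".join(f.name for f in self.factors)

    @property
    def variables(self):
        return tuple(f.name for f in self.factors)

    def set_knots(self, df):
        pass

    def pen_basis(self, df):
        mats = [f.pen_basis(df) for f in self.factors]
        out = mats[0]
        for m in mats[1:]:
            out = (out[:, :, None] * m[:, None, :]).reshape(len(m), -1)
        return out

    def penalty(self):
        mats = [f.penalty() for f in self.factors]
        out = mats[0]
        for m in mats[1:]:
            out = np.kron(out, m)
        return out


def make_term(name: str) -> Term:
    """Build a term from its name, e.g. ``"age"`` or ``"angle:extent"``."""
    if ":" in name:
        parts = name.split(":")
        return TensorTerm(tuple(OrdinalTerm(p) for p in parts))
    dom = DOMAINS[name]
    if dom.kind == "continuous":
        return CubicTerm(name)
    if dom.kind == "nominal":
        return NominalTerm(name)
    return OrdinalTerm(name)


@dataclass
class PenaltyBlock:
    name: str
    cols: slice
    matrix: np.ndarray


class ModelDesign:
    """Assembled design for one model: basis matrix plus penalty blocks.

    Column layout: intercept first, then per term its null-space columns
    followed by its penalized kernel columns.  Keeps per-term column indices
    so that individual effect functions can be predicted with their Bayesian
    covariance.
    """

    def __init__(self, term_names: list[str], data: pd.DataFrame):
        self.terms = [make_term(t) for t in term_names]
        missing = sorted(
            {VAR_COLUMNS[v] for t in self.terms for v in t.variables}
            - set(data.columns)
        )
        if missing:
            raise KeyError(f"data lacks required columns: {missing}")
        for t in self.terms:
            t.set_knots(data)
        # column bookkeeping; each penalty block is eigen-reduced to the
        # kernel's range so the penalized system is positive definite
        self.term_cols: dict[str, list[int]] = {}
        self.penalties: list[PenaltyBlock] = []
        col = 1  # 0 = intercept
        self._layout = []
        for t in self.terms:
            nb = t.null_basis(data)
            n_null = 0 if nb is None else nb.shape[1]
            P = t.penalty()
            w, U = np.linalg.eigh(0.5 * (P + P.T))
            keep = w > 1e-10 * max(w.max(), 1.0)
            w, U = w[keep], U[:, keep]
            m = int(keep.sum())
            null_idx = list(range(col, col + n_null))
            pen = slice(col + n_null, col + n_null + m)
            self._layout.append((t, null_idx, pen, U))
            self.term_cols[t.name] = null_idx + list(range(pen.start, pen.stop))
            self.penalties.append(PenaltyBlock(t.name, pen, np.diag(w)))
            col += n_null + m
        self.n_cols = col
        self.matrix = self.build(data)

    def build(self, df: pd.DataFrame) -> np.ndarray:
        """Evaluate the full basis at new data (used for prediction)."""
        n = len(df)
        B = np.zeros((n, self.n_cols))
        B[:, 0] = 1.0
        for t, null_idx, pen, U in self._layout:
            nb = t.null_basis(df)
            if nb is not None:
                B[:, null_idx] = nb
            B[:, pen] = t.pen_basis(df) @ U
        return B

    def term_rows(self, name: str, df: pd.DataFrame,
                  include_intercept: bool = False) -> np.ndarray:
        """Rows selecting one term's effect (optionally plus intercept).

        ``name`` may be a single term, ``"smile"`` (intercept + all spatial
        smile terms) or a ``+``-joined combination of terms.
        """
        names = self.resolve_terms(name)
        n = len(df)
        X = np.zeros((n, self.n_cols))
        if include_intercept:
            X[:, 0] = 1.0
        for t, null_idx, pen, U in self._layout:
            if t.name not in names:
                continue
            nb = t.null_basis(df)
            if nb is not None:
                X[:, null_idx] = nb
            X[:, pen] = t.pen_basis(df) @ U
        return X

    def resolve_terms(self, name: str) -> set[str]:
        have = {t.name for t in self.terms}
        if name == "smile":
            names = {t for t in have
                     if set(t.split(":")) <= {"angle", "extent", "dental"}}
            if not names:
                raise KeyError(
                    f"no spatial smile terms in this model; available: {sorted(have)}")
            return names
        names = set(name.split("+"))
        unknown = names - have
        if unknown:
            raise KeyError(
                f"term(s) {sorted(unknown)} not in model; available: {sorted(have)}")
        return names
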