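"""Polynomial response-surface models: fitting, selection, and ANOVA.

Models are linear combinations of monomials in the coded factors, up to
cubic degree.  All selection routines enforce *model hierarchy*: whenever a
term such as A²B is retained, every divisor term obtained by decrementing
one of its exponents (A², AB, and transitively A, B) is retained too, so
the fitted surface is invariant to recoding shifts of the factors.

Validation follows standard designed-experiment practice: the residual sum
of squares is split into *pure error* (replicate scatter at identical design
points) and *lack of fit* (systematic model inadequacy), tested by an F
ratio, and out-of-sample quality is summarized by the PRESS-based predicted
R².
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .doe import DesignTable
from .errors import (
    DegenerateAnovaError,
    DimensionError,
    EmptyPoolError,
    LeverageError,
    SingularDesignError,
    UnsupportedDegreeError,
)

__all__ = [
    "Term",
    "FitStats",
    "PolynomialModel",
    "AnovaRow",
    "AnovaTable",
    "build_terms",
    "hierarchy_closure",
    "estimable_subset",
    "fit_ols",
    "forward_select",
    "backward_eliminate",
    "anova",
    "predicted_r2",
]

MAX_DEGREE = 3

_SUP = {"2": "²", "3": "³"}


@dataclass(frozen=True, order=True)
class Term:
    """A monomial, stored as its exponent vector; (2,1,0) is A²B."""

    exponents: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.exponents):
            raise ValueError("exponents must be non-negative")

    @property
    def degree(self) -> int:
        return sum(self.exponents)

    @property
    def is_intercept(self) -> bool:
        return self.degree == 0

    def parents(self) -> set["Term"]:
        """Immediate divisor terms (one exponent decremented)."""
        out = set()
        for i, e in enumerate(self.exponents):
            if e > 0:
                dec = list(self.exponents)
                dec[i] -= 1
                out.add(Term(tuple(dec)))
        return out

    def label(self, names: list[str] | None = None) -> str:
        if self.is_intercept:
            return "1"
        if names is None:
            names = [chr(ord("A") + i) for i in range(len(self.exponents))]
        parts = []
        for n, e in zip(names, self.exponents):
            if e == 1:
                parts.append(n)
            elif e > 1:
                parts.append(n + _SUP.get(str(e), f"^{e}"))
        return "".join(parts)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Monomial value at coded point(s) ``x`` of shape (..., k)."""
        x = np.asarray(x, dtype=float)
        return np.prod(x ** np.asarray(self.exponents), axis=-1)


def _term_sort_key(t: Term):
    # by degree, then A-major lexicographic (A before B before C ...)
    return (t.degree, tuple(-e for e in t.exponents))


def build_terms(k: int, max_degree: int) -> list[Term]:
    """All monomials in ``k`` factors of total degree <= ``max_degree``.

    Deterministic order: by degree, then lexicographic with the first factor
    ranked highest (1, A, B, C, A², AB, ...).
    """
    if k < 1:
        raise DimensionError("k must be >= 1")
    if not 1 <= max_degree <= MAX_DEGREE:
        raise UnsupportedDegreeError(
            f"max_degree must be in 1..{MAX_DEGREE}, got {max_degree}"
        )
    terms = [
        Term(exps)
        for exps in itertools.product(range(max_degree + 1), repeat=k)
        if sum(exps) <= max_degree
    ]
    return sorted(terms, key=_term_sort_key)


def hierarchy_closure(terms: list[Term]) -> list[Term]:
    """Close a term set under divisors; result ordered canonically."""
    closed: set[Term] = set(terms)
    frontier = list(terms)
    while frontier:
        t = frontier.pop()
        for p in t.parents():
            if p not in closed:
                closed.add(p)
                frontier.append(p)
    return sorted(closed, key=_term_sort_key)


def is_hierarchical(terms: list[Term]) -> bool:
    s = set(terms)
    return all(p in s for t in terms for p in t.parents())


def estimable_subset(design: DesignTable, terms: list[Term]) -> list[Term]:
    """Largest hierarchical, full-rank prefix-greedy subset of ``terms``.

    On a CCD some mixed cubic monomials are aliased (e.g. BC² lies in the
    span of B and B³, since both agree on factorial points and vanish on
    the others).  Walking terms in canonical order (low degree first), a
    term is dropped when its column does not increase the model-matrix
    rank, or when one of its divisors was dropped (keeping hierarchy).
    """
    ordered = sorted(set(terms), key=_term_sort_key)
    coded = design.coded_matrix()
    kept: list[Term] = []
    dropped: set[Term] = set()
    cols: list[np.ndarray] = []
    rank = 0
    for t in ordered:
        if any(p in dropped for p in t.parents()):
            dropped.add(t)
            continue
        trial = cols + [t.evaluate(coded)]
        r = np.linalg.matrix_rank(np.column_stack(trial))
        if r > rank:
            kept.append(t)
            cols = trial
            rank = r
        else:
            dropped.add(t)
    return kept


@dataclass
class FitStats:
    r2: float
    r2_adj: float
    r2_pred: float | None
    press: float | None
    df_model: int
    df_residual: int
    sigma2: float = float("nan")


@dataclass
class PolynomialModel:
    """A fitted (or constructed) polynomial response surface.

    ``coefficients[i]`` multiplies ``terms[i]``; the intercept comes first.
    ``block_offsets`` holds additive fixed block effects estimated during
    fitting; they are part of the in-sample fit but excluded from
    :meth:`predict` at new points.
    """

    terms: list[Term]
    coefficients: np.ndarray
    response_name: str = "y"
    fit_stats: FitStats | None = None
    block_offsets: dict[int, float] = field(default_factory=dict)
    stderr: np.ndarray | None = None
    pvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.terms):
            raise DimensionError("one coefficient per term required")

    @property
    def k(self) -> int:
        return len(self.terms[0].exponents)

    def predict(self, x) -> np.ndarray | float:
        """Evaluate the polynomial at coded point(s), ignoring block effects."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        if x.shape[-1] != self.k:
            raise DimensionError(f"point has {x.shape[-1]} coords, model has {self.k}")
        cols = np.stack([t.evaluate(x) for t in self.terms], axis=-1)
        y = cols @ self.coefficients
        return float(y) if scalar else y

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        if self.stderr is None or self.fit_stats is None:
            raise ValueError("model was not fitted; no standard errors available")
        tcrit = stats.t.ppf(0.5 + level / 2, self.fit_stats.df_residual)
        half = tcrit * self.stderr
        return np.column_stack([self.coefficients - half, self.coefficients + half])

    def summary(self, names: list[str] | None = None) -> pd.DataFrame:
        data = {"term": [t.label(names) for t in self.terms], "coef": self.coefficients}
        if self.stderr is not None:
            data["stderr"] = self.stderr
        if self.pvalues is not None:
            data["p"] = self.pvalues
        return pd.DataFrame(data)

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "response": self.response_name,
            "terms": [list(t.exponents) for t in self.terms],
            "coefficients": [float(c) for c in self.coefficients],
        }
        if self.fit_stats is not None:
            s = self.fit_stats
            d["stats"] = {
                "r2": s.r2,
                "r2_adj": s.r2_adj,
                "r2_pred": s.r2_pred,
                "press": s.press,
                "df_model": s.df_model,
                "df_residual": s.df_residual,
            }
        if self.block_offsets:
            d["block_offsets"] = {str(b): v for b, v in self.block_offsets.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialModel":
        stats_d = d.get("stats")
        fs = None
        if stats_d is not None:
            fs = FitStats(
                r2=stats_d["r2"],
                r2_adj=stats_d["r2_adj"],
                r2_pred=stats_d.get("r2_pred"),
                press=stats_d.get("press"),
                df_model=stats_d.get("df_model", 0),
                df_residual=stats_d.get("df_residual", 0),
            )
        return cls(
            terms=[Term(tuple(e)) for e in d["terms"]],
            coefficients=np.array(d["coefficients"], dtype=float),
            response_name=d.get("response", "y"),
            fit_stats=fs,
            block_offsets={int(b): v for b, v in d.get("block_offsets", {}).items()},
        )


# -- fitting ----------------------------------------------------------------

def _model_matrix(design: DesignTable, terms: list[Term]) -> np.ndarray:
    coded = design.coded_matrix()
    return np.column_stack([t.evaluate(coded) for t in terms])


def _block_columns(design: DesignTable) -> tuple[np.ndarray, list[int]]:
    """Sum-to-zero coded block dummies (effects average to zero)."""
    blocks = sorted({p.block for p in design.points})
    labels = np.array([p.block for p in design.points])
    cols = []
    for b in blocks[:-1]:
        col = np.where(labels == b, 1.0, 0.0)
        col[labels == blocks[-1]] = -1.0
        cols.append(col)
    if not cols:
        return np.empty((len(design.points), 0)), blocks
    return np.column_stack(cols), blocks


def _check_rank(X: np.ndarray, terms: list[Term], names=None) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    # walk columns accumulating an independent set to name the culprits
    dependent = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        sub = X[:, keep + [j]]
        if np.linalg.matrix_rank(sub) == len(keep) + 1:
            keep.append(j)
        else:
            dependent.append(terms[j].label(names) if j < len(terms) else f"col{j}")
    raise SingularDesignError(
        "model matrix is rank deficient; collinear terms: " + ", ".join(dependent)
    )


def fit_ols(
    design: DesignTable,
    response,
    terms: list[Term],
    block_effect: bool = False,
) -> PolynomialModel:
    """Ordinary least-squares fit of the given monomial basis.

    With ``block_effect`` the design's blocks enter as additive fixed
    offsets (sum-to-zero coded) which are reported separately and excluded
    from prediction at new points.
    """
    y = np.asarray(response, dtype=float)
    if y.shape[0] != len(design.points):
        raise DimensionError(
            f"response has {y.shape[0]} values for {len(design.points)} runs"
        )
    if not terms:
        raise EmptyPoolError("no terms to fit")
    terms = sorted(terms, key=_term_sort_key)
    X = _model_matrix(design, terms)
    n_blocks = 0
    if block_effect:
        B, block_labels = _block_columns(design)
        n_blocks = B.shape[1]
        X = np.column_stack([X, B])
    names = [f.name for f in design.factors]
    _check_rank(X, terms, names)

    res = sm.OLS(y, X, hasconst=any(t.is_intercept for t in terms)).fit()
    coefs = res.params[: len(terms)]
    p = X.shape[1]
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(res.ssr)
    if ss_tot <= 1e-300:
        r2 = r2_adj = 0.0  # constant-response convention
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = (
            1.0 - (ss_res / max(n - p, 1)) / (ss_tot / (n - 1)) if n > p else float("nan")
        )

    model = PolynomialModel(
        terms=terms,
        coefficients=coefs,
        fit_stats=FitStats(
            r2=r2,
            r2_adj=r2_adj,
            r2_pred=None,
            press=None,
            df_model=p - 1,
            df_residual=n - p,
            sigma2=float(res.mse_resid) if n > p else float("nan"),
        ),
        stderr=res.bse[: len(terms)],
        pvalues=res.pvalues[: len(terms)],
    )
    if block_effect and n_blocks:
        raw = res.params[len(terms):]
        offs = dict(zip(block_labels[:-1], map(float, raw)))
        offs[block_labels[-1]] = float(-np.sum(raw))
        model.block_offsets = offs

    # PRESS / predicted R² from the leverage shortcut when well defined
    h = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    if np.all(h < 1 - 1e-10):
        press = float(np.sum((res.resid / (1 - h)) ** 2))
        model.fit_stats.press = press
        model.fit_stats.r2_pred = 1.0 - press / ss_tot if ss_tot > 1e-300 else 0.0
    return model


def _predict_insample(model: PolynomialModel, design: DesignTable) -> np.ndarray:
    yhat = model.predict(design.coded_matrix())
    if model.block_offsets:
        yhat = yhat + np.array([model.block_offsets[p.block] for p in design.points])
    return yhat


# -- stepwise selection ------------------------------------------------------

def forward_select(
    design: DesignTable,
    response,
    candidate_terms: list[Term],
    alpha_enter: float = 0.10,
    block_effect: bool = False,
) -> PolynomialModel:
    """Forward stepwise selection by partial-F p-value, hierarchy-corrected.

    Starting from the intercept, the candidate with the smallest partial-F
    p-value is added while that p-value is below ``alpha_enter`` (ties broken
    by lower degree, then canonical term order).  After termination any
    missing divisor terms are added and the model refitted.
    """
    if not candidate_terms:
        raise EmptyPoolError("candidate term pool is empty")
    candidates = sorted(set(candidate_terms), key=_term_sort_key)
    intercept = Term((0,) * design.k)
    current = [intercept]
    pool = [t for t in candidates if t != intercept]

    while pool:
        best = None  # (p-value, sort key, term, fitted)
        for t in pool:
            trial = current + [t]
            try:
                m = fit_ols(design, response, trial, block_effect=block_effect)
            except SingularDesignError:
                continue
            if m.fit_stats.df_residual < 1:
                continue
            pval = float(m.pvalues[m.terms.index(t)])
            key = (pval, _term_sort_key(t))
            if best is None or key < best[0]:
                best = (key, t)
        if best is None or best[0][0] >= alpha_enter:
            break
        current.append(best[1])
        pool.remove(best[1])

    # hierarchy repair can re-create an aliased basis; keep the estimable part
    final_terms = estimable_subset(design, hierarchy_closure(current))
    return fit_ols(design, response, final_terms, block_effect=block_effect)


def backward_eliminate(
    design: DesignTable,
    response,
    start_terms: list[Term],
    alpha_remove: float = 0.10,
    block_effect: bool = False,
) -> PolynomialModel:
    """Backward stepwise elimination by p-value, respecting hierarchy.

    Repeatedly drops the non-intercept term with the largest p-value at or
    above ``alpha_remove`` whose removal leaves the model hierarchical;
    stops when every removable term is significant.
    """
    if not start_terms:
        raise EmptyPoolError("start term pool is empty")
    current = hierarchy_closure(start_terms)
    intercept = Term((0,) * design.k)
    if intercept not in current:
        current = [intercept] + current
    # the full cubic basis is aliased on a CCD; start from its estimable part
    current = estimable_subset(design, current)

    model = fit_ols(design, response, current, block_effect=block_effect)
    while True:
        removable = []
        for t in model.terms:
            if t.is_intercept:
                continue
            others = [u for u in model.terms if u != t]
            if is_hierarchical(others):
                removable.append(t)
        worst = None
        for t in removable:
            pval = float(model.pvalues[model.terms.index(t)])
            # alpha_remove >= 1 means unconditional removal (p-values < 1)
            if (alpha_remove >= 1.0 or pval >= alpha_remove) and (
                worst is None or pval > worst[0]
            ):
                worst = (pval, t)
        if worst is None:
            return model
        current = [u for u in model.terms if u != worst[1]]
        model = fit_ols(design, response, current, block_effect=block_effect)


# -- ANOVA -------------------------------------------------------------------

@dataclass
class AnovaRow:
    source: str
    ss: float
    df: int
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    rows: list[AnovaRow]

    def __getitem__(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def __contains__(self, source: str) -> bool:
        return any(r.source == source for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": r.source, "ss": r.ss, "df": r.df, "ms": r.ms, "f": r.f, "p": r.p}
                for r in self.rows
            ]
        )


def _replicate_groups(design: DesignTable, decimals: int = 9) -> list[np.ndarray]:
    """Indices of runs sharing identical coded levels (to 1e-9)."""
    keys: dict[tuple, list[int]] = {}
    for i, p in enumerate(design.points):
        key = tuple(np.round(p.coded_levels, decimals))
        keys.setdefault(key, []).append(i)
    return [np.array(ix) for ix in keys.values()]


def anova(model: PolynomialModel, design: DesignTable, response) -> AnovaTable:
    """Sums-of-squares decomposition with pure-error / lack-of-fit split.

    Pure error pools within-replicate deviations at identical coded points;
    lack of fit is the remainder of the residual, tested against pure error
    by an F ratio.  Per-term rows carry partial (drop-one) sums of squares.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if y.shape[0] != len(design.points):
        raise DimensionError("response length does not match design")
    p = len(model.terms) + max(len(model.block_offsets) - 1, 0)
    df_resid = n - p
    if df_resid <= 0:
        raise DegenerateAnovaError("zero residual degrees of freedom")

    resid = y - _predict_insample(model, design)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_model = ss_tot - ss_res
    df_model = p - 1
    ms_res = ss_res / df_resid
    names = [f.name for f in design.factors]

    rows = [
        AnovaRow(
            "model",
            ss_model,
            df_model,
            ss_model / df_model if df_model else None,
            (ss_model / df_model) / ms_res if df_model and ms_res > 0 else None,
            float(stats.f.sf((ss_model / df_model) / ms_res, df_model, df_resid))
            if df_model and ms_res > 0
            else None,
        )
    ]

    # partial SS per non-intercept term (hierarchy ignored for testing)
    block = bool(model.block_offsets)
    for t in model.terms:
        if t.is_intercept:
            continue
        reduced = [u for u in model.terms if u != t]
        try:
            m_red = fit_ols(design, y, reduced, block_effect=block)
        except SingularDesignError:
            continue
        resid_red = y - _predict_insample(m_red, design)
        ss_t = float(resid_red @ resid_red) - ss_res
        f_t = (ss_t / 1) / ms_res if ms_res > 0 else None
        rows.append(
            AnovaRow(
                t.label(names),
                ss_t,
                1,
                ss_t,
                f_t,
                float(stats.f.sf(f_t, 1, df_resid)) if f_t is not None else None,
            )
        )

    rows.append(AnovaRow("residual", ss_res, df_resid, ms_res))

    groups = _replicate_groups(design)
    df_pe = sum(len(g) - 1 for g in groups)
    if df_pe > 0:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups))
        df_lof = df_resid - df_pe
        ss_lof = ss_res - ss_pe
        if df_lof > 0 and df_pe > 0:
            ms_lof = ss_lof / df_lof
            ms_pe = ss_pe / df_pe
            f_lof = ms_lof / ms_pe if ms_pe > 0 else float("inf")
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
            rows.append(AnovaRow("lack_of_fit", ss_lof, df_lof, ms_lof, f_lof, p_lof))
            rows.append(AnovaRow("pure_error", ss_pe, df_pe, ms_pe))
        else:
            rows.append(AnovaRow("lack_of_fit", max(ss_lof, 0.0), max(df_lof, 0)))
            rows.append(AnovaRow("pure_error", ss_pe, df_pe, ss_pe / df_pe))
    else:
        warnings.warn(
            "no replicated design points: lack-of-fit/pure-error rows omitted",
            stacklevel=2,
        )

    rows.append(AnovaRow("total", ss_tot, n - 1))
    return AnovaTable(rows)


def predicted_r2(model: PolynomialModel, design: DesignTable, response) -> float:
    """PRESS-based predicted R²: ``1 - PRESS / SS_total``.

    PRESS uses the leave-one-out shortcut ``sum((e_i / (1 - h_ii))**2)``
    with ``h`` the hat-matrix diagonal; identical to refitting with each run
    held out.
    """
    y = np.asarray(response, dtype=float)
    X = _model_matrix(design, model.terms)
    if model.block_offsets:
        B, _ = _block_columns(design)
        X = np.column_stack([X, B])
    h = np.einsum("ij,jk,ik->i", X, np.linalg.pinv(X.T @ X), X)
    if np.any(h >= 1 - 1e-10):
        raise LeverageError("a leverage equals 1; leave-one-out undefined")
    resid = y - _predict_insample(model, design)
    press = float(np.sum((resid / (1 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_tot if ss_tot > 1e-300 else 0.0
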