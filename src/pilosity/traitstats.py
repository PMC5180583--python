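"""All-subsets OLS with AICc ranking — linking hairiness to pollination.

The trait table holds one row per pollinator species: mean combined entropy
for each of the eight body regions, body length (mm), and one or both
response variables — single-visit pollen deposition (SVD, mean conspecific
pollen grains deposited on a virgin stigma in one visit) and pollen load
(mean grains carried on the body surface).

Every subset of the global model's main effects (optionally with
body-length x region interactions under marginality) is fitted by ordinary
least squares and ranked by the small-sample-corrected Akaike information
criterion::

    AICc = 2k - 2 logL + 2k(k+1) / (n - k - 1)

with the Gaussian log-likelihood including its normalizing constants
(``logL = -n/2 (log(2 pi RSS/n) + 1)``, the R ``lm``/``AIC`` convention) and
``k`` counting intercept, slopes and the residual variance. Akaike weights
``w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2)`` quantify relative support.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import CANONICAL_LABELS

log = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ModelFit",
    "RankingTable",
    "read_trait_csv",
    "complete_cases",
    "fit_ols",
    "aicc",
    "enumerate_models",
    "rank_models",
    "vif",
]

#: Predictors of the global model: the eight region entropies plus body length.
GLOBAL_PREDICTORS: tuple[str, ...] = CANONICAL_LABELS + ("body_length",)

# relative RSS below this is treated as an exact (degenerate) fit
_DEGENERATE_RTOL = 1e-10


@dataclass(frozen=True)
class ModelSpec:
    """One candidate regression model.

    ``mains`` are predictor column names; ``interactions`` are pairs of main
    effects (marginality: both mains of an interaction must be present).
    """

    response: str
    mains: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for a, b in self.interactions:
            if a not in self.mains or b not in self.mains:
                raise ValueError(
                    f"interaction {a}:{b} without both main effects present"
                )

    @property
    def terms(self) -> tuple[str, ...]:
        return self.mains + tuple(f"{a}:{b}" for a, b in self.interactions)

    @property
    def n_terms(self) -> int:
        return len(self.mains) + len(self.interactions)

    def describe(self) -> str:
        return " + ".join(self.terms) if self.terms else "(intercept)"


@dataclass
class ModelFit:
    """OLS fit of one :class:`ModelSpec`."""

    spec: ModelSpec
    n: int
    coefficients: dict[str, float]
    rss: float
    r2: float
    adj_r2: float
    loglik: float  # +inf sentinel for a degenerate (RSS = 0) fit
    k: int  # intercept + slopes + residual variance
    aicc: float  # nan when undefined or degenerate

    @property
    def degenerate(self) -> bool:
        return math.isinf(self.loglik)


@dataclass
class RankingTable:
    """Candidate models sorted ascending by AICc, with Akaike weights."""

    fits: list[ModelFit]
    delta: np.ndarray
    weight: np.ndarray
    acc_weight: np.ndarray
    n_dropped: int = 0  # candidates unfittable or degenerate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.spec.describe() for f in self.fits],
                "adj_r2": [f.adj_r2 for f in self.fits],
                "aicc": [f.aicc for f in self.fits],
                "delta": self.delta,
                "weight": self.weight,
                "acc_weight": self.acc_weight,
            }
        )

    @property
    def top(self) -> ModelFit:
        return self.fits[0]


def read_trait_csv(path) -> pd.DataFrame:
    """Read a species-level trait table.

    Expected columns: ``species``, the eight region entropies, ``body_length``
    and optionally ``svd`` / ``pollen_load``. Species names must be unique.
    """
    df = pd.read_csv(path)
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    dupes = df["species"][df["species"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicated species names: {dupes}")
    return df


def complete_cases(table: pd.DataFrame, response: str, predictors=None) -> pd.DataFrame:
    """Rows with finite response and predictors (species kept as a column)."""
    predictors = list(predictors) if predictors is not None else [
        c for c in GLOBAL_PREDICTORS if c in table.columns
    ]
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in trait table")
    cols = [response] + predictors
    sub = table.dropna(subset=cols)
    sub = sub[np.isfinite(sub[cols]).all(axis=1)]
    return sub.reset_index(drop=True)


def _design_matrix(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table))]
    names = ["(intercept)"]
    for m in spec.mains:
        if m not in table.columns:
            raise ValueError(f"predictor {m!r} not in trait table")
        cols.append(table[m].to_numpy(dtype=float))
        names.append(m)
    for a, b in spec.interactions:
        cols.append(table[a].to_numpy(dtype=float) * table[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    return np.column_stack(cols), names


def fit_ols(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Least-squares fit with intercept; reports R2, adjusted R2, logL, AICc.

    A perfect fit (RSS = 0) gets a ``+inf`` log-likelihood sentinel and is
    excluded from weight computation by :func:`rank_models`.
    """
    y = table[spec.response].to_numpy(dtype=float)
    X, names = _design_matrix(table, spec)
    n, ncoef = X.shape
    p = ncoef - 1
    if n <= p + 1:
        raise ValueError(
            f"insufficient data: n = {n} rows for {p} predictors "
            f"({spec.describe()})"
        )
    if np.linalg.matrix_rank(X) < ncoef:
        raise ValueError(
            f"rank-deficient design: collinear terms among {names[1:]}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = rss <= _DEGENERATE_RTOL * max(tss, 1.0)
    r2 = 1.0 if tss == 0 else 1.0 - rss / tss
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    k = p + 2
    if degenerate:
        loglik = float("inf")
        aicc_val = float("nan")
    else:
        loglik = -n / 2.0 * (math.log(2.0 * math.pi * rss / n) + 1.0)
        aicc_val = aicc(loglik, k, n) if n - k - 1 > 0 else float("nan")
    return ModelFit(
        spec=spec,
        n=n,
        coefficients=dict(zip(names, beta)),
        rss=rss,
        r2=r2,
        adj_r2=adj_r2,
        loglik=loglik,
        k=k,
        aicc=aicc_val,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: ``2k - 2 logL + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n = {n}, k = {k} (n - k - 1 <= 0)")
    return 2.0 * k - 2.0 * loglik + 2.0 * k * (k + 1) / (n - k - 1)


def enumerate_models(
    global_spec: ModelSpec,
    max_terms: int | None = None,
    n: int | None = None,
) -> list[ModelSpec]:
    """All subsets of the global model's main effects, under marginality.

    Includes the intercept-only model. For each interaction of the global
    model, candidates containing both of its mains are emitted with and
    without the interaction. Subsets larger than ``max_terms`` (default
    ``n - 4`` when ``n`` is given, so AICc stays finite with headroom) or
    with AICc undefined at ``n`` are excluded; the exclusion count is logged.
    """
    if max_terms is None and n is not None:
        max_terms = max(n - 4, 1)
    out: list[ModelSpec] = []
    n_excluded = 0
    mains = global_spec.mains
    for size in range(len(mains) + 1):
        for subset in itertools.combinations(mains, size):
            applicable = [
                (a, b)
                for a, b in global_spec.interactions
                if a in subset and b in subset
            ]
            for isize in range(len(applicable) + 1):
                for inter in itertools.combinations(applicable, isize):
                    nt = len(subset) + len(inter)
                    if max_terms is not None and nt > max_terms:
                        n_excluded += 1
                        continue
                    if n is not None and n - (nt + 2) - 1 <= 0:
                        n_excluded += 1
                        continue
                    out.append(
                        ModelSpec(global_spec.response, subset, inter)
                    )
    if n_excluded:
        log.info("enumerate_models: %d candidate(s) excluded by size/AICc caps",
                 n_excluded)
    return out


def rank_models(table: pd.DataFrame, candidates: list[ModelSpec]) -> RankingTable:
    """Fit all candidates and rank ascending by AICc with Akaike weights.

    Unfittable candidates (insufficient rows, collinearity, undefined AICc)
    are dropped with a warning. Degenerate RSS = 0 fits rank first (a
    perfect fit dominates) but are excluded from the weight computation,
    with a warning; their delta/weight entries are NaN and Akaike weights
    sum to 1 over the remaining models. Ties are broken by fewer terms,
    then lexicographic term names.
    """
    fits: list[ModelFit] = []
    dropped = 0
    for spec in candidates:
        try:
            f = fit_ols(table, spec)
        except ValueError as exc:
            log.warning("dropping candidate %s: %s", spec.describe(), exc)
            dropped += 1
            continue
        if not f.degenerate and math.isnan(f.aicc):
            log.warning("dropping candidate %s: AICc undefined", spec.describe())
            dropped += 1
            continue
        if f.degenerate:
            log.warning(
                "candidate %s is a perfect fit (RSS = 0); excluded from "
                "Akaike weights", spec.describe(),
            )
        fits.append(f)
    if not fits:
        raise ValueError("no fittable candidate models")
    fits.sort(
        key=lambda f: (
            -math.inf if f.degenerate else f.aicc,
            f.spec.n_terms,
            f.spec.terms,
        )
    )
    finite = np.array([not f.degenerate for f in fits])
    delta = np.full(len(fits), np.nan)
    weight = np.full(len(fits), np.nan)
    acc_weight = np.full(len(fits), np.nan)
    if finite.any():
        aiccs = np.array([f.aicc for f, ok in zip(fits, finite) if ok])
        d = aiccs - aiccs.min()
        raw = np.exp(-d / 2.0)
        w = raw / raw.sum()
        delta[finite] = d
        weight[finite] = w
        acc_weight[finite] = np.cumsum(w)
    return RankingTable(
        fits=fits,
        delta=delta,
        weight=weight,
        acc_weight=acc_weight,
        n_dropped=dropped,
    )


def vif(table: pd.DataFrame, terms: list[str]) -> dict[str, float]:
    """Variance inflation factors: ``VIF_j = 1 / (1 - R2_j)``.

    ``R2_j`` is from regressing term ``j`` on the remaining terms with an
    intercept. Perfect collinearity yields an ``inf`` sentinel with a
    warning.
    """
    if len(terms) < 2:
        raise ValueError("VIF needs at least two terms")
    n = len(table)
    if n <= len(terms) + 1:
        raise ValueError(f"insufficient data for VIF: n = {n}, {len(terms)} terms")
    out: dict[str, float] = {}
    cols = {t: table[t].to_numpy(dtype=float) for t in terms}
    for j, t in enumerate(terms):
        y = cols[t]
        X = np.column_stack(
            [np.ones(n)] + [cols[u] for u in terms if u != t]
        )
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        r2j = 1.0 if tss == 0 else 1.0 - rss / tss
        if r2j >= 1.0 - 1e-12:
            log.warning("VIF: term %r perfectly collinear with the rest", t)
            out[t] = float("inf")
        else:
            out[t] = 1.0 / (1.0 - r2j)
    return out
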