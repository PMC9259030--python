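"""Linear-model quantification of epistasis and host-dependent epistasis.

Single-host model: selection rate regressed on the ``L`` mutation indicators
and all C(L,2) pairwise products,

    y = b** + sum_i b_i G_i + sum_{i<j} b_ij G_i G_j            (L=10: 55 terms)

Combined two-host model adds a host indicator E and its interactions,

    y = b*** + sum b_i G_i + b_E E + sum b_iE G_i E
        + sum b_ij G_i G_j + sum b_ijE G_i G_j E                (L=10: 111 terms)

On top of the OLS fit this module provides Benjamini-Hochberg FDR control
over the coefficient family, R ``step``-style bidirectional AIC selection
respecting marginality, and a sequential (type-I) variance partition by term
group — the computation behind "percent of variance explained by direct
effects / pairwise epistasis / host interactions".

Observations are genotype means (one row per genotype, or per genotype-host
pair in combined mode), matching how the landscape is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .fitness import FitnessLandscape
from .genotypes import to_string

__all__ = [
    "Term",
    "DesignMatrix",
    "RegressionResult",
    "build_design",
    "fit_ols",
    "bh_adjust",
    "aic_stepwise",
    "variance_partition",
    "GROUP_ORDER",
]

GROUP_ORDER = ("main", "pairwise", "host", "host_x_main", "host_x_pair")


@dataclass(frozen=True, order=True)
class Term:
    """A predictor term: a set of loci, optionally crossed with the host
    indicator E.  ``Term((), host=True)`` is the E main effect."""

    loci: tuple[int, ...]
    host: bool = False

    @property
    def name(self) -> str:
        parts = [f"G{i + 1}" for i in self.loci] + (["E"] if self.host else [])
        return ":".join(parts)

    @property
    def group(self) -> str:
        n = len(self.loci)
        if not self.host:
            return "main" if n == 1 else "pairwise"
        if n == 0:
            return "host"
        return "host_x_main" if n == 1 else "host_x_pair"

    def is_margin_of(self, other: "Term") -> bool:
        """True if self is a strict lower-order component of other."""
        return (
            self != other
            and set(self.loci) <= set(other.loci)
            and self.host <= other.host
        )


def _terms(L: int, combined: bool) -> list[Term]:
    terms = [Term((i,)) for i in range(L)]
    terms += [Term((i, j)) for i in range(L) for j in range(i + 1, L)]
    if combined:
        terms.append(Term((), host=True))
        terms += [Term((i,), host=True) for i in range(L)]
        terms += [Term((i, j), host=True) for i in range(L) for j in range(i + 1, L)]
    return terms


@dataclass
class DesignMatrix:
    """Named predictor matrix (no intercept column; fits add one)."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # (n,)
    terms: list[Term]
    genotypes: np.ndarray  # bitmask per row
    host: np.ndarray  # 0/1 per row
    L: int

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.terms]

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.names)
        df.insert(0, "genotype", [to_string(g, self.L) for g in self.genotypes])
        df.insert(1, "y", self.y)
        return df


def _term_columns(terms: Sequence[Term], genotypes: np.ndarray, host: np.ndarray,
                  L: int) -> np.ndarray:
    bits = ((genotypes[:, None] >> np.arange(L)) & 1).astype(float)
    cols = []
    for t in terms:
        col = np.ones(len(genotypes))
        for i in t.loci:
            col = col * bits[:, i]
        if t.host:
            col = col * host
        cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(genotypes), 0))


def build_design(
    landscape: FitnessLandscape,
    landscape2: FitnessLandscape | None = None,
    mode: str = "single",
) -> DesignMatrix:
    """Design matrix over measured genotypes (means as response).

    ``mode="single"`` uses one landscape; ``mode="combined"`` stacks two with
    the host indicator E = 0 for the first (ancestral) and 1 for the second
    (malT-) landscape.
    """
    if mode not in ("single", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "combined" and landscape2 is None:
        raise ValueError("combined mode requires both hosts' landscapes")
    if not landscape.records:
        raise ValueError("empty landscape")
    L = landscape.L
    gs = np.array(landscape.genotypes, dtype=np.int64)
    ys = np.array([landscape.mean(g) for g in gs])
    host = np.zeros(len(gs))
    if mode == "combined":
        gs2 = np.array(landscape2.genotypes, dtype=np.int64)
        ys2 = np.array([landscape2.mean(g) for g in gs2])
        gs = np.concatenate([gs, gs2])
        ys = np.concatenate([ys, ys2])
        host = np.concatenate([host, np.ones(len(gs2))])
    terms = _terms(L, combined=(mode == "combined"))
    X = _term_columns(terms, gs, host, L)
    return DesignMatrix(X=X, y=ys, terms=terms, genotypes=gs, host=host, L=L)


@dataclass
class RegressionResult:
    """OLS fit summary over the named terms (intercept reported separately)."""

    terms: list[Term]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    fvalue: float
    f_pvalue: float
    df_model: int
    df_resid: int
    aic: float
    inestimable: list[str] = field(default_factory=list)
    bh_significant: pd.Series | None = None
    bh_adjusted: pd.Series | None = None

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"estimate": self.params, "se": self.bse, "p": self.pvalues}
        )
        if self.bh_adjusted is not None:
            df["p_bh"] = self.bh_adjusted
            df["significant"] = self.bh_significant
        return df


def _rank_check(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Identify columns made redundant by earlier ones (QR with pivoting)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return np.array([], dtype=bool), []
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = np.zeros(X.shape[1], dtype=bool)
    keep[piv[:rank]] = True
    dropped = [names[i] for i in np.nonzero(~keep)[0]]
    return keep, dropped


def fit_ols(design: DesignMatrix, q: float | None = 0.05) -> RegressionResult:
    """Ordinary least squares with per-term t tests and overall F.

    Rank-deficient designs (e.g. duplicated columns, or terms constant over
    the observed genotypes) have the offending columns flagged inestimable and
    excluded from inference rather than silently dropped.  When ``q`` is not
    None, Benjamini-Hochberg flags at FDR level ``q`` are attached over the
    estimable coefficient family (intercept excluded).
    """
    Xc = sm.add_constant(design.X, has_constant="add")
    names = ["Intercept"] + design.names
    keep, dropped = _rank_check(Xc, names)
    if dropped:
        import warnings

        warnings.warn(
            f"rank-deficient design: terms flagged inestimable: {dropped}",
            stacklevel=2,
        )
    model = sm.OLS(design.y, Xc[:, keep]).fit()
    kept_names = [n for n, k in zip(names, keep) if k]
    with np.errstate(divide="ignore", invalid="ignore"):
        # a constant response has zero total SS: report R^2 = 0, F undefined
        degenerate = float(((design.y - design.y.mean()) ** 2).sum()) == 0.0
        r2 = 0.0 if degenerate else float(model.rsquared)
        r2_adj = 0.0 if degenerate else float(model.rsquared_adj)
        fval = float("nan") if degenerate else float(model.fvalue)
        fp = float("nan") if degenerate else float(model.f_pvalue)
    params = pd.Series(np.nan, index=names)
    bse = pd.Series(np.nan, index=names)
    pvalues = pd.Series(np.nan, index=names)
    params[kept_names] = model.params
    bse[kept_names] = model.bse
    pvalues[kept_names] = model.pvalues
    result = RegressionResult(
        terms=design.terms,
        params=params,
        bse=bse,
        pvalues=pvalues,
        rsquared=r2,
        rsquared_adj=r2_adj,
        fvalue=fval,
        f_pvalue=fp,
        df_model=int(model.df_model),
        df_resid=int(model.df_resid),
        aic=float(model.aic),
        inestimable=dropped,
    )
    if q is not None:
        family = pvalues.drop("Intercept").dropna()
        flags, adj = bh_adjust(family.to_numpy(), q=q)
        result.bh_significant = pd.Series(flags, index=family.index)
        result.bh_adjusted = pd.Series(adj, index=family.index)
    return result


def bh_adjust(pvalues: Iterable[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control at level ``q``.

    Returns ``(significant_flags, adjusted_pvalues)`` in input order.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return flags, adjusted


# --- AIC stepwise selection ----------------------------------------------


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    Xc = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    resid = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
    return float(resid @ resid)


def _aic(rss: float, n: int, k: int) -> float:
    """R ``extractAIC``-style AIC for a linear model: n ln(RSS/n) + 2 edf,
    with edf = number of coefficients including the intercept."""
    return n * np.log(rss / n) + 2 * (k + 1)


def aic_stepwise(
    design: DesignMatrix,
    scope: Sequence[Term] | None = None,
    trace: bool = False,
) -> tuple[list[Term], list[dict]]:
    """Bidirectional greedy AIC minimization over the term lattice.

    Starts from the full model and, at each step, evaluates every marginality-
    respecting single-term drop or add (a lower-order term is not removable
    while a containing higher-order term remains; a term is addable only when
    all its lower-order components are in the model), taking the move with the
    lowest AIC.  Ties break to the first-listed candidate; the search stops
    when no move improves AIC.  Returns ``(selected_terms, trace_records)``.
    """
    scope = list(scope) if scope is not None else list(design.terms)
    col = {t: i for i, t in enumerate(design.terms)}
    y, n = design.y, len(design.y)

    def model_aic(terms: list[Term]) -> float:
        X = design.X[:, [col[t] for t in terms]]
        return _aic(_rss(X, y), n, len(terms))

    current = list(scope)
    current_aic = model_aic(current)
    log = [{"action": "start", "term": None, "aic": current_aic, "k": len(current)}]
    while True:
        best: tuple[float, str, Term] | None = None
        in_model = set(current)
        for t in current:  # drops first, in term order
            if any(t.is_margin_of(u) for u in in_model):
                continue
            cand = [u for u in current if u != t]
            a = model_aic(cand)
            if best is None or a < best[0] - 1e-12:
                best = (a, "drop", t)
        for t in scope:  # then adds
            if t in in_model:
                continue
            margins = [u for u in scope if u.is_margin_of(t)]
            if any(u not in in_model for u in margins):
                continue
            cand = current + [t]
            a = model_aic(cand)
            if best is None or a < best[0] - 1e-12:
                best = (a, "add", t)
        if best is None or best[0] >= current_aic - 1e-9:
            break
        a, action, t = best
        current = [u for u in current if u != t] if action == "drop" else current + [t]
        current = [u for u in design.terms if u in set(current)]  # canonical order
        current_aic = a
        log.append({"action": action, "term": t.name, "aic": a, "k": len(current)})
        if trace:
            print(f"step: {action} {t.name} -> AIC {a:.3f}")
    return current, log


def fit_terms(design: DesignMatrix, terms: Sequence[Term]) -> RegressionResult:
    """OLS on a sub-model (e.g. the AIC-selected term set)."""
    col = {t: i for i, t in enumerate(design.terms)}
    sub = DesignMatrix(
        X=design.X[:, [col[t] for t in terms]],
        y=design.y,
        terms=list(terms),
        genotypes=design.genotypes,
        host=design.host,
        L=design.L,
    )
    return fit_ols(sub)


# --- variance partition ---------------------------------------------------


def variance_partition(
    design: DesignMatrix, group_order: Sequence[str] = GROUP_ORDER
) -> pd.DataFrame:
    """Sequential (type-I) sums of squares by term group.

    Groups are entered cumulatively in ``group_order`` (mains, then pairwise
    epistasis, then — in combined mode — host, host-by-main, host-by-pair);
    each group's incremental SS is divided by the total SS of ``y`` and
    reported as a percentage.  The remainder row is the residual.  On a
    complete balanced factorial design the groups are orthogonal and the
    partition is order-independent.
    """
    y = design.y
    n = len(y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("response has zero variance")
    present_groups = [g for g in group_order if any(t.group == g for t in design.terms)]
    rows = []
    included: list[Term] = []
    prev_rss = ss_total
    for g in present_groups:
        included += [t for t in design.terms if t.group == g]
        cols = [i for i, t in enumerate(design.terms) if t in set(included)]
        rss = _rss(design.X[:, cols], y)
        ss = prev_rss - rss
        rows.append({"group": g, "ss": ss, "percent": 100.0 * ss / ss_total,
                     "n_terms": sum(1 for t in design.terms if t.group == g)})
        prev_rss = rss
    rows.append({"group": "residual", "ss": prev_rss,
                 "percent": 100.0 * prev_rss / ss_total, "n_terms": n - 1 - len(included)})
    return pd.DataFrame(rows)
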