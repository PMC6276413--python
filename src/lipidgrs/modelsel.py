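"""Linear-model selection, internal validation and variance decomposition.

Each lipid is regressed on its genetic risk score plus conventional
predictors (age, sex, adiposity, diet, physical activity, smoking,
drinking).  Three selection strategies are compared:

* **BSRP** -- best-subset regression: every subset of the candidates is
  scored by an information criterion (AIC, AICC or BIC) and the minimiser
  wins.
* **LARS** -- least-angle regression: the support minimising Mallows' Cp
  along the LARS path, refit by OLS.
* **BSM** -- bootstrapped stepwise: bidirectional p-value stepwise run on B
  bootstrap resamples; predictors included in >= 60% of resamples form the
  final support.

Every candidate model is internally validated with Harrell's bootstrap
optimism correction: the *entire* selection procedure is rerun on each
resample, the performance drop from resample to original data is averaged,
and corrected metric = apparent metric - mean optimism.  The winner per
lipid is the model with the largest optimism-corrected adjusted R^2.

Squared partial correlations PC^2 = t^2 / (t^2 + df_resid) report each
predictor's unique contribution.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FitReport", "OptimismReport", "ols_fit", "best_subset", "lars_select",
    "bootstrap_stepwise", "optimism_correct", "squared_partial_correlation",
    "interaction_scan", "select_best_model", "compare_strategies",
    "make_selector", "build_candidates", "format_model_table",
]

#: Candidate predictors offered to every lipid model, in reporting order.
#: Energy enters per 100 kcal; sex is coded female=0 / male=1.
CANDIDATE_ORDER = [
    "age", "sex", "bmi", "tfat", "vfat", "mets", "energy_100kcal",
    "carb_pct", "prot_pct", "fat_pct", "chol_intake", "smoker", "drinker",
]


# ---------------------------------------------------------------------------
# fit report + OLS
# ---------------------------------------------------------------------------

@dataclass
class FitReport:
    predictors: List[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    aic: float
    aicc: float
    bic: float
    pc2: pd.Series
    nobs: int
    df_resid: int
    strategy: str = "ols"
    criterion: str = ""

    @property
    def intercept(self) -> float:
        return float(self.params["const"])


@dataclass
class OptimismReport:
    apparent_r2: float
    apparent_adj_r2: float
    optimism_r2: float
    optimism_adj_r2: float
    corrected_r2: float
    corrected_adj_r2: float
    n_boot: int
    seed: int | None
    n_redrawn: int = 0
    support: List[str] = field(default_factory=list)


def _criteria_from_rss(rss: float, n: int, n_coef: int) -> Tuple[float, float, float]:
    """(AIC, AICC, BIC) from a Gaussian log-likelihood.

    ``k`` counts the regression coefficients (intercept included) plus the
    error variance, so an intercept-only model has k=2.  AICC adds the
    small-sample correction 2k(k+1)/(n-k-1).
    """
    rss = max(rss, 1e-300)
    llf = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    k = n_coef + 1
    aic = -2 * llf + 2 * k
    bic = -2 * llf + k * np.log(n)
    aicc = aic + (2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf)
    return aic, aicc, bic


def _check_full_rank(X: pd.DataFrame) -> None:
    Z = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # walk the columns to name the offenders
        bad, cur = [], np.ones((len(X), 1))
        for col in X.columns:
            cand = np.column_stack([cur, X[col].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(col)
            else:
                cur = cand
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {bad}")


def ols_fit(y: pd.Series, X: pd.DataFrame, strategy: str = "ols",
            criterion: str = "") -> FitReport:
    """Ordinary least squares of ``y`` on ``X`` (intercept added).

    Requires n > p + 1 and a full-rank design; rank deficiency is an error
    naming the collinear columns.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    n, p = len(y), X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if p:
        _check_full_rank(X)
    Z = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y.to_numpy(), Z).fit()
    rss = float(res.ssr)
    aic, aicc, bic = _criteria_from_rss(rss, n, p + 1)
    tv = res.tvalues.drop("const")
    pc2 = squared_partial_correlation(tv, int(res.df_resid))
    return FitReport(
        predictors=list(X.columns),
        params=res.params, bse=res.bse, tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared) if p else 0.0,
        adj_r2=float(res.rsquared_adj) if p else 0.0,
        aic=aic, aicc=aicc, bic=bic, pc2=pc2,
        nobs=n, df_resid=int(res.df_resid),
        strategy=strategy, criterion=criterion,
    )


def squared_partial_correlation(tvalues: pd.Series, df_resid: int) -> pd.Series:
    """PC^2_j = t_j^2 / (t_j^2 + df_resid): the squared correlation between
    the response and predictor j after both are residualised on the other
    predictors."""
    if df_resid <= 0:
        raise ValueError("df_resid must be positive")
    t2 = np.asarray(tvalues, dtype=float) ** 2
    return pd.Series(t2 / (t2 + df_resid), index=tvalues.index)


# ---------------------------------------------------------------------------
# fast RSS-per-subset machinery (shared by BSRP and stepwise)
# ---------------------------------------------------------------------------

class _GramRss:
    """RSS of the OLS fit (with intercept) on any predictor subset, from
    precomputed cross-products.

    Predictors are centred and scaled internally -- the subset RSS is
    invariant to both, and the resulting correlation-like Gram matrices stay
    well conditioned whatever the covariate units.  Constant columns are
    flagged; subsets containing one are reported as RSS = inf (rank
    deficient with the intercept).
    """

    def __init__(self, y: pd.Series, X: pd.DataFrame):
        self.columns = list(X.columns)
        yv = np.asarray(y, dtype=float)
        Xv = np.asarray(X, dtype=float).reshape(len(yv), -1)
        self.n = len(yv)
        sd = Xv.std(axis=0)
        self.usable = sd > 0
        Xc = (Xv - Xv.mean(axis=0)) / np.where(self.usable, sd, 1.0)
        yc = yv - yv.mean()
        self.G = Xc.T @ Xc
        self.b = Xc.T @ yc
        self.sst = float(yc @ yc)

    def rss(self, subset: Sequence[int]) -> float:
        """subset: candidate-column indices."""
        idx = list(subset)
        if not idx:
            return self.sst
        if not self.usable[idx].all():
            return np.inf
        Gs = self.G[np.ix_(idx, idx)]
        bs = self.b[idx]
        try:
            coef = np.linalg.solve(Gs, bs)
        except np.linalg.LinAlgError:
            return np.inf
        return max(self.sst - float(bs @ coef), 0.0)


def _batched_rss(gram: _GramRss, subsets: np.ndarray) -> np.ndarray:
    """RSS for many same-size subsets at once (rows of candidate indices)."""
    if subsets.shape[1] == 0:
        return np.full(len(subsets), gram.sst)
    ok = gram.usable[subsets].all(axis=1)
    rss = np.full(len(subsets), np.inf)
    idx = subsets[ok]
    Gs = gram.G[idx[:, :, None], idx[:, None, :]]
    bs = gram.b[idx]
    try:
        coef = np.linalg.solve(Gs, bs[:, :, None])[:, :, 0]
        rss[ok] = gram.sst - np.einsum("ij,ij->i", bs, coef)
    except np.linalg.LinAlgError:
        rss[ok] = [gram.rss(list(s)) for s in idx]
    return np.maximum(rss, 0.0)


def _enumerate_best(gram: _GramRss, criterion: str, max_size: int | None,
                    ) -> List[int]:
    p = len(gram.columns)
    max_size = p if max_size is None else min(max_size, p)
    crit_idx = {"aic": 0, "aicc": 1, "bic": 2}[criterion]
    best: Tuple[float, int, Tuple[str, ...]] | None = None
    best_subset: List[int] = []
    for size in range(0, max_size + 1):
        subsets = (np.empty((1, 0), dtype=int) if size == 0 else
                   np.array(list(itertools.combinations(range(p), size)),
                            dtype=int))
        rss = _batched_rss(gram, subsets)
        # within a size every criterion is monotone in RSS: argmin RSS wins;
        # RSS ties break lexicographically on predictor names
        r_min = float(np.min(rss))
        tied = np.flatnonzero(rss <= r_min + 1e-10 * max(r_min, 1.0))
        names_of = lambda row: tuple(gram.columns[j] for j in row)  # noqa: E731
        j_best = min(tied, key=lambda j: names_of(subsets[j]))
        crit = _criteria_from_rss(float(rss[j_best]), gram.n, size + 1)[crit_idx]
        key = (round(float(crit), 10), size, names_of(subsets[j_best]))
        if best is None or key < best:
            best, best_subset = key, list(subsets[j_best])
    return best_subset


def best_subset(y: pd.Series, X: pd.DataFrame, criterion: str = "aic",
                max_size: int | None = None) -> FitReport:
    """Exhaustive best-subset selection under an information criterion.

    All subsets of the candidates up to ``max_size`` are scored; ties break
    toward fewer predictors, then lexicographically.  An empty candidate set
    yields the intercept-only model.  Enumeration is limited to 20
    candidates (2^20 subsets).
    """
    if criterion not in ("aic", "aicc", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    X = pd.DataFrame(X)
    if X.shape[1] > 20:
        raise ValueError("best_subset enumerates exhaustively; "
                         f"{X.shape[1]} candidates is above the 20-column cap")
    gram = _GramRss(y, X)
    subset = _enumerate_best(gram, criterion, max_size)
    return ols_fit(y, X.iloc[:, subset], strategy="bsrp", criterion=criterion)


# ---------------------------------------------------------------------------
# LARS
# ---------------------------------------------------------------------------

def adjusted_r2(r2: float, n: int, p: int) -> float:
    """adj R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1) for p predictors beside
    the intercept."""
    if n - p - 1 <= 0:
        raise ValueError("need n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def lars_supports(y: pd.Series, X: pd.DataFrame) -> List[List[str]]:
    """Ordered supports along the LARS path (entry order), from empty to
    the full active set."""
    from sklearn.linear_model import lars_path

    X = pd.DataFrame(X).astype(float)
    Xs = (X - X.mean()) / X.std(ddof=0)
    yc = np.asarray(y, dtype=float) - float(np.mean(y))
    _, active, _ = lars_path(Xs.to_numpy(), yc, method="lar")
    return [[X.columns[j] for j in active[:k]] for k in range(len(active) + 1)]


def lars_select(y: pd.Series, X: pd.DataFrame, choose: str = "cp") -> FitReport:
    """Least-angle regression: run the LARS path on standardised predictors
    and return the OLS refit of the path support minimising Mallows' Cp.

    Constant columns cannot be standardised and are excluded with a warning.
    """
    from sklearn.linear_model import lars_path

    X = pd.DataFrame(X).astype(float)
    keep = [c for c in X.columns if X[c].std(ddof=0) > 0]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"constant predictors excluded from LARS: {dropped}")
    X = X[keep]
    n, p = len(y), X.shape[1]
    if n <= 2 or p == 0:
        return ols_fit(y, X.iloc[:, :0], strategy="lars", criterion=choose)

    Xs = (X - X.mean()) / X.std(ddof=0)
    yc = np.asarray(y, dtype=float) - float(np.mean(y))
    _, active, _ = lars_path(Xs.to_numpy(), yc, method="lar")

    gram = _GramRss(y, X)
    sigma2 = (gram.rss(list(range(p))) / (n - p - 1)) if n > p + 1 else None
    supports = [list(active[:k]) for k in range(0, len(active) + 1)]
    best_key, best_support = None, []
    for s in supports:
        rss = gram.rss(s)
        if sigma2:
            crit = rss / sigma2 - n + 2 * (len(s) + 1)      # Mallows' Cp
        else:
            crit = rss
        key = (round(float(crit), 10), len(s))
        if best_key is None or key < best_key:
            best_key, best_support = key, s
    return ols_fit(y, X.iloc[:, best_support], strategy="lars", criterion=choose)


# ---------------------------------------------------------------------------
# stepwise + bootstrapped stepwise (BSM)
# ---------------------------------------------------------------------------

def _stepwise_support(gram: _GramRss, p_enter: float = 0.05,
                      p_remove: float = 0.10, max_iter: int = 100) -> List[int]:
    """Bidirectional p-value stepwise on precomputed cross-products."""
    p = len(gram.columns)
    current: List[int] = []
    rss_cur = gram.rss(current)
    for _ in range(max_iter):
        changed = False
        # forward: most significant addition
        best_p, best_j, best_rss = 1.0, None, None
        df_new = gram.n - len(current) - 2
        if df_new > 0:
            for j in range(p):
                if j in current:
                    continue
                rss_j = gram.rss(current + [j])
                if not np.isfinite(rss_j) or rss_j >= rss_cur:
                    continue
                f = (rss_cur - rss_j) / (rss_j / df_new)
                p_val = float(stats.f.sf(f, 1, df_new))
                if p_val < best_p:
                    best_p, best_j, best_rss = p_val, j, rss_j
        if best_j is not None and best_p < p_enter:
            current.append(best_j)
            rss_cur = best_rss
            changed = True
        # backward: least significant retained term
        if current:
            df_cur = gram.n - len(current) - 1
            worst_p, worst_j, worst_rss = -1.0, None, None
            for j in current:
                rss_wo = gram.rss([k for k in current if k != j])
                f = (rss_wo - rss_cur) / (rss_cur / df_cur)
                p_val = float(stats.f.sf(max(f, 0.0), 1, df_cur))
                if p_val > worst_p:
                    worst_p, worst_j, worst_rss = p_val, j, rss_wo
            if worst_j is not None and worst_p > p_remove:
                current.remove(worst_j)
                rss_cur = worst_rss
                changed = True
        if not changed:
            break
    return sorted(current)


def bootstrap_stepwise(y: pd.Series, X: pd.DataFrame, B: int = 200,
                       inclusion_threshold: float = 0.60,
                       p_enter: float = 0.05, p_remove: float = 0.10,
                       seed: int | None = None) -> FitReport:
    """Bootstrapped stepwise (BSM): bidirectional stepwise on each of B
    bootstrap resamples; predictors selected in >= ``inclusion_threshold``
    of resamples form the final support, refit by OLS on the full data.

    An empty final support yields the intercept-only model (with a warning).
    """
    if B < 50:
        raise ValueError("B must be >= 50 for a stable inclusion frequency")
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X).astype(float)
    rng = np.random.default_rng(seed)
    n, p = len(y), X.shape[1]
    freq = np.zeros(p)
    yv, Xv = y.to_numpy(), X.to_numpy()
    for _ in range(B):
        idx = rng.integers(0, n, n)
        gram = _GramRss(pd.Series(yv[idx]), pd.DataFrame(Xv[idx], columns=X.columns))
        for j in _stepwise_support(gram, p_enter, p_remove):
            freq[j] += 1
    freq /= B
    support = [c for c, f in zip(X.columns, freq) if f >= inclusion_threshold]
    if not support:
        warnings.warn("no predictor reached the inclusion threshold; "
                      "returning the intercept-only model")
    report = ols_fit(y, X[support], strategy="bsm", criterion="")
    report.inclusion_frequency = pd.Series(freq, index=X.columns)  # type: ignore[attr-defined]
    return report


# ---------------------------------------------------------------------------
# Harrell optimism correction
# ---------------------------------------------------------------------------

Selector = Callable[[pd.Series, pd.DataFrame], List[str]]


def make_selector(strategy: str, **kwargs) -> Selector:
    """Package a selection strategy as a deterministic data -> support map
    (the unit Harrell's bootstrap revalidates)."""
    strategy = strategy.lower()
    if strategy == "bsrp":
        crit = kwargs.get("criterion", "aic")
        max_size = kwargs.get("max_size")

        def sel(y, X):
            return best_subset(y, X, criterion=crit, max_size=max_size).predictors
    elif strategy == "lars":
        def sel(y, X):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return lars_select(y, X).predictors
    elif strategy == "bsm":
        B = kwargs.get("B", 100)
        thr = kwargs.get("inclusion_threshold", 0.60)
        inner_seed = kwargs.get("seed", 0)

        def sel(y, X):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return bootstrap_stepwise(y, X, B=B, inclusion_threshold=thr,
                                          seed=inner_seed).predictors
    elif strategy == "none":
        def sel(y, X):
            return list(X.columns)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    sel.__name__ = f"selector_{strategy}"
    return sel


def _r2_pair(y: np.ndarray, Z: np.ndarray, coef: np.ndarray, p: int,
             ) -> Tuple[float, float]:
    resid = y - Z @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    n = len(y)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    return r2, adj


def optimism_correct(selector: Selector, y: pd.Series, X: pd.DataFrame,
                     B: int = 500, seed: int | None = None) -> OptimismReport:
    """Harrell's bootstrap optimism correction of R^2 and adjusted R^2.

    For each resample the *whole* selection procedure is rerun, the selected
    model is fit on the resample, and the optimism contribution is
    metric(model on resample) - metric(same fitted model applied to the
    original data).  Corrected = apparent - mean optimism (a bookkeeping
    identity, held exactly).  Rank-deficient resamples are redrawn and
    counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = pd.Series(y).astype(float).reset_index(drop=True)
    X = pd.DataFrame(X).astype(float).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(y)

    def fit_coef(yv: np.ndarray, Xv: np.ndarray) -> np.ndarray:
        Z = np.column_stack([np.ones(len(yv)), Xv])
        coef, _, rank, _ = np.linalg.lstsq(Z, yv, rcond=None)
        if rank < Z.shape[1]:
            raise np.linalg.LinAlgError("rank deficient")
        return coef

    support = selector(y, X)
    Xv_app = X[support].to_numpy()
    coef_app = fit_coef(y.to_numpy(), Xv_app)
    Z_app = np.column_stack([np.ones(n), Xv_app])
    apparent_r2, apparent_adj = _r2_pair(y.to_numpy(), Z_app, coef_app,
                                         len(support))

    opt_r2, opt_adj = [], []
    n_redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        yb = y.to_numpy()[idx]
        Xb = X.iloc[idx].reset_index(drop=True)
        try:
            sup_b = selector(pd.Series(yb), Xb)
            Xb_s = Xb[sup_b].to_numpy()
            coef_b = fit_coef(yb, Xb_s)
        except (np.linalg.LinAlgError, ValueError):
            n_redrawn += 1
            if n_redrawn > 10 * B:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        p_b = len(sup_b)
        Zb = np.column_stack([np.ones(n), Xb_s])
        r2_boot, adj_boot = _r2_pair(yb, Zb, coef_b, p_b)
        Zo = np.column_stack([np.ones(n), X[sup_b].to_numpy()])
        r2_orig, adj_orig = _r2_pair(y.to_numpy(), Zo, coef_b, p_b)
        opt_r2.append(r2_boot - r2_orig)
        opt_adj.append(adj_boot - adj_orig)
        b += 1

    optimism_r2 = float(np.mean(opt_r2))
    optimism_adj = float(np.mean(opt_adj))
    return OptimismReport(
        apparent_r2=apparent_r2, apparent_adj_r2=apparent_adj,
        optimism_r2=optimism_r2, optimism_adj_r2=optimism_adj,
        corrected_r2=apparent_r2 - optimism_r2,
        corrected_adj_r2=apparent_adj - optimism_adj,
        n_boot=B, seed=seed, n_redrawn=n_redrawn, support=list(support),
    )


# ---------------------------------------------------------------------------
# interactions, model comparison, reporting
# ---------------------------------------------------------------------------

def interaction_scan(y: pd.Series, grs: pd.Series, lifestyle: pd.DataFrame,
                     ) -> pd.DataFrame:
    """Gene-lifestyle interaction scan: for each lifestyle variable L fit
    ``y ~ GRS + L + GRS*L`` and report the product-term coefficient and
    p-value.  Constant variables are skipped (logged in the table)."""
    rows = []
    g = np.asarray(grs, dtype=float)
    yv = np.asarray(y, dtype=float)
    for col in lifestyle.columns:
        x = np.asarray(lifestyle[col], dtype=float)
        if np.ptp(x[~np.isnan(x)]) == 0:
            rows.append({"variable": col, "beta_interaction": np.nan,
                         "p_interaction": np.nan, "skipped": True})
            continue
        ok = ~np.isnan(yv) & ~np.isnan(g) & ~np.isnan(x)
        Z = np.column_stack([np.ones(ok.sum()), g[ok], x[ok], g[ok] * x[ok]])
        res = sm.OLS(yv[ok], Z).fit()
        rows.append({"variable": col, "beta_interaction": float(res.params[3]),
                     "p_interaction": float(res.pvalues[3]), "skipped": False})
    return pd.DataFrame(rows).set_index("variable")


def select_best_model(reports: Mapping[str, Tuple[FitReport, OptimismReport]],
                      ) -> str:
    """Winner among candidate strategies: the largest optimism-corrected
    adjusted R^2, ties toward fewer predictors."""
    if len(reports) < 1:
        raise ValueError("need at least one candidate report")
    def key(label: str):
        fit, opt = reports[label]
        return (-round(opt.corrected_adj_r2, 10), len(fit.predictors), label)
    return min(reports, key=key)


DEFAULT_STRATEGIES: Tuple[Tuple[str, dict], ...] = (
    ("lars", {}),
    ("bsrp_aic", {"criterion": "aic"}),
    ("bsrp_aicc", {"criterion": "aicc"}),
    ("bsrp_bic", {"criterion": "bic"}),
    ("bsm", {}),
)


def compare_strategies(y: pd.Series, X: pd.DataFrame, B: int = 500,
                       seed: int | None = None,
                       strategies: Sequence[Tuple[str, dict]] = DEFAULT_STRATEGIES,
                       bsm_inner_B: int = 100,
                       ) -> Tuple[str, Dict[str, Tuple[FitReport, OptimismReport]]]:
    """Run every strategy with optimism correction and pick the winner."""
    ss = np.random.SeedSequence(seed)
    reports: Dict[str, Tuple[FitReport, OptimismReport]] = {}
    for (label, kw), child in zip(strategies, ss.spawn(len(strategies))):
        name = label.split("_")[0]
        kwargs = dict(kw)
        if name == "bsm":
            kwargs.setdefault("B", bsm_inner_B)
            kwargs.setdefault("seed", int(child.generate_state(1)[0] % 2 ** 31))
        selector = make_selector(name, **kwargs)
        sub_seed = int(child.generate_state(1)[0] % 2 ** 31)
        opt = optimism_correct(selector, y, X, B=B, seed=sub_seed)
        fit = ols_fit(y, pd.DataFrame(X)[opt.support], strategy=name,
                      criterion=kw.get("criterion", ""))
        reports[label] = (fit, opt)
    winner = select_best_model(reports)
    return winner, reports


def build_candidates(cohort: pd.DataFrame, grs: pd.DataFrame, lipid: str,
                     ) -> Tuple[pd.Series, pd.DataFrame]:
    """Assemble the response and candidate design for one lipid model.

    Sex is coded female=0 / male=1; energy enters per 100 kcal; the lipid's
    own GRS is always in the candidate set.  Rows with any missing value
    (including complete-case GRS) are dropped; the fitted n is reported in
    the FitReport.
    """
    df = pd.DataFrame(index=cohort.index)
    for col in CANDIDATE_ORDER:
        if col == "sex":
            if "sex" in cohort.columns:
                df["sex"] = (cohort["sex"] == "M").astype(float)
        elif col == "energy_100kcal":
            if "energy" in cohort.columns:
                df["energy_100kcal"] = cohort["energy"] / 100.0
        elif col in cohort.columns:
            df[col] = cohort[col].astype(float)
    gcol = f"grs_{lipid}"
    if gcol not in grs.columns:
        raise KeyError(f"GRS table lacks {gcol!r}")
    df[gcol] = grs[gcol].astype(float)
    y = cohort[lipid].astype(float)
    ok = df.notna().all(axis=1) & y.notna()
    return y[ok], df[ok]


def format_model_table(results: Mapping[str, Tuple[FitReport, OptimismReport]],
                       winners: Mapping[str, str]) -> str:
    """Markdown summary in the conventional per-lipid layout: beta +/- SE and
    PC^2 per predictor, then fit criteria and optimism-corrected metrics."""
    lipids = list(results)
    rows: Dict[str, Dict[str, str]] = {}
    for lipid in lipids:
        fit, opt = results[lipid]
        for name in fit.predictors:
            cell = (f"{fit.params[name]:.2f} +/- {fit.bse[name]:.2f} "
                    f"(PC2={fit.pc2[name]:.3f})")
            rows.setdefault(name, {})[lipid] = cell
    lines = ["| Predictor | " + " | ".join(l.upper() for l in lipids) + " |",
             "| --- |" + " --- |" * len(lipids)]
    for name, by_lipid in rows.items():
        lines.append("| " + name + " | "
                     + " | ".join(by_lipid.get(l, "") for l in lipids) + " |")
    footer = [
        ("Constant", lambda f, o: f"{f.intercept:.2f}"),
        ("n", lambda f, o: f"{f.nobs}"),
        ("R2", lambda f, o: f"{f.r2:.4f}"),
        ("Adj. R2", lambda f, o: f"{f.adj_r2:.4f}"),
        ("Optimism (R2)", lambda f, o: f"{o.optimism_r2:.4f}"),
        ("Optimism (adj. R2)", lambda f, o: f"{o.optimism_adj_r2:.4f}"),
        ("Corrected R2", lambda f, o: f"{o.corrected_r2:.4f}"),
        ("Corrected adj. R2", lambda f, o: f"{o.corrected_adj_r2:.4f}"),
    ]
    for label, fn in footer:
        cells = [fn(*results[lipid]) for lipid in lipids]
        lines.append(f"| {label} | " + " | ".join(cells) + " |")
    lines.append("| Strategy | " + " | ".join(
        winners.get(l, results[l][0].strategy) for l in lipids) + " |")
    return "\n".join(lines) + "\n"
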