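"""Prognostic risk modelling: Cox screen, survival forest, risk scores,
maximally-selected-rank-statistic stratification and Kaplan-Meier curves.

The full pipeline realised by :class:`PrognosticModel`:

1. univariate Cox proportional-hazards screen per gene (Efron ties), keeping
   genes with p < alpha;
2. a random survival forest on the screened genes, ranked by permutation
   importance, with the out-of-bag error tracked against tree count;
3. a multivariable Cox refit on the top-m forest-ranked genes, yielding the
   printed risk function f(t|x) = f0(t) * exp(sum_i coef_i * gene_i) with a
   Breslow baseline; the reported per-sample risk score is exp(linear
   predictor), the time-free factor;
4. the stratification cutoff maximising the standardised two-group log-rank
   statistic over all admissible score cutpoints (maximally selected rank
   statistic), and Kaplan-Meier curves plus a log-rank test for the resulting
   high/low risk groups.

The log-rank scan, concordance index and score arithmetic are implemented
here; Cox fitting and Kaplan-Meier estimation are delegated to lifelines and
the forest to scikit-survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.inspection import permutation_importance
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .io import ExpressionMatrix, SurvivalTable


# ---------------------------------------------------------------------------
# univariate Cox screen
# ---------------------------------------------------------------------------


def _join(X: ExpressionMatrix, surv: SurvivalTable):
    """Align expression and survival on shared sample ids (order of surv)."""
    common = [s for s in surv.sample_ids if s in set(X.sample_ids)]
    if not common:
        raise ValueError("expression matrix and survival table share no samples")
    return X.subset_samples(common), surv.subset(common)


def cox_screen(
    X: ExpressionMatrix, surv: SurvivalTable, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene univariate Cox proportional-hazards screen.

    Returns one row per gene with the log hazard ratio, HR and its 95% CI,
    the Wald p-value and a significance flag (p < alpha). Constant genes get
    an NA row and are never flagged significant.
    """
    X, surv = _join(X, surv)
    if surv.n_events < 10:
        raise ValueError(f"need >= 10 events for the Cox screen, got {surv.n_events}")
    base = pd.DataFrame({"time": surv.time, "event": surv.event})
    rows = []
    for i, gene in enumerate(X.gene_ids):
        expr = X.values[i]
        if np.ptp(expr) == 0:
            rows.append(
                {"gene": gene, "coef": np.nan, "hr": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "significant": False, "na": True}
            )
            continue
        df = base.copy()
        df["x"] = expr
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            coef = float(cph.params_["x"])
            p = float(cph.summary.loc["x", "p"])
            ci_low = float(cph.summary.loc["x", "coef lower 95%"])
            ci_high = float(cph.summary.loc["x", "coef upper 95%"])
            rows.append(
                {"gene": gene, "coef": coef, "hr": float(np.exp(coef)),
                 "ci_low": float(np.exp(ci_low)), "ci_high": float(np.exp(ci_high)),
                 "p": p, "significant": bool(p < alpha), "na": False}
            )
        except Exception:
            rows.append(
                {"gene": gene, "coef": np.nan, "hr": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "significant": False, "na": True}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random survival forest
# ---------------------------------------------------------------------------


@dataclass
class RSFFit:
    forest: RandomSurvivalForest
    genes: list
    importance: dict                 # gene -> permutation importance
    ranking: list                    # genes by decreasing importance
    oob_trajectory: pd.DataFrame     # n_trees, oob_error
    plateau: bool


def rsf_fit(
    X: ExpressionMatrix,
    surv: SurvivalTable,
    n_trees: int = 1000,
    seed: int = 0,
    oob_step: int = 25,
    plateau_tol: float = 0.02,
    n_permutations: int = 5,
) -> RSFFit:
    """Random survival forest (log-rank splitting) with importance ranking.

    The out-of-bag error (1 - OOB concordance) is recorded at tree counts
    ``{oob_step, 2*oob_step, ..., n_trees}`` by growing the forest
    incrementally; a plateau flag is set when the error range over the last
    quartile of the trajectory falls below ``plateau_tol``.
    """
    if X.n_genes < 2:
        raise ValueError("rsf_fit needs at least 2 genes")
    X, surv = _join(X, surv)
    if surv.n_events == 0:
        raise ValueError("all samples are censored")
    if surv.n_events < 10:
        raise ValueError(f"need >= 10 events, got {surv.n_events}")
    M = X.samples_matrix()
    y = Surv.from_arrays(event=surv.event.astype(bool), time=surv.time)

    forest = RandomSurvivalForest(
        n_estimators=oob_step, oob_score=True, warm_start=True,
        random_state=seed, n_jobs=1,
    )
    grid = list(range(oob_step, n_trees + 1, oob_step))
    if grid[-1] != n_trees:
        grid.append(n_trees)
    traj = []
    for m in grid:
        forest.set_params(n_estimators=m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(M, y)
        traj.append({"n_trees": m, "oob_error": 1.0 - float(forest.oob_score_)})
    traj = pd.DataFrame(traj)
    last_q = traj["oob_error"].iloc[-max(1, len(traj) // 4):]
    plateau = bool(last_q.max() - last_q.min() < plateau_tol)

    imp = permutation_importance(
        forest, M, y, n_repeats=n_permutations, random_state=seed, n_jobs=1
    )
    importance = {g: float(v) for g, v in zip(X.gene_ids, imp.importances_mean)}
    order = np.argsort(-imp.importances_mean, kind="stable")
    ranking = [X.gene_ids[i] for i in order]
    return RSFFit(
        forest=forest, genes=list(X.gene_ids), importance=importance,
        ranking=ranking, oob_trajectory=traj, plateau=plateau,
    )


# ---------------------------------------------------------------------------
# risk model + scores
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """The printed risk function: genes, per-gene Cox coefficients, a Breslow
    baseline cumulative hazard and the stratification cutoff."""

    genes: list
    coefs: np.ndarray
    baseline_times: np.ndarray        # step-function support
    baseline_cumhaz: np.ndarray       # H0 at those times
    cutoff: float = np.nan
    importance: dict = field(default_factory=dict)

    def linear_predictor(self, X: ExpressionMatrix) -> np.ndarray:
        sub = X.subset_genes(self.genes)  # raises naming missing genes
        return self.coefs @ sub.values

    def baseline_cumulative_hazard(self, t) -> np.ndarray:
        """H0(t) of the Breslow estimator, right-continuous step function."""
        idx = np.searchsorted(self.baseline_times, np.atleast_1d(t), side="right") - 1
        H = np.concatenate([[0.0], self.baseline_cumhaz])
        return H[idx + 1]

    def cumulative_hazard(self, t, X: ExpressionMatrix) -> np.ndarray:
        """H(t|x) = H0(t) * exp(lp): the integrated risk function per sample."""
        return np.outer(self.baseline_cumulative_hazard(t), np.exp(self.linear_predictor(X)))

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "coefs": self.coefs.tolist(),
            "baseline_times": self.baseline_times.tolist(),
            "baseline_cumhaz": self.baseline_cumhaz.tolist(),
            "cutoff": None if np.isnan(self.cutoff) else float(self.cutoff),
            "importance": self.importance,
        }

    @staticmethod
    def from_dict(d: dict) -> "RiskModel":
        return RiskModel(
            genes=list(d["genes"]),
            coefs=np.asarray(d["coefs"], float),
            baseline_times=np.asarray(d["baseline_times"], float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], float),
            cutoff=float(d["cutoff"]) if d.get("cutoff") is not None else np.nan,
            importance=dict(d.get("importance", {})),
        )


def risk_score(model: RiskModel, X: ExpressionMatrix) -> np.ndarray:
    """Per-sample risk score exp(sum_i coef_i * gene_i) — the time-free factor
    of the risk function. Missing model genes are an error, never imputed."""
    return np.exp(model.linear_predictor(X))


# ---------------------------------------------------------------------------
# log-rank machinery (authored; oracle-checked against lifelines in tests)
# ---------------------------------------------------------------------------


def logrank_statistic(time, event, group) -> float:
    """Standardised two-group log-rank statistic (O - E) / sqrt(V) for group 1.

    Hypergeometric variance at each distinct event time; censoring handled by
    the risk-set construction.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    event_times = np.unique(time[event == 1])
    O = E = V = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & (group == 1)).sum())
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V <= 0:
        return 0.0
    return (O - E) / np.sqrt(V)


@dataclass
class MaxstatResult:
    cutoff: float
    statistic: float           # |standardised log-rank| at the cutoff
    candidates: pd.DataFrame   # cutoff, statistic for every admissible cutpoint


def maxstat_cutoff(scores, surv: SurvivalTable, min_prop: float = 0.1) -> MaxstatResult:
    """Maximally selected rank statistic over candidate score cutpoints.

    Candidates are midpoints between consecutive sorted unique scores whose
    induced split keeps both groups at least ``min_prop`` of the cohort. The
    returned cutoff maximises the absolute standardised log-rank statistic
    (ties: the smallest such cutoff). The selection is exploratory: no
    multiplicity correction is applied here.
    """
    scores = np.asarray(scores, float)
    if np.ptp(scores) == 0:
        raise ValueError("scores are constant; no cutoff exists")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n = scores.size
    lo = max(1, int(np.ceil(min_prop * n)))
    records = []
    for c in mids:
        n_high = int((scores > c).sum())
        if n_high < lo or (n - n_high) < lo:
            continue
        stat = abs(logrank_statistic(surv.time, surv.event, (scores > c).astype(int)))
        records.append({"cutoff": float(c), "statistic": float(stat)})
    if not records:
        raise ValueError("no admissible cutoff candidate under min_prop")
    df = pd.DataFrame(records)
    best = int(df["statistic"].idxmax())
    return MaxstatResult(
        cutoff=float(df.loc[best, "cutoff"]),
        statistic=float(df.loc[best, "statistic"]),
        candidates=df,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier stratification
# ---------------------------------------------------------------------------


@dataclass
class RiskStratification:
    scores: np.ndarray
    group: np.ndarray          # "high"/"low" per sample
    cutoff: float
    logrank_p: float           # post-selection when the cutoff was maximised
    km_curves: dict            # group -> DataFrame(time, survival)

    def to_frame(self, sample_ids) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(sample_ids), "score": self.scores, "group": self.group}
        )


def km_stratify(scores, cutoff: float, surv: SurvivalTable) -> RiskStratification:
    """Product-limit curves and a two-group log-rank test at a given cutoff.

    ``group == "high"`` iff score > cutoff. When the cutoff came from
    :func:`maxstat_cutoff`, the p-value is post-selection and should be read
    as descriptive.
    """
    scores = np.asarray(scores, float)
    high = scores > cutoff
    if high.all() or not high.any():
        raise ValueError("cutoff leaves one risk group empty")
    curves = {}
    for name, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(surv.time[mask], surv.event[mask])
        sf = km.survival_function_
        curves[name] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )
    lr = logrank_test(
        surv.time[high], surv.time[~high], surv.event[high], surv.event[~high]
    )
    return RiskStratification(
        scores=scores,
        group=np.where(high, "high", "low"),
        cutoff=float(cutoff),
        logrank_p=float(lr.p_value),
        km_curves=curves,
    )


def km_curve(surv: SurvivalTable) -> pd.DataFrame:
    """Single-group product-limit estimate as a (time, survival) table."""
    km = KaplanMeierFitter()
    km.fit(surv.time, surv.event)
    sf = km.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def cindex(scores, surv: SurvivalTable, horizon: Optional[float] = None) -> float:
    """Censoring-aware concordance index of a risk score.

    A pair is usable iff the smaller observed time is an event (and, when a
    ``horizon`` is given, that event occurs at or before the horizon);
    concordance means the earlier-event sample has the higher score; score
    ties count 0.5. Higher score = higher risk.
    """
    scores = np.asarray(scores, float)
    time = surv.time
    event = surv.event.astype(bool)
    if horizon is not None:
        event = event & (time <= horizon)
    # usable pairs: t_i < t_j with event_i, plus t_i == t_j with event_i != event_j
    ti = time[:, None]
    tj = time[None, :]
    ei = event[:, None]
    usable = (ti < tj) & ei
    usable |= (ti == tj) & ei & ~event[None, :]
    si = scores[:, None]
    sj = scores[None, :]
    concordant = usable & (si > sj)
    tied = usable & (si == sj)
    n_usable = usable.sum()
    if n_usable == 0:
        raise ValueError("no comparable pairs for the concordance index")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_usable)


def cindex_over_time(scores, surv: SurvivalTable, horizons: Sequence[float]) -> pd.DataFrame:
    """C-index truncated at a grid of horizons (pairs comparable by then)."""
    rows = []
    for h in horizons:
        try:
            c = cindex(scores, surv, horizon=h)
        except ValueError:
            c = np.nan
        rows.append({"horizon": float(h), "cindex": c})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class PrognosticModel:
    """End-to-end prognostic model: Cox screen -> survival forest ranking ->
    multivariable Cox risk function -> maxstat stratification.

    Parameters
    ----------
    X : ExpressionMatrix
    surv : SurvivalTable
    alpha : float
        Univariate screen significance level (default 0.05).
    top_m : int
        Number of forest-ranked genes entering the multivariable Cox refit
        (default 9).
    n_trees : int
        Survival forest size (default 1000).
    """

    def __init__(
        self,
        X: ExpressionMatrix,
        surv: SurvivalTable,
        alpha: float = 0.05,
        top_m: int = 9,
        n_trees: int = 1000,
        min_prop: float = 0.1,
        seed: int = 0,
    ):
        self.X, self.surv = _join(X, surv)
        self.alpha = alpha
        self.top_m = top_m
        self.n_trees = n_trees
        self.min_prop = min_prop
        self.seed = seed

    def fit(self) -> "PrognosisResults":
        screen = cox_screen(self.X, self.surv, alpha=self.alpha)
        sig_genes = screen.loc[screen["significant"], "gene"].tolist()
        if len(sig_genes) < 2:
            raise ValueError(
                f"only {len(sig_genes)} gene(s) pass the univariate screen; "
                "cannot build a forest"
            )
        X_sig = self.X.subset_genes(sig_genes)
        forest = rsf_fit(X_sig, self.surv, n_trees=self.n_trees, seed=self.seed)
        top = forest.ranking[: min(self.top_m, len(forest.ranking))]

        # multivariable Cox on the forest-ranked genes gives the printed
        # coefficients; Breslow baseline cumulative hazard from the same fit
        df = pd.DataFrame(self.X.subset_genes(top).values.T, columns=top)
        df["time"] = self.surv.time
        df["event"] = self.surv.event
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        coefs = cph.params_[top].to_numpy(float)
        bh = cph.baseline_cumulative_hazard_
        # lifelines anchors the baseline at the covariate means; re-anchor at
        # covariate zero so H(t|x) = H0(t) * exp(coef . x) composes directly
        rescale = float(np.exp(-coefs @ df[top].mean().to_numpy(float)))
        model = RiskModel(
            genes=top,
            coefs=coefs,
            baseline_times=bh.index.to_numpy(float),
            baseline_cumhaz=bh.iloc[:, 0].to_numpy(float) * rescale,
            importance={g: forest.importance[g] for g in top},
        )
        scores = risk_score(model, self.X)
        ms = maxstat_cutoff(scores, self.surv, min_prop=self.min_prop)
        model.cutoff = ms.cutoff
        strat = km_stratify(scores, ms.cutoff, self.surv)
        horizons = np.quantile(self.surv.time[self.surv.event == 1], [0.25, 0.5, 0.75, 1.0])
        return PrognosisResults(
            model=self,
            screen=screen,
            forest=forest,
            risk_model=model,
            scores=scores,
            maxstat=ms,
            stratification=strat,
            cindex=cindex(scores, self.surv),
            cindex_time=cindex_over_time(scores, self.surv, horizons),
            cox_summary=cph.summary.loc[top, ["coef", "exp(coef)", "p"]].copy(),
        )


@dataclass
class PrognosisResults:
    model: PrognosticModel
    screen: pd.DataFrame
    forest: RSFFit
    risk_model: RiskModel
    scores: np.ndarray
    maxstat: MaxstatResult
    stratification: RiskStratification
    cindex: float
    cindex_time: pd.DataFrame
    cox_summary: pd.DataFrame

    def summary(self) -> str:
        n_sig = int(self.screen["significant"].sum())
        rm = self.risk_model
        lines = [
            "Prognostic risk model (Cox screen -> survival forest -> Cox refit)",
            f"  samples: {self.model.surv.n}    events: {self.model.surv.n_events}",
            f"  genes passing univariate screen (p < {self.model.alpha}): {n_sig}",
            f"  survival forest: {self.model.n_trees} trees, OOB error "
            f"{self.forest.oob_trajectory['oob_error'].iloc[-1]:.3f}"
            f" (plateau: {self.forest.plateau})",
            f"  risk function genes ({len(rm.genes)}): " + ", ".join(rm.genes),
            "  coefficients: "
            + ", ".join(f"{g}={c:+.3f}" for g, c in zip(rm.genes, rm.coefs)),
            f"  concordance index: {self.cindex:.3f}",
            f"  maxstat cutoff: {rm.cutoff:.4g} "
            f"(|standardised log-rank| = {self.maxstat.statistic:.2f})",
            f"  high/low split: {int((self.stratification.group == 'high').sum())}"
            f"/{int((self.stratification.group == 'low').sum())}, "
            f"log-rank p = {self.stratification.logrank_p:.3g} (post-selection)",
        ]
        return "\n".join(lines)
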