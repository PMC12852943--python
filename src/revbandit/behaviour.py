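"""Behavioural statistics: consecutive-error switch rates, per-session
logistic switch regressions, two-stage group inference, and the session-type
by error-number ANOVA.

Group inference is two-stage: the switch/stay regression is fitted per session
by maximum likelihood and group-level hypotheses are tested on the per-session
coefficients (one-sample tests against zero within condition, two-sample tests
between conditions). The long-format coefficient table is exposed so full
hierarchical mixed models can be refitted in external software if desired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .observer import ObserverTrace
from .schedules import LEFT
from .session import Session

LMEM1 = "lmem1"
LMEM2 = "lmem2"

#: Regressor columns per design variant (besides the intercept).
VARIANT_COLUMNS = {
    LMEM1: ["dprob", "dunc", "rev"],
    LMEM2: ["chosen_prob", "unchosen_prob", "chosen_unc", "unchosen_unc", "rev"],
}

MIN_USABLE_TRIALS = 10
#: Coefficient-norm threshold flagging (near-)perfect separation.
SEPARATION_NORM = 25.0


# ---------------------------------------------------------------------------
# consecutive-error switch rates
# ---------------------------------------------------------------------------

def consecutive_error_switch(session: Session, max_run: int = 3) -> pd.DataFrame:
    """Switch rates after runs of exactly 1..max_run consecutive non-rewards.

    An event of run length r is a trial t whose trailing r outcomes, for the
    same repeatedly chosen option, were all non-rewards (a reward or a switch
    resets the run); the response is whether the animal switches on trial t+1.
    A run that reaches length 3 contributed one event at each length along the
    way, so the event sets are the nested "after 1/2/3 errors" counts.
    Rates are NaN where no events occurred.
    """
    ch, out = session.choices, session.outcomes
    n = session.n_trials
    counts = {r: [0, 0] for r in range(1, max_run + 1)}  # r -> [switches, events]
    run = 0
    for t in range(n - 1):
        if out[t] == 0:
            same = t > 0 and ch[t] == ch[t - 1]
            run = run + 1 if (same and run > 0) else 1
        else:
            run = 0
        if 1 <= run <= max_run:
            counts[run][1] += 1
            counts[run][0] += int(ch[t + 1] != ch[t])
    rows = [
        {
            "run_length": r,
            "n_events": counts[r][1],
            "n_switches": counts[r][0],
            "switch_rate": (counts[r][0] / counts[r][1]) if counts[r][1] else np.nan,
        }
        for r in range(1, max_run + 1)
    ]
    return pd.DataFrame(rows)


def overall_switch_rate(session: Session) -> float:
    return float(session.switches().mean())


# ---------------------------------------------------------------------------
# switch regression designs
# ---------------------------------------------------------------------------

@dataclass
class SwitchDesign:
    """Design matrix for one session's switch/stay logistic regression.

    ``x`` includes the intercept as its first column; ``scales``/``centers``
    record the per-session standardisation so raw-scale coefficients can be
    recovered.
    """

    session_id: str
    variant: str
    response: np.ndarray
    x: np.ndarray
    columns: list[str]
    centers: np.ndarray
    scales: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        if self.x.shape[0] != self.response.size:
            raise ValueError("response and design must have equal length")
        if self.x.shape[1] != len(self.columns):
            raise ValueError("column names must match the design")


def build_design(
    trace: ObserverTrace,
    session: Session,
    variant: str = LMEM1,
    reversal_trace: ObserverTrace | None = None,
    standardize: bool = True,
) -> SwitchDesign:
    """Build the switch/stay regression design for one session.

    Regressors are the decision-time estimates referenced to the previous
    trial's choice (the option the animal would repeat by staying); the
    response is whether the current trial's choice differs from it. The first
    trial is dropped. The reversal estimate comes from ``reversal_trace``
    (normally a Model 2 trace) when given, so value/uncertainty regressors may
    be taken from Model 1 while the reversal regressor comes from Model 2, as
    in the behavioural analyses; otherwise it is taken from ``trace`` and a
    Model 1 ``trace`` yields a design without a reversal column.
    """
    if variant not in VARIANT_COLUMNS:
        raise ValueError(f"unknown variant: {variant!r}")
    if len(trace) != session.n_trials:
        raise ValueError("trace is not aligned to the session")
    rev_trace = reversal_trace if reversal_trace is not None else trace
    if reversal_trace is not None and len(reversal_trace) != session.n_trials:
        raise ValueError("reversal_trace is not aligned to the session")

    y = session.switches().astype(float)
    if y.size < MIN_USABLE_TRIALS:
        raise ValueError(
            f"need >= {MIN_USABLE_TRIALS} usable trials, got {y.size}")

    prev_is_left = session.choices[:-1] == LEFT

    def ref_alt(frame: pd.DataFrame, kind: str) -> tuple[np.ndarray, np.ndarray]:
        left = frame[f"left_{kind}"].to_numpy()[1:]
        right = frame[f"right_{kind}"].to_numpy()[1:]
        ref = np.where(prev_is_left, left, right)
        alt = np.where(prev_is_left, right, left)
        return ref, alt

    f = trace.frame
    cp, up = ref_alt(f, "prob")
    cu, uu = ref_alt(f, "unc")
    rev, _ = ref_alt(rev_trace.frame, "rev")
    have_rev = not np.all(np.isnan(rev))

    values = {
        "dprob": cp - up, "dunc": cu - uu,
        "chosen_prob": cp, "unchosen_prob": up,
        "chosen_unc": cu, "unchosen_unc": uu,
        "rev": rev,
    }
    names = [c for c in VARIANT_COLUMNS[variant] if c != "rev" or have_rev]
    cols = []
    centers, scales = [0.0], [1.0]  # intercept
    for name in names:
        col = values[name].astype(float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"regressor {name} contains non-finite values")
        sd = col.std()
        if sd == 0:
            raise ValueError(f"regressor {name} is constant in this session")
        if standardize:
            centers.append(col.mean())
            scales.append(sd)
            col = (col - col.mean()) / sd
        else:
            centers.append(0.0)
            scales.append(1.0)
        cols.append(col)
    x = np.column_stack([np.ones_like(y)] + cols)
    return SwitchDesign(
        session_id=session.session_id, variant=variant, response=y, x=x,
        columns=["intercept"] + names, centers=np.array(centers),
        scales=np.array(scales),
        group=session.tus if session.tus != "none" else session.condition,
    )


# ---------------------------------------------------------------------------
# per-session logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """Per-session logistic regression coefficients and their uncertainty."""

    session_id: str
    columns: list[str]
    coef: np.ndarray
    bse: np.ndarray
    zvalues: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    separation_flag: bool
    group: str = ""

    def to_series(self) -> pd.Series:
        return pd.Series(self.coef, index=self.columns, name=self.session_id)

    def summary(self) -> str:
        lines = [f"Logistic switch regression, session {self.session_id} "
                 f"(group {self.group or '-'})",
                 f"  loglik = {self.loglik:.4f}  iterations = {self.n_iter}"
                 f"  converged = {self.converged}"
                 + ("  [separation flagged]" if self.separation_flag else "")]
        for c, b, se, z in zip(self.columns, self.coef, self.bse, self.zvalues):
            lines.append(f"  {c:>14s}  {b: .4f}  (se {se:.4f}, z {z: .3f})")
        return "\n".join(lines)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def logistic_irls(design: SwitchDesign, tol: float = 1e-8,
                  max_iter: int = 100) -> RegressionFit:
    """Maximum-likelihood logistic regression by iteratively reweighted least
    squares.

    Standard errors come from the inverse observed information at the optimum.
    Diverging coefficient norms (near-perfect separation) flag the fit instead
    of raising.
    """
    x, y = design.x, design.response
    beta = np.zeros(x.shape[1])
    ll_old = _bernoulli_loglik(y, x @ beta)
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-10)
        z = eta + (y - mu) / w
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            separation = True
            break
        ll_new = _bernoulli_loglik(y, x @ beta_new)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.linalg.norm(beta) > SEPARATION_NORM:
            separation = True
            break
        if abs(ll_new - ll_old) < tol and step < np.sqrt(tol):
            ll_old = ll_new
            converged = True
            break
        ll_old = ll_new
    mu = expit(x @ beta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    info = x.T @ (x * w[:, None])
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        bse = np.full(beta.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = beta / bse
    return RegressionFit(
        session_id=design.session_id, columns=list(design.columns),
        coef=beta, bse=bse, zvalues=zvals, loglik=_bernoulli_loglik(y, x @ beta),
        n_iter=it, converged=converged and not separation,
        separation_flag=separation, group=design.group,
    )


def fits_to_frame(fits: list[RegressionFit]) -> pd.DataFrame:
    """Long-format per-session coefficient table (for plotting or refitting
    hierarchical models externally)."""
    rows = []
    for f in fits:
        for c, b, se in zip(f.columns, f.coef, f.bse):
            rows.append({"session_id": f.session_id, "group": f.group,
                         "term": c, "coef": b, "se": se,
                         "converged": f.converged,
                         "separation_flag": f.separation_flag})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# two-stage group inference
# ---------------------------------------------------------------------------

@dataclass
class GroupResult:
    """Group-level summary of per-session regression coefficients."""

    per_group: pd.DataFrame     # term x group: mean, t/p, wilcoxon p
    contrasts: pd.DataFrame     # term x (group pair): t/p, mann-whitney p
    n_per_group: dict[str, int] = field(default_factory=dict)

    def report(self) -> str:
        lines = ["Two-stage group inference on per-session switch regressions",
                 "", "Within-group tests against zero:"]
        lines.append(self.per_group.to_string(float_format=lambda v: f"{v: .4f}"))
        lines.append("")
        lines.append("Between-group contrasts:")
        lines.append(self.contrasts.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def group_contrast(fits: list[RegressionFit], labels: list[str] | None = None,
                   reference: str | None = None) -> GroupResult:
    """Group tests on per-session coefficients.

    ``labels`` assigns each fit to a group (defaults to each fit's ``group``
    attribute). Within each group, every coefficient is tested against zero
    (one-sample t and Wilcoxon signed-rank); between the reference group
    (default: first label encountered) and every other group, coefficients are
    compared by Welch t and Mann-Whitney tests. Requires >= 3 sessions per
    group.
    """
    if labels is None:
        labels = [f.group for f in fits]
    if len(labels) != len(fits):
        raise ValueError("labels must match fits")
    frame = pd.DataFrame([f.to_series() for f in fits])
    frame["__group"] = labels
    groups = list(dict.fromkeys(labels))
    counts = {g: int((frame["__group"] == g).sum()) for g in groups}
    small = [g for g, n in counts.items() if n < 3]
    if small:
        raise ValueError(f"groups too small (<3 sessions): {small}")
    if reference is None:
        reference = groups[0]
    terms = [c for c in frame.columns if c != "__group"]

    per_rows = []
    for g in groups:
        sub = frame.loc[frame["__group"] == g, terms]
        for term in terms:
            v = sub[term].to_numpy()
            t, p_t = stats.ttest_1samp(v, 0.0)
            if np.allclose(v, 0.0):
                p_w = 1.0
            else:
                p_w = stats.wilcoxon(v, zero_method="wilcox").pvalue
            per_rows.append({"group": g, "term": term, "n": v.size,
                             "mean": v.mean(), "t": t, "p_t": p_t,
                             "p_wilcoxon": p_w})
    per_group = pd.DataFrame(per_rows).set_index(["group", "term"])

    con_rows = []
    ref_vals = frame.loc[frame["__group"] == reference, terms]
    for g in groups:
        if g == reference:
            continue
        other = frame.loc[frame["__group"] == g, terms]
        for term in terms:
            a = ref_vals[term].to_numpy()
            b = other[term].to_numpy()
            t, p_t = stats.ttest_ind(a, b, equal_var=False)
            if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(
                    np.concatenate([a, b])) == 0:
                u, p_u = 0.0, 1.0
            else:
                u, p_u = stats.mannwhitneyu(a, b, alternative="two-sided")
            con_rows.append({"contrast": f"{reference} vs {g}", "term": term,
                             "mean_diff": a.mean() - b.mean(), "t": t,
                             "p_t": p_t, "p_mannwhitney": p_u})
    contrasts = pd.DataFrame(con_rows).set_index(["contrast", "term"])
    return GroupResult(per_group=per_group, contrasts=contrasts,
                       n_per_group=counts)


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (optional; raw p-values are the default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    adj = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# session-type x error-number ANOVA
# ---------------------------------------------------------------------------

def switch_rate_table(sessions: list[Session],
                      conditions: list[str] | None = None,
                      max_run: int = 3) -> pd.DataFrame:
    """Per-session consecutive-error switch rates in long format."""
    rows = []
    for i, s in enumerate(sessions):
        cond = conditions[i] if conditions is not None else s.condition
        tab = consecutive_error_switch(s, max_run=max_run)
        for _, r in tab.iterrows():
            rows.append({"session_id": s.session_id, "condition": cond,
                         "run_length": int(r["run_length"]),
                         "switch_rate": r["switch_rate"],
                         "n_events": int(r["n_events"])})
    return pd.DataFrame(rows)


def anova_session_by_errors(table: pd.DataFrame) -> dict:
    """Two-way ANOVA of switch rate on session type x consecutive-error count.

    ``table`` is the long format of :func:`switch_rate_table` (columns
    ``condition``, ``run_length``, ``switch_rate``; one row per session and
    run length). Returns the interaction F statistic, its degrees of freedom
    and p-value, along with the full ANOVA table.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table.dropna(subset=["switch_rate"]).copy()
    cells = data.groupby(["condition", "run_length"]).size()
    n_cond = data["condition"].nunique()
    n_run = data["run_length"].nunique()
    if len(cells) < n_cond * n_run:
        raise ValueError("empty cells in the condition x run-length layout")
    model = smf.ols("switch_rate ~ C(condition) * C(run_length)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    inter = "C(condition):C(run_length)"
    return {
        "F": float(anova.loc[inter, "F"]),
        "p": float(anova.loc[inter, "PR(>F)"]),
        "df": (int(anova.loc[inter, "df"]), int(anova.loc["Residual", "df"])),
        "table": anova,
    }
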