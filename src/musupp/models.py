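"""Mixed-effects models coupling suppression indices to accuracy.

Two model families, both with crossed random intercepts for participant
and video (every participant sees every video):

* video level - a linear mixed model predicting empathic accuracy from
  the four per-trial mean suppression indices plus viewing condition;
* epoch level - a binomial (logit) generalized linear mixed model
  predicting per-epoch change-detection success from the epoch-wise
  suppression indices plus condition.

Model contribution is assessed with a four-step hierarchical ladder
(null -> +suppression -> +condition -> +interaction) compared by
maximum-likelihood likelihood-ratio tests, and condition effects are
probed with Bonferroni-corrected pairwise contrasts (m=3).

The linear model is fit by profiled ML/REML: with
``V = sigma^2 (I + g_p Zp Zp' + g_v Zv Zv')`` both beta and sigma^2
have closed forms given the two variance ratios, leaving a 2-parameter
outer optimization.  The binomial model uses the Laplace approximation:
an inner Newton solve for the joint mode of (beta, u) and an outer
2-parameter search over the random-intercept variances.  Problem sizes
here are small (hundreds to a few thousand rows, tens of random
levels), so everything is dense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import expit

from .types import CONDITIONS

CHANNELS = ("C3", "C4", "O1", "O2")
SUPPRESSION_COLS = tuple(f"S_{c}" for c in CHANNELS)
LOGISTIC_RESIDUAL_VAR = np.pi ** 2 / 3.0


class SeparationError(ValueError):
    """Raised when a binomial outcome admits no information (one class)."""


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted mixed model: coefficients, variance components, fit stats."""

    params: pd.DataFrame            # index: term; beta, se, ci_low, ci_high, stat, p
    family: str                     # gaussian | binomial
    method: str                     # REML | ML | Laplace-ML
    sigma2: float                   # residual variance (pi^2/3 for binomial)
    tau_participant: float
    tau_video: float
    loglik: float
    aic: float
    n_obs: int
    n_participants: int
    n_videos: int
    converged: bool
    singular: bool
    icc: float
    r2_marginal: float
    r2_conditional: float
    vcov: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    design_info: dict = field(default_factory=dict, repr=False)
    metadata: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        """Human-readable report mirroring a mixed-model summary table."""
        lines = [f"{self.family} mixed model ({self.method})",
                 "", self.params.to_string(float_format=lambda v: f"{v: .4f}"), "",
                 "Random effects",
                 f"  sigma^2        {self.sigma2:.4f}",
                 f"  tau00 participant {self.tau_participant:.4f}",
                 f"  tau00 video       {self.tau_video:.4f}",
                 f"  ICC            {self.icc:.4f}",
                 f"N  {self.n_participants} participants, {self.n_videos} videos",
                 f"Observations   {self.n_obs}",
                 f"Marginal R2 / conditional R2  {self.r2_marginal:.4f} / "
                 f"{self.r2_conditional:.4f}",
                 f"AIC            {self.aic:.2f}",
                 f"Log-likelihood {self.loglik:.2f}"]
        if self.singular:
            lines.append("note: singular fit (a variance component is ~0)")
        if not self.converged:
            lines.append("WARNING: optimizer did not converge")
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """A nested ladder of fits with one test per added block."""

    steps: pd.DataFrame   # step, added, df, stat, p, loglik
    fits: List[ModelFit]
    level: str
    method: str           # "LRT (ML)"
    metadata: dict = field(default_factory=dict)


@dataclass
class ContrastResult:
    """Pairwise condition contrasts with Bonferroni-adjusted p (m=3)."""

    table: pd.DataFrame   # contrast, estimate, se, stat, p_raw, p_adj
    m: int = 3


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _condition_dummies(cond: pd.Series) -> Tuple[np.ndarray, List[str]]:
    unknown = set(cond.unique()) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition level(s): {sorted(unknown)}")
    cols, names = [], []
    for level in CONDITIONS[1:]:  # Audio-Video is the reference
        cols.append((cond == level).to_numpy(float))
        names.append(f"condition[{level}]")
    return np.column_stack(cols), names


def build_design(
    table: pd.DataFrame,
    outcome: str,
    suppression: bool = True,
    condition: bool = True,
    interaction: str = "none",
    center: bool = False,
) -> Tuple[np.ndarray, np.ndarray, List[str], pd.DataFrame, dict]:
    """Assemble y, X and metadata for one rung of the model ladder.

    ``interaction`` is ``"none"``, ``"all"`` (every channel x condition)
    or ``"C4_only"``.  Predictors are entered raw unless ``center``.
    Rows with any missing value among the used columns are dropped
    listwise.  Returns (y, X, column names, used rows, info dict).
    """
    if interaction not in ("none", "all", "C4_only"):
        raise ValueError(f"unknown interaction mode {interaction!r}")
    if interaction != "none" and not (suppression and condition):
        raise ValueError("interaction requires suppression and condition terms")

    used_cols = [outcome, "participant", "video"]
    if suppression:
        used_cols += list(SUPPRESSION_COLS)
    if condition:
        used_cols += ["condition"]
    missing = [c for c in used_cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns: {missing}")
    df = table.dropna(subset=used_cols).reset_index(drop=True)

    y = df[outcome].to_numpy(float)
    parts: List[np.ndarray] = [np.ones((len(df), 1))]
    names: List[str] = ["(Intercept)"]
    supp_means: Dict[str, float] = {}
    if suppression:
        S = df[list(SUPPRESSION_COLS)].to_numpy(float)
        supp_means = {c: float(m) for c, m in zip(SUPPRESSION_COLS, S.mean(axis=0))}
        if center:
            S = S - S.mean(axis=0)
        parts.append(S)
        names += list(SUPPRESSION_COLS)
    if condition:
        dummies, dnames = _condition_dummies(df["condition"])
        parts.append(dummies)
        names += dnames
    if interaction != "none":
        chans = list(SUPPRESSION_COLS) if interaction == "all" else ["S_C4"]
        Sx = df[chans].to_numpy(float)
        if center:
            Sx = Sx - Sx.mean(axis=0)
        for j, ch in enumerate(chans):
            for k, level in enumerate(CONDITIONS[1:]):
                parts.append((Sx[:, j] * dummies[:, k])[:, None])
                names.append(f"{ch}:condition[{level}]")
    X = np.hstack(parts)
    info = {"n_dropped": len(table) - len(df), "suppression_means": supp_means,
            "centered": center, "interaction": interaction,
            "has_condition": condition, "has_suppression": suppression}
    return y, X, names, df, info


def _group_codes(df: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, int, int]:
    p_codes, p_levels = pd.factorize(df["participant"], sort=True)
    v_codes, v_levels = pd.factorize(df["video"], sort=True)
    return p_codes, v_codes, len(p_levels), len(v_levels)


# ---------------------------------------------------------------------------
# Linear mixed model (profiled ML / REML)
# ---------------------------------------------------------------------------

def _lmm_precompute(X, y, participant, video):
    """Cross-products reused by every objective evaluation.

    With U = [Z_participant, Z_video] (n x q indicators), the Woodbury
    identity reduces every W^-1 product and log-determinant to q x q
    work: W^-1 = I - U B (I + B U'U B)^-1 B U', B = diag(sqrt gamma).
    """
    n = y.size
    n_p = participant.max() + 1
    n_v = video.max() + 1
    q = n_p + n_v
    U = np.zeros((n, q))
    U[np.arange(n), participant] = 1.0
    U[np.arange(n), n_p + video] = 1.0
    return {"XtX": X.T @ X, "Xty": X.T @ y, "yty": float(y @ y),
            "UtU": U.T @ U, "UtX": U.T @ X, "Uty": U.T @ y,
            "n_p": n_p, "n_v": n_v, "q": q}


def _lmm_profile(theta, pre, n, p, reml):
    """Negative profiled log-likelihood at variance ratios exp(theta)."""
    g1, g2 = np.exp(np.clip(theta, -30.0, 10.0))
    b = np.sqrt(np.concatenate([np.full(pre["n_p"], g1),
                                np.full(pre["n_v"], g2)]))
    K = np.eye(pre["q"]) + (b[:, None] * pre["UtU"]) * b[None, :]
    try:
        c, low = linalg.cho_factor(K, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return np.inf, None
    logdet_w = 2.0 * np.sum(np.log(np.diag(c)))
    BUtX = b[:, None] * pre["UtX"]
    BUty = b * pre["Uty"]
    Ki_BUtX = linalg.cho_solve((c, low), BUtX, check_finite=False)
    Ki_BUty = linalg.cho_solve((c, low), BUty, check_finite=False)
    XtWiX = pre["XtX"] - BUtX.T @ Ki_BUtX
    XtWiy = pre["Xty"] - BUtX.T @ Ki_BUty
    ytWiy = pre["yty"] - float(BUty @ Ki_BUty)
    try:
        beta = linalg.solve(XtWiX, XtWiy, assume_a="pos")
    except linalg.LinAlgError:
        return np.inf, None
    qform = float(ytWiy - beta @ XtWiy)  # r' W^-1 r by GLS orthogonality
    if qform <= 0:
        return np.inf, None
    if reml:
        dof = n - p
        sigma2 = qform / dof
        sign, logdet_xx = np.linalg.slogdet(XtWiX)
        nll = 0.5 * (dof * np.log(2 * np.pi * sigma2) + logdet_w + logdet_xx + dof)
    else:
        sigma2 = qform / n
        nll = 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_w + n)
    aux = (beta, sigma2, g1, g2, XtWiX, logdet_w)
    return nll, aux


def fit_crossed_lmm(
    y: np.ndarray,
    X: np.ndarray,
    participant: np.ndarray,
    video: np.ndarray,
    names: Sequence[str],
    reml: bool = True,
) -> dict:
    """Fit y = X beta + b_participant + b_video + eps.

    Random intercepts for both grouping factors, residual variance
    profiled out.  Returns a dict of estimates; use
    :func:`fit_video_level` for the DataFrame-facing interface.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    pre = _lmm_precompute(X, y, participant, video)

    best = None
    for x0 in ([np.log(0.3), np.log(0.3)], [-4.0, -4.0]):
        res = optimize.minimize(
            lambda th: _lmm_profile(th, pre, n, p, reml)[0],
            x0=np.asarray(x0), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    nll, aux = _lmm_profile(best.x, pre, n, p, reml)
    beta, sigma2, g1, g2, XtWiX, _ = aux
    vcov = sigma2 * linalg.inv(XtWiX)
    se = np.sqrt(np.diag(vcov))
    dof = n - p
    tstat = beta / se
    pvals = 2 * stats.t.sf(np.abs(tstat), dof)
    tcrit = stats.t.ppf(0.975, dof)
    params = pd.DataFrame(
        {"beta": beta, "se": se, "ci_low": beta - tcrit * se,
         "ci_high": beta + tcrit * se, "stat": tstat, "p": pvals},
        index=list(names))
    # ML log-likelihood is what AIC and the LRT ladder consume
    if reml:
        ml_nll, _ = _lmm_profile(best.x, pre, n, p, reml=False)
    else:
        ml_nll = nll
    return {"params": params, "sigma2": sigma2, "tau_participant": g1 * sigma2,
            "tau_video": g2 * sigma2, "loglik": -nll, "loglik_ml": -ml_nll,
            "vcov": vcov, "converged": bool(best.success),
            "singular": bool(g1 < 1e-6 or g2 < 1e-6), "df_resid": dof,
            "fitted_fixed": X @ beta}


# ---------------------------------------------------------------------------
# Binomial GLMM (Laplace approximation)
# ---------------------------------------------------------------------------

def _glmm_laplace(log_tau, X, y, p_codes, v_codes, n_p, n_v, start=None,
                  max_newton=60):
    """Laplace log-likelihood at variance components exp(log_tau).

    Inner Newton maximization of the joint penalized log-likelihood over
    (beta, u); the Laplace correction uses the curvature at the mode.
    """
    tau1, tau2 = np.exp(np.clip(log_tau, -30.0, 10.0))
    n, p = X.shape
    q = n_p + n_v
    Dinv = np.concatenate([np.full(n_p, 1.0 / tau1), np.full(n_v, 1.0 / tau2)])
    logdet_D = n_p * np.log(tau1) + n_v * np.log(tau2)
    z1, z2 = p_codes, v_codes + n_p

    bu = np.zeros(p + q) if start is None else start.copy()

    def eta_of(bu):
        return X @ bu[:p] + bu[p:][z1] + bu[p:][z2]

    def joint(bu):
        eta = eta_of(bu)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float((bu[p:] ** 2 * Dinv).sum())

    f_cur = joint(bu)
    converged = False
    for _ in range(max_newton):
        eta = eta_of(bu)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        resid = y - mu
        grad = np.empty(p + q)
        grad[:p] = X.T @ resid
        gu = np.bincount(z1, weights=resid, minlength=q) \
            + np.bincount(z2, weights=resid, minlength=q)
        grad[p:] = gu - bu[p:] * Dinv
        # Hessian blocks
        XtWX = (X * w[:, None]).T @ X
        XtWZ = np.zeros((p, q))
        for j in range(p):
            XtWZ[j] = np.bincount(z1, weights=w * X[:, j], minlength=q) \
                + np.bincount(z2, weights=w * X[:, j], minlength=q)
        ZtWZ = np.zeros((q, q))
        d1 = np.bincount(z1, weights=w, minlength=q)
        d2 = np.bincount(z2, weights=w, minlength=q)
        np.fill_diagonal(ZtWZ, d1 + d2)
        # participant x video cross block (each row belongs to one of each)
        cross = np.zeros((n_p, n_v))
        np.add.at(cross, (p_codes, v_codes), w)
        ZtWZ[:n_p, n_p:] += cross
        ZtWZ[n_p:, :n_p] += cross.T
        H = np.block([[XtWX, XtWZ], [XtWZ.T, ZtWZ]])
        H[np.arange(p, p + q), np.arange(p, p + q)] += Dinv
        try:
            step = linalg.solve(H, grad, assume_a="pos")
        except linalg.LinAlgError:
            return -np.inf, None
        # damped Newton with step halving
        t = 1.0
        for _ in range(30):
            cand = bu + t * step
            f_new = joint(cand)
            if f_new >= f_cur - 1e-12:
                break
            t *= 0.5
        if f_new < f_cur:
            break
        moved = np.max(np.abs(t * step))
        bu, f_cur = cand, f_new
        if moved < 1e-9:
            converged = True
            break
    eta = eta_of(bu)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    # curvature of the u-block at the mode
    ZtWZ = np.zeros((q, q))
    d1 = np.bincount(z1, weights=w, minlength=q)
    d2 = np.bincount(z2, weights=w, minlength=q)
    np.fill_diagonal(ZtWZ, d1 + d2)
    cross = np.zeros((n_p, n_v))
    np.add.at(cross, (p_codes, v_codes), w)
    ZtWZ[:n_p, n_p:] += cross
    ZtWZ[n_p:, :n_p] += cross.T
    Hu = ZtWZ + np.diag(Dinv)
    sign, logdet_Hu = np.linalg.slogdet(Hu)
    if sign <= 0:
        return -np.inf, None
    ll = f_cur - 0.5 * logdet_D - 0.5 * logdet_Hu
    aux = {"bu": bu, "mu": mu, "w": w, "converged": converged}
    return ll, aux


def fit_crossed_binomial_glmm(
    y: np.ndarray,
    X: np.ndarray,
    participant: np.ndarray,
    video: np.ndarray,
    names: Sequence[str],
) -> dict:
    """Logit GLMM with crossed random intercepts, Laplace approximation."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if np.all(y == y[0]):
        raise SeparationError(
            "outcome has a single class; the binomial model is not estimable")
    p_codes, p_lv = pd.factorize(pd.Series(participant), sort=True)
    v_codes, v_lv = pd.factorize(pd.Series(video), sort=True)
    n_p, n_v = len(p_lv), len(v_lv)

    state = {"start": None}

    def nll(log_tau):
        ll, aux = _glmm_laplace(log_tau, X, y, p_codes, v_codes, n_p, n_v,
                                start=state["start"])
        if aux is not None:
            state["start"] = aux["bu"]
        return -ll

    best = None
    for x0 in ([np.log(0.2), np.log(0.2)], [-4.0, -4.0]):
        res = optimize.minimize(nll, x0=np.asarray(x0), method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7,
                                         "maxiter": 300})
        if best is None or res.fun < best.fun:
            best = res
    ll, aux = _glmm_laplace(best.x, X, y, p_codes, v_codes, n_p, n_v,
                            start=state["start"])
    tau1, tau2 = np.exp(np.clip(best.x, -30.0, 10.0))
    bu, w = aux["bu"], aux["w"]
    beta = bu[:p]
    if np.max(np.abs(beta)) > 15:
        warnings.warn("extreme coefficients: possible quasi-separation")
    # observed-information vcov for beta: Schur complement of the u block
    q = n_p + n_v
    Dinv = np.concatenate([np.full(n_p, 1.0 / tau1), np.full(n_v, 1.0 / tau2)])
    z1, z2 = p_codes, v_codes + n_p
    XtWX = (X * w[:, None]).T @ X
    XtWZ = np.zeros((p, q))
    for j in range(p):
        XtWZ[j] = np.bincount(z1, weights=w * X[:, j], minlength=q) \
            + np.bincount(z2, weights=w * X[:, j], minlength=q)
    ZtWZ = np.zeros((q, q))
    d1 = np.bincount(z1, weights=w, minlength=q)
    d2 = np.bincount(z2, weights=w, minlength=q)
    np.fill_diagonal(ZtWZ, d1 + d2)
    cross = np.zeros((n_p, n_v))
    np.add.at(cross, (p_codes, v_codes), w)
    ZtWZ[:n_p, n_p:] += cross
    ZtWZ[n_p:, :n_p] += cross.T
    Hu = ZtWZ + np.diag(Dinv)
    S = XtWX - XtWZ @ linalg.solve(Hu, XtWZ.T, assume_a="pos")
    vcov = linalg.inv(S)
    se = np.sqrt(np.diag(vcov))
    zstat = beta / se
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    zc = stats.norm.ppf(0.975)
    params = pd.DataFrame(
        {"beta": beta, "se": se, "ci_low": beta - zc * se,
         "ci_high": beta + zc * se, "stat": zstat, "p": pvals},
        index=list(names))
    return {"params": params, "sigma2": LOGISTIC_RESIDUAL_VAR,
            "tau_participant": tau1, "tau_video": tau2, "loglik": ll,
            "loglik_ml": ll, "vcov": vcov,
            "converged": bool(best.success and aux["converged"]),
            "singular": bool(tau1 < 1e-6 or tau2 < 1e-6),
            "fitted_fixed": X @ beta}


# ---------------------------------------------------------------------------
# DataFrame-facing fits
# ---------------------------------------------------------------------------

def _assemble_fit(raw: dict, family: str, method: str, df: pd.DataFrame,
                  names: List[str], info: dict) -> ModelFit:
    n = len(df)
    n_p = df["participant"].nunique()
    n_v = df["video"].nunique()
    tau = raw["tau_participant"] + raw["tau_video"]
    resid = raw["sigma2"]
    var_f = float(np.var(raw["fitted_fixed"]))
    total = var_f + tau + resid
    k = len(names) + (3 if family == "gaussian" else 2)
    aic = -2 * raw["loglik_ml"] + 2 * k
    return ModelFit(
        params=raw["params"], family=family, method=method,
        sigma2=resid, tau_participant=raw["tau_participant"],
        tau_video=raw["tau_video"], loglik=raw["loglik_ml"], aic=aic,
        n_obs=n, n_participants=n_p, n_videos=n_v,
        converged=raw["converged"], singular=raw["singular"],
        icc=tau / (tau + resid) if tau + resid > 0 else float("nan"),
        r2_marginal=var_f / total, r2_conditional=(var_f + tau) / total,
        vcov=raw["vcov"], design_info=info,
        metadata={"epoch_pairing": "EEG epoch t paired with behavioral "
                                    "change from epoch t-1 to t"})


def fit_video_level(table: pd.DataFrame, interaction: str = "none",
                    reml: bool = True, center: bool = False,
                    suppression: bool = True, condition: bool = True) -> ModelFit:
    """LMM: EA ~ S_C3 + S_C4 + S_O1 + S_O2 + condition (+ C4 x condition).

    Random intercepts for participant and video; REML by default.
    ``interaction="C4_only"`` adds the C4 x condition terms (the
    replication variant); ``"all"`` crosses every channel.
    """
    y, X, names, df, info = build_design(table, "EA", suppression=suppression,
                                         condition=condition,
                                         interaction=interaction, center=center)
    if df["participant"].nunique() < 2 or df["video"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 videos")
    p_codes, v_codes, _, _ = _group_codes(df)
    raw = fit_crossed_lmm(y, X, p_codes, v_codes, names, reml=reml)
    return _assemble_fit(raw, "gaussian", "REML" if reml else "ML",
                         df, names, info)


def fit_epoch_level(table: pd.DataFrame, interaction: str = "none",
                    center: bool = False, suppression: bool = True,
                    condition: bool = True) -> ModelFit:
    """Binomial GLMM: success ~ suppression + condition, logit link."""
    y, X, names, df, info = build_design(table, "success", suppression=suppression,
                                         condition=condition,
                                         interaction=interaction, center=center)
    if df["participant"].nunique() < 2 or df["video"].nunique() < 2:
        raise ValueError("need >= 2 participants and >= 2 videos")
    raw = fit_crossed_binomial_glmm(y, X, df["participant"].to_numpy(),
                                    df["video"].to_numpy(), names)
    return _assemble_fit(raw, "binomial", "Laplace-ML", df, names, info)


# ---------------------------------------------------------------------------
# Ladder, contrasts, outliers
# ---------------------------------------------------------------------------

_LADDER = (
    ("null", dict(suppression=False, condition=False, interaction="none")),
    ("+suppression", dict(suppression=True, condition=False, interaction="none")),
    ("+condition", dict(suppression=True, condition=True, interaction="none")),
    ("+interaction", dict(suppression=True, condition=True, interaction=None)),
)


def hierarchical_compare(table: pd.DataFrame, level: str = "video",
                         interaction: str = "all") -> ModelComparison:
    """Four-step nested ladder with likelihood-ratio tests.

    ``null -> +suppression -> +condition -> +interaction``, every model
    fit by maximum likelihood.  The video level reports LRT as the
    documented small-sample fallback (no Kenward-Roger machinery in
    this stack); the epoch level uses LRT by construction.
    """
    if level not in ("video", "epoch"):
        raise ValueError(f"unknown level {level!r}")
    fits: List[ModelFit] = []
    rows = []
    prev: Optional[ModelFit] = None
    for name, spec in _LADDER:
        kw = dict(spec)
        if kw["interaction"] is None:
            kw["interaction"] = interaction
        if level == "video":
            fit = fit_video_level(table, reml=False, **kw)
        else:
            fit = fit_epoch_level(table, **kw)
        stat = df_diff = p = np.nan
        if prev is not None:
            df_diff = len(fit.params) - len(prev.params)
            if df_diff <= 0:
                raise ValueError("ladder models are not strictly nested")
            stat = max(0.0, 2.0 * (fit.loglik - prev.loglik))
            p = float(stats.chi2.sf(stat, df_diff)) if stat > 0 else 1.0
        rows.append({"step": name, "added_df": df_diff, "stat": stat, "p": p,
                     "loglik": fit.loglik, "aic": fit.aic,
                     "converged": fit.converged})
        fits.append(fit)
        prev = fit
    steps = pd.DataFrame(rows)
    return ModelComparison(steps=steps, fits=fits, level=level,
                           method="LRT (ML)",
                           metadata={"interaction": interaction,
                                     "note": "likelihood-ratio fallback; no "
                                             "small-sample F correction"})


def condition_contrasts(fit: ModelFit) -> ContrastResult:
    """Pairwise condition contrasts at the mean suppression profile.

    Estimated marginal means are formed at the sample means of the
    suppression predictors; the three pairwise differences (AV-VO,
    AV-AO, AO-VO) are tested and Bonferroni-adjusted with m=3.
    """
    if not fit.design_info.get("has_condition", False):
        raise ValueError("fit has no condition term")
    names = list(fit.params.index)
    means = fit.design_info.get("suppression_means", {})
    centered = fit.design_info.get("centered", False)

    def profile(level: str) -> np.ndarray:
        x = np.zeros(len(names))
        for i, nm in enumerate(names):
            if nm == "(Intercept)":
                x[i] = 1.0
            elif nm in means:
                x[i] = 0.0 if centered else means[nm]
            elif nm == f"condition[{level}]":
                x[i] = 1.0
            elif ":" in nm:
                ch, dummy = nm.split(":")
                if dummy == f"condition[{level}]":
                    x[i] = 0.0 if centered else means.get(ch, 0.0)
        return x

    pairs = [("Audio-Video", "Video-Only"), ("Audio-Video", "Audio-Only"),
             ("Audio-Only", "Video-Only")]
    beta = fit.params["beta"].to_numpy()
    rows = []
    for a, b in pairs:
        c = profile(a) - profile(b)
        est = float(c @ beta)
        se = float(np.sqrt(c @ fit.vcov @ c))
        if fit.family == "gaussian":
            dof = fit.n_obs - len(names)
            statv = est / se
            p_raw = 2 * stats.t.sf(abs(statv), dof)
        else:
            statv = est / se
            p_raw = 2 * stats.norm.sf(abs(statv))
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "stat": statv, "p_raw": float(p_raw),
                     "p_adj": float(min(1.0, 3.0 * p_raw))})
    return ContrastResult(table=pd.DataFrame(rows), m=3)


def remove_outlier_trials(table: pd.DataFrame, k_sd: float = 2.0,
                          column: str = "EA") -> pd.DataFrame:
    """Drop trials more than k_sd SDs from the grand mean score.

    Single pass: mean and SD are computed once on all non-missing
    values, never re-computed after removal.  With zero variance
    nothing is removed (a warning is issued).
    """
    if table[column].notna().sum() < 3:
        raise ValueError("need at least 3 scored trials")
    vals = table[column]
    mu, sd = vals.mean(), vals.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        warnings.warn("zero-variance scores: no outliers removed")
        return table.copy()
    keep = vals.isna() | ((vals - mu).abs() <= k_sd * sd)
    return table[keep].reset_index(drop=True)
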