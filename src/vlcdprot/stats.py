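"""Repeated-measures inference per protein.

The model for one protein's abundances over the patient samples is a linear
mixed model with a per-subject random intercept,

    y = b0 + b1*time + b2*treatment + b3*time*treatment + u_subject + e,

fitted by maximum likelihood.  Time is 0 (baseline) / 1 (week 16); treatment
is effect-coded -1/2 (diet only) / +1/2 (diet + exercise), so b1 is the
arm-averaged diet (time) effect and b3 the extra time effect of exercise.
The diet effect is tested by a df-1 likelihood-ratio test dropping the time
term; the exercise effect by dropping the interaction.  Because every subject
contributes at most two observations, the marginal covariance factorizes into
1x1 and 2x2 blocks and the profile likelihood over the variance ratio
lambda = sigma_b^2/sigma_e^2 is available in closed form, which the fitter
exploits to process all proteins of a study simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import BASELINE, T2DM_EX, StudyDesign

_FIXED_EFFECTS = ("intercept", "time", "treatment", "interaction")
_SIGMA2_FLOOR = 1e-300  # guards log() on exactly-interpolating (noise-free) fits


# ---------------------------------------------------------------------------
# vectorized profile-likelihood ML fitter
# ---------------------------------------------------------------------------

def _suff_stats(Y: np.ndarray, X: np.ndarray, subject: np.ndarray):
    """Sufficient statistics for the block-diagonal random-intercept likelihood."""
    n_obs = X.shape[0]
    subj_ids, subj_idx = np.unique(subject, return_inverse=True)
    n_subj = len(subj_ids)
    counts = np.bincount(subj_idx, minlength=n_subj)
    if counts.max() > 2:
        raise ValueError("random-intercept fitter supports <= 2 observations per subject")
    # per-subject sums of X rows and of y
    S = np.zeros((n_subj, X.shape[1]))
    np.add.at(S, subj_idx, X)
    T = np.zeros((Y.shape[0], n_subj))
    np.add.at(T.T, subj_idx, Y.T)
    m1 = counts == 1
    m2 = counts == 2
    return {
        "N": n_obs,
        "XtX": X.T @ X,
        "XtY": Y @ X,                     # (P, k)
        "yty": (Y * Y).sum(axis=1),
        "S1": S[m1].T @ S[m1],
        "S2": S[m2].T @ S[m2],
        "U1": T[:, m1] @ S[m1],           # (P, k)
        "U2": T[:, m2] @ S[m2],
        "q1": (T[:, m1] ** 2).sum(axis=1),
        "q2": (T[:, m2] ** 2).sum(axis=1),
        "c1": int(m1.sum()),
        "c2": int(m2.sum()),
    }


def _profile_loglik(lam: np.ndarray, st: dict, want_beta: bool = False):
    """Profile log-likelihood at per-protein variance ratios ``lam``."""
    g1 = lam / (1.0 + lam)
    g2 = lam / (1.0 + 2.0 * lam)
    A = (st["XtX"][None, :, :]
         - g1[:, None, None] * st["S1"]
         - g2[:, None, None] * st["S2"])
    b = st["XtY"] - g1[:, None] * st["U1"] - g2[:, None] * st["U2"]
    beta = np.linalg.solve(A, b[..., None])[..., 0]
    rss = st["yty"] - g1 * st["q1"] - g2 * st["q2"] - (beta * b).sum(axis=1)
    rss = np.maximum(rss, 0.0)
    n = st["N"]
    sigma2 = np.maximum(rss / n, _SIGMA2_FLOOR)
    ll = (-0.5 * n * (np.log(2.0 * np.pi * sigma2) + rss / (n * sigma2))
          - 0.5 * (st["c1"] * np.log1p(lam) + st["c2"] * np.log1p(2.0 * lam)))
    if want_beta:
        return ll, beta, A, sigma2
    return ll


def fit_lmm_ml(Y: np.ndarray, X: np.ndarray, subject: np.ndarray) -> dict:
    """ML fit of the random-intercept model for many responses at once.

    Y: (P, N) responses; X: (N, k) fixed-effect design; subject: (N,) labels.
    Returns per-protein arrays: loglik, beta (P, k), se (P, k), sigma_e2,
    sigma_b2.  The profile likelihood over lambda >= 0 is maximized by a
    coarse log-grid followed by golden-section refinement (final bracket far
    below 1e-10 relative log-likelihood change).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if not np.isfinite(Y).all():
        raise ValueError("non-finite response values")
    st = _suff_stats(Y, np.asarray(X, dtype=float), np.asarray(subject))
    P = Y.shape[0]

    grid = np.concatenate([[0.0], np.logspace(-6, 4, 81)])
    ll_grid = np.stack([_profile_loglik(np.full(P, lam), st) for lam in grid])
    j = ll_grid.argmax(axis=0)
    lo = grid[np.maximum(j - 1, 0)]
    hi = grid[np.minimum(j + 1, len(grid) - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    f1 = _profile_loglik(x1, st)
    f2 = _profile_loglik(x2, st)
    for _ in range(80):
        left = f1 > f2                      # maximum lies in [lo, x2]
        hi = np.where(left, x2, hi)
        lo = np.where(left, lo, x1)
        probe = np.where(left, hi - invphi * (hi - lo), lo + invphi * (hi - lo))
        fp = _profile_loglik(probe, st)
        x1, x2, f1, f2 = (
            np.where(left, probe, x2),
            np.where(left, x1, probe),
            np.where(left, fp, f2),
            np.where(left, f1, fp),
        )
    lam = np.where(f1 > f2, x1, x2)
    lam = np.where(lam < 1e-12, 0.0, lam)

    ll, beta, A, sigma2 = _profile_loglik(lam, st, want_beta=True)
    cov = np.linalg.inv(A) * sigma2[:, None, None]
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return {
        "loglik": ll,
        "beta": beta,
        "se": se,
        "sigma_e2": sigma2,
        "sigma_b2": lam * sigma2,
        "lambda": lam,
    }


# ---------------------------------------------------------------------------
# study-level wrappers
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """ML fit of the repeated-measures model for one protein."""

    beta: dict[str, float]
    se: dict[str, float]
    sigma_b2: float
    sigma_e2: float
    loglik_full: float
    loglik_no_time: float
    loglik_no_interaction: float
    p_time: float
    p_interaction: float
    converged: bool
    n_obs: int
    n_subjects: int


def patient_frame(design: StudyDesign) -> pd.DataFrame:
    """Modelling covariates for the patient samples (time, treatment, subject)."""
    rows = []
    for s in design.patient_samples:
        rows.append((
            s.sample_id,
            s.subject_id,
            0.0 if s.timepoint == BASELINE else 1.0,
            0.5 if s.group == T2DM_EX else -0.5,
        ))
    return pd.DataFrame(rows, columns=["sample_id", "subject_id", "time", "treatment"])


def _design_matrices(frame: pd.DataFrame):
    t = frame["time"].to_numpy()
    g = frame["treatment"].to_numpy()
    one = np.ones(len(frame))
    two_arms = len(np.unique(g)) > 1
    if two_arms:
        X_full = np.column_stack([one, t, g, t * g])
        X_no_time = np.column_stack([one, g, t * g])
        X_no_int = np.column_stack([one, t, g])
        cols = list(_FIXED_EFFECTS)
    else:
        X_full = np.column_stack([one, t])
        X_no_time = one[:, None]
        X_no_int = None
        cols = ["intercept", "time"]
    return X_full, X_no_time, X_no_int, cols


def _validate_patient_design(frame: pd.DataFrame) -> None:
    arms = frame.groupby("treatment")["subject_id"].nunique()
    if len(arms) != 2:
        raise ValueError("the study model needs both treatment arms")
    if (arms < 3).any():
        raise ValueError(
            f"need >= 3 subjects per arm, have {arms.to_dict()}"
        )


def fit_vlcd_models(
    abundance: pd.DataFrame,
    design: StudyDesign,
    log2_scale: bool = False,
) -> pd.DataFrame:
    """Fit the repeated-measures model protein-by-protein over patient samples.

    Returns one row per protein with fixed effects, variance components, LRT
    p-values for the diet (time) and exercise (time x treatment) effects, and
    BH-adjusted p-values (one family per contrast across proteins).
    Analysis is on the ratio scale by default (``log2_scale=True`` transforms).
    """
    frame = patient_frame(design)
    _validate_patient_design(frame)
    cols = [c for c in frame["sample_id"] if c in abundance.columns]
    if len(cols) < len(frame):
        missing = set(frame["sample_id"]) - set(cols)
        raise ValueError(f"abundance lacks patient samples: {sorted(missing)[:5]} ...")
    frame = frame.set_index("sample_id").loc[cols].reset_index()
    Y = abundance[cols].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("missing values in modelled abundances; apply the "
                         "complete-case filter first")
    if log2_scale:
        Y = np.log2(Y)
    X_full, X_no_time, X_no_int, _ = _design_matrices(frame)
    subj = frame["subject_id"].to_numpy()

    full = fit_lmm_ml(Y, X_full, subj)
    red_t = fit_lmm_ml(Y, X_no_time, subj)
    red_i = fit_lmm_ml(Y, X_no_int, subj)
    p_time = lrt_pvalue(full["loglik"], red_t["loglik"], df=1)
    p_inter = lrt_pvalue(full["loglik"], red_i["loglik"], df=1)

    res = pd.DataFrame({
        "beta_intercept": full["beta"][:, 0],
        "beta_time": full["beta"][:, 1],
        "beta_treatment": full["beta"][:, 2],
        "beta_interaction": full["beta"][:, 3],
        "se_time": full["se"][:, 1],
        "se_interaction": full["se"][:, 3],
        "sigma_b2": full["sigma_b2"],
        "sigma_e2": full["sigma_e2"],
        "loglik_full": full["loglik"],
        "p_time": p_time,
        "p_interaction": p_inter,
    }, index=abundance.index)
    res["p_time_bh"] = bh_adjust(res["p_time"].to_numpy())
    res["p_interaction_bh"] = bh_adjust(res["p_interaction"].to_numpy())
    return res


def fit_random_intercept_ml(y: pd.Series, design: StudyDesign) -> ModelResult:
    """Single-protein convenience wrapper around the vectorized fitter.

    ``y`` is indexed by sample id; only patient samples are modelled.  With a
    single treatment arm present the treatment and interaction terms are
    dropped (p_interaction is NaN).
    """
    frame = patient_frame(design)
    frame = frame[frame["sample_id"].isin(y.index)]
    arms = frame.groupby("treatment")["subject_id"].nunique()
    if (arms < 3).any():
        raise ValueError(f"need >= 3 subjects per arm, have {arms.to_dict()}")
    yv = y.loc[frame["sample_id"]].to_numpy(dtype=float)
    if not np.isfinite(yv).all():
        raise ValueError("non-finite response values")
    X_full, X_no_time, X_no_int, cols = _design_matrices(frame)
    subj = frame["subject_id"].to_numpy()

    full = fit_lmm_ml(yv, X_full, subj)
    red_t = fit_lmm_ml(yv, X_no_time, subj)
    beta = {c: float(full["beta"][0, i]) for i, c in enumerate(cols)}
    se = {c: float(full["se"][0, i]) for i, c in enumerate(cols)}
    p_time = float(lrt_pvalue(full["loglik"], red_t["loglik"], df=1)[0])
    if X_no_int is not None:
        red_i = fit_lmm_ml(yv, X_no_int, subj)
        ll_noint = float(red_i["loglik"][0])
        p_inter = float(lrt_pvalue(full["loglik"], red_i["loglik"], df=1)[0])
    else:
        ll_noint, p_inter = np.nan, np.nan
    return ModelResult(
        beta=beta,
        se=se,
        sigma_b2=float(full["sigma_b2"][0]),
        sigma_e2=float(full["sigma_e2"][0]),
        loglik_full=float(full["loglik"][0]),
        loglik_no_time=float(red_t["loglik"][0]),
        loglik_no_interaction=ll_noint,
        p_time=p_time,
        p_interaction=p_inter,
        converged=True,
        n_obs=len(yv),
        n_subjects=frame["subject_id"].nunique(),
    )


def lrt_pvalue(ll_full, ll_reduced, df: int = 1, tol: float = 1e-6) -> np.ndarray:
    """Likelihood-ratio test of nested ML fits: 2*dlogL ~ chi-square(df)."""
    ll_full = np.atleast_1d(np.asarray(ll_full, dtype=float))
    ll_reduced = np.atleast_1d(np.asarray(ll_reduced, dtype=float))
    stat = 2.0 * (ll_full - ll_reduced)
    if (stat < -tol).any():
        raise RuntimeError(
            "reduced model out-fitted the full model beyond tolerance; refit"
        )
    stat = np.maximum(stat, 0.0)
    return sps.chi2.sf(stat, df)


def test_fixed_effect(ll_full: float, ll_reduced: float, df: int = 1) -> float:
    """p-value of the LRT comparing a full and a nested reduced ML fit."""
    return float(lrt_pvalue(ll_full, ll_reduced, df)[0])


# ---------------------------------------------------------------------------
# t-test families and multiplicity
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    t: float
    p: float
    zero_variance: bool = False


def paired_ttest(x_baseline, x_followup) -> TTestResult:
    """Two-sided paired t-test on within-subject differences."""
    x0 = np.asarray(x_baseline, dtype=float)
    x1 = np.asarray(x_followup, dtype=float)
    if x0.shape != x1.shape:
        raise ValueError("paired vectors must have equal length")
    if len(x0) < 2:
        raise ValueError("need >= 2 pairs")
    d = x1 - x0
    if np.var(d, ddof=1) == 0.0:
        return TTestResult(t=0.0, p=np.nan, zero_variance=True)
    t, p = sps.ttest_rel(x1, x0)
    return TTestResult(t=float(t), p=float(p))


def independent_ttest(x, y, equal_var: bool = False) -> TTestResult:
    """Two-sided independent t-test (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        return TTestResult(t=0.0, p=np.nan, zero_variance=True)
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


VLCD_RULE = "VLCD"
EXERCISE_RULE = "EXERCISE"


def flag_significant(
    results: pd.DataFrame,
    rule: str,
    alpha_raw: float = 0.05,
    alpha_bh: float = 0.10,
) -> pd.DataFrame:
    """Apply the study's significance rules to a fitted results table.

    VLCD rule: raw p_time < alpha_raw AND BH-adjusted p_time < alpha_bh.
    EXERCISE rule: raw p_interaction < alpha_raw (adjusted values reported).
    Direction follows the sign of the tested fixed effect (positive = up
    after 16 weeks).
    """
    if rule == VLCD_RULE:
        sig = (results["p_time"] < alpha_raw) & (results["p_time_bh"] < alpha_bh)
        beta = results["beta_time"]
    elif rule == EXERCISE_RULE:
        sig = results["p_interaction"] < alpha_raw
        beta = results["beta_interaction"]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    out = results.copy()
    out["significant"] = sig
    out["direction"] = np.where(beta > 0, "up", "down")
    return out
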