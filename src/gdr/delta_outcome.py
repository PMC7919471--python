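"""Normalized delta statistic and local-recurrence outcome modeling.

The core statistic divides the relative feature change during treatment
by the feature's relative variability across the pre-treatment breathing
phases,

    delta = delta_r / sigma_4d,
    delta_r  = 100 * (post - pre) / |pre|        [%]
    sigma_4d = 100 * SD(phases) / |mean(phases)| [%]

so a change is expressed in units of the patient's own noise floor.
Group separation uses the Mann–Whitney U test (BH-adjusted across
features); prediction uses binary logistic regression whose performance
is estimated by stratified (imbalance-preserving) bootstrap with
out-of-bag scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gdr.robustness_screen import bh_adjust

__all__ = [
    "SIGMA_FLOOR_PCT",
    "compute_delta",
    "group_test",
    "roc_curve",
    "fit_logistic_bootstrap",
    "ModelResult",
]

SIGMA_FLOOR_PCT = 0.1  # relative SD below this is treated as zero noise floor
_EPS_REF = 1e-12  # |reference| below this makes a relative change undefined


def compute_delta(
    table: pd.DataFrame,
    eligible: list[str] | tuple[str, ...],
    sigma_floor_pct: float = SIGMA_FLOOR_PCT,
    min_phases: int = 3,
) -> pd.DataFrame:
    """Per (patient, feature) normalized delta records.

    Returns a frame with columns ``patient_id, feature_name, delta_r,
    sigma_4d, delta, excluded, reason``; excluded records keep their
    partial quantities but a NaN delta.
    """
    pre3d = table[table["scan_role"] == "pre3d"].set_index(
        ["patient_id", "feature_name"]
    )["value"]
    post3d = table[table["scan_role"] == "post3d"].set_index(
        ["patient_id", "feature_name"]
    )["value"]
    phases = table[table["scan_role"].str.startswith("pre4d_phase_")]

    rows = []
    for (pid, feat), grp in phases.groupby(["patient_id", "feature_name"]):
        if feat not in eligible:
            continue
        rec = {
            "patient_id": pid,
            "feature_name": feat,
            "delta_r": np.nan,
            "sigma_4d": np.nan,
            "delta": np.nan,
            "excluded": True,
            "reason": "",
        }
        v = grp["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size < min_phases:
            rec["reason"] = "too_few_phases"
            rows.append(rec)
            continue
        if (pid, feat) not in pre3d.index or (pid, feat) not in post3d.index:
            rec["reason"] = "missing_scan"
            rows.append(rec)
            continue
        pre = float(pre3d.loc[(pid, feat)])
        post = float(post3d.loc[(pid, feat)])
        if not (np.isfinite(pre) and np.isfinite(post)):
            rec["reason"] = "undefined_feature"
            rows.append(rec)
            continue
        pmean = float(v.mean())
        if abs(pre) < _EPS_REF or abs(pmean) < _EPS_REF:
            rec["reason"] = "zero_reference"
            rows.append(rec)
            continue
        delta_r = 100.0 * (post - pre) / abs(pre)
        sigma = 100.0 * float(v.std(ddof=1)) / abs(pmean)
        rec["delta_r"] = delta_r
        rec["sigma_4d"] = sigma
        if sigma < sigma_floor_pct:
            rec["reason"] = "sigma_below_floor"
            rows.append(rec)
            continue
        rec["delta"] = delta_r / sigma
        rec["excluded"] = False
        rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "feature_name",
            "delta_r",
            "sigma_4d",
            "delta",
            "excluded",
            "reason",
        ],
    )


def group_test(
    deltas: pd.DataFrame,
    outcome: pd.Series | dict,
    exact_max_n: int = 20,
) -> pd.DataFrame:
    """Per-feature two-sided Mann–Whitney U between outcome groups.

    Exact null distribution for total n <= ``exact_max_n`` without ties,
    tie-corrected normal approximation otherwise; p-values BH-adjusted
    across features.
    """
    labels = pd.Series(outcome)
    rows = []
    ok = deltas[~deltas["excluded"]]
    for feat, grp in ok.groupby("feature_name", sort=True):
        merged = grp.set_index("patient_id")["delta"]
        y = labels.reindex(merged.index)
        x1 = merged[y == 1].to_numpy(dtype=float)
        x0 = merged[y == 0].to_numpy(dtype=float)
        if x1.size == 0 or x0.size == 0:
            raise ValueError(f"feature {feat!r}: one outcome group is empty")
        n = x1.size + x0.size
        has_ties = np.unique(np.concatenate([x1, x0])).size < n
        method = "exact" if (n <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x1, x0, alternative="two-sided", method=method)
        rows.append(
            {
                "feature_name": feat,
                "U": float(res.statistic),
                "p": float(res.pvalue),
                "n1": int(x1.size),
                "n0": int(x0.size),
                "median_1": float(np.median(x1)),
                "median_0": float(np.median(x0)),
            }
        )
    df = pd.DataFrame(rows).set_index("feature_name")
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def roc_curve(
    scores, labels
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Empirical ROC with tied scores grouped.

    Returns (thresholds, sensitivity, specificity, auc); the AUC is the
    trapezoidal area, equal to the tie-corrected concordance probability.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1D of equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-s, kind="stable")
    ss = s[order]
    ys = y[order]
    # last index of each tied-score group
    ends = np.flatnonzero(np.r_[ss[1:] != ss[:-1], True])
    thr = ss[ends]
    tp = np.cumsum(ys == 1)[ends]
    fp = np.cumsum(ys == 0)[ends]
    sens = tp / n1
    spec = 1.0 - fp / n0

    # concordance with ties counted half
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return thr, sens, spec, float(auc)


@dataclass
class ModelResult:
    features: list[str]
    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    separation_flag: bool
    auc: float
    sensitivity: float
    specificity: float
    operating_threshold: float
    n_bootstrap: int
    auc_replicates_mean: float
    auc_replicates_sd: float
    extras: dict = field(default_factory=dict)


def _fit_logit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Unpenalized logistic fit by Newton iterations; returns [intercept, coefs]."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(50):
        eta = np.clip(Xd @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = Xd.T @ (y - p)
        H = (Xd * W[:, None]).T @ Xd + 1e-10 * np.eye(Xd.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10 or np.abs(beta).max() > 1e3:
            break
    return beta


def fit_logistic_bootstrap(
    deltas: pd.DataFrame,
    outcome: pd.Series | dict,
    features: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> ModelResult:
    """Logistic model with imbalance-adjusted bootstrap performance.

    Coefficients come from the full-data fit (with Wald 95% CI; flagged
    when separation makes them unstable).  Performance (AUC, sensitivity
    and specificity at the Youden-optimal threshold) is the mean over
    ``B`` stratified bootstrap resamples — class proportions preserved in
    each resample — scored on the out-of-bag cases.
    """
    ok = deltas[~deltas["excluded"]]
    wide = ok.pivot(index="patient_id", columns="feature_name", values="delta")
    if features is None:
        features = sorted(wide.columns)
    wide = wide[list(features)].dropna()
    labels = pd.Series(outcome).reindex(wide.index)
    if labels.isna().any():
        raise ValueError("missing outcome label for some patients")
    X = wide.to_numpy(dtype=float)
    y = labels.to_numpy(dtype=int)
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise ValueError("need >= 3 cases per class")

    beta = _fit_logit(X, y)
    separation = bool(np.abs(beta).max() > 50)
    # Wald CI from observed information
    Xd = np.column_stack([np.ones(len(y)), X])
    eta = np.clip(Xd @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    H = (Xd * (p * (1 - p))[:, None]).T @ Xd + 1e-10 * np.eye(Xd.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = np.sqrt(np.diag(np.linalg.inv(H)))
    names = ["intercept"] + list(features)
    coefficients = dict(zip(names, beta.tolist()))
    conf_int = {
        n: (float(b - 1.96 * s), float(b + 1.96 * s))
        for n, b, s in zip(names, beta, se)
    }

    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    aucs, sens_l, spec_l, thr_l = [], [], [], []
    for _ in range(B):
        boot = np.concatenate(
            [rng.choice(idx1, idx1.size, replace=True),
             rng.choice(idx0, idx0.size, replace=True)]
        )
        oob = np.setdiff1d(np.arange(len(y)), boot)
        if oob.size == 0 or len(np.unique(y[oob])) < 2:
            continue
        b = _fit_logit(X[boot], y[boot])
        scores = np.clip(
            np.column_stack([np.ones(oob.size), X[oob]]) @ b, -30, 30
        )
        thr, sn, sp, auc = roc_curve(scores, y[oob])
        j = np.argmax(sn + sp - 1.0)
        aucs.append(auc)
        sens_l.append(sn[j])
        spec_l.append(sp[j])
        thr_l.append(thr[j])
    if not aucs:
        raise RuntimeError("no bootstrap replicate had both classes out-of-bag")

    return ModelResult(
        features=list(features),
        coefficients=coefficients,
        conf_int=conf_int,
        separation_flag=separation,
        auc=float(np.mean(aucs)),
        sensitivity=float(np.mean(sens_l)),
        specificity=float(np.mean(spec_l)),
        operating_threshold=float(np.mean(thr_l)),
        n_bootstrap=len(aucs),
        auc_replicates_mean=float(np.mean(aucs)),
        auc_replicates_sd=float(np.std(aucs)),
        extras={"n_patients": int(len(y)), "n_positive": int((y == 1).sum())},
    )
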