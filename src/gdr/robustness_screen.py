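"""Feature eligibility screening: phase normality and 3D-vs-4D comparability.

A feature is eligible when

1. its values across the gated breathing phases are compatible with a
   normal distribution (Shapiro–Wilk, p >= alpha) in strictly more than
   70% of evaluable patients, and
2. it is comparable between the static 3D scan and the 4D summary
   (per-patient mean across phases): a Benjamini–Hochberg-adjusted
   Wilcoxon signed-rank test is non-significant, or a significant test is
   not confirmed by the Bland–Altman 95% CI of the mean percentage
   difference (CI containing zero).

The long feature table uses columns
``patient_id, scan_role, segmentation, feature_name, value``
with ``scan_role`` in {pre3d, pre4d_phase_<k>, post3d}.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TABLE_COLUMNS",
    "ScreenReport",
    "bh_adjust",
    "normality_screen",
    "comparability_screen",
    "select_eligible",
    "run_screen",
]

TABLE_COLUMNS = ["patient_id", "scan_role", "segmentation", "feature_name", "value"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _phase_frame(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["scan_role"].str.startswith("pre4d_phase_")]


def normality_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    patient_fraction: float = 0.70,
    min_phases: int = 3,
) -> pd.DataFrame:
    """Per-feature Shapiro–Wilk verdict across gated phases.

    A patient passes for a feature iff the Shapiro–Wilk p-value on its
    K phase values is >= alpha.  Constant-across-phases values (test
    undefined) count as a pass — zero intrinsic variability is maximal
    stability — but are flagged ``constant`` for exclusion downstream.
    The feature passes iff strictly more than ``patient_fraction`` of
    evaluable patients pass.
    """
    phases = _phase_frame(table)
    rows = []
    for feat, grp in phases.groupby("feature_name", sort=True):
        n_pass = 0
        n_eval = 0
        n_const = 0
        for _, pg in grp.groupby("patient_id"):
            v = pg["value"].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size < min_phases:
                continue
            n_eval += 1
            if np.ptp(v) == 0.0:
                n_const += 1
                n_pass += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = stats.shapiro(v).pvalue
            if p >= alpha:
                n_pass += 1
        frac = n_pass / n_eval if n_eval else 0.0
        rows.append(
            {
                "feature_name": feat,
                "n_evaluable": n_eval,
                "n_constant": n_const,
                "normal_fraction": frac,
                "normality_pass": bool(n_eval and frac > patient_fraction),
            }
        )
    return pd.DataFrame(rows).set_index("feature_name")


def _bland_altman_pct(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mean percentage difference and its 95% CI (mean ± 1.96 SD/sqrt(n))."""
    denom = (x + y) / 2.0
    ok = denom != 0
    pct = 100.0 * (x[ok] - y[ok]) / denom[ok]
    n = pct.size
    mean = float(pct.mean())
    half = 1.96 * float(pct.std(ddof=1)) / np.sqrt(n) if n > 1 else np.inf
    return mean, mean - half, mean + half


def comparability_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    min_patients: int = 6,
    min_phases: int = 3,
) -> pd.DataFrame:
    """Per-feature 3D-vs-4D comparability verdict.

    Pairs the static pre-treatment value with the mean across gated
    phases per patient; Wilcoxon signed-rank p-values are BH-adjusted
    across features, and significant results are confirmed (or rescued)
    by the Bland–Altman percentage CI.
    """
    pre3d = table[table["scan_role"] == "pre3d"].set_index(
        ["patient_id", "feature_name"]
    )["value"]
    phases = _phase_frame(table)

    feats = sorted(phases["feature_name"].unique())
    rows = []
    for feat in feats:
        grp = phases[phases["feature_name"] == feat]
        xs, ys = [], []
        for pid, pg in grp.groupby("patient_id"):
            v = pg["value"].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size < min_phases or (pid, feat) not in pre3d.index:
                continue
            x = float(pre3d.loc[(pid, feat)])
            if not np.isfinite(x):
                continue
            xs.append(x)
            ys.append(float(v.mean()))
        x = np.asarray(xs)
        y = np.asarray(ys)
        if x.size < min_patients:
            raise ValueError(
                f"comparability screen needs >= {min_patients} complete "
                f"patients for feature {feat!r}, got {x.size}"
            )
        d = x - y
        if np.all(d == 0):
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(stats.wilcoxon(x, y).pvalue)
        ba_mean, ba_lo, ba_hi = _bland_altman_pct(x, y)
        rows.append(
            {
                "feature_name": feat,
                "n_patients": int(x.size),
                "wsr_p": p,
                "ba_mean_pct": ba_mean,
                "ba_lo": ba_lo,
                "ba_hi": ba_hi,
            }
        )
    df = pd.DataFrame(rows).set_index("feature_name")
    df["wsr_p_adj"] = bh_adjust(df["wsr_p"].to_numpy())
    ci_contains_zero = (df["ba_lo"] <= 0) & (df["ba_hi"] >= 0)
    df["comparable_pass"] = (df["wsr_p_adj"] >= alpha) | ci_contains_zero
    return df


def select_eligible(
    normality: pd.DataFrame, comparability: pd.DataFrame
) -> list[str]:
    """Features passing both screens, sorted by name."""
    a = set(normality.index[normality["normality_pass"]])
    b = set(comparability.index[comparability["comparable_pass"]])
    out = sorted(a & b)
    if not out:
        warnings.warn("no feature passed both screens", stacklevel=2)
    return out


@dataclass
class ScreenReport:
    normality: pd.DataFrame
    comparability: pd.DataFrame
    eligible: list[str]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        feats = sorted(
            set(self.normality.index) | set(self.comparability.index)
        )
        per_feature = {}
        for f in feats:
            entry: dict = {}
            if f in self.normality.index:
                r = self.normality.loc[f]
                entry.update(
                    normal_fraction=float(r["normal_fraction"]),
                    normality_pass=bool(r["normality_pass"]),
                )
            if f in self.comparability.index:
                r = self.comparability.loc[f]
                entry.update(
                    wsr_p_adj=float(r["wsr_p_adj"]),
                    ba_ci=[float(r["ba_lo"]), float(r["ba_hi"])],
                    comparable_pass=bool(r["comparable_pass"]),
                )
            entry["eligible"] = f in self.eligible
            per_feature[f] = entry
        doc = {
            "config": self.config,
            "eligible": self.eligible,
            "features": per_feature,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def run_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    patient_fraction: float = 0.70,
    min_patients: int = 6,
) -> ScreenReport:
    """Run both screens and intersect the verdicts."""
    norm = normality_screen(table, alpha=alpha, patient_fraction=patient_fraction)
    comp = comparability_screen(table, alpha=alpha, min_patients=min_patients)
    eligible = select_eligible(norm, comp)
    return ScreenReport(
        normality=norm,
        comparability=comp,
        eligible=eligible,
        config={
            "alpha": alpha,
            "patient_fraction": patient_fraction,
            "min_patients": min_patients,
        },
    )
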