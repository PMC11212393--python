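"""Combining the two sequence-based predictors and scoring candidates.

The observed ASB phenotype is regressed on the BLUP prediction and the
deltaSVM score, y = b0 + b1*u_hat + b2*deltaSVM + e, by ordinary least
squares. Candidate asbQTL are the sites with the largest predicted magnitude
under each method, and a method's direction accuracy is the fraction of its
candidates whose predicted sign matches the observed allelic-imbalance sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from asbqtl._util import AsbqtlError, InputError


@dataclass
class MlrFit:
    beta0: float
    beta1: float  # coefficient on the BLUP prediction
    beta2: float  # coefficient on deltaSVM
    se: tuple[float, float, float]
    p_values: tuple[float, float, float]
    r2: float
    adjusted_r2: float
    n: int

    def predict(self, u_hat: np.ndarray, delta_svm: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(u_hat) \
            + self.beta2 * np.asarray(delta_svm)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": ["intercept", "blup", "gkmsvm"],
            "estimate": [self.beta0, self.beta1, self.beta2],
            "se": list(self.se),
            "p_value": list(self.p_values),
            "adjusted_r2": [self.adjusted_r2] * 3,
            "n": [self.n] * 3,
        })


def fit_mlr(records: pd.DataFrame) -> MlrFit:
    """OLS fit of y on (u_hat, delta_svm) over complete records.

    ``records`` needs columns y_observed, u_hat, delta_svm. Rows with a
    missing predictor are dropped; at least 10 complete records are required.
    """
    req = {"y_observed", "u_hat", "delta_svm"}
    if not req <= set(records.columns):
        raise InputError(f"fit_mlr needs columns {sorted(req)}")
    rec = records.dropna(subset=list(req))
    if len(rec) < 10:
        raise InputError("fit_mlr needs at least 10 complete records")
    x = sm.add_constant(rec[["u_hat", "delta_svm"]].to_numpy(), has_constant="add")
    if np.linalg.cond(x) > 1e10:
        raise AsbqtlError("predictors are collinear (condition number > 1e10)")
    res = sm.OLS(rec.y_observed.to_numpy(), x).fit()
    return MlrFit(
        beta0=float(res.params[0]), beta1=float(res.params[1]),
        beta2=float(res.params[2]),
        se=tuple(float(v) for v in res.bse),
        p_values=tuple(float(v) for v in res.pvalues),
        r2=float(res.rsquared), adjusted_r2=float(res.rsquared_adj),
        n=int(res.nobs),
    )


def select_candidates(scores: pd.DataFrame, n_top: int = 1000,
                      score_col: str = "score") -> pd.DataFrame:
    """The n_top sites with the largest |score|.

    Ties (including the all-zero degenerate case) break by (chrom, pos) so
    selection is invariant to input order. Requires columns site_id, chrom,
    pos and the score column. If fewer sites than n_top exist, all are
    returned with a warning.
    """
    import warnings

    if not {"site_id", "chrom", "pos", score_col} <= set(scores.columns):
        raise InputError("select_candidates: missing required columns")
    df = scores.copy()
    df["_mag"] = df[score_col].abs()
    if (df["_mag"] == 0).all() and len(df):
        warnings.warn("all scores are zero; selection is positional only")
    df = df.sort_values(["_mag", "chrom", "pos"],
                        ascending=[False, True, True], kind="mergesort")
    if len(df) < n_top:
        warnings.warn(f"only {len(df)} sites available for n_top={n_top}")
    return df.head(n_top).drop(columns="_mag").reset_index(drop=True)


def default_n_top(n_sites: int, n_top: int = 1000) -> int:
    """The headline candidate-set size, scaled to min(n_top, 10% of sites)
    so small runs keep a meaningful non-candidate comparison group."""
    return max(1, min(n_top, n_sites // 10 or 1))


def direction_accuracy(candidates: pd.DataFrame, score_col: str = "score",
                       observed_col: str = "y_observed") -> float:
    """Fraction of candidates with sign(score) = sign(observed phenotype).

    A predicted score of exactly zero counts as a mismatch (no direction was
    predicted). Sites with observed y = 0 must be excluded upstream.
    """
    if len(candidates) == 0:
        raise InputError("direction_accuracy: empty candidate set")
    s = np.sign(candidates[score_col].to_numpy())
    o = np.sign(candidates[observed_col].to_numpy())
    return float(np.mean((s == o) & (s != 0)))


def two_by_two_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) of [[a,b],[c,d]]."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stat), float(stats.chi2.sf(stat, df=1))


def compare_accuracies(acc_a: float, acc_b: float, n_a: int, n_b: int
                       ) -> tuple[float, float]:
    """Two-proportion chi-square test of matched/mismatched counts."""
    if n_a <= 0 or n_b <= 0:
        raise InputError("compare_accuracies needs positive group sizes")
    a = int(round(acc_a * n_a))
    c = int(round(acc_b * n_b))
    return two_by_two_chi2(a, n_a - a, c, n_b - c)
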