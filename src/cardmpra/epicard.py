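"""EpiCard: annotation-overlap features, LASSO activity models, variant
scoring over 200 bp windows and cohort burden statistics.

Each genomic window gets, per annotation track, the length of overlap in
bp and — for tracks carrying a quantitative value — the length-weighted
mean and the total (value x overlap bp) over overlapping intervals.  A
LASSO is trained on MPRA activity (continuous family, log activity) or on
active/inactive labels (binary family, L1-penalized logistic regression);
the final penalty is the cross-validated lambda divided by ten.  The
binary model's linear predictor, evaluated on the 200 bp window centered
on a variant, is the EpiCard score of that variant.  Cohort burden
combines a two-sided t-test on mean scores with a 2x2 enrichment above the
95th percentile of the control-cohort score distribution (sample odds
ratio and Fisher exact p), repeated on per-participant score maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression, LogisticRegressionCV

WINDOW_SIZE = 200
PERCENTILE_CUTOFF = 95.0
LAMBDA_SHRINK = 10.0   # final penalty = lambda_cv / 10
N_LAMBDA = 100


def build_features(windows: pd.DataFrame,
                   tracks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Overlap features for each window against each annotation track.

    ``windows``: frame with chrom, start, end and a ``window_id`` column
    (0-based half-open).  ``tracks``: track_id -> frame with chrom, start,
    end and optionally value.  Output columns per track: ``<id>__bp``
    (overlap length) and, when the track has values, ``<id>__mean``
    (length-weighted mean value over the overlap, 0 when disjoint) and
    ``<id>__total`` (sum of value x overlap bp).
    """
    cols: dict[str, np.ndarray] = {}
    w_chrom = windows["chrom"].to_numpy()
    w_start = windows["start"].to_numpy(float)
    w_end = windows["end"].to_numpy(float)
    for tid, tr in tracks.items():
        if len(tr) and (tr["end"] < tr["start"]).any():
            bad = tr.index[(tr["end"] < tr["start"])][0]
            raise ValueError(f"track {tid}: malformed interval at line {bad}")
        has_value = "value" in tr.columns
        by_chrom = {
            c: (g["start"].to_numpy(float), g["end"].to_numpy(float),
                g["value"].to_numpy(float) if has_value else None)
            for c, g in tr.groupby("chrom")
        } if len(tr) else {}
        bp = np.zeros(len(windows))
        total = np.zeros(len(windows))
        for i in range(len(windows)):
            arrs = by_chrom.get(w_chrom[i])
            if arrs is None:
                continue
            ts, te, tv = arrs
            ov = np.clip(np.minimum(te, w_end[i]) - np.maximum(ts, w_start[i]),
                         0, None)
            bp[i] = ov.sum()
            if has_value:
                total[i] = float((ov * tv).sum())
        cols[f"{tid}__bp"] = bp
        if has_value:
            with np.errstate(invalid="ignore"):
                mean = np.where(bp > 0, total / np.where(bp > 0, bp, 1.0), 0.0)
            cols[f"{tid}__mean"] = mean
            cols[f"{tid}__total"] = total
    return pd.DataFrame(cols, index=pd.Index(windows["window_id"], name="window_id"))


@dataclass
class EpiCardModel:
    """A fitted LASSO activity model."""

    family: str                         # 'continuous' or 'binary'
    feature_names: list[str]
    coefficients: list[float]           # on the original feature scale
    intercept: float
    penalty: float                      # final lambda (after /10)
    cv_penalty: float                   # lambda chosen by cross-validation
    folds: int = 5
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Linear predictor (link scale for the binary family)."""
        X = features.reindex(columns=self.feature_names, fill_value=0.0)
        return self.intercept + X.to_numpy(float) @ np.asarray(self.coefficients)

    @property
    def support(self) -> list[str]:
        return [n for n, c in zip(self.feature_names, self.coefficients) if c != 0.0]

    def to_json(self) -> str:
        return json.dumps({"schema": "epicard-model/1", **asdict(self)})

    @classmethod
    def from_json(cls, text: str) -> "EpiCardModel":
        d = json.loads(text)
        d.pop("schema", None)
        return cls(**d)


def train_lasso(features: pd.DataFrame, response: np.ndarray, family: str,
                folds: int = 5, seed: int = 0) -> EpiCardModel:
    """Cross-validated LASSO with the final penalty set to lambda_cv / 10.

    Features are z-scored internally; reported coefficients are rescaled to
    the original feature units.  ``continuous`` fits log activity by least
    squares; ``binary`` fits active/inactive labels by L1-penalized
    logistic regression.  A constant response yields an intercept-only
    model with a warning.
    """
    X = features.to_numpy(float)
    y = np.asarray(response, float)
    if len(y) < 2 * folds:
        raise ValueError("need at least 2 samples per CV fold")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    names = list(features.columns)
    if np.allclose(y, y[0]):
        warnings.warn("constant response; returning intercept-only model")
        return EpiCardModel(family=family, feature_names=names,
                            coefficients=[0.0] * len(names),
                            intercept=float(y[0]) if family == "continuous" else 0.0,
                            penalty=np.inf, cv_penalty=np.inf, folds=folds, seed=seed)
    rng = np.random.RandomState(seed)
    if family == "continuous":
        cv = LassoCV(alphas=N_LAMBDA, cv=folds, random_state=rng, max_iter=50_000)
        cv.fit(Xs, y)
        lam = cv.alpha_ / LAMBDA_SHRINK
        fit = Lasso(alpha=lam, max_iter=200_000).fit(Xs, y)
        coef_std, intercept = fit.coef_, fit.intercept_
        cv_lam = cv.alpha_
    elif family == "binary":
        Cs = np.logspace(-4, 4, N_LAMBDA)
        cv = LogisticRegressionCV(Cs=Cs, cv=folds, l1_ratios=[1.0],
                                  solver="liblinear", scoring="neg_log_loss",
                                  random_state=rng, max_iter=10_000)
        cv.fit(Xs, y)
        c_cv = float(cv.C_[0])
        # lambda = 1/C, so lambda/10 corresponds to C * 10
        fit = LogisticRegression(C=c_cv * LAMBDA_SHRINK, l1_ratio=1.0,
                                 solver="liblinear", max_iter=10_000).fit(Xs, y)
        coef_std, intercept = fit.coef_[0], float(fit.intercept_[0])
        lam, cv_lam = 1.0 / (c_cv * LAMBDA_SHRINK), 1.0 / c_cv
    else:
        raise ValueError("family must be 'continuous' or 'binary'")
    coef = coef_std / sd
    intercept = float(intercept - (coef * mu).sum())
    return EpiCardModel(family=family, feature_names=names,
                        coefficients=[float(c) for c in coef],
                        intercept=intercept, penalty=float(lam),
                        cv_penalty=float(cv_lam), folds=folds, seed=seed)


def variant_windows(variants: pd.DataFrame, window: int = WINDOW_SIZE,
                    chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """200 bp windows centered on each variant (1-based pos in input).

    Variants whose window would leave the chromosome are skipped.
    """
    half = window // 2
    rows, skipped = [], 0
    for i, v in variants.reset_index(drop=True).iterrows():
        start = int(v["pos"]) - 1 - half
        end = start + window
        if start < 0 or (chrom_sizes is not None
                         and end > chrom_sizes.get(v["chrom"], np.inf)):
            skipped += 1
            continue
        rows.append((v["chrom"], start, end, f"var_{i:06d}",
                     v.get("participant_id", ""), v.get("cohort", "")))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "window_id",
                                      "participant_id", "cohort"])
    out.attrs["n_skipped"] = skipped
    return out


def epicard_score(model: EpiCardModel, variants: pd.DataFrame,
                  tracks: dict[str, pd.DataFrame],
                  chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """EpiCard scores for variants: binary-model linear predictor on the
    200 bp window centered on each variant."""
    if model.family != "binary":
        raise ValueError("EpiCard scoring requires the binary model")
    win = variant_windows(variants, chrom_sizes=chrom_sizes)
    feats = build_features(win, tracks)
    win = win.set_index("window_id")
    win["score"] = model.predict(feats)
    return win.reset_index()


def sample_odds_ratio(a: float, n1: float, b: float, n2: float) -> float:
    """Sample OR of a/n1 vs b/n2 (ad/bc on the implied 2x2 table)."""
    c, d = n1 - a, n2 - b
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


@dataclass
class BurdenResult:
    mean_case: float
    mean_control: float
    t_p: float
    cutoff: float
    n_above_case: int
    n_case: int
    n_above_control: int
    n_control: int
    or_value: float
    fisher_p: float
    per_participant: "BurdenResult | None" = None


def burden_tests(case_scores: pd.DataFrame, control_scores: pd.DataFrame,
                 percentile: float = PERCENTILE_CUTOFF) -> BurdenResult:
    """Cohort burden statistics on variant score tables.

    Inputs carry ``score`` and ``participant_id`` columns.  The cutoff is
    the ``percentile`` (default 95th) of the control-cohort scores with
    linear interpolation.  The per-participant analysis repeats the 2x2
    test on each participant's maximum score.
    """
    for name, df in (("case", case_scores), ("control", control_scores)):
        if len(df) < 2:
            raise ValueError(f"{name} cohort has fewer than two scores")
    cs = case_scores["score"].to_numpy(float)
    ks = control_scores["score"].to_numpy(float)
    t_p = float(stats.ttest_ind(cs, ks).pvalue)
    cutoff = float(np.percentile(ks, percentile))

    def table(c, k):
        a, b = int((c > cutoff).sum()), int((k > cutoff).sum())
        n1, n2 = len(c), len(k)
        orv = sample_odds_ratio(a, n1, b, n2)
        fp = float(stats.fisher_exact([[a, n1 - a], [b, n2 - b]]).pvalue)
        return a, n1, b, n2, orv, fp

    a, n1, b, n2, orv, fp = table(cs, ks)
    res = BurdenResult(mean_case=float(cs.mean()), mean_control=float(ks.mean()),
                       t_p=t_p, cutoff=cutoff, n_above_case=a, n_case=n1,
                       n_above_control=b, n_control=n2, or_value=orv, fisher_p=fp)
    cmax = case_scores.groupby("participant_id")["score"].max().to_numpy()
    kmax = control_scores.groupby("participant_id")["score"].max().to_numpy()
    if len(cmax) >= 2 and len(kmax) >= 2:
        a, n1, b, n2, orv, fp = table(cmax, kmax)
        res.per_participant = BurdenResult(
            mean_case=float(cmax.mean()), mean_control=float(kmax.mean()),
            t_p=float(stats.ttest_ind(cmax, kmax).pvalue), cutoff=cutoff,
            n_above_case=a, n_case=n1, n_above_control=b, n_control=n2,
            or_value=orv, fisher_p=fp)
    return res


def univariate_correlations(columns: pd.DataFrame,
                            activity: np.ndarray) -> pd.DataFrame:
    """Pearson r and two-sided p of each column against activity."""
    y = np.asarray(activity, float)
    if len(y) < 3:
        raise ValueError("need at least three paired observations")
    rows = []
    for name in columns.columns:
        x = columns[name].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((name, np.nan, np.nan, True))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((name, float(r), float(p), False))
    return pd.DataFrame(rows, columns=["feature", "r", "p", "degenerate"])
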