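"""Longitudinal medication-response analysis.

Symptom scores are tracked at baseline and weeks 1, 2, 3, 4 and 8 under
one of two medication arms (MPH or ATX). The reduction rate at week t is
(baseline - score_t) / baseline, optionally residualized on the baseline
score cross-sectionally at each week. Biotype and medication effects are
assessed with linear mixed-effects models:

* reduction ~ week * biotype, subject random intercept and slope;
* score ~ week * biotype + med * biotype + week * med, subject random
  intercept and slope;

with per-term F tests at alpha = 0.05. Estimation is delegated to
statsmodels MixedLM; the term-wise F statistic is the Wald chi-square of
the term's fixed-effect block divided by its numerator degrees of freedom,
referred to an F distribution with containment-style denominator degrees
of freedom (observations minus subjects minus fixed-effect rank). The
type-I-error simulation in the test suite checks this approximation's
calibration at the study's sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .exceptions import ConfigurationError, DataShapeError, UndefinedReductionError

ALPHA = 0.05


@dataclass(frozen=True)
class LMESpec:
    """Mixed-model specification for one response."""

    response: str = "adjusted_reduction"
    fixed: str = "week * biotype"
    random_slope: bool = True
    groups: str = "id"

    def formula(self) -> str:
        return f"{self.response} ~ {self.fixed}"


def compute_reduction(records: pd.DataFrame, adjust: str = "residualize") -> pd.DataFrame:
    """Add ``reduction_rate`` and ``adjusted_reduction`` columns.

    reduction_rate(t) = (baseline - score_t) / baseline per id x scale,
    so week 0 always yields 0 and the rate is invariant to rescaling all
    scores. ``adjusted_reduction`` residualizes the rate on the baseline
    score across subjects, cross-sectionally at each week (``adjust=
    "residualize"``); with ``adjust="none"`` it equals the raw rate and the
    baseline belongs in the downstream model instead.
    """
    df = records.copy()
    required = {"id", "week", "scale", "score"}
    if not required.issubset(df.columns):
        raise DataShapeError(f"records must have columns {sorted(required)}")
    base = df[df["week"] == 0].set_index(["id", "scale"])["score"]
    if base.index.has_duplicates:
        raise DataShapeError("multiple baseline rows for an id x scale pair")
    missing = set(map(tuple, df[["id", "scale"]].drop_duplicates().values)) - set(base.index)
    if missing:
        raise DataShapeError(f"missing baseline (week 0) for {sorted(missing)[:5]}")
    if (base <= 0).any():
        bad = base[base <= 0].index[0]
        raise UndefinedReductionError(f"baseline is 0 for id x scale {bad}")
    df["baseline"] = base.reindex(pd.MultiIndex.from_frame(df[["id", "scale"]])).to_numpy()
    df["reduction_rate"] = (df["baseline"] - df["score"]) / df["baseline"]

    if adjust == "none":
        df["adjusted_reduction"] = df["reduction_rate"]
        return df
    if adjust != "residualize":
        raise ConfigurationError("adjust must be 'residualize' or 'none'")
    df["adjusted_reduction"] = np.nan
    for (scale, week), sub in df.groupby(["scale", "week"]):
        y = sub["reduction_rate"].to_numpy(dtype=float)
        b = sub["baseline"].to_numpy(dtype=float)
        design = np.column_stack([np.ones_like(b), b])
        if np.linalg.matrix_rank(design) < 2:  # identical baselines: center only
            resid = y - y.mean()
        else:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            resid = y - design @ beta
        df.loc[sub.index, "adjusted_reduction"] = resid
    return df


def _term_blocks(design_info):
    """Map term name -> column indices in the fixed-effects design."""
    return {
        term.name(): list(range(*design_info.term_slices[term].indices(len(design_info.column_names))))
        for term in design_info.terms
        if term.name() != "Intercept"
    }


def fit_interaction_model(records: pd.DataFrame, spec: LMESpec) -> pd.DataFrame:
    """Per-term F statistics and p-values from the mixed model.

    Returns a tidy table (term, F, df_num, df_den, p, significant). On a
    singular fit with a random slope, falls back to a random-intercept-only
    model and records this in the ``fallback`` column.
    """
    df = records.copy()
    for col in ("id", spec.response):
        if col not in df.columns:
            raise DataShapeError(f"records missing column {col!r}")
    if df.groupby("id").size().min() < 2:
        raise DataShapeError("every subject needs at least 2 observations")
    if df["id"].nunique() < 2:
        raise DataShapeError("grouping factor needs at least 2 levels")
    for col in ("biotype", "med"):
        if col in df.columns:
            df[col] = df[col].astype("category")

    fallback = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(
                spec.formula(), df, groups=df[spec.groups],
                re_formula="~week" if spec.random_slope else "~1",
            )
            res = model.fit(reml=True)
            if not np.all(np.isfinite(res.bse_fe)):
                raise np.linalg.LinAlgError("non-finite fixed-effect SEs")
        except Exception:
            if not spec.random_slope:
                raise
            fallback = True
            model = smf.mixedlm(spec.formula(), df, groups=df[spec.groups], re_formula="~1")
            res = model.fit(reml=True)

    design_info = model.data.design_info
    k_fe = model.k_fe
    n_obs = model.nobs
    n_groups = df[spec.groups].nunique()
    df_den = max(int(n_obs - n_groups - k_fe + 1), 1)

    params = res.fe_params.to_numpy()
    cov = res.cov_params().to_numpy()[:k_fe, :k_fe]
    rows = []
    for term, cols in _term_blocks(design_info).items():
        c = np.asarray(cols)
        block = params[c]
        vcv = cov[np.ix_(c, c)]
        chi2 = float(block @ np.linalg.solve(vcv, block))
        df_num = len(cols)
        f = chi2 / df_num
        p = float(sps.f.sf(f, df_num, df_den))
        rows.append(
            {
                "term": term,
                "F": f,
                "df_num": df_num,
                "df_den": df_den,
                "p": p,
                "significant": p < ALPHA,
                "fallback": fallback,
            }
        )
    return pd.DataFrame(rows)


def week_by_biotype_test(records: pd.DataFrame, response: str = "adjusted_reduction") -> pd.DataFrame:
    """The first analysis stage: response ~ week * biotype with random
    intercept and slope, on post-baseline weeks."""
    post = records[records["week"] > 0]
    return fit_interaction_model(post, LMESpec(response=response, fixed="week * biotype"))


def biotype_by_medication_test(records: pd.DataFrame, response: str = "score") -> pd.DataFrame:
    """The second stage: score ~ week*biotype + med*biotype + week*med with
    a subject-specific random intercept and slope."""
    spec = LMESpec(
        response=response,
        fixed="week * biotype + med * biotype + week * med",
    )
    return fit_interaction_model(records, spec)
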