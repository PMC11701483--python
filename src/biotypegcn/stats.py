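"""Cross-cohort biotype validation and characterization.

Biotype templates (per-biotype mean FNC vectors) learned on a discovery
cohort are projected onto an independent cohort by nearest Euclidean
distance; the most discriminative connections are extracted by
covariate-adjusted two-sample t-tests, grouped into the 7 functional
networks, and compared across cohorts; group differences on clinical
measures use covariate-adjusted t-tests with Benjamini-Hochberg FDR
correction and Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    CollinearityError,
    DataShapeError,
    PartitionError,
    ProjectionError,
    UndefinedCorrelationError,
    UndefinedEffectError,
)
from .fnc import NetworkPartition, edge_index, regress_covariates


@dataclass
class FNCTemplate:
    """Per-biotype mean FNC vector from a source cohort."""

    biotype_id: int
    mean_fnc: np.ndarray
    source_cohort: str = ""
    n_members: int = 1

    def __post_init__(self):
        if self.n_members < 1:
            raise DataShapeError("template needs at least one member")


@dataclass
class StatResult:
    """One test: t statistic, raw/adjusted p, effect size, optional r."""

    measure: str
    t: float
    p: float
    p_fdr: float | None = None
    cohens_d: float | None = None
    r: float | None = None


def project_to_templates(fnc: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Assign subjects to the biotype of the nearest template (Euclidean).

    ``templates`` is a (K, d) stack ordered by biotype; ties resolve to the
    lower biotype number. Returns 1-based labels.
    """
    f = np.atleast_2d(np.asarray(fnc, dtype=float))
    t = np.asarray(templates, dtype=float)
    if f.shape[1] != t.shape[1]:
        raise ProjectionError(
            f"subject dimension {f.shape[1]} != template dimension {t.shape[1]}"
        )
    d2 = ((f[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (lowest) index on ties -> biotype 1 wins
    return d2.argmin(axis=1) + 1


def _group_t_all_edges(values: np.ndarray, group: np.ndarray, covariates: np.ndarray | None):
    """Vectorized OLS t statistic of the group indicator for every column."""
    n = values.shape[0]
    cols = [np.ones(n), group.astype(float)]
    if covariates is not None:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
        cols.extend(z.T)
    design = np.column_stack(cols)
    q = design.shape[1]
    if np.linalg.matrix_rank(design) < q:
        raise CollinearityError("rank-deficient design in adjusted t-test")
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ values
    resid = values - design @ beta
    dof = n - q
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    t = beta[1] / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return t, p, dof


def adjusted_two_sample_t(
    values: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    measure: str = "",
) -> StatResult:
    """Two-sample t-test via least squares on a group indicator.

    With no covariates this is exactly the classical pooled-variance
    two-sample t-test; covariate columns (age, gender, ...) are partialled
    out through the same linear model.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise DataShapeError("groups must have exactly 2 levels")
    if min((groups == g).sum() for g in levels) < 2:
        raise DataShapeError("both groups need at least 2 observations")
    indicator = (groups == levels[0]).astype(float)
    t, p, _ = _group_t_all_edges(values[:, None], indicator, covariates)
    d = None
    try:
        d = cohens_d(values, groups)
    except UndefinedEffectError:
        pass
    return StatResult(measure=measure, t=float(t[0]), p=float(p[0]), cohens_d=d)


def cohens_d(values: np.ndarray, groups: np.ndarray) -> float:
    """Standardized mean difference with df-weighted pooled SD."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise DataShapeError("groups must have exactly 2 levels")
    a, b = values[groups == levels[0]], values[groups == levels[1]]
    if a.size < 2 or b.size < 2:
        raise DataShapeError("both groups need at least 2 observations")
    pooled = np.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    if pooled == 0:
        raise UndefinedEffectError("zero pooled standard deviation")
    return float((a.mean() - b.mean()) / pooled)


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataShapeError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def top_discriminative_fnc(
    fnc: np.ndarray,
    groups: np.ndarray,
    covariates: np.ndarray | None = None,
    k: int = 100,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Edges ranked by |t| of a covariate-adjusted two-group contrast.

    ``groups`` is a binary indicator (biotype members vs the reference
    group — the complementary biotype or healthy controls, per analysis
    mode). Returns the top-k edges with their statistics; if k exceeds the
    edge count the full ranking is returned with a warning.
    """
    fnc = np.asarray(fnc, dtype=float)
    groups = np.asarray(groups)
    d = fnc.shape[1]
    if min((groups == g).sum() for g in np.unique(groups)) < 3:
        raise DataShapeError("both groups need at least 3 subjects")
    if k > d:
        warnings.warn(f"k={k} exceeds {d} edges; returning all edges")
        k = d
    # t is signed as (case group = higher label) minus reference
    indicator = (groups == np.unique(groups)[-1]).astype(float)
    t, p, _ = _group_t_all_edges(fnc, indicator, covariates)
    if n_components is None:
        n_components = int(round((1 + np.sqrt(1 + 8 * d)) / 2))
    pairs = edge_index(n_components)
    if len(pairs) != d:  # feature columns are not a full upper triangle
        pairs = [(-1, -1)] * d
    table = pd.DataFrame(
        {
            "edge": np.arange(d),
            "comp_i": [i for i, _ in pairs],
            "comp_j": [j for _, j in pairs],
            "t": t,
            "p": p,
        }
    )
    table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    table = table.reindex(table["t"].abs().sort_values(ascending=False).index)
    return table.head(k).reset_index(drop=True)


def network_contribution(
    edges, partition: NetworkPartition, n_components: int | None = None
) -> pd.DataFrame:
    """Count top edges per unordered network pair.

    ``edges`` is a sequence of (comp_i, comp_j) pairs or canonical edge
    indices. Returns a symmetric networks-by-networks count matrix whose
    upper triangle plus diagonal sums to the number of edges supplied.
    """
    labels = list(partition.labels)
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    if n_components is None:
        n_components = partition.n_components
    pairs = edge_index(n_components)
    for e in edges:
        i, j = pairs[int(e)] if np.isscalar(e) or isinstance(e, (int, np.integer)) else e
        a, b = partition.network_of(int(i)), partition.network_of(int(j))
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    return counts


def _contribution_vector(contrib: pd.DataFrame) -> np.ndarray:
    m = contrib.to_numpy(dtype=float)
    iu = np.triu_indices(m.shape[0])
    return m[iu]


def cross_cohort_consistency(
    contrib_a: pd.DataFrame,
    contrib_b: pd.DataFrame,
    template_diff_a: np.ndarray | None = None,
    template_diff_b: np.ndarray | None = None,
) -> dict:
    """Pearson correlations between cohorts' network contributions and,
    optionally, their whole-FNC biotype-minus-reference difference vectors."""
    va, vb = _contribution_vector(contrib_a), _contribution_vector(contrib_b)
    if va.std() == 0 or vb.std() == 0:
        raise UndefinedCorrelationError("zero-variance contribution vector")
    r, p = sps.pearsonr(va, vb)
    out = {"contribution_r": float(r), "contribution_p": float(p)}
    if template_diff_a is not None and template_diff_b is not None:
        da = np.asarray(template_diff_a, dtype=float)
        db = np.asarray(template_diff_b, dtype=float)
        if da.std() == 0 or db.std() == 0:
            raise UndefinedCorrelationError("zero-variance difference vector")
        r2, p2 = sps.pearsonr(da, db)
        out["fnc_diff_r"] = float(r2)
        out["fnc_diff_p"] = float(p2)
    return out


def overlap_top_sets(set_a, set_b) -> list[int]:
    """Intersection of two top-edge sets, ordered by canonical edge index."""
    return sorted(set(int(e) for e in set_a) & set(int(e) for e in set_b))


def fnc_scale_correlations(
    fnc_subset: np.ndarray,
    scales: pd.DataFrame | np.ndarray,
    edge_names: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r and p per (edge, scale) pair, FDR-adjusted within the table.

    Constant columns yield NaN for their pairs (flagged, not fatal).
    """
    f = np.atleast_2d(np.asarray(fnc_subset, dtype=float))
    if isinstance(scales, pd.DataFrame):
        scale_names = list(scales.columns)
        s = scales.to_numpy(dtype=float)
    else:
        s = np.atleast_2d(np.asarray(scales, dtype=float))
        scale_names = [f"scale{j}" for j in range(s.shape[1])]
    if f.shape[0] < 4:
        raise DataShapeError("need at least 4 paired observations")
    if edge_names is None:
        edge_names = [f"edge{j}" for j in range(f.shape[1])]
    rows = []
    for ei in range(f.shape[1]):
        for sj in range(s.shape[1]):
            x, y = f[:, ei], s[:, sj]
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 4 or x[ok].std() == 0 or y[ok].std() == 0:
                rows.append({"edge": edge_names[ei], "scale": scale_names[sj],
                             "r": np.nan, "p": np.nan, "constant": True})
                continue
            r, p = sps.pearsonr(x[ok], y[ok])
            rows.append({"edge": edge_names[ei], "scale": scale_names[sj],
                         "r": float(r), "p": float(p), "constant": False})
    table = pd.DataFrame(rows)
    valid = table["p"].notna()
    table["p_fdr"] = np.nan
    if valid.any():
        table.loc[valid, "p_fdr"] = fdr_adjust(table.loc[valid, "p"].to_numpy())
    return table
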