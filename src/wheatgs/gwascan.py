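"""Kinship + principal-component mixed-linear-model association scan.

The scan exists to pick marker subsets on training data only, so that the
markers fed to the genomic prediction model were never chosen using the
validation lines ("inside trading").  The null model

    y = intercept + PCs (fixed) + polygenic u, u ~ N(0, K s2_u), + e

is fitted once by REML; every marker is then tested by generalized least
squares with the null variance structure held fixed (the classical
two-stage approximation to per-marker REML).  On the rotated, whitened data
the per-marker test is an ordinary 1-df regression F-test, which makes the
scan collapse exactly onto simple linear regression when ``K = I`` and no
PCs are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomat import GenotypeMatrix, RelationshipMatrix, pca_scores
from .mixedcore import solve_mixed

__all__ = ["MarkerScan", "MarkerSubset", "scan_markers", "select_subset", "random_subset"]

_MAF_FLOOR = 0.05  # markers rarer than this in the training lines are not tested


@dataclass
class MarkerScan:
    """Per-marker effect, SE, test statistic and p-value from the MLM scan."""

    table: pd.DataFrame  # columns: marker, effect, se, stat, p, tested
    n_pc: int = 3

    def __post_init__(self) -> None:
        p = self.table.loc[self.table["tested"], "p"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")


@dataclass
class MarkerSubset:
    label: str
    markers: list[str]
    source: str = ""
    seed: int | None = None
    meta: dict = field(default_factory=dict)


def scan_markers(
    g_train: GenotypeMatrix,
    y_train: pd.Series | np.ndarray,
    K: RelationshipMatrix | np.ndarray | None = None,
    n_pc: int = 3,
    maf_floor: float = _MAF_FLOOR,
) -> MarkerScan:
    """MLM association scan of every marker against the training phenotype.

    ``K`` defaults to the identity (no polygenic correction).  Markers with
    training-set MAF below ``maf_floor`` (monomorphic ones in particular)
    are skipped and flagged ``tested=False`` rather than given p = 1.
    """
    if g_train.missing_mask.any():
        raise ValueError("scan_markers requires imputed genotypes")
    if isinstance(y_train, pd.Series):
        y = y_train.reindex(g_train.line_ids).to_numpy(float)
    else:
        y = np.asarray(y_train, float).ravel()
    n = g_train.n_lines
    if y.size != n:
        raise ValueError("one phenotype per training line required")

    X = np.ones((n, 1))
    if n_pc > 0:
        X = np.column_stack([X, pca_scores(g_train, n_pc)])

    if K is None:
        k_mat = np.eye(n)
    elif isinstance(K, RelationshipMatrix):
        if K.line_ids != g_train.line_ids:
            raise ValueError("K lines do not match the training genotypes")
        k_mat = K.values
    else:
        k_mat = np.asarray(K, float)

    null_fit = solve_mixed(y, X, np.eye(n), K=k_mat)
    lam = null_fit.lam

    # whiten by V^{-1/2} with V proportional to K + lam I (null components fixed)
    d, u = np.linalg.eigh((k_mat + k_mat.T) / 2.0)
    d = np.maximum(d, 0.0)
    w = 1.0 / np.sqrt(d + lam)
    yt = w * (u.T @ y)
    Xt = w[:, None] * (u.T @ X)
    Gt = w[:, None] * (u.T @ g_train.values)

    # project phenotype and markers off the null fixed effects (FWL)
    q, _ = np.linalg.qr(Xt)
    ry = yt - q @ (q.T @ yt)
    rG = Gt - q @ (q.T @ Gt)

    p0 = X.shape[1]
    df = n - p0 - 1
    if df < 1:
        raise ValueError("not enough lines for the per-marker test")

    sxx = np.einsum("ij,ij->j", rG, rG)
    sxy = ry @ rG
    syy = float(ry @ ry)
    maf = g_train.maf()
    tested = maf >= maf_floor
    tested &= sxx > 1e-12 * max(1.0, syy)

    effect = np.full(g_train.n_markers, np.nan)
    se = np.full(g_train.n_markers, np.nan)
    fstat = np.full(g_train.n_markers, np.nan)
    pval = np.full(g_train.n_markers, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = sxy / sxx
        rss = syy - sxy**2 / sxx
        s2 = rss / df
        se_all = np.sqrt(s2 / sxx)
        f_all = np.where(s2 > 0, b**2 * sxx / s2, np.inf)
    effect[tested] = b[tested]
    se[tested] = se_all[tested]
    fstat[tested] = f_all[tested]
    pval[tested] = stats.f.sf(f_all[tested], 1, df)
    pval[tested] = np.clip(pval[tested], np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "marker": g_train.marker_ids,
            "effect": effect,
            "se": se,
            "stat": fstat,
            "p": pval,
            "tested": tested,
        }
    )
    if g_train.genetic_map is not None:
        table.insert(1, "chrom", g_train.genetic_map["chrom"].to_numpy())
        table.insert(2, "position_cM", g_train.genetic_map["position_cM"].to_numpy())
    return MarkerScan(table=table, n_pc=n_pc)


def select_subset(scan: MarkerScan, alpha: float, label: str | None = None) -> MarkerSubset:
    """Markers with raw p < alpha, in stable scan order (no multiplicity correction).

    An empty result is returned as an empty subset so callers can fall back
    to the whole-genome marker set explicitly.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    t = scan.table
    chosen = t.loc[t["tested"] & (t["p"] < alpha), "marker"].tolist()
    return MarkerSubset(
        label=label or f"SS_{alpha:g}",
        markers=chosen,
        meta={"alpha": alpha, "n": len(chosen)},
    )


def random_subset(g: GenotypeMatrix, size: int, seed: int = 0) -> MarkerSubset:
    """Uniform random marker sample without replacement (seeded)."""
    if size > g.n_markers:
        raise ValueError("subset size exceeds marker count")
    rng = np.random.default_rng(seed)
    idx = rng.choice(g.n_markers, size=size, replace=False)
    return MarkerSubset(
        label=f"random_{size}",
        markers=[g.marker_ids[i] for i in idx],
        seed=seed,
        meta={"n": size},
    )
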