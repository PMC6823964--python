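"""Multi-environment phenotype analysis: variance components, entry BLUPs, H2.

The plot model is

    Y_ijk = mu + Env_i + Entry_j + Entry_j x Env_i + Block_k(Env_i) + e_ijk

with environments fixed and entry, entry-by-environment and block-within-
environment random.  For the balanced designs produced by the synthetic
generator the restricted likelihood factorizes over orthogonal ANOVA strata
(entries; entry x env; blocks within env; residual), each contributing
``-0.5 (df log(lam) + SS / lam)`` with ``lam`` a known linear combination of
the variance components.  REML therefore reduces to a small bounded
optimization over the four non-negative components; interior solutions
coincide with the classical ANOVA estimators, and negative ANOVA solutions
are handled by the non-negativity constraint (reported as 0 with a flag).

Broad-sense heritability is on the entry-mean basis:

    H2 = s2_G / (s2_G + s2_GxE / e + s2_E / (e r))

with ``e`` environments and ``r`` replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VarianceComponents",
    "HeritabilityEstimate",
    "validate_phenotypes",
    "fit_env_model",
    "heritability",
]


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_GEI: float
    sigma2_block: float
    sigma2_E: float
    loglik: float
    at_boundary: bool  # any component pinned at zero


@dataclass
class HeritabilityEstimate:
    sigma2_G: float
    sigma2_GEI: float
    sigma2_E: float
    e: int
    r: int
    H2: float


def validate_phenotypes(data: pd.DataFrame) -> pd.DataFrame:
    required = {"entry", "env", "rep", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    if data.duplicated(subset=[c for c in ("entry", "env", "block", "rep", "trait") if c in data.columns]).any():
        raise ValueError("duplicate (entry, env, block, rep, trait) keys")
    if not np.isfinite(data["value"].to_numpy(float)).all():
        raise ValueError("non-finite trait values")
    return data


def _strata(data: pd.DataFrame) -> tuple[list[tuple[float, int, np.ndarray]], int, int, int]:
    """Balanced ANOVA strata: list of (SS, df, coefficient-vector) per stratum.

    The coefficient vector gives the stratum expected mean square as a linear
    combination of (s2_G, s2_GxE, s2_block, s2_E).
    """
    wide = data.pivot_table(index="entry", columns=["env", "rep"], values="value")
    if wide.isna().any().any():
        raise ValueError("design must be balanced: every entry in every env x rep cell")
    g = wide.shape[0]
    envs = wide.columns.get_level_values(0).unique()
    e = len(envs)
    r = wide.columns.get_level_values(1).nunique()
    if g < 2:
        raise ValueError("need at least 2 entries")

    y = wide.to_numpy(float).reshape(g, e, r)
    grand = y.mean()
    m_ge = y.mean(axis=2)          # entry x env means
    m_g = m_ge.mean(axis=1)        # entry means
    m_e = m_ge.mean(axis=0)        # env means
    m_er = y.mean(axis=0)          # env x rep (block) means

    ss_g = e * r * float(np.sum((m_g - grand) ** 2))
    ss_ge = r * float(np.sum((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2))
    ss_b = g * float(np.sum((m_er - m_e[:, None]) ** 2))
    resid = y - m_ge[:, :, None] - m_er[None, :, :] + m_e[None, :, None]
    ss_res = float(np.sum(resid**2))

    strata = [(ss_g, g - 1, np.array([e * r, r, 0.0, 1.0]))]
    if e > 1:
        strata.append((ss_ge, (g - 1) * (e - 1), np.array([0.0, r, 0.0, 1.0])))
    if r > 1:
        strata.append((ss_b, e * (r - 1), np.array([0.0, 0.0, g, 1.0])))
        strata.append((ss_res, e * (g - 1) * (r - 1), np.array([0.0, 0.0, 0.0, 1.0])))
    return strata, g, e, r


def restricted_loglik(components: np.ndarray, strata: list[tuple[float, int, np.ndarray]]) -> float:
    """Restricted log-likelihood (up to constant) at the given components."""
    total = 0.0
    for ss, df, coef in strata:
        lam = float(coef @ components)
        if lam <= 0.0:
            return -np.inf
        total += -0.5 * (df * np.log(lam) + ss / lam)
    return total


def fit_env_model(
    data: pd.DataFrame, grouping: list[str] | None = None
) -> tuple[VarianceComponents, pd.Series]:
    """REML variance components and entry BLUPs for an environment grouping.

    ``grouping`` restricts the table to a subset of environments (the
    site-year groupings behind the ALL / by-year / by-region BLUP datasets);
    ``None`` uses every environment present.  With a single environment the
    genotype-by-environment component is not estimable and is fixed at 0
    with a warning; with one replicate the residual is likewise confounded
    and fixed at 0.

    Entry BLUPs are the grand mean plus the shrunken entry deviations
    ``w (mean_j - grand)`` with ``w = s2_G / (s2_G + s2_GxE/e + s2_E/(e r))``
    (+ block variance averaging out in the balanced design).
    """
    data = validate_phenotypes(data)
    if grouping is not None:
        data = data[data["env"].isin(grouping)]
        if data.empty:
            raise ValueError(f"no observations for environments {grouping}")
    strata, g, e, r = _strata(data)
    if e < 2:
        warnings.warn("single environment: sigma2_GEI fixed at 0")
    if r < 2:
        warnings.warn("single replicate: sigma2_E confounded with GxE, fixed at 0")

    # start from ANOVA estimators (solve E[MS] = MS), clipped to >= 0
    ms = np.array([ss / df for ss, df, _ in strata])
    coefs = np.stack([c for _, _, c in strata])
    # components estimable in this design (GxE needs e>1; block/residual need r>1)
    active = [0] + ([1] if e > 1 else []) + ([2, 3] if r > 1 else [])
    start = np.zeros(4)
    sol, *_ = np.linalg.lstsq(coefs[:, active], ms, rcond=None)
    start[active] = np.maximum(sol, 0.0)
    scale = max(float(ms.mean()), 1e-12)

    def neg(x: np.ndarray) -> float:
        full = np.zeros(4)
        full[active] = x
        ll = restricted_loglik(full, strata)
        return 1e300 if not np.isfinite(ll) else -ll

    res = optimize.minimize(
        neg,
        np.maximum(start[active], 1e-8 * scale),
        method="L-BFGS-B",
        bounds=[(0.0, None)] * len(active),
    )
    comps = np.zeros(4)
    comps[active] = np.maximum(res.x, 0.0)
    s2g, s2ge, s2b, s2e = (float(v) for v in comps)
    vc = VarianceComponents(
        sigma2_G=s2g,
        sigma2_GEI=s2ge,
        sigma2_block=s2b,
        sigma2_E=s2e,
        loglik=-float(res.fun),
        at_boundary=bool(np.any(comps[active] <= 1e-10 * scale)),
    )

    wide = data.pivot_table(index="entry", values="value", aggfunc="mean")
    entry_means = wide["value"]
    grand = float(entry_means.mean())
    denom = s2g + s2ge / e + s2e / (e * r)
    w = s2g / denom if denom > 0 else 0.0
    blups = grand + w * (entry_means - grand)
    blups.name = "blup"
    return vc, blups


def heritability(vc: VarianceComponents | HeritabilityEstimate, e: int, r: int) -> HeritabilityEstimate:
    """Entry-mean broad-sense heritability H2 = s2_G/(s2_G + s2_GxE/e + s2_E/(e r))."""
    if e < 1 or r < 1:
        raise ValueError("e and r must be >= 1")
    s2g, s2ge, s2e = vc.sigma2_G, vc.sigma2_GEI, vc.sigma2_E
    if min(s2g, s2ge, s2e) < 0:
        raise ValueError("variance components must be non-negative")
    denom = s2g + s2ge / e + s2e / (e * r)
    if denom == 0.0:
        raise ValueError("heritability undefined: all variance components are zero")
    return HeritabilityEstimate(
        sigma2_G=s2g, sigma2_GEI=s2ge, sigma2_E=s2e, e=e, r=r, H2=s2g / denom
    )
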