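"""Genotype matrices: QC, EM imputation, kinship, PCA, and cross-panel comparison.

Genotypes are biallelic marker scores for inbred lines coded ``-1`` / ``+1``
for the two homozygous classes and ``0`` for (rare, residual) heterozygotes.
Missing calls are ``NaN``.  Per-haplotype allele doses used for frequency
arithmetic are ``(code + 1) / 2``, so a line contributes 0, 1 or 2 copies of
the ``+1`` allele.

The additive genomic relationship matrix follows the VanRaden construction
``K = W W' / c`` with ``W`` the column-centred score matrix and
``c = 2 * sum_j p_j (1 - p_j)`` over markers, frequencies estimated from the
sample itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "filter_markers",
    "impute_em",
    "additive_relationship",
    "pca_scores",
    "common_markers",
    "simple_matching",
    "read_genotypes",
    "read_vcf",
]


@dataclass
class GenotypeMatrix:
    """Lines x markers numeric genotype matrix with identifiers and optional map.

    Parameters
    ----------
    values
        Float array, shape ``(n_lines, n_markers)``; entries in ``{-1, 0, 1}``
        (or ``[-1, 1]`` after imputation), ``NaN`` for missing.
    line_ids, marker_ids
        Unique string identifiers for rows and columns.
    genetic_map
        Optional frame with columns ``marker``, ``chrom``, ``position_cM``
        aligned with ``marker_ids``.
    """

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]
    genetic_map: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.line_ids = [str(i) for i in self.line_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        n, m = self.values.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line IDs")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker IDs")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("genotype codes must lie in [-1, 1]")
        if self.genetic_map is not None:
            gm = self.genetic_map
            if list(gm["marker"].astype(str)) != self.marker_ids:
                raise ValueError("genetic map markers do not match marker_ids")

    # -- basic views ------------------------------------------------------

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def allele_freq(self) -> np.ndarray:
        """Per-marker frequency of the ``+1`` allele from observed calls."""
        dose = (self.values + 1.0) / 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(dose, axis=0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return self.missing_mask.mean(axis=0)

    # -- subsetting -------------------------------------------------------

    def take_lines(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.values[idx],
            [self.line_ids[i] for i in idx],
            list(self.marker_ids),
            self.genetic_map,
        )

    def take_markers(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        gm = None
        if self.genetic_map is not None:
            gm = self.genetic_map.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(
            self.values[:, idx],
            list(self.line_ids),
            [self.marker_ids[i] for i in idx],
            gm,
        )

    def select_markers(self, names: list[str]) -> "GenotypeMatrix":
        pos = {m: j for j, m in enumerate(self.marker_ids)}
        missing = [m for m in names if m not in pos]
        if missing:
            raise KeyError(f"unknown markers: {missing[:5]}")
        return self.take_markers([pos[m] for m in names])

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.marker_ids)

    def write(self, path: str | Path, map_path: str | Path | None = None) -> None:
        """Write tab-delimited numeric genotypes (rows=lines, header=marker IDs)."""
        df = self.to_frame()
        df.index.name = "line"
        df.to_csv(path, sep="\t", na_rep="NA")
        if map_path is not None and self.genetic_map is not None:
            self.genetic_map.to_csv(map_path, index=False)


def read_genotypes(path: str | Path, map_path: str | Path | None = None) -> GenotypeMatrix:
    """Read the tab-delimited numeric format written by :meth:`GenotypeMatrix.write`."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    gm = pd.read_csv(map_path) if map_path is not None else None
    return GenotypeMatrix(df.to_numpy(float), list(df.index), list(df.columns), gm)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Import biallelic sites from a VCF into the -1/0/1 coding.

    Heterozygous calls map to 0; multi-allelic sites are skipped with a
    warning; missing genotypes become NaN.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF import requires cyvcf2") from exc

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    cols: list[np.ndarray] = []
    ids: list[str] = []
    rows: list[tuple[str, str, float]] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        code = np.full_like(gts, np.nan)
        code[gts == 0] = -1.0
        code[gts == 1] = 0.0
        code[gts == 3] = 1.0
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        ids.append(mid)
        cols.append(code)
        rows.append((mid, str(var.CHROM), float(var.POS)))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multi-allelic site(s)")
    gm = pd.DataFrame(rows, columns=["marker", "chrom", "position_cM"])
    return GenotypeMatrix(np.column_stack(cols), lines, ids, gm)


@dataclass
class RelationshipMatrix:
    """Symmetric additive relationship (kinship) matrix over lines."""

    values: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.line_ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix must be square over line_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def is_psd(self, rtol: float = 1e-8) -> bool:
        """PSD up to tolerance: min eigenvalue > -rtol * trace / n."""
        w = np.linalg.eigvalsh(self.values)
        return w.min() > -rtol * np.trace(self.values) / len(self.line_ids)

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids).to_csv(path)


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.2
) -> GenotypeMatrix:
    """Drop markers with MAF below ``maf_min`` or missing rate above ``max_missing``.

    Marker order is preserved; the number of removals is logged.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError("max_missing must be in [0, 1]")
    keep = (g.maf() >= maf_min) & (g.missing_rate() <= max_missing)
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("no markers survive QC thresholds")
    logger.info("filter_markers: removed %d of %d markers", n_drop, g.n_markers)
    return g.take_markers(np.flatnonzero(keep))


def impute_em(
    g: GenotypeMatrix,
    tol: float = 1e-4,
    max_iter: int = 50,
    ridge: float = 1e-6,
) -> GenotypeMatrix:
    """Fill missing genotypes by an EM-style multivariate-normal imputation.

    Marker scores for each line are modelled as jointly Gaussian with a shared
    marker covariance.  Each iteration alternates (E) replacing every line's
    missing scores with their conditional expectation given that line's
    observed scores, and (M) re-estimating marker means and covariance from
    the completed matrix.  The covariance carries a small ridge on its
    diagonal so conditioning stays well-posed when markers far outnumber
    lines; the rank structure is exploited through the Woodbury identity so
    no markers-by-markers matrix is ever formed.

    Converges when the largest absolute change in an imputed value drops
    below ``tol``; emits a warning if ``max_iter`` is reached first.
    Observed entries are never modified; imputed values are clipped to
    ``[-1, 1]``.
    """
    miss = g.missing_mask
    if not miss.any():
        return g
    all_missing = np.flatnonzero(miss.all(axis=0))
    if all_missing.size:
        raise ValueError(
            f"marker(s) with no observed values: {[g.marker_ids[j] for j in all_missing[:5]]}"
        )

    x = g.values.copy()
    n = x.shape[0]
    col_mean = np.nanmean(g.values, axis=0)
    x[miss] = np.take(col_mean, np.where(miss)[1])  # start from column means

    for _ in range(max_iter):
        mu = x.mean(axis=0)
        u = (x - mu) / np.sqrt(n)  # covariance S = U'U + ridge*I, U is n x p ... rows!
        # Gram over lines: G_full[i, k] = sum_j u[i, j] u[k, j]
        gram = u @ u.T
        new_vals = x.copy()
        max_delta = 0.0
        for i in range(n):
            m_j = np.flatnonzero(miss[i])
            if m_j.size == 0:
                continue
            o_j = np.flatnonzero(~miss[i])
            if o_j.size == 0:
                new_vals[i, m_j] = mu[m_j]
                continue
            # Conditional mean under S = ridge*I + U'U restricted to observed cols:
            # S_mo S_oo^{-1} r with Woodbury on S_oo = ridge*I + U_o' U_o.
            u_m = u[:, m_j]  # n x |m|
            r = g.values[i, o_j] - mu[o_j]
            gram_o = gram - u_m @ u_m.T  # U_o U_o'
            # alpha = S_oo^{-1} r = (r - U_o'(ridge I + U_o U_o')^{-1} U_o r) / ridge
            u_o = u[:, o_j]
            uor = u_o @ r  # length n
            core = np.linalg.solve(gram_o + ridge * np.eye(n), uor)
            # S_mo alpha = U_m' U_o alpha ; U_o alpha = (uor - U_oU_o' core)/ridge
            uo_alpha = (uor - gram_o @ core) / ridge
            fill = mu[m_j] + u_m.T @ uo_alpha
            max_delta = max(max_delta, float(np.abs(fill - x[i, m_j]).max()))
            new_vals[i, m_j] = fill
        x = new_vals
        if max_delta < tol:
            break
    else:
        warnings.warn(f"impute_em did not converge within {max_iter} iterations")

    x[miss] = np.clip(x[miss], -1.0, 1.0)
    x[~miss] = g.values[~miss]
    return GenotypeMatrix(x, list(g.line_ids), list(g.marker_ids), g.genetic_map)


def additive_relationship(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden additive relationship matrix ``K = W W' / c`` from imputed genotypes.

    ``W`` is the column-centred score matrix and ``c = 2 sum_j p_j (1 - p_j)``
    with ``p_j`` the sample allele frequency.  Monomorphic markers contribute
    nothing (zero column of W, zero term in c).
    """
    if g.missing_mask.any():
        raise ValueError("additive_relationship requires a fully imputed matrix")
    p = g.allele_freq()
    c = 2.0 * float(np.sum(p * (1.0 - p)))
    if c <= 0.0:
        raise ValueError("all markers monomorphic: relationship matrix undefined")
    w = g.values - g.values.mean(axis=0)
    k = (w @ w.T) / c
    k = (k + k.T) / 2.0
    return RelationshipMatrix(k, list(g.line_ids))


def pca_scores(g: GenotypeMatrix, n_pc: int) -> np.ndarray:
    """Principal-component scores of the column-centred genotype matrix.

    Components are ordered by decreasing variance explained.  Signs are fixed
    by making each component's largest-magnitude marker loading positive, so
    scores are comparable across platforms and runs.
    """
    if n_pc <= 0:
        raise ValueError("n_pc must be positive")
    if n_pc >= min(g.n_lines, g.n_markers):
        raise ValueError("n_pc must be smaller than both dimensions")
    if g.missing_mask.any():
        raise ValueError("pca_scores requires a fully imputed matrix")
    w = g.values - g.values.mean(axis=0)
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s
    return scores[:, :n_pc] * flip[:n_pc]


def common_markers(
    g1: GenotypeMatrix, g2: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both matrices to their shared markers, identically ordered.

    Order follows the first matrix. Counts are logged; an empty intersection
    is an error.
    """
    in_two = set(g2.marker_ids)
    shared = [m for m in g1.marker_ids if m in in_two]
    if not shared:
        raise ValueError("no common markers between the two panels")
    logger.info(
        "common_markers: %d shared of %d / %d", len(shared), g1.n_markers, g2.n_markers
    )
    return g1.select_markers(shared), g2.select_markers(shared)


def simple_matching(g1: GenotypeMatrix, g2: GenotypeMatrix) -> tuple[float, pd.DataFrame]:
    """Simple matching coefficients between all cross-population line pairs.

    For each pair (line in ``g1``, line in ``g2``) the coefficient is the
    fraction of common markers with identical genotype codes (pairs with a
    missing call at a marker skip that marker).  Returns the mean over all
    pairs and the full pairwise matrix.
    """
    if g1.marker_ids != g2.marker_ids:
        raise ValueError("apply common_markers before simple_matching")
    if g1.n_markers == 0:
        raise ValueError("zero common markers")
    a, b = g1.values, g2.values
    n1, n2 = a.shape[0], b.shape[0]
    mat = np.empty((n1, n2))
    for i in range(n1):
        both = np.isfinite(a[i])[None, :] & np.isfinite(b)
        eq = (a[i][None, :] == b) & both
        with np.errstate(invalid="ignore"):
            mat[i] = eq.sum(axis=1) / both.sum(axis=1)
    frame = pd.DataFrame(mat, index=g1.line_ids, columns=g2.line_ids)
    return float(np.nanmean(mat)), frame
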