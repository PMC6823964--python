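"""Evaluation designs for genomic selection accuracy and response to selection.

Implements the cross-validation schemes of a genomic-selection accuracy
study on an inbred crop panel:

* GWAS -> GS cycles: repeated TP/VP splits where an association scan run on
  the training lines only picks the marker subsets used for prediction, so
  marker choice never sees the validation lines;
* a training-population-size sweep at constant validation size;
* directed cross-prediction between subpopulations;
* with/without major-gene fixed covariates under k-fold cross-validation;
* independent prediction of external (biparental) populations on the common
  marker set;
* the breeder's-equation comparison of five selection strategies
  (phenotypic, genomic, marker-based, random, phenotypic+genomic) with
  response R = H2 * S and S = mean(selected) - mean(population).

Every scheme records per-replicate accuracies so means and standard errors
are recomputable, and is bit-reproducible given its design and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomat import GenotypeMatrix, additive_relationship, common_markers, simple_matching
from .gwascan import random_subset, scan_markers, select_subset
from .mixedcore import accuracy, fit_rrblup, predict_gebv

__all__ = [
    "AccuracyReport",
    "SelectionOutcome",
    "run_gwas_gs_cycles",
    "run_tp_sweep",
    "run_subpop_cross",
    "run_fixed_effect_compare",
    "run_independent",
    "cv_mean_gebvs",
    "selection_response",
    "response_table",
    "response_from_means",
]


@dataclass
class AccuracyReport:
    """Per-replicate accuracies plus the design metadata that produced them."""

    table: pd.DataFrame
    design: dict = field(default_factory=dict)

    def summarize(self, by: list[str]) -> pd.DataFrame:
        grp = self.table.groupby(by)["accuracy"]
        out = grp.agg(mean="mean", sd="std", n="count").reset_index()
        out["se"] = out["sd"] / np.sqrt(out["n"])
        return out


@dataclass
class SelectionOutcome:
    """One selection strategy's outcome under the breeder's equation."""

    strategy: str
    selected: list[str]
    mu_sel: float
    mu_pop: float
    S: float
    R: float
    variance: float
    sd_sel: float
    pct_change_vs_PS: float | None = None
    meta: dict = field(default_factory=dict)


def _as_series(y, line_ids: list[str]) -> pd.Series:
    if isinstance(y, pd.Series):
        s = y.reindex(line_ids)
        if s.isna().any():
            raise ValueError("phenotypes missing for some lines")
        return s.astype(float)
    arr = np.asarray(y, float).ravel()
    if arr.size != len(line_ids):
        raise ValueError("phenotype length does not match line count")
    return pd.Series(arr, index=line_ids)


def _split(n: int, tp_size: int, vp_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    return perm[:tp_size], perm[tp_size : tp_size + vp_size]


def run_gwas_gs_cycles(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    alphas: tuple[float, ...] = (0.15, 0.10, 0.05),
    n_cycles: int = 10,
    tp_size: int = 219,
    vp_size: int = 20,
    seed: int = 0,
    n_pc: int = 3,
    random_baselines: bool = False,
) -> AccuracyReport:
    """GWAS-selected marker subsets vs whole-genome prediction, without inside trading.

    Each cycle draws a fresh TP/VP split, scans the markers on the TP alone
    (kinship + ``n_pc`` principal components), builds one subset per raw
    p-value threshold in ``alphas`` plus the whole-genome baseline, fits
    ridge BLUP on the TP with each marker set and scores Pearson accuracy on
    the VP.  An empty subset falls back to the whole genome for that cycle
    (recorded in the ``fallback`` column).  With ``random_baselines=True``,
    random marker sets matched in size to each threshold subset's per-cycle
    size are evaluated as well.
    """
    y = _as_series(y, g.line_ids)
    if tp_size + vp_size > g.n_lines:
        raise ValueError("tp_size + vp_size exceeds panel size")
    rng = np.random.default_rng(seed)
    rows = []
    for cycle in range(n_cycles):
        tp_idx, vp_idx = _split(g.n_lines, tp_size, vp_size, rng)
        g_tp, g_vp = g.take_lines(tp_idx), g.take_lines(vp_idx)
        y_tp, y_vp = y.iloc[tp_idx], y.iloc[vp_idx]
        k_tp = additive_relationship(g_tp)
        scan = scan_markers(g_tp, y_tp, K=k_tp, n_pc=n_pc)

        marker_sets: list[tuple[str, list[str], bool]] = [("WG", list(g.marker_ids), False)]
        for alpha in alphas:
            sub = select_subset(scan, alpha)
            if sub.markers:
                marker_sets.append((f"SS_{alpha:.2f}", sub.markers, False))
            else:
                marker_sets.append((f"SS_{alpha:.2f}", list(g.marker_ids), True))
        if random_baselines:
            for name, markers, _fb in list(marker_sets[1:]):
                size = len(markers)
                rsub = random_subset(g, size, seed=int(rng.integers(2**31)))
                marker_sets.append((name.replace("SS", "RM"), rsub.markers, False))

        for name, markers, fallback in marker_sets:
            fit = fit_rrblup(g_tp.select_markers(markers), y_tp)
            gebv = predict_gebv(fit, g_vp.select_markers(markers))
            rows.append(
                {
                    "cycle": cycle,
                    "condition": name,
                    "n_markers": len(markers),
                    "fallback": fallback,
                    "accuracy": accuracy(gebv, y_vp),
                }
            )
    design = {
        "scheme": "gwas_gs_cycles",
        "alphas": list(alphas),
        "n_cycles": n_cycles,
        "tp_size": tp_size,
        "vp_size": vp_size,
        "seed": seed,
        "n_pc": n_pc,
    }
    return AccuracyReport(pd.DataFrame(rows), design)


def run_tp_sweep(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    sizes: tuple[int, ...] = (25, 50, 75, 100, 125, 150),
    vp_size: int = 60,
    n_samples: int = 50,
    seed: int = 0,
) -> AccuracyReport:
    """Accuracy as a function of training-population size at constant VP size."""
    if vp_size <= 0:
        raise ValueError("vp_size must be positive")
    y = _as_series(y, g.line_ids)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size + vp_size > g.n_lines:
            warnings.warn(f"TP size {size} skipped: exceeds panel with vp_size={vp_size}")
            continue
        for sample in range(n_samples):
            tp_idx, vp_idx = _split(g.n_lines, size, vp_size, rng)
            fit = fit_rrblup(g.take_lines(tp_idx), y.iloc[tp_idx])
            gebv = predict_gebv(fit, g.take_lines(vp_idx))
            rows.append({"tp_size": size, "sample": sample, "accuracy": accuracy(gebv, y.iloc[vp_idx])})
    design = {"scheme": "tp_sweep", "sizes": list(sizes), "vp_size": vp_size, "n_samples": n_samples, "seed": seed}
    return AccuracyReport(pd.DataFrame(rows), design)


def run_subpop_cross(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    labels: np.ndarray,
    tp_size: int = 50,
    vp_size: int = 30,
    n_draws: int = 10,
    seed: int = 0,
) -> AccuracyReport:
    """Directed cross-prediction between subpopulations (train Qi, predict Qj)."""
    y = _as_series(y, g.line_ids)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 distinct subpopulation labels")
    rng = np.random.default_rng(seed)
    rows = []
    for qi in groups:
        for qj in groups:
            if qi == qj:
                continue
            src = np.flatnonzero(labels == qi)
            dst = np.flatnonzero(labels == qj)
            if src.size < tp_size or dst.size < vp_size:
                warnings.warn(f"pair {qi}->{qj} skipped: subpopulation too small")
                continue
            for draw in range(n_draws):
                tp_idx = rng.choice(src, size=tp_size, replace=False)
                vp_idx = rng.choice(dst, size=vp_size, replace=False)
                fit = fit_rrblup(g.take_lines(tp_idx), y.iloc[tp_idx])
                gebv = predict_gebv(fit, g.take_lines(vp_idx))
                rows.append(
                    {
                        "tp": str(qi),
                        "vp": str(qj),
                        "draw": draw,
                        "accuracy": accuracy(gebv, y.iloc[vp_idx]),
                    }
                )
    design = {"scheme": "subpop_cross", "tp_size": tp_size, "vp_size": vp_size, "n_draws": n_draws, "seed": seed}
    return AccuracyReport(pd.DataFrame(rows), design)


def _kfold_indices(n_total: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n_total)
    return [fold for fold in np.array_split(perm, n_folds)]


def run_fixed_effect_compare(
    g: GenotypeMatrix,
    y_datasets: dict[str, pd.Series],
    covariates: pd.DataFrame,
    tp_size: int = 144,
    n_folds: int = 10,
    seed: int = 0,
) -> AccuracyReport:
    """Major-gene fixed covariates vs none, under k-fold cross-validation.

    For each phenotype dataset and each covariate condition (none, each
    column alone, all together) the panel is subsampled to
    ``tp_size * n_folds / (n_folds - 1)`` lines so every fold trains on
    exactly ``tp_size`` lines.  GEBVs for held-out lines include the fixed
    covariate contribution, so major-gene signal counts toward accuracy.
    Lines with missing covariate values are dropped (count recorded).
    """
    cov = covariates.reindex(g.line_ids)
    keep = ~cov.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} line(s) dropped for missing covariate values")
        g = g.take_lines(np.flatnonzero(keep.to_numpy()))
        cov = cov.loc[keep]

    n_total = int(round(tp_size * n_folds / (n_folds - 1)))
    if n_total > g.n_lines:
        raise ValueError("tp_size too large for this panel under k-fold CV")

    conditions: list[tuple[str, list[str]]] = [("none", [])]
    conditions += [(c, [c]) for c in covariates.columns]
    if len(covariates.columns) > 1:
        conditions.append(("all", list(covariates.columns)))

    rng = np.random.default_rng(seed)
    rows = []
    for dataset, y in y_datasets.items():
        ys = _as_series(y, g.line_ids)
        sub = rng.choice(g.n_lines, size=n_total, replace=False)
        g_sub, y_sub, cov_sub = g.take_lines(sub), ys.iloc[sub], cov.iloc[sub]
        folds = _kfold_indices(n_total, n_folds, rng)
        for cond_name, cols in conditions:
            for fold_no, vp in enumerate(folds):
                tp = np.setdiff1d(np.arange(n_total), vp)
                g_tp, g_vp = g_sub.take_lines(tp), g_sub.take_lines(vp)
                if cols:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", UserWarning)
                        fit = fit_rrblup(g_tp, y_sub.iloc[tp], covariates=cov_sub.iloc[tp][cols])
                    kept = fit.fixed_names[1:]  # covariates that survived collinearity checks
                    gebv = predict_gebv(
                        fit,
                        g_vp,
                        covariates_new=cov_sub.iloc[vp][kept] if kept else None,
                        include_fixed=True,
                    )
                else:
                    fit = fit_rrblup(g_tp, y_sub.iloc[tp])
                    gebv = predict_gebv(fit, g_vp)
                rows.append(
                    {
                        "dataset": dataset,
                        "condition": cond_name,
                        "fold": fold_no,
                        "accuracy": accuracy(gebv, y_sub.iloc[vp]),
                    }
                )
    design = {"scheme": "fixed_effect_compare", "tp_size": tp_size, "n_folds": n_folds, "seed": seed}
    return AccuracyReport(pd.DataFrame(rows), design)


def run_independent(
    g_tp: GenotypeMatrix,
    blups_tp_by_dataset: dict[str, pd.Series],
    g_vp: GenotypeMatrix,
    blups_vp_by_grouping: dict[str, pd.Series],
) -> tuple[AccuracyReport, float]:
    """Train on the panel, predict an external population on common markers.

    Returns one accuracy per (training dataset x validation grouping) cell —
    negative values are reported, never clipped — plus the mean simple
    matching coefficient between the two populations.
    """
    g1, g2 = common_markers(g_tp, g_vp)
    matching_mean, _ = simple_matching(g1, g2)
    rows = []
    for ds_name, y_tp in blups_tp_by_dataset.items():
        fit = fit_rrblup(g1, _as_series(y_tp, g1.line_ids))
        gebv = predict_gebv(fit, g2)
        for grp_name, y_vp in blups_vp_by_grouping.items():
            if len(y_vp) < 3:
                raise ValueError(f"grouping {grp_name} has fewer than 3 validation lines")
            rows.append(
                {
                    "tp_dataset": ds_name,
                    "vp_grouping": grp_name,
                    "n_common_markers": g1.n_markers,
                    "accuracy": accuracy(gebv, y_vp),
                }
            )
    report = AccuracyReport(
        pd.DataFrame(rows),
        {"scheme": "independent", "n_common_markers": g1.n_markers, "matching_mean": matching_mean},
    )
    return report, matching_mean


def cv_mean_gebvs(
    g: GenotypeMatrix,
    y: pd.Series | np.ndarray,
    n_rounds: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Mean held-out GEBV per line over repeated k-fold cross-validation.

    This is the genomic ranking criterion for selection-response analysis:
    every line's GEBV is predicted only by models that did not see its
    phenotype, averaged over ``n_rounds`` fold randomizations.
    """
    y = _as_series(y, g.line_ids)
    rng = np.random.default_rng(seed)
    acc = np.zeros(g.n_lines)
    for _ in range(n_rounds):
        folds = _kfold_indices(g.n_lines, n_folds, rng)
        for vp in folds:
            tp = np.setdiff1d(np.arange(g.n_lines), vp)
            fit = fit_rrblup(g.take_lines(tp), y.iloc[tp])
            acc[vp] += predict_gebv(fit, g.take_lines(vp)).to_numpy()
    return pd.Series(acc / n_rounds, index=g.line_ids, name="mean_gebv")


def _top_k(scores: pd.Series, k: int) -> list[str]:
    # stable: ties at the k-th rank broken by line-ID order
    ordered = scores.sort_index().sort_values(ascending=False, kind="stable")
    return list(ordered.index[:k])


def _outcome(strategy: str, selected: list[str], pheno: pd.Series, h2: float, **meta) -> SelectionOutcome:
    """Breeder's-equation bookkeeping; ``pheno`` is the measurement scale."""
    mu_pop = float(pheno.mean())
    sel_vals = pheno.loc[selected]
    mu_sel = float(sel_vals.mean())
    s = mu_sel - mu_pop
    return SelectionOutcome(
        strategy=strategy,
        selected=list(selected),
        mu_sel=mu_sel,
        mu_pop=mu_pop,
        S=s,
        R=h2 * s,
        variance=float(sel_vals.var(ddof=1)) if len(sel_vals) > 1 else 0.0,
        sd_sel=float(sel_vals.std(ddof=1)) if len(sel_vals) > 1 else 0.0,
        meta=meta,
    )


def selection_response(
    pheno_means: pd.Series,
    h2: float,
    strategy: str,
    gebvs: pd.Series | None = None,
    marker_carriers: pd.DataFrame | None = None,
    intensity: float = 0.10,
    n_random_draws: int = 10,
    seed: int = 0,
    measure: pd.Series | None = None,
) -> SelectionOutcome:
    """Response to selection R = H2 * S for one strategy.

    Strategies: ``PS`` selects the top ``k = round(intensity * N)`` lines on
    phenotype; ``GS`` the top k on GEBV (pass ``gebvs``, typically
    cross-validated means); ``MS`` every line carrying the favorable allele
    at all loci of ``marker_carriers`` (boolean lines x loci frame ordered
    most- to least-significant; if no line carries all, loci are dropped
    from the least significant end until the carrier set is non-empty, so
    the selected count may differ from k); ``RS`` averages ``n_random_draws``
    seeded random draws of k lines; ``PS+GS`` selects the lines that appear
    in both top-k sets (phenotype and GEBV), falling back to the smallest
    phenotype-rank + GEBV-rank sum only if that agreement set is empty.

    ``measure`` optionally separates the scale on which the differential S
    and response are evaluated from the selection criterion — e.g. select on
    averaged per-dataset BLUPs but measure response on the across-trial mean
    yield.  Defaults to the selection phenotype itself.
    """
    pheno = pheno_means.astype(float)
    measure = pheno if measure is None else measure.reindex(pheno.index).astype(float)
    n = len(pheno)
    k = int(round(intensity * n))
    if k < 1:
        raise ValueError("selection intensity selects zero lines")

    if strategy == "PS":
        return _outcome("PS", _top_k(pheno, k), measure, h2, k=k)

    if strategy == "GS":
        if gebvs is None:
            raise ValueError("GS strategy requires gebvs")
        return _outcome("GS", _top_k(gebvs.reindex(pheno.index), k), measure, h2, k=k)

    if strategy == "MS":
        if marker_carriers is None:
            raise ValueError("MS strategy requires marker_carriers")
        carriers = marker_carriers.reindex(pheno.index).fillna(False).astype(bool)
        cols = list(carriers.columns)
        while cols:
            mask = carriers[cols].all(axis=1)
            if mask.any():
                break
            cols = cols[:-1]  # drop least-significant locus
        else:
            raise ValueError("no line carries a favorable allele at any locus")
        selected = list(pheno.index[mask])
        return _outcome("MS", selected, measure, h2, loci_used=cols)

    if strategy == "RS":
        rng = np.random.default_rng(seed)
        draws = [list(pheno.sample(n=k, random_state=rng).index) for _ in range(n_random_draws)]
        outs = [_outcome("RS", d, measure, h2) for d in draws]
        out = outs[0]
        return SelectionOutcome(
            strategy="RS",
            selected=draws[0],
            mu_sel=float(np.mean([o.mu_sel for o in outs])),
            mu_pop=out.mu_pop,
            S=float(np.mean([o.S for o in outs])),
            R=float(np.mean([o.R for o in outs])),
            variance=float(np.mean([o.variance for o in outs])),
            sd_sel=float(np.mean([o.sd_sel for o in outs])),
            meta={"n_draws": n_random_draws, "k": k},
        )

    if strategy == "PS+GS":
        if gebvs is None:
            raise ValueError("PS+GS strategy requires gebvs")
        gebv = gebvs.reindex(pheno.index)
        top_p = _top_k(pheno, k)
        top_g = _top_k(gebv, k)
        # lines that are top-k on BOTH criteria: a subset of the phenotypic
        # top-k enriched for lines whose merit both rankings agree on, so
        # the selected count may fall below k (cf. marker-based selection)
        selected = [x for x in top_p if x in set(top_g)]
        fallback = not selected
        if fallback:  # empty agreement set: fall back to smallest rank-sum
            rank_sum = (pheno.rank(ascending=False) + gebv.rank(ascending=False))
            selected = list(rank_sum.sort_index().sort_values(kind="stable").index[:k])
        return _outcome("PS+GS", selected, measure, h2, k=k, fallback=fallback)

    raise ValueError(f"unknown strategy {strategy!r}")


def response_table(
    pheno_means: pd.Series,
    gebvs: pd.Series,
    h2: float,
    marker_carriers: pd.DataFrame | None = None,
    intensity: float = 0.10,
    seed: int = 0,
    measure: pd.Series | None = None,
) -> pd.DataFrame:
    """All five strategies side by side, with % change in R relative to PS.

    Percent change is computed from R rounded to two decimals, the
    granularity at which selection responses are conventionally reported.
    ``measure`` is forwarded to :func:`selection_response`.
    """
    strategies = ["GS", "MS", "PS", "RS", "PS+GS"] if marker_carriers is not None else ["GS", "PS", "RS", "PS+GS"]
    outs = {
        s: selection_response(
            pheno_means, h2, s, gebvs=gebvs, marker_carriers=marker_carriers,
            intensity=intensity, seed=seed, measure=measure,
        )
        for s in strategies
    }
    r_ps = round(outs["PS"].R, 2)
    rows = []
    for s, o in outs.items():
        r_2 = round(o.R, 2)
        pct = None if s == "PS" else round((r_2 - r_ps) / r_ps * 100.0, 1) if r_ps else None
        o.pct_change_vs_PS = pct
        rows.append(
            {
                "strategy": s,
                "n_selected": len(o.selected),
                "mu_sel": o.mu_sel,
                "sd_sel": o.sd_sel,
                "variance": o.variance,
                "S": o.S,
                "R": r_2,
                "pct_change_vs_PS": pct,
            }
        )
    return pd.DataFrame(rows)


def response_from_means(
    mu_sel_by_strategy: dict[str, float], mu_pop: float, h2: float
) -> pd.DataFrame:
    """Breeder's-equation arithmetic from per-strategy selected-group means.

    Given mean performance of each strategy's selected group and the single
    population mean: S = mu_sel - mu_pop, R = h2 * S (reported to two
    decimals), and % change of each strategy's R relative to PS computed
    from the two-decimal-rounded responses.
    """
    if "PS" not in mu_sel_by_strategy:
        raise ValueError("need a PS entry as the % change baseline")
    r_ps = round(h2 * (mu_sel_by_strategy["PS"] - mu_pop), 2)
    rows = []
    for strat, mu_sel in mu_sel_by_strategy.items():
        s = mu_sel - mu_pop
        r = round(h2 * s, 2)
        pct = None if strat == "PS" else round((r - r_ps) / r_ps * 100.0, 1)
        rows.append({"strategy": strat, "mu_sel": mu_sel, "S": round(s, 2), "R": r, "pct_change_vs_PS": pct})
    return pd.DataFrame(rows)
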