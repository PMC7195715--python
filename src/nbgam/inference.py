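"""DE testing, multiplicity adjustment, classification and the pipeline.

The workflow: size factors -> per-gene initial fit (smoothing-parameter
selection and gene-wise dispersion) -> mean-dispersion trend and prior
width -> MAP dispersion -> final warm-started fit at the MAP dispersion ->
chi-squared term tests -> Benjamini-Hochberg -> linear/nonlinear
classification of DE genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import dispersion as disp
from . import nbgam_fit as fitmod
from .io_design import (
    CountMatrix,
    DesignSpec,
    LinearTerm,
    SampleTable,
    SmoothTerm,
    ValidationError,
)
from .normalization import estimate_size_factors, normalized_counts
from .smooth_basis import build_smooth

logger = logging.getLogger(__name__)


@dataclass
class DETest:
    """One term's test: chi-squared statistic, rank, edf and p/q values."""

    term: str
    stat: float
    df_test: int
    edf: float
    p_value: float
    q_value: float = np.nan
    estimate: float = np.nan
    std_err: float = np.nan


def test_smooth_term(fit: fitmod.GeneGAMFit, term: str) -> DETest:
    """Chi-squared test of a smooth term on the final fit.

    The test inverts the smooth-coefficient covariance block on its
    leading ``r = round(edf)`` eigen-directions (rank-r pseudo-inverse) and
    refers ``beta_s' V_s^- beta_s`` to a chi-squared with r df.  As the
    smoothing parameter grows the construction degenerates to the squared
    Wald z of the straight-line coefficient.
    """
    sl = fit.slices[term]
    beta_s = fit.beta[sl]
    V_s = fit.V_beta[sl, sl]
    edf = fit.edf_term[term]
    km1 = beta_s.size
    r = int(min(km1, max(1, round(edf))))
    evals, evecs = np.linalg.eigh(V_s)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(evals[0], 0.0)
    r_used = int(min(r, np.sum(evals > tol)))
    if r_used < r:
        logger.warning("term %s: covariance rank %d below edf rank %d", term, r_used, r)
    if r_used == 0:
        return DETest(term, 0.0, 1, edf, 1.0)
    proj = evecs[:, :r_used].T @ beta_s
    stat = float(np.sum(proj**2 / evals[:r_used]))
    p = float(stats.chi2.sf(stat, r_used))
    return DETest(term, stat, r_used, edf, p)


def test_linear_term(fit: fitmod.GeneGAMFit, term: str) -> DETest:
    """Squared Wald z on a single linear coefficient, chi-squared(1)."""
    sl = fit.slices[term]
    idx = sl.start
    if sl.stop - sl.start != 1:
        raise ValueError(f"term {term!r} is not a single-column linear term")
    est = float(fit.beta[idx])
    se = float(np.sqrt(fit.V_beta[idx, idx]))
    if se == 0:
        raise ValidationError(f"zero standard error for term {term!r}")
    stat = (est / se) ** 2
    p = float(stats.chi2.sf(stat, 1))
    return DETest(term, stat, 1, 1.0, p, estimate=est, std_err=se)


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs propagate."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if (~ok).any():
        logger.warning("adjust_bh: %d NaN p-values propagated", int((~ok).sum()))
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_effect(
    fit: fitmod.GeneGAMFit,
    de: DETest,
    method: str = "edf",
    linear_fit: fitmod.GeneGAMFit | None = None,
    q_threshold: float = 0.05,
) -> str:
    """Label a gene nonlinear / linear / not_DE.

    DE genes (q below threshold) are nonlinear under the edf rule iff the
    smooth's effective degrees of freedom exceed 1.5, or under the aic/bic
    rules iff the smooth model's criterion beats the linear refit's.
    """
    if not np.isfinite(de.q_value) or de.q_value >= q_threshold:
        return "not_DE"
    if method == "edf":
        return "nonlinear" if fit.edf_term[de.term] > 1.5 else "linear"
    if method in ("aic", "bic"):
        if linear_fit is None:
            raise ValidationError(f"classification method {method!r} needs a linear refit")
        a = fit.aic if method == "aic" else fit.bic
        b = linear_fit.aic if method == "aic" else linear_fit.bic
        return "nonlinear" if a < b else "linear"
    raise ValidationError(f"unknown classification method {method!r}")


@dataclass
class PipelineOptions:
    gamma: float = 2.5
    q_threshold: float = 0.05
    classify_method: str = "edf"  # edf | aic | bic
    size_factors: str | np.ndarray = "estimate"  # "estimate" | "unit" | array
    threads: int = 1
    moment_alpha_bounds: tuple = (1e-4, 10.0)


@dataclass
class DesignMatrices:
    X: np.ndarray
    penalties: list
    slices: dict
    smooth_slices: dict
    column_names: list
    smooth_kminus1: dict = field(default_factory=dict)


def build_design_matrices(design: DesignSpec, table: SampleTable) -> DesignMatrices:
    """Assemble intercept + linear + centered smooth columns and penalties."""
    df = table.data
    n = df.shape[0]
    cols = [np.ones((n, 1))]
    names = ["(intercept)"]
    slices: dict = {}
    smooth_slices: dict = {}
    penalties_blocks: list = []
    smooth_kminus1: dict = {}
    pos = 1
    for term in design.terms:
        if isinstance(term, LinearTerm):
            if table.is_continuous(term.name):
                v = df[term.name].to_numpy(float)
                if np.ptp(v) == 0:
                    raise ValidationError(f"covariate {term.name!r} is constant")
                cols.append(v[:, None])
                slices[term.name] = slice(pos, pos + 1)
                names.append(term.name)
                pos += 1
            else:
                levels = sorted(df[term.name].astype(str).unique())
                if len(levels) < 2:
                    raise ValidationError(f"covariate {term.name!r} is constant")
                dummies = np.column_stack(
                    [(df[term.name].astype(str) == lv).astype(float) for lv in levels[1:]]
                )
                cols.append(dummies)
                slices[term.name] = slice(pos, pos + len(levels) - 1)
                names.extend(f"{term.name}[{lv}]" for lv in levels[1:])
                pos += len(levels) - 1
        elif isinstance(term, SmoothTerm):
            v = df[term.name].to_numpy(float)
            if np.ptp(v) == 0:
                raise ValidationError(
                    f"covariate {term.name!r} inside a smooth is constant"
                )
            sb = build_smooth(v, k=term.k)
            cols.append(sb.X_s)
            width = sb.X_s.shape[1]
            slices[term.name] = slice(pos, pos + width)
            smooth_slices[term.name] = slices[term.name]
            smooth_kminus1[term.name] = width
            names.extend(f"s({term.name}).{i}" for i in range(width))
            penalties_blocks.append((slices[term.name], sb.S))
            pos += width
    X = np.hstack(cols)
    p = X.shape[1]
    penalties = []
    for sl, S in penalties_blocks:
        S_full = np.zeros((p, p))
        S_full[sl, sl] = S
        penalties.append(S_full)
    return DesignMatrices(X, penalties, slices, smooth_slices, names, smooth_kminus1)


@dataclass
class PipelineState:
    """Everything the pipeline computed, for diagnostics and benchmarking."""

    results: pd.DataFrame
    alpha_gw: np.ndarray
    alpha_trend: np.ndarray
    alpha_map: np.ndarray
    outlier: np.ndarray
    trend_coef: tuple
    prior_var: float
    base_mean: np.ndarray
    size_factors: np.ndarray
    edf: np.ndarray
    fits: list  # final GeneGAMFit per gene (None where failed)


def _moment_alpha(y_norm: np.ndarray, lo: float, hi: float) -> float:
    mu = y_norm.mean()
    if mu <= 0:
        return lo
    v = y_norm.var(ddof=1)
    return float(np.clip((v - mu) / mu**2, lo, hi))


def _initial_gene(y, dm: DesignMatrices, offset, gamma, a0):
    """Initial pass: select lambda at a moment dispersion, then CR gene-wise
    dispersion at the selected fit's means."""
    try:
        lam = fitmod.select_smoothing(
            y, dm.X, dm.penalties, a0, offset, gamma=gamma,
            smooth_slices=dm.smooth_slices,
        )
        fit = fitmod.finalize_fit(
            y, dm.X, dm.penalties, lam, a0, offset, dm.slices, dm.smooth_slices
        )
        S_pen = fitmod._penalty_total(dm.penalties, fit.lam)
        a_gw = disp.genewise_dispersion(y, fit.mu_hat, dm.X, S_pen=S_pen)
        return fit, a_gw, None
    except Exception as exc:  # noqa: BLE001 - per-gene failures are contained
        return None, np.nan, str(exc)


def _final_gene(y, dm: DesignMatrices, offset, init_fit, a_map):
    try:
        fit = fitmod.finalize_fit(
            y, dm.X, dm.penalties, init_fit.lam, a_map, offset,
            dm.slices, dm.smooth_slices, beta_init=init_fit.beta,
        )
        return fit, None
    except Exception as exc:  # noqa: BLE001
        return None, str(exc)


def _map_over_genes(func, items, threads):
    if threads and threads > 1:
        return Parallel(n_jobs=threads, batch_size=64)(delayed(func)(*it) for it in items)
    return [func(*it) for it in items]


def run_pipeline_full(
    counts: CountMatrix,
    coldata: SampleTable,
    design: DesignSpec,
    options: PipelineOptions | None = None,
) -> PipelineState:
    """Run the full workflow and return results plus internal state."""
    options = options or PipelineOptions()
    if counts.sample_ids != coldata.sample_ids:
        raise ValidationError("sample IDs of counts and covariate table differ")
    if counts.n_samples < 3:
        raise ValidationError("at least 3 samples are required for model fitting")
    dm = build_design_matrices(design, coldata)
    m = counts.n_samples
    n_genes = counts.n_genes

    if isinstance(options.size_factors, str):
        if options.size_factors == "unit":
            s = np.ones(m)
        elif options.size_factors == "estimate":
            s = estimate_size_factors(counts)
        else:
            raise ValidationError(f"unknown size factor mode {options.size_factors!r}")
    else:
        s = np.asarray(options.size_factors, float)
    offset = np.log(s)
    norm = normalized_counts(counts, s)
    base_mean = norm.mean(axis=1)

    lo, hi = options.moment_alpha_bounds
    ys = [counts.counts[i].astype(float) for i in range(n_genes)]
    fit_mask = np.array([y.sum() > 0 for y in ys])

    init_items = [
        (ys[i], dm, offset, options.gamma, _moment_alpha(norm[i], lo, hi))
        for i in range(n_genes) if fit_mask[i]
    ]
    init_out = _map_over_genes(_initial_gene, init_items, options.threads)
    init_fits: list = [None] * n_genes
    alpha_gw = np.full(n_genes, np.nan)
    j = 0
    n_fail = 0
    for i in range(n_genes):
        if not fit_mask[i]:
            continue
        fit, a_gw, err = init_out[j]
        j += 1
        if fit is None:
            n_fail += 1
            continue
        init_fits[i] = fit
        alpha_gw[i] = a_gw
    if n_fail:
        logger.warning("initial fit failed for %d genes", n_fail)

    ok = np.array([f is not None for f in init_fits])
    a0_tr, a1_tr = disp.fit_dispersion_trend(alpha_gw[ok], base_mean[ok])
    alpha_trend = disp.trend_values(base_mean, a0_tr, a1_tr)
    edf_init = np.array([f.edf_total if f else np.nan for f in init_fits])
    p_df = int(round(np.nanmean(edf_init))) if ok.any() else dm.X.shape[1]
    p_df = min(p_df, m - 1)
    sigma2_lp = disp.prior_variance(alpha_gw[ok], alpha_trend[ok], m, p_df)

    alpha_map = np.full(n_genes, np.nan)
    outlier = np.zeros(n_genes, dtype=bool)
    map_items = [
        (
            ys[i], init_fits[i].mu_hat, dm.X, alpha_trend[i], sigma2_lp,
            alpha_gw[i], fitmod._penalty_total(dm.penalties, init_fits[i].lam),
        )
        for i in range(n_genes) if ok[i]
    ]

    def _map_one(y, mu, X, tr, s2, agw, S_pen):
        return disp.map_dispersion(y, mu, X, tr, s2, agw, S_pen=S_pen)

    map_out = _map_over_genes(_map_one, map_items, options.threads)
    j = 0
    for i in range(n_genes):
        if not ok[i]:
            continue
        alpha_map[i], outlier[i] = map_out[j]
        j += 1

    final_items = [
        (ys[i], dm, offset, init_fits[i], alpha_map[i])
        for i in range(n_genes) if ok[i]
    ]
    final_out = _map_over_genes(_final_gene, final_items, options.threads)
    fits: list = [None] * n_genes
    j = 0
    for i in range(n_genes):
        if not ok[i]:
            continue
        fit, err = final_out[j]
        j += 1
        if fit is not None:
            fits[i] = fit

    smooth_names = [t.name for t in design.smooth_terms]
    linear_names = [t.name for t in design.linear_terms
                    if fits and dm.slices[t.name].stop - dm.slices[t.name].start == 1]
    # term of interest for classification: first smooth, else first linear
    interest = smooth_names[0] if smooth_names else (
        linear_names[0] if linear_names else None
    )

    rows: dict = {"base_mean": base_mean}
    tests_by_term: dict = {}
    for name in smooth_names + linear_names:
        is_smooth = name in dm.smooth_slices
        stats_, edfs, ps, ests, ses = [], [], [], [], []
        tests = []
        for i in range(n_genes):
            f = fits[i]
            if f is None or not f.converged:
                tests.append(None)
                stats_.append(np.nan); edfs.append(np.nan); ps.append(np.nan)
                ests.append(np.nan); ses.append(np.nan)
                continue
            t = test_smooth_term(f, name) if is_smooth else test_linear_term(f, name)
            tests.append(t)
            stats_.append(t.stat); edfs.append(t.edf); ps.append(t.p_value)
            ests.append(t.estimate); ses.append(t.std_err)
        q = adjust_bh(np.array(ps))
        for t, qi in zip(tests, q):
            if t is not None:
                t.q_value = float(qi)
        tests_by_term[name] = tests
        if is_smooth:
            rows[f"{name}_chisq"] = stats_
            rows[f"{name}_edf"] = edfs
        else:
            rows[f"{name}_estimate"] = ests
            rows[f"{name}_stderr"] = ses
            rows[f"{name}_chisq"] = stats_
        rows[f"{name}_pvalue"] = ps
        rows[f"{name}_qvalue"] = q

    need_linear_refit = (
        options.classify_method in ("aic", "bic") and bool(smooth_names)
    )
    linear_refits: list = [None] * n_genes
    if need_linear_refit:
        lin_design = DesignSpec(
            [LinearTerm(t.name) if isinstance(t, SmoothTerm) else t
             for t in design.terms]
        )
        dml = build_design_matrices(lin_design, coldata)
        lin_items = [
            (ys[i], dml, offset, init_fits[i], alpha_map[i])
            for i in range(n_genes) if fits[i] is not None
        ]

        def _lin_one(y, dml_, off, init_fit, a_map):
            try:
                return fitmod.finalize_fit(
                    y, dml_.X, dml_.penalties, np.empty(0), a_map, off,
                    dml_.slices, dml_.smooth_slices,
                )
            except Exception:  # noqa: BLE001
                return None

        lin_out = _map_over_genes(_lin_one, lin_items, options.threads)
        j = 0
        for i in range(n_genes):
            if fits[i] is None:
                continue
            linear_refits[i] = lin_out[j]
            j += 1

    classification = []
    aics, bics, convs = [], [], []
    for i in range(n_genes):
        f = fits[i]
        if f is None:
            classification.append("not_DE")
            aics.append(np.nan); bics.append(np.nan); convs.append(False)
            continue
        aics.append(f.aic); bics.append(f.bic); convs.append(bool(f.converged))
        if interest is None:
            classification.append("not_DE")
            continue
        t = tests_by_term[interest][i]
        if t is None:
            classification.append("not_DE")
            continue
        if interest in dm.smooth_slices:
            classification.append(
                classify_effect(
                    f, t, method=options.classify_method,
                    linear_fit=linear_refits[i],
                    q_threshold=options.q_threshold,
                )
            )
        else:
            # purely linear design: a declared gene is a linear effect
            classification.append(
                "linear" if (np.isfinite(t.q_value) and t.q_value < options.q_threshold)
                else "not_DE"
            )
    rows["aic"] = aics
    rows["bic"] = bics
    rows["classification"] = classification
    rows["converged"] = convs
    results = pd.DataFrame(rows, index=pd.Index(counts.gene_ids, name="gene_id"))

    edf_arr = np.array(
        [f.edf_term.get(interest, np.nan) if (f and interest in dm.smooth_slices)
         else np.nan for f in fits]
    )
    return PipelineState(
        results=results,
        alpha_gw=alpha_gw,
        alpha_trend=alpha_trend,
        alpha_map=alpha_map,
        outlier=outlier,
        trend_coef=(a0_tr, a1_tr),
        prior_var=sigma2_lp,
        base_mean=base_mean,
        size_factors=s,
        edf=edf_arr,
        fits=fits,
    )


def run_pipeline(
    counts: CountMatrix,
    coldata: SampleTable,
    design: DesignSpec,
    options: PipelineOptions | None = None,
) -> pd.DataFrame:
    """Run the workflow and return the per-gene result table."""
    return run_pipeline_full(counts, coldata, design, options).results
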