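"""Normalization and per-barcode differential abundance testing.

Barcode read counts behave like RNA-seq tag counts: sampling noise plus
extra biological/technical variability between replicate cultures, so they
are modelled as negative binomial with a common dispersion φ (variance
μ + φμ²).  Samples are normalized with trimmed-mean-of-M-values (TMM)
scaling factors, the common dispersion is estimated by quantile-adjusted
conditional maximum likelihood (qCML), and each barcode is tested for a
drug-vs-vehicle abundance shift with an exact conditional negative-binomial
test: condition on the total count, enumerate every split between the two
groups, and sum the probabilities of all splits no more likely than the one
observed.  All three pieces are implemented here rather than delegated, so
their conventions (trim fractions, tie rules, prior counts) are explicit
and testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_TRIM_LOGRATIO = 0.3
DEFAULT_TRIM_ABUNDANCE = 0.05
DEFAULT_PRIOR_COUNT = 0.125
DEFAULT_DISPERSION = 0.1
DISPERSION_BOUNDS = (1e-6, 10.0)


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors (geometric mean 1) and library sizes."""

    factors: pd.Series
    lib_sizes: pd.Series

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


@dataclass
class DispersionEstimate:
    dispersion: float
    method: str


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_logratio, trim_abundance):
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / lib_obs, ref / lib_ref
    logr = np.log2(p_obs / p_ref)
    abse = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
    var = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    n = logr.size
    lo_l = np.floor(n * trim_logratio) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_abundance) + 1
    hi_s = n + 1 - lo_s
    rank_l = stats.rankdata(logr)
    rank_s = stats.rankdata(abse)
    keep2 = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep2.any():
        return 1.0
    f = np.sum(logr[keep2] / var[keep2]) / np.sum(1.0 / var[keep2])
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return 2.0**f


def tmm_factors(
    matrix: pd.DataFrame,
    trim_logratio: float = DEFAULT_TRIM_LOGRATIO,
    trim_abundance: float = DEFAULT_TRIM_ABUNDANCE,
    ref_column: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scaling factors between samples.

    For each sample against a reference column (the sample whose
    counts-per-library-size upper quartile is closest to the mean upper
    quartile), M (log-ratio) and A (log-abundance) values are computed on
    barcodes nonzero in both samples, doubly trimmed (default 30% of M,
    5% of A from each end), and combined by inverse-asymptotic-variance
    weighting.  Factors are rescaled to geometric mean 1, so they modify
    relative, not absolute, library sizes.
    """
    if matrix.shape[1] < 2:
        raise ValueError("TMM normalization requires at least 2 samples")
    lib_sizes = matrix.sum(axis=0).astype(float)
    zero = lib_sizes[lib_sizes == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {', '.join(map(str, zero.index))}")
    counts = matrix.to_numpy(dtype=float)
    if ref_column is None:
        f75 = np.array(
            [np.quantile(counts[:, j], 0.75) / lib_sizes.iloc[j] for j in range(counts.shape[1])]
        )
        if np.all(f75 == 0):
            raise ValueError("cannot choose a TMM reference: all upper quartiles are zero")
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = list(matrix.columns).index(ref_column)
    ref = counts[:, ref_idx]
    lib_ref = lib_sizes.iloc[ref_idx]
    factors = np.array(
        [
            _tmm_pair(counts[:, j], ref, lib_sizes.iloc[j], lib_ref, trim_logratio, trim_abundance)
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        pd.Series(factors, index=matrix.columns, name="tmm_factor"),
        lib_sizes.rename("lib_size"),
    )


# ---------------------------------------------------------------------------
# common dispersion (qCML)


def _q2qnbinom(x, input_mean, output_mean, dispersion):
    """Quantile-to-quantile mapping of counts between library sizes under a
    negative binomial model, averaging normal and gamma approximations."""
    x = np.asarray(x, dtype=float)
    input_mean = np.broadcast_to(np.asarray(input_mean, dtype=float), x.shape).copy()
    output_mean = np.broadcast_to(np.asarray(output_mean, dtype=float), x.shape).copy()
    eps = 1e-14
    zero = (input_mean < eps) | (output_mean < eps)
    input_mean[zero] += 0.25
    output_mean[zero] += 0.25
    vi = input_mean * (1.0 + dispersion * input_mean)
    vo = output_mean * (1.0 + dispersion * output_mean)
    out = np.empty_like(x)
    upper = x >= input_mean
    for mask, tail in ((upper, "upper"), (~upper, "lower")):
        if not mask.any():
            continue
        xm, im, om = x[mask], input_mean[mask], output_mean[mask]
        vim, vom = vi[mask], vo[mask]
        if tail == "upper":
            p_norm = stats.norm.sf(xm, loc=im, scale=np.sqrt(vim))
            p_gamma = stats.gamma.sf(xm, a=im**2 / vim, scale=vim / im)
            q_norm = stats.norm.isf(p_norm, loc=om, scale=np.sqrt(vom))
            q_gamma = stats.gamma.isf(p_gamma, a=om**2 / vom, scale=vom / om)
        else:
            p_norm = stats.norm.cdf(xm, loc=im, scale=np.sqrt(vim))
            p_gamma = stats.gamma.cdf(xm, a=im**2 / vim, scale=vim / im)
            q_norm = stats.norm.ppf(p_norm, loc=om, scale=np.sqrt(vom))
            q_gamma = stats.gamma.ppf(p_gamma, a=om**2 / vom, scale=vom / om)
        out[mask] = (q_norm + q_gamma) / 2.0
    return np.clip(out, 0.0, None)


def equalize_lib_sizes(counts: np.ndarray, lib_sizes: np.ndarray, dispersion: float):
    """Map each sample's counts onto the geometric-mean library size.

    Returns ``(pseudo_counts, common_lib_size)``.  Per-barcode input means
    are proportional to the barcode's overall relative abundance.
    """
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    common = np.exp(np.mean(np.log(lib_sizes)))
    props = counts.sum(axis=1) / lib_sizes.sum()
    pseudo = np.empty_like(counts, dtype=float)
    for j in range(counts.shape[1]):
        pseudo[:, j] = _q2qnbinom(
            counts[:, j], props * lib_sizes[j], props * common, dispersion
        )
    return pseudo, common


def _cond_log_lik(pseudo: np.ndarray, group_cols: list[np.ndarray], phi: float) -> float:
    """Conditional log-likelihood of φ given per-group totals, summed over
    barcodes and groups (library sizes already equalized)."""
    r = 1.0 / phi
    total = 0.0
    for cols in group_cols:
        y = pseudo[:, cols]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += np.sum(
            gammaln(y + r).sum(axis=1) + gammaln(n * r) - gammaln(z + n * r) - n * gammaln(r)
        )
    return float(total)


def _golden_section_max(fn, lo: float, hi: float, tol: float = 1e-8, max_iter: int = 200):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fn(c), fn(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fn(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fn(d)
    return (a + b) / 2.0


def estimate_common_dispersion(
    matrix: pd.DataFrame,
    groups: pd.Series | list,
    lib_sizes: pd.Series | None = None,
    default_dispersion: float = DEFAULT_DISPERSION,
    n_iter: int = 2,
) -> DispersionEstimate:
    """Estimate the common NB dispersion by quantile-adjusted conditional
    maximum likelihood.

    Library sizes are equalized to their geometric mean by a
    quantile-to-quantile NB mapping, then the summed conditional
    log-likelihood (conditioning on each barcode's per-group total) is
    maximized over φ by golden-section search on [1e-6, 10]; adjustment and
    maximization are alternated twice.  With no replicated condition the
    estimate is undefined and the configured default is returned with a
    warning.
    """
    groups = pd.Series(list(groups), index=matrix.columns)
    group_cols = [
        np.array([i for i, s in enumerate(matrix.columns) if groups[s] == g])
        for g in groups.unique()
    ]
    if max(len(c) for c in group_cols) < 2:
        log.warning(
            "no condition has >=2 replicates; falling back to default dispersion %.3g",
            default_dispersion,
        )
        return DispersionEstimate(default_dispersion, "default")
    counts = matrix.to_numpy(dtype=float)
    counts = counts[counts.sum(axis=1) > 0]
    if lib_sizes is None:
        lib_sizes = matrix.sum(axis=0).astype(float)
    lib = np.asarray(lib_sizes, dtype=float)
    phi = 0.01
    for _ in range(n_iter):
        pseudo, _ = equalize_lib_sizes(counts, lib, phi)
        phi = _golden_section_max(
            lambda p: _cond_log_lik(pseudo, group_cols, p), *DISPERSION_BOUNDS
        )
    return DispersionEstimate(float(phi), "qCML")


# ---------------------------------------------------------------------------
# exact test


def _conditional_pmf(t: int, n_a: float, n_b: float, phi: float) -> np.ndarray:
    """Null probabilities of every split (a, t-a) of total t between groups
    of (effective) size n_a and n_b, conditioned on the total."""
    a = np.arange(t + 1)
    frac = n_a / (n_a + n_b)
    if phi == 0.0:
        # Poisson limit: conditional distribution is binomial
        probs = stats.binom.pmf(a, t, frac)
    else:
        size_a, size_b = n_a / phi, n_b / phi
        mu_a, mu_b = t * frac, t * (1.0 - frac)
        pa = size_a / (size_a + mu_a)
        pb = size_b / (size_b + mu_b)
        probs = stats.nbinom.pmf(a, size_a, pa) * stats.nbinom.pmf(t - a, size_b, pb)
    return probs


def nb_exact_test(
    counts_a,
    counts_b,
    dispersion: float,
    lib_sizes_a=None,
    lib_sizes_b=None,
) -> float:
    """Exact conditional negative-binomial P-value for a two-group split.

    Counts are assumed already adjusted to a common library size, so the sum
    of a group's counts is treated as NB with size parameter proportional to
    the number of replicates.  Conditioning on the total ``t``, the P-value
    is the summed probability of every split ``(a, t-a)`` whose null
    probability does not exceed that of the observed split, normalized by
    the total conditional probability (two-sided by minimal likelihood).
    ``t = 0`` returns 1 by convention; the result is always in (0, 1].
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    counts_a = np.atleast_1d(np.asarray(counts_a, dtype=float))
    counts_b = np.atleast_1d(np.asarray(counts_b, dtype=float))
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("counts must be non-negative")
    s_a = int(round(counts_a.sum()))
    s_b = int(round(counts_b.sum()))
    t = s_a + s_b
    if t == 0:
        return 1.0
    if lib_sizes_a is not None and lib_sizes_b is not None:
        n_a = float(np.sum(lib_sizes_a)) / float(np.mean(np.concatenate(
            [np.atleast_1d(lib_sizes_a), np.atleast_1d(lib_sizes_b)], dtype=float)))
        n_b = float(np.sum(lib_sizes_b)) / float(np.mean(np.concatenate(
            [np.atleast_1d(lib_sizes_a), np.atleast_1d(lib_sizes_b)], dtype=float)))
    else:
        n_a, n_b = float(counts_a.size), float(counts_b.size)
    probs = _conditional_pmf(t, n_a, n_b, dispersion)
    p_obs = probs[s_a]
    # tolerate floating-point ties at the observed probability
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum() / probs.sum()
    return float(min(max(p, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# fold changes and the screen-level driver


def cpm(
    matrix: pd.DataFrame,
    lib_sizes: pd.Series,
    prior: float = 0.0,
) -> pd.DataFrame:
    """Counts per million against (effective) library sizes, with an
    optional prior count scaled by relative library size."""
    lib = lib_sizes.astype(float)
    prior_j = prior * lib / lib.mean()
    return (matrix + prior_j) / (lib + 2.0 * prior_j) * 1e6


def log_fold_change(
    counts_a,
    counts_b,
    lib_sizes_a,
    lib_sizes_b,
    prior: float = DEFAULT_PRIOR_COUNT,
) -> float:
    """log2 fold change of group A over group B on prior-augmented CPMs.

    The prior count is scaled by each sample's relative library size before
    being added, so the fold change is finite even at zero counts.
    """
    counts = np.concatenate([np.atleast_1d(counts_a), np.atleast_1d(counts_b)]).astype(float)
    lib = np.concatenate([np.atleast_1d(lib_sizes_a), np.atleast_1d(lib_sizes_b)]).astype(float)
    prior_j = prior * lib / lib.mean()
    cpms = (counts + prior_j) / (lib + 2.0 * prior_j) * 1e6
    n_a = np.atleast_1d(counts_a).size
    return float(np.log2(cpms[:n_a].mean()) - np.log2(cpms[n_a:].mean()))


def run_screen_test(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    condition_a: str = "drug",
    condition_b: str = "dmso",
    dispersion: float | None = None,
    prior: float = DEFAULT_PRIOR_COUNT,
) -> pd.DataFrame:
    """Per-barcode drug-vs-vehicle differential abundance for one screen.

    Pipeline: TMM factors → qCML common dispersion (unless ``dispersion``
    is given) → library-size equalization → per-barcode exact NB test and
    prior-augmented log2 fold change → Benjamini–Hochberg adjustment over
    the tested barcodes.  Barcodes with zero counts in every sample are
    excluded from testing and from the BH denominator.

    ``design`` must index sample → condition (columns ``sample`` and
    ``condition`` or an indexed Series-like frame).  Returns a DataFrame
    with columns barcode, logFC, PValue, FDR, meanCPM_<a>, meanCPM_<b>.
    """
    if "sample" in design.columns:
        design = design.set_index("sample")
    conditions = design["condition"]
    cols_a = [s for s in matrix.columns if conditions.get(s) == condition_a]
    cols_b = [s for s in matrix.columns if conditions.get(s) == condition_b]
    if not cols_a or not cols_b:
        raise ValueError(
            f"design must provide at least one {condition_a!r} and one {condition_b!r} sample"
        )
    sub = matrix[cols_a + cols_b]
    nonzero = sub.sum(axis=1) > 0
    tested = sub[nonzero]
    norm = tmm_factors(sub)
    eff = norm.effective_lib_sizes
    groups = pd.Series(
        [condition_a] * len(cols_a) + [condition_b] * len(cols_b), index=sub.columns
    )
    if dispersion is None:
        disp = estimate_common_dispersion(tested, groups, lib_sizes=eff)
    else:
        disp = DispersionEstimate(float(dispersion), "fixed")
    pseudo, _ = equalize_lib_sizes(
        tested.to_numpy(dtype=float), eff.to_numpy(), disp.dispersion
    )
    idx_a = [sub.columns.get_loc(c) for c in cols_a]
    idx_b = [sub.columns.get_loc(c) for c in cols_b]
    pvals = np.array(
        [
            nb_exact_test(row[idx_a], row[idx_b], disp.dispersion)
            for row in pseudo
        ]
    )
    cpms = cpm(tested, eff, prior=prior)
    mean_a = cpms[cols_a].mean(axis=1)
    mean_b = cpms[cols_b].mean(axis=1)
    logfc = np.log2(mean_a) - np.log2(mean_b)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "barcode": tested.index,
            "logFC": logfc.to_numpy(),
            "PValue": pvals,
            "FDR": fdr,
            f"meanCPM_{condition_a}": mean_a.to_numpy(),
            f"meanCPM_{condition_b}": mean_b.to_numpy(),
        }
    )
    result.attrs["dispersion"] = disp.dispersion
    result.attrs["tmm_factors"] = dict(norm.factors)
    return result.sort_values("PValue", kind="mergesort").reset_index(drop=True)
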