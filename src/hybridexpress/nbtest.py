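"""Two-group exact test for negative-binomial counts, with BH FDR control.

The test conditions on the total count of a gene across both groups.  With
counts pre-scaled to a common library size, the sum of n i.i.d. NB(mu, phi)
variables is NB(n*mu, phi/n); conditional on the total T = A + B the split
A | T follows a negative-hypergeometric-type distribution that does not
depend on the unknown mean, so it can be enumerated exactly.  Two-sided
p-values use the minimum-likelihood rule: the sum of probabilities of all
splits no more likely than the observed one.  Dispersion phi parameterizes
the NB variance as mu + phi * mu^2; phi = 0 is the Poisson limit, where the
conditional split distribution is binomial.

A single common dispersion shared across genes is estimated by maximizing
the conditional log-likelihood of the within-group splits, the classic
quantile-conditional approach for small-replicate RNA-seq designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .io import CountsMatrix, cpm_normalize

__all__ = [
    "DispersionEstimate",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "de_compare",
    "write_de_table",
]

# log-probability tolerance when deciding "no more likely than observed";
# protects exact ties (symmetric splits) against floating-point jitter
_TIE_TOL = 1e-10
_MAX_DISPERSION = 10.0
_CHUNK = 1 << 20


@dataclass
class DispersionEstimate:
    """NB dispersion phi (variance = mu + phi mu^2), common and per-gene."""

    common_dispersion: float
    per_gene: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.common_dispersion) or self.common_dispersion < 0:
            raise ValueError("dispersion must be finite and nonnegative")


def _equalize(counts: np.ndarray, lib_sizes: np.ndarray | None) -> np.ndarray:
    """Scale counts to the geometric-mean library size, rounding half-even.

    Returns pseudo-counts on a common scale so the conditional argument
    (equal per-sample means under the null) applies.  With equal library
    sizes the counts are returned unchanged.
    """
    counts = np.asarray(counts)
    if lib_sizes is None:
        return np.asarray(np.round(counts), dtype=np.int64)
    lib = np.asarray(lib_sizes, dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    ref = np.exp(np.mean(np.log(lib)))
    scaled = counts * (ref / lib)
    return np.asarray(np.round(scaled), dtype=np.int64)


def _cond_split_logpmf(T: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """Log-pmf of the split A | A + B = T over k = 0..T.

    A is the sum of n_a equal-mean NB counts, B of n_b; the conditional pmf
    is free of the mean because both group sums share the NB success
    probability.  dispersion 0 gives Binomial(T, n_a / (n_a + n_b)).
    """
    k = np.arange(T + 1, dtype=float)
    if dispersion <= 0:
        p = n_a / (n_a + n_b)
        logpmf = (
            gammaln(T + 1)
            - gammaln(k + 1)
            - gammaln(T - k + 1)
            + k * np.log(p)
            + (T - k) * np.log1p(-p)
        )
        return logpmf
    r_a = n_a / dispersion
    r_b = n_b / dispersion
    logw = (
        gammaln(k + r_a)
        - gammaln(k + 1)
        + gammaln(T - k + r_b)
        - gammaln(T - k + 1)
    )
    return logw - logsumexp(logw)


def nb_exact_test(
    counts_a,
    counts_b,
    dispersion: float,
    lib_sizes_a=None,
    lib_sizes_b=None,
    two_sided_rule: str = "min_likelihood",
) -> float:
    """Exact two-sided p-value for a difference in NB means between groups.

    Parameters
    ----------
    counts_a, counts_b
        Nonnegative integer counts, one entry per replicate sample.
    dispersion
        Common NB dispersion phi (variance = mu + phi mu^2); 0 for Poisson.
    lib_sizes_a, lib_sizes_b
        Per-sample library sizes.  When given, counts are first scaled to the
        geometric mean library size of all samples (rounded half-even).
    two_sided_rule
        "min_likelihood" (default): sum of conditional probabilities of all
        splits no more likely than the observed one.  "doubling": twice the
        smaller tail, capped at 1.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be nonnegative")
    if dispersion < 0:
        raise ValueError("dispersion must be nonnegative")
    if two_sided_rule not in ("min_likelihood", "doubling"):
        raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one sample")

    if lib_sizes_a is not None or lib_sizes_b is not None:
        lib = np.concatenate(
            [np.asarray(lib_sizes_a, dtype=float), np.asarray(lib_sizes_b, dtype=float)]
        )
        eq = _equalize(np.concatenate([a, b]), lib)
        A = int(eq[:n_a].sum())
        B = int(eq[n_a:].sum())
    else:
        A = int(round(float(a.sum())))
        B = int(round(float(b.sum())))
    T = A + B
    if T == 0:
        return 1.0

    if T <= _CHUNK:
        logpmf = _cond_split_logpmf(T, n_a, n_b, dispersion)
        lobs = logpmf[A]
        if two_sided_rule == "doubling":
            pmf = np.exp(logpmf)
            lower = pmf[: A + 1].sum()
            upper = pmf[A:].sum()
            return float(min(1.0, 2.0 * min(lower, upper)))
        mask = logpmf <= lobs + _TIE_TOL
        if mask.all():  # observed split is modal: every split counted
            return 1.0
        return float(min(1.0, np.exp(logsumexp(logpmf[mask]))))

    return _nb_exact_test_chunked(T, A, n_a, n_b, dispersion, two_sided_rule)


def _chunk_logw(lo: int, hi: int, T: int, n_a: int, n_b: int, disp: float) -> np.ndarray:
    k = np.arange(lo, hi, dtype=float)
    if disp <= 0:
        p = n_a / (n_a + n_b)
        return (
            gammaln(T + 1)
            - gammaln(k + 1)
            - gammaln(T - k + 1)
            + k * np.log(p)
            + (T - k) * np.log1p(-p)
        )
    r_a = n_a / disp
    r_b = n_b / disp
    return (
        gammaln(k + r_a) - gammaln(k + 1) + gammaln(T - k + r_b) - gammaln(T - k + 1)
    )


def _nb_exact_test_chunked(
    T: int, A: int, n_a: int, n_b: int, disp: float, rule: str
) -> float:
    """Memory-bounded variant for very large totals: two log-space passes."""
    lobs = _chunk_logw(A, A + 1, T, n_a, n_b, disp)[0]
    tot_parts, sel_parts, low_parts, up_parts = [], [], [], []
    for lo in range(0, T + 1, _CHUNK):
        hi = min(lo + _CHUNK, T + 1)
        lw = _chunk_logw(lo, hi, T, n_a, n_b, disp)
        tot_parts.append(logsumexp(lw))
        if rule == "doubling":
            if lo <= A:
                low_parts.append(logsumexp(lw[: max(0, min(hi, A + 1) - lo)]))
            if hi > A:
                up_parts.append(logsumexp(lw[max(0, A - lo):]))
        else:
            sel = lw[lw <= lobs + _TIE_TOL]
            if sel.size:
                sel_parts.append(logsumexp(sel))
    log_total = logsumexp(tot_parts)
    if rule == "doubling":
        lower = np.exp(logsumexp(low_parts) - log_total)
        upper = np.exp(logsumexp(up_parts) - log_total)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if not sel_parts:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(sel_parts) - log_total)))


def _group_cond_loglik(y: np.ndarray, dispersion: float) -> float:
    """Conditional log-likelihood of within-group splits given group totals.

    y is genes x replicates for ONE group (equalized counts).  Additive terms
    free of the dispersion are dropped; the retained part tends to
    -z * log(n) as phi -> 0 (the Poisson/multinomial limit), which is used
    directly at phi = 0 so the boundary is comparable with interior values.
    """
    n = y.shape[1]
    if n < 2:
        return 0.0
    z = y.sum(axis=1)
    if dispersion <= 0:
        return float(-(z * np.log(n)).sum())
    r = 1.0 / dispersion
    ll = (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        - gammaln(z + n * r)
    )
    return float(ll.sum())


def estimate_common_dispersion(
    m: CountsMatrix, group_a, group_b, per_gene: bool = False
) -> DispersionEstimate:
    """Maximize the summed conditional log-likelihood over a shared phi.

    Counts are pre-scaled to the geometric-mean library size; the estimate is
    clamped to [0, 10].  With ``per_gene``, method-of-moments per-gene
    estimates on the equalized counts are also returned.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    sub = m.counts[group_a + group_b].to_numpy(dtype=float)
    if sub.sum() == 0:
        raise ValueError("no information to estimate dispersion: all counts zero")
    lib = m.library_sizes[group_a + group_b].to_numpy(dtype=float)
    ref = np.exp(np.mean(np.log(lib)))
    eq = np.asarray(np.round(sub * (ref / lib)), dtype=np.int64)
    ya = eq[:, : len(group_a)]
    yb = eq[:, len(group_a):]

    def neg_ll(phi: float) -> float:
        return -(_group_cond_loglik(ya, phi) + _group_cond_loglik(yb, phi))

    res = minimize_scalar(
        neg_ll, bounds=(0.0, _MAX_DISPERSION), method="bounded",
        options={"xatol": 1e-6},
    )
    phi = float(res.x)
    # bounded Brent never returns the boundary exactly; snap when the
    # likelihood is no better than the Poisson limit
    if neg_ll(phi) >= neg_ll(0.0):
        phi = 0.0
    phi = float(np.clip(phi, 0.0, _MAX_DISPERSION))

    pg = None
    if per_gene:
        means, var_parts, dfs = [], [], []
        for y in (ya, yb):
            means.append(y.mean(axis=1))
            var_parts.append(((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
            dfs.append(y.shape[1] - 1)
        mu = (ya.sum(axis=1) + yb.sum(axis=1)) / (ya.shape[1] + yb.shape[1])
        df = max(1, dfs[0] + dfs[1])
        s2 = (var_parts[0] + var_parts[1]) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            pg = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        pg = np.clip(pg, 0.0, _MAX_DISPERSION)
    return DispersionEstimate(common_dispersion=phi, per_gene=pg)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_compare(
    m: CountsMatrix,
    group_a,
    group_b,
    alpha: float = 0.001,
    min_abs_log2fc: float = 1.0,
    dispersion: float | None = None,
    fc_pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene exact-test comparison of two sample groups.

    Returns a frame indexed by gene with columns log2_fold_change (group a
    over group b, mean CPM + pseudocount), p_value, fdr (BH) and significant
    (fdr < alpha and |log2FC| >= min_abs_log2fc).  Dispersion is estimated
    from the data when not supplied.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError(f"groups overlap: {sorted(set(group_a) & set(group_b))}")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    if dispersion is None:
        dispersion = estimate_common_dispersion(m, group_a, group_b).common_dispersion

    cpm = cpm_normalize(m).values
    mean_a = cpm[group_a].mean(axis=1)
    mean_b = cpm[group_b].mean(axis=1)
    log2fc = np.log2((mean_a + fc_pseudocount) / (mean_b + fc_pseudocount))

    lib_a = m.library_sizes[group_a].to_numpy(dtype=float)
    lib_b = m.library_sizes[group_b].to_numpy(dtype=float)
    ca = m.counts[group_a].to_numpy()
    cb = m.counts[group_b].to_numpy()
    pvals = np.empty(m.shape[0])
    for i in range(m.shape[0]):
        pvals[i] = nb_exact_test(ca[i], cb[i], dispersion, lib_a, lib_b)
    fdr = bh_adjust(pvals)
    sig = (fdr < alpha) & (np.abs(log2fc) >= min_abs_log2fc)
    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "fdr": fdr,
            "significant": sig,
        },
        index=m.gene_ids,
    )


def write_de_table(result: pd.DataFrame, path) -> None:
    out = result.rename(
        columns={"log2_fold_change": "log2FC", "p_value": "p", "fdr": "FDR"}
    )
    out.to_csv(path, sep="\t", index_label="gene_id")
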