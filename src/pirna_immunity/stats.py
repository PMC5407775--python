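"""Phenotype statistics: reactivity, correlation/regression, differential
piRNA abundance with pseudo-replicates, maternal deposition, and the ChIP
percent-input / relative-qPCR calculators.

Differential abundance uses trimmed-mean (TMM-style) size factors and a
negative-binomial exact test with a single common dispersion estimated by
method of moments across features; the method tag is recorded in every
output so results are never presented as method-free.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DE_METHOD_TAG = "tmm-common-dispersion-nb-exact"


# ---------------------------------------------------------------------------
# reactivity
# ---------------------------------------------------------------------------

@dataclass
class ReactivityMeasure:
    strain: str
    replicates: list[tuple[int, int]]  # (non_hatched, total)
    percent: float  # mean over replicate percentages
    sd: float | None  # sample SD over >= 2 replicates
    n: int  # total embryos

    @property
    def replicate_percents(self) -> list[float]:
        return [100.0 * nh / tot for nh, tot in self.replicates]


def reactivity(
    replicates: Sequence[tuple[int, int]], strain: str = ""
) -> ReactivityMeasure:
    """Percent non-hatched embryos: per-replicate percent, mean, sample SD, n."""
    if not replicates:
        raise ValueError("at least one replicate required")
    for nh, tot in replicates:
        if tot <= 0:
            raise ValueError("replicate total must be positive")
        if not 0 <= nh <= tot:
            raise ValueError("non_hatched must be within [0, total]")
    percents = [100.0 * nh / tot for nh, tot in replicates]
    mean = float(np.mean(percents))
    sd = float(np.std(percents, ddof=1)) if len(percents) >= 2 else None
    return ReactivityMeasure(
        strain=strain,
        replicates=list(replicates),
        percent=mean,
        sd=sd,
        n=sum(tot for _, tot in replicates),
    )


# ---------------------------------------------------------------------------
# reactivity / piRNA correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float | None
    p_two_sided: float | None
    p_one_sided: float | None
    p_method: str  # "exact-permutation" | "t-approximation"
    slope: float | None = None
    intercept: float | None = None
    adj_r_squared: float | None = None
    conf_level: float = 0.90
    conf_band: pd.DataFrame | None = None
    n: int = 0


def _spearman_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt(float((xc**2).sum() * (yc**2).sum()))
    if denom == 0:
        return math.nan
    return float((xc * yc).sum() / denom)


def spearman_exact(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float]:
    """Spearman rho with exact permutation p-values (two- and one-sided).

    Enumerates all n! permutations of the y ranks; two-sided p is
    P(|rho_perm| >= |rho_obs|), one-sided is P(rho_perm <= rho_obs) for
    negative observed rho (and >= for positive).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = _spearman_rho(xr, yr)
    if math.isnan(rho):
        return rho, math.nan, math.nan
    perms = np.array(list(itertools.permutations(range(n))))
    rho_perm = np.array([_spearman_rho(xr, yr[p]) for p in perms])
    eps = 1e-12
    p_two = float(np.mean(np.abs(rho_perm) >= abs(rho) - eps))
    if rho < 0:
        p_one = float(np.mean(rho_perm <= rho + eps))
    else:
        p_one = float(np.mean(rho_perm >= rho - eps))
    return rho, p_two, p_one


def correlate_reactivity(
    pirna: Sequence[float],
    reactivity_percent: Sequence[float],
    conf_level: float = 0.90,
    exact_limit: int = 8,
) -> CorrelationResult:
    """Spearman correlation of reactivity against piRNA abundance, plus OLS.

    Exact permutation p for n <= ``exact_limit``; t-approximation otherwise.
    The regression (reactivity ~ piRNA) reports adjusted R^2 and a pointwise
    confidence band at ``conf_level``.
    """
    x = np.asarray(pirna, dtype=float)
    y = np.asarray(reactivity_percent, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need matched samples with n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(None, None, None, "undefined", n=x.size)

    if x.size <= exact_limit:
        rho, p_two, p_one = spearman_exact(x, y)
        method = "exact-permutation"
    else:
        res = sps.spearmanr(x, y)
        rho, p_two = float(res.statistic), float(res.pvalue)
        p_one = p_two / 2 if rho != 0 else 0.5
        method = "t-approximation"

    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = fit.get_prediction(sm.add_constant(grid))
    band = pred.conf_int(alpha=1 - conf_level)
    conf_band = pd.DataFrame(
        {"x": grid, "fit": pred.predicted_mean, "lower": band[:, 0], "upper": band[:, 1]}
    )
    return CorrelationResult(
        rho=rho,
        p_two_sided=p_two,
        p_one_sided=p_one,
        p_method=method,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adj_r_squared=float(fit.rsquared_adj),
        conf_level=conf_level,
        conf_band=conf_band,
        n=x.size,
    )


# ---------------------------------------------------------------------------
# differential abundance (pseudo-replicates)
# ---------------------------------------------------------------------------

def tmm_size_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M size factors (normalized to geometric mean 1).

    The reference library is the one whose 75th-percentile count fraction is
    closest to the mean; per-library factors are 2^(trimmed mean of M) using
    genes positive in both libraries, trimming the extremes of the log-ratio
    (M) and abundance (A) distributions.
    """
    mat = counts.to_numpy(dtype=float)
    lib_sizes = mat.sum(axis=0)
    if np.any(lib_sizes <= 0):
        raise ValueError("every library needs a positive total count")
    frac = mat / lib_sizes
    q75 = np.array([np.quantile(frac[:, j][frac[:, j] > 0], 0.75) if (frac[:, j] > 0).any() else 0 for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_j:
            continue
        mask = (mat[:, j] > 0) & (mat[:, ref_j] > 0)
        if mask.sum() < 3:
            continue
        pj = frac[mask, j]
        pr = frac[mask, ref_j]
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        keep = np.ones(mask.sum(), dtype=bool)
        for vals, trim in ((m, trim_m), (a, trim_a)):
            lo, hi = np.quantile(vals, [trim, 1 - trim])
            keep &= (vals >= lo) & (vals <= hi)
        if keep.sum() == 0:
            keep[:] = True
        factors[j] = 2 ** np.mean(m[keep])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def estimate_common_dispersion(norm_counts: pd.DataFrame, groups: Mapping[str, str]) -> float:
    """Pooled method-of-moments NB dispersion from within-group variability.

    phi = max(0, sum(var - mean) / sum(mean^2)) over all (feature, group)
    cells with >= 2 replicates.
    """
    num = 0.0
    den = 0.0
    for g in sorted(set(groups.values())):
        cols = [c for c in norm_counts.columns if groups[c] == g]
        if len(cols) < 2:
            continue
        sub = norm_counts[cols].to_numpy(dtype=float)
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float((v - m).sum())
        den += float((m**2).sum())
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _nb_exact_p(sum_a: float, sum_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Exact two-sided NB test on group sums, conditional on the total.

    Group sums of n i.i.d. NB(mu, phi) counts are NB(n*mu, phi/n).  Under
    the null the per-library mean is estimated from the pooled total; the
    two-sided p sums the conditional probabilities of all splits at most as
    likely as the observed one.
    """
    a_obs = int(round(sum_a))
    total = int(round(sum_a + sum_b))
    if total == 0:
        return math.nan
    mu = total / (n_a + n_b)
    mean_a, mean_b = n_a * mu, n_b * mu

    def logpmf(k: np.ndarray, mean: float, n_libs: int) -> np.ndarray:
        if phi <= 0:
            return sps.poisson.logpmf(k, mean)
        disp = phi / n_libs
        size = 1.0 / disp
        return sps.nbinom.logpmf(k, size, size / (size + mean))

    # restrict enumeration to a generous window around the conditional mean
    sd = math.sqrt(mean_a * (1 + phi * mu)) + math.sqrt(mean_b * (1 + phi * mu))
    lo = max(0, int(mean_a * total / (mean_a + mean_b) - 30 * sd - 10))
    hi = min(total, int(mean_a * total / (mean_a + mean_b) + 30 * sd + 10))
    if a_obs < lo or a_obs > hi:
        lo, hi = 0, total
    ks = np.arange(lo, hi + 1)
    logp = logpmf(ks, mean_a, n_a) + logpmf(total - ks, mean_b, n_b)
    logp_obs = logp[ks == a_obs][0]
    with np.errstate(over="ignore"):
        probs = np.exp(logp - logp.max())
    p = probs[logp <= logp_obs + 1e-9].sum() / probs.sum()
    return min(1.0, float(p))


@dataclass(slots=True)
class DEResult:
    te_id: str
    log2fc: float
    p_value: float
    fdr: float
    mean_weak: float
    mean_strong: float
    pseudocount: float
    method: str = DE_METHOD_TAG


def differential_abundance(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    weak_label: str = "weak",
    strong_label: str = "strong",
) -> pd.DataFrame:
    """Differential piRNA abundance between pseudo-replicate groups.

    ``counts`` is features x libraries (weighted counts, integer-like);
    ``groups`` maps each library to ``weak_label`` or ``strong_label``.
    log2FC is weak over strong on TMM-normalized group means (pseudocount 0
    when both means are positive, 0.5 otherwise); p-values come from the
    common-dispersion NB exact test, with Benjamini-Hochberg FDR alongside.
    """
    libs = list(counts.columns)
    for lib in libs:
        if lib not in groups:
            raise ValueError(f"library {lib!r} has no group assignment")
    weak_cols = [c for c in libs if groups[c] == weak_label]
    strong_cols = [c for c in libs if groups[c] == strong_label]
    if len(weak_cols) < 2 or len(strong_cols) < 2:
        raise ValueError("need >= 2 libraries per group (pseudo-replicates)")

    factors = tmm_size_factors(counts)
    eff_sizes = counts.sum(axis=0) * factors
    scale = float(np.exp(np.mean(np.log(eff_sizes))))
    norm = counts / eff_sizes * scale
    phi = estimate_common_dispersion(norm, dict(groups))

    rows = []
    pvals = []
    for te_id, row in norm.iterrows():
        mw = float(row[weak_cols].mean())
        ms = float(row[strong_cols].mean())
        pc = 0.0 if (mw > 0 and ms > 0) else 0.5
        if mw + pc > 0 and ms + pc > 0:
            lfc = math.log2((mw + pc) / (ms + pc))
        else:
            lfc = math.inf if mw > ms else (-math.inf if ms > mw else 0.0)
        p = _nb_exact_p(
            row[weak_cols].sum(), row[strong_cols].sum(), len(weak_cols), len(strong_cols), phi
        )
        pvals.append(p)
        rows.append(
            {
                "te_id": te_id,
                "log2fc": lfc,
                "p_value": p,
                "mean_weak": mw,
                "mean_strong": ms,
                "pseudocount": pc,
            }
        )
    out = pd.DataFrame(rows).set_index("te_id")
    finite = out["p_value"].notna()
    fdr = np.full(len(out), np.nan)
    if finite.any():
        fdr[finite.to_numpy()] = multipletests(out.loc[finite, "p_value"], method="fdr_bh")[1]
    out["fdr"] = fdr
    out.attrs["method"] = DE_METHOD_TAG
    out.attrs["dispersion"] = phi
    out.attrs["size_factors"] = factors
    return out


# ---------------------------------------------------------------------------
# maternal deposition
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class DepositionRatio:
    te_id: str
    ovary_value: float
    embryo_value: float
    ratio: float | None
    log2_ratio: float | None
    cn_normalized_log2: float | None
    deposition_class: str


def maternal_deposition(
    ovary: pd.DataFrame,
    embryo: pd.DataFrame,
    dna_rpm: Mapping[str, float] | pd.Series | None = None,
    metric: str = "tpm",
    deposition_classes: Mapping[str, str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Ovary/embryo abundance ratios per transposon, optionally copy-number
    normalized (log-ratio dialect on the log2 ovary/embryo ratio).

    ``ovary``/``embryo`` are :func:`pirna_immunity.quant.normalize` tables;
    ``metric`` selects the column ('tpm' per the figure conventions, 'rpm'
    for depth-anchored comparisons).  Transposons with zero embryo signal
    are flagged missing, not dropped.
    """
    if metric not in ("tpm", "rpm"):
        raise ValueError("metric must be 'tpm' or 'rpm'")
    feats = ovary.index.intersection(embryo.index).sort_values()
    dna = pd.Series(dna_rpm, dtype=float) if dna_rpm is not None else None
    rows = []
    for te_id in feats:
        ov = float(ovary.loc[te_id, metric])
        em = float(embryo.loc[te_id, metric])
        if em > 0:
            ratio = ov / em
            log2_ratio = math.log2(ratio) if ratio > 0 else None
        else:
            ratio = None
            log2_ratio = None
        cn = None
        if log2_ratio is not None and dna is not None and te_id in dna.index:
            cn = log2_ratio - math.log2(dna[te_id] + pseudocount)
        rows.append(
            {
                "te_id": te_id,
                "ovary_value": ov,
                "embryo_value": em,
                "ratio": ratio,
                "log2_ratio": log2_ratio,
                "cn_normalized_log2": cn,
                "deposition_class": (deposition_classes or {}).get(te_id, ""),
            }
        )
    out = pd.DataFrame(rows).set_index("te_id")
    out.attrs["metric"] = metric
    return out


# ---------------------------------------------------------------------------
# ChIP / qPCR calculators
# ---------------------------------------------------------------------------

def chip_percent_input(ct_input: float, ct_ip: float, f_d: float = 1.0) -> float:
    """Percent input = 2^(Ct_input - Ct_IP) x F_d x 100."""
    if not (math.isfinite(ct_input) and math.isfinite(ct_ip)):
        raise ValueError("Ct values must be finite")
    if f_d <= 0:
        raise ValueError("dilution factor must be positive")
    return 2.0 ** (ct_input - ct_ip) * f_d * 100.0


@dataclass
class QPCRResult:
    relative_expression: float
    delta_ct: float
    sem: float | None = None
    replicate_values: list[float] = field(default_factory=list)


def qpcr_relative(
    ct_target: float | Sequence[float],
    ct_reference: float | Sequence[float],
    calibrator_delta_ct: float = 0.0,
) -> QPCRResult:
    """Relative expression 2^-ddCt against a reference gene and calibrator.

    Scalar inputs give a single value; paired replicate sequences also
    report the SEM over replicates.
    """
    t = np.atleast_1d(np.asarray(ct_target, dtype=float))
    r = np.atleast_1d(np.asarray(ct_reference, dtype=float))
    if t.shape != r.shape:
        raise ValueError("target and reference Ct shapes must match")
    if not (np.isfinite(t).all() and np.isfinite(r).all()):
        raise ValueError("Ct values must be finite")
    rel = 2.0 ** -((t - r) - calibrator_delta_ct)
    sem = float(sps.sem(rel)) if rel.size >= 3 else None
    return QPCRResult(
        relative_expression=float(rel.mean()),
        delta_ct=float((t - r).mean()),
        sem=sem,
        replicate_values=rel.tolist(),
    )


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * 0.05-0.01, ** 0.01-0.001, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def ttest_with_stars(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, str]:
    """Two-sample t-test helper returning (t, p, stars)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(a, b) and np.all(a == a[0]):
        return 0.0, 1.0, ""
    t, p = sps.ttest_ind(a, b)
    if math.isnan(p):
        p = 1.0
    return float(t), float(p), significance_stars(p)
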