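"""Per-SNP association statistics for case-control genotype tables.

Implements the classical single-locus toolkit for a 3-genotype x 2-status
table: collapse to 2x2 under the heterozygous, extreme (recessive-type) and
dominant genetic models; crude odds ratios with Woolf (log-OR) confidence
intervals; two-sided Fisher exact p-values; covariate-adjusted odds ratios
by binary logistic regression; a 1-df chi-square test of Hardy-Weinberg
equilibrium; and pairwise linkage disequilibrium from unphased genotypes via
EM haplotype-frequency estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import MISSING, DataError, GenotypeDataset

#: genetic collapse models: which genotypes count as exposed vs reference
COLLAPSE_MODELS = ("heterozygous", "extreme", "dominant")

_Z95 = 1.96  # conventional 95% normal quantile, used for all Wald-type CIs


@dataclass
class GenotypeCountTable:
    """3x2 genotype-by-status counts for one SNP in one case group.

    Rows are genotype codes 0/1/2, columns ``[controls, cases]``.
    """

    counts: np.ndarray
    factor: str = ""
    labels: tuple[str, str, str] = ("0", "1", "2")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 2):
            raise DataError("genotype count table must be 3x2")
        if (self.counts < 0).any():
            raise DataError("genotype counts must be non-negative")

    @property
    def n_controls(self) -> int:
        return int(self.counts[:, 0].sum())

    @property
    def n_cases(self) -> int:
        return int(self.counts[:, 1].sum())


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 exposure-by-status counts.

    ``a`` exposed cases, ``b`` unexposed cases, ``c`` exposed controls,
    ``d`` unexposed controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("2x2 cells must be non-negative")


@dataclass
class AssociationResult:
    model: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    table: TwoByTwo | None = None
    ci_method: str = "woolf"
    p_method: str = "fisher"
    zero_corrected: bool = False
    converged: bool = True
    extra: dict = field(default_factory=dict)


@dataclass
class HWEResult:
    chi_square: float
    p_value: float
    expected: tuple[float, float, float]
    variant_freq: float


@dataclass
class LDResult:
    d: float
    d_prime: float
    r_squared: float
    chi_square: float
    chi_square_p: float
    haplotype_freqs: dict[tuple[int, int], float]
    em_iterations: int
    converged: bool
    defined: bool = True
    n: int = 0


# ---------------------------------------------------------------------------
# Tabulation and collapse
# ---------------------------------------------------------------------------

def tabulate(ds: GenotypeDataset, factor: str,
             case_group: str | None = None) -> GenotypeCountTable:
    """Count non-missing genotypes by status (available-case).

    Controls are all subjects with status 0; cases are subjects with status 1,
    optionally restricted to one stratum tag via ``case_group``.
    """
    j = ds.factor_index(factor)
    fdef = ds.factors[j]
    if fdef.kind != "snp":
        raise DataError(f"factor {factor!r} is not a 3-level SNP")
    col = ds.values[:, j]
    counts = np.zeros((3, 2), dtype=np.int64)
    ctrl = ds.status == 0
    case = ds.status == 1
    if case_group is not None:
        case &= ds.group == case_group
    for g in (0, 1, 2):
        counts[g, 0] = int(((col == g) & ctrl).sum())
        counts[g, 1] = int(((col == g) & case).sum())
    labels = tuple(fdef.label_for(g) for g in (0, 1, 2))
    return GenotypeCountTable(counts=counts, factor=factor, labels=labels)


def collapse(table: GenotypeCountTable, model: str) -> TwoByTwo:
    """Collapse a 3x2 genotype table to 2x2 under a genetic model.

    heterozygous: genotype 1 vs 0 (variant homozygotes dropped);
    extreme:      genotype 2 vs 0 (heterozygotes dropped);
    dominant:     genotypes 1+2 (carriers) vs 0.
    """
    c = table.counts
    if model == "heterozygous":
        a, b, cc, d = c[1, 1], c[0, 1], c[1, 0], c[0, 0]
    elif model == "extreme":
        a, b, cc, d = c[2, 1], c[0, 1], c[2, 0], c[0, 0]
    elif model == "dominant":
        a, b, cc, d = c[1, 1] + c[2, 1], c[0, 1], c[1, 0] + c[2, 0], c[0, 0]
    else:
        raise DataError(f"unknown collapse model {model!r}; "
                        f"expected one of {COLLAPSE_MODELS}")
    return TwoByTwo(int(a), int(b), int(cc), int(d))


# ---------------------------------------------------------------------------
# Odds ratios and exact tests
# ---------------------------------------------------------------------------

def _woolf_ci(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log((a * d) / (b * c))
    return math.exp(log_or - _Z95 * se), math.exp(log_or + _Z95 * se)


def crude_odds_ratio(t: TwoByTwo, zero_correction: str = "none",
                     model: str = "") -> AssociationResult:
    """Crude odds ratio (a*d)/(b*c) with a Woolf 95% confidence interval.

    With ``zero_correction="haldane"`` and any zero cell, 0.5 is added to
    all four cells (Haldane-Anscombe) and the result flagged.  With
    ``"none"``, a single zero yields an OR of 0 or +inf; the finite CI bound
    is then taken from the 0.5-corrected cells so that the interval remains
    informative.  A zero in both the numerator and the denominator product
    leaves the OR undefined and raises :class:`DataError`.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if (a * d == 0 and b * c == 0) or (a == 0 and d == 0) \
            or (b == 0 and c == 0):
        raise DataError("odds ratio undefined: two diagonal zero cells")
    p = fisher_exact_p(t)
    if zero_correction not in ("none", "haldane"):
        raise DataError(f"unknown zero correction {zero_correction!r}")

    if min(a, b, c, d) > 0:
        or_ = (a * d) / (b * c)
        lo, hi = _woolf_ci(a, b, c, d)
        return AssociationResult(model=model, or_estimate=or_, ci_low=lo,
                                 ci_high=hi, p_value=p, table=t)

    if zero_correction == "haldane":
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        or_ = (ah * dh) / (bh * ch)
        lo, hi = _woolf_ci(ah, bh, ch, dh)
        return AssociationResult(model=model, or_estimate=or_, ci_low=lo,
                                 ci_high=hi, p_value=p, table=t,
                                 zero_corrected=True)

    # no correction: report the degenerate OR, corrected cells for the
    # finite CI bound only
    lo_c, hi_c = _woolf_ci(a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    if a * d == 0:
        return AssociationResult(model=model, or_estimate=0.0, ci_low=0.0,
                                 ci_high=hi_c, p_value=p, table=t)
    return AssociationResult(model=model, or_estimate=math.inf, ci_low=lo_c,
                             ci_high=math.inf, p_value=p, table=t)


def fisher_exact_p(t: TwoByTwo, mid_p: bool = False) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums hypergeometric probabilities of all same-margin tables whose
    probability does not exceed the observed table's.  ``mid_p=True`` gives
    the mid-P variant: tables strictly less probable count fully, equally
    probable tables (including the observed one) count half.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if not mid_p:
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    # relative tolerance guards float noise in "equally probable"
    eq = np.isclose(probs, p_obs, rtol=1e-7)
    less = (probs < p_obs) & ~eq
    return float(probs[less].sum() + 0.5 * probs[eq].sum())


def adjusted_odds_ratio(ds: GenotypeDataset, factor: str, model: str,
                        covariates: tuple[str, ...] = ("age", "gender"),
                        case_group: str | None = None,
                        maxiter: int = 100) -> AssociationResult:
    """Covariate-adjusted odds ratio from a binary logistic regression.

    Fits status ~ exposure + covariates by maximum likelihood, where the
    exposure indicator follows the chosen collapse model (subjects whose
    genotype the model drops are excluded, as are subjects missing the
    genotype or any covariate).  Returns exp(coefficient) with a Wald 95%
    CI; separation or non-convergence is reported via ``converged=False``
    with NaN estimates.
    """
    import statsmodels.api as sm

    j = ds.factor_index(factor)
    g = ds.values[:, j].astype(float)

    rows = g != MISSING
    if case_group is not None:
        rows &= (ds.status == 0) | (ds.group == case_group)
    if model == "heterozygous":
        rows &= (g == 0) | (g == 1)
        x = (g == 1).astype(float)
    elif model == "extreme":
        rows &= (g == 0) | (g == 2)
        x = (g == 2).astype(float)
    elif model == "dominant":
        x = (g >= 1).astype(float)
    else:
        raise DataError(f"unknown collapse model {model!r}")

    cols = {"exposure": x[rows]}
    if covariates:
        if ds.covariates is None:
            raise DataError("dataset has no covariates")
        for cv in covariates:
            if cv not in ds.covariates.columns:
                raise DataError(f"covariate {cv!r} not present")
            vals = np.asarray(ds.covariates[cv], dtype=float)[rows]
            cols[cv] = vals
    X = np.column_stack(list(cols.values()))
    y = ds.status[rows].astype(float)
    ok = ~np.isnan(X).any(axis=1)
    X, y = X[ok], y[ok]
    # drop constant covariate columns: they carry no information and make
    # the design singular alongside the intercept
    keep = [0] + [k for k in range(1, X.shape[1])
                  if np.unique(X[:, k]).size > 1]
    X = X[:, keep]
    Xc = sm.add_constant(X, has_constant="add")

    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=maxiter)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        converged = False
        fit = None
    if fit is None or not converged or not np.isfinite(fit.bse[1]):
        return AssociationResult(model=model, or_estimate=math.nan,
                                 ci_low=math.nan, ci_high=math.nan,
                                 p_value=math.nan, ci_method="wald",
                                 p_method="wald", converged=False)
    beta = fit.params[1]
    se = fit.bse[1]
    return AssociationResult(
        model=model, or_estimate=math.exp(beta),
        ci_low=math.exp(beta - _Z95 * se), ci_high=math.exp(beta + _Z95 * se),
        p_value=float(fit.pvalues[1]), ci_method="wald", p_method="wald",
        converged=True,
        extra={"n": int(len(y)), "covariates": list(cols)[1:]})


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(counts: tuple[int, int, int] | np.ndarray) -> HWEResult:
    """1-df chi-square goodness-of-fit test of Hardy-Weinberg proportions.

    ``counts`` are observed genotype counts (n0, n1, n2) — conventionally
    taken in controls as a genotyping-quality check.  The variant allele
    frequency is q = (n1 + 2 n2) / 2n and expected counts (p^2 n, 2pq n,
    q^2 n).  A monomorphic sample (q = 0 or 1) is in equilibrium by
    definition: chi-square 0, p 1.
    """
    n0, n1, n2 = (int(x) for x in counts)
    if min(n0, n1, n2) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise DataError("empty genotype counts")
    q = (n1 + 2 * n2) / (2 * n)
    p = 1.0 - q
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    if q == 0.0 or q == 1.0:
        return HWEResult(chi_square=0.0, p_value=1.0, expected=expected,
                         variant_freq=q)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), expected))
    return HWEResult(chi_square=float(chi2),
                     p_value=float(stats.chi2.sf(chi2, df=1)),
                     expected=expected, variant_freq=q)


# ---------------------------------------------------------------------------
# Pairwise linkage disequilibrium (EM over unphased genotypes)
# ---------------------------------------------------------------------------

def _em_haplotypes(n33: np.ndarray, tol: float = 1e-8, max_iter: int = 1000
                   ) -> tuple[np.ndarray, int, bool]:
    """EM haplotype frequencies (f00, f01, f10, f11) from a 3x3 genotype table.

    Indices are variant-allele counts at the two loci.  Only the double
    heterozygote is phase-ambiguous; it is split between the cis (00/11) and
    trans (01/10) configurations proportionally to the current haplotype
    frequencies.  Initialised at linkage-equilibrium products, hence
    deterministic.
    """
    n = n33.sum()
    qa = (n33[1, :].sum() + 2 * n33[2, :].sum()) / (2 * n)
    qb = (n33[:, 1].sum() + 2 * n33[:, 2].sum()) / (2 * n)
    # f[i, j]: haplotype carrying i variant alleles at A, j at B
    f = np.array([[(1 - qa) * (1 - qb), (1 - qa) * qb],
                  [qa * (1 - qb), qa * qb]])
    ndh = n33[1, 1]  # double heterozygotes
    # haplotype contributions fixed by genotype, excluding double hets:
    base = np.zeros((2, 2))
    for ga in range(3):
        for gb in range(3):
            if ga == 1 and gb == 1:
                continue
            cnt = n33[ga, gb]
            if cnt == 0:
                continue
            if ga == 1:
                base[0, gb // 2] += cnt
                base[1, gb // 2] += cnt
            elif gb == 1:
                base[ga // 2, 0] += cnt
                base[ga // 2, 1] += cnt
            else:
                base[ga // 2, gb // 2] += 2 * cnt
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        denom = f[0, 0] * f[1, 1] + f[0, 1] * f[1, 0]
        cis = 0.5 if denom == 0 else f[0, 0] * f[1, 1] / denom
        new = base.copy()
        new[0, 0] += ndh * cis
        new[1, 1] += ndh * cis
        new[0, 1] += ndh * (1 - cis)
        new[1, 0] += ndh * (1 - cis)
        new /= 2 * n
        if np.abs(new - f).max() < tol:
            f = new
            converged = True
            break
        f = new
    return f, it, converged


def ld_pairwise(ds: GenotypeDataset, snp_a: str, snp_b: str,
                tol: float = 1e-8, max_iter: int = 1000) -> LDResult:
    """Pairwise LD between two SNPs from unphased genotypes.

    Haplotype frequencies are estimated by EM; D = p_AB - p_A p_B on the
    variant alleles, D' = |D| / D_max, and r^2 = D^2 / (p_A p_a p_B p_b).
    Also reports a chi-square test of association on the 3x3 genotype table
    (zero rows/columns dropped).  Monomorphic input yields ``defined=False``.
    """
    ja, jb = ds.factor_index(snp_a), ds.factor_index(snp_b)
    ga, gb = ds.values[:, ja], ds.values[:, jb]
    rows = (ga != MISSING) & (gb != MISSING)
    ga, gb = ga[rows], gb[rows]
    n = int(rows.sum())
    if n < 5:
        raise DataError("fewer than 5 subjects with both genotypes available")
    n33 = np.zeros((3, 3), dtype=np.int64)
    np.add.at(n33, (ga, gb), 1)

    qa = (n33[1, :].sum() + 2 * n33[2, :].sum()) / (2 * n)
    qb = (n33[:, 1].sum() + 2 * n33[:, 2].sum()) / (2 * n)
    if qa in (0.0, 1.0) or qb in (0.0, 1.0):
        return LDResult(d=math.nan, d_prime=math.nan, r_squared=math.nan,
                        chi_square=math.nan, chi_square_p=math.nan,
                        haplotype_freqs={}, em_iterations=0, converged=False,
                        defined=False, n=n)

    f, iters, converged = _em_haplotypes(n33, tol=tol, max_iter=max_iter)
    pa = f[1, 0] + f[1, 1]   # variant allele freq at A
    pb = f[0, 1] + f[1, 1]
    d = f[1, 1] - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = 0.0 if dmax == 0 else abs(d) / dmax
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))

    sub = n33[n33.sum(axis=1) > 0][:, n33.sum(axis=0) > 0]
    if min(sub.shape) < 2:
        chi2, chi2_p = 0.0, 1.0
    else:
        chi2, chi2_p = stats.chi2_contingency(sub)[:2]
    return LDResult(d=float(d), d_prime=float(min(d_prime, 1.0)),
                    r_squared=float(min(r2, 1.0)), chi_square=float(chi2),
                    chi_square_p=float(chi2_p),
                    haplotype_freqs={(i, j): float(f[i, j])
                                     for i in (0, 1) for j in (0, 1)},
                    em_iterations=iters, converged=converged, n=n)
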