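"""Association statistics for haplotype patterns.

Case-control side: weighted haplotype logistic regression on posterior-
expected dosages, with a global likelihood-ratio test against the
covariates-only model, rare-haplotype pooling (haplotypes under the rare
threshold are collapsed into one predictor, itself dropped when its pooled
mass stays under the threshold), and per-haplotype Wald tests.

Family side: the weighted transmission/disequilibrium test (TDT).  Every
weighted family configuration contributes its weight to the transmitted (T)
or untransmitted (U) count of a haplotype for each heterozygous parent and
affected child; the biallelic statistic is (T-U)^2/(T+U), the multiallelic
(pattern-level) statistic the Spielman-Ewens form.  Odds ratios are T/U with
exact-McNemar (Clopper-Pearson) intervals on the rounded counts.

Both Bonferroni corrections of the search workflow live here: the search
correction over all patterns up to the final length, and the replication
correction over the number of patterns carried into the family set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .phasing import FamilyConfig, HaplotypeFreqs

__all__ = [
    "RegressionConfig",
    "GlobalTestResult",
    "HaplotypeEffect",
    "TDTResult",
    "PoolResult",
    "pool_rare",
    "haplotype_lrt",
    "single_haplotype_test",
    "weighted_tdt",
    "tdt_from_counts",
    "tdt_global",
    "mcnemar_exact_ci",
    "bonferroni_search",
    "bonferroni_replication",
]

SEPARATION_BETA = 15.0  # |beta| beyond this is treated as (quasi-)separation
MAX_FIT_ITER = 100


@dataclass
class RegressionConfig:
    """Pooling and modelling options for the haplotype regression.

    ``rare_threshold`` declares haplotypes rare (default 5%); haplotypes are
    kept as individual predictors down to ``min_keep_freq`` (defaults to the
    rare threshold; set to e.g. 0.001 to study low-frequency haplotypes, as
    in composite analyses that append rare mutation loci).  The baseline is
    always the most frequent kept haplotype.
    """

    rare_threshold: float = 0.05
    min_keep_freq: float | None = None
    covariates: np.ndarray | None = None

    @property
    def keep_threshold(self) -> float:
        t = self.rare_threshold if self.min_keep_freq is None else self.min_keep_freq
        if not 0.0 <= t <= self.rare_threshold <= 1.0:
            raise ValueError("need 0 <= min_keep_freq <= rare_threshold <= 1")
        return t


@dataclass
class GlobalTestResult:
    chi2: float
    df: int
    p: float
    loglik_full: float = math.nan
    loglik_reduced: float = math.nan
    nagelkerke_r2: float = math.nan
    aic: float = math.nan
    bic: float = math.nan
    skipped: bool = False
    skip_reason: Literal["none", "all_rare", "separation", "no_variation"] = "none"

    @classmethod
    def skip(cls, reason: str) -> "GlobalTestResult":
        return cls(chi2=math.nan, df=0, p=1.0, skipped=True, skip_reason=reason)


@dataclass
class HaplotypeEffect:
    haplotype: str | None
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float


@dataclass
class TDTResult:
    haplotype: str | None
    T: float
    U: float
    chi2: float
    p: float
    or_: float  # T/U; inf when U == 0, nan when both are 0
    ci95: tuple[float, float]
    defined: bool = True


@dataclass
class PoolResult:
    kept: list[str]  # non-rare haplotypes, descending frequency (incl. baseline)
    baseline: str | None
    pooled: list[str]  # rare haplotypes collapsed into one column
    drop_pooled: bool  # pooled mass itself under the rare threshold
    skip: bool  # no non-rare haplotype -> no model

    @property
    def predictors(self) -> list[str]:
        """Kept haplotypes minus the baseline, in descending frequency."""
        return [h for h in self.kept if h != self.baseline]


def pool_rare(
    freqs: HaplotypeFreqs | Mapping[str, float], config: RegressionConfig | None = None
) -> PoolResult:
    """Apply the rare-haplotype pooling and skip rules to EM frequencies.

    Haplotypes below the keep threshold are pooled into one synthetic
    predictor; the pooled column is dropped when its total mass is still
    below the rare threshold (the sparse-data guard).  If no haplotype
    clears the threshold, the whole pattern is skipped.
    """
    config = config or RegressionConfig()
    fmap = freqs.freqs if isinstance(freqs, HaplotypeFreqs) else dict(freqs)
    thr = config.keep_threshold
    items = sorted(fmap.items(), key=lambda kv: (-kv[1], kv[0]))
    kept = [h for h, f in items if f >= thr]
    pooled = [h for h, f in items if f < thr]
    pooled_mass = sum(fmap[h] for h in pooled)
    return PoolResult(
        kept=kept,
        baseline=kept[0] if kept else None,
        pooled=pooled,
        drop_pooled=pooled_mass < config.rare_threshold,
        skip=not kept,
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _as_binary(phenotype: np.ndarray) -> np.ndarray:
    """Map linkage phenotype codes {1,2} to {0,1}; anything else is an error."""
    ph = np.asarray(phenotype)
    if not np.isin(ph, (1, 2)).all():
        raise ValueError("phenotype must be coded 1 (unaffected) / 2 (affected)")
    y = (ph == 2).astype(float)
    if y.min() == y.max():
        raise ValueError("both phenotype classes must be present")
    return y


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Newton fit; returns the result object or None on (quasi-)separation."""
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is detected below
            with np.errstate(all="ignore"):
                res = sm.Logit(y, X).fit(
                    method="newton", maxiter=MAX_FIT_ITER, disp=0
                )
    except Exception:
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    if np.abs(res.params).max() > SEPARATION_BETA:
        return None
    if not np.isfinite(res.llf):
        return None
    return res


def haplotype_lrt(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> GlobalTestResult:
    """Global likelihood-ratio test of a pattern's haplotype dosage columns.

    Full model: intercept + dosage columns (+ covariates); reduced model:
    intercept (+ covariates).  The chi-square df is the number of dosage
    columns.  Nagelkerke R^2 is computed against the intercept-only null;
    AIC/BIC refer to the full model.
    """
    y = _as_binary(phenotype)
    n = len(y)
    D = np.atleast_2d(np.asarray(dosages, dtype=float))
    if D.shape[0] != n:
        D = D.T
    if D.size == 0 or D.shape[1] == 0:
        return GlobalTestResult.skip("no_variation")
    if np.any(D.std(axis=0) == 0.0):
        return GlobalTestResult.skip("no_variation")

    parts = [np.ones((n, 1)), D]
    red_parts = [np.ones((n, 1))]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        parts.append(C)
        red_parts.append(C)
    X_full = np.hstack(parts)
    X_red = np.hstack(red_parts)

    full = _fit_logit(y, X_full)
    red = _fit_logit(y, X_red)
    if full is None or red is None:
        return GlobalTestResult.skip("separation")

    df = D.shape[1]
    chi2 = max(0.0, 2.0 * (full.llf - red.llf))
    p = float(stats.chi2.sf(chi2, df))

    # intercept-only null for Nagelkerke R^2
    n1 = y.sum()
    pbar = n1 / n
    ll0 = float(n1 * math.log(pbar) + (n - n1) * math.log(1.0 - pbar))
    chi2_vs_null = max(0.0, 2.0 * (full.llf - ll0))
    r2_cs = 1.0 - math.exp(-chi2_vs_null / n)
    r2_max = 1.0 - math.exp(2.0 * ll0 / n)
    k = X_full.shape[1]
    return GlobalTestResult(
        chi2=chi2,
        df=df,
        p=p,
        loglik_full=float(full.llf),
        loglik_reduced=float(red.llf),
        nagelkerke_r2=r2_cs / r2_max if r2_max > 0 else math.nan,
        aic=2.0 * k - 2.0 * float(full.llf),
        bic=k * math.log(n) - 2.0 * float(full.llf),
    )


def single_haplotype_test(
    dosage_h: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    haplotype: str | None = None,
) -> HaplotypeEffect:
    """Wald test of one haplotype's dosage column (per-haplotype OR and CI)."""
    y = _as_binary(phenotype)
    d = np.asarray(dosage_h, dtype=float).reshape(-1, 1)
    parts = [np.ones((len(y), 1)), d]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != len(y):
            C = C.T
        parts.append(C)
    res = _fit_logit(y, np.hstack(parts))
    if res is None:
        raise ValueError("single-haplotype fit failed (separation or no fit)")
    beta = float(res.params[1])
    se = float(res.bse[1])
    z = beta / se if se > 0 else math.inf
    return HaplotypeEffect(
        haplotype=haplotype,
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci95=(math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        p=float(2.0 * stats.norm.sf(abs(z))),
    )


# ---------------------------------------------------------------------------
# weighted TDT
# ---------------------------------------------------------------------------

def mcnemar_exact_ci(
    T_int: int, U_int: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) CI for the T/U odds ratio on integer counts.

    The binomial parameter T/(T+U) gets an exact two-sided interval which is
    mapped to the odds-ratio scale p/(1-p); ``U == 0`` yields an infinite
    upper endpoint.
    """
    n = T_int + U_int
    if n < 1:
        raise ValueError("need T + U >= 1")
    alpha = 1.0 - level
    p_lo = 0.0 if T_int == 0 else float(stats.beta.ppf(alpha / 2, T_int, n - T_int + 1))
    p_hi = 1.0 if T_int == n else float(stats.beta.ppf(1 - alpha / 2, T_int + 1, n - T_int))
    lo = p_lo / (1.0 - p_lo) if p_lo < 1.0 else math.inf
    hi = p_hi / (1.0 - p_hi) if p_hi < 1.0 else math.inf
    return (lo, hi)


def tdt_from_counts(T: float, U: float, haplotype: str | None = None) -> TDTResult:
    """Weighted-TDT statistics from transmitted/untransmitted counts.

    chi2 = (T-U)^2/(T+U) on 1 df; OR = T/U; the exact CI is computed on the
    nearest-integer counts.  T + U = 0 returns a flagged null result.
    """
    if T < 0 or U < 0:
        raise ValueError("counts must be non-negative")
    if T + U == 0:
        return TDTResult(
            haplotype=haplotype, T=0.0, U=0.0, chi2=0.0, p=1.0,
            or_=math.nan, ci95=(math.nan, math.nan), defined=False,
        )
    chi2 = (T - U) ** 2 / (T + U)
    p = float(stats.chi2.sf(chi2, 1))
    or_ = T / U if U > 0 else math.inf
    Ti, Ui = round(T), round(U)
    ci = mcnemar_exact_ci(Ti, Ui) if Ti + Ui >= 1 else (math.nan, math.nan)
    return TDTResult(haplotype=haplotype, T=T, U=U, chi2=chi2, p=p, or_=or_, ci95=ci)


def _count_tu(
    configs: Iterable[FamilyConfig], h: str, affected_only: bool
) -> tuple[float, float]:
    T = U = 0.0
    for cfg in configs:
        for (tf, tm), affected in zip(cfg.transmissions, cfg.child_affected):
            if affected_only and not affected:
                continue
            for pair, transmitted in (
                (cfg.father_pair, tf),
                (cfg.mother_pair, tm),
            ):
                if (pair[0] == h) != (pair[1] == h):  # heterozygous for h
                    if transmitted == h:
                        T += cfg.weight
                    else:
                        U += cfg.weight
    return T, U


def weighted_tdt(
    configs: Sequence[FamilyConfig], h: str, affected_only: bool = True
) -> TDTResult:
    """Weighted TDT for one haplotype over weighted family configurations.

    Every parent heterozygous for ``h`` (exactly one copy) contributes the
    configuration weight to T if it transmitted ``h`` to the (affected)
    child, otherwise to U.
    """
    T, U = _count_tu(configs, h, affected_only)
    return tdt_from_counts(T, U, haplotype=h)


def tdt_global(
    configs: Sequence[FamilyConfig],
    hap_set: Sequence[str],
    method: Literal["multiallelic", "minp"] = "multiallelic",
    affected_only: bool = True,
) -> GlobalTestResult:
    """Pattern-level family test over a set of haplotypes.

    Default is the Spielman-Ewens multiallelic statistic
    ``((H-1)/H) * sum_h (T_h-U_h)^2/(T_h+U_h)`` on H-1 df over the H
    haplotypes with informative transmissions; ``method='minp'`` instead
    Bonferroni-adjusts the smallest per-haplotype p by H.  With fewer than
    two informative haplotypes the single biallelic test is used.
    """
    tu = [(h, *_count_tu(configs, h, affected_only)) for h in hap_set]
    usable = [(h, T, U) for h, T, U in tu if T + U > 0]
    H = len(usable)
    if H == 0:
        return GlobalTestResult.skip("no_variation")
    if H == 1:
        r = tdt_from_counts(usable[0][1], usable[0][2])
        return GlobalTestResult(chi2=r.chi2, df=1, p=r.p)
    if method == "minp":
        pmin = min(tdt_from_counts(T, U).p for _, T, U in usable)
        return GlobalTestResult(
            chi2=math.nan, df=H - 1, p=min(1.0, pmin * H)
        )
    chi2 = (H - 1) / H * sum((T - U) ** 2 / (T + U) for _, T, U in usable)
    return GlobalTestResult(chi2=chi2, df=H - 1, p=float(stats.chi2.sf(chi2, H - 1)))


# ---------------------------------------------------------------------------
# multiple-testing corrections
# ---------------------------------------------------------------------------

def bonferroni_search(p: float, n_snps: int, max_len: int) -> tuple[float, int]:
    """Search-strategy Bonferroni correction over all patterns up to max_len.

    The factor is the number of possible SNP subsets of size 1..max_len,
    ``sum_i C(n_snps, i)``; returns (corrected p capped at 1, factor).
    """
    if not 1 <= max_len <= n_snps:
        raise ValueError("need n_snps >= max_len >= 1")
    factor = sum(math.comb(n_snps, i) for i in range(1, max_len + 1))
    return (min(1.0, p * factor), factor)


def bonferroni_replication(p: float, n_tested: int) -> float:
    """Bonferroni correction over the number of patterns replicated."""
    if n_tested < 1:
        raise ValueError("need n_tested >= 1")
    return min(1.0, p * n_tested)
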