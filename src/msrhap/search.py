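"""The multi-locus stepwise regression (MSR) search engine.

The search starts from all SNP pairs, scores every pattern with a global
haplotype association test (case-control likelihood-ratio test or family
TDT), keeps the ``nt`` best patterns, and repeatedly extends each kept
pattern by one SNP from the region.  It terminates when no SNPs remain, a
maximum pattern length is reached, or the empirical stop criterion fires:
the arithmetic mean of the ten best -log10 p values no longer improves by
more than the configured relative threshold (default 10%), in which case the
previous step's ranked list is the final result.  Final p values carry the
search Bonferroni correction over all possible patterns up to the final
length.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import assoc, phasing
from .assoc import GlobalTestResult, RegressionConfig
from .dataio import PedigreeDataset

__all__ = [
    "SearchConfig",
    "PatternResult",
    "StepSummary",
    "enumerate_pairs",
    "evaluate_pattern",
    "msr_step",
    "stop_check",
    "run_msr",
    "replicate_patterns",
    "steps_to_frame",
]


@dataclass
class SearchConfig:
    """Tuning knobs of the stepwise search (defaults: the reference workflow)."""

    nt: int = 300
    max_snp: int = 10
    stop_rel_decrease: float = 0.10
    top_k_for_stop: int = 10
    engine: Literal["case_control", "family"] = "case_control"
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    em_tol: float = 1e-8
    em_max_iter: int = 500

    def __post_init__(self) -> None:
        if self.nt < 1:
            raise ValueError("nt must be >= 1")
        if self.max_snp < 2:
            raise ValueError("max_snp must be >= 2")
        if not 0.0 < self.stop_rel_decrease < 1.0:
            raise ValueError("stop_rel_decrease must be in (0, 1)")


@dataclass
class PatternResult:
    loci: tuple[str, ...]  # order of addition (labels haplotype positions)
    key: tuple[str, ...]  # sorted snp_id set: canonical identity
    global_p: float
    test: GlobalTestResult
    corrected_p: float | None = None

    @property
    def skipped(self) -> bool:
        return self.test.skipped


@dataclass
class StepSummary:
    k: int
    ranked: list[PatternResult]
    mean_neglog10: float
    rel_change: float  # vs previous step; nan for the pair step
    stopped: bool  # stop criterion fired when moving past this step
    n_evaluated: int
    n_skipped: int
    is_final: bool = False


def _canon(loci: Sequence[str]) -> tuple[str, ...]:
    return tuple(sorted(loci))


def enumerate_pairs(snp_ids: Sequence[str]) -> list[tuple[str, ...]]:
    """All C(n,2) unordered SNP pairs, each once."""
    ids = list(snp_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 SNPs to enumerate pairs")
    return [tuple(c) for c in itertools.combinations(ids, 2)]


def evaluate_pattern(
    dataset: PedigreeDataset,
    loci: Sequence[str],
    config: SearchConfig | None = None,
) -> PatternResult:
    """Score one SNP pattern with the engine's global test.

    Case-control: EM phasing, rare pooling, dosage LRT (individuals with a
    missing phenotype are phased but excluded from the regression).
    Family: child-restricted EM then the multiallelic weighted TDT.
    Skipped patterns (all haplotypes rare, separation, no variation) carry
    the p = 1 sentinel and rank last.
    """
    config = config or SearchConfig()
    loci = tuple(loci)
    if config.engine == "family":
        freqs, cfgs = phasing.em_families(
            dataset, loci, tol=config.em_tol, max_iter=config.em_max_iter
        )
        test = assoc.tdt_global(cfgs, [h for h, _ in freqs.sorted_items()])
    else:
        freqs, post = phasing.em_unrelated(
            dataset, loci, tol=config.em_tol, max_iter=config.em_max_iter
        )
        pool = assoc.pool_rare(freqs, config.regression)
        if pool.skip:
            test = GlobalTestResult.skip("all_rare")
        else:
            D, names = phasing.expected_dosages(post, pool.kept)
            mat = {h: D[:, j] for j, h in enumerate(names)}
            X = [mat[h] for h in pool.predictors]
            # rare haplotypes all fall into the "other" column
            if pool.pooled and not pool.drop_pooled and "other" in mat:
                X.append(mat["other"])
            ph = dataset.phenotypes
            use = np.isin(ph, (1, 2))
            if not X:
                test = GlobalTestResult.skip("no_variation")
            else:
                Xm = np.column_stack(X)[use]
                cov = config.regression.covariates
                cov = cov[use] if cov is not None else None
                test = assoc.haplotype_lrt(Xm, ph[use], cov)
    return PatternResult(
        loci=loci, key=_canon(loci), global_p=float(test.p), test=test
    )


def _rank(results: list[PatternResult]) -> list[PatternResult]:
    # ascending p; skipped (p = 1 sentinel) last; ties by canonical key
    return sorted(results, key=lambda r: (r.skipped, r.global_p, r.key))


def _mean_neglog10(ranked: list[PatternResult], top_k: int) -> float:
    usable = [r for r in ranked if not r.skipped]
    if len(usable) < top_k:
        warnings.warn(
            f"fewer than {top_k} valid patterns available for the stop "
            f"criterion; using all {len(usable)}"
        )
    top = usable[: top_k] if usable else ranked[: top_k]
    return float(np.mean([-math.log10(max(r.global_p, 1e-300)) for r in top]))


def stop_check(prev_mean: float, curr_mean: float, threshold: float = 0.10) -> bool:
    """True (continue) iff the mean -log10 p improved by more than threshold."""
    if prev_mean <= 0:
        raise ValueError("previous step mean must be positive")
    return (curr_mean - prev_mean) / prev_mean > threshold


def _evaluate_all(
    keys: list[tuple[str, ...]],
    dataset: PedigreeDataset,
    config: SearchConfig,
    cache: dict[tuple[str, ...], PatternResult],
    loci_of: dict[tuple[str, ...], tuple[str, ...]],
) -> list[PatternResult]:
    out = []
    for key in keys:
        if key not in cache:
            cache[key] = evaluate_pattern(dataset, loci_of[key], config)
        out.append(cache[key])
    return out


def msr_step(
    prev: StepSummary,
    dataset: PedigreeDataset,
    all_snps: Sequence[str],
    config: SearchConfig,
    cache: dict[tuple[str, ...], PatternResult] | None = None,
) -> StepSummary:
    """Extend every kept pattern by one SNP and re-rank.

    Candidate patterns reached from several parents are deduplicated by
    their canonical (sorted) SNP-set key and evaluated once; the first
    addition order encountered labels the pattern.
    """
    if not prev.ranked:
        raise ValueError("previous step has no patterns to extend")
    cache = cache if cache is not None else {}
    loci_of: dict[tuple[str, ...], tuple[str, ...]] = {}
    for pat in prev.ranked:
        for s in all_snps:
            if s in pat.key:
                continue
            loci = (*pat.loci, s)
            key = _canon(loci)
            loci_of.setdefault(key, loci)
    if not loci_of:
        return StepSummary(
            k=prev.k + 1, ranked=[], mean_neglog10=math.nan,
            rel_change=math.nan, stopped=True, n_evaluated=0, n_skipped=0,
        )
    results = _evaluate_all(sorted(loci_of), dataset, config, cache, loci_of)
    ranked = _rank(results)[: config.nt]
    mean = _mean_neglog10(ranked, config.top_k_for_stop)
    rel = (mean - prev.mean_neglog10) / prev.mean_neglog10
    return StepSummary(
        k=prev.k + 1,
        ranked=ranked,
        mean_neglog10=mean,
        rel_change=rel,
        stopped=False,
        n_evaluated=len(results),
        n_skipped=sum(r.skipped for r in results),
    )


def run_msr(
    dataset: PedigreeDataset, config: SearchConfig | None = None
) -> list[StepSummary]:
    """Run the full stepwise search; returns one summary per step.

    The step whose ranked list is the final result is flagged ``is_final``
    (the last step whose extension did not clear the stop criterion is the
    final one, mirroring a stop at length k after observing the k -> k+1
    change), and its patterns carry search-corrected p values.
    """
    config = config or SearchConfig()
    snp_ids = dataset.snp_ids
    cache: dict[tuple[str, ...], PatternResult] = {}
    loci_of = {_canon(p): p for p in enumerate_pairs(snp_ids)}
    results = _evaluate_all(sorted(loci_of), dataset, config, cache, loci_of)
    ranked = _rank(results)[: config.nt]
    steps = [
        StepSummary(
            k=2,
            ranked=ranked,
            mean_neglog10=_mean_neglog10(ranked, config.top_k_for_stop),
            rel_change=math.nan,
            stopped=False,
            n_evaluated=len(results),
            n_skipped=sum(r.skipped for r in results),
        )
    ]
    final = steps[0]
    while steps[-1].k < config.max_snp:
        nxt = msr_step(steps[-1], dataset, snp_ids, config, cache)
        if not nxt.ranked:
            break
        steps.append(nxt)
        if not stop_check(
            steps[-2].mean_neglog10, nxt.mean_neglog10, config.stop_rel_decrease
        ):
            steps[-2].stopped = True
            final = steps[-2]
            break
        final = nxt
    final.is_final = True
    for r in final.ranked:
        r.corrected_p, _ = assoc.bonferroni_search(
            r.global_p, len(snp_ids), final.k
        )
    return steps


def replicate_patterns(
    patterns: Sequence[PatternResult | Sequence[str]],
    family_dataset: PedigreeDataset,
    config: SearchConfig | None = None,
) -> pd.DataFrame:
    """Test discovery patterns in an independent family set (weighted TDT).

    Each pattern's TDT p is Bonferroni-corrected by the number of patterns
    tested.  The result is sorted by replication p; the discovery order is
    preserved in ``discovery_rank``.
    """
    if len(patterns) == 0:
        raise ValueError("no patterns to replicate")
    config = config or SearchConfig(engine="family")
    config.engine = "family"
    known = set(family_dataset.snp_ids)
    rows = []
    for rank, pat in enumerate(patterns, start=1):
        loci = tuple(pat.loci) if isinstance(pat, PatternResult) else tuple(pat)
        missing = [s for s in loci if s not in known]
        if missing:
            raise KeyError(
                f"pattern SNPs absent from family dataset: {', '.join(missing)}"
            )
        res = evaluate_pattern(family_dataset, loci, config)
        rows.append(
            {
                "discovery_rank": rank,
                "snps": ",".join(loci),
                "discovery_p": (
                    pat.global_p if isinstance(pat, PatternResult) else math.nan
                ),
                "discovery_p_corrected": (
                    pat.corrected_p if isinstance(pat, PatternResult) else math.nan
                ),
                "tdt_chi2": res.test.chi2,
                "tdt_df": res.test.df,
                "tdt_p": res.global_p,
                "tdt_p_corrected": assoc.bonferroni_replication(
                    res.global_p, len(patterns)
                ),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["tdt_p", "snps"], kind="mergesort", ignore_index=True
    )


def steps_to_frame(
    steps: Sequence[StepSummary], n_snps: int | None = None
) -> pd.DataFrame:
    """Flatten step summaries into one table (per-step TSV layout)."""
    rows = []
    for step in steps:
        for rank, r in enumerate(step.ranked, start=1):
            corr = r.corrected_p
            if corr is None and n_snps is not None:
                corr, _ = assoc.bonferroni_search(r.global_p, n_snps, step.k)
            rows.append(
                {
                    "step": step.k,
                    "rank": rank,
                    "snps": ",".join(r.loci),
                    "p": r.global_p,
                    "p_corrected": corr,
                    "chi2": r.test.chi2,
                    "df": r.test.df,
                    "skip_reason": r.test.skip_reason,
                    "nagelkerke_r2": r.test.nagelkerke_r2,
                    "aic": r.test.aic,
                    "bic": r.test.bic,
                }
            )
    return pd.DataFrame(rows)
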