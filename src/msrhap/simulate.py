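"""Seeded generators of case-control and nuclear-family genotype data.

The generators draw haplotypes from a Hardy-Weinberg pool and plant a
logistic disease effect on a designated risk haplotype: affection is
Bernoulli(logistic(baseline_logit + log_or * copies-of-risk-haplotype)).
Case/control quotas and the >= 2-affected-sibling family ascertainment are
met by rejection sampling (vectorized in batches), so the sampled genotype
distributions are exact conditionals of the generating model.  All
randomness flows from one ``numpy`` generator seeded by ``SimConfig.seed``.

Study-scale defaults mirror a candidate-region GWAS follow-up: ~1,000 cases
and ~1,000 controls, a few hundred nuclear families with two children and
both affected, and a baseline logit of -1.7 (about 15% background disease
probability, a realistic childhood-prevalence figure for a common complex
skin disease).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dataio import Individual, PedigreeDataset, SnpRecord

__all__ = ["SimConfig", "sim_case_control", "sim_families", "sim_msr_scenario"]

MAX_CANDIDATES = 10_000_000  # rejection-sampling iteration cap


@dataclass
class SimConfig:
    """Generating model for the synthetic datasets.

    ``hap_pool`` maps haplotype strings (over {'1','2'}) to frequencies that
    sum to 1; ``risk_hap`` must be one of them (or None for a pure null).
    ``log_or`` is the per-copy log odds ratio of the risk haplotype.  In
    :func:`sim_msr_scenario` the pool describes only the planted loci and
    neutral loci are filled in independently.
    """

    hap_pool: Mapping[str, float]
    risk_hap: str | None = None
    log_or: float = 0.0
    baseline_logit: float = -1.7
    n_cases: int = 1000
    n_controls: int = 1000
    n_families: int = 250
    children_per_family: int = 2
    min_affected_children: int = 2
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.hap_pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"hap_pool frequencies sum to {total}, not 1")
        lengths = {len(h) for h in self.hap_pool}
        if len(lengths) != 1:
            raise ValueError("hap_pool haplotypes must share one length")
        if self.risk_hap is not None and self.risk_hap not in self.hap_pool:
            raise ValueError("risk_hap must be drawn from hap_pool")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_loci(self) -> int:
        return len(next(iter(self.hap_pool)))


def _pool_arrays(config: SimConfig) -> tuple[np.ndarray, np.ndarray, int]:
    haps = sorted(config.hap_pool)
    mat = np.array([[int(c) for c in h] for h in haps], dtype=np.int8)
    freqs = np.array([config.hap_pool[h] for h in haps], dtype=float)
    freqs = freqs / freqs.sum()
    risk = haps.index(config.risk_hap) if config.risk_hap is not None else -1
    return mat, freqs, risk


def _affection(rng, dosage: np.ndarray, config: SimConfig) -> np.ndarray:
    logit = config.baseline_logit + config.log_or * dosage
    return rng.random(dosage.shape) < 1.0 / (1.0 + np.exp(-logit))


def _snp_records(n_loci: int, prefix: str = "snp") -> list[SnpRecord]:
    return [
        SnpRecord(
            snp_id=f"{prefix}{j + 1}", chrom="1", pos_bp=10_000 * (j + 1),
            code_minor="1", code_major="2",
        )
        for j in range(n_loci)
    ]


def _mask_missing(rng, geno: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0.0:
        geno = geno.copy()
        geno[rng.random(geno.shape) < rate] = 0
    return geno


def _cc_individuals(n_cases: int, n_controls: int) -> list[Individual]:
    return [
        Individual(family_id=f"F{i + 1}", individual_id="1",
                   sex=0, phenotype=2 if i < n_cases else 1)
        for i in range(n_cases + n_controls)
    ]


def _fill_quotas(rng, config: SimConfig, draw_batch):
    """Run batched rejection sampling until case/control quotas are met.

    ``draw_batch(batch_size)`` must return (genotypes (B, L, 2), dosage (B,)).
    Returns genotypes stacked cases-first.
    """
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    n_case = n_ctrl = 0
    drawn = 0
    batch = int(max(1024, 2 * (config.n_cases + config.n_controls)))
    while n_case < config.n_cases or n_ctrl < config.n_controls:
        if drawn >= MAX_CANDIDATES:
            raise RuntimeError(
                "case/control quotas unattainable within the candidate cap"
            )
        geno, dosage = draw_batch(batch)
        drawn += batch
        aff = _affection(rng, dosage, config)
        take_case = geno[aff][: config.n_cases - n_case]
        take_ctrl = geno[~aff][: config.n_controls - n_ctrl]
        if len(take_case):
            cases.append(take_case)
            n_case += len(take_case)
        if len(take_ctrl):
            ctrls.append(take_ctrl)
            n_ctrl += len(take_ctrl)
    return np.concatenate(cases + ctrls, axis=0)


def sim_case_control(config: SimConfig) -> PedigreeDataset:
    """Sample unrelated cases and controls from the planted-effect model.

    Candidates draw two haplotypes i.i.d. from the pool (HWE), get affection
    from the logistic model, and are accepted against the case/control
    quotas until both are met.  Each allele is independently masked to
    missing at ``missing_rate``.
    """
    if config.n_cases < 1 or config.n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(config.seed)
    mat, freqs, risk = _pool_arrays(config)

    def draw(batch: int):
        idx = rng.choice(len(freqs), size=(batch, 2), p=freqs)
        geno = mat[idx].transpose(0, 2, 1)  # (B, L, 2)
        dosage = (idx == risk).sum(axis=1) if risk >= 0 else np.zeros(batch)
        return geno, dosage

    geno = _fill_quotas(rng, config, draw)
    geno = _mask_missing(rng, geno, config.missing_rate)
    return PedigreeDataset(
        individuals=_cc_individuals(config.n_cases, config.n_controls),
        snps=_snp_records(config.n_loci), genotypes=geno, mode="case_control",
    )


def sim_families(config: SimConfig) -> PedigreeDataset:
    """Sample ascertained nuclear families (>= min_affected affected kids).

    Parental haplotypes are drawn from the pool; each child receives one
    haplotype per parent, chosen uniformly and without recombination across
    the pattern loci; affection follows the same logistic model.  A family
    enters the sample only if at least ``min_affected_children`` of its
    ``children_per_family`` children are affected.
    """
    if config.n_families < 1:
        raise ValueError("need at least one family")
    if config.children_per_family < config.min_affected_children:
        raise ValueError("children_per_family < min_affected_children")
    rng = np.random.default_rng(config.seed)
    mat, freqs, risk = _pool_arrays(config)
    nc = config.children_per_family

    kept_par: list[np.ndarray] = []
    kept_child: list[np.ndarray] = []
    kept_aff: list[np.ndarray] = []
    n_fam = 0
    drawn = 0
    batch = max(1024, 8 * config.n_families)
    while n_fam < config.n_families:
        if drawn >= MAX_CANDIDATES:
            raise RuntimeError("family ascertainment unattainable within cap")
        par = rng.choice(len(freqs), size=(batch, 4), p=freqs)  # f1 f2 m1 m2
        drawn += batch
        pick = rng.integers(0, 2, size=(batch, nc, 2))
        rows = np.arange(batch)[:, None]
        child = np.stack(
            [par[rows, pick[:, :, 0]], par[rows, 2 + pick[:, :, 1]]], axis=2
        )  # (B, nc, 2) haplotype pool indices
        dosage = (
            (child == risk).sum(axis=2) if risk >= 0 else np.zeros((batch, nc))
        )
        aff = _affection(rng, dosage, config)
        ok = aff.sum(axis=1) >= config.min_affected_children
        take = min(int(ok.sum()), config.n_families - n_fam)
        if take:
            sel = np.flatnonzero(ok)[:take]
            kept_par.append(par[sel])
            kept_child.append(child[sel])
            kept_aff.append(aff[sel])
            n_fam += take

    par = np.concatenate(kept_par)
    child = np.concatenate(kept_child)
    aff = np.concatenate(kept_aff)

    inds: list[Individual] = []
    rows: list[np.ndarray] = []
    for f in range(config.n_families):
        fid = f"F{f + 1}"
        inds.append(Individual(fid, "1", sex=1, phenotype=1))
        inds.append(Individual(fid, "2", sex=2, phenotype=1))
        rows.append(mat[par[f, :2]].T)  # (L, 2)
        rows.append(mat[par[f, 2:]].T)
        for c in range(nc):
            inds.append(
                Individual(
                    fid, str(3 + c), father_id="1", mother_id="2",
                    sex=0, phenotype=2 if aff[f, c] else 1,
                )
            )
            rows.append(mat[child[f, c]].T)
    geno = _mask_missing(rng, np.stack(rows), config.missing_rate)
    return PedigreeDataset(
        individuals=inds, snps=_snp_records(config.n_loci), genotypes=geno,
        mode="family",
    )


def sim_msr_scenario(
    config: SimConfig,
    n_snps: int,
    planted_loci: Sequence[int],
    neutral_maf: tuple[float, float] = (0.2, 0.5),
) -> PedigreeDataset:
    """Case-control panel with a risk haplotype planted at chosen loci.

    ``config.hap_pool`` describes the sub-haplotype pool over the planted
    loci (1-based indices into the ``n_snps`` panel) and ``config.risk_hap``
    the planted risk combination; every other locus is independent noise
    with a minor-allele frequency drawn once, uniformly from
    ``neutral_maf``.  The returned dataset is ready for the stepwise search.
    """
    planted = [int(i) for i in planted_loci]
    if not planted or not all(1 <= i <= n_snps for i in planted):
        raise ValueError("planted_loci must be 1-based indices into the panel")
    if len(set(planted)) != len(planted):
        raise ValueError("planted_loci must be distinct")
    if config.n_loci != len(planted):
        raise ValueError("hap_pool haplotype length must match planted_loci")

    rng = np.random.default_rng(config.seed)
    mat, freqs, risk = _pool_arrays(config)
    planted0 = [j - 1 for j in planted]
    neutral0 = [j for j in range(n_snps) if j not in planted0]
    maf = rng.uniform(*neutral_maf, size=len(neutral0))

    def draw(batch: int):
        idx = rng.choice(len(freqs), size=(batch, 2), p=freqs)
        noise = np.where(
            rng.random((batch, 2, len(neutral0))) < maf, 1, 2
        ).astype(np.int8)
        geno = np.empty((batch, n_snps, 2), dtype=np.int8)
        geno[:, planted0, :] = mat[idx].transpose(0, 2, 1)
        geno[:, neutral0, :] = noise.transpose(0, 2, 1)
        dosage = (idx == risk).sum(axis=1) if risk >= 0 else np.zeros(batch)
        return geno, dosage

    geno = _fill_quotas(rng, config, draw)
    geno = _mask_missing(rng, geno, config.missing_rate)
    return PedigreeDataset(
        individuals=_cc_individuals(config.n_cases, config.n_controls),
        snps=_snp_records(n_snps), genotypes=geno, mode="case_control",
    )
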