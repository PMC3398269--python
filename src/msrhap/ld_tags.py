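"""Pairwise linkage disequilibrium (r^2) and greedy tagSNP selection.

tagSNP selection compresses a dense SNP panel: a SNP is "tagged" when its
pairwise r^2 with some selected tag exceeds the threshold (strictly), so
high-LD near-duplicates are represented once.  Selection is a greedy set
cover with deterministic tie-breaks; two-locus haplotype frequencies come
from the same EM used everywhere else (founders only in family mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import PedigreeDataset
from .phasing import em_unrelated

__all__ = ["TagConfig", "MonomorphicSnpError", "pairwise_r2", "select_tagsnps"]


class MonomorphicSnpError(ValueError):
    """r^2 is undefined when either locus is monomorphic."""


@dataclass
class TagConfig:
    r2_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")


def _founder_rows(dataset: PedigreeDataset) -> list[int] | None:
    if dataset.mode == "family":
        return list(np.flatnonzero(dataset.founder_mask))
    return None


def pairwise_r2(dataset: PedigreeDataset, snp_i: str, snp_j: str) -> float:
    """Squared allelic correlation r^2 = D^2 / (pA(1-pA) pB(1-pB)).

    Two-locus haplotype frequencies are EM-estimated; D is the deviation of
    the '11' haplotype frequency from the product of the code-1 allele
    frequencies.  Symmetric in its arguments and invariant to swapping
    allele codes at either locus.
    """
    freqs, _ = em_unrelated(
        dataset, [snp_i, snp_j], rows=_founder_rows(dataset)
    )
    f = freqs.freqs
    p_ab = f.get("11", 0.0)
    p_a = p_ab + f.get("12", 0.0)
    p_b = p_ab + f.get("21", 0.0)
    denom = p_a * (1.0 - p_a) * p_b * (1.0 - p_b)
    if denom <= 0.0:
        raise MonomorphicSnpError(
            f"r^2 undefined: {snp_i} or {snp_j} is monomorphic"
        )
    d = p_ab - p_a * p_b
    return min(1.0, d * d / denom)


def _maf(dataset: PedigreeDataset, j: int, rows: list[int] | None) -> float:
    g = dataset.genotypes[rows, j, :] if rows is not None else dataset.genotypes[:, j, :]
    n1 = float((g == 1).sum())
    n2 = float((g == 2).sum())
    tot = n1 + n2
    return 0.0 if tot == 0 else min(n1, n2) / tot


def select_tagsnps(
    dataset: PedigreeDataset, config: TagConfig | None = None
) -> pd.DataFrame:
    """Greedy set-cover tagSNP selection under an r^2 coverage criterion.

    Repeatedly picks the SNP that tags (r^2 > threshold, itself included)
    the most not-yet-covered SNPs; ties go to the higher minor-allele
    frequency, then the lower panel index.  Returns a table with one row
    per SNP: its covering tag and the pairwise r^2 with that tag.
    """
    config = config or TagConfig()
    ids = dataset.snp_ids
    m = len(ids)
    if m == 0:
        raise ValueError("dataset has no SNPs")
    rows = _founder_rows(dataset)
    maf = [_maf(dataset, j, rows) for j in range(m)]

    r2 = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            try:
                r2[a, b] = r2[b, a] = pairwise_r2(dataset, ids[a], ids[b])
            except MonomorphicSnpError:
                r2[a, b] = r2[b, a] = 0.0

    covers = [set(np.flatnonzero(r2[a] > config.r2_threshold)) | {a} for a in range(m)]
    uncovered = set(range(m))
    tagged_by: dict[int, int] = {}
    while uncovered:
        best = max(
            range(m),
            key=lambda a: (len(covers[a] & uncovered), maf[a], -a),
        )
        gain = covers[best] & uncovered
        if not gain:  # isolated SNPs each become their own tag
            best = min(uncovered)
            gain = {best}
        for j in gain:
            tagged_by[j] = best
        uncovered -= gain
    assert set(tagged_by) == set(range(m)), "coverage postcondition violated"
    return pd.DataFrame(
        {
            "snp_id": ids,
            "tagged_by": [ids[tagged_by[j]] for j in range(m)],
            "r2": [float(r2[j, tagged_by[j]]) for j in range(m)],
            "is_tag": [tagged_by[j] == j for j in range(m)],
        }
    )
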