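"""Shared fixtures and independent oracles for the test suite.

The oracle helpers deliberately avoid the library's own code paths: the EM
estimates are checked against brute-force likelihood maximization over a
frequency grid, the logistic LRT against a generic numeric optimizer, and
the weighted TDT against hand-counted transmissions.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from msrhap.dataio import Individual, PedigreeDataset, SnpRecord


def snp_records(n: int, prefix: str = "snp") -> list[SnpRecord]:
    return [
        SnpRecord(f"{prefix}{j + 1}", "1", 1000 * (j + 1), "1", "2")
        for j in range(n)
    ]


def make_cc(genos, phenos=None) -> PedigreeDataset:
    """Case-control dataset from explicit genotypes.

    ``genos[i][j]`` is the (a, b) allele-code pair of individual i at SNP j.
    """
    geno = np.array(genos, dtype=np.int8)
    n, m = geno.shape[:2]
    phenos = phenos if phenos is not None else [1] * n
    inds = [
        Individual(f"F{i + 1}", "1", sex=0, phenotype=int(p))
        for i, p in enumerate(phenos)
    ]
    return PedigreeDataset(
        individuals=inds, snps=snp_records(m), genotypes=geno,
        mode="case_control",
    )


def make_families(families) -> PedigreeDataset:
    """Family dataset from explicit per-family genotypes.

    Each family is (father_geno, mother_geno, [(child_geno, phenotype), ...])
    with genotypes as lists of (a, b) pairs per SNP.
    """
    inds, rows = [], []
    m = len(families[0][0])
    for f, (fg, mg, kids) in enumerate(families, start=1):
        fid = f"F{f}"
        inds.append(Individual(fid, "1", sex=1, phenotype=1))
        inds.append(Individual(fid, "2", sex=2, phenotype=1))
        rows += [fg, mg]
        for c, (cg, ph) in enumerate(kids):
            inds.append(
                Individual(fid, str(3 + c), father_id="1", mother_id="2",
                           sex=0, phenotype=ph)
            )
            rows.append(cg)
    return PedigreeDataset(
        individuals=inds, snps=snp_records(m),
        genotypes=np.array(rows, dtype=np.int8), mode="family",
    )


# ---------------------------------------------------------------------------
# oracle: brute-force likelihood maximization on a frequency simplex grid
# ---------------------------------------------------------------------------

def simplex_grid(dim: int, step: float) -> np.ndarray:
    """All frequency vectors of length ``dim`` on a grid of spacing step."""
    n = round(1.0 / step)
    pts = []
    for cuts in itertools.combinations_with_replacement(range(n + 1), dim - 1):
        prev = 0
        vec = []
        for c in cuts:
            vec.append((c - prev) * step)
            prev = c
        vec.append((n - prev) * step)
        pts.append(vec)
    return np.asarray(pts)


def grid_max_loglik(loglik, dim: int, coarse: float = 0.02, fine: float = 1e-5):
    """Staged grid-search maximizer of a likelihood over the simplex.

    ``loglik`` maps an (N, dim) array of frequency vectors to (N,) values.
    Starts from a coarse simplex grid and repeatedly re-grids a shrinking
    box (in the dim-1 free coordinates; the last coordinate is the simplex
    remainder) around the incumbent until the spacing reaches ``fine``.
    Returns (argmax frequency vector, max log-likelihood).
    """
    grid = simplex_grid(dim, coarse)
    best = grid[int(np.argmax(loglik(grid)))]
    step = coarse
    while step > fine:
        new_step = max(step / 10.0, fine)
        axes = [
            np.arange(best[d] - 2 * step, best[d] + 2 * step + new_step / 2,
                      new_step)
            for d in range(dim - 1)
        ]
        mesh = np.array(np.meshgrid(*axes, indexing="ij")).reshape(dim - 1, -1).T
        last = 1.0 - mesh.sum(axis=1)
        ok = (mesh >= 0.0).all(axis=1) & (last >= 0.0)
        cand = np.hstack([mesh[ok], last[ok, None]])
        cand = np.vstack([best, cand])
        best = cand[int(np.argmax(loglik(cand)))]
        step = new_step
    return best, float(loglik(best[None])[0])


def cc_loglik_fn(pair_index_lists, hap_order):
    """Observed-data log-likelihood of unrelated genotypes.

    ``pair_index_lists[i]`` lists the (k, l, c) index triples of the
    haplotype pairs compatible with individual i (c = 1 homozygous pair,
    2 otherwise), indices into ``hap_order``.
    """

    def ll(freq_matrix: np.ndarray) -> np.ndarray:
        out = np.zeros(len(freq_matrix))
        for triples in pair_index_lists:
            s = np.zeros(len(freq_matrix))
            for k, l, c in triples:
                s += c * freq_matrix[:, k] * freq_matrix[:, l]
            out += np.log(np.maximum(s, 1e-300))
        return out

    return ll


# ---------------------------------------------------------------------------
# oracle: generic-optimizer logistic regression
# ---------------------------------------------------------------------------

def logit_loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logit_oracle(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Maximize the Bernoulli log-likelihood with a generic optimizer."""
    res = minimize(
        lambda b: -logit_loglik(b, X, y),
        x0=np.zeros(X.shape[1]),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x, -res.fun


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
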