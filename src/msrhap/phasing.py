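"""EM haplotype-frequency estimation and phase posteriors.

Two estimators are provided, both assuming Hardy-Weinberg proportions at the
level of haplotypes over the chosen pattern loci:

* :func:`em_unrelated` -- the classical EM for unrelated individuals: the
  E-step weights every haplotype pair compatible with an individual's
  (possibly partially missing) genotype by ``(2 - delta_kl) * p_k * p_l``,
  the M-step re-estimates frequencies from the posterior-expected counts.
* :func:`em_families` -- the nuclear-family variant: EM over the parents,
  with each joint parental pair configuration restricted to those that are
  Mendelian-compatible with *all* children of the family.  On convergence,
  per-family configurations (parental phases plus the haplotype each parent
  transmitted to each child) are enumerated with weights proportional to the
  product of the four parental haplotype frequencies, normalized within the
  family.

Haplotypes are strings over {'1','2'}, one character per pattern locus, in
pattern-locus order.  Missing alleles (code 0) are marginalized: every
completion is considered compatible, so no individual is ever dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dataio import PedigreeDataset

__all__ = [
    "HaplotypeFreqs",
    "PhasePosterior",
    "FamilyConfig",
    "MendelError",
    "em_unrelated",
    "em_families",
    "expected_dosages",
    "freq_by_group",
]

Hap = tuple[int, ...]  # internal representation; API uses strings

PRUNE_EPS = 1e-10  # haplotypes below this frequency are pruned each M-step


class MendelError(ValueError):
    """A family admits no haplotype configuration (Mendelian inconsistency)."""


def hap_str(h: Hap) -> str:
    return "".join(map(str, h))


@dataclass
class HaplotypeFreqs:
    """EM output: haplotype -> frequency, with convergence diagnostics."""

    freqs: dict[str, float]
    loglik: float
    n_iter: int
    converged: bool
    ll_trace: list[float] = field(default_factory=list, repr=False)

    def sorted_items(self) -> list[tuple[str, float]]:
        return sorted(self.freqs.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class PhasePosterior:
    """Per-individual posterior over compatible (unordered) haplotype pairs."""

    pairs: list[list[tuple[tuple[str, str], float]]]

    @property
    def n_individuals(self) -> int:
        return len(self.pairs)


@dataclass
class FamilyConfig:
    """One weighted phase/transmission configuration of a nuclear family."""

    family_id: str
    father_pair: tuple[str, str]
    mother_pair: tuple[str, str]
    # per child: (haplotype transmitted by father, by mother)
    transmissions: list[tuple[str, str]]
    child_ids: list[str]
    child_affected: list[bool]
    weight: float


# ---------------------------------------------------------------------------
# genotype -> compatible pair enumeration
# ---------------------------------------------------------------------------

def _locus_options(a: int, b: int) -> list[tuple[int, int]]:
    """Ordered (chrom1, chrom2) allele assignments consistent with (a, b)."""
    if a and b:
        return [(a, b)] if a == b else [(a, b), (b, a)]
    if a or b:
        x = a or b
        return sorted({(x, 1), (x, 2), (1, x), (2, x)})
    return [(1, 1), (1, 2), (2, 1), (2, 2)]


def compatible_pairs(row: np.ndarray) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs compatible with one genotype row.

    ``row`` has shape (L, 2) with codes {0,1,2}.  Missing alleles match
    anything.  Pairs are returned with the lexicographically smaller
    haplotype first and each unordered pair listed once.
    """
    per_locus = [_locus_options(int(a), int(b)) for a, b in row]
    seen: set[tuple[Hap, Hap]] = set()
    for combo in itertools.product(*per_locus):
        h1 = tuple(x for x, _ in combo)
        h2 = tuple(y for _, y in combo)
        seen.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(seen)


def _extract(dataset: PedigreeDataset, loci: Sequence[str]) -> np.ndarray:
    loci = list(loci)
    if not loci:
        raise ValueError("empty locus list")
    if len(set(loci)) != len(loci):
        raise ValueError("pattern loci must be distinct")
    cols = [dataset.snp_index(s) for s in loci]
    return dataset.genotypes[:, cols, :]


# ---------------------------------------------------------------------------
# EM for unrelated individuals
# ---------------------------------------------------------------------------

def em_unrelated(
    dataset: PedigreeDataset,
    loci: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 500,
    rows: Sequence[int] | None = None,
) -> tuple[HaplotypeFreqs, PhasePosterior]:
    """EM haplotype-frequency estimation for unrelated individuals.

    ``rows`` restricts the estimation to a subset of individuals (e.g.
    founders); by default all are used.  Convergence is declared when the
    maximum absolute frequency change drops below ``tol``.
    """
    geno = _extract(dataset, loci)
    if rows is not None:
        geno = geno[list(rows)]
    n = geno.shape[0]
    if n == 0:
        raise ValueError("no individuals to phase")

    # group identical genotype rows: EM cost depends on distinct rows only
    keys = [tuple(map(tuple, g)) for g in geno]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    uniq = list(groups)
    counts = np.array([len(groups[k]) for k in uniq], dtype=float)
    pair_lists = [compatible_pairs(np.array(k)) for k in uniq]

    support: dict[Hap, int] = {}
    for pl in pair_lists:
        for h1, h2 in pl:
            for h in (h1, h2):
                support.setdefault(h, len(support))
    H = len(support)
    idx = [
        (
            np.array([support[h1] for h1, _ in pl], dtype=np.intp),
            np.array([support[h2] for _, h2 in pl], dtype=np.intp),
            np.array([1.0 if h1 == h2 else 2.0 for h1, h2 in pl]),
        )
        for pl in pair_lists
    ]

    p = np.full(H, 1.0 / H)
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        newp = np.zeros(H)
        ll = 0.0
        for (k1, k2, c), ng in zip(idx, counts):
            w = c * p[k1] * p[k2]
            s = w.sum()
            if s <= 0.0:  # support pruned from under this genotype; re-seed
                w = np.full(len(k1), 1.0 / len(k1))
                s = 1.0
                ll += -np.inf
            else:
                ll += ng * np.log(s)
                w = w / s
            np.add.at(newp, k1, ng * w)
            np.add.at(newp, k2, ng * w)
        newp /= 2.0 * n
        newp[newp < PRUNE_EPS] = 0.0
        newp /= newp.sum()
        ll_trace.append(float(ll))
        delta = float(np.abs(newp - p).max())
        p = newp
        if delta < tol:
            converged = True
            break

    # final posteriors per individual, at the converged frequencies
    post_by_group: list[list[tuple[tuple[str, str], float]]] = []
    ll = 0.0
    for (k1, k2, c), pl, ng in zip(idx, pair_lists, counts):
        w = c * p[k1] * p[k2]
        s = w.sum()
        if s <= 0.0:
            w = np.full(len(k1), 1.0 / len(k1))
        else:
            ll += ng * np.log(s)
            w = w / s
        post_by_group.append(
            [
                ((hap_str(h1), hap_str(h2)), float(wi))
                for (h1, h2), wi in zip(pl, w)
                if wi > 0.0
            ]
        )
    posts: list[list[tuple[tuple[str, str], float]]] = [[] for _ in range(n)]
    for k, gpost in zip(uniq, post_by_group):
        for i in groups[k]:
            posts[i] = gpost

    freqs = HaplotypeFreqs(
        freqs={hap_str(h): float(p[j]) for h, j in support.items() if p[j] > 0.0},
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        ll_trace=ll_trace,
    )
    return freqs, PhasePosterior(pairs=posts)


# ---------------------------------------------------------------------------
# dosages and group frequencies
# ---------------------------------------------------------------------------

def expected_dosages(
    posterior: PhasePosterior, hap_set: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Posterior-expected haplotype copy counts, one row per individual.

    Haplotypes appearing in the posterior but not in ``hap_set`` accumulate
    in a trailing ``"other"`` column.  Each row sums to 2.
    """
    cols = list(hap_set)
    col_of = {h: j for j, h in enumerate(cols)}
    need_other = any(
        h not in col_of
        for plist in posterior.pairs
        for (h1, h2), _ in plist
        for h in (h1, h2)
    )
    if need_other:
        cols = cols + ["other"]
    mat = np.zeros((posterior.n_individuals, len(cols)))
    other = len(cols) - 1
    for i, plist in enumerate(posterior.pairs):
        for (h1, h2), w in plist:
            for h in (h1, h2):
                mat[i, col_of.get(h, other)] += w
    return mat, cols


def freq_by_group(
    posterior: PhasePosterior, labels: Sequence[object]
) -> dict[object, dict[str, float]]:
    """Within-group haplotype frequencies from phase posteriors.

    ``labels`` is aligned with the posterior's individuals; a label of
    ``None`` excludes the individual.  Frequencies are posterior-expected
    haplotype counts over twice the group size, so they sum to 1 per group.
    """
    if len(labels) != posterior.n_individuals:
        raise ValueError("labels must align with posterior individuals")
    acc: dict[object, dict[str, float]] = {}
    sizes: dict[object, int] = {}
    for lab, plist in zip(labels, posterior.pairs):
        if lab is None:
            continue
        sizes[lab] = sizes.get(lab, 0) + 1
        d = acc.setdefault(lab, {})
        for (h1, h2), w in plist:
            d[h1] = d.get(h1, 0.0) + w
            d[h2] = d.get(h2, 0.0) + w
    if not acc:
        raise ValueError("no labelled individuals (empty groups)")
    return {
        lab: {h: c / (2.0 * sizes[lab]) for h, c in sorted(d.items())}
        for lab, d in acc.items()
    }


# ---------------------------------------------------------------------------
# EM for nuclear families
# ---------------------------------------------------------------------------

def _family_layout(dataset: PedigreeDataset) -> list[tuple[str, int, int, list[int]]]:
    """Per family: (family_id, father_row, mother_row, child_rows)."""
    out = []
    for fid, rows in dataset.families().items():
        parents = [i for i in rows if dataset.individuals[i].is_founder]
        children = [i for i in rows if not dataset.individuals[i].is_founder]
        # identify father/mother by the children's parent references
        ref = dataset.individuals[children[0]]
        by_iid = {dataset.individuals[i].individual_id: i for i in parents}
        fa = by_iid.get(ref.father_id, parents[0])
        mo = by_iid.get(ref.mother_id, parents[1] if len(parents) > 1 else parents[0])
        if fa == mo and len(parents) > 1:
            mo = next(i for i in parents if i != fa)
        out.append((fid, fa, mo, children))
    return out


def em_families(
    dataset: PedigreeDataset,
    loci: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 500,
    normalize_weights: bool = True,
) -> tuple[HaplotypeFreqs, list[FamilyConfig]]:
    """Child-compatibility-restricted EM for complete nuclear families.

    The EM runs over the parents; a joint (father-pair, mother-pair)
    configuration enters the likelihood only if every child's genotype is
    compatible with some pair of transmitted haplotypes.  Transmission
    ambiguity within a configuration is split uniformly over the distinct
    compatible transmitted pairs, matching the uniform Mendelian
    transmission prior.
    """
    if dataset.mode != "family":
        raise ValueError("em_families requires a family-mode dataset")
    geno = _extract(dataset, loci)
    layout = _family_layout(dataset)
    n_fam = len(layout)

    # per family: enumerate joint configurations
    # each entry: (f_pair, m_pair, c_factor, [per-child transmitted options])
    fam_configs: list[list[tuple]] = []
    support: dict[Hap, int] = {}

    def sidx(h: Hap) -> int:
        return support.setdefault(h, len(support))

    for fid, fa, mo, children in layout:
        f_pairs = compatible_pairs(geno[fa])
        m_pairs = compatible_pairs(geno[mo])
        child_sets = [set(compatible_pairs(geno[c])) for c in children]
        configs = []
        for f1, f2 in f_pairs:
            for m1, m2 in m_pairs:
                per_child: list[list[tuple[Hap, Hap]]] = []
                ok = True
                for cs in child_sets:
                    opts = sorted(
                        {
                            (fh, mh)
                            for fh in {f1, f2}
                            for mh in {m1, m2}
                            if ((fh, mh) if fh <= mh else (mh, fh)) in cs
                        }
                    )
                    if not opts:
                        ok = False
                        break
                    per_child.append(opts)
                if not ok:
                    continue
                c = (1.0 if f1 == f2 else 2.0) * (1.0 if m1 == m2 else 2.0)
                configs.append(
                    (
                        (sidx(f1), sidx(f2)),
                        (sidx(m1), sidx(m2)),
                        c,
                        per_child,
                        ((f1, f2), (m1, m2)),
                    )
                )
        if not configs:
            raise MendelError(
                f"family {fid}: no haplotype configuration is compatible "
                f"with all children (Mendelian inconsistency)"
            )
        fam_configs.append(configs)

    H = len(support)
    p = np.full(H, 1.0 / H)
    ll_trace: list[float] = []
    converged = False
    it = 0
    n_parents = 2 * n_fam
    for it in range(1, max_iter + 1):
        newp = np.zeros(H)
        ll = 0.0
        for configs in fam_configs:
            w = np.array(
                [c * p[f[0]] * p[f[1]] * p[m[0]] * p[m[1]] for f, m, c, _, _ in configs]
            )
            s = w.sum()
            if s <= 0.0:
                w = np.full(len(configs), 1.0 / len(configs))
                ll += -np.inf
            else:
                ll += np.log(s)
                w = w / s
            for wi, (f, m, _, _, _) in zip(w, configs):
                for j in (*f, *m):
                    newp[j] += wi
        newp /= 2.0 * n_parents
        newp[newp < PRUNE_EPS] = 0.0
        newp /= newp.sum()
        ll_trace.append(float(ll))
        delta = float(np.abs(newp - p).max())
        p = newp
        if delta < tol:
            converged = True
            break

    # final family configurations at converged frequencies
    out: list[FamilyConfig] = []
    ll = 0.0
    for (fid, fa, mo, children), configs in zip(layout, fam_configs):
        child_ids = [dataset.individuals[c].individual_id for c in children]
        child_aff = [dataset.individuals[c].phenotype == 2 for c in children]
        w = np.array(
            [c * p[f[0]] * p[f[1]] * p[m[0]] * p[m[1]] for f, m, c, _, _ in configs]
        )
        s = w.sum()
        if s > 0.0:
            ll += np.log(s)
        if normalize_weights:
            w = w / s if s > 0.0 else np.full(len(configs), 1.0 / len(configs))
        for wi, (_, _, _, per_child, (fp, mp)) in zip(w, configs):
            if wi <= 0.0:
                continue
            n_tv = int(np.prod([len(o) for o in per_child]))
            for tv in itertools.product(*per_child):
                out.append(
                    FamilyConfig(
                        family_id=fid,
                        father_pair=(hap_str(fp[0]), hap_str(fp[1])),
                        mother_pair=(hap_str(mp[0]), hap_str(mp[1])),
                        transmissions=[
                            (hap_str(fh), hap_str(mh)) for fh, mh in tv
                        ],
                        child_ids=list(child_ids),
                        child_affected=list(child_aff),
                        weight=float(wi) / n_tv,
                    )
                )

    freqs = HaplotypeFreqs(
        freqs={hap_str(h): float(p[j]) for h, j in support.items() if p[j] > 0.0},
        loglik=float(ll),
        n_iter=it,
        converged=converged,
        ll_trace=ll_trace,
    )
    return freqs, out
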