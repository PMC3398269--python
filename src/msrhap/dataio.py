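"""Linkage-format (PED/MAP) input/output and the pedigree dataset model.

Genotypes are held as an ``(n_individuals, n_snps, 2)`` int8 array of allele
codes, where 0 marks a missing allele and the non-zero codes 1/2 map to the
allele labels recorded per SNP (``code_minor`` -> 1, ``code_major`` -> 2).
The convention throughout the package is the linkage one: phenotype 1 =
unaffected, 2 = affected, 0/-9 = missing; parent ids of '0' mean founder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "SnpRecord",
    "Individual",
    "PedigreeDataset",
    "PedError",
    "PedigreeError",
    "read_ped_map",
    "write_ped_map",
    "recode_minor_major",
    "exclude_carriers",
]


class PedError(ValueError):
    """Malformed PED/MAP content (row length, allele count, codes)."""


class PedigreeError(ValueError):
    """Inconsistent pedigree structure (unknown parents, bad family layout)."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP: identity, map position and the 1/2 allele coding.

    ``code_minor`` is the allele label written for code 1 and ``code_major``
    the label for code 2.  After :func:`recode_minor_major` code 1 is the
    minor (lower sample frequency) allele, matching the convention that risk
    alleles are reported on the minor-allele scale.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    code_minor: str | None = None
    code_major: str | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1")
        if self.code_minor is not None and self.code_minor == self.code_major:
            raise ValueError(f"{self.snp_id}: allele labels must differ")


@dataclass(frozen=True)
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = 0
    phenotype: int = 0

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)


@dataclass
class PedigreeDataset:
    """Individuals x SNPs genotype matrix plus pedigree/phenotype metadata."""

    individuals: list[Individual]
    snps: list[SnpRecord]
    genotypes: np.ndarray  # (n, m, 2) int8, codes {0,1,2}
    mode: Literal["case_control", "family"] = "case_control"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    @property
    def phenotypes(self) -> np.ndarray:
        return np.array([i.phenotype for i in self.individuals], dtype=int)

    @property
    def founder_mask(self) -> np.ndarray:
        return np.array([i.is_founder for i in self.individuals], dtype=bool)

    def families(self) -> dict[str, list[int]]:
        """Family id -> list of individual row indices, in file order."""
        fams: dict[str, list[int]] = {}
        for idx, ind in enumerate(self.individuals):
            fams.setdefault(ind.family_id, []).append(idx)
        return fams

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n, m = len(self.individuals), len(self.snps)
        if self.genotypes.shape != (n, m, 2):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n} individuals x {m} SNPs"
            )
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise PedError("allele codes must be in {0, 1, 2}")
        seen_snp: set[str] = set()
        for s in self.snps:
            if s.snp_id in seen_snp:
                raise ValueError(f"duplicate SNP id: {s.snp_id}")
            seen_snp.add(s.snp_id)
        seen_ind: set[tuple[str, str]] = set()
        by_family: dict[str, dict[str, Individual]] = {}
        for ind in self.individuals:
            if ind.key in seen_ind:
                raise PedigreeError(f"duplicate individual: {ind.key}")
            seen_ind.add(ind.key)
            by_family.setdefault(ind.family_id, {})[ind.individual_id] = ind
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in by_family[ind.family_id]:
                    raise PedigreeError(
                        f"individual {ind.key} names unknown parent {pid!r}"
                    )
        if self.mode == "case_control":
            for ind in self.individuals:
                if not ind.is_founder:
                    raise PedigreeError(
                        f"case_control mode requires founders only, but "
                        f"{ind.key} has parents"
                    )
        else:
            for fid, members in by_family.items():
                parents = [i for i in members.values() if i.is_founder]
                children = [i for i in members.values() if not i.is_founder]
                if len(parents) != 2 or not children:
                    raise PedigreeError(
                        f"family {fid}: family mode requires exactly two "
                        f"parents and at least one child "
                        f"(found {len(parents)} parents, {len(children)} children)"
                    )

    def subset_individuals(self, keep: Sequence[int]) -> "PedigreeDataset":
        keep = list(keep)
        return PedigreeDataset(
            individuals=[self.individuals[i] for i in keep],
            snps=list(self.snps),
            genotypes=self.genotypes[keep].copy(),
            mode=self.mode,
        )


def _parse_pheno(token: str) -> int:
    try:
        v = int(float(token))
    except ValueError:
        raise PedError(f"unparsable phenotype token {token!r}") from None
    if v == -9:
        return 0
    if v not in (0, 1, 2):
        raise PedError(f"phenotype must be 0/1/2/-9, got {token!r}")
    return v


def read_ped_map(
    ped_path: str | Path,
    map_path: str | Path,
    mode: Literal["case_control", "family"] | None = None,
) -> PedigreeDataset:
    """Read a linkage-dialect PED + MAP file pair.

    Allele labels are preserved: the two labels observed per SNP are mapped
    to codes 1/2 (lexicographically at read time; use
    :func:`recode_minor_major` for the minor=1/major=2 convention) and the
    mapping is stored on each :class:`SnpRecord`.  ``mode`` is inferred
    (family if any non-founder is present) unless given explicitly.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    snps_raw: list[tuple[str, str, int]] = []
    for ln, line in enumerate(map_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) < 4:
            raise PedError(f"{map_path}:{ln}: MAP row needs 4 columns, got {len(tok)}")
        snps_raw.append((tok[0], tok[1], int(tok[3])))
    m = len(snps_raw)

    inds: list[Individual] = []
    rows: list[list[str]] = []
    for ln, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 6 + 2 * m:
            raise PedError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} fields "
                f"(6 + 2x{m} SNPs), got {len(tok)}"
            )
        fid, iid, fat, mot, sex, phe = tok[:6]
        inds.append(
            Individual(
                family_id=fid,
                individual_id=iid,
                father_id=None if fat == "0" else fat,
                mother_id=None if mot == "0" else mot,
                sex=int(float(sex)) if sex in ("0", "1", "2") else 0,
                phenotype=_parse_pheno(phe),
            )
        )
        rows.append(tok[6:])

    n = len(inds)
    geno = np.zeros((n, m, 2), dtype=np.int8)
    snps: list[SnpRecord] = []
    for j, (chrom, snp_id, pos) in enumerate(snps_raw):
        labels = sorted(
            {rows[i][2 * j + k] for i in range(n) for k in (0, 1)} - {"0"}
        )
        if len(labels) > 2:
            raise PedError(
                f"SNP {snp_id} is not biallelic: alleles {', '.join(labels)}"
            )
        code_of = {lab: c + 1 for c, lab in enumerate(labels)}
        for i in range(n):
            for k in (0, 1):
                tokij = rows[i][2 * j + k]
                geno[i, j, k] = 0 if tokij == "0" else code_of[tokij]
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos_bp=pos,
                code_minor=labels[0] if labels else None,
                code_major=labels[1] if len(labels) > 1 else None,
            )
        )

    if mode is None:
        mode = "family" if any(not i.is_founder for i in inds) else "case_control"
    return PedigreeDataset(individuals=inds, snps=snps, genotypes=geno, mode=mode)


def write_ped_map(
    dataset: PedigreeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write the dataset back to linkage-dialect PED/MAP files.

    MAP columns: chrom, snp_id, genetic distance (written 0), pos_bp.
    Missing alleles are written as 0.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    with map_path.open("w") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\n")
    label = []
    for s in dataset.snps:
        label.append({0: "0", 1: s.code_minor or "1", 2: s.code_major or "2"})
    with ped_path.open("w") as fh:
        for i, ind in enumerate(dataset.individuals):
            cols = [
                ind.family_id,
                ind.individual_id,
                ind.father_id or "0",
                ind.mother_id or "0",
                str(ind.sex),
                str(ind.phenotype),
            ]
            for j in range(dataset.n_snps):
                a, b = dataset.genotypes[i, j]
                cols.append(label[j][int(a)])
                cols.append(label[j][int(b)])
            fh.write(" ".join(cols) + "\n")


def recode_minor_major(dataset: PedigreeDataset) -> PedigreeDataset:
    """Recode alleles so code 1 is the minor and code 2 the major allele.

    Frequencies are taken over non-missing alleles; in family mode only
    founders are counted, to avoid transmission-induced bias.  Ties are
    broken by lexicographic allele label (smaller label becomes code 1).
    A monomorphic SNP gets its single observed allele coded 2, with a
    warning.  The missingness pattern is never changed.
    """
    geno = dataset.genotypes.copy()
    if dataset.mode == "family":
        count_rows = np.flatnonzero(dataset.founder_mask)
    else:
        count_rows = np.arange(dataset.n_individuals)
    new_snps: list[SnpRecord] = []
    for j, snp in enumerate(dataset.snps):
        col = dataset.genotypes[count_rows, j, :]
        n1 = int((col == 1).sum())
        n2 = int((col == 2).sum())
        lab1 = snp.code_minor if snp.code_minor is not None else "1"
        lab2 = snp.code_major if snp.code_major is not None else "2"
        if n1 == 0 or n2 == 0:
            # monomorphic among the counted rows: observed allele becomes code 2
            warnings.warn(f"SNP {snp.snp_id} is monomorphic; coding allele as 2")
            swap = n1 > 0  # only-code-1 observed -> flip it to 2; else keep
        elif n1 < n2:
            swap = False
        elif n1 > n2:
            swap = True
        else:
            swap = lab2 < lab1  # tie: smaller label -> code 1
        if swap:
            g = geno[:, j, :]
            one, two = g == 1, g == 2
            g[one], g[two] = 2, 1
            lab1, lab2 = lab2, lab1
        new_snps.append(replace(snp, code_minor=lab1, code_major=lab2))
    return PedigreeDataset(
        individuals=list(dataset.individuals),
        snps=new_snps,
        genotypes=geno,
        mode=dataset.mode,
    )


@dataclass
class ExclusionResult:
    dataset: PedigreeDataset
    n_individuals_removed: int
    n_families_removed: int = 0


def exclude_carriers(
    dataset: PedigreeDataset,
    loci: Iterable[str],
    unit: Literal["individual", "family"] = "individual",
) -> ExclusionResult:
    """Drop carriers of a code-1 allele at any of the listed loci.

    ``unit='individual'`` drops each carrier; ``unit='family'`` drops the
    whole family whenever any member carries.  Used e.g. to remove all
    carriers of known loss-of-function mutations before re-testing a
    pattern for an independent effect.
    """
    loci = list(loci)
    if not loci:
        raise ValueError("exclude_carriers: empty locus list")
    cols = [dataset.snp_index(s) for s in loci]
    carrier = (dataset.genotypes[:, cols, :] == 1).any(axis=(1, 2))
    if unit == "individual":
        keep = np.flatnonzero(~carrier)
        return ExclusionResult(
            dataset=dataset.subset_individuals(keep),
            n_individuals_removed=int(carrier.sum()),
        )
    if unit != "family":
        raise ValueError(f"unknown exclusion unit {unit!r}")
    bad_fams = {
        dataset.individuals[i].family_id for i in np.flatnonzero(carrier)
    }
    keep = [
        i
        for i, ind in enumerate(dataset.individuals)
        if ind.family_id not in bad_fams
    ]
    return ExclusionResult(
        dataset=dataset.subset_individuals(keep),
        n_individuals_removed=dataset.n_individuals - len(keep),
        n_families_removed=len(bad_fams),
    )
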