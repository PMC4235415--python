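"""Pedigree parsing, validation, and relationship matrices.

A pedigree is a list of individuals with optional father/mother links and a
family label.  From it we compute the kinship matrix K (entry phi_ij is the
probability that two alleles drawn at random, one from each individual, are
identical by descent) by the classic tabular recursion, and the additive
genetic relationship matrix A = 2K that scales the polygenic variance in the
phenotypic covariance Cov(y_i, y_j) = 2 k_ij sigma_g^2.

Individuals flagged ``sampled=False`` are phantom connecting ancestors: they
participate in the kinship recursion but are dropped from every matrix
delivered to inference.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "KinshipMatrix",
    "RelationshipMatrix",
    "FamilyOffsets",
    "read_pedigree",
    "kinship",
    "additive_matrix",
    "family_offsets",
]

MISSING = ""  # canonical in-memory encoding of a missing parent


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees."""


@dataclass(frozen=True)
class Individual:
    """One pedigree record.

    Sex codes follow PLINK: 1 = male, 2 = female, 0 = unknown.  Sex is
    carried through for output fidelity but plays no role in the autosomal
    kinship computation.
    """

    iid: str
    father: str = MISSING
    mother: str = MISSING
    sex: int = 0
    family: str = "1"
    sampled: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father == MISSING and self.mother == MISSING


@dataclass
class Pedigree:
    """Validated pedigree, family-contiguous and topologically sorted.

    ``records`` holds every individual including phantom ancestors; use
    :attr:`sampled_records` for the individuals that enter matrices.
    """

    records: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.iid: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.iid in seen:
                    raise PedigreeError(f"duplicate individual id {r.iid!r}")
                seen.add(r.iid)
        self._validate()

    def _validate(self) -> None:
        for r in self.records:
            has_f = r.father != MISSING
            has_m = r.mother != MISSING
            if has_f != has_m:
                raise PedigreeError(
                    f"individual {r.iid!r} has exactly one parent recorded; "
                    "non-founders need both, founders neither"
                )
            if has_f:
                for pid in (r.father, r.mother):
                    if pid not in self._index:
                        raise PedigreeError(
                            f"parent {pid!r} of individual {r.iid!r} not in pedigree"
                        )
                    parent = self.records[self._index[pid]]
                    if parent.family != r.family:
                        raise PedigreeError(
                            f"parent {pid!r} of individual {r.iid!r} belongs to a "
                            f"different family ({parent.family!r} vs {r.family!r})"
                        )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        for start in self._index:
            if start in state:
                continue
            stack = [(start, False)]
            while stack:
                iid, processed = stack.pop()
                if processed:
                    state[iid] = 1
                    continue
                if state.get(iid) == 1:
                    continue
                if state.get(iid) == 0:
                    raise PedigreeError(f"cyclic ancestry involving individual {iid!r}")
                state[iid] = 0
                stack.append((iid, True))
                r = self.records[self._index[iid]]
                for pid in (r.father, r.mother):
                    if pid != MISSING and state.get(pid) != 1:
                        stack.append((pid, False))

    # -- views ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def sampled_records(self) -> list[Individual]:
        return [r for r in self.records if r.sampled]

    @property
    def sampled_ids(self) -> list[str]:
        return [r.iid for r in self.records if r.sampled]

    @property
    def family_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.family not in out:
                out.append(r.family)
        return out

    def is_topologically_sorted(self) -> bool:
        seen: set[str] = set()
        for r in self.records:
            if r.father != MISSING and (r.father not in seen or r.mother not in seen):
                return False
            seen.add(r.iid)
        return True

    def is_family_contiguous(self) -> bool:
        seen: set[str] = set()
        prev: str | None = None
        for r in self.records:
            if r.family != prev:
                if r.family in seen:
                    return False
                seen.add(r.family)
                prev = r.family
        return True

    def sorted(self) -> "Pedigree":
        """Family-contiguous, parents-before-children copy.

        Families keep first-appearance order; within a family the order is
        topological with ties broken by input order.
        """
        by_family: dict[str, list[Individual]] = {}
        for r in self.records:
            by_family.setdefault(r.family, []).append(r)
        out: list[Individual] = []
        for fam in self.family_ids:
            members = by_family[fam]
            placed: set[str] = set()
            pending = list(members)
            while pending:
                progressed = False
                rest: list[Individual] = []
                for r in pending:
                    ready = all(
                        p == MISSING or p in placed or p not in self._index
                        for p in (r.father, r.mother)
                    )
                    if ready:
                        out.append(r)
                        placed.add(r.iid)
                        progressed = True
                    else:
                        rest.append(r)
                if not progressed:  # pragma: no cover - caught by _check_acyclic
                    raise PedigreeError(f"cannot topologically sort family {fam!r}")
                pending = rest
        return Pedigree(out)

    def to_fam(self, stream: TextIO) -> None:
        """Write PLINK FAM (FID IID PAT MAT SEX PHENO).

        Phantom connecting ancestors are written too — the file must stay
        self-contained so the kinship recursion works on re-read.  Which
        individuals are sampled is re-established downstream by matching
        against a phenotype table.
        """
        for r in self.records:
            pat = r.father if r.father != MISSING else "0"
            mat = r.mother if r.mother != MISSING else "0"
            stream.write(f"{r.family}\t{r.iid}\t{pat}\t{mat}\t{r.sex}\t-9\n")

    def restrict_sampled(self, sampled_ids: Iterable[str]) -> "Pedigree":
        """Copy with ``sampled`` set from membership in ``sampled_ids``."""
        wanted = set(sampled_ids)
        missing = wanted - set(self._index)
        if missing:
            raise PedigreeError(f"sampled ids not in pedigree: {sorted(missing)[:5]}")
        return Pedigree(
            [replace(r, sampled=r.iid in wanted) for r in self.records]
        )


@dataclass
class KinshipMatrix:
    """Kinship coefficients among sampled individuals.

    The diagonal is (1 + f_i)/2 with f_i the inbreeding coefficient, so it is
    0.5 for non-inbred individuals; off-diagonal entries vanish between
    families.
    """

    values: np.ndarray
    ids: list[str]
    families: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class RelationshipMatrix:
    """Additive genetic relationship matrix A = 2K (block-diagonal by family)."""

    values: np.ndarray
    ids: list[str]
    families: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class FamilyOffsets:
    """1-based first index of each family block plus the terminal N + 1.

    Mirrors the BUGS ``offset`` vector: block i (1-based) spans
    ``offsets[i] .. offsets[i+1] - 1``.  :meth:`slices` yields the equivalent
    0-based Python slices.
    """

    offsets: np.ndarray
    families: list[str]

    @property
    def n_fam(self) -> int:
        return len(self.offsets) - 1

    @property
    def n(self) -> int:
        return int(self.offsets[-1]) - 1

    def slices(self) -> list[slice]:
        return [
            slice(int(self.offsets[i]) - 1, int(self.offsets[i + 1]) - 1)
            for i in range(self.n_fam)
        ]

    def sizes(self) -> np.ndarray:
        return np.diff(self.offsets)

    def to_json(self) -> str:
        return json.dumps(
            {"offsets": [int(v) for v in self.offsets], "families": self.families}
        )


# ---------------------------------------------------------------------------
# parsing


def _norm_parent(tok: str) -> str:
    return MISSING if tok in ("0", "", "NA") else tok


def read_pedigree(source: str | TextIO | Iterable[str], dialect: str = "fam") -> Pedigree:
    """Read a pedigree from delimited text.

    Parameters
    ----------
    source
        Path, open text stream, or iterable of lines.
    dialect
        ``"fam"``: headerless 6-column PLINK FAM (FID IID PAT MAT SEX PHENO);
        ``"ped"``: same columns but with a header row naming at least
        ``fid iid father mother`` (``sex`` optional).

    Missing parents may be encoded as ``0``, ``NA`` or an empty field; records
    are returned family-contiguous and topologically sorted.
    """
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as fh:
            return read_pedigree(fh, dialect=dialect)
    lines = [ln.strip() for ln in source]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if dialect == "ped" and lines:
        lines = lines[1:]
    elif dialect != "fam" and dialect != "ped":
        raise ValueError(f"unknown pedigree dialect {dialect!r}")

    records: list[Individual] = []
    for ln in lines:
        toks = ln.replace(",", " ").split()
        if len(toks) < 4:
            raise PedigreeError(f"pedigree row too short: {ln!r}")
        fid, iid, pat, mat = toks[:4]
        sex = int(toks[4]) if len(toks) > 4 and toks[4] in ("0", "1", "2") else 0
        records.append(
            Individual(
                iid=iid,
                father=_norm_parent(pat),
                mother=_norm_parent(mat),
                sex=sex,
                family=fid,
            )
        )
    return Pedigree(records).sorted()


# ---------------------------------------------------------------------------
# kinship


def kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the tabular recursion, restricted to sampled members.

    Founders are taken unrelated and non-inbred (phi_ii = 1/2); for a
    non-founder i with parents f and m,

        phi_ii = (1 + phi_fm) / 2
        phi_ij = (phi_fj + phi_mj) / 2   for j preceding i.

    The recursion runs over the full pedigree (phantom ancestors included)
    and the result is then restricted to sampled individuals, which equals
    the corresponding submatrix of the full kinship matrix.

    Raises
    ------
    PedigreeError
        If the pedigree is not topologically sorted; the numeric kernel
        never re-sorts silently.
    """
    if not ped.is_topologically_sorted():
        raise PedigreeError("pedigree must list parents before children; call .sorted()")
    n = len(ped)
    phi = np.zeros((n, n))
    idx = {r.iid: i for i, r in enumerate(ped.records)}
    for i, r in enumerate(ped.records):
        if r.is_founder:
            phi[i, i] = 0.5
        else:
            fi, mi = idx[r.father], idx[r.mother]
            phi[i, i] = 0.5 * (1.0 + phi[fi, mi])
            phi[i, :i] = 0.5 * (phi[fi, :i] + phi[mi, :i])
            phi[:i, i] = phi[i, :i]
    keep = [i for i, r in enumerate(ped.records) if r.sampled]
    sub = phi[np.ix_(keep, keep)]
    ids = [ped.records[i].iid for i in keep]
    fams = [ped.records[i].family for i in keep]
    return KinshipMatrix(values=sub, ids=ids, families=fams)


def additive_matrix(K: KinshipMatrix) -> RelationshipMatrix:
    """Additive relationship matrix A = 2K."""
    return RelationshipMatrix(values=2.0 * K.values, ids=list(K.ids), families=list(K.families))


def family_offsets(ped: Pedigree) -> FamilyOffsets:
    """Offset vector over the sampled individuals, 1-based per BUGS convention."""
    fams = [r.family for r in ped.sampled_records]
    order: list[str] = []
    for f in fams:
        if f not in order:
            order.append(f)
    # contiguity check
    seen_done: set[str] = set()
    prev: str | None = None
    for f in fams:
        if f != prev:
            if f in seen_done:
                raise PedigreeError(f"family {f!r} is not contiguous in the ordering")
            if prev is not None:
                seen_done.add(prev)
            prev = f
    counts = [sum(1 for f in fams if f == fam) for fam in order]
    offsets = np.concatenate([[1], 1 + np.cumsum(counts)]).astype(int)
    return FamilyOffsets(offsets=offsets, families=order)


# ---------------------------------------------------------------------------
# Monte Carlo oracle


def drop_alleles(
    ped: Pedigree, n_drops: int, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Simulate allele transmission down the pedigree.

    Founders receive unique allele labels; each child draws one of each
    parent's two alleles uniformly per drop.  Returns the (n, 2, n_drops)
    allele-label array over all pedigree records plus the indices of the
    sampled individuals.
    """
    if not ped.is_topologically_sorted():
        raise PedigreeError("pedigree must list parents before children")
    n = len(ped)
    idx = {r.iid: i for i, r in enumerate(ped.records)}
    alleles = np.empty((n, 2, n_drops), dtype=np.int32)
    label = 0
    for i, r in enumerate(ped.records):
        if r.is_founder:
            alleles[i, 0] = label
            alleles[i, 1] = label + 1
            label += 2
        else:
            fi, mi = idx[r.father], idx[r.mother]
            pick_f = rng.integers(0, 2, size=n_drops)
            pick_m = rng.integers(0, 2, size=n_drops)
            cols = np.arange(n_drops)
            alleles[i, 0] = alleles[fi, pick_f, cols]
            alleles[i, 1] = alleles[mi, pick_m, cols]
    keep = [i for i, r in enumerate(ped.records) if r.sampled]
    return alleles, keep


def gene_drop_kinship(
    ped: Pedigree, n_drops: int, seed: int | np.random.Generator = 0
) -> tuple[KinshipMatrix, np.ndarray]:
    """Estimate kinship by gene dropping (Monte Carlo identity by descent).

    Founders receive unique allele labels; every transmission picks one of
    each parent's two alleles uniformly.  The kinship estimate for a pair is
    the fraction of the four allele comparisons that are identical by
    descent, averaged over ``n_drops`` independent drops.  Returns the
    estimated matrix over sampled individuals and the matching matrix of
    standard errors of the estimates.

    This is the independent oracle against which the exact recursion is
    validated; it is O(n_drops * n) and intended for small pedigrees.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alleles, keep = drop_alleles(ped, n_drops, rng)
    m = len(keep)
    est = np.zeros((m, m))
    se = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            ia, ib = keep[a], keep[b]
            if a == b:
                # phi_ii = (1 + P(two alleles of i are IBD)) / 2
                match = (alleles[ia, 0] == alleles[ia, 1]).astype(float)
                f_hat = match.mean()
                est[a, a] = 0.5 * (1.0 + f_hat)
                se[a, a] = 0.5 * match.std(ddof=1) / np.sqrt(n_drops)
            else:
                ibd = np.zeros(n_drops)
                for x in range(2):
                    for y in range(2):
                        ibd += alleles[ia, x] == alleles[ib, y]
                ibd *= 0.25
                est[a, b] = est[b, a] = ibd.mean()
                se[a, b] = se[b, a] = ibd.std(ddof=1) / np.sqrt(n_drops)
    ids = [ped.records[i].iid for i in keep]
    fams = [ped.records[i].family for i in keep]
    return KinshipMatrix(values=est, ids=ids, families=fams), se


def write_matrix_tsv(mat: KinshipMatrix | RelationshipMatrix, stream: TextIO) -> None:
    """Write a relationship matrix as TSV with id header row and column."""
    mat.to_frame().to_csv(stream, sep="\t", index_label="id")


def read_matrix_tsv(stream: TextIO | str) -> pd.DataFrame:
    if isinstance(stream, str):
        stream = io.StringIO(open(stream, "rt", encoding="utf-8").read())
    return pd.read_csv(stream, sep="\t", index_col=0)
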