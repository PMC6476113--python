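"""Pedigree representation and kinship computation.

A pedigree is the directed acyclic graph of parent-offspring relationships in
a (possibly inbred) multigenerational family. From it we compute the kinship
matrix Phi, whose entry phi(i, j) is the probability that one allele sampled
at random from i and one from j are identical by descent at an autosomal
locus. The doubled matrix 2*Phi is the additive-relationship ("coefficient of
relationship") structuring matrix used by every variance-component model in
this package.

Two independent routes to Phi are provided: the exact tabular recursion
(:func:`compute_kinship`) and a Monte-Carlo gene-dropping estimator
(:func:`kinship_oracle`) used to cross-check it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "load_pedigree",
    "compute_kinship",
    "kinship_oracle",
]

#: encodings accepted for sex in input tables
_SEX_CODES = {
    "1": "male", "2": "female",
    "m": "male", "f": "female",
    "male": "male", "female": "female",
}

#: values interpreted as "no parent recorded"
_MISSING_PARENT = {"", "0", "na", "nan", "none", "."}


class PedigreeError(ValueError):
    """Raised when a pedigree table violates a structural invariant."""


def _norm_id(value) -> str:
    """Identifiers are compared as exact strings (no case folding)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    s = str(value)
    # integer-valued floats from pandas ("12.0") are common in ped files
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def _is_missing_parent(value) -> bool:
    return _norm_id(value).lower() in _MISSING_PARENT


@dataclass(frozen=True)
class Pedigree:
    """A validated pedigree.

    Attributes
    ----------
    ids : list of str
        Member identifiers in input order.
    father_idx, mother_idx : ndarray of int
        Index (into ``ids``) of each member's father/mother, or -1 for
        founders. A member has either both parents or neither.
    sex : ndarray of str
        ``"male"`` or ``"female"`` per member.
    topo_order : ndarray of int
        A topological ordering of member indices (parents before offspring).
    """

    ids: list[str]
    father_idx: np.ndarray
    mother_idx: np.ndarray
    sex: np.ndarray
    topo_order: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return self.father_idx < 0

    @property
    def n_founders(self) -> int:
        return int(np.sum(self.is_founder))

    def index_of(self, ids) -> np.ndarray:
        lookup = {m: k for k, m in enumerate(self.ids)}
        try:
            return np.array([lookup[_norm_id(i)] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"identifier not in pedigree: {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        """Return the pedigree as an ``id,father,mother,sex`` table."""
        father = ["0" if k < 0 else self.ids[k] for k in self.father_idx]
        mother = ["0" if k < 0 else self.ids[k] for k in self.mother_idx]
        return pd.DataFrame(
            {"id": self.ids, "father": father, "mother": mother, "sex": self.sex}
        )


def load_pedigree(table) -> Pedigree:
    """Validate an ``id/father/mother/sex`` table into a :class:`Pedigree`.

    Parameters
    ----------
    table : DataFrame or iterable of (id, father, mother, sex) rows
        Missing parents may be encoded as empty, ``0``, ``NA`` or None.
        Sex accepts ``1``/``2`` or ``m``/``f`` (case-insensitive).

    Raises
    ------
    PedigreeError
        On duplicate identifiers, unknown parent identifiers, half-recorded
        parentage, parent-sex inconsistencies, or cycles; the offending
        identifiers are named in the message.
    """
    if isinstance(table, pd.DataFrame):
        cols = {c.lower(): c for c in table.columns}
        for required in ("id", "father", "mother", "sex"):
            if required not in cols:
                raise PedigreeError(f"pedigree table lacks a {required!r} column")
        rows = zip(
            table[cols["id"]], table[cols["father"]],
            table[cols["mother"]], table[cols["sex"]],
        )
        rows = list(rows)
    else:
        rows = [tuple(r) for r in table]

    ids: list[str] = []
    seen: set[str] = set()
    raw_parents: list[tuple[str, str]] = []
    sexes: list[str] = []
    for iid_raw, fa_raw, mo_raw, sex_raw in rows:
        iid = _norm_id(iid_raw)
        if not iid or iid.lower() in _MISSING_PARENT:
            raise PedigreeError(f"invalid member identifier {iid_raw!r}")
        if iid in seen:
            raise PedigreeError(f"duplicate identifier {iid!r}")
        seen.add(iid)
        fa_missing = _is_missing_parent(fa_raw)
        mo_missing = _is_missing_parent(mo_raw)
        if fa_missing != mo_missing:
            raise PedigreeError(
                f"member {iid!r} has exactly one recorded parent; parents must "
                "be recorded both-or-neither"
            )
        sex_key = _norm_id(sex_raw).lower()
        if sex_key not in _SEX_CODES:
            raise PedigreeError(f"member {iid!r} has unrecognized sex {sex_raw!r}")
        ids.append(iid)
        sexes.append(_SEX_CODES[sex_key])
        raw_parents.append(
            ("" if fa_missing else _norm_id(fa_raw),
             "" if mo_missing else _norm_id(mo_raw))
        )

    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    father_idx = np.full(n, -1, dtype=int)
    mother_idx = np.full(n, -1, dtype=int)
    sex_arr = np.array(sexes, dtype=object)
    for k, (fa, mo) in enumerate(raw_parents):
        if not fa:
            continue
        if fa not in index:
            raise PedigreeError(f"member {ids[k]!r} lists unknown father {fa!r}")
        if mo not in index:
            raise PedigreeError(f"member {ids[k]!r} lists unknown mother {mo!r}")
        if fa == ids[k] or mo == ids[k]:
            raise PedigreeError(f"member {ids[k]!r} lists itself as a parent")
        father_idx[k] = index[fa]
        mother_idx[k] = index[mo]
        if sex_arr[father_idx[k]] != "male":
            raise PedigreeError(
                f"father {fa!r} of member {ids[k]!r} is not recorded as male"
            )
        if sex_arr[mother_idx[k]] != "female":
            raise PedigreeError(
                f"mother {mo!r} of member {ids[k]!r} is not recorded as female"
            )

    topo = _toposort(ids, father_idx, mother_idx)
    return Pedigree(
        ids=ids, father_idx=father_idx, mother_idx=mother_idx,
        sex=sex_arr, topo_order=topo,
    )


def _toposort(ids, father_idx, mother_idx) -> np.ndarray:
    """Kahn's algorithm over the parent->offspring DAG (bounded, no recursion)."""
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k in range(n):
        for p in (father_idx[k], mother_idx[k]):
            if p >= 0:
                children[p].append(k)
                indeg[k] += 1
    queue = [k for k in range(n) if indeg[k] == 0]
    order: list[int] = []
    while queue:
        k = queue.pop()
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        stuck = [ids[k] for k in range(n) if indeg[k] > 0]
        raise PedigreeError(
            f"pedigree contains an ancestry cycle involving: {', '.join(sorted(stuck)[:5])}"
        )
    return np.array(order, dtype=int)


@dataclass(frozen=True)
class KinshipMatrix:
    """Kinship coefficients phi(i, j) for an ordered set of individuals."""

    ids: list[str]
    phi: np.ndarray

    def __post_init__(self):
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape does not match ids")
        object.__setattr__(self, "phi", phi)

    @property
    def two_phi(self) -> np.ndarray:
        """The additive-relationship structuring matrix 2*Phi."""
        return 2.0 * self.phi

    @property
    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficients F = 2*phi_ii - 1."""
        return 2.0 * np.diag(self.phi) - 1.0

    def subset(self, ids) -> "KinshipMatrix":
        """Kinship submatrix for ``ids`` (in the given order)."""
        lookup = {m: k for k, m in enumerate(self.ids)}
        idx = np.array([lookup[_norm_id(i)] for i in ids], dtype=int)
        return KinshipMatrix(
            ids=[self.ids[k] for k in idx], phi=self.phi[np.ix_(idx, idx)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.ids, columns=self.ids)


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Exact kinship by the tabular recursion, evaluated in topological order.

    Founders: phi(i, i) = 1/2 and phi = 0 between founders. For a non-founder
    i with parents f and m, and any j placed earlier in topological order
    (hence never a descendant of i): phi(i, j) = [phi(f, j) + phi(m, j)] / 2,
    and phi(i, i) = [1 + phi(f, m)] / 2, which accommodates inbreeding.
    """
    n = ped.n
    order = ped.topo_order
    pos = np.empty(n, dtype=int)   # member index -> position in topo order
    pos[order] = np.arange(n)

    # work in topological layout, permute back at the end
    phi = np.zeros((n, n))
    fa = ped.father_idx[order]
    mo = ped.mother_idx[order]
    for t in range(n):
        if fa[t] < 0:
            phi[t, t] = 0.5
        else:
            pf, pm = pos[fa[t]], pos[mo[t]]
            if t > 0:
                row = 0.5 * (phi[pf, :t] + phi[pm, :t])
                phi[t, :t] = row
                phi[:t, t] = row
            phi[t, t] = 0.5 * (1.0 + phi[pf, pm])

    phi_member = phi[np.ix_(pos, pos)]
    return KinshipMatrix(ids=list(ped.ids), phi=phi_member)


def _drop_alleles(ped: Pedigree, n_drops: int, rng: np.random.Generator) -> np.ndarray:
    """Gene-drop founder allele labels: returns labels of shape (n, 2, n_drops)."""
    n = ped.n
    alleles = np.zeros((n, 2, n_drops), dtype=np.int32)
    label = 0
    for k in range(n):
        if ped.father_idx[k] < 0:
            alleles[k, 0, :] = label
            alleles[k, 1, :] = label + 1
            label += 2
    cols = np.arange(n_drops)
    for k in ped.topo_order:
        f, m = ped.father_idx[k], ped.mother_idx[k]
        if f < 0:
            continue
        alleles[k, 0, :] = alleles[f, rng.integers(0, 2, size=n_drops), cols]
        alleles[k, 1, :] = alleles[m, rng.integers(0, 2, size=n_drops), cols]
    return alleles


def kinship_oracle(
    ped: Pedigree, n_drops: int, seed: int, return_se: bool = False,
    chunk: int = 2048,
):
    """Monte-Carlo kinship via gene dropping (verification oracle).

    Each founder receives two globally unique allele labels; every drop
    transmits one randomly chosen allele per parent per meiosis down the
    pedigree. phi(i, j) is estimated as the mean over drops of
    (number of identical-by-descent pairs among the four cross-individual
    allele pairs) / 4, and phi(i, i) as (1 + F_i)/2 with F_i the fraction of
    drops in which i's own two alleles are IBD. Kept independent of
    :func:`compute_kinship` so the two can cross-validate each other.

    With ``return_se=True`` also returns the elementwise Monte-Carlo standard
    error of the phi estimate (sample s.d. of the per-drop share / sqrt(drops)).
    Work proceeds in chunks of drops to bound memory.
    """
    if n_drops < 1:
        raise ValueError("n_drops must be >= 1")
    rng = np.random.default_rng(seed)
    n = ped.n
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    done = 0
    while done < n_drops:
        m = min(chunk, n_drops - done)
        alleles = _drop_alleles(ped, m, rng)
        share = np.zeros((n, n, m), dtype=np.float32)
        for a in range(2):
            for b in range(2):
                share += alleles[:, a, :][:, None, :] == alleles[:, b, :][None, :, :]
        share *= 0.25
        # diagonal carries the self-IBD based definition (1 + F)/2
        self_share = 0.5 * (1.0 + (alleles[:, 0, :] == alleles[:, 1, :]))
        share[np.arange(n), np.arange(n), :] = self_share
        s1 += share.sum(axis=2, dtype=np.float64)
        s2 += np.square(share, dtype=np.float64).sum(axis=2)
        done += m
    phi = s1 / n_drops
    km = KinshipMatrix(ids=list(ped.ids), phi=phi)
    if not return_se:
        return km
    var = (s2 - n_drops * phi**2) / max(n_drops - 1, 1)
    se = np.sqrt(np.maximum(var, 0.0) / n_drops)
    return km, se
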