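"""Pedigree parsing and the additive (numerator) relationship matrix.

The additive relationship matrix ``A`` holds expected additive-genetic
relatedness between animals: diagonal ``1 + F`` (``F`` the inbreeding
coefficient), 0.5 between a non-inbred parent and its offspring, 0 between
unrelated founders.  It is the pedigree kernel of the animal-model genetic
covariance ``A (x) G`` used throughout the REML machinery.

Conventions: unknown parents are coded ``0`` or empty in files and treated as
unrelated, non-inbred founders.  Parents that are referenced but never
declared as animals are auto-added as founders (a warning is logged).
Inbreeding is fully accounted for by the tabular recursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = -1
_UNKNOWN_CODES = {"", "0", "na", "nan", "none", ".", "unknown"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, bad rows)."""


@dataclass
class Pedigree:
    """A topologically ordered pedigree.

    ``ids[i]`` is the i-th animal; ``sire[i]``/``dam[i]`` are integer indices
    into ``ids`` or :data:`UNKNOWN`.  Every known parent index is < its
    offspring's index, so recursions down the pedigree are single passes.
    """

    ids: tuple
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    index: dict = field(repr=False)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal) -> bool:
        return animal in self.index

    def parents_of(self, animal):
        i = self.index[animal]
        s, d = self.sire[i], self.dam[i]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build an ordered pedigree from (animal, sire-or-None, dam-or-None) triples.

        Raises :class:`PedigreeError` on duplicate ids or cyclic ancestry.
        Undeclared parents are appended as founders with a logged warning.
        """
        rows = [(a, s, d) for a, s, d in records]
        ids = [a for a, _, _ in rows]
        seen = set()
        for a in ids:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen.add(a)
        declared = set(ids)
        position = {a: k for k, (a, _, _) in enumerate(rows)}
        parents = {a: (s, d) for a, s, d in rows}
        extra = []
        for a, s, d in rows:
            for p in (s, d):
                if p is not None and p not in declared and p not in extra:
                    extra.append(p)
        if extra:
            logger.warning(
                "%d parent(s) referenced but not declared; added as founders: %s",
                len(extra), ", ".join(map(str, extra[:10])),
            )
        for p in extra:
            parents[p] = (None, None)
            # stable: auto-added founders sort where first referenced
            position[p] = min(position[a] for a, s, d in rows if p in (s, d))
        all_ids = list(parents)

        # generation depth by iterative resolution; failure to resolve => cycle
        depth: dict = {}
        pending = set(all_ids)
        while pending:
            progressed = False
            for a in list(pending):
                s, d = parents[a]
                if (s is None or s in depth) and (d is None or d in depth):
                    if s is None and d is None:
                        depth[a] = 0
                    else:
                        ds = depth[s] if s is not None else 0
                        dd = depth[d] if d is not None else 0
                        depth[a] = max(ds, dd) + 1
                    pending.discard(a)
                    progressed = True
            if not progressed:
                raise PedigreeError(
                    f"cyclic ancestry involving: {sorted(map(str, pending))[:10]}"
                )

        order = sorted(all_ids, key=lambda a: (depth[a], position[a]))
        index = {a: i for i, a in enumerate(order)}
        sire = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam = np.full(len(order), UNKNOWN, dtype=np.int64)
        gen = np.zeros(len(order), dtype=np.int64)
        for a in order:
            i = index[a]
            s, d = parents[a]
            if s is not None:
                sire[i] = index[s]
            if d is not None:
                dam[i] = index[d]
            gen[i] = depth[a]
        return cls(ids=tuple(order), sire=sire, dam=dam, generation=gen, index=index)

    def to_frame(self) -> pd.DataFrame:
        sires = [self.ids[s] if s >= 0 else None for s in self.sire]
        dams = [self.ids[d] if d >= 0 else None for d in self.dam]
        return pd.DataFrame({"animal": list(self.ids), "sire": sires, "dam": dams})

    def subset(self, animals) -> "Pedigree":
        """Restrict to ``animals`` plus all their ancestors, preserving order."""
        keep = set()
        stack = [a for a in animals]
        missing = [a for a in stack if a not in self.index]
        if missing:
            raise PedigreeError(f"animals not in pedigree: {missing[:10]}")
        while stack:
            a = stack.pop()
            if a in keep:
                continue
            keep.add(a)
            for p in self.parents_of(a):
                if p is not None:
                    stack.append(p)
        rows = [
            (a, *self.parents_of(a))
            for a in self.ids
            if a in keep
        ]
        return Pedigree.from_records(rows)


def _normalise_parent(value):
    if value is None:
        return None
    text = str(value).strip()
    return None if text.lower() in _UNKNOWN_CODES else text


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with header ``animal,sire,dam``.

    Unknown parents are coded 0 or empty.  Lines starting with ``#`` are
    ignored.  Returns a deterministically ordered :class:`Pedigree`.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    for needed in ("animal", "sire", "dam"):
        if needed not in cols:
            raise PedigreeError(f"pedigree file {path} lacks column {needed!r}")
    records = []
    for k, row in enumerate(df.itertuples(index=False)):
        animal = str(getattr(row, cols["animal"])).strip()
        if not animal or animal.lower() in _UNKNOWN_CODES:
            raise PedigreeError(f"malformed pedigree row {k + 2}: missing animal id")
        records.append(
            (
                animal,
                _normalise_parent(getattr(row, cols["sire"])),
                _normalise_parent(getattr(row, cols["dam"])),
            )
        )
    return Pedigree.from_records(records)


def write_pedigree(ped: Pedigree, path, header_comment: str | None = None) -> None:
    """Write the pedigree CSV dialect read by :func:`read_pedigree`."""
    df = ped.to_frame().fillna("0")
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


@dataclass
class RelationshipMatrix:
    """Dense additive relationship matrix with its animal-id index."""

    ids: tuple
    matrix: np.ndarray
    index: dict = field(repr=False)

    def __getitem__(self, pair):
        a, b = pair
        return self.matrix[self.index[a], self.index[b]]

    def inbreeding(self) -> pd.Series:
        """Inbreeding coefficient F per animal (diagonal minus one)."""
        return pd.Series(np.diag(self.matrix) - 1.0, index=list(self.ids))


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix by the tabular (recursive) method.

    For animal ``i`` with parents ``s, d`` (already processed):
    ``a_ii = 1 + 0.5 a_sd`` and ``a_ij = 0.5 (a_js + a_jd)`` for ``j < i``,
    unknown parents contributing zero.  Handles inbreeding exactly.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[s, :i]
            if d >= 0:
                row += A[d, :i]
            row *= 0.5
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=ped.ids, matrix=A, index=dict(ped.index))
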