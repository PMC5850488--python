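"""Observation containers for aligned homologous protein pairs.

Each aligned column carries up to three observation pairs — amino acids,
(φ, ψ) dihedral angles, and 3-class secondary structure — any field of
which may be missing.  Insert/delete columns are marked non-homologous and
carry data on exactly one side.

Two representations are provided: a per-site :class:`ObservationPair`
(convenient for scalar likelihood calls and tests) and the columnar
:class:`PairObservations` used by the vectorized likelihood engine
(integer codes with −1 for missing; angle arrays with NaN for missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ctmc import AA_ALPHABET, AA_INDEX, SS_ALPHABET, SS_INDEX
from .torus import TorusPoint, wrap_array


@dataclass
class ObservationPair:
    """One aligned column: (amino acid, dihedral, secondary structure) pairs."""

    aa_a: Optional[str] = None
    aa_b: Optional[str] = None
    x_a: Optional[TorusPoint] = None
    x_b: Optional[TorusPoint] = None
    ss_a: Optional[str] = None
    ss_b: Optional[str] = None
    homologous: bool = True

    def __post_init__(self) -> None:
        for name in ("aa_a", "aa_b"):
            v = getattr(self, name)
            if v is not None and v not in AA_INDEX:
                raise ValueError(f"unknown amino acid {v!r}")
        for name in ("ss_a", "ss_b"):
            v = getattr(self, name)
            if v is not None and v not in SS_INDEX:
                raise ValueError(f"unknown secondary-structure class {v!r}")
        if not self.homologous:
            a_side = any(v is not None for v in (self.aa_a, self.x_a, self.ss_a))
            b_side = any(v is not None for v in (self.aa_b, self.x_b, self.ss_b))
            if a_side == b_side:
                raise ValueError("non-homologous column must have data on exactly one side")

    def swapped(self) -> "ObservationPair":
        return ObservationPair(
            aa_a=self.aa_b, aa_b=self.aa_a,
            x_a=self.x_b, x_b=self.x_a,
            ss_a=self.ss_b, ss_b=self.ss_a,
            homologous=self.homologous,
        )


def _code(sym: Optional[str], index: dict) -> int:
    return -1 if sym is None else index[sym]


@dataclass
class PairObservations:
    """Columnar observations for m aligned sites of a protein pair."""

    aa_a: np.ndarray  # (m,) int, −1 = missing
    aa_b: np.ndarray
    x_a: np.ndarray  # (m, 2) float, NaN = missing
    x_b: np.ndarray
    ss_a: np.ndarray  # (m,) int, −1 = missing
    ss_b: np.ndarray
    #: column type per site: 0 = homologous, 1 = delete (residue in a only),
    #: 2 = insert (residue in b only)
    col_type: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        m = len(self.aa_a)
        self.aa_a = np.asarray(self.aa_a, dtype=int)
        self.aa_b = np.asarray(self.aa_b, dtype=int)
        self.ss_a = np.asarray(self.ss_a, dtype=int)
        self.ss_b = np.asarray(self.ss_b, dtype=int)
        self.x_a = np.asarray(self.x_a, dtype=float).reshape(m, 2)
        self.x_b = np.asarray(self.x_b, dtype=float).reshape(m, 2)
        ok = np.isfinite(self.x_a)
        self.x_a = np.where(ok, wrap_array(np.where(ok, self.x_a, 0.0)), np.nan)
        ok = np.isfinite(self.x_b)
        self.x_b = np.where(ok, wrap_array(np.where(ok, self.x_b, 0.0)), np.nan)
        if self.col_type is None:
            self.col_type = np.zeros(m, dtype=int)
        self.col_type = np.asarray(self.col_type, dtype=int)
        if np.any((self.col_type < 0) | (self.col_type > 2)):
            raise ValueError("col_type entries must be 0 (homologous), 1 (delete) or 2 (insert)")

    @property
    def homologous(self) -> np.ndarray:
        return self.col_type == 0

    @property
    def has_a(self) -> np.ndarray:
        """Sites where protein a has a residue."""
        return self.col_type != 2

    @property
    def has_b(self) -> np.ndarray:
        return self.col_type != 1

    @property
    def n_sites(self) -> int:
        return len(self.aa_a)

    @classmethod
    def empty(cls, m: int) -> "PairObservations":
        return cls(
            aa_a=np.full(m, -1), aa_b=np.full(m, -1),
            x_a=np.full((m, 2), np.nan), x_b=np.full((m, 2), np.nan),
            ss_a=np.full(m, -1), ss_b=np.full(m, -1),
        )

    @classmethod
    def from_sites(cls, sites: Sequence[ObservationPair]) -> "PairObservations":
        m = len(sites)
        out = cls.empty(m)
        for i, o in enumerate(sites):
            out.aa_a[i] = _code(o.aa_a, AA_INDEX)
            out.aa_b[i] = _code(o.aa_b, AA_INDEX)
            out.ss_a[i] = _code(o.ss_a, SS_INDEX)
            out.ss_b[i] = _code(o.ss_b, SS_INDEX)
            if o.x_a is not None:
                out.x_a[i] = o.x_a.as_array()
            if o.x_b is not None:
                out.x_b[i] = o.x_b.as_array()
            if not o.homologous:
                a_side = any(v is not None for v in (o.aa_a, o.x_a, o.ss_a))
                out.col_type[i] = 1 if a_side else 2
        return out

    def site(self, i: int) -> ObservationPair:
        return ObservationPair(
            aa_a=None if self.aa_a[i] < 0 else AA_ALPHABET[self.aa_a[i]],
            aa_b=None if self.aa_b[i] < 0 else AA_ALPHABET[self.aa_b[i]],
            x_a=None if not np.all(np.isfinite(self.x_a[i])) else TorusPoint(*self.x_a[i]),
            x_b=None if not np.all(np.isfinite(self.x_b[i])) else TorusPoint(*self.x_b[i]),
            ss_a=None if self.ss_a[i] < 0 else SS_ALPHABET[self.ss_a[i]],
            ss_b=None if self.ss_b[i] < 0 else SS_ALPHABET[self.ss_b[i]],
            homologous=bool(self.col_type[i] == 0),
        )

    def sites(self) -> list[ObservationPair]:
        return [self.site(i) for i in range(self.n_sites)]

    def copy(self) -> "PairObservations":
        return PairObservations(
            aa_a=self.aa_a.copy(), aa_b=self.aa_b.copy(),
            x_a=self.x_a.copy(), x_b=self.x_b.copy(),
            ss_a=self.ss_a.copy(), ss_b=self.ss_b.copy(),
            col_type=self.col_type.copy(),
        )

    def swapped(self) -> "PairObservations":
        return PairObservations(
            aa_a=self.aa_b.copy(), aa_b=self.aa_a.copy(),
            x_a=self.x_b.copy(), x_b=self.x_a.copy(),
            ss_a=self.ss_b.copy(), ss_b=self.ss_a.copy(),
            col_type=np.choose(self.col_type, [0, 2, 1]),
        )

    def mask_tracks(self, *, aa_a=True, aa_b=True, x_a=True, x_b=True,
                    ss_a=True, ss_b=True) -> "PairObservations":
        """Return a copy keeping only the selected tracks (True = keep)."""
        out = self.copy()
        if not aa_a:
            out.aa_a[:] = -1
        if not aa_b:
            out.aa_b[:] = -1
        if not x_a:
            out.x_a[:] = np.nan
        if not x_b:
            out.x_b[:] = np.nan
        if not ss_a:
            out.ss_a[:] = -1
        if not ss_b:
            out.ss_b[:] = -1
        return out


@dataclass
class SideObservations:
    """Per-residue observations of a single (unaligned) protein: amino-acid
    codes (−1 missing), (φ, ψ) angles (NaN missing), secondary structure."""

    aa: np.ndarray
    x: np.ndarray
    ss: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.aa)
        self.aa = np.asarray(self.aa, dtype=int)
        self.ss = np.asarray(self.ss, dtype=int)
        self.x = np.asarray(self.x, dtype=float).reshape(n, 2)
        if len(self.ss) != n or len(self.x) != n:
            raise ValueError("track lengths differ")

    @property
    def n_residues(self) -> int:
        return len(self.aa)

    @classmethod
    def blank(cls, n: int) -> "SideObservations":
        return cls(aa=np.full(n, -1), x=np.full((n, 2), np.nan), ss=np.full(n, -1))

    def mask_tracks(self, *, aa=True, x=True, ss=True) -> "SideObservations":
        out = SideObservations(self.aa.copy(), self.x.copy(), self.ss.copy())
        if not aa:
            out.aa[:] = -1
        if not x:
            out.x[:] = np.nan
        if not ss:
            out.ss[:] = -1
        return out


def split_sides(obs: PairObservations) -> tuple[SideObservations, SideObservations]:
    """Project an aligned pair onto the two unaligned protein tracks."""
    a = SideObservations(obs.aa_a[obs.has_a], obs.x_a[obs.has_a], obs.ss_a[obs.has_a])
    b = SideObservations(obs.aa_b[obs.has_b], obs.x_b[obs.has_b], obs.ss_b[obs.has_b])
    return a, b
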