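"""Canonical genotype representation.

Every input dialect (A/B/H letters, AA/AB/BB pairs, nucleotide pairs, 0/1/2
dosages, VCF GT fields) is normalised to a four-state coding of a biallelic
SNP call.  Internally calls are held as a dense ``int8`` array whose values
coincide with the alternate-allele dosage (0, 1, 2) with −1 for missing, so
dosage arithmetic (LD, allele counting) needs no translation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import IdentityError

__all__ = ["GenotypeCall", "GenotypeMatrix", "MISSING"]


class GenotypeCall(IntEnum):
    """One biallelic SNP call. Values equal the ALT-allele dosage (−1 = no call)."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


MISSING = GenotypeCall.MISSING

_VALID_CODES = frozenset(int(c) for c in GenotypeCall)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise IdentityError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class GenotypeMatrix:
    """Accessions × markers call grid with optional metadata.

    Parameters
    ----------
    accession_ids, marker_ids
        Ordered, unique identifiers for rows and columns of ``calls``.
    calls
        ``(n_accessions, n_markers)`` integer array with values in
        {−1, 0, 1, 2} (see :class:`GenotypeCall`).
    marker_meta
        Optional frame indexed by marker id; recognised columns include
        ``chromosome``, ``position_bp``, ``allele_ref``, ``allele_alt``.
    accession_meta
        Optional frame indexed by accession id; free-form group/origin labels.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    marker_meta: pd.DataFrame | None = None
    accession_meta: pd.DataFrame | None = None
    _marker_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _accession_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        _check_unique(self.accession_ids, "accession")
        _check_unique(self.marker_ids, "marker")
        self.calls = np.asarray(self.calls)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        n, m = self.calls.shape
        if n != len(self.accession_ids) or m != len(self.marker_ids):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions × {len(self.marker_ids)} markers"
            )
        bad = set(np.unique(self.calls)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid call codes present: {sorted(bad)}")
        self.calls = self.calls.astype(np.int8, copy=False)
        if self.marker_meta is not None and "position_bp" in self.marker_meta:
            pos = pd.to_numeric(self.marker_meta["position_bp"], errors="coerce")
            if (pos.dropna() < 0).any():
                raise ValueError("marker positions must be non-negative")
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}
        self._accession_index = {a: i for i, a in enumerate(self.accession_ids)}

    # -- basic geometry -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise IdentityError(f"unknown marker identifier: {marker_id!r}") from None

    def accession_index(self, accession_id: str) -> int:
        try:
            return self._accession_index[accession_id]
        except KeyError:
            raise IdentityError(f"unknown accession identifier: {accession_id!r}") from None

    def marker_calls(self, marker_id: str) -> np.ndarray:
        """Call vector (one per accession) for a single marker."""
        return self.calls[:, self.marker_index(marker_id)]

    # -- subsetting ------------------------------------------------------

    def subset(
        self,
        accessions: Iterable[str] | None = None,
        markers: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset preserving the given order."""
        acc = list(accessions) if accessions is not None else self.accession_ids
        mks = list(markers) if markers is not None else self.marker_ids
        ai = [self.accession_index(a) for a in acc]
        mi = [self.marker_index(m) for m in mks]
        mm = self.marker_meta.loc[mks] if self.marker_meta is not None else None
        am = self.accession_meta.loc[acc] if self.accession_meta is not None else None
        return GenotypeMatrix(acc, mks, self.calls[np.ix_(ai, mi)].copy(), mm, am)

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Cell-for-cell identity of ids and calls (metadata ignored)."""
        return (
            self.accession_ids == other.accession_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.calls, other.calls)
        )
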