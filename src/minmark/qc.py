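"""Quality-control filters applied before marker selection.

Markers are kept when call rate and minor allele frequency strictly exceed
their thresholds (the defaults mirror the usual genebank-genomics practice of
">95% call rate, >5% MAF"); accessions are kept when their call rate strictly
exceeds the threshold and their heterozygous fraction is strictly below the
cap (inbred material is expected to be almost fully homozygous).  Each removed
item records exactly one primary reason — the first failing test in the
documented order: call rate, then MAF (markers) / heterozygosity (accessions),
then monomorphism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .genotype import GenotypeCall, GenotypeMatrix
from .stats import _frequency_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReason",
    "FilterReport",
    "filter_markers",
    "filter_accessions",
    "drop_monomorphic",
]


class FilterReason(str, Enum):
    LOW_CALL_RATE = "LOW_CALL_RATE"
    LOW_MAF = "LOW_MAF"
    HIGH_HET = "HIGH_HET"
    MONOMORPHIC = "MONOMORPHIC"


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass.

    ``removed`` maps each removed identifier to its primary reason code;
    the in/out counts reconcile exactly with the matrix dimensions.
    """

    axis: str  # "markers" or "accessions"
    n_markers_in: int
    n_markers_out: int
    n_accessions_in: int
    n_accessions_out: int
    removed: dict[str, FilterReason] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def __post_init__(self) -> None:
        if self.axis == "markers":
            assert self.n_markers_in == self.n_markers_out + self.n_removed
            assert self.n_accessions_in == self.n_accessions_out
        else:
            assert self.n_accessions_in == self.n_accessions_out + self.n_removed
            assert self.n_markers_in == self.n_markers_out

    def to_dict(self) -> dict:
        return {
            "axis": self.axis,
            "n_markers_in": self.n_markers_in,
            "n_markers_out": self.n_markers_out,
            "n_accessions_in": self.n_accessions_in,
            "n_accessions_out": self.n_accessions_out,
            "removed": {k: v.value for k, v in self.removed.items()},
        }


def _marker_report(gm: GenotypeMatrix, kept: list[str], removed: dict[str, FilterReason]):
    out = gm.subset(markers=kept)
    report = FilterReport(
        axis="markers",
        n_markers_in=gm.n_markers,
        n_markers_out=out.n_markers,
        n_accessions_in=gm.n_accessions,
        n_accessions_out=out.n_accessions,
        removed=removed,
    )
    return out, report


def filter_markers(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep markers with call_rate > min_call_rate and MAF > min_maf (strict).

    Column order is preserved.  An all-missing marker fails the call-rate test
    first (reason LOW_CALL_RATE).
    """
    _check_threshold(min_call_rate, "min_call_rate")
    _check_threshold(min_maf, "min_maf")
    if gm.n_markers == 0 or gm.n_accessions == 0:
        logger.warning("filter_markers: empty matrix, nothing to filter")
        return _marker_report(gm, list(gm.marker_ids), {})
    _, call_rate, _, _, maf = _frequency_arrays(gm)
    kept: list[str] = []
    removed: dict[str, FilterReason] = {}
    for j, marker in enumerate(gm.marker_ids):
        if not call_rate[j] > min_call_rate:
            removed[marker] = FilterReason.LOW_CALL_RATE
        elif not maf[j] > min_maf:  # NaN maf also fails (call rate caught it above)
            removed[marker] = FilterReason.LOW_MAF
        else:
            kept.append(marker)
    return _marker_report(gm, kept, removed)


def filter_accessions(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.995,
    max_het: float = 0.001,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep accessions with call_rate > min_call_rate and het fraction < max_het.

    The heterozygosity denominator is the accession's non-missing calls
    (missing calls carry no genotype information).
    """
    _check_threshold(min_call_rate, "min_call_rate")
    _check_threshold(max_het, "max_het")
    if gm.n_markers == 0 or gm.n_accessions == 0:
        logger.warning("filter_accessions: empty matrix, nothing to filter")
        rep = FilterReport("accessions", gm.n_markers, gm.n_markers, gm.n_accessions, gm.n_accessions)
        return gm.subset(), rep
    c = gm.calls
    n_obs = np.count_nonzero(c != GenotypeCall.MISSING, axis=1)
    n_het = np.count_nonzero(c == GenotypeCall.HET, axis=1)
    call_rate = n_obs / gm.n_markers
    with np.errstate(invalid="ignore"):
        het_frac = np.where(n_obs > 0, n_het / np.maximum(n_obs, 1), np.nan)
    kept: list[str] = []
    removed: dict[str, FilterReason] = {}
    for i, acc in enumerate(gm.accession_ids):
        if not call_rate[i] > min_call_rate:
            removed[acc] = FilterReason.LOW_CALL_RATE
        elif not het_frac[i] < max_het:
            removed[acc] = FilterReason.HIGH_HET
        else:
            kept.append(acc)
    out = gm.subset(accessions=kept)
    report = FilterReport(
        axis="accessions",
        n_markers_in=gm.n_markers,
        n_markers_out=out.n_markers,
        n_accessions_in=gm.n_accessions,
        n_accessions_out=out.n_accessions,
        removed=removed,
    )
    return out, report


def drop_monomorphic(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove markers whose non-missing calls are a single homozygous state.

    A marker containing any heterozygote is polymorphic (both alleles are
    present) and is retained.  All-missing markers are classed MONOMORPHIC —
    a degenerate case folded into the same reason code to keep the report
    enumeration closed.
    """
    c = gm.calls
    kept: list[str] = []
    removed: dict[str, FilterReason] = {}
    for j, marker in enumerate(gm.marker_ids):
        col = c[:, j]
        obs = col[col != GenotypeCall.MISSING]
        states = set(np.unique(obs))
        monomorphic = len(states) == 0 or (
            len(states) == 1 and int(GenotypeCall.HET) not in states
        )
        if monomorphic:
            removed[marker] = FilterReason.MONOMORPHIC
        else:
            kept.append(marker)
    return _marker_report(gm, kept, removed)


def _check_threshold(x: float, name: str) -> None:
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {x}")
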