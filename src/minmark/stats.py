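"""Per-marker informativeness statistics and pairwise LD.

For a biallelic marker with reference-allele frequency ``p`` (``q = 1 − p``):

* minor allele frequency  MAF = min(p, q)
* expected heterozygosity He = 1 − (p² + q²) = 2pq
* polymorphic information content  PIC = 1 − (p² + q²) − 2p²q²
* observed heterozygosity Ho = fraction of heterozygous calls

Frequencies are allele-based: a heterozygote contributes one copy of each
allele, so ``p = (2·n_HOM_REF + n_HET) / (2·n_non_missing)``.  PIC is
maximal (0.375) at p = 0.5 and satisfies PIC ≤ He ≤ 0.5 throughout.

Linkage disequilibrium is reported as r², the squared Pearson correlation of
ALT-allele dosages over pairwise-complete accessions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedFrequencyError
from .genotype import GenotypeCall, GenotypeMatrix

__all__ = [
    "allele_frequencies",
    "expected_heterozygosity",
    "pic",
    "marker_summary",
    "pairwise_r2",
]


def expected_heterozygosity(p: float) -> float:
    """He = 1 − (p² + q²)."""
    q = 1.0 - p
    return 1.0 - (p * p + q * q)


def pic(p: float) -> float:
    """PIC = 1 − (p² + q²) − 2p²q² for a biallelic marker."""
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2.0 * p * p * q * q


def allele_frequencies(calls) -> tuple[float, float]:
    """Reference/alternate allele frequencies of one marker's call vector.

    Raises
    ------
    UndefinedFrequencyError
        If every call is missing.
    """
    c = np.asarray(calls)
    n_obs = int(np.count_nonzero(c != GenotypeCall.MISSING))
    if n_obs == 0:
        raise UndefinedFrequencyError("allele frequencies undefined: all calls missing")
    n_ref = int(np.count_nonzero(c == GenotypeCall.HOM_REF))
    n_het = int(np.count_nonzero(c == GenotypeCall.HET))
    p = (2 * n_ref + n_het) / (2 * n_obs)
    return p, 1.0 - p


def _frequency_arrays(gm: GenotypeMatrix):
    """Vectorised (p, call_rate, ho, n_obs, maf) per marker; NaN when undefined.

    ``maf`` is computed from integer allele counts (min count over allele
    total) so threshold comparisons at printed precisions are exact.
    """
    c = gm.calls
    n = gm.n_accessions
    n_obs = np.count_nonzero(c != GenotypeCall.MISSING, axis=0)
    n_ref = np.count_nonzero(c == GenotypeCall.HOM_REF, axis=0)
    n_alt = np.count_nonzero(c == GenotypeCall.HOM_ALT, axis=0)
    n_het = np.count_nonzero(c == GenotypeCall.HET, axis=0)
    ref_alleles = 2 * n_ref + n_het
    alt_alleles = 2 * n_alt + n_het
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_obs > 0, ref_alleles / np.maximum(2 * n_obs, 1), np.nan)
        maf = np.where(
            n_obs > 0,
            np.minimum(ref_alleles, alt_alleles) / np.maximum(2 * n_obs, 1),
            np.nan,
        )
        ho = np.where(n_obs > 0, n_het / np.maximum(n_obs, 1), np.nan)
    call_rate = n_obs / n if n else np.zeros(gm.n_markers)
    return p, call_rate, ho, n_obs, maf


def marker_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker statistics frame indexed by marker id.

    Columns: ``p``, ``q``, ``maf``, ``he``, ``ho``, ``pic``, ``call_rate``,
    ``n_obs``.  Markers with no non-missing calls carry NaN statistics
    (undefined, deliberately not zero).
    """
    p, call_rate, ho, n_obs, maf = _frequency_arrays(gm)
    q = 1.0 - p
    he = 1.0 - (p**2 + q**2)
    pic_ = he - 2.0 * p**2 * q**2
    return pd.DataFrame(
        {
            "p": p,
            "q": q,
            "maf": maf,
            "he": he,
            "ho": ho,
            "pic": pic_,
            "call_rate": call_rate,
            "n_obs": n_obs,
        },
        index=pd.Index(gm.marker_ids, name="marker"),
    )


def rounded_summary(gm: GenotypeMatrix, decimals: int = 3) -> pd.DataFrame:
    """marker_summary rounded for reporting; internal use keeps full precision."""
    out = marker_summary(gm).copy()
    for col in ("p", "q", "maf", "he", "ho", "pic", "call_rate"):
        out[col] = out[col].round(decimals)
    return out


def pairwise_r2(gm: GenotypeMatrix, marker_subset: list[str] | None = None) -> pd.DataFrame:
    """Pairwise LD (r²) between markers as squared Pearson correlation of dosages.

    Missing calls are handled pairwise-complete: each marker pair uses the
    accessions where both calls are non-missing.  Entries are NaN when a
    marker is constant (or has < 2 calls) within the pairwise-complete
    subset; the diagonal is 1 for markers with any variation.
    """
    markers = marker_subset if marker_subset is not None else gm.marker_ids
    sub = gm.subset(markers=markers)
    if sub.n_markers < 2:
        raise ValueError("pairwise_r2 requires at least two markers")
    dosage = sub.calls.astype(float)
    dosage[sub.calls == GenotypeCall.MISSING] = np.nan
    df = pd.DataFrame(dosage, columns=markers)
    r = df.corr(min_periods=2)  # pairwise-complete Pearson
    return r**2
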