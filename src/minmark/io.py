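"""Delimited-text and VCF input/output.

Genotype matrices travel as plain CSV/TSV under one of four call-coding
dialects (the formats KASP/array pipelines typically export).  All readers
normalise to the canonical four-state coding; writers invert the same maps so
``write → read`` under an identical dialect is cell-for-cell stable.
Orientation is never guessed: the dialect states whether accessions are rows
or columns (silent transposition is a worse failure mode than an error).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
import numpy as np
import pandas as pd

from .errors import CodingError, IdentityError
from .genotype import GenotypeCall, GenotypeMatrix
from .panel import MarkerPanel

logger = logging.getLogger(__name__)

__all__ = [
    "Coding",
    "DialectSpec",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "import_vcf",
    "read_panel",
    "write_panel",
    "read_fingerprint_registry",
    "write_fingerprint_registry",
]

#: Missing tokens accepted by default; KASP/array exports vary, a superset is safe.
DEFAULT_MISSING_TOKENS = frozenset({"NA", "N", "-", "./.", ".", ""})


class Coding(str, Enum):
    """Call coding of a delimited genotype file."""

    AB = "AB"                  # A / B / H
    PAIR = "PAIR"              # AA / AB / BB
    NUCLEOTIDE = "NUCLEOTIDE"  # e.g. G/G, G/T, T/T
    DOSAGE = "DOSAGE"          # 0 / 1 / 2 (ALT-allele dosage)


@dataclass(frozen=True)
class DialectSpec:
    """How to interpret a delimited genotype file.

    ``orientation`` is ``"accessions"`` when accessions are rows (markers in
    the header) and ``"markers"`` when markers are rows.
    ``missing_out`` is the token emitted for missing calls when writing.
    """

    delimiter: str = "\t"
    coding: Coding = Coding.AB
    orientation: str = "accessions"
    missing_tokens: frozenset[str] = DEFAULT_MISSING_TOKENS
    missing_out: str = "NA"

    def __post_init__(self) -> None:
        if self.orientation not in ("accessions", "markers"):
            raise ValueError("orientation must be 'accessions' or 'markers'")
        object.__setattr__(self, "coding", Coding(self.coding))
        object.__setattr__(self, "missing_tokens", frozenset(self.missing_tokens))


_AB_MAP = {"A": GenotypeCall.HOM_REF, "B": GenotypeCall.HOM_ALT, "H": GenotypeCall.HET}
_PAIR_MAP = {
    "AA": GenotypeCall.HOM_REF,
    "BB": GenotypeCall.HOM_ALT,
    "AB": GenotypeCall.HET,
    "BA": GenotypeCall.HET,
}
_DOSAGE_MAP = {"0": GenotypeCall.HOM_REF, "1": GenotypeCall.HET, "2": GenotypeCall.HOM_ALT}


def _split_nucleotide_token(token: str) -> tuple[str, str] | None:
    t = token.strip().upper()
    if "/" in t:
        parts = t.split("/")
        if len(parts) != 2:
            return None
        a, b = parts
    elif len(t) == 2:
        a, b = t[0], t[1]
    else:
        return None
    if a in "ACGT" and b in "ACGT":
        return a, b
    return None


def _read_table(path, dialect: DialectSpec) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        index_col=0,
        keep_default_na=False,
        na_filter=False,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _check_axis_unique(labels, what: str) -> None:
    dup = pd.Index(labels)[pd.Index(labels).duplicated()]
    if len(dup):
        raise IdentityError(f"duplicate {what} identifier: {dup[0]!r}")


def read_genotype_matrix(
    path,
    dialect: DialectSpec,
    marker_meta: pd.DataFrame | None = None,
    accession_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read a delimited genotype matrix under an explicit dialect.

    For the NUCLEOTIDE coding the reference allele of each marker is taken
    from ``marker_meta['allele_ref']`` when provided, otherwise the
    alphabetically first allele observed at that marker (deterministic).

    Raises
    ------
    IdentityError
        Duplicate accession or marker identifier.
    CodingError
        A token resolvable under neither the coding nor the missing set;
        the error names the row, the column and the token.
    """
    df = _read_table(path, dialect)
    _check_axis_unique(df.index, "accession" if dialect.orientation == "accessions" else "marker")
    _check_axis_unique(df.columns, "marker" if dialect.orientation == "accessions" else "accession")
    if dialect.orientation == "markers":
        df = df.T
    accession_ids = list(df.index)
    marker_ids = list(df.columns)
    _check_axis_unique(accession_ids, "accession")
    _check_axis_unique(marker_ids, "marker")

    calls = np.full(df.shape, GenotypeCall.MISSING, dtype=np.int8)
    values = df.to_numpy(dtype=object)

    if dialect.coding is Coding.NUCLEOTIDE:
        ref_alleles = _nucleotide_ref_alleles(values, accession_ids, marker_ids, dialect, marker_meta)
        for j, marker in enumerate(marker_ids):
            ref = ref_alleles[j]
            for i, acc in enumerate(accession_ids):
                tok = str(values[i, j]).strip()
                if tok in dialect.missing_tokens:
                    continue
                pair = _split_nucleotide_token(tok)
                if pair is None:
                    raise CodingError(
                        f"unresolvable token {tok!r} at accession {acc!r}, marker {marker!r}"
                    )
                a, b = pair
                if a == b:
                    calls[i, j] = GenotypeCall.HOM_REF if a == ref else GenotypeCall.HOM_ALT
                else:
                    calls[i, j] = GenotypeCall.HET
    else:
        token_map = {
            Coding.AB: _AB_MAP,
            Coding.PAIR: _PAIR_MAP,
            Coding.DOSAGE: _DOSAGE_MAP,
        }[dialect.coding]
        for i, acc in enumerate(accession_ids):
            for j, marker in enumerate(marker_ids):
                tok = str(values[i, j]).strip()
                if tok in dialect.missing_tokens:
                    continue
                key = tok.upper() if dialect.coding in (Coding.AB, Coding.PAIR) else tok
                state = token_map.get(key)
                if state is None:
                    raise CodingError(
                        f"unresolvable token {tok!r} at accession {acc!r}, marker {marker!r}"
                    )
                calls[i, j] = state

    return GenotypeMatrix(accession_ids, marker_ids, calls, marker_meta, accession_meta)


def _nucleotide_ref_alleles(values, accession_ids, marker_ids, dialect, marker_meta):
    """Per-marker reference allele: metadata wins, else alphabetically first observed."""
    refs: list[str | None] = []
    meta_ref = None
    if marker_meta is not None and "allele_ref" in marker_meta:
        meta_ref = marker_meta["allele_ref"]
    for j, marker in enumerate(marker_ids):
        if meta_ref is not None and marker in meta_ref.index and pd.notna(meta_ref.loc[marker]):
            refs.append(str(meta_ref.loc[marker]).upper())
            continue
        observed: set[str] = set()
        for i in range(len(accession_ids)):
            tok = str(values[i, j]).strip()
            if tok in dialect.missing_tokens:
                continue
            pair = _split_nucleotide_token(tok)
            if pair is not None:
                observed.update(pair)
        refs.append(min(observed) if observed else None)
    return refs


def write_genotype_matrix(gm: GenotypeMatrix, path, dialect: DialectSpec) -> None:
    """Write ``gm`` so that :func:`read_genotype_matrix` round-trips it.

    NUCLEOTIDE output requires ``allele_ref``/``allele_alt`` in
    ``gm.marker_meta`` for every marker.
    """
    if dialect.coding is Coding.NUCLEOTIDE:
        if gm.marker_meta is None or not {"allele_ref", "allele_alt"} <= set(gm.marker_meta.columns):
            raise CodingError(
                "NUCLEOTIDE output requires marker_meta with allele_ref and allele_alt"
            )
        tokens = np.empty(gm.shape, dtype=object)
        for j, marker in enumerate(gm.marker_ids):
            ref = str(gm.marker_meta.loc[marker, "allele_ref"]).upper()
            alt = str(gm.marker_meta.loc[marker, "allele_alt"]).upper()
            col = gm.calls[:, j]
            out = np.empty(len(col), dtype=object)
            out[col == GenotypeCall.HOM_REF] = f"{ref}/{ref}"
            out[col == GenotypeCall.HOM_ALT] = f"{alt}/{alt}"
            out[col == GenotypeCall.HET] = f"{ref}/{alt}"
            out[col == GenotypeCall.MISSING] = dialect.missing_out
            tokens[:, j] = out
    else:
        inv = {
            Coding.AB: {0: "A", 1: "H", 2: "B"},
            Coding.PAIR: {0: "AA", 1: "AB", 2: "BB"},
            Coding.DOSAGE: {0: "0", 1: "1", 2: "2"},
        }[dialect.coding]
        lut = np.array(
            [inv[0], inv[1], inv[2], dialect.missing_out], dtype=object
        )  # index by call, −1 wraps to last slot
        tokens = lut[gm.calls]

    df = pd.DataFrame(tokens, index=gm.accession_ids, columns=gm.marker_ids)
    if dialect.orientation == "markers":
        df = df.T
    df.index.name = "id"
    df.to_csv(path, sep=dialect.delimiter)


def import_vcf(path) -> GenotypeMatrix:
    """Import biallelic SNP records from a VCF.

    GT fields map 0/0 → HOM_REF, 1/1 → HOM_ALT, 0/1 or 1/0 (phased or not)
    → HET, ./. → MISSING.  Non-biallelic or non-SNP records are skipped and
    the skip count is logged.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(variant.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = GenotypeCall.MISSING
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        marker_ids.append(vid)
        rows.append(gt)
        meta_rows.append(
            {
                "marker": vid,
                "chromosome": variant.CHROM,
                "position_bp": variant.POS,
                "allele_ref": variant.REF,
                "allele_alt": variant.ALT[0],
            }
        )
    if n_skipped:
        logger.info("import_vcf: skipped %d non-biallelic-SNP record(s)", n_skipped)
    calls = (
        np.column_stack(rows)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    marker_meta = pd.DataFrame(meta_rows).set_index("marker") if meta_rows else None
    return GenotypeMatrix(samples, marker_ids, calls, marker_meta)


# -- marker panels -----------------------------------------------------------


def write_panel(panel: MarkerPanel, path) -> None:
    """Panel file: TSV with marker, rank and (when known) newly_resolved."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        if panel.newly_resolved is not None:
            w.writerow(["marker", "rank", "newly_resolved"])
            for rank, (m, c) in enumerate(zip(panel.markers, panel.newly_resolved), start=1):
                w.writerow([m, rank, c])
        else:
            w.writerow(["marker", "rank"])
            for rank, m in enumerate(panel.markers, start=1):
                w.writerow([m, rank])


def read_panel(path) -> MarkerPanel:
    """Read a panel file (header-less one-marker-per-line also accepted)."""
    markers: list[str] = []
    counts: list[int] = []
    with open(path) as fh:
        rows = [line.rstrip("\n") for line in fh if line.strip()]
    if not rows:
        return MarkerPanel([])
    header = rows[0].split("\t")
    has_header = header[0].strip().lower() == "marker"
    has_counts = has_header and "newly_resolved" in [h.strip().lower() for h in header]
    for line in rows[1:] if has_header else rows:
        fields = line.split("\t")
        markers.append(fields[0].strip())
        if has_counts:
            counts.append(int(fields[2]))
    return MarkerPanel(markers, newly_resolved=counts if has_counts else None)


# -- fingerprint registries --------------------------------------------------

_REGISTRY_TOKENS = {0: "0", 1: "1", 2: "2", -1: "NA"}


def write_fingerprint_registry(ft, path) -> None:
    """Registry TSV: accession id plus one dosage-coded column per panel marker."""
    lut = np.array(["0", "1", "2", "NA"], dtype=object)
    df = pd.DataFrame(lut[ft.calls], index=ft.accession_ids, columns=ft.panel)
    df.index.name = "accession"
    df.to_csv(path, sep="\t")


def read_fingerprint_registry(path, policy=None):
    """Read a registry TSV back into a :class:`~minmark.fingerprinting.FingerprintTable`."""
    from .fingerprinting import fingerprint_table
    from .selection import DiscriminationPolicy

    dialect = DialectSpec(delimiter="\t", coding=Coding.DOSAGE)
    gm = read_genotype_matrix(path, dialect)
    pol = policy if policy is not None else DiscriminationPolicy.STRICT
    return fingerprint_table(gm, MarkerPanel(gm.marker_ids), pol)
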