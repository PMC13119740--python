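"""Dialect normalisation, round-trip stability and VCF import."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from minmark import (
    Coding,
    DialectSpec,
    GenotypeCall,
    GenotypeMatrix,
    MarkerPanel,
    import_vcf,
    read_genotype_matrix,
    read_panel,
    write_genotype_matrix,
    write_panel,
)
from minmark.errors import CodingError, IdentityError

from helpers import gm_from_rows, random_gm


def test_ab_dialect_maps_tokens_to_canonical_states(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text("id\tm1\tm2\tm3\nacc1\tA\tB\tH\nacc2\tNA\tA\tB\nacc3\tH\tNA\tA\n")
    gm = read_genotype_matrix(path, DialectSpec(coding=Coding.AB))
    expected = np.array(
        [
            [GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT, GenotypeCall.HET],
            [GenotypeCall.MISSING, GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT],
            [GenotypeCall.HET, GenotypeCall.MISSING, GenotypeCall.HOM_REF],
        ],
        dtype=np.int8,
    )
    assert np.array_equal(gm.calls, expected)
    assert gm.accession_ids == ["acc1", "acc2", "acc3"]
    assert gm.marker_ids == ["m1", "m2", "m3"]


def test_duplicate_accession_id_raises_identity_error(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("id\tm1\nACC1\tA\nACC1\tB\n")
    with pytest.raises(IdentityError, match="ACC1"):
        read_genotype_matrix(path, DialectSpec(coding=Coding.AB))


def test_unresolvable_token_names_row_column_token(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("id\tm1\nacc1\tZ\n")
    with pytest.raises(CodingError) as exc:
        read_genotype_matrix(path, DialectSpec(coding=Coding.AB))
    msg = str(exc.value)
    assert "Z" in msg and "acc1" in msg and "m1" in msg


@pytest.mark.parametrize("coding", [Coding.AB, Coding.PAIR, Coding.DOSAGE, Coding.NUCLEOTIDE])
@pytest.mark.parametrize("orientation", ["accessions", "markers"])
def test_round_trip_identity_random_matrix(tmp_path, coding, orientation):
    """write ∘ read is the identity for every dialect, 50×20 random matrix."""
    rng = np.random.default_rng(42)
    gm = random_gm(rng, 50, 20, het=True, missing=0.1)
    if coding is Coding.NUCLEOTIDE:
        gm.marker_meta = pd.DataFrame(
            {"allele_ref": "A", "allele_alt": "G"}, index=pd.Index(gm.marker_ids)
        )
    dialect = DialectSpec(coding=coding, orientation=orientation)
    path = tmp_path / "m.tsv"
    write_genotype_matrix(gm, path, dialect)
    back = read_genotype_matrix(path, dialect, marker_meta=gm.marker_meta)
    assert back.equals(gm)


def test_canonical_coding_is_dialect_independent(tmp_path):
    """The same biological calls read under AB and DOSAGE give identical matrices."""
    gm = gm_from_rows(["RAH.", "ARRA"])
    p1, p2 = tmp_path / "ab.tsv", tmp_path / "dos.csv"
    write_genotype_matrix(gm, p1, DialectSpec(coding=Coding.AB))
    write_genotype_matrix(gm, p2, DialectSpec(delimiter=",", coding=Coding.DOSAGE))
    gm_ab = read_genotype_matrix(p1, DialectSpec(coding=Coding.AB))
    gm_dos = read_genotype_matrix(p2, DialectSpec(delimiter=",", coding=Coding.DOSAGE))
    assert gm_ab.equals(gm_dos)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_round_trip_property_ab(tmp_path_factory, seed):
    rng = np.random.default_rng(seed)
    gm = random_gm(rng, rng.integers(1, 12), rng.integers(1, 12), het=True, missing=0.2)
    path = tmp_path_factory.mktemp("rt") / "m.tsv"
    dialect = DialectSpec(coding=Coding.AB)
    write_genotype_matrix(gm, path, dialect)
    assert read_genotype_matrix(path, dialect).equals(gm)


def test_empty_matrix_writes_header_only(tmp_path):
    gm = GenotypeMatrix([], ["m1", "m2"], np.empty((0, 2), dtype=np.int8))
    path = tmp_path / "empty.tsv"
    write_genotype_matrix(gm, path, DialectSpec(coding=Coding.AB))
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and "m1" in lines[0]
    assert read_genotype_matrix(path, DialectSpec(coding=Coding.AB)).n_accessions == 0


def test_missing_token_emitted_for_missing_calls(tmp_path):
    gm = gm_from_rows(["R."])
    path = tmp_path / "miss.tsv"
    write_genotype_matrix(gm, path, DialectSpec(coding=Coding.AB, missing_out="NA"))
    assert "NA" in path.read_text()


def test_nucleotide_ref_is_alphabetically_first_without_metadata(tmp_path):
    path = tmp_path / "nuc.tsv"
    path.write_text("id\tm1\nacc1\tT/T\nacc2\tG/G\nacc3\tG/T\n")
    gm = read_genotype_matrix(path, DialectSpec(coding=Coding.NUCLEOTIDE))
    assert gm.calls[:, 0].tolist() == [
        GenotypeCall.HOM_ALT,  # T/T: ref is G (alphabetically first)
        GenotypeCall.HOM_REF,
        GenotypeCall.HET,
    ]


# -- VCF ---------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


def test_vcf_import_maps_gt_fields(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(
        VCF_HEADER
        + "1\t100\tsnp1\tG\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        + "1\t200\tsnp2\tA\tC\t.\tPASS\t.\tGT\t0/1\t./.\n"
    )
    gm = import_vcf(path)
    assert gm.accession_ids == ["S1", "S2"]
    assert gm.marker_ids == ["snp1", "snp2"]
    assert gm.calls[0].tolist() == [GenotypeCall.HOM_REF, GenotypeCall.HET]
    assert gm.calls[1].tolist() == [GenotypeCall.HOM_ALT, GenotypeCall.MISSING]


def test_vcf_import_skips_triallelic_and_logs(tmp_path, caplog):
    path = tmp_path / "tri.vcf"
    path.write_text(
        VCF_HEADER
        + "1\t100\tsnp1\tG\tT\t.\tPASS\t.\tGT\t0/0\t1/1\n"
        + "1\t150\ttri\tG\tT,C\t.\tPASS\t.\tGT\t0/1\t1/2\n"
    )
    with caplog.at_level("INFO", logger="minmark.io"):
        gm = import_vcf(path)
    assert gm.marker_ids == ["snp1"]
    assert "skipped 1" in caplog.text


def test_vcf_phased_het_is_het(tmp_path):
    path = tmp_path / "ph.vcf"
    path.write_text(VCF_HEADER + "1\t100\tsnp1\tG\tT\t.\tPASS\t.\tGT\t0|1\t1|0\n")
    gm = import_vcf(path)
    assert gm.calls[0, 0] == GenotypeCall.HET
    assert gm.calls[1, 0] == GenotypeCall.HET


# -- panels ------------------------------------------------------------------


def test_panel_round_trips_in_order(tmp_path):
    markers = [f"mk{i}" for i in range(24)]
    panel = MarkerPanel(markers, newly_resolved=list(range(24)))
    path = tmp_path / "panel.tsv"
    write_panel(panel, path)
    back = read_panel(path)
    assert back.markers == markers
    assert back.newly_resolved == list(range(24))


def test_empty_panel_file_gives_empty_panel(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("")
    assert read_panel(path).markers == []


def test_duplicate_marker_in_panel_raises(tmp_path):
    path = tmp_path / "dup.txt"
    path.write_text("mk1\nmk2\nmk1\n")
    with pytest.raises(IdentityError):
        read_panel(path)
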