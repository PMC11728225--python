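"""Fingerprint coding, core-marker selection and duplicate detection."""

import itertools

import pytest

from ssrkit import (
    GenotypeMatrix,
    barcode_payload,
    build_codebook,
    decode_fingerprint,
    encode_fingerprints,
    find_duplicates,
    select_core_markers,
    simulate_genotypes,
)
from ssrkit.fingerprint import FingerprintCodebook, FingerprintRecord, _resolves


def _gm(calls, pops=None, loci=None):
    n = len(calls)
    pops = pops or ["p"] * n
    loci = loci or [f"L{j + 1}" for j in range(len(calls[0]))]
    return GenotypeMatrix(
        accessions=[(f"a{i + 1}", pops[i]) for i in range(n)], loci=loci, calls=calls
    )


# -- codebook -----------------------------------------------------------------


def test_tenth_allele_coded_a(reference_codebook):
    """A 10-allele locus uses codes 1..9 then A for the largest allele."""
    assert reference_codebook.code_of("G744", 139) == "1"
    assert reference_codebook.code_of("G744", 180) == "A"


def test_codebook_single_allele():
    cb = build_codebook(_gm([[(150, 150)]]))
    assert cb.alleles["L1"] == [150]
    assert cb.code_of("L1", 150) == "1"


def test_codebook_row_order_independent():
    calls = [[(100, 103)], [(106, 106)], [(100, 109)]]
    a = build_codebook(_gm(calls))
    b = build_codebook(_gm(list(reversed(calls))))
    assert a.alleles == b.alleles


def test_codespace_exhaustion():
    with pytest.raises(ValueError, match="codespace"):
        FingerprintCodebook(loci=["L1"], alleles={"L1": list(range(100, 100 + 36))})


# -- encode / decode ----------------------------------------------------------


def test_encode_known_heterozygote(reference_codebook):
    gm = GenotypeMatrix(
        accessions=[("x", "p")],
        loci=reference_codebook.loci,
        calls=[[(191, 203)] + [None] * 15],
    )
    rec = encode_fingerprints(gm, reference_codebook)[0]
    assert rec.code[:2] == "35"
    assert rec.code[2:] == "00" * 15


def test_all_missing_is_all_zeros(reference_codebook):
    gm = GenotypeMatrix(
        accessions=[("x", "p")], loci=reference_codebook.loci, calls=[[None] * 16]
    )
    rec = encode_fingerprints(gm, reference_codebook)[0]
    assert rec.code == "0" * 32


def test_unknown_allele_names_locus_and_size(reference_codebook):
    gm = GenotypeMatrix(
        accessions=[("x", "p")],
        loci=reference_codebook.loci,
        calls=[[(190, 190)] + [None] * 15],
    )
    with pytest.raises(KeyError, match="190.*G676"):
        encode_fingerprints(gm, reference_codebook)


def test_decode_known_pair(reference_codebook):
    calls = decode_fingerprint("35" + "00" * 15, reference_codebook)
    assert calls[0] == (191, 203)
    assert calls[1:] == [None] * 15


def test_decode_rejects_bad_length_and_chars(reference_codebook):
    with pytest.raises(ValueError, match="length"):
        decode_fingerprint("35", reference_codebook)
    with pytest.raises(ValueError, match="position 0"):
        decode_fingerprint("9Z" + "00" * 15, reference_codebook)  # G676 has 7 alleles
    with pytest.raises(ValueError, match="half-missing"):
        decode_fingerprint("30" + "00" * 15, reference_codebook)


def test_published_fingerprints_decode_and_reencode(
    reference_codebook, reference_fingerprints
):
    """Every published fingerprint string decodes into ascending allele pairs
    and re-encodes byte-exactly."""
    for name, code in reference_fingerprints.items():
        calls = decode_fingerprint(code, reference_codebook)
        assert all(c is None or c[0] <= c[1] for c in calls)
        gm = GenotypeMatrix(
            accessions=[(name, "ref")], loci=reference_codebook.loci, calls=[calls]
        )
        assert encode_fingerprints(gm, reference_codebook)[0].code == code


def test_round_trip_on_simulated_panel():
    gm, _ = simulate_genotypes(
        K=2, n_loci=16, alleles_per_locus=6, n_per_pop=[25, 25], missing_rate=0.05, seed=8
    )
    cb = build_codebook(gm)
    for rec, row in zip(encode_fingerprints(gm, cb), gm.calls):
        assert decode_fingerprint(rec.code, cb) == row


def test_fingerprints_unique_iff_genotypes_distinct():
    gm, _ = simulate_genotypes(K=1, n_loci=10, alleles_per_locus=6, n_per_pop=[30], seed=14)
    cb = build_codebook(gm)
    codes = [r.code for r in encode_fingerprints(gm, cb)]
    for (i, ci), (j, cj) in itertools.combinations(enumerate(codes), 2):
        assert (ci == cj) == (gm.calls[i] == gm.calls[j])


# -- core-marker selection ----------------------------------------------------


def test_greedy_selection_two_complementary_splits():
    """L1 splits {a,b}|{c,d}, L2 splits {a,c}|{b,d}, L3 duplicates L1; two
    markers resolve all six pairs."""
    calls = [
        [(100, 100), (200, 200), (100, 100)],
        [(100, 100), (206, 206), (100, 100)],
        [(106, 106), (200, 200), (106, 106)],
        [(106, 106), (206, 206), (106, 106)],
    ]
    gm = _gm(calls)
    selected, report = select_core_markers(gm)
    # ties (L1 and L3 are equivalent, equal PIC) break to the lexicographically
    # earlier name, then the complementary split is picked
    assert selected == ["L1", "L2"]
    assert report.iloc[-1]["resolved_pairs"] == 6
    assert report.iloc[-1]["distinguishable_accessions"] == 4


def test_all_identical_selects_nothing():
    gm = _gm([[(100, 100)], [(100, 100)], [(100, 100)]])
    selected, report = select_core_markers(gm)
    assert selected == []
    assert report.empty


def test_missing_never_resolves():
    assert not _resolves(None, (100, 100))
    gm = _gm([[None], [(100, 100)]])
    selected, _ = select_core_markers(gm)
    assert selected == []


def test_selected_set_matches_full_panel_resolution():
    gm, _ = simulate_genotypes(
        K=2, n_loci=20, alleles_per_locus=5, n_per_pop=[15, 15], missing_rate=0.05, seed=6
    )
    selected, report = select_core_markers(gm)
    full = sum(
        1
        for i, j in itertools.combinations(range(gm.n_accessions), 2)
        if any(_resolves(gm.calls[i][l], gm.calls[j][l]) for l in range(gm.n_loci))
    )
    assert report.iloc[-1]["resolved_pairs"] == full


def test_greedy_matches_all_subsets_oracle_resolution():
    """On small instances the greedy set's resolution equals the best any
    subset achieves (brute-force over all subsets of <= 6 loci)."""
    for seed in range(4):
        gm, _ = simulate_genotypes(
            K=1, n_loci=6, alleles_per_locus=3, n_per_pop=[8], missing_rate=0.1, seed=seed
        )
        pairs = list(itertools.combinations(range(gm.n_accessions), 2))
        def resolved_by_subset(subset):
            return sum(
                1 for i, j in pairs
                if any(_resolves(gm.calls[i][l], gm.calls[j][l]) for l in subset)
            )
        best = max(
            resolved_by_subset(sub)
            for r in range(gm.n_loci + 1)
            for sub in itertools.combinations(range(gm.n_loci), r)
        )
        _, report = select_core_markers(gm)
        greedy = report.iloc[-1]["resolved_pairs"] if len(report) else 0
        assert greedy == best


# -- duplicates ---------------------------------------------------------------


def test_identical_pair_reported_with_zero_differences():
    gm = _gm([[(100, 100), (200, 203)], [(100, 100), (200, 203)]])
    assert find_duplicates(gm) == [("a1", "a2", [])]


def test_one_locus_difference_at_default_threshold():
    calls_a = [(100, 100)] + [(200, 200)] * 15
    calls_b = [(106, 106)] + [(200, 200)] * 15
    gm = _gm([calls_a, calls_b])
    dups = find_duplicates(gm)
    assert dups == [("a1", "a2", ["L1"])]
    assert find_duplicates(gm, max_differing_loci=0) == []


def test_planted_clones_recovered_exactly():
    gm, _ = simulate_genotypes(K=1, n_loci=16, alleles_per_locus=6, n_per_pop=[48], seed=10)
    calls = [list(row) for row in gm.calls]
    calls.append(list(calls[3]))  # clone of a4
    calls.append(list(calls[17]))  # clone of a18
    gm2 = _gm(calls)
    found = {(a, b) for a, b, d in find_duplicates(gm2) if not d}
    assert found == {("a4", "a49"), ("a18", "a50")}


# -- barcode payload ----------------------------------------------------------


def test_barcode_payload_fields(reference_fingerprints):
    rec = FingerprintRecord(
        accession_id="Irwin", origin="Japan", code=reference_fingerprints["Irwin"]
    )
    payload = barcode_payload(rec)
    assert payload == f"Irwin|Japan|{reference_fingerprints['Irwin']}"


def test_barcode_payload_empty_origin():
    rec = FingerprintRecord(accession_id="n", origin="", code="0000")
    assert barcode_payload(rec) == "n||0000"


def test_barcode_payload_escapes_delimiter():
    rec = FingerprintRecord(accession_id="a|b", origin="c", code="11")
    payload = barcode_payload(rec)
    # unescaped split still yields 3 logical fields after unescaping
    import re

    fields = re.split(r"(?<!\\)\|", payload)
    assert len(fields) == 3
    assert fields[0].replace("\\|", "|") == "a|b"
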