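"""Perfect SSR detection against a quadratic brute-force oracle."""

import numpy as np
import pytest

from ssrkit import canonical_motif_class, find_perfect_ssrs, mine_fasta, summarize_ssrs
from ssrkit.ssr_mining import DEFAULT_THRESHOLDS, _is_primitive, _revcomp


def brute_force_ssrs(seq: str, thresholds=DEFAULT_THRESHOLDS):
    """Independent oracle: test every (start, motif length) pair, then apply
    the same leftmost-longest / shortest-unit non-overlap rule."""
    n = len(seq)
    cands = []
    for i in range(n):
        for ml in range(1, 7):
            motif = seq[i : i + ml]
            if len(motif) < ml or "N" in motif or not _is_primitive(motif):
                continue
            j = i + ml
            while j < n and seq[j] != "N" and seq[j] == seq[j - ml]:
                j += 1
            reps = (j - i) // ml
            if reps >= thresholds[ml]:
                cands.append((i, reps * ml, ml))
    cands.sort(key=lambda c: (c[0], -c[1], c[2]))
    chosen, end = [], -1
    for i, tract, ml in cands:
        if i > end:
            chosen.append((i + 1, i + tract, seq[i : i + ml]))
            end = i + tract - 1
    return chosen


def test_mononucleotide_threshold_boundary():
    found = find_perfect_ssrs("A" * 12)
    assert len(found) == 1
    assert (found[0].motif, found[0].repeats, found[0].start, found[0].end) == ("A", 12, 1, 12)
    assert find_perfect_ssrs("A" * 11) == []


def test_trinucleotide_with_flanks():
    loci = find_perfect_ssrs("TT" + "ACG" * 5 + "TT")
    assert len(loci) == 1
    l = loci[0]
    assert (l.motif, l.repeats, l.motif_class, l.start, l.end) == ("ACG", 5, "ACG/CGT", 3, 17)
    assert l.tract_length == 15


def test_poly_a_reported_as_mononucleotide():
    """A 12-bp poly-A is a mono run, never 6 × AA (non-primitive unit)."""
    (l,) = find_perfect_ssrs("A" * 12)
    assert len(l.motif) == 1


@pytest.mark.parametrize(
    "motif,expected",
    [
        ("TTA", "AAT/ATT"),
        ("AT", "AT/AT"),
        ("A", "A/T"),
        ("GA", "AG/CT"),
        ("ACG", "ACG/CGT"),
    ],
)
def test_canonical_class(motif, expected):
    assert canonical_motif_class(motif) == expected


def test_canonical_class_no_rotation_mode():
    # under rotation GA merges with AG; without it GA groups only with its revcomp TC
    assert canonical_motif_class("GA", rotate=False) == "GA/TC"
    assert canonical_motif_class("TC", rotate=False) == "GA/TC"


def test_non_primitive_motif_rejected():
    with pytest.raises(ValueError, match="primitive"):
        canonical_motif_class("ATAT")


def test_invalid_characters_rejected():
    with pytest.raises(ValueError, match="invalid"):
        find_perfect_ssrs("ACGTX" * 20)


def test_empty_sequence():
    assert find_perfect_ssrs("") == []


def test_tracts_broken_at_n():
    seq = "A" * 12 + "N" + "A" * 12
    loci = find_perfect_ssrs(seq)
    assert [(l.start, l.end) for l in loci] == [(1, 12), (14, 25)]
    assert find_perfect_ssrs("A" * 6 + "N" + "A" * 6) == []


def test_matches_brute_force_on_random_sequences():
    rng = np.random.default_rng(7)
    for trial in range(5):
        # salt with repeat-rich stretches so tracts actually occur
        parts = []
        for _ in range(40):
            parts.append("".join(rng.choice(list("ACGT"), size=200)))
            motif = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
            parts.append(motif * rng.integers(3, 16))
        seq = "".join(parts)[:10_000]
        found = [(l.start, l.end, l.motif) for l in find_perfect_ssrs(seq)]
        assert found == brute_force_ssrs(seq)


def test_revcomp_leaves_class_multiset_unchanged():
    """Isolated tracts (N-separated, so segmentation is orientation-free)
    yield the same canonical class multiset on either strand."""
    rng = np.random.default_rng(11)
    tracts = [
        "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7))) * rng.integers(12, 20)
        for _ in range(30)
    ]
    seq = "NN".join(tracts)
    fwd = sorted(l.motif_class for l in find_perfect_ssrs(seq))
    rev = sorted(l.motif_class for l in find_perfect_ssrs(_revcomp(seq)))
    assert len(fwd) > 10
    assert fwd == rev


def test_class_label_strand_and_rotation_symmetric():
    rng = np.random.default_rng(13)
    n_checked = 0
    while n_checked < 40:
        motif = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 7)))
        if not _is_primitive(motif):
            continue
        n_checked += 1
        label = canonical_motif_class(motif)
        assert canonical_motif_class(_revcomp(motif)) == label
        for i in range(len(motif)):
            assert canonical_motif_class(motif[i:] + motif[:i]) == label


def test_no_overlapping_loci():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACT"), size=5000))
    loci = find_perfect_ssrs(seq, thresholds={1: 5, 2: 3, 3: 3, 4: 3, 5: 3, 6: 3})
    for a, b in zip(loci, loci[1:]):
        assert a.end < b.start


def test_summary_mean_spacing_and_proportions():
    seq = ("A" * 12 + "C" * 30) * 5 + ("AG" * 7 + "T" * 30) * 5
    loci = find_perfect_ssrs(seq)
    mono = [l for l in loci if len(l.motif) == 1]
    di = [l for l in loci if len(l.motif) == 2]
    summary = summarize_ssrs(loci, genome_length=36_000)
    by_unit = summary["by_unit_length"].set_index("unit_length")
    total = summary["total"]
    assert total == len(mono) + len(di)
    assert by_unit.loc[1, "count"] == len(mono)
    assert np.isclose(by_unit["proportion"].sum(), 1.0)
    assert summary["mean_distance_bp"] == pytest.approx(36_000 / total)
    # class counts regroup to unit-length totals
    cls = summary["class_counts"]
    assert cls.groupby("unit_length")["count"].sum().to_dict() == by_unit["count"].to_dict()


def test_ten_loci_in_36kb_spacing():
    loci = find_perfect_ssrs(("A" * 12 + "N" * 50) * 10)
    assert len(loci) == 10
    assert summarize_ssrs(loci, 36_000)["mean_distance_bp"] == pytest.approx(3600.0)


def test_zero_loci_distance_absent():
    assert summarize_ssrs([], 1000)["mean_distance_bp"] is None


def test_mine_fasta_multirecord(tmp_path):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1\n" + "A" * 12 + "CGCGT\n" + "ACG" * 5 + "\n>chr2\n" + "AT" * 7 + "\n")
    loci, total = mine_fasta(fa)
    assert total == 12 + 5 + 15 + 14
    assert {l.seq_id for l in loci} == {"chr1", "chr2"}
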