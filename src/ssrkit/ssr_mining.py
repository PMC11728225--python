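"""Perfect microsatellite (SSR) detection and motif-class summaries.

A perfect SSR is a tandem run of a primitive 1–6 bp motif meeting a
per-motif-length minimum repeat count. Defaults follow the common
genome-screening convention: mono 12, di 7, tri 5, tetra 4, penta 4, hexa 4
repeats. Tracts are reported leftmost-maximal and non-overlapping, each under
its shortest primitive unit (a 12-bp poly-A is a mononucleotide run, not
six AAs), and runs containing N are broken at the N.

Motifs are grouped into canonical classes, written ``motif/reverse-complement``
(e.g. ``AAT/ATT``): by default the canonical representative is the
lexicographically smallest string among all cyclic rotations of the motif and
of its reverse complement. A ``rotate=False`` mode groups only a motif with
its reverse complement, which keeps e.g. AG/CT and TC/GA as distinct classes
as some screening tools tabulate them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

DEFAULT_THRESHOLDS: dict[int, int] = {1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRLocus:
    """A detected perfect repeat tract (coordinates 1-based, inclusive)."""

    seq_id: str
    start: int
    end: int
    motif: str
    motif_class: str
    repeats: int

    @property
    def tract_length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.tract_length != self.repeats * len(self.motif):
            raise ValueError("tract length must equal repeats × motif length")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif_class(motif: str, rotate: bool = True) -> str:
    """Canonical class label for a primitive motif, as ``canon/revcomp(canon)``.

    With ``rotate=True`` the canonical representative is the smallest string
    among all cyclic rotations of the motif and of its reverse complement;
    with ``rotate=False`` only the motif and its reverse complement compete.
    """
    motif = motif.upper()
    if not 1 <= len(motif) <= 6:
        raise ValueError("motif length must be 1-6")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if not _is_primitive(motif):
        raise ValueError(f"motif is not primitive: {motif!r}")
    rc = _revcomp(motif)
    if rotate:
        candidates = [motif[i:] + motif[:i] for i in range(len(motif))]
        candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    else:
        candidates = [motif, rc]
    canon = min(candidates)
    return f"{canon}/{_revcomp(canon)}"


def _scan_segment(
    seq: str, offset: int, seq_id: str, thresholds: Mapping[int, int], rotate: bool
) -> list[SSRLocus]:
    """Scan an N-free segment; offset is the 0-based position of seq[0]."""
    n = len(seq)
    loci: list[SSRLocus] = []
    max_ml = max(thresholds)
    i = 0
    while i < n:
        best: tuple[int, int] | None = None  # (tract_len, motif_len)
        for ml in range(1, max_ml + 1):
            thr = thresholds.get(ml)
            if thr is None or i + ml * thr > n:
                continue
            motif = seq[i : i + ml]
            if not _is_primitive(motif):
                continue
            j = i + ml
            while j < n and seq[j] == seq[j - ml]:
                j += 1
            repeats = (j - i) // ml
            if repeats >= thr:
                tract = repeats * ml
                # leftmost-longest, then shortest primitive unit
                if best is None or tract > best[0]:
                    best = (tract, ml)
        if best is None:
            i += 1
            continue
        tract, ml = best
        motif = seq[i : i + ml]
        loci.append(
            SSRLocus(
                seq_id=seq_id,
                start=offset + i + 1,
                end=offset + i + tract,
                motif=motif,
                motif_class=canonical_motif_class(motif, rotate=rotate),
                repeats=tract // ml,
            )
        )
        i += tract
    return loci


def find_perfect_ssrs(
    seq: str,
    thresholds: Mapping[int, int] | None = None,
    seq_id: str = "seq",
    rotate: bool = True,
) -> list[SSRLocus]:
    """Detect perfect SSRs in a DNA sequence.

    Parameters
    ----------
    seq : DNA over A/C/G/T/N (case-insensitive). Tracts never span an N.
    thresholds : minimum repeat count per motif length (1–6); defaults to
        ``{1: 12, 2: 7, 3: 5, 4: 4, 5: 4, 6: 4}``.
    rotate : passed to :func:`canonical_motif_class`.

    Returns leftmost-maximal, non-overlapping tracts in coordinate order.
    """
    thresholds = dict(thresholds or DEFAULT_THRESHOLDS)
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    loci: list[SSRLocus] = []
    start = 0
    for i, ch in enumerate(seq + "N"):  # sentinel N flushes the last segment
        if ch == "N":
            if i > start:
                loci.extend(_scan_segment(seq[start:i], start, seq_id, thresholds, rotate))
            start = i + 1
    return loci


def mine_fasta(
    path: str | Path,
    thresholds: Mapping[int, int] | None = None,
    rotate: bool = True,
) -> tuple[list[SSRLocus], int]:
    """Mine every record of a (multi-)FASTA file.

    Returns the loci plus the total genome length in bp.
    """
    loci: list[SSRLocus] = []
    total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        total += len(s)
        loci.extend(find_perfect_ssrs(s, thresholds, seq_id=rec.id, rotate=rotate))
    return loci, total


def summarize_ssrs(loci: Iterable[SSRLocus], genome_length: int) -> dict:
    """Summarize a mining run: counts by unit length, class counts, spacing.

    Returns a dict with

    - ``total``: locus count
    - ``by_unit_length``: DataFrame (unit_length, count, proportion)
    - ``class_counts``: DataFrame (unit_length, motif_class, count, proportion
      within unit length), most frequent first
    - ``mean_distance_bp``: genome_length / locus count, or None for zero loci
    """
    loci = list(loci)
    total = len(loci)
    rows = [(len(l.motif), l.motif_class) for l in loci]
    df = pd.DataFrame(rows, columns=["unit_length", "motif_class"])
    if total:
        by_unit = (
            df.groupby("unit_length").size().rename("count").reset_index().sort_values("unit_length")
        )
        by_unit["proportion"] = by_unit["count"] / total
        cls = (
            df.groupby(["unit_length", "motif_class"]).size().rename("count").reset_index()
        )
        unit_totals = cls.groupby("unit_length")["count"].transform("sum")
        cls["proportion"] = cls["count"] / unit_totals
        cls = cls.sort_values(
            ["unit_length", "count", "motif_class"], ascending=[True, False, True]
        ).reset_index(drop=True)
    else:
        by_unit = pd.DataFrame(columns=["unit_length", "count", "proportion"])
        cls = pd.DataFrame(columns=["unit_length", "motif_class", "count", "proportion"])
    return {
        "total": total,
        "by_unit_length": by_unit.reset_index(drop=True),
        "class_counts": cls,
        "mean_distance_bp": (genome_length / total) if total else None,
    }


def ssrs_to_tsv(loci: Iterable[SSRLocus], path: str | Path) -> Path:
    path = Path(path)
    rows = ["\t".join(["seq_id", "start", "end", "motif", "class", "repeats", "tract_length"])]
    for l in loci:
        rows.append(
            f"{l.seq_id}\t{l.start}\t{l.end}\t{l.motif}\t{l.motif_class}\t{l.repeats}\t{l.tract_length}"
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


def ssrs_to_gff3(loci: Iterable[SSRLocus], path: str | Path) -> Path:
    """Write loci as GFF3 ``SSR`` features (1-based inclusive coordinates)."""
    path = Path(path)
    rows = ["##gff-version 3"]
    for l in loci:
        attrs = f"motif={l.motif};class={l.motif_class};repeats={l.repeats}"
        rows.append(
            "\t".join(
                [l.seq_id, "ssrkit", "SSR", str(l.start), str(l.end), ".", "+", ".", attrs]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path
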