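"""DNA fingerprint databases from SSR genotypes.

Alleles at each locus are sorted ascending and coded ``1``–``9`` then
``A``, ``B``, … in order; ``0`` is reserved for a missing call. An
accession's fingerprint string concatenates, in fixed panel order, the two
code characters of its diploid call at each locus (within a locus the codes
ascend), giving a string of 2 × panel size characters that uniquely
identifies a genotype over the panel.

Also provided: greedy minimal core-marker selection (set cover over the
unordered accession pairs a locus can resolve), duplicate/synonym candidate
detection (pairs differing at ≤ N loci), and a plain-text barcode payload
(``name|origin|code``) suitable for any QR generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .diversity import allele_frequencies, locus_statistics
from .io_genotypes import Call, GenotypeMatrix, MarkerPanel

#: Code characters in ascending allele order; '0' is reserved for missing.
CODE_CHARS = "123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class FingerprintCodebook:
    """Ordered per-locus allele→code assignment (Table-of-allele-codes style)."""

    loci: list[str]
    alleles: dict[str, list[int]]  # ascending allele sizes per locus

    def __post_init__(self) -> None:
        for locus in self.loci:
            sizes = self.alleles[locus]
            if sorted(set(sizes)) != sizes:
                raise ValueError(f"allele list for {locus} must be strictly increasing")
            if len(sizes) > len(CODE_CHARS):
                raise ValueError(
                    f"locus {locus} has {len(sizes)} alleles; codespace "
                    f"supports at most {len(CODE_CHARS)}"
                )

    def code_of(self, locus: str, allele: int) -> str:
        try:
            return CODE_CHARS[self.alleles[locus].index(allele)]
        except ValueError:
            raise KeyError(f"allele {allele} bp not in codebook for locus {locus}") from None

    def allele_of(self, locus: str, code: str) -> int:
        idx = CODE_CHARS.find(code)
        if idx < 0 or idx >= len(self.alleles[locus]):
            raise KeyError(f"code {code!r} not in codespace of locus {locus}")
        return self.alleles[locus][idx]

    def to_tsv(self, path: str | Path) -> Path:
        """Codebook table: one locus per row, columns are codes 1..9,A.."""
        path = Path(path)
        width = max(len(a) for a in self.alleles.values())
        rows = ["\t".join(["locus"] + list(CODE_CHARS[:width]))]
        for locus in self.loci:
            sizes = [str(s) for s in self.alleles[locus]]
            rows.append("\t".join([locus] + sizes + [""] * (width - len(sizes))))
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
        return path


@dataclass
class FingerprintRecord:
    """Per-accession fingerprint: id, origin and the code string."""

    accession_id: str
    origin: str
    code: str

    def __post_init__(self) -> None:
        if any(ch != "0" and ch not in CODE_CHARS for ch in self.code):
            raise ValueError("fingerprint characters must be 0-9 or A-Z")


def build_codebook(gm: GenotypeMatrix, panel: MarkerPanel | None = None) -> FingerprintCodebook:
    """Codebook from the alleles observed in a matrix, in panel locus order.

    Deterministic: depends only on the set of observed alleles per locus,
    not on row order.
    """
    loci = panel.names if panel is not None else list(gm.loci)
    missing = [l for l in loci if l not in gm.loci]
    if missing:
        raise ValueError(f"panel loci absent from matrix: {missing}")
    alleles: dict[str, list[int]] = {}
    for locus in loci:
        j = gm.loci.index(locus)
        alleles[locus] = sorted({a for row in gm.calls for c in [row[j]] if c for a in c})
    return FingerprintCodebook(loci=loci, alleles=alleles)


def encode_fingerprints(
    gm: GenotypeMatrix, codebook: FingerprintCodebook
) -> list[FingerprintRecord]:
    """Fingerprint string per accession: two ascending code characters per
    locus in codebook order; a missing call encodes as ``00``."""
    idx = [gm.loci.index(l) for l in codebook.loci]
    records = []
    for (acc, pop), row in zip(gm.accessions, gm.calls):
        chunks = []
        for locus, j in zip(codebook.loci, idx):
            c = row[j]
            if c is None:
                chunks.append("00")
            else:
                chunks.append(codebook.code_of(locus, c[0]) + codebook.code_of(locus, c[1]))
        records.append(FingerprintRecord(accession_id=acc, origin=pop, code="".join(chunks)))
    return records


def decode_fingerprint(code: str, codebook: FingerprintCodebook) -> list[Call]:
    """Invert a fingerprint string into diploid calls in codebook locus order."""
    if len(code) != 2 * len(codebook.loci):
        raise ValueError(
            f"code length {len(code)} != 2 × panel size {len(codebook.loci)}"
        )
    calls: list[Call] = []
    for k, locus in enumerate(codebook.loci):
        c1, c2 = code[2 * k], code[2 * k + 1]
        if c1 == "0" and c2 == "0":
            calls.append(None)
            continue
        if "0" in (c1, c2):
            raise ValueError(f"half-missing code at position {2 * k} (locus {locus})")
        try:
            a, b = codebook.allele_of(locus, c1), codebook.allele_of(locus, c2)
        except KeyError as e:
            raise ValueError(f"position {2 * k}: {e}") from None
        calls.append((a, b) if a <= b else (b, a))
    return calls


# -- core-marker selection and duplicates ------------------------------------


def _resolves(a: Call, b: Call) -> bool:
    """A locus resolves a pair iff both calls are present and differ."""
    return a is not None and b is not None and a != b


def select_core_markers(
    gm: GenotypeMatrix,
    candidates: MarkerPanel | None = None,
    pic: Mapping[str, float] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy minimal marker set distinguishing the accessions.

    Repeatedly selects the locus resolving the most currently-unresolved
    accession pairs until no remaining pair is resolvable by any candidate.
    Ties are broken toward the higher-PIC locus, then lexicographic name.
    A missing call never resolves a pair.

    Returns the selected locus names (in selection order) and a report with,
    per selection prefix, the cumulative resolved pair count and the number
    of accessions distinguishable from every other accession.
    """
    if gm.n_accessions < 2:
        raise ValueError("core-marker selection needs >= 2 accessions")
    loci = candidates.names if candidates is not None else list(gm.loci)
    if pic is None:
        stats = locus_statistics(gm, freqs=allele_frequencies(gm))
        pic = {l: float(stats.loc[l, "PIC"]) for l in loci if l in stats.index}
    n = gm.n_accessions
    pairs = list(itertools.combinations(range(n), 2))
    col = {l: gm.loci.index(l) for l in loci}
    resolved_by: dict[str, set[int]] = {
        l: {
            k
            for k, (i, j) in enumerate(pairs)
            if _resolves(gm.calls[i][col[l]], gm.calls[j][col[l]])
        }
        for l in loci
    }

    unresolved: set[int] = set(range(len(pairs)))
    selected: list[str] = []
    report_rows = []
    remaining = list(loci)
    while True:
        best_locus = None
        best_key = None
        for l in remaining:
            gain = len(resolved_by[l] & unresolved)
            if gain == 0:
                continue
            key = (-gain, -pic.get(l, 0.0), l)
            if best_key is None or key < best_key:
                best_key = key
                best_locus = l
        if best_locus is None:
            break
        selected.append(best_locus)
        remaining.remove(best_locus)
        unresolved -= resolved_by[best_locus]
        undistinguished = {i for k in unresolved for i in pairs[k]}
        report_rows.append(
            {
                "n_markers": len(selected),
                "locus": best_locus,
                "resolved_pairs": len(pairs) - len(unresolved),
                "distinguishable_accessions": n - len(undistinguished),
            }
        )
    report = pd.DataFrame(
        report_rows,
        columns=["n_markers", "locus", "resolved_pairs", "distinguishable_accessions"],
    )
    return selected, report


def find_duplicates(
    gm: GenotypeMatrix, max_differing_loci: int = 1
) -> list[tuple[str, str, list[str]]]:
    """Accession pairs differing at no more than ``max_differing_loci`` loci.

    A locus counts as differing only when both calls are present and unequal
    (the synonym-candidate rule); the differing loci are listed per pair.
    """
    out = []
    ids = gm.accession_ids
    for i, j in itertools.combinations(range(gm.n_accessions), 2):
        diff = [
            gm.loci[l]
            for l in range(gm.n_loci)
            if _resolves(gm.calls[i][l], gm.calls[j][l])
        ]
        if len(diff) <= max_differing_loci:
            out.append((ids[i], ids[j], diff))
    return out


def barcode_payload(record: FingerprintRecord, origin: Optional[str] = None) -> str:
    """Single-line ``name|origin|code`` payload for a QR/barcode generator.

    ``|`` and ``\\`` inside fields are backslash-escaped so the payload
    always parses back into exactly three fields.
    """

    def esc(s: str) -> str:
        return s.replace("\\", "\\\\").replace("|", "\\|")

    o = record.origin if origin is None else origin
    return f"{esc(record.accession_id)}|{esc(o)}|{record.code}"


def records_to_tsv(records: Sequence[FingerprintRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = ["accession\torigin\tfingerprint"]
    for r in records:
        rows.append(f"{r.accession_id}\t{r.origin}\t{r.code}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path
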