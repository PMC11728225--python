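"""Data model and I/O for diploid codominant SSR genotype tables.

Genotypes are fragment sizes in base pairs, two alleles per accession and
locus (unordered; stored ascending). Tables follow the GenAlEx-style
"two columns per locus" layout: one header row, then one row per accession
with an accession id column, a population column, and two integer columns
per locus. ``0`` in a file marks a missing call; in memory missing is
``None``, never 0 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: In-memory sentinel for a missing diploid call.
MISSING: None = None

Call = Optional[tuple[int, int]]


@dataclass(frozen=True)
class LocusDescriptor:
    """A marker locus: name, optional repeat motif and expected product range."""

    name: str
    motif: Optional[str] = None
    product_range: Optional[tuple[int, int]] = None


@dataclass
class MarkerPanel:
    """An ordered panel of marker loci.

    Panel order is stable and is the order used for fingerprint strings.
    """

    loci: list[LocusDescriptor]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate locus names in panel: {dup}")

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.loci]

    def __len__(self) -> int:
        return len(self.loci)

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "MarkerPanel":
        return cls([LocusDescriptor(n) for n in names])


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls per accession × locus, with population labels.

    ``calls[i][j]`` is an ascending ``(a, b)`` pair of allele sizes in bp for
    accession ``i`` at locus ``j``, or ``None`` for a missing call.
    """

    accessions: list[tuple[str, str]]  # (accession id, population label)
    loci: list[str]
    calls: list[list[Call]]
    parse_warnings: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        ids = [a for a, _ in self.accessions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate accession ids: {dup}")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        if len(self.calls) != len(self.accessions):
            raise ValueError("calls row count != accession count")
        norm: list[list[Call]] = []
        for row in self.calls:
            if len(row) != len(self.loci):
                raise ValueError("calls column count != locus count")
            out_row: list[Call] = []
            for c in row:
                if c is None:
                    out_row.append(None)
                    continue
                a, b = int(c[0]), int(c[1])
                if a <= 0 or b <= 0:
                    raise ValueError(
                        f"allele sizes must be positive, got ({a}, {b}); "
                        "use None for missing"
                    )
                out_row.append((a, b) if a <= b else (b, a))
            norm.append(out_row)
        self.calls = norm

    # -- conveniences -----------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def accession_ids(self) -> list[str]:
        return [a for a, _ in self.accessions]

    @property
    def populations(self) -> list[str]:
        return [p for _, p in self.accessions]

    def call(self, accession: int | str, locus: int | str) -> Call:
        i = accession if isinstance(accession, int) else self.accession_ids.index(accession)
        j = locus if isinstance(locus, int) else self.loci.index(locus)
        return self.calls[i][j]

    def population_groups(self) -> dict[str, list[int]]:
        """Accession indices grouped by population label, in label first-seen order."""
        groups: dict[str, list[int]] = {}
        for i, (_, pop) in enumerate(self.accessions):
            groups.setdefault(pop, []).append(i)
        return groups

    def subset_loci(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.loci.index(n) for n in names]
        return GenotypeMatrix(
            accessions=list(self.accessions),
            loci=list(names),
            calls=[[row[j] for j in idx] for row in self.calls],
        )

    def subset_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        idx = [lookup[a] for a in ids]
        return GenotypeMatrix(
            accessions=[self.accessions[i] for i in idx],
            loci=list(self.loci),
            calls=[list(self.calls[i]) for i in idx],
        )


# -- genotype table I/O ----------------------------------------------------


def read_genotype_table(path: str | Path, delimiter: str = "\t") -> GenotypeMatrix:
    """Read a two-columns-per-locus genotype table.

    Layout: header row ``accession <sep> population <sep> L1 L1 L2 L2 ...``
    (each locus contributes exactly two adjacent columns), then one row per
    accession. Unparsable or zero-valued cells become missing calls; the
    number of such cells is logged and recorded on
    :attr:`GenotypeMatrix.parse_warnings`.

    Raises
    ------
    ValueError
        On an odd allele-column count (names the offending locus) or
        duplicate accession ids.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split(delimiter)
    if len(header) < 2:
        raise ValueError(f"{path}: header must have accession and population columns")
    allele_cols = header[2:]
    if len(allele_cols) % 2 != 0:
        raise ValueError(
            f"{path}: odd number of allele columns; locus "
            f"{allele_cols[-1]!r} contributes only one column"
        )
    loci = []
    for j in range(0, len(allele_cols), 2):
        name = allele_cols[j]
        loci.append(name)

    accessions: list[tuple[str, str]] = []
    calls: list[list[Call]] = []
    warnings = 0
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(delimiter)
        if len(cells) != len(header):
            raise ValueError(
                f"{path}:{ln}: expected {len(header)} columns, got {len(cells)}"
            )
        accessions.append((cells[0], cells[1]))
        row: list[Call] = []
        for j in range(len(loci)):
            raw_a, raw_b = cells[2 + 2 * j], cells[3 + 2 * j]
            try:
                a, b = int(raw_a), int(raw_b)
            except ValueError:
                a = b = 0
            if a <= 0 or b <= 0:
                warnings += 1
                row.append(None)
            else:
                row.append((a, b))
        calls.append(row)

    gm = GenotypeMatrix(accessions=accessions, loci=loci, calls=calls)
    gm.parse_warnings = warnings
    if warnings:
        logger.warning("%s: %d zero/unparsable cells read as missing", path, warnings)
    return gm


def write_genotype_table(gm: GenotypeMatrix, path: str | Path, delimiter: str = "\t") -> Path:
    """Write a genotype matrix in the dialect :func:`read_genotype_table` accepts.

    Missing calls are written as the ``0 0`` sentinel. Round-trip stable.
    """
    path = Path(path)
    out = [delimiter.join(["accession", "population"] + [n for l in gm.loci for n in (l, l)])]
    for (acc, pop), row in zip(gm.accessions, gm.calls):
        cells = [acc, pop]
        for c in row:
            if c is None:
                cells += ["0", "0"]
            else:
                cells += [str(c[0]), str(c[1])]
        out.append(delimiter.join(cells))
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


# -- marker panel I/O -------------------------------------------------------


def read_marker_panel(path: str | Path, delimiter: str = "\t") -> MarkerPanel:
    """Read a marker panel TSV with columns: name, motif (optional), range (optional).

    The range column is ``lo-hi`` in bp. Empty cells mean unknown.
    """
    path = Path(path)
    loci: list[LocusDescriptor] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    for ln, line in enumerate(lines, start=1):
        if not line.strip() or (ln == 1 and line.split(delimiter)[0].lower() == "name"):
            continue
        cells = (line.split(delimiter) + ["", ""])[:3]
        name, motif, rng = cells[0], cells[1] or None, cells[2]
        product_range = None
        if rng:
            lo, hi = rng.split("-")
            product_range = (int(lo), int(hi))
        loci.append(LocusDescriptor(name=name, motif=motif, product_range=product_range))
    return MarkerPanel(loci)


def write_marker_panel(panel: MarkerPanel, path: str | Path, delimiter: str = "\t") -> Path:
    path = Path(path)
    rows = [delimiter.join(["name", "motif", "range"])]
    for l in panel.loci:
        rng = f"{l.product_range[0]}-{l.product_range[1]}" if l.product_range else ""
        rows.append(delimiter.join([l.name, l.motif or "", rng]))
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path
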