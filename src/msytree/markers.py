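"""Marker catalogs for Y-chromosome binary polymorphisms.

A *marker* is a named variant on the male-specific region of the Y
chromosome (MSY): a single-nucleotide substitution, a short deletion, or a
substitution hitting several paralogous copies of the same sequence at
once.  Because the MSY does not recombine, each marker is treated as a
unique-event polymorphism: it arose once, on one branch of the haplogroup
genealogy, and every chromosome below that branch carries the derived
allele.

Two tab-separated dialects are understood:

* the *canonical* dialect written by this package
  (``name  positions  ancestral  derived  class  source_tag``), which
  round-trips exactly, and
* a *lenient* dialect matching published marker tables
  (``SNP  Y-Position  Mutation  Forward Primer  Reverse Primer``), which
  tolerates irregular whitespace such as ``27120952`` glued after a
  semicolon or ``toG/G/G`` missing its space.

Coordinates are 1-based, inclusive, on the GRCh37 Y chromosome and are
stored exactly as printed; no liftover is attempted.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, TextIO, Union

__all__ = [
    "Marker",
    "MarkerCatalog",
    "OutgroupAllele",
    "CatalogError",
    "MarkerValidationError",
    "parse_marker_table",
    "write_marker_table",
    "read_outgroup_table",
    "write_outgroup_table",
    "base_site",
    "SUBSTITUTION",
    "DELETION",
    "MULTI_COPY",
]

SUBSTITUTION = "substitution"
DELETION = "deletion"
MULTI_COPY = "multi_copy_substitution"

_NUCS = set("ACGT")

# V-style names optionally carry a ".k" event suffix assigned when a
# recurrent site is split into independent mutation events (V161.1, V161.2).
_NAME_RE = re.compile(r"^(?P<base>.+?)(?:\.(?P<event>\d+))?$")
_V_RE = re.compile(r"^V(?P<num>\d+)(?:\.\d+)?$")


class CatalogError(ValueError):
    """Catalog-level problem: duplicate names, unknown markers, bad header."""


class MarkerValidationError(ValueError):
    """Record-level problem; the message names the offending row."""


def base_site(name: str) -> str:
    """Strip a trailing ``.k`` event suffix: ``V161.2`` -> ``V161``."""
    m = _NAME_RE.match(name)
    return m.group("base") if m else name


@dataclass(frozen=True)
class Marker:
    """One binary character of the Y phylogeny.

    ``positions`` holds one coordinate for a substitution, the inclusive
    (start, end) pair for a deletion, and one coordinate per paralogous
    copy for a multi-copy substitution.  For multi-copy markers
    ``ancestral``/``derived`` are '/'-separated with one allele per copy;
    for deletions ``ancestral`` is the deleted sequence and ``derived`` the
    deletion symbol ``-``.
    """

    name: str
    positions: tuple[int, ...]
    ancestral: str
    derived: str
    mutation_class: str
    source_tag: str = "new"
    primers: tuple[str, str] = ("", "")
    note: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise MarkerValidationError("marker with empty name")
        if not self.positions or any(p <= 0 for p in self.positions):
            raise MarkerValidationError(
                f"{self.name}: positions must be strictly positive"
            )
        if tuple(sorted(self.positions)) != self.positions:
            raise MarkerValidationError(f"{self.name}: positions must be sorted")
        if self.mutation_class == SUBSTITUTION:
            if len(self.positions) != 1:
                raise MarkerValidationError(
                    f"{self.name}: substitution needs exactly one position"
                )
            if (
                self.ancestral not in _NUCS
                or self.derived not in _NUCS
                or self.ancestral == self.derived
            ):
                raise MarkerValidationError(
                    f"{self.name}: substitution needs two distinct nucleotides,"
                    f" got {self.ancestral!r} -> {self.derived!r}"
                )
        elif self.mutation_class == DELETION:
            if len(self.positions) != 2:
                raise MarkerValidationError(
                    f"{self.name}: deletion needs an inclusive (start, end) range"
                )
            if self.derived != "-":
                raise MarkerValidationError(
                    f"{self.name}: deletion derived state must be '-'"
                )
            if not self.ancestral or set(self.ancestral) - _NUCS:
                raise MarkerValidationError(
                    f"{self.name}: deleted sequence must be nucleotides"
                )
            if self.span != len(self.ancestral):
                raise MarkerValidationError(
                    f"{self.name}: range span {self.span} != deleted-sequence"
                    f" length {len(self.ancestral)}"
                )
        elif self.mutation_class == MULTI_COPY:
            anc = self.ancestral.split("/")
            der = self.derived.split("/")
            if len(self.positions) < 2:
                raise MarkerValidationError(
                    f"{self.name}: multi-copy marker needs >=2 paralogous positions"
                )
            if len(anc) != len(self.positions) or len(der) != len(self.positions):
                raise MarkerValidationError(
                    f"{self.name}: per-copy alleles must be listed for every"
                    f" position ({len(self.positions)} copies)"
                )
            for a, d in zip(anc, der):
                if a not in _NUCS or d not in _NUCS or a == d:
                    raise MarkerValidationError(
                        f"{self.name}: bad per-copy alleles {a!r} -> {d!r}"
                    )
        else:
            raise MarkerValidationError(
                f"{self.name}: unknown mutation class {self.mutation_class!r}"
            )

    @property
    def span(self) -> int:
        """Genomic footprint: 1 for substitutions, range width for deletions."""
        if self.mutation_class == DELETION:
            return self.positions[1] - self.positions[0] + 1
        return 1

    @property
    def base(self) -> str:
        return base_site(self.name)

    @property
    def v_number(self) -> Optional[int]:
        """Numeric suffix of a V-style name (``V161.1`` -> 161), else None."""
        m = _V_RE.match(self.name)
        return int(m.group("num")) if m else None


@dataclass(frozen=True)
class OutgroupAllele:
    """Allele observed at a marker's site in the outgroup reference.

    The outgroup (the chimpanzee reference in practice) anchors the
    ancestral state of the human tree root, which is what lets a
    triallelic site be decomposed into independent mutation events.
    """

    site: str
    allele: str

    def __post_init__(self) -> None:
        if self.allele not in _NUCS:
            raise MarkerValidationError(
                f"outgroup allele for {self.site} must be a single nucleotide,"
                f" got {self.allele!r}"
            )


class MarkerCatalog:
    """Ordered, name-unique collection of :class:`Marker` records."""

    def __init__(self, markers: Iterable[Marker] = ()) -> None:
        self._markers: dict[str, Marker] = {}
        for m in markers:
            self.add(m)

    def add(self, marker: Marker) -> None:
        if marker.name in self._markers:
            raise CatalogError(f"duplicate marker name {marker.name!r}")
        self._markers[marker.name] = marker

    def __len__(self) -> int:
        return len(self._markers)

    def __iter__(self) -> Iterator[Marker]:
        return iter(self._markers.values())

    def __contains__(self, name: str) -> bool:
        return name in self._markers

    def __getitem__(self, name: str) -> Marker:
        try:
            return self._markers[name]
        except KeyError:
            raise CatalogError(f"unknown marker {name!r}") from None

    def names(self) -> list[str]:
        return list(self._markers)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerCatalog):
            return NotImplemented
        return list(self) == list(other)

    def select_by_name_range(self, lo: int, hi: int) -> "MarkerCatalog":
        """Markers whose V-number lies in ``[lo, hi]``.

        Event suffixes (``.k``) are ignored when reading the number;
        non-V-style names are skipped, not errors.
        """
        if lo > hi:
            raise CatalogError(f"empty range: {lo} > {hi}")
        out = MarkerCatalog()
        for m in self:
            n = m.v_number
            if n is not None and lo <= n <= hi:
                out.add(m)
        return out


# ---------------------------------------------------------------------------
# parsing

_CANONICAL_HEADER = ["name", "positions", "ancestral", "derived", "class", "source_tag"]


def _parse_positions(text: str, row_label: str) -> tuple[tuple[int, ...], bool]:
    """Return (positions, is_range).  Tolerates ragged whitespace."""
    text = text.strip()
    range_m = re.match(r"^(\d+)\s*-\s*(\d+)$", text)
    if range_m:
        start, end = int(range_m.group(1)), int(range_m.group(2))
        if end < start:
            raise MarkerValidationError(f"{row_label}: inverted range {text!r}")
        return (start, end), True
    parts = [p.strip() for p in text.split(";") if p.strip()]
    try:
        positions = tuple(int(p) for p in parts)
    except ValueError:
        raise MarkerValidationError(
            f"{row_label}: malformed position field {text!r}"
        ) from None
    if not positions:
        raise MarkerValidationError(f"{row_label}: empty position field")
    return tuple(sorted(positions)), False


_MUT_DEL_RE = re.compile(r"^del\s*(?P<seq>[ACGT]+)$", re.IGNORECASE)
# "A to C", "T/T/T toG/G/G" (missing space tolerated on either side of "to")
_MUT_SUB_RE = re.compile(
    r"^(?P<anc>[ACGT](?:/[ACGT])*)\s*to\s*(?P<der>[ACGT](?:/[ACGT])*)$"
)


def _parse_lenient_row(fields: list[str], row_label: str) -> Marker:
    name = fields[0].strip()
    positions, is_range = _parse_positions(fields[1], row_label)
    mut = fields[2].strip()
    fwd = fields[3].strip() if len(fields) > 3 else ""
    rev = fields[4].strip() if len(fields) > 4 else ""

    del_m = _MUT_DEL_RE.match(mut)
    if del_m:
        seq = del_m.group("seq").upper()
        if not is_range:
            # single-coordinate deletions get a degenerate range
            if len(positions) != 1:
                raise MarkerValidationError(
                    f"{row_label}: deletion with multiple positions"
                )
            positions = (positions[0], positions[0] + len(seq) - 1)
        return Marker(name, positions, seq, "-", DELETION, "new", (fwd, rev))

    sub_m = _MUT_SUB_RE.match(mut)
    if sub_m is None:
        raise MarkerValidationError(
            f"{row_label}: malformed mutation field {mut!r}"
        )
    anc, der = sub_m.group("anc"), sub_m.group("der")
    if "/" in anc or "/" in der or len(positions) > 1:
        return Marker(name, positions, anc, der, MULTI_COPY, "new", (fwd, rev))
    return Marker(name, positions, anc, der, SUBSTITUTION, "new", (fwd, rev))


def _parse_canonical_row(fields: list[str], row_label: str) -> Marker:
    if len(fields) < 6:
        raise MarkerValidationError(f"{row_label}: expected 6 columns")
    name, pos_text, anc, der, cls, tag = (f.strip() for f in fields[:6])
    positions, _ = _parse_positions(pos_text, row_label)
    primers: tuple[str, str] = ("", "")
    if len(fields) >= 8:
        primers = (fields[6].strip(), fields[7].strip())
    note = fields[8].strip() if len(fields) > 8 else ""
    return Marker(name, positions, anc, der, cls, tag, primers, note)


def parse_marker_table(source: Union[str, TextIO]) -> MarkerCatalog:
    """Parse a marker table in either dialect, chosen from the header row.

    Raises :class:`MarkerValidationError` naming the row on malformed
    position or mutation fields, and :class:`CatalogError` on duplicate
    names or an unrecognizable header.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    lines = [ln.rstrip("\n") for ln in stream]
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise CatalogError("empty marker table: no header row")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    catalog = MarkerCatalog()
    if header[: len(_CANONICAL_HEADER)] == _CANONICAL_HEADER:
        parse_row = _parse_canonical_row
    elif header and header[0] in {"snp", "marker", "name"}:
        parse_row = _parse_lenient_row
    else:
        raise CatalogError(f"unrecognized marker-table header: {lines[0]!r}")
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 3:
            raise MarkerValidationError(f"row {i}: expected >=3 columns")
        catalog.add(parse_row(fields, f"row {i} ({fields[0].strip()!r})"))
    return catalog


def write_marker_table(catalog: MarkerCatalog, stream: Optional[TextIO] = None) -> str:
    """Serialize to the canonical dialect (round-trip safe)."""
    out = io.StringIO()
    out.write(
        "name\tpositions\tancestral\tderived\tclass\tsource_tag"
        "\tprimer_f\tprimer_r\tnote\n"
    )
    for m in catalog:
        if m.mutation_class == DELETION:
            pos = f"{m.positions[0]}-{m.positions[1]}"
        else:
            pos = ";".join(str(p) for p in m.positions)
        out.write(
            "\t".join(
                [
                    m.name,
                    pos,
                    m.ancestral,
                    m.derived,
                    m.mutation_class,
                    m.source_tag,
                    m.primers[0],
                    m.primers[1],
                    m.note,
                ]
            )
            + "\n"
        )
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# outgroup table


def read_outgroup_table(source: Union[str, TextIO]) -> dict[str, OutgroupAllele]:
    """Two-column TSV ``site  allele`` -> mapping keyed by base site name."""
    stream = io.StringIO(source) if isinstance(source, str) else source
    out: dict[str, OutgroupAllele] = {}
    for i, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if i == 1 and fields[0].lower() in {"site", "marker", "name"}:
            continue
        if len(fields) < 2:
            raise MarkerValidationError(f"outgroup row {i}: expected 2 columns")
        site = base_site(fields[0])
        if site in out:
            raise CatalogError(f"duplicate outgroup record for site {site!r}")
        out[site] = OutgroupAllele(site, fields[1].upper())
    return out


def write_outgroup_table(
    table: Mapping[str, OutgroupAllele], stream: Optional[TextIO] = None
) -> str:
    out = io.StringIO()
    out.write("site\tallele\n")
    for site in table:
        rec = table[site]
        out.write(f"{rec.site}\t{rec.allele}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text
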