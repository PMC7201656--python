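"""Catalog of known HERV-K (HML-2) integration loci.

The catalog is the reference list of proviral and solo-LTR integration
sites against which uniquely mapped junction reads are counted.  Internal
coordinates are always 0-based half-open; tabular listings in the
literature style ("Chr6: 32643459-32643464", 1-based inclusive) are
converted on load.  Contig names are normalised to a lower-case ``chr``
prefix, while unplaced-scaffold names such as ``Un_gl000212`` are kept
verbatim.

A provirus is stored as a single interval spanning its 5'LTR through its
3'LTR; a non-reference locus (absent from the reference assembly) spans
only its target-site-duplication footprint, which is at most 10 bp.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

ELEMENT_TYPES = frozenset({"provirus", "solo_LTR"})
LTR_SUBTYPES = frozenset({"LTR5_Hs", "LTR5A", "LTR5B", "other", "unknown"})
CATALOG_STATUSES = frozenset(
    {"reference", "non_reference", "novel_reference", "novel_non_reference"}
)
POLYMORPHIC_ANNOTATIONS = frozenset({"fixed", "polymorphic", "unknown"})
STRANDS = frozenset({"+", "-", "unknown"})

#: maximum internal span, in bp, of a record that is absent from the
#: reference assembly (its TSD footprint).
MAX_NONREF_SPAN = 10

_NONREF = frozenset({"non_reference", "novel_non_reference"})


def normalize_contig(name: str) -> str:
    """Lower-case the ``chr`` prefix; leave scaffold names verbatim."""
    if name[:3].lower() == "chr":
        return "chr" + name[3:]
    return name


class CatalogError(ValueError):
    """Malformed catalog input."""


@dataclass
class LocusRecord:
    """One catalogued integration site (0-based half-open coordinates)."""

    locus_id: str
    contig: str
    start: int
    end: int
    strand: str = "unknown"
    element_type: str = "solo_LTR"
    ltr_subtype: str = "unknown"
    catalog_status: str = "reference"
    polymorphic_annotation: str = "unknown"
    population_frequency: Optional[float] = None
    est_age_mya: Optional[float] = None
    gene_context: Optional[str] = None

    def validate(self) -> None:
        if not self.locus_id:
            raise CatalogError("empty locus_id")
        if not self.contig:
            raise CatalogError(f"{self.locus_id}: empty contig")
        if self.start >= self.end:
            raise CatalogError(
                f"{self.locus_id}: start {self.start} >= end {self.end} "
                "after normalization to 0-based half-open"
            )
        for val, allowed, what in (
            (self.strand, STRANDS, "strand"),
            (self.element_type, ELEMENT_TYPES, "element_type"),
            (self.ltr_subtype, LTR_SUBTYPES, "ltr_subtype"),
            (self.catalog_status, CATALOG_STATUSES, "catalog_status"),
            (self.polymorphic_annotation, POLYMORPHIC_ANNOTATIONS, "polymorphic_annotation"),
        ):
            if val not in allowed:
                raise CatalogError(
                    f"{self.locus_id}: unknown {what} {val!r}; "
                    f"allowed: {sorted(allowed)}"
                )
        if self.catalog_status in _NONREF and self.end - self.start > MAX_NONREF_SPAN:
            raise CatalogError(
                f"{self.locus_id}: non-reference record spans "
                f"{self.end - self.start} bp (> {MAX_NONREF_SPAN} bp TSD footprint)"
            )
        if self.population_frequency is not None and not (
            0.0 <= self.population_frequency <= 1.0
        ):
            raise CatalogError(f"{self.locus_id}: population_frequency outside [0,1]")
        if self.est_age_mya is not None and self.est_age_mya < 0:
            raise CatalogError(f"{self.locus_id}: negative est_age_mya")


class Catalog:
    """Ordered collection of :class:`LocusRecord` with an interval index."""

    coordinate_system_tag = "zero_half_open"

    def __init__(self, records: Iterable[LocusRecord] = (), source_files=None):
        self.records: list[LocusRecord] = []
        self.source_files: list[str] = list(source_files or [])
        self._by_id: dict[str, LocusRecord] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._warned_contigs: set[str] = set()
        for rec in records:
            self.add(rec)

    def add(self, rec: LocusRecord) -> None:
        rec.validate()
        if rec.locus_id in self._by_id:
            raise CatalogError(f"duplicate locus_id {rec.locus_id!r}")
        self.records.append(rec)
        self._by_id[rec.locus_id] = rec
        self._trees.setdefault(rec.contig, IntervalTree()).addi(
            rec.start, rec.end, rec
        )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LocusRecord]:
        return iter(self.records)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def get(self, locus_id: str) -> LocusRecord:
        return self._by_id[locus_id]

    @property
    def locus_ids(self) -> list[str]:
        return [r.locus_id for r in self.records]

    def contigs(self) -> list[str]:
        return sorted(self._trees)

    def records_on(self, contig: str) -> list[LocusRecord]:
        tree = self._trees.get(contig)
        return sorted((iv.data for iv in tree), key=lambda r: r.start) if tree else []

    def query_window(self, contig: str, position: int, window_nt: int) -> list[LocusRecord]:
        """Records whose interval, expanded by ``window_nt`` on both sides,
        contains ``position``.  Unknown contigs yield an empty list (logged
        once per contig)."""
        if window_nt < 0:
            raise ValueError("window_nt must be >= 0")
        tree = self._trees.get(contig)
        if tree is None:
            if contig not in self._warned_contigs:
                self._warned_contigs.add(contig)
                logger.warning("query for unknown contig %r", contig)
            return []
        hits = tree.overlap(position - window_nt, position + window_nt + 1)
        return sorted((iv.data for iv in hits), key=lambda r: (r.start, r.locus_id))

    def nearest_distance(self, contig: str, lo: int, hi: int) -> Optional[int]:
        """Distance in nt from the inclusive position span [lo, hi] to the
        nearest record on ``contig`` (0 when overlapping); None if the
        contig carries no records."""
        recs = self.records_on(contig)
        if not recs:
            return None
        best = None
        for rec in recs:
            if rec.start > hi:
                d = rec.start - hi
            elif rec.end - 1 < lo:
                d = lo - (rec.end - 1)
            else:
                d = 0
            if best is None or d < best:
                best = d
        return best


def count_by_category(catalog: Catalog) -> dict[str, int]:
    """Counts keyed by ``"<catalog_status>/<element_type>"`` plus ``"total"``."""
    counts: dict[str, int] = {}
    for rec in catalog:
        key = f"{rec.catalog_status}/{rec.element_type}"
        counts[key] = counts.get(key, 0) + 1
    counts["total"] = len(catalog)
    return counts


@dataclass
class MergeResult:
    catalog: Catalog
    accepted: list[LocusRecord] = field(default_factory=list)
    rejected: list[tuple[LocusRecord, str]] = field(default_factory=list)


def merge_novel(
    catalog: Catalog, novel: Iterable[LocusRecord], window_nt: int = 10
) -> MergeResult:
    """Extend a catalog with newly discovered loci.

    Novel records must carry a ``novel_*`` status.  A novel record lying
    within ``window_nt`` of an existing record is a re-detection of a known
    locus: it is rejected with a report entry rather than silently merged.
    """
    merged = Catalog(catalog.records, source_files=catalog.source_files)
    result = MergeResult(catalog=merged)
    for rec in novel:
        if rec.catalog_status not in ("novel_reference", "novel_non_reference"):
            raise CatalogError(
                f"{rec.locus_id}: merge_novel requires novel_* status, "
                f"got {rec.catalog_status!r}"
            )
        if rec.locus_id in merged:
            raise CatalogError(f"locus_id collision on merge: {rec.locus_id!r}")
        near = [
            r
            for pos in (rec.start, rec.end - 1)
            for r in merged.query_window(rec.contig, pos, window_nt)
        ]
        if near:
            result.rejected.append(
                (rec, f"duplicate-of-known:{near[0].locus_id}")
            )
            continue
        merged.add(rec)
        result.accepted.append(rec)
    return result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "locus_id",
    "coordinate",
    "orientation",
    "type",
    "status",
    "subtype",
    "frequency",
    "age_mya",
    "gene_context",
    "polymorphic",  # optional trailing column; absent -> unknown
]

BED_EXTRA_COLUMNS = [
    "element_type",
    "ltr_subtype",
    "catalog_status",
    "polymorphic_annotation",
    "population_frequency",
    "est_age_mya",
    "gene_context",
]

_COORD_RE = re.compile(r"^\s*(\S+?)\s*:\s*([\d,]+)\s*-\s*([\d,]+)\s*$")

_STRAND_MAP = {
    "+": "+", "(+)": "+",
    "-": "-", "(-)": "-",
    "−": "-", "(−)": "-",  # unicode minus as printed in tables
    ".": "unknown", "": "unknown", "unknown": "unknown",
}


def _parse_strand(tok: str, line_no: int) -> str:
    try:
        return _STRAND_MAP[tok.strip()]
    except KeyError:
        raise CatalogError(f"line {line_no}: unknown orientation {tok!r}") from None


def _parse_element_type(tok: str, line_no: int) -> str:
    norm = tok.strip().replace("-", "_")
    if norm.lower() in ("solo_ltr", "sololtr"):
        return "solo_LTR"
    if norm.lower() == "provirus":
        return "provirus"
    raise CatalogError(
        f"line {line_no}: unknown element type {tok!r}; allowed: provirus, solo_LTR"
    )


def _parse_subtype(tok: str, line_no: int) -> str:
    tok = tok.strip()
    if tok in ("", "."):
        return "unknown"
    for allowed in LTR_SUBTYPES:
        if tok.lower() == allowed.lower():
            return allowed
    raise CatalogError(
        f"line {line_no}: unknown LTR subtype {tok!r}; allowed: {sorted(LTR_SUBTYPES)}"
    )


def _opt_float(tok: str) -> Optional[float]:
    tok = tok.strip()
    return None if tok in ("", ".", "NA", "nan") else float(tok)


def _fmt_opt(val) -> str:
    return "." if val in (None, "") else str(val)


def load_catalog(path, dialect: str = "table_s1_tsv") -> Catalog:
    """Load a catalog from a TSV (1-based inclusive coordinates) or BED6+
    (0-based half-open) file; all records are normalised to 0-based
    half-open internally."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    return _parse_catalog(lines, dialect, str(path))


def _parse_catalog(lines: list[str], dialect: str, source: str) -> Catalog:
    if dialect not in ("table_s1_tsv", "bed6plus"):
        raise ValueError(f"unknown dialect {dialect!r}")
    cat = Catalog(source_files=[source])
    header_seen = False
    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if dialect == "table_s1_tsv":
            if not header_seen:
                header_seen = True
                if fields[0].strip().lower() == "locus_id":
                    continue  # header row
                raise CatalogError(
                    f"line {line_no}: expected header starting with 'locus_id', "
                    f"got {fields[0]!r}"
                )
            rec = _parse_table_row(fields, line_no)
        else:
            rec = _parse_bed_row(fields, line_no)
        try:
            cat.add(rec)
        except CatalogError as exc:
            raise CatalogError(f"line {line_no}: {exc}") from None
    return cat


def _parse_table_row(fields: list[str], line_no: int) -> LocusRecord:
    if len(fields) < 6:
        raise CatalogError(
            f"line {line_no}: expected >= 6 tab-separated columns "
            f"({', '.join(TABLE_COLUMNS)}), got {len(fields)}"
        )
    fields = fields + [""] * (len(TABLE_COLUMNS) - len(fields))
    m = _COORD_RE.match(fields[1])
    if not m:
        raise CatalogError(f"line {line_no}: malformed coordinate {fields[1]!r}")
    contig = normalize_contig(m.group(1))
    start1 = int(m.group(2).replace(",", ""))
    end1 = int(m.group(3).replace(",", ""))
    status = fields[4].strip()
    if status not in CATALOG_STATUSES:
        raise CatalogError(
            f"line {line_no}: unknown status {status!r}; "
            f"allowed: {sorted(CATALOG_STATUSES)}"
        )
    try:
        freq = _opt_float(fields[6])
        age = _opt_float(fields[7])
    except ValueError as exc:
        raise CatalogError(f"line {line_no}: {exc}") from None
    gene = fields[8].strip()
    poly = fields[9].strip() or "unknown"
    if poly == ".":
        poly = "unknown"
    return LocusRecord(
        locus_id=fields[0].strip(),
        contig=contig,
        start=start1 - 1,  # 1-based inclusive -> 0-based half-open
        end=end1,
        strand=_parse_strand(fields[2], line_no),
        element_type=_parse_element_type(fields[3], line_no),
        catalog_status=status,
        ltr_subtype=_parse_subtype(fields[5], line_no),
        polymorphic_annotation=poly,
        population_frequency=freq,
        est_age_mya=age,
        gene_context=gene if gene not in ("", ".", "-", "–") else None,
    )


def _parse_bed_row(fields: list[str], line_no: int) -> LocusRecord:
    if len(fields) < 6 + len(BED_EXTRA_COLUMNS):
        raise CatalogError(
            f"line {line_no}: expected {6 + len(BED_EXTRA_COLUMNS)} BED6+ columns, "
            f"got {len(fields)}"
        )
    try:
        start = int(fields[1])
        end = int(fields[2])
    except ValueError:
        raise CatalogError(f"line {line_no}: non-integer BED coordinates") from None
    extra = dict(zip(BED_EXTRA_COLUMNS, fields[6:]))
    status = extra["catalog_status"].strip()
    if status not in CATALOG_STATUSES:
        raise CatalogError(
            f"line {line_no}: unknown status {status!r}; "
            f"allowed: {sorted(CATALOG_STATUSES)}"
        )
    try:
        freq = _opt_float(extra["population_frequency"])
        age = _opt_float(extra["est_age_mya"])
    except ValueError as exc:
        raise CatalogError(f"line {line_no}: {exc}") from None
    gene = extra["gene_context"].strip()
    return LocusRecord(
        locus_id=fields[3].strip(),
        contig=normalize_contig(fields[0]),
        start=start,
        end=end,
        strand=_parse_strand(fields[5], line_no),
        element_type=_parse_element_type(extra["element_type"], line_no),
        ltr_subtype=_parse_subtype(extra["ltr_subtype"], line_no),
        catalog_status=status,
        polymorphic_annotation=extra["polymorphic_annotation"].strip() or "unknown",
        population_frequency=freq,
        est_age_mya=age,
        gene_context=gene if gene not in ("", ".") else None,
    )


def write_catalog(catalog: Catalog, path, dialect: str = "table_s1_tsv") -> None:
    """Write a catalog; the header line names the coordinate convention."""
    path = Path(path)
    lines = []
    if dialect == "table_s1_tsv":
        lines.append("# coordinates: 1-based inclusive")
        lines.append("\t".join(TABLE_COLUMNS))
        for r in catalog:
            lines.append(
                "\t".join(
                    [
                        r.locus_id,
                        f"{r.contig}: {r.start + 1}-{r.end}",
                        "." if r.strand == "unknown" else r.strand,
                        r.element_type,
                        r.catalog_status,
                        r.ltr_subtype,
                        _fmt_opt(r.population_frequency),
                        _fmt_opt(r.est_age_mya),
                        _fmt_opt(r.gene_context),
                        r.polymorphic_annotation,
                    ]
                )
            )
    elif dialect == "bed6plus":
        lines.append("# coordinates: 0-based half-open (BED)")
        for r in catalog:
            lines.append(
                "\t".join(
                    [
                        r.contig,
                        str(r.start),
                        str(r.end),
                        r.locus_id,
                        "0",
                        "." if r.strand == "unknown" else r.strand,
                        r.element_type,
                        r.ltr_subtype,
                        r.catalog_status,
                        r.polymorphic_annotation,
                        _fmt_opt(r.population_frequency),
                        _fmt_opt(r.est_age_mya),
                        _fmt_opt(r.gene_context),
                    ]
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Packaged fixture catalogs
# ---------------------------------------------------------------------------

#: category composition of the full reported-locus list:
#: (catalog_status, element_type) -> count
REPORTED_COMPOSITION = {
    ("reference", "provirus"): 85,
    ("reference", "solo_LTR"): 946,
    ("non_reference", "provirus"): 5,
    ("non_reference", "solo_LTR"): 27,
}

_SUBTYPE_AGES = {"LTR5_Hs": (0.2, 10.0), "LTR5A": (8.0, 25.0), "LTR5B": (18.0, 35.0)}
_CONTIG_NAMES = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def builtin_catalog() -> Catalog:
    """The packaged 1063-record reference catalog.

    Category counts reproduce the reported composition (85 reference
    proviruses, 946 reference solo LTRs, 5 + 27 non-reference loci; 69
    polymorphic, 89 fixed-in-Chinese annotations).  Coordinates are
    synthetic: the full supplementary locus list is not part of the public
    record, so positions are drawn deterministically while the bookkeeping
    structure is preserved.
    """
    rng = np.random.default_rng(10631098)  # fixed: fixture, not a simulation
    records: list[LocusRecord] = []
    n_total = sum(REPORTED_COMPOSITION.values())
    contig_of = rng.integers(0, len(_CONTIG_NAMES), n_total)
    subtype_of = rng.choice(
        ["LTR5_Hs", "LTR5A", "LTR5B"], size=n_total, p=[0.40, 0.35, 0.25]
    )
    # deterministic, collision-free positions: per-contig running offset
    next_pos = {c: 1_000_000 for c in _CONTIG_NAMES}
    i = 0
    solo_n = 0
    prov_n = 0
    for (status, etype), count in REPORTED_COMPOSITION.items():
        for _ in range(count):
            contig = _CONTIG_NAMES[contig_of[i]]
            subtype = str(subtype_of[i])
            lo_age, hi_age = _SUBTYPE_AGES[subtype]
            age = round(float(rng.uniform(lo_age, hi_age)), 2)
            start = next_pos[contig] + int(rng.integers(0, 50_000))
            if status == "non_reference":
                end = start + 6  # TSD footprint
            elif etype == "provirus":
                end = start + 9470
            else:
                end = start + 968
            next_pos[contig] = end + 150_000
            if etype == "solo_LTR":
                solo_n += 1
                prefix = "N-solo" if status == "non_reference" else "solo-LTR"
                locus_id = f"{prefix}{solo_n}"
            else:
                prov_n += 1
                locus_id = ("N-prov" if status == "non_reference" else "prov") + str(prov_n)
            records.append(
                LocusRecord(
                    locus_id=locus_id,
                    contig=contig,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    element_type=etype,
                    ltr_subtype=subtype,
                    catalog_status=status,
                    est_age_mya=age,
                )
            )
            i += 1
    # polymorphism annotations: 69 polymorphic, 89 fixed, rest unknown
    order = rng.permutation(n_total)
    for j in order[:69]:
        records[j].polymorphic_annotation = "polymorphic"
        records[j].population_frequency = round(float(rng.uniform(0.05, 0.95)), 2)
    for j in order[69 : 69 + 89]:
        records[j].polymorphic_annotation = "fixed"
        records[j].population_frequency = 1.0
    return Catalog(records, source_files=["builtin:reported-loci-fixture"])


def novel_catalog() -> Catalog:
    """The 35 novel integration loci (30 reference + 5 non-reference) with
    their published coordinates, loaded from packaged data."""
    data = resources.files("hervkmap.data").joinpath("novel_loci.tsv").read_text()
    return _parse_catalog(data.splitlines(), "table_s1_tsv", "packaged:novel_loci.tsv")
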