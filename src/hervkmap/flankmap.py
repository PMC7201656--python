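"""Unique mapping of host flanks to a genome.

The internal aligner is a deterministic exact-k-mer seed + ungapped
extension scheme over both strands.  A flank is reported only when exactly
one best-scoring placement exists ("uniquely mapped"); any second placement
tying the best score disqualifies the flank.  This is the strictest
reproducible reading of unique mapping and is what makes repeat-embedded
loci drop out of the analysis.

Flanks arrive in molecule orientation (LTR abutting the left edge), so
after alignment the junction — the host base adjacent to the LTR — is the
flank's left genome edge on '+' placements and its right edge on '-'
placements.

For real-genome runs any external aligner can be used instead; its SAM
output is imported with MAPQ > 0 and primary-record status as the
uniqueness proxy.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .chimera import ChimericHit
from .dna import encode, revcomp

_SEP = 50  # N-run separating concatenated contigs in the packed genome


@dataclass(frozen=True)
class FlankAlignment:
    read_id: str
    ltr_end: str            # five_prime | three_prime
    contig: str
    pos: int                # 0-based leftmost
    strand: str             # + | -
    length: int
    score: int              # matching bases
    n_best: int             # equally-best placements (reported only when 1)
    junction_side: str      # left_of_flank | right_of_flank

    @property
    def junction(self) -> int:
        """Genome position of the flank base that abuts the LTR."""
        return self.pos if self.junction_side == "left_of_flank" else self.pos + self.length - 1


class GenomeIndex:
    """Exact k-mer positional index over a genome (forward strand stored;
    reverse-strand hits are found by querying the reverse-complemented
    flank)."""

    def __init__(self, contigs: dict[str, str], k: int = 15):
        if not contigs:
            raise ValueError("empty genome")
        if not 11 <= k <= 31:
            raise ValueError("k must lie in [11, 31]")
        self.k = k
        self.names: list[str] = []
        self.starts: list[int] = []
        parts: list[str] = []
        offset = 0
        import logging

        for name, seq in contigs.items():
            if len(seq) < k:
                logging.getLogger(__name__).warning(
                    "contig %r shorter than k=%d: skipped", name, k
                )
                continue
            self.names.append(name)
            self.starts.append(offset)
            parts.append(seq)
            offset += len(seq) + _SEP
            parts.append("N" * _SEP)
        if not self.names:
            raise ValueError("no contig of length >= k")
        self.genome = "".join(parts)
        self.codes = encode(self.genome)
        self.lengths = {n: len(contigs[n]) for n in self.names}
        # vectorised k-mer extraction: integer value of every window, with
        # windows containing N (including the contig separators) dropped
        c = self.codes.astype(np.int64)
        n = len(c) - k + 1
        valid = np.ones(n, dtype=bool)
        kmer = np.zeros(n, dtype=np.int64)
        for j in range(k):
            cj = c[j : n + j]
            kmer = kmer * 4 + np.where(cj > 3, 0, cj)
            valid &= cj < 4
        pos = np.flatnonzero(valid)
        vals = kmer[pos]
        order = np.argsort(vals, kind="stable")
        self._kmer_sorted = vals[order]
        self._pos_sorted = pos[order].astype(np.int64)
        self._pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)

    def _kmer_value(self, kmer: str) -> Optional[int]:
        codes = encode(kmer)
        if (codes > 3).any():
            return None
        return int(codes @ self._pow4)

    def lookup(self, kmer: str) -> np.ndarray:
        val = self._kmer_value(kmer)
        if val is None:
            return _EMPTY
        lo = np.searchsorted(self._kmer_sorted, val, side="left")
        hi = np.searchsorted(self._kmer_sorted, val, side="right")
        return self._pos_sorted[lo:hi]

    def contig_of(self, packed_pos: int) -> tuple[str, int]:
        i = bisect_right(self.starts, packed_pos) - 1
        return self.names[i], packed_pos - self.starts[i]

    def within_one_contig(self, packed_pos: int, length: int) -> bool:
        i = bisect_right(self.starts, packed_pos) - 1
        return packed_pos + length <= self.starts[i] + self.lengths[self.names[i]]


_EMPTY = np.empty(0, dtype=np.int64)


def build_index(contigs: dict[str, str], k: int = 15) -> GenomeIndex:
    return GenomeIndex(contigs, k=k)


def _seed_candidates(
    index: GenomeIndex, flank: str, max_mm: int
) -> Optional[np.ndarray]:
    """Seed positions for all placements with <= max_mm mismatches.

    The flank is cut into (max_mm + 1) contiguous segments; by pigeonhole
    one segment is mismatch-free in any qualifying placement, so its
    leading k-mer seeds that placement.  Returns None when the flank is
    too short to carry enough disjoint seeds (caller falls back to an
    exhaustive scan).
    """
    k = index.k
    L = len(flank)
    nseg = max_mm + 1
    if L < nseg * k:
        return None
    cands: list[np.ndarray] = []
    for i in range(nseg):
        off = i * L // nseg
        hits = index.lookup(flank[off : off + k])
        if hits.size:
            cands.append(hits - off)
    if not cands:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(cands))


def _mismatches_at(index: GenomeIndex, fcodes: np.ndarray, pos: int) -> int:
    g = index.codes[pos : pos + len(fcodes)]
    return int(np.count_nonzero((g != fcodes) | (g > 3) | (fcodes > 3)))


def _exhaustive_positions(index: GenomeIndex, fcodes: np.ndarray, max_mm: int) -> np.ndarray:
    """All packed positions with <= max_mm mismatches (brute-force; used
    for flanks too short for guaranteed seeding)."""
    g = index.codes
    L = len(fcodes)
    n = len(g) - L + 1
    if n <= 0:
        return _EMPTY
    mism = np.zeros(n, dtype=np.int32)
    for j in range(L):
        gj = g[j : j + n]
        mism += (gj != fcodes[j]) | (gj > 3)
    return np.flatnonzero(mism <= max_mm).astype(np.int64)


def align_flank(
    hit_or_seq,
    index: GenomeIndex,
    max_mismatch_frac: float = 0.06,
) -> tuple[Optional[FlankAlignment], str]:
    """Align one flank; returns (alignment, reason) where reason is
    ``mapped``, ``unmapped``, ``multi_mapped`` or ``too_short``."""
    if isinstance(hit_or_seq, ChimericHit):
        flank, read_id, ltr_end = hit_or_seq.flank_seq, hit_or_seq.read_id, hit_or_seq.ltr_end
    else:
        flank, read_id, ltr_end = hit_or_seq, "", "five_prime"
    L = len(flank)
    if L < 10:
        return None, "too_short"
    max_mm = int(np.floor(max_mismatch_frac * L + 1e-9))
    placements: list[tuple[int, str, int]] = []  # (mm, strand, packed_pos)
    for strand, query in (("+", flank), ("-", revcomp(flank))):
        fcodes = encode(query)
        cands = _seed_candidates(index, query, max_mm)
        if cands is None:
            cands = _exhaustive_positions(index, fcodes, max_mm)
        for p in cands:
            p = int(p)
            if p < 0 or p + L > len(index.codes):
                continue
            if not index.within_one_contig(p, L):
                continue
            mm = _mismatches_at(index, fcodes, p)
            if mm <= max_mm:
                placements.append((mm, strand, p))
    if not placements:
        return None, "unmapped"
    best_mm = min(p[0] for p in placements)
    best = sorted(p for p in placements if p[0] == best_mm)
    if len(best) > 1:
        return None, "multi_mapped"
    mm, strand, packed = best[0]
    contig, pos = index.contig_of(packed)
    return (
        FlankAlignment(
            read_id=read_id,
            ltr_end=ltr_end,
            contig=contig,
            pos=pos,
            strand=strand,
            length=L,
            score=L - mm,
            n_best=1,
            junction_side="left_of_flank" if strand == "+" else "right_of_flank",
        ),
        "mapped",
    )


def map_flanks(
    hits: Sequence[ChimericHit],
    index: GenomeIndex,
    max_mismatch_frac: float = 0.06,
) -> tuple[list[FlankAlignment], dict]:
    """Align many flanks; only uniquely mapped ones are returned."""
    alignments: list[FlankAlignment] = []
    stats = {"flanks_in": len(hits), "mapped": 0, "unmapped": 0,
             "multi_mapped": 0, "too_short": 0}
    for h in hits:
        aln, reason = align_flank(h, index, max_mismatch_frac)
        stats[reason if reason != "mapped" else "mapped"] += 1
        if aln is not None:
            alignments.append(aln)
    return alignments, stats


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------

_LTR_END_TAG = "XE"


def export_alignments(
    alignments: Iterable[FlankAlignment],
    path,
    contig_lengths: dict[str, int],
) -> None:
    """Write internal alignments as SAM (flank orientation in the FLAG
    strand bit, junction end in the XE tag)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_name = aln.contig
            rec.reference_start = aln.pos
            rec.mapping_quality = 60
            rec.cigarstring = f"{aln.length}M"
            rec.set_tag(_LTR_END_TAG, aln.ltr_end)
            rec.set_tag("NM", aln.length - aln.score)
            out.write(rec)


def import_alignments(sam_path) -> tuple[list[FlankAlignment], dict]:
    """Import an external aligner's SAM/BAM.

    Records that are unmapped, secondary, supplementary, or MAPQ 0 are
    excluded (uniqueness proxy).  The junction end is read from the XE tag
    or from an ``|end=<...>`` token in the read name; records without
    either are skipped and counted.
    """
    stats = {"records": 0, "imported": 0, "excluded_nonunique": 0, "missing_tag": 0}
    out: list[FlankAlignment] = []
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            stats["records"] += 1
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.mapping_quality == 0
            ):
                stats["excluded_nonunique"] += 1
                continue
            ltr_end = None
            if rec.has_tag(_LTR_END_TAG):
                ltr_end = rec.get_tag(_LTR_END_TAG)
            else:
                for token in rec.query_name.split("|"):
                    if token.startswith("end="):
                        ltr_end = token[4:]
            if ltr_end not in ("five_prime", "three_prime"):
                stats["missing_tag"] += 1
                continue
            length = rec.query_length or rec.infer_query_length() or 0
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            strand = "-" if rec.is_reverse else "+"
            out.append(
                FlankAlignment(
                    read_id=rec.query_name,
                    ltr_end=ltr_end,
                    contig=rec.reference_name,
                    pos=rec.reference_start,
                    strand=strand,
                    length=int(length),
                    score=int(length) - int(nm),
                    n_best=1,
                    junction_side="left_of_flank" if strand == "+" else "right_of_flank",
                )
            )
            stats["imported"] += 1
    return out, stats
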