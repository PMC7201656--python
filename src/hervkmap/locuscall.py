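"""Locus detection and quantification from uniquely mapped flanks.

Each alignment contributes its *junction* coordinate — the host base
adjacent to the LTR — which is the biologically fixed point of an
integration.  Junctions within a 10-nt window of a catalogued locus count
toward that locus; junctions clustering more than 2 kb away from every
catalogued locus define candidate novel loci, classified as
novel-non-reference when 5' and 3' junction clusters delimit a target-site
duplication, or novel-reference when they abut an annotated but
uncatalogued LTR element.  Relative abundance is expressed as counts per
million uniquely mapped flanks (CPM), with an optional CPM >= 50 detection
filter.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import Catalog
from .flankmap import FlankAlignment


@dataclass
class SampleQuant:
    """Per-sample locus x count/CPM table."""

    sample_id: str
    library_size: int
    counts: dict[str, int]
    cpm: dict[str, float]
    detected: dict[str, bool]
    detected_filtered: dict[str, bool]
    cpm_min: float

    def to_frame(self) -> pd.DataFrame:
        loci = list(self.counts)
        return pd.DataFrame(
            {
                "locus_id": loci,
                "count": [self.counts[l] for l in loci],
                "cpm": [self.cpm[l] for l in loci],
                "detected": [self.detected[l] for l in loci],
                "detected_filtered": [self.detected_filtered[l] for l in loci],
            }
        )

    @property
    def n_detected(self) -> int:
        return sum(self.detected.values())

    @property
    def n_detected_filtered(self) -> int:
        return sum(self.detected_filtered.values())


def quantify(
    counts: dict[str, int],
    library_size: int,
    sample_id: str = "",
    locus_universe: Optional[Iterable[str]] = None,
    cpm_min: float = 50.0,
) -> SampleQuant:
    """CPM-normalise locus counts: cpm = count / library_size * 1e6.

    Loci at exactly the CPM threshold pass the filter (>=).  The universe
    defaults to the counted loci; passing a catalog's locus ids gives a
    dense table including zeros.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    universe = list(locus_universe) if locus_universe is not None else list(counts)
    full = {l: int(counts.get(l, 0)) for l in universe}
    cpm = {l: c / library_size * 1e6 for l, c in full.items()}
    return SampleQuant(
        sample_id=sample_id,
        library_size=library_size,
        counts=full,
        cpm=cpm,
        detected={l: c >= 1 for l, c in full.items()},
        detected_filtered={l: (full[l] >= 1 and cpm[l] >= cpm_min) for l in universe},
        cpm_min=cpm_min,
    )


def assign_to_catalog(
    alignments: Sequence[FlankAlignment],
    catalog: Catalog,
    window_nt: int = 10,
) -> tuple[dict[str, int], list[FlankAlignment], dict]:
    """Count each alignment toward at most one catalogued locus.

    The junction must fall within ``window_nt`` of the locus interval;
    with several qualifying loci the nearest edge wins and exact ties go
    to the lower-coordinate locus (counted).  Returns (counts, unassigned
    alignments, stats).
    """
    counts: dict[str, int] = {}
    unassigned: list[FlankAlignment] = []
    stats = {"assigned": 0, "unassigned": 0, "ties": 0}
    for aln in alignments:
        j = aln.junction
        matches = catalog.query_window(aln.contig, j, window_nt)
        if not matches:
            unassigned.append(aln)
            stats["unassigned"] += 1
            continue
        if len(matches) == 1:
            winner = matches[0]
        else:
            def dist(rec):
                if rec.start <= j < rec.end:
                    return 0
                return min(abs(j - rec.start), abs(j - (rec.end - 1)))

            dmin = min(dist(r) for r in matches)
            nearest = [r for r in matches if dist(r) == dmin]
            if len(nearest) > 1:
                stats["ties"] += 1
            winner = min(nearest, key=lambda r: (r.start, r.locus_id))
        counts[winner.locus_id] = counts.get(winner.locus_id, 0) + 1
        stats["assigned"] += 1
    return counts, unassigned, stats


@dataclass
class NovelLocusCall:
    contig: str
    start: int                      # junction-span, 0-based inclusive
    end: int                        # 0-based inclusive
    supporting_reads: int
    ltr_end_support: dict[str, int]
    junctions: dict[str, list[int]] = field(default_factory=dict)
    classification: str = "ambiguous"   # novel_reference | novel_non_reference | ambiguous
    tsd: Optional[tuple[int, int]] = None  # 1-based inclusive interval
    distance_to_catalog: Optional[int] = None

    @property
    def tsd_len(self) -> Optional[int]:
        return None if self.tsd is None else self.tsd[1] - self.tsd[0] + 1


def discover_novel(
    unassigned: Sequence[FlankAlignment],
    catalog: Catalog,
    min_novel_dist: int = 2000,
    cluster_gap: int = 50,
    min_reads: int = 2,
) -> tuple[list[NovelLocusCall], list[NovelLocusCall]]:
    """Cluster unassigned junctions and split them into novel candidates
    (single-linkage clusters of >= min_reads whose span lies more than
    ``min_novel_dist`` from every catalogued locus) and ambiguous clusters
    (closer than that but outside the counting window).

    Returns (candidates, ambiguous)."""
    by_contig: dict[str, list[FlankAlignment]] = {}
    for aln in unassigned:
        by_contig.setdefault(aln.contig, []).append(aln)
    candidates: list[NovelLocusCall] = []
    ambiguous: list[NovelLocusCall] = []
    for contig in sorted(by_contig):
        alns = sorted(by_contig[contig], key=lambda a: a.junction)
        cluster: list[FlankAlignment] = []
        for aln in alns + [None]:
            if cluster and (
                aln is None or aln.junction - cluster[-1].junction > cluster_gap
            ):
                if len(cluster) >= min_reads:
                    call = _make_call(contig, cluster, catalog, min_novel_dist)
                    (candidates if call.distance_to_catalog is None
                     or call.distance_to_catalog > min_novel_dist
                     else ambiguous).append(call)
                cluster = []
            if aln is not None:
                cluster.append(aln)
    return candidates, ambiguous


def _make_call(
    contig: str,
    cluster: list[FlankAlignment],
    catalog: Catalog,
    min_novel_dist: int,
) -> NovelLocusCall:
    lo = min(a.junction for a in cluster)
    hi = max(a.junction for a in cluster)
    support = Counter(a.ltr_end for a in cluster)
    junctions = {
        end: sorted(a.junction for a in cluster if a.ltr_end == end)
        for end in ("five_prime", "three_prime")
        if support.get(end)
    }
    return NovelLocusCall(
        contig=contig,
        start=lo,
        end=hi,
        supporting_reads=len(cluster),
        ltr_end_support=dict(support),
        junctions=junctions,
        distance_to_catalog=catalog.nearest_distance(contig, lo, hi),
    )


def _mode(values: list[int]) -> int:
    cnt = Counter(values)
    top = max(cnt.values())
    return min(v for v, c in cnt.items() if c == top)


def classify_novel(
    candidate: NovelLocusCall,
    max_tsd: int = 10,
    ltr_annotation: Optional[Sequence[tuple[str, int, int]]] = None,
) -> NovelLocusCall:
    """Classify a candidate novel locus.

    Both-end support whose junction clusters overlap or abut within
    ``max_tsd`` bases marks a target-site duplication: the element is
    absent from the reference (novel_non_reference) and the TSD interval
    is reported 1-based inclusive.  Otherwise, overlap with an annotated
    but uncatalogued LTR element (when a track is supplied) marks a
    reference element missing from the catalog (novel_reference).
    """
    five = candidate.junctions.get("five_prime")
    three = candidate.junctions.get("three_prime")
    if five and three:
        a = _mode(five)
        b = _mode(three)
        span = abs(a - b) + 1
        if span <= max_tsd:
            candidate.tsd = (min(a, b) + 1, max(a, b) + 1)  # 1-based inclusive
            candidate.classification = "novel_non_reference"
            return candidate
    if ltr_annotation:
        for contig, lo, hi in ltr_annotation:
            if contig == candidate.contig and candidate.start <= hi and candidate.end >= lo - 1:
                candidate.classification = "novel_reference"
                return candidate
    candidate.classification = "ambiguous"
    return candidate


def call_novel(
    unassigned: Sequence[FlankAlignment],
    catalog: Catalog,
    min_novel_dist: int = 2000,
    cluster_gap: int = 50,
    min_reads: int = 2,
    max_tsd: int = 10,
    ltr_annotation: Optional[Sequence[tuple[str, int, int]]] = None,
) -> tuple[list[NovelLocusCall], list[NovelLocusCall]]:
    """Full novel-locus stage: cluster, classify, and merge the paired
    flanking clusters of one uncatalogued reference element into a single
    call spanning the annotated element."""
    candidates, ambiguous = discover_novel(
        unassigned, catalog, min_novel_dist=min_novel_dist,
        cluster_gap=cluster_gap, min_reads=min_reads,
    )
    candidates = [
        classify_novel(c, max_tsd=max_tsd, ltr_annotation=ltr_annotation)
        for c in candidates
    ]
    if not ltr_annotation:
        return candidates, ambiguous
    # merge the two edge clusters of one annotated element
    ann_tree: dict[str, IntervalTree] = {}
    for contig, lo, hi in ltr_annotation:
        ann_tree.setdefault(contig, IntervalTree()).addi(lo, hi, (contig, lo, hi))
    grouped: dict[tuple, list[NovelLocusCall]] = {}
    rest: list[NovelLocusCall] = []
    for c in candidates:
        if c.classification != "novel_reference":
            rest.append(c)
            continue
        hits = ann_tree.get(c.contig, IntervalTree()).overlap(c.start - 1, c.end + 2)
        key = sorted(iv.data for iv in hits)[0]
        grouped.setdefault(key, []).append(c)
    merged: list[NovelLocusCall] = []
    for (contig, lo, hi), calls in sorted(grouped.items()):
        merged.append(
            NovelLocusCall(
                contig=contig,
                start=lo,
                end=hi - 1,
                supporting_reads=sum(c.supporting_reads for c in calls),
                ltr_end_support=dict(
                    sum((Counter(c.ltr_end_support) for c in calls), Counter())
                ),
                junctions={
                    k: sorted(j for c in calls for j in c.junctions.get(k, []))
                    for k in ("five_prime", "three_prime")
                },
                classification="novel_reference",
                distance_to_catalog=min(
                    (c.distance_to_catalog for c in calls
                     if c.distance_to_catalog is not None),
                    default=None,
                ),
            )
        )
    return rest + merged, ambiguous


def saturation(
    pairs: Sequence,
    depths: Sequence[int],
    pipeline_fn: Callable,
    seed: int,
) -> pd.DataFrame:
    """Detected-locus counts across nested read subsamples.

    One seeded permutation defines the nesting (each smaller subsample is
    a prefix of the larger).  ``pipeline_fn(pairs) -> SampleQuant`` runs
    the full analysis.  Depths exceeding the available reads are reported
    as NA.  Returns a frame with one row per requested depth, in input
    order.
    """
    if list(depths) != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    rows = []
    for depth in depths:
        if depth > len(pairs):
            import logging

            logging.getLogger(__name__).warning(
                "saturation depth %d exceeds available reads (%d)", depth, len(pairs)
            )
            rows.append({"depth": depth, "n_detected": np.nan,
                         "n_detected_filtered": np.nan})
            continue
        if depth == 0:
            rows.append({"depth": 0, "n_detected": 0, "n_detected_filtered": 0})
            continue
        subset = [pairs[i] for i in perm[:depth]]
        quant = pipeline_fn(subset)
        rows.append(
            {
                "depth": depth,
                "n_detected": quant.n_detected,
                "n_detected_filtered": quant.n_detected_filtered,
            }
        )
    return pd.DataFrame(rows)
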