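"""Read preparation: sliding-window quality trimming, PCR-duplicate
removal, and overlap merging of paired-end reads.

Duplicates are collapsed on exact sequence identity of the pair (the
pipeline deduplicates *before* alignment, so a sequence-level criterion is
the only available one).  Merging joins read 1 with the reverse complement
of read 2 at the overlap that minimises the mismatch ratio (ties broken
toward the longer overlap); pairs without a qualifying overlap pass
through as two single reads.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .dna import encode, revcomp


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class Read:
    """A single (merged or unpaired) read."""

    read_id: str
    seq: str
    qual: str


def _phred(qual: str, offset: int = 33) -> np.ndarray:
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - offset


def _trim_one(seq: str, qual: str, window: int, mean_q: int) -> tuple[str, str]:
    # fast path: no window can fail when every base clears the threshold
    if qual and min(qual) >= chr(33 + mean_q):
        return seq, qual
    q = _phred(qual)
    n = len(q)
    if n < window:
        return (seq, qual) if (n == 0 or q.mean() >= mean_q) else ("", "")
    # mean quality of every window; cut at the start of the first failing one
    csum = np.concatenate([[0], np.cumsum(q)])
    means = (csum[window:] - csum[:-window]) / window
    bad = np.flatnonzero(means < mean_q)
    if bad.size == 0:
        return seq, qual
    cut = int(bad[0])
    return seq[:cut], qual[:cut]


def quality_trim(
    pair: ReadPair, window: int = 4, mean_q: int = 15, min_len: int = 36
) -> Optional[ReadPair]:
    """Trim 3' bases from the first sliding window whose mean quality falls
    below ``mean_q``; drop the pair if either mate ends up shorter than
    ``min_len``."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s1, q1 = _trim_one(pair.seq1, pair.qual1, window, mean_q)
    s2, q2 = _trim_one(pair.seq2, pair.qual2, window, mean_q)
    if len(s1) < min_len or len(s2) < min_len:
        return None
    if (s1, s2) == (pair.seq1, pair.seq2):
        return pair
    return ReadPair(pair.read_id, s1, s2, q1, q2)


def dedup_pairs(pairs: Iterable[ReadPair]) -> tuple[list[ReadPair], int]:
    """Collapse pairs with identical (seq1, seq2) to one representative.

    The copy with the highest mean base quality wins; ties keep the first
    encountered.  Returns (survivors in first-encounter order, number of
    duplicates removed).
    """
    best: dict[tuple[str, str], tuple[int, float, ReadPair]] = {}
    n_in = 0
    for order, pair in enumerate(pairs):
        n_in += 1
        key = (pair.seq1, pair.seq2)
        nq = len(pair.qual1) + len(pair.qual2)
        q = (sum(pair.qual1.encode()) + sum(pair.qual2.encode())) / nq if nq else 0.0
        kept = best.get(key)
        if kept is None or q > kept[1]:
            best[key] = (kept[0] if kept else order, q, pair)
    survivors = [rec[2] for rec in sorted(best.values(), key=lambda r: r[0])]
    return survivors, n_in - len(survivors)


def _resolve_overlap(
    s1_ov: str, q1_ov: str, s2_ov: str, q2_ov: str
) -> tuple[str, str]:
    """Per-base consensus of an overlap: higher quality wins, read-1 base on
    quality ties; quality is the max of the two."""
    a, b = np.frombuffer(s1_ov.encode(), np.uint8), np.frombuffer(s2_ov.encode(), np.uint8)
    qa, qb = _phred(q1_ov), _phred(q2_ov)
    take_b = (a != b) & (qb > qa)
    seq = np.where(take_b, b, a).astype(np.uint8).tobytes().decode()
    qual = np.maximum(qa, qb) + 33
    return seq, qual.astype(np.uint8).tobytes().decode()


def merge_pair(
    pair: ReadPair, min_overlap: int = 10, max_mismatch_ratio: float = 0.1
):
    """Merge one pair; returns a :class:`Read` on success, else ``None``.

    All overlap lengths between ``min_overlap`` and ``min(len1, len2)`` are
    evaluated between seq1 and reverse-complement(seq2); the qualifying
    overlap with the lowest mismatch ratio wins (longer overlap on exact
    ratio ties).
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    s1, s2 = pair.seq1, revcomp(pair.seq2)
    q2 = pair.qual2[::-1]
    l1, l2 = len(s1), len(s2)
    a1, a2 = encode(s1), encode(s2)
    best = None  # (mm, ov)
    for ov in range(min_overlap, min(l1, l2) + 1):
        mm = int(np.count_nonzero(a1[l1 - ov :] != a2[:ov]))
        if mm > max_mismatch_ratio * ov + 1e-9:
            continue
        if best is None or mm * best[1] < best[0] * ov or (
            mm * best[1] == best[0] * ov and ov > best[1]
        ):
            best = (mm, ov)
    if best is None:
        return None
    ov = best[1]
    cons_seq, cons_qual = _resolve_overlap(
        s1[l1 - ov :], pair.qual1[l1 - ov :], s2[:ov], q2[:ov]
    )
    return Read(
        pair.read_id, s1[: l1 - ov] + cons_seq + s2[ov:],
        pair.qual1[: l1 - ov] + cons_qual + q2[ov:],
    )


def merge_pairs(
    pairs: list[ReadPair], min_overlap: int = 10, max_mismatch_ratio: float = 0.1
) -> tuple[list[Read], int]:
    """Vectorised merge of many pairs.

    Returns (reads, n_merged): merged pairs contribute one read; unmerged
    pairs contribute both mates as single reads (suffix ``/1``, ``/2``).
    Decisions are identical to :func:`merge_pair` per pair.
    """
    by_shape: dict[tuple[int, int], list[int]] = {}
    for i, p in enumerate(pairs):
        by_shape.setdefault((len(p.seq1), len(p.seq2)), []).append(i)
    out: list[Optional[Read]] = [None] * len(pairs)
    merged_flag = [False] * len(pairs)
    for (l1, l2), idx in by_shape.items():
        if l1 == 0 or l2 == 0:
            continue
        a1 = np.vstack([encode(pairs[i].seq1) for i in idx])
        a2 = np.vstack([encode(revcomp(pairs[i].seq2)) for i in idx])
        n = len(idx)
        best_mm = np.zeros(n, dtype=np.int64)
        best_ov = np.zeros(n, dtype=np.int64)  # 0 = none
        for ov in range(min_overlap, min(l1, l2) + 1):
            mm = np.count_nonzero(a1[:, l1 - ov :] != a2[:, :ov], axis=1)
            ok = mm <= max_mismatch_ratio * ov + 1e-9
            better = ok & (
                (best_ov == 0)
                | (mm * best_ov < best_mm * ov)
                | ((mm * best_ov == best_mm * ov) & (ov > best_ov))
            )
            best_mm[better] = mm[better]
            best_ov[better] = ov
        for j, i in enumerate(idx):
            ov = int(best_ov[j])
            if ov == 0:
                continue
            p = pairs[i]
            s2 = revcomp(p.seq2)
            q2 = p.qual2[::-1]
            cons_seq, cons_qual = _resolve_overlap(
                p.seq1[l1 - ov :], p.qual1[l1 - ov :], s2[:ov], q2[:ov]
            )
            out[i] = Read(
                p.read_id, p.seq1[: l1 - ov] + cons_seq + s2[ov:],
                p.qual1[: l1 - ov] + cons_qual + q2[ov:],
            )
            merged_flag[i] = True
    reads: list[Read] = []
    n_merged = 0
    for i, p in enumerate(pairs):
        if merged_flag[i]:
            reads.append(out[i])
            n_merged += 1
        else:
            reads.append(Read(p.read_id + "/1", p.seq1, p.qual1))
            reads.append(Read(p.read_id + "/2", p.seq2, p.qual2))
    return reads, n_merged


def prep_sample(
    pairs: list[ReadPair],
    window: int = 4,
    mean_q: int = 15,
    min_len: int = 36,
    min_overlap: int = 10,
    max_mismatch_ratio: float = 0.1,
) -> tuple[list[Read], dict]:
    """Full preparation stage: trim -> deduplicate -> merge.

    Returns the merged + single reads and a metrics dict.
    """
    trimmed = []
    for p in pairs:
        t = quality_trim(p, window=window, mean_q=mean_q, min_len=min_len)
        if t is not None:
            trimmed.append(t)
    unique, n_dup = dedup_pairs(trimmed)
    reads, n_merged = merge_pairs(
        unique, min_overlap=min_overlap, max_mismatch_ratio=max_mismatch_ratio
    )
    metrics = {
        "input_pairs": len(pairs),
        "dropped_low_quality": len(pairs) - len(trimmed),
        "duplicates_removed": n_dup,
        "pairs_after_dedup": len(unique),
        "pairs_merged": n_merged,
        "merged_fraction": n_merged / len(unique) if unique else 0.0,
        "reads_out": len(reads),
    }
    return reads, metrics
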