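"""LTR-host chimeric read detection.

A read is chimeric when a 20-bp *bait* — the terminal 20 bp of the LTR
consensus — occurs in it at >= 90% ungapped identity (either orientation).
The host-side portion of the read (the *flank*) is extracted, the
suppression-PCR linker is stripped from its far end, flanks shorter than
10 nt are abandoned, and flanks homologous to catalogued HERV-K sequence
(LTR-gag / LTR-env amplicons from proviral interiors) are removed.

Matching is ungapped sliding-window identity: the printed contract is a
bait length and a percent identity, which an ungapped scan realises
deterministically and oracle-checkably.  The batch scanner packs windows
three bits per base into ``uint64`` (20 x 3 = 60 bits) so N, encoded as a
fifth symbol, can never match; ``match_bait`` is the single-read wrapper.

Extracted flanks are normalised to "molecule orientation": the LTR abuts
the flank's left edge and the linker (fragment end) lies at its right.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .dna import encode, revcomp
from .readprep import Read

_M3 = np.uint64(sum(1 << (3 * i) for i in range(20)))  # low bit of each 3-bit group
_MASK60 = np.uint64((1 << 60) - 1)


@dataclass
class BaitSet:
    """Terminal-LTR baits; four per LTR consensus (start/end of the 5' and
    3' LTR, identical sequences for a solo consensus)."""

    baits: dict[str, str]
    bait_len: int = 20
    min_identity: float = 0.90

    def __post_init__(self):
        if not 0.5 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0.5, 1]")
        for name, seq in self.baits.items():
            if len(seq) != self.bait_len:
                raise ValueError(f"bait {name!r} is not {self.bait_len} nt")
            if "N" in seq.upper():
                raise ValueError(f"bait {name!r} contains N")

    @property
    def names(self) -> list[str]:
        return list(self.baits)

    @property
    def max_mismatch(self) -> int:
        return int(np.floor(self.bait_len * (1 - self.min_identity) + 1e-9))

    @classmethod
    def from_consensus(cls, ltr5: str, ltr3: Optional[str] = None, bait_len: int = 20,
                       min_identity: float = 0.90) -> "BaitSet":
        ltr3 = ltr3 or ltr5
        return cls(
            baits={
                "five_prime_start": ltr5[:bait_len],
                "five_prime_end": ltr5[-bait_len:],
                "three_prime_start": ltr3[:bait_len],
                "three_prime_end": ltr3[-bait_len:],
            },
            bait_len=bait_len,
            min_identity=min_identity,
        )

    @classmethod
    def from_library(cls, consensus: dict[str, str], bait_len: int = 20,
                     min_identity: float = 0.90) -> "BaitSet":
        """Baits from every subtype consensus (older subtypes diverge from
        the youngest, so subtype-specific baits keep them detectable)."""
        baits = {}
        for subtype, seq in consensus.items():
            baits[f"{subtype}_start"] = seq[:bait_len]
            baits[f"{subtype}_end"] = seq[-bait_len:]
        return cls(baits=baits, bait_len=bait_len, min_identity=min_identity)


def bait_junction_end(bait_name: str) -> str:
    """Which junction a bait marks: an LTR-*start* bait sits at the 5'
    junction, an LTR-*end* bait at the 3' junction."""
    if bait_name.endswith("_start"):
        return "five_prime"
    if bait_name.endswith("_end"):
        return "three_prime"
    raise ValueError(f"bait name {bait_name!r} must end in _start or _end")


@dataclass
class ChimericHit:
    read_id: str
    ltr_end: str               # five_prime | three_prime
    bait_name: str
    orientation: str           # '+' bait as declared, '-' reverse complement
    read_offset: int
    identity: float
    flank_seq: Optional[str] = None
    flank_qual: Optional[str] = None


def _pack(seq_codes: np.ndarray, w: int) -> np.uint64:
    """Pack the first *w* 3-bit codes of a sequence into one uint64."""
    val = np.uint64(0)
    for c in seq_codes[:w]:
        val = np.uint64((int(val) << 3) | int(c))
    return val


def scan_reads(
    seqs: Sequence[str], baitset: BaitSet
) -> list[Optional[tuple[str, str, int, int]]]:
    """Best bait hit per read: ``(bait_name, orientation, offset,
    mismatches)`` or None.

    Every bait and its reverse complement is evaluated at every offset;
    identity is matching positions / bait_len with N never matching.  The
    maximal-identity hit wins; ties break toward the smaller offset, then
    bait declaration order (forward before reverse complement).
    """
    w = baitset.bait_len
    n = len(seqs)
    if n == 0:
        return []
    # bait-orientation list in tie-break order
    bo: list[tuple[str, str, np.uint64]] = []
    for name, seq in baitset.baits.items():
        bo.append((name, "+", _pack(encode(seq), w)))
        bo.append((name, "-", _pack(encode(revcomp(seq)), w)))
    bo_vals = np.array([v for (_, _, v) in bo], dtype=np.uint64)[:, None]
    out: list[Optional[tuple[str, str, int, int]]] = [None] * n
    # batch reads of equal length: the rolling-window scan then needs no
    # per-read padding or validity masks
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    cutoff = baitset.max_mismatch
    for length, idx in by_len.items():
        if length < w:
            continue
        codes = np.vstack([encode(seqs[i]) for i in idx])
        m = len(idx)
        best_mm = np.full(m, 255, dtype=np.uint8)
        best_bo = np.full(m, -1, dtype=np.int16)
        best_off = np.full(m, -1, dtype=np.int64)
        win = np.zeros(m, dtype=np.uint64)
        for j in range(w):
            win = (win << np.uint64(3)) | codes[:, j].astype(np.uint64)
        for off in range(length - w + 1):
            if off > 0:
                win = ((win << np.uint64(3)) & _MASK60) | codes[:, off + w - 1].astype(
                    np.uint64
                )
            x = win[None, :] ^ bo_vals               # (n_bo, m)
            nz = (x | (x >> np.uint64(1)) | (x >> np.uint64(2))) & _M3
            mm = np.bitwise_count(nz).astype(np.uint8)
            k = np.argmin(mm, axis=0)                # first index on ties
            mmin = mm[k, np.arange(m)]
            upd = mmin < best_mm
            best_mm[upd] = mmin[upd]
            best_bo[upd] = k[upd].astype(np.int16)
            best_off[upd] = off
        for jj, i in enumerate(idx):
            if best_bo[jj] >= 0 and best_mm[jj] <= cutoff:
                name, orient, _ = bo[int(best_bo[jj])]
                out[i] = (name, orient, int(best_off[jj]), int(best_mm[jj]))
    return out


def match_bait(read_seq: str, baitset: BaitSet) -> Optional[ChimericHit]:
    """Best qualifying bait hit in one read, or None (reads shorter than
    the bait count as "too short")."""
    res = scan_reads([read_seq], baitset)[0]
    if res is None:
        return None
    name, orient, off, mm = res
    return ChimericHit(
        read_id="",
        ltr_end=bait_junction_end(name),
        bait_name=name,
        orientation=orient,
        read_offset=off,
        identity=(baitset.bait_len - mm) / baitset.bait_len,
    )


def extract_flank(
    read_seq: str, read_qual: str, hit: ChimericHit, bait_len: int = 20
) -> Optional[ChimericHit]:
    """Split the read at the bait boundary and keep the host side,
    normalised to molecule orientation (LTR abutting the flank's left
    edge).  LTR-side bases are discarded.  Returns None for a zero-length
    flank."""
    off = hit.read_offset
    start_bait = hit.bait_name.endswith("_start")
    take_prefix_rc = (start_bait and hit.orientation == "+") or (
        not start_bait and hit.orientation == "-"
    )
    if take_prefix_rc:
        flank = revcomp(read_seq[:off])
        qual = read_qual[:off][::-1]
    else:
        flank = read_seq[off + bait_len :]
        qual = read_qual[off + bait_len :]
    if not flank:
        return None
    return replace(hit, flank_seq=flank, flank_qual=qual)


def strip_linker(
    hit: ChimericHit, linker_seq: str, min_flank: int = 10,
    min_overlap: int = 6, max_mismatch_ratio: float = 0.10,
) -> Optional[ChimericHit]:
    """Remove a (possibly partial) linker from the fragment end of the
    flank; drop the hit if the remaining flank is shorter than
    ``min_flank``.

    The best (longest qualifying) suffix-of-flank vs prefix-of-linker
    overlap with <= 10% mismatches over >= 6 nt is stripped.
    """
    if len(linker_seq) < 8:
        raise ValueError("linker must be >= 8 nt")
    flank = hit.flank_seq
    a = encode(flank)
    b = encode(linker_seq)
    best_ov = 0
    for ov in range(min(len(flank), len(linker_seq)), min_overlap - 1, -1):
        mm = int(np.count_nonzero(a[len(flank) - ov :] != b[:ov]))
        if mm <= max_mismatch_ratio * ov + 1e-9:
            best_ov = ov
            break
    if best_ov:
        hit = replace(
            hit,
            flank_seq=flank[: len(flank) - best_ov],
            flank_qual=hit.flank_qual[: len(flank) - best_ov],
        )
    if len(hit.flank_seq) < min_flank:
        return None
    return hit


# ---------------------------------------------------------------------------
# internal HERV-K homology filter
# ---------------------------------------------------------------------------


class HervkHomologyFilter:
    """Removes flanks with a local ungapped match to any catalogued HERV-K
    sequence at >= ``min_identity`` over >= ``min_len`` nt.

    These flanks are LTR-gag / LTR-env amplicon interiors, not host
    sequence.  Seeds are 6-mers: any 20-nt window with <= 2 mismatches
    contains at least three exact seed hits on its diagonal (pigeonhole
    over <= 3 match runs), so requiring 3 co-diagonal seed hits before the
    exact window check loses nothing within the contract.
    """

    SEED_K = 6

    def __init__(self, hervk_seqs: dict[str, str], min_identity: float = 0.90,
                 min_len: int = 20):
        if not hervk_seqs:
            raise ValueError("hervk_seqs must be non-empty")
        self.min_identity = min_identity
        self.min_len = min_len
        self.max_mm = int(np.floor(min_len * (1 - min_identity) + 1e-9))
        # worst-case number of exact co-diagonal seeds inside a qualifying
        # window: the matches split into <= max_mm+1 runs, each run of
        # length r contributing max(0, r-k+1) seeds
        self.min_diag_hits = max(
            1,
            (min_len - self.max_mm) - (self.max_mm + 1) * (self.SEED_K - 1),
        )
        parts = []
        for name in sorted(hervk_seqs):
            parts.append(hervk_seqs[name])
            parts.append(revcomp(hervk_seqs[name]))
        self.target = ("N" * 25).join(parts)
        self._tcodes = encode(self.target)
        # sentinel-padded copy so anchored window checks never index out
        self._tpad = 2 * min_len
        pad = np.full(self._tpad, 4, dtype=np.uint8)
        self._tcodes_padded = np.concatenate([pad, self._tcodes, pad])
        k = self.SEED_K
        codes = self._tcodes.astype(np.int64)
        valid = np.ones(len(codes) - k + 1, dtype=bool)
        kmer = np.zeros(len(codes) - k + 1, dtype=np.int64)
        for j in range(k):
            c = codes[j : len(codes) - k + 1 + j]
            kmer = kmer * 4 + np.where(c > 3, 0, c)
            valid &= c < 4
        order = np.argsort(kmer[valid], kind="stable")
        pos_valid = np.flatnonzero(valid)
        self._positions = pos_valid[order].astype(np.int64)
        counts = np.bincount(kmer[valid], minlength=4 ** k)
        self._indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        # fast anchors for the canonical 20-nt / 2-mismatch contract: any
        # qualifying window has an exact run >= 7, except the unique
        # (6,6,6) layout whose two leading runs sit exactly 7 apart
        self._fast = self.min_len == 20 and self.max_mm == 2
        if self._fast:
            k1 = 7
            vals7, pos7 = self._kmer_scan(self._tcodes, k1)
            counts = np.bincount(vals7, minlength=4 ** k1)
            order = np.argsort(vals7, kind="stable")
            self._pos7 = pos7[order].astype(np.int64)
            self._indptr7 = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
            vals6, pos6 = self._kmer_scan(self._tcodes, 6)
            val_at = np.full(len(self._tcodes), -1, dtype=np.int64)
            val_at[pos6] = vals6
            j = pos6[(pos6 + 7 < len(self._tcodes))]
            j = j[val_at[j + 7] >= 0]
            pv = val_at[j] * 4096 + val_at[j + 7]
            order = np.argsort(pv, kind="stable")
            self._pat_vals = pv[order]
            self._pat_pos = j[order].astype(np.int64)
            self._m3 = np.uint64(sum(1 << (3 * i) for i in range(self.min_len)))
            # target N and pad encoded as 5 so N never matches a query N (4)
            t5 = np.where(self._tcodes_padded > 3, 5, self._tcodes_padded).astype(
                np.uint8
            )
            self._twin = self._packed_windows(t5, self.min_len)

    def _kmer_scan(
        self, codes: np.ndarray, k: Optional[int] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(k-mer values, start positions) of N-free windows."""
        k = k or self.SEED_K
        n = len(codes) - k + 1
        if n <= 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        c = codes.astype(np.int64)
        valid = np.ones(n, dtype=bool)
        kmer = np.zeros(n, dtype=np.int64)
        for j in range(k):
            cj = c[j : n + j]
            kmer = kmer * 4 + np.where(cj > 3, 0, cj)
            valid &= cj < 4
        idx = np.flatnonzero(valid)
        return kmer[idx], idx

    def flags(self, flanks: Sequence[str], chunk: int = 4096) -> np.ndarray:
        """Boolean internal-homology flag per flank (vectorised).

        Flanks are packed into one padded query with N separators; seed
        hits are grouped per (flank, diagonal), and every consecutive seed
        triple that can fit inside one window anchors an exact check of
        the windows containing it.
        """
        out = np.zeros(len(flanks), dtype=bool)
        for lo in range(0, len(flanks), chunk):
            if self._fast:
                self._flag_chunk_fast(flanks[lo : lo + chunk], out[lo : lo + chunk])
            else:
                self._flag_chunk(flanks[lo : lo + chunk], out[lo : lo + chunk])
        return out

    def _pack_query(self, flanks: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        sep = "N" * (self.min_len + self.min_len - self.SEED_K)
        query = sep + sep.join(flanks) + sep
        qcodes = encode(query)
        fstarts = np.empty(len(flanks), dtype=np.int64)
        off = len(sep)
        for i, f in enumerate(flanks):
            fstarts[i] = off
            off += len(f) + len(sep)
        return qcodes, fstarts

    @staticmethod
    def _packed_windows(codes: np.ndarray, w: int) -> np.ndarray:
        """3-bit-per-base packing of every w-window (w <= 21)."""
        n = len(codes) - w + 1
        if n <= 0:
            return np.empty(0, dtype=np.uint64)
        win = np.zeros(n, dtype=np.uint64)
        for j in range(w):
            win = (win << np.uint64(3)) | codes[j : j + n].astype(np.uint64)
        return win

    def _verify_anchors(
        self,
        qwin: np.ndarray,
        w0: np.ndarray,
        t0: np.ndarray,
        n_win: np.ndarray,
    ) -> np.ndarray:
        """Exact check of each anchor: does any of its n_win candidate
        windows (query window start w0, padded-target window start t0)
        carry <= max_mm mismatches?  Works on packed windows, N never
        matches."""
        max_nwin = int(n_win.max())
        c = np.arange(max_nwin)
        x = qwin[w0[:, None] + c] ^ self._twin[t0[:, None] + c]
        nz = (x | (x >> np.uint64(1)) | (x >> np.uint64(2))) & self._m3
        mm = np.bitwise_count(nz)
        valid = c[None, :] < n_win[:, None]
        return ((mm <= self.max_mm) & valid).any(axis=1)

    def _flag_chunk_fast(self, flanks: Sequence[str], out: np.ndarray) -> None:
        w = self.min_len
        k1 = 7
        qcodes, fstarts = self._pack_query(flanks)
        anchors_qp: list[np.ndarray] = []
        anchors_tp: list[np.ndarray] = []
        anchors_nw: list[np.ndarray] = []
        # pass 1: exact 7-mer runs
        vals, qpos = self._kmer_scan(qcodes, k1)
        if vals.size:
            starts = self._indptr7[vals]
            lens = self._indptr7[vals + 1] - starts
            total = int(lens.sum())
            if total:
                rep = np.repeat(np.arange(vals.size), lens)
                within = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
                tpos = self._pos7[starts[rep] + within]
                qp = qpos[rep]
                # necessary condition: a qualifying window around the 7-mer
                # keeps one 6-base adjacency (left or right) almost clean,
                # so most chance anchors can be dropped before full verify
                offs6 = np.arange(6)
                lq = qcodes[(qp - 6)[:, None] + offs6]
                lt = self._tcodes_padded[(tpos - 6 + self._tpad)[:, None] + offs6]
                rq = qcodes[(qp + k1)[:, None] + offs6]
                rt = self._tcodes_padded[(tpos + k1 + self._tpad)[:, None] + offs6]
                mm_l = ((lq != lt) | (lq > 3)).sum(axis=1)
                mm_r = ((rq != rt) | (rq > 3)).sum(axis=1)
                keep = np.minimum(mm_l, mm_r) <= self.max_mm
                qp, tpos = qp[keep], tpos[keep]
                if qp.size:
                    anchors_qp.append(qp + k1 - w)
                    anchors_tp.append(tpos + k1 - w)
                    anchors_nw.append(np.full(qp.size, w - k1 + 1, dtype=np.int64))
        # pass 2: the (6,6,6) layout via a gapped 6+6 seed at spacing 7
        vals6, qpos6 = self._kmer_scan(qcodes, 6)
        if vals6.size:
            val_at = np.full(len(qcodes), -1, dtype=np.int64)
            val_at[qpos6] = vals6
            j = qpos6[qpos6 + 7 < len(qcodes)]
            j = j[val_at[j + 7] >= 0]
            if j.size:
                pv = val_at[j] * 4096 + val_at[j + 7]
                lo = np.searchsorted(self._pat_vals, pv, side="left")
                hi = np.searchsorted(self._pat_vals, pv, side="right")
                lens = hi - lo
                total = int(lens.sum())
                if total:
                    rep = np.repeat(np.arange(j.size), lens)
                    within = np.arange(total) - np.repeat(
                        np.cumsum(lens) - lens, lens
                    )
                    tpos = self._pat_pos[lo[rep] + within]
                    anchors_qp.append(j[rep])
                    anchors_tp.append(tpos)
                    anchors_nw.append(np.ones(total, dtype=np.int64))
        if not anchors_qp:
            return
        w0 = np.concatenate(anchors_qp)
        tp = np.concatenate(anchors_tp)
        nw = np.concatenate(anchors_nw)
        qwin = self._packed_windows(qcodes, w)
        hit = self._verify_anchors(qwin, w0, tp + self._tpad, nw)
        if hit.any():
            fid = np.searchsorted(fstarts, w0[hit] + w - 1, side="right") - 1
            out[np.unique(fid)] = True

    def _flag_chunk(self, flanks: Sequence[str], out: np.ndarray) -> None:
        k = self.SEED_K
        w = self.min_len
        span = w - k  # max distance between first/last seed start in a window
        sep = "N" * (w + span)
        query = sep + sep.join(flanks) + sep
        qcodes = encode(query)
        fstarts = np.empty(len(flanks), dtype=np.int64)
        off = len(sep)
        for i, f in enumerate(flanks):
            fstarts[i] = off
            off += len(f) + len(sep)
        kmers, qpos = self._kmer_scan(qcodes)
        if kmers.size == 0:
            return
        starts = self._indptr[kmers]
        lens = self._indptr[kmers + 1] - starts
        total = int(lens.sum())
        if total == 0:
            return
        rep = np.repeat(np.arange(kmers.size), lens)
        within = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        tpos = self._tpad + self._positions[starts[rep] + within]
        qp = qpos[rep]
        fid = np.searchsorted(fstarts, qp, side="right") - 1
        diag = tpos - qp
        order = np.lexsort((qp, diag, fid))
        qp = qp[order]
        diag = diag[order]
        fid = fid[order]
        if qp.size < self.min_diag_hits:
            return
        h = self.min_diag_hits
        same_run = (diag[h - 1 :] == diag[: qp.size - h + 1]) & (
            fid[h - 1 :] == fid[: qp.size - h + 1]
        )
        anchors = np.flatnonzero(
            same_run & (qp[h - 1 :] - qp[: qp.size - h + 1] <= span)
        )
        if anchors.size == 0:
            return
        # window starts for anchor i range over [q_last + k - w, q_first];
        # verify all of them on the (padded) target diagonal
        q_first = qp[anchors]
        q_last = qp[anchors + h - 1]
        w0 = q_last + k - w
        n_win = q_first - w0 + 1          # <= span + 1
        width = w + span
        offs = np.arange(width)
        qm = qcodes[w0[:, None] + offs]
        tm = self._tcodes_padded[(w0 + diag[anchors])[:, None] + offs]
        mism = ((qm != tm) | (qm > 3) | (tm > 3)).astype(np.int16)
        csum = np.zeros((anchors.size, width + 1), dtype=np.int16)
        np.cumsum(mism, axis=1, out=csum[:, 1:])
        win_mm = csum[:, w:] - csum[:, :-w]  # columns = window offsets 0..span
        col = np.arange(span + 1)
        valid = col[None, :] < n_win[:, None]
        hit = ((win_mm <= self.max_mm) & valid).any(axis=1)
        out[np.unique(fid[anchors[hit]])] = True

    def is_internal(self, flank: str) -> bool:
        return bool(self.flags([flank])[0])


def filter_internal_hervk(
    hits: Iterable[ChimericHit], hervk_seqs: dict[str, str],
    min_identity: float = 0.90, min_len: int = 20,
) -> tuple[list[ChimericHit], int]:
    """Partition hits into (survivors, n_removed) by HERV-K homology."""
    filt = HervkHomologyFilter(hervk_seqs, min_identity=min_identity, min_len=min_len)
    hits = list(hits)
    internal = filt.flags([h.flank_seq for h in hits])
    survivors = [h for h, bad in zip(hits, internal) if not bad]
    return survivors, int(internal.sum())


# ---------------------------------------------------------------------------
# stage driver
# ---------------------------------------------------------------------------


def find_chimeras(
    reads: Sequence[Read],
    baitset: BaitSet,
    linker_seq: str,
    hervk_seqs: Optional[dict[str, str]] = None,
    min_flank: int = 10,
) -> tuple[list[ChimericHit], dict]:
    """Full chimera stage on merged + single reads.

    Returns surviving hits (flank filled, linker stripped, internal
    homology removed) and stage metrics.
    """
    seqs = [r.seq for r in reads]
    results = scan_reads(seqs, baitset)
    metrics = {
        "reads_in": len(reads),
        "too_short": sum(1 for s in seqs if len(s) < baitset.bait_len),
        "no_bait": 0,
        "zero_length_flank": 0,
        "short_flank_dropped": 0,
        "internal_hervk_removed": 0,
        "chimeric_out": 0,
    }
    hits: list[ChimericHit] = []
    for read, res in zip(reads, results):
        if res is None:
            metrics["no_bait"] += 1
            continue
        name, orient, off, mm = res
        hit = ChimericHit(
            read_id=read.read_id,
            ltr_end=bait_junction_end(name),
            bait_name=name,
            orientation=orient,
            read_offset=off,
            identity=(baitset.bait_len - mm) / baitset.bait_len,
        )
        hit = extract_flank(read.seq, read.qual, hit, bait_len=baitset.bait_len)
        if hit is None:
            metrics["zero_length_flank"] += 1
            continue
        hit = strip_linker(hit, linker_seq, min_flank=min_flank)
        if hit is None:
            metrics["short_flank_dropped"] += 1
            continue
        hits.append(hit)
    if hervk_seqs:
        hits, removed = filter_internal_hervk(hits, hervk_seqs)
        metrics["internal_hervk_removed"] = removed
    metrics["chimeric_out"] = len(hits)
    metrics["no_bait"] -= metrics["too_short"]
    return hits, metrics
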