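"""Simulator for LTR-targeted enrichment sequencing of HERV-K (HML-2).

Emulates the wet-lab phases of the protocol on a synthetic genome:

* a background genome (optionally carrying repeated cassettes) into which
  proviruses and solo LTRs are inserted with a target-site duplication
  (TSD), point mutations accumulating with element age, and diploid
  presence/absence genotypes across individuals;
* random enzymatic fragmentation, ligation of a suppression-PCR linker,
  selection of fragments that carry an LTR terminus with a primer site
  (primer mismatches down-weight amplification through a logistic curve),
  250-450 bp size selection, and paired-end sequencing with a flat
  per-base error rate and a configurable PCR-duplicate fraction.

Every emitted read carries a truth tag in its name
(``...|ins=<locus>|end=<five_prime|three_prime>|cls=<host|internal|bg>``)
so that downstream stages can be scored without side-channel files.

Each library molecule is generated in a fixed "molecule orientation":
``[LTR terminus (ending at the LTR edge)] + [host or internal flank] +
[linker]``.  Proviruses additionally yield LTR-gag / LTR-env molecules
(``cls=internal``) because the two LTRs of a provirus are near-identical
and both anneal each primer group.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .catalog import Catalog, LocusRecord
from .dna import mutate, random_seq, revcomp, hamming
from .readprep import ReadPair

GENOTYPES = ("absent", "het", "hom")

# Internal seed for the synthetic sequence library (LTR consensi, internal
# segment, linker, cassette).  Fixed so that every run of the package sees
# the same element sequences; experiment-level randomness is separate.
_LIBRARY_SEED = 52


@dataclass
class LtrLibrary:
    """Synthetic consensus sequences standing in for the real element
    sequence set (which is genome-build specific and not shipped)."""

    consensus: dict[str, str]       # subtype -> LTR consensus
    internal: str                   # gag/pol/env stand-in (desk scale)
    ltr_len: int

    @property
    def reference_seqs(self) -> dict[str, str]:
        """All catalogued element sequences, for the internal-homology filter."""
        seqs = dict(self.consensus)
        seqs["HERVK-int"] = self.internal
        return seqs


def default_ltr_library(ltr_len: int = 968, internal_len: int = 2000) -> LtrLibrary:
    """Deterministic synthetic LTR consensi.

    LTR5_Hs is the base consensus; LTR5A and LTR5B diverge from it by ~4%
    and ~8% to mimic the subtype ladder (LTR5B oldest).  The internal
    segment is shorter than a real provirus interior; only its junctions
    matter at desk scale.
    """
    rng = np.random.default_rng(_LIBRARY_SEED)
    hs = random_seq(rng, ltr_len)
    return LtrLibrary(
        consensus={
            "LTR5_Hs": hs,
            "LTR5A": mutate(hs, 0.04, rng),
            "LTR5B": mutate(hs, 0.08, rng),
        },
        internal=random_seq(rng, internal_len),
        ltr_len=ltr_len,
    )


def default_linker(length: int = 25) -> str:
    rng = np.random.default_rng(_LIBRARY_SEED + 1)
    return random_seq(rng, length)


@dataclass
class ProtocolParams:
    """Wet-lab protocol parameters.

    ``ltr_carry`` is the number of LTR bases carried on each amplicon
    (primer offset from the LTR edge); the primer anneals to the inner
    ``primer_len`` bases of that carried stretch, and mismatches between an
    element's aged LTR and the consensus primer reduce its amplification
    weight via ``1 / (1 + exp(k (m - m0)))``.
    """

    fragment_len_mean: int = 330
    fragment_len_sd: int = 60
    size_select_min: int = 250
    size_select_max: int = 450
    read_len: int = 150
    seq_error_rate: float = 0.001
    pcr_duplicate_rate: float = 0.15
    linker_seq: str = field(default_factory=default_linker)
    ltr_carry: int = 55
    primer_len: int = 25
    primer_5ltr: Optional[str] = None   # filled from the LTR consensus
    primer_3ltr: Optional[str] = None
    ltr_mutation_rate_per_mya: float = 0.0023
    depth_reads: int = 100_000
    off_target_fraction: float = 0.2
    logistic_k: float = 2.0
    logistic_m0: float = 3.0

    def validate(self) -> None:
        if not self.size_select_min < self.size_select_max:
            raise ValueError("size_select_min must be < size_select_max")
        if self.read_len > self.size_select_max:
            raise ValueError("read_len must be <= size_select_max")
        if not 0 <= self.pcr_duplicate_rate < 1:
            raise ValueError("pcr_duplicate_rate must be in [0, 1)")
        if len(self.linker_seq) < 8:
            raise ValueError("linker_seq must be >= 8 nt")
        if self.primer_len > self.ltr_carry:
            raise ValueError("primer_len must be <= ltr_carry")

    def resolve_primers(self, lib: LtrLibrary) -> None:
        """Default primers: the annealing stretches of the youngest-subtype
        consensus just inside each LTR terminus."""
        cons = lib.consensus["LTR5_Hs"]
        if self.primer_5ltr is None:
            self.primer_5ltr = cons[self.ltr_carry - self.primer_len : self.ltr_carry]
        if self.primer_3ltr is None:
            self.primer_3ltr = cons[-self.ltr_carry : -self.ltr_carry + self.primer_len]


@dataclass
class InsertionSpec:
    """One planned integration event in the synthetic genome."""

    locus_id: str
    contig: str
    site: int                      # 0-based insertion point in the background
    element_type: str = "solo_LTR"  # provirus | solo_LTR
    ltr_subtype: str = "LTR5_Hs"
    age_mya: float = 1.0
    tsd_len: int = 6
    strand: str = "+"
    in_reference_sequence: bool = True
    in_repeat: bool = False
    allele_frequency: float = 1.0
    catalogued: bool = True         # False for planted novel loci

    def validate(self) -> None:
        if self.tsd_len < 0 or self.tsd_len > 20:
            raise ValueError(f"{self.locus_id}: tsd_len must be in [0, 20]")
        if self.age_mya < 0:
            raise ValueError(f"{self.locus_id}: negative age")
        if not 0 < self.allele_frequency <= 1:
            raise ValueError(f"{self.locus_id}: allele_frequency outside (0, 1]")
        if self.element_type not in ("provirus", "solo_LTR"):
            raise ValueError(f"{self.locus_id}: bad element_type")


@dataclass
class TruthManifest:
    """Ground truth for a simulated study."""

    individuals: list[str]
    n_replicates: int
    insertions: list[InsertionSpec]
    genotypes: dict[tuple[str, str], str]  # (individual, locus_id) -> genotype
    seed: int
    protocol_params: Optional[ProtocolParams] = None
    # filled by build_genome:
    ref_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    element_seqs: dict[str, str] = field(default_factory=dict)
    # filled by simulate_reads: sample_id -> stats
    sample_stats: dict[str, dict] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{ind}{rep}"
            for ind in self.individuals
            for rep in range(1, self.n_replicates + 1)
        ]

    def individual_of(self, sample_id: str) -> str:
        for ind in sorted(self.individuals, key=len, reverse=True):
            if sample_id.startswith(ind):
                return ind
        raise KeyError(sample_id)

    def present(self, individual: str, locus_id: str) -> bool:
        return self.genotypes.get((individual, locus_id), "absent") != "absent"

    def carriers(self, locus_id: str) -> list[str]:
        return [i for i in self.individuals if self.present(i, locus_id)]


def design_experiment(
    insertions: list[InsertionSpec],
    n_individuals: int,
    n_replicates: int,
    polymorphic_fraction: float,
    seed: int,
) -> TruthManifest:
    """Assign diploid presence/absence genotypes.

    A ``polymorphic_fraction`` of the insertions is drawn as polymorphic;
    their genotypes follow each spec's allele frequency, redrawn until at
    least one discordant individual pair exists.  Fixed loci are
    homozygous-present in everyone.  Replicates share genotypes.
    """
    if not 0 <= polymorphic_fraction <= 1:
        raise ValueError("polymorphic_fraction must be in [0, 1]")
    if n_individuals < 2 and polymorphic_fraction > 0:
        raise ValueError(
            "polymorphic loci need >= 2 individuals for a presence/absence contrast"
        )
    rng = np.random.default_rng(seed)
    individuals = [chr(ord("A") + i) for i in range(n_individuals)]
    n_poly = int(round(polymorphic_fraction * len(insertions)))
    poly_idx = set(map(int, rng.choice(len(insertions), size=n_poly, replace=False)))
    genotypes: dict[tuple[str, str], str] = {}
    for i, spec in enumerate(insertions):
        if i not in poly_idx:
            for ind in individuals:
                genotypes[(ind, spec.locus_id)] = "hom"
            continue
        af = min(spec.allele_frequency, 0.9)  # keep absence reachable
        for _ in range(200):
            gts = []
            for _ind in individuals:
                n_alleles = int(rng.random() < af) + int(rng.random() < af)
                gts.append(GENOTYPES[min(n_alleles, 2)] if n_alleles else "absent")
            present = [g != "absent" for g in gts]
            if any(present) and not all(present):
                break
        else:
            gts = ["hom"] + ["absent"] * (n_individuals - 1)
        for ind, g in zip(individuals, gts):
            genotypes[(ind, spec.locus_id)] = g
    return TruthManifest(
        individuals=individuals,
        n_replicates=n_replicates,
        insertions=insertions,
        genotypes=genotypes,
        seed=int(seed),
    )


def _insertion_rng(seed: int, locus_id: str) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(locus_id.encode())])


class GenomeBuild:
    """Synthetic genomes for one study: background, reference assembly, and
    per-individual haplotypes, plus realized element coordinates."""

    def __init__(
        self,
        background: dict[str, str],
        manifest: TruthManifest,
        lib: LtrLibrary,
        repeat_intervals: list[tuple[str, int, int]],
    ):
        self.background = background
        self.manifest = manifest
        self.lib = lib
        self.repeat_intervals = repeat_intervals
        self.reference: dict[str, str] = {}
        self.ltr_annotation: list[tuple[str, int, int]] = []
        self._hap_cache: dict[tuple[str, int], dict] = {}
        self._build_reference()

    # -- construction -----------------------------------------------------

    def _specs_on(self, contig: str, which) -> list[InsertionSpec]:
        return sorted(
            (s for s in self.manifest.insertions if s.contig == contig and which(s)),
            key=lambda s: s.site,
        )

    def _apply(self, contig: str, specs: list[InsertionSpec]):
        """Insert elements into a background contig.

        Returns (sequence, {locus_id: (elem_start, elem_end)}).  An
        insertion at background site ``s`` with TSD length ``d`` yields
        ``bg[:s] + ELEM + bg[s-d:]`` (the ``d`` bases left of the site are
        duplicated after the element).
        """
        bg = self.background[contig]
        out: list[str] = []
        coords: dict[str, tuple[int, int]] = {}
        prev = 0
        length = 0
        for spec in specs:
            elem = self.manifest.element_seqs[spec.locus_id]
            if spec.strand == "-":
                elem = revcomp(elem)
            out.append(bg[prev : spec.site])
            length += spec.site - prev
            coords[spec.locus_id] = (length, length + len(elem))
            out.append(elem)
            length += len(elem)
            prev = spec.site - spec.tsd_len  # re-emit the TSD after the element
        out.append(bg[prev:])
        return "".join(out), coords

    def _build_reference(self) -> None:
        man = self.manifest
        rate = (
            man.protocol_params.ltr_mutation_rate_per_mya
            if man.protocol_params
            else 0.0023
        )
        for spec in man.insertions:
            spec.validate()
            if spec.site - spec.tsd_len < 500 or spec.site > len(
                self.background[spec.contig]
            ) - 500:
                raise ValueError(f"{spec.locus_id}: site too close to contig edge")
            if spec.locus_id not in man.element_seqs:
                rng = _insertion_rng(man.seed, spec.locus_id)
                cons = self.lib.consensus[spec.ltr_subtype]
                mu = rate * spec.age_mya
                if spec.element_type == "solo_LTR":
                    elem = mutate(cons, mu, rng)
                else:
                    # the two LTR copies of a provirus diverge independently
                    elem = (
                        mutate(cons, mu, rng)
                        + mutate(self.lib.internal, mu, rng)
                        + mutate(cons, mu, rng)
                    )
                man.element_seqs[spec.locus_id] = elem
        # overlapping insertions / minimum spacing
        for contig in self.background:
            specs = self._specs_on(contig, lambda s: True)
            for a, b in zip(specs, specs[1:]):
                if b.site - a.site < 1000:
                    raise ValueError(
                        f"insertions {a.locus_id} and {b.locus_id} closer than 1 kb"
                    )
        for contig in self.background:
            ref_specs = self._specs_on(contig, lambda s: s.in_reference_sequence)
            seq, coords = self._apply(contig, ref_specs)
            self.reference[contig] = seq
            offset_specs = ref_specs
            for spec in ref_specs:
                lo, hi = coords[spec.locus_id]
                self.manifest.ref_intervals[spec.locus_id] = (contig, lo, hi)
                self.ltr_annotation.append((contig, lo, hi))
            # non-reference loci: TSD footprint in reference coordinates
            for spec in self._specs_on(contig, lambda s: not s.in_reference_sequence):
                off = sum(
                    len(self.manifest.element_seqs[r.locus_id]) + r.tsd_len
                    for r in offset_specs
                    if r.site < spec.site
                )
                s_ref = spec.site + off
                lo = s_ref - max(spec.tsd_len, 1)
                self.manifest.ref_intervals[spec.locus_id] = (contig, lo, s_ref)

    # -- haplotypes --------------------------------------------------------

    def haplotype(self, individual: str, hap: int) -> dict:
        """Sequence and element coordinates of one haplotype.

        Heterozygous insertions ride on haplotype 0 by convention.
        """
        key = (individual, hap)
        if key not in self._hap_cache:
            def carried(spec: InsertionSpec) -> bool:
                g = self.manifest.genotypes.get((individual, spec.locus_id), "absent")
                return g == "hom" or (g == "het" and hap == 0)

            seqs: dict[str, str] = {}
            coords: dict[str, tuple[str, int, int]] = {}
            for contig in self.background:
                seq, c = self._apply(contig, self._specs_on(contig, carried))
                seqs[contig] = seq
                for lid, (lo, hi) in c.items():
                    coords[lid] = (contig, lo, hi)
            self._hap_cache[key] = {"seqs": seqs, "coords": coords}
        return self._hap_cache[key]


def make_background(
    n_contigs: int,
    contig_len: int,
    seed: int,
    cassette_groups: int = 0,
    cassette_len: int = 2000,
    cassette_copies: int = 3,
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Random background contigs, optionally carrying groups of identical
    repeated cassettes (all copies of a group on contig 1, spaced out)."""
    rng = np.random.default_rng(seed)
    contigs = {f"ctg{i + 1}": random_seq(rng, contig_len) for i in range(n_contigs)}
    repeat_intervals: list[tuple[str, int, int]] = []
    if cassette_groups:
        name = "ctg1"
        seq = list(contigs[name])
        pos = contig_len // (cassette_groups * cassette_copies + 1)
        step = pos
        for g in range(cassette_groups):
            cassette = random_seq(rng, cassette_len)
            for _c in range(cassette_copies):
                seq[pos : pos + cassette_len] = cassette
                repeat_intervals.append((name, pos, pos + cassette_len))
                pos += step
        contigs[name] = "".join(seq)
    return contigs, repeat_intervals


def build_genome(
    n_contigs: int,
    contig_len: int,
    insertions: list[InsertionSpec],
    seed: int,
    manifest: Optional[TruthManifest] = None,
    lib: Optional[LtrLibrary] = None,
    params: Optional[ProtocolParams] = None,
    cassette_groups: int = 0,
) -> GenomeBuild:
    """Build background, reference assembly, and haplotype machinery.

    Without an explicit manifest all insertions are treated as fixed
    (single individual, homozygous)."""
    lib = lib or default_ltr_library()
    params = params or ProtocolParams()
    params.resolve_primers(lib)
    if manifest is None:
        manifest = design_experiment(insertions, 1, 1, 0.0, seed)
    manifest.protocol_params = params
    background, repeats = make_background(
        n_contigs, contig_len, seed, cassette_groups=cassette_groups
    )
    return GenomeBuild(background, manifest, lib, repeats)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _logistic_weight(m: int, params: ProtocolParams) -> float:
    return 1.0 / (1.0 + np.exp(params.logistic_k * (m - params.logistic_m0)))


@dataclass
class _Junction:
    locus_id: str
    end: str          # five_prime | three_prime (primer group)
    cls: str          # host | internal
    ltr_part: str     # molecule prefix, ends at the LTR edge
    flank_src: str    # molecule-oriented flank context (>= max flank length)
    weight: float


def _junctions_for_hap(
    build: GenomeBuild, individual: str, hap: int, params: ProtocolParams
) -> list[_Junction]:
    lib = build.lib
    man = build.manifest
    ctx = 400
    out: list[_Junction] = []
    hapinfo = build.haplotype(individual, hap)
    for spec in man.insertions:
        if spec.locus_id not in hapinfo["coords"]:
            continue
        contig, lo, hi = hapinfo["coords"][spec.locus_id]
        hap_seq = hapinfo["seqs"][contig]
        elem = man.element_seqs[spec.locus_id]  # element-local orientation
        if spec.strand == "+":
            up_local = hap_seq[max(lo - ctx, 0) : lo]
            down_local = hap_seq[hi : hi + ctx]
        else:
            up_local = revcomp(hap_seq[hi : hi + ctx])
            down_local = revcomp(hap_seq[max(lo - ctx, 0) : lo])
        L = lib.ltr_len
        carry = params.ltr_carry
        if spec.element_type == "solo_LTR":
            ltr5 = ltr3 = elem
        else:
            ltr5, ltr3 = elem[:L], elem[-L:]
        m5 = hamming(ltr5[carry - params.primer_len : carry], params.primer_5ltr)
        m3 = hamming(ltr3[-carry : -carry + params.primer_len], params.primer_3ltr)
        # molecule = revcomp(up_local[-lf:] + ltr_head) + linker, i.e. the
        # reverse-complemented LTR head followed by revcomp(up_local)[:lf]
        out.append(
            _Junction(
                spec.locus_id, "five_prime", "host",
                revcomp(ltr5[:carry]), revcomp(up_local), _logistic_weight(m5, params),
            )
        )
        out.append(
            _Junction(
                spec.locus_id, "three_prime", "host",
                ltr3[-carry:], down_local, _logistic_weight(m3, params),
            )
        )
        if spec.element_type == "provirus":
            internal = elem[L : len(elem) - L]
            m5i = hamming(ltr3[carry - params.primer_len : carry], params.primer_5ltr)
            m3i = hamming(ltr5[-carry : -carry + params.primer_len], params.primer_3ltr)
            out.append(
                _Junction(
                    spec.locus_id, "five_prime", "internal",
                    revcomp(ltr3[:carry]), revcomp(internal[-ctx:]),
                    _logistic_weight(m5i, params),
                )
            )
            out.append(
                _Junction(
                    spec.locus_id, "three_prime", "internal",
                    ltr5[-carry:], internal[:ctx], _logistic_weight(m3i, params),
                )
            )
    return out


def _draw_fragment_lengths(
    rng: np.random.Generator, n: int, params: ProtocolParams
) -> np.ndarray:
    """Genomic-fragment lengths passing size selection (molecule = fragment
    + linker must fall in [size_select_min, size_select_max])."""
    lo = params.size_select_min - len(params.linker_seq)
    hi = params.size_select_max - len(params.linker_seq)
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.normal(params.fragment_len_mean, params.fragment_len_sd, 2 * n + 16)
        draw = np.rint(draw).astype(np.int64)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out = np.concatenate([out, keep])
    return out[:n]


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    return mutate(seq, rate, rng) if rate > 0 else seq


def simulate_reads(
    build: GenomeBuild,
    sample_id: str,
    individual: str,
    params: ProtocolParams,
    depth: int,
    seed: int,
) -> list[ReadPair]:
    """Simulate one sample's paired-end library.

    ``depth`` is the number of read pairs before PCR duplication; truth
    tags ride in the read names.  Per-sample statistics (distinct molecule
    counts, molecules per insertion) are recorded in the manifest.
    """
    if depth <= 0:
        raise ValueError("requested depth must be > 0")
    params.validate()
    rng = np.random.default_rng(
        [build.manifest.seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode()), int(seed) & 0x7FFFFFFF]
    )
    junctions: list[_Junction] = []
    for hap in (0, 1):
        junctions.extend(_junctions_for_hap(build, individual, hap, params))
    n_off = int(round(depth * params.off_target_fraction))
    n_target = depth - n_off if junctions else 0
    n_off = depth - n_target
    qline = chr(33 + 37)
    molecules: list[tuple[str, str]] = []  # (name-tag, molecule sequence)
    per_insertion: dict[str, int] = {}
    distinct: set[tuple] = set()  # distinguishable fragments (haplotype-agnostic)
    if n_target:
        w = np.array([j.weight for j in junctions])
        picks = rng.choice(len(junctions), size=n_target, p=w / w.sum())
        frags = _draw_fragment_lengths(rng, n_target, params)
        carry = params.ltr_carry
        for j_idx, frag in zip(picks, frags):
            jn = junctions[j_idx]
            lf = int(frag) - carry
            if lf < 1 or lf > len(jn.flank_src):
                continue
            mol = jn.ltr_part + jn.flank_src[:lf] + params.linker_seq
            tag = f"ins={jn.locus_id}|end={jn.end}|cls={jn.cls}"
            molecules.append((tag, mol))
            per_insertion[jn.locus_id] = per_insertion.get(jn.locus_id, 0) + 1
            distinct.add((jn.locus_id, jn.end, jn.cls, lf))
    if n_off:
        contigs = list(build.background)
        lens = np.array([len(build.background[c]) for c in contigs], dtype=float)
        ci = rng.choice(len(contigs), size=n_off, p=lens / lens.sum())
        frags = _draw_fragment_lengths(rng, n_off, params)
        strands = rng.random(n_off) < 0.5
        for k in range(n_off):
            contig = contigs[int(ci[k])]
            seq = build.background[contig]
            fl = int(frags[k])
            pos = int(rng.integers(0, max(len(seq) - fl, 1)))
            frag = seq[pos : pos + fl]
            if strands[k]:
                frag = revcomp(frag)
            molecules.append(("ins=.|end=.|cls=bg", frag + params.linker_seq))
            distinct.add(("bg", contig, pos, bool(strands[k]), fl))
    # PCR duplication: a fraction of molecules is emitted twice
    emit: list[tuple[str, str]] = list(molecules)
    if params.pcr_duplicate_rate > 0 and molecules:
        dup_mask = rng.random(len(molecules)) < params.pcr_duplicate_rate
        emit += [molecules[i] for i in np.flatnonzero(dup_mask)]
    pairs: list[ReadPair] = []
    rl = params.read_len
    for i, (tag, mol) in enumerate(emit):
        r1 = _apply_errors(mol[:rl], params.seq_error_rate, rng)
        r2 = _apply_errors(revcomp(mol[-rl:]), params.seq_error_rate, rng)
        pairs.append(
            ReadPair(f"{sample_id}:{i}|{tag}", r1, r2, qline * len(r1), qline * len(r2))
        )
    # warn about present insertions that produced no amplifiable molecule
    missing = [
        s.locus_id
        for s in build.manifest.insertions
        if build.manifest.present(individual, s.locus_id)
        and s.locus_id not in per_insertion
    ]
    if missing:
        import logging

        logging.getLogger(__name__).warning(
            "%s: no amplifiable molecule for present insertions: %s",
            sample_id, ", ".join(missing),
        )
    build.manifest.sample_stats[sample_id] = {
        "individual": individual,
        "depth": depth,
        "n_molecules": len(molecules),
        "n_distinct_molecules": len(distinct),
        "n_read_pairs": len(pairs),
        "per_insertion_molecules": per_insertion,
    }
    return pairs


# ---------------------------------------------------------------------------
# study-level conveniences
# ---------------------------------------------------------------------------

_SUBTYPE_CYCLE = ("LTR5_Hs", "LTR5_Hs", "LTR5A", "LTR5_Hs", "LTR5B", "LTR5A")
_SUBTYPE_AGE = {"LTR5_Hs": (0.5, 10.0), "LTR5A": (8.0, 25.0), "LTR5B": (18.0, 35.0)}


def make_insertion_panel(
    contigs: dict[str, int],
    seed: int,
    n_solo: int = 20,
    n_provirus: int = 5,
    n_nonref: int = 3,
    n_novel_ref: int = 1,
    n_novel_nonref: int = 1,
    repeat_sites: Iterable[tuple[str, int]] = (),
    tsd_len: int = 6,
    age_range: Optional[tuple[float, float]] = None,
    spacing: int = 4000,
    allele_frequency: float = 0.6,
) -> list[InsertionSpec]:
    """A deterministic locus panel for a simulated study.

    Loci are laid left-to-right across the given contigs at ``spacing``
    intervals (plus jitter), far enough apart that planted novel loci sit
    well beyond the 2-kb novelty distance from catalogued ones.  Ages are
    drawn per subtype (young LTR5_Hs through old LTR5B) unless a flat
    ``age_range`` is forced.  ``repeat_sites`` plants additional catalogued
    solo LTRs at the given (contig, site) positions, flagged ``in_repeat``.
    """
    rng = np.random.default_rng(seed)
    names = list(contigs)
    cursors = {c: 2000 for c in names}
    order: list[tuple[str, dict]] = []
    for i in range(n_solo):
        order.append(("solo", {}))
    for i in range(n_provirus):
        order.append(("provirus", {}))
    for i in range(n_nonref):
        order.append(("nonref", {}))
    for i in range(n_novel_ref):
        order.append(("novel_ref", {}))
    for i in range(n_novel_nonref):
        order.append(("novel_nonref", {}))
    rng.shuffle(order)
    specs: list[InsertionSpec] = []
    counters = {k: 0 for k in ("solo", "provirus", "nonref", "novel_ref", "novel_nonref")}
    ci = 0
    for kind, _ in order:
        # find a contig with room
        for _try in range(len(names)):
            contig = names[ci % len(names)]
            ci += 1
            if cursors[contig] + spacing < contigs[contig] - 2500:
                break
        else:
            raise ValueError("panel does not fit on the given contigs")
        site = cursors[contig] + int(rng.integers(0, 500))
        cursors[contig] = site + spacing
        counters[kind] += 1
        n = counters[kind]
        subtype = _SUBTYPE_CYCLE[(len(specs)) % len(_SUBTYPE_CYCLE)]
        if age_range is not None:
            age = float(rng.uniform(*age_range))
        else:
            age = float(rng.uniform(*_SUBTYPE_AGE[subtype]))
        strand = "+" if len(specs) % 2 == 0 else "-"
        common = dict(
            contig=contig, site=site, ltr_subtype=subtype, age_mya=round(age, 2),
            tsd_len=tsd_len, strand=strand, allele_frequency=allele_frequency,
        )
        if kind == "solo":
            specs.append(InsertionSpec(f"solo-LTR{n:03d}", **common))
        elif kind == "provirus":
            specs.append(InsertionSpec(f"prov{n:02d}", element_type="provirus", **common))
        elif kind == "nonref":
            specs.append(
                InsertionSpec(f"NR{n:02d}", in_reference_sequence=False, **common)
            )
        elif kind == "novel_ref":
            specs.append(
                InsertionSpec(f"novelR{n:02d}", catalogued=False, **common)
            )
        else:
            specs.append(
                InsertionSpec(
                    f"novelN{n:02d}", catalogued=False,
                    in_reference_sequence=False, **common,
                )
            )
    for k, (contig, site) in enumerate(repeat_sites, start=1):
        specs.append(
            InsertionSpec(
                f"rep-solo{k:02d}", contig=contig, site=site,
                ltr_subtype="LTR5_Hs", age_mya=2.0, tsd_len=tsd_len,
                strand="+", in_repeat=True,
            )
        )
    return specs


def catalog_from_manifest(
    manifest: TruthManifest, include_novel: bool = False
) -> Catalog:
    """Derive a locus catalog (reference-assembly coordinates) from the
    simulation ground truth.

    Catalogued loci become ``reference`` / ``non_reference`` records;
    planted novel loci are included only on request, as ``novel_*``.
    Reference records span the element; non-reference records span the TSD
    footprint.
    """
    records = []
    for spec in manifest.insertions:
        if not spec.catalogued and not include_novel:
            continue
        contig, lo, hi = manifest.ref_intervals[spec.locus_id]
        if spec.in_reference_sequence:
            status = "reference" if spec.catalogued else "novel_reference"
        else:
            status = "non_reference" if spec.catalogued else "novel_non_reference"
        gts = {manifest.genotypes.get((i, spec.locus_id), "absent") for i in manifest.individuals}
        records.append(
            LocusRecord(
                locus_id=spec.locus_id,
                contig=contig,
                start=lo,
                end=hi,
                strand=spec.strand,
                element_type=spec.element_type,
                ltr_subtype=spec.ltr_subtype,
                catalog_status=status,
                polymorphic_annotation="polymorphic" if "absent" in gts else "fixed",
                est_age_mya=spec.age_mya,
            )
        )
    return Catalog(records, source_files=["simulated:truth"])


def _cassette_sites(
    contig_len: int, groups: int, copies: int = 3, cassette_len: int = 2000
) -> list[list[int]]:
    """Start positions of the planted cassette copies (mirrors
    :func:`make_background`)."""
    step = contig_len // (groups * copies + 1)
    pos = step
    out = []
    for _g in range(groups):
        grp = []
        for _c in range(copies):
            grp.append(pos)
            pos += step
        out.append(grp)
    return out


@dataclass
class Study:
    """A fully specified simulated experiment."""

    build: GenomeBuild
    manifest: TruthManifest
    params: ProtocolParams
    lib: LtrLibrary
    catalog: Catalog        # catalogued loci only (the pipeline's input)
    full_catalog: Catalog   # including planted novel loci (truth)
    depth: int

    @property
    def sample_ids(self) -> list[str]:
        return self.manifest.sample_ids

    def sample_reads(self, sample_id: str) -> list[ReadPair]:
        individual = self.manifest.individual_of(sample_id)
        return simulate_reads(
            self.build, sample_id, individual, self.params,
            self.depth, self.manifest.seed,
        )


def write_study(study: Study, outdir) -> None:
    """Write a simulated study as a run-ready directory: reference FASTA,
    catalog TSV, gzipped per-sample FASTQ, sample sheet, LTR/element
    FASTA for bait building and homology filtering, LTR annotation BED,
    and a truth manifest (JSON lines)."""
    import json
    from pathlib import Path

    from .catalog import write_catalog
    from .io import write_fasta, write_fastq_pairs

    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    write_fasta(study.build.reference, outdir / "reference.fasta")
    write_fasta(study.lib.reference_seqs, outdir / "hervk_sequences.fasta")
    write_fasta(study.lib.consensus, outdir / "ltr_consensus.fasta")
    write_catalog(study.catalog, outdir / "catalog.tsv")
    write_catalog(study.full_catalog, outdir / "full_catalog.tsv")
    with open(outdir / "ltr_annotation.bed", "w") as fh:
        fh.write("# coordinates: 0-based half-open (BED)\n")
        for contig, lo, hi in sorted(study.build.ltr_annotation):
            fh.write(f"{contig}\t{lo}\t{hi}\tLTR_element\n")
    rows = ["sample_id\tindividual\tfastq_r1\tfastq_r2"]
    for sid in study.sample_ids:
        pairs = study.sample_reads(sid)
        r1 = outdir / "samples" / f"{sid}_R1.fastq.gz"
        r2 = outdir / "samples" / f"{sid}_R2.fastq.gz"
        write_fastq_pairs(pairs, r1, r2)
        # paths relative to the sheet so the directory is relocatable
        rows.append(
            f"{sid}\t{study.manifest.individual_of(sid)}\t"
            f"samples/{sid}_R1.fastq.gz\tsamples/{sid}_R2.fastq.gz"
        )
    (outdir / "sample_sheet.tsv").write_text("\n".join(rows) + "\n")
    man = study.manifest
    with open(outdir / "truth_manifest.jsonl", "w") as fh:
        header = {
            "record": "study",
            "individuals": man.individuals,
            "n_replicates": man.n_replicates,
            "seed": man.seed,
            "linker_seq": study.params.linker_seq,
            "depth": study.depth,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for spec in man.insertions:
            rec = {
                "record": "insertion",
                "locus_id": spec.locus_id,
                "contig": spec.contig,
                "site": spec.site,
                "element_type": spec.element_type,
                "ltr_subtype": spec.ltr_subtype,
                "age_mya": spec.age_mya,
                "tsd_len": spec.tsd_len,
                "strand": spec.strand,
                "in_reference_sequence": spec.in_reference_sequence,
                "in_repeat": spec.in_repeat,
                "catalogued": spec.catalogued,
                "ref_interval": man.ref_intervals.get(spec.locus_id),
                "genotypes": {
                    ind: man.genotypes.get((ind, spec.locus_id), "absent")
                    for ind in man.individuals
                },
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
        for sid, stats in sorted(man.sample_stats.items()):
            fh.write(
                json.dumps({"record": "sample", "sample_id": sid, **stats},
                           sort_keys=True) + "\n"
            )


def simulate_study(
    seed: int,
    n_individuals: int = 3,
    n_replicates: int = 3,
    depth: int = 100_000,
    n_contigs: int = 4,
    contig_len: int = 120_000,
    cassette_groups: int = 0,
    polymorphic_fraction: float = 0.25,
    params: Optional[ProtocolParams] = None,
    **panel_kwargs,
) -> Study:
    """Build a complete synthetic study: genomes, genotypes, catalog.

    When ``cassette_groups`` > 0, contig 1 carries that many groups of
    three identical 2-kb cassettes and one catalogued solo LTR is planted
    inside the first copy of each group (``in_repeat``); all other loci go
    on the remaining contigs.
    """
    lib = default_ltr_library()
    params = params or ProtocolParams()
    params.resolve_primers(lib)
    contigs = {f"ctg{i + 1}": contig_len for i in range(n_contigs)}
    repeat_sites = []
    if cassette_groups:
        for grp in _cassette_sites(contig_len, cassette_groups):
            repeat_sites.append(("ctg1", grp[0] + 1000))  # centre of first copy
        contigs = {c: l for c, l in contigs.items() if c != "ctg1"}
    panel = make_insertion_panel(
        contigs, seed, repeat_sites=repeat_sites, **panel_kwargs
    )
    manifest = design_experiment(
        panel, n_individuals, n_replicates, polymorphic_fraction, seed
    )
    # repeat-embedded and novel loci stay fixed so their loss/recovery is
    # attributable to the pipeline, not to genotype sampling
    for spec in panel:
        if spec.in_repeat or not spec.catalogued:
            for ind in manifest.individuals:
                manifest.genotypes[(ind, spec.locus_id)] = "hom"
    manifest.protocol_params = params
    background, repeats = make_background(
        n_contigs, contig_len, seed, cassette_groups=cassette_groups
    )
    build = GenomeBuild(background, manifest, lib, repeats)
    return Study(
        build=build,
        manifest=manifest,
        params=params,
        lib=lib,
        catalog=catalog_from_manifest(manifest, include_novel=False),
        full_catalog=catalog_from_manifest(manifest, include_novel=True),
        depth=depth,
    )
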