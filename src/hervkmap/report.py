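"""Pipeline orchestration and evaluation statistics.

``process_sample`` drives one sample through read preparation, chimeric
read detection, unique flank mapping, and catalog quantification;
``run_study`` applies it to a whole simulated study and pools the
unassigned junctions for novel-locus discovery.  The evaluation helpers
compute the repeatability, chi-square, correlation, and age-vs-CPM
summaries used to characterise the method.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import Catalog
from .chimera import BaitSet, find_chimeras
from .flankmap import GenomeIndex, map_flanks
from .locuscall import (
    NovelLocusCall,
    SampleQuant,
    assign_to_catalog,
    call_novel,
    quantify,
)
from .polymorph import pairwise_scan
from .readprep import ReadPair, prep_sample
from .simulate import Study


@dataclass
class RunConfig:
    """All stage parameters, serialised verbatim into output headers."""

    bait_len: int = 20
    min_identity: float = 0.90
    min_flank: int = 10
    window_nt: int = 10
    min_novel_dist: int = 2000
    cluster_gap: int = 50
    min_novel_reads: int = 2
    max_tsd: int = 10
    cpm_min: float = 50.0
    fc_min: float = 20.0
    p_max: float = 1e-10
    pseudocount: float = 0.5
    index_k: int = 13
    max_mismatch_frac: float = 0.06
    trim_window: int = 4
    trim_mean_q: int = 15
    trim_min_len: int = 36
    merge_min_overlap: int = 10
    merge_max_mismatch_ratio: float = 0.1
    subsample_depths: tuple[int, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if not 0.5 < self.min_identity <= 1:
            raise ValueError("min_identity outside (0.5, 1]")
        for name in ("bait_len", "min_flank", "window_nt", "min_novel_dist",
                     "cluster_gap", "min_novel_reads", "max_tsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cpm_min < 0 or self.fc_min < 0 or not 0 < self.p_max <= 1:
            raise ValueError("bad filter thresholds")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


def process_sample(
    pairs: Sequence[ReadPair],
    catalog: Catalog,
    index: GenomeIndex,
    baitset: BaitSet,
    linker_seq: str,
    hervk_seqs: dict[str, str],
    config: Optional[RunConfig] = None,
    sample_id: str = "",
) -> dict:
    """One sample through the full bioinformatic phase.

    Returns a dict with the :class:`SampleQuant`, the unassigned
    alignments (novel-locus material), and per-stage metrics.  The CPM
    base (library size) is the number of uniquely mapped flanks after all
    filters, which makes CPM invariant to sequencing depth differences.
    """
    cfg = config or RunConfig()
    reads, prep_metrics = prep_sample(
        list(pairs),
        window=cfg.trim_window,
        mean_q=cfg.trim_mean_q,
        min_len=cfg.trim_min_len,
        min_overlap=cfg.merge_min_overlap,
        max_mismatch_ratio=cfg.merge_max_mismatch_ratio,
    )
    hits, chim_metrics = find_chimeras(
        reads, baitset, linker_seq, hervk_seqs, min_flank=cfg.min_flank
    )
    alignments, map_metrics = map_flanks(hits, index, cfg.max_mismatch_frac)
    counts, unassigned, assign_stats = assign_to_catalog(
        alignments, catalog, window_nt=cfg.window_nt
    )
    library_size = len(alignments)
    quant = (
        quantify(
            counts,
            library_size,
            sample_id=sample_id,
            locus_universe=catalog.locus_ids,
            cpm_min=cfg.cpm_min,
        )
        if library_size
        else SampleQuant(sample_id, 0, {l: 0 for l in catalog.locus_ids},
                         {l: 0.0 for l in catalog.locus_ids},
                         {l: False for l in catalog.locus_ids},
                         {l: False for l in catalog.locus_ids}, cfg.cpm_min)
    )
    return {
        "sample_id": sample_id,
        "quant": quant,
        "unassigned": unassigned,
        "metrics": {
            "prep": prep_metrics,
            "chimera": chim_metrics,
            "mapping": map_metrics,
            "assignment": assign_stats,
            "library_size": library_size,
        },
    }


@dataclass
class StudyResult:
    quants: dict[str, SampleQuant]
    metrics: dict[str, dict]
    novel_calls: list[NovelLocusCall]
    ambiguous_calls: list[NovelLocusCall]
    contrast_tables: Optional[dict] = None
    polymorphic_summary: Optional[pd.DataFrame] = None

    def quants_by_individual(self, manifest) -> dict[str, list[SampleQuant]]:
        out: dict[str, list[SampleQuant]] = {}
        for sid, q in self.quants.items():
            out.setdefault(manifest.individual_of(sid), []).append(q)
        return out


def run_study(study: Study, config: Optional[RunConfig] = None) -> StudyResult:
    """Process every sample of a simulated study and pool unassigned
    junctions for novel-locus discovery; with >= 2 individuals, run the
    pairwise polymorphism scan."""
    cfg = config or RunConfig()
    cfg.validate()
    baitset = BaitSet.from_library(
        study.lib.consensus, bait_len=cfg.bait_len, min_identity=cfg.min_identity
    )
    index = GenomeIndex(study.build.reference, k=cfg.index_k)
    quants: dict[str, SampleQuant] = {}
    metrics: dict[str, dict] = {}
    pooled_unassigned = []
    for sid in study.sample_ids:
        res = process_sample(
            study.sample_reads(sid),
            study.catalog,
            index,
            baitset,
            study.params.linker_seq,
            study.lib.reference_seqs,
            config=cfg,
            sample_id=sid,
        )
        quants[sid] = res["quant"]
        metrics[sid] = res["metrics"]
        pooled_unassigned.extend(res["unassigned"])
    novel, ambiguous = call_novel(
        pooled_unassigned,
        study.catalog,
        min_novel_dist=cfg.min_novel_dist,
        cluster_gap=cfg.cluster_gap,
        min_reads=cfg.min_novel_reads,
        max_tsd=cfg.max_tsd,
        ltr_annotation=study.build.ltr_annotation,
    )
    result = StudyResult(
        quants=quants, metrics=metrics, novel_calls=novel, ambiguous_calls=ambiguous
    )
    if len(study.manifest.individuals) >= 2:
        tables, summary = pairwise_scan(
            result.quants_by_individual(study.manifest),
            fc_min=cfg.fc_min, p_max=cfg.p_max, pseudocount=cfg.pseudocount,
        )
        result.contrast_tables = tables
        result.polymorphic_summary = summary
    return result


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------


def repeatability_summary(
    quants: Sequence[SampleQuant], filtered: bool = False
) -> dict:
    """Venn-style detection counts across one individual's replicates:
    per-replicate counts, intersection (detected in all), union (detected
    in any)."""
    if len(quants) < 2:
        raise ValueError("repeatability needs >= 2 replicates")
    key = "detected_filtered" if filtered else "detected"
    sets = [
        {l for l, d in getattr(q, key).items() if d}
        for q in quants
    ]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    return {
        "per_replicate": [len(s) for s in sets],
        "in_all": len(inter),
        "in_any": len(union),
        "loci_in_all": sorted(inter),
    }


def chisq_detection(
    counts_detected: Sequence[int], universe_size: int
) -> tuple[float, float]:
    """Pearson chi-square on the 2 x k detected/undetected contingency
    table (k replicates against a shared locus universe)."""
    counts = [int(c) for c in counts_detected]
    if len(counts) < 2:
        raise ValueError("need >= 2 replicates")
    if universe_size <= 0:
        raise ValueError("universe_size must be > 0")
    if max(counts) > universe_size:
        raise ValueError("detected count exceeds universe size")
    table = np.array([counts, [universe_size - c for c in counts]])
    if np.all(np.array(counts) == counts[0]):
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def cpm_correlation(
    quants: Sequence[SampleQuant], filtered: bool = False
) -> pd.DataFrame:
    """Pearson correlation matrix of per-locus CPM between samples, over
    the union of detected loci with absent entries as 0."""
    if len(quants) < 2:
        raise ValueError("need >= 2 samples")
    key = "detected_filtered" if filtered else "detected"
    union = sorted(
        set().union(*({l for l, d in getattr(q, key).items() if d} for q in quants))
    )
    mat = np.array([[q.cpm.get(l, 0.0) for l in union] for q in quants])
    names = [q.sample_id for q in quants]
    n = len(quants)
    out = np.full((n, n), np.nan)
    with np.errstate(invalid="ignore"):
        for i in range(n):
            for j in range(n):
                if i == j:
                    out[i, j] = 1.0
                elif mat[i].std() == 0 or mat[j].std() == 0:
                    out[i, j] = np.nan
                else:
                    out[i, j] = np.corrcoef(mat[i], mat[j])[0, 1]
    return pd.DataFrame(out, index=names, columns=names)


def age_cpm_summary(
    mean_cpm: dict[str, float],
    catalog: Catalog,
    bins: Sequence[float] = (0, 5, 10, 15, 20, 25, 30, 40),
) -> tuple[pd.DataFrame, float]:
    """Mean/median CPM per element-age bin plus the Spearman rank
    correlation between age and CPM.

    Bins are half-open [lo, hi).  Only age-annotated catalogued loci
    enter; an empty annotation yields an empty table (warned).
    """
    rows = []
    ages, cpms = [], []
    for rec in catalog:
        if rec.est_age_mya is None or rec.locus_id not in mean_cpm:
            continue
        ages.append(rec.est_age_mya)
        cpms.append(mean_cpm[rec.locus_id])
    if not ages:
        import logging

        logging.getLogger(__name__).warning("no age-annotated loci with CPM")
        return pd.DataFrame(columns=["age_bin", "n", "mean_cpm", "median_cpm"]), float("nan")
    ages_arr = np.array(ages)
    cpms_arr = np.array(cpms)
    for lo, hi in zip(bins[:-1], bins[1:]):
        mask = (ages_arr >= lo) & (ages_arr < hi)
        if not mask.any():
            continue
        rows.append(
            {
                "age_bin": f"[{lo},{hi})",
                "n": int(mask.sum()),
                "mean_cpm": float(cpms_arr[mask].mean()),
                "median_cpm": float(np.median(cpms_arr[mask])),
            }
        )
    rho = float(sps.spearmanr(ages_arr, cpms_arr).statistic) if len(ages) > 1 else float("nan")
    return pd.DataFrame(rows), rho


def mean_cpm_across_samples(quants: Sequence[SampleQuant]) -> dict[str, float]:
    """Average CPM of each locus over samples (absent entries as 0)."""
    loci = sorted(set().union(*(set(q.cpm) for q in quants)))
    return {
        l: float(np.mean([q.cpm.get(l, 0.0) for q in quants])) for l in loci
    }


# ---------------------------------------------------------------------------
# file-based pipeline run (CLI backend)
# ---------------------------------------------------------------------------


def run_pipeline(
    config: RunConfig,
    sample_sheet: pd.DataFrame,
    catalog: Catalog,
    genome: dict[str, str],
    baitset: BaitSet,
    linker_seq: str,
    hervk_seqs: dict[str, str],
    outdir,
    ltr_annotation=None,
) -> StudyResult:
    """Run the bioinformatic phase from files and write a run directory.

    ``sample_sheet`` columns: sample_id, individual, fastq_r1, fastq_r2.
    Every output carries a provenance header (config hash + seed); reruns
    with identical inputs are byte-identical.
    """
    from .io import read_fastq_pairs

    cfg = config
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n"
    index = GenomeIndex(genome, k=cfg.index_k)
    quants: dict[str, SampleQuant] = {}
    metrics: dict[str, dict] = {}
    pooled = []
    individuals: dict[str, str] = {}
    for row in sample_sheet.itertuples():
        pairs = read_fastq_pairs(row.fastq_r1, row.fastq_r2)
        res = process_sample(
            pairs, catalog, index, baitset, linker_seq, hervk_seqs,
            config=cfg, sample_id=row.sample_id,
        )
        quants[row.sample_id] = res["quant"]
        metrics[row.sample_id] = res["metrics"]
        individuals[row.sample_id] = row.individual
        pooled.extend(res["unassigned"])
        qpath = outdir / f"{row.sample_id}.quant.tsv"
        with open(qpath, "w") as fh:
            fh.write(header)
            fh.write(f"# library_size={res['quant'].library_size} (uniquely mapped flanks)\n")
            res["quant"].to_frame().to_csv(fh, sep="\t", index=False)
    novel, ambiguous = call_novel(
        pooled, catalog,
        min_novel_dist=cfg.min_novel_dist, cluster_gap=cfg.cluster_gap,
        min_reads=cfg.min_novel_reads, max_tsd=cfg.max_tsd,
        ltr_annotation=ltr_annotation,
    )
    with open(outdir / "novel_loci.bed", "w") as fh:
        fh.write(header)
        fh.write("# coordinates: 0-based half-open (BED); TSD 1-based inclusive\n")
        for c in sorted(novel, key=lambda c: (c.contig, c.start)):
            tsd = f"{c.tsd[0]}-{c.tsd[1]}" if c.tsd else "."
            fh.write(
                f"{c.contig}\t{c.start}\t{c.end + 1}\tnovel\t{c.supporting_reads}\t.\t"
                f"{c.classification}\t{tsd}\n"
            )
    result = StudyResult(
        quants=quants, metrics=metrics, novel_calls=novel, ambiguous_calls=ambiguous
    )
    by_ind: dict[str, list[SampleQuant]] = {}
    for sid, q in quants.items():
        by_ind.setdefault(individuals[sid], []).append(q)
    if len(by_ind) >= 2:
        from .polymorph import contrasts_to_frame

        tables, summary = pairwise_scan(
            by_ind, fc_min=cfg.fc_min, p_max=cfg.p_max, pseudocount=cfg.pseudocount
        )
        result.contrast_tables = tables
        result.polymorphic_summary = summary
        for (a, b), contrasts in tables.items():
            with open(outdir / f"contrast_{a}_vs_{b}.tsv", "w") as fh:
                fh.write(header)
                contrasts_to_frame(contrasts).to_csv(fh, sep="\t", index=False)
        with open(outdir / "polymorphic_summary.tsv", "w") as fh:
            fh.write(header)
            summary.to_csv(fh, sep="\t", index=False)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(
            {"config": json.loads(cfg.to_json()), "samples": metrics},
            fh, indent=2, sort_keys=True,
        )
    return result
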