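"""Polymorphic-locus calling between individuals.

A locus is called polymorphic between two individuals when the fold
change of its mean CPM exceeds 20 *and* an exact count test rejects equal
relative abundance at p < 1e-10.  The test conditions on the total count
t = ya + yb: under the null of equal relative abundance ya is
Binomial(t, Na / (Na + Nb)) given the library sizes Na, Nb, and the
two-sided p-value sums P(k) over every outcome k no more probable than
the observed one.  This is the zero-dispersion limit of the exact
negative-binomial test used by count-based differential packages, which
is the appropriate reading for presence/absence contrasts.

Absent loci still attract a few stray reads in practice, so fold changes
are kept finite structurally with a pseudocount of 0.5 per replicate
count before CPM.
"""
from __future__ import annotations

import itertools
from bisect import bisect_right
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .locuscall import SampleQuant, quantify

#: totals up to this value use exact integer arithmetic; beyond it a
#: log-space evaluation with a 1e-12 relative tie tolerance takes over.
EXACT_T_MAX = 300


@lru_cache(maxsize=4096)
def _exact_table(t: int, na: int, nb: int):
    """Sorted unnormalised outcome weights and their prefix sums.

    Weight of outcome k is C(t,k) * na^k * nb^(t-k); the normaliser is
    (na+nb)^t.  Everything is exact integer arithmetic.
    """
    weights = [comb(t, k) * na**k * nb ** (t - k) for k in range(t + 1)]
    order = sorted(range(t + 1), key=weights.__getitem__)
    sorted_w = [weights[k] for k in order]
    prefix = list(itertools.accumulate(sorted_w))
    return weights, sorted_w, prefix


def _exact_p(ya: int, t: int, na: int, nb: int) -> float:
    weights, sorted_w, prefix = _exact_table(t, na, nb)
    w_obs = weights[ya]
    idx = bisect_right(sorted_w, w_obs)
    num = prefix[idx - 1]
    return float(Fraction(num, (na + nb) ** t))


def _log_p(ya: int, t: int, na: int, nb: int) -> float:
    k = np.arange(t + 1)
    logp = np.log(na / (na + nb))
    logq = np.log(nb / (na + nb))
    logpmf = (
        gammaln(t + 1) - gammaln(k + 1) - gammaln(t - k + 1) + k * logp + (t - k) * logq
    )
    include = logpmf <= logpmf[ya] + 1e-12
    return float(min(1.0, np.exp(logsumexp(logpmf[include]))))


def exact_count_test(ya: int, yb: int, na: int, nb: int) -> float:
    """Two-sided exact test of equal relative abundance.

    Conditional on t = ya + yb, sums the probabilities of all outcomes at
    most as probable as the observed split.  t = 0 carries no evidence
    (p = 1).  Symmetric: p(ya, yb, Na, Nb) == p(yb, ya, Nb, Na).
    """
    if na <= 0 or nb <= 0:
        raise ValueError("library sizes must be > 0")
    if ya < 0 or yb < 0 or ya > na or yb > nb:
        raise ValueError("counts must lie in [0, library size]")
    t = ya + yb
    if t == 0:
        return 1.0
    if t <= EXACT_T_MAX:
        return _exact_p(ya, t, na, nb)
    return _log_p(ya, t, na, nb)


@dataclass
class Contrast:
    locus_id: str
    individual_a: str
    individual_b: str
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]
    libsizes_a: tuple[int, ...]
    libsizes_b: tuple[int, ...]
    mean_cpm_a: float
    mean_cpm_b: float
    cpm_fold_change: float   # max/min, >= 1
    p_value: float
    call: str                # polymorphic | not_polymorphic


def fold_change(a: float, b: float) -> float:
    """Fold change reported as max/min (>= 1)."""
    if a <= 0 or b <= 0:
        raise ValueError("fold_change requires positive values")
    return max(a, b) / min(a, b)


def detectable_percent(n_detected: int, n_total: int) -> float:
    """Percentage of an annotated locus set that was detected."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return 100.0 * n_detected / n_total


def call_polymorphic(
    quants_a: Sequence[SampleQuant],
    quants_b: Sequence[SampleQuant],
    individual_a: str = "A",
    individual_b: str = "B",
    fc_min: float = 20.0,
    p_max: float = 1e-10,
    pseudocount: float = 0.5,
) -> list[Contrast]:
    """Per-locus contrasts between two individuals' replicate sets.

    Mean CPM per individual uses ``pseudocount`` added to each replicate
    count; the exact test runs on replicate-summed raw counts and library
    sizes.  A locus is polymorphic iff fold change > fc_min and
    p < p_max (both strict).  All loci are reported with their call.
    """
    if not quants_a or not quants_b:
        raise ValueError("each individual needs >= 1 replicate")
    uni_a = set(quants_a[0].counts)
    for q in list(quants_a) + list(quants_b):
        if set(q.counts) != uni_a:
            diff = set(q.counts) ^ uni_a
            raise ValueError(
                f"mismatched locus universes between samples; differing loci: "
                f"{sorted(diff)[:10]}{'...' if len(diff) > 10 else ''}"
            )
    loci = sorted(uni_a)
    out = []
    na = sum(q.library_size for q in quants_a)
    nb = sum(q.library_size for q in quants_b)
    for locus in loci:
        ca = tuple(q.counts[locus] for q in quants_a)
        cb = tuple(q.counts[locus] for q in quants_b)
        mean_a = float(
            np.mean([
                (c + pseudocount) / q.library_size * 1e6
                for c, q in zip(ca, quants_a)
            ])
        )
        mean_b = float(
            np.mean([
                (c + pseudocount) / q.library_size * 1e6
                for c, q in zip(cb, quants_b)
            ])
        )
        fc = fold_change(mean_a, mean_b)
        p = exact_count_test(sum(ca), sum(cb), na, nb)
        out.append(
            Contrast(
                locus_id=locus,
                individual_a=individual_a,
                individual_b=individual_b,
                counts_a=ca,
                counts_b=cb,
                libsizes_a=tuple(q.library_size for q in quants_a),
                libsizes_b=tuple(q.library_size for q in quants_b),
                mean_cpm_a=mean_a,
                mean_cpm_b=mean_b,
                cpm_fold_change=fc,
                p_value=p,
                call="polymorphic" if (fc > fc_min and p < p_max) else "not_polymorphic",
            )
        )
    return out


def pairwise_scan(
    quants_by_individual: dict[str, Sequence[SampleQuant]],
    fc_min: float = 20.0,
    p_max: float = 1e-10,
    pseudocount: float = 0.5,
) -> tuple[dict[tuple[str, str], list[Contrast]], pd.DataFrame]:
    """Contrast every unordered pair of individuals.

    Returns (per-pair contrast lists, union summary frame listing each
    locus with the set of pairs in which it is called polymorphic)."""
    individuals = sorted(quants_by_individual)
    if len(individuals) < 2:
        raise ValueError("pairwise_scan needs >= 2 individuals")
    tables: dict[tuple[str, str], list[Contrast]] = {}
    called_in: dict[str, list[str]] = {}
    for a, b in itertools.combinations(individuals, 2):
        contrasts = call_polymorphic(
            quants_by_individual[a], quants_by_individual[b],
            individual_a=a, individual_b=b,
            fc_min=fc_min, p_max=p_max, pseudocount=pseudocount,
        )
        tables[(a, b)] = contrasts
        for c in contrasts:
            if c.call == "polymorphic":
                called_in.setdefault(c.locus_id, []).append(f"{a}-{b}")
    summary = pd.DataFrame(
        [
            {"locus_id": locus, "n_pairs": len(pairs), "pairs": ",".join(pairs)}
            for locus, pairs in sorted(called_in.items())
        ],
        columns=["locus_id", "n_pairs", "pairs"],
    )
    return tables, summary


def contrasts_to_frame(contrasts: Sequence[Contrast]) -> pd.DataFrame:
    """Volcano-ready table (log2 fold change signed toward individual A)."""
    rows = []
    for c in contrasts:
        rows.append(
            {
                "locus_id": c.locus_id,
                "individual_a": c.individual_a,
                "individual_b": c.individual_b,
                "mean_cpm_a": c.mean_cpm_a,
                "mean_cpm_b": c.mean_cpm_b,
                "fold_change": c.cpm_fold_change,
                "log2_fc": float(np.log2(c.mean_cpm_a / c.mean_cpm_b)),
                "p_value": c.p_value,
                "neg_log10_p": float(-np.log10(max(c.p_value, 1e-300))),
                "call": c.call,
            }
        )
    return pd.DataFrame(rows)


def simulate_locus_counts(
    n_fixed: int,
    n_polymorphic: int,
    n_individuals: int,
    n_replicates: int,
    depth: int,
    seed: int,
    background_rate: float = 1.0,
    cpm_min: float = 50.0,
) -> tuple[dict[str, list[SampleQuant]], dict[str, list[str]]]:
    """Counts-level simulation of a replicate study design.

    Per-locus amplification propensities are log-normal; carriers of a
    locus draw Poisson counts at their propensity share of the library,
    non-carriers draw a small Poisson background (absent loci are never
    entirely read-free in enrichment data).  Polymorphic loci get a random
    carrier pattern with at least one discordant pair.  Returns
    (quants per individual, carriers per polymorphic locus)."""
    rng = np.random.default_rng(seed)
    n_loci = n_fixed + n_polymorphic
    loci = [f"L{i:04d}" for i in range(n_loci)]
    poly = loci[n_fixed:]
    propensity = rng.lognormal(mean=0.0, sigma=0.7, size=n_loci)
    carriers: dict[str, list[str]] = {}
    individuals = [chr(ord("A") + i) for i in range(n_individuals)]
    for locus in poly:
        while True:
            mask = rng.random(n_individuals) < 0.5
            if mask.any() and not mask.all():
                break
        carriers[locus] = [ind for ind, m in zip(individuals, mask) if m]
    quants: dict[str, list[SampleQuant]] = {}
    for ind in individuals:
        present = np.array(
            [locus not in carriers or ind in carriers[locus] for locus in loci]
        )
        lam = np.where(present, propensity, 0.0)
        reps = []
        for rep in range(n_replicates):
            rates = lam / lam.sum() * depth
            counts = rng.poisson(rates) + rng.poisson(
                np.where(present, 0.0, background_rate)
            )
            libsize = int(counts.sum()) + int(rng.poisson(depth * 0.02))
            reps.append(
                quantify(
                    dict(zip(loci, map(int, counts))),
                    libsize,
                    sample_id=f"{ind}{rep + 1}",
                    cpm_min=cpm_min,
                )
            )
        quants[ind] = reps
    return quants, carriers
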