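"""Binomial copy-number calling from GC-corrected expected read counts.

Under uniform sampling of read start sites, the count c_i of reads mapping
to a gene of length L_i in a library of N reads is Binomial(N, P_i). The
uncorrected success probability is L_i/G (G the haploid genome size); with
the per-sample GC model c/L = a + b*x the corrected probability becomes

    P_i = L_i * (a + b * x_i) / N

which no longer involves G, so it can be computed for samples of unknown
genome size. A two-sided binomial confidence interval at family confidence
0.99 (Bonferroni-corrected over the M genes tested) brackets the counts
compatible with a single copy; counts above the interval indicate
duplication, and the continuous copy estimate is k_i = c_i / E(c_i) with
E(c_i) = N * P_i. Classification is repeated once per member of the GC-fit
ensemble, yielding per-gene consensus calls and min/median/max summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dosagescan.gcbias import GCFit, GCFitEnsemble
from dosagescan.io import CountTable, GeneRecord

logger = logging.getLogger(__name__)

LABEL_SINGLE = "single"
LABEL_DUPLICATED = "duplicated"
LABEL_ABSENT = "absent"
LABEL_BELOW = "below_ci_removed"
LABEL_EXCLUDED = "excluded_ci_spans_zero"
LABEL_UNUSABLE = "unusable_rate"

#: labels that enter the analysed denominator of per-sample summaries
ANALYSED_LABELS = (LABEL_SINGLE, LABEL_DUPLICATED, LABEL_ABSENT)

DEFAULT_GENOME_SIZE_GB = 2.2  # largest diploid 2Cx value; used when unknown


class ModelViolationError(ValueError):
    """Raised when a per-gene success probability reaches 1 or more."""


@dataclass(frozen=True)
class CopyNumberCall:
    """Copy-number decision for one gene under one GC fit."""

    gene_id: str
    observed_count: int
    expected_count: float
    success_prob: float
    ci_lower: int
    ci_upper: int
    k_estimate: float
    k_rounded: int | None
    label: str


@dataclass(frozen=True)
class CallSummary:
    """Min/median/max (over the GC-fit ensemble) of per-sample call
    proportions, in percent of the analysed genes (single + duplicated +
    absent; removed categories are outside the denominator)."""

    sample_id: str
    n_genes_analysed: int
    prop_single: tuple[float, float, float]
    prop_duplicated: tuple[float, float, float]
    prop_absent: tuple[float, float, float]


def expected_count(
    gene: GeneRecord, fit: GCFit, total_reads: int
) -> tuple[float, float]:
    """GC-corrected success probability and expected single-copy count.

    Returns ``(P_i, E(c_i))`` with ``P_i = L_i (a + b x_i) / N`` and
    ``E(c_i) = N P_i = L_i (a + b x_i)``. A non-positive rate means the GC
    model cannot describe the gene (flag it unusable upstream); a
    probability at or above 1 violates the binomial model and is an error.
    """
    rate = fit.a + fit.b * gene.gc_fraction
    if rate <= 0:
        raise ValueError(
            f"{gene.gene_id}: non-positive rate a + b*x = {rate:.4g}; "
            "gene unusable under this GC fit"
        )
    e_count = gene.length_bp * rate
    p = e_count / total_reads
    if p >= 1:
        raise ModelViolationError(
            f"{gene.gene_id}: success probability {p:.4g} >= 1"
        )
    return p, e_count


def binomial_ci(
    total_reads: int,
    success_prob: float,
    family_size: int,
    family_confidence: float = 0.99,
) -> tuple[int, int]:
    """Bonferroni-corrected two-sided binomial confidence interval.

    The per-gene two-sided level is alpha = (1 - family_confidence) /
    family_size, split equally per tail. Bounds follow the standard quantile
    convention: the smallest integer q with CDF(q) >= alpha/2 (lower) or
    >= 1 - alpha/2 (upper). The interval is inclusive on both sides.
    """
    if not 0 < success_prob < 1:
        raise ValueError("success probability must lie strictly in (0, 1)")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    lo, hi = binomial_ci_array(total_reads, np.array([success_prob]),
                               family_size, family_confidence)
    return int(lo[0]), int(hi[0])


def binomial_ci_array(
    total_reads: int,
    success_probs: np.ndarray,
    family_size: int,
    family_confidence: float = 0.99,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized form of :func:`binomial_ci` over an array of
    probabilities (scipy's quantile function is numerically stable across
    the extreme N*P regime, so no special-casing is needed)."""
    success_probs = np.asarray(success_probs, dtype=float)
    if np.any((success_probs <= 0) | (success_probs >= 1)):
        raise ValueError("success probabilities must lie strictly in (0, 1)")
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    alpha = (1.0 - family_confidence) / family_size
    lo = stats.binom.ppf(alpha / 2.0, total_reads, success_probs).astype(int)
    hi = stats.binom.ppf(1.0 - alpha / 2.0, total_reads,
                         success_probs).astype(int)
    return lo, hi


def classify_gene(observed_count: int, ci_lower: int, ci_upper: int) -> str:
    """Label a gene from its count and single-copy confidence interval.

    Counts above the interval indicate duplication; counts within it
    (inclusive on both sides) a single copy. A zero count means the gene is
    absent, but only when the interval excludes zero — an interval reaching
    zero cannot distinguish absence from sampling noise, so such zero-count
    genes are excluded. Non-zero counts below the interval are removed (copy
    number not estimable).
    """
    if observed_count == 0:
        return LABEL_EXCLUDED if ci_lower == 0 else LABEL_ABSENT
    if observed_count < ci_lower:
        return LABEL_BELOW
    if observed_count <= ci_upper:
        return LABEL_SINGLE
    return LABEL_DUPLICATED


def _round_k(k: float, label: str, rounding: str) -> int | None:
    if label == LABEL_SINGLE:
        return 1
    if label == LABEL_ABSENT:
        return 0
    if label == LABEL_DUPLICATED:
        if rounding == "ceil":
            return int(np.ceil(k))
        if rounding == "nearest":
            return max(2, int(np.floor(k + 0.5)))
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    return None


def estimate_k(
    observed_count: int,
    e_count: float,
    label: str = LABEL_DUPLICATED,
    rounding: str = "ceil",
) -> tuple[float, int | None]:
    """Continuous copy estimate k = c / E(c) and its integer version.

    Duplicated genes are rounded up by default (partial copies inflate the
    follow-up count rather than vanish); ``rounding="nearest"`` selects
    conventional rounding instead. Single-copy genes map to 1, absent to 0,
    removed/excluded categories to None.
    """
    if e_count <= 0:
        raise ValueError("expected count must be positive")
    k = observed_count / e_count
    return k, _round_k(k, label, rounding)


def _call_one_member(
    genes: list[GeneRecord],
    counts: CountTable,
    fit: GCFit,
    family_confidence: float,
    rounding: str,
) -> pd.DataFrame:
    n = counts.total_reads
    gid = np.array([g.gene_id for g in genes])
    length = np.array([g.length_bp for g in genes], dtype=float)
    gc = np.array([g.gc_fraction for g in genes])
    c = np.array([counts.counts.get(g.gene_id, 0) for g in genes])

    rate = fit.a + fit.b * gc
    e_count = length * rate
    p = e_count / n
    usable = rate > 0
    if np.any(p >= 1):
        bad = gid[p >= 1][0]
        raise ModelViolationError(f"{bad}: success probability >= 1")
    m = int(usable.sum())
    if m == 0:
        raise ValueError("no gene has a usable success probability")
    lo = np.zeros(len(genes), dtype=int)
    hi = np.zeros(len(genes), dtype=int)
    lo[usable], hi[usable] = binomial_ci_array(
        n, p[usable], m, family_confidence)

    label = np.full(len(genes), LABEL_UNUSABLE, dtype=object)
    u = usable
    label[u & (c == 0) & (lo == 0)] = LABEL_EXCLUDED
    label[u & (c == 0) & (lo > 0)] = LABEL_ABSENT
    label[u & (c > 0) & (c < lo)] = LABEL_BELOW
    label[u & (c >= lo) & (c <= hi)] = LABEL_SINGLE
    label[u & (c > hi)] = LABEL_DUPLICATED

    k = np.where(usable & (e_count > 0), c / np.where(e_count > 0, e_count, 1.0),
                 np.nan)
    k_rounded = [
        _round_k(kk, ll, rounding) if u_ else None
        for kk, ll, u_ in zip(k, label, usable)
    ]
    return pd.DataFrame({
        "gene_id": gid, "c": c, "E": e_count, "P": p,
        "ci_lower": lo, "ci_upper": hi, "k": k,
        "k_rounded": k_rounded, "label": label,
    })


def _consensus(per_member: pd.DataFrame, rounding: str) -> pd.DataFrame:
    rows = []
    for gid, grp in per_member.groupby("gene_id", sort=False):
        label_counts = grp["label"].value_counts()
        label = label_counts.index[0]
        k_med = float(np.nanmedian(grp["k"].to_numpy(dtype=float)))
        rows.append((gid, int(grp["c"].iloc[0]),
                     float(grp["E"].median()), k_med,
                     _round_k(k_med, label, rounding), label))
    return pd.DataFrame(
        rows, columns=["gene_id", "c", "E_median", "k_median",
                       "k_rounded", "label"])


def call_sample(
    genes: list[GeneRecord],
    counts: CountTable,
    ensemble: GCFitEnsemble,
    family_confidence: float = 0.99,
    rounding: str = "ceil",
) -> tuple[pd.DataFrame, pd.DataFrame, CallSummary]:
    """Run the classifier once per GC-fit ensemble member.

    Returns the per-member call table (one row per gene per member), the
    per-gene consensus (majority label, median k), and the ensemble summary
    of call proportions. The Bonferroni family size M is the number of genes
    with a usable success probability for that member, recorded implicitly
    through the interval widths.
    """
    if len(ensemble) == 0:
        raise ValueError("empty GC-fit ensemble")
    members = []
    for idx, fit in enumerate(ensemble.fits):
        df = _call_one_member(genes, counts, fit, family_confidence, rounding)
        df.insert(1, "ensemble_member", idx)
        members.append(df)
    per_member = pd.concat(members, ignore_index=True)
    consensus = _consensus(per_member, rounding)

    props = {lab: [] for lab in ANALYSED_LABELS}
    denoms = []
    for _, grp in per_member.groupby("ensemble_member"):
        vc = grp["label"].value_counts()
        denom = int(sum(vc.get(lab, 0) for lab in ANALYSED_LABELS))
        denoms.append(denom)
        for lab in ANALYSED_LABELS:
            props[lab].append(100.0 * vc.get(lab, 0) / denom if denom else
                              float("nan"))

    def mmm(vals: list[float]) -> tuple[float, float, float]:
        arr = np.asarray(vals, dtype=float)
        return float(np.min(arr)), float(np.median(arr)), float(np.max(arr))

    summary = CallSummary(
        sample_id=counts.sample_id,
        n_genes_analysed=int(np.median(denoms)),
        prop_single=mmm(props[LABEL_SINGLE]),
        prop_duplicated=mmm(props[LABEL_DUPLICATED]),
        prop_absent=mmm(props[LABEL_ABSENT]),
    )
    return per_member, consensus, summary


def theoretical_coverage(
    read_pairs: int,
    read_length_bp: int,
    genome_size_2cx_gb: float | None = None,
) -> float:
    """Expected x-fold genome coverage of a paired-end library.

    Coverage = (pairs * 2 * read length) / (2C genome size in bases), where
    the 2C size is twice the tabulated Gb/2Cx value. When the genome size is
    unknown, 2.2 Gb is assumed (the largest value measured for a diploid of
    the genus). Reported to two decimals.
    """
    if read_pairs <= 0 or read_length_bp <= 0:
        raise ValueError("read_pairs and read_length_bp must be positive")
    if genome_size_2cx_gb is None:
        logger.info("genome size unknown; assuming %.1f Gb/2Cx",
                    DEFAULT_GENOME_SIZE_GB)
        genome_size_2cx_gb = DEFAULT_GENOME_SIZE_GB
    elif genome_size_2cx_gb <= 0:
        raise ValueError("genome_size_2cx_gb must be positive")
    cov = (read_pairs * 2 * read_length_bp) / (2 * genome_size_2cx_gb * 1e9)
    return round(cov, 2)
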