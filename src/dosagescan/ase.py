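"""Allele-dosage analysis of SNP read depths in genome vs transcriptome.

For a gene present in k copies in a diploid individual there are 2k alleles;
a variant base carried on m of them should appear in a fraction m/(2k) of
genomic reads covering the site. If all copies are transcribed at the same
rate, the same fraction is expected in transcriptome reads, so regressing
per-site transcriptome frequencies on genome frequencies quantifies how
evenly duplicate copies contribute to transcript abundance: slope near 1
with high r-squared indicates equal per-copy expression.

The minor variant at each site is defined on the transcriptome depths (the
base receiving fewer transcriptome reads), so the transcriptome frequency is
bounded by 0.5 while the genome frequency of that same base may exceed it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from dosagescan.io import SNPDepthRecord


@dataclass(frozen=True)
class SNPFrequencyPair:
    """Minor-variant frequency of one site in both data sets."""

    gene_id: str
    position: int
    f_genome: float
    f_transcriptome: float
    total_depth_genome: int
    total_depth_transcriptome: int


@dataclass(frozen=True)
class ASEResult:
    """OLS fit of transcriptome on genome minor-variant frequencies."""

    n_sites: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float


class UninformativeSitesError(ValueError):
    pass


def minor_frequencies(record: SNPDepthRecord) -> SNPFrequencyPair | None:
    """Per-site minor-variant frequencies in genome and transcriptome.

    The minor base is the one with the smaller transcriptome depth; ties are
    broken towards the lexicographically smaller base symbol so the result
    does not depend on record order. Sites with zero total depth in either
    data set are dropped (returns None); callers count the drops.
    """
    t_total = record.transcriptome_depth_a + record.transcriptome_depth_b
    g_total = record.genome_depth_a + record.genome_depth_b
    if t_total == 0 or g_total == 0:
        return None
    if record.transcriptome_depth_a < record.transcriptome_depth_b:
        minor_is_a = True
    elif record.transcriptome_depth_a > record.transcriptome_depth_b:
        minor_is_a = False
    else:
        minor_is_a = record.base_a < record.base_b
    if minor_is_a:
        t_minor, g_minor = record.transcriptome_depth_a, record.genome_depth_a
    else:
        t_minor, g_minor = record.transcriptome_depth_b, record.genome_depth_b
    return SNPFrequencyPair(
        gene_id=record.gene_id,
        position=record.position,
        f_genome=g_minor / g_total,
        f_transcriptome=t_minor / t_total,
        total_depth_genome=g_total,
        total_depth_transcriptome=t_total,
    )


def pair_up(records: list[SNPDepthRecord]) -> tuple[list[SNPFrequencyPair], int]:
    """Convert depth records to frequency pairs; returns (pairs, n_dropped)."""
    pairs = []
    dropped = 0
    for rec in records:
        pair = minor_frequencies(rec)
        if pair is None:
            dropped += 1
        else:
            pairs.append(pair)
    return pairs, dropped


def ase_correlation(pairs: list[SNPFrequencyPair]) -> ASEResult:
    """OLS of transcriptome frequency on genome frequency across sites."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 sites for the frequency regression")
    x = np.array([p.f_genome for p in pairs])
    y = np.array([p.f_transcriptome for p in pairs])
    if np.ptp(x) == 0:
        raise UninformativeSitesError(
            "uninformative sites: genome frequencies have zero variance")
    fit = stats.linregress(x, y)
    return ASEResult(
        n_sites=len(pairs),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
    )


def expected_minor_frequency(m_alleles: int, k_copies: int) -> float:
    """Analytic genomic frequency of a variant on m of the 2k alleles of a
    k-copy gene in a diploid individual."""
    if k_copies < 1 or not 1 <= m_alleles <= 2 * k_copies:
        raise ValueError("need 1 <= m <= 2k and k >= 1")
    return m_alleles / (2 * k_copies)
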