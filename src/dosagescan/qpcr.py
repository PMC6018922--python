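"""Efficiency-corrected relative quantification of qPCR assays.

The quantification cycle Ct of an amplicon with per-cycle amplification
efficiency E (2.0 = perfect doubling) relates to starting template quantity
Q as Q proportional to E^(-Ct). The Pfaffl method forms the ratio of target
to reference quantities with each amplicon's own efficiency:

    relative copy = E_target^(-Ct_target) / E_reference^(-Ct_reference)

which reduces to the classic 2^(dCt) when all efficiencies equal 2.
Measurements with efficiencies outside [1.85, 2.1] are discarded before
quantification; technical replicates are averaged on the Ct scale and their
spread propagated to a first-order standard error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

EFFICIENCY_MIN = 1.85
EFFICIENCY_MAX = 2.1


@dataclass(frozen=True)
class QPCRMeasure:
    """One technical replicate of one amplicon in one sample."""

    sample_id: str
    amplicon_id: str
    ct: float
    efficiency: float
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")
        if self.efficiency <= 1:
            raise ValueError("efficiency must exceed 1 (fold-change scale)")
        if self.efficiency > 2.2:
            raise ValueError(
                f"efficiency {self.efficiency} > 2.2: efficiencies are on "
                "the fold-change scale (2 = doubling), not percent")


@dataclass(frozen=True)
class RelativeCopy:
    """Copy number of a gene relative to the reference gene in one sample."""

    sample_id: str
    gene_id: str
    relative_copy: float
    se: float


def filter_efficiency(
    measures: list[QPCRMeasure],
) -> tuple[list[QPCRMeasure], list[QPCRMeasure]]:
    """Drop measurements with amplification efficiency < 1.85 or > 2.1.

    The bounds themselves are retained. Returns (kept, rejected); amplicons
    losing all their measurements trigger a warning.
    """
    kept = [m for m in measures
            if EFFICIENCY_MIN <= m.efficiency <= EFFICIENCY_MAX]
    rejected = [m for m in measures
                if not EFFICIENCY_MIN <= m.efficiency <= EFFICIENCY_MAX]
    surviving = {m.amplicon_id for m in kept}
    for amp in sorted({m.amplicon_id for m in rejected} - surviving):
        warnings.warn(f"amplicon {amp}: all measurements rejected by the "
                      "efficiency filter", stacklevel=2)
    return kept, rejected


def _amplicon_quantity(measures: list[QPCRMeasure]) -> tuple[float, float, float]:
    """Mean-Ct quantity Q = E^(-mean Ct) with its delta-method variance.

    Var(Q) ~ Q^2 (ln E)^2 Var(mean Ct). Returns (Q, var_Q, efficiency).
    """
    cts = np.array([m.ct for m in measures])
    effs = {m.efficiency for m in measures}
    if len(effs) != 1:
        raise ValueError("mixed efficiencies within one amplicon")
    eff = effs.pop()
    mean_ct = float(cts.mean())
    var_mean = float(cts.var(ddof=1) / len(cts)) if len(cts) > 1 else 0.0
    q = eff ** (-mean_ct)
    var_q = q * q * math.log(eff) ** 2 * var_mean
    return q, var_q, eff


def pfaffl_relative_copy(
    target: list[QPCRMeasure],
    reference: list[QPCRMeasure],
    gene_id: str | None = None,
) -> RelativeCopy:
    """Pfaffl ratio of a target amplicon to the reference amplicon(s).

    ``reference`` may contain one or several primer pairs for the reference
    gene; their quantities are averaged before forming the ratio, so the
    reference gene itself scores exactly 1. The standard error combines the
    replicate Ct spread of target and reference by first-order propagation.
    """
    if not target:
        raise ValueError("no target measurements")
    if not reference:
        raise ValueError("missing reference measurements")
    sample_ids = {m.sample_id for m in target} | {m.sample_id for m in reference}
    if len(sample_ids) != 1:
        raise ValueError("target and reference must come from one sample")

    by_amp: dict[str, list[QPCRMeasure]] = {}
    for m in reference:
        by_amp.setdefault(m.amplicon_id, []).append(m)
    ref_qs, ref_vars = [], []
    for amp_measures in by_amp.values():
        q, v, _ = _amplicon_quantity(amp_measures)
        ref_qs.append(q)
        ref_vars.append(v)
    ref_mean = float(np.mean(ref_qs))
    ref_var = float(np.sum(ref_vars)) / len(ref_qs) ** 2

    q_t, var_t, _ = _amplicon_quantity(target)
    ratio = q_t / ref_mean
    # first-order: Var(r)/r^2 = Var(Qt)/Qt^2 + Var(Qr)/Qr^2
    rel_var = (var_t / q_t ** 2 if q_t > 0 else 0.0) + \
              (ref_var / ref_mean ** 2 if ref_mean > 0 else 0.0)
    se = ratio * math.sqrt(rel_var)
    return RelativeCopy(
        sample_id=next(iter(sample_ids)),
        gene_id=gene_id or target[0].amplicon_id,
        relative_copy=ratio,
        se=se,
    )


def quantify_sample(
    measures: list[QPCRMeasure],
    reference_amplicons: list[str],
    amplicon_to_gene: dict[str, str] | None = None,
) -> list[RelativeCopy]:
    """Filter by efficiency, then Pfaffl-quantify every non-reference
    amplicon against the reference amplicons, within one sample."""
    kept, _ = filter_efficiency(measures)
    reference = [m for m in kept if m.amplicon_id in reference_amplicons]
    if not reference:
        raise ValueError("no reference measurements survive the filters")
    out = []
    targets = sorted({m.amplicon_id for m in kept}
                     - set(reference_amplicons))
    for amp in targets:
        t_measures = [m for m in kept if m.amplicon_id == amp]
        gene = amplicon_to_gene.get(amp, amp) if amplicon_to_gene else amp
        out.append(pfaffl_relative_copy(t_measures, reference, gene_id=gene))
    return out
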