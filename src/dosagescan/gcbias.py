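"""Per-sample estimation of the GC bias in length-normalized read counts.

Library preparation with PCR makes sequencing depth depend on the GC content
of the target region, and the strength of that dependence varies between
sequencing batches. The model is linear on the fraction scale:

    c_i / L_i = a + b * x_i

where c_i is the read count of gene i, L_i its length and x_i its GC
fraction. Coefficients (a, b) are estimated per sample from a pool enriched
in putative single-copy genes, with a class-balanced resampling scheme that
equalizes the weight of nine GC classes spanning 0.38-0.78; repeating the
resampling (default 100 times) yields a non-parametric ensemble describing
the coefficients' uncertainty, which is propagated through the copy-number
caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dosagescan.io import CountTable, GeneRecord

DEFAULT_CLASS_RANGE = (0.38, 0.78)
DEFAULT_N_CLASSES = 9
DEFAULT_GENES_PER_CLASS = 60
DEFAULT_N_REPEATS = 100
MIN_LENGTH_BP = 700
MEDIAN_FILTER_FACTOR = 1.5


@dataclass(frozen=True)
class GCFit:
    """One OLS fit of length-normalized count on GC fraction.

    ``a`` is the expected reads per base at GC = 0 and ``b`` the change in
    that rate per unit GC fraction. ``valid_over(lo, hi)`` reports whether the
    implied rate stays positive over a GC range.
    """

    a: float
    b: float
    n_genes_used: int

    def rate(self, gc_fraction: float | np.ndarray) -> float | np.ndarray:
        return self.a + self.b * np.asarray(gc_fraction)

    def valid_over(self, lo: float = DEFAULT_CLASS_RANGE[0],
                   hi: float = DEFAULT_CLASS_RANGE[1]) -> bool:
        return bool(min(self.a + self.b * lo, self.a + self.b * hi) > 0)


@dataclass(frozen=True)
class GCFitEnsemble:
    """Resampled coefficient pairs from repeated class-balanced fits."""

    fits: tuple[GCFit, ...]
    seed: int
    class_bounds: tuple[tuple[float, float], ...]

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def a_values(self) -> np.ndarray:
        return np.array([f.a for f in self.fits])

    @property
    def b_values(self) -> np.ndarray:
        return np.array([f.b for f in self.fits])

    def median_fit(self) -> GCFit:
        return GCFit(
            a=float(np.median(self.a_values)),
            b=float(np.median(self.b_values)),
            n_genes_used=int(np.median([f.n_genes_used for f in self.fits])),
        )


class InsufficientPoolError(ValueError):
    """Raised when too few genes survive the single-copy enrichment filter."""


def filter_candidate_single_copy(
    genes: list[GeneRecord],
    counts: CountTable,
    min_length_bp: int = MIN_LENGTH_BP,
    min_pool: int = 200,
) -> list[tuple[GeneRecord, float]]:
    """Enrich for putative single-copy genes before the GC fit.

    Keeps genes longer than ``min_length_bp`` with a non-zero count whose
    length-normalized count is at most 1.5 times the median normalized count
    (median over genes with non-zero counts). Duplicated genes sit near
    integer multiples of the single-copy rate and are shed by the median
    filter; absent genes are shed by the zero-count rule.

    Returns (gene, normalized count) pairs.
    """
    with_counts = [
        (g, counts.counts.get(g.gene_id, 0) / g.length_bp)
        for g in genes
        if counts.counts.get(g.gene_id, 0) > 0
    ]
    if not with_counts:
        raise InsufficientPoolError("no genes with non-zero counts")
    median_norm = float(np.median([nc for _, nc in with_counts]))
    kept = [
        (g, nc) for g, nc in with_counts
        if g.length_bp > min_length_bp
        and nc <= MEDIAN_FILTER_FACTOR * median_norm
    ]
    if len(kept) < min_pool:
        raise InsufficientPoolError(
            f"insufficient single-copy pool: {len(kept)} genes survive the "
            f"filters (minimum {min_pool})"
        )
    return kept


def fit_gc_linear(subset: list[tuple[GeneRecord, float]]) -> GCFit:
    """Ordinary least squares of normalized count on GC fraction."""
    if len(subset) < 2:
        raise ValueError("need at least 2 genes for a linear fit")
    x = np.array([g.gc_fraction for g, _ in subset])
    y = np.array([nc for _, nc in subset])
    if np.ptp(x) == 0:
        raise ValueError("singular design: all GC fractions identical")
    b, a = np.polyfit(x, y, 1)
    return GCFit(a=float(a), b=float(b), n_genes_used=len(subset))


def gc_class_bounds(
    class_range: tuple[float, float] = DEFAULT_CLASS_RANGE,
    n_classes: int = DEFAULT_N_CLASSES,
) -> tuple[tuple[float, float], ...]:
    """Equally spaced GC classes; half-open [lo, hi) except the last, closed."""
    edges = np.linspace(class_range[0], class_range[1], n_classes + 1)
    return tuple((float(edges[i]), float(edges[i + 1]))
                 for i in range(n_classes))


def fit_gc_ensemble(
    genes: list[GeneRecord],
    counts: CountTable,
    n_repeats: int = DEFAULT_N_REPEATS,
    genes_per_class: int = DEFAULT_GENES_PER_CLASS,
    class_range: tuple[float, float] = DEFAULT_CLASS_RANGE,
    n_classes: int = DEFAULT_N_CLASSES,
    seed: int = 0,
    min_pool: int = 200,
) -> GCFitEnsemble:
    """Class-balanced resampled estimation of the GC coefficients.

    Each repeat draws ``genes_per_class`` genes without replacement from each
    GC class of the filtered pool, pools the draws and fits OLS. Classes with
    fewer genes contribute all of them (with a warning); empty classes are
    skipped (with a warning). Genes with GC outside ``class_range`` are never
    sampled.
    """
    pool = filter_candidate_single_copy(genes, counts, min_pool=min_pool)
    bounds = gc_class_bounds(class_range, n_classes)
    by_class: list[list[tuple[GeneRecord, float]]] = [[] for _ in bounds]
    for g, nc in pool:
        for ci, (lo, hi) in enumerate(bounds):
            last = ci == len(bounds) - 1
            if (lo <= g.gc_fraction < hi) or (last and g.gc_fraction == hi):
                by_class[ci].append((g, nc))
                break
    for ci, members in enumerate(by_class):
        if not members:
            warnings.warn(
                f"GC class [{bounds[ci][0]:.3f}, {bounds[ci][1]:.3f}) is "
                "empty and will be skipped", stacklevel=2)
        elif len(members) < genes_per_class:
            warnings.warn(
                f"GC class [{bounds[ci][0]:.3f}, {bounds[ci][1]:.3f}) has "
                f"only {len(members)} genes (< {genes_per_class}); using all "
                "of them without replacement", stacklevel=2)

    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_repeats):
        subset: list[tuple[GeneRecord, float]] = []
        for members in by_class:
            if not members:
                continue
            if len(members) <= genes_per_class:
                subset.extend(members)
            else:
                idx = rng.choice(len(members), size=genes_per_class,
                                 replace=False)
                subset.extend(members[i] for i in idx)
        fit = fit_gc_linear(subset)
        if not fit.valid_over(*class_range):
            warnings.warn(
                "fitted rate a + b*x is non-positive somewhere on the GC "
                "class range; the fit is retained but flagged", stacklevel=2)
        fits.append(fit)
    return GCFitEnsemble(fits=tuple(fits), seed=seed, class_bounds=bounds)
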