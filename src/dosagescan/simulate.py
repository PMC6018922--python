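"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates the statistical structure the corresponding analysis
assumes, so recovery of the generating parameters is a meaningful test:

* reference genes with lengths, GC fractions and integer copy numbers drawn
  from a configurable spectrum (including absent genes, copy 0);
* read counts Binomial(N, k_i * P_i) with the linear GC-rate bias
  P_i = L_i (a + b x_i) / N;
* biallelic SNP read depths proportional to allele dosage in the genome and
  to per-allele expression weights in the transcriptome (diploid convention:
  2k alleles for a k-copy gene);
* pure-birth (Yule) gene-family trees with Brownian trait evolution and a
  known copy-number -> log-abundance slope;
* qPCR quantification cycles consistent with known relative copy numbers and
  per-amplicon amplification efficiencies.

All generators are reproducible under a fixed seed. Default parameter values
describe a low-coverage plant resequencing experiment: a two-million-read
library over a CDS reference, GC-rate coefficients (a, b) = (0.008, 0.005)
reads per base, and a copy spectrum dominated by single-copy genes with a
minority of duplicates and rare absences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from dosagescan.io import (
    CountTable,
    GeneRecord,
    SNPDepthRecord,
    write_count_table,
    write_gene_table,
    write_snp_table,
)
from dosagescan.qpcr import QPCRMeasure

#: background copy-number spectrum: mostly single copy, a minority of
#: duplicates, and rare absences
DEFAULT_COPY_SPECTRUM = {0: 0.01, 1: 0.86, 2: 0.09, 3: 0.03, 4: 0.01}


@dataclass
class SimulationConfig:
    """Parameters of the reference + count generator."""

    n_genes: int = 2000
    seed: int = 0
    library_size: int = 2_000_000
    gc_intercept: float = 0.008   # reads per base at GC = 0
    gc_slope: float = 0.005       # reads per base per unit GC fraction
    copy_spectrum: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_COPY_SPECTRUM))
    length_log_mean: float = math.log(1000.0)
    length_log_sd: float = 0.45
    length_floor_bp: int = 150
    gc_low: float = 0.38
    gc_high: float = 0.78

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        total = sum(self.copy_spectrum.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("copy_spectrum probabilities must sum to 1")
        if any(k < 0 for k in self.copy_spectrum):
            raise ValueError("copy numbers must be non-negative")
        if not 0.30 <= self.gc_low < self.gc_high <= 0.85:
            raise ValueError("gc distribution must be bounded on [0.30, 0.85]")
        lo_rate = self.gc_intercept + self.gc_slope * self.gc_low
        hi_rate = self.gc_intercept + self.gc_slope * self.gc_high
        if min(lo_rate, hi_rate) <= 0:
            raise ValueError(
                "degenerate GC model: a + b*x must stay positive over the "
                "GC support")
        if self.length_log_sd < 0:
            raise ValueError("length_log_sd must be non-negative")


@dataclass
class GroundTruth:
    """Generator-side truth used to score downstream recovery."""

    true_copy: dict[str, int] = field(default_factory=dict)
    true_slope_beta: float | None = None
    true_allele_multiplicity: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Reference and counts
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig,
) -> tuple[list[GeneRecord], GroundTruth]:
    """Draw gene lengths, GC fractions and true integer copy numbers."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = np.maximum(
        config.length_floor_bp,
        np.round(rng.lognormal(config.length_log_mean,
                               config.length_log_sd,
                               config.n_genes)).astype(int),
    )
    gc = rng.uniform(config.gc_low, config.gc_high, config.n_genes)
    copies = list(config.copy_spectrum.keys())
    probs = np.array([config.copy_spectrum[k] for k in copies], dtype=float)
    true_k = rng.choice(copies, size=config.n_genes, p=probs / probs.sum())
    genes = []
    truth = GroundTruth()
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gid = f"g{i:0{width}d}"
        genes.append(GeneRecord(gene_id=gid, family_id=gid,
                                length_bp=int(lengths[i]),
                                gc_fraction=float(gc[i])))
        truth.true_copy[gid] = int(true_k[i])
    return genes, truth


def simulate_counts(
    genes: list[GeneRecord],
    truth: GroundTruth,
    total_reads: int,
    gc_intercept: float,
    gc_slope: float,
    seed: int,
    sample_id: str = "sim",
) -> CountTable:
    """Draw read counts c_i ~ Binomial(N, k_i * L_i (a + b x_i) / N).

    Absent genes (true copy 0) always receive zero counts.
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for g in genes:
        k = truth.true_copy.get(g.gene_id, 1)
        p = k * g.length_bp * (gc_intercept + gc_slope * g.gc_fraction) \
            / total_reads
        if p >= 1:
            raise ValueError(
                f"{g.gene_id}: per-read success probability {p:.4g} >= 1; "
                "increase library size or reduce copy number")
        counts[g.gene_id] = int(rng.binomial(total_reads, p)) if k > 0 else 0
    return CountTable(sample_id=sample_id, counts=counts,
                      total_reads=total_reads)


# ---------------------------------------------------------------------------
# SNP allele dosage
# ---------------------------------------------------------------------------

def simulate_snp_sites(
    k_copies: int,
    n_sites: int,
    genome_total_depth: int,
    transcriptome_total_depth: int,
    expression_weights: list[float] | np.ndarray | None = None,
    seed: int = 0,
    gene_id: str = "simgene",
) -> tuple[list[SNPDepthRecord], GroundTruth]:
    """Biallelic SNP depths for a k-copy gene in a diploid individual.

    Each site carries its variant on m alleles, m drawn uniformly in
    [1, k_copies] out of the 2k alleles; genome depths of the variant base
    are Binomial(depth, m / 2k). Transcriptome depths are Binomial with
    success probability equal to the expression-weight share of the
    variant-bearing alleles (``expression_weights``, length 2k, defaults to
    equal expression).
    """
    if k_copies < 1:
        raise ValueError("k_copies must be >= 1")
    n_alleles = 2 * k_copies
    if expression_weights is None:
        weights = np.ones(n_alleles)
    else:
        weights = np.asarray(expression_weights, dtype=float)
        if len(weights) != n_alleles:
            raise ValueError(
                f"need {n_alleles} expression weights (2 per copy)")
        if np.any(weights < 0):
            raise ValueError("expression weights must be non-negative")
    total_w = weights.sum()
    if total_w == 0:
        raise ValueError("zero total expression weight")

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records = []
    truth = GroundTruth()
    for s in range(n_sites):
        m = int(rng.integers(1, k_copies + 1))
        carriers = rng.choice(n_alleles, size=m, replace=False)
        p_genome = m / n_alleles
        p_trans = weights[carriers].sum() / total_w
        g_var = int(rng.binomial(genome_total_depth, p_genome))
        t_var = int(rng.binomial(transcriptome_total_depth, p_trans))
        b_var, b_ref = rng.choice(4, size=2, replace=False)
        rec = SNPDepthRecord(
            gene_id=gene_id, position=s + 1,
            base_a=str(bases[b_var]), base_b=str(bases[b_ref]),
            genome_depth_a=g_var,
            genome_depth_b=genome_total_depth - g_var,
            transcriptome_depth_a=t_var,
            transcriptome_depth_b=transcriptome_total_depth - t_var,
        )
        records.append(rec)
        truth.true_allele_multiplicity[f"{gene_id}:{s + 1}"] = m
    return records, truth


# ---------------------------------------------------------------------------
# Trees and Brownian traits
# ---------------------------------------------------------------------------

def _yule_newick(n_tips: int, birth_rate: float,
                 rng: np.random.Generator) -> str:
    """Pure-birth tree as a Newick string with branch lengths in time units."""
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    # each node: [label_or_None, birth_time, child_a, child_b]
    next_tip = iter(range(1, 10 * n_tips))
    root = {"t": 0.0, "kids": []}
    active = []
    for _ in range(2):
        node = {"t": 0.0, "kids": []}
        root["kids"].append(node)
        active.append(node)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        parent = active.pop(int(rng.integers(len(active))))
        parent["t_split"] = t
        for _ in range(2):
            node = {"t": t, "kids": []}
            parent["kids"].append(node)
            active.append(node)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))

    def render(node: dict, parent_t: float) -> str:
        if node["kids"]:
            t_here = node["kids"][0]["t"]
            inner = ",".join(render(k, t_here) for k in node["kids"])
            return f"({inner}):{t_here - parent_t:.10g}"
        label = f"t{next(next_tip)}"
        return f"{label}:{t_end - parent_t:.10g}"

    inner = ",".join(render(k, 0.0) for k in root["kids"])
    return f"({inner});"


def simulate_tree_and_traits(
    n_tips: int,
    birth_rate: float = 1.0,
    beta: float = 0.3,
    sigma2: float = 0.1,
    seed: int = 0,
) -> tuple[str, list[str], np.ndarray, np.ndarray]:
    """Yule tree plus per-tip copy numbers and log abundances.

    Copy numbers come from thresholding a unit-rate Brownian trait into the
    integers 1..5 at the 20/40/60/80% quantiles of its root-to-present
    marginal; log abundance is beta * copy_number plus a Brownian deviation
    with tip covariance sigma2 * C(tree). Returns
    ``(newick, tip_labels, copy_numbers, log_abundance)``.
    """
    from dosagescan.phylo import brownian_covariance

    rng = np.random.default_rng(seed)
    newick = _yule_newick(n_tips, birth_rate, rng)
    cov = brownian_covariance(newick)
    c = cov.matrix + 1e-10 * np.eye(len(cov.tip_labels))
    chol = np.linalg.cholesky(c)

    u = chol @ rng.standard_normal(n_tips)
    scale = math.sqrt(float(np.mean(np.diag(cov.matrix))))
    cuts = stats.norm.ppf([0.2, 0.4, 0.6, 0.8], scale=scale)
    copies = 1 + np.searchsorted(cuts, u)

    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    dev = (math.sqrt(sigma2) * (chol @ rng.standard_normal(n_tips))
           if sigma2 > 0 else np.zeros(n_tips))
    log_abund = beta * copies + dev
    return newick, list(cov.tip_labels), copies.astype(int), log_abund


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_relative_copy: dict[str, float],
    efficiencies: dict[str, float],
    base_ct: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    sample_id: str = "sim",
) -> list[QPCRMeasure]:
    """Quantification cycles consistent with known relative copy numbers.

    All amplicons share one fluorescence threshold, so a unit template
    quantity satisfies E^(-Ct) = 2^(-base_ct) for every amplicon and

        Ct = (base_ct * ln 2 - ln(quantity)) / ln(E) + Gaussian noise.

    One extra template doubling removes exactly one cycle at E = 2, and the
    efficiency-corrected quantity E^(-Ct) recovers the relative copy exactly
    in the noise-free limit, whatever the per-amplicon efficiencies.
    """
    rng = np.random.default_rng(seed)
    out = []
    for amp, q in true_relative_copy.items():
        if q <= 0:
            raise ValueError(f"{amp}: relative copy must be positive")
        eff = efficiencies[amp]
        if eff <= 1:
            raise ValueError(f"{amp}: efficiency must exceed 1")
        ct_mean = (base_ct * math.log(2.0) - math.log(q)) / math.log(eff)
        for rep in range(n_replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            out.append(QPCRMeasure(
                sample_id=sample_id, amplicon_id=amp,
                ct=ct_mean + noise, efficiency=eff, replicate_index=rep))
    return out


# ---------------------------------------------------------------------------
# Whole-scenario writer (CLI backend)
# ---------------------------------------------------------------------------

def parse_config(path: str | Path) -> SimulationConfig:
    """Plain-text key = value configuration for the simulate CLI."""
    cfg = SimulationConfig()
    spectrum: dict[int, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected key = value")
        key, value = (part.strip() for part in line.split("=", 1))
        if key.startswith("copy_"):
            spectrum[int(key.removeprefix("copy_"))] = float(value)
        elif key in ("n_genes", "seed", "library_size", "length_floor_bp"):
            setattr(cfg, key, int(value))
        elif key in ("gc_intercept", "gc_slope", "length_log_mean",
                     "length_log_sd", "gc_low", "gc_high"):
            setattr(cfg, key, float(value))
        else:
            raise ValueError(f"config line {lineno}: unknown key '{key}'")
    if spectrum:
        cfg.copy_spectrum = spectrum
    cfg.validate()
    return cfg


def write_scenario(config: SimulationConfig, outdir: str | Path) -> None:
    """Generate one full scenario and write every table io_formats reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    genes, truth = simulate_reference(config)
    counts = simulate_counts(
        genes, truth, config.library_size, config.gc_intercept,
        config.gc_slope, seed=seeds[0].generate_state(1)[0] % (2**31))
    write_gene_table(genes, outdir / "genes.tsv")
    write_count_table([counts], outdir / "counts.tsv",
                      outdir / "samples.tsv")
    snps, snp_truth = simulate_snp_sites(
        k_copies=4, n_sites=200, genome_total_depth=500,
        transcriptome_total_depth=500,
        seed=seeds[1].generate_state(1)[0] % (2**31))
    write_snp_table(snps, outdir / "snp.tsv")
    newick, tips, copies, log_abund = simulate_tree_and_traits(
        n_tips=20, beta=0.3, sigma2=0.1,
        seed=seeds[2].generate_state(1)[0] % (2**31))
    (outdir / "tree.nwk").write_text(newick + "\n")
    with open(outdir / "expr.tsv", "w") as fh:
        fh.write("accession_id\tgene_id\trpkm\n")
        for tip, la in zip(tips, log_abund):
            fh.write(f"{tip}\tfam1\t{max(0.0, 10 ** la - 1):.6g}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"seed\t{config.seed}\n")
        for gid, k in truth.true_copy.items():
            fh.write(f"copy:{gid}\t{k}\n")
        for site, m in snp_truth.true_allele_multiplicity.items():
            fh.write(f"snp_m:{site}\t{m}\n")
        for tip, k in zip(tips, copies):
            fh.write(f"tip_copy:{tip}\t{k}\n")
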