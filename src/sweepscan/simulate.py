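"""Two-population synthetic genotype data matched to the scan's model.

The generator works at the allele-frequency level: each SNP gets an ancestral
frequency from a chosen site-frequency spectrum, both populations drift away
from it under the Gaussian approximation Var(p_i) = omega_i * p_a * (1 - p_a)
(draws outside [0, 1] collapse to the boundary, mirroring the scan's
boundary-mass treatment), and diploid genotypes are binomial samples from the
post-drift frequencies.  An optional hard selective sweep in the focal
population applies the deterministic hitchhiking transform: a neutral lineage
at recombination distance r escapes the sweep with probability
c = 1 - q0 ** (r / s); each SNP's tracked allele either rode the sweep
(probability = its pre-sweep focal frequency) or escaped.

Because the generative model is exactly the model the scan assumes, parameter
recovery (omega-hat, sweep localization) has clean semantics.  The generator
does not emulate linkage disequilibrium beyond sweep-induced correlation,
demography, or sequencing error.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GenotypeMatrix, write_vcf

logger = logging.getLogger("sweepscan")


@dataclass(frozen=True)
class SweepConfig:
    """A hard sweep in the focal population.

    position : 0-based bp coordinate of the swept site
    s        : selection coefficient (> 0)
    q0       : initial beneficial-allele frequency
    rho      : recombination rate in Morgans per bp
    """

    position: int
    s: float
    q0: float = 0.005
    rho: float = 3e-8

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"sweep requires s > 0, got {self.s}")
        if not (0 < self.q0 < 1):
            raise ValueError(f"q0 must be in (0, 1), got {self.q0}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_focal: int = 15
    n_reference: int = 15
    chrom: str = "chr1"
    chrom_length: int = 5_000_000
    n_snps: int = 20_000
    omega_focal: float = 0.05
    omega_reference: float = 0.05
    sfs_mode: str = "uniform"  # "uniform" on [0.05, 0.95] or "one_over_x"
    sweep: SweepConfig | None = None

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be > 0")
        if self.omega_focal < 0 or self.omega_reference < 0:
            raise ValueError("omega must be >= 0")
        if self.sfs_mode not in ("uniform", "one_over_x"):
            raise ValueError(f"unknown sfs_mode {self.sfs_mode!r}")
        if self.sweep is not None and not (0 <= self.sweep.position < self.chrom_length):
            raise ValueError("sweep position outside [0, chrom_length)")


@dataclass
class SimulationTruth:
    """Ground truth for a simulated dataset (per-SNP arrays are position-sorted)."""

    config: SimulationConfig
    p_ancestral: np.ndarray
    p_focal: np.ndarray
    p_reference: np.ndarray
    c: np.ndarray                       # escape probability; 1.0 when no sweep
    sweep_window: tuple[int, int] | None  # position +/- the c < 0.5 footprint
    n_monomorphic: int = 0


def _ancestral_frequencies(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    lo, hi = 0.05, 0.95
    if config.sfs_mode == "uniform":
        return rng.uniform(lo, hi, size=config.n_snps)
    # density proportional to 1/x on [lo, hi]: inverse-CDF sampling
    u = rng.random(config.n_snps)
    return lo * (hi / lo) ** u


def _drift(rng: np.random.Generator, p_a: np.ndarray, omega: float) -> np.ndarray:
    if omega == 0:
        return p_a.copy()
    sd = np.sqrt(omega * p_a * (1.0 - p_a))
    return np.clip(p_a + rng.normal(0.0, 1.0, size=p_a.shape) * sd, 0.0, 1.0)


def simulate_neutral(config: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Draw a neutral two-population dataset under Gaussian drift.

    Positions are a sorted sample without replacement from ``[0, L)``;
    monomorphic-in-both-samples SNPs are retained (they still inform windowed
    diversity) but counted in the truth record.
    """
    if config.n_snps > config.chrom_length:
        raise ValueError("n_snps exceeds chromosome length")
    rng = np.random.default_rng(config.seed)
    positions = np.sort(rng.choice(config.chrom_length, size=config.n_snps, replace=False))
    p_a = _ancestral_frequencies(rng, config)
    p_f = _drift(rng, p_a, config.omega_focal)
    p_r = _drift(rng, p_a, config.omega_reference)
    d_f = rng.binomial(2, p_f[:, None], size=(config.n_snps, config.n_focal))
    d_r = rng.binomial(2, p_r[:, None], size=(config.n_snps, config.n_reference))
    dosages = np.hstack([d_f, d_r]).astype(np.int8)
    n_mono = int(((dosages.sum(axis=1) == 0) | (dosages == 2).all(axis=1)).sum())

    n = config.n_snps
    matrix = GenotypeMatrix(
        chroms=np.array([config.chrom] * n, dtype=object),
        pos=positions.astype(np.int64) + 1,
        ref=np.array(["A"] * n, dtype=object),
        alt=np.array(["G"] * n, dtype=object),
        dosages=dosages,
        sample_ids=focal_sample_ids(config) + reference_sample_ids(config),
    )
    truth = SimulationTruth(
        config=config,
        p_ancestral=p_a,
        p_focal=p_f,
        p_reference=p_r,
        c=np.ones(n),
        sweep_window=None,
        n_monomorphic=n_mono,
    )
    return matrix, truth


def focal_sample_ids(config: SimulationConfig) -> list[str]:
    return [f"NY_{i + 1:02d}" for i in range(config.n_focal)]


def reference_sample_ids(config: SimulationConfig) -> list[str]:
    return [f"OT_{i + 1:02d}" for i in range(config.n_reference)]


def apply_sweep(
    matrix: GenotypeMatrix, truth: SimulationTruth, sweep: SweepConfig
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Overlay a hard sweep on a neutral dataset.

    Per SNP at distance d bp from the swept site, with r = d * rho and
    c = 1 - q0 ** (r / s): with probability equal to the SNP's pre-sweep focal
    frequency the tracked (alt) allele rode the sweep, giving post-sweep
    frequency p' = 1 - c + c * p; otherwise p' = c * p.  Focal genotypes are
    re-drawn from Binomial(2, p'); reference genotypes are untouched, as are
    focal genotypes at SNPs with c >= 1 - 1e-12 (fully escaped).
    """
    config = truth.config
    rng = np.random.default_rng([config.seed, 104729])
    pos0 = matrix.pos - 1
    d = np.abs(pos0 - sweep.position).astype(float)
    c = escape_probability_profile(d, sweep)
    p = truth.p_focal
    rode = rng.random(len(p)) < p
    p_new = np.where(rode, 1.0 - c + c * p, c * p)

    affected = c < 1.0 - 1e-12
    n_focal = config.n_focal
    new_dos = matrix.dosages.copy()
    redraw = rng.binomial(2, p_new[affected, None], size=(int(affected.sum()), n_focal))
    new_dos[affected, :n_focal] = redraw.astype(np.int8)

    # footprint where hitchhiking dominates (c < 0.5)
    half = sweep.s * math.log(0.5) / math.log(sweep.q0) / sweep.rho
    lo = max(0, int(sweep.position - half))
    hi = min(config.chrom_length, int(sweep.position + half))

    new_matrix = GenotypeMatrix(
        matrix.chroms, matrix.pos, matrix.ref, matrix.alt, new_dos, matrix.sample_ids
    )
    new_truth = SimulationTruth(
        config=replace(config, sweep=sweep),
        p_ancestral=truth.p_ancestral,
        p_focal=np.where(affected, p_new, p),
        p_reference=truth.p_reference,
        c=c,
        sweep_window=(lo, hi),
        n_monomorphic=truth.n_monomorphic,
    )
    return new_matrix, new_truth


def escape_probability_profile(distance_bp: np.ndarray, sweep: SweepConfig) -> np.ndarray:
    """c = 1 - q0 ** (r / s) with r = d * rho, clipped to [0, 1]; c = 0 at d = 0."""
    r = distance_bp * sweep.rho
    with np.errstate(over="ignore"):
        c = 1.0 - np.power(sweep.q0, r / sweep.s)
    return np.clip(c, 0.0, 1.0)


def simulate(config: SimulationConfig) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Neutral draw plus the configured sweep, if any."""
    matrix, truth = simulate_neutral(config)
    if config.sweep is not None:
        matrix, truth = apply_sweep(matrix, truth, config.sweep)
    return matrix, truth


GENE_TILE_SPACING = 50_000
GENE_TILE_LENGTH = 20_000


def write_fixture(matrix: GenotypeMatrix, truth: SimulationTruth, out_dir: str) -> dict[str, str]:
    """Write VCF + popmap + tiled-gene GFF3 + truth TSV; returns path map.

    Synthetic genes are tiled every 50 kb (length 20 kb) purely to exercise
    gene assignment; popmap labels are "NY" (focal) and "Others".
    """
    os.makedirs(out_dir, exist_ok=True)
    config = truth.config
    paths = {
        "vcf": os.path.join(out_dir, "synthetic.vcf"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_vcf(matrix, paths["vcf"], {config.chrom: config.chrom_length})

    with open(paths["popmap"], "w") as fh:
        for s in focal_sample_ids(config):
            fh.write(f"{s}\tNY\n")
        for s in reference_sample_ids(config):
            fh.write(f"{s}\tOthers\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {config.chrom} 1 {config.chrom_length}\n")
        i = 0
        start = 0
        while start + GENE_TILE_LENGTH <= config.chrom_length:
            fh.write(
                f"{config.chrom}\tsweepscan\tgene\t{start + 1}\t{start + GENE_TILE_LENGTH}"
                f"\t.\t+\t.\tID=SYNGENE{i:04d}\n"
            )
            i += 1
            start += GENE_TILE_SPACING

    with open(paths["truth"], "w") as fh:
        fh.write(f"# seed={config.seed} omega_focal={config.omega_focal} "
                 f"omega_reference={config.omega_reference} sweep={config.sweep}\n")
        fh.write("chrom\tpos\tp_ancestral\tp_focal\tp_reference\tc\n")
        for i in range(matrix.n_variants):
            fh.write(
                f"{matrix.chroms[i]}\t{matrix.pos[i]}\t{truth.p_ancestral[i]:.6g}\t"
                f"{truth.p_focal[i]:.6g}\t{truth.p_reference[i]:.6g}\t{truth.c[i]:.6g}\n"
            )
    logger.info("wrote fixture to %s (%d SNPs, %d samples)",
                out_dir, matrix.n_variants, matrix.n_samples)
    return paths
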