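"""Case-control genotype simulator with LD-structured haplotypes and a
three-genotype penetrance disease model.

Haplotypes come from a latent-Gaussian threshold model: within a block of
SNPs the latent variables share a common correlation rho and are thresholded
at each SNP's minor-allele-frequency quantile, which produces correlated 0/1
haplotypes (an offline stand-in for resampling real reference haplotypes).
Genotypes are sums of two independently drawn haplotypes, so they always lie
in {0, 1, 2}.

Disease status follows the penetrance model P(case | G) = f0, f0*rr1 or
f0*rr2 for 0, 1 or 2 minor alleles at a causal SNP, combined multiplicatively
across causal SNPs and capped at 1; case/control quotas are filled by
rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .setio import GenotypeMatrix, Phenotype, SnpSet

__all__ = [
    "HaplotypePool",
    "DiseaseModel",
    "Scenario",
    "build_haplotype_pool",
    "sample_case_control",
    "generate_scenario",
    "make_scenario",
]


@dataclass
class HaplotypePool:
    """m x d pool of 0/1 haplotypes with block structure and target MAFs."""

    haplotypes: np.ndarray
    blocks: list[tuple[int, int]]  # [start, end) SNP index ranges
    mafs: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if not np.isin(self.haplotypes, [0, 1]).all():
            raise ValueError("haplotype entries must be 0/1")

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class DiseaseModel:
    """Penetrance model: P(case) = min(1, f0 * prod over causal SNPs of
    rr(G)), with rr(0)=1, rr(1)=rr1, rr(2)=rr2."""

    causal_snps: np.ndarray
    f0: float = 0.05
    rr1: float = 1.0
    rr2: float = 1.0

    def __post_init__(self) -> None:
        self.causal_snps = np.asarray(self.causal_snps, dtype=np.int64)
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.rr1 < 0 or self.rr2 < 0:
            raise ValueError("relative risks must be non-negative")

    def penetrance(self, genotypes: np.ndarray) -> np.ndarray:
        """Per-sample disease probability for an (n, d) genotype matrix."""
        rr = np.array([1.0, self.rr1, self.rr2])
        if self.causal_snps.size:
            mult = rr[genotypes[:, self.causal_snps]].prod(axis=1)
        else:
            mult = np.ones(genotypes.shape[0])
        return np.minimum(1.0, self.f0 * mult)


def build_haplotype_pool(
    d: int,
    blocks: int | Sequence[tuple[int, int]] = 10,
    mafs: Optional[np.ndarray] = None,
    rho: float = 0.7,
    pool_size: int = 10000,
    seed: int | np.random.SeedSequence = 0,
) -> HaplotypePool:
    """Draw a haplotype pool from the block latent-Gaussian threshold model.

    ``blocks`` is either a block size (SNPs per block) or explicit
    [start, end) ranges.  ``mafs`` defaults to Uniform(0.05, 0.5) draws.
    Within a block latent normals share correlation rho; across blocks they
    are independent.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(0.05, 0.5, size=d)
    mafs = np.asarray(mafs, dtype=float)
    if mafs.shape != (d,):
        raise ValueError("mafs must have length d")
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    if isinstance(blocks, (int, np.integer)):
        bounds = [(s, min(s + int(blocks), d)) for s in range(0, d, int(blocks))]
    else:
        bounds = [(int(a), int(b)) for a, b in blocks]
    z = np.empty((pool_size, d))
    for a, b in bounds:
        shared = rng.standard_normal((pool_size, 1))
        noise = rng.standard_normal((pool_size, b - a))
        z[:, a:b] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    thresholds = norm.ppf(mafs)
    haplotypes = (z < thresholds).astype(np.uint8)
    return HaplotypePool(haplotypes=haplotypes, blocks=bounds, mafs=mafs, rho=rho)


def sample_case_control(
    pool: HaplotypePool,
    model: DiseaseModel,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.SeedSequence = 0,
    snp_ids: Optional[list[str]] = None,
    batch: int = 4096,
) -> tuple[GenotypeMatrix, Phenotype]:
    """Rejection-sample genotypes until the case and control quotas are met.

    Each individual is two haplotypes drawn uniformly with replacement from
    the pool; status is Bernoulli(penetrance).
    """
    rng = np.random.default_rng(seed)
    m, d = pool.haplotypes.shape
    if model.causal_snps.size and n_cases > 0:
        if model.f0 * max(model.rr1, model.rr2, 1.0) <= 0:
            raise ValueError("disease model gives zero case probability")
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_case_have = n_ctrl_have = 0
    guard = 0
    while n_case_have < n_cases or n_ctrl_have < n_controls:
        guard += 1
        if guard > 10000:
            raise RuntimeError("rejection sampling failed to fill quotas")
        idx = rng.integers(0, m, size=(batch, 2))
        G = pool.haplotypes[idx[:, 0]].astype(np.int8) + pool.haplotypes[idx[:, 1]]
        pi = model.penetrance(G)
        is_case = rng.random(batch) < pi
        if n_case_have < n_cases:
            take = G[is_case][: n_cases - n_case_have]
            if take.size:
                cases.append(take)
                n_case_have += take.shape[0]
        if n_ctrl_have < n_controls:
            take = G[~is_case][: n_controls - n_ctrl_have]
            if take.size:
                controls.append(take)
                n_ctrl_have += take.shape[0]
    values = np.vstack(
        ([np.vstack(cases)] if cases else []) + ([np.vstack(controls)] if controls else [])
    )
    y = np.concatenate([np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)])
    ids = snp_ids or [f"snp{j}" for j in range(d)]
    sample_ids = [f"s{i}" for i in range(n_cases + n_controls)]
    G = GenotypeMatrix(values=values, snp_ids=ids, sample_ids=sample_ids)
    return G, Phenotype(y=y, sample_ids=sample_ids)


@dataclass
class Scenario:
    """A gene-based simulation design: which genes exist, which are causal
    (with 3 disease SNPs each by default), and at what risk level."""

    n_cases: int
    n_controls: int
    genes: list[SnpSet]
    disease_snps: dict[str, np.ndarray]  # gene_id -> local causal SNP indices
    rr1: float
    rr2: float
    f0: float = 0.05
    n_replicates: int = 100
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    rho: float = 0.7
    block_size: int = 10
    pool_size: int = 10000

    def __post_init__(self) -> None:
        gene_ids = {g.set_id for g in self.genes}
        for gid in self.disease_snps:
            if gid not in gene_ids:
                raise ValueError(f"causal gene {gid} not among scenario genes")


def make_scenario(
    n_genes: int = 50,
    n_causal: int = 5,
    snps_per_gene: tuple[int, int] = (11, 175),
    n_disease_snps: int = 3,
    rr: tuple[float, float] = (1.2, 1.3),
    f0: float = 0.05,
    n_cases: int = 500,
    n_controls: int = 500,
    n_replicates: int = 100,
    seed: int = 0,
    **kwargs,
) -> Scenario:
    """Build a scenario with random gene sizes and random disease SNPs.

    Gene SNP counts are drawn uniformly from ``snps_per_gene`` (inclusive);
    the first ``n_causal`` genes carry ``n_disease_snps`` disease SNPs each,
    selected uniformly without replacement.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    sizes = rng.integers(snps_per_gene[0], snps_per_gene[1] + 1, size=n_genes)
    causal_ids = rng.choice(n_genes, size=n_causal, replace=False)
    genes: list[SnpSet] = []
    disease: dict[str, np.ndarray] = {}
    offset = 0
    for g in range(n_genes):
        gid = f"gene{g}"
        genes.append(SnpSet(set_id=gid, snp_indices=np.arange(offset, offset + sizes[g])))
        if g in causal_ids:
            disease[gid] = np.sort(rng.choice(sizes[g], size=n_disease_snps, replace=False))
        offset += sizes[g]
    return Scenario(
        n_cases=n_cases,
        n_controls=n_controls,
        genes=genes,
        disease_snps=disease,
        rr1=rr[0],
        rr2=rr[1],
        f0=f0,
        n_replicates=n_replicates,
        seed=seed,
        **kwargs,
    )


def generate_scenario(
    scenario: Scenario,
) -> Iterator[tuple[int, str, GenotypeMatrix, Phenotype, bool]]:
    """Yield one (replicate_id, gene_id, genotypes, phenotype, is_causal)
    dataset per replicate and gene.

    Each gene has its own haplotype pool (fixed across replicates); causal
    genes use their disease model, null genes the rr1 = rr2 = 1 null model.
    Seeds derive deterministically from (scenario.seed, replicate, gene).
    """
    pools: dict[str, HaplotypePool] = {}
    for g_idx, gene in enumerate(scenario.genes):
        d = len(gene)
        pool_seed = np.random.SeedSequence([scenario.seed, 1, g_idx])
        rng = np.random.default_rng(pool_seed)
        mafs = rng.uniform(*scenario.maf_range, size=d)
        pools[gene.set_id] = build_haplotype_pool(
            d,
            blocks=scenario.block_size,
            mafs=mafs,
            rho=scenario.rho,
            pool_size=scenario.pool_size,
            seed=pool_seed.spawn(1)[0],
        )
    for rep in range(scenario.n_replicates):
        for g_idx, gene in enumerate(scenario.genes):
            gid = gene.set_id
            is_causal = gid in scenario.disease_snps
            if is_causal:
                model = DiseaseModel(
                    causal_snps=scenario.disease_snps[gid],
                    f0=scenario.f0,
                    rr1=scenario.rr1,
                    rr2=scenario.rr2,
                )
            else:
                model = DiseaseModel(causal_snps=np.empty(0, dtype=np.int64), f0=scenario.f0)
            G, y = sample_case_control(
                pools[gid],
                model,
                scenario.n_cases,
                scenario.n_controls,
                seed=np.random.SeedSequence([scenario.seed, 2, rep, g_idx]),
                snp_ids=[f"{gid}:snp{j}" for j in range(len(gene))],
            )
            yield rep, gid, G, y, is_causal
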