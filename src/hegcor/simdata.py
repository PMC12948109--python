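"""Synthetic genotypes, founder-haplotype probabilities and phenotypes.

Generates cohorts with the statistical structure of a multiparental outbred
(Diversity Outbred-style) mapping population: unlinked diploid SNPs drawn at
seeded minor allele frequencies, sparse additive causal architectures with a
known narrow-sense heritability h2, pleiotropic trait pairs with a known
genetic correlation r_g, and random split-half subcohorts.  Everything
downstream (kinship, Haseman-Elston regression, clustering, genome scans) is
testable against these known ground truths.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SimSpec",
    "GenotypeMatrix",
    "SimulatedTrait",
    "Population",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_correlated_pair",
    "simulate_trait_blocks",
    "simulate_founder_probs",
    "simulate_founder_trait",
    "split_half",
    "standardize_dosages",
    "write_genotypes_csv",
    "write_genotypes_hdf5",
    "write_phenotypes_csv",
]

#: Seeded minor allele frequencies used throughout the simulation study.
DEFAULT_MAF_POOL = (0.05, 0.1, 0.3, 0.4)


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Parameters of a simulated cohort.

    Defaults follow the reference simulation design: 1,000 unlinked diploid
    markers, MAFs drawn from {0.05, 0.1, 0.3, 0.4}, 10 causal markers.
    """

    n_individuals: int
    n_markers: int = 1000
    maf_pool: tuple[float, ...] = DEFAULT_MAF_POOL
    n_causal: int = 10
    h2: float = 0.4
    seed: int = 0
    n_founders: int = 8
    map_length: float = 100.0  # Mb per chromosome
    n_chromosomes: int = 1

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_markers < 1:
            raise ValueError("n_individuals and n_markers must be positive")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must lie in [0, 1], got {self.h2}")
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        for p in self.maf_pool:
            if not 0.0 < p <= 0.5:
                raise ValueError(f"allele frequency {p} outside (0, 0.5]")


@dataclasses.dataclass
class GenotypeMatrix:
    """Biallelic dosages (individuals x markers, values 0/1/2) plus marker map."""

    dosages: np.ndarray
    mafs: np.ndarray
    marker_map: pd.DataFrame  # columns: marker, chromosome, position
    ids: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        if len(self.marker_map) != self.dosages.shape[1]:
            raise ValueError("one marker-map row required per marker")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]


@dataclasses.dataclass
class SimulatedTrait:
    """A simulated phenotype with its causal architecture recorded."""

    values: np.ndarray
    causal_indices: np.ndarray
    causal_effects: np.ndarray
    true_h2: float
    genetic_values: np.ndarray


@dataclasses.dataclass
class Population:
    """A cohort bundle: genotypes, optional phenotypes and kinship rows."""

    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame | None = None  # rows aligned with genotype ids
    kinship: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    def subset(self, idx: np.ndarray) -> "Population":
        g = self.genotypes
        sub_g = GenotypeMatrix(
            dosages=g.dosages[idx],
            mafs=g.mafs,
            marker_map=g.marker_map,
            ids=g.ids[idx],
        )
        phen = self.phenotypes.iloc[idx].reset_index(drop=True) if self.phenotypes is not None else None
        kin = self.kinship[np.ix_(idx, idx)] if self.kinship is not None else None
        return Population(sub_g, phen, kin)


def _marker_map(n_markers: int, n_chromosomes: int, map_length: float) -> pd.DataFrame:
    """Uniform marker layout: markers evenly spread over the chromosomes."""
    chrom = np.repeat(np.arange(1, n_chromosomes + 1), -(-n_markers // n_chromosomes))[:n_markers]
    pos = np.empty(n_markers)
    for c in np.unique(chrom):
        m = chrom == c
        k = m.sum()
        pos[m] = np.linspace(0.0, map_length, k) if k > 1 else map_length / 2.0
    names = [f"m{c}_{i}" for i, c in enumerate(chrom, start=1)]
    return pd.DataFrame({"marker": names, "chromosome": chrom, "position": pos})


def simulate_genotypes(spec: SimSpec) -> GenotypeMatrix:
    """Draw unlinked diploid dosages, one binomial(2, p) draw per marker.

    Each marker's allele frequency is sampled from ``spec.maf_pool``; markers
    are mutually independent (no linkage).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    mafs = rng.choice(np.asarray(spec.maf_pool, dtype=float), size=spec.n_markers)
    dosages = rng.binomial(2, mafs, size=(spec.n_individuals, spec.n_markers)).astype(np.int8)
    ids = np.array([f"ind{i:06d}" for i in range(spec.n_individuals)])
    return GenotypeMatrix(dosages, mafs, _marker_map(spec.n_markers, spec.n_chromosomes, spec.map_length), ids)


def standardize_dosages(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Center/scale dosages to (x - 2p) / sqrt(2 p (1-p)) at the given freqs."""
    p = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (dosages - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return z


def _genetic_values(G: GenotypeMatrix, causal_idx: np.ndarray, effects: np.ndarray) -> np.ndarray:
    # seeded (not empirical) allele frequencies keep standardization deterministic
    z = standardize_dosages(G.dosages[:, causal_idx].astype(float), G.mafs[causal_idx])
    return z @ effects


def _calibrate(g: np.ndarray, h2: float, rng: np.random.Generator) -> np.ndarray:
    """Scale genetic values and noise so the realized variance split equals h2."""
    n = g.shape[0]
    sd_g = g.std(ddof=1)
    if h2 == 0.0 or sd_g == 0.0:
        e = rng.standard_normal(n)
        return np.zeros(n) + e / e.std(ddof=1) * np.sqrt(1.0 - h2) if h2 < 1 else np.zeros(n)
    g_scaled = g / sd_g * np.sqrt(h2)
    if h2 == 1.0:
        return g_scaled
    e = rng.standard_normal(n)
    e = e / e.std(ddof=1) * np.sqrt(1.0 - h2)
    return g_scaled + e


def simulate_trait(
    G: GenotypeMatrix,
    h2: float,
    n_causal: int = 10,
    seed: int | np.random.Generator = 0,
) -> SimulatedTrait:
    """Simulate an additive polygenic trait at a known heritability.

    ``n_causal`` markers are chosen at random; their effects are i.i.d.
    standard normal on standardized dosages.  Independent Gaussian noise is
    added and both components are rescaled so that the realized variance of
    the genetic part is exactly ``h2`` of the total (in-sample calibration,
    which keeps small-cohort ground truth tight).
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1], got {h2}")
    if n_causal > G.n_markers:
        raise ValueError("n_causal cannot exceed the number of markers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(G.n_markers, size=n_causal, replace=False))
    effects = rng.standard_normal(n_causal)
    g = _genetic_values(G, causal_idx, effects)
    sd_g = g.std(ddof=1)
    g_scaled = g / sd_g * np.sqrt(h2) if (h2 > 0 and sd_g > 0) else np.zeros_like(g)
    if h2 < 1.0:
        e = rng.standard_normal(G.n_individuals)
        e = e / e.std(ddof=1) * np.sqrt(1.0 - h2)
    else:
        e = np.zeros(G.n_individuals)
    y = g_scaled + e
    return SimulatedTrait(y, causal_idx, effects, float(h2), g_scaled)


def simulate_correlated_pair(
    G: GenotypeMatrix,
    h2_M: float,
    h2_N: float,
    rg_target: float,
    n_causal: int = 10,
    seed: int | np.random.Generator = 0,
) -> tuple[SimulatedTrait, SimulatedTrait]:
    """Simulate a pleiotropic trait pair with a known genetic correlation.

    Both traits share one causal marker set; their per-marker effect pairs are
    drawn from a bivariate normal with correlation ``rg_target``, so the
    correlation of the genetic values converges to ``rg_target`` as the number
    of causal markers grows.  Environmental noise is independent per trait.
    """
    if abs(rg_target) > 1.0:
        raise ValueError(f"|rg_target| must be <= 1, got {rg_target}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    causal_idx = np.sort(rng.choice(G.n_markers, size=n_causal, replace=False))
    cov = np.array([[1.0, rg_target], [rg_target, 1.0]])
    effects = rng.multivariate_normal([0.0, 0.0], cov, size=n_causal)

    traits = []
    for col, h2 in ((0, h2_M), (1, h2_N)):
        g = _genetic_values(G, causal_idx, effects[:, col])
        sd_g = g.std(ddof=1)
        g_scaled = g / sd_g * np.sqrt(h2) if (h2 > 0 and sd_g > 0) else np.zeros_like(g)
        if h2 < 1.0:
            e = rng.standard_normal(G.n_individuals)
            e = e / e.std(ddof=1) * np.sqrt(1.0 - h2)
        else:
            e = np.zeros(G.n_individuals)
        traits.append(SimulatedTrait(g_scaled + e, causal_idx, effects[:, col], float(h2), g_scaled))
    return traits[0], traits[1]


def simulate_trait_blocks(
    G: GenotypeMatrix,
    n_blocks: int = 4,
    traits_per_block: int = 5,
    h2: float = 0.5,
    rg_within: float = 0.9,
    n_causal: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a panel of pleiotropic trait blocks.

    Traits within a block share a common polygenic signal (pairwise genetic
    correlation ``rg_within``); blocks are genetically independent.  Every
    trait has heritability ``h2`` and independent environmental noise, and is
    returned z-scored.  This is the planted structure used to exercise the
    genetic-correlation clustering machinery.
    """
    rng = np.random.default_rng(seed)
    traits = {}
    for b in range(n_blocks):
        shared = simulate_trait(G, 1.0, n_causal, seed=rng)
        gs = shared.genetic_values / shared.genetic_values.std(ddof=1)
        for t in range(traits_per_block):
            own = simulate_trait(G, 1.0, n_causal, seed=rng)
            go = own.genetic_values / own.genetic_values.std(ddof=1)
            g = np.sqrt(rg_within) * gs + np.sqrt(1.0 - rg_within) * go
            g = g / g.std(ddof=1) * np.sqrt(h2)
            e = rng.standard_normal(G.n_individuals)
            e = e / e.std(ddof=1) * np.sqrt(1.0 - h2)
            y = g + e
            traits[f"b{b}t{t}"] = (y - y.mean()) / y.std(ddof=1)
    return pd.DataFrame(traits, index=pd.Index(G.ids, name="id"))


def simulate_founder_probs(
    n_individuals: int,
    n_markers: int = 200,
    n_founders: int = 8,
    seed: int = 0,
    n_chromosomes: int = 1,
    map_length: float = 100.0,
):
    """Simulate founder-haplotype probabilities for an outbred cohort.

    Each individual carries two founder haplotypes drawn independently and
    uniformly at every marker (unlinked ancestry), so the probability vector
    at a marker is (1[f=a] + 1[f=b]) / 2 — a valid distribution over founders.
    Returns a :class:`hegcor.kinship.FounderProbs`.
    """
    from .kinship import FounderProbs  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    hap = rng.integers(0, n_founders, size=(2, n_individuals, n_markers))
    probs = np.zeros((n_individuals, n_markers, n_founders))
    rows = np.arange(n_individuals)[:, None]
    cols = np.arange(n_markers)[None, :]
    for strand in range(2):
        np.add.at(probs, (rows, cols, hap[strand]), 0.5)
    ids = np.array([f"ind{i:06d}" for i in range(n_individuals)])
    labels = np.array([chr(ord("A") + f) for f in range(n_founders)])
    return FounderProbs(probs, _marker_map(n_markers, n_chromosomes, map_length), labels, ids)


def simulate_founder_trait(
    probs,
    marker_index: int,
    founder_effects: np.ndarray,
    h2: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Phenotype driven by founder-allele effects at one planted locus."""
    rng = np.random.default_rng(seed)
    g = probs.probs[:, marker_index, :] @ np.asarray(founder_effects, dtype=float)
    return _calibrate(g - g.mean(), h2, rng)


def split_half(
    population: Population,
    target_sizes: tuple[int, int] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[Population, Population]:
    """Randomly partition a cohort into two disjoint subcohorts.

    Genotype rows, phenotype rows and kinship rows/columns are subset
    consistently.  Defaults to an even split.
    """
    n = population.n_individuals
    if target_sizes is None:
        target_sizes = (n // 2, n - n // 2)
    n1, n2 = target_sizes
    if n1 + n2 > n:
        raise ValueError(f"requested {n1}+{n2} individuals from a cohort of {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    return population.subset(np.sort(perm[:n1])), population.subset(np.sort(perm[n1 : n1 + n2]))


# ---------------------------------------------------------------------------
# writers

def write_genotypes_csv(G: GenotypeMatrix, dosage_path, map_path) -> None:
    df = pd.DataFrame(G.dosages, index=pd.Index(G.ids, name="id"),
                      columns=G.marker_map["marker"])
    df.to_csv(dosage_path)
    G.marker_map.to_csv(map_path, index=False)


def write_genotypes_hdf5(G: GenotypeMatrix, path) -> None:
    """Chunked container, one group per chromosome."""
    with h5py.File(path, "w") as f:
        f.create_dataset("ids", data=np.asarray(G.ids, dtype="S"))
        for c in G.marker_map["chromosome"].unique():
            m = (G.marker_map["chromosome"] == c).to_numpy()
            grp = f.create_group(f"chr{c}")
            grp.create_dataset("dosages", data=G.dosages[:, m], chunks=True)
            grp.create_dataset("position", data=G.marker_map.loc[m, "position"].to_numpy())
            grp.create_dataset("marker", data=G.marker_map.loc[m, "marker"].to_numpy(dtype="S"))
            grp.create_dataset("maf", data=G.mafs[m])


def write_phenotypes_csv(values: pd.DataFrame, path, covariates: pd.DataFrame | None = None) -> None:
    out = values.copy()
    if covariates is not None:
        out = pd.concat([covariates, out], axis=1)
    out.index.name = "id"
    out.to_csv(Path(path))
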