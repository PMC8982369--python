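"""Synthetic multigenerational outbred population and complex-trait simulator.

Eight inbred founder haplotypes are dropped through nonoverlapping
generations of unequal size by random mating with recombinant gametes, so
every animal's genome is a mosaic of founder blocks. Traits are composed
of additive QTL effects, additive-by-additive pair interactions, fixed
covariate shifts (diet, sex, litter, generation) and Gaussian residuals;
the drawn effect vectors are rescaled so the realized variance fractions
hit their targets exactly in the simulated sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError
from .pheno import TraitTable
from .qc import GenotypePanel

__all__ = [
    "FounderHaplotypeSet",
    "PopulationDesign",
    "TraitArchitecture",
    "SimulatedPopulation",
    "SimulatedDataset",
    "simulate_founders",
    "drop_generations",
    "simulate_trait",
    "simulate_traits",
    "inject_missing",
]

N_FOUNDERS = 8


@dataclass
class FounderHaplotypeSet:
    """Binary founder haplotypes plus the SNP map they live on."""

    haplotypes: np.ndarray          # n_founders x n_snps, values in {0, 1}
    snp_map: pd.DataFrame           # snp_id, chrom, cm (strictly increasing per chrom)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ParameterError("founder haplotype entries must be 0/1")
        if self.haplotypes.shape[1] != len(self.snp_map):
            raise ParameterError("haplotype width does not match SNP map")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def segregating(self) -> np.ndarray:
        """Mask of SNPs polymorphic within the founder pool."""
        freq = self.haplotypes.mean(axis=0)
        return (freq > 0) & (freq < 1)


@dataclass
class PopulationDesign:
    """Layout of the simulated generations.

    Defaults mirror a six-generation outbred design with per-generation
    sizes 97, 48, 200, 184, 99 and 197 animals (825 in total).
    """

    generation_labels: tuple = (4, 5, 7, 8, 9, 11)
    generation_sizes: tuple = (97, 48, 200, 184, 99, 197)
    litters_per_generation: int = 2
    sex_ratio: float = 0.5
    diet_levels: tuple = ("A", "B")
    mating: str = "random_pair"

    def __post_init__(self):
        if len(self.generation_labels) != len(self.generation_sizes):
            raise ParameterError("generation labels and sizes differ in length")
        if any(s <= 0 for s in self.generation_sizes):
            raise ParameterError("generation sizes must be positive")
        labels = list(self.generation_labels)
        if labels != sorted(labels) or len(set(labels)) != len(labels):
            raise ParameterError("generation labels must be strictly increasing")
        if len(self.diet_levels) != 2:
            raise ParameterError("exactly two diet levels are supported")
        if not 0.0 < self.sex_ratio < 1.0:
            raise ParameterError("sex_ratio must be in (0, 1)")

    @property
    def n_animals(self) -> int:
        return int(sum(self.generation_sizes))


@dataclass
class TraitArchitecture:
    """Genetic architecture of one simulated trait.

    Fractions refer to the phenotypic variance before fixed effects are
    added (phenotype SD standardized to 1 at that stage).
    """

    n_additive_qtl: int = 1000
    n_epistatic_pairs: int = 0
    h2_additive: float = 0.4
    epistatic_fraction: float = 0.0
    fixed_effect_sizes: dict = field(default_factory=dict)  # keys: diet,sex,litter,generation
    mean: float = 0.0
    # when set, interacting pairs are drawn among this many largest-effect
    # additive QTL (major loci with both main and interaction effects);
    # None draws pairs from all segregating SNPs
    epistatic_pair_pool: int | None = None

    def __post_init__(self):
        for name, v in (
            ("h2_additive", self.h2_additive),
            ("epistatic_fraction", self.epistatic_fraction),
        ):
            if not 0.0 <= v < 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1)")
        if self.h2_additive + self.epistatic_fraction >= 1.0:
            raise ParameterError("h2_additive + epistatic_fraction must be < 1")
        if self.n_additive_qtl < 0 or self.n_epistatic_pairs < 0:
            raise ParameterError("QTL counts must be non-negative")


@dataclass
class SimulatedPopulation:
    """Genotype panel plus pedigree/covariate metadata and gamete bookkeeping."""

    panel: GenotypePanel
    meta: pd.DataFrame                   # animal_id, generation, sex, litter, diet, sire, dam
    haplotypes: np.ndarray               # n_animals x 2 x n_snps (uint8)
    transmissions: np.ndarray | None     # which parental haplotype each gamete copied
    founders: FounderHaplotypeSet


@dataclass
class SimulatedDataset:
    """One simulated trait with its full phenotype decomposition."""

    panel: GenotypePanel
    traits: TraitTable
    trait_name: str
    true_additive_values: np.ndarray
    true_total_genetic_values: np.ndarray
    components: dict                     # mean, fixed, additive, epistatic, residual
    realized_variances: dict
    qtl_registry: dict                   # additive: DataFrame, epistatic: DataFrame
    fixed_effect_values: dict


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def simulate_founders(
    n_snps: int,
    n_chromosomes: int,
    maf_range=(0.1, 0.5),
    seed: int = 0,
    chrom_length_cm: float = 100.0,
) -> FounderHaplotypeSet:
    """Draw 8 binary founder haplotypes on an evenly spaced genetic map.

    For each SNP a founder-pool allele frequency is drawn uniformly from
    ``maf_range`` and rounded to a count out of 8 (clipped to keep the SNP
    segregating); that many founders, chosen at random, carry allele 1.
    SNPs are split across chromosomes as evenly as possible with positions
    evenly spaced along ``chrom_length_cm``.
    """
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ParameterError(f"maf_range {maf_range} must lie within (0, 0.5]")
    if n_snps < n_chromosomes:
        raise ParameterError("need at least one SNP per chromosome")
    rng = np.random.default_rng(seed)

    freqs = rng.uniform(lo, hi, size=n_snps)
    counts = np.clip(np.rint(freqs * N_FOUNDERS).astype(int), 1, N_FOUNDERS - 1)
    haps = np.zeros((N_FOUNDERS, n_snps), dtype=np.uint8)
    for k in range(n_snps):
        carriers = rng.choice(N_FOUNDERS, size=counts[k], replace=False)
        haps[carriers, k] = 1

    per_chrom = np.full(n_chromosomes, n_snps // n_chromosomes)
    per_chrom[: n_snps % n_chromosomes] += 1
    chroms, cms, ids = [], [], []
    k = 0
    for c, m_c in enumerate(per_chrom, start=1):
        spacing = chrom_length_cm / m_c
        for j in range(m_c):
            chroms.append(c)
            cms.append((j + 1) * spacing)
            ids.append(f"snp{c}_{j + 1}")
            k += 1
    snp_map = pd.DataFrame({"snp_id": ids, "chrom": chroms, "cm": cms})
    return FounderHaplotypeSet(haplotypes=haps, snp_map=snp_map)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def _chrom_slices(snp_map: pd.DataFrame):
    out = []
    chroms = np.asarray(snp_map["chrom"])
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        out.append((idx, np.asarray(snp_map["cm"])[idx]))
    return out


def _recombine(hap0, hap1, chrom_info, rate, rng):
    """One recombinant gamete from a pair of haplotypes.

    Crossover count per chromosome is Poisson(length_Morgans * rate) with
    uniform breakpoint positions; returns the gamete and the per-SNP
    source indicator (0 = hap0, 1 = hap1).
    """
    m = hap0.shape[0]
    gamete = np.empty(m, dtype=np.uint8)
    source = np.empty(m, dtype=np.uint8)
    for idx, cm in chrom_info:
        length_morgans = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
        k = rng.poisson(length_morgans * rate) if length_morgans > 0 else 0
        start = rng.integers(0, 2)
        if k == 0:
            src = np.full(len(idx), start, dtype=np.uint8)
        else:
            breaks = rng.uniform(cm[0], cm[-1], size=k)
            src = ((start + np.searchsorted(np.sort(breaks), cm)) % 2).astype(np.uint8)
        source[idx] = src
        gamete[idx] = np.where(src == 0, hap0[idx], hap1[idx])
    return gamete, source


def _founder_mosaic(founders: FounderHaplotypeSet, chrom_info, rate, mosaic_density, rng):
    """A single haplotype stitched from random founder blocks."""
    m = founders.n_snps
    hap = np.empty(m, dtype=np.uint8)
    for idx, cm in chrom_info:
        length_morgans = (cm[-1] - cm[0]) / 100.0 if len(cm) > 1 else 0.0
        k = rng.poisson(length_morgans * rate * mosaic_density) if length_morgans > 0 else 0
        breaks = np.sort(rng.uniform(cm[0], cm[-1], size=k)) if k else np.empty(0)
        seg = np.searchsorted(breaks, cm)
        founders_per_seg = rng.integers(0, founders.n_founders, size=k + 1)
        hap[idx] = founders.haplotypes[founders_per_seg[seg], idx]
    return hap


def _assign_cells(n, design: PopulationDesign, gen_label, rng):
    """Balanced litter/sex/diet assignment within a generation."""
    litters = np.arange(n) % design.litters_per_generation
    sex = np.empty(n, dtype=object)
    diet = np.empty(n, dtype=object)
    for lit in range(design.litters_per_generation):
        cell = np.flatnonzero(litters == lit)
        half = int(round(len(cell) * design.sex_ratio))
        sx = np.array(["F"] * half + ["M"] * (len(cell) - half), dtype=object)
        sex[cell] = sx[rng.permutation(len(cell))]
        dt = np.array(
            [design.diet_levels[i % 2] for i in range(len(cell))], dtype=object
        )
        diet[cell] = dt[rng.permutation(len(cell))]
    # global litter labels: nesting them within generation would alias the
    # generation factor in the precorrection design
    litter_ids = np.array([f"l{v}" for v in litters], dtype=object)
    return litter_ids, sex, diet


def _breed(parent_haps, parent_sex, size, chrom_info, rate, rng):
    """Breed one generation by random sire/dam pairing with recombination.

    Returns (haps, sources, sire_idx, dam_idx); indices refer to rows of
    ``parent_haps``.
    """
    males = np.flatnonzero(parent_sex == "M")
    females = np.flatnonzero(parent_sex == "F")
    if len(males) == 0 or len(females) == 0:
        raise DesignError("no available sire/dam pair in the parent generation")
    m = parent_haps.shape[2]
    haps = np.zeros((size, 2, m), dtype=np.uint8)
    srcs = np.zeros((size, 2, m), dtype=np.uint8)
    sires = rng.choice(males, size=size)
    dams = rng.choice(females, size=size)
    for j in range(size):
        haps[j, 0], srcs[j, 0] = _recombine(
            parent_haps[sires[j], 0], parent_haps[sires[j], 1], chrom_info, rate, rng
        )
        haps[j, 1], srcs[j, 1] = _recombine(
            parent_haps[dams[j], 0], parent_haps[dams[j], 1], chrom_info, rate, rng
        )
    return haps, srcs, sires, dams


def drop_generations(
    founders: FounderHaplotypeSet,
    design: PopulationDesign | None = None,
    crossover_rate: float = 1.0,
    seed: int = 0,
    founder_mosaic_density: float = 5.0,
    track_transmission: bool = True,
    breed_through_gaps: bool = True,
) -> SimulatedPopulation:
    """Drop founder haplotypes through the generations of ``design``.

    First-generation animals receive haplotypes that are direct founder
    mosaics (block density controlled by ``founder_mosaic_density`` extra
    meioses-worth of breakpoints). Every later generation is bred by
    random sire/dam pairing with recombinant gametes
    (Poisson(map length in Morgans x ``crossover_rate``) crossovers).
    Gaps in the generation labels (e.g. 9 -> 11) are bred through
    unrecorded bridge generations when ``breed_through_gaps`` is set, so
    genetic distance tracks the label difference; animals whose parents
    belong to a bridge generation carry empty sire/dam ids.
    """
    design = design or PopulationDesign()
    if founders.n_founders < 2:
        raise DesignError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    chrom_info = _chrom_slices(founders.snp_map)
    m = founders.n_snps

    n_total = design.n_animals
    haps = np.zeros((n_total, 2, m), dtype=np.uint8)
    trans = np.zeros((n_total, 2, m), dtype=np.uint8) if track_transmission else None

    rows = []
    offset = 0
    prev_label = None
    cur_haps: np.ndarray | None = None   # haplotypes of the current parent pool
    cur_sex: np.ndarray | None = None
    cur_ids: list | None = None          # recorded ids, or None for bridge pools
    for gen_label, size in zip(design.generation_labels, design.generation_sizes):
        litter_ids, sex, diet = _assign_cells(size, design, gen_label, rng)
        if cur_haps is None:
            gen_haps = np.zeros((size, 2, m), dtype=np.uint8)
            for j in range(size):
                for h in range(2):
                    gen_haps[j, h] = _founder_mosaic(
                        founders, chrom_info, crossover_rate, founder_mosaic_density, rng
                    )
            srcs = None
            sires = dams = np.full(size, -1)
            parents_recorded = False
        else:
            n_bridge = (gen_label - prev_label - 1) if breed_through_gaps else 0
            for _ in range(int(n_bridge)):
                bridge_size = max(size, 20)
                cur_haps, _, _, _ = _breed(
                    cur_haps, cur_sex, bridge_size, chrom_info, crossover_rate, rng
                )
                half = bridge_size // 2
                cur_sex = np.array(
                    ["F"] * half + ["M"] * (bridge_size - half), dtype=object
                )
                cur_ids = None
            gen_haps, srcs, sires, dams = _breed(
                cur_haps, cur_sex, size, chrom_info, crossover_rate, rng
            )
            parents_recorded = cur_ids is not None

        idx = np.arange(offset, offset + size)
        haps[idx] = gen_haps
        if track_transmission and srcs is not None and parents_recorded:
            trans[idx] = srcs
        for j in range(size):
            if parents_recorded:
                sire_id, dam_id = cur_ids[sires[j]], cur_ids[dams[j]]
            else:
                sire_id = dam_id = ""
            rows.append(
                {
                    "animal_id": f"an{idx[j]:05d}",
                    "generation": gen_label,
                    "sex": sex[j],
                    "litter": litter_ids[j],
                    "diet": diet[j],
                    "sire": sire_id,
                    "dam": dam_id,
                }
            )
        cur_haps, cur_sex = gen_haps, sex
        cur_ids = [f"an{i:05d}" for i in idx]
        prev_label = gen_label
        offset += size

    meta = pd.DataFrame(rows)
    dosages = haps.sum(axis=1).astype(float)
    panel = GenotypePanel(
        animal_ids=meta["animal_id"].to_numpy(object),
        snp_ids=founders.snp_map["snp_id"].to_numpy(object),
        dosages=dosages,
        snp_map=founders.snp_map.copy(),
    )
    return SimulatedPopulation(
        panel=panel, meta=meta, haplotypes=haps, transmissions=trans, founders=founders
    )


def inject_missing(panel: GenotypePanel, rate: float, seed: int = 0) -> GenotypePanel:
    """Set each dosage entry to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ParameterError("missing rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    d = panel.dosages.copy()
    d[rng.random(d.shape) < rate] = np.nan
    return GenotypePanel(panel.animal_ids.copy(), panel.snp_ids.copy(), d, panel.snp_map.copy())


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _rescale(v: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a vector so its sample variance equals target exactly."""
    s = v.var()
    if target_var == 0.0 or s == 0.0:
        return np.zeros_like(v)
    return v * np.sqrt(target_var / s)


def _orthogonalize(v: np.ndarray, others) -> np.ndarray:
    """Project out the span of 1 and the given vectors (sample exactness)."""
    out = v - v.mean()
    basis = []
    for o in others:
        w = o - o.mean()
        for b in basis:
            w = w - (w @ b) * b
        nrm = np.linalg.norm(w)
        if nrm > 1e-12:
            basis.append(w / nrm)
    for b in basis:
        out = out - (out @ b) * b
    return out


def _fixed_effects(meta: pd.DataFrame, sizes: dict, rng) -> tuple[np.ndarray, dict]:
    n = len(meta)
    total = np.zeros(n)
    values: dict = {}
    if not sizes:
        return total, values
    if "diet" in sizes:
        levels = sorted(map(str, pd.unique(meta["diet"])))
        contrast = float(sizes["diet"])
        total += np.where(meta["diet"].astype(str) == levels[-1], contrast, 0.0)
        values["diet"] = {levels[0]: 0.0, levels[-1]: contrast}
    if "sex" in sizes:
        contrast = float(sizes["sex"])
        total += np.where(meta["sex"].astype(str) == "M", contrast, 0.0)
        values["sex"] = {"F": 0.0, "M": contrast}
    if "generation" in sizes:
        levels = sorted(pd.unique(meta["generation"]))
        offs = rng.normal(0.0, float(sizes["generation"]), size=len(levels))
        lut = dict(zip(levels, offs))
        total += np.array([lut[g] for g in meta["generation"]])
        values["generation"] = {str(k): float(v) for k, v in lut.items()}
    if "litter" in sizes:
        levels = sorted(map(str, pd.unique(meta["litter"])))
        offs = rng.normal(0.0, float(sizes["litter"]), size=len(levels))
        lut = dict(zip(levels, offs))
        total += np.array([lut[str(v)] for v in meta["litter"]])
        values["litter"] = {k: float(v) for k, v in lut.items()}
    return total, values


def simulate_trait(
    panel: GenotypePanel,
    arch: TraitArchitecture,
    seed: int = 0,
    meta: pd.DataFrame | None = None,
    trait_name: str = "trait",
) -> SimulatedDataset:
    """Simulate one trait on an existing genotype panel.

    The additive value is a sum over sampled QTL of centered dosages times
    normal effects, rescaled so its realized variance fraction equals
    ``h2_additive`` exactly; the additive-by-additive value does the same
    over products of centered codes for sampled SNP pairs. Residuals are
    rescaled to the remaining variance, so the pre-fixed-effect phenotype
    SD is ~1 by construction. Fixed covariate shifts (requires ``meta``)
    are added last; phenotype = mean + fixed + a + aa + e exactly.
    """
    rng = np.random.default_rng(seed)
    x = panel.dosages
    if np.isnan(x).any():
        raise ParameterError("panel has missing dosages; simulate traits before "
                             "injecting missingness or impute first")
    n = panel.n_animals
    p = x.mean(axis=0) / 2.0
    segregating = np.flatnonzero((p > 0) & (p < 1))
    if arch.n_additive_qtl > segregating.size:
        raise ParameterError(
            f"{arch.n_additive_qtl} additive QTL requested but only "
            f"{segregating.size} segregating SNPs available"
        )
    zc = x - 2.0 * p  # centered codes

    # additive
    if arch.n_additive_qtl > 0 and arch.h2_additive > 0:
        qtl = np.sort(rng.choice(segregating, size=arch.n_additive_qtl, replace=False))
        beta = rng.standard_normal(arch.n_additive_qtl)
        a_raw = zc[:, qtl] @ beta
        a = _rescale(a_raw, arch.h2_additive)
        if a_raw.var() > 0:
            beta = beta * np.sqrt(arch.h2_additive / a_raw.var())
    else:
        qtl = np.empty(0, dtype=int)
        beta = np.empty(0)
        a = np.zeros(n)

    # additive-by-additive pairs
    if arch.n_epistatic_pairs > 0 and arch.epistatic_fraction > 0:
        if arch.epistatic_pair_pool is not None:
            if qtl.size == 0:
                raise ParameterError("epistatic_pair_pool requires additive QTL")
            pool = qtl[np.argsort(-np.abs(beta))[: arch.epistatic_pair_pool]]
        else:
            pool = segregating
        max_pairs = pool.size * (pool.size - 1) // 2
        if arch.n_epistatic_pairs > max_pairs:
            raise ParameterError("more epistatic pairs requested than distinct SNP pairs")
        pairs = set()
        while len(pairs) < arch.n_epistatic_pairs:
            i, j = rng.choice(pool, size=2, replace=False)
            pairs.add((min(i, j), max(i, j)))
        pairs = sorted(pairs)
        gamma = rng.standard_normal(len(pairs))
        epi_raw = np.zeros(n)
        for g, (i, j) in zip(gamma, pairs):
            epi_raw += g * zc[:, i] * zc[:, j]
        # remove the part collinear with the additive value so the
        # epistatic fraction is a pure orthogonal variance share
        epi = _rescale(_orthogonalize(epi_raw, [a]), arch.epistatic_fraction)
        if epi_raw.var() > 0:
            gamma = gamma * np.sqrt(arch.epistatic_fraction / epi_raw.var())
    else:
        pairs = []
        gamma = np.empty(0)
        epi = np.zeros(n)

    resid_var = 1.0 - arch.h2_additive - arch.epistatic_fraction
    e = _rescale(_orthogonalize(rng.standard_normal(n), [a, epi]), resid_var)

    if meta is not None:
        fixed, fx_values = _fixed_effects(meta, arch.fixed_effect_sizes, rng)
    else:
        if arch.fixed_effect_sizes:
            raise ParameterError("fixed_effect_sizes requires animal metadata")
        fixed, fx_values = np.zeros(n), {}

    y = arch.mean + fixed + a + epi + e

    if meta is not None:
        data = meta.copy()
    else:
        data = pd.DataFrame({"animal_id": panel.animal_ids})
        for cov in ("generation", "sex", "diet", "litter"):
            data[cov] = "0"
    data[trait_name] = y
    traits = TraitTable(data=data, trait_names=[trait_name])

    var_y = float(y.var())
    var_nofixed = float((a + epi + e).var())  # variance of the precorrectable part
    realized = {
        "additive": float(a.var()),
        "epistatic": float(epi.var()),
        "residual": float(e.var()),
        "fixed": float(np.asarray(fixed).var()),
        "phenotypic": var_y,
        "h2_additive_realized": float(a.var() / var_nofixed) if var_nofixed > 0 else 0.0,
    }
    registry = {
        "additive": pd.DataFrame(
            {"snp_idx": qtl, "snp_id": panel.snp_ids[qtl], "effect": beta}
        ),
        "epistatic": pd.DataFrame(
            {
                "snp_idx_1": [i for i, _ in pairs],
                "snp_idx_2": [j for _, j in pairs],
                "effect": gamma,
            }
        ),
    }
    return SimulatedDataset(
        panel=panel,
        traits=traits,
        trait_name=trait_name,
        true_additive_values=a,
        true_total_genetic_values=a + epi,
        components={
            "mean": arch.mean,
            "fixed": np.asarray(fixed),
            "additive": a,
            "epistatic": epi,
            "residual": e,
        },
        realized_variances=realized,
        qtl_registry=registry,
        fixed_effect_values=fx_values,
    )


def simulate_traits(
    population: SimulatedPopulation,
    architectures: dict,
    seed: int = 0,
) -> tuple[TraitTable, dict]:
    """Simulate several named traits on one population.

    Returns a combined :class:`TraitTable` and a dict of per-trait
    :class:`SimulatedDataset` objects. Each trait gets an independent
    child seed derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(architectures))
    data = population.meta.copy()
    datasets = {}
    for (name, arch), child in zip(architectures.items(), children):
        ds = simulate_trait(
            population.panel,
            arch,
            seed=child.generate_state(1)[0],
            meta=population.meta,
            trait_name=name,
        )
        data[name] = ds.traits.data[name].to_numpy()
        datasets[name] = ds
    return TraitTable(data=data, trait_names=list(architectures)), datasets
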