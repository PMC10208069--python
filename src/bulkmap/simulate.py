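"""Synthetic bi-parental mapping population and pool-sequencing generator.

Emulates the study design behind a dominant-locus bulked-segregant scan:

* an F2 of ~241 plants from two inbred parents differing at a single
  dominant causal locus (green stigma dominant over yellow),
* 30 + 30 phenotype-selected DNA bulks sequenced to ~54x mean depth,
* F3 families from selfed marker-heterozygous F2 plants for fine mapping,
* a 45-line inbred panel segregating a 15 bp diagnostic insertion.

Meiosis uses the Haldane model (no crossover interference): the number of
crossovers per chromosome is Poisson(L_cM / 100) with breakpoints uniform
on the genetic map. Variant genetic positions are linear in physical
position. Allele "A" is the green parent's (REF) allele and "B" the yellow
parent's (ALT) allele throughout, which fixes the SNP-index orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ConfigError, SamplingError
from .variant_io import SampleCall, SampleRoles, VariantRecord

DEFAULT_ROLES = SampleRoles()


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults reproduce the conditions of the mapping study this package
    models: 11 chromosomes of 30 Mb / 100 cM (~3.3 cM/Mb), 4000 variants
    per chromosome (a down-scaled but same-order density as the study's
    ~392k genome-wide SNPs) plus the causal variant, an F2 of 241, bulks
    of 30, 53.83x
    mean pool depth, 1% per-read error, causal locus at chr6:23,800,000
    with the green (A) allele dominant.
    """

    n_chromosomes: int = 11
    chrom_length_bp: int = 30_000_000
    chrom_length_cM: float = 100.0
    n_variants_per_chrom: int = 4000
    n_f2: int = 241
    bulk_size: int = 30
    mean_depth: float = 53.83
    seq_error_rate: float = 0.01
    causal_chrom: int = 5            # 0-based index -> "chr6"
    causal_pos_bp: int = 23_800_000
    dominance: bool = True
    seed: int = 0
    # GQ emission: two-point mixture exercising the GQ >= 50 filter
    gq_fail_fraction: float = 0.02
    gq_pass: int = 99
    gq_fail: int = 20

    def __post_init__(self):
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length_bp": self.chrom_length_bp,
            "n_variants_per_chrom": self.n_variants_per_chrom,
            "n_f2": self.n_f2,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigError(f"{name} must be > 0, got {value}")
        if self.bulk_size < 0:
            raise ConfigError("bulk_size must be >= 0")
        if not 0.0 <= self.seq_error_rate < 0.5:
            raise ConfigError(
                f"seq_error_rate must be in [0, 0.5), got {self.seq_error_rate}"
            )
        if self.chrom_length_cM < 0:
            raise ConfigError("chrom_length_cM must be >= 0")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if not 0 <= self.causal_chrom < self.n_chromosomes:
            raise ConfigError(
                f"causal_chrom {self.causal_chrom} outside 0..{self.n_chromosomes - 1}"
            )
        if not 1 <= self.causal_pos_bp <= self.chrom_length_bp:
            raise ConfigError("causal_pos_bp outside chromosome")
        if not 0.0 <= self.gq_fail_fraction <= 1.0:
            raise ConfigError("gq_fail_fraction must be in [0, 1]")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class VariantMap:
    """Positions of the simulated variants on physical and genetic maps."""

    chrom_names: tuple
    chrom_index: np.ndarray      # per variant, index into chrom_names
    pos_bp: np.ndarray           # per variant, 1-based position
    pos_cM: np.ndarray           # per variant, genetic position on its chromosome
    causal_index: int            # index of the causal variant

    @property
    def n_variants(self) -> int:
        return len(self.pos_bp)

    def chrom_of(self, index: int) -> str:
        return self.chrom_names[self.chrom_index[index]]

    def indices_on(self, chrom: str) -> np.ndarray:
        ci = self.chrom_names.index(chrom)
        return np.flatnonzero(self.chrom_index == ci)


@dataclass
class Individual:
    """One plant: two phased haplotypes (0 = A/green allele, 1 = B/yellow)."""

    id: str
    hap1: np.ndarray
    hap2: np.ndarray
    phenotype: str

    @property
    def genotypes(self) -> np.ndarray:
        """Count of B (yellow-parent) alleles per variant: 0=AA, 1=AB, 2=BB."""
        return self.hap1 + self.hap2

    def genotype_at(self, index: int) -> str:
        return ("AA", "AB", "BB")[int(self.hap1[index] + self.hap2[index])]


@dataclass
class F2Population:
    """A simulated F2 with its variant map and generating configuration."""

    config: SimConfig
    vmap: VariantMap
    individuals: list

    def __iter__(self):
        return iter(self.individuals)

    def __len__(self):
        return len(self.individuals)

    def phenotype_counts(self) -> dict:
        counts = {"green": 0, "yellow": 0}
        for ind in self.individuals:
            counts[ind.phenotype] += 1
        return counts

    def phenotypes(self) -> dict:
        return {ind.id: ind.phenotype for ind in self.individuals}

    def by_id(self) -> dict:
        return {ind.id: ind for ind in self.individuals}


def build_variant_map(config: SimConfig) -> VariantMap:
    """Uniformly spaced variants per chromosome, plus the causal variant."""
    chrom_names = tuple(f"chr{i + 1}" for i in range(config.n_chromosomes))
    chrom_index, pos_bp = [], []
    causal_index = -1
    offset = 0
    for ci in range(config.n_chromosomes):
        n = config.n_variants_per_chrom
        pos = np.round(np.arange(1, n + 1) * config.chrom_length_bp / (n + 1))
        pos = pos.astype(np.int64)
        if ci == config.causal_chrom and config.causal_pos_bp not in pos:
            pos = np.sort(np.append(pos, config.causal_pos_bp))
        if ci == config.causal_chrom:
            causal_index = offset + int(np.searchsorted(pos, config.causal_pos_bp))
        offset += len(pos)
        chrom_index.append(np.full(len(pos), ci, dtype=np.int64))
        pos_bp.append(pos)
    chrom_index = np.concatenate(chrom_index)
    pos_bp = np.concatenate(pos_bp)
    pos_cM = pos_bp / config.chrom_length_bp * config.chrom_length_cM
    return VariantMap(chrom_names=chrom_names, chrom_index=chrom_index,
                      pos_bp=pos_bp, pos_cM=pos_cM, causal_index=causal_index)


def _gamete(hap_a, hap_b, vmap: VariantMap, length_cM: float, rng) -> np.ndarray:
    """One meiotic product of the diplotype (hap_a, hap_b), Haldane model."""
    gamete = np.empty_like(hap_a)
    for ci in range(len(vmap.chrom_names)):
        idx = vmap.chrom_index == ci
        cm = vmap.pos_cM[idx]
        n_co = rng.poisson(length_cM / 100.0) if length_cM > 0 else 0
        start = rng.integers(2)
        if n_co == 0:
            phase = np.full(cm.shape, start)
        else:
            breaks = np.sort(rng.uniform(0.0, length_cM, size=n_co))
            phase = (start + np.searchsorted(breaks, cm)) % 2
        gamete[idx] = np.where(phase == 0, hap_a[idx], hap_b[idx])
    return gamete


def _phenotype_from_genotype(n_b_alleles: int, dominance: bool) -> str:
    # dominant green: any A allele suffices; otherwise green requires AA
    if dominance:
        return "yellow" if n_b_alleles == 2 else "green"
    return "green" if n_b_alleles == 0 else "yellow"


def simulate_f2(config: SimConfig, rng=None) -> F2Population:
    """Simulate an F2 from two inbred parents (AA... x BB...).

    Both gametes of each individual come from the doubly heterozygous F1,
    so with a zero-length genetic map each gamete is an intact parental
    haplotype and no recombinant haplotypes occur.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vmap = build_variant_map(config)
    hap_a = np.zeros(vmap.n_variants, dtype=np.int8)
    hap_b = np.ones(vmap.n_variants, dtype=np.int8)
    individuals = []
    width = len(str(config.n_f2))
    for i in range(config.n_f2):
        h1 = _gamete(hap_a, hap_b, vmap, config.chrom_length_cM, rng)
        h2 = _gamete(hap_a, hap_b, vmap, config.chrom_length_cM, rng)
        g_causal = int(h1[vmap.causal_index] + h2[vmap.causal_index])
        individuals.append(Individual(
            id=f"F2_{i + 1:0{width}d}", hap1=h1, hap2=h2,
            phenotype=_phenotype_from_genotype(g_causal, config.dominance),
        ))
    return F2Population(config=config, vmap=vmap, individuals=individuals)


def build_bulks(individuals, bulk_size: int, seed=None, rng=None):
    """Select two disjoint phenotype bulks by simple random sampling.

    Returns ``(green_ids, yellow_ids)``, each of length ``bulk_size``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    by_class = {"green": [], "yellow": []}
    for ind in individuals:
        by_class[ind.phenotype].append(ind.id)
    out = {}
    for cls in ("green", "yellow"):
        pool = by_class[cls]
        if len(pool) < bulk_size:
            raise SamplingError(
                f"cannot sample bulk of {bulk_size} from {len(pool)} "
                f"{cls}-phenotype individuals"
            )
        out[cls] = sorted(rng.choice(pool, size=bulk_size, replace=False).tolist())
    return out["green"], out["yellow"]


def _pool_allele_freq(ids, by_id, vmap) -> np.ndarray:
    if not ids:
        raise SamplingError("empty bulk")
    total = np.zeros(vmap.n_variants, dtype=np.int64)
    for ind_id in ids:
        total += by_id[ind_id].genotypes
    return total / (2 * len(ids))


def sample_pool_depths(green_ids, yellow_ids, population: F2Population,
                       config: SimConfig | None = None, rng=None,
                       roles: SampleRoles = DEFAULT_ROLES) -> list:
    """Emit pooled-sequencing variant records for both parents and bulks.

    At each site the bulk's true B-allele frequency is perturbed by the
    per-read error rate (f_obs = f(1-e) + (1-f)e), total depth is Poisson
    with the configured mean, and B-supporting reads are Binomial. Parents
    are emitted as fixed opposite homozygotes. GQ values come from a
    two-point 99/20 mixture with the configured failure fraction.
    """
    if config is None:
        config = population.config
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vmap = population.vmap
    by_id = population.by_id()
    e = config.seq_error_rate
    n = vmap.n_variants

    freqs = {
        roles.pool_green: _pool_allele_freq(green_ids, by_id, vmap),
        roles.pool_yellow: _pool_allele_freq(yellow_ids, by_id, vmap),
        roles.parent_green: np.zeros(n),
        roles.parent_yellow: np.ones(n),
    }
    sample_data = {}
    for name in roles.as_tuple():
        f_obs = freqs[name] * (1 - e) + (1 - freqs[name]) * e
        depth = rng.poisson(config.mean_depth, size=n)
        alt = rng.binomial(depth, f_obs)
        gq = np.where(rng.random(n) < config.gq_fail_fraction,
                      config.gq_fail, config.gq_pass)
        sample_data[name] = (depth, alt, gq)

    # naive genotype call from the alt-read fraction
    def call_gt(depth, alt):
        if depth == 0:
            return "./."
        frac = alt / depth
        if frac <= 0.15:
            return "0/0"
        if frac >= 0.85:
            return "1/1"
        return "0/1"

    records = []
    for i in range(n):
        calls = {}
        for name in roles.as_tuple():
            depth, alt, gq = sample_data[name]
            d, a = int(depth[i]), int(alt[i])
            if name == roles.parent_green:
                gt = "0/0" if d > 0 else "./."
            elif name == roles.parent_yellow:
                gt = "1/1" if d > 0 else "./."
            else:
                gt = call_gt(d, a)
            calls[name] = SampleCall(gt=gt, ad=(d - a, a), gq=int(gq[i]))
        records.append(VariantRecord(
            chrom=vmap.chrom_of(i), pos=int(vmap.pos_bp[i]),
            ref="A", alt="T", calls=calls,
        ))
    return records


CODE_FROM_COUNT = np.array(["A", "H", "B"])


def simulate_f3_family(f2_parent: Individual, vmap: VariantMap,
                       n_offspring: int, marker_indices, marker_labels=None,
                       seed=None, rng=None, length_cM: float | None = None,
                       config: SimConfig | None = None) -> GenotypeMatrix:
    """Self one F2 plant and genotype its offspring at a marker subset.

    ``marker_indices`` index into ``vmap``; phenotypes are assigned from
    the offspring's causal-locus genotype. Warns (and still returns the
    uniform matrix) if the parent is homozygous at every requested marker.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if length_cM is None:
        length_cM = config.chrom_length_cM if config else 100.0
    dominance = config.dominance if config else True
    marker_indices = np.asarray(marker_indices, dtype=np.int64)
    if marker_labels is None:
        marker_labels = [f"M{j + 1}" for j in range(len(marker_indices))]
    het = (f2_parent.hap1[marker_indices] != f2_parent.hap2[marker_indices])
    if len(marker_indices) and not het.any():
        warnings.warn(
            f"parent {f2_parent.id} is homozygous at all requested markers; "
            "offspring will be uniform", stacklevel=2)
    ids, rows, phenotypes = [], [], {}
    width = max(3, len(str(max(n_offspring, 1))))
    for i in range(n_offspring):
        h1 = _gamete(f2_parent.hap1, f2_parent.hap2, vmap, length_cM, rng)
        h2 = _gamete(f2_parent.hap1, f2_parent.hap2, vmap, length_cM, rng)
        ind_id = f"F3_{i + 1:0{width}d}"
        g = h1[marker_indices] + h2[marker_indices]
        ids.append(ind_id)
        rows.append(CODE_FROM_COUNT[g])
        g_causal = int(h1[vmap.causal_index] + h2[vmap.causal_index])
        phenotypes[ind_id] = _phenotype_from_genotype(g_causal, dominance)
    codes = (np.array(rows, dtype="<U1") if rows
             else np.empty((0, len(marker_indices)), dtype="<U1"))
    chroms = {vmap.chrom_of(j) for j in marker_indices}
    return GenotypeMatrix(
        ids=ids, markers=list(marker_labels), codes=codes,
        phenotypes=phenotypes,
        positions=vmap.pos_bp[marker_indices] if len(marker_indices) else None,
        chrom=chroms.pop() if len(chroms) == 1 else None,
    )


def select_markers(vmap: VariantMap, chrom: str, start_bp: int, end_bp: int,
                   n_markers: int, labels_prefix: str = "ST"):
    """Pick ``n_markers`` variants evenly spread over [start_bp, end_bp].

    Returns ``(indices, labels)``; labels are ST1..STn in map order.
    """
    on_chrom = vmap.indices_on(chrom)
    window = on_chrom[(vmap.pos_bp[on_chrom] >= start_bp)
                      & (vmap.pos_bp[on_chrom] <= end_bp)]
    if len(window) < n_markers:
        raise ConfigError(
            f"only {len(window)} variants in {chrom}:{start_bp}-{end_bp}, "
            f"need {n_markers}"
        )
    picks = np.unique(np.round(np.linspace(0, len(window) - 1, n_markers)).astype(int))
    indices = window[picks]
    labels = [f"{labels_prefix}{j + 1}" for j in range(len(indices))]
    return indices, labels


def simulate_panel(n_green: int, n_yellow: int, discordant: int = 0,
                   seed=None, rng=None) -> pd.DataFrame:
    """Inbred diagnostic panel: insertion present iff yellow, minus flips.

    ``discordant`` randomly chosen lines have their insertion state flipped.
    """
    if discordant > n_green + n_yellow:
        raise ConfigError("discordant exceeds panel size")
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = [f"L{i + 1:03d}" for i in range(n_green + n_yellow)]
    phenotype = ["green"] * n_green + ["yellow"] * n_yellow
    insertion = np.array([ph == "yellow" for ph in phenotype])
    if discordant:
        flip = rng.choice(len(ids), size=discordant, replace=False)
        insertion[flip] = ~insertion[flip]
    return pd.DataFrame({"id": ids, "phenotype": phenotype,
                         "insertion": insertion})
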