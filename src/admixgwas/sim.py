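"""Synthetic admixed-cohort generator.

Simulates cohorts with the statistical structure that makes principal-component
adjustment in admixed GWAS interesting: heterogeneous global ancestry
(admixture proportions pi_i drawn from a Beta law), ancestry-differentiated
allele frequencies (each variant has a frequency in each of the two ancestral
populations), local-ancestry structure (independent per-variant draws, or
recombination-block structure from a Poisson crossover process), and
injectable localized-LD features — latent factors tied to one or more genomic
regions, possibly spanning chromosomes — that a top PC can capture instead of
genome-wide ancestry.

The generative model per variant j and individual i: each of the two allele
copies descends from ancestral population 1 with probability pi_i (so the
local-ancestry copy count a_ij is Binomial(2, pi_i) marginally), and carries
the counted allele with probability p_j1 if from population 1, else p_j0.
Hence E[g_ij | pi_i] = 2 (p_j0 + (p_j1 - p_j0) pi_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "AncestralFrequencyPanel",
    "LdFeatureSpec",
    "SimConfig",
    "Cohort",
    "simulate_panel",
    "draw_admixture_proportions",
    "draw_local_ancestry",
    "draw_genotypes",
    "inject_ld_feature",
    "sample_crossovers",
    "true_global_ancestry",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class AncestralFrequencyPanel:
    """Per-variant positions and allele frequencies in two ancestral populations.

    Attributes
    ----------
    chrom : array of str
        Chromosome label per variant.
    pos_bp : array of int
        1-based physical position (bp), strictly increasing within chromosome.
    p0, p1 : array of float
        Frequency of the counted allele in ancestral population 0 / 1.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    p0: np.ndarray
    p1: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=str)
        pos = np.asarray(self.pos_bp, dtype=np.int64)
        p0 = np.asarray(self.p0, dtype=float)
        p1 = np.asarray(self.p1, dtype=float)
        lengths = {len(chrom), len(pos), len(p0), len(p1)}
        if len(lengths) != 1:
            raise ValueError(f"per-variant vectors have unequal lengths {lengths}")
        for name, p in (("p0", p0), ("p1", p1)):
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"{name} contains frequencies outside [0, 1]")
        for c in pd.unique(chrom):
            cpos = pos[chrom == c]
            if np.any(np.diff(cpos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_bp", pos)
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)

    @property
    def n_variants(self) -> int:
        return len(self.pos_bp)

    @property
    def freq_diff(self) -> np.ndarray:
        """Ancestral allele-frequency difference d_j = p_j1 - p_j0."""
        return self.p1 - self.p0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos_bp": self.pos_bp, "p0": self.p0, "p1": self.p1}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AncestralFrequencyPanel":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            chrom=df["chrom"].to_numpy(),
            pos_bp=df["pos_bp"].to_numpy(),
            p0=df["p0"].to_numpy(),
            p1=df["p1"].to_numpy(),
        )


@dataclass(frozen=True)
class LdFeatureSpec:
    """A latent localized-LD feature.

    A diploid latent factor h_i (allele frequency ``latent_freq0`` /
    ``latent_freq1`` in ancestral population 0 / 1) is drawn per individual.
    Every genotype entry at a variant inside one of ``regions`` is then
    independently replaced by h_i with probability ``coupling``; entries not
    replaced keep their original value. Pairwise r^2 among in-region variants
    is therefore approximately ``coupling**2`` and a strongly coupled feature
    forms a block of long-range LD that PCA can pick up — including across
    chromosomes when the regions span several.
    """

    regions: tuple  # of (chrom, start_bp, end_bp)
    latent_freq0: float = 0.5
    latent_freq1: float = 0.5
    coupling: float = 0.9

    def __post_init__(self):
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError(f"coupling must be in [0, 1], got {self.coupling}")
        for f in (self.latent_freq0, self.latent_freq1):
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"latent frequency {f} outside [0, 1]")
        regions = tuple((str(c), int(s), int(e)) for c, s, e in self.regions)
        if not regions:
            raise ValueError("feature must span at least one region")
        for c, s, e in regions:
            if s < 1 or e < s:
                raise ValueError(f"invalid region ({c}, {s}, {e})")
        object.__setattr__(self, "regions", regions)

    def variant_mask(self, panel: AncestralFrequencyPanel) -> np.ndarray:
        mask = np.zeros(panel.n_variants, dtype=bool)
        for c, s, e in self.regions:
            mask |= (panel.chrom == c) & (panel.pos_bp >= s) & (panel.pos_bp <= e)
        return mask


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings.

    ``admixture_mean``/``admixture_sd`` parameterize the Beta law of the
    admixture proportion; ``ancestry_mode`` selects independent per-variant
    local-ancestry draws or recombination blocks (Poisson crossovers at
    ``generations`` per Morgan, positions mapped at ``cm_per_mb``).
    """

    n: int = 500
    admixture_mean: float = 0.8
    admixture_sd: float = 0.1
    ancestry_mode: str = "independent"
    generations: int = 6
    cm_per_mb: float = 1.0
    seed: int = 0
    features: tuple = ()

    def __post_init__(self):
        if not (0.0 < self.admixture_mean < 1.0):
            raise ValueError("admixture_mean must lie in (0, 1)")
        if self.admixture_sd < 0:
            raise ValueError("admixture_sd must be >= 0")
        m, s = self.admixture_mean, self.admixture_sd
        if s**2 >= m * (1 - m):
            raise ValueError(
                f"invalid Beta moments: need sd^2 < mean*(1-mean) "
                f"({s**2:.4g} >= {m * (1 - m):.4g})"
            )
        if self.ancestry_mode not in ("independent", "block"):
            raise ValueError(f"unknown ancestry_mode {self.ancestry_mode!r}")
        if self.ancestry_mode == "block" and self.generations < 1:
            raise ValueError("generations must be >= 1 in block mode")
        object.__setattr__(self, "features", tuple(self.features))


@dataclass
class Cohort:
    """A simulated admixed cohort.

    Attributes
    ----------
    pi : (n,) array
        Admixture proportion (fraction of the genome from population 1).
    ancestry : (n, m) int array
        Copies (0/1/2) at each variant inherited from population 1.
    genotypes : (n, m) int array
        Allele dosage (0/1/2).
    panel : AncestralFrequencyPanel
    latent : dict
        Realized latent feature genotypes, keyed by feature index.
    """

    pi: np.ndarray
    ancestry: np.ndarray
    genotypes: np.ndarray
    panel: AncestralFrequencyPanel
    latent: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.ancestry = np.asarray(self.ancestry)
        self.genotypes = np.asarray(self.genotypes)
        if np.any((self.pi < 0) | (self.pi > 1)):
            raise ValueError("pi outside [0, 1]")
        for name, a in (("ancestry", self.ancestry), ("genotypes", self.genotypes)):
            if a.shape != (len(self.pi), self.panel.n_variants):
                raise ValueError(
                    f"{name} shape {a.shape} inconsistent with "
                    f"n={len(self.pi)}, m={self.panel.n_variants}"
                )
            if np.any((a < 0) | (a > 2)):
                raise ValueError(f"{name} outside {{0, 1, 2}}")

    @property
    def n(self) -> int:
        return len(self.pi)

    @property
    def m(self) -> int:
        return self.panel.n_variants

    def allele_frequencies(self) -> np.ndarray:
        """Sample allele frequency per variant (mean dosage / 2)."""
        return self.genotypes.mean(axis=0) / 2.0


# ---------------------------------------------------------------------------
# generators


def simulate_panel(
    m: int = 5000,
    n_chrom: int = 10,
    chrom_length_bp: int = 10_000_000,
    diff_fraction: float = 0.85,
    diff_range: tuple = (0.2, 0.8),
    neutral_half_width: float = 0.05,
    seed: int = 0,
) -> AncestralFrequencyPanel:
    """Draw an ancestry-informative frequency panel on a desk-scale genome.

    A fraction ``diff_fraction`` of variants get a signed ancestral frequency
    difference |p1 - p0| drawn uniformly on ``diff_range``; the rest are
    near-neutral (|p1 - p0| <= ``neutral_half_width``). A desk-scale panel of
    a few thousand variants has to carry the genome-wide ancestry signal that
    hundreds of thousands of array variants carry in a real cohort, so the
    default panel is enriched for ancestry-informative content; the
    near-neutral minority provides the small-frequency-difference stratum.
    """
    rng = substream(seed, "panel")
    if m % n_chrom != 0:
        raise ValueError("m must be divisible by n_chrom")
    per = m // n_chrom
    chroms, positions = [], []
    for c in range(1, n_chrom + 1):
        pos = np.sort(rng.choice(np.arange(1, chrom_length_bp + 1), size=per, replace=False))
        chroms.append(np.full(per, str(c)))
        positions.append(pos)
    p0 = rng.uniform(0.05, 0.95, size=m)
    differentiated = rng.random(m) < diff_fraction
    lo, hi = diff_range
    delta = np.where(
        differentiated,
        rng.uniform(lo, hi, size=m),
        rng.uniform(0.0, neutral_half_width, size=m),
    ) * rng.choice([-1.0, 1.0], size=m)
    p1 = np.clip(p0 + delta, 0.01, 0.99)
    return AncestralFrequencyPanel(
        chrom=np.concatenate(chroms),
        pos_bp=np.concatenate(positions),
        p0=p0,
        p1=p1,
    )


def demo_multiregion_feature(coupling: float = 0.9) -> LdFeatureSpec:
    """A cross-chromosome LD feature sized for the default desk-scale genome.

    Two 0.4 Mb regions on different chromosomes share one ancestry-neutral
    latent factor, so an un-pruned PCA picks the feature up as a single PC
    with correlation peaks on both chromosomes, while each region fits inside
    the default 0.5 Mb pruning window.
    """
    return LdFeatureSpec(
        regions=(("3", 5_000_001, 5_400_000), ("7", 7_000_001, 7_400_000)),
        coupling=coupling,
    )


def draw_admixture_proportions(
    n: int, mean: float, sd: float, seed: int = 0
) -> np.ndarray:
    """Draw n admixture proportions from a Beta law with given mean and sd.

    ``sd = 0`` yields the degenerate point mass at ``mean``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie in (0, 1)")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.full(n, mean, dtype=float)
    if sd**2 >= mean * (1 - mean):
        raise ValueError(
            f"invalid Beta moments: need sd^2 < mean*(1-mean), "
            f"got sd^2={sd**2:.4g} >= {mean * (1 - mean):.4g}"
        )
    nu = mean * (1 - mean) / sd**2 - 1.0
    rng = substream(seed, "admixture")
    return rng.beta(mean * nu, (1 - mean) * nu, size=n)


def draw_local_ancestry(
    pi: np.ndarray,
    panel: AncestralFrequencyPanel,
    mode: str = "independent",
    generations: int = 6,
    cm_per_mb: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw local-ancestry copy counts a_ij (copies from population 1).

    independent mode: both copies at every variant are population 1 with
    probability pi_i, independently across variants. block mode: per
    haplotype and chromosome, crossovers form a Poisson process with rate
    ``generations`` per Morgan (physical positions mapped at ``cm_per_mb``)
    and each segment is population 1 with probability pi_i. Either way
    E[a_ij] = 2 pi_i.
    """
    pi = np.asarray(pi, dtype=float)
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("pi outside [0, 1]")
    n, m = len(pi), panel.n_variants
    rng = substream(seed, "ancestry")
    if mode == "independent":
        return rng.binomial(2, pi[:, None], size=(n, m)).astype(np.int8)
    if mode != "block":
        raise ValueError(f"unknown ancestry mode {mode!r}")

    a = np.zeros((n, m), dtype=np.int8)
    for c in pd.unique(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        pos_morgan = panel.pos_bp[idx] * cm_per_mb / 1e6 / 100.0
        for i in range(n):
            for _hap in range(2):
                cuts = sample_crossovers(
                    rng, pos_morgan[0], pos_morgan[-1], generations
                )
                seg = np.searchsorted(cuts, pos_morgan, side="right")
                states = rng.random(len(cuts) + 1) < pi[i]
                a[i, idx] += states[seg]
    return a


def sample_crossovers(
    rng: np.random.Generator, start_morgan: float, end_morgan: float, generations: int
) -> np.ndarray:
    """Sample crossover positions on one haplotype of one chromosome.

    A homogeneous Poisson process with rate ``generations`` per Morgan (no
    interference), as accumulated over that many meioses since admixture.
    """
    k = rng.poisson(generations * max(end_morgan - start_morgan, 0.0))
    return np.sort(rng.uniform(start_morgan, end_morgan, size=k))


def draw_genotypes(
    ancestry: np.ndarray, panel: AncestralFrequencyPanel, seed: int = 0
) -> np.ndarray:
    """Draw genotype dosages given local ancestry.

    Each allele copy is Bernoulli(p_j1) if inherited from population 1, else
    Bernoulli(p_j0); the dosage is the sum over the two copies.
    """
    ancestry = np.asarray(ancestry)
    if ancestry.ndim != 2 or ancestry.shape[1] != panel.n_variants:
        raise ValueError(
            f"ancestry shape {ancestry.shape} does not match panel with "
            f"{panel.n_variants} variants"
        )
    rng = substream(seed, "genotypes")
    from_pop1 = rng.binomial(ancestry, panel.p1[None, :])
    from_pop0 = rng.binomial(2 - ancestry, panel.p0[None, :])
    return (from_pop1 + from_pop0).astype(np.int8)


def inject_ld_feature(
    cohort: Cohort, spec: LdFeatureSpec, seed: int = 0
) -> Cohort:
    """Overlay a localized-LD feature on a cohort (returns a new cohort).

    Draws the diploid latent factor h_i (each copy's ancestry Bernoulli(pi_i),
    allele Bernoulli of the corresponding latent frequency), then replaces
    each in-region genotype entry by h_i independently with probability
    ``spec.coupling``. The realized h is recorded in ``cohort.latent``.
    """
    mask = spec.variant_mask(cohort.panel)
    if not mask.any():
        warnings.warn("feature regions contain no panel variants; cohort unchanged")
        return cohort
    rng = substream(seed, "feature", str(len(cohort.latent)))
    n = cohort.n
    copies_pop1 = rng.binomial(2, cohort.pi)
    h = rng.binomial(copies_pop1, spec.latent_freq1) + rng.binomial(
        2 - copies_pop1, spec.latent_freq0
    )
    idx = np.flatnonzero(mask)
    g = cohort.genotypes.copy()
    replace_mask = rng.random((n, len(idx))) < spec.coupling
    g[:, idx] = np.where(replace_mask, h[:, None], g[:, idx])
    latent = dict(cohort.latent)
    latent[len(latent)] = h.astype(np.int8)
    return Cohort(
        pi=cohort.pi,
        ancestry=cohort.ancestry,
        genotypes=g,
        panel=cohort.panel,
        latent=latent,
    )


def true_global_ancestry(ancestry: np.ndarray) -> np.ndarray:
    """Genome-wide average local ancestry, (1/2m) sum_j a_ij, per individual."""
    ancestry = np.asarray(ancestry)
    if ancestry.ndim != 2 or ancestry.shape[1] == 0:
        raise ValueError("ancestry must be a non-empty (n, m) array")
    return ancestry.mean(axis=1) / 2.0


def simulate_cohort(
    panel: AncestralFrequencyPanel, config: SimConfig | None = None, **kwargs
) -> Cohort:
    """Run the full generator: pi -> local ancestry -> genotypes -> features."""
    if config is None:
        config = SimConfig(**kwargs)
    elif kwargs:
        config = replace(config, **kwargs)
    pi = draw_admixture_proportions(
        config.n, config.admixture_mean, config.admixture_sd, seed=config.seed
    )
    ancestry = draw_local_ancestry(
        pi,
        panel,
        mode=config.ancestry_mode,
        generations=config.generations,
        cm_per_mb=config.cm_per_mb,
        seed=config.seed,
    )
    genotypes = draw_genotypes(ancestry, panel, seed=config.seed)
    cohort = Cohort(pi=pi, ancestry=ancestry, genotypes=genotypes, panel=panel)
    for spec in config.features:
        cohort = inject_ld_feature(cohort, spec, seed=config.seed)
    return cohort
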