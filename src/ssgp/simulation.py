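"""Forward simulation of a livestock population under sire selection.

The generator emulates the study design that motivates this package: a
base population of 721 diplotypes carrying realistic linkage
disequilibrium (LD) across ten 0.1 Morgan chromosomes, expanded by random
mating to a founder generation G0 of ``2 * n_dams`` individuals, then five
discrete generations of mass phenotypic selection of sires (top
``n_sires`` males on own phenotype; every dam leaves one male and one
female offspring per generation).

Because the original base came from real cattle haplotypes, the base here
is synthetic: an ancestral pool is initialized at linkage equilibrium with
uniform allele frequencies and drifted through small-population random
mating until the measured adjacent-locus LD reaches the target (drift in
a small population is the standard mechanism for building LD between
tightly linked loci).  Loci that fall below the minimum minor allele
frequency along the way are discarded from an oversampled candidate set,
mirroring the MAF filter applied to the real marker panel.

Trait model: ``n_qtl`` of the loci are causal; substitution effects are
drawn from Normal(mu_alpha, sigma_alpha^2); the true breeding value (TBV)
of an individual is its uncentered allele count at the QTL times the
effects; phenotype = TBV + residual, with the residual variance set from
the sample variance of TBV in G0 and the target heritability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, sort_and_validate

__all__ = [
    "LocusMap",
    "HaplotypeSet",
    "TraitArchitecture",
    "SimulationConfig",
    "StudyDataset",
    "default_locus_map",
    "generate_base_haplotypes",
    "expand_to_founders",
    "select_and_mate",
    "meiosis",
    "sample_qtl_effects",
    "calibrate_trait",
    "simulate_study",
    "mean_adjacent_ld",
    "substream",
]

PANELS = ("qtl_plus_markers", "qtl_only", "markers_only")


def substream(seed: int, stage: str) -> np.random.Generator:
    """Named, reproducible random substream of a master seed.

    Every stochastic stage of the simulator draws from its own stream so a
    stage can be reproduced without replaying the stages before it.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class LocusMap:
    """Genetic map: chromosome, position (Morgans) and QTL flag per locus."""

    chromosome: np.ndarray  # int, 1-based
    position: np.ndarray  # Morgans within chromosome
    is_qtl: np.ndarray  # bool

    def __post_init__(self):
        object.__setattr__(self, "chromosome", np.asarray(self.chromosome, dtype=np.int64))
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "is_qtl", np.asarray(self.is_qtl, dtype=bool))
        for c in np.unique(self.chromosome):
            p = self.position[self.chromosome == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_loci(self) -> int:
        return self.chromosome.size

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    def locus_ids(self) -> np.ndarray:
        return np.array(
            [f"c{c}p{i}" for c, i in zip(self.chromosome, self._within_index())]
        )

    def _within_index(self) -> np.ndarray:
        out = np.zeros(self.n_loci, dtype=int)
        for c in np.unique(self.chromosome):
            m = self.chromosome == c
            out[m] = np.arange(m.sum())
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus_ids(),
                "chromosome": self.chromosome,
                "position": self.position,
                "is_qtl": self.is_qtl.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LocusMap":
        return cls(
            chromosome=frame["chromosome"].to_numpy(),
            position=frame["position"].to_numpy(),
            is_qtl=frame["is_qtl"].to_numpy().astype(bool),
        )


def default_locus_map(
    n_loci: int = 200,
    n_chrom: int = 10,
    chrom_length: float = 0.1,
    qtl_per_chrom: int = 5,
    seed: int = 0,
) -> LocusMap:
    """Evenly spaced loci on ``n_chrom`` chromosomes with random QTL picks.

    Defaults give the 200-locus panel (20 per 0.1 M chromosome, 5 QTL and
    15 markers each); ``n_loci=2000, qtl_per_chrom=50`` gives the dense
    panel (500 QTL + 1500 markers).
    """
    if n_loci % n_chrom:
        raise ValueError("n_loci must be divisible by n_chrom")
    per = n_loci // n_chrom
    if qtl_per_chrom > per:
        raise ValueError("more QTL than loci per chromosome")
    rng = substream(seed, "qtl_placement")
    spacing = chrom_length / per
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)
    pos = np.tile((np.arange(per) + 0.5) * spacing, n_chrom)
    is_qtl = np.zeros(n_loci, dtype=bool)
    for c in range(n_chrom):
        pick = rng.choice(per, size=qtl_per_chrom, replace=False)
        is_qtl[c * per + pick] = True
    return LocusMap(chrom, pos, is_qtl)


@dataclass
class HaplotypeSet:
    """Phased biallelic haplotypes: array (n_individuals, 2, n_loci) in {0,1}.

    The genotype view is the allele sum, the number of copies of the
    reference ("A") allele, in {0, 1, 2}.
    """

    haplotypes: np.ndarray
    locus_map: LocusMap

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.shape[2] != self.locus_map.n_loci:
            raise ValueError("haplotype and locus-map dimensions differ")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    def genotypes(self) -> np.ndarray:
        """Allele-count matrix (n_individuals, n_loci) in {0,1,2}."""
        return self.haplotypes.sum(axis=1, dtype=np.int16).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def subset(self, rows) -> "HaplotypeSet":
        return HaplotypeSet(self.haplotypes[rows], self.locus_map)


def mean_adjacent_ld(
    haplotypes: np.ndarray,
    locus_map: LocusMap,
    measure: str = "r2",
    maf_min: float = 0.0,
) -> float:
    """Mean LD between adjacent loci within chromosomes over all haplotypes.

    ``measure`` is ``"r2"`` (squared allele correlation, the common
    convention) or ``"r"`` (absolute correlation).  Pairs involving a locus
    with MAF below ``maf_min`` are excluded.
    """
    H = haplotypes.reshape(-1, haplotypes.shape[-1]).astype(float)
    freq = H.mean(axis=0)
    ok = np.minimum(freq, 1 - freq) >= max(maf_min, 1e-12)
    vals = []
    for c in np.unique(locus_map.chromosome):
        idx = np.flatnonzero((locus_map.chromosome == c) & ok)
        if idx.size < 2:
            continue
        X = H[:, idx]
        Xc = X - X.mean(axis=0)
        sd = Xc.std(axis=0)
        r = (Xc[:, :-1] * Xc[:, 1:]).mean(axis=0) / (sd[:-1] * sd[1:])
        vals.append(r**2 if measure == "r2" else np.abs(r))
    if not vals:
        return float("nan")
    return float(np.concatenate(vals).mean())


# ---------------------------------------------------------------------------
# meiosis


def _gamete_sources(
    rng: np.random.Generator, positions: np.ndarray, length: float, n_gametes: int
) -> np.ndarray:
    """Source-haplotype indicator (n_gametes, n_loci) for one chromosome.

    Crossover count ~ Poisson(length in Morgans), positions uniform, no
    interference; the source at a locus flips with each crossover to its
    left.  Starting haplotype is a fair coin (independent assortment).
    """
    start = rng.integers(0, 2, size=n_gametes)
    k = rng.poisson(length, size=n_gametes)
    src = np.repeat(start[:, None], positions.size, axis=1)
    for i in np.flatnonzero(k > 0):
        cx = np.sort(rng.uniform(0.0, length, size=k[i]))
        src[i] = (start[i] + np.searchsorted(cx, positions)) % 2
    return src.astype(np.int8)


def _chromosome_slices(locus_map: LocusMap):
    for c in np.unique(locus_map.chromosome):
        idx = np.flatnonzero(locus_map.chromosome == c)
        yield idx, locus_map.position[idx]


def make_gametes(
    parent_haplotypes: np.ndarray,
    locus_map: LocusMap,
    rng: np.random.Generator,
    chrom_length: float,
) -> np.ndarray:
    """One recombinant gamete per parent row: (n, 2, L) -> (n, L)."""
    n = parent_haplotypes.shape[0]
    out = np.empty((n, locus_map.n_loci), dtype=np.int8)
    rows = np.arange(n)[:, None]
    for idx, pos in _chromosome_slices(locus_map):
        src = _gamete_sources(rng, pos, chrom_length, n)
        block = parent_haplotypes[:, :, idx]  # (n, 2, Lc)
        out[:, idx] = block[rows, src, np.arange(idx.size)[None, :]]
    return out


def meiosis(
    parent_haplotypes: np.ndarray,
    locus_map: LocusMap,
    rng: np.random.Generator,
    chrom_length: float = 0.1,
) -> np.ndarray:
    """A single gamete from one phased parent (2, L) -> (L,)."""
    return make_gametes(parent_haplotypes[None], locus_map, rng, chrom_length)[0]


# ---------------------------------------------------------------------------
# base population


def generate_base_haplotypes(
    n_individuals: int,
    locus_map: LocusMap,
    maf_min: float = 0.01,
    ld_target: float = 0.30,
    seed: int = 0,
    *,
    ld_measure: str = "r2",
    ld_tolerance: float = 0.05,
    pool_size: int = 100,
    oversample: int = 4,
    freq_range: tuple[float, float] = (0.1, 0.9),
    burnin_generations: int | None = None,
    max_generations: int = 600,
    check_every: int = 5,
    chrom_length: float = 0.1,
) -> HaplotypeSet:
    """Synthesize a base population with target adjacent-locus LD.

    A pool of ``pool_size`` diploids starts at linkage equilibrium with
    per-locus allele frequencies drawn uniform on ``freq_range``; random
    mating with meiosis is iterated and adjacent-locus LD measured every
    ``check_every`` generations until it reaches ``ld_target`` (or for a
    fixed ``burnin_generations`` when given).  The pool carries
    ``oversample`` times the requested loci; after the final sampling of
    ``n_individuals`` offspring, loci with MAF < ``maf_min`` are dropped
    and the requested number of surviving loci per chromosome (evenly
    thinned) inherit the requested map positions.

    Returns a :class:`HaplotypeSet` aligned with ``locus_map``; the first
    ``n_individuals // 2`` rows are the males by convention.
    """
    n_chrom = np.unique(locus_map.chromosome).size
    per_target = locus_map.n_loci // n_chrom
    per_cand = per_target * oversample
    spacing = chrom_length / per_cand
    cand_map = LocusMap(
        chromosome=np.repeat(np.unique(locus_map.chromosome), per_cand),
        position=np.tile((np.arange(per_cand) + 0.5) * spacing, n_chrom),
        is_qtl=np.zeros(per_cand * n_chrom, dtype=bool),
    )
    L = cand_map.n_loci
    chrom_ids = np.unique(cand_map.chromosome)

    def drift_generation(pool, rng):
        npool = pool.shape[0]
        sires = rng.integers(0, npool, size=npool)
        dams = rng.integers(0, npool, size=npool)
        pat = make_gametes(pool[sires], cand_map, rng, chrom_length)
        mat = make_gametes(pool[dams], cand_map, rng, chrom_length)
        return np.stack([pat, mat], axis=1)

    def assemble(pool, rng):
        """Sample the base from the pool, MAF-filter and thin to the map.

        Returns (haplotypes or None, measured adjacent LD, minimum per-
        chromosome survivor count); the sample that passes the stopping
        rule is the one returned, so the measured statistic holds for the
        delivered base.
        """
        npool = pool.shape[0]
        sires = rng.integers(0, npool, size=n_individuals)
        dams = rng.integers(0, npool, size=n_individuals)
        pat = make_gametes(pool[sires], cand_map, rng, chrom_length)
        mat = make_gametes(pool[dams], cand_map, rng, chrom_length)
        base = np.stack([pat, mat], axis=1)
        f = base.mean(axis=(0, 1))
        maf_ok = np.minimum(f, 1 - f) >= maf_min
        keep = np.zeros(L, dtype=bool)
        min_surv = L
        short = False
        for c in chrom_ids:
            idx = np.flatnonzero((cand_map.chromosome == c) & maf_ok)
            min_surv = min(min_surv, idx.size)
            if idx.size < per_target:
                short = True
                continue
            picks = idx[np.round(np.linspace(0, idx.size - 1, per_target)).astype(int)]
            keep[picks] = True
        if short:
            return None, float("nan"), min_surv
        hap = base[:, :, keep]
        ld = mean_adjacent_ld(hap, locus_map, measure=ld_measure)
        return hap, ld, min_surv

    def attempt(pool_size, rng):
        freq = rng.uniform(freq_range[0], freq_range[1], size=L)
        pool = (rng.random((pool_size, 2, L)) < freq).astype(np.int8)
        if burnin_generations is not None:
            for _ in range(burnin_generations):
                pool = drift_generation(pool, rng)
            hap, ld, _ = assemble(pool, rng)
            if hap is None:
                raise RuntimeError(
                    f"too few loci with MAF >= {maf_min} after "
                    f"{burnin_generations} burn-in generations"
                )
            return HaplotypeSet(hap, locus_map)
        # adaptive burn-in: drift until the measured statistic reaches the
        # target; when LD stalls (fixation keeps removing high-LD pairs)
        # and locus survivorship is comfortable, shrink the pool to
        # strengthen drift
        gen = 0
        last_ld = -np.inf
        shrink_at = max(check_every, max_generations // 4)
        while True:
            hap, ld, min_surv = assemble(pool, rng)
            if hap is not None and np.isfinite(ld) and ld >= ld_target:
                return HaplotypeSet(hap, locus_map)
            if gen >= max_generations or min_surv < per_target:
                raise RuntimeError(
                    f"adjacent LD {ld:.3f} did not reach target {ld_target} "
                    f"after {gen} burn-in generations "
                    f"(minimum surviving loci per chromosome: {min_surv})"
                )
            if (
                gen
                and gen % shrink_at == 0
                and pool.shape[0] > 50
                and ld <= last_ld + 0.01
                and min_surv >= 2 * per_target
            ):
                pool = pool[: max(50, pool.shape[0] * 2 // 3)]
            last_ld = max(last_ld, ld) if np.isfinite(ld) else last_ld
            for _ in range(check_every):
                pool = drift_generation(pool, rng)
            gen += check_every

    err = None
    for k in range(4):  # deterministic retries with a larger pool
        stage = "base_population" if k == 0 else f"base_population/retry{k}"
        try:
            return attempt(int(pool_size * 1.5**k), substream(seed, stage))
        except RuntimeError as e:
            err = e
    raise RuntimeError(
        f"{err}; consider a different pool_size or a larger oversample factor"
    )


# ---------------------------------------------------------------------------
# trait


@dataclass
class TraitArchitecture:
    """Additive trait: QTL effects, variances and the founder genotype mean.

    ``sigma2_g`` is the sample variance of TBV in G0 and ``sigma2_e`` the
    residual variance implied by the target heritability; both are the
    (fixed, known) variances later used by every fitter.  ``k`` records
    the true mean genotype covariate vector of the founders, so the
    founder mean mu_g = k @ alpha is available as a diagnostic.
    """

    alpha: np.ndarray  # substitution effect per QTL
    mu_alpha: float
    beta: float
    h2: float
    sigma2_g: float = np.nan
    sigma2_e: float = np.nan
    k: np.ndarray | None = None

    @property
    def mu_g_true(self) -> float:
        """Founder-mean genotypic component k'alpha (QTL covariates only)."""
        if self.k is None:
            return float("nan")
        return float(self.k @ self.alpha)


def sample_qtl_effects(
    n_qtl: int, mu_alpha: float, seed: int, sigma_alpha: float = 1.0
) -> np.ndarray:
    """i.i.d. Normal(mu_alpha, sigma_alpha^2) substitution effects."""
    rng = substream(seed, "qtl_effects")
    return rng.normal(mu_alpha, sigma_alpha, size=n_qtl)


def calibrate_trait(tbv_g0: np.ndarray, h2: float) -> tuple[float, float]:
    """Variances from G0: sigma2_g = var(TBV in G0), sigma2_e from h2."""
    if not 0 < h2 < 1:
        raise ValueError(f"heritability {h2} outside (0, 1)")
    sigma2_g = float(np.var(tbv_g0, ddof=1))
    sigma2_e = sigma2_g * (1 - h2) / h2
    return sigma2_g, sigma2_e


# ---------------------------------------------------------------------------
# study configuration and dataset


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the forward simulation; defaults are the study design.

    ``reduced()`` gives the desk-scale variant (800 dams / 40 sires, same
    5% selected proportion) used by the fast test grid.
    """

    n_loci: int = 200
    n_chrom: int = 10
    chrom_length: float = 0.1
    qtl_per_chrom: int = 5
    n_base: int = 721
    n_dams: int = 4000
    n_sires: int = 200
    n_generations: int = 5
    n_expansion_generations: int = 4
    h2: float = 0.5
    mu_alpha: float = 0.2
    sigma_alpha: float = 0.05
    beta: float = 0.0
    maf_min: float = 0.01
    ld_target: float = 0.30
    ld_measure: str = "r2"
    pool_size: int = 100
    oversample: int = 4
    same_sire_per_dam: bool = False
    select_sires: bool = True

    @classmethod
    def reduced(cls, **overrides) -> "SimulationConfig":
        base = dict(n_dams=800, n_sires=40)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class StudyDataset:
    """Everything a fitter consumes: pedigree, genotypes, trait, masks.

    The pedigree spans generations 0..n_generations with G0 as founders;
    phenotypes are observed for generations 0..n_generations-1; genotypes
    are observed for the selected sires of each of those generations plus
    the whole final generation, which is the validation set (TBVs known,
    phenotypes withheld).
    """

    pedigree: Pedigree
    haplotypes: HaplotypeSet
    tbv: np.ndarray
    phenotype: np.ndarray  # NaN where unobserved
    genotyped: np.ndarray  # bool per pedigree member
    trait: TraitArchitecture
    config: SimulationConfig
    seed: int
    expansion_pedigree: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def generation(self) -> np.ndarray:
        return self.pedigree.generation

    @property
    def genotyped_ids(self) -> np.ndarray:
        return self.pedigree.ids[self.genotyped]

    @property
    def validation_mask(self) -> np.ndarray:
        return self.generation == self.config.n_generations

    @property
    def training_mask(self) -> np.ndarray:
        return ~np.isnan(self.phenotype)

    def panel_loci(self, panel: str = "qtl_plus_markers") -> np.ndarray:
        """Locus indices of a panel, with loci fixed in the genotyped set
        removed (a fixed covariate column carries no information)."""
        if panel not in PANELS:
            raise ValueError(f"panel must be one of {PANELS}, got {panel!r}")
        is_qtl = self.haplotypes.locus_map.is_qtl
        if panel == "qtl_only":
            mask = is_qtl.copy()
        elif panel == "markers_only":
            mask = ~is_qtl
        else:
            mask = np.ones_like(is_qtl)
        geno = self.haplotypes.genotypes()[self.genotyped]
        fixed = (geno == geno[0]).all(axis=0)
        return np.flatnonzero(mask & ~fixed)

    def observed_genotypes(self, panel: str = "qtl_plus_markers") -> np.ndarray:
        """Mg: allele counts of genotyped individuals at the panel loci."""
        cols = self.panel_loci(panel)
        return self.haplotypes.genotypes()[self.genotyped][:, cols].astype(float)


def _tbv_of(haplotypes: np.ndarray, qtl_cols: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    geno = haplotypes[:, 0, :][:, qtl_cols] + haplotypes[:, 1, :][:, qtl_cols]
    return geno.astype(float) @ alpha


def expand_to_founders(
    base: HaplotypeSet,
    n_dams: int,
    n_expansion_generations: int,
    rng: np.random.Generator,
    chrom_length: float = 0.1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Expand the base to the founder generation G0 by random mating.

    Base individuals (first half male) are sampled in male-female pairs
    with replacement to produce ``n_dams`` male and ``n_dams`` female
    offspring; then ``n_expansion_generations`` nonoverlapping random-
    mating generations follow (one male and one female offspring per dam,
    sires drawn at random).  No mutation.  Returns the G0 haplotypes
    (males first) and the recorded expansion pedigree (row indices within
    each generation).
    """
    locus_map = base.locus_map
    n_gen_size = 2 * n_dams
    n_base_males = base.n_individuals // 2

    pair_s = rng.integers(0, n_base_males, size=n_gen_size)
    pair_d = n_base_males + rng.integers(
        0, base.n_individuals - n_base_males, size=n_gen_size
    )
    hap = np.stack(
        [
            make_gametes(base.haplotypes[pair_s], locus_map, rng, chrom_length),
            make_gametes(base.haplotypes[pair_d], locus_map, rng, chrom_length),
        ],
        axis=1,
    )
    rows = [
        pd.DataFrame(
            {
                "generation": -n_expansion_generations - 1,
                "sire_row": pair_s,
                "dam_row": pair_d,
            }
        )
    ]
    males = np.arange(n_dams)
    dams = np.arange(n_dams, n_gen_size)
    for g in range(n_expansion_generations):
        sire_of = males[rng.integers(0, males.size, size=n_gen_size)]
        dam_of = np.concatenate([dams, dams])  # one male + one female per dam
        pat = make_gametes(hap[sire_of], locus_map, rng, chrom_length)
        mat = make_gametes(hap[dam_of], locus_map, rng, chrom_length)
        hap = np.stack([pat, mat], axis=1)
        rows.append(
            pd.DataFrame(
                {
                    "generation": g - n_expansion_generations,
                    "sire_row": sire_of,
                    "dam_row": dam_of,
                }
            )
        )
    return hap, pd.concat(rows, ignore_index=True)


def select_and_mate(
    haplotypes: np.ndarray,
    sex: np.ndarray,
    phenotype: np.ndarray,
    n_sires: int,
    locus_map: LocusMap,
    rng: np.random.Generator,
    chrom_length: float = 0.1,
    same_sire_per_dam: bool = False,
    select_sires: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One round of mass sire selection and mating.

    Males are ranked on own phenotype (ties broken by position, for
    determinism) and the top ``n_sires`` selected; every dam produces one
    male and one female offspring, each offspring's sire drawn uniformly
    from the selected set (or one shared sire per dam when
    ``same_sire_per_dam``).  Returns (child haplotypes with males first,
    sire row of each child, dam row of each child, selected male rows).
    """
    males = np.flatnonzero(sex == "M")
    dams = np.flatnonzero(sex == "F")
    n_gen_size = haplotypes.shape[0]
    if males.size < n_sires:
        raise ValueError(f"only {males.size} males, cannot select {n_sires} sires")
    if select_sires:
        order = np.lexsort((males, -phenotype[males]))
        selected = males[order[:n_sires]]
    else:
        selected = rng.choice(males, size=n_sires, replace=False)
    if same_sire_per_dam:
        per_dam = selected[rng.integers(0, n_sires, size=dams.size)]
        sire_of = np.concatenate([per_dam, per_dam])
    else:
        sire_of = selected[rng.integers(0, n_sires, size=n_gen_size)]
    dam_of = np.concatenate([dams, dams])
    child = np.stack(
        [
            make_gametes(haplotypes[sire_of], locus_map, rng, chrom_length),
            make_gametes(haplotypes[dam_of], locus_map, rng, chrom_length),
        ],
        axis=1,
    )
    return child, sire_of, dam_of, selected


def simulate_study(config: SimulationConfig = SimulationConfig(), seed: int = 0) -> StudyDataset:
    """Run the full forward simulation for one replicate.

    Stages (each on its own random substream of ``seed``): base population
    with LD - expansion by random mating to G0 - QTL effects and trait
    calibration on G0 - n_generations rounds of sire selection and mating.
    """
    locus_map = default_locus_map(
        config.n_loci, config.n_chrom, config.chrom_length, config.qtl_per_chrom, seed
    )
    base = generate_base_haplotypes(
        config.n_base,
        locus_map,
        maf_min=config.maf_min,
        ld_target=config.ld_target,
        seed=seed,
        ld_measure=config.ld_measure,
        pool_size=config.pool_size,
        oversample=config.oversample,
        chrom_length=config.chrom_length,
    )
    n_per_sex = config.n_dams
    n_gen_size = 2 * n_per_sex
    g0_hap, expansion_pedigree = expand_to_founders(
        base,
        config.n_dams,
        config.n_expansion_generations,
        substream(seed, "expansion"),
        config.chrom_length,
    )
    sex = np.array(["M"] * n_per_sex + ["F"] * n_per_sex)

    # trait architecture calibrated on G0
    qtl_cols = np.flatnonzero(locus_map.is_qtl)
    alpha = sample_qtl_effects(locus_map.n_qtl, config.mu_alpha, seed, config.sigma_alpha)
    tbv_g0 = _tbv_of(g0_hap, qtl_cols, alpha)
    sigma2_g, sigma2_e = calibrate_trait(tbv_g0, config.h2)
    k_true = g0_hap[:, :, qtl_cols].sum(axis=1).mean(axis=0).astype(float)
    trait = TraitArchitecture(
        alpha=alpha,
        mu_alpha=config.mu_alpha,
        beta=config.beta,
        h2=config.h2,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        k=k_true,
    )

    pheno_rng = substream(seed, "phenotypes")
    select_rng = substream(seed, "selection")

    n_total = n_gen_size * (config.n_generations + 1)
    all_hap = np.empty((n_total, 2, locus_map.n_loci), dtype=np.int8)
    all_sire = np.full(n_total, -1, dtype=np.int64)
    all_dam = np.full(n_total, -1, dtype=np.int64)
    all_gen = np.repeat(np.arange(config.n_generations + 1), n_gen_size)
    all_sex = np.tile(sex, config.n_generations + 1)
    genotyped = np.zeros(n_total, dtype=bool)

    all_hap[:n_gen_size] = g0_hap
    all_tbv = np.empty(n_total)
    all_tbv[:n_gen_size] = tbv_g0
    all_pheno = np.full(n_total, np.nan)

    for g in range(config.n_generations):
        lo = g * n_gen_size
        sl = slice(lo, lo + n_gen_size)
        all_pheno[sl] = all_tbv[sl] + pheno_rng.normal(0.0, np.sqrt(sigma2_e), n_gen_size)
        child_hap, sire_of, dam_of, selected = select_and_mate(
            all_hap[sl],
            all_sex[sl],
            all_pheno[sl],
            config.n_sires,
            locus_map,
            select_rng,
            config.chrom_length,
            same_sire_per_dam=config.same_sire_per_dam,
            select_sires=config.select_sires,
        )
        genotyped[lo + selected] = True
        child = slice(lo + n_gen_size, lo + 2 * n_gen_size)
        all_hap[child] = child_hap
        all_sire[child] = lo + sire_of
        all_dam[child] = lo + dam_of
        all_tbv[child] = _tbv_of(all_hap[child], qtl_cols, alpha)

    genotyped[all_gen == config.n_generations] = True  # whole validation generation

    ids = np.arange(1, n_total + 1)
    pedigree = sort_and_validate(
        Pedigree(ids=ids, sire=all_sire, dam=all_dam, generation=all_gen, sex=all_sex)
    )
    return StudyDataset(
        pedigree=pedigree,
        haplotypes=HaplotypeSet(all_hap, locus_map),
        tbv=all_tbv,
        phenotype=all_pheno,
        genotyped=genotyped,
        trait=trait,
        config=config,
        seed=seed,
        expansion_pedigree=expansion_pedigree,
    )
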