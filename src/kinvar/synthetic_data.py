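"""Forward pedigree simulation with gene-dropped markers and selection.

The generator emulates a discrete-generation livestock scheme: a founder
population of unrelated males and females, random 1:1 mating of the selected
half of the females each generation, fixed litter size, selection of dams on
their own phenotype, and neutral unlinked markers gene-dropped from founder
alleles.  Genotypes are retained only for the late generations, phenotypes
are missing for founders and a share of males, and a fraction of sire/dam
links is masked to mimic incomplete pedigree recording.

True breeding values follow the pedigree recursion
``u_i = (u_s + u_d)/2 + m_i`` with Mendelian-sampling variance
``(1 - (F_s + F_d)/2) * sigma2_g / 2``; inbreeding coefficients are tracked
exactly through an incrementally built numerator relationship matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import PhenotypeTable
from .relmat import UNKNOWN, GenotypeMatrix, Pedigree

__all__ = [
    "SimulationConfig",
    "SimulatedPopulation",
    "simulate_population",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated population.

    Defaults follow the reference design: 100 + 100 founders, 10 discrete
    generations, litter size 4, the top half of females selected as dams on
    own phenotype, 5,000 markers with genotypes kept for generations 8–10,
    phenotypes missing for founders and 25% of males, 10% of sires and 5% of
    dams masked, true h² 0.30 with phenotypic sd 6.5 around a mean of 48.
    """

    n_founder_males: int = 100
    n_founder_females: int = 100
    n_generations: int = 10
    litter_size: int = 4
    prop_dams_selected: float = 0.5
    n_markers: int = 5000
    genotyped_generations: tuple[int, int] = (8, 10)
    male_phenotype_missing_rate: float = 0.25
    sire_mask_rate: float = 0.10
    dam_mask_rate: float = 0.05
    h2: float = 0.30
    var_phenotypic: float = 42.25
    mean_phenotype: float = 48.0
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int | None = None

    def __post_init__(self):
        for r in (
            self.prop_dams_selected,
            self.male_phenotype_missing_rate,
            self.sire_mask_rate,
            self.dam_mask_rate,
        ):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_generations < 0 or self.litter_size < 1:
            raise ValueError("invalid generation count or litter size")
        if not 0 < self.h2 < 1 or self.var_phenotypic <= 0:
            raise ValueError("h2 must be in (0,1) and phenotypic variance positive")

    @property
    def sigma2_g(self) -> float:
        return self.h2 * self.var_phenotypic

    @property
    def sigma2_e(self) -> float:
        return (1 - self.h2) * self.var_phenotypic


@dataclass
class SimulatedPopulation:
    """Full truth plus the masked/observed views handed to an analysis."""

    config: SimulationConfig
    pedigree: Pedigree
    masked_pedigree: Pedigree
    genotypes: GenotypeMatrix | None
    phenotypes: PhenotypeTable
    true_breeding_values: np.ndarray  # aligned with pedigree.ids
    generation: np.ndarray
    sex: np.ndarray  # 0 = male, 1 = female
    inbreeding: np.ndarray
    # true base-population marker frequencies; genotypes themselves default
    # to observed frequencies, as with real data
    founder_allele_freqs: np.ndarray | None = None

    @property
    def genotyped_ids(self) -> list[str]:
        return [] if self.genotypes is None else list(self.genotypes.ids)


MALE, FEMALE = 0, 1


def simulate_population(
    cfg: SimulationConfig, seed: int | None = None
) -> SimulatedPopulation:
    """Run the forward simulation; ``seed`` overrides ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sg2, se2 = cfg.sigma2_g, cfg.sigma2_e
    n0 = cfg.n_founder_males + cfg.n_founder_females

    # growable state, A kept incrementally for exact inbreeding
    cap = max(1024, 2 * n0)
    A = np.zeros((cap, cap))
    sire = [UNKNOWN] * n0
    dam = [UNKNOWN] * n0
    sex = [MALE] * cfg.n_founder_males + [FEMALE] * cfg.n_founder_females
    gen = [0] * n0
    u = list(rng.normal(0.0, np.sqrt(sg2), size=n0))
    y = [np.nan] * n0  # founder phenotypes missing
    A[np.diag_indices(n0)] = 1.0
    n = n0

    def grow(extra: int):
        nonlocal A, cap
        if n + extra > cap:
            cap = max(2 * cap, n + extra)
            newA = np.zeros((cap, cap))
            newA[:n, :n] = A[:n, :n]
            A = newA

    for g in range(1, cfg.n_generations + 1):
        prev = [i for i in range(n) if gen[i] == g - 1]
        males = [i for i in prev if sex[i] == MALE]
        females = [i for i in prev if sex[i] == FEMALE]
        n_dams = int(round(cfg.prop_dams_selected * len(females)))
        if n_dams == 0 or not males:
            raise ValueError(
                f"generation {g}: selection leaves no breeding pairs "
                f"({len(males)} males, {n_dams} selected dams)"
            )
        fy = np.array([y[i] for i in females])
        if np.isnan(fy).all():
            dams = list(rng.choice(females, size=n_dams, replace=False))
        else:
            order = np.argsort(-np.nan_to_num(fy, nan=-np.inf))
            dams = [females[k] for k in order[:n_dams]]
        sires = list(
            rng.choice(males, size=n_dams, replace=len(males) < n_dams)
        )
        grow(n_dams * cfg.litter_size)
        for s, d in zip(sires, dams):
            fs, fd = A[s, s] - 1.0, A[d, d] - 1.0
            msv = 0.5 * (1.0 - 0.5 * (fs + fd)) * sg2
            for _ in range(cfg.litter_size):
                i = n
                A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
                A[:i, i] = A[i, :i]
                A[i, i] = 1.0 + 0.5 * A[s, d]
                sire.append(s)
                dam.append(d)
                child_sex = FEMALE if rng.random() < 0.5 else MALE
                sex.append(child_sex)
                gen.append(g)
                u.append(0.5 * (u[s] + u[d]) + rng.normal(0.0, np.sqrt(msv)))
                if child_sex == MALE and rng.random() < cfg.male_phenotype_missing_rate:
                    y.append(np.nan)
                else:
                    y.append(cfg.mean_phenotype + u[-1] + rng.normal(0.0, np.sqrt(se2)))
                n += 1

    ids = tuple(str(i + 1) for i in range(n))
    sire_idx = np.array(sire, dtype=np.int64)
    dam_idx = np.array(dam, dtype=np.int64)
    pedigree = Pedigree(ids, sire_idx, dam_idx)
    gen_arr = np.array(gen)
    sex_arr = np.array(sex)
    u_arr = np.array(u)
    y_arr = np.array(y)
    inbreeding = np.diag(A[:n, :n]).copy() - 1.0

    genotypes, founder_freqs = _gene_drop(cfg, rng, sire_idx, dam_idx, gen_arr, ids)

    # mask a share of parent links for generations >= 1
    masked_sire = sire_idx.copy()
    masked_dam = dam_idx.copy()
    later = gen_arr >= 1
    masked_sire[later & (rng.random(n) < cfg.sire_mask_rate)] = UNKNOWN
    masked_dam[later & (rng.random(n) < cfg.dam_mask_rate)] = UNKNOWN
    masked_pedigree = Pedigree(ids, masked_sire, masked_dam)

    observed = ~np.isnan(y_arr)
    phenotypes = PhenotypeTable(
        ids=[ids[i] for i in np.nonzero(observed)[0]], y=y_arr[observed]
    )
    return SimulatedPopulation(
        config=cfg,
        pedigree=pedigree,
        masked_pedigree=masked_pedigree,
        genotypes=genotypes,
        phenotypes=phenotypes,
        true_breeding_values=u_arr,
        generation=gen_arr,
        sex=sex_arr,
        inbreeding=inbreeding,
        founder_allele_freqs=founder_freqs,
    )


def _gene_drop(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    gen_arr: np.ndarray,
    ids: Sequence[str],
) -> tuple[GenotypeMatrix | None, np.ndarray | None]:
    """Drop unlinked biallelic markers through the pedigree; keep late generations."""
    m = cfg.n_markers
    if m == 0:
        return None, None
    lo, hi = cfg.founder_freq_range
    p0 = rng.uniform(lo, hi, size=m)
    n = len(ids)
    dos = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s == UNKNOWN and d == UNKNOWN:
            dos[i] = rng.binomial(2, p0).astype(np.int8)
        else:
            # founders always precede non-founders here, so both parents known
            gs = rng.random(m) < dos[s] / 2.0
            gd = rng.random(m) < dos[d] / 2.0
            dos[i] = gs.astype(np.int8) + gd.astype(np.int8)
    glo, ghi = cfg.genotyped_generations
    keep = np.nonzero((gen_arr >= glo) & (gen_arr <= ghi))[0]
    if keep.size == 0:
        return None, p0
    geno = GenotypeMatrix(
        ids=[ids[i] for i in keep],
        markers=[f"m{l + 1}" for l in range(m)],
        dosages=dos[keep],
        coding="dosage",
    )
    return geno, p0


# ---------------------------------------------------------------------------
# Deterministic desk-scale fixtures

FIXTURE_NAMES = ("trio", "fullsib", "threegen", "toy_geno")

_THREEGEN_RECORDS = (
    # 10 founders, 10 second-generation, 10 third-generation individuals
    [(str(i), "0", "0") for i in range(1, 11)]
    + [
        ("11", "1", "6"), ("12", "1", "6"), ("13", "2", "7"), ("14", "2", "7"),
        ("15", "3", "8"), ("16", "3", "8"), ("17", "4", "9"), ("18", "4", "9"),
        ("19", "5", "10"), ("20", "5", "10"),
    ]
    + [
        ("21", "11", "14"), ("22", "11", "14"), ("23", "13", "16"),
        ("24", "13", "16"), ("25", "15", "18"), ("26", "15", "18"),
        ("27", "17", "20"), ("28", "17", "20"), ("29", "19", "12"),
        ("30", "19", "12"),
    ]
)


def make_fixture(name: str) -> Pedigree | GenotypeMatrix:
    """Small deterministic datasets for unit tests and examples.

    ``trio``: founders 1, 2 and their offspring 3.
    ``fullsib``: two founders, two full sibs and a full-sib-mating offspring.
    ``threegen``: a 30-individual, 3-generation pedigree.
    ``toy_geno``: 10 individuals × 20 markers (fixed rng stream, seed 20_24).
    """
    if name == "trio":
        return Pedigree.from_records([("1", 0, 0), ("2", 0, 0), ("3", "1", "2")])
    if name == "fullsib":
        return Pedigree.from_records(
            [("1", 0, 0), ("2", 0, 0), ("3", "1", "2"), ("4", "1", "2"),
             ("5", "3", "4")]
        )
    if name == "threegen":
        return Pedigree.from_records(_THREEGEN_RECORDS)
    if name == "toy_geno":
        rng = np.random.default_rng(20_24)
        p = rng.uniform(0.2, 0.8, size=20)
        dos = rng.binomial(2, p, size=(10, 20)).astype(np.int8)
        return GenotypeMatrix(
            ids=[f"g{i}" for i in range(1, 11)],
            markers=[f"m{l}" for l in range(1, 21)],
            dosages=dos,
        )
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
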