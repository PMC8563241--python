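"""Synthetic crossbreeding data with known ground truth.

Emulates a two-purebred-line terminal cross: a sire line (LK) and a dam
line (SUT) whose matings produce the crossbred (KR).  Founders of both
lines may be bred within line for several generations before the final
cross.  Phenotypes follow the generative counterpart of the analysis
model,

    y = mu + line offset + sex + hatch + a + d + e,

with additive effects ``a ~ N(0, A sa2)`` drawn from the pedigree's
numerator relationship structure, dominance deviations ``d ~ N(0, D sd2)``
from the dominance structure, and i.i.d. residuals.  Drawing ``d``
directly from the D-structured normal (rather than from an explicit
multi-locus genotypic model) gives exactly the covariance the analysis
model assumes, which makes parameter recovery a clean end-to-end test.

Two biallelic marker loci (``gh``: alleles A1/A3; ``igf1``: alleles A/C)
are assigned to founders from per-line genotype frequencies and
transmitted by Mendelian sampling; by default they carry no phenotypic
effect (null calibration), with optional per-genotype effects to create
real association signal.

Defaults reproduce the study conditions: ~600 crossbred offspring from
150 sire-line and 300 dam-line founders, week-6 variance components
(sa2, sd2, se2) = (14250.04, 3314.70, 712.57) g², and line offsets giving
a true midparent heterosis of 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._linalg import chol_psd
from .pedigree import (
    Pedigree,
    PedigreeRecord,
    RelationshipMatrix,
    additive_relationship_matrix,
    dominance_relationship_matrix,
    write_pedigree,
)

__all__ = [
    "Locus",
    "LOCI",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_pedigree",
    "simulate_marker_genotypes",
    "simulate_genetic_effects",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class Locus:
    """A biallelic marker locus with an ordered allele alphabet."""

    name: str
    alleles: tuple[str, str]

    def genotype(self, a: str, b: str) -> str:
        """Canonical genotype string (alleles sorted by alphabet order)."""
        order = {al: i for i, al in enumerate(self.alleles)}
        first, second = sorted((a, b), key=order.__getitem__)
        return first + second

    def parse(self, genotype: str) -> tuple[str, str]:
        for a in self.alleles:
            for b in self.alleles:
                if a + b == genotype:
                    return a, b
        raise ValueError(f"cannot parse genotype {genotype!r} for locus {self.name}")


LOCI: dict[str, Locus] = {
    "gh": Locus("gh", ("A1", "A3")),
    "igf1": Locus("igf1", ("A", "C")),
}


def _default_marker_design() -> dict:
    # founder genotype frequencies per line, from the study's mating design
    return {
        "gh": {
            "LK": {"A1A1": 13, "A3A3": 48},
            "SUT": {"A1A1": 57, "A3A3": 34},
        },
        "igf1": {
            "LK": {"AC": 18, "CC": 63},
            "SUT": {"AA": 143, "CC": 25},
        },
    }


def _default_fixed_effects() -> dict:
    # mean-zero within factor, so line means (and heterosis %) are not
    # shifted by the fixed-effect averages
    return {
        "sex": {"M": 40.0, "F": -40.0},
        "hatch": {"H1": 15.0, "H2": -15.0, "H3": 5.0, "H4": -5.0},
    }


def _default_line_offsets() -> dict:
    # KR offset = 25% of the midparent baseline: true heterosis 25%
    return {"LK": 0.0, "SUT": 0.0, "KR": 143.09}


@dataclass
class SimulationConfig:
    """Generating parameters of one synthetic crossbreeding dataset.

    ``n_lk_founders`` / ``n_sut_founders`` count line founders (sexes
    alternate within line, so half are available as sires or dams).  With
    ``n_generations=2`` founders are crossed directly; deeper pedigrees
    breed within line first and cross the final purebred generation.
    Every dam is mated once; sires are reused round-robin, giving the
    half-sib/full-sib structure that identifies sa2 and sd2 jointly.
    """

    n_lk_founders: int = 150
    n_sut_founders: int = 300
    n_generations: int = 2
    n_offspring_per_mating: int = 4
    ages: tuple[int, ...] = (6,)
    mu: float = 572.36
    sigma2_a: float = 14250.04
    sigma2_d: float = 3314.70
    sigma2_e: float = 712.57
    fixed_effect_sizes: dict = field(default_factory=_default_fixed_effects)
    line_mean_offsets: dict = field(default_factory=_default_line_offsets)
    marker_design: dict = field(default_factory=_default_marker_design)
    marker_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_lk_founders, self.n_sut_founders) < 1:
            raise ValueError("each line needs at least one founder")
        if self.n_generations < 2:
            raise ValueError("need at least two generations (founders + cross)")
        if self.n_offspring_per_mating < 1:
            raise ValueError("n_offspring_per_mating must be >= 1")
        if min(self.sigma2_a, self.sigma2_d, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def hatch_levels(self) -> tuple[str, ...]:
        return tuple(self.fixed_effect_sizes.get("hatch", {"H1": 0.0}))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ages" in raw:
            raw["ages"] = tuple(raw["ages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ages"] = list(self.ages)
        return d


@dataclass(frozen=True)
class SyntheticDataset:
    """A pedigree, its phenotype table and the generating ground truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": out / "ped.csv",
            "phenotypes": out / "pheno.csv",
            "truth": out / "truth.csv",
        }
        write_pedigree(self.pedigree, paths["pedigree"])
        self.phenotypes.to_csv(paths["phenotypes"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _founders(line: str, n: int, hatches: Sequence[str]) -> list[PedigreeRecord]:
    return [
        PedigreeRecord(
            animal=f"{line}0-{i:05d}",
            line=line,
            sex="M" if i % 2 == 0 else "F",
            # pairs share a hatch so sex and hatch stay unconfounded
            hatch=hatches[(i // 2) % len(hatches)],
            generation=0,
        )
        for i in range(n)
    ]


def _mate(
    sires: list[PedigreeRecord],
    dams: list[PedigreeRecord],
    line: str,
    generation: int,
    n_offspring: int,
    hatches: Sequence[str],
    start: int,
) -> list[PedigreeRecord]:
    """Round-robin matings: dam i with sire (i mod n_sires)."""
    out = []
    k = start
    for i, dam in enumerate(dams):
        sire = sires[i % len(sires)]
        for _ in range(n_offspring):
            out.append(
                PedigreeRecord(
                    animal=f"{line}{generation}-{k:05d}",
                    sire=sire.animal,
                    dam=dam.animal,
                    line=line,
                    sex="M" if k % 2 == 0 else "F",
                    hatch=hatches[(k // 2) % len(hatches)],
                    generation=generation,
                )
            )
            k += 1
    return out


def simulate_pedigree(cfg: SimulationConfig) -> Pedigree:
    """Crossbreeding pedigree: line founders, within-line generations, final cross.

    Deterministic for a given config (mating assignment is round-robin,
    sex alternates 50:50, hatch cycles through its levels), so the same
    config always yields a byte-identical pedigree file.
    """
    hatches = cfg.hatch_levels
    lk = [_founders("LK", cfg.n_lk_founders, hatches)]
    sut = [_founders("SUT", cfg.n_sut_founders, hatches)]
    records: list[PedigreeRecord] = lk[0] + sut[0]
    # within-line generations 1 .. n_generations-2
    for g in range(1, cfg.n_generations - 1):
        for line, gens in (("LK", lk), ("SUT", sut)):
            prev = gens[-1]
            sires = [r for r in prev if r.sex == "M"]
            dams = [r for r in prev if r.sex == "F"]
            if not sires or not dams:
                raise ValueError(f"line {line} has no breeding pair at generation {g}")
            kids = _mate(sires, dams, line, g, cfg.n_offspring_per_mating, hatches, 0)
            gens.append(kids)
            records.extend(kids)
    # final cross: LK males x SUT females -> KR
    sires = [r for r in lk[-1] if r.sex == "M"]
    dams = [r for r in sut[-1] if r.sex == "F"]
    if not sires or not dams:
        raise ValueError("final cross needs LK males and SUT females")
    records.extend(
        _mate(sires, dams, "KR", cfg.n_generations - 1, cfg.n_offspring_per_mating,
              hatches, 0)
    )
    return Pedigree(records)


def simulate_marker_genotypes(
    ped: Pedigree, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Marker genotypes at the two loci, indexed by animal.

    Founders draw genotypes from the per-line frequencies of
    ``cfg.marker_design``; every other animal receives one allele from
    each parent by Mendelian sampling.  A founder whose line has no
    genotype assignment for a locus is an error.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for name, locus in LOCI.items():
        design = cfg.marker_design.get(name)
        if design is None:
            raise ValueError(f"marker_design lacks locus {name!r}")
        genos: dict[str, tuple[str, str]] = {}
        for r in ped:
            if r.sire is None or r.dam is None:
                if r.line not in design:
                    raise ValueError(
                        f"founder {r.animal!r} of line {r.line!r} has no genotype "
                        f"assignment for locus {name!r}"
                    )
                options = list(design[r.line])
                weights = np.array([design[r.line][g] for g in options], float)
                pick = options[rng.choice(len(options), p=weights / weights.sum())]
                genos[r.animal] = locus.parse(pick)
            else:
                pa = genos[r.sire][rng.integers(0, 2)]
                pb = genos[r.dam][rng.integers(0, 2)]
                genos[r.animal] = (pa, pb)
        out[name] = genos
    return pd.DataFrame(
        {
            "animal": list(ped.ids),
            "gh_genotype": [LOCI["gh"].genotype(*out["gh"][a]) for a in ped.ids],
            "igf1_genotype": [LOCI["igf1"].genotype(*out["igf1"][a]) for a in ped.ids],
        }
    ).set_index("animal")


def simulate_genetic_effects(
    ped: Pedigree,
    A: RelationshipMatrix,
    D: RelationshipMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One draw of true additive and dominance effect vectors.

    ``a ~ N(0, A sa2)`` and ``d ~ N(0, D sd2)`` via jittered Cholesky;
    a zero variance yields an exactly-zero vector.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = len(ped)
    if tuple(A.ids) != ped.ids or tuple(D.ids) != ped.ids:
        raise ValueError("relationship matrices do not match the pedigree")
    if cfg.sigma2_a > 0:
        La, _ = chol_psd(A.values)
        a = np.sqrt(cfg.sigma2_a) * (La @ rng.standard_normal(n))
    else:
        a = np.zeros(n)
    if cfg.sigma2_d > 0:
        Ld, _ = chol_psd(D.values)
        d = np.sqrt(cfg.sigma2_d) * (Ld @ rng.standard_normal(n))
    else:
        d = np.zeros(n)
    return a, d


def simulate_phenotypes(
    ped: Pedigree,
    effects: Mapping[int, tuple[np.ndarray, np.ndarray]],
    genotypes: pd.DataFrame,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Long-format phenotype table: one row per animal and age.

    ``bw_g = mu + line offset + sex + hatch + marker effects + a + d + e``
    with residuals i.i.d. ``N(0, se2)``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sex_eff = cfg.fixed_effect_sizes.get("sex", {})
    hatch_eff = cfg.fixed_effect_sizes.get("hatch", {})
    rows = []
    for age in cfg.ages:
        a, d = effects[age]
        eps = (
            np.sqrt(cfg.sigma2_e) * rng.standard_normal(len(ped))
            if cfg.sigma2_e > 0
            else np.zeros(len(ped))
        )
        for i, r in enumerate(ped):
            bw = (
                cfg.mu
                + cfg.line_mean_offsets.get(r.line, 0.0)
                + sex_eff.get(r.sex, 0.0)
                + hatch_eff.get(r.hatch, 0.0)
                + a[i]
                + d[i]
                + eps[i]
            )
            for locus, eff in cfg.marker_effects.items():
                bw += eff.get(genotypes.loc[r.animal, f"{locus}_genotype"], 0.0)
            rows.append(
                {
                    "animal": r.animal,
                    "age_wk": age,
                    "bw_g": bw,
                    "sex": r.sex,
                    "hatch": r.hatch,
                    "line": r.line,
                    "gh_genotype": genotypes.loc[r.animal, "gh_genotype"],
                    "igf1_genotype": genotypes.loc[r.animal, "igf1_genotype"],
                }
            )
    return pd.DataFrame(rows)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full synthetic dataset: pedigree, genotypes, effects, phenotypes, truth.

    All randomness flows from a single generator seeded with
    ``cfg.seed``, so outputs are bit-reproducible per config.
    """
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg)
    A = additive_relationship_matrix(ped)
    D = dominance_relationship_matrix(ped, A)
    genos = simulate_marker_genotypes(ped, cfg, rng)
    effects = {age: simulate_genetic_effects(ped, A, D, cfg, rng) for age in cfg.ages}
    pheno = simulate_phenotypes(ped, effects, genos, cfg, rng)
    truth = pd.DataFrame(
        [
            {"animal": animal, "age_wk": age, "a_true": effects[age][0][i],
             "d_true": effects[age][1][i]}
            for age in cfg.ages
            for i, animal in enumerate(ped.ids)
        ]
    )
    return SyntheticDataset(pedigree=ped, phenotypes=pheno, truth=truth, config=cfg)
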