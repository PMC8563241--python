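"""Shared fixtures: hand-built pedigrees and small simulated datasets."""

import numpy as np
import pytest

from kradom.pedigree import Pedigree, PedigreeRecord
from kradom.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def trio() -> Pedigree:
    """Unrelated sire and dam with one offspring."""
    return Pedigree(
        [
            PedigreeRecord("s", line="LK", sex="M"),
            PedigreeRecord("d", line="SUT", sex="F"),
            PedigreeRecord("o", "s", "d", line="KR", sex="M"),
        ]
    )


@pytest.fixture
def full_sib_mating() -> Pedigree:
    """Two founders, two full-sib offspring, and their inbred offspring."""
    return Pedigree(
        [
            PedigreeRecord("s"),
            PedigreeRecord("d"),
            PedigreeRecord("o1", "s", "d"),
            PedigreeRecord("o2", "s", "d"),
            PedigreeRecord("x", "o1", "o2"),
        ]
    )


@pytest.fixture(scope="session")
def family_dataset():
    """Small two-line cross with genetic signal (90 animals, one age)."""
    cfg = SimulationConfig(
        n_lk_founders=10, n_sut_founders=20, n_offspring_per_mating=3,
        sigma2_a=100.0, sigma2_d=40.0, sigma2_e=60.0, mu=300.0,
        line_mean_offsets={}, seed=2,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def random_pedigree_factory():
    """Random non-inbred two-lineage crossbreeding pedigrees.

    Structure: founders of two disjoint lines, one generation of random
    within-line matings (parents are always unrelated founders), and a
    terminal cross between the lines.  Every mating pairs unrelated,
    non-inbred parents, so the classical dominance-relationship formula is
    exact and gene dropping is a valid oracle for both A and D.
    """

    def make(rng: np.random.Generator) -> Pedigree:
        records = []
        pools: dict[str, dict[str, list[str]]] = {}
        for line in ("LK", "SUT"):
            n_f = int(rng.integers(4, 10))
            males, females = [], []
            for i in range(n_f):
                name = f"{line}F{i}"
                records.append(PedigreeRecord(name, line=line,
                                              sex="M" if i % 2 == 0 else "F"))
                (males if i % 2 == 0 else females).append(name)
            kids_m, kids_f = [], []
            for j in range(int(rng.integers(3, 12))):
                name = f"{line}G{j}"
                sex = "M" if j % 2 == 0 else "F"
                records.append(
                    PedigreeRecord(
                        name,
                        sire=males[rng.integers(len(males))],
                        dam=females[rng.integers(len(females))],
                        line=line, sex=sex, generation=1,
                    )
                )
                (kids_m if sex == "M" else kids_f).append(name)
            pools[line] = {"M": males + kids_m, "F": females + kids_f}
        for j in range(int(rng.integers(4, 16))):
            records.append(
                PedigreeRecord(
                    f"KR{j}",
                    sire=pools["LK"]["M"][rng.integers(len(pools["LK"]["M"]))],
                    dam=pools["SUT"]["F"][rng.integers(len(pools["SUT"]["F"]))],
                    line="KR", sex="M" if j % 2 == 0 else "F", generation=2,
                )
            )
        return Pedigree(records)

    return make
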