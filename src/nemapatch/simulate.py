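"""Synthetic survey and experiment generators with known ground truth.

The generators emulate the statistical structure the analyses assume, so
every estimator can be validated by parameter recovery:

* **Collections / flower survey** — patches sit in a hierarchy
  (locality → site/tree → quadrat → patch). For each species s the number of
  colonization events on a patch is K ~ Poisson(λ_s · u), where the
  multiplicative heterogeneity u = exp(ε_site + ε_quadrat − σ_s²/2) carries
  lognormal site- and quadrat-level random effects (each with standard
  deviation σ_s/√2 on the log scale, so the total log-variance is σ_s² and
  E[u] = 1; the marginal mean of K stays λ_s). σ_s = 0 gives the homogeneous
  Poisson world in which the zero-class estimator is exact; σ_s > 0 creates
  the patchy, overdispersed occupancy the field data show and biases the
  zero-class λ estimate downward.
* **Bait experiment** — the 7-site × 5-array × 6-bait-type design (210
  baits): independent Bernoulli colonization per bait by Caenorhabditis and
  by other nematodes with type-specific probabilities, plus independent
  Bernoulli bait loss.
* **Exclosure experiment** — the 6-site × 24-bait design (144 baits) with 4
  replicates of 6 accessibility treatments, treatment-specific colonization
  probabilities (Caenorhabditis defaults are zero behind mesh of 1 mm or
  finer) and Bernoulli loss.

True colonization counts K are returned in a sidecar table, never inside
the records, so analysis code cannot accidentally read the truth. A given
config (which includes the seed) always yields identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .records import (
    BaitRecord,
    BaitType,
    CollectionRecord,
    ExclosureRecord,
    ExclosureTreatment,
    SubstrateCategory,
)

__all__ = [
    "ConfigError",
    "SpeciesParams",
    "BaitDesign",
    "ExclosureDesign",
    "SimulationConfig",
    "SimulatedCollections",
    "simulate_collections",
    "simulate_gustavia_survey",
    "simulate_bait_experiment",
    "simulate_exclosure",
]


class ConfigError(ValueError):
    """A simulation config field is out of its valid range."""


@dataclass(frozen=True)
class SpeciesParams:
    """Mean colonization intensity and log-scale heterogeneity for a species."""

    lam: float
    sigma: float = 0.0


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= float(value) <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: float) -> None:
    if float(value) < 0.0:
        raise ConfigError(f"{name} must be nonnegative, got {value!r}")


@dataclass(frozen=True)
class BaitDesign:
    """7 sites × 5 arrays × 6 bait types; Bernoulli colonization and loss.

    Default probabilities are illustrative values with the qualitative
    structure of the experiment: ground-contact baits beat dish baits,
    peptone beats flower slurry, and the Caenorhabditis and
    other-nematode profiles rise and fall together across types.
    """

    n_sites: int = 7
    arrays_per_site: int = 5
    loss_prob: float = 29 / 210
    p_caenorhabditis: Mapping[str, float] = field(
        default_factory=lambda: {
            "peptone_ground": 0.22,
            "peptone_dish": 0.06,
            "gustavia_ground": 0.12,
            "gustavia_raw_ground": 0.08,
            "gustavia_dish": 0.04,
            "gustavia_mesh": 0.04,
        }
    )
    p_other_nematode: Mapping[str, float] = field(
        default_factory=lambda: {
            "peptone_ground": 0.55,
            "peptone_dish": 0.16,
            "gustavia_ground": 0.33,
            "gustavia_raw_ground": 0.22,
            "gustavia_dish": 0.11,
            "gustavia_mesh": 0.10,
        }
    )
    # given a Caenorhabditis-positive bait, which species are present
    species_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "C. briggsae": 0.80,
            "C. tropicalis": 0.15,
            "both": 0.05,
        }
    )

    def validate(self) -> None:
        if self.n_sites < 1 or self.arrays_per_site < 1:
            raise ConfigError("bait design sizes must be >= 1")
        _check_prob("bait loss_prob", self.loss_prob)
        for bt in BaitType:
            for name, table in (
                ("p_caenorhabditis", self.p_caenorhabditis),
                ("p_other_nematode", self.p_other_nematode),
            ):
                if bt.value not in table:
                    raise ConfigError(f"bait {name} missing type {bt.value!r}")
                _check_prob(f"bait {name}[{bt.value}]", table[bt.value])
        total = sum(self.species_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("bait species_mix must sum to 1")


@dataclass(frozen=True)
class ExclosureDesign:
    """6 sites × (4 replicates × 6 treatments); accessibility-graded rates.

    Caenorhabditis defaults are zero behind mesh of 1 mm or finer,
    reflecting phoretic carriers too large to pass; other nematodes keep a
    declining but nonzero rate (soil taxa can crawl).
    """

    n_sites: int = 6
    replicates_per_treatment: int = 4
    loss_prob: float = 1 / 144
    p_caenorhabditis: Mapping[str, float] = field(
        default_factory=lambda: {
            "direct_ground": 0.15,
            "open_cup": 0.10,
            "mesh_4mm": 0.08,
            "mesh_1mm": 0.0,
            "mesh_0p064mm": 0.0,
            "mesh_0p01mm": 0.0,
        }
    )
    p_other_nematode: Mapping[str, float] = field(
        default_factory=lambda: {
            "direct_ground": 0.42,
            "open_cup": 0.30,
            "mesh_4mm": 0.20,
            "mesh_1mm": 0.10,
            "mesh_0p064mm": 0.05,
            "mesh_0p01mm": 0.03,
        }
    )
    caeno_mix: Mapping[str, float] = field(
        default_factory=lambda: {"C. briggsae": 0.6, "C. tropicalis": 0.4}
    )

    def validate(self) -> None:
        if self.n_sites < 1 or self.replicates_per_treatment < 1:
            raise ConfigError("exclosure design sizes must be >= 1")
        _check_prob("exclosure loss_prob", self.loss_prob)
        for tr in ExclosureTreatment:
            for name, table in (
                ("p_caenorhabditis", self.p_caenorhabditis),
                ("p_other_nematode", self.p_other_nematode),
            ):
                if tr.value not in table:
                    raise ConfigError(f"exclosure {name} missing {tr.value!r}")
                _check_prob(f"exclosure {name}[{tr.value}]", table[tr.value])
        if abs(sum(self.caeno_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("exclosure caeno_mix must sum to 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Full study design: hierarchy sizes, species intensities, experiments.

    Default species intensities are illustrative values consistent with the
    flower-survey occupancies (C. briggsae λ = 1.08 near-homogeneous; rarer
    species patchy, with large log-scale heterogeneity).
    """

    seed: int = 0
    n_localities: int = 1
    sites_per_locality: int = 4
    quadrats_per_site: int = 3
    patches_per_quadrat: int = 4
    species: Mapping[str, SpeciesParams] = field(
        default_factory=lambda: {
            "C. briggsae": SpeciesParams(lam=1.08, sigma=0.3),
            "C. tropicalis": SpeciesParams(lam=0.10, sigma=1.5),
            "C. becei": SpeciesParams(lam=0.25, sigma=1.5),
            "C. panamensis": SpeciesParams(lam=0.25, sigma=1.5),
        }
    )
    substrate_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "fruit": 0.40,
            "flower": 0.25,
            "fungus": 0.10,
            "leaf_litter": 0.15,
            "stem": 0.05,
            "other": 0.05,
        }
    )
    # G. superba survey: quadrats sampled at each focal tree (one tree had
    # only two), four flowers per quadrat -> 44 flowers.
    gustavia_quadrats: tuple[int, ...] = (3, 3, 3, 2)
    flowers_per_quadrat: int = 4
    bait: BaitDesign = field(default_factory=BaitDesign)
    exclosure: ExclosureDesign = field(default_factory=ExclosureDesign)

    def validate(self) -> None:
        for name in (
            "n_localities", "sites_per_locality",
            "quadrats_per_site", "patches_per_quadrat",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not self.species:
            raise ConfigError("at least one species required")
        for sp, par in self.species.items():
            _check_nonneg(f"species[{sp}].lam", par.lam)
            _check_nonneg(f"species[{sp}].sigma", par.sigma)
        for cat, w in self.substrate_mix.items():
            SubstrateCategory(cat)
            _check_nonneg(f"substrate_mix[{cat}]", w)
        if sum(self.substrate_mix.values()) <= 0:
            raise ConfigError("substrate_mix weights must sum to > 0")
        if self.flowers_per_quadrat < 1 or not self.gustavia_quadrats:
            raise ConfigError("gustavia design must be nonempty")
        self.bait.validate()
        self.exclosure.validate()

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "species" in data:
            data["species"] = {
                name: SpeciesParams(**params) if isinstance(params, Mapping)
                else params
                for name, params in data["species"].items()
            }
        if "bait" in data and isinstance(data["bait"], Mapping):
            data["bait"] = BaitDesign(**data["bait"])
        if "exclosure" in data and isinstance(data["exclosure"], Mapping):
            data["exclosure"] = ExclosureDesign(**data["exclosure"])
        if "gustavia_quadrats" in data:
            data["gustavia_quadrats"] = tuple(data["gustavia_quadrats"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(Path(path), encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedCollections:
    """Records plus the ground-truth sidecar of colonization counts K."""

    records: tuple[CollectionRecord, ...]
    truth: pd.DataFrame  # columns: sample_id, species, k

    def write_truth(self, dest) -> None:
        self.truth.to_csv(dest, index=False)


def _species_draw(rng: np.random.Generator, lam: float, sigma: float,
                  eps_site: float, eps_quadrat: float) -> int:
    rate = lam * float(np.exp(eps_site + eps_quadrat - sigma * sigma / 2.0))
    return int(rng.poisson(rate))


def _simulate_patch_block(
    config: SimulationConfig,
    rng: np.random.Generator,
    hierarchy: list[tuple[str, str, str, str]],
    substrate_for_patch,
    year: int,
) -> SimulatedCollections:
    """Core hierarchical Poisson sampler shared by both collection designs.

    ``hierarchy`` lists (locality, site, quadrat, sample_id) per patch in a
    fixed order; random effects are drawn once per (species, site) and per
    (species, quadrat).
    """
    species = list(config.species)
    level_sd = {
        sp: config.species[sp].sigma / np.sqrt(2.0) for sp in species
    }
    sites = sorted({(loc, s) for loc, s, _, _ in hierarchy})
    quadrats = sorted({(loc, s, q) for loc, s, q, _ in hierarchy})
    eps_site = {
        (sp, key): rng.normal(0.0, level_sd[sp]) for sp in species for key in sites
    }
    eps_quad = {
        (sp, key): rng.normal(0.0, level_sd[sp])
        for sp in species
        for key in quadrats
    }
    records: list[CollectionRecord] = []
    truth_rows: list[tuple[str, str, int]] = []
    for loc, site, quad, sid in hierarchy:
        present: set[str] = set()
        for sp in species:
            par = config.species[sp]
            k = _species_draw(
                rng, par.lam, par.sigma,
                eps_site[(sp, (loc, site))], eps_quad[(sp, (loc, site, quad))],
            )
            truth_rows.append((sid, sp, k))
            if k >= 1:
                present.add(sp)
        cat, taxon = substrate_for_patch(rng)
        records.append(
            CollectionRecord(
                sample_id=sid,
                locality=loc,
                year=year,
                substrate_category=cat,
                substrate_taxon=taxon,
                nematodes_present=bool(present),
                species_present=frozenset(present),
                site=site,
                quadrat=quad,
            )
        )
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "species", "k"])
    return SimulatedCollections(tuple(records), truth)


def simulate_collections(config: SimulationConfig) -> SimulatedCollections:
    """Simulate an opportunistic hierarchical collection survey."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cats = sorted(config.substrate_mix)
    weights = np.array([config.substrate_mix[c] for c in cats], dtype=float)
    weights = weights / weights.sum()

    def substrate(rng_: np.random.Generator):
        cat = cats[int(rng_.choice(len(cats), p=weights))]
        return SubstrateCategory(cat), None

    hierarchy = []
    for li in range(config.n_localities):
        loc = f"L{li + 1}"
        for si in range(config.sites_per_locality):
            site = f"S{si + 1}"
            for qi in range(config.quadrats_per_site):
                quad = f"Q{qi + 1}"
                for pi in range(config.patches_per_quadrat):
                    sid = f"{loc}-{site}-{quad}-P{pi + 1}"
                    hierarchy.append((loc, site, quad, sid))
    return _simulate_patch_block(config, rng, hierarchy, substrate, year=2018)


def simulate_gustavia_survey(config: SimulationConfig) -> SimulatedCollections:
    """Simulate the systematic flower survey (default 4 trees, 44 flowers)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    def substrate(_rng):
        return SubstrateCategory.FLOWER, "Gustavia superba"

    hierarchy = []
    for ti, n_quads in enumerate(config.gustavia_quadrats):
        site = f"T{ti + 1}"
        for qi in range(n_quads):
            quad = f"Q{qi + 1}"
            for fi in range(config.flowers_per_quadrat):
                sid = f"GS-{site}-{quad}-F{fi + 1}"
                hierarchy.append(("BCI", site, quad, sid))
    return _simulate_patch_block(config, rng, hierarchy, substrate, year=2012)


def _mix_draw(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    names = sorted(mix)
    probs = np.array([mix[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


def simulate_bait_experiment(config: SimulationConfig) -> list[BaitRecord]:
    """Simulate the bait-type experiment (default design: 210 baits)."""
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
    )
    design = config.bait
    records: list[BaitRecord] = []
    for si in range(design.n_sites):
        for ai in range(design.arrays_per_site):
            for bt in BaitType:
                lost = rng.random() < design.loss_prob
                if lost:
                    records.append(
                        BaitRecord(
                            site=f"S{si + 1}", array=f"A{ai + 1}", bait_type=bt,
                            recovered=False, nematodes_present=False,
                            caenorhabditis_present=False,
                        )
                    )
                    continue
                caeno = rng.random() < design.p_caenorhabditis[bt.value]
                other = rng.random() < design.p_other_nematode[bt.value]
                species: set[str] = set()
                if caeno:
                    pick = _mix_draw(rng, design.species_mix)
                    species |= (
                        {"C. briggsae", "C. tropicalis"} if pick == "both"
                        else {pick}
                    )
                records.append(
                    BaitRecord(
                        site=f"S{si + 1}", array=f"A{ai + 1}", bait_type=bt,
                        recovered=True,
                        nematodes_present=caeno or other,
                        caenorhabditis_present=caeno,
                        species_present=frozenset(species),
                    )
                )
    return records


def simulate_exclosure(config: SimulationConfig) -> list[ExclosureRecord]:
    """Simulate the exclosure experiment (default design: 144 baits)."""
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
    )
    design = config.exclosure
    treatments = list(ExclosureTreatment)
    records: list[ExclosureRecord] = []
    for si in range(design.n_sites):
        # randomized grid: replicates of each treatment shuffled over positions
        layout = treatments * design.replicates_per_treatment
        order = rng.permutation(len(layout))
        for pos, idx in enumerate(order):
            tr = layout[int(idx)]
            lost = rng.random() < design.loss_prob
            position = f"R{pos // 6 + 1}C{pos % 6 + 1}"
            if lost:
                records.append(
                    ExclosureRecord(
                        site=f"S{si + 1}", position=position, treatment=tr,
                        recovered=False, nematodes_present=False,
                    )
                )
                continue
            caeno = rng.random() < design.p_caenorhabditis[tr.value]
            other = rng.random() < design.p_other_nematode[tr.value]
            species: set[str] = set()
            if caeno:
                species.add(_mix_draw(rng, design.caeno_mix))
            if other:
                species.add(
                    "Oscheius tipulae"
                    if tr == ExclosureTreatment.DIRECT_GROUND
                    else "Rhabditidae sp."
                )
            records.append(
                ExclosureRecord(
                    site=f"S{si + 1}", position=position, treatment=tr,
                    recovered=True,
                    nematodes_present=bool(species) or caeno or other,
                    species_present=frozenset(species),
                )
            )
    return records
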