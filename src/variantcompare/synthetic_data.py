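"""Synthetic knowledge bases and Mendelian family genotype datasets.

The comparison pipeline needs datasets with controllable sharing structure:
a nuclear family (two parents plus up to two children), genotyped at every
knowledge-base variant. Parents are drawn independently per site under
Hardy-Weinberg equilibrium at the variant's population allele frequency;
each child allele is drawn uniformly from the corresponding parent's two
alleles, independently per site. There are no de novo mutations and no
linkage -- sites are independent -- so Mendelian consistency is exact and
exhaustively checkable, and every child variant is traceable to a parent.

Everything is driven by a single integer seed: the same
:class:`SimulationConfig` always reproduces byte-identical output files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .genotype_io import write_effect_kb, write_raw_genotypes
from .models import (
    BaseImpact,
    Certainty,
    EffectKB,
    EffectRecord,
    GenotypeRecord,
    GenotypeSet,
    Inheritance,
)

__all__ = ["SimulationConfig", "generate_kb", "simulate_family", "write_dataset"]

#: Non-risk allele paired with each risk allele in simulated genotypes.
_OTHER_ALLELE = {"A": "G", "G": "A", "C": "T", "T": "C", "I": "D", "D": "I"}

_IMPACTS = tuple(BaseImpact)
_CERTAINTIES = tuple(Certainty)

DEFAULT_CATEGORIES = (
    "Blood",
    "Cancer",
    "Cardiovascular",
    "Drug Response",
    "Immune System",
    "Metabolism",
    "Neurological",
    "Vision",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a 4-member nuclear family (2 parents, 2 siblings)
    genotyped at 50 knowledge-base variants with a clinically plausible
    impact mix and log-uniform allele frequencies between 0.1% and 50%.
    """

    n_variants: int = 50
    n_children: int = 2
    seed: int = 0
    #: proportions over (pathogenic, benign, protective, pharmacogenetic)
    impact_mix: tuple[float, float, float, float] = (0.35, 0.40, 0.10, 0.15)
    frequency_range: tuple[float, float] = (0.001, 0.5)
    category_pool: tuple[str, ...] = DEFAULT_CATEGORIES
    #: simulate a fraction of sites on chromosome X (hemizygous father/sons)
    include_x: bool = False

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigError("n_variants must be >= 1")
        if not 0 <= self.n_children <= 2:
            raise ConfigError("n_children must be 0, 1, or 2")
        if len(self.impact_mix) != len(_IMPACTS) or any(
            p < 0 for p in self.impact_mix
        ):
            raise ConfigError("impact_mix must be 4 nonnegative proportions")
        if abs(sum(self.impact_mix) - 1.0) > 1e-9:
            raise ConfigError("impact_mix must sum to 1")
        lo, hi = self.frequency_range
        if not 0.0 < lo < hi <= 1.0:
            raise ConfigError("frequency_range must satisfy 0 < min < max <= 1")
        if not self.category_pool:
            raise ConfigError("category_pool must be nonempty")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams for KB vs genotype sampling
    return np.random.default_rng([cfg.seed, stream])


def generate_kb(cfg: SimulationConfig) -> EffectKB:
    """Generate a synthetic variant-effect knowledge base.

    Variant names follow the GENE{i}-X{i}Y convention, frequencies are
    log-uniform within the configured range, impacts follow the configured
    mix, categories cycle through the pool, and inheritance is assigned to
    pathogenic variants (at least one recessive is guaranteed whenever any
    variant is pathogenic, so carrier status is always exercisable).
    """
    rng = _rng(cfg, 0)
    n = cfg.n_variants
    lo, hi = cfg.frequency_range
    freqs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    impact_idx = rng.choice(len(_IMPACTS), size=n, p=list(cfg.impact_mix))
    certainty_idx = rng.integers(len(_CERTAINTIES), size=n)
    risk_alleles = rng.choice(list("ACGT"), size=n)
    recessive_draw = rng.random(size=n) < 0.5

    inheritances: list[Inheritance] = []
    for i in range(n):
        if _IMPACTS[impact_idx[i]] is BaseImpact.PATHOGENIC:
            inheritances.append(
                Inheritance.RECESSIVE if recessive_draw[i] else Inheritance.DOMINANT
            )
        else:
            inheritances.append(Inheritance.UNKNOWN)
    pathogenic = [
        i for i in range(n) if _IMPACTS[impact_idx[i]] is BaseImpact.PATHOGENIC
    ]
    if pathogenic and not any(
        inheritances[i] is Inheritance.RECESSIVE for i in pathogenic
    ):
        inheritances[pathogenic[0]] = Inheritance.RECESSIVE

    records = []
    for i in range(n):
        impact = _IMPACTS[impact_idx[i]]
        category = cfg.category_pool[i % len(cfg.category_pool)]
        records.append(
            EffectRecord(
                variant_name=f"GENE{i}-X{i}Y",
                rsid=f"rs{1000 + i}",
                risk_allele=str(risk_alleles[i]),
                base_impact=impact,
                inheritance=inheritances[i],
                certainty=_CERTAINTIES[certainty_idx[i]],
                allele_frequency=float(freqs[i]),
                category=category,
                clinical_importance=f"{impact.value} association, synthetic entry {i}",
                effect_summary=(
                    f"Synthetic {impact.value} effect of GENE{i} in the "
                    f"{category} category."
                ),
            )
        )
    return EffectKB(records=tuple(records), source_label=f"synthetic(seed={cfg.seed})")


def _positions(cfg: SimulationConfig, rng: np.random.Generator):
    """Deterministic synthetic coordinates: autosomes cycled (or X when
    enabled), positions spaced to stay strictly increasing per chromosome."""
    chroms = []
    on_x = (
        rng.random(cfg.n_variants) < 0.1
        if cfg.include_x
        else np.zeros(cfg.n_variants, dtype=bool)
    )
    for i in range(cfg.n_variants):
        chroms.append("X" if on_x[i] else str(1 + i % 22))
    positions = [100_000 + 1_000 * i for i in range(cfg.n_variants)]
    return chroms, positions, on_x


def simulate_family(
    kb: EffectKB, cfg: SimulationConfig
) -> dict[str, GenotypeSet]:
    """Simulate genotypes for 2 parents and ``cfg.n_children`` children.

    Returns genotype sets keyed by person id (``parent1``, ``parent2``,
    ``child1``, ``child2``), each covering every KB variant. Parent alleles
    are Bernoulli(frequency) risk-allele draws (Hardy-Weinberg); each child
    inherits one uniformly chosen allele from each parent per site. With
    ``include_x`` enabled, X sites make parent2 and even-numbered children
    hemizygous (single maternal allele for sons; no paternal X).
    """
    rng = _rng(cfg, 1)
    n = len(kb.records)
    if n != cfg.n_variants:
        raise ConfigError(
            f"knowledge base has {n} records but config says {cfg.n_variants}"
        )
    freqs = np.array([rec.allele_frequency for rec in kb])
    risk = [rec.risk_allele for rec in kb]
    other = [_OTHER_ALLELE[a] for a in risk]
    chroms, positions, on_x = _positions(cfg, rng)

    # allele matrices: True = risk allele
    parent_alleles = {
        "parent1": rng.random((n, 2)) < freqs[:, None],
        "parent2": rng.random((n, 2)) < freqs[:, None],
    }
    persons = ["parent1", "parent2"] + [
        f"child{k}" for k in range(1, cfg.n_children + 1)
    ]
    child_alleles = {}
    for k in range(1, cfg.n_children + 1):
        pick1 = rng.integers(2, size=n)
        pick2 = rng.integers(2, size=n)
        paternal = parent_alleles["parent2"][np.arange(n), pick2]
        # the father carries a single X allele (slot 0): daughters inherit
        # exactly that one at X sites
        paternal = np.where(on_x, parent_alleles["parent2"][:, 0], paternal)
        child_alleles[f"child{k}"] = np.stack(
            [parent_alleles["parent1"][np.arange(n), pick1], paternal],
            axis=1,
        )

    def genotype_string(i: int, alleles: np.ndarray, person: str) -> str:
        a = risk[i] if alleles[0] else other[i]
        b = risk[i] if alleles[1] else other[i]
        if on_x[i]:
            # parent2 is the father; even-numbered children are sons:
            # a single maternal (or the father's own single) X allele
            if person == "parent2":
                return a
            if person.startswith("child") and int(person[5:]) % 2 == 0:
                return a  # sons: maternal allele only
        return a + b

    out: dict[str, GenotypeSet] = {}
    for person in persons:
        alleles = parent_alleles.get(person)
        if alleles is None:
            alleles = child_alleles[person]
        records = tuple(
            GenotypeRecord(
                rsid=kb.records[i].rsid,
                chromosome=chroms[i],
                position=positions[i],
                genotype=genotype_string(i, alleles[i], person),
            )
            for i in range(n)
        )
        out[person] = GenotypeSet(person_id=person, records=records)
    return out


def write_dataset(
    out_dir: str,
    cfg: SimulationConfig,
    kb: EffectKB | None = None,
    members: Mapping[str, GenotypeSet] | None = None,
) -> dict:
    """Write a complete synthetic dataset to a directory.

    Emits ``kb.csv``, one raw genotype file per family member
    (``<person>.txt`` in the consumer tab-separated dialect), and a
    ``manifest.json`` recording the configuration. Returns the manifest.
    Identical configs produce byte-identical files.
    """
    if kb is None:
        kb = generate_kb(cfg)
    if members is None:
        members = simulate_family(kb, cfg)
    os.makedirs(out_dir, exist_ok=True)
    kb_path = os.path.join(out_dir, "kb.csv")
    with open(kb_path, "w", newline="") as fh:
        write_effect_kb(kb, fh)
    files = {"kb": "kb.csv"}
    for person, genotypes in members.items():
        name = f"{person}.txt"
        with open(os.path.join(out_dir, name), "w") as fh:
            write_raw_genotypes(genotypes, fh)
        files[person] = name
    manifest = {
        "config": {
            "n_variants": cfg.n_variants,
            "n_children": cfg.n_children,
            "seed": cfg.seed,
            "impact_mix": list(cfg.impact_mix),
            "frequency_range": list(cfg.frequency_range),
            "category_pool": list(cfg.category_pool),
            "include_x": cfg.include_x,
        },
        "files": files,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
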