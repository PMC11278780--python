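"""Synthetic presence/absence profiles with known ground-truth chemotypes.

Field collections of *Epichloë* strains show two modes of gene loss: entire
biosynthetic clusters missing (e.g. strains with no ergot or
indole-diterpene genes at all) and single genes missing within an otherwise
intact cluster (e.g. idtP dropped from the indole-diterpene core).  The
generator reproduces exactly this two-level structure — whole-cluster
retention with probability π per cluster, then independent per-gene dropout
with probability δ within retained clusters — plus the mutually exclusive
ppzA allele choice (full-length R vs the ΔR deletion) and mutually
exclusive mating-type idiomorphs.

Ground truth is computed at generation time with a fixed-point reachability
oracle and a definitional re-statement of the type/category rules, both
independent of :mod:`endochem.engine`, so engine results can be checked
against stored truth without circularity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .io import ABSENT, PRESENT, UNKNOWN, GeneProfile
from .models import PathwayModel

_PPZ_ALLELE_MARKERS = ("ppzA-R", "ppzA-dR")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_cluster_probs() -> dict[str, float]:
    # Defaults emulate observed field structure: the peramine gene is nearly
    # universal; ergot and indole-diterpene clusters are lost as a unit in a
    # minority of strains; loline clusters are likewise cluster-level events.
    return {"PPZ": 1.0, "EAS": 0.8, "IDT": 0.8, "LOL": 0.8}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic profile generator.

    gene_dropout_prob (δ) defaults to 0.2, the approximate per-gene absence
    rate observed within retained clusters in field isolates (e.g. three of
    fourteen ergot-cluster genes missing across an otherwise intact core).
    allele_R_prob is the probability a PPZ-carrying strain has the
    full-length allele rather than the ΔR deletion (0.5: both alleles are
    common).  mating_type_a_prob defaults to 1.0 — field populations of a
    single asexual lineage are typically fixed for one idiomorph.
    """

    n_strains: int = 20
    seed: int = 0
    cluster_presence_prob: dict[str, float] = field(default_factory=_default_cluster_probs)
    gene_dropout_prob: float = 0.2
    allele_R_prob: float = 0.5
    unknown_prob: float = 0.0
    mating_type_a_prob: float = 1.0

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ConfigError(f"n_strains must be >= 1, got {self.n_strains}")
        probs = {"gene_dropout_prob": self.gene_dropout_prob,
                 "allele_R_prob": self.allele_R_prob,
                 "unknown_prob": self.unknown_prob,
                 "mating_type_a_prob": self.mating_type_a_prob,
                 **{f"cluster_presence_prob[{k}]": v for k, v in self.cluster_presence_prob.items()}}
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass
class StrainTruth:
    strain_id: str
    retained_clusters: list[str]
    dropped_genes: list[str]
    allele: str
    producible: dict[str, list[str]]  # model name -> sorted producible ids
    chem_type: int | str
    category: str

    def to_dict(self) -> dict:
        return {
            "strain": self.strain_id,
            "retained_clusters": self.retained_clusters,
            "dropped_genes": self.dropped_genes,
            "allele": self.allele,
            "producible": self.producible,
            "type": self.chem_type,
            "category": self.category,
        }


@dataclass
class SimulatedTruth:
    strains: list[StrainTruth]

    def by_strain(self) -> dict[str, StrainTruth]:
        return {t.strain_id: t for t in self.strains}

    def to_json(self) -> str:
        return json.dumps([t.to_dict() for t in self.strains], indent=2, sort_keys=True) + "\n"


def fixed_point_producible(
    profile: GeneProfile,
    model: PathwayModel,
    unknown_policy: str = "strict",
) -> set[str]:
    """Independent producibility oracle: start from the empty set and
    repeatedly add any step whose gate genes and precursor are satisfied
    until nothing changes.  No topological sorting; used to cross-check the
    engine's single-pass computation."""
    def gene_ok(g: str) -> bool:
        call = profile.calls[g]
        if call == UNKNOWN:
            return unknown_policy == "optimistic"
        return call == PRESENT

    producible: set[str] = set()
    changed = True
    while changed:
        changed = False
        for step in model.steps:
            if step.product in producible:
                continue
            if step.precursor is not None and step.precursor not in producible:
                continue
            if all(gene_ok(g) for g in step.required_genes):
                producible.add(step.product)
                changed = True
    return producible


# Definitional chemotype rules, restated here so stored truth never depends
# on the engine module.
def _truth_type(producible: Mapping[str, set[str]]) -> int | str:
    per = "PER" in producible.get("PPZ", set())
    eas = frozenset(producible.get("EAS", set()))
    idt = frozenset(producible.get("IDT", set()))
    triple_eas = frozenset({"CC", "D-LC", "ERV"})
    triple_idt = frozenset({"PAS", "PAX", "TDK"})
    if per and not eas and not idt:
        return 1
    if per and eas == triple_eas and idt == triple_idt:
        return 2
    if not per and eas == triple_eas and idt == frozenset({"PAS"}):
        return 3
    if not per and eas == triple_eas and idt == triple_idt:
        return 4
    return "unclassified"


def _truth_category(producible: Mapping[str, set[str]], models: Mapping[str, PathwayModel]) -> str:
    toxic = set().union(*(m.toxic_products for m in models.values()))
    produced = set().union(*producible.values()) if producible else set()
    return "I" if not (produced & toxic) else "II"


def simulate_profiles(
    config: SimulationConfig,
    models: Mapping[str, PathwayModel],
) -> tuple[list[GeneProfile], SimulatedTruth]:
    """Draw ``n_strains`` synthetic profiles and their ground truth.

    Reproducible under a fixed seed; the two ppzA allele segments are never
    both present; the two mating-type idiomorphs are drawn mutually
    exclusively.  Truth (producible sets, type, category) is evaluated on
    the profile *before* any unknown-masking, under the strict policy.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    profiles: list[GeneProfile] = []
    truths: list[StrainTruth] = []
    width = max(4, len(str(config.n_strains)))
    for i in range(config.n_strains):
        strain = f"SIM{i + 1:0{width}d}"
        calls: dict[str, str] = {}
        retained: list[str] = []
        dropped: list[str] = []

        mt_a = rng.random() < config.mating_type_a_prob
        calls["mtAC"] = PRESENT if mt_a else ABSENT
        calls["mtBA"] = ABSENT if mt_a else PRESENT

        allele = "none"
        for name, model in models.items():
            pi = config.cluster_presence_prob.get(name, 1.0)
            keep = rng.random() < pi
            if keep:
                retained.append(name)
            plain = sorted(model.markers - set(_PPZ_ALLELE_MARKERS))
            for g in plain:
                if keep and rng.random() >= config.gene_dropout_prob:
                    calls[g] = PRESENT
                else:
                    calls[g] = ABSENT
                    if keep:
                        dropped.append(g)
            if set(_PPZ_ALLELE_MARKERS) & model.markers:
                carried = "ppzA-R" if rng.random() < config.allele_R_prob else "ppzA-dR"
                other = "ppzA-dR" if carried == "ppzA-R" else "ppzA-R"
                calls[other] = ABSENT
                if keep and rng.random() >= config.gene_dropout_prob:
                    calls[carried] = PRESENT
                    allele = "ppzA-1" if carried == "ppzA-R" else "ppzA-2"
                else:
                    calls[carried] = ABSENT
                    if keep:
                        dropped.append(carried)

        profile = GeneProfile(strain_id=strain, calls=calls)
        producible = {name: fixed_point_producible(profile, model) for name, model in models.items()}
        truths.append(
            StrainTruth(
                strain_id=strain,
                retained_clusters=sorted(retained),
                dropped_genes=sorted(dropped),
                allele=allele,
                producible={k: sorted(v) for k, v in producible.items()},
                chem_type=_truth_type(producible),
                category=_truth_category(producible, models),
            )
        )
        profiles.append(profile)

    if config.unknown_prob > 0:
        profiles = mask_unknowns(profiles, config.unknown_prob, seed=int(rng.integers(2**31)))
    return profiles, SimulatedTruth(truths)


def mask_unknowns(profiles: Sequence[GeneProfile], prob: float, seed: int) -> list[GeneProfile]:
    """Independently mask each call to *unknown* with probability ``prob``.

    Under the strict policy, masking can only shrink producible sets (a
    present gene resolved to absent closes gates; nothing opens)."""
    if not (0.0 <= prob <= 1.0):
        raise ConfigError(f"mask probability must be in [0, 1], got {prob}")
    rng = np.random.default_rng(seed)
    out: list[GeneProfile] = []
    for p in profiles:
        masked = {
            m: (UNKNOWN if rng.random() < prob else call)
            for m, call in p.calls.items()
        }
        out.append(replace(p, calls=masked))
    return out
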