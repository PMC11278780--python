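"""Chemotype inference from gene presence/absence profiles.

A metabolite is *producible* when every gene in its step's all-of gate is
present and its pathway precursor (if any) is itself producible.  Evaluating
steps in topological order of the precursor DAG gives the full producible
set in one pass.  On top of this reachability computation the engine calls
the peramine (ppzA) allele, the mating-type idiomorph, per-cluster pattern
codes, a chemotype label (types 1-4) and a livestock-safety category:

* Category I — the strain can produce no ergot or indole-diterpene
  alkaloid, i.e. nothing toxic to grazing livestock; candidate for
  animal-safe inoculation programmes.
* Category II — at least one toxic product is producible.

Unknown marker calls are resolved by policy: ``strict`` (default) treats
unknown as absent, which is the conservative choice when screening for
animal-safe strains (a gene that might be present might make a toxin);
``optimistic`` treats unknown as present and is intended for sensitivity
analysis only.  Either resolution of an unknown gate gene is recorded as a
warning on the result.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import ABSENT, PRESENT, UNKNOWN, GeneProfile
from .models import PathwayModel

logger = logging.getLogger(__name__)

PATHWAY_ORDER = ("PPZ", "EAS", "IDT", "LOL")

UNKNOWN_POLICIES = ("strict", "optimistic")

# Gene lists behind the per-cluster pattern-code letters.  Codes are derived
# from the raw calls of each strain, never copied from a published table.
EAS_CORE_11 = frozenset(
    {"dmaW", "easF", "easE", "easC", "easD", "easA", "easG", "cloA", "lpsA", "lpsB", "easH"}
)
EAS_ALL_14 = EAS_CORE_11 | {"lpsC", "easO", "easP"}
IDT_CORE_8 = frozenset({"idtG", "idtB", "idtM", "idtC", "idtS", "idtQ", "idtF", "idtK"})
IDT_WITH_P_9 = IDT_CORE_8 | {"idtP"}
IDT_ALL_11 = IDT_WITH_P_9 | {"idtE", "idtJ"}


class EngineError(ValueError):
    """Profile/model mismatch or invalid engine configuration."""


@dataclass
class ChemotypeResult:
    """Full inference output for one strain."""

    strain_id: str
    producible: frozenset[str]
    producible_ordered: tuple[str, ...]
    terminal_products: frozenset[str]
    ppz_allele: str
    mating_type: str
    pattern_codes: dict[str, str]
    chem_type: int | str
    safety_category: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "strain": self.strain_id,
            "producible": list(self.producible_ordered),
            "terminal_products": sorted(self.terminal_products),
            "ppz_allele": self.ppz_allele,
            "mating_type": self.mating_type,
            "pattern_codes": dict(self.pattern_codes),
            "type": self.chem_type,
            "category": self.safety_category,
            "warnings": list(self.warnings),
        }


def _resolve_call(
    profile: GeneProfile,
    gene: str,
    unknown_policy: str,
    warnings: list[str] | None,
) -> bool:
    call = profile.calls[gene]
    if call == PRESENT:
        return True
    if call == ABSENT:
        return False
    resolved = unknown_policy == "optimistic"
    if warnings is not None:
        warnings.append(
            f"{gene} unknown, treated as {'present' if resolved else 'absent'} ({unknown_policy} policy)"
        )
    return resolved


def producible_metabolites(
    profile: GeneProfile,
    model: PathwayModel,
    unknown_policy: str = "strict",
    warnings: list[str] | None = None,
) -> set[str]:
    """Producible metabolites of one pathway model for one strain.

    Steps are evaluated in topological order of the precursor DAG, so each
    step sees the final producibility of its precursor.  Deterministic.
    """
    if unknown_policy not in UNKNOWN_POLICIES:
        raise EngineError(f"unknown_policy must be one of {UNKNOWN_POLICIES}, got {unknown_policy!r}")
    missing = sorted(model.markers - set(profile.calls))
    if missing:
        raise EngineError(f"strain {profile.strain_id}: profile lacks calls for model {model.name} markers {missing}")

    producible: set[str] = set()
    steps = {s.product: s for s in model.steps}
    for product in model.topological_order():
        step = steps[product]
        if step.precursor is not None and step.precursor not in producible:
            continue
        if all(_resolve_call(profile, g, unknown_policy, warnings) for g in step.required_genes):
            producible.add(product)
    return producible


def call_ppz_allele(profile: GeneProfile) -> str:
    """Peramine-gene allele from the R / ΔR segment calls.

    The full-length allele (ppzA-1) carries the reductase (R) domain and
    releases peramine; the deletion allele (ppzA-2, ΔR) releases
    pyrrolopyrazine-1,4-diones instead.  The two segments are mutually
    exclusive in clean data; both present is a conflict.
    """
    r = profile.call("ppzA-R") == PRESENT
    dr = profile.call("ppzA-dR") == PRESENT
    if r and dr:
        return "conflict"
    if r:
        return "ppzA-1"
    if dr:
        return "ppzA-2"
    return "none"


def call_mating_type(profile: GeneProfile) -> str:
    """Mating type from the idiomorph markers mtAC (type A) and mtBA (type B)."""
    ac = profile.call("mtAC") == PRESENT
    ba = profile.call("mtBA") == PRESENT
    if ac and ba:
        return "conflict"
    if ac:
        return "A"
    if ba:
        return "B"
    return "undetermined"


def _all_present(profile: GeneProfile, genes: Iterable[str]) -> bool:
    return all(profile.calls.get(g) == PRESENT for g in genes)


def _all_absent(profile: GeneProfile, genes: Iterable[str]) -> bool:
    return all(profile.calls.get(g) == ABSENT for g in genes)


def assign_pattern_codes(profile: GeneProfile, warnings: list[str] | None = None) -> dict[str, str]:
    """Per-cluster pattern-code letters, derived from the raw calls.

    PPZ: A = ΔR segment absent (full allele), B = R segment absent
    (deletion allele).  EAS: A = the 11-gene core present, B = the whole
    cluster absent.  IDT: A = whole cluster absent, B = core plus idtP,
    idtQ, idtF, idtK present, C = same but idtP absent.  LOL: A = lolC
    present.  Anything that matches no letter codes as X with a warning.
    """
    codes: dict[str, str] = {}

    r = profile.calls.get("ppzA-R") == PRESENT
    dr = profile.calls.get("ppzA-dR") == PRESENT
    if r and not dr:
        codes["PPZ"] = "A"
    elif dr and not r:
        codes["PPZ"] = "B"
    else:
        codes["PPZ"] = "X"

    if _all_present(profile, EAS_CORE_11):
        codes["EAS"] = "A"
    elif _all_absent(profile, EAS_ALL_14):
        codes["EAS"] = "B"
    else:
        codes["EAS"] = "X"

    if _all_absent(profile, IDT_ALL_11):
        codes["IDT"] = "A"
    elif _all_present(profile, IDT_WITH_P_9):
        codes["IDT"] = "B"
    elif _all_present(profile, IDT_CORE_8) and profile.calls.get("idtP") == ABSENT:
        codes["IDT"] = "C"
    else:
        codes["IDT"] = "X"

    codes["LOL"] = "A" if profile.calls.get("lolC") == PRESENT else "X"

    if warnings is not None:
        for cluster, code in codes.items():
            if code == "X":
                warnings.append(f"{cluster} calls match no defined pattern code")
    return codes


#: Producible-set signatures that define the four chemotype labels.  The
#: labels are defined over producible sets, not pattern codes, because the
#: published code letters are not always consistent with the underlying
#: marker table (see IDT code B vs C for idtP-negative strains).
_EAS_TRIPLE = frozenset({"CC", "D-LC", "ERV"})
_IDT_TRIPLE = frozenset({"PAS", "PAX", "TDK"})
_IDT_PAS = frozenset({"PAS"})


def assign_type(producible_by_model: Mapping[str, frozenset[str] | set[str]]) -> int | str:
    """Chemotype label 1-4 from the per-pathway producible sets.

    1: peramine only (no ergot, no indole-diterpene);
    2: peramine + CC/D-LC/ERV + PAS/PAX/TDK;
    3: CC/D-LC/ERV + paspaline only, no peramine;
    4: CC/D-LC/ERV + PAS/PAX/TDK, no peramine.
    Any other combination is 'unclassified'.
    """
    per = "PER" in producible_by_model.get("PPZ", set())
    eas = frozenset(producible_by_model.get("EAS", set()))
    idt = frozenset(producible_by_model.get("IDT", set()))
    if per and not eas and not idt:
        return 1
    if per and eas == _EAS_TRIPLE and idt == _IDT_TRIPLE:
        return 2
    if not per and eas == _EAS_TRIPLE and idt == _IDT_PAS:
        return 3
    if not per and eas == _EAS_TRIPLE and idt == _IDT_TRIPLE:
        return 4
    return "unclassified"


def assign_safety_category(producible: Iterable[str], models: Mapping[str, PathwayModel]) -> str:
    """Category I iff nothing producible is toxic to livestock, else II."""
    toxic = frozenset().union(*(m.toxic_products for m in models.values()))
    return "I" if not (set(producible) & toxic) else "II"


def _terminal_products(producible_by_model: Mapping[str, set[str]], models: Mapping[str, PathwayModel]) -> frozenset[str]:
    """Producible metabolites with no producible successor (for reporting)."""
    terminal: set[str] = set()
    for name, produced in producible_by_model.items():
        model = models[name]
        successors: dict[str, set[str]] = {p: set() for p in model.products}
        for s in model.steps:
            if s.precursor is not None:
                successors[s.precursor].add(s.product)
        for p in produced:
            if not (successors[p] & produced):
                terminal.add(p)
    return frozenset(terminal)


def _ordered(producible_by_model: Mapping[str, set[str]], models: Mapping[str, PathwayModel]) -> tuple[str, ...]:
    out: list[str] = []
    for name in PATHWAY_ORDER:
        if name in models:
            out.extend(p for p in models[name].products if p in producible_by_model.get(name, set()))
    return tuple(out)


def infer_chemotype(
    profile: GeneProfile,
    models: Mapping[str, PathwayModel],
    unknown_policy: str = "strict",
) -> ChemotypeResult:
    """Run the full per-strain inference."""
    warnings: list[str] = []

    by_model: dict[str, set[str]] = {
        name: producible_metabolites(profile, model, unknown_policy, warnings)
        for name, model in models.items()
    }

    allele = call_ppz_allele(profile)
    if allele == "conflict":
        warnings.append("both ppzA-R and ppzA-dR amplified; producibility computed from raw domain gates")
    mating = call_mating_type(profile)
    if mating == "conflict":
        warnings.append("both mating-type idiomorphs amplified")

    codes = assign_pattern_codes(profile, warnings)
    chem_type = assign_type(by_model)
    producible = frozenset().union(*by_model.values()) if by_model else frozenset()
    if chem_type == "unclassified":
        if producible:
            warnings.append("producible sets match no defined chemotype")
        else:
            warnings.append("no alkaloid genes detected; no defined chemotype")
    category = assign_safety_category(producible, models)
    if category == "I" and not producible:
        warnings.append("category I is vacuous: no producible metabolite at all")

    return ChemotypeResult(
        strain_id=profile.strain_id,
        producible=producible,
        producible_ordered=_ordered(by_model, models),
        terminal_products=_terminal_products(by_model, models),
        ppz_allele=allele,
        mating_type=mating,
        pattern_codes=codes,
        chem_type=chem_type,
        safety_category=category,
        warnings=warnings,
    )


def run_pipeline(
    profiles: Sequence[GeneProfile],
    models: Mapping[str, PathwayModel],
    unknown_policy: str = "strict",
) -> list[ChemotypeResult]:
    """Infer chemotypes for every strain, preserving input order, and log a
    summary of type / category / mating-type counts."""
    results = [infer_chemotype(p, models, unknown_policy) for p in profiles]
    types = Counter(str(r.chem_type) for r in results)
    cats = Counter(r.safety_category for r in results)
    mats = Counter(r.mating_type for r in results)
    logger.info(
        "%d strains | types %s | categories %s | mating types %s",
        len(results), dict(sorted(types.items())), dict(sorted(cats.items())), dict(sorted(mats.items())),
    )
    return results
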