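"""Declarative alkaloid pathway-dependency models.

Four gene clusters govern the alkaloid repertoire of *Epichloë* grass
endophytes: PPZ (peramine / pyrrolopyrazines, the multi-domain ``ppzA``
NRPS), EAS (ergot alkaloids), IDT/LTM (indole-diterpenes) and LOL
(lolines).  Each pathway is represented as a small DAG of metabolites in
which every production step is gated by an all-of set of gene markers and,
optionally, a pathway precursor that must itself be producible.

The bundled default models live under ``endochem/data/models`` as YAML and
can be replaced by user files with the same layout (JSON Schema in
``endochem/data/pathway_model.schema.json``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

logger = logging.getLogger(__name__)

CLUSTERS = ("PPZ", "EAS", "IDT", "LOL", "MAT")
MODEL_NAMES = ("PPZ", "EAS", "IDT", "LOL")

#: Marker-name aliases accepted on input.  Table transcriptions use bare
#: ppzA segment names (A1 ... R, ΔR) and one published text uses "idtO" for
#: the gene the cluster table calls "idtQ"; both spellings map to idtQ with
#: a warning so the discrepancy is visible, not silently dropped.
MARKER_ALIASES: dict[str, str] = {
    "A1": "ppzA-A1",
    "T1": "ppzA-T1",
    "C": "ppzA-C",
    "A2": "ppzA-A2",
    "M": "ppzA-M",
    "T2": "ppzA-T2",
    "R": "ppzA-R",
    "dR": "ppzA-dR",
    "ΔR": "ppzA-dR",
    "∆R": "ppzA-dR",
    "ppzA-ΔR": "ppzA-dR",
    "ppzA-∆R": "ppzA-dR",
    "idtO": "idtQ",
}

#: Aliases whose use indicates a known naming inconsistency worth flagging.
_NOISY_ALIASES = {"idtO"}


@dataclass(frozen=True)
class GeneMarker:
    """One PCR-assayed marker: a cluster gene, a ppzA domain segment, or a
    mating-type idiomorph."""

    id: str
    cluster: str

    def __post_init__(self) -> None:
        if self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r} for marker {self.id!r}")


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str


#: Canonical metabolite registry keyed by the abbreviation used in reports.
METABOLITES: dict[str, Metabolite] = {
    m.id: m
    for m in (
        Metabolite("CC", "chanoclavine I"),
        Metabolite("D-LC", "D-lysergic acid"),
        Metabolite("ERV", "ergovaline"),
        Metabolite("EN", "ergonovine"),
        Metabolite("LAH", "lysergic acid alpha-hydroxyacetamide"),
        Metabolite("PAS", "paspaline"),
        Metabolite("PAX", "paxilline"),
        Metabolite("TDK", "terpendole K"),
        Metabolite("LTM-B", "lolitrem B"),
        Metabolite("AcAP", "1-acetamidopyrrolizidine"),
        Metabolite("NFL", "N-formylloline"),
        Metabolite("NAL", "N-acetylloline"),
        Metabolite("PER", "peramine"),
        Metabolite("PPZ-dione", "pyrrolopyrazine-1,4-diones"),
    )
}

#: Mating-type idiomorphs are assayed alongside the clusters but belong to
#: no pathway model.
MATING_TYPE_MARKERS = (GeneMarker("mtAC", "MAT"), GeneMarker("mtBA", "MAT"))


class ModelError(Exception):
    """Structural problem in a pathway-model definition."""

    def __init__(self, message: str, *, source: str | None = None, step: str | None = None, fld: str | None = None):
        self.source = source
        self.step = step
        self.field = fld
        where = ", ".join(p for p in (source, step and f"step {step}", fld and f"field {fld}") if p)
        super().__init__(f"{message}" + (f" [{where}]" if where else ""))


class CycleError(ModelError):
    """Precursor graph contains a cycle."""

    def __init__(self, cycle: Sequence[str], *, source: str | None = None):
        self.cycle = list(cycle)
        super().__init__(f"cyclic precursor graph: {' -> '.join(self.cycle)}", source=source)


@dataclass(frozen=True)
class Finding:
    """One validation finding: advisory, never raised."""

    severity: str  # "error" | "warning"
    step: str | None
    message: str


@dataclass(frozen=True)
class PathwayStep:
    product: str
    precursor: str | None = None
    required_genes: frozenset[str] = frozenset()
    notes: str = ""


@dataclass(frozen=True)
class PathwayModel:
    """One cluster's producibility logic.

    ``toxic_products`` are the products considered toxic to grazing
    livestock; for the default registry that is every ergot and
    indole-diterpene product and nothing from PPZ or LOL.
    """

    name: str
    steps: tuple[PathwayStep, ...]
    terminal_products: frozenset[str] = frozenset()
    toxic_products: frozenset[str] = frozenset()

    @property
    def products(self) -> tuple[str, ...]:
        """Product ids in definition (pathway) order."""
        return tuple(s.product for s in self.steps)

    @property
    def markers(self) -> frozenset[str]:
        """Every gene marker referenced by any step gate."""
        return frozenset(g for s in self.steps for g in s.required_genes)

    def step_for(self, product: str) -> PathwayStep:
        for s in self.steps:
            if s.product == product:
                return s
        raise KeyError(product)

    def precursor_graph(self) -> "nx.DiGraph":
        g = nx.DiGraph()
        g.add_nodes_from(self.products)
        for s in self.steps:
            if s.precursor is not None:
                g.add_edge(s.precursor, s.product)
        return g

    def topological_order(self) -> list[str]:
        return list(nx.topological_sort(self.precursor_graph()))

    def gene_markers(self) -> tuple[GeneMarker, ...]:
        return tuple(GeneMarker(g, self.name) for g in sorted(self.markers))

    def to_dict(self) -> dict:
        """Normalised plain-dict form (round-trips through the loader)."""
        return {
            "name": self.name,
            "steps": [
                {
                    "product": s.product,
                    "precursor": s.precursor,
                    "required_genes": sorted(s.required_genes),
                    **({"notes": s.notes} if s.notes else {}),
                }
                for s in self.steps
            ],
            "terminal_products": sorted(self.terminal_products),
            "toxic_products": sorted(self.toxic_products),
        }


def canonical_marker(name: str) -> str:
    """Map an input marker name to its canonical id, logging noisy aliases."""
    name = name.strip()
    canon = MARKER_ALIASES.get(name, name)
    if name in _NOISY_ALIASES:
        logger.warning("marker %r read as alias of %r (known naming inconsistency)", name, canon)
    return canon


def _parse_model(doc: Mapping, source: str) -> PathwayModel:
    if not isinstance(doc, Mapping):
        raise ModelError("model document must be a mapping", source=source)
    unknown = set(doc) - {"name", "steps", "terminal_products", "toxic_products"}
    if unknown:
        raise ModelError(f"unknown top-level keys {sorted(unknown)}", source=source)
    name = doc.get("name")
    if name not in MODEL_NAMES:
        raise ModelError(f"name must be one of {MODEL_NAMES}, got {name!r}", source=source, fld="name")
    raw_steps = doc.get("steps")
    if not isinstance(raw_steps, Sequence) or not raw_steps:
        raise ModelError("steps must be a non-empty list", source=source, fld="steps")

    steps: list[PathwayStep] = []
    for i, raw in enumerate(raw_steps):
        if not isinstance(raw, Mapping):
            raise ModelError(f"step #{i} is not a mapping", source=source, step=str(i))
        extra = set(raw) - {"product", "precursor", "required_genes", "notes"}
        if extra:
            raise ModelError(f"unknown keys {sorted(extra)}", source=source, step=str(raw.get("product", i)))
        product = raw.get("product")
        if not isinstance(product, str) or not product:
            raise ModelError("product must be a non-empty string", source=source, step=str(i), fld="product")
        genes_raw = raw.get("required_genes", [])
        if not isinstance(genes_raw, Sequence) or isinstance(genes_raw, str):
            raise ModelError("required_genes must be a list", source=source, step=product, fld="required_genes")
        genes = frozenset(canonical_marker(str(g)) for g in genes_raw)
        precursor = raw.get("precursor")
        if precursor is not None and not isinstance(precursor, str):
            raise ModelError("precursor must be a string or null", source=source, step=product, fld="precursor")
        steps.append(PathwayStep(product, precursor, genes, str(raw.get("notes", ""))))

    model = PathwayModel(
        name=name,
        steps=tuple(steps),
        terminal_products=frozenset(doc.get("terminal_products") or ()),
        toxic_products=frozenset(doc.get("toxic_products") or ()),
    )

    # Hard gates: references resolve, products unique, graph acyclic.
    products = model.products
    seen: set[str] = set()
    for s in model.steps:
        if s.product in seen:
            raise ModelError("duplicate product", source=source, step=s.product, fld="product")
        seen.add(s.product)
    for s in model.steps:
        if s.precursor is not None and s.precursor not in seen:
            raise ModelError(
                f"precursor {s.precursor!r} does not name a declared product",
                source=source, step=s.product, fld="precursor",
            )
    graph = model.precursor_graph()
    if not nx.is_directed_acyclic_graph(graph):
        cycle = [u for u, _ in nx.find_cycle(graph)]
        raise CycleError(cycle + [cycle[0]], source=source)
    for fld in ("terminal_products", "toxic_products"):
        stray = getattr(model, fld) - set(products)
        if stray:
            raise ModelError(f"{fld} not produced by any step: {sorted(stray)}", source=source, fld=fld)
    return model


def validate_model(model: PathwayModel) -> list[Finding]:
    """Advisory re-validation of an already-loaded model.

    Structural invariants that the loader enforces as hard errors are
    re-checked here as findings so that programmatically constructed models
    can be audited without exception handling.
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    for s in model.steps:
        if not s.required_genes and s.precursor is None:
            findings.append(Finding("error", s.product, "vacuous step: no required genes and no precursor"))
        if s.product in seen:
            findings.append(Finding("error", s.product, "duplicate product"))
        seen.add(s.product)
    for s in model.steps:
        if s.precursor is not None and s.precursor not in seen:
            findings.append(Finding("error", s.product, f"dangling precursor {s.precursor!r}"))
    graph = model.precursor_graph()
    if not nx.is_directed_acyclic_graph(graph):
        findings.append(Finding("error", None, "precursor graph is cyclic"))
    for fld in ("terminal_products", "toxic_products"):
        stray = getattr(model, fld) - set(model.products)
        if stray:
            findings.append(Finding("error", None, f"{fld} not produced by any step: {sorted(stray)}"))
    if model.name not in MODEL_NAMES:
        findings.append(Finding("error", None, f"unknown model name {model.name!r}"))
    return findings


def _read_document(path: Path) -> Mapping:
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_model_file(path: str | Path) -> PathwayModel:
    path = Path(path)
    return _parse_model(_read_document(path), source=str(path))


def builtin_models() -> dict[str, PathwayModel]:
    """The four bundled default models keyed by name (PPZ, EAS, IDT, LOL)."""
    out: dict[str, PathwayModel] = {}
    base = resources.files("endochem.data") / "models"
    for stem in ("ppz", "eas", "idt", "lol"):
        doc = yaml.safe_load((base / f"{stem}.yaml").read_text(encoding="utf-8"))
        model = _parse_model(doc, source=f"builtin:{stem}")
        out[model.name] = model
    return out


def load_models(paths: Iterable[str | Path] | None = None) -> dict[str, PathwayModel]:
    """Load pathway models from files, or the built-in registry if ``paths``
    is None/empty.  Returns a dict keyed by model name."""
    if not paths:
        return builtin_models()
    out: dict[str, PathwayModel] = {}
    for p in paths:
        model = load_model_file(p)
        if model.name in out:
            raise ModelError(f"model {model.name} defined twice", source=str(p))
        out[model.name] = model
    return out


def marker_registry(models: Mapping[str, PathwayModel]) -> dict[str, GeneMarker]:
    """All markers known to a model set, plus the mating-type idiomorphs."""
    registry: dict[str, GeneMarker] = {m.id: m for m in MATING_TYPE_MARKERS}
    for model in models.values():
        for marker in model.gene_markers():
            existing = registry.get(marker.id)
            if existing is not None and existing.cluster != marker.cluster:
                raise ModelError(
                    f"marker {marker.id!r} claimed by clusters {existing.cluster} and {marker.cluster}"
                )
            registry[marker.id] = marker
    return registry
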