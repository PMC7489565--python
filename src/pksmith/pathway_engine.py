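"""Post-PKS tailoring as an ordered reaction table with knockout simulation.

The tailoring pathway (tetronate formation and chain release, exocyclic
double-bond installation, double epoxidation and the tetrahydrofuran cascade,
the two [4+2] cyclisations and the two cytochrome P450 hydroxylations) is
encoded as data: each step lists its required genes, the cluster capability
that licenses it, a signed element delta and its prerequisites.  Simulation is
pure bookkeeping -- a step is blocked when a required gene is knocked out or a
prerequisite is blocked, and the product formula is the chain formula plus the
deltas of the applied steps.  That makes the wild-type endpoint C42H64O12 and
the PyrE3-like-cyclase knockout endpoint C42H64O11 exact, reproducible
quantities rather than estimates.

Precursor-supply genes are capability gates: knocking out any member of the
methoxymalonate subcluster removes that extender's supply, and a chain that
needs it yields no product at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .chain_assembler import LinearChain, chain_formula
from .cluster_model import ClusterModel
from .errors import ValidationError
from .ms_adducts import Formula

logger = logging.getLogger(__name__)

_DATA = Path(__file__).parent / "data"


@dataclass
class TailoringStep:
    step_id: str
    name: str
    required_genes: list[str]
    capability: str
    formula_delta: dict[str, int] = field(default_factory=dict)
    prerequisites: list[str] = field(default_factory=list)
    site_note: str = ""


@dataclass
class ReactionTable:
    steps: list[TailoringStep]
    final_product_label: str
    extender_supply: dict[str, list[str]] = field(default_factory=dict)
    label_rules: list[dict] = field(default_factory=list)
    version: int = 1

    def known_genes(self) -> set[str]:
        genes: set[str] = set()
        for s in self.steps:
            genes.update(s.required_genes)
        for g in self.extender_supply.values():
            genes.update(g)
        return genes


def load_reaction_table(path: str | Path | None = None) -> ReactionTable:
    """Load the packaged reaction table (or a user override)."""
    p = Path(path) if path is not None else _DATA / "reaction_table.yaml"
    raw = yaml.safe_load(p.read_text())
    steps = [
        TailoringStep(
            step_id=s["id"],
            name=s["name"],
            required_genes=list(s.get("genes", [])),
            capability=s.get("capability", ""),
            formula_delta={k: int(v) for k, v in (s.get("delta") or {}).items()},
            prerequisites=list(s.get("prerequisites", [])),
            site_note=s.get("site", ""),
        )
        for s in raw["steps"]
    ]
    table = ReactionTable(
        steps=steps,
        final_product_label=raw.get("final_product_label", "final product"),
        extender_supply={k: list(v) for k, v in (raw.get("extender_supply") or {}).items()},
        label_rules=list(raw.get("label_rules", [])),
        version=int(raw.get("version", 1)),
    )
    _check_acyclic(table.steps)
    return table


def _check_acyclic(steps: Sequence[TailoringStep]) -> None:
    graph = {s.step_id: s.prerequisites for s in steps}
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 1:
            raise ValidationError(f"cyclic prerequisite configuration at step {node}")
        if state.get(node) == 2:
            return
        state[node] = 1
        for dep in graph.get(node, []):
            visit(dep)
        state[node] = 2

    for sid in graph:
        visit(sid)


# ---------------------------------------------------------------------------
# Capabilities
# ---------------------------------------------------------------------------

@dataclass
class CapabilityReport:
    """Which tailoring machinery a cluster encodes, from product labels alone."""

    has_glycerate_operon: bool = False
    has_methoxymalonate_subcluster: bool = False
    has_epoxidase_hydrolase_pair: bool = False
    p450_count: int = 0
    pyrE3_like_cyclase: bool = False
    vstJ_like_cyclase: bool = False
    evidence: dict[str, list[str]] = field(default_factory=dict)

    def supports(self, capability: str) -> bool:
        if capability == "":
            return True
        if capability == "p450":
            return self.p450_count >= 1
        if capability == "p450_pair":
            return self.p450_count >= 2
        return bool(getattr(self, capability, False))


#: label multisets behind the two five-gene operon flags
_GLYCERATE_NEEDS = [
    "FkbH-like",
    "ACP",
    "FabH-like",
    "acyltransferase(Agg4-like)",
    "dehydratase(Agg5-like)",
]
_METHOXYMALONATE_NEEDS = ["FkbH-like", "ACP", "dehydrogenase", "dehydrogenase", "O-methyltransferase"]


def detect_capabilities(cluster: ClusterModel) -> CapabilityReport:
    """Compute capability flags purely from gene product-label counts."""
    by_label: dict[str, list[str]] = {}
    for g in cluster.genes:
        by_label.setdefault(g.product_label, []).append(g.gene_id)

    def have(needs: list[str]) -> Optional[list[str]]:
        from collections import Counter

        need_counts = Counter(needs)
        evidence: list[str] = []
        for label, n in need_counts.items():
            ids = by_label.get(label, [])
            if len(ids) < n:
                return None
            evidence.extend(ids[:n])
        return evidence

    report = CapabilityReport()
    ev = have(_GLYCERATE_NEEDS)
    if ev is not None:
        report.has_glycerate_operon = True
        report.evidence["has_glycerate_operon"] = ev
    ev = have(_METHOXYMALONATE_NEEDS)
    if ev is not None:
        report.has_methoxymalonate_subcluster = True
        report.evidence["has_methoxymalonate_subcluster"] = ev
    if by_label.get("epoxidase") and by_label.get("epoxide-hydrolase"):
        report.has_epoxidase_hydrolase_pair = True
        report.evidence["has_epoxidase_hydrolase_pair"] = (
            by_label["epoxidase"][:1] + by_label["epoxide-hydrolase"][:1]
        )
    report.p450_count = len(by_label.get("P450", []))
    if report.p450_count:
        report.evidence["p450"] = by_label["P450"]
    if by_label.get("PyrE3-like-cyclase"):
        report.pyrE3_like_cyclase = True
        report.evidence["pyrE3_like_cyclase"] = by_label["PyrE3-like-cyclase"][:1]
    if by_label.get("VstJ-like-cyclase"):
        report.vstJ_like_cyclase = True
        report.evidence["vstJ_like_cyclase"] = by_label["VstJ-like-cyclase"][:1]
    return report


# ---------------------------------------------------------------------------
# Pathway construction and simulation
# ---------------------------------------------------------------------------

def build_pathway(
    capabilities: CapabilityReport,
    chain: LinearChain,
    table: Optional[ReactionTable] = None,
    c38_hydroxylation_after: str = "XV",
) -> list[TailoringStep]:
    """Instantiate the canonical step list for a cluster's capabilities.

    Steps whose capability is missing are omitted with a warning.  Whether the
    final C38 hydroxylation requires only the oxadecalin (XV) or the finished
    tetrahydropyran (XVII) is not settled; the default keeps XV.
    """
    if table is None:
        table = load_reaction_table()
    if c38_hydroxylation_after not in ("XV", "XVII"):
        raise ValidationError("c38_hydroxylation_after must be 'XV' or 'XVII'")
    steps: list[TailoringStep] = []
    for s in table.steps:
        if not capabilities.supports(s.capability):
            logger.warning(
                "step %s (%s) omitted: cluster lacks capability %s", s.step_id, s.name, s.capability
            )
            continue
        if s.step_id == "XVIII" and c38_hydroxylation_after == "XVII":
            s = TailoringStep(
                step_id=s.step_id,
                name=s.name,
                required_genes=list(s.required_genes),
                capability=s.capability,
                formula_delta=dict(s.formula_delta),
                prerequisites=["XVII"],
                site_note=s.site_note,
            )
        steps.append(s)
    _check_acyclic(steps)
    return steps


@dataclass
class PathwayState:
    """Outcome of a (possibly knocked-out) pathway simulation."""

    formula: Optional[Formula]
    applied_steps: list[str] = field(default_factory=list)
    blocked_steps: list[tuple[str, str]] = field(default_factory=list)
    product_label: str = ""

    @property
    def blocked_ids(self) -> set[str]:
        return {sid for sid, _ in self.blocked_steps}


def simulate(
    pathway: Sequence[TailoringStep],
    chain: LinearChain,
    knockouts: Iterable[str] = (),
    cluster: Optional[ClusterModel] = None,
    table: Optional[ReactionTable] = None,
) -> PathwayState:
    """Apply the pathway to a chain under a set of gene knockouts.

    A step is blocked when a required gene is knocked out or any prerequisite
    is blocked; blocking is therefore monotone in the knockout set.  Knocking
    out a precursor-supply gene for an extender the chain uses aborts with a
    "no product" state.  Unknown knockout gene ids are a hard error.
    """
    if table is None:
        table = load_reaction_table()
    knockouts = set(knockouts)
    known = table.known_genes()
    if cluster is not None:
        known |= {g.gene_id for g in cluster.genes}
    unknown = knockouts - known
    if unknown:
        raise ValidationError(f"unknown gene(s) in knockouts: {sorted(unknown)}")

    # precursor-supply gate
    used_extenders = {chain.starter.extender.name} | {m.extender.name for m in chain.extensions}
    for extender, supply in table.extender_supply.items():
        if extender in used_extenders and knockouts & set(supply):
            return PathwayState(
                formula=None,
                blocked_steps=[(s.step_id, f"{extender} extender unavailable") for s in pathway],
                product_label=f"no product ({extender} extender unavailable)",
            )

    formula = chain_formula(chain)
    state = PathwayState(formula=formula)
    blocked: dict[str, str] = {}
    for step in pathway:
        missing = sorted(set(step.required_genes) & knockouts)
        bad_prereq = [p for p in step.prerequisites if p in blocked]
        unmet = [p for p in step.prerequisites if p not in blocked and p not in state.applied_steps]
        if missing:
            blocked[step.step_id] = f"required gene(s) knocked out: {', '.join(missing)}"
        elif bad_prereq:
            blocked[step.step_id] = f"prerequisite step(s) blocked: {', '.join(bad_prereq)}"
        elif unmet:
            blocked[step.step_id] = f"prerequisite step(s) absent from pathway: {', '.join(unmet)}"
        else:
            formula = formula.shifted(step.formula_delta)
            state.applied_steps.append(step.step_id)
    state.formula = formula
    state.blocked_steps = sorted(blocked.items())
    state.product_label = _label(table, pathway, state)
    return state


def _label(table: ReactionTable, pathway: Sequence[TailoringStep], state: PathwayState) -> str:
    if not state.blocked_steps:
        return table.final_product_label
    blocked = state.blocked_ids
    for rule in table.label_rules:
        if set(rule["blocked"]) == blocked:
            return rule["label"]
    return f"partial pathway product ({len(blocked)} step(s) blocked)"
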