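"""Core data model for type I PKS gene clusters.

A :class:`ClusterModel` holds the genes of a biosynthetic gene cluster with
controlled-vocabulary functional labels and, for the PKS multienzymes, the
ordered extension modules with their catalytic domains.  Everything downstream
(domain annotation, chain assembly, pathway simulation) consumes this model.

An :class:`ArchitectureSpec` is the declarative ground-truth counterpart: per
module, which domains exist and which motif state each carries.  The synthetic
fixture generator reads it to plant motifs; the annotator is tested blind
against it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_SET = frozenset(AA20)

DOMAIN_KINDS = ("KS", "AT", "DH", "ER", "KR", "ACP")
#: canonical intra-module order; deviations are stored but warned about
DOMAIN_ORDER = {k: i for i, k in enumerate(DOMAIN_KINDS)}

#: closed controlled vocabulary for gene product labels.  The pathway engine
#: keys cluster capabilities off these strings, so free text would silently
#: disable tailoring steps; anything else must use "other".
PRODUCT_LABELS = frozenset(
    {
        "FkbH-like",
        "FabH-like",
        "acyltransferase(Agg4-like)",
        "dehydratase(Agg5-like)",
        "epoxidase",
        "epoxide-hydrolase",
        "P450",
        "PyrE3-like-cyclase",
        "VstJ-like-cyclase",
        "O-methyltransferase",
        "ACP",
        "dehydrogenase",
        "PKS",
        "regulator",
        "transporter",
        "other",
    }
)


def _check_protein(sequence: str, context: str) -> None:
    for i, ch in enumerate(sequence):
        if ch not in _AA20_SET:
            raise ValidationError(
                f"{context}: non-standard amino-acid letter {ch!r} at position {i}"
            )


def module_sort_key(module_index: str) -> tuple[int, int]:
    """Loading module first, then numeric order."""
    if module_index == "LM":
        return (0, 0)
    try:
        return (1, int(module_index))
    except ValueError as exc:  # pragma: no cover - guarded by validation
        raise ValidationError(f"bad module index {module_index!r}") from exc


@dataclass
class GeneRecord:
    """One gene of the cluster with its functional label.

    ``cds_length_nt``, when given alongside a protein sequence, must equal
    3*(len(sequence)+1) (coding frame including the stop codon).
    """

    gene_id: str
    product_label: str = "other"
    sequence: Optional[str] = None
    cds_length_nt: Optional[int] = None

    def __post_init__(self) -> None:
        if self.product_label not in PRODUCT_LABELS:
            raise ValidationError(
                f"gene {self.gene_id}: unknown product_label "
                f"{self.product_label!r} (use 'other' for unclassified genes)"
            )
        if self.sequence is not None:
            _check_protein(self.sequence, f"gene {self.gene_id}")
        if self.cds_length_nt is not None:
            if self.cds_length_nt <= 0:
                raise ValidationError(f"gene {self.gene_id}: cds_length_nt must be positive")
            if self.sequence is not None and self.cds_length_nt != 3 * (len(self.sequence) + 1):
                raise ValidationError(
                    f"gene {self.gene_id}: cds_length_nt={self.cds_length_nt} does not "
                    f"equal 3*(protein length {len(self.sequence)} + 1)"
                )


@dataclass
class DomainRecord:
    """One catalytic domain of a PKS module."""

    domain_kind: str
    sequence: str
    module_index: str

    def __post_init__(self) -> None:
        if self.domain_kind not in DOMAIN_KINDS:
            raise ValidationError(f"unknown domain kind {self.domain_kind!r}")
        _check_protein(self.sequence, f"domain {self.domain_kind} (module {self.module_index})")


@dataclass
class ModuleRecord:
    """One PKS module: its index label, parent gene, and ordered domains."""

    module_index: str
    gene_id: str
    domains: list[DomainRecord] = field(default_factory=list)

    def domain(self, kind: str) -> Optional[DomainRecord]:
        for d in self.domains:
            if d.domain_kind == kind:
                return d
        return None

    def validate(self) -> None:
        kinds = [d.domain_kind for d in self.domains]
        for required in ("KS", "AT", "ACP"):
            if kinds.count(required) != 1:
                raise ValidationError(
                    f"module {self.module_index}: expected exactly one {required} domain, "
                    f"found {kinds.count(required)}"
                )
        for optional in ("DH", "ER", "KR"):
            if kinds.count(optional) > 1:
                raise ValidationError(
                    f"module {self.module_index}: more than one {optional} domain"
                )
        order = [DOMAIN_ORDER[k] for k in kinds]
        if order != sorted(order):
            warnings.warn(
                f"module {self.module_index}: domain order {kinds} deviates from "
                "canonical KS-AT-(DH)-(ER)-(KR)-ACP; stored as given",
                stacklevel=2,
            )


@dataclass
class ClusterModel:
    """A gene cluster: ordered genes plus the ordered PKS module list."""

    cluster_id: str
    genes: list[GeneRecord] = field(default_factory=list)
    pks_modules: list[ModuleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.pks_modules:
            if m.module_index in seen:
                raise ValidationError(f"duplicate module index {m.module_index!r}")
            seen.add(m.module_index)
            m.validate()
        if "LM" in seen and self.pks_modules[0].module_index != "LM":
            raise ValidationError("loading module LM must come first in pks_modules")
        indices = [module_sort_key(m.module_index) for m in self.pks_modules]
        if indices != sorted(indices):
            warnings.warn(
                f"cluster {self.cluster_id}: pks_modules are not in ascending "
                "module order; downstream chain assembly uses the order given",
                stacklevel=2,
            )

    def gene(self, gene_id: str) -> Optional[GeneRecord]:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        return None

    def module(self, module_index: str) -> Optional[ModuleRecord]:
        for m in self.pks_modules:
            if m.module_index == module_index:
                return m
        return None

    # -- JSON round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "product_label": g.product_label,
                    "sequence": g.sequence,
                    "cds_length_nt": g.cds_length_nt,
                }
                for g in self.genes
            ],
            "pks_modules": [
                {
                    "module_index": m.module_index,
                    "gene_id": m.gene_id,
                    "domains": [
                        {
                            "domain_kind": d.domain_kind,
                            "sequence": d.sequence,
                            "module_index": d.module_index,
                        }
                        for d in m.domains
                    ],
                }
                for m in self.pks_modules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ClusterModel":
        try:
            genes = [GeneRecord(**g) for g in data["genes"]]
            modules = [
                ModuleRecord(
                    module_index=m["module_index"],
                    gene_id=m["gene_id"],
                    domains=[DomainRecord(**d) for d in m["domains"]],
                )
                for m in data["pks_modules"]
            ]
            return cls(cluster_id=data["cluster_id"], genes=genes, pks_modules=modules)
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed cluster JSON: {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# ArchitectureSpec: declarative ground truth for fixtures
# ---------------------------------------------------------------------------

#: motif-state field names allowed per domain kind (closed vocabulary)
_DOMAIN_SPEC_FIELDS = {
    "KS": {"ks_residue"},
    "AT": {"at_motif"},
    "DH": {"ygp_tyr", "catalytic_asp"},
    "KR": {"catalytic_tyr", "ldd", "pro_at_tyr_plus2", "nadph_deletion"},
    "ER": {"key_tyr"},
    "ACP": set(),
}

_DOMAIN_SPEC_DEFAULTS = {
    "KS": {"ks_residue": "C"},
    "AT": {"at_motif": "YASH"},
    "DH": {"ygp_tyr": True, "catalytic_asp": True},
    "KR": {
        "catalytic_tyr": True,
        "ldd": True,
        "pro_at_tyr_plus2": False,
        "nadph_deletion": False,
    },
    "ER": {"key_tyr": False},
    "ACP": {},
}


@dataclass
class DomainSpec:
    """Intended motif state of one domain (generator input / annotator truth)."""

    kind: str
    state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in DOMAIN_KINDS:
            raise ValidationError(f"unknown domain kind {self.kind!r}")
        allowed = _DOMAIN_SPEC_FIELDS[self.kind]
        extra = set(self.state) - allowed
        if extra:
            raise ValidationError(f"{self.kind} spec: unknown state fields {sorted(extra)}")
        merged = dict(_DOMAIN_SPEC_DEFAULTS[self.kind])
        merged.update(self.state)
        self.state = merged
        if self.kind == "KS" and self.state["ks_residue"] not in _AA20_SET:
            raise ValidationError(f"KS spec: ks_residue must be one amino-acid letter")
        if self.kind == "AT":
            motif = self.state["at_motif"]
            if len(motif) != 4 or any(c not in _AA20_SET for c in motif):
                raise ValidationError(f"AT spec: at_motif must be 4 amino-acid letters, got {motif!r}")


@dataclass
class ModuleSpec:
    module_index: str
    gene_id: str
    domains: list[DomainSpec] = field(default_factory=list)


@dataclass
class ArchitectureSpec:
    """Declarative cluster description; round-trips losslessly through JSON."""

    cluster_id: str
    modules: list[ModuleSpec] = field(default_factory=list)
    tailoring_genes: list[dict] = field(default_factory=list)
    notes: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for m in self.modules:
            if m.module_index in seen:
                raise ValidationError(f"duplicate module index {m.module_index!r} in spec")
            seen.add(m.module_index)
        if sum(1 for m in self.modules if m.module_index == "LM") > 1:
            raise ValidationError("module LM appears more than once")
        for t in self.tailoring_genes:
            if t.get("product_label", "other") not in PRODUCT_LABELS:
                raise ValidationError(
                    f"tailoring gene {t.get('gene_id')}: bad label {t.get('product_label')!r}"
                )

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "modules": [
                {
                    "module_index": m.module_index,
                    "gene_id": m.gene_id,
                    "domains": [{"kind": d.kind, **d.state} for d in m.domains],
                }
                for m in self.modules
            ],
            "tailoring_genes": self.tailoring_genes,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ArchitectureSpec":
        try:
            modules = []
            for m in data["modules"]:
                domains = []
                for d in m["domains"]:
                    d = dict(d)
                    kind = d.pop("kind")
                    domains.append(DomainSpec(kind=kind, state=d))
                modules.append(
                    ModuleSpec(module_index=m["module_index"], gene_id=m["gene_id"], domains=domains)
                )
            return cls(
                cluster_id=data["cluster_id"],
                modules=modules,
                tailoring_genes=data.get("tailoring_genes", []),
                notes=data.get("notes", ""),
            )
        except (KeyError, TypeError) as exc:
            raise ParseError(f"malformed architecture spec: {exc}") from exc

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ArchitectureSpec":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        try:
            return cls.from_dict(json.loads(text))
        except json.JSONDecodeError as exc:
            raise ParseError(f"architecture spec is not valid JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cluster_fasta(path: str | Path, module_map: dict | ArchitectureSpec) -> ClusterModel:
    """Build a :class:`ClusterModel` from a protein FASTA plus a module map.

    ``module_map`` is either a dict (the JSON module-map schema: ``gene_labels``
    mapping gene_id -> product_label, and ``modules`` with 0-based half-open
    ``[start, end)`` domain coordinates on the parent protein) or an
    :class:`ArchitectureSpec` accompanied by coordinates is not supported --
    specs describe intent, maps describe layout.
    """
    if isinstance(module_map, ArchitectureSpec):
        raise ValidationError(
            "read_cluster_fasta needs a coordinate module map; an ArchitectureSpec "
            "carries motif intent, not coordinates (generate a bundle instead)"
        )
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no sequences")
    gene_labels = module_map.get("gene_labels", {})
    sequences: dict[str, str] = {}
    genes: list[GeneRecord] = []
    for rec in records:
        gene_id = rec.id.split()[0]
        if gene_id not in gene_labels:
            raise ValidationError(
                f"FASTA header {gene_id!r} is absent from the module map gene_labels"
            )
        seq = str(rec.seq).upper()
        _check_protein(seq, f"gene {gene_id}")
        sequences[gene_id] = seq
        genes.append(GeneRecord(gene_id=gene_id, product_label=gene_labels[gene_id], sequence=seq))
    modules: list[ModuleRecord] = []
    for m in module_map.get("modules", []):
        gene_id = m["gene_id"]
        if gene_id not in sequences:
            raise ValidationError(f"module map references gene {gene_id!r} not present in FASTA")
        parent = sequences[gene_id]
        domains = []
        for d in m["domains"]:
            start, end = int(d["start"]), int(d["end"])
            if not (0 <= start < end <= len(parent)):
                raise ValidationError(
                    f"module {m['module_index']} {d['kind']}: coordinates [{start}, {end}) "
                    f"fall outside gene {gene_id} (length {len(parent)})"
                )
            domains.append(
                DomainRecord(
                    domain_kind=d["kind"],
                    sequence=parent[start:end],
                    module_index=m["module_index"],
                )
            )
        modules.append(ModuleRecord(module_index=m["module_index"], gene_id=gene_id, domains=domains))
    return ClusterModel(
        cluster_id=module_map.get("cluster_id", Path(path).stem), genes=genes, pks_modules=modules
    )


def write_cluster_fasta(cluster: ClusterModel, path: str | Path) -> None:
    """Inverse of :func:`read_cluster_fasta` for the gene sequences."""
    with open(path, "w") as fh:
        for g in cluster.genes:
            if g.sequence is None:
                continue
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.sequence), 60):
                fh.write(g.sequence[i : i + 60] + "\n")


def read_cluster_genbank(path: str | Path) -> ClusterModel:
    """One GeneRecord per CDS feature; PKS module splitting is deferred.

    CDS features must carry ``/gene`` or ``/locus_tag`` plus ``/translation``;
    those without a translation are skipped with a warning.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path}: unparseable GenBank record: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: unparseable GenBank record: no records found")
    genes: list[GeneRecord] = []
    for rec in records:
        n_cds = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            quals = feat.qualifiers
            gene_id = (quals.get("gene") or quals.get("locus_tag") or [None])[0]
            if gene_id is None:
                gene_id = f"cds{n_cds}"
            translation = (quals.get("translation") or [None])[0]
            if translation is None:
                logger.warning("CDS %s lacks /translation; skipped", gene_id)
                continue
            label = (quals.get("product") or ["other"])[0]
            if label not in PRODUCT_LABELS:
                label = "other"
            genes.append(GeneRecord(gene_id=gene_id, product_label=label, sequence=translation))
        if n_cds == 0:
            logger.warning("GenBank record %s contains no CDS features", rec.id)
    return ClusterModel(cluster_id=records[0].id, genes=genes, pks_modules=[])


ANNOTATION_COLUMNS = [
    "gene",
    "module",
    "kind",
    "subtype",
    "active",
    "motif_evidence",
    "stereo_outcome",
]


def write_annotation_table(cluster: ClusterModel, calls: Sequence, path: str | Path) -> None:
    """Write domain calls as a deterministic TSV (module order, then KS<AT<DH<ER<KR<ACP)."""
    import pandas as pd

    known_modules = {m.module_index for m in cluster.pks_modules}
    seen: set[tuple[str, str]] = set()
    rows = []
    for call in calls:
        if call.module_index not in known_modules:
            raise ValidationError(f"call references unknown module {call.module_index!r}")
        key = (call.module_index, call.kind)
        if key in seen:
            raise ValidationError(f"duplicate call for module {key[0]} domain {key[1]}")
        seen.add(key)
        rows.append(
            {
                "gene": call.gene_id,
                "module": call.module_index,
                "kind": call.kind,
                "subtype": call.subtype,
                "active": call.active,
                "motif_evidence": json.dumps(call.motif_evidence, sort_keys=True),
                "stereo_outcome": call.stereo_outcome,
            }
        )
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    if len(df):
        df = df.sort_values(
            by=["module", "kind"],
            key=lambda col: (
                col.map(lambda v: module_sort_key(v)) if col.name == "module" else col.map(DOMAIN_ORDER)
            ),
            kind="stable",
        ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)
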