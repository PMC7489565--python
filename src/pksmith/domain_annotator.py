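"""Classify PKS domains from sequence via reference-anchored motifs.

Each domain sequence is globally aligned to the packaged scaffold of its kind
(BLOSUM62, affine gaps); the residues landing in the scaffold's anchor columns
are then read off and interpreted by per-kind rules:

* KS: C at the catalytic column -> extension; Q -> KS^Q (decarboxylating
  loading KS); anything else -> inactive.
* AT: 4-residue selectivity window; exact HASH -> relaxed hybrid,
  (H/T/V/Y)AFH -> acetate (malonyl-CoA), (Y/V/W)ASH -> propionate
  ((2S)-methylmalonyl-CoA), otherwise unknown.  HASH is checked first so the
  hybrid is not swallowed by the acetate pattern.
* KR: catalytic tyrosine absent -> inactive; present with (L/V/I)DD -> B1
  (no Pro two residues after the tyrosine) or B2 (Pro there); present without
  the motif -> A-type.  B-types give a D-configured beta-hydroxyl (B1 also a
  D alpha-methyl); A-type gives L.  A >50% gap fraction over the NADPH window
  flags a binding-site deletion and forces inactivity.
* DH: active iff the YGP tyrosine and the catalytic aspartate are both present.
* ER: key tyrosine present -> L-configuring, absent -> D-configuring.

Annotation is deterministic: identical inputs give identical calls.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .cluster_model import ClusterModel, module_sort_key
from .errors import UnalignableDomainError, ValidationError
from .scaffolds import DEFAULT_SCAFFOLDS, ReferenceScaffold

GAP = "-"

#: minimum fraction of identical alignment columns before a domain is refused
DEFAULT_IDENTITY_FLOOR = 0.20

#: minimum domain length accepted by anchor_align
MIN_DOMAIN_LENGTH = 50

_AT_HYBRID = "HASH"
_AT_ACETATE = re.compile(r"^[HTVY]AFH$")
_AT_PROPIONATE = re.compile(r"^[YVW]ASH$")

#: gap fraction over the KR NADPH window above which the site counts as deleted
DEFAULT_NADPH_GAP_THRESHOLD = 0.5


@dataclass(frozen=True)
class ExtenderUnit:
    """One chain-extension building block and its atom bookkeeping."""

    name: str
    backbone_carbons: int
    side_group: str  # none | methyl | methoxy
    total_carbons: int


EXTENDERS: dict[str, ExtenderUnit] = {
    "acetate": ExtenderUnit("acetate", 2, "none", 2),
    "propionate": ExtenderUnit("propionate", 2, "methyl", 3),
    "methoxymalonate": ExtenderUnit("methoxymalonate", 2, "methoxy", 3),
    "glycerate": ExtenderUnit("glycerate", 3, "none", 3),
}

_AT_SUBTYPE_TO_EXTENDER = {
    "acetate": "acetate",
    "propionate": "propionate",
    "methoxymalonate_override": "methoxymalonate",
}


@dataclass
class DomainCall:
    """One domain's classification with its motif evidence."""

    gene_id: str
    module_index: str
    kind: str
    subtype: str
    active: bool
    motif_evidence: dict
    stereo_outcome: str = "none"  # D | L | none
    notes: list[str] = field(default_factory=list)


@dataclass
class AnchorMap:
    """Residues of a query found at a scaffold's anchor columns."""

    anchors: dict[str, str]  # anchor name -> residues (GAP for deletions)
    identity: float
    score: float
    scaffold_version: str

    def evidence(self) -> dict:
        return {
            "anchors": dict(self.anchors),
            "identity": round(self.identity, 4),
            "score": self.score,
            "scaffold_version": self.scaffold_version,
        }


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def anchor_align(
    domain_seq: str,
    scaffold: ReferenceScaffold,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> AnchorMap:
    """Map scaffold anchor columns onto a domain sequence by global alignment.

    Raises :class:`UnalignableDomainError` when alignment identity (identical
    columns over total alignment columns) falls below ``identity_floor``.
    Deterministic: Biopython enumerates co-optimal paths in a fixed order and
    the first (high-road) alignment is used.
    """
    if len(domain_seq) < MIN_DOMAIN_LENGTH:
        raise ValidationError(
            f"domain sequence too short ({len(domain_seq)} < {MIN_DOMAIN_LENGTH}) for anchoring"
        )
    alignment = _ALIGNER.align(scaffold.sequence, domain_seq)[0]
    # column map scaffold index -> query index (or None for a gap)
    colmap: dict[int, Optional[int]] = {}
    identical = 0
    columns = 0
    coords = alignment.coordinates
    for k in range(coords.shape[1] - 1):
        t0, t1 = int(coords[0, k]), int(coords[0, k + 1])
        q0, q1 = int(coords[1, k]), int(coords[1, k + 1])
        if t1 > t0 and q1 > q0:  # aligned block
            for off in range(t1 - t0):
                colmap[t0 + off] = q0 + off
                if scaffold.sequence[t0 + off] == domain_seq[q0 + off]:
                    identical += 1
            columns += t1 - t0
        elif t1 > t0:  # deletion in query
            for off in range(t1 - t0):
                colmap[t0 + off] = None
            columns += t1 - t0
        else:  # insertion in query
            columns += q1 - q0
    identity = identical / columns if columns else 0.0
    if identity < identity_floor:
        raise UnalignableDomainError(
            f"unalignable domain: identity {identity:.3f} below floor {identity_floor:.2f} "
            f"against {scaffold.domain_kind} scaffold v{scaffold.version}"
        )
    anchors = {
        name: "".join(
            domain_seq[colmap[c]] if colmap.get(c) is not None else GAP for c in cols
        )
        for name, cols in scaffold.anchors.items()
    }
    return AnchorMap(
        anchors=anchors,
        identity=identity,
        score=float(alignment.score),
        scaffold_version=scaffold.version,
    )


def _call(
    kind: str,
    domain_seq: str,
    scaffolds: dict[str, ReferenceScaffold],
    identity_floor: float,
    gene_id: str,
    module_index: str,
) -> tuple[AnchorMap, DomainCall]:
    amap = anchor_align(domain_seq, scaffolds[kind], identity_floor=identity_floor)
    call = DomainCall(
        gene_id=gene_id,
        module_index=module_index,
        kind=kind,
        subtype="",
        active=True,
        motif_evidence=amap.evidence(),
    )
    return amap, call


def call_ks(
    domain_seq: str,
    *,
    gene_id: str = "",
    module_index: str = "",
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> DomainCall:
    amap, call = _call("KS", domain_seq, scaffolds, identity_floor, gene_id, module_index)
    residue = amap.anchors["catalytic_cys"]
    if residue == "C":
        call.subtype, call.active = "extension", True
    elif residue == "Q":
        call.subtype, call.active = "KSQ", True
        if module_index not in ("", "LM"):
            call.notes.append(
                f"KSQ (decarboxylating loading KS) found in module {module_index}; "
                "expected only in the loading module"
            )
    else:
        call.subtype, call.active = "extension", False
        call.notes.append(f"catalytic cysteine column holds {residue!r}; domain inactive")
    return call


def call_at(
    domain_seq: str,
    *,
    gene_id: str = "",
    module_index: str = "",
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> DomainCall:
    amap, call = _call("AT", domain_seq, scaffolds, identity_floor, gene_id, module_index)
    motif = amap.anchors["selectivity_motif"]
    # priority: exact hybrid first, then acetate, then propionate
    if motif == _AT_HYBRID:
        call.subtype = "relaxed_hybrid"
        call.notes.append(
            "HASH hybrid motif: relaxed selectivity; resolves to propionate when a "
            "target decomposition demands it"
        )
    elif _AT_ACETATE.match(motif):
        call.subtype = "acetate"
    elif _AT_PROPIONATE.match(motif):
        call.subtype = "propionate"
    else:
        call.subtype = "unknown"
        call.active = False
    return call


def call_kr(
    domain_seq: str,
    *,
    gene_id: str = "",
    module_index: str = "",
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    nadph_gap_threshold: float = DEFAULT_NADPH_GAP_THRESHOLD,
) -> DomainCall:
    amap, call = _call("KR", domain_seq, scaffolds, identity_floor, gene_id, module_index)
    tyr = amap.anchors["catalytic_tyr"]
    ldd = amap.anchors["ldd"]
    plus2 = amap.anchors["tyr_plus2"]
    window = amap.anchors["nadph_window"]
    gap_fraction = window.count(GAP) / len(window)
    nadph_deleted = gap_fraction > nadph_gap_threshold
    call.motif_evidence["nadph_gap_fraction"] = round(gap_fraction, 3)
    if nadph_deleted:
        call.motif_evidence["nadph_site_deletion"] = True
        call.notes.append("significant deletion in the NADPH binding site")
    ldd_ok = len(ldd) == 3 and ldd[0] in "LVI" and ldd[1:] == "DD"
    if tyr != "Y" or nadph_deleted:
        call.subtype, call.active, call.stereo_outcome = "inactive", False, "none"
        if tyr != "Y":
            call.notes.append(f"catalytic tyrosine column holds {tyr!r}")
    elif ldd_ok:
        if plus2 == "P":
            call.subtype = "B2"
            call.notes.append(
                "proline two residues after the catalytic tyrosine (B2 marker; an "
                "alternative convention places this proline in A-type domains)"
            )
        else:
            call.subtype = "B1"
        call.stereo_outcome = "D"
    else:
        call.subtype = "A"
        call.stereo_outcome = "L"
        call.notes.append(
            "no (L/V/I)DD motif: A-type assignment (L-hydroxyl) follows the general "
            "ketoreductase stereochemistry literature"
        )
    return call


def call_dh(
    domain_seq: str,
    *,
    gene_id: str = "",
    module_index: str = "",
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> DomainCall:
    amap, call = _call("DH", domain_seq, scaffolds, identity_floor, gene_id, module_index)
    tyr = amap.anchors["ygp_tyr"]
    asp = amap.anchors["catalytic_asp"]
    if tyr == "Y" and asp == "D":
        call.subtype, call.active = "active", True
    else:
        call.subtype, call.active = "inactive", False
        if tyr != "Y":
            call.notes.append(f"YGP tyrosine column holds {tyr!r}")
        if asp != "D":
            call.notes.append(f"catalytic aspartate column holds {asp!r}")
    return call


def call_er(
    domain_seq: str,
    *,
    gene_id: str = "",
    module_index: str = "",
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
) -> DomainCall:
    amap, call = _call("ER", domain_seq, scaffolds, identity_floor, gene_id, module_index)
    tyr = amap.anchors["key_tyr"]
    if tyr == "Y":
        call.subtype, call.stereo_outcome = "L_configuring", "L"
    else:
        call.subtype, call.stereo_outcome = "D_configuring", "D"
    return call


_CALLERS = {"KS": call_ks, "AT": call_at, "KR": call_kr, "DH": call_dh, "ER": call_er}


@dataclass
class AnnotationResult:
    """Batch annotation output: calls plus collected per-domain errors."""

    calls: list[DomainCall] = field(default_factory=list)
    errors: list[dict] = field(default_factory=list)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def call(self, module_index: str, kind: str) -> Optional[DomainCall]:
        for c in self.calls:
            if c.module_index == module_index and c.kind == kind:
                return c
        return None

    def extender_tally(self) -> Counter:
        """Count AT subtypes mapped to extender units (hybrids left as-is)."""
        tally: Counter = Counter()
        for c in self.calls:
            if c.kind != "AT":
                continue
            tally[_AT_SUBTYPE_TO_EXTENDER.get(c.subtype, c.subtype)] += 1
        return tally


def annotate_cluster(
    cluster: ClusterModel,
    target=None,
    *,
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
    identity_floor: float = DEFAULT_IDENTITY_FLOOR,
    nadph_gap_threshold: float = DEFAULT_NADPH_GAP_THRESHOLD,
) -> AnnotationResult:
    """Call every KS/AT/DH/ER/KR domain of a cluster.

    ``target`` is an optional retrobiosynthetic decomposition
    (:class:`~pksmith.chain_assembler.LinearChain` or the dict schema).  When
    supplied, a cluster-level post-pass runs: a relaxed-hybrid loading AT is
    resolved to the target's starter unit, and if the cluster carries the full
    five-gene methoxymalonate subcluster and the target marks a position as
    methoxymalonate, the corresponding propionate AT call is re-labelled
    ``methoxymalonate_override`` with both motifs recorded.

    Per-domain alignment failures are collected in ``errors``; they do not
    abort the batch.
    """
    if not cluster.pks_modules:
        raise ValidationError(f"cluster {cluster.cluster_id} has no PKS modules to annotate")
    result = AnnotationResult()
    for mod in cluster.pks_modules:
        for dom in mod.domains:
            caller = _CALLERS.get(dom.domain_kind)
            if caller is None:  # ACP: presence only, no call
                continue
            kwargs = {}
            if dom.domain_kind == "KR":
                kwargs["nadph_gap_threshold"] = nadph_gap_threshold
            try:
                result.calls.append(
                    caller(
                        dom.sequence,
                        gene_id=mod.gene_id,
                        module_index=mod.module_index,
                        scaffolds=scaffolds,
                        identity_floor=identity_floor,
                        **kwargs,
                    )
                )
            except UnalignableDomainError as exc:
                result.errors.append(
                    {
                        "gene": mod.gene_id,
                        "module": mod.module_index,
                        "kind": dom.domain_kind,
                        "error": str(exc),
                    }
                )
    if target is not None:
        _apply_target_overrides(cluster, result, target)
    return result


def _target_extenders(target) -> dict[str, str]:
    """Extender name per module position from a target decomposition."""
    if hasattr(target, "extensions"):  # LinearChain
        mapping = {"LM": target.starter.extender.name}
        for ext in target.extensions:
            mapping[str(ext.position)] = ext.extender.name
        return mapping
    mapping = {"LM": target["starter"]["extender"]}
    for ext in target["extensions"]:
        mapping[str(ext["position"])] = ext["extender"]
    return mapping


def _apply_target_overrides(cluster: ClusterModel, result: AnnotationResult, target) -> None:
    from .pathway_engine import detect_capabilities

    extenders = _target_extenders(target)
    has_mxm = detect_capabilities(cluster).has_methoxymalonate_subcluster
    for call in result.calls:
        if call.kind != "AT":
            continue
        want = extenders.get(call.module_index)
        if want is None:
            continue
        if call.subtype == "relaxed_hybrid" and want in ("acetate", "propionate"):
            call.notes.append(f"hybrid motif resolved to {want} by the target decomposition")
            call.subtype = want
        elif call.subtype == "propionate" and want == "methoxymalonate" and has_mxm:
            call.motif_evidence["sequence_motif_subtype"] = "propionate"
            call.notes.append(
                "re-labelled methoxymalonate: the cluster carries the full five-gene "
                "methoxymalonate subcluster and the target marks this position as "
                "methoxymalonate; selectivity motifs for this extender typically "
                "resemble methylmalonyl-selective domains"
            )
            call.subtype = "methoxymalonate_override"


def sorted_calls(calls: Sequence[DomainCall]) -> list[DomainCall]:
    from .cluster_model import DOMAIN_ORDER

    return sorted(calls, key=lambda c: (module_sort_key(c.module_index), DOMAIN_ORDER[c.kind]))
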