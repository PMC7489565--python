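"""Assemble and compare linear polyketide intermediates.

Two routes produce a :class:`LinearChain`:

* :func:`assemble_from_calls` walks ordered module annotations and applies the
  textbook reduction ladder per extension -- no active KR leaves a beta-ketone;
  KR alone (or KR with an inactive DH) leaves a beta-hydroxyl with the KR's
  stereochemistry; KR+DH give an alpha-beta double bond; KR+DH+ER give full
  saturation (methylene).
* :func:`chain_from_target` reads a retrobiosynthetic decomposition of the
  final metabolite (starter plus per-position extender and reduction state).

:func:`compare_chains` diffs the two position-by-position -- the collinearity
check: a fully collinear assembly line explains every chemical feature of the
product in module order.

Carbon numbering follows the tetronate-proximal convention: C1 is the carboxyl
carbon of the last extension, so extension ``i`` of ``n`` contributes carbons
C(2(n-i)+1) (carbonyl) and C(2(n-i)+2) (alpha), and its beta-carbon C(2(n-i)+3)
belongs to the preceding unit.  The starter's carbons are all counted as chain
carbons, which makes the canonical 15-module chain 31 carbons long.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .domain_annotator import EXTENDERS, DomainCall, ExtenderUnit
from .errors import ParseError, ValidationError
from .ms_adducts import Formula

BETA_STATES = ("ketone", "hydroxyl", "enoyl_double_bond", "methylene")
ALPHA_SUBSTITUENTS = ("none", "methyl", "methoxy")
STEREO = ("D", "L", "none")


@dataclass
class MonomerState:
    """One monomer of a linear chain: extender plus reduction/stereo state."""

    position: str  # "LM" for the starter, "1".. for extensions
    extender: ExtenderUnit
    beta_state: Optional[str] = None  # None for the starter
    beta_stereo: str = "none"
    alpha_substituent: str = "none"
    alpha_stereo: str = "none"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.beta_state is not None and self.beta_state not in BETA_STATES:
            raise ValidationError(f"position {self.position}: bad beta_state {self.beta_state!r}")
        if self.alpha_substituent not in ALPHA_SUBSTITUENTS:
            raise ValidationError(
                f"position {self.position}: bad alpha_substituent {self.alpha_substituent!r}"
            )
        if self.beta_stereo not in STEREO or self.alpha_stereo not in STEREO:
            raise ValidationError(f"position {self.position}: bad stereo label")
        if (self.beta_stereo != "none") != (self.beta_state == "hydroxyl"):
            raise ValidationError(
                f"position {self.position}: beta_stereo must be set exactly when "
                f"beta_state is hydroxyl (got {self.beta_state}/{self.beta_stereo})"
            )
        if self.alpha_stereo != "none" and self.alpha_substituent != "methyl":
            raise ValidationError(
                f"position {self.position}: alpha_stereo requires an alpha-methyl"
            )


def _starter_backbone_carbons(starter: MonomerState) -> int:
    # a starter's alpha-methyl is part of the main chain (propionate -> 3)
    extra = 1 if starter.extender.side_group == "methyl" else 0
    return starter.extender.backbone_carbons + extra


@dataclass
class LinearChain:
    """An ordered linear polyketide intermediate (free-acid bookkeeping)."""

    starter: MonomerState
    extensions: list[MonomerState] = field(default_factory=list)
    provenance: str = "from_modules"  # from_modules (assembly) | from_target (retro)

    def __post_init__(self) -> None:
        if self.starter.beta_state is not None:
            raise ValidationError("the starter unit has no beta state")
        for i, ext in enumerate(self.extensions, start=1):
            if ext.beta_state is None:
                raise ValidationError(f"extension {ext.position} lacks a beta state")

    @property
    def backbone_carbons(self) -> int:
        return _starter_backbone_carbons(self.starter) + 2 * len(self.extensions)

    @property
    def total_carbons(self) -> int:
        n = _starter_backbone_carbons(self.starter)
        if self.starter.extender.side_group == "methoxy":
            n += 1
        for ext in self.extensions:
            n += ext.extender.total_carbons
        return n

    def carbon_numbering(self) -> dict[str, int]:
        """Backbone position -> carbon number, C1 at the carboxy/tetronate end."""
        n = len(self.extensions)
        numbering: dict[str, int] = {}
        for i, ext in enumerate(self.extensions, start=1):
            numbering[f"carbonyl_{ext.position}"] = 2 * (n - i) + 1
            numbering[f"alpha_{ext.position}"] = 2 * (n - i) + 2
            numbering[f"beta_{ext.position}"] = 2 * (n - i) + 3
        base = 2 * n
        for j in range(_starter_backbone_carbons(self.starter)):
            numbering[f"starter_{j}"] = base + 1 + j
        values = sorted(v for k, v in numbering.items() if not k.startswith("beta_"))
        if values != list(range(1, len(values) + 1)):  # pragma: no cover - invariant
            raise ValidationError("carbon numbering is not contiguous")
        return numbering

    # -- JSON ------------------------------------------------------------
    def to_dict(self) -> dict:
        def monomer(m: MonomerState) -> dict:
            return {
                "position": m.position,
                "extender": m.extender.name,
                "beta_state": m.beta_state,
                "beta_stereo": m.beta_stereo,
                "alpha_substituent": m.alpha_substituent,
                "alpha_stereo": m.alpha_stereo,
                "notes": m.notes,
            }

        return {
            "provenance": self.provenance,
            "starter": monomer(self.starter),
            "extensions": [monomer(m) for m in self.extensions],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LinearChain":
        def monomer(d: dict, is_starter: bool) -> MonomerState:
            name = d["extender"]
            if name not in EXTENDERS:
                raise ValidationError(f"unknown extender {name!r}")
            return MonomerState(
                position=str(d.get("position", "LM" if is_starter else "?")),
                extender=EXTENDERS[name],
                beta_state=None if is_starter else d["beta_state"],
                beta_stereo=d.get("beta_stereo", "none"),
                alpha_substituent=d.get(
                    "alpha_substituent",
                    EXTENDERS[name].side_group if not is_starter else "none",
                ),
                alpha_stereo=d.get("alpha_stereo", "none"),
                notes=list(d.get("notes", [])),
            )

        try:
            return cls(
                starter=monomer(data["starter"], True),
                extensions=[monomer(d, False) for d in data["extensions"]],
                provenance=data.get("provenance", "from_target"),
            )
        except KeyError as exc:
            raise ParseError(f"malformed chain/decomposition: missing {exc}") from exc

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearChain":
        return cls.from_dict(json.loads(Path(path).read_text()))


def assemble_from_calls(
    calls: Sequence[DomainCall], module_order: Sequence[str]
) -> LinearChain:
    """Build the predicted linear chain from domain calls in module order.

    ``module_order`` must start with the loading module; every module needs a
    KS and an AT call.  An unknown AT subtype is a hard error (the chain's
    formula would be undefined); a KS^Q outside the first position only warns
    via a note, mirroring how such oddities are reported rather than fatal.
    """
    if not module_order:
        raise ValidationError("empty module order")
    by_module: dict[str, dict[str, DomainCall]] = {}
    for c in calls:
        by_module.setdefault(c.module_index, {})[c.kind] = c

    def module_calls(idx: str) -> dict[str, DomainCall]:
        if idx not in by_module:
            raise ValidationError(f"no calls for module {idx!r}")
        m = by_module[idx]
        if "KS" not in m or "AT" not in m:
            raise ValidationError(f"module {idx!r} lacks a KS or AT call")
        return m

    # starter
    lm_idx = module_order[0]
    lm = module_calls(lm_idx)
    starter_notes: list[str] = []
    at_subtype = lm["AT"].subtype
    if at_subtype == "relaxed_hybrid":
        at_subtype = "propionate"
        starter_notes.append(
            "relaxed-hybrid loading AT mapped to propionate (no desmethyl congener "
            "is known); pass a target decomposition to resolve it explicitly"
        )
    if at_subtype == "methoxymalonate_override":
        at_subtype = "methoxymalonate"
    if at_subtype not in EXTENDERS:
        raise ValidationError(f"loading module AT subtype {lm['AT'].subtype!r} unusable")
    starter = MonomerState(position=lm_idx, extender=EXTENDERS[at_subtype], notes=starter_notes)

    extensions: list[MonomerState] = []
    for pos_i, idx in enumerate(module_order[1:], start=1):
        m = module_calls(idx)
        notes: list[str] = []
        if m["KS"].subtype == "KSQ":
            notes.append("KSQ domain outside the loading position")
        sub = m["AT"].subtype
        if sub == "relaxed_hybrid":
            raise ValidationError(
                f"module {idx}: unresolved relaxed-hybrid AT in an extension module; "
                "resolve against a target decomposition first"
            )
        if sub == "methoxymalonate_override":
            sub = "methoxymalonate"
        if sub not in EXTENDERS:
            raise ValidationError(f"module {idx}: AT subtype {m['AT'].subtype!r} unusable")
        extender = EXTENDERS[sub]

        kr = m.get("KR")
        dh = m.get("DH")
        er = m.get("ER")
        kr_active = kr is not None and kr.active
        dh_active = dh is not None and dh.active
        er_present = er is not None

        beta_stereo = "none"
        if not kr_active:
            beta_state = "ketone"
            if kr is not None:
                notes.append("inactive KR leaves a beta-ketone")
            if dh_active:
                notes.append(
                    "DH present but without a beta-hydroxyl substrate; an enoyl "
                    "state is also conceivable should the ketone be reduced in "
                    "trans (trans-acting KR candidate in an adjacent module)"
                )
        elif not dh_active:
            beta_state = "hydroxyl"
            beta_stereo = kr.stereo_outcome if kr.stereo_outcome != "none" else "D"
            if dh is not None:
                notes.append("DH inactive: beta-hydroxyl retained")
        elif not er_present:
            beta_state = "enoyl_double_bond"
        else:
            beta_state = "methylene"

        alpha_sub = extender.side_group
        alpha_stereo = "none"
        if alpha_sub == "methyl" and beta_state in ("hydroxyl", "ketone", "methylene"):
            if er_present and beta_state == "methylene":
                alpha_stereo = er.stereo_outcome
            elif kr_active and kr.subtype == "B1" and beta_state == "hydroxyl":
                alpha_stereo = "D"
        extensions.append(
            MonomerState(
                position=idx,
                extender=extender,
                beta_state=beta_state,
                beta_stereo=beta_stereo,
                alpha_substituent=alpha_sub,
                alpha_stereo=alpha_stereo,
                notes=notes,
            )
        )
    return LinearChain(starter=starter, extensions=extensions, provenance="from_modules")


def chain_from_target(decomposition: dict | str | Path) -> LinearChain:
    """Parse a retrobiosynthetic decomposition (dict, JSON text or path)."""
    if isinstance(decomposition, (str, Path)):
        p = Path(decomposition)
        try:
            text = p.read_text() if p.exists() else str(decomposition)
            decomposition = json.loads(text)
        except (OSError, json.JSONDecodeError) as exc:
            raise ParseError(f"cannot read decomposition: {exc}") from exc
    chain = LinearChain.from_dict(decomposition)
    chain.provenance = "from_target"
    return chain


_DIFF_FIELDS = ("extender", "beta_state", "beta_stereo", "alpha_substituent", "alpha_stereo")


@dataclass
class Discrepancy:
    position: str
    field: str
    value_a: str
    value_b: str
    note: str = ""


@dataclass
class ChainDiff:
    discrepancies: list[Discrepancy] = field(default_factory=list)
    verdict: str = "collinear"  # collinear | near_collinear | incompatible

    @property
    def count(self) -> int:
        return len(self.discrepancies)

    def positions(self) -> list[str]:
        seen = []
        for d in self.discrepancies:
            if d.position not in seen:
                seen.append(d.position)
        return seen


def compare_chains(a: LinearChain, b: LinearChain) -> ChainDiff:
    """Field-wise positional diff of two chains of equal length.

    Chains of different length are ``incompatible``.  Where the assembly-line
    chain shows a ketone (or enoyl) against a hydroxyl in the retro chain, the
    note flags the trans-acting KR possibility rather than choosing a state.
    """
    if len(a.extensions) != len(b.extensions):
        return ChainDiff(verdict="incompatible")
    diff = ChainDiff()

    def values(m: MonomerState) -> dict[str, str]:
        return {
            "extender": m.extender.name,
            "beta_state": m.beta_state or "",
            "beta_stereo": m.beta_stereo,
            "alpha_substituent": m.alpha_substituent,
            "alpha_stereo": m.alpha_stereo,
        }

    pairs = [(a.starter, b.starter)] + list(zip(a.extensions, b.extensions))
    for ma, mb in pairs:
        va, vb = values(ma), values(mb)
        for f in _DIFF_FIELDS:
            if ma.beta_state is None and f in ("beta_state", "beta_stereo"):
                continue
            if va[f] != vb[f]:
                note = ""
                if f == "beta_state" and {va[f], vb[f]} & {"ketone", "enoyl_double_bond"} and "hydroxyl" in (va[f], vb[f]):
                    note = (
                        "assembly predicts a ketone (or, via the module's DH, an "
                        "enoyl) where the product shows a hydroxyl: trans-acting KR "
                        "candidate in an adjacent module"
                    )
                diff.discrepancies.append(
                    Discrepancy(position=ma.position, field=f, value_a=va[f], value_b=vb[f], note=note)
                )
    diff.verdict = "collinear" if not diff.discrepancies else "near_collinear"
    return diff


# ---------------------------------------------------------------------------
# Formula and SMILES
# ---------------------------------------------------------------------------

_BETA_DELTA = {
    "methylene": (0, 0),  # (O, H) relative to the saturated baseline
    "hydroxyl": (1, 0),
    "enoyl_double_bond": (0, -2),
    "ketone": (1, -2),
}


def chain_formula(chain: LinearChain) -> Formula:
    """Molecular formula of the free-acid chain, computed monomer-wise.

    Baseline is the fully saturated fatty acid C_B H_2B O2 for B backbone
    carbons; each side methyl adds CH2, each methoxy adds CH2O, and each
    beta-state applies its oxygen/hydrogen delta relative to methylene.
    """
    b = chain.backbone_carbons
    c, h, o = b, 2 * b, 2
    members = [chain.starter] + chain.extensions
    for m in members:
        side = m.alpha_substituent if m is not chain.starter else (
            "methoxy" if m.extender.side_group == "methoxy" else "none"
        )
        if side == "methyl":
            c += 1
            h += 2
        elif side == "methoxy":
            c += 1
            h += 2
            o += 1
    for m in chain.extensions:
        do, dh = _BETA_DELTA[m.beta_state]
        o += do
        h += dh
    return Formula({"C": c, "H": h, "O": o})


def chain_to_smiles(chain: LinearChain) -> str:
    """Canonical SMILES of the free acid, without stereo descriptors.

    D/L labels live on the chain itself (export them as an annotation sidecar
    if needed); converting them to R/S would require full substituent
    priorities, which the positional model deliberately avoids.
    """
    from rdkit import Chem

    tokens: list[str] = []
    # starter tail: all backbone carbons except the carbonyl (which is the
    # first extension's beta-carbon)
    tail = _starter_backbone_carbons(chain.starter) - 1
    tokens.extend("C" * tail)
    for m in chain.extensions:
        if m.beta_state == "ketone":
            tokens.append("C(=O)")
        elif m.beta_state == "hydroxyl":
            tokens.append("C(O)")
        elif m.beta_state == "enoyl_double_bond":
            tokens.append("C=")
        else:
            tokens.append("C")
        if m.alpha_substituent == "methyl":
            tokens.append("C(C)")
        elif m.alpha_substituent == "methoxy":
            tokens.append("C(OC)")
        else:
            tokens.append("C")
    tokens.append("C(=O)O")
    smiles = "".join(tokens)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:  # pragma: no cover - construction is by pattern
        raise ValidationError(f"internal SMILES construction failed: {smiles}")
    return Chem.MolToSmiles(mol)


def smiles_formula(smiles: str) -> Formula:
    """Element counts of a SMILES string (hydrogens included)."""
    from rdkit import Chem
    from rdkit.Chem.rdMolDescriptors import CalcMolFormula

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"bad SMILES {smiles!r}")
    return Formula.parse(CalcMolFormula(mol))
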