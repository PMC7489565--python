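"""Packaged reference scaffolds for PKS domain annotation.

Each scaffold is a synthetic consensus amino-acid sequence for one domain kind
with named *anchor columns*: the alignment columns a practitioner would read a
motif off.  The anchor set mirrors how activity and selectivity are diagnosed
in modular PKSs:

* KS  -- the C-H-H catalytic triad; a glutamine in place of the catalytic
  cysteine marks a decarboxylating loading-module KS (KS^Q).
* AT  -- the 4-residue substrate-selectivity window ((H/T/V/Y)AFH acetate,
  (Y/V/W)ASH propionate, HASH relaxed hybrid).
* DH  -- the YGP tyrosine and the catalytic aspartate of the HPALLDAAL context.
* KR  -- the NADPH-binding (Rossmann) window containing the (L/V/I)DD motif,
  the catalytic tyrosine, and the tyrosine+2 column whose proline marks a
  B2-type domain.
* ER  -- the key tyrosine whose presence predicts an L-configured alpha-methyl.

The scaffolds are built once from a frozen seed (background residues are
arbitrary; only the anchor columns carry meaning) and are versioned so that
annotation output can record which anchor convention produced it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .cluster_model import AA20
from .errors import ValidationError

SCAFFOLD_VERSION = "1.0"

_BUILD_SEED = 77_2020


@dataclass(frozen=True)
class ReferenceScaffold:
    """A domain-kind reference sequence with named anchor columns.

    ``anchors`` maps an anchor name to a tuple of 0-based columns of
    ``sequence``.  Single-residue anchors are 1-tuples; windows (the AT motif,
    the KR NADPH site) list every column they cover.
    """

    domain_kind: str
    sequence: str
    anchors: dict[str, tuple[int, ...]] = field(default_factory=dict)
    version: str = SCAFFOLD_VERSION

    def __post_init__(self) -> None:
        for name, cols in self.anchors.items():
            for c in cols:
                if not 0 <= c < len(self.sequence):
                    raise ValidationError(
                        f"{self.domain_kind} scaffold: anchor {name!r} column {c} "
                        f"outside sequence of length {len(self.sequence)}"
                    )

    def anchor_columns(self) -> set[int]:
        cols: set[int] = set()
        for c in self.anchors.values():
            cols.update(c)
        return cols

    def residues(self, name: str) -> str:
        return "".join(self.sequence[c] for c in self.anchors[name])


def _build(kind: str, seed: int, blocks: list) -> ReferenceScaffold:
    """Assemble a scaffold from random filler and (motif, {anchor: cols}) blocks."""
    rng = random.Random(seed)
    seq: list[str] = []
    anchors: dict[str, tuple[int, ...]] = {}
    for item in blocks:
        if isinstance(item, int):
            seq.extend(rng.choice(AA20) for _ in range(item))
        else:
            motif, names = item
            base = len(seq)
            for name, offsets in names.items():
                anchors[name] = tuple(base + o for o in offsets)
            seq.extend(motif)
    return ReferenceScaffold(domain_kind=kind, sequence="".join(seq), anchors=anchors)


def _default_scaffolds() -> dict[str, ReferenceScaffold]:
    ks = _build(
        "KS",
        _BUILD_SEED + 1,
        [
            28,
            ("VDTACSSSLVA", {"catalytic_cys": (4,)}),
            30,
            ("HGTGTPLGDPIE", {"triad_his1": (0,)}),
            28,
            ("GSVKSNIGHLE", {"triad_his2": (8,)}),
            25,
        ],
    )
    at = _build(
        "AT",
        _BUILD_SEED + 2,
        [
            24,
            ("GQGAQW", {}),
            22,
            ("YASH", {"selectivity_motif": (0, 1, 2, 3)}),
            28,
            ("HSVGE", {}),
            27,
        ],
    )
    dh = _build(
        "DH",
        _BUILD_SEED + 3,
        [
            18,
            ("LYGPV", {"ygp_tyr": (1,)}),
            32,
            ("HPALLDAAL", {"catalytic_asp": (5,)}),
            38,
        ],
    )
    # NADPH window: 16 columns, the trailing three being the (L/V/I)DD motif
    nadph_cols = tuple(range(16))
    kr = _build(
        "KR",
        _BUILD_SEED + 4,
        [
            20,
            (
                "GGTGGLGAEVARWLDD",
                {"nadph_window": nadph_cols, "ldd": (13, 14, 15)},
            ),
            34,
            ("SYAAN", {"catalytic_tyr": (1,), "tyr_plus2": (3,)}),
            32,
        ],
    )
    er = _build(
        "ER",
        _BUILD_SEED + 5,
        [
            26,
            ("GDVYSLG", {"key_tyr": (3,)}),
            40,
            ("AGGLGGV", {}),
            25,
        ],
    )
    acp = _build(
        "ACP",
        _BUILD_SEED + 6,
        [
            30,
            ("GLDSL", {"ppant_ser": (3,)}),
            35,
        ],
    )
    return {s.domain_kind: s for s in (ks, at, dh, kr, er, acp)}


DEFAULT_SCAFFOLDS: dict[str, ReferenceScaffold] = _default_scaffolds()

#: columns that the synthetic-data generator must never mutate: every anchor
#: column plus a 2-residue guard band on each side, so planted ground truth
#: stays readable after neutral mutation.
GUARD_BAND = 2


def protected_columns(scaffold: ReferenceScaffold) -> set[int]:
    cols: set[int] = set()
    for c in scaffold.anchor_columns():
        for g in range(-GUARD_BAND, GUARD_BAND + 1):
            if 0 <= c + g < len(scaffold.sequence):
                cols.add(c + g)
    return cols
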