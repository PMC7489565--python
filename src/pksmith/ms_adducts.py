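"""Molecular-formula arithmetic, adduct m/z computation and delta-mass diagnosis.

The diagnosis workflow reproduces how a low-resolution positive-mode LC-MS
spectrum of a mutant metabolite is interpreted against the parent compound:
compute the standard adduct series ([M+H]+, [M+Na]+, [M+NH4]+ and the water
losses), match peaks within a unit-resolution tolerance, estimate the modal
mass shift between the two spectra, and map the rounded shift to a small loss
table (16 Da = a missing hydroxyl, 18 = dehydration, 14 = a missing methylene).

Average masses are the default: the instrument class this models reports
unit-resolution observed values that neither average nor monoisotopic masses
reproduce exactly, so all comparisons to observed ions are tolerance-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import ParseError, ValidationError

# element -> (average, monoisotopic, nominal) mass in Da
_MASSES: dict[str, tuple[float, float, int]] = {
    "C": (12.011, 12.0, 12),
    "H": (1.008, 1.0078250319, 1),
    "N": (14.007, 14.0030740052, 14),
    "O": (15.999, 15.9949146221, 16),
    "Na": (22.98977, 22.98976928, 23),
    "S": (32.06, 31.97207069, 32),
    "P": (30.97376, 30.97376151, 31),
    "Cl": (35.45, 34.96885271, 35),
}

_MODES = {"average": 0, "monoisotopic": 1, "nominal": 2}

ELECTRON_MASS = 0.000548579909  # Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(dict):
    """An element->count map with Hill-notation parsing and exact arithmetic."""

    def __init__(self, counts: Optional[dict[str, int]] = None):
        super().__init__()
        for el, n in (counts or {}).items():
            if n < 0:
                raise ValidationError(f"negative count for element {el}")
            if n:
                self[el] = int(n)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ParseError(f"cannot parse formula {text!r} at position {pos}")
            if not m.group(0):
                break
            el = m.group(1)
            counts[el] = counts.get(el, 0) + (int(m.group(2)) if m.group(2) else 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise ParseError(f"cannot parse formula {text!r}")
        return cls(counts)

    def hill(self) -> str:
        """Hill notation: C, then H, then the rest alphabetically."""
        parts = []
        for el in ["C", "H"] + sorted(k for k in self if k not in ("C", "H")):
            n = self.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def shifted(self, delta: dict[str, int]) -> "Formula":
        """Apply a signed element delta; negative results are an error."""
        counts = dict(self)
        for el, n in delta.items():
            counts[el] = counts.get(el, 0) + n
            if counts[el] < 0:
                raise ValidationError(
                    f"delta {delta} drives element {el} negative on {self.hill()}"
                )
        return Formula(counts)

    def __add__(self, other: "Formula") -> "Formula":
        return self.shifted(dict(other))

    def __sub__(self, other: "Formula") -> "Formula":
        return self.shifted({el: -n for el, n in other.items()})


def formula_mass(f: Formula | dict, mode: str = "average") -> float:
    """Sum of element masses; ``nominal`` uses integer isotope masses."""
    if mode not in _MODES:
        raise ValidationError(f"unknown mass mode {mode!r}; use average/monoisotopic/nominal")
    idx = _MODES[mode]
    total = 0.0
    for el, n in f.items():
        if el not in _MASSES:
            raise ValidationError(f"unknown element {el!r} in formula")
        total += _MASSES[el][idx] * n
    return total


@dataclass(frozen=True)
class AdductSpec:
    """A named positive-mode adduct: formula delta plus charge."""

    name: str
    delta: tuple[tuple[str, int], ...]
    charge: int = 1

    def mz(self, f: Formula, mode: str = "average") -> float:
        return adduct_mz(f, self, mode)


PACKAGED_ADDUCTS: tuple[AdductSpec, ...] = (
    AdductSpec("[M+H]+", (("H", 1),)),
    AdductSpec("[M+Na]+", (("Na", 1),)),
    AdductSpec("[M+NH4]+", (("N", 1), ("H", 4))),
    AdductSpec("[M+H-H2O]+", (("H", -1), ("O", -1))),
    AdductSpec("[M+H-2H2O]+", (("H", -3), ("O", -2))),
)

ADDUCTS_BY_NAME = {a.name: a for a in PACKAGED_ADDUCTS}


def adduct_mz(f: Formula | dict, adduct: AdductSpec, mode: str = "average") -> float:
    """(mass(M + delta) - z*m_e) / z; the electron term is kept for correctness."""
    ion = Formula(dict(f)).shifted(dict(adduct.delta))
    return (formula_mass(ion, mode) - ELECTRON_MASS * adduct.charge) / adduct.charge


@dataclass
class Peak:
    mz: float
    intensity: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError("peak intensity must be non-negative")


@dataclass
class PeakList:
    """Observed peaks, sorted ascending in m/z on construction."""

    peaks: list[Peak] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.peaks.sort(key=lambda p: p.mz)

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "") -> "PeakList":
        import pandas as pd

        try:
            df = pd.read_csv(path, comment="#")
        except Exception as exc:
            raise ParseError(f"{path}: cannot read peak CSV: {exc}") from exc
        if "mz" not in df.columns:
            raise ParseError(f"{path}: peak CSV needs an 'mz' column")
        peaks = [
            Peak(
                mz=float(row["mz"]),
                intensity=float(row.get("intensity", 1.0)) if "intensity" in df.columns else 1.0,
                label=str(row["label"]) if "label" in df.columns and not pd.isna(row["label"]) else "",
            )
            for _, row in df.iterrows()
        ]
        return cls(peaks=peaks, source=source or str(path))

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [{"mz": p.mz, "intensity": p.intensity, "label": p.label} for p in self.peaks]
        ).to_csv(path, index=False)


@dataclass
class PeakMatch:
    adduct: str
    peak_mz: float
    computed_mz: float
    delta_da: float


@dataclass
class MatchResult:
    matches: list[PeakMatch] = field(default_factory=list)
    unmatched_adducts: list[str] = field(default_factory=list)

    def match(self, adduct_name: str) -> Optional[PeakMatch]:
        for m in self.matches:
            if m.adduct == adduct_name:
                return m
        return None


def match_peaks(
    peaks: PeakList,
    f: Formula | dict,
    tolerance: float = 0.5,
    mode: str = "average",
    adducts: Sequence[AdductSpec] = PACKAGED_ADDUCTS,
) -> MatchResult:
    """Greedily assign each adduct's computed m/z to the nearest unused peak.

    Candidate (adduct, peak) pairs within ``tolerance`` are taken best-first,
    so every peak is used at most once; adducts left over are reported.
    """
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    usable = []
    computed = {}
    for a in adducts:
        try:
            computed[a.name] = adduct_mz(f, a, mode)
        except ValidationError:
            continue  # e.g. a double water loss from an anhydrous formula
    candidates = [
        (abs(p.mz - cmz), a_name, i)
        for a_name, cmz in computed.items()
        for i, p in enumerate(peaks.peaks)
        if abs(p.mz - cmz) <= tolerance
    ]
    candidates.sort()
    used_peaks: set[int] = set()
    used_adducts: set[str] = set()
    result = MatchResult()
    for dist, a_name, i in candidates:
        if a_name in used_adducts or i in used_peaks:
            continue
        used_adducts.add(a_name)
        used_peaks.add(i)
        p = peaks.peaks[i]
        result.matches.append(
            PeakMatch(adduct=a_name, peak_mz=p.mz, computed_mz=computed[a_name], delta_da=p.mz - computed[a_name])
        )
    result.unmatched_adducts = [a.name for a in adducts if a.name not in used_adducts]
    result.matches.sort(key=lambda m: m.computed_mz)
    return result


#: rounded nominal shift -> (interpretation, formula delta applied to the reference)
LOSS_TABLE: dict[int, tuple[str, dict[str, int]]] = {
    0: ("same formula", {}),
    -16: ("absent hydroxyl (-O)", {"O": -1}),
    -18: ("dehydration (-H2O)", {"H": -2, "O": -1}),
    -14: ("demethylation (-CH2)", {"C": -1, "H": -2}),
    16: ("additional hydroxyl (+O)", {"O": 1}),
}


@dataclass
class Diagnosis:
    status: str  # diagnosed | same_formula | undiagnosed
    shift_nominal: Optional[int] = None
    interpretation: str = ""
    proposed_formula: Optional[Formula] = None
    confirmation: Optional[MatchResult] = None
    votes: dict = field(default_factory=dict)


def diagnose_delta(
    ref_formula: Formula | dict,
    peaks_ref: PeakList,
    peaks_unknown: PeakList,
    tolerance: float = 0.5,
    mode: str = "average",
    adducts: Sequence[AdductSpec] = PACKAGED_ADDUCTS,
) -> Diagnosis:
    """Estimate the modal mass shift of an unknown spectrum against a reference.

    For every adduct assigned in the reference spectrum, differences to every
    unknown peak are collected; the modal rounded shift (at least two adducts
    agreeing, ties toward the smaller magnitude) is mapped through the loss
    table, a formula is proposed, and the proposal is confirmed by re-matching
    the unknown peaks.  An inconsistent spectrum yields ``undiagnosed`` rather
    than an exception.
    """
    if not len(peaks_ref) or not len(peaks_unknown):
        raise ValidationError("both peak lists must be non-empty")
    ref_formula = Formula(dict(ref_formula))
    ref_match = match_peaks(peaks_ref, ref_formula, tolerance, mode, adducts)
    votes: dict[int, int] = {}
    for m in ref_match.matches:
        seen_for_adduct: set[int] = set()
        for q in peaks_unknown:
            shift = round(q.mz - m.peak_mz)
            if shift not in seen_for_adduct:
                seen_for_adduct.add(shift)
                votes[shift] = votes.get(shift, 0) + 1
    if not votes:
        return Diagnosis(status="undiagnosed", votes=votes)
    best = sorted(votes.items(), key=lambda kv: (-kv[1], abs(kv[0])))[0]
    shift, support = best
    if support < min(2, len(ref_match.matches)):
        return Diagnosis(status="undiagnosed", votes=votes)
    if shift == 0:
        return Diagnosis(
            status="same_formula",
            shift_nominal=0,
            interpretation=LOSS_TABLE[0][0],
            proposed_formula=ref_formula,
            confirmation=match_peaks(peaks_unknown, ref_formula, tolerance, mode, adducts),
            votes=votes,
        )
    if shift not in LOSS_TABLE:
        return Diagnosis(status="undiagnosed", shift_nominal=shift, votes=votes)
    interpretation, delta = LOSS_TABLE[shift]
    try:
        proposal = ref_formula.shifted(delta)
    except ValidationError:
        return Diagnosis(status="undiagnosed", shift_nominal=shift, votes=votes)
    confirmation = match_peaks(peaks_unknown, proposal, tolerance, mode, adducts)
    if not confirmation.matches:
        return Diagnosis(status="undiagnosed", shift_nominal=shift, votes=votes)
    return Diagnosis(
        status="diagnosed",
        shift_nominal=shift,
        interpretation=interpretation,
        proposed_formula=proposal,
        confirmation=confirmation,
        votes=votes,
    )
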