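"""In-frame deletion validation, screening-amplicon prediction and
start-codon revision.

The arithmetic here is what a genetics bench scientist does on paper when
designing a markerless knockout: check the deleted segment is a multiple of
three (so the downstream frame survives), predict the mutant screening-PCR
product as the wild-type product minus the deletion, locate primer pairs on a
template, and scan upstream of an annotated start codon for an alternative
in-frame ATG with no intervening stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .errors import AmbiguousAmpliconError, NoAmpliconError, ValidationError

_DNA = frozenset("ACGT")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValidationError(f"{what}: non-ACGT characters {sorted(bad)}")
    return seq


@dataclass
class DeletionDesign:
    """One gene's in-frame deletion design."""

    gene_id: str
    gene_cds_length_nt: int
    deleted_length_nt: int
    wt_amplicon_nt: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gene_cds_length_nt <= 0 or self.deleted_length_nt <= 0:
            raise ValidationError(f"{self.gene_id}: lengths must be positive")
        if self.deleted_length_nt > self.gene_cds_length_nt:
            raise ValidationError(
                f"{self.gene_id}: deletion ({self.deleted_length_nt} nt) exceeds the "
                f"coding frame ({self.gene_cds_length_nt} nt)"
            )


@dataclass
class InFrameReport:
    gene_id: str
    in_frame: bool
    remaining_nt: int
    deleted_fraction: float
    message: str = ""


def validate_inframe(design: DeletionDesign) -> InFrameReport:
    """A deletion is in frame iff its length is a multiple of 3."""
    in_frame = design.deleted_length_nt % 3 == 0
    remaining = design.gene_cds_length_nt - design.deleted_length_nt
    message = (
        f"{design.gene_id}: {design.deleted_length_nt}/{design.gene_cds_length_nt} nt deleted, "
        f"{remaining} nt remain"
    )
    if not in_frame:
        message += (
            f"; WARNING out of frame (deletion mod 3 = {design.deleted_length_nt % 3}), "
            "downstream frame is shifted"
        )
    return InFrameReport(
        gene_id=design.gene_id,
        in_frame=in_frame,
        remaining_nt=remaining,
        deleted_fraction=design.deleted_length_nt / design.gene_cds_length_nt,
        message=message,
    )


def predict_mutant_amplicon(wt_amplicon_nt: int, deleted_length_nt: int) -> int:
    """Mutant screening-PCR product size: wild type minus the deletion."""
    if wt_amplicon_nt <= 0 or deleted_length_nt <= 0:
        raise ValidationError("amplicon and deletion lengths must be positive")
    if deleted_length_nt >= wt_amplicon_nt:
        raise ValidationError(
            f"deletion ({deleted_length_nt} nt) must be smaller than the wild-type "
            f"amplicon ({wt_amplicon_nt} nt): the primers must flank the deletion"
        )
    return wt_amplicon_nt - deleted_length_nt


@dataclass
class AmpliconHit:
    """A located PCR product, inclusive of both primer footprints."""

    start: int  # 0-based start of the forward primer
    end: int  # exclusive end of the reverse-primer footprint
    length: int


def locate_amplicon(template: str, fwd: str, rev: str) -> AmpliconHit:
    """Exact-match the primer pair on the plus strand of a template.

    The forward primer is searched as given; the reverse primer as its
    reverse complement, downstream of the forward site.  Exactly one
    candidate amplicon must exist; zero raises :class:`NoAmpliconError` and
    several raise :class:`AmbiguousAmpliconError`.  Matching is exact by
    design -- screening-primer arithmetic is exact, and mismatch tolerance is
    a primer-design problem, not a bookkeeping one.
    """
    template = _check_dna(template, "template")
    fwd = _check_dna(fwd, "forward primer")
    rev = _check_dna(rev, "reverse primer")
    if len(fwd) < 15 or len(rev) < 15:
        raise ValidationError("primers must be at least 15 nt")
    if len(template) < max(len(fwd), len(rev)):
        raise ValidationError("template shorter than a primer")
    rev_rc = str(Seq(rev).reverse_complement())

    def all_hits(needle: str) -> list[int]:
        hits, i = [], template.find(needle)
        while i != -1:
            hits.append(i)
            i = template.find(needle, i + 1)
        return hits

    fwd_hits = all_hits(fwd)
    rev_hits = all_hits(rev_rc)
    candidates = [
        (f, r + len(rev_rc))
        for f in fwd_hits
        for r in rev_hits
        if r >= f + len(fwd)
    ]
    if not candidates:
        raise NoAmpliconError("no amplicon: primer pair does not bracket a product")
    if len(candidates) > 1:
        raise AmbiguousAmpliconError(
            f"ambiguous: {len(candidates)} candidate amplicons from "
            f"{len(fwd_hits)} forward and {len(rev_hits)} reverse site(s)"
        )
    start, end = candidates[0]
    return AmpliconHit(start=start, end=end, length=end - start)


@dataclass
class StartCandidate:
    codons_upstream: int
    offset_nt: int  # 0-based offset of the candidate ATG in the context
    added_peptide: str


@dataclass
class StartRevision:
    annotated_start: int
    candidates: list[StartCandidate] = field(default_factory=list)


def revise_start(nt_context: str, annotated_start: int) -> StartRevision:
    """Scan upstream, in frame, for alternative ATG start codons.

    Candidates are reported with the peptide the revision would prepend to
    the annotated protein; the scan stops at the first in-frame stop codon,
    so no candidate's added peptide ever contains a stop.
    """
    nt_context = _check_dna(nt_context, "context")
    if not 0 <= annotated_start <= len(nt_context) - 3:
        raise ValidationError("annotated_start outside the context sequence")
    revision = StartRevision(annotated_start=annotated_start)
    k = 1
    while True:
        pos = annotated_start - 3 * k
        if pos < 0:
            break
        codon = nt_context[pos : pos + 3]
        if codon in STOP_CODONS:
            break
        if codon == "ATG":
            peptide = str(Seq(nt_context[pos:annotated_start]).translate())
            revision.candidates.append(
                StartCandidate(codons_upstream=k, offset_nt=pos, added_peptide=peptide)
            )
        k += 1
    return revision
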