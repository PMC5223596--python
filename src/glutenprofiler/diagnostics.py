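"""Diagnostic peptides discriminating near-identical isoforms.

HMW glutenin alleles such as Dx2 and Dx5 differ by single substitutions
and repeat-count changes over >800 mostly identical residues, so
protein-level discrimination rests on the few digest peptides unique to
each isoform.  Given a family of isoform sequences, this module digests
every member, set-differences the peptide sequence sets, classifies the
underlying variant (substitution vs insertion/deletion), and checks a
list of theoretical diagnostics against observed evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .digestion import CleavageRule, PeptideSpan, digest, get_rule
from .seqdb import ProteinRecord


class VariantClass(str, Enum):
    substitution = "substitution"
    insertion_or_deletion = "insertion_or_deletion"
    repeat_variation = "repeat_variation"
    unclassified = "unclassified"


@dataclass(frozen=True)
class IsoformFamily:
    """Two or more homologous isoforms compared for unique peptides."""

    label: str
    members: tuple[ProteinRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        accs = [m.accession for m in self.members]
        if len(set(accs)) != len(accs):
            raise ValueError("family members must have distinct accessions")

    def __len__(self) -> int:
        return len(self.members)

    def member(self, accession: str) -> ProteinRecord:
        for m in self.members:
            if m.accession == accession:
                return m
        raise KeyError(accession)


@dataclass(frozen=True)
class DiagnosticPeptide:
    """A digest peptide present in exactly one family member."""

    sequence: str
    owner: str
    absent_from: frozenset
    owner_start: int
    owner_end: int
    missed_cleavages: int
    variant_class: VariantClass = VariantClass.unclassified


def _digest_keys(
    record: ProteinRecord,
    rule: CleavageRule,
    max_missed: int,
    collapse_il: bool,
) -> dict[str, PeptideSpan]:
    """Map comparison key -> first span with that key."""
    out: dict[str, PeptideSpan] = {}
    for span in digest(record.sequence, rule, max_missed, parent=record.accession):
        key = span.sequence.replace("I", "L") if collapse_il else span.sequence
        out.setdefault(key, span)
    return out


def unique_peptides(
    family: IsoformFamily,
    rule: CleavageRule | str,
    max_missed: int = 0,
    collapse_il: bool = False,
) -> dict[str, list[DiagnosticPeptide]]:
    """Per-member diagnostic peptides within *family*.

    A peptide is diagnostic for a member iff its sequence occurs in
    that member's digest and in no other member's digest.  Comparison
    is on exact sequence strings; ``collapse_il`` treats I and L as
    indistinguishable (as they are by mass spectrometry) — off by
    default because search engines report sequences as written.
    """
    if len(family) < 2:
        raise ValueError("uniqueness is undefined for a single-member family")
    rule = get_rule(rule)
    digests = {
        m.accession: _digest_keys(m, rule, max_missed, collapse_il)
        for m in family.members
    }
    result: dict[str, list[DiagnosticPeptide]] = {}
    for m in family.members:
        others = frozenset(a for a in digests if a != m.accession)
        other_keys: set[str] = set()
        for a in others:
            other_keys.update(digests[a])
        diags = []
        for key, span in digests[m.accession].items():
            if key not in other_keys:
                diags.append(
                    DiagnosticPeptide(
                        sequence=span.sequence,
                        owner=m.accession,
                        absent_from=others,
                        owner_start=span.start,
                        owner_end=span.end,
                        missed_cleavages=span.missed_cleavages,
                    )
                )
        diags.sort(key=lambda d: (d.owner_start, d.owner_end))
        result[m.accession] = diags
    return result


_local_aligner = PairwiseAligner()
_local_aligner.mode = "local"
_local_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_local_aligner.open_gap_score = -10.0
_local_aligner.extend_gap_score = -0.5


def classify_variant(
    peptide: DiagnosticPeptide, family: IsoformFamily
) -> VariantClass:
    """Classify the sequence variant that makes *peptide* diagnostic.

    The peptide is aligned locally against every non-owner member; the
    best-scoring counterpart decides the class:

    * equal-length gapless counterpart with >= 1 mismatch  -> substitution
    * gapped alignment (or counterpart of different length) -> insertion_or_deletion
    * identical counterpart (uniqueness arose only from cleavage-
      boundary or missed-cleavage context)                  -> unclassified
    """
    best_score = None
    best_class = VariantClass.unclassified
    for member in family.members:
        if member.accession == peptide.owner:
            continue
        if peptide.sequence in member.sequence:
            # locally identical: diagnostic only through boundary context
            cls, score = VariantClass.unclassified, float("inf")
        else:
            alns = _local_aligner.align(peptide.sequence, member.sequence)
            try:
                aln = alns[0]
            except IndexError:
                continue
            score = aln.score
            blocks_q, _blocks_t = aln.aligned
            q_covered = sum(e - s for s, e in blocks_q)
            gapped = len(blocks_q) > 1 or q_covered < len(peptide.sequence)
            cls = (
                VariantClass.insertion_or_deletion
                if gapped
                else VariantClass.substitution
            )
        if best_score is None or score > best_score:
            best_score = score
            best_class = cls
    return best_class


def classify_all(
    diagnostics: Mapping[str, Sequence[DiagnosticPeptide]],
    family: IsoformFamily,
) -> dict[str, list[DiagnosticPeptide]]:
    """Return diagnostics with ``variant_class`` filled in."""
    out: dict[str, list[DiagnosticPeptide]] = {}
    for owner, peps in diagnostics.items():
        out[owner] = [
            DiagnosticPeptide(
                sequence=p.sequence,
                owner=p.owner,
                absent_from=p.absent_from,
                owner_start=p.owner_start,
                owner_end=p.owner_end,
                missed_cleavages=p.missed_cleavages,
                variant_class=classify_variant(p, family),
            )
            for p in peps
        ]
    return out


def detect_diagnostics(
    diagnostics: Iterable[DiagnosticPeptide],
    evidence_rows: Iterable,
) -> dict[str, list]:
    """Which theoretical diagnostics appear in observed evidence.

    A diagnostic is observed when an evidence row's peptide sequence
    equals it exactly; modification state is ignored, so deamidated
    forms match their base sequence.  Returns diagnostic sequence ->
    supporting rows (only observed diagnostics appear).
    """
    wanted = {d.sequence for d in diagnostics}
    hits: dict[str, list] = {}
    for row in evidence_rows:
        seq = row.peptide_sequence
        if seq in wanted:
            hits.setdefault(seq, []).append(row)
    return hits
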