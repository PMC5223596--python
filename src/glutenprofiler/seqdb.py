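"""Curated prolamin sequence databases, pairwise identity and NJ trees.

Public sequence repositories hold many gluten entries that are
fragments, exact duplicates, or come from grasses other than wheat;
searching MS data against such a database inflates apparent isoform
diversity.  This module reproduces the standard curation workflow —
fragment removal, taxon whitelisting, exact-sequence deduplication —
with an explicit log of every removal, plus BLOSUM62 global-alignment
percent identity and neighbor-joining trees over the curated set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .digestion import validate_sequence


class ProteinClass(str, Enum):
    alpha_gliadin = "alpha_gliadin"
    gamma_gliadin = "gamma_gliadin"
    omega_gliadin = "omega_gliadin"
    lmw_glutenin = "lmw_glutenin"
    hmw_glutenin = "hmw_glutenin"
    other = "other"


_CLASS_PATTERNS = [
    (ProteinClass.alpha_gliadin, re.compile(r"alpha[/ -]?(beta[- ]?)?gliadin", re.I)),
    (ProteinClass.gamma_gliadin, re.compile(r"gamma[- ]?gliadin", re.I)),
    (ProteinClass.omega_gliadin, re.compile(r"omega[- ]?gliadin", re.I)),
    (ProteinClass.hmw_glutenin, re.compile(r"(HMW|high[- ]molecular[- ]weight).{0,20}glutenin|glutenin.{0,30}(HMW|high[- ]molecular)", re.I)),
    (ProteinClass.lmw_glutenin, re.compile(r"(LMW|low[- ]molecular[- ]weight).{0,20}glutenin|glutenin.{0,30}(LMW|low[- ]molecular)", re.I)),
]


def infer_protein_class(description: str) -> ProteinClass:
    """Best-effort gluten class from a free-text description."""
    for cls, pat in _CLASS_PATTERNS:
        if pat.search(description):
            return cls
    return ProteinClass.other


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: a full-length prolamin sequence."""

    accession: str
    description: str = ""
    organism: str = ""
    protein_class: ProteinClass = ProteinClass.other
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        try:
            validate_sequence(self.sequence, "sequence")
        except ValueError as exc:
            raise ValueError(f"record {self.accession}: {exc}") from None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDatabase:
    """A curated collection of :class:`ProteinRecord` with provenance.

    ``curation_log`` is an ordered list of ``(step, removals)`` where
    ``removals`` maps accession -> human-readable reason.
    """

    records: list[ProteinRecord] = field(default_factory=list)
    curation_log: list[tuple[str, dict[str, str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        for rec in self.records:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)

    @property
    def accessions(self) -> list[str]:
        return [r.accession for r in self.records]

    def removed(self) -> dict[str, str]:
        """All removals across curation steps, accession -> reason."""
        out: dict[str, str] = {}
        for _step, removals in self.curation_log:
            out.update(removals)
        return out


# ---------------------------------------------------------------------------
# FASTA I/O

_OS_RE = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")


def _parse_organism(description: str) -> str:
    m = _OS_RE.search(description)
    return m.group(1).strip() if m else ""


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    The header is ``accession description`` with the organism taken
    from a UniProt-style ``OS=`` field when present.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(
                accession=rec.id,
                description=desc,
                organism=_parse_organism(desc),
                protein_class=infer_protein_class(desc),
                sequence=str(rec.seq).upper(),
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA with
    ``accession description OS=organism`` headers."""
    out = []
    for r in records:
        desc = r.description
        if r.organism and "OS=" not in desc:
            desc = f"{desc} OS={r.organism}".strip()
        out.append(SeqRecord(Seq(r.sequence), id=r.accession, description=desc))
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# curation

@dataclass(frozen=True)
class CurationConfig:
    """Rules for database curation.

    The fragment rule fires when the header carries a "Fragment" token,
    when the sequence lacks an initiator methionine, or when it is
    shorter than ``min_length`` residues (gluten storage proteins are
    long; the default length floor is a pragmatic operationalisation of
    "fragment").  Each sub-rule can be toggled independently.
    """

    drop_fragment_header: bool = True
    require_initiator_met: bool = True
    min_length: int = 120
    taxon_whitelist: tuple[str, ...] = ("Triticum",)
    dedup: bool = True


_FRAGMENT_RE = re.compile(r"\bfragment\b", re.I)


def curate_database(
    records: Sequence[ProteinRecord],
    config: CurationConfig = CurationConfig(),
) -> SequenceDatabase:
    """Apply fragment, taxon and duplicate rules, logging every removal.

    Surviving records keep their input order; duplicates keep the first
    occurrence.  Curation is idempotent: re-curating an already curated
    database removes nothing.
    """
    if not records:
        raise ValueError("cannot curate an empty record collection")

    survivors = list(records)
    log: list[tuple[str, dict[str, str]]] = []

    def apply(step: str, drop_reason) -> None:
        nonlocal survivors
        removals: dict[str, str] = {}
        kept = []
        for rec in survivors:
            reason = drop_reason(rec)
            if reason:
                removals[rec.accession] = reason
            else:
                kept.append(rec)
        survivors = kept
        log.append((step, removals))

    def fragment_reason(rec: ProteinRecord) -> str | None:
        if config.drop_fragment_header and _FRAGMENT_RE.search(rec.description):
            return "header marked as fragment"
        if config.require_initiator_met and not rec.sequence.startswith("M"):
            return "missing initiator methionine"
        if len(rec.sequence) < config.min_length:
            return f"shorter than {config.min_length} residues"
        return None

    def taxon_reason(rec: ProteinRecord) -> str | None:
        if not config.taxon_whitelist:
            return None
        organism = rec.organism or _parse_organism(rec.description)
        if any(organism.startswith(genus) for genus in config.taxon_whitelist):
            return None
        return f"organism {organism or 'unknown'!r} not in whitelist"

    apply("fragment", fragment_reason)
    apply("taxon", taxon_reason)

    if config.dedup:
        seen: dict[str, str] = {}
        removals = {}
        kept = []
        for rec in survivors:
            if rec.sequence in seen:
                removals[rec.accession] = (
                    f"duplicate sequence of {seen[rec.sequence]}"
                )
            else:
                seen[rec.sequence] = rec.accession
                kept.append(rec)
        survivors = kept
        log.append(("duplicate", removals))

    log.append(
        ("summary", {"": f"{len(records)} in, {len(survivors)} kept"})
    )
    return SequenceDatabase(records=survivors, curation_log=log)


# ---------------------------------------------------------------------------
# pairwise identity and NJ trees

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def percent_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Fractional identity from a BLOSUM62 global alignment.

    Identity is counted over columns where both sequences place a
    residue (gap columns excluded from the denominator), the convention
    used by most aligners when reporting percent identity.
    """
    seq_a = a.sequence if isinstance(a, ProteinRecord) else a
    seq_b = b.sequence if isinstance(b, ProteinRecord) else b
    for s, lab in ((seq_a, "a"), (seq_b, "b")):
        validate_sequence(s, lab)
        if set(s) == {"X"}:
            raise ValueError(f"sequence {lab} contains only unknown residues")
    aln = _make_aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    matched = 0
    aligned_cols = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        aligned_cols += ea - sa
        matched += sum(
            seq_a[sa + k] == seq_b[sb + k] for k in range(ea - sa)
        )
    if aligned_cols == 0:
        return 0.0
    return matched / aligned_cols


@dataclass
class IdentityMatrix:
    """Square symmetric matrix of fractional identities in [0, 1]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("identity matrix diagonal must be 1")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("identities must lie in [0, 1]")

    def to_distances(self) -> np.ndarray:
        """Distance matrix 1 - identity with an exactly zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.maximum((d + d.T) / 2.0, 0.0)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="accession"
        )


def identity_matrix(records: Sequence[ProteinRecord]) -> IdentityMatrix:
    """All-vs-all percent identity over a record collection."""
    n = len(records)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = percent_identity(records[i], records[j])
    return IdentityMatrix([r.accession for r in records], values)


def nj_tree(matrix: IdentityMatrix | DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from identities (distance = 1 - identity).

    Negative branch lengths produced by the NJ formulas are clamped to
    zero.  Requires at least three labels.  The agglomeration itself is
    delegated to scikit-bio.
    """
    if isinstance(matrix, IdentityMatrix):
        dm = DistanceMatrix(matrix.to_distances(), matrix.labels)
    else:
        dm = matrix
    if len(dm.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    tree = _skbio_nj(dm, neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions of an (unrooted) tree.

    Each internal edge splits the leaf set in two; the split is encoded
    as a frozenset of the two leaf-name frozensets, so comparison is
    rooting-independent.  Splits with a side of fewer than two leaves
    are trivial and omitted.
    """
    leaves = frozenset(t.name for t in tree.tips())
    splits: set[frozenset] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits
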