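"""Peptide evidence ingestion, filtering and protein inference.

The evidence table emulates a search-engine export: one row per
observed peptide per run, where a run is a cell of the experimental
design (platform x extract x seed x technical replicate).  The default
design is two MS platforms (a QTOF run in triplicate and an LTQ in
duplicate) over three extraction buffers (E1-E3) and three seeds.

Inference proceeds in explicit, individually testable stages:

1. validation against the CSV schema and modification grammar;
2. filtering on peptide score, precursor ppm error and membership in
   the in-silico digest of the curated database;
3. collapse of modification-position isomers into peptide entities
   (positional deamidation isomers of one sequence are one entity);
4. the replicate criterion: an entity is reliable within an extract
   when at least two seeds each show it in at least two replicates;
5. uniqueness against the database digest and protein inference at a
   minimum number of reliable unique peptides (1 or 3);
6. sequence coverage and platform-overlap accounting.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .digestion import (
    CleavageRule,
    MODIFICATIONS,
    PeptideSpan,
    digest,
    get_modification,
    get_rule,
    peptide_mass,
    peptide_mz,
    validate_sequence,
)
from .seqdb import SequenceDatabase

EVIDENCE_COLUMNS = [
    "platform", "extract", "seed", "tech_rep", "peptide_sequence",
    "modifications", "charge", "observed_mz", "score", "intensity",
    "retention_time",
]


@dataclass(frozen=True)
class RunDesign:
    """The replicate structure evidence rows must reference."""

    platforms: Mapping[str, int] = field(
        default_factory=lambda: {"QTOF": 3, "LTQ": 2})
    extracts: tuple[str, ...] = ("E1", "E2", "E3")
    seeds: tuple[str, ...] = ("S1", "S2", "S3")

    def cells(self):
        """Iterate (platform, extract, seed, tech_rep) run cells."""
        for platform, n_reps in self.platforms.items():
            for extract in self.extracts:
                for seed in self.seeds:
                    for rep in range(1, n_reps + 1):
                        yield platform, extract, seed, rep


@dataclass(frozen=True)
class Modification:
    """One applied modification with its (possibly ambiguous) site(s).

    ``positions`` is a frozenset of candidate 1-based positions; a
    singleton set is a confidently localised site.  Exactly one of the
    candidate positions carries the modification.
    """

    name: str
    positions: frozenset

    def __str__(self) -> str:
        pos = sorted(self.positions)
        if len(pos) == 1:
            return f"{self.name}@{pos[0]}"
        return f"{self.name}@{{{'|'.join(map(str, pos))}}}"


_MOD_RE = re.compile(r"^(\w+)@(?:(\d+)|\{(\d+(?:\|\d+)*)\})$")


def parse_modifications(text: str) -> list[Modification]:
    """Parse the modification grammar ``Name@P`` / ``Name@{P1|P2|...}``,
    semicolon-separated, positions 1-based."""
    text = text.strip()
    if not text:
        return []
    mods = []
    for token in text.split(";"):
        token = token.strip()
        m = _MOD_RE.match(token)
        if not m:
            raise ValueError(f"unparseable modification {token!r}")
        name = get_modification(m.group(1)).name
        if m.group(2) is not None:
            positions = frozenset({int(m.group(2))})
        else:
            positions = frozenset(int(p) for p in m.group(3).split("|"))
        mods.append(Modification(name, positions))
    return mods


def format_modifications(mods: Sequence[Modification]) -> str:
    return ";".join(str(m) for m in mods)


@dataclass(frozen=True)
class EvidenceRow:
    """One observed peptide in one run."""

    platform: str
    extract: str
    seed: str
    tech_rep: int
    peptide_sequence: str
    modifications: tuple[Modification, ...] = ()
    charge: int = 2
    observed_mz: float = 0.0
    score: float = 0.0
    intensity: float = 0.0
    retention_time: float | None = None
    line_no: int | None = None

    @property
    def run(self) -> tuple:
        return (self.platform, self.extract, self.seed, self.tech_rep)

    def mod_counts(self) -> Counter:
        """Multiset of modification names, positions ignored."""
        return Counter(m.name for m in self.modifications)

    def theoretical_mass(self) -> float | None:
        base = peptide_mass(self.peptide_sequence)
        if base is None:
            return None
        return base + sum(
            get_modification(m.name).delta_mass for m in self.modifications
        )

    def theoretical_mz(self) -> float | None:
        mass = self.theoretical_mass()
        if mass is None:
            return None
        return peptide_mz(mass, self.charge)


def _validate_row(row: EvidenceRow) -> None:
    validate_sequence(row.peptide_sequence, "peptide_sequence")
    n = len(row.peptide_sequence)
    if row.charge < 1:
        raise ValueError("charge must be >= 1")
    if row.score < 0 or row.intensity < 0:
        raise ValueError("score and intensity must be non-negative")
    for mod in row.modifications:
        spec = MODIFICATIONS[mod.name]
        for pos in mod.positions:
            if not 1 <= pos <= n:
                raise ValueError(
                    f"{mod.name} position {pos} beyond peptide length {n}")
            residue = row.peptide_sequence[pos - 1]
            if residue not in spec.targets:
                raise ValueError(
                    f"{mod.name} cannot target residue {residue} at {pos}")


def load_and_validate_evidence(
    path: str | Path,
) -> tuple[list[EvidenceRow], list[tuple[int, str]]]:
    """Read the evidence CSV; return (valid rows, rejects).

    Rejects carry the 1-based data line number and the first violated
    invariant.  A missing required column is an error, not a reject.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in EVIDENCE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"evidence file missing required columns: {missing}")
        rows: list[EvidenceRow] = []
        rejects: list[tuple[int, str]] = []
        for line_no, raw in enumerate(reader, start=1):
            try:
                rt = raw.get("retention_time", "")
                row = EvidenceRow(
                    platform=raw["platform"].strip(),
                    extract=raw["extract"].strip(),
                    seed=raw["seed"].strip(),
                    tech_rep=int(raw["tech_rep"]),
                    peptide_sequence=raw["peptide_sequence"].strip(),
                    modifications=tuple(parse_modifications(raw["modifications"] or "")),
                    charge=int(raw["charge"]),
                    observed_mz=float(raw["observed_mz"]),
                    score=float(raw["score"]),
                    intensity=float(raw["intensity"]),
                    retention_time=float(rt) if rt not in ("", None) else None,
                    line_no=line_no,
                )
                _validate_row(row)
            except (ValueError, KeyError) as exc:
                rejects.append((line_no, str(exc)))
                continue
            rows.append(row)
    return rows, rejects


def write_evidence(rows: Iterable[EvidenceRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVIDENCE_COLUMNS)
        for r in rows:
            writer.writerow([
                r.platform, r.extract, r.seed, r.tech_rep, r.peptide_sequence,
                format_modifications(r.modifications), r.charge,
                f"{r.observed_mz:.6f}", f"{r.score:.4f}", f"{r.intensity:.4f}",
                "" if r.retention_time is None else f"{r.retention_time:.3f}",
            ])


# ---------------------------------------------------------------------------
# filtering

@dataclass(frozen=True)
class InferenceConfig:
    """Thresholds of the identification pipeline.

    ``fragment_ppm_max`` is accepted for config completeness but inert:
    no fragment-ion data is ingested at this level.
    """

    score_min: float = 5.0
    precursor_ppm_max: float = 10.0
    fragment_ppm_max: float = 20.0
    max_missed: int = 2
    min_unique_peptides: int = 3
    min_tech_reps: int = 2
    min_seeds: int = 2
    uniqueness_mode: str = "sequence_only"  # or "sequence_with_mods"
    reliability_per_platform: bool = False

    def __post_init__(self) -> None:
        for name in ("score_min", "precursor_ppm_max", "fragment_ppm_max",
                     "max_missed", "min_unique_peptides", "min_tech_reps",
                     "min_seeds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.uniqueness_mode not in ("sequence_only", "sequence_with_mods"):
            raise ValueError("unknown uniqueness_mode")


class DigestIndex:
    """In-silico digest of a whole database, indexed by peptide sequence."""

    def __init__(
        self,
        database: SequenceDatabase | Sequence,
        rule: CleavageRule | str,
        max_missed: int = 2,
    ) -> None:
        self.rule = get_rule(rule)
        self.max_missed = max_missed
        self.spans: dict[str, list[PeptideSpan]] = defaultdict(list)
        records = list(database)
        for rec in records:
            for span in digest(rec.sequence, self.rule, max_missed, rec.accession):
                self.spans[span.sequence].append(span)
        self.spans = dict(self.spans)
        self._lengths = {r.accession: len(r.sequence) for r in records}
        self._sequences = {r.accession: r.sequence for r in records}
        # cleavage geometry per protein, for classifying peptides that
        # are boundary-valid but exceed the missed-cleavage budget
        from .digestion import find_cleavage_sites

        self._sites = {
            r.accession: find_cleavage_sites(r.sequence, self.rule)
            for r in records
        }
        self._bounds = {
            acc: {0, self._lengths[acc]} | {s + 1 for s in sites}
            for acc, sites in self._sites.items()
        }

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.spans

    def accessions_of(self, sequence: str) -> set[str]:
        return {s.parent for s in self.spans.get(sequence, ())}

    def protein_length(self, accession: str) -> int:
        return self._lengths[accession]

    def min_missed(self, sequence: str) -> int | None:
        spans = self.spans.get(sequence)
        if not spans:
            return None
        return min(s.missed_cleavages for s in spans)

    def product_missed_cleavages(self, sequence: str) -> int | None:
        """Minimum internal cleavage sites over all boundary-valid
        occurrences of *sequence* in the database, regardless of the
        index's missed-cleavage cap; None if it is no digest product."""
        known = self.min_missed(sequence)
        if known is not None:
            return known
        best: int | None = None
        for acc, parent in self._sequences.items():
            bounds = self._bounds[acc]
            sites = self._sites[acc]
            start = parent.find(sequence)
            while start != -1:
                end = start + len(sequence)
                if start in bounds and end in bounds:
                    internal = sum(1 for s in sites if start <= s < end - 1)
                    if best is None or internal < best:
                        best = internal
                start = parent.find(sequence, start + 1)
        return best


def filter_evidence(
    rows: Sequence[EvidenceRow],
    config: InferenceConfig,
    index: DigestIndex,
) -> tuple[list[EvidenceRow], list[tuple[EvidenceRow, str]]]:
    """Retain rows passing score, precursor-ppm and digest-membership
    criteria; each rejection is tagged with the first failing criterion
    (``score``, ``ppm``, ``unmatched`` or ``missed_cleavages``).

    The retained set is independent of the criterion order; only the
    rejection tags depend on it.
    """
    retained = []
    rejected = []
    for row in rows:
        if row.score < config.score_min:
            rejected.append((row, "score"))
            continue
        theo = row.theoretical_mz()
        if theo is None:
            rejected.append((row, "unmatched"))
            continue
        ppm = abs(row.observed_mz - theo) / theo * 1e6
        if ppm > config.precursor_ppm_max:
            rejected.append((row, "ppm"))
            continue
        missed = (
            index.min_missed(row.peptide_sequence)
            if row.peptide_sequence in index
            else index.product_missed_cleavages(row.peptide_sequence)
        )
        if missed is None:
            rejected.append((row, "unmatched"))
            continue
        if missed > config.max_missed:
            rejected.append((row, "missed_cleavages"))
            continue
        retained.append(row)
    return retained, rejected


# ---------------------------------------------------------------------------
# entities: modification-ambiguity collapse

@dataclass
class PeptideEntity:
    """A peptide identification unit after modification collapse.

    In ``sequence_with_mods`` mode the key is the peptide sequence plus
    the multiset of modification *names* (positions ignored), so all
    positional deamidation isomers with the same deamidation count are
    one entity, while different deamidation counts stay distinct.  In
    ``sequence_only`` mode the key is the bare sequence.
    """

    key: tuple
    sequence: str
    mod_counts: Counter
    rows: list[EvidenceRow] = field(default_factory=list)
    accessions: frozenset = frozenset()
    is_unique: bool = False
    is_orphan: bool = False
    reliable_extracts: frozenset = frozenset()

    @property
    def platforms(self) -> set[str]:
        return {r.platform for r in self.rows}

    @property
    def is_modified(self) -> bool:
        return any(
            n != "Carbamidomethyl" for n in self.mod_counts.elements()
        )

    def intensity(self, extract: str | None = None) -> float | None:
        """Mean intensity across supporting runs (optionally one extract)."""
        vals = [
            r.intensity
            for r in self.rows
            if extract is None or r.extract == extract
        ]
        return float(np.mean(vals)) if vals else None


def collapse_modification_variants(
    rows: Sequence[EvidenceRow],
    uniqueness_mode: str = "sequence_with_mods",
) -> list[PeptideEntity]:
    """Group rows into :class:`PeptideEntity` by the collapse key.

    Deamidation observed at multiple alternative positions of one
    sequence is a single entity, because the exact site cannot be
    localised in Q runs.
    """
    entities: dict[tuple, PeptideEntity] = {}
    for row in rows:
        counts = row.mod_counts()
        if uniqueness_mode == "sequence_only":
            key = (row.peptide_sequence,)
        elif uniqueness_mode == "sequence_with_mods":
            key = (row.peptide_sequence, tuple(sorted(counts.items())))
        else:
            raise ValueError(f"unknown uniqueness_mode {uniqueness_mode!r}")
        ent = entities.get(key)
        if ent is None:
            ent = PeptideEntity(key=key, sequence=row.peptide_sequence,
                                mod_counts=counts)
            entities[key] = ent
        ent.rows.append(row)
    return list(entities.values())


# ---------------------------------------------------------------------------
# reliability, uniqueness, inference

def reliable_peptides(
    entities: Sequence[PeptideEntity],
    config: InferenceConfig,
) -> list[PeptideEntity]:
    """Flag each entity with the extracts in which it is reliable.

    Within an extract, an entity is reliable iff at least
    ``config.min_seeds`` seeds each contribute at least
    ``config.min_tech_reps`` distinct replicate observations.
    Replicates are pooled across platforms by default (a replicate is a
    distinct (platform, tech_rep) pair); with
    ``config.reliability_per_platform`` the criterion must hold within
    a single platform.
    """
    for ent in entities:
        extracts: set[str] = set()
        by_extract: dict[str, dict[str, set]] = defaultdict(lambda: defaultdict(set))
        for row in ent.rows:
            by_extract[row.extract][row.seed].add((row.platform, row.tech_rep))
        for extract, seeds in by_extract.items():
            if config.reliability_per_platform:
                ok_seeds = 0
                for reps in seeds.values():
                    per_platform = Counter(p for p, _r in reps)
                    if any(c >= config.min_tech_reps for c in per_platform.values()):
                        ok_seeds += 1
            else:
                ok_seeds = sum(
                    1 for reps in seeds.values()
                    if len(reps) >= config.min_tech_reps
                )
            if ok_seeds >= config.min_seeds:
                extracts.add(extract)
        ent.reliable_extracts = frozenset(extracts)
    return list(entities)


def assign_uniqueness(
    entities: Sequence[PeptideEntity],
    index: DigestIndex,
    warn: list | None = None,
) -> list[PeptideEntity]:
    """Map each entity to the database proteins whose digest contains
    its sequence; unique = exactly one protein, orphan = none.

    A peptide occurring at several positions within ONE protein is
    still unique to it.  Entities matching several proteins with
    byte-identical sequences indicate skipped curation; a warning is
    appended to *warn* in that case.
    """
    flagged: set[frozenset] = set()
    for ent in entities:
        accs = index.accessions_of(ent.sequence)
        ent.accessions = frozenset(accs)
        ent.is_unique = len(accs) == 1
        ent.is_orphan = len(accs) == 0
        if warn is not None and len(accs) > 1 and ent.accessions not in flagged:
            seqs = {index._sequences[a] for a in accs}
            if len(seqs) < len(accs):
                flagged.add(ent.accessions)
                warn.append(
                    "accessions %s have byte-identical sequences; "
                    "database curation appears to have been skipped"
                    % sorted(accs)
                )
    return list(entities)


@dataclass
class ProteinIdentification:
    """One inferred protein with its reliable unique peptide support."""

    accession: str
    peptides: list[PeptideEntity]
    coverage: float = 0.0
    coverage_mask: np.ndarray | None = None
    per_extract: dict[str, int] = field(default_factory=dict)
    platforms: set[str] = field(default_factory=set)

    @property
    def n_unique_reliable(self) -> int:
        return len(self.peptides)


def infer_proteins(
    entities: Sequence[PeptideEntity],
    config: InferenceConfig,
    index: DigestIndex | None = None,
) -> tuple[list[ProteinIdentification], dict[int, int]]:
    """Protein inference from reliable unique peptide entities.

    A protein is reported iff its number of unique entities reliable in
    at least one extract reaches ``config.min_unique_peptides``.  The
    returned counts dict holds the protein tally at thresholds 1 and 3
    from the same pass (raising the threshold can only shrink the set).
    """
    support: dict[str, list[PeptideEntity]] = defaultdict(list)
    for ent in entities:
        if ent.is_unique and ent.reliable_extracts:
            (acc,) = ent.accessions
            support[acc].append(ent)

    counts = {
        t: sum(1 for peps in support.values() if len(peps) >= t) for t in (1, 3)
    }

    identifications = []
    for acc in sorted(support):
        peps = support[acc]
        if len(peps) < config.min_unique_peptides:
            continue
        per_extract = Counter()
        platforms: set[str] = set()
        for ent in peps:
            for extract in ent.reliable_extracts:
                per_extract[extract] += 1
            platforms |= ent.platforms
        ident = ProteinIdentification(
            accession=acc,
            peptides=sorted(peps, key=lambda e: e.sequence),
            per_extract=dict(per_extract),
            platforms=platforms,
        )
        if index is not None:
            ident.coverage, ident.coverage_mask = sequence_coverage(ident, index)
        identifications.append(ident)
    return identifications, counts


def sequence_coverage(
    identification: ProteinIdentification,
    index: DigestIndex,
) -> tuple[float, np.ndarray]:
    """Covered fraction of the protein plus a per-residue platform mask.

    The mask holds, per residue, the set of platforms whose evidence
    covers it (encoded as a bitmask over the sorted platform names), so
    platform-exclusive and shared stretches can be rendered separately.
    All occurrences of a multi-copy peptide contribute.
    """
    length = index.protein_length(identification.accession)
    platform_names = sorted(
        {p for ent in identification.peptides for p in ent.platforms})
    bit = {p: 1 << i for i, p in enumerate(platform_names)}
    mask = np.zeros(length, dtype=np.int8)
    for ent in identification.peptides:
        bits = 0
        for p in ent.platforms:
            bits |= bit[p]
        for span in index.spans.get(ent.sequence, ()):
            if span.parent == identification.accession:
                mask[span.start:span.end] |= bits
    coverage = float(np.count_nonzero(mask)) / length if length else 0.0
    return coverage, mask


def platform_overlap(items: Iterable) -> dict:
    """Raw per-platform counts, shared count and union size.

    *items* are peptide entities (or identifications) exposing a
    ``platforms`` attribute.  ``union == sum(per_platform) - shared``
    holds whenever there are two platforms.
    """
    per_platform: Counter = Counter()
    total = 0
    shared = 0
    for item in items:
        platforms = item.platforms
        total += 1
        for p in platforms:
            per_platform[p] += 1
        if len(platforms) > 1:
            shared += 1
    return {"total": total, "per_platform": dict(per_platform), "shared": shared}


def identifications_to_json(
    identifications: Sequence[ProteinIdentification],
    counts: Mapping[int, int],
    path: str | Path,
) -> None:
    payload = {
        "n_proteins_min1": counts.get(1),
        "n_proteins_min3": counts.get(3),
        "proteins": [
            {
                "accession": ident.accession,
                "n_unique_reliable_peptides": ident.n_unique_reliable,
                "coverage": round(ident.coverage, 4),
                "platforms": sorted(ident.platforms),
                "per_extract": ident.per_extract,
                "peptides": [ent.sequence for ent in ident.peptides],
            }
            for ident in identifications
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
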