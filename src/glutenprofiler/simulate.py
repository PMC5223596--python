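"""Synthetic gluten-like sequences and peptide evidence with ground truth.

Real gluten MS data cannot be regenerated at desk scale, so every
pipeline stage is exercised against a generator that emulates the
salient structure of the problem:

* isoform families of P/Q-rich repetitive sequences (signal peptide,
  N- and C-terminal domains, a repetitive core built from prolamin
  motifs) differing by point substitutions and repeat-count changes,
  with every planted variant annotated;
* an evidence table over a 2-platform x 3-extract x 3-seed replicate
  design with platform-dependent peptide-length detectability,
  log-normal intensities, per-Q deamidation (with ambiguity sets over
  runs of adjacent glutamines), per-M oxidation, fixed cysteine
  carbamidomethylation, Gaussian ppm error on m/z, and score-separated
  noise rows.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .digestion import CARBAMIDOMETHYL, DEAMIDATION, OXIDATION, digest, get_rule, peptide_mz
from .evidence import EvidenceRow, Modification, RunDesign
from .seqdb import ProteinClass, ProteinRecord, SequenceDatabase, curate_database

# Background residue composition of prolamin non-repetitive domains:
# glutamine/proline dominated, almost no lysine or arginine.
_BACKGROUND = {
    "Q": 0.22, "P": 0.11, "S": 0.08, "G": 0.08, "L": 0.08, "F": 0.05,
    "E": 0.05, "A": 0.05, "V": 0.05, "T": 0.04, "Y": 0.04, "I": 0.03,
    "N": 0.03, "H": 0.02, "D": 0.02, "C": 0.015, "M": 0.015, "W": 0.01,
    "R": 0.01, "K": 0.005,
}
_SIGNAL_POOL = list("AILVFMTS")


def _draw_sequence(rng: np.random.Generator, length: int,
                   composition: Mapping[str, float] = _BACKGROUND) -> str:
    letters = list(composition)
    probs = np.array([composition[a] for a in letters], dtype=float)
    probs /= probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of the gluten-like isoform family generator."""

    n_families: int = 6
    isoforms_per_family: int = 2
    signal_peptide_length: int = 20
    nterm_length: int = 80
    cterm_length: int = 60
    repeat_motifs: tuple[str, ...] = ("PQQPFPQ", "QQPFP", "LQPFP", "QQQFP")
    repeat_count_range: tuple[int, int] = (25, 40)
    point_substitution_rate: float = 0.01
    indel_probability: float = 0.3
    max_kr_frequency: float = 0.03

    def __post_init__(self) -> None:
        for name in ("point_substitution_rate", "indel_probability",
                     "max_kr_frequency"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def _substitute(rng: np.random.Generator, residue: str) -> str:
    pool = [a for a in _BACKGROUND if a != residue and a not in "KR"]
    probs = np.array([_BACKGROUND[a] for a in pool])
    return str(rng.choice(pool, p=probs / probs.sum()))


def generate_isoform_family(
    spec: FamilySpec,
    rng: np.random.Generator | int,
    family_label: str = "FAM1",
    protein_class: ProteinClass = ProteinClass.alpha_gliadin,
) -> tuple[list[ProteinRecord], list[dict]]:
    """One family of isoforms derived from a common base sequence.

    The base is signal peptide + N-terminal domain + repeated motifs +
    C-terminal domain.  Each isoform applies independent per-residue
    substitutions and, with ``indel_probability``, the insertion or
    deletion of one whole repeat unit.  Every variant is annotated as a
    dict with keys ``isoform``, ``type``, ``position`` (and
    ``old``/``new`` or ``motif``).
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    longest = max(len(m) for m in spec.repeat_motifs)

    signal = "M" + "".join(
        rng.choice(_SIGNAL_POOL, size=spec.signal_peptide_length - 1))
    nterm = _draw_sequence(rng, spec.nterm_length)
    n_rep = int(rng.integers(*spec.repeat_count_range, endpoint=True))
    repeats = [str(rng.choice(spec.repeat_motifs)) for _ in range(n_rep)]
    cterm = _draw_sequence(rng, spec.cterm_length)

    base_parts = [signal + nterm] + repeats + [cterm]
    base_len = sum(len(p) for p in base_parts)
    if base_len < 3 * longest:
        raise ValueError(
            f"spec produces sequences of {base_len} residues, shorter than "
            f"3x the longest motif ({longest})"
        )

    records: list[ProteinRecord] = []
    annotations: list[dict] = []
    for iso in range(1, spec.isoforms_per_family + 1):
        accession = f"{family_label}I{iso}"
        parts = list(base_parts)
        # repeat-unit insertion or deletion
        if rng.random() < spec.indel_probability and len(parts) > 3:
            at = int(rng.integers(1, len(parts) - 1))
            if rng.random() < 0.5:
                motif = str(rng.choice(spec.repeat_motifs))
                parts.insert(at, motif)
                annotations.append(
                    {"isoform": accession, "type": "repeat_insertion",
                     "position": sum(len(p) for p in parts[:at]),
                     "motif": motif})
            else:
                motif = parts.pop(at)
                annotations.append(
                    {"isoform": accession, "type": "repeat_deletion",
                     "position": sum(len(p) for p in parts[:at]),
                     "motif": motif})
        seq = list("".join(parts))
        # point substitutions (never in the initiator methionine)
        hits = np.flatnonzero(
            rng.random(len(seq)) < spec.point_substitution_rate)
        for pos in hits:
            if pos == 0:
                continue
            old = seq[pos]
            new = _substitute(rng, old)
            seq[pos] = new
            annotations.append(
                {"isoform": accession, "type": "substitution",
                 "position": int(pos), "old": old, "new": new})
        sequence = "".join(seq)
        kr = (sequence.count("K") + sequence.count("R")) / len(sequence)
        if kr > spec.max_kr_frequency:
            raise ValueError(
                f"{accession}: K+R frequency {kr:.3f} exceeds "
                f"{spec.max_kr_frequency}")
        records.append(
            ProteinRecord(
                accession=accession,
                description=(f"synthetic {protein_class.value.replace('_', ' ')} "
                             f"{family_label} isoform {iso}"),
                organism="Triticum aestivum",
                protein_class=protein_class,
                sequence=sequence,
            )
        )
    return records, annotations


_CLASS_CYCLE = (
    ProteinClass.alpha_gliadin, ProteinClass.gamma_gliadin,
    ProteinClass.lmw_glutenin, ProteinClass.hmw_glutenin,
    ProteinClass.omega_gliadin,
)


def generate_database(
    spec: FamilySpec, seed: int
) -> tuple[SequenceDatabase, list[dict]]:
    """A curated database of ``n_families`` synthetic isoform families."""
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    annotations: list[dict] = []
    for fam in range(1, spec.n_families + 1):
        recs, anns = generate_isoform_family(
            spec, rng, family_label=f"GF{fam:02d}",
            protein_class=_CLASS_CYCLE[(fam - 1) % len(_CLASS_CYCLE)],
        )
        records.extend(recs)
        annotations.extend(anns)
    return curate_database(records), annotations


# ---------------------------------------------------------------------------
# a deterministic HMW-glutenin-like allelic pair

_HMW_MOTIFS = ("PGQGQQ", "GYYPTSLQQ", "GQQ")


def make_hmw_like_pair(seed: int = 2016) -> tuple[ProteinRecord, ProteinRecord, list[dict]]:
    """A synthetic stand-in for a HMW glutenin allelic pair (Dx2/Dx5 style).

    Both sequences share a signal peptide, an N-terminal domain, a long
    repetitive core of HMW-type motifs and a C-terminal domain.  The
    second allele plants the classic discriminators: a serine-to-
    cysteine substitution shortly after the start of the repetitive
    domain, one extra repeat block (insertion), one missing repeat
    block elsewhere (deletion), and three scattered substitutions.
    Fully deterministic given *seed*; returns both records plus the
    variant annotations.
    """
    rng = np.random.default_rng(seed)
    signal = "M" + "".join(rng.choice(_SIGNAL_POOL, size=20))
    nterm = _draw_sequence(rng, 90)
    repeats = [str(rng.choice(_HMW_MOTIFS)) for _ in range(120)]
    cterm = _draw_sequence(rng, 42)

    parts_a = [signal + nterm] + repeats + [cterm]
    seq_a = "".join(parts_a)

    annotations: list[dict] = []
    parts_b = list(parts_a)
    # extra repeat block near the middle of the repetitive domain
    ins_at = 30
    parts_b.insert(ins_at, "PGQGQQGYYPTSLQQ")
    annotations.append({"isoform": "B", "type": "repeat_insertion",
                        "position": sum(len(p) for p in parts_b[:ins_at]),
                        "motif": "PGQGQQGYYPTSLQQ"})
    # one repeat block deleted towards the end
    del_at = 50
    motif = parts_b.pop(del_at)
    annotations.append({"isoform": "B", "type": "repeat_deletion",
                        "position": sum(len(p) for p in parts_b[:del_at]),
                        "motif": motif})
    seq_b = list("".join(parts_b))

    # the S->C discriminator just after the repetitive-domain start,
    # then three scattered substitutions in non-repetitive regions
    planted = [("S", "C", None)]
    s_positions = [i for i, a in enumerate(seq_b)
                   if a == "S" and 111 <= i <= 160]
    pos = s_positions[0] if s_positions else seq_b.index("S", 21)
    seq_b[pos] = "C"
    annotations.append({"isoform": "B", "type": "substitution",
                        "position": pos, "old": "S", "new": "C"})
    del planted
    mid = len(seq_b) // 2
    for target_region in ((30, 90), (40, 100), (mid - 60, mid + 60),
                          (mid + 80, mid + 200), (len(seq_b) - 120, len(seq_b) - 60),
                          (len(seq_b) - 40, len(seq_b) - 5)):
        pos = int(rng.integers(*target_region))
        old = seq_b[pos]
        new = _substitute(rng, old)
        seq_b[pos] = new
        annotations.append({"isoform": "B", "type": "substitution",
                            "position": pos, "old": old, "new": new})

    rec_a = ProteinRecord(
        accession="HGA1",
        description="synthetic HMW glutenin subunit allele A (Dx2-like stand-in)",
        organism="Triticum aestivum",
        protein_class=ProteinClass.hmw_glutenin,
        sequence=seq_a,
    )
    rec_b = ProteinRecord(
        accession="HGB1",
        description="synthetic HMW glutenin subunit allele B (Dx5-like stand-in)",
        organism="Triticum aestivum",
        protein_class=ProteinClass.hmw_glutenin,
        sequence="".join(seq_b),
    )
    return rec_a, rec_b, annotations


# ---------------------------------------------------------------------------
# evidence simulation

@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the evidence simulator.

    ``missed_cleavage_emission`` gives the relative emission
    probability of digest products with 0/1/2 missed cleavages;
    ``platform length bias`` is a logistic multiplier in peptide length
    that right-shifts the long-read platform's detected-length
    distribution relative to the other platform.
    """

    design: RunDesign = field(default_factory=RunDesign)
    rule: str = "chymotrypsin-search"
    base_detection: float = 0.9
    long_platform: str = "QTOF"
    length_bias_midpoint: float = 14.0
    length_bias_scale: float = 4.0
    length_bias_floor: float = 0.55
    intensity_base: float = 1.0e6
    protein_sigma: float = 1.0
    peptide_sigma: float = 0.8
    run_sigma: float = 0.3
    deamidation_per_q: float = 0.4
    oxidation_per_m: float = 0.03
    missed_cleavage_emission: tuple[float, float, float] = (1.0, 0.4, 0.15)
    mz_ppm_sigma: float = 3.0
    mz_ppm_clip: float = 9.5
    noise_rate: float = 0.02
    matched_score: tuple[float, float] = (2.0, 8.0)   # gamma shape/scale above 5
    noise_score_scale: float = 1.0                     # exponential mean

    def __post_init__(self) -> None:
        for name in ("base_detection", "deamidation_per_q", "oxidation_per_m",
                     "noise_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    def detection_probability(self, platform: str, length: int,
                              missed: int) -> float:
        x = (length - self.length_bias_midpoint) / self.length_bias_scale
        if platform != self.long_platform:
            x = -x
        bias = self.length_bias_floor + (1 - self.length_bias_floor) / (
            1 + np.exp(-x))
        return self.base_detection * bias * self.missed_cleavage_emission[missed]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    present: list[str]
    abundances: dict[str, float]
    row_origins: list  # per row: [parent, start, end, missed] or "noise"
    deamidated_positions: list  # per row: list of true 1-based Q sites
    q_sites_total: int = 0
    q_sites_deamidated: int = 0
    unique_peptide_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _deamidation_mods(
    sequence: str, deamidated: Sequence[int]
) -> list[Modification]:
    """Build modification entries with ambiguity sets over Q runs.

    Each truly deamidated site yields one entry; when the site sits in
    a run of adjacent glutamines the position set spans the whole run
    (the mass spectrum cannot localise the site within the run).
    """
    runs: list[list[int]] = []
    current: list[int] = []
    for i, aa in enumerate(sequence, start=1):
        if aa == "Q":
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    run_of = {pos: tuple(run) for run in runs for pos in run}
    mods = []
    for pos in deamidated:
        run = run_of.get(pos, (pos,))
        positions = frozenset(run) if len(run) > 1 else frozenset({pos})
        mods.append(Modification(DEAMIDATION.name, positions))
    return mods


def simulate_evidence(
    database: SequenceDatabase,
    present: Sequence[str],
    spec: SimulationSpec,
    seed: int,
) -> tuple[list[EvidenceRow], GroundTruth]:
    """Emit an evidence table for the *present* proteins plus noise rows.

    For every run cell and every digest product (up to two missed
    cleavages) of every present protein, a row is emitted with the
    length- and platform-dependent detection probability; intensities
    are log-normal around the protein's true abundance times a fixed
    per-peptide ionisation efficiency; each glutamine deamidates
    independently, each methionine oxidises independently, every
    cysteine is carbamidomethylated; observed m/z carries clipped
    Gaussian ppm error.  Noise rows (random prolamin-composition
    sequences absent from the database digest) are appended at
    ``spec.noise_rate`` with low, score-separated scores.
    """
    if not present:
        raise ValueError("empty truth selection")
    rng = np.random.default_rng(seed)
    rule = get_rule(spec.rule)
    present = list(present)
    missing = [a for a in present if a not in database.accessions]
    if missing:
        raise ValueError(f"present accessions not in database: {missing}")

    abundances = {
        acc: float(spec.intensity_base
                   * rng.lognormal(0.0, spec.protein_sigma))
        for acc in present
    }
    # digest products per present protein, with per-peptide efficiency
    peptides = []
    for acc in present:
        rec = database[acc]
        for span in digest(rec.sequence, rule, 2, parent=acc):
            eff = float(rng.lognormal(0.0, spec.peptide_sigma))
            peptides.append((span, eff))

    rows: list[EvidenceRow] = []
    origins: list = []
    deam_truth: list = []
    q_total = 0
    q_deam = 0

    for platform, extract, seed_id, rep in spec.design.cells():
        for span, eff in peptides:
            p = spec.detection_probability(platform, len(span),
                                           span.missed_cleavages)
            if rng.random() >= p:
                continue
            seq = span.sequence
            q_positions = [i + 1 for i, aa in enumerate(seq) if aa == "Q"]
            deamidated = [
                pos for pos in q_positions
                if rng.random() < spec.deamidation_per_q
            ]
            q_total += len(q_positions)
            q_deam += len(deamidated)
            mods = _deamidation_mods(seq, deamidated)
            for i, aa in enumerate(seq, start=1):
                if aa == "M" and rng.random() < spec.oxidation_per_m:
                    mods.append(Modification(OXIDATION.name, frozenset({i})))
                elif aa == "C":
                    mods.append(Modification(CARBAMIDOMETHYL.name,
                                             frozenset({i})))
            charge = 3 if len(seq) >= 15 else 2
            row = EvidenceRow(
                platform=platform, extract=extract, seed=seed_id,
                tech_rep=rep, peptide_sequence=seq,
                modifications=tuple(mods), charge=charge,
                observed_mz=0.0, score=0.0, intensity=0.0,
            )
            theo = row.theoretical_mz()
            eps = float(np.clip(rng.normal(0.0, spec.mz_ppm_sigma),
                                -spec.mz_ppm_clip, spec.mz_ppm_clip))
            score = 5.0 + float(rng.gamma(*spec.matched_score))
            intensity = float(
                abundances[span.parent] * eff
                * rng.lognormal(0.0, spec.run_sigma))
            row = replace(row, observed_mz=theo * (1 + eps * 1e-6),
                           score=round(score, 4),
                           intensity=round(intensity, 4))
            rows.append(row)
            origins.append([span.parent, span.start, span.end,
                            span.missed_cleavages])
            deam_truth.append(deamidated)

    # noise rows: shuffled-database composition, absent from the digest
    if spec.noise_rate > 0 and rows:
        comp = Counter()
        for rec in database:
            comp.update(rec.sequence)
        letters = sorted(comp)
        probs = np.array([comp[a] for a in letters], dtype=float)
        probs /= probs.sum()
        known = set()
        for rec in database:
            for span in digest(rec.sequence, rule, 2):
                known.add(span.sequence)
        lengths = [len(r.peptide_sequence) for r in rows]
        cells = list(spec.design.cells())
        n_noise = int(round(spec.noise_rate * len(rows)))
        for _ in range(n_noise):
            while True:
                length = int(rng.choice(lengths))
                seq = "".join(rng.choice(letters, size=length, p=probs))
                if seq not in known:
                    break
            platform, extract, seed_id, rep = cells[int(rng.integers(len(cells)))]
            charge = 3 if length >= 15 else 2
            mz = peptide_mz(seq, charge) or float(rng.uniform(400, 1500))
            rows.append(EvidenceRow(
                platform=platform, extract=extract, seed=seed_id,
                tech_rep=rep, peptide_sequence=seq, modifications=(),
                charge=charge, observed_mz=mz,
                score=round(float(rng.exponential(spec.noise_score_scale)), 4),
                intensity=round(float(rng.lognormal(np.log(1e4), 1.0)), 4),
            ))
            origins.append("noise")
            deam_truth.append([])

    # how many digest peptides are unique to each present protein
    seq_owners: dict[str, set[str]] = {}
    for rec in database:
        for span in digest(rec.sequence, rule, 2):
            seq_owners.setdefault(span.sequence, set()).add(rec.accession)
    unique_counts = Counter()
    for seq, owners in seq_owners.items():
        if len(owners) == 1:
            (owner,) = owners
            if owner in present:
                unique_counts[owner] += 1

    truth = GroundTruth(
        present=present,
        abundances=abundances,
        row_origins=origins,
        deamidated_positions=deam_truth,
        q_sites_total=q_total,
        q_sites_deamidated=q_deam,
        unique_peptide_counts=dict(unique_counts),
    )
    return rows, truth


def random_additive_tree(
    n_taxa: int, rng: np.random.Generator | int
) -> tuple[list[str], np.ndarray, set[frozenset]]:
    """A random unrooted binary tree with positive branch lengths,
    returned as (labels, additive distance matrix, non-trivial leaf
    bipartitions).

    Built by repeatedly attaching a new leaf to a uniformly chosen
    edge.  On such a matrix neighbor joining provably recovers the
    generating topology, so the bipartition set is an exact oracle.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    labels = [f"T{i+1}" for i in range(n_taxa)]

    def blen() -> float:
        return float(rng.uniform(0.1, 1.0))

    # adjacency: node -> {neighbor: length}; leaves are 0..n_taxa-1
    nxt = n_taxa
    adj: dict[int, dict[int, float]] = {i: {} for i in range(3)}
    adj[nxt] = {}
    for leaf in range(3):
        w = blen()
        adj[nxt][leaf] = w
        adj[leaf][nxt] = w
    nxt += 1
    for leaf in range(3, n_taxa):
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        length = adj[u].pop(v)
        adj[v].pop(u)
        mid, nxt = nxt, nxt + 1
        lam = float(rng.uniform(0.2, 0.8))
        adj[mid] = {u: lam * length, v: (1 - lam) * length, leaf: blen()}
        adj[u][mid] = lam * length
        adj[v][mid] = (1 - lam) * length
        adj[leaf] = {mid: blen()}

    # pairwise path lengths by BFS/DFS from each leaf
    dist = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node].items():
                if nb not in seen:
                    seen[nb] = seen[node] + w
                    stack.append(nb)
        for dst in range(n_taxa):
            dist[src, dst] = seen[dst]
    dist = (dist + dist.T) / 2.0  # exact symmetry despite fp path order

    # bipartitions from internal edges
    splits: set[frozenset] = set()
    internal = [(u, v) for u in adj for v in adj[u]
                if u < v and u >= n_taxa and v >= n_taxa]
    for u, v in internal:
        side = set()
        stack = [u]
        seen_nodes = {u, v}
        while stack:
            node = stack.pop()
            if node < n_taxa:
                side.add(labels[node])
            for nb in adj[node]:
                if nb not in seen_nodes:
                    seen_nodes.add(nb)
                    stack.append(nb)
        other = frozenset(labels) - frozenset(side)
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({frozenset(side), other}))
    return labels, dist, splits


def default_scenario(
    seed: int,
    n_families: int = 10,
    isoforms_per_family: int = 2,
    sim_spec: SimulationSpec | None = None,
) -> tuple[SequenceDatabase, list[EvidenceRow], GroundTruth, SimulationSpec]:
    """The default closed-loop benchmark: 20 true proteins (10 families
    of 2 isoforms), every database protein present, default evidence
    design."""
    fam_spec = FamilySpec(n_families=n_families,
                          isoforms_per_family=isoforms_per_family)
    database, _ = generate_database(fam_spec, seed)
    spec = sim_spec or SimulationSpec()
    rows, truth = simulate_evidence(
        database, database.accessions, spec, seed=seed + 1)
    return database, rows, truth, spec
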