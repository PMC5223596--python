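"""Rule-based in-silico protease digestion and peptide mass arithmetic.

Chymotrypsin is the protease of choice for gluten because prolamins
contain almost no Lys/Arg; cleavage is C-terminal to bulky hydrophobic
residues unless the following residue is proline.  Two presets are
provided because search engines and the ExPASy PeptideMass tool draw
the specificity slightly differently:

``chymotrypsin-search``
    cleave after F/Y/W/L, blocked before P (the common search-engine
    setting for gluten work).
``chymotrypsin-expasy``
    cleave after F/Y/W/M/L, blocked before P (the ExPASy convention).

Masses are monoisotopic by default, using the residue masses shipped
with :mod:`pyteomics`; average masses are available by flag.  Peptides
containing the unknown residue ``X`` have undefined mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from pyteomics import mass as _ptmass

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}

WATER_MONO = 18.0105646863
WATER_AVG = 18.01528
PROTON = 1.007276466812


def validate_sequence(sequence: str, name: str = "sequence") -> None:
    """Raise ``ValueError`` unless *sequence* is non-empty, uppercase
    and restricted to the 20 amino-acid letters plus X."""
    if not sequence:
        raise ValueError(f"{name} is empty")
    if not sequence.isupper():
        raise ValueError(f"{name} must be uppercase")
    bad = set(sequence) - ALPHABET
    if bad:
        raise ValueError(f"{name} contains illegal letters: {sorted(bad)}")


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cut C-terminal to ``cleave_after`` unless
    the next residue is in ``blocked_before``."""

    name: str
    cleave_after: frozenset = field(default_factory=frozenset)
    blocked_before: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cleave_after", frozenset(self.cleave_after))
        object.__setattr__(self, "blocked_before", frozenset(self.blocked_before))
        if not self.cleave_after:
            raise ValueError("cleave_after must contain at least one residue")
        for res_set, label in ((self.cleave_after, "cleave_after"),
                               (self.blocked_before, "blocked_before")):
            bad = set(res_set) - AMINO_ACIDS
            if bad:
                raise ValueError(f"{label} contains illegal letters: {sorted(bad)}")


CHYMOTRYPSIN_SEARCH = CleavageRule(
    "chymotrypsin-search", frozenset("FYWL"), frozenset("P"))
CHYMOTRYPSIN_EXPASY = CleavageRule(
    "chymotrypsin-expasy", frozenset("FYWML"), frozenset("P"))

RULES = {r.name: r for r in (CHYMOTRYPSIN_SEARCH, CHYMOTRYPSIN_EXPASY)}


def get_rule(name: str | CleavageRule) -> CleavageRule:
    """Resolve a rule preset by name, passing rules through unchanged."""
    if isinstance(name, CleavageRule):
        return name
    try:
        return RULES[name]
    except KeyError:
        raise KeyError(
            f"unknown cleavage rule {name!r}; available: {sorted(RULES)}"
        ) from None


def find_cleavage_sites(sequence: str, rule: CleavageRule | str) -> list[int]:
    """Return the 0-based positions after which *rule* cuts *sequence*.

    Position ``p`` is a site iff ``sequence[p]`` is a cleavable residue
    and the next residue is not blocking.  The terminal residue is never
    a site (cutting after the last residue is vacuous).
    """
    validate_sequence(sequence)
    rule = get_rule(rule)
    last = len(sequence) - 1
    return [
        p
        for p in range(last)
        if sequence[p] in rule.cleave_after
        and sequence[p + 1] not in rule.blocked_before
    ]


@dataclass(frozen=True)
class PeptideSpan:
    """A digest product anchored to its parent protein.

    ``start``/``end`` are 0-based half-open coordinates on the parent;
    ``missed_cleavages`` counts internal uncut sites within the span.
    """

    parent: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __len__(self) -> int:
        return self.end - self.start


def digest(
    sequence: str,
    rule: CleavageRule | str,
    max_missed: int = 0,
    parent: str = "",
) -> list[PeptideSpan]:
    """Digest *sequence*, allowing up to *max_missed* missed cleavages.

    Returns all maximal fragments between consecutive cleavage sites
    plus every concatenation of at most ``max_missed + 1`` adjacent
    fragments, sorted by ``(start, end)``.  With ``f`` fragments and
    ``max_missed = k`` the number of spans is
    ``sum_{j=0..min(k, f-1)} (f - j)``.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    rule = get_rule(rule)
    sites = find_cleavage_sites(sequence, rule)
    # fragment boundaries: 0, s+1 for each site, len
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    spans: list[PeptideSpan] = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for j in range(i, min(i + max_missed + 1, nfrag)):
            start, end = bounds[i], bounds[j + 1]
            spans.append(
                PeptideSpan(parent, start, end, sequence[start:end], j - i)
            )
    spans.sort(key=lambda s: (s.start, s.end))
    return spans


# ---------------------------------------------------------------------------
# modifications and mass arithmetic

@dataclass(frozen=True)
class ModificationSpec:
    """A residue modification with its mass shift in Da."""

    name: str
    delta_mass: float
    targets: frozenset
    mode: str  # "fixed" | "variable"

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        if self.mode not in ("fixed", "variable"):
            raise ValueError("mode must be 'fixed' or 'variable'")


#: Fixed carbamidomethylation of cysteine from iodoacetamide alkylation.
CARBAMIDOMETHYL = ModificationSpec("Carbamidomethyl", 57.02146, frozenset("C"), "fixed")
#: Variable oxidation of methionine (sample-handling artifact).
OXIDATION = ModificationSpec("Oxidation", 15.99491, frozenset("M"), "variable")
#: Variable deamidation of Asn/Gln; positionally ambiguous in Q runs.
DEAMIDATION = ModificationSpec("Deamidation", 0.98402, frozenset("NQ"), "variable")

MODIFICATIONS = {m.name: m for m in (CARBAMIDOMETHYL, OXIDATION, DEAMIDATION)}


def get_modification(name: str | ModificationSpec) -> ModificationSpec:
    if isinstance(name, ModificationSpec):
        return name
    try:
        return MODIFICATIONS[name.capitalize()]
    except KeyError:
        raise KeyError(
            f"unknown modification {name!r}; available: {sorted(MODIFICATIONS)}"
        ) from None


def _aa_masses(monoisotopic: bool) -> dict:
    if monoisotopic:
        return _ptmass.std_aa_mass
    return {aa: comp.mass(average=True)
            for aa, comp in _ptmass.std_aa_comp.items() if len(aa) == 1}


def peptide_mass(
    peptide: str | PeptideSpan,
    modifications: Iterable[ModificationSpec | str] = (),
    monoisotopic: bool = True,
) -> float | None:
    """Neutral peptide mass in Da: residue masses + water + modification
    mass shifts.

    *modifications* lists each applied modification once per occurrence
    (e.g. two deamidations contribute ``2 x 0.98402``).  Every listed
    modification must target a residue actually present in the peptide.
    Returns ``None`` for peptides containing the unknown residue ``X``.
    """
    sequence = peptide.sequence if isinstance(peptide, PeptideSpan) else peptide
    validate_sequence(sequence, "peptide")
    mods = [get_modification(m) for m in modifications]
    for m in mods:
        if not (m.targets & set(sequence)):
            raise ValueError(
                f"modification {m.name} targets {sorted(m.targets)} "
                f"but none present in {sequence!r}"
            )
    if "X" in sequence:
        return None
    table = _aa_masses(monoisotopic)
    water = WATER_MONO if monoisotopic else WATER_AVG
    return sum(table[aa] for aa in sequence) + water + sum(m.delta_mass for m in mods)


def peptide_mz(
    peptide: str | PeptideSpan | float,
    charge: int,
    modifications: Iterable[ModificationSpec | str] = (),
    monoisotopic: bool = True,
) -> float | None:
    """m/z of a peptide (or of a precomputed neutral mass) at *charge*.

    ``m/z = (M + z * m_proton) / z``.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1 for m/z")
    if isinstance(peptide, (int, float)):
        mass = float(peptide)
        if modifications:
            mass += sum(get_modification(m).delta_mass for m in modifications)
    else:
        mass = peptide_mass(peptide, modifications, monoisotopic)
    if mass is None:
        return None
    return (mass + charge * PROTON) / charge
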