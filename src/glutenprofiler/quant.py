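"""Top-3 (T3PQ / Hi3) protein quantification and summary analytics.

Label-free Top-3 quantification rests on the observation that the mean
MS signal of a protein's three most efficiently ionised peptides is
proportional to its molar amount.  Absolute amounts follow by ratio to
a standard protein (here phosphorylase B, "PhosB") spiked at a known
amount, typically 100 fmol.

Only UNIQUE peptide entities feed quantification — shared peptides
would double-count signal across isoforms of these highly homologous
families.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import PeptideEntity, ProteinIdentification


@dataclass
class AbundanceRecord:
    """Top-3 abundance of one protein (per extract or pooled)."""

    accession: str
    relative_abundance: float
    n_quant_peptides: int
    partial: bool = False
    absolute_fmol: float | None = None
    rank: int | None = None


def _aggregate(values: Sequence[float], method: str) -> float:
    if method == "mean":
        return float(np.mean(values))
    if method == "median":
        return float(np.median(values))
    raise ValueError(f"unknown aggregation {method!r}")


def t3pq_abundance(
    identifications: Sequence[ProteinIdentification],
    extract: str | None = None,
    aggregate: str = "mean",
    warnings: list | None = None,
) -> list[AbundanceRecord]:
    """Mean of the three most intense unique peptide entities per protein.

    Each entity's intensity is first aggregated (arithmetic mean by
    default, median by flag) across the runs where it was observed,
    optionally restricted to one extract.  Proteins with only one or
    two intensity-bearing unique entities get the mean of what exists
    and are flagged ``partial``; proteins with none are excluded with a
    warning.  Records are returned ranked by descending abundance.
    """
    records: list[AbundanceRecord] = []
    for ident in identifications:
        intensities = []
        for ent in ident.peptides:
            val = _entity_intensity(ent, extract, aggregate)
            if val is not None and val > 0:
                intensities.append(val)
        if not intensities:
            if warnings is not None:
                warnings.append(
                    f"{ident.accession}: no intensity-bearing unique peptides"
                    + (f" in {extract}" if extract else "")
                )
            continue
        top3 = sorted(intensities, reverse=True)[:3]
        records.append(
            AbundanceRecord(
                accession=ident.accession,
                relative_abundance=float(np.mean(top3)),
                n_quant_peptides=len(top3),
                partial=len(top3) < 3,
            )
        )
    records.sort(key=lambda r: -r.relative_abundance)
    for i, rec in enumerate(records, start=1):
        rec.rank = i
    return records


def _entity_intensity(
    ent: PeptideEntity, extract: str | None, aggregate: str
) -> float | None:
    vals = [
        r.intensity for r in ent.rows if extract is None or r.extract == extract
    ]
    return _aggregate(vals, aggregate) if vals else None


def hi3_calibrate(
    abundances: Sequence[AbundanceRecord],
    standard_accession: str,
    spike_fmol: float = 100.0,
    warnings: list | None = None,
) -> list[AbundanceRecord]:
    """Convert relative Top-3 abundances to fmol by ratio to the spiked
    standard: ``amount(P) = T3(P) / T3(standard) * spike_fmol``.

    If the standard is absent or itself partial (fewer than three
    quantifiable peptides), calibration is skipped with a warning and
    relative values are kept.
    """
    standard = next(
        (r for r in abundances if r.accession == standard_accession), None)
    if standard is None or standard.partial or standard.relative_abundance <= 0:
        if warnings is not None:
            warnings.append(
                f"standard {standard_accession!r} missing or partial; "
                "calibration skipped"
            )
        return list(abundances)
    for rec in abundances:
        rec.absolute_fmol = (
            rec.relative_abundance / standard.relative_abundance * spike_fmol
        )
    return list(abundances)


def abundance_table(records: Sequence[AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "rank": [r.rank for r in records],
            "relative_abundance": [r.relative_abundance for r in records],
            "absolute_fmol": [r.absolute_fmol for r in records],
            "n_quant_peptides": [r.n_quant_peptides for r in records],
            "partial": [r.partial for r in records],
        }
    )


# ---------------------------------------------------------------------------
# summary analytics

#: exclusive modification classes used for prevalence reporting;
#: carbamidomethylation is fixed chemistry, reported separately.
MOD_CLASSES = ("none", "deamidated", "oxidized", "both")


def _mod_class(ent: PeptideEntity) -> str:
    deam = ent.mod_counts.get("Deamidation", 0) > 0
    oxid = ent.mod_counts.get("Oxidation", 0) > 0
    if deam and oxid:
        return "both"
    if deam:
        return "deamidated"
    if oxid:
        return "oxidized"
    return "none"


def summarize_distributions(
    entities: Sequence[PeptideEntity],
    identifications: Sequence[ProteinIdentification] = (),
    extracts: Iterable[str] = ("E1", "E2", "E3"),
) -> dict[str, pd.DataFrame]:
    """Tidy summary tables of the peptide-level results.

    Returns a dict of DataFrames:

    ``length_histogram``
        peptide-length counts per platform, split modified/unmodified;
    ``modification_prevalence``
        per platform, fractions of the exclusive classes
        none/deamidated/oxidized/both (summing to 1) plus the
        carbamidomethylated fraction;
    ``deamidation_by_length``
        per platform and length, fraction of entities deamidated;
    ``abundance_curve``
        per extract, protein rank vs log10 Top-3 abundance.
    """
    rows_hist = []
    rows_prev = []
    rows_deam = []

    by_platform: dict[str, list[PeptideEntity]] = {}
    for ent in entities:
        for platform in ent.platforms:
            by_platform.setdefault(platform, []).append(ent)

    for platform, ents in sorted(by_platform.items()):
        hist = Counter(
            (len(e.sequence), e.is_modified) for e in ents)
        for (length, modified), count in sorted(hist.items()):
            rows_hist.append(
                {"platform": platform, "length": length,
                 "modified": modified, "count": count}
            )
        classes = Counter(_mod_class(e) for e in ents)
        n = len(ents)
        row = {"platform": platform, "n_peptides": n}
        for cls in MOD_CLASSES:
            row[cls] = classes.get(cls, 0) / n if n else 0.0
        row["carbamidomethyl"] = (
            sum(1 for e in ents if e.mod_counts.get("Carbamidomethyl", 0) > 0) / n
            if n else 0.0
        )
        rows_prev.append(row)
        lengths = Counter(len(e.sequence) for e in ents)
        deam = Counter(
            len(e.sequence) for e in ents
            if e.mod_counts.get("Deamidation", 0) > 0
        )
        for length in sorted(lengths):
            rows_deam.append(
                {"platform": platform, "length": length,
                 "n": lengths[length],
                 "deamidated_fraction": deam.get(length, 0) / lengths[length]}
            )

    rows_curve = []
    for extract in extracts:
        for rec in t3pq_abundance(list(identifications), extract=extract):
            rows_curve.append(
                {"extract": extract, "accession": rec.accession,
                 "rank": rec.rank,
                 "log10_abundance": float(np.log10(rec.relative_abundance))}
            )

    return {
        "length_histogram": pd.DataFrame(rows_hist),
        "modification_prevalence": pd.DataFrame(rows_prev),
        "deamidation_by_length": pd.DataFrame(rows_deam),
        "abundance_curve": pd.DataFrame(rows_curve),
    }


def plot_summary(report: Mapping[str, pd.DataFrame], out_dir) -> list:
    """Optional matplotlib rendering of the summary tables (length
    histograms and per-extract abundance curves).  Returns the written
    paths."""
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    hist = report["length_histogram"]
    if not hist.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        for platform, sub in hist.groupby("platform"):
            agg = sub.groupby("length")["count"].sum()
            ax.plot(agg.index, agg.values, marker="o", label=platform)
        ax.set_xlabel("peptide length (residues)")
        ax.set_ylabel("peptides")
        ax.legend()
        fig.tight_layout()
        p = out_dir / "length_histogram.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    curve = report["abundance_curve"]
    if not curve.empty:
        fig, ax = plt.subplots(figsize=(7, 4))
        for extract, sub in curve.groupby("extract"):
            ax.plot(sub["rank"], sub["log10_abundance"], marker=".",
                    linestyle="none", label=extract)
        ax.set_xlabel("protein rank")
        ax.set_ylabel("log10 Top-3 abundance")
        ax.legend()
        fig.tight_layout()
        p = out_dir / "abundance_curve.svg"
        fig.savefig(p)
        plt.close(fig)
        written.append(p)

    return written
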