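"""Species-level aggregation of architecture calls.

A species counts as possessing a chemoreceptor when any of its proteins is
a soluble or membrane-bound chemoreceptor, and as possessing a diguanylate
cyclase when any is dgc or dgc_eal.  The eal_czb, chew_czb and czb_only
subgroups contribute to neither class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .architecture import ArchitectureCall

CHEMORECEPTOR_SUBGROUPS = {"soluble_chemoreceptor", "membrane_chemoreceptor"}
DGC_SUBGROUPS = {"dgc", "dgc_eal"}

CATEGORIES = ("chemoreceptor_only", "dgc_only", "both", "neither")


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    phylum: str
    candidate_phylum: bool
    subgroups_present: frozenset
    category: str


def normalize_species(name: str, strip_strain: bool = False) -> str:
    """Case-fold and optionally collapse 'Genus sp. CODE' to 'Genus sp.'."""
    s = " ".join(name.split()).strip()
    if strip_strain:
        s = re.sub(r"(\bsp\.)\s+\S+.*$", r"\1", s)
    return s.casefold()


def categorize(subgroups: Iterable[str]) -> str:
    s = set(subgroups)
    chem = bool(s & CHEMORECEPTOR_SUBGROUPS)
    dgc = bool(s & DGC_SUBGROUPS)
    if chem and dgc:
        return "both"
    if chem:
        return "chemoreceptor_only"
    if dgc:
        return "dgc_only"
    return "neither"


def aggregate_species(
    arch_calls: Sequence[ArchitectureCall],
    taxonomy: pd.DataFrame,
    strip_strain: bool = False,
) -> tuple[list[SpeciesSummary], int]:
    """One summary per distinct species; proteins without a species
    mapping are excluded and counted (second return value)."""
    tax = taxonomy.set_index("protein_id")
    buckets: dict[str, dict] = {}
    unmapped = 0
    for call in arch_calls:
        if call.protein_id not in tax.index:
            unmapped += 1
            continue
        row = tax.loc[call.protein_id]
        species_raw = str(row["species"]).strip()
        if not species_raw:
            unmapped += 1
            continue
        key = normalize_species(species_raw, strip_strain)
        b = buckets.setdefault(
            key,
            dict(
                species=species_raw,
                phylum=str(row["phylum"]).strip() or "unclassified",
                candidate=bool(row["candidate_phylum_flag"]),
                subgroups=set(),
            ),
        )
        b["subgroups"].add(call.subgroup)
    summaries = [
        SpeciesSummary(
            species=b["species"],
            phylum=b["phylum"],
            candidate_phylum=b["candidate"],
            subgroups_present=frozenset(b["subgroups"]),
            category=categorize(b["subgroups"]),
        )
        for key, b in sorted(buckets.items())
    ]
    return summaries, unmapped


def category_counts(summaries: Iterable[SpeciesSummary]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for s in summaries:
        counts[s.category] += 1
    return counts


def phylum_distribution(
    summaries: Iterable[SpeciesSummary],
) -> tuple[pd.Series, int, int]:
    """Per-phylum species counts plus distinct (named, candidate) phyla
    counts; missing phylum labels bucket as 'unclassified'."""
    rows = [(s.phylum or "unclassified", s.candidate_phylum) for s in summaries]
    if not rows:
        return pd.Series(dtype=int), 0, 0
    df = pd.DataFrame(rows, columns=["phylum", "candidate"])
    counts = df["phylum"].value_counts().sort_index()
    named = df.loc[~df["candidate"], "phylum"].nunique()
    candidate = df.loc[df["candidate"], "phylum"].nunique()
    return counts, named, candidate


def summaries_to_frame(summaries: Iterable[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                species=s.species,
                phylum=s.phylum,
                candidate_phylum=s.candidate_phylum,
                subgroups=";".join(sorted(s.subgroups_present)),
                category=s.category,
            )
            for s in summaries
        ],
        columns=["species", "phylum", "candidate_phylum", "subgroups", "category"],
    )
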