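"""Domain-architecture subgroup assignment and periplasmic flagging.

The seven subgroups, in classification priority order: membrane-bound
chemoreceptor, soluble chemoreceptor, DGC+EAL, DGC, EAL-CZB, CheW-CZB,
CZB-only.  A CZB is flagged periplasmic when it lies strictly between two
transmembrane regions of a membrane-bound chemoreceptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import CZBDomainCall
from .iolib import DomainAnnotation, ProteinRecord

logger = logging.getLogger(__name__)

SUBGROUPS = (
    "soluble_chemoreceptor",
    "membrane_chemoreceptor",
    "dgc",
    "dgc_eal",
    "eal_czb",
    "chew_czb",
    "czb_only",
)

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}


@dataclass(frozen=True)
class TMRegion:
    start: int
    end: int
    mean_hydropathy: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    subgroup: str
    czb_terminus: str  # N | C | internal
    periplasmic: bool
    length: int = 0


def predict_tm(
    record: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_length: int = 15,
    merge_gap: int = 3,
) -> list[TMRegion]:
    """Sliding-window Kyte-Doolittle transmembrane segment prediction.

    Maximal runs of window centers above ``threshold`` are expanded to the
    window extent, merged when separated by fewer than ``merge_gap``
    residues, and reported when at least ``min_length`` residues long.
    """
    if window < 7 or window % 2 == 0:
        raise ValueError("window must be odd and >= 7")
    seq = record.sequence
    n = len(seq)
    if n < window:
        return []
    values = np.array([KYTE_DOOLITTLE[c] for c in seq])
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")  # center i -> means[i - half]
    half = window // 2
    above = means > threshold
    regions: list[list[int]] = []
    for idx in np.flatnonzero(above):
        center = idx + half  # 0-based residue index of window center
        start = max(0, center - half)
        end = min(n - 1, center + half)
        if regions and start <= regions[-1][1] + merge_gap:
            regions[-1][1] = max(regions[-1][1], end)
        else:
            regions.append([start, end])
    out = []
    for s, e in regions:
        if e - s + 1 >= min_length:
            mh = float(np.mean(values[s:e + 1]))
            out.append(TMRegion(s + 1, e + 1, mh))
    return out


def classify_architecture(
    record: ProteinRecord,
    annotations: Sequence[DomainAnnotation],
    czb_call: CZBDomainCall,
    tm_regions: Sequence[TMRegion] = (),
    terminus_fraction: float = 0.15,
) -> ArchitectureCall:
    """Assign one of the seven subgroups by priority rules.

    MCP presence dominates (chemoreceptors with auxiliary catalytic
    domains are still chemoreceptors); then GGDEF/EAL combinations, CheW,
    and finally CZB-only.
    """
    if not czb_call.accepted:
        raise ValueError(f"{record.id}: no accepted CZB call; classification undefined")
    names = {a.domain_name for a in annotations if a.protein_id == record.id}
    has_tm = bool(tm_regions) or "TM" in names
    if "MCP" in names:
        subgroup = "membrane_chemoreceptor" if has_tm else "soluble_chemoreceptor"
    elif "GGDEF" in names and "EAL" in names:
        subgroup = "dgc_eal"
    elif "GGDEF" in names:
        subgroup = "dgc"
    elif "EAL" in names:
        subgroup = "eal_czb"
    elif "CheW" in names:
        subgroup = "chew_czb"
    else:
        if names - {"CZB", "TM", "other"}:
            logger.warning("%s: unexpected annotations %s", record.id, names)
        if "other" in names:
            logger.info("%s: only 'other' annotations besides CZB -> czb_only", record.id)
        subgroup = "czb_only"

    length = len(record)
    start, end = czb_call.region
    if start <= terminus_fraction * length:
        terminus = "N"
    elif end >= (1.0 - terminus_fraction) * length:
        terminus = "C"
    else:
        terminus = "internal"
    call = ArchitectureCall(record.id, subgroup, terminus, False, length)
    peri = flag_periplasmic(call, czb_call, tm_regions)
    return ArchitectureCall(record.id, subgroup, terminus, peri, length)


def flag_periplasmic(
    call: ArchitectureCall,
    czb_call: CZBDomainCall,
    tm_regions: Sequence[TMRegion],
) -> bool:
    """True iff a membrane chemoreceptor's CZB sits strictly between two
    transmembrane regions (one fully on each side)."""
    if call.subgroup != "membrane_chemoreceptor":
        return False
    start, end = czb_call.region
    before = any(tm.end < start for tm in tm_regions)
    after = any(tm.start > end for tm in tm_regions)
    return before and after


def summarize_subgroups(calls: Iterable[ArchitectureCall]) -> pd.DataFrame:
    """Counts and fractions per subgroup, with a periplasmic overlay count."""
    calls = list(calls)
    if not calls:
        return pd.DataFrame(columns=["subgroup", "count", "fraction", "periplasmic"])
    df = pd.DataFrame(
        [(c.subgroup, c.periplasmic) for c in calls],
        columns=["subgroup", "periplasmic"],
    )
    total = len(df)
    rows = []
    for sg in SUBGROUPS:
        sub = df[df["subgroup"] == sg]
        rows.append(
            dict(
                subgroup=sg,
                count=len(sub),
                fraction=len(sub) / total,
                periplasmic=int(sub["periplasmic"].sum()),
            )
        )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Iterable[ArchitectureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                protein_id=c.protein_id,
                subgroup=c.subgroup,
                czb_terminus=c.czb_terminus,
                periplasmic=c.periplasmic,
                length=c.length,
            )
            for c in calls
        ],
        columns=["protein_id", "subgroup", "czb_terminus", "periplasmic", "length"],
    )
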