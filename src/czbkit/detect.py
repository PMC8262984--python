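"""CZB domain identification.

A candidate region is accepted when four attributes hold simultaneously:

* ``core`` — at least 3 His residues within a window of the anchor Cys
  (the 3His/1Cys zinc-binding core);
* ``motif`` — a seven-residue match to C-x-(L/F)-G-x-W-(Y/L) whose first
  residue is the anchor Cys;
* ``coverage`` — the candidate region spans at least a configurable
  minimum of the canonical ~128-residue domain;
* ``alignment`` — a log-odds score against a profile built from confirmed
  domains reaches a configurable threshold.

The anchor frame places the Cys at domain position 52 of a 1..128 domain,
so the candidate region is ``[cys - 51, cys + 76]`` clipped to the
sequence.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .iolib import ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

# X never satisfies a motif position, including the wildcards.
MOTIF_REGEX = re.compile(r"(?=(C[ACDEFGHIKLMNPQRSTVWY][LF]G[ACDEFGHIKLMNPQRSTVWY]W[YL]))")

MOTIF_LENGTH = 7

#: Offsets of the anchor Cys inside the canonical domain frame (C52 of 1..128).
REGION_UPSTREAM = 51
REGION_DOWNSTREAM = 76

NEG_INF = float("-inf")


@dataclass(frozen=True)
class MotifHit:
    """One C-x-(L/F)-G-x-W-(Y/L) match; cys_position is 1-based."""

    protein_id: str
    cys_position: int
    motif_seq: str


@dataclass(frozen=True)
class CZBDomainCall:
    protein_id: str
    region: tuple[int, int]
    cys_position: int | None
    his_positions: tuple[int, ...]
    core: bool
    motif: bool
    coverage: bool
    alignment: bool
    profile_score: float
    accepted: bool
    flagged: bool = False

    @property
    def attributes(self) -> tuple[bool, bool, bool, bool]:
        return (self.core, self.motif, self.coverage, self.alignment)


@dataclass
class DetectConfig:
    """Tunable identification parameters, echoed into all outputs."""

    his_window: int = 45
    min_coverage: int = 100
    score_threshold: float = 0.0
    gap_penalty: float = -2.0
    flag_margin: float = 1.0  # |score - threshold| below this => flagged for review

    def __post_init__(self) -> None:
        if self.his_window < 1:
            raise ValueError("his_window must be >= 1")


def scan_motif(record: ProteinRecord) -> list[MotifHit]:
    """Report every 7-residue window matching the motif, left to right.

    Overlapping hits are allowed; returns an empty list when nothing
    matches.
    """
    hits = []
    for m in MOTIF_REGEX.finditer(record.sequence):
        hits.append(MotifHit(record.id, m.start() + 1, m.group(1)))
    return hits


def check_zinc_core(
    record: ProteinRecord, hit: MotifHit, window: int = 45
) -> tuple[bool, tuple[int, ...]]:
    """True iff >= 3 His lie within +/- ``window`` residues of the Cys."""
    if window < 1:
        raise ValueError("window must be >= 1")
    cys = hit.cys_position
    lo = max(1, cys - window)
    hi = min(len(record), cys + window)
    his = tuple(
        i for i in range(lo, hi + 1) if record.sequence[i - 1] == "H"
    )
    return len(his) >= 3, his


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class Profile:
    """Position-frequency matrix with uniform background, in log2 odds."""

    frequencies: np.ndarray  # (columns, 20), rows sum to 1
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.ndim != 2 or self.frequencies.shape[1] != 20:
            raise ValueError("profile must be (columns, 20)")

    def __len__(self) -> int:
        return self.frequencies.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        bg = 1.0 / 20.0
        return np.log2(self.frequencies / bg)


def build_profile(
    seed_rows: Sequence[str], pseudocount: float = 0.5
) -> Profile:
    """Column frequencies over a seed alignment of confirmed domains.

    Rows must be equal length; gaps ('-') and X are excluded from column
    counts.  A pseudocount keeps every log-odds entry finite.
    """
    if not seed_rows:
        raise ValueError("no seed rows")
    width = len(seed_rows[0])
    if any(len(r) != width for r in seed_rows):
        raise ValueError("seed rows must be equal length")
    counts = np.full((width, 20), pseudocount, dtype=float)
    for row in seed_rows:
        for j, ch in enumerate(row.upper()):
            k = _AA_INDEX.get(ch)
            if k is not None:
                counts[j, k] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return Profile(freqs, pseudocount)


def score_against_profile(
    record: ProteinRecord,
    region: tuple[int, int],
    profile: Profile,
    gap_penalty: float = -2.0,
) -> float:
    """Sum of per-column log2 odds of the region against the profile.

    X scores as background (0); '-' takes the fixed gap penalty.  A region
    shorter than half the profile is a coverage failure and scores -inf.
    """
    start, end = region
    seg = record.sequence[start - 1:end]
    if len(seg) < math.ceil(len(profile) / 2):
        return NEG_INF
    lo = profile.log_odds
    score = 0.0
    for j in range(min(len(seg), len(profile))):
        ch = seg[j]
        if ch == "-":
            score += gap_penalty
        else:
            k = _AA_INDEX.get(ch)
            if k is not None:
                score += lo[j, k]
    return score


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def candidate_region(record: ProteinRecord, cys_position: int) -> tuple[int, int]:
    return (
        max(1, cys_position - REGION_UPSTREAM),
        min(len(record), cys_position + REGION_DOWNSTREAM),
    )


def call_czb(
    record: ProteinRecord,
    profile: Profile,
    config: DetectConfig | None = None,
) -> CZBDomainCall:
    """Evaluate the four identification attributes for one protein.

    When several motif hits exist the highest profile score wins, ties
    broken by the smallest Cys position.  Without any motif hit, the Cys
    with the most surrounding His anchors the (rejected) candidate so the
    remaining attributes are still reported.
    """
    config = config or DetectConfig()
    hits = scan_motif(record)
    motif_found = bool(hits)
    if not hits:
        # anchor on the best available Cys so core/coverage stay informative
        cys_positions = [i + 1 for i, c in enumerate(record.sequence) if c == "C"]
        if not cys_positions:
            return CZBDomainCall(
                record.id, (1, len(record)), None, (), False, False,
                len(record) >= config.min_coverage, False, NEG_INF, False,
            )
        def his_count(p: int) -> int:
            lo = max(1, p - config.his_window)
            hi = min(len(record), p + config.his_window)
            return record.sequence[lo - 1:hi].count("H")

        best_cys = max(cys_positions, key=lambda p: (his_count(p), -p))
        hits = [
            MotifHit(
                record.id, best_cys,
                record.sequence[best_cys - 1:best_cys + 6].ljust(7, "X"),
            )
        ]

    best: tuple[float, int, MotifHit] | None = None
    for h in hits:
        region = candidate_region(record, h.cys_position)
        s = score_against_profile(record, region, profile, config.gap_penalty)
        key = (-s, h.cys_position)
        if best is None or key < (-best[0], best[2].cys_position):
            best = (s, h.cys_position, h)
    assert best is not None
    score, _, hit = best
    region = candidate_region(record, hit.cys_position)
    core, his = check_zinc_core(record, hit, config.his_window)
    coverage = (region[1] - region[0] + 1) >= config.min_coverage
    alignment = score >= config.score_threshold
    accepted = core and motif_found and coverage and alignment
    flagged = accepted and abs(score - config.score_threshold) < config.flag_margin
    return CZBDomainCall(
        record.id, region, hit.cys_position, his,
        core, motif_found, coverage, alignment, score, accepted, flagged,
    )


def calibrate_threshold(
    positive_scores: Sequence[float],
    decoy_scores: Sequence[float],
    margin: float = 1.0,
) -> float:
    """Threshold from a labeled bench: decoy max + margin when separable,
    otherwise just below the weakest positive."""
    pos_min = min(positive_scores)
    finite_decoys = [s for s in decoy_scores if s > NEG_INF]
    if not finite_decoys:
        return pos_min - margin
    neg_max = max(finite_decoys)
    if neg_max + 2 * margin < pos_min:
        return neg_max + margin
    return pos_min - 1e-9


# ---------------------------------------------------------------------------
# Iterative search
# ---------------------------------------------------------------------------

def kmer_backend(k: int = 4, min_shared: int = 8) -> Callable:
    """Naive shared k-mer search backend (stand-in for BLAST).

    Returns candidate ids from the database sharing at least ``min_shared``
    distinct k-mers with any query sequence.
    """

    def backend(
        queries: Iterable[ProteinRecord], database: Sequence[ProteinRecord]
    ) -> set[str]:
        query_kmers: set[str] = set()
        for q in queries:
            s = q.sequence
            query_kmers.update(s[i:i + k] for i in range(len(s) - k + 1))
        out: set[str] = set()
        for rec in database:
            s = rec.sequence
            kmers = {s[i:i + k] for i in range(len(s) - k + 1)}
            if len(kmers & query_kmers) >= min_shared:
                out.add(rec.id)
        return out

    return backend


def iterative_search(
    seeds: Sequence[ProteinRecord],
    database: Sequence[ProteinRecord],
    profile: Profile,
    config: DetectConfig | None = None,
    backend: Callable | None = None,
) -> tuple[dict[str, CZBDomainCall], int]:
    """Expand the accepted set to a fixed point.

    Repeats {candidates = backend(accepted, database); accept those passing
    call_czb} until no new ids are accepted.  Monotone and bounded by the
    database, so termination is guaranteed.  Returns the accepted calls and
    the iteration count.
    """
    config = config or DetectConfig()
    backend = backend or kmer_backend()
    by_id = {r.id: r for r in database}
    accepted: dict[str, CZBDomainCall] = {}
    for seed in sorted(seeds, key=lambda r: r.id):
        call = call_czb(seed, profile, config)
        if call.accepted:
            accepted[seed.id] = call
    iterations = 0
    while True:
        iterations += 1
        frontier = [by_id[i] for i in sorted(accepted) if i in by_id] or list(seeds)
        candidates = backend(frontier, database)
        new_ids = sorted(candidates - set(accepted))
        grew = False
        for cid in new_ids:
            call = call_czb(by_id[cid], profile, config)
            if call.accepted:
                accepted[cid] = call
                grew = True
        if not grew:
            break
    return accepted, iterations


def calls_to_frame(calls: Iterable[CZBDomainCall]):
    """Tabulate calls for the scan TSV output."""
    import pandas as pd

    rows = []
    for c in calls:
        rows.append(
            dict(
                protein_id=c.protein_id,
                start=c.region[0],
                end=c.region[1],
                cys_position=c.cys_position if c.cys_position is not None else -1,
                core=c.core, motif=c.motif, coverage=c.coverage,
                alignment=c.alignment,
                score=(c.profile_score if c.profile_score > NEG_INF else float("nan")),
                accepted=c.accepted, flagged=c.flagged,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "start", "end", "cys_position", "core", "motif",
            "coverage", "alignment", "score", "accepted", "flagged",
        ],
    )
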