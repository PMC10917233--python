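"""Donor pseudogene nomination by seeded local alignment.

The external seeded-search binary used historically for this step is
replaced by an in-package equivalent: donors are tiled into exact k-mers
(default length 6, step 1); any donor sharing a k-mer with the query is
gap-extended with a Smith-Waterman-style local alignment, and hits below
the minimum score are discarded.  Queries shorter than the seed length
fall back to exhaustive local alignment of every donor.  Forward strand
only: V-region amplicons are assumed sense-oriented.

Hits are ranked by identity (matches / alignment columns), ties broken by
raw score then donor name, so permuting the library never changes the
nominated donor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .event_detection import Params, _aligner
from .germline_io import NamedSequence


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.arange(len(b) + 1, dtype=np.int64)
    idx = np.arange(len(b) + 1, dtype=np.int64)
    for i, ca in enumerate(a.encode("ascii"), start=1):
        cur = np.empty_like(prev)
        cur[0] = i
        cur[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (bv != ca))
        # insertion pass: cur[j] = min(cur[j], cur[j-1] + 1) via prefix min
        cur = np.minimum.accumulate(cur - idx) + idx
        prev = cur
    return int(prev[-1])


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a query against a donor pseudogene.

    Coordinates are 1-based inclusive; ``blocks`` holds the aligned
    (query, donor) block pairs as 0-based half-open ranges for interval
    projection.
    """

    donor: str
    query_start: int
    query_end: int
    donor_start: int
    donor_end: int
    score: float
    matches: int
    mismatches: int
    gaps: int
    blocks: tuple[tuple[int, int, int, int], ...]

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gaps

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    def project_query_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """Map a 1-based query interval onto donor coordinates through the hit."""
        lo, hi = None, None
        for qs, qe, ds, de in self.blocks:
            a = max(start - 1, qs)
            b = min(end, qe)
            if a < b:
                d0 = ds + (a - qs)
                d1 = ds + (b - qs)
                lo = d0 if lo is None else min(lo, d0)
                hi = d1 if hi is None else max(hi, d1)
        if lo is None:
            return None
        return (lo + 1, hi)


@dataclass(frozen=True)
class DonorAssignment:
    """The nominated donor for one candidate event."""

    donor: str | None
    levenshtein: int
    match_status: str  # 'optimal' | 'suboptimal' | 'unmatched'
    co_best: tuple[str, ...] = ()
    source_set: str | None = None  # 'event' | 'full_length' | 'strict_event'
    donor_start: int | None = None
    donor_end: int | None = None

    def __post_init__(self) -> None:
        if (self.donor is None) != (self.match_status == "unmatched"):
            raise ValueError("donor must be absent iff match_status is 'unmatched'")


class SeedIndex:
    """Exact k-mer index over the donor library (forward strand)."""

    def __init__(self, library: Sequence[NamedSequence], seed_len: int, seed_step: int = 1):
        if not library:
            raise ValueError("empty donor library")
        self.seed_len = seed_len
        self.library = {p.name: p.seq for p in library}
        self._index: dict[str, set[str]] = {}
        for p in library:
            for i in range(0, len(p.seq) - seed_len + 1, seed_step):
                self._index.setdefault(p.seq[i : i + seed_len], set()).add(p.name)

    def candidate_donors(self, query: str) -> list[str]:
        k = self.seed_len
        names: set[str] = set()
        for i in range(len(query) - k + 1):
            names |= self._index.get(query[i : i + k], set())
        return sorted(names)


def _score_threshold(params: Params) -> float:
    # min_local_score is on a "matching bases" scale; convert to raw score.
    return params.min_local_score * params.align_match


def _align_local(query: str, donor: NamedSequence, params: Params) -> AlignmentHit | None:
    aligner = _aligner(params, "local")
    alignments = aligner.align(donor.seq, query)
    try:
        aln = next(iter(alignments))
    except (StopIteration, IndexError):
        return None
    if aln.score <= 0:
        return None
    d_blocks, q_blocks = aln.aligned
    if len(d_blocks) == 0:
        return None
    counts = aln.counts()
    blocks = tuple(
        (int(qb[0]), int(qb[1]), int(db[0]), int(db[1]))
        for db, qb in zip(d_blocks, q_blocks)
    )
    return AlignmentHit(
        donor=donor.name,
        query_start=int(q_blocks[0][0]) + 1,
        query_end=int(q_blocks[-1][1]),
        donor_start=int(d_blocks[0][0]) + 1,
        donor_end=int(d_blocks[-1][1]),
        score=float(aln.score),
        matches=int(counts.identities),
        mismatches=int(counts.mismatches),
        gaps=int(counts.gaps),
        blocks=blocks,
    )


def local_search(
    query: str,
    library: Sequence[NamedSequence],
    params: Params | None = None,
    index: SeedIndex | None = None,
) -> list[AlignmentHit]:
    """Seeded local search of a query against the donor library.

    Returns score-filtered hits sorted by identity desc, then score desc,
    then donor name asc.  One (best) hit per donor is reported.
    """
    if params is None:
        params = Params()
    if not library:
        raise ValueError("empty donor library")
    if not query:
        return []
    by_name = {p.name: p for p in library}
    if len(query) >= params.seed_len:
        if index is None:
            index = SeedIndex(library, params.seed_len, params.seed_step)
        candidates = index.candidate_donors(query)
    else:
        candidates = sorted(by_name)  # exhaustive fallback for tiny queries
    threshold = _score_threshold(params)
    hits = []
    for name in candidates:
        hit = _align_local(query, by_name[name], params)
        if hit is not None and hit.score >= threshold:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.identity, -h.score, h.donor))
    return hits


def _padded_donor_segment(hit: AlignmentHit, donor_seq: str, query_len: int) -> tuple[int, int]:
    """Donor interval for the whole query: hit interval padded by the
    unaligned query prefix/suffix, clipped at the donor ends (1-based)."""
    lo = max(1, hit.donor_start - (hit.query_start - 1))
    hi = min(len(donor_seq), hit.donor_end + (query_len - hit.query_end))
    return lo, hi


@dataclass(frozen=True)
class DonorCandidate:
    """A donor option for an event, with the event-specific edit distance."""

    donor: str
    identity: float
    score: float
    levenshtein: int
    donor_start: int
    donor_end: int


def candidates_from_event_hits(
    segment: str,
    hits: Iterable[AlignmentHit],
    library_by_name: Mapping[str, str],
) -> list[DonorCandidate]:
    """Donor candidates when the query was the event segment itself."""
    out = []
    for h in hits:
        lo, hi = _padded_donor_segment(h, library_by_name[h.donor], len(segment))
        donor_seg = library_by_name[h.donor][lo - 1 : hi]
        out.append(
            DonorCandidate(
                donor=h.donor,
                identity=h.identity,
                score=h.score,
                levenshtein=levenshtein(segment, donor_seg),
                donor_start=lo,
                donor_end=hi,
            )
        )
    return out


def candidates_from_full_length_hits(
    segment: str,
    obs_interval: tuple[int, int],
    hits: Iterable[AlignmentHit],
    library_by_name: Mapping[str, str],
) -> list[DonorCandidate]:
    """Donor candidates from full-length-sequence hits, restricted to the event.

    The event's observed interval is projected through each hit onto donor
    coordinates; hits not covering the event are skipped.  Identity is
    recomputed on the event segment (edit-distance based) so short events
    inside long full-length hits are ranked on local, not global, fit.
    """
    out = []
    for h in hits:
        proj = h.project_query_interval(*obs_interval)
        if proj is None:
            continue
        donor_seg = library_by_name[h.donor][proj[0] - 1 : proj[1]]
        if not donor_seg:
            continue
        dist = levenshtein(segment, donor_seg)
        width = max(len(segment), len(donor_seg))
        out.append(
            DonorCandidate(
                donor=h.donor,
                identity=1.0 - dist / width if width else 0.0,
                score=h.score,
                levenshtein=dist,
                donor_start=proj[0],
                donor_end=proj[1],
            )
        )
    return out


def is_adequate(assignment: DonorAssignment, width: int, params: Params) -> bool:
    """Adequacy bound: event-specific edit distance at most ratio * width."""
    return assignment.levenshtein <= params.suboptimal_ratio * width


def choose_donor(
    candidates: Sequence[DonorCandidate],
    width: int,
    params: Params,
    source_set: str,
) -> DonorAssignment | None:
    """Pick the best-identity candidate among the donor options for an event.

    ``match_status`` is 'optimal' when the edit distance satisfies the
    adequacy bound (at most ``suboptimal_ratio * width``) and 'suboptimal'
    otherwise; the caller decides whether a suboptimal assignment triggers
    a strict-definition re-search or falls through to the next alignment
    set.  Returns None when there are no candidates at all.
    """
    if not candidates:
        return None
    ranked = sorted(candidates, key=lambda c: (-c.identity, -c.score, c.donor))
    best = ranked[0]
    co_best = tuple(
        c.donor
        for c in ranked[1:]
        if abs(c.identity - best.identity) < 1e-9 and c.levenshtein == best.levenshtein
    )
    assignment = DonorAssignment(
        donor=best.donor,
        levenshtein=best.levenshtein,
        match_status="optimal",
        co_best=co_best,
        source_set=source_set,
        donor_start=best.donor_start,
        donor_end=best.donor_end,
    )
    if not is_adequate(assignment, width, params):
        assignment = DonorAssignment(
            donor=best.donor,
            levenshtein=best.levenshtein,
            match_status="suboptimal",
            co_best=co_best,
            source_set=source_set,
            donor_start=best.donor_start,
            donor_end=best.donor_end,
        )
    return assignment
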