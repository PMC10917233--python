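"""Event refinement: prune/merge, min/max lengths, flank and motif context.

A detected event has two extents.  The *min* interval is bounded by
mismatches against the functional allele.  The *max* interval additionally
absorbs the flanking sequence on either side over which the functional
allele and the nominated donor are 100% identical — conversion there would
be silent, so the true tract may extend that far.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .donor_search import DonorAssignment, levenshtein
from .event_detection import PairwiseAlignment, Params, align_global
from .germline_io import NamedSequence, ReferenceSet


@dataclass(frozen=True)
class AnnotatedEvent:
    """A fully annotated gene conversion event on functional coordinates."""

    min_start: int
    min_end: int
    max_start: int
    max_end: int
    donor: str | None
    levenshtein: int
    match_status: str  # 'optimal' | 'suboptimal' | 'unmatched'
    flank5: str = ""
    flank3: str = ""
    aid_distance_5prime: int | None = None
    introduces_new_hotspot: bool = False
    identical_flank_5len: int = 0
    identical_flank_3len: int = 0
    definition: str = "loose"
    co_best: tuple[str, ...] = ()
    source_set: str | None = None
    obs_start: int | None = None
    obs_end: int | None = None
    suboptimal_parent: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (self.max_start <= self.min_start <= self.min_end <= self.max_end):
            raise ValueError("max interval must contain min interval")

    @property
    def span(self) -> int:
        return self.min_end - self.min_start + 1


class DonorProjection:
    """Per-donor global alignments to the functional allele.

    Lets every functional position be queried for the donor base aligned
    to it, which drives max-extension and identical-stretch merging.
    Donor-side insertions are invisible to these queries; agreement is
    column-wise on functional positions.
    """

    def __init__(self, refset: ReferenceSet, params: Params | None = None):
        self.refset = refset
        self.params = params or Params()
        self.functional = refset.functional.seq
        self._char: dict[str, list[str | None]] = {}
        self._pos: dict[str, list[int | None]] = {}

    def _ensure(self, donor: str) -> None:
        if donor in self._char:
            return
        seq = self.refset.pseudogene(donor).seq
        aln = align_global(seq, self.functional, self.params)
        n = len(self.functional)
        chars: list[str | None] = [None] * (n + 1)
        poss: list[int | None] = [None] * (n + 1)
        for c in range(aln.n_columns):
            fp = aln.func_pos[c]
            if fp and aln.obs_pos[c]:
                chars[fp] = aln.observed_aln[c]
                poss[fp] = aln.obs_pos[c]
        self._char[donor] = chars
        self._pos[donor] = poss

    def donor_char(self, donor: str, position: int) -> str | None:
        self._ensure(donor)
        return self._char[donor][position]

    def donor_position(self, donor: str, position: int) -> int | None:
        self._ensure(donor)
        return self._pos[donor][position]

    def agrees(self, donor: str, position: int) -> bool:
        """True iff the donor base aligned to this functional position equals it."""
        ch = self.donor_char(donor, position)
        return ch is not None and ch == self.functional[position - 1]

    def segment(self, donor: str, start: int, end: int) -> str:
        """Donor bases aligned to functional positions [start, end] (gaps dropped)."""
        self._ensure(donor)
        return "".join(
            ch for p in range(start, end + 1) if (ch := self._char[donor][p]) is not None
        )


def prune_merge(
    events: Sequence[AnnotatedEvent],
    projection: DonorProjection,
    observed: str,
    obs_aln: PairwiseAlignment,
) -> list[AnnotatedEvent]:
    """Merge adjacent same-donor events separated by functional==donor sequence.

    The intervening functional stretch must be identical, position by
    position, to the donor bases aligned across it.  The merged event's
    edit distance is recomputed on the merged observed segment.  Idempotent.
    """
    if not events:
        return []
    ordered = sorted(events, key=lambda e: (e.min_start, e.min_end))
    merged = [ordered[0]]
    for ev in ordered[1:]:
        prev = merged[-1]
        if (
            prev.donor is not None
            and ev.donor == prev.donor
            and ev.min_start > prev.min_end
            and all(
                projection.agrees(prev.donor, p)
                for p in range(prev.min_end + 1, ev.min_start)
            )
        ):
            seg = obs_aln.observed_segment(observed, prev.min_start, ev.min_end)
            donor_seg = projection.segment(prev.donor, prev.min_start, ev.min_end)
            obs_iv = obs_aln.observed_interval(prev.min_start, ev.min_end)
            merged[-1] = replace(
                prev,
                min_end=ev.min_end,
                max_end=ev.min_end,
                max_start=prev.min_start,
                levenshtein=levenshtein(seg, donor_seg),
                match_status="optimal"
                if prev.match_status == "optimal" and ev.match_status == "optimal"
                else "suboptimal",
                obs_start=obs_iv[0] if obs_iv else None,
                obs_end=obs_iv[1] if obs_iv else None,
            )
        else:
            merged.append(ev)
    return merged


def extend_max(
    event: AnnotatedEvent, functional: str, projection: DonorProjection
) -> AnnotatedEvent:
    """Grow the max interval outward while functional and donor agree."""
    if event.donor is None:
        return replace(
            event,
            max_start=event.min_start,
            max_end=event.min_end,
            identical_flank_5len=0,
            identical_flank_3len=0,
        )
    start = event.min_start
    while start > 1 and projection.agrees(event.donor, start - 1):
        start -= 1
    end = event.min_end
    while end < len(functional) and projection.agrees(event.donor, end + 1):
        end += 1
    return replace(
        event,
        max_start=start,
        max_end=end,
        identical_flank_5len=event.min_start - start,
        identical_flank_3len=end - event.min_end,
    )


def flank_context(
    event: AnnotatedEvent, functional: str, flank_len: int = 10
) -> tuple[str, str]:
    """10 nt of functional-allele context 5' and 3' of the min interval."""
    f5 = functional[max(0, event.min_start - 1 - flank_len) : event.min_start - 1]
    f3 = functional[event.min_end : event.min_end + flank_len]
    return f5, f3


def motif_positions(sequence: str, motifs: Iterable[str]) -> list[int]:
    """Sorted 1-based start positions of any motif occurrence (forward strand)."""
    motifs = set(motifs)
    if not motifs:
        return []
    k = len(next(iter(motifs)))
    return [
        i + 1 for i in range(len(sequence) - k + 1) if sequence[i : i + k] in motifs
    ]


def aid_distance(
    position: int, functional: str, motifs: Iterable[str] = None
) -> int | None:
    """Distance from a position to the nearest AID hotspot motif 5' of it.

    Measured from the motif's 3'-most base: 0 when the position immediately
    follows a motif.  None when no motif lies entirely 5' of the position.
    """
    if motifs is None:
        motifs = Params().aid_motifs
    best: int | None = None
    for start in motif_positions(functional, motifs):
        end = start + 2  # trinucleotide 3' base
        if end < position:
            d = position - end - 1
            if best is None or d < best:
                best = d
    return best


def aid_distance_for_event(
    event: AnnotatedEvent,
    functional: str,
    motifs: Iterable[str],
    definition: str = "min",
) -> int | None:
    pos = event.min_start if definition == "min" else event.max_start
    return aid_distance(pos, functional, motifs)


def introduces_new_hotspot(
    event: AnnotatedEvent,
    functional: str,
    observed: str,
    obs_aln: PairwiseAlignment,
    motifs: Iterable[str] = None,
    pad: int = 2,
) -> bool:
    """True iff the converted window gains an AID motif occurrence.

    The window is the min interval padded by ``pad`` nt (default 2, so
    motifs straddling the event edge are seen); a motif counts as gained
    when it occurs more often in the observed window than in the matching
    functional window.
    """
    if motifs is None:
        motifs = Params().aid_motifs
    lo = max(1, event.min_start - pad)
    hi = min(len(functional), event.min_end + pad)
    func_window = functional[lo - 1 : hi]
    obs_window = obs_aln.observed_segment(observed, lo, hi)
    for m in set(motifs):
        if obs_window.count(m) > func_window.count(m):
            return True
    return False


def annotate_context(
    events: Sequence[AnnotatedEvent],
    functional: str,
    observed: str,
    obs_aln: PairwiseAlignment,
    params: Params,
) -> list[AnnotatedEvent]:
    """Attach flank, AID-distance and new-hotspot annotations to events."""
    out = []
    for ev in events:
        f5, f3 = flank_context(ev, functional, params.flank_len)
        out.append(
            replace(
                ev,
                flank5=f5,
                flank3=f3,
                aid_distance_5prime=aid_distance(ev.min_start, functional, params.aid_motifs),
                introduces_new_hotspot=introduces_new_hotspot(
                    ev, functional, observed, obs_aln, params.aid_motifs, params.new_hotspot_pad
                ),
            )
        )
    return out
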