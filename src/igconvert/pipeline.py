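"""End-to-end per-sequence annotation.

For each observed sequence: global alignment to the functional allele,
loose/strict candidate detection, donor nomination through three alignment
sets — (a) loose-event queries, (b) the full-length observed sequence,
(c) strict-event queries — suboptimal-match rescue via strict sub-events,
identical-stretch pruning, max-extension, and context annotation.
"""

from __future__ import annotations

from typing import Sequence

from . import donor_search as ds
from .donor_search import DonorAssignment, SeedIndex
from .event_detection import (
    CandidateEvent,
    PairwiseAlignment,
    Params,
    align_global,
    detect_candidates,
)
from .germline_io import ReferenceSet, RepertoireRecord
from .refine_annotate import (
    AnnotatedEvent,
    DonorProjection,
    annotate_context,
    extend_max,
    prune_merge,
)


class Annotator:
    """Reusable annotation engine for one reference set + parameter set."""

    def __init__(self, refset: ReferenceSet, params: Params | None = None):
        self.refset = refset
        self.params = params or Params()
        self.functional = refset.functional.seq
        self.library = list(refset.pseudogenes)
        self.library_by_name = {p.name: p.seq for p in self.library}
        self.seed_index = SeedIndex(self.library, self.params.seed_len, self.params.seed_step)
        self.projection = DonorProjection(refset, self.params)

    # -- donor assignment -------------------------------------------------

    def _search(self, query: str) -> list[ds.AlignmentHit]:
        if not query:
            return []
        return ds.local_search(query, self.library, self.params, self.seed_index)

    def _assign(
        self,
        event: CandidateEvent,
        aln: PairwiseAlignment,
        observed: str,
        full_hits: list[ds.AlignmentHit],
        source_set: str,
    ) -> DonorAssignment | None:
        """Best assignment from the event's own query, then full-length hits."""
        segment = aln.observed_segment(observed, event.start, event.end)
        width = event.span
        best: DonorAssignment | None = None
        cands = ds.candidates_from_event_hits(
            segment, self._search(segment), self.library_by_name
        )
        asg = ds.choose_donor(cands, width, self.params, source_set)
        if asg is not None:
            if asg.match_status == "optimal":
                return asg
            best = asg
        obs_iv = aln.observed_interval(event.start, event.end)
        if obs_iv is not None:
            cands = ds.candidates_from_full_length_hits(
                segment, obs_iv, full_hits, self.library_by_name
            )
            asg = ds.choose_donor(cands, width, self.params, "full_length")
            if asg is not None:
                if asg.match_status == "optimal":
                    return asg
                if best is None or asg.levenshtein < best.levenshtein:
                    best = asg
        return best

    def _to_annotated(
        self,
        event: CandidateEvent,
        assignment: DonorAssignment | None,
        aln: PairwiseAlignment,
        observed: str,
        parent: tuple[int, int] | None = None,
    ) -> AnnotatedEvent:
        obs_iv = aln.observed_interval(event.start, event.end)
        segment = aln.observed_segment(observed, event.start, event.end)
        if assignment is None:
            return AnnotatedEvent(
                min_start=event.start,
                min_end=event.end,
                max_start=event.start,
                max_end=event.end,
                donor=None,
                levenshtein=len(segment),
                match_status="unmatched",
                definition=event.definition,
                obs_start=obs_iv[0] if obs_iv else None,
                obs_end=obs_iv[1] if obs_iv else None,
                suboptimal_parent=parent,
            )
        return AnnotatedEvent(
            min_start=event.start,
            min_end=event.end,
            max_start=event.start,
            max_end=event.end,
            donor=assignment.donor,
            levenshtein=assignment.levenshtein,
            match_status=assignment.match_status,
            definition=event.definition,
            co_best=assignment.co_best,
            source_set=assignment.source_set,
            obs_start=obs_iv[0] if obs_iv else None,
            obs_end=obs_iv[1] if obs_iv else None,
            suboptimal_parent=parent,
        )

    def annotate_sequence(self, observed: str) -> list[AnnotatedEvent]:
        """Annotate one observed sequence; returns final events sorted by start."""
        params = self.params
        aln = align_global(observed, self.functional, params)
        cands = detect_candidates(observed, self.functional, params, aln)
        full_hits = self._search(observed)

        final: list[AnnotatedEvent] = []
        for loose in cands["loose"]:
            asg = self._assign(loose, aln, observed, full_hits, "event")
            sub = [
                s for s in cands["strict"] if loose.start <= s.start and s.end <= loose.end
            ]
            needs_rescue = (
                (asg is None or asg.match_status == "suboptimal")
                and loose.span > params.suboptimal_min_width
                and len(sub) > 1
            )
            if needs_rescue:
                # suboptimal loose parent: report its strict sub-events instead
                parent = (loose.start, loose.end)
                for s in sub:
                    sub_asg = self._assign(s, aln, observed, full_hits, "strict_event")
                    if sub_asg is not None and sub_asg.match_status == "suboptimal":
                        sub_asg = None
                    final.append(self._to_annotated(s, sub_asg, aln, observed, parent))
            else:
                if asg is not None and asg.match_status == "suboptimal" and loose.span <= params.suboptimal_min_width:
                    # small events are never flagged suboptimal: accept or reject
                    asg = None
                final.append(self._to_annotated(loose, asg, aln, observed))

        final = prune_merge(final, self.projection, observed, aln)
        final = [extend_max(ev, self.functional, self.projection) for ev in final]
        final = annotate_context(final, self.functional, observed, aln, params)
        return sorted(final, key=lambda e: (e.min_start, e.min_end))

    def annotate_records(self, records: Sequence[RepertoireRecord]) -> list[RepertoireRecord]:
        for rec in records:
            rec.events = self.annotate_sequence(rec.seq)
        return list(records)


def annotate_repertoire(
    refset: ReferenceSet,
    records: Sequence[RepertoireRecord],
    params: Params | None = None,
) -> list[RepertoireRecord]:
    """Convenience wrapper: annotate every record in place and return them."""
    return Annotator(refset, params).annotate_records(records)
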