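"""Candidate conversion-event detection.

Each observed sequence is globally aligned to the functional allele,
maximal mismatch stretches are extracted on functional coordinates, and
stretches are merged under a loose (default 6 nt) and a strict (default
3 nt) inter-stretch window into candidate gene conversion events.  Events
spanning fewer than ``min_event_span`` nucleotides (default 3) are
discarded after merging, so isolated 1-2 nt substitutions — point-mutation
noise — never become events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_AID_MOTIFS = ("AGC", "AGT", "GGC", "GGT", "TGC", "AAC", "TAC")


@dataclass(frozen=True)
class Params:
    """All tunable thresholds of the pipeline.

    The merge windows, minimum event span, seeded-search settings,
    suboptimal-match rule, flank length, AID motif list and preferred-donor
    threshold follow the published defaults; alignment scores are not
    published and the defaults below are recorded in every output header.
    """

    merge_window_loose: int = 6
    merge_window_strict: int = 3
    min_event_span: int = 3
    seed_len: int = 6
    seed_step: int = 1
    min_local_score: float = 20.0
    suboptimal_ratio: float = 0.5
    suboptimal_min_width: int = 10
    flank_len: int = 10
    aid_motifs: tuple[str, ...] = DEFAULT_AID_MOTIFS
    preferred_threshold: float = 2.0
    new_hotspot_pad: int = 2
    align_match: float = 2.0
    align_mismatch: float = -3.0
    align_gap_open: float = -5.0
    align_gap_extend: float = -2.0

    def __post_init__(self) -> None:
        if self.merge_window_strict > self.merge_window_loose:
            raise ValueError("merge_window_strict must be <= merge_window_loose")
        if self.min_event_span < 1:
            raise ValueError("min_event_span must be >= 1")
        if self.seed_len < 1 or self.seed_step < 1:
            raise ValueError("seed_len and seed_step must be >= 1")
        if self.merge_window_strict < 0:
            raise ValueError("merge windows must be >= 0")
        for m in self.aid_motifs:
            if len(m) != 3 or set(m) - set("ACGT"):
                raise ValueError(f"AID motif must be a DNA trinucleotide: {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Params":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        if "aid_motifs" in data:
            data["aid_motifs"] = tuple(str(m).upper() for m in data["aid_motifs"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["aid_motifs"] = list(data["aid_motifs"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def with_(self, **kwargs) -> "Params":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global observed-vs-functional alignment with column position maps.

    ``func_pos[c]`` / ``obs_pos[c]`` give the 1-based position consumed at
    column ``c`` on the functional / observed sequence, or 0 for a gap.
    """

    functional_aln: str
    observed_aln: str
    func_pos: tuple[int, ...]
    obs_pos: tuple[int, ...]
    score: float

    def __post_init__(self) -> None:
        n = len(self.functional_aln)
        if len(self.observed_aln) != n or len(self.func_pos) != n or len(self.obs_pos) != n:
            raise ValueError("alignment rows and position maps must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.functional_aln)

    def observed_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """Observed-coordinate interval covered by functional positions [start, end].

        Includes insertion columns internal to the interval.  Returns None
        when the interval is entirely deleted in the observed sequence.
        """
        cols = [c for c in range(self.n_columns) if start <= self.func_pos[c] <= end]
        if not cols:
            return None
        obs = [self.obs_pos[c] for c in range(cols[0], cols[-1] + 1) if self.obs_pos[c]]
        if not obs:
            return None
        return (min(obs), max(obs))

    def observed_segment(self, observed: str, start: int, end: int) -> str:
        """Observed subsequence for functional interval [start, end] ('' if deleted)."""
        iv = self.observed_interval(start, end)
        if iv is None:
            return ""
        return observed[iv[0] - 1 : iv[1]]


@dataclass(frozen=True)
class Stretch:
    """Maximal run of non-matching alignment columns, on functional coords."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid stretch ({self.start}, {self.end})")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CandidateEvent:
    """Merged mismatch region, before donor assignment."""

    start: int
    end: int
    stretches: tuple[Stretch, ...]
    definition: str  # 'strict' | 'loose' | 'full_length'

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _substitution_matrix(params: Params) -> substitution_matrices.Array:
    # N in reads is scored neutrally so ambiguity never distorts the alignment;
    # stretch-finding additionally treats observed N as a match.
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                mat[a, b] = 0.0
            else:
                mat[a, b] = params.align_match if a == b else params.align_mismatch
    return mat


def _aligner(params: Params, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _substitution_matrix(params)
    # Affine gaps: a length-L gap costs open + L*extend.
    aligner.open_gap_score = params.align_gap_open + params.align_gap_extend
    aligner.extend_gap_score = params.align_gap_extend
    return aligner


def align_global(observed: str, functional: str, params: Params | None = None) -> PairwiseAlignment:
    """End-to-end alignment of an observed sequence to the functional allele.

    Deterministic for fixed inputs and scores: of the co-optimal alignments
    the aligner's first traceback is taken.
    """
    if params is None:
        params = Params()
    if not observed or not functional:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(params, "global")
    aln = next(iter(aligner.align(functional, observed)))
    func_row, obs_row = str(aln[0]), str(aln[1])
    func_pos, obs_pos = [], []
    fp = op = 0
    for fc, oc in zip(func_row, obs_row):
        if fc != "-":
            fp += 1
        if oc != "-":
            op += 1
        func_pos.append(fp if fc != "-" else 0)
        obs_pos.append(op if oc != "-" else 0)
    return PairwiseAlignment(
        functional_aln=func_row,
        observed_aln=obs_row,
        func_pos=tuple(func_pos),
        obs_pos=tuple(obs_pos),
        score=float(aln.score),
    )


def _column_matches(fc: str, oc: str) -> bool:
    if fc == "-" or oc == "-":
        return False
    return fc == oc or oc == "N"


def mismatch_stretches(aln: PairwiseAlignment) -> list[Stretch]:
    """Maximal runs of substitution/indel columns projected to functional coords.

    An observed N counts as a match (never creates an event).  A pure
    insertion between functional positions p and p+1 is recorded as the
    flanking interval (p, p+1), clipped at the allele ends.
    """
    runs: list[tuple[int, int]] = []  # column intervals
    in_run = False
    for c in range(aln.n_columns):
        mismatch = not _column_matches(aln.functional_aln[c], aln.observed_aln[c])
        if mismatch and not in_run:
            runs.append((c, c))
            in_run = True
        elif mismatch:
            runs[-1] = (runs[-1][0], c)
        else:
            in_run = False

    func_len = max(aln.func_pos) if aln.func_pos else 0
    stretches: list[Stretch] = []
    for c0, c1 in runs:
        fps = [aln.func_pos[c] for c in range(c0, c1 + 1) if aln.func_pos[c]]
        if fps:
            start, end = min(fps), max(fps)
        else:
            # pure insertion: flanking functional positions
            prev = max((aln.func_pos[c] for c in range(c0)), default=0)
            start = max(prev, 1)
            end = min(prev + 1, func_len) if func_len else start
            end = max(end, start)
        if stretches and start <= stretches[-1].end:
            merged = Stretch(stretches[-1].start, max(stretches[-1].end, end))
            stretches[-1] = merged
        else:
            stretches.append(Stretch(start, end))
    return stretches


def merge_stretches(
    stretches: Iterable[Stretch],
    window: int,
    min_event_span: int,
    definition: str = "loose",
) -> list[CandidateEvent]:
    """Merge stretches within ``window`` intervening positions; filter by span.

    The gap between consecutive stretches is the number of functional
    positions strictly between them (next.start - prev.end - 1).  The
    minimum-span filter is applied after merging, so interspersed short
    mismatch runs can still combine into a reportable event.
    """
    groups: list[list[Stretch]] = []
    for s in sorted(stretches, key=lambda s: (s.start, s.end)):
        if groups and s.start - groups[-1][-1].end - 1 <= window:
            groups[-1].append(s)
        else:
            groups.append([s])
    events = []
    for grp in groups:
        start, end = grp[0].start, grp[-1].end
        if end - start + 1 >= min_event_span:
            events.append(CandidateEvent(start, end, tuple(grp), definition))
    return events


def detect_candidates(
    observed: str,
    functional: str,
    params: Params | None = None,
    aln: PairwiseAlignment | None = None,
) -> dict[str, list[CandidateEvent]]:
    """Loose and strict candidate events from a single shared alignment."""
    if params is None:
        params = Params()
    if aln is None:
        aln = align_global(observed, functional, params)
    stretches = mismatch_stretches(aln)
    return {
        "loose": merge_stretches(
            stretches, params.merge_window_loose, params.min_event_span, "loose"
        ),
        "strict": merge_stretches(
            stretches, params.merge_window_strict, params.min_event_span, "strict"
        ),
    }
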