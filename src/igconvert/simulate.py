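"""Synthetic repertoire generation with known implanted conversion tracts.

Sequences are built from the functional allele by replacing sampled tracts
with the donor pseudogene's aligned segment, then sprinkling uniform
per-site point mutations (SHM-like noise) and, optionally, simulating
template-jumping chimeras.  Ground truth is recorded per sequence so any
downstream caller can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .event_detection import Params
from .germline_io import NamedSequence, ReferenceSet, RepertoireRecord
from .refine_annotate import DonorProjection, motif_positions

BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the repertoire simulator; the seed fixes every draw."""

    n_sequences: int = 100
    events_per_sequence_mean: float = 2.0
    events_min: int = 0
    events_max: int | None = None
    tract_len_min: int = 10
    tract_len_max: int = 300  # conversion tracts can run to ~300 nt
    donor_weights: Mapping[str, float] | None = None
    shm_rate: float = 0.0
    aid_seeded: bool = False
    aid_seed_max_offset: int = 3
    template_jump_rate: float = 0.0
    min_tract_diffs: int = 0
    min_tract_gap: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.shm_rate, self.template_jump_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.tract_len_min < 3:
            raise ValueError("tract lengths must be >= 3")
        if self.tract_len_max < self.tract_len_min:
            raise ValueError("tract_len_max must be >= tract_len_min")
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")


@dataclass(frozen=True)
class Tract:
    donor: str
    start: int  # functional coords, 1-based inclusive
    end: int
    donor_start: int
    donor_end: int


@dataclass
class TruthRecord:
    sequence_id: str
    tracts: list[Tract] = field(default_factory=list)
    shm_positions: list[int] = field(default_factory=list)  # on the emitted sequence
    jumped: bool = False


def make_reference_set(
    n_donors: int = 10,
    length: int = 300,
    divergence: float = 0.2,
    seed: int = 0,
    distances_kb: bool = False,
) -> ReferenceSet:
    """Random functional allele plus donors mutated away from it.

    ``divergence`` is the per-site substitution probability used to derive
    each donor, giving pseudogene-like libraries at ~80-90% identity when
    left near the default.
    """
    rng = np.random.default_rng(seed)
    functional = "".join(rng.choice(list(BASES), size=length))
    donors = []
    for i in range(n_donors):
        seq = list(functional)
        for p in range(length):
            if rng.random() < divergence:
                seq[p] = rng.choice([b for b in BASES if b != seq[p]])
        donors.append(NamedSequence(f"PV{i + 1:02d}", "".join(seq)))
    distances = (
        {d.name: float(5 * (i + 1)) for i, d in enumerate(donors)} if distances_kb else None
    )
    return ReferenceSet(
        functional=NamedSequence("FUNC", functional),
        pseudogenes=tuple(donors),
        distances_kb=distances,
    )


def _sample_tract(
    rng: np.random.Generator,
    functional: str,
    donors: Sequence[str],
    weights: np.ndarray,
    projection: DonorProjection,
    cfg: SimConfig,
    occupied: list[tuple[int, int]],
    aid_starts: Sequence[int],
    max_attempts: int = 200,
) -> Tract | None:
    L = len(functional)
    for _ in range(max_attempts):
        length = int(rng.integers(cfg.tract_len_min, min(cfg.tract_len_max, L) + 1))
        if cfg.aid_seeded and aid_starts:
            start = int(rng.choice(aid_starts))
        else:
            start = int(rng.integers(1, L - length + 2))
        end = start + length - 1
        if end > L:
            continue
        if any(start - cfg.min_tract_gap <= e and end + cfg.min_tract_gap >= s for s, e in occupied):
            continue
        donor = str(rng.choice(donors, p=weights))
        seg = projection.segment(donor, start, end)
        if not seg:
            continue
        if cfg.min_tract_diffs:
            diffs = sum(1 for p in range(start, end + 1) if not projection.agrees(donor, p))
            if diffs < cfg.min_tract_diffs:
                continue
        dpos = [
            dp for p in range(start, end + 1)
            if (dp := projection.donor_position(donor, p)) is not None
        ]
        return Tract(donor, start, end, min(dpos), max(dpos))
    return None


def _assemble(functional: str, tracts: Sequence[Tract], projection: DonorProjection) -> str:
    parts = []
    cursor = 1
    for t in sorted(tracts, key=lambda t: t.start):
        parts.append(functional[cursor - 1 : t.start - 1])
        parts.append(projection.segment(t.donor, t.start, t.end))
        cursor = t.end + 1
    parts.append(functional[cursor - 1 :])
    return "".join(parts)


def _apply_shm(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, list[int]]:
    if rate <= 0.0:
        return seq, []
    chars = list(seq)
    positions = []
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for p in hits:
        chars[p] = rng.choice([b for b in BASES if b != chars[p]])
        positions.append(int(p) + 1)
    return "".join(chars), positions


def simulate_repertoire(
    refset: ReferenceSet,
    cfg: SimConfig,
    params: Params | None = None,
) -> tuple[list[RepertoireRecord], list[TruthRecord]]:
    """Generate a synthetic repertoire plus its ground truth.

    Deterministic for a fixed config (the seed drives all randomness).
    Tract intervals are sampled on functional coordinates and mapped onto
    donors through the donor<->functional pairwise alignment; tracts whose
    donor projection is empty are resampled.
    """
    rng = np.random.default_rng(cfg.seed)
    functional = refset.functional.seq
    if len(functional) < cfg.tract_len_min:
        raise ValueError("functional allele shorter than the minimum tract length")
    projection = DonorProjection(refset, params or Params())
    donors = refset.pseudogene_names
    if cfg.donor_weights is not None:
        weights = np.array([cfg.donor_weights.get(d, 0.0) for d in donors], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("donor_weights assign no mass to any library donor")
    else:
        weights = np.ones(len(donors), dtype=float)
    weights = weights / weights.sum()

    aid_starts: list[int] = []
    if cfg.aid_seeded:
        p = params or Params()
        for m_start in motif_positions(functional, p.aid_motifs):
            m_end = m_start + 2
            for off in range(cfg.aid_seed_max_offset + 1):
                s = m_end + 1 + off
                if s <= len(functional):
                    aid_starts.append(s)

    records: list[RepertoireRecord] = []
    truths: list[TruthRecord] = []
    for i in range(cfg.n_sequences):
        n_events = int(rng.poisson(cfg.events_per_sequence_mean))
        n_events = max(cfg.events_min, n_events)
        if cfg.events_max is not None:
            n_events = min(cfg.events_max, n_events)
        tracts: list[Tract] = []
        occupied: list[tuple[int, int]] = []
        for _ in range(n_events):
            t = _sample_tract(
                rng, functional, donors, weights, projection, cfg, occupied, aid_starts
            )
            if t is None:
                continue
            tracts.append(t)
            occupied.append((t.start, t.end))
        seq = _assemble(functional, tracts, projection)
        seq, shm_positions = _apply_shm(rng, seq, cfg.shm_rate)
        seq_id = f"sim{i:05d}"
        records.append(RepertoireRecord(id=seq_id, seq=seq, bird="sim"))
        truths.append(TruthRecord(seq_id, sorted(tracts, key=lambda t: t.start), shm_positions))

    if cfg.template_jump_rate > 0.0:
        jump = np.flatnonzero(rng.random(cfg.n_sequences) < cfg.template_jump_rate)
        for idx in jump:
            partner = int(rng.integers(cfg.n_sequences))
            a, b = records[idx].seq, records[partner].seq
            cut = int(rng.integers(1, min(len(a), len(b))))
            records[idx].seq = a[:cut] + b[cut:]
            truths[idx].jumped = True

    return records, truths


def truth_to_frame(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Tract-level truth table; zero-tract sequences appear with empty donor."""
    rows = []
    for t in truths:
        if not t.tracts:
            rows.append(
                {
                    "sequence_id": t.sequence_id,
                    "donor": "",
                    "start": pd.NA,
                    "end": pd.NA,
                    "donor_start": pd.NA,
                    "donor_end": pd.NA,
                    "n_shm": len(t.shm_positions),
                    "jumped": t.jumped,
                }
            )
        for tr in t.tracts:
            rows.append(
                {
                    "sequence_id": t.sequence_id,
                    "donor": tr.donor,
                    "start": tr.start,
                    "end": tr.end,
                    "donor_start": tr.donor_start,
                    "donor_end": tr.donor_end,
                    "n_shm": len(t.shm_positions),
                    "jumped": t.jumped,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "donor", "start", "end", "donor_start", "donor_end", "n_shm", "jumped"],
    )


def frame_to_truths(df: pd.DataFrame) -> list[TruthRecord]:
    truths: dict[str, TruthRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["sequence_id"])
        rec = truths.setdefault(sid, TruthRecord(sid, jumped=bool(row.get("jumped", False))))
        if row["donor"] and not pd.isna(row["start"]):
            rec.tracts.append(
                Tract(
                    str(row["donor"]),
                    int(row["start"]),
                    int(row["end"]),
                    int(row["donor_start"]),
                    int(row["donor_end"]),
                )
            )
    return list(truths.values())


def score_recovery(
    truths: Sequence[TruthRecord],
    predicted: pd.DataFrame,
    overlap_frac: float = 0.5,
) -> dict:
    """Score predicted events (event-table frame) against simulated truth.

    A tract is detected when a predicted min interval on the same sequence
    overlaps at least ``overlap_frac`` of it; the best-overlapping
    prediction supplies the donor call and boundary errors.  False
    positives are counted on tract-free sequences.
    """
    truth_ids = {t.sequence_id for t in truths}
    pred_ids = set(predicted["sequence_id"].astype(str)) if len(predicted) else set()
    unknown = pred_ids - truth_ids
    if unknown:
        raise ValueError(f"predictions reference unknown sequence ids: {sorted(unknown)[:5]}")

    by_seq: dict[str, list[dict]] = {}
    for _, row in predicted.iterrows():
        by_seq.setdefault(str(row["sequence_id"]), []).append(row.to_dict())

    n_tracts = n_detected = n_donor_correct = 0
    boundary_errors: list[float] = []
    fp_counts: list[int] = []
    for t in truths:
        preds = by_seq.get(t.sequence_id, [])
        if not t.tracts:
            fp_counts.append(len(preds))
            continue
        for tr in t.tracts:
            n_tracts += 1
            tract_len = tr.end - tr.start + 1
            best, best_ov = None, 0
            for p in preds:
                ov = min(tr.end, p["min_end"]) - max(tr.start, p["min_start"]) + 1
                if ov > best_ov:
                    best, best_ov = p, ov
            if best is not None and best_ov >= overlap_frac * tract_len:
                n_detected += 1
                donor = best["donor"]
                if isinstance(donor, str) and donor == tr.donor:
                    n_donor_correct += 1
                boundary_errors.append(
                    (abs(best["min_start"] - tr.start) + abs(best["min_end"] - tr.end)) / 2.0
                )
    return {
        "n_tracts": n_tracts,
        "detection_rate": n_detected / n_tracts if n_tracts else float("nan"),
        "donor_accuracy": n_donor_correct / n_detected if n_detected else float("nan"),
        "mean_boundary_error": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
        "mean_fp_per_negative_sequence": float(np.mean(fp_counts)) if fp_counts else float("nan"),
        "n_negative_sequences": len(fp_counts),
    }
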