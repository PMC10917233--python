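"""Repertoire-level summaries of annotated gene conversion events.

Positional event maps, per-position pseudogene diversity profiles (Hill
numbers over aligned library columns), donor usage with the "preferred"
(> 2% of events in a group) rule, usage-vs-germline-distance correlation,
AID-hotspot distance distributions with a per-position baseline, and the
false-discovery control mode that swaps the donor library for same-family
alleles.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .event_detection import Params, align_global
from .germline_io import NamedSequence, ReferenceSet, RepertoireRecord
from .refine_annotate import aid_distance


# -- positional coverage --------------------------------------------------

def positional_coverage(
    records: Iterable[RepertoireRecord],
    functional_length: int,
    definition: str = "min",
    group_by: str | None = None,
) -> pd.DataFrame:
    """Per-position count of events covering each functional position.

    Returns a long table (group, position, count); group is '' when no
    grouping key is requested.  Count mass equals the sum of event spans.
    """
    if definition not in ("min", "max"):
        raise ValueError("definition must be 'min' or 'max'")
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        group = str(getattr(rec, group_by)) if group_by else ""
        arr = counts.setdefault(group, np.zeros(functional_length, dtype=np.int64))
        for ev in rec.events:
            s, e = (ev.min_start, ev.min_end) if definition == "min" else (ev.max_start, ev.max_end)
            arr[s - 1 : e] += 1
    rows = [
        {"group": g, "position": p + 1, "definition": definition, "count": int(c)}
        for g, arr in sorted(counts.items())
        for p, c in enumerate(arr)
    ]
    return pd.DataFrame(rows, columns=["group", "position", "definition", "count"])


def event_track(records: Iterable[RepertoireRecord], definition: str = "min") -> pd.DataFrame:
    """One row per event (sequence, interval, donor) for positional plotting."""
    rows = []
    for rec in records:
        for ev in rec.events:
            s, e = (ev.min_start, ev.min_end) if definition == "min" else (ev.max_start, ev.max_end)
            rows.append(
                {
                    "sequence_id": rec.id,
                    "bird": rec.bird,
                    "tissue": rec.tissue,
                    "start": s,
                    "end": e,
                    "donor": ev.donor,
                }
            )
    return pd.DataFrame(rows, columns=["sequence_id", "bird", "tissue", "start", "end", "donor"])


# -- pseudogene diversity profile -----------------------------------------

def hill_number(frequencies: Sequence[float], q: float = 1.0) -> float:
    """Hill number of order q over a frequency vector (effective symbol count)."""
    freqs = np.asarray([f for f in frequencies if f > 0], dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency vector")
    freqs = freqs / freqs.sum()
    if q == 1.0:
        return float(math.exp(-np.sum(freqs * np.log(freqs))))
    if q == 0.0:
        return float(freqs.size)
    return float(np.sum(freqs**q) ** (1.0 / (1.0 - q)))


def library_columns(refset: ReferenceSet, params: Params | None = None) -> list[list[str]]:
    """Bases of every pseudogene aligned to each functional position.

    Each pseudogene is pairwise-aligned to the functional allele and its
    bases projected onto functional coordinates; donor-gap positions are
    excluded from the column.
    """
    params = params or Params()
    functional = refset.functional.seq
    columns: list[list[str]] = [[] for _ in range(len(functional))]
    for donor in refset.pseudogenes:
        aln = align_global(donor.seq, functional, params)
        for c in range(aln.n_columns):
            fp = aln.func_pos[c]
            if fp and aln.obs_pos[c]:
                columns[fp - 1].append(aln.observed_aln[c])
    return columns


def diversity_profile(
    aligned_columns: Sequence[Sequence[str]], q: float = 1.0
) -> pd.DataFrame:
    """Per-position diversity score in [1, 4] over library columns.

    Score is the Hill number of order ``q`` (default 1: exponential of
    Shannon entropy) of the A/C/G/T frequency distribution in the column;
    1 for monomorphic columns, 4 when all four bases are equifrequent.
    Empty (all-gap) columns yield a missing score.
    """
    rows = []
    for i, col in enumerate(aligned_columns, start=1):
        bases = [b for b in col if b in "ACGT"]
        if not bases:
            rows.append({"position": i, "score": np.nan, "n_bases": 0})
            continue
        counts = Counter(bases)
        score = hill_number([counts[b] for b in "ACGT" if counts[b]], q=q)
        rows.append({"position": i, "score": score, "n_bases": len(bases)})
    return pd.DataFrame(rows, columns=["position", "score", "n_bases"])


def diversity_profile_for(refset: ReferenceSet, params: Params | None = None, q: float = 1.0) -> pd.DataFrame:
    return diversity_profile(library_columns(refset, params), q=q)


# -- pseudogene usage ------------------------------------------------------

def pseudogene_usage(
    records: Iterable[RepertoireRecord],
    group_by: str = "bird",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-group per-donor percentage of donor-assigned events.

    Unmatched events are excluded from the denominator and reported in the
    ``unmatched_events`` column.  ``preferred`` marks donors above the
    threshold in that group; ``preferred_all`` / ``preferred_any`` apply
    the rule across every / at least one group.
    """
    events: list[tuple[str, str | None]] = []
    for rec in records:
        group = str(getattr(rec, group_by)) if group_by else ""
        for ev in rec.events:
            events.append((group, ev.donor))
    if not events:
        return pd.DataFrame(
            columns=["group", "donor", "n_events", "percent", "preferred",
                     "preferred_any", "preferred_all", "unmatched_events"]
        )
    groups = sorted({g for g, _ in events})
    matched = {g: Counter() for g in groups}
    unmatched = Counter()
    for g, donor in events:
        if donor is None:
            unmatched[g] += 1
        else:
            matched[g][donor] += 1
    usable_groups = [g for g in groups if sum(matched[g].values()) > 0]
    for g in groups:
        if g not in usable_groups:
            import warnings

            warnings.warn(f"group {g!r} has no donor-assigned events; excluded")
    donors = sorted({d for g in usable_groups for d in matched[g]})
    percent: dict[tuple[str, str], float] = {}
    for g in usable_groups:
        total = sum(matched[g].values())
        for d in donors:
            percent[(g, d)] = 100.0 * matched[g][d] / total
    rows = []
    for d in donors:
        above = [percent[(g, d)] > threshold for g in usable_groups]
        for g in usable_groups:
            rows.append(
                {
                    "group": g,
                    "donor": d,
                    "n_events": matched[g][d],
                    "percent": percent[(g, d)],
                    "preferred": percent[(g, d)] > threshold,
                    "preferred_any": any(above),
                    "preferred_all": all(above),
                    "unmatched_events": unmatched[g],
                }
            )
    return pd.DataFrame(rows)


def usage_vs_distance(
    usage: pd.DataFrame, distances_kb: Mapping[str, float]
) -> tuple[pd.DataFrame, dict | None]:
    """Mean donor usage paired with germline distance, plus Spearman rank rho.

    The p-value is an exact permutation p-value for n <= 8 paired donors,
    otherwise the asymptotic value.  With fewer than 3 paired donors only
    the table is returned (correlation None).
    """
    mean_usage = usage.groupby("donor")["percent"].mean()
    rows = [
        {"donor": d, "distance_kb": distances_kb[d], "mean_percent": mean_usage[d]}
        for d in mean_usage.index
        if d in distances_kb
    ]
    table = pd.DataFrame(rows, columns=["donor", "distance_kb", "mean_percent"])
    if len(table) < 3:
        return table, None
    x = table["distance_kb"].to_numpy()
    y = table["mean_percent"].to_numpy()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho):
        rho = 0.0  # constant input: no monotone association
        pval = 1.0
    elif len(table) <= 8:
        pval = _exact_spearman_pvalue(x, y, abs(rho))
    else:
        pval = float(stats.spearmanr(x, y).pvalue)
    return table, {"spearman_rho": float(rho), "p_value": float(pval), "n": len(table)}


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray, observed_abs_rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    n = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = stats.spearmanr(x, y[list(perm)]).statistic
        if np.isnan(r):
            r = 0.0
        if abs(r) >= observed_abs_rho - 1e-12:
            count += 1
        total += 1
    return count / total


# -- AID distance distributions -------------------------------------------

def aid_distance_baseline(
    functional: str, motifs: Sequence[str]
) -> pd.DataFrame:
    """Distance to the nearest 5' AID motif for every functional position."""
    rows = []
    for pos in range(1, len(functional) + 1):
        rows.append({"position": pos, "distance": aid_distance(pos, functional, motifs)})
    return pd.DataFrame(rows)


def aid_distance_distribution(
    records: Iterable[RepertoireRecord],
    functional: str,
    motifs: Sequence[str],
    definition: str = "min",
    group_by: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent histograms of event AID distances plus the positional baseline.

    Event distances are taken from the chosen definition's start position;
    with a grouping key the per-group percent histograms are averaged.
    """
    if definition not in ("min", "max"):
        raise ValueError("definition must be 'min' or 'max'")
    per_group: dict[str, Counter] = {}
    for rec in records:
        group = str(getattr(rec, group_by)) if group_by else ""
        ctr = per_group.setdefault(group, Counter())
        for ev in rec.events:
            start = ev.min_start if definition == "min" else ev.max_start
            d = aid_distance(start, functional, motifs)
            if d is not None:
                ctr[d] += 1
    hist: Counter[int] = Counter()
    if per_group:
        all_d = sorted({d for ctr in per_group.values() for d in ctr})
        rows = []
        for d in all_d:
            pct = np.mean(
                [100.0 * ctr[d] / sum(ctr.values()) if sum(ctr.values()) else 0.0
                 for ctr in per_group.values()]
            )
            rows.append({"distance": d, "percent": float(pct)})
        event_hist = pd.DataFrame(rows, columns=["distance", "percent"])
    else:
        event_hist = pd.DataFrame(columns=["distance", "percent"])

    base = aid_distance_baseline(functional, motifs)
    base = base.dropna(subset=["distance"])
    if len(base):
        counts = base["distance"].astype(int).value_counts().sort_index()
        baseline_hist = pd.DataFrame(
            {"distance": counts.index, "percent": 100.0 * counts.values / counts.values.sum()}
        )
    else:
        baseline_hist = pd.DataFrame(columns=["distance", "percent"])
    return event_hist, baseline_hist


# -- sequence-level statistics and control mode ---------------------------

def sequence_event_stats(
    records: Sequence[RepertoireRecord], group_by: str | None = None
) -> pd.DataFrame:
    """Per-group percentages of sequences with >=1 / >=2 events and counts."""
    groups: dict[str, list[int]] = {}
    for rec in records:
        group = str(getattr(rec, group_by)) if group_by else ""
        groups.setdefault(group, []).append(len(rec.events))
    rows = []
    for g, counts in sorted(groups.items()):
        arr = np.asarray(counts)
        rows.append(
            {
                "group": g,
                "n_sequences": len(arr),
                "percent_with_event": 100.0 * np.mean(arr >= 1),
                "percent_with_multiple": 100.0 * np.mean(arr >= 2),
                "mean_events": float(arr.mean()),
                "median_events": float(np.median(arr)),
            }
        )
    return pd.DataFrame(rows)


def control_mode_rate(
    sequences: Sequence[RepertoireRecord],
    functional: NamedSequence,
    family_alleles: Sequence[NamedSequence],
    params: Params | None = None,
) -> float:
    """Fraction of sequences with >=1 event when same-family alleles act as donors.

    Implements the false-discovery control: the pipeline is run unchanged
    with the donor library replaced by same-family alleles (the assigned
    functional allele excluded).
    """
    from .pipeline import Annotator  # local import to avoid a cycle

    donors = tuple(a for a in family_alleles if a.name != functional.name)
    if not donors:
        raise ValueError("control mode requires at least one same-family allele")
    refset = ReferenceSet(functional=functional, pseudogenes=donors)
    annotator = Annotator(refset, params)
    n_with = 0
    for rec in sequences:
        if annotator.annotate_sequence(rec.seq):
            n_with += 1
    return n_with / len(sequences) if sequences else 0.0
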