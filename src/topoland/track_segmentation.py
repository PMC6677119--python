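"""Segment calling on per-residue score tracks.

Turns continuous predictor outputs (disorder, early folding, aggregation)
into discrete regions and per-protein summaries:

* IDRs — intrinsically disordered regions, runs of >= 5 residues above the
  disorder threshold; *short* 5–19 residues, *long* >= 20.  A protein is an
  IDP when merged IDRs cover >= 30% of its mature length.
* early foldons — runs of >= 5 residues of high early-folding propensity,
  read as folding-nucleation elements.
* APRs — aggregation-prone regions, with *gatekeeper* positions flanking
  them (the charged/Pro/Gly residues that suppress aggregation in vivo).

Default thresholds follow the conventions of the predictors these tracks
come from (disorder 0.5, early folding 0.163, aggregation 5.0 on a 0–100
scale); all are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_annotation import ScoreTrack, Segment

DISORDER_THRESHOLD = 0.5
EARLY_FOLDING_THRESHOLD = 0.163
AGGREGATION_THRESHOLD = 5.0
IDP_COVERAGE_THRESHOLD = 0.30
TERMINAL_WINDOW = 30  # residues defining N-/C-terminal segment position


def extract_segments(track: ScoreTrack | Sequence[float], threshold: float, min_len: int, kind: str = "IDR") -> list[Segment]:
    """Maximal runs of positions with score >= threshold, kept if long enough.

    Returns segments in left-to-right order with their mean score filled in.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    values = track.as_array() if isinstance(track, ScoreTrack) else np.asarray(track, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite track values")
    above = values >= threshold
    segments = []
    start = None
    for i, flag in enumerate(np.append(above, False), start=1):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                segments.append(
                    Segment(start=start, end=i - 1, kind=kind, mean_score=float(values[start - 1 : i - 1].mean()))
                )
            start = None
    return segments


def merge_segments(segments: Sequence[Segment]) -> list[Segment]:
    """Fuse overlapping or directly adjacent segments; idempotent.

    Two segments fuse when ``next.start <= prev.end + 1``.  Mean scores are
    length-weighted over the fused parts (overlaps weighted once per source
    segment, which matters only for already-overlapping inputs).
    """
    if not segments:
        return []
    ordered = sorted(segments, key=lambda s: (s.start, s.end))
    merged = [ordered[0]]
    weights = [ordered[0].length]
    for seg in ordered[1:]:
        prev = merged[-1]
        if seg.start <= prev.end + 1:
            w_prev, w_seg = weights[-1], seg.length
            score = np.nansum([prev.mean_score * w_prev, seg.mean_score * w_seg]) / (w_prev + w_seg)
            merged[-1] = Segment(
                start=prev.start,
                end=max(prev.end, seg.end),
                kind=prev.kind,
                mean_score=float(score),
            )
            weights[-1] = w_prev + w_seg
        else:
            merged.append(seg)
            weights.append(seg.length)
    return merged


def classify_segment_position(segment: Segment, L: int, window: int = TERMINAL_WINDOW) -> str:
    """N (starts in the first 30 residues), C (extends into the last 30), else M.

    For short proteins satisfying both conditions, N takes precedence.
    """
    if segment.start < 1 or segment.end > L:
        raise ValueError(f"segment ({segment.start}, {segment.end}) out of bounds for L={L}")
    if segment.start <= window:
        return "N"
    if segment.end >= L - window + 1:
        return "C"
    return "M"


@dataclass(frozen=True)
class IdrSummary:
    idr_segments: tuple
    idrs_per_100: float
    n_short: int
    n_long: int
    coverage: float
    is_idp: bool
    longest: int
    mean_score: float


def idr_summary(
    disorder_track: ScoreTrack | Sequence[float],
    threshold: float = DISORDER_THRESHOLD,
    idp_threshold: float = IDP_COVERAGE_THRESHOLD,
    min_len: int = 5,
) -> IdrSummary:
    """Call IDRs on a disorder track and summarise them.

    Coverage is computed from merged segments so overlaps are not double
    counted; the IDP call is ``coverage >= idp_threshold`` (>= semantics, so
    exactly 30% coverage is an IDP).
    """
    values = disorder_track.as_array() if isinstance(disorder_track, ScoreTrack) else np.asarray(disorder_track, float)
    L = len(values)
    segments = extract_segments(values, threshold, min_len, kind="IDR")
    classified = tuple(
        Segment(
            start=s.start,
            end=s.end,
            kind="IDR",
            mean_score=s.mean_score,
            length_class="short" if s.length <= 19 else "long",
            position_class=classify_segment_position(s, L),
        )
        for s in segments
    )
    covered = sum(s.length for s in merge_segments(segments))
    coverage = covered / L
    return IdrSummary(
        idr_segments=classified,
        idrs_per_100=100.0 * len(segments) / L,
        n_short=sum(1 for s in classified if s.length_class == "short"),
        n_long=sum(1 for s in classified if s.length_class == "long"),
        coverage=coverage,
        is_idp=coverage >= idp_threshold,
        longest=max((s.length for s in segments), default=0),
        mean_score=float(np.mean([s.mean_score for s in segments])) if segments else float("nan"),
    )


@dataclass(frozen=True)
class FoldonSummary:
    foldon_segments: tuple
    foldons_per_100: float
    mean_length: float
    mean_score: float


def foldon_summary(
    early_folding_track: ScoreTrack | Sequence[float],
    threshold: float = EARLY_FOLDING_THRESHOLD,
    min_len: int = 5,
) -> FoldonSummary:
    """Call early foldons (>= ``min_len`` residues above threshold) and summarise.

    Mean score is the mean over per-segment means.  When no foldon is called
    the mean fields are NaN (reported as absent downstream).
    """
    values = (
        early_folding_track.as_array()
        if isinstance(early_folding_track, ScoreTrack)
        else np.asarray(early_folding_track, float)
    )
    segments = extract_segments(values, threshold, min_len, kind="foldon")
    n = len(segments)
    return FoldonSummary(
        foldon_segments=tuple(segments),
        foldons_per_100=100.0 * n / len(values),
        mean_length=float(np.mean([s.length for s in segments])) if n else float("nan"),
        mean_score=float(np.mean([s.mean_score for s in segments])) if n else float("nan"),
    )


@dataclass(frozen=True)
class AprSummary:
    apr_segments: tuple
    aprs_per_100: float
    gatekeeper_positions: frozenset
    gatekeeper_composition: dict = field(default_factory=dict)


def apr_gatekeepers(
    aggregation_track: ScoreTrack | Sequence[float],
    sequence: str,
    threshold: float = AGGREGATION_THRESHOLD,
    min_len: int = 5,
    flank: int = 3,
) -> AprSummary:
    """Call APRs and the composition of their gatekeeper flanks.

    Gatekeepers are up to ``flank`` residues on each side of each APR,
    truncated at the termini, deduplicated across APRs and excluded when they
    fall inside another APR.  Composition is the residue frequency over the
    gatekeeper positions (sums to 1 when any exist).
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    values = (
        aggregation_track.as_array()
        if isinstance(aggregation_track, ScoreTrack)
        else np.asarray(aggregation_track, float)
    )
    if len(values) != len(sequence):
        raise ValueError(f"track length {len(values)} != sequence length {len(sequence)}")
    L = len(sequence)
    segments = extract_segments(values, threshold, min_len, kind="APR")
    in_apr = set()
    for s in segments:
        in_apr.update(range(s.start, s.end + 1))
    gatekeepers: set[int] = set()
    for s in segments:
        for p in range(max(1, s.start - flank), s.start):
            gatekeepers.add(p)
        for p in range(s.end + 1, min(L, s.end + flank) + 1):
            gatekeepers.add(p)
    gatekeepers -= in_apr
    composition: dict[str, float] = {}
    if gatekeepers:
        for p in gatekeepers:
            aa = sequence[p - 1]
            composition[aa] = composition.get(aa, 0) + 1
        composition = {aa: c / len(gatekeepers) for aa, c in sorted(composition.items())}
    return AprSummary(
        apr_segments=tuple(segments),
        aprs_per_100=100.0 * len(segments) / L,
        gatekeeper_positions=frozenset(gatekeepers),
        gatekeeper_composition=composition,
    )
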