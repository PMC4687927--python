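"""Second prediction layer: window labels -> transmembrane regions.

Window-level tm/ntm calls from the SVM are consolidated in five steps:

1. stretch detection — maximal runs of >= 4 consecutive tm windows; a single
   isolated ntm window may be bridged when the merged run holds >= 7 tm
   windows (tight hairpin turns blur the window labels);
2. span arithmetic — a run of windows i..i+j (width w, step 1) covers
   residues i .. i+j+w-1, so the minimal 4-window run spans 13 residues;
3. hairpin splitting — spans of >= 26 residues (two strands seen as one
   stretch) are cut into floor(length/13) near-equal sub-regions treated
   independently;
4. boundary enumeration — every (window first residue, window last residue)
   pair with length 6..12 is a candidate strand;
5. terminus scoring and selection — candidates are scored by the preference
   table at their two boundary residues; among the top three positive
   scorers, the one whose midpoint lies closest to the stretch midpoint is
   reported.  A stretch with no positive-scoring candidate reports nothing.

Window index i is 1-based and, with step 1, window i starts at residue i —
so window and residue coordinates share one axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .dataset import NTM, TM
from .encoding import (
    ProteinSequence,
    SequenceTooShortError,
    encode_windows,
    segment_protein,
)
from .preference import PreferenceTable
from .svm import TrainedClassifier, predict_segments

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictParams:
    """Tunable constants of the region-consolidation layer (defaults validated)."""

    w: int = 10              # window length, matched to membrane thickness
    min_run: int = 4         # minimum consecutive tm windows per stretch
    bridge_min_total: int = 7  # tm windows needed before one ntm gap is bridged
    len_min: int = 6         # candidate strand length bounds
    len_max: int = 12
    split_threshold: int = 26  # spans >= this are split into sub-regions
    piece: int = 13          # target sub-region length

    def __post_init__(self) -> None:
        if self.w < 2 or self.min_run < 1 or self.len_min < 1:
            raise ValueError("invalid predictor parameters")
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")


@dataclass(frozen=True)
class Stretch:
    """A run of consecutive tm windows (possibly bridging isolated ntm gaps)."""

    first_window: int
    last_window: int
    tm_windows: tuple[int, ...]
    bridged_gaps: tuple[int, ...] = ()
    w: int = 10

    @property
    def run_length(self) -> int:
        return len(self.tm_windows)

    @property
    def span_start(self) -> int:
        return self.first_window

    @property
    def span_end(self) -> int:
        return self.last_window + self.w - 1


@dataclass(frozen=True)
class SubSegment:
    start: int
    end: int
    score: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class TMPrediction:
    """A reported transmembrane region with its selection provenance."""

    protein_id: str
    start: int
    end: int
    score: float
    stretch_id: int
    rank: int  # rank within the stretch's Top3 (1 = highest score)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_stretches(
    labels: list[str],
    min_run: int = 4,
    bridge_min_total: int = 7,
    w: int = 10,
) -> list[Stretch]:
    """Maximal runs of >= min_run consecutive tm windows, with gap bridging.

    Two runs separated by exactly one ntm window are merged (left to right,
    to fixpoint) when the merged run holds >= bridge_min_total tm windows;
    two or more consecutive ntm windows always terminate a run.  Runs below
    min_run that are never absorbed by a merge are discarded.
    """
    # each run: [first_window, last_window, tm_count, bridged_gap_positions]
    runs: list[list] = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == TM:
            j = i
            while j + 1 < n and labels[j + 1] == TM:
                j += 1
            runs.append([i + 1, j + 1, j - i + 1, []])  # 1-based windows
            i = j + 1
        else:
            i += 1

    merged = True
    while merged:
        merged = False
        for k in range(len(runs) - 1):
            a, b = runs[k], runs[k + 1]
            if b[0] - a[1] == 2 and a[2] + b[2] >= bridge_min_total:
                runs[k] = [a[0], b[1], a[2] + b[2], a[3] + [a[1] + 1] + b[3]]
                del runs[k + 1]
                merged = True
                break

    out = []
    for first, last, count, bridged in runs:
        if count < min_run:
            continue
        tm_wins = tuple(
            win for win in range(first, last + 1) if win not in bridged
        )
        out.append(
            Stretch(
                first_window=first,
                last_window=last,
                tm_windows=tm_wins,
                bridged_gaps=tuple(bridged),
                w=w,
            )
        )
    return out


def stretch_span(stretch: Stretch, w: int | None = None) -> tuple[int, int]:
    """Residue range covered by the stretch's windows (1-based inclusive)."""
    w = stretch.w if w is None else w
    return stretch.first_window, stretch.first_window + (
        stretch.last_window - stretch.first_window
    ) + w - 1


def split_stretch(
    span: tuple[int, int], split_threshold: int = 26, piece: int = 13
) -> list[tuple[int, int]]:
    """Cut long spans (>= split_threshold residues) into ~piece-long sub-regions.

    k = floor(length / piece) contiguous sub-regions with lengths as equal as
    possible (difference <= 1, earlier pieces longer); shorter spans are
    returned whole.
    """
    start, end = span
    length = end - start + 1
    if length < split_threshold:
        return [span]
    k = length // piece
    base, rem = divmod(length, k)
    out = []
    cur = start
    for idx in range(k):
        size = base + (1 if idx < rem else 0)
        out.append((cur, cur + size - 1))
        cur += size
    return out


def enumerate_subsegments(
    stretch: Stretch,
    subregion: tuple[int, int] | None = None,
    len_min: int = 6,
    len_max: int = 12,
) -> list[SubSegment]:
    """All candidate (start, end) pairs from the stretch's window termini.

    Candidate starts are the first residues of the constituent tm windows and
    candidate ends their last residues; pairs with length in [len_min,
    len_max] are kept, deduplicated, ordered by (start, end).  Within a
    sub-region from :func:`split_stretch`, only windows overlapping it
    contribute and their termini are clipped to the sub-region.
    """
    w = stretch.w
    if subregion is None:
        wins = stretch.tm_windows
        starts = {win for win in wins}
        ends = {win + w - 1 for win in wins}
    else:
        sub_s, sub_e = subregion
        wins = [
            win
            for win in stretch.tm_windows
            if win <= sub_e and win + w - 1 >= sub_s
        ]
        starts = {max(win, sub_s) for win in wins}
        ends = {min(win + w - 1, sub_e) for win in wins}
    pairs = sorted(
        {
            (s, e)
            for s in starts
            for e in ends
            if len_min <= e - s + 1 <= len_max
        }
    )
    return [SubSegment(s, e) for s, e in pairs]


def score_subsegments(
    subsegments: list[SubSegment],
    sequence: str,
    table: PreferenceTable,
    span: tuple[int, int],
) -> list[SubSegment]:
    """Score each candidate at its two boundary residues and rank.

    score = score_N(first residue) + score_C(last residue); descending by
    score, ties toward the candidate whose midpoint is nearest the span
    midpoint, then toward the smaller start.
    """
    span_mid = (span[0] + span[1]) / 2.0
    scored = [
        replace(
            sub,
            score=table.segment_score(
                sequence[sub.start - 1], sequence[sub.end - 1]
            ),
        )
        for sub in subsegments
    ]
    scored.sort(
        key=lambda sub: (-sub.score, abs(sub.midpoint - span_mid), sub.start)
    )
    return scored


def select_tm(
    ranked: list[SubSegment], span: tuple[int, int]
) -> tuple[SubSegment, int] | None:
    """Pick the reported region from the ranked candidates, or None.

    Top3 = up to three highest-ranked candidates with positive score; among
    them the one whose midpoint is closest to the span midpoint wins (ties:
    higher score, then smaller start).  Returns (candidate, rank-in-Top3) or
    None when no candidate scores positive.
    """
    top3 = [sub for sub in ranked if sub.score > 0][:3]
    if not top3:
        return None
    span_mid = (span[0] + span[1]) / 2.0
    best = min(
        enumerate(top3, start=1),
        key=lambda item: (
            abs(item[1].midpoint - span_mid),
            -item[1].score,
            item[1].start,
        ),
    )
    return best[1], best[0]


def predict_from_labels(
    seq: ProteinSequence,
    labels: list[str],
    table: PreferenceTable,
    params: PredictParams = PredictParams(),
) -> list[TMPrediction]:
    """Consolidate a per-window label track into transmembrane regions.

    Exposed separately from :func:`predict_protein` so the consolidation
    layer can be exercised (or debugged) with any label source.
    """
    stretches = find_stretches(
        labels, params.min_run, params.bridge_min_total, params.w
    )
    logger.info(
        "%s: %d windows, %d tm, %d stretches",
        seq.id,
        len(labels),
        sum(1 for l in labels if l == TM),
        len(stretches),
    )
    predictions: list[TMPrediction] = []
    for sid, stretch in enumerate(stretches, start=1):
        span = stretch_span(stretch)
        for sub_span in split_stretch(
            span, params.split_threshold, params.piece
        ):
            subregion = None if sub_span == span else sub_span
            candidates = enumerate_subsegments(
                stretch, subregion, params.len_min, params.len_max
            )
            ranked = score_subsegments(
                candidates, seq.residues, table, sub_span
            )
            chosen = select_tm(ranked, sub_span)
            if chosen is None:
                logger.info(
                    "%s: stretch %d sub-span %s suppressed "
                    "(no positive-scoring candidate)",
                    seq.id,
                    sid,
                    sub_span,
                )
                continue
            sub, rank = chosen
            predictions.append(
                TMPrediction(
                    protein_id=seq.id,
                    start=sub.start,
                    end=sub.end,
                    score=sub.score,
                    stretch_id=sid,
                    rank=rank,
                )
            )
    predictions.sort(key=lambda p: (p.start, p.end))
    # spans of adjacent stretches overlap by up to w-2 residues, so regions
    # chosen independently per stretch may collide; report disjoint regions,
    # keeping the better-scoring one of any overlapping pair
    resolved: list[TMPrediction] = []
    for pred in predictions:
        if resolved and pred.start <= resolved[-1].end:
            if pred.score > resolved[-1].score:
                logger.info(
                    "%s: dropping overlapped region %d-%d (score %.3f)",
                    seq.id, resolved[-1].start, resolved[-1].end,
                    resolved[-1].score,
                )
                resolved[-1] = pred
            else:
                logger.info(
                    "%s: dropping overlapped region %d-%d (score %.3f)",
                    seq.id, pred.start, pred.end, pred.score,
                )
            continue
        resolved.append(pred)
    return resolved


def predict_protein(
    seq: ProteinSequence,
    model: TrainedClassifier,
    table: PreferenceTable,
    params: PredictParams = PredictParams(),
) -> list[TMPrediction]:
    """Full pipeline: segment, encode, classify, consolidate.

    Deterministic given (model, table, params).  A sequence shorter than the
    window length yields an empty prediction with a warning rather than an
    error.
    """
    try:
        windows = segment_protein(seq, params.w)
    except SequenceTooShortError as exc:
        logger.warning("%s: %s; no regions predicted", seq.id, exc)
        return []
    labels = predict_segments(model, encode_windows(windows))
    return predict_from_labels(seq, labels, table, params)


def window_labels(
    seq: ProteinSequence,
    model: TrainedClassifier,
    params: PredictParams = PredictParams(),
) -> list[str]:
    """Per-window tm/ntm label track (first-layer output, for debugging)."""
    windows = segment_protein(seq, params.w)
    return predict_segments(model, encode_windows(windows))
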