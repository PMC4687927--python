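"""Region-level scoring of predictions against annotated strands.

A true positive is a predicted region that overlaps exactly one observed
region (>= 1 shared residue by default); a prediction overlapping zero or two
or more observed regions is a false positive, and each observed region can be
consumed by at most one prediction.  Sensitivity is TP/(TP+FN), precision
TP/(TP+FP), both in percent.  Boundary quality is summarized by an SOV-style
segment-overlap score on the transmembrane state: per matched pair,
(minov + delta) / maxov weighted by the observed strand length and normalized
over all observed transmembrane residues, where minov is the shared length,
maxov the union span, and delta a bounded extension allowance.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

Region = tuple[int, int]


def _check_sorted_disjoint(regions: list[Region], name: str) -> None:
    prev_end = None
    for start, end in regions:
        if start > end:
            raise ValueError(f"{name}: malformed region {start}..{end}")
        if prev_end is not None and start <= prev_end:
            raise ValueError(f"{name}: overlapping regions at {start}..{end}")
        prev_end = end


def _overlap(a: Region, b: Region) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def match_regions(
    predicted: list[Region],
    observed: list[Region],
    min_overlap: int = 1,
) -> tuple[int, int, int, list[tuple[Region, Region]]]:
    """(TP, FP, FN, matched pairs) under the exactly-one-overlap rule.

    Predictions overlapping zero or >= 2 observed regions are FP.  When
    several predictions overlap the same single observed region, the one with
    the largest overlap (ties: leftmost) is the TP and the rest are FP.
    Observed regions left unmatched are FN.  Both lists must be sorted and
    internally non-overlapping.
    """
    predicted = sorted(predicted)
    observed = sorted(observed)
    _check_sorted_disjoint(predicted, "predicted")
    _check_sorted_disjoint(observed, "observed")

    claims: dict[Region, list[Region]] = {}
    fp = 0
    for pred in predicted:
        hits = [obs for obs in observed if _overlap(pred, obs) >= min_overlap]
        if len(hits) == 1:
            claims.setdefault(hits[0], []).append(pred)
        else:
            fp += 1
    matching: list[tuple[Region, Region]] = []
    for obs, preds in claims.items():
        winner = max(preds, key=lambda p: (_overlap(p, obs), -p[0]))
        matching.append((winner, obs))
        fp += len(preds) - 1
    tp = len(matching)
    fn = len(observed) - tp
    matching.sort(key=lambda pair: pair[1])
    return tp, fp, fn, matching


def sensitivity(tp: int, fn: int) -> float | None:
    """100 * TP / (TP + FN); None when there are no observed regions."""
    if tp + fn == 0:
        return None
    return 100.0 * tp / (tp + fn)


def precision(tp: int, fp: int) -> float | None:
    """100 * TP / (TP + FP); None when nothing was predicted."""
    if tp + fp == 0:
        return None
    return 100.0 * tp / (tp + fp)


def _sov_numerator(
    matching: list[tuple[Region, Region]]
) -> float:
    total = 0.0
    for pred, obs in matching:
        minov = _overlap(pred, obs)
        maxov = max(pred[1], obs[1]) - min(pred[0], obs[0]) + 1
        len_obs = obs[1] - obs[0] + 1
        len_pred = pred[1] - pred[0] + 1
        obs_only = len_obs - minov
        pred_only = len_pred - minov
        delta = min(obs_only, pred_only, len_obs // 2, minov // 2)
        total += len_obs * (minov + delta) / maxov
    return total


def segment_overlap(
    predicted: list[Region],
    observed: list[Region],
    min_overlap: int = 1,
) -> float | None:
    """SOV-style overlap score (percent) on the transmembrane state.

    100 for identical region sets, 0 when no prediction touches any observed
    region; None when there are no observed regions.
    """
    _, _, _, matching = match_regions(predicted, observed, min_overlap)
    total_obs = sum(end - start + 1 for start, end in observed)
    if total_obs == 0:
        return None
    return 100.0 * _sov_numerator(matching) / total_obs


@dataclass
class EvaluationResult:
    known_regions: int
    predicted_regions: int
    tp: int
    fp: int
    fn: int
    sensitivity: float | None
    precision: float | None
    segment_overlap: float | None
    per_protein: pd.DataFrame


def evaluate_corpus(
    predictions: dict[str, list[Region]],
    annotations: dict[str, list[Region]],
    min_overlap: int = 1,
) -> EvaluationResult:
    """Pool counts over proteins and emit a per-protein breakdown.

    Every annotated protein must appear in ``predictions`` (an empty list is
    a valid prediction); extra predicted ids raise an error.
    """
    missing = sorted(set(annotations) - set(predictions))
    extra = sorted(set(predictions) - set(annotations))
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"unpredicted proteins: {', '.join(missing)}")
        if extra:
            parts.append(f"unannotated proteins: {', '.join(extra)}")
        raise ValueError("; ".join(parts))

    rows = []
    tp = fp = fn = 0
    sov_num = 0.0
    total_obs_res = 0
    for pid in sorted(annotations):
        pred = sorted(predictions[pid])
        obs = sorted(annotations[pid])
        p_tp, p_fp, p_fn, matching = match_regions(pred, obs, min_overlap)
        tp, fp, fn = tp + p_tp, fp + p_fp, fn + p_fn
        sov_num += _sov_numerator(matching)
        obs_res = sum(e - s + 1 for s, e in obs)
        total_obs_res += obs_res
        rows.append(
            {
                "protein_id": pid,
                "known": len(obs),
                "predicted": len(pred),
                "TP": p_tp,
                "sensitivity": sensitivity(p_tp, p_fn),
                "precision": precision(p_tp, p_fp),
                "segment_overlap": (
                    100.0 * _sov_numerator(matching) / obs_res
                    if obs_res
                    else None
                ),
            }
        )
    return EvaluationResult(
        known_regions=tp + fn,
        predicted_regions=tp + fp,
        tp=tp,
        fp=fp,
        fn=fn,
        sensitivity=sensitivity(tp, fn),
        precision=precision(tp, fp),
        segment_overlap=(
            100.0 * sov_num / total_obs_res if total_obs_res else None
        ),
        per_protein=pd.DataFrame(rows),
    )


def format_percent(value: float | None) -> str:
    """Two-decimal rendering; 'NA' for undefined ratios (never 0)."""
    return "NA" if value is None else f"{value:.2f}"
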