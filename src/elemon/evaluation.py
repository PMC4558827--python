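"""Event-level scoring: greedy one-to-one interval matching.

Detection rate is the fraction of ground-truth events matched by at least one
detection; false-positive rate is the fraction of emitted detections that
match nothing ("every 40th detection is not an elephant" corresponds to 2.5%).
"""

from __future__ import annotations

from collections.abc import Sequence

from .types import DetectionEvent, EvalReport, EventAnnotation


def _overlap(a, b) -> float:
    return max(0.0, min(a.end, b.end) - max(a.start, b.start))


def match_events(
    detections: Sequence[DetectionEvent],
    truth: Sequence[EventAnnotation],
) -> list[tuple[int, int]]:
    """One-to-one matching of detections to annotations.

    A (detection, truth) pair is matchable iff its temporal overlap is
    strictly positive.  Among all one-to-one assignments the matching is of
    maximum cardinality (greedy assignment in decreasing-overlap order can
    strand a truth event when one detection overlaps two of them); pairs are
    then chosen greedily by decreasing overlap within that cardinality.
    Returns (detection index, truth index) pairs.
    """
    cand = []
    for i, d in enumerate(detections):
        for j, t in enumerate(truth):
            ov = _overlap(d, t)
            if ov > 0:
                cand.append((ov, i, j))
    if not cand:
        return []
    cand.sort(key=lambda c: (-c[0], c[1], c[2]))
    target = _max_matching_size(len(detections), len(truth), cand)

    def extend(pairs, used_d, used_t, start):
        if len(pairs) == target:
            return pairs
        for k in range(start, len(cand)):
            ov, i, j = cand[k]
            if i in used_d or j in used_t:
                continue
            # feasibility: can the remainder still reach the target?
            trial = extend(
                pairs + [(i, j)], used_d | {i}, used_t | {j}, k + 1
            )
            if trial is not None:
                return trial
        return None

    result = extend([], set(), set(), 0)
    return result if result is not None else []


def _max_matching_size(n_d: int, n_t: int, cand) -> int:
    """Maximum-cardinality bipartite matching (Hopcroft-Karp via scipy)."""
    import numpy as np
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching

    rows = np.array([i for _, i, _ in cand])
    cols = np.array([j for _, _, j in cand])
    graph = coo_matrix((np.ones(len(cand)), (rows, cols)), shape=(n_d, n_t)).tocsr()
    perm = maximum_bipartite_matching(graph, perm_type="column")
    return int((perm >= 0).sum())


def evaluate_events(
    detections: Sequence[DetectionEvent],
    truth: Sequence[EventAnnotation],
) -> EvalReport:
    """Score detections against annotations with one-to-one matching."""
    pairs = match_events(detections, truth)
    return EvalReport(
        n_truth=len(truth),
        n_detections=len(detections),
        n_matched=len(pairs),
    )
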