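"""Independent test oracles, kept free of the implementation under test."""

from __future__ import annotations

import datetime as dt


def brute_force_chronicity(
    observations: list[tuple[dt.date, bool]], window_days: int = 90
) -> tuple[bool, dt.date | None]:
    """O(n^2) scan over all abnormal pairs with an intervening-normal check.

    ``observations`` are (date, positive) tuples; positive=True is an
    abnormal kidney finding, False a normal kidney-function observation.
    Returns (met, earliest date at which any qualifying pair completes).
    """
    abnormal = sorted(d for d, p in observations if p)
    normals = sorted(d for d, p in observations if not p)
    first_met = None
    for i, a in enumerate(abnormal):
        for b in abnormal[i:]:
            if (b - a).days < window_days:
                continue
            if any(a < n < b for n in normals):
                continue
            if first_met is None or b < first_met:
                first_met = b
    return first_met is not None, first_met


def brute_force_hypernym_choice(graph, leaf: str, threshold: float):
    """Exhaustive ancestor enumeration mirroring the mapping contract.

    Deepest hypernym ancestor whose leaf cohesion passes the threshold
    (ties to the smallest id); otherwise the most general hypernym ancestor;
    None when the leaf has no hypernym ancestor at all.
    """
    from fedkg.vocabulary import EmbeddingError, leaf_similarity

    candidates = [
        c
        for c in graph.ancestors(leaf, include_self=True)
        if graph.get(c).is_hypernym
    ]
    if not candidates:
        return None
    passing = []
    for c in candidates:
        try:
            if leaf_similarity(graph, c) >= threshold:
                passing.append(c)
        except EmbeddingError:
            pass
    pool = passing or candidates
    if passing:
        best_depth = max(graph.depth(c) for c in pool)
    else:
        best_depth = min(graph.depth(c) for c in pool)
    return min(c for c in pool if graph.depth(c) == best_depth)
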