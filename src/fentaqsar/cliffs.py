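"""Activity-landscape analysis: pairwise disparity and top-cliff ranking.

An activity cliff is a pair of structurally similar compounds with a large
potency difference.  The disparity of a pair is the activity difference
divided by the structural distance between the two molecules; large
magnitudes flag cliffs (the SALI idea).  Pairs are reported once with the
more-active molecule first, so delta_activity = pki_less - pki_more and
disparity are always <= 0 under this convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .chemio import MoleculeTable
from .fingerprints import distance as fp_distance, fingerprint

__all__ = ["CliffPair", "pairwise_disparity", "top_cliffs", "write_cliff_table",
           "tanimoto_distance_metric", "field_cosine_metric"]

DEFAULT_MIN_DISTANCE = 0.01


@dataclass(frozen=True)
class CliffPair:
    """Ordered molecule pair (more-active first) with its disparity."""

    id_more: str
    id_less: str
    pki_more: float
    pki_less: float
    distance: float
    delta_activity: float  # pki_less - pki_more, <= 0
    disparity: float  # delta_activity / distance, <= 0


def tanimoto_distance_metric(flavor: str = "ECFP6", length: int = 2048) -> Callable:
    """Default 2D landscape metric: 1 - Tanimoto over circular fingerprints."""
    cache: dict[str, object] = {}

    def metric(a, b) -> float:
        for rec in (a, b):
            if rec.id not in cache:
                cache[rec.id] = fingerprint(rec, flavor, length)
        return fp_distance(cache[a.id], cache[b.id])

    return metric


def field_cosine_metric(field_results) -> Callable:
    """3D landscape metric: normalized cosine distance of field descriptors.

    Uses the same template alignment as the fitted field model, mirroring
    an activity-landscape analysis run on the 3D model's own similarity.
    """
    cache: dict[str, np.ndarray] = {}

    def metric(a, b) -> float:
        for rec in (a, b):
            if rec.id not in cache:
                cache[rec.id] = field_results.descriptor_row(rec)
        u, v = cache[a.id], cache[b.id]
        denom = np.linalg.norm(u) * np.linalg.norm(v)
        if denom == 0:
            return 1.0
        cos = float(np.dot(u, v) / denom)
        return float(np.clip((1.0 - cos) / 2.0, 0.0, 1.0))

    return metric


def make_cliff_pair(id_a, pki_a, id_b, pki_b, dist: float) -> CliffPair:
    """Order a pair by activity (ties by id) and compute its disparity."""
    if not 0.0 <= dist <= 1.0:
        raise ValueError(f"distance {dist} outside [0, 1]")
    if (pki_a, id_b) > (pki_b, id_a) or (pki_a == pki_b and id_a <= id_b):
        more, less = (id_a, pki_a), (id_b, pki_b)
    else:
        more, less = (id_b, pki_b), (id_a, pki_a)
    delta = less[1] - more[1]
    return CliffPair(
        id_more=more[0],
        id_less=less[0],
        pki_more=more[1],
        pki_less=less[1],
        distance=dist,
        delta_activity=delta,
        disparity=delta / dist,
    )


def pairwise_disparity(
    table: MoleculeTable,
    metric: Callable | None = None,
    min_distance: float = DEFAULT_MIN_DISTANCE,
) -> tuple[list[CliffPair], int]:
    """All-pairs disparity over a molecule table.

    Returns ``(pairs, n_near_duplicates)`` where near-duplicate pairs
    (distance < min_distance) are excluded from the landscape but counted.
    Each unordered pair appears once, more-active molecule first.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 molecules")
    if not min_distance > 0:
        raise ValueError("min_distance must be positive")
    if metric is None:
        metric = tanimoto_distance_metric()
    records = list(table)
    pairs: list[CliffPair] = []
    skipped = 0
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            d = metric(a, b)
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"metric returned {d} for ({a.id}, {b.id})")
            if d < min_distance:
                skipped += 1
                continue
            pairs.append(make_cliff_pair(a.id, a.pki, b.id, b.pki, d))
    return pairs, skipped


def top_cliffs(pairs: Iterable[CliffPair], n: int) -> list[CliffPair]:
    """The n pairs with the largest |disparity|.

    Ties broken by larger |delta activity|, then lexicographic ids.
    """
    ranked = sorted(
        pairs,
        key=lambda p: (
            -abs(p.disparity),
            -abs(p.delta_activity),
            p.id_more,
            p.id_less,
        ),
    )
    return ranked[:n]


def write_cliff_table(pairs: Iterable[CliffPair], path) -> None:
    """Cliff table CSV with the standard column layout."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id_more", "id_less", "pki_more", "pki_less", "distance", "delta", "disparity"]
        )
        for p in pairs:
            writer.writerow(
                [p.id_more, p.id_less, f"{p.pki_more:.4f}", f"{p.pki_less:.4f}",
                 f"{p.distance:.6f}", f"{p.delta_activity:.4f}", f"{p.disparity:.4f}"]
            )
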