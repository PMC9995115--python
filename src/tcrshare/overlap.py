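"""Clone sharing across compartments and visits.

All operations here expect repertoires collapsed to amino-acid junctions
(:func:`tcrshare.io.collapse_by_junction_aa`); sharing is defined on the
amino-acid sequence. Ranking for top-N statistics breaks count ties by
lexicographic junction order so every statistic is reproducible and invariant
to input row order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Repertoire

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (1, 2, 10, 100)  # count bins: 1, 2-9, 10-99, >=100


@dataclass(frozen=True)
class OverlapMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray  # symmetric Jaccard matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class TopNCurve:
    sample_a: str
    sample_b: str
    n_values: tuple[int, ...]
    percent_overlap: tuple[float, ...]


def clonal_proportion_summary(rep: Repertoire, bin_edges: Sequence[int] = DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Fraction of total count mass per clonal-expansion bin.

    ``bin_edges`` are the left edges of count bins (last bin open-ended);
    default (1, 2, 10, 100) reproduces the bins 1, 2-9, 10-99, ≥100.
    """
    edges = list(bin_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges) or edges[0] != 1:
        raise ValidationError("bin edges must be strictly increasing and start at 1")
    labels = []
    for i, lo in enumerate(edges):
        hi = edges[i + 1] - 1 if i + 1 < len(edges) else None
        labels.append(f"{lo}" if hi == lo else (f"{lo}-{hi}" if hi else f">={lo}"))
    total = rep.total_count
    mass = np.zeros(len(edges))
    for c in rep.clonotypes:
        idx = int(np.searchsorted(edges, c.count, side="right")) - 1
        mass[idx] += c.count
    return pd.DataFrame({"bin": labels, "proportion": mass / total})


def ranked_junctions(rep: Repertoire) -> list[str]:
    """Junctions ranked by count descending, ties broken lexicographically."""
    counts = rep.junction_counts()
    return [j for j, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def top_n_intersection(rep_a: Repertoire, rep_b: Repertoire, n_grid: Sequence[int]) -> TopNCurve:
    """Percentage of the top-n clonotype sets shared between two samples."""
    ranked_a = ranked_junctions(rep_a)
    ranked_b = ranked_junctions(rep_b)
    limit = min(len(ranked_a), len(ranked_b))
    ns, pct = [], []
    for n in sorted(set(int(n) for n in n_grid)):
        if n < 1:
            raise ValidationError("n must be ≥ 1")
        if n > limit:
            logger.warning("top_n_intersection: n=%d exceeds smallest repertoire (%d); dropped", n, limit)
            continue
        shared = len(set(ranked_a[:n]) & set(ranked_b[:n]))
        ns.append(n)
        pct.append(100.0 * shared / n)
    return TopNCurve(rep_a.sample_id, rep_b.sample_id, tuple(ns), tuple(pct))


def jaccard_index(set_a: set, set_b: set) -> float:
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def jaccard_matrix(reps: Sequence[Repertoire]) -> OverlapMatrix:
    """Pairwise Jaccard indices over unique amino-acid junction sets."""
    if len(reps) < 2:
        raise ValidationError("need ≥ 2 repertoires")
    sets = []
    for rep in reps:
        s = rep.junction_set()
        if not s:
            raise ValidationError(f"repertoire {rep.sample_id} is empty")
        sets.append(s)
    k = len(reps)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = jaccard_index(sets[i], sets[j])
    return OverlapMatrix(tuple(r.sample_id for r in reps), mat)


def classify_sharing(reps: Sequence[Repertoire]) -> pd.DataFrame:
    """Per junction in the union, the number of samples containing it."""
    presence: dict[str, int] = {}
    for rep in reps:
        for j in rep.junction_set():
            presence[j] = presence.get(j, 0) + 1
    rows = sorted(presence.items())
    return pd.DataFrame(
        {
            "junction_aa": [j for j, _ in rows],
            "n_samples_present": [n for _, n in rows],
        }
    )


def paired_frequency_table(rep_a: Repertoire, rep_b: Repertoire, context: Sequence[Repertoire] = ()) -> pd.DataFrame:
    """Union of junctions with per-sample frequencies and sharing class.

    ``n_samples_present`` counts presence over {rep_a, rep_b} ∪ context (the
    context lets three-sample coloring include e.g. a blood sample).
    """
    fa = rep_a.junction_frequencies()
    fb = rep_b.junction_frequencies()
    everything = [rep_a, rep_b, *context]
    counts: dict[str, int] = {}
    for rep in everything:
        for j in rep.junction_set():
            counts[j] = counts.get(j, 0) + 1
    keys = sorted(set(fa) | set(fb))
    return pd.DataFrame(
        {
            "junction_aa": keys,
            "freq_a": [fa.get(j, 0.0) for j in keys],
            "freq_b": [fb.get(j, 0.0) for j in keys],
            "n_samples_present": [counts[j] for j in keys],
        }
    )


def venn_counts(reps: Sequence[Repertoire], top_n: int = 100) -> dict[tuple[str, ...], int]:
    """Counts of every intersection region over the top-N junction sets.

    Returns a map from the tuple of member sample_ids (the region) to the
    number of junctions exclusive to that region; regions sum to |union|.
    """
    if not 2 <= len(reps) <= 4:
        raise ValidationError("venn_counts supports 2-4 repertoires")
    tops: dict[str, set[str]] = {}
    for rep in reps:
        ranked = ranked_junctions(rep)
        if len(ranked) < top_n:
            logger.info("venn_counts: %s has only %d clonotypes (< top_n=%d); using all", rep.sample_id, len(ranked), top_n)
        tops[rep.sample_id] = set(ranked[:top_n])
    ids = [r.sample_id for r in reps]
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(ids) + 1):
        for members in itertools.combinations(ids, r):
            inside = set.intersection(*(tops[m] for m in members))
            outside = set.union(set(), *(tops[m] for m in ids if m not in members))
            out[members] = len(inside - outside)
    return out
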