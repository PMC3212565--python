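"""Windowed repeat annotation of query sequences against family read databases.

Each family database pools the long reads of clusters sharing a family
label.  Every database read is locally aligned to the query (both strands,
seed-and-extend); alignments at or above the score threshold add +1 to the
per-base hit depth over their query span, and window means divided by the
long-read genome coverage give per-window copy-number estimates, so a
single-copy region reads out at ~1.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import align
from ._seq import encode, revcomp_codes
from .clustering import ReadCluster

DEFAULT_MIN_SCORE = 50   # +1/-1/-2 local score; ~matches a stringent e-value cutoff
DEFAULT_WINDOW = 1000
DEFAULT_STEP = 100
SEED_K = 12


@dataclass
class ReadDatabase:
    """Pooled reads of all clusters assigned one family label."""

    family_label: str
    reads: dict[str, str]


def build_family_dbs(clusters: list[ReadCluster], seqs: dict[str, str],
                     labels: dict[str, str] | None = None) -> dict[str, ReadDatabase]:
    """One database per family label; unlabeled clusters pool as 'unclassified'.

    ``labels`` maps cluster id -> family label and overrides any
    ``family_label`` already set on the clusters.
    """
    dbs: dict[str, ReadDatabase] = {}
    owner: dict[str, str] = {}
    for cl in clusters:
        label = (labels or {}).get(cl.id, cl.family_label) or "unclassified"
        db = dbs.setdefault(label, ReadDatabase(label, {}))
        for rid in cl.members:
            if rid in owner:
                raise ValueError(f"read {rid!r} present in both "
                                 f"{owner[rid]!r} and {label!r}")
            owner[rid] = label
            db.reads[rid] = seqs[rid]
    return dbs


def _query_kmer_index(codes: np.ndarray, k: int) -> dict[int, list[int]]:
    index: dict[int, list[int]] = defaultdict(list)
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return index
    idx = np.arange(n)[:, None] + np.arange(k)[None, :]
    windows = codes[idx]
    ok = (windows < 4).all(axis=1)
    packed = windows.astype(np.int64) @ weights
    for pos in np.flatnonzero(ok):
        index[int(packed[pos])].append(int(pos))
    return index


def _candidate_intervals(read: np.ndarray, qindex: dict[int, list[int]],
                         qlen: int, k: int) -> list[tuple[int, int]]:
    """Query intervals worth aligning against, from shared k-mer seeds."""
    hits: list[int] = []
    weights = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    n = len(read) - k + 1
    if n <= 0:
        return []
    idx = np.arange(n)[:, None] + np.arange(k)[None, :]
    windows = read[idx]
    ok = (windows < 4).all(axis=1)
    packed = windows.astype(np.int64) @ weights
    for pos in np.flatnonzero(ok):
        hits.extend(qindex.get(int(packed[pos]), ()))
    if not hits:
        return []
    hits.sort()
    pad = len(read)
    merged: list[list[int]] = []
    for h in hits:
        lo, hi = max(0, h - pad), min(qlen, h + k + pad)
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def _alignments_in_window(query_codes: np.ndarray, read: np.ndarray,
                          min_score: int, max_hits: int = 25
                          ) -> list[tuple[int, int]]:
    """Distinct local alignments (query spans) found by iterative masking."""
    work = query_codes.copy()
    spans: list[tuple[int, int]] = []
    for _ in range(max_hits):
        if align.sw_score(work, read) < min_score:
            break
        aln = align.sw_align(work, read)
        if aln.score < min_score or aln.a_end <= aln.a_start:
            break
        spans.append((aln.a_start, aln.a_end))
        work[aln.a_start:aln.a_end] = 5  # sentinel: never matches again
    return spans


@dataclass
class HitProfile:
    """Windowed per-family hit depths and copy numbers for one query."""

    query_id: str
    table: pd.DataFrame  # query, start, end, family, hits, copies
    depth: dict[str, np.ndarray]  # per-family per-base alignment depth


def profile_sequence(query: str, databases: dict[str, ReadDatabase],
                     coverage: float,
                     min_alignment_score: int = DEFAULT_MIN_SCORE,
                     window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
                     query_id: str = "query") -> HitProfile:
    """Windowed hit profile of a query against the family databases.

    ``coverage`` is the long-read genome sequencing coverage used as the
    copy-number normaliser (hits per base / coverage = copies).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if len(query) < window:
        raise ValueError("query shorter than the window")
    qcodes = encode(query)
    qindex = _query_kmer_index(qcodes, SEED_K)
    depth: dict[str, np.ndarray] = {}
    for label, db in databases.items():
        d = np.zeros(len(query), dtype=np.int32)
        for rid, seq in db.reads.items():
            fcodes = encode(seq)
            for read in (fcodes, revcomp_codes(fcodes)):
                for lo, hi in _candidate_intervals(read, qindex, len(query), SEED_K):
                    for a0, a1 in _alignments_in_window(qcodes[lo:hi], read,
                                                        min_alignment_score):
                        d[lo + a0:lo + a1] += 1
        depth[label] = d

    rows = []
    starts = range(0, len(query) - window + 1, step)
    for label in sorted(databases):
        d = depth[label]
        for s in starts:
            hits = float(d[s:s + window].mean())
            rows.append({"query": query_id, "start": s, "end": s + window,
                         "family": label, "hits": hits,
                         "copies": hits / coverage})
    table = pd.DataFrame(rows, columns=["query", "start", "end", "family",
                                        "hits", "copies"])
    return HitProfile(query_id, table, depth)
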