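"""Read preprocessing: duplicate removal, tag trimming/filtering, subsampling.

Short 36-nt reads are converted to 30-nt tags by extracting positions 3-32
(1-based, inclusive) and keeping only tags whose extracted window has a base
quality of at least ``min_quality`` over at least ``min_fraction`` of its
positions (>= 27 of 30 at the defaults).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .records import ReadSet, SequenceRead, SequenceTag

logger = logging.getLogger(__name__)

TRIM_START = 3   # 1-based, inclusive
TRIM_END = 32    # 1-based, inclusive
TAG_LENGTH = TRIM_END - TRIM_START + 1

REJECT_TOO_SHORT = "too_short"
REJECT_LOW_QUALITY = "low_quality"
REJECT_NO_QUALITIES = "no_qualities"


def dedup_long_reads(reads: list[SequenceRead] | ReadSet,
                     linker_trimmer=None) -> tuple[list[SequenceRead], int]:
    """Remove artificially duplicated reads (identical full-length sequence).

    The first read of each identity group (by input order) is retained.
    ``linker_trimmer`` is a hook applied to each read before comparison; the
    simulator emits linker-free reads so the default is a no-op.
    Returns (kept reads, number removed).
    """
    kept: list[SequenceRead] = []
    seen: set[str] = set()
    removed = 0
    for read in reads:
        if linker_trimmer is not None:
            read = linker_trimmer(read)
        if read.bases in seen:
            removed += 1
            continue
        seen.add(read.bases)
        kept.append(read)
    if removed:
        logger.info("dedup_long_reads: removed %d duplicate reads", removed)
    return kept, removed


@dataclass(frozen=True)
class TrimRule:
    """Trim window and quality-acceptance rule for tag extraction."""

    start: int = TRIM_START      # 1-based inclusive
    end: int = TRIM_END          # 1-based inclusive
    min_quality: int = 10
    min_fraction: float = 0.9

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def min_good(self) -> int:
        # "at least 90%" of 30 positions -> ceil(0.9 * 30) = 27
        return math.ceil(self.min_fraction * self.length)


def trim_and_filter(read: SequenceRead, rule: TrimRule = TrimRule()
                    ) -> SequenceTag | str:
    """Convert one short read to a tag, or return a rejection reason code."""
    if len(read.bases) < rule.end:
        return REJECT_TOO_SHORT
    if read.qualities is None:
        return REJECT_NO_QUALITIES
    lo, hi = rule.start - 1, rule.end
    window_q = read.qualities[lo:hi]
    if int((window_q >= rule.min_quality).sum()) < rule.min_good:
        return REJECT_LOW_QUALITY
    return SequenceTag(read.id, read.bases[lo:hi])


def filter_tags(reads: ReadSet, rule: TrimRule = TrimRule()
                ) -> tuple[list[str], dict[str, int]]:
    """Vectorised tag extraction for a fixed-length short-read batch.

    Returns (tag sequences, rejection counts by reason code).
    """
    stats = {REJECT_TOO_SHORT: 0, REJECT_LOW_QUALITY: 0, "accepted": 0}
    if len(reads) == 0:
        return [], stats
    if reads.qualities is None:
        raise ValueError("short-read batch lacks qualities")
    read_len = len(reads.seqs[0])
    if read_len < rule.end:
        stats[REJECT_TOO_SHORT] = len(reads)
        return [], stats
    lo, hi = rule.start - 1, rule.end
    good = (reads.qualities[:, lo:hi] >= rule.min_quality).sum(axis=1)
    ok = good >= rule.min_good
    tags = [reads.seqs[i][lo:hi] for i in np.flatnonzero(ok)]
    stats["accepted"] = len(tags)
    stats[REJECT_LOW_QUALITY] = int(len(reads) - len(tags))
    return tags, stats


def subsample_tags(tags: list, n: int, seed: int) -> list:
    """Uniform sample of ``n`` tags without replacement (original order kept)."""
    if n > len(tags):
        raise ValueError(f"cannot sample {n} tags from {len(tags)} available")
    if n == len(tags):
        return list(tags)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tags), size=n, replace=False)
    return [tags[i] for i in np.sort(idx)]
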