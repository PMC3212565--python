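"""Satellite consensus reconstruction from tag k-mer spectra.

The monomer of a tandem repeat is recovered by a greedy walk through the
k-mer frequency spectrum of the tags assigned to its cluster: start at the
globally most frequent k-mer and repeatedly extend by the highest-count
k-mer overlapping the current end by k-1 bases.  Revisiting the start
closes a circular consensus whose length equals the walk length; failing to
reach the count floor yields a linear fragment.  Branches that diverge from
and rejoin the consensus above a relative-frequency floor are reported as
sequence variants (subfamilies), and the per-position support vector drives
conserved-window probe selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp


@dataclass
class KmerSpectrum:
    """k-mer occurrence counts over the tags of one cluster."""

    k: int
    counts: dict[str, int]
    strand_policy: str = "both-strands"  # or "as-is"

    def max_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0


@dataclass
class Variant:
    """A branch path diverging from and rejoining the consensus."""

    start: int           # first consensus position replaced (canonical coords)
    length: int          # number of consensus positions replaced
    sequence: str        # alternative bases over that span
    frequency: float     # branch count / (branch + consensus count)


@dataclass
class ConsensusMonomer:
    """Reconstructed satellite monomer (circular unless noted)."""

    sequence: str                 # canonical (lexicographically minimal) rotation
    circular: bool
    k: int
    support: np.ndarray           # per-position branch-frequency of consensus base
    variants: list[Variant] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def kmer_census(tags: list[str], k: int,
                strand_policy: str = "both-strands") -> KmerSpectrum:
    """Count every length-k window of every tag (plus reverse complements
    under the both-strands policy)."""
    if strand_policy not in ("both-strands", "as-is"):
        raise ValueError(f"unknown strand policy {strand_policy!r}")
    counts: dict[str, int] = {}
    for tag in tags:
        if len(tag) < k:
            raise ValueError(f"k={k} exceeds tag length {len(tag)}")
        for i in range(len(tag) - k + 1):
            kmer = tag[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    if strand_policy == "both-strands":
        rc_counts: dict[str, int] = dict(counts)
        for kmer, n in counts.items():
            rc = revcomp(kmer)
            rc_counts[rc] = rc_counts.get(rc, 0) + n
        counts = rc_counts
    return KmerSpectrum(k, counts, strand_policy)


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation of a circular sequence."""
    doubled = seq + seq
    return min(doubled[i:i + len(seq)] for i in range(len(seq)))


def _rotation_offset(seq: str) -> int:
    doubled = seq + seq
    best = min(range(len(seq)), key=lambda i: doubled[i:i + len(seq)])
    return best


def reconstruct_monomer(spectrum: KmerSpectrum,
                        count_floor_frac: float = 0.01,
                        max_steps: int | None = None) -> ConsensusMonomer | None:
    """Greedy most-frequent-path reconstruction of the consensus monomer.

    Deterministic given the spectrum: all ties are broken lexicographically.
    Returns ``None`` when no k-mer reaches the count floor.  The count floor
    (default 1% of the maximum k-mer count) suppresses sequencing-error
    k-mers while keeping ~5% variants visible as branches.
    """
    k = spectrum.k
    if not spectrum.counts:
        return None
    floor = max(1.0, count_floor_frac * spectrum.max_count())
    eligible = {m: c for m, c in spectrum.counts.items() if c >= floor}
    if not eligible:
        return None
    start = min(eligible, key=lambda m: (-eligible[m], m))
    path = [start]
    visited = {start: 0}
    circular = False
    limit = max_steps if max_steps is not None else 4 * len(eligible) + 10
    cur = start
    for _ in range(limit):
        suffix = cur[1:]
        candidates = [suffix + b for b in "ACGT" if (suffix + b) in eligible]
        if not candidates:
            break
        nxt = min(candidates, key=lambda m: (-eligible[m], m))
        if nxt == start:
            circular = True
            break
        if nxt in visited:
            break  # internal loop without closing the cycle: stop as fragment
        visited[nxt] = len(path)
        path.append(nxt)
        cur = nxt

    if circular:
        seq = "".join(p[0] for p in path)
    else:
        seq = path[0] + "".join(p[-1] for p in path[1:])

    support = _position_support(path, spectrum, circular)
    monomer = ConsensusMonomer(seq, circular, k, support)
    if circular:
        off = _rotation_offset(seq)
        monomer.sequence = seq[off:] + seq[:off]
        monomer.support = np.roll(support, -off)
    monomer.variants = call_variants(spectrum, monomer, path=path,
                                     rotation_offset=off if circular else 0)
    return monomer


def _branch_frequency(kmer: str, counts: dict[str, int]) -> float:
    """Count of a k-mer relative to all k-mers sharing its (k-1)-prefix."""
    prefix = kmer[:-1]
    total = sum(counts.get(prefix + b, 0) for b in "ACGT")
    return counts[kmer] / total if total else 0.0


def _position_support(path: list[str], spectrum: KmerSpectrum,
                      circular: bool) -> np.ndarray:
    sup = np.array([_branch_frequency(m, spectrum.counts) for m in path])
    if not circular:
        # linear fragment: pad tail positions with the last step's support
        sup = np.concatenate([sup, np.full(len(path[0]) - 1, sup[-1])])
    return sup


def call_variants(spectrum: KmerSpectrum, consensus: ConsensusMonomer,
                  min_rel_freq: float = 0.05,
                  path: list[str] | None = None,
                  rotation_offset: int = 0,
                  max_branch_steps: int | None = None) -> list[Variant]:
    """Branch paths diverging from and rejoining the consensus.

    A branch starts where an alternative continuation of a consensus
    (k-1)-prefix reaches at least ``min_rel_freq`` of the local k-mer flow,
    is followed greedily, and is reported if it rejoins the consensus.
    Positions are reported on the canonical rotation.
    """
    k = consensus.k
    counts = spectrum.counts
    L = consensus.length
    if path is None:
        if not consensus.circular:
            raise ValueError("need the walk path for linear fragments")
        doubled = consensus.sequence + consensus.sequence
        path = [doubled[i:i + k] for i in range(L)]
        rotation_offset = 0
    cons_pos = {m: i for i, m in enumerate(path)}
    limit = max_branch_steps if max_branch_steps is not None else 4 * k
    variants: list[Variant] = []
    seen: set[tuple[int, str]] = set()
    for i, kmer in enumerate(path):
        prefix = kmer[:-1]
        local = {b: counts.get(prefix + b, 0) for b in "ACGT"}
        cons_count = counts.get(kmer, 0)
        for b, c in sorted(local.items()):
            alt = prefix + b
            if alt == kmer or c == 0:
                continue
            freq = c / (c + cons_count) if (c + cons_count) else 0.0
            if freq < min_rel_freq:
                continue
            branch = _follow_branch(alt, counts, cons_pos, limit)
            if branch is None:
                continue
            alt_bases, rejoin_pos = branch
            # the branch replaces consensus positions starting where the
            # alternative last base sits: walk position i emits base i+k-1
            start = (i + k - 1) % max(L, 1)
            span = (rejoin_pos + k - 1 - start) % max(L, 1)
            if span == 0:
                span = len(alt_bases)
            # trim the shared suffix so only the divergent stretch remains
            doubled = consensus.sequence * 2
            cons_span = doubled[(start - rotation_offset) % L:][:span] \
                if consensus.circular else consensus.sequence[start:start + span]
            while len(alt_bases) > 1 and len(cons_span) > 1 \
                    and alt_bases[-1] == cons_span[-1]:
                alt_bases = alt_bases[:-1]
                cons_span = cons_span[:-1]
                span -= 1
            canon_start = (start - rotation_offset) % L if consensus.circular else start
            key = (canon_start, alt_bases)
            if key in seen:
                continue
            seen.add(key)
            variants.append(Variant(canon_start, span, alt_bases, freq))
    variants.sort(key=lambda v: (v.start, v.sequence))
    return variants


def _follow_branch(start_kmer: str, counts: dict[str, int],
                   cons_pos: dict[str, int], limit: int
                   ) -> tuple[str, int] | None:
    """Greedy walk from a branch k-mer until it rejoins the consensus."""
    bases = [start_kmer[-1]]
    cur = start_kmer
    for _ in range(limit):
        suffix = cur[1:]
        candidates = [suffix + b for b in "ACGT" if counts.get(suffix + b, 0) > 0]
        if not candidates:
            return None
        nxt = max(candidates, key=lambda m: (counts[m], m))
        if nxt in cons_pos:
            return "".join(bases), cons_pos[nxt]
        bases.append(nxt[-1])
        cur = nxt
    return None


def design_probe(consensus: ConsensusMonomer,
                 length_range: tuple[int, int] = (26, 50),
                 variant: Variant | None = None) -> tuple[str, int, int]:
    """Select the hybridisation-probe window of maximal conserved support.

    The window maximises the minimum per-position support; ties go to the
    longest, then the leftmost window on the canonical rotation.  In
    variant-targeting mode the window must cover the variant span and the
    probe sequence carries the variant bases in place of the consensus.
    Returns (probe sequence, start, end) with end possibly wrapping.
    """
    lo, hi = length_range
    L = consensus.length
    if L < lo:
        raise ValueError(f"consensus length {L} below minimum window {lo}")
    hi = min(hi, L)
    seq = consensus.sequence
    sup = consensus.support
    if variant is not None:
        seq = (seq[:variant.start] + variant.sequence
               + seq[variant.start + variant.length:]) if not consensus.circular \
            else _splice_circular(seq, variant)
        sup = _splice_support(sup, variant)
        L = len(seq)
        hi = min(hi, L)
    doubled_seq = seq + seq
    doubled_sup = np.concatenate([sup, sup])
    starts = range(L) if consensus.circular else range(L - lo + 1)
    best = None
    for w in range(hi, lo - 1, -1):
        for s in starts:
            if not consensus.circular and s + w > L:
                continue
            if variant is not None:
                v_lo, v_hi = variant.start, variant.start + len(variant.sequence)
                covered = s <= v_lo and v_hi <= s + w if not consensus.circular \
                    else _covers_circular(s, w, v_lo, v_hi, L)
                if not covered:
                    continue
            score = float(doubled_sup[s:s + w].min())
            key = (score, w, -s)
            if best is None or key > best[0]:
                best = (key, s, w)
    if best is None:
        raise ValueError("no admissible probe window")
    _, s, w = best
    return doubled_seq[s:s + w], s, s + w


def _splice_circular(seq: str, variant: Variant) -> str:
    end = variant.start + variant.length
    if end <= len(seq):
        return seq[:variant.start] + variant.sequence + seq[end:]
    wrap = end - len(seq)
    return variant.sequence[-wrap:] + seq[wrap:variant.start] + variant.sequence[:len(variant.sequence) - wrap]


def _splice_support(sup: np.ndarray, variant: Variant) -> np.ndarray:
    out = sup.copy()
    for i in range(len(variant.sequence)):
        out[(variant.start + i) % len(sup)] = variant.frequency
    return out


def _covers_circular(s: int, w: int, v_lo: int, v_hi: int, L: int) -> bool:
    window = {(s + i) % L for i in range(w)}
    return all(p % L in window for p in range(v_lo, v_hi))
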