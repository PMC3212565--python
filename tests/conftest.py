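"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from collections import Counter

import edlib
import numpy as np
import pytest

import replowpass as rp
from replowpass._seq import encode, revcomp, revcomp_codes
from replowpass.records import read_origin

# ---------------------------------------------------------------------------
# independent local-alignment oracle: numpy antidiagonal DP + python traceback
# (same scoring definition as the package aligner, entirely different code)
# ---------------------------------------------------------------------------


def sw_oracle_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Full Smith-Waterman matrix by antidiagonal wavefront (slice-only).

    Diagonal d holds cells (i, j) with i + j = d, stored in arrays indexed
    by i; all recurrence reads are then contiguous slices of the previous
    two diagonals, with matrix boundaries appearing naturally as zeros.
    """
    n, m = len(a), len(b)
    a16 = a.astype(np.int16)
    diags = [np.zeros(n + 1, dtype=np.int16), np.zeros(n + 1, dtype=np.int16)]
    prev2, prev = diags[0], diags[1]
    for d in range(2, n + m + 1):
        cur = np.zeros(n + 1, dtype=np.int16)
        ilo, ihi = max(1, d - m), min(n, d - 1)
        if ilo <= ihi:
            # b[d-i-1] for i in [ilo..ihi] is a reversed contiguous slice
            bseg = b[d - ihi - 1:d - ilo][::-1].astype(np.int16)
            aseg = a16[ilo - 1:ihi]
            s = np.where((aseg == bseg) & (aseg < 4), 1, -1).astype(np.int16)
            diag = prev2[ilo - 1:ihi] + s
            up = prev[ilo - 1:ihi] - 2
            left = prev[ilo:ihi + 1] - 2
            cur[ilo:ihi + 1] = np.maximum(
                0, np.maximum(diag, np.maximum(up, left)))
        diags.append(cur)
        prev2, prev = prev, cur
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    for d in range(2, n + m + 1):
        ilo, ihi = max(1, d - m), min(n, d - 1)
        if ilo <= ihi:
            i = np.arange(ilo, ihi + 1)
            H[i, d - i] = diags[d][ilo:ihi + 1]
    return H


def sw_oracle_align(a: np.ndarray, b: np.ndarray):
    """(score, matches, columns, a_start, a_end, b_start, b_end), same
    tie-break rules as the package aligner (first row-major max; diagonal
    preferred over up over left)."""
    H = sw_oracle_matrix(a, b)
    flat = int(np.argmax(H))
    bi, bj = divmod(flat, H.shape[1])
    score = int(H[bi, bj])
    matches = columns = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i, j] > 0:
        s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else -1
        h, p = H[i - 1, j - 1] + s, 1
        if H[i - 1, j] - 2 > h:
            h, p = H[i - 1, j] - 2, 2
        if H[i, j - 1] - 2 > h:
            h, p = H[i, j - 1] - 2, 3
        columns += 1
        if p == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i, j = i - 1, j - 1
        elif p == 2:
            i -= 1
        else:
            j -= 1
    return score, matches, columns, i, bi, j, bj


def sw_oracle_best(a: np.ndarray, b: np.ndarray) -> int:
    """Best local score only (wavefront, no matrix kept)."""
    n, m = len(a), len(b)
    a16 = a.astype(np.int16)
    prev2 = np.zeros(n + 1, dtype=np.int16)
    prev = np.zeros(n + 1, dtype=np.int16)
    best = 0
    for d in range(2, n + m + 1):
        cur = np.zeros(n + 1, dtype=np.int16)
        ilo, ihi = max(1, d - m), min(n, d - 1)
        if ilo <= ihi:
            bseg = b[d - ihi - 1:d - ilo][::-1].astype(np.int16)
            aseg = a16[ilo - 1:ihi]
            s = np.where((aseg == bseg) & (aseg < 4), 1, -1).astype(np.int16)
            cur[ilo:ihi + 1] = np.maximum(
                0, np.maximum(prev2[ilo - 1:ihi] + s,
                              np.maximum(prev[ilo - 1:ihi] - 2,
                                         prev[ilo:ihi + 1] - 2)))
            best = max(best, int(cur[ilo:ihi + 1].max()))
        prev2, prev = prev, cur
    return best


def find_overlaps_oracle(items, min_identity=0.90, min_cov=0.55):
    """Exhaustive all-pairs, both-strand overlap detection via the numpy DP.

    Pairs whose best score falls below the provable lower bound implied by
    the identity/coverage thresholds cannot form an edge and skip traceback;
    everything else is fully traced and checked.
    """
    from replowpass.align import min_overlap_score

    ids = [i for i, _ in items]
    fwd = [encode(s) for _, s in items]
    rev = [revcomp_codes(c) for c in fwd]
    edges = set()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            shorter = min(len(fwd[i]), len(fwd[j]))
            floor = min_overlap_score(shorter, min_identity, min_cov)
            for b in (fwd[j], rev[j]):
                if sw_oracle_best(fwd[i], b) < floor:
                    continue
                score, matches, columns, a0, a1, b0, b1 = sw_oracle_align(fwd[i], b)
                if columns == 0:
                    continue
                aligned_shorter = (a1 - a0) if len(fwd[i]) <= len(fwd[j]) else (b1 - b0)
                if (matches / columns >= min_identity
                        and aligned_shorter / shorter >= min_cov):
                    edges.add((ids[i], ids[j]))
                    break
    return edges


# ---------------------------------------------------------------------------
# brute-force tag assignment oracle (exhaustive edlib scan, same selection)
# ---------------------------------------------------------------------------


def assign_tag_oracle(tag, read_ids, read_seqs, cluster_of, cluster_sizes,
                      max_mm=2):
    best_by_cluster = {}
    for oriented in (tag, revcomp(tag)):
        for rid, seq in zip(read_ids, read_seqs):
            res = edlib.align(oriented, seq, mode="HW", task="distance", k=max_mm)
            d = res["editDistance"]
            if d == -1:
                continue
            cl = cluster_of[rid]
            if d < best_by_cluster.get(cl, max_mm + 1):
                best_by_cluster[cl] = d
    if not best_by_cluster:
        return None
    best = min(best_by_cluster.values())
    winners = [c for c, d in best_by_cluster.items() if d == best]
    from replowpass.quantify import TagIndex
    winners.sort(key=lambda c: (-cluster_sizes.get(c, 0),
                                TagIndex._cluster_rank(c), c))
    return winners[0], best


# ---------------------------------------------------------------------------
# truth helpers
# ---------------------------------------------------------------------------


def family_of_reads(read_ids, pair, sample_of=None):
    """Map simulated read ids to their true family via the genome layout."""
    lookups = {"male": pair.interval_lookup("male"),
               "female": pair.interval_lookup("female")}
    out = {}
    for rid in read_ids:
        origin = read_origin(rid)
        sex = (sample_of or {}).get(rid) or ("male" if rid.startswith("m") else "female")
        if "pos" not in origin:  # duplicate reads carry their twin's name only
            out[rid] = None
            continue
        mid = origin["pos"] + 100
        out[rid] = str(lookups[sex](np.array([mid]))[0])
    return out


def majority_family(cluster, fam_of):
    votes = Counter(fam_of.get(r) for r in cluster.members)
    votes.pop(None, None)
    return votes.most_common(1)[0][0] if votes else "background"


def rand_index(labels_a, labels_b) -> float:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    agree = 0
    total = n * (n - 1) // 2
    for i in range(n):
        sa = a[i] == a[i + 1:]
        sb = b[i] == b[i + 1:]
        agree += int((sa == sb).sum())
    return agree / total


# ---------------------------------------------------------------------------
# session fixture: zero-error, zero-divergence end-to-end dataset
# ---------------------------------------------------------------------------

SPIKE_TOTAL = 0.03
TAGS_PER_SAMPLE = 100_000


def _zero_div_spec(seed: int = 101) -> rp.GenomeSimSpec:
    """Megabase-scale, low-pass study conditions: the genome is sampled far
    below 1x so single-copy sequence cannot cluster, while repeat families
    reach the deep effective coverage their copy numbers imply."""
    families = (
        rp.RepeatFamilySpec("dispA", "dispersed", 6000, 100, 100),
        rp.RepeatFamilySpec("dispB", "dispersed", 3000, 120, 120),
        rp.RepeatFamilySpec("satS", "tandem", 43, 2000, 2000),
        rp.RepeatFamilySpec("ringT", "tandem", 1500, 100, 100),
        rp.RepeatFamilySpec("staryS", "tandem", 40, 2000, 40),
        rp.RepeatFamilySpec("lambda_ctrl", "spike_in", 8000, 0, 0, gc_target=0.5),
        rp.RepeatFamilySpec("t4_ctrl", "spike_in", 8000, 0, 0, gc_target=0.4),
    )
    male_foot = sum(f.footprint("male") for f in families)
    female_foot = sum(f.footprint("female") for f in families)
    background = 4_000_000 - male_foot
    return rp.GenomeSimSpec(families, background, male_foot + background,
                            female_foot + background, seed=seed)


@pytest.fixture(scope="session")
def zero_div_run():
    """Full pipeline on a noise-free simulation with known truth.

    Zero divergence and zero sequencing error isolate the statistical
    behaviour of clustering and quantification from the error model.
    """
    spec = _zero_div_spec()
    pair = rp.build_genome_pair(spec)

    long_reads = []
    sample_of = {}
    for sex, genome, seed in (("male", pair.male, 102), ("female", pair.female, 103)):
        cfg = rp.long_read_config(640, seed=seed, sub_rate=0, ins_rate=0,
                                  del_rate=0, duplicate_rate=0)
        batch = rp.simulate_reads(genome, cfg, prefix=f"{sex[0]}L", sample=sex)
        for r in batch:
            sample_of[r.id] = sex
        long_reads.extend(batch)
    seqs = {r.id: r.bases for r in long_reads}

    edges = rp.find_overlaps(long_reads)
    clusters, singletons = rp.build_clusters(list(seqs), edges)
    fam_of = family_of_reads(list(seqs), pair, sample_of)
    cluster_family = {cl.id: majority_family(cl, fam_of) for cl in clusters}

    # control reference clusters from dedicated control-derived long reads
    ctrl_reads, ctrl_cluster_of, ctrl_ids = {}, {}, {}
    for k, name in enumerate(sorted(pair.controls)):
        cfg = rp.long_read_config(100, seed=120 + k, sub_rate=0, ins_rate=0,
                                  del_rate=0, duplicate_rate=0)
        for r in rp.simulate_reads(pair.controls[name], cfg, prefix=f"ctl{k}"):
            ctrl_reads[r.id] = r.bases
            ctrl_cluster_of[r.id] = f"CTRL{k + 1}"
        ctrl_ids[name] = f"CTRL{k + 1}"

    cluster_of = {rid: cl.id for cl in clusters for rid in cl.members}
    index = rp.TagIndex({**seqs, **ctrl_reads}, {**cluster_of, **ctrl_cluster_of})

    split = {"male": {"lambda_ctrl": 0.75 * SPIKE_TOTAL, "t4_ctrl": 0.25 * SPIKE_TOTAL},
             "female": {"lambda_ctrl": 0.25 * SPIKE_TOTAL, "t4_ctrl": 0.75 * SPIKE_TOTAL}}
    tags, counts = {}, {}
    for i, (sex, genome) in enumerate((("male", pair.male), ("female", pair.female))):
        cfg = rp.short_read_config(103_200, seed=104 + i, sub_rate=0.0)
        pool = rp.simulate_reads(genome, cfg, prefix=f"{sex[0]}S", sample=sex)
        pool, _ = rp.add_spike_ins(pool, pair.controls, split[sex], cfg, seed=106 + i)
        extracted, _ = rp.filter_tags(pool)
        tags[sex] = rp.subsample_tags(extracted, TAGS_PER_SAMPLE, seed=108 + i)
        counts[sex], _ = rp.assign_tags(tags[sex], index)

    from replowpass.quantify import cluster_gc_from_reads
    gc = cluster_gc_from_reads(clusters, seqs)
    # the reporting floor is 0.005% of a 5M-tag sample, i.e. >= 250 tags;
    # at this run's 100k-tag depth the same absolute count is 0.25%
    table = rp.quantify(counts["male"], counts["female"],
                        TAGS_PER_SAMPLE, TAGS_PER_SAMPLE, cluster_gc=gc,
                        reporting_floor=250 / TAGS_PER_SAMPLE)
    controls = [rp.SpikeInControl("lambda_ctrl", split["male"]["lambda_ctrl"],
                                  split["female"]["lambda_ctrl"]),
                rp.SpikeInControl("t4_ctrl", split["male"]["t4_ctrl"],
                                  split["female"]["t4_ctrl"])]
    calib = rp.calibrate_with_controls(table, controls, ctrl_ids)

    return {
        "spec": spec, "pair": pair, "reads": long_reads, "seqs": seqs,
        "edges": edges, "clusters": clusters, "singletons": singletons,
        "fam_of": fam_of, "cluster_family": cluster_family,
        "tags": tags, "counts": counts, "table": table, "calib": calib,
        "control_ids": ctrl_ids, "index": index,
        "spike_total": SPIKE_TOTAL, "n_tags": TAGS_PER_SAMPLE,
    }
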