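"""Tag-based repeat quantification and male/female comparison.

Each 30-nt tag is assigned to at most one cluster: the one containing the
long read at minimal edit distance (unit-cost substitutions and indels,
i.e. "two mismatches including gaps" at the default ``max_mismatches=2``),
with ties across clusters resolved deterministically (larger cluster first,
then smaller cluster id).  Per-sample tag counts become genome proportions;
the male/female contrast is the ratio M/(M+F), calibrated against spike-in
controls of known asymmetry; a rank-correlation diagnostic tests for
GC-dependent sampling bias between the samples.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._seq import gc_content, revcomp

SEGMENT_LEN = 10  # pigeonhole: a 30-nt tag within 2 edits keeps one exact third


@dataclass(frozen=True)
class SpikeInControl:
    """Expected and observed sample fractions of one spike-in control."""

    name: str
    expected_male: float
    expected_female: float
    observed_male: float = float("nan")
    observed_female: float = float("nan")

    @property
    def expected_mf(self) -> float:
        return mf_ratio(self.expected_male, self.expected_female)

    @property
    def observed_mf(self) -> float:
        return mf_ratio(self.observed_male, self.observed_female)


class TagIndex:
    """k-mer index over clustered long reads for fast best-hit tag assignment.

    A tag within ``max_mismatches`` (<= 2) edits of a read substring must
    share an exact 10-mer third with it, so candidate reads are found by
    exact lookup of the tag's three segments (both orientations) and then
    verified with edlib infix alignment.  The result equals an exhaustive
    edit-distance scan over every read.
    """

    def __init__(self, reads: dict[str, str], cluster_of: dict[str, str],
                 cluster_sizes: dict[str, int] | None = None,
                 max_mismatches: int = 2):
        if max_mismatches > SEGMENT_LEN - 1:
            raise ValueError("max_mismatches too large for the 10-mer index")
        self.max_mismatches = max_mismatches
        self.read_ids = [r for r in reads if r in cluster_of]
        self.read_seqs = [reads[r] for r in self.read_ids]
        self.read_cluster = [cluster_of[r] for r in self.read_ids]
        if cluster_sizes is None:
            cluster_sizes = Counter(self.read_cluster)
        self.cluster_sizes = dict(cluster_sizes)
        self._kmers: dict[str, list[int]] = defaultdict(list)
        for idx, seq in enumerate(self.read_seqs):
            seen = set()
            for start in range(0, len(seq) - SEGMENT_LEN + 1):
                kmer = seq[start:start + SEGMENT_LEN]
                if kmer not in seen:
                    self._kmers[kmer].append(idx)
                    seen.add(kmer)

    @staticmethod
    def _cluster_rank(cluster_id: str) -> int:
        m = re.search(r"(\d+)$", cluster_id)
        return int(m.group(1)) if m else 10**9

    def _candidates(self, tag: str) -> set[int]:
        cands: set[int] = set()
        for start in range(0, len(tag) - SEGMENT_LEN + 1, SEGMENT_LEN):
            cands.update(self._kmers.get(tag[start:start + SEGMENT_LEN], ()))
        return cands

    def assign(self, tag: str) -> tuple[str, int] | None:
        """Best cluster for one tag, or None if nothing is within range."""
        best_by_cluster: dict[str, int] = {}
        for oriented in (tag, revcomp(tag)):
            by_cluster: dict[str, list[int]] = defaultdict(list)
            for idx in self._candidates(oriented):
                by_cluster[self.read_cluster[idx]].append(idx)
            for cluster, idxs in by_cluster.items():
                current = best_by_cluster.get(cluster, self.max_mismatches + 1)
                if current == 0:
                    continue
                for idx in idxs:
                    res = edlib.align(oriented, self.read_seqs[idx], mode="HW",
                                      task="distance", k=self.max_mismatches)
                    d = res["editDistance"]
                    if d != -1 and d < current:
                        current = d
                        if d == 0:
                            break
                if current <= self.max_mismatches:
                    best_by_cluster[cluster] = current
        if not best_by_cluster:
            return None
        best = min(best_by_cluster.values())
        winners = [c for c, d in best_by_cluster.items() if d == best]
        winners.sort(key=lambda c: (-self.cluster_sizes.get(c, 0), self._cluster_rank(c), c))
        return winners[0], best


def assign_tags(tags: list[str], index: TagIndex) -> tuple[Counter, int]:
    """Assign a batch of tags; returns (per-cluster counts, unassigned count)."""
    counts: Counter = Counter()
    unassigned = 0
    for tag in tags:
        hit = index.assign(tag)
        if hit is None:
            unassigned += 1
        else:
            counts[hit[0]] += 1
    return counts, unassigned


REPORTING_FLOOR = 5e-5  # 0.005% of sampled tags


def quantify(counts_male: Counter, counts_female: Counter,
             total_male: int, total_female: int,
             cluster_gc: dict[str, float] | None = None,
             reporting_floor: float = REPORTING_FLOOR) -> pd.DataFrame:
    """Per-cluster proportion table for the two samples.

    Proportions are fractions of the sampled tag totals.  Clusters whose
    mean proportion falls below ``reporting_floor`` are flagged unreliable
    rather than dropped.
    """
    if total_male <= 0 or total_female <= 0:
        raise ValueError("tag totals must be positive")
    clusters = sorted(set(counts_male) | set(counts_female),
                      key=lambda c: (TagIndex._cluster_rank(c), c))
    rows = []
    for cl in clusters:
        tm, tf = counts_male.get(cl, 0), counts_female.get(cl, 0)
        pm, pf = tm / total_male, tf / total_female
        rows.append({
            "cluster_id": cl,
            "tags_male": tm, "tags_female": tf,
            "p_male": pm, "p_female": pf,
            "mf_ratio": mf_ratio(pm, pf) if (pm + pf) > 0 else np.nan,
            "gc": (cluster_gc or {}).get(cl, np.nan),
            "reliable": (pm + pf) / 2 >= reporting_floor,
        })
    df = pd.DataFrame(rows, columns=["cluster_id", "tags_male", "tags_female",
                                     "p_male", "p_female", "mf_ratio", "gc",
                                     "reliable"])
    df.attrs["total_male"] = total_male
    df.attrs["total_female"] = total_female
    return df


def mf_ratio(p_male: float, p_female: float) -> float:
    """Male proportion over summed proportions; 0.5 means equal abundance."""
    total = p_male + p_female
    if total <= 0:
        raise ValueError("mf_ratio undefined when both proportions are zero")
    return p_male / total


def cluster_gc_from_reads(clusters, seqs: dict[str, str]) -> dict[str, float]:
    """Mean GC fraction of each cluster's member long reads."""
    return {cl.id: float(np.mean([gc_content(seqs[r]) for r in cl.members]))
            for cl in clusters}


@dataclass
class CalibrationResult:
    envelope: float                 # most extreme control |mf - 0.5|
    controls: list[SpikeInControl]  # with observed fractions filled in
    flagged: list[str]              # sex-differential cluster ids


def calibrate_with_controls(table: pd.DataFrame,
                            controls: list[SpikeInControl],
                            control_clusters: dict[str, str] | None = None,
                            only_reliable: bool = True) -> CalibrationResult:
    """Flag clusters deviating from 0.5 more than the most extreme control.

    ``control_clusters`` maps control name -> cluster id in ``table``; when
    given, observed control fractions are taken from the table itself and
    control rows are excluded from flagging.
    """
    if not controls:
        raise ValueError("at least one spike-in control is required for calibration")
    observed: list[SpikeInControl] = []
    control_ids = set()
    for ctrl in controls:
        if control_clusters and ctrl.name in control_clusters:
            cid = control_clusters[ctrl.name]
            control_ids.add(cid)
            row = table[table["cluster_id"] == cid]
            if len(row) == 0:
                raise ValueError(f"control cluster {cid!r} absent from table")
            ctrl = SpikeInControl(ctrl.name, ctrl.expected_male, ctrl.expected_female,
                                  float(row["p_male"].iloc[0]),
                                  float(row["p_female"].iloc[0]))
        observed.append(ctrl)
    deviations = [abs(c.observed_mf - 0.5) for c in observed]
    envelope = max(deviations)
    flagged = []
    for _, row in table.iterrows():
        if row["cluster_id"] in control_ids or np.isnan(row["mf_ratio"]):
            continue
        if only_reliable and not row["reliable"]:
            continue
        if abs(row["mf_ratio"] - 0.5) > envelope:
            flagged.append(row["cluster_id"])
    return CalibrationResult(envelope, observed, flagged)


def copy_number(proportion: float, genome_1c: float, unit_length: float) -> float:
    """Copies per 1C: genome proportion x 1C size / monomer length."""
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    return proportion * genome_1c / unit_length


def genome_coverage(total_sequenced_bases: float, genome_1c: float) -> float:
    """Sequenced bases as a fraction of the haploid genome size."""
    if genome_1c <= 0:
        raise ValueError("genome_1c must be positive")
    return total_sequenced_bases / genome_1c


def male_female_abundance_ratio(y_density_fold: float,
                                y_fraction: float = 0.10,
                                x_fraction: float = 0.075) -> float:
    """Male:female total-abundance ratio for a repeat denser on Y.

    The male genome is autosomes + X + Y (fractions 1 - x - y, x, y); the
    female genome is autosomes + two X.  With unit repeat density on
    autosomes and X and ``y_density_fold`` on Y, the male repeat fraction is
    (1 - y) + fold * y while the female fraction is exactly the unit density,
    so the ratio is 1 + (fold - 1) * y.
    """
    a = 1.0 - x_fraction - y_fraction
    male_fraction = a + x_fraction + y_density_fold * y_fraction
    female_fraction = (a + 2 * x_fraction) / (a + 2 * x_fraction)
    return male_fraction / female_fraction


@dataclass
class GcBiasResult:
    rho: float       # Spearman correlation of GC with (mf_ratio - 0.5)
    p_value: float   # two-sided permutation p-value
    n_clusters: int
    defined: bool = True


def gc_bias_diagnostic(table: pd.DataFrame, n_permutations: int = 999,
                       seed: int = 0) -> GcBiasResult:
    """Rank correlation between cluster GC and male/female deviation.

    Sign convention: a negative ``rho`` means GC-rich clusters are shifted
    towards the female sample (mf_ratio below 0.5), the direction produced
    by a GC-penalising bias acting on the male sample and vice versa.  The
    p-value is a two-sided permutation test (GC column permuted).
    """
    sub = table.dropna(subset=["mf_ratio", "gc"])
    if len(sub) < 10:
        raise ValueError("need at least 10 clusters with defined mf_ratio and GC")
    gc = sub["gc"].to_numpy()
    dev = (sub["mf_ratio"] - 0.5).to_numpy()
    if np.allclose(gc, gc[0]) or np.allclose(dev, dev[0]):
        return GcBiasResult(float("nan"), float("nan"), len(sub), defined=False)
    rho = float(sstats.spearmanr(gc, dev).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(gc)
        r = float(sstats.spearmanr(perm, dev).statistic)
        if abs(r) >= abs(rho):
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return GcBiasResult(rho, p, len(sub))
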