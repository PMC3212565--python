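"""Tag assignment, proportion estimation, calibration, GC diagnostic."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import replowpass as rp
from replowpass._seq import gc_content, random_seq, revcomp
from replowpass.quantify import cluster_gc_from_reads
from tests.conftest import assign_tag_oracle


@pytest.fixture(scope="module")
def small_index():
    rng = np.random.default_rng(0)
    reads = {f"r{i}": random_seq(rng, 250) for i in range(12)}
    cluster_of = {f"r{i}": ("CL1" if i < 8 else "CL2") for i in range(12)}
    return reads, cluster_of, rp.TagIndex(reads, cluster_of)


class TestAssignTag:
    def test_exact_substring_assigned_at_distance_zero(self, small_index):
        reads, cluster_of, index = small_index
        tag = reads["r10"][100:130]
        assert index.assign(tag) == ("CL2", 0)

    def test_reverse_complement_matches(self, small_index):
        reads, _, index = small_index
        assert index.assign(revcomp(reads["r3"][5:35])) == ("CL1", 0)

    def test_distance_three_unassigned(self, small_index):
        reads, _, index = small_index
        tag = list(reads["r0"][50:80])
        for pos in (3, 14, 25):  # three substitutions, one per index third
            tag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[pos]]
        assert index.assign("".join(tag)) is None

    def test_best_distance_wins_across_clusters(self, small_index):
        reads, _, index = small_index
        # distance 1 to CL2 (one substitution), distance >=2 elsewhere
        tag = list(reads["r9"][60:90])
        tag[14] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[14]]
        hit = index.assign("".join(tag))
        assert hit == ("CL2", 1)

    def test_gap_counts_as_one_mismatch(self, small_index):
        reads, _, index = small_index
        window = reads["r5"][40:71]          # 31 nt
        tag = window[:15] + window[16:]      # one deletion -> 30 nt tag
        cluster, dist = index.assign(tag)
        assert cluster == "CL1" and dist <= 1

    def test_tie_breaks_to_larger_cluster(self):
        rng = np.random.default_rng(1)
        shared = random_seq(rng, 30)
        reads = {"a1": shared + random_seq(rng, 200),
                 "a2": random_seq(rng, 200),
                 "b1": random_seq(rng, 100) + shared}
        cluster_of = {"a1": "CLbig", "a2": "CLbig", "b1": "CLsmall"}
        index = rp.TagIndex(reads, cluster_of)
        assert index.assign(shared)[0] == "CLbig"

    def test_accelerated_index_equals_brute_force_scan(self):
        # pigeonhole index vs exhaustive edlib scan: 1000 tags x 100 reads
        rng = np.random.default_rng(2)
        unit = random_seq(rng, 500)
        reads = {}
        for i in range(100):
            if i < 60:
                s = int(rng.integers(0, 250))
                seq = (unit * 2)[s:s + 250]
            else:
                seq = random_seq(rng, 250)
            reads[f"r{i}"] = seq
        cluster_of = {f"r{i}": f"CL{1 + i % 7}" for i in range(100)}
        index = rp.TagIndex(reads, cluster_of)
        ids = list(reads)
        seqs = [reads[r] for r in ids]
        sizes = Counter(cluster_of.values())
        rng2 = np.random.default_rng(3)
        tags = []
        for i in range(1000):
            if i % 2 == 0:
                src = reads[ids[int(rng2.integers(0, 100))]]
                s = int(rng2.integers(0, 220))
                t = list(src[s:s + 30])
                for _ in range(int(rng2.integers(0, 4))):  # 0-3 edits
                    t[int(rng2.integers(0, 30))] = "ACGT"[int(rng2.integers(0, 4))]
                tags.append("".join(t))
            else:
                tags.append(random_seq(rng2, 30))
        for tag in tags:
            assert index.assign(tag) == assign_tag_oracle(
                tag, ids, seqs, cluster_of, sizes)


class TestQuantify:
    def test_proportions_are_count_fractions(self):
        table = rp.quantify(Counter({"CL1": 1000}), Counter({"CL1": 500}),
                            100_000, 100_000)
        row = table.iloc[0]
        assert row["p_male"] == 0.01 and row["p_female"] == 0.005
        assert row["mf_ratio"] == pytest.approx(2 / 3)

    def test_zero_count_cluster_has_undefined_ratio(self):
        table = rp.quantify(Counter({"CL1": 10, "CL2": 0}),
                            Counter({"CL2": 0}), 100, 100)
        sub = table.set_index("cluster_id")
        assert np.isnan(sub.loc["CL2", "mf_ratio"])

    def test_reporting_floor_flags_sparse_clusters(self):
        table = rp.quantify(Counter({"CL1": 1000, "CL2": 2}),
                            Counter({"CL1": 900, "CL2": 1}),
                            100_000, 100_000)
        sub = table.set_index("cluster_id")
        assert bool(sub.loc["CL1", "reliable"]) is True
        assert bool(sub.loc["CL2", "reliable"]) is False

    def test_zero_totals_rejected(self):
        with pytest.raises(ValueError):
            rp.quantify(Counter(), Counter(), 0, 100)

    def test_assignment_conservation(self, zero_div_run):
        run = zero_div_run
        for sex in ("male", "female"):
            assigned = sum(run["counts"][sex].values())
            assert assigned <= run["n_tags"]
            # conservation re-checked directly on a subsample
            sample = run["tags"][sex][:2000]
            hits = [run["index"].assign(t) for t in sample]
            assert sum(h is not None for h in hits) + \
                sum(h is None for h in hits) == len(sample)


class TestMfRatio:
    def test_fig_anchor_values(self):
        assert rp.mf_ratio(0.02, 0.02) == 0.5
        assert round(rp.mf_ratio(0.02, 0.01), 2) == 0.67
        assert round(rp.mf_ratio(0.01, 0.03), 2) == 0.25

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    @settings(derandomize=True, max_examples=100)
    def test_antisymmetry(self, m, f):
        assert rp.mf_ratio(m, f) == pytest.approx(1 - rp.mf_ratio(f, m))

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            rp.mf_ratio(0.0, 0.0)


class TestCalibration:
    def _table(self, rows):
        recs = []
        for cid, pm, pf in rows:
            recs.append({"cluster_id": cid, "tags_male": int(pm * 1e5),
                         "tags_female": int(pf * 1e5), "p_male": pm,
                         "p_female": pf,
                         "mf_ratio": rp.mf_ratio(pm, pf) if pm + pf else np.nan,
                         "gc": 0.4, "reliable": True})
        return pd.DataFrame(recs)

    def test_control_envelope_contains_observed_deviation(self):
        table = self._table([("CTRL1", 0.0219, 0.0081), ("CL1", 0.01, 0.01)])
        ctrl = rp.SpikeInControl("lam", 0.0225, 0.0075)
        result = rp.calibrate_with_controls(table, [ctrl], {"lam": "CTRL1"})
        obs_mf = 0.0219 / 0.0300
        assert result.envelope == pytest.approx(abs(obs_mf - 0.5))
        assert result.controls[0].observed_mf == pytest.approx(obs_mf)

    def test_cluster_outside_envelope_flagged(self):
        table = self._table([("CTRL1", 0.0225, 0.0075), ("CTRL2", 0.0075, 0.0225),
                             ("CL1", 0.049, 0.001), ("CL2", 0.02, 0.02)])
        controls = [rp.SpikeInControl("lam", 0.0225, 0.0075),
                    rp.SpikeInControl("t4", 0.0075, 0.0225)]
        result = rp.calibrate_with_controls(
            table, controls, {"lam": "CTRL1", "t4": "CTRL2"})
        assert result.flagged == ["CL1"]

    def test_balanced_clusters_never_flagged(self):
        table = self._table([("CTRL1", 0.022, 0.008)] +
                            [(f"CL{i}", 0.01, 0.01) for i in range(5)])
        result = rp.calibrate_with_controls(
            table, [rp.SpikeInControl("lam", 0.0225, 0.0075)], {"lam": "CTRL1"})
        assert result.flagged == []

    def test_no_controls_is_an_error(self):
        with pytest.raises(ValueError):
            rp.calibrate_with_controls(self._table([("CL1", 0.01, 0.01)]), [])


class TestScalars:
    def test_copy_number_formula(self):
        assert rp.copy_number(0.0099, 2.925e9, 313) == pytest.approx(9.25e4, rel=0.01)
        assert rp.copy_number(0, 1e9, 100) == 0
        with pytest.raises(ValueError):
            rp.copy_number(0.1, 1e9, 0)

    def test_genome_coverage(self):
        assert rp.genome_coverage(161.7e6, 2.895e9) == pytest.approx(0.0559, abs=1e-4)
        assert rp.genome_coverage(0, 1e9) == 0
        assert rp.genome_coverage(5e8, 5e8) == 1.0

    def test_y_density_ratio_closed_form(self):
        # 10-fold Y density with Y = 10% of the male genome -> 1.9-fold
        assert rp.male_female_abundance_ratio(10) == pytest.approx(1.9)
        assert rp.male_female_abundance_ratio(1) == pytest.approx(1.0)


class TestGcBias:
    def _table_from_counts(self, counts_m, counts_f, gc, n):
        return rp.quantify(Counter(counts_m), Counter(counts_f), n, n,
                           cluster_gc=gc)

    def test_degenerate_constant_gc_undefined(self):
        counts = {f"CL{i}": 100 + i for i in range(12)}
        table = self._table_from_counts(counts, counts,
                                        {c: 0.5 for c in counts}, 10_000)
        result = rp.gc_bias_diagnostic(table)
        assert not result.defined

    def test_too_few_clusters_rejected(self):
        counts = {"CL1": 10}
        table = self._table_from_counts(counts, counts, {"CL1": 0.5}, 100)
        with pytest.raises(ValueError):
            rp.gc_bias_diagnostic(table)

    def test_injected_gc_bias_detected_and_null_stays_null(self):
        # 50 dispersed families spanning GC 0.30-0.70; the female sample is
        # simulated with a GC-penalising sampling bias, the male without
        rng = np.random.default_rng(20)
        fams = tuple(
            rp.RepeatFamilySpec(f"F{i:02d}", "dispersed", 800, 3, 3,
                                gc_target=0.30 + 0.40 * i / 49)
            for i in range(50)
        )
        foot = sum(f.footprint("male") for f in fams)
        spec = rp.GenomeSimSpec(fams, 8000, foot + 8000, foot + 8000, seed=21)
        pair = rp.build_genome_pair(spec)
        lookup = pair.interval_lookup("male")

        def family_counts(slope, seed):
            cfg = rp.short_read_config(30_000, seed=seed, sub_rate=0,
                                       gc_bias_slope=slope)
            reads = rp.simulate_reads(pair.male, cfg)
            pos = np.array([int(r.split("|pos=")[1].split("|")[0])
                            for r in reads.ids]) + 18
            fams_hit = lookup(pos)
            return Counter(f for f in fams_hit if f != "background")

        gc = {}
        for row in pair.layout.query("sex == 'male'").itertuples():
            gc.setdefault(row.family, gc_content(pair.male[row.start:row.end]))

        # GC-penalised sampling of the male sample depletes its GC-rich
        # clusters, pushing their mf_ratio below 0.5: negative correlation
        biased = self._table_from_counts(family_counts(-3.0, 22),
                                         family_counts(0.0, 23), gc, 30_000)
        res = rp.gc_bias_diagnostic(biased, seed=24)
        assert res.rho < 0 and res.p_value < 0.05

        significant = 0
        for rep in range(4):
            null = self._table_from_counts(family_counts(0.0, 25 + 2 * rep),
                                           family_counts(0.0, 26 + 2 * rep),
                                           gc, 30_000)
            res0 = rp.gc_bias_diagnostic(null, seed=27 + rep)
            significant += res0.p_value < 0.05
        assert significant <= 1


class TestYSegmentRecovery:
    def test_simulated_y_dense_repeat_shows_19_fold(self):
        # genome model: male = A + X + Y (82.5/7.5/10), female = A + 2X;
        # repeat density d on A and X, 10d on Y -> male:female fractions 1.9
        rng = np.random.default_rng(30)
        monomer = random_seq(rng, 43)

        def segment(total, density, seed):
            srng = np.random.default_rng(seed)
            n_copies = round(total * density / 43)
            array = monomer * n_copies
            bg = random_seq(srng, total - len(array))
            half = len(bg) // 2
            return bg[:half] + array + bg[half:]

        A = segment(165_000, 0.02, 31)
        X = segment(15_000, 0.02, 32)
        Y = segment(20_000, 0.20, 33)
        male, female = A + X + Y, A + X + X

        reads = {"mono": monomer * 8}
        index = rp.TagIndex(reads, {"mono": "CL1"})
        fracs = {}
        for sex, genome, seed in (("male", male, 34), ("female", female, 35)):
            cfg = rp.short_read_config(60_000, seed=seed, sub_rate=0)
            pool = rp.simulate_reads(genome, cfg)
            tags, _ = rp.filter_tags(pool)
            counts, _ = rp.assign_tags(tags, index)
            fracs[sex] = counts["CL1"] / len(tags)
        ratio = fracs["male"] / fracs["female"]
        se = ratio * np.sqrt(sum(1 / (fracs[s] * 60_000) for s in fracs))
        assert abs(ratio - 1.9) < 3 * se
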