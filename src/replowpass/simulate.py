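"""Synthetic genome-pair and read simulator with known ground truth.

The simulator emulates the statistical structure a low-pass repeat analysis
assumes: a male/female genome pair built from shared repeat-family master
sequences (dispersed retroelement-like units, head-to-tail satellite arrays,
and an rDNA-like unit with a tandem subrepeat block embedded in its
intergenic spacer), single-copy background, long shotgun reads (~250 nt,
with optional artificial duplicates), fixed-length 36-nt short reads with
per-position quality profiles, spike-in control sequences at requested mass
fractions, and an optional GC-dependent sampling bias.

Every random choice flows from explicit integer seeds; a fixed seed yields
byte-identical genomes and read sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode, gc_content, random_codes, revcomp_codes
from .records import ReadSet

logger = logging.getLogger(__name__)

FAMILY_KINDS = ("dispersed", "tandem", "rdna_like", "spike_in")


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One simulated repeat family.

    ``divergence`` is the mean per-site substitution divergence between copy
    pairs: individual copies mutate away from the family master at rates
    drawn uniformly from [0, 2 x divergence], reproducing the similarity
    spectrum of a family amplified over time (recent copies near-identical,
    old copies diverged).

    ``monomer_variants`` lists substitution edits as (position, new_base,
    relative_frequency); each copy of the family carries the edit with the
    given probability, emulating satellite subfamily variants.
    """

    name: str
    kind: str
    unit_length: int
    copies_male: int
    copies_female: int
    divergence: float = 0.0
    gc_target: float = 0.4
    monomer_variants: tuple[tuple[int, str, float], ...] = ()
    subrepeat_length: int = 43  # rdna_like only: embedded IGS subrepeat monomer

    def validate(self) -> None:
        if self.kind not in FAMILY_KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.unit_length < 20:
            raise ValueError(f"{self.name}: unit_length {self.unit_length} < 20")
        if min(self.copies_male, self.copies_female) < 0:
            raise ValueError(f"{self.name}: negative copy number")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError(f"{self.name}: divergence {self.divergence} outside [0, 0.3]")
        if not 0.2 <= self.gc_target <= 0.8:
            raise ValueError(f"{self.name}: gc_target {self.gc_target} outside [0.2, 0.8]")
        if sum(f for _, _, f in self.monomer_variants) > 1.0:
            raise ValueError(f"{self.name}: variant frequencies sum above 1")
        for pos, base, freq in self.monomer_variants:
            if not 0 <= pos < self.unit_length or base not in "ACGT" or not 0 < freq <= 1:
                raise ValueError(f"{self.name}: bad variant ({pos}, {base!r}, {freq})")

    def footprint(self, sex: str) -> int:
        if self.kind == "spike_in":
            return 0
        copies = self.copies_male if sex == "male" else self.copies_female
        return copies * self.unit_length


@dataclass(frozen=True)
class GenomeSimSpec:
    """Declarative description of a simulated male/female genome pair."""

    families: tuple[RepeatFamilySpec, ...]
    background_length: int
    genome_1C_male: int
    genome_1C_female: int
    seed: int = 0
    background_gc: float = 0.38

    def validate(self) -> None:
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names")
        for fam in self.families:
            fam.validate()
        for sex, size in (("male", self.genome_1C_male), ("female", self.genome_1C_female)):
            foot = sum(f.footprint(sex) for f in self.families)
            if foot + self.background_length > size:
                raise ValueError(
                    f"{sex} genome too small: families + background = "
                    f"{foot + self.background_length} bp > 1C = {size} bp"
                )


@dataclass(frozen=True)
class ReadSimConfig:
    """Read sampling model for one platform.

    ``gc_bias_slope`` is the change in log sampling odds per unit GC fraction
    of the sampled read (0 = uniform sampling); positive values favour GC-rich
    templates.
    """

    platform: str  # "long" | "short"
    n_reads: int
    mean_length: int = 250
    length_sd: float = 30.0
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    duplicate_rate: float = 0.0
    gc_bias_slope: float = 0.0
    quality_profile: tuple[float, ...] | None = None
    quality_sd: float = 3.0
    seed: int = 0

    SHORT_LENGTH = 36

    def validate(self) -> None:
        if self.platform not in ("long", "short"):
            raise ValueError(f"unknown platform {self.platform!r}")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.05:
                raise ValueError(f"{name} {v} outside [0, 0.05]")
        if not 0.0 <= self.duplicate_rate <= 0.2:
            raise ValueError(f"duplicate_rate {self.duplicate_rate} outside [0, 0.2]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


def long_read_config(n_reads: int, seed: int = 0, **kw) -> ReadSimConfig:
    """Study-condition defaults for long shotgun reads.

    ~250 nt mean, ~0.5% total error (pyrosequencing-like accuracy, indel
    dominated), 5% artificial duplicates from emulsion-PCR-style artefacts.
    """
    kw.setdefault("mean_length", 250)
    kw.setdefault("length_sd", 30.0)
    kw.setdefault("sub_rate", 0.002)
    kw.setdefault("ins_rate", 0.0015)
    kw.setdefault("del_rate", 0.0015)
    kw.setdefault("duplicate_rate", 0.05)
    return ReadSimConfig(platform="long", n_reads=n_reads, seed=seed, **kw)


def short_read_config(n_reads: int, seed: int = 0, **kw) -> ReadSimConfig:
    """Study-condition defaults for 36-nt short reads."""
    kw.setdefault("sub_rate", 0.002)
    kw.setdefault("quality_profile", tuple(default_quality_profile()))
    return ReadSimConfig(platform="short", n_reads=n_reads, seed=seed, **kw)


def default_quality_profile(length: int = 36) -> np.ndarray:
    """Per-position expected Phred scores: noisy start, decaying tail.

    The first two cycles and the final four are markedly worse than the
    middle of the read, which is what motivates trimming to positions 3-32.
    """
    prof = np.linspace(38.0, 32.0, length)
    prof[:2] = 26.0
    prof[-4:] = 18.0
    return prof


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


@dataclass
class GenomePair:
    """Simulated genomes plus their ground truth."""

    male: str
    female: str
    layout: pd.DataFrame       # sex, family, kind, start, end, n_copies
    proportions: pd.DataFrame  # family, sex, footprint_bp, proportion
    controls: dict[str, str]   # spike-in control sequences
    spec: GenomeSimSpec

    def sequence(self, sex: str) -> str:
        return self.male if sex == "male" else self.female

    def family_of_position(self, sex: str, pos: int) -> str:
        """Family name covering a genome position, or 'background'."""
        sub = self.layout[self.layout["sex"] == sex]
        hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
        return hit["family"].iloc[0] if len(hit) else "background"

    def interval_lookup(self, sex: str):
        """Vectorised position -> family mapper for one sex."""
        sub = self.layout[self.layout["sex"] == sex].sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        fams = sub["family"].to_numpy()

        def lookup(pos: np.ndarray) -> np.ndarray:
            idx = np.searchsorted(starts, pos, side="right") - 1
            idx = np.clip(idx, 0, len(starts) - 1)
            inside = (pos >= starts[idx]) & (pos < ends[idx])
            out = np.where(inside, fams[idx], "background")
            return out

        return lookup


def _mutate(master: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    copy = master.copy()
    if divergence > 0:
        mask = rng.random(len(copy)) < divergence
        shift = rng.integers(1, 4, size=len(copy)).astype(np.uint8)
        mut = (copy + shift) % 4
        copy[mask] = mut[mask]
    return copy


def _family_master(fam: RepeatFamilySpec, rng: np.random.Generator) -> np.ndarray:
    if fam.kind != "rdna_like":
        return random_codes(rng, fam.unit_length, fam.gc_target)
    # rDNA-like unit: gene block, then an intergenic spacer carrying a
    # head-to-tail subrepeat array flanked by spacer sequence.
    gene_len = fam.unit_length // 2
    igs_len = fam.unit_length - gene_len
    sub = random_codes(rng, fam.subrepeat_length, fam.gc_target)
    n_sub = max(1, int(0.6 * igs_len) // fam.subrepeat_length)
    block = np.tile(sub, n_sub)
    spacer_len = igs_len - len(block)
    gene = random_codes(rng, gene_len, fam.gc_target)
    sp_a = random_codes(rng, spacer_len // 2, fam.gc_target)
    sp_b = random_codes(rng, spacer_len - len(sp_a), fam.gc_target)
    return np.concatenate([gene, sp_a, block, sp_b])


def _apply_variants(copy: np.ndarray, fam: RepeatFamilySpec,
                    rng: np.random.Generator) -> np.ndarray:
    for pos, base, freq in fam.monomer_variants:
        if rng.random() < freq:
            copy[pos] = "ACGT".index(base)
    return copy


def build_genome_pair(spec: GenomeSimSpec) -> GenomePair:
    """Construct the male/female genome pair described by ``spec``.

    Family master sequences, copy pools and the background are shared
    between the sexes, so the two genomes differ only in copy numbers and
    block order, exactly as a conspecific pair should.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    seq_rng, male_rng, female_rng, ctrl_rng = rng.spawn(4)

    copy_pools: dict[str, list[np.ndarray]] = {}
    controls: dict[str, str] = {}
    for fam in spec.families:
        master = _family_master(fam, seq_rng)
        if fam.kind == "spike_in":
            controls[fam.name] = decode(master)
            continue
        n = max(fam.copies_male, fam.copies_female)
        rates = (seq_rng.uniform(0, 2 * fam.divergence, size=n)
                 if fam.divergence > 0 else np.zeros(n))
        pool = [
            _apply_variants(_mutate(master, rates[i], seq_rng), fam, seq_rng)
            for i in range(n)
        ]
        copy_pools[fam.name] = pool

    max_bg = max(
        spec.genome_1C_male - sum(f.footprint("male") for f in spec.families),
        spec.genome_1C_female - sum(f.footprint("female") for f in spec.families),
    )
    background = random_codes(seq_rng, max_bg, spec.background_gc)

    genomes: dict[str, str] = {}
    layout_rows: list[dict] = []
    prop_rows: list[dict] = []
    for sex, sex_rng, size_1c in (
        ("male", male_rng, spec.genome_1C_male),
        ("female", female_rng, spec.genome_1C_female),
    ):
        blocks: list[tuple[str, np.ndarray, int]] = []  # (family, seq, n_copies)
        for fam in spec.families:
            if fam.kind == "spike_in":
                continue
            copies = fam.copies_male if sex == "male" else fam.copies_female
            if copies == 0:
                continue
            pool = copy_pools[fam.name][:copies]
            if fam.kind == "dispersed":
                blocks.extend((fam.name, c, 1) for c in pool)
            else:  # tandem or rdna_like: contiguous head-to-tail array
                blocks.append((fam.name, np.concatenate(pool), copies))
        order = sex_rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]

        bg_total = size_1c - sum(f.footprint(sex) for f in spec.families)
        bg = background[:bg_total]
        cuts = np.sort(sex_rng.integers(0, bg_total + 1, size=len(blocks)))
        bg_chunks = np.split(bg, cuts)

        parts: list[np.ndarray] = []
        pos = 0
        kind_of = {f.name: f.kind for f in spec.families}
        for i, chunk in enumerate(bg_chunks):
            parts.append(chunk)
            pos += len(chunk)
            if i < len(blocks):
                name, seq, ncop = blocks[i]
                layout_rows.append({
                    "sex": sex, "family": name, "kind": kind_of[name],
                    "start": pos, "end": pos + len(seq), "n_copies": ncop,
                })
                parts.append(seq)
                pos += len(seq)
        genomes[sex] = decode(np.concatenate(parts))
        assert len(genomes[sex]) == size_1c
        for fam in spec.families:
            if fam.kind == "spike_in":
                continue
            foot = fam.footprint(sex)
            prop_rows.append({
                "family": fam.name, "sex": sex, "footprint_bp": foot,
                "proportion": foot / size_1c,
            })

    layout = pd.DataFrame(layout_rows, columns=["sex", "family", "kind", "start", "end", "n_copies"])
    props = pd.DataFrame(prop_rows, columns=["family", "sex", "footprint_bp", "proportion"])
    return GenomePair(genomes["male"], genomes["female"], layout, props, controls, spec)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _gc_accept(windows_gc: np.ndarray, slope: float, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sampling acceptance mask for GC-biased sampling."""
    logw = slope * (windows_gc - 0.5)
    logw -= abs(slope) * 0.5  # normalise so max weight is 1
    return rng.random(len(windows_gc)) < np.exp(logw)


def simulate_reads(genome: str, config: ReadSimConfig, prefix: str = "r",
                   sample: str | None = None) -> ReadSet:
    """Sample reads from one genome sequence.

    Start positions are uniform (or GC-biased when ``gc_bias_slope`` is not
    zero), both strands are sampled with probability 0.5, long-read lengths
    are Gaussian truncated to [50, 2 x mean], and ``duplicate_rate`` of long
    reads are exact copies of previously emitted reads.
    """
    config.validate()
    if not genome:
        raise ValueError("empty genome sequence")
    if config.n_reads == 0:
        logger.warning("simulate_reads called with n_reads=0; returning empty set")
        quals = (np.zeros((0, ReadSimConfig.SHORT_LENGTH), dtype=np.int16)
                 if config.platform == "short" else None)
        return ReadSet([], [], quals, sample)
    rng = np.random.default_rng(config.seed)
    codes = encode(genome)
    if config.platform == "short":
        return _simulate_short(codes, config, rng, prefix, sample)
    return _simulate_long(codes, config, rng, prefix, sample)


def _apply_errors_codes(read: np.ndarray, config: ReadSimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    if config.sub_rate > 0:
        mask = (rng.random(len(read)) < config.sub_rate) & (read < 4)
        if mask.any():
            shift = rng.integers(1, 4, size=int(mask.sum())).astype(np.uint8)
            read = read.copy()
            read[mask] = (read[mask] + shift) % 4
    if config.ins_rate > 0 or config.del_rate > 0:
        out = []
        for b in read:
            if config.del_rate > 0 and rng.random() < config.del_rate:
                continue
            out.append(b)
            if config.ins_rate > 0 and rng.random() < config.ins_rate:
                out.append(rng.integers(0, 4))
        read = np.array(out, dtype=np.uint8) if out else read[:1]
    return read


def _simulate_long(codes: np.ndarray, config: ReadSimConfig,
                   rng: np.random.Generator, prefix: str,
                   sample: str | None) -> ReadSet:
    glen = len(codes)
    ids: list[str] = []
    seqs: list[str] = []
    lo, hi = 50, 2 * config.mean_length
    for i in range(config.n_reads):
        if seqs and rng.random() < config.duplicate_rate:
            j = int(rng.integers(0, len(seqs)))
            ids.append(f"{prefix}_{i}|dup_of={ids[j].split('|')[0]}")
            seqs.append(seqs[j])
            continue
        while True:
            length = int(np.clip(round(rng.normal(config.mean_length, config.length_sd)),
                                 lo, min(hi, glen)))
            start = int(rng.integers(0, glen - length + 1))
            window = codes[start:start + length]
            if config.gc_bias_slope != 0.0:
                acgt = window < 4
                gc = ((window == 1) | (window == 2)).sum() / max(int(acgt.sum()), 1)
                if not _gc_accept(np.array([gc]), config.gc_bias_slope, rng)[0]:
                    continue
            break
        strand = "-" if rng.random() < 0.5 else "+"
        read = revcomp_codes(window) if strand == "-" else window.copy()
        read = _apply_errors_codes(read, config, rng)
        ids.append(f"{prefix}_{i}|pos={start}|strand={strand}")
        seqs.append(decode(read))
    return ReadSet(ids, seqs, None, sample)


def _simulate_short(codes: np.ndarray, config: ReadSimConfig,
                    rng: np.random.Generator, prefix: str,
                    sample: str | None) -> ReadSet:
    L = ReadSimConfig.SHORT_LENGTH
    glen = len(codes)
    if glen < L:
        raise ValueError(f"genome shorter than read length {L}")
    n_pos = glen - L + 1
    n = config.n_reads

    if config.gc_bias_slope != 0.0:
        is_gc = ((codes == 1) | (codes == 2)).astype(np.int32)
        cum = np.concatenate([[0], np.cumsum(is_gc)])
        win_gc = (cum[L:] - cum[:-L]) / L
        w = np.exp(config.gc_bias_slope * (win_gc - 0.5))
        starts = rng.choice(n_pos, size=n, replace=True, p=w / w.sum())
    else:
        starts = rng.integers(0, n_pos, size=n)

    idx = starts[:, None] + np.arange(L)[None, :]
    mat = codes[idx]
    minus = rng.random(n) < 0.5
    if minus.any():
        sub = mat[minus][:, ::-1]
        acgt = sub < 4
        sub[acgt] = 3 - sub[acgt]
        mat[minus] = sub

    if config.sub_rate > 0:
        mask = (rng.random(mat.shape) < config.sub_rate) & (mat < 4)
        shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
        mat[mask] = (mat[mask] + shift[mask]) % 4
    if config.ins_rate > 0 or config.del_rate > 0:
        for i in range(n):
            edited = _apply_errors_codes(
                mat[i],
                ReadSimConfig(platform="short", n_reads=1,
                              ins_rate=config.ins_rate, del_rate=config.del_rate),
                rng,
            )
            if len(edited) >= L:
                mat[i] = edited[:L]
            else:
                mat[i, :len(edited)] = edited
                mat[i, len(edited):] = 4

    profile = np.asarray(config.quality_profile if config.quality_profile is not None
                         else default_quality_profile(L), dtype=float)
    quals = np.clip(np.rint(rng.normal(profile[None, :], config.quality_sd, size=(n, L))),
                    2, 41).astype(np.int16)

    strands = np.where(minus, "-", "+")
    ids = [f"{prefix}_{i}|pos={int(starts[i])}|strand={strands[i]}" for i in range(n)]
    from ._seq import _DECODE  # local import to avoid polluting module namespace
    seqs = [_DECODE[row].tobytes().decode("ascii") for row in mat]
    return ReadSet(ids, seqs, quals, sample)


# ---------------------------------------------------------------------------
# spike-in controls
# ---------------------------------------------------------------------------


def add_spike_ins(pool: ReadSet, controls: Mapping[str, str],
                  mass_fractions: Mapping[str, float],
                  config: ReadSimConfig, seed: int = 0) -> tuple[ReadSet, dict[str, float]]:
    """Append control-derived reads so each control's expected base fraction
    of the final pool equals its requested mass fraction.

    Returns the augmented pool and the truth fractions actually requested.
    """
    total = sum(mass_fractions.values())
    if any(f < 0 for f in mass_fractions.values()) or total >= 0.5:
        raise ValueError("mass fractions must be >= 0 and sum below 0.5")
    for name, f in mass_fractions.items():
        if f > 0 and not controls.get(name):
            raise ValueError(f"empty control sequence for {name!r}")
    base_total = pool.total_bases()
    final_total = base_total / (1.0 - total)
    read_len = (ReadSimConfig.SHORT_LENGTH if config.platform == "short"
                else config.mean_length)
    out = pool
    truth: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    for name, frac in mass_fractions.items():
        truth[name] = frac
        if frac == 0:
            continue
        n = max(1, round(frac * final_total / read_len))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = ReadSimConfig(
            platform=config.platform, n_reads=n, mean_length=config.mean_length,
            length_sd=config.length_sd, sub_rate=config.sub_rate,
            ins_rate=config.ins_rate, del_rate=config.del_rate,
            duplicate_rate=0.0, gc_bias_slope=config.gc_bias_slope,
            quality_profile=config.quality_profile, quality_sd=config.quality_sd,
            seed=sub_seed,
        )
        spike = simulate_reads(controls[name], cfg, prefix=name, sample=pool.sample)
        spike.ids = [f"{rid}|src={name}" for rid in spike.ids]
        out = out.extend(spike)
    return out, truth


# ---------------------------------------------------------------------------
# demo specification (desk-scale study conditions)
# ---------------------------------------------------------------------------


def demo_spec(seed: int = 0) -> GenomeSimSpec:
    """A desk-scale genome pair mirroring the analysed repeat categories.

    The family roster emulates the composition the analysis targets: two
    dispersed retroelement-like families, a homogeneous centromeric-style
    satellite, a male-amplified satellite subfamily (STAR-Y analogue), an
    rDNA-like unit with embedded IGS subrepeats, and two spike-in controls.
    Proportions are scaled to a ~100 kb 1C so that a full pipeline run
    stays in the seconds-to-minutes range while keeping realistic category
    sizes.
    """
    families = (
        RepeatFamilySpec("angela_like", "dispersed", 1000, 12, 12,
                         divergence=0.02, gc_target=0.40),
        RepeatFamilySpec("ogre_like", "dispersed", 1200, 10, 11,
                         divergence=0.02, gc_target=0.36),
        RepeatFamilySpec("star_sat", "tandem", 43, 300, 300,
                         divergence=0.01, gc_target=0.35),
        RepeatFamilySpec("stary_sat", "tandem", 40, 100, 4,
                         divergence=0.01, gc_target=0.35),
        RepeatFamilySpec("rdna_like", "rdna_like", 2500, 3, 3,
                         divergence=0.005, gc_target=0.60),
        RepeatFamilySpec("lambda_ctrl", "spike_in", 8000, 0, 0, gc_target=0.50),
        RepeatFamilySpec("t4_ctrl", "spike_in", 8000, 0, 0, gc_target=0.40),
    )
    male_foot = sum(f.footprint("male") for f in families)
    female_foot = sum(f.footprint("female") for f in families)
    return GenomeSimSpec(
        families=families,
        background_length=45000,
        genome_1C_male=male_foot + 51000,
        genome_1C_female=female_foot + 51000,
        seed=seed,
    )
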