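"""Published reference quantities for the *Silene latifolia* genome.

These constants and the bundled composition table are the published
estimates for the organism the pipeline was designed around; they serve as
inputs for copy-number arithmetic, coverage calculations and comparisons
against pipeline output.  All genome sizes are in base pairs.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

#: DNA amounts of the diploid (2C) nucleus, bp.
GENOME_SIZE_2C = {"male": 5.85e9, "female": 5.73e9}

#: Haploid (1C) genome sizes, bp (half the 2C amounts).
GENOME_SIZE_1C = {sex: v / 2 for sex, v in GENOME_SIZE_2C.items()}

#: Combined long-read yield of the two shotgun runs, bp.
LONG_READ_TOTAL_BASES = 161.7e6

#: High-quality 30-nt tag yields per sample (before equal subsampling).
TAG_YIELD = {"male": 5.2e6, "female": 8.9e6}

#: Number of tags subsampled from each dataset for the comparison.
TAGS_SAMPLED_PER_DATASET = 5_000_000

#: Long-read genome coverage used for copy-number normalisation of profiles.
LONG_READ_COVERAGE = 0.056

#: Reconstructed satellite monomer lengths, bp.
MONOMER_LENGTHS = {
    "STAR-C": 43,
    "15Ssp": 159,
    "TRAYC-like_CL68": 165,
    "TRAYC-like_CL156": 200,
    "X43.1": 313,
}

#: Published group subtotals of the genome-proportion table, percent.
#: (The per-family rows below them omit minor clusters, so the subtotals
#: are carried separately.)
COMPOSITION_SUBTOTALS = {
    "Retroelements": {"male": 49.7, "female": 51.4},
    "Ty3/gypsy": {"male": 35.7, "female": 37.5},
    "Ty1/copia": {"male": 13.7, "female": 13.7},
    "DNA transposons": {"male": 1.45, "female": 1.44},
    "Satellite repeats": {"male": 3.09, "female": 3.19},
    "TOTAL": {"male": 61.4, "female": 63.3},
}


def repeat_composition() -> pd.DataFrame:
    """Per-family genome proportions (percent) for the male/female genomes."""
    ref = importlib.resources.files("replowpass.data") / "silene_repeat_composition.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def gypsy_copia_ratio() -> float:
    """Ty3/gypsy : Ty1/copia genome-proportion ratio, both sexes pooled."""
    g = COMPOSITION_SUBTOTALS["Ty3/gypsy"]
    c = COMPOSITION_SUBTOTALS["Ty1/copia"]
    return (g["male"] + g["female"]) / (c["male"] + c["female"])


def ltr_total_percent() -> dict[str, float]:
    """LTR-retrotransposon (gypsy + copia) genome percentage per sex."""
    g = COMPOSITION_SUBTOTALS["Ty3/gypsy"]
    c = COMPOSITION_SUBTOTALS["Ty1/copia"]
    return {sex: g[sex] + c[sex] for sex in ("male", "female")}


def satellite_total_percent() -> dict[str, float]:
    """Summed satellite-family genome percentage per sex (from family rows)."""
    comp = repeat_composition()
    sat = comp[comp["type"] == "satellite"]
    return {"male": float(sat["male_pct"].sum()),
            "female": float(sat["female_pct"].sum())}
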