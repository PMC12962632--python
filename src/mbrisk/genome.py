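"""Packaged genome reference tables (hg19).

Chromosome sizes bound segment coordinates; the chr17 p-arm boundary
supports arm-level 17p calls; gene loci are used by the synthetic
segment-profile generator to place biologically plausible focal events.
"""

from __future__ import annotations

# hg19 chromosome lengths (bp)
CHROM_SIZES: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "8": 146_364_022,
    "9": 141_213_431,
    "10": 135_534_747,
    "11": 135_006_516,
    "12": 133_851_895,
    "13": 115_169_878,
    "14": 107_349_540,
    "15": 102_531_392,
    "16": 90_354_753,
    "17": 81_195_210,
    "18": 78_077_248,
    "19": 59_128_983,
    "20": 63_025_520,
    "21": 48_129_895,
    "22": 51_304_566,
    "X": 155_270_560,
    "Y": 59_373_566,
}

AUTOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23))
CHROMOSOMES: tuple[str, ...] = AUTOSOMES + ("X", "Y")

# Rank used to order chromosomes in outputs.
CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}

# End of the chr17 p arm (p-arm side of the hg19 centromere gap).
CHR17_P_END: int = 24_000_000

# hg19 gene loci relevant to medulloblastoma focal-event phenotypes.
GENE_LOCI: dict[str, tuple[str, int, int]] = {
    "MYC": ("8", 128_748_315, 128_753_680),
    "MYCN": ("2", 16_080_683, 16_087_129),
    "GLI2": ("2", 121_554_866, 121_750_229),
}


def normalize_chrom(label: str) -> str:
    """Map 'chr7'/'7' style labels onto the packaged naming ('7', 'X', ...)."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    if c not in CHROM_SIZES:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return c
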