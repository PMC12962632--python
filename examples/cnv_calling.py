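"""Focal copy-number event calling and chromosome-level phenotypes.

Builds a synthetic segmented profile with a planted 3-Mb MYCN-locus
amplification, a 17p deletion, and a whole-chromosome-7 gain, then
calls focal events (<10 Mb span, deviation > 4x the profile MAD) and
chromosome/arm-level aberrations, including the whole-chromosome-
aberration favorable-risk (WCA-FR) phenotype.
"""

from mbrisk import (
    call_chromosome_aberrations,
    call_focal_events,
    generate_segment_profile,
    profile_baseline_and_mad,
    wca_fr_phenotype,
)
from mbrisk.genome import CHROM_SIZES, GENE_LOCI

mycn_chrom, mycn_start, mycn_end = GENE_LOCI["MYCN"]
profile = generate_segment_profile(
    "EXAMPLE-01",
    planted_events=[
        (mycn_chrom, mycn_start - 1_000_000, mycn_end + 1_000_000, 0.9),  # MYCN amp
        ("17", 2_000_000, 6_000_000, -0.6),                               # 17p deletion
        ("7", 0, CHROM_SIZES["7"], 0.3),                                  # chr7 gain
    ],
    noise_sd=0.02,
    seed=7,
)

baseline, mad = profile_baseline_and_mad(profile)
print(f"baseline={baseline:+.4f}  MAD={mad:.4f}  threshold=4xMAD={4 * max(mad, 0.01):.4f}")

print("\nFocal events (<10 Mb, 0-based half-open coordinates):")
for ev in call_focal_events(profile):
    print(f"  chr{ev.chrom}:{ev.start:,}-{ev.end:,}  {ev.kind:13s} log2={ev.log2_ratio:+.2f}")
print("(the whole-chr7 gain is correctly NOT focal)")

calls = call_chromosome_aberrations(profile)
print(f"\nchr7={calls['7']}  chr8={calls['8']}  chr11={calls['11']}  17p={calls.arm_17p}")
print(f"WCA-FR phenotype (>=2 of 7 gain / 8 loss / 11 loss): {wca_fr_phenotype(calls)}")
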