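"""Copy-number segment filtering, SNV overlap, and gain-allele placement.

Builds the 3q-gain / 7q-loss analog profile (plus sub-threshold decoys),
overlaps the discovery call set with it, and asks on which allele of a
single-copy gain a mutation seen in 14 of 50 reads must sit.
"""

import math

from somaticmz import (
    filter_segments,
    gain_allele_placement,
    load_discovery_snvs,
    overlap_cna,
    simulate_cna_profile,
)

segments = simulate_cna_profile(include_decoys=True)
kept = filter_segments(segments)
print(f"segments: {len(segments)} raw -> {len(kept)} after the 5-marker/100-kb filter")

observations = load_discovery_snvs()
hits = overlap_cna(observations, kept)
for obs, seg in zip(observations, hits):
    if seg is not None:
        print(f"{obs.gene} ({obs.chrom}:{obs.pos}) falls inside the {seg.state} segment")

placement = gain_allele_placement(14, 50)
print(
    f"14/50 variant reads under a 3-copy gain: LR = 2^{math.log2(placement.lr):.0f} "
    f"-> {placement.call}"
)
print(
    "-> a mutation on the duplicated allele would show ~2/3 of reads; "
    "one third of reads puts it on the non-duplicated homolog."
)
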