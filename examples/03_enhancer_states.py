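"""Enhancer chromatin-state classification and activation switching.

States follow the three-mark convention: active = H3K27ac without
H3K27me3; primed = H3K4me1 alone; poised = H3K4me1 + H3K27me3.
"""
from chromlink import GenomicInterval, classify_enhancer_state, classify_enhancers

for marks in [{"H3K27ac"}, {"H3K4me1"}, {"H3K4me1", "H3K27me3"}, set()]:
    print(f"{sorted(marks) or ['(none)']} -> {classify_enhancer_state(marks)}")

enhancer = [GenomicInterval("chr1", 10_000, 11_000)]
peaks = {
    "control": {"H3K27ac": [GenomicInterval("chr1", 10_200, 10_700)]},
    "dex": {
        "H3K4me1": [GenomicInterval("chr1", 10_100, 10_900)],
        "H3K27me3": [GenomicInterval("chr1", 10_000, 11_000)],
    },
}
(elem,) = classify_enhancers(enhancer, peaks)
print(f"control={elem.state_control} treated={elem.state_treated} "
      f"switch={elem.switch}")
# An enhancer that loses H3K27ac and gains H3K4me1+H3K27me3 after
# treatment shifts from active to poised: a "deactivated" switch.
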