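"""Replicate-consensus peaks and condition-level gain/loss calling.

Consensus keeps union-merged regions supported by >= k replicates;
diff labels each consensus peak stable / gained / lost by >= 1 bp
overlap between conditions.
"""
from chromlink import PeakSet, GenomicInterval, consensus_peaks, diff_peaks

def peaks(*spans):
    return [GenomicInterval("chr1", s, e) for s, e in spans]

replicates = [
    PeakSet("H3K27ac", "control", "1", peaks((100, 300), (1000, 1200))),
    PeakSet("H3K27ac", "control", "2", peaks((120, 320), (5000, 5200))),
    PeakSet("H3K27ac", "control", "3", peaks((90, 280))),
]
control = consensus_peaks(replicates, k=2)
print("control consensus (region, replicate support):")
for iv in control:
    print(f"  {iv}  support={iv.score:.0f}")

treated = peaks((150, 350), (8000, 8200))
d = diff_peaks(control, treated, mark="H3K27ac")
print(f"stable={len(d.stable)} lost={len(d.lost)} gained={len(d.gained)}")
# The region near 100-320 is seen in all three replicates (support 3)
# and persists after treatment (stable); 1000-1200 and 5000-5200 are
# single-replicate peaks and never reach consensus; 8000-8200 is a
# treatment-specific (gained) peak.
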