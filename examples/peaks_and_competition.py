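"""Apply the two auxiliary rule-based analyses.

1) High-confidence peak filtering: keep peaks with 100-5000 wild-type reads
   that are overrepresented in the wild type (fold change > 1).
2) Competition-assay normalization: GFP+ percentages divided by their day-0
   value and by the negative control's trajectory, so a neutral guide is a
   flat line at 1 and a depleting guide decays below 1.
"""

import pandas as pd

from epiguide.screen_analysis import (PeakRecord, filter_high_confidence_peaks,
                                      normalize_competition)

peaks = [
    PeakRecord("chr5", 1000, 1600, 150, 1.8),   # kept
    PeakRecord("chr5", 4000, 4400, 50, 2.0),    # too few reads
    PeakRecord("chr5", 9000, 9900, 6000, 2.0),  # too many reads
    PeakRecord("chr5", 12000, 12500, 300, 0.9), # not WT-enriched
]
kept = filter_high_confidence_peaks(peaks)
print(f"high-confidence peaks: {len(kept)}/{len(peaks)}")
for p in kept:
    print(f"  {p.chrom}:{p.start}-{p.end} reads={p.wt_read_count} fc={p.fc_wt}")

days = [0, 2, 4, 6, 8]
gfp = pd.DataFrame(
    [[50, 40, 28, 18, 10],   # guide against an essential gene
     [48, 47, 49, 46, 48]],  # neutral guide
    index=["sgEssential", "sgNeutral"], columns=days, dtype=float)
neg = pd.Series([50, 49, 51, 50, 49], index=days, dtype=float)

norm = normalize_competition(gfp, neg)
print()
print(norm.round(3).to_string())
# sgEssential falls towards 0 (GFP+ knockout cells are outcompeted) while
# sgNeutral stays near 1 after control normalization.
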