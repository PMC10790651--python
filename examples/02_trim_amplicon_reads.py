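"""Quality-trim 16S amplicon Read-1 sequences before classification.

The amplicon path head-crops the first 15 bases (primer/adapter remnant),
strips low-quality ends, cuts at the first 4-base window with mean Phred
below 15, and discards reads shorter than 36 bases — reads that fail never
reach the taxonomic classifier.
"""

from scbacteria.quant import TrimParams, quality_trim

params = TrimParams(adapter_sequences=("AGATCGGAAGAGCACACGTC",))

reads = {
    "clean_120bp": ("ACGT" * 30, [37] * 120),
    "degrading_tail": ("ACGT" * 25, [37] * 60 + [30] * 20 + [8] * 20),
    "adapter_readthrough": ("GATTACA" * 10 + "AGATCGGAAGAGCACACGTC",
                            [37] * 90),
    "too_short_after_headcrop": ("ACGT" * 12, [37] * 48),
}

for name, (seq, quals) in reads.items():
    out = quality_trim(seq, quals, params)
    if out is None:
        print(f"{name:28s} -> discarded (below 36 bases after trimming)")
    else:
        print(f"{name:28s} -> {len(seq):3d} bp in, {len(out[0]):3d} bp kept")
# Kept lengths show each operator acting: the clean read loses only the
# 15-base headcrop; the degrading tail is cut at the first bad window; the
# adapter read is clipped at the adapter start before quality steps.
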