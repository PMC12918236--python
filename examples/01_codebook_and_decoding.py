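"""Build the MERFISH barcode codebook and decode noisy reads.

Constructs the maximal 16-bit, weight-4, distance-4 code, assigns 136
genes plus 4 blank barcodes, simulates reads with 1% per-bit errors, and
decodes them with single-bit correction.
"""

from omlo import codec, synth

words = codec.build_codebook(16, 4, 4)
print(f"codebook: {len(words)} words (maximal: {codec.verify_maximal(words)})")

cb = codec.assign_barcodes(words, [f"gene_{i:03d}" for i in range(1, 137)],
                           n_blanks=4, seed=0)
print(f"assigned: {len(cb.genes)} genes + {len(cb.blanks)} blanks")

spots, truth = synth.gen_spot_reads(cb, n_spots=5000, error_rate=0.01, seed=0)
decoded = codec.decode_spots(spots, cb, correct_single_bit=True)
exact_only = codec.decode_spots(spots, cb, correct_single_bit=False)

rec = (decoded["decoded"] == truth["true_gene"]).mean()
rec0 = (exact_only["decoded"] == truth["true_gene"]).mean()
fdr = codec.blank_fdr(decoded, cb)
print(f"recovery with correction: {rec:.3f}  exact-match only: {rec0:.3f}")
print(f"blank-based misidentification estimate: {fdr:.4f}")
# With 1% bit flips ~85% of reads are error-free and ~14% carry one flip;
# single-bit correction recovers nearly all of the latter, and the blank
# rate stays near zero because double errors rarely land on a codeword.
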