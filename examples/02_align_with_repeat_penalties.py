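"""Align a read against a repeat-bearing window and inspect the penalty.

A one-copy homopolymer shortening costs N[1, l, l-1] (the measured -log
frequency of that miscall) instead of the context-blind affine G_open = 5,
so the aligner places the gap inside the repeat where the error most likely
happened.
"""

from npore import PenaltyModel, align

model = PenaltyModel.default()

ref = "GGCAAAAAAAGT"   # 7-copy A homopolymer
read = "GGCAAAAAAGT"   # one A missing

res = align(read, ref, model)
print(f"read {read} vs ref {ref}")
print(f"CIGAR {res.cigar}  penalty {res.score:.3f}")
print(f"copy-number penalty N[1,7,6] = {model.n_cost(1, 7, 6):.3f} "
      f"(affine G_open would be {model.G_open:.1f})")

# With the tensor disabled the same deletion must pay the affine price:
affine = PenaltyModel.affine_only(match_cost=0.0)
res_affine = align(read, ref, affine)
print(f"affine-only: CIGAR {res_affine.cigar}  penalty {res_affine.score:.3f}")
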