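"""Rewrite a phased truth VCF into the realigner's preferred representation.

Two SNPs that encode "one homopolymer longer, the next one shorter" are
re-expressed as an insertion plus a deletion. The haplotype sequences the
VCF implies are unchanged -- only the representation moves.
"""

from npore import PenaltyModel
from npore.standardize import apply_phased_vcf, standardize

ref = {"chr1": "GCGATT" + "AAAAAAAA" + "G" + "TTTTTTTT" + "CAGTCA"}
records = {"chr1": [
    (14, "G", ("A",), (1, 0)),   # SNP-wise: the spacer G read as A ...
    (15, "T", ("G",), (1, 0)),   # ... and the first T read as G
]}

before = apply_phased_vcf(ref, records)["chr1"]
model = PenaltyModel.default()
std = standardize(ref, records, model, anchor_len=50)
after = apply_phased_vcf(ref, std)["chr1"]

print("input records:")
for pos, r, alts, gt in records["chr1"]:
    print(f"  pos {pos + 1}: {r} -> {','.join(alts)}  GT {gt[0]}|{gt[1]}")
print("standardized records:")
for pos, r, alts, gt in std["chr1"]:
    print(f"  pos {pos + 1}: {r} -> {','.join(alts)}  GT {gt[0]}|{gt[1]}")
print("haplotype 1 unchanged:", before[0].seq == after[0].seq)

# The standardized VCF holds an insertion (extra A) and a deletion (missing
# T) anchored at the two homopolymers: the same haplotype, in the coordinates
# the realigned reads will actually show.
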