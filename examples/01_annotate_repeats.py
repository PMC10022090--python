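"""Annotate n-polymers in a reference sequence.

Every position that starts a unit of an eligible repeat (>= 3 exact copies
of a 1-6 bp unit) is tagged with the polymer's copy count l and the unit's
index idx. These annotations are what later gates the aligner's cheap
copy-number indel transitions.
"""

from npore import annotate_reference

seq = "ATATATATTTTTAAAGCGCGC"
ann = annotate_reference(seq)

print("reference:", seq)
for n in (1, 2):
    print(f"n={n}  l  :", "".join(str(x) for x in ann.l[n - 1]))
    print(f"n={n}  idx:", "".join(str(x) for x in ann.idx[n - 1]))
for n in (1, 2):
    for start, copies in ann.anchors(n):
        unit = seq[start:start + n]
        print(f"polymer: unit {unit!r} x {copies} at position {start}")

# The l row for n=1 places 5 on the five T's (a 5-copy homopolymer) and 3 on
# the AAA run; for n=2 both the AT x 4 and the phase-shifted TA x 3 repeats
# are annotated, which is why l alternates 4,3,4,3,... at the start.
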