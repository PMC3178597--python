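"""Degeneracy and amplicon arithmetic for the packaged COI primer panel.

Each degenerate primer encodes a pool of exact oligos (its degeneracy);
amplicon length between a forward start and a reverse-window start
includes both primers.
"""

from mycobarcode import preprocess as pp

primers = {p.name: p for p in pp.load_primer_table()}

print("primer      direction  start  degeneracy")
for p in primers.values():
    print(f"{p.name:10s}  {p.direction:8s}  {p.start_position:5d}  "
          f"{pp.primer_degeneracy(p):6d}")

# predicted span between the 11F forward site and the 2eR reverse window,
# both primers included
fwd, rev = primers["11F"], primers["2eR"]
length = pp.predict_amplicon(fwd.start_position, rev.start_position,
                             len(rev.sequence))
print(f"\n11F/2eR predicted span on the reference exon: {length} bp")
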