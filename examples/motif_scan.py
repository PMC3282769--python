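"""Scan a sequence with the degenerate transcarbamylase signatures.

The notation: capitals are predominant residues, lower case residues
occur at lower frequency, X matches anything, and (A/b/c) groups list
alternatives. The 230-loop heptapeptide DVWYGLY of E. faecalis PTC
contains YGLY, which matches the loop signature (Y/W)(G/W)(V/L/I)X.
"""

from ptcsig import SequenceRecord, parse_pattern, scan

seq = SequenceRecord(id="demo", residues="AASTRTAADVWYGLYAALAAFLAA")

for notation in ("STRT", "(Y/W)(G/W)(V/L/I)X", "(L/f/v/i/m)XX(F/Y/L/M/v)(L/i/m)"):
    pattern = parse_pattern(notation)
    for m in scan(seq, pattern):
        print(
            f"{notation:<32} match {m.matched!r} at {m.start}-{m.end} "
            f"(primary fraction {m.primary_fraction:.2f})"
        )

print(
    "\nprimary fraction = share of non-wildcard positions satisfied by the\n"
    "predominant residue set; 1.00 means a fully canonical match."
)
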