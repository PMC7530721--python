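"""Scan a 5'-UTR for upstream ORFs.

Every ATG with an in-frame stop inside the UTR yields one uORF; nested
and overlapping uORFs are all reported, and uORFs sharing a start or
stop codon are merged for counting.
"""

from cpuorf import scan_uorfs

utr = "CCTTATGGCACATTGGAAATAACCTTATGATGCCCTAATT"
#          ^uORF 1 (MAHWK)         ^uORF 2+3 share a stop

for start, end in scan_uorfs(utr):
    nt = utr[start:end]
    print(f"uORF at [{start}, {end}): {nt}")

print()
print("The two ATGs at offsets 26/29 share one stop codon, so a gene-level")
print("count would merge them into a single uORF unit.")
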