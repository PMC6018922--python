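"""Theoretical sequencing coverage from library and genome metrics.

Coverage is the sequenced bases (read pairs x 2 x read length) over the
2C genome size (twice the tabulated Gb/2Cx value); when the genome size
of an accession is unknown, a conservative 2.2 Gb/2Cx maximum is
assumed, understating the true coverage.
"""

import dosagescan as ds

libraries = [
    ("accession A", 18_899_157, 100, 1.88),
    ("accession B", 13_824_190, 100, 5.22),
    ("accession C (size unknown)", 33_933_832, 150, None),
]
for name, pairs, read_len, size_gb in libraries:
    cov = ds.theoretical_coverage(pairs, read_len, size_gb)
    size_str = f"{size_gb} Gb" if size_gb else "2.2 Gb assumed"
    print(f"{name}: {pairs:,} pairs x 2 x {read_len} bp over {size_str} "
          f"-> {cov:.2f}x")
print("(around 1x per monoploid genome is enough for interval-based "
      "copy-number calls on gene-sized targets)")
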