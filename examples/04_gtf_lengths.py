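"""Exon-union transcript lengths from a GTF.

Writes a three-transcript toy GTF and computes effective lengths as the union
of each transcript's exons, the length that enters the RPKM denominator.
"""

import tempfile
from pathlib import Path

from coldscreen.model import transcript_lengths_from_gtf

GTF = """\
chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttoy\texon\t51\t150\t.\t+\t.\tgene_id "gA"; transcript_id "tA1";
chr1\ttoy\texon\t1\t100\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
chr1\ttoy\texon\t201\t300\t.\t+\t.\tgene_id "gA"; transcript_id "tA2";
chr2\ttoy\texon\t10\t59\t.\t-\t.\tgene_id "gB"; transcript_id "tB1";
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.gtf"
    path.write_text(GTF)
    annotation = transcript_lengths_from_gtf(path)

print("transcript  gene  effective_length_nt")
for tid in annotation.transcript_ids:
    print(f"{tid:10s}  {annotation.gene_ids[tid]:4s}  {annotation.lengths[tid]}")
print()
print("tA1 spans 1-100 and 51-150: overlapping bases counted once -> 150 nt")
print("tA2 spans 1-100 and 201-300: disjoint exons summed -> 200 nt")
print("tB1 is a single 50 nt exon (1-based inclusive coordinates)")
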