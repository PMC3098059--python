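"""Extract peak sequences with 100-base flanks for motif discovery.

Writes a small synthetic genome, fetches the flanked sequence of two peaks
(the first is clipped at the chromosome start), and writes wrapped FASTA —
the input format motif finders such as MEME expect.
"""

import tempfile
from pathlib import Path

from peakannot import (
    FixtureSpec, GenomicRegion, RegionSet, get_peak_sequences, load_genome,
    make_genome, write_fasta,
)

workdir = Path(tempfile.mkdtemp())
genome_path = workdir / "genome.fa"
make_genome(FixtureSpec(seed=3, n_chroms=2, chrom_length=800), genome_path)
genome = load_genome(genome_path)

peaks = RegionSet("peaks", [
    GenomicRegion("chr1", 100, 300, "peak1"),
    GenomicRegion("chr2", 500, 600, "peak2"),
])
seqs = get_peak_sequences(peaks, upstream=100, downstream=100, genome=genome)
for s in seqs:
    print(f"{s.name}: fetched {s.chrom}:{s.fetch_start}-{s.fetch_end} "
          f"({len(s.sequence)} bases)")
write_fasta(seqs, workdir / "peaks.fa", width=50)
print("wrote", workdir / "peaks.fa")
# peak1's upstream flank would start at base 0, so the fetch clips to
# [1,400] (400 bases); peak2 gets the full [400,700] window (301 bases).
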