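"""Generate the synthetic stress study and summarize what was planted.

Emulates the study layout: one low-GC contig with 60 operons, 20 planted novel
sRNAs (half carrying the terminator + poly-U Hfq cassette), 8 known sRNAs, 10
UTR-bleed decoys, and a 7-condition x 4-time-point x 2-replicate RNA-seq
design at 50 k reads/library. Writes the genome, annotation, design and truth
tables under results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, SEED, load_study  # noqa: E402

from srnome import io as sio  # noqa: E402


def main() -> None:
    annotation, truth, design, readsets = load_study()
    sio.write_fasta(RESULTS / "genome.fasta", {annotation.contig_id: annotation.sequence})
    sio.write_annotation_gff3(RESULTS / "annotation.gff3", annotation)
    truth.to_frame().to_csv(RESULTS / "truth.tsv", sep="\t", index=False)
    design.to_frame().to_csv(RESULTS / "design.tsv", sep="\t", index=False)

    seq = annotation.sequence
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    n_reads = sum(len(rs) for rs in readsets.values())
    print(f"seed {SEED}: contig of {annotation.contig_length:,} nt at GC {gc:.3f}")
    print(f"planted: {len(truth.of_class('srna_true'))} novel sRNAs, "
          f"{len(truth.of_class('known_srna'))} known sRNAs, "
          f"{len(truth.of_class('utr_decoy'))} UTR-bleed decoys")
    print(f"{len(readsets)} libraries, {n_reads:,} reads total")
    print(f"tables under {RESULTS}")


if __name__ == "__main__":
    main()
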