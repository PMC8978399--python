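#!/usr/bin/env python
"""Reconstruct the five published Jozin element families and embed them
in synthetic contigs with ground truth.

Each family is rebuilt from its printed structural parameters (TIR,
12-bp subTIR unit motif, per-end copy counts, conserved-domain set,
total element length) and placed in a random background contig with a
3-bp target-site duplication. Writes, per family, a contig FASTA, a
ground-truth GFF3 and a DANTE-style domain hit table under
results/simulated/.
"""

import sys
from pathlib import Path

from cactascan import fixtures
from cactascan.gffio import truth_to_gff3_rows, write_gff3, write_truth_hit_table
from cactascan.sequence import write_fasta
from cactascan.simulate import build_element, embed_in_background, published_family_spec

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 20220404


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    for k, name in enumerate(sorted(fixtures.TIRS)):
        spec = published_family_spec(name, seed=SEED + k)
        seq, gt = build_element(spec)
        contig, truths = embed_in_background([(seq, gt)], 22000, 0.38,
                                             seed=SEED + 100 + k)
        contig.id = f"{name}_contig"
        write_fasta([contig], OUT / f"{name}.fasta")
        write_gff3(truth_to_gff3_rows(contig.id, truths),
                   OUT / f"{name}.truth.gff3")
        write_truth_hit_table(contig.id, truths, OUT / f"{name}.hits.gff3")
        print(f"{name}: element {len(seq)} bp "
              f"(published {fixtures.ELEMENT_LENGTHS[name]}), "
              f"subTIR copies {spec.n5}+{spec.n3}, "
              f"CDA {fixtures.FAMILY_CDA[name]} -> {OUT / name}.fasta")
    return 0


if __name__ == "__main__":
    sys.exit(main())
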