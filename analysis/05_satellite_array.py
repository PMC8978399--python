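#!/usr/bin/env python
"""Satellite-array arithmetic and dot-plot structure.

Reproduces the published figure of 32.5 monomers: tandem copies of the
171-bp consensus monomer truncated at a 5550-bp total yield a detected
array of monomer length 171 and copy number 32.5. Also builds an
element carrying the array near its 3' end (the published layout),
annotates it, and exports a self dot-plot hit list whose parallel
diagonals are spaced by the monomer length. Writes results/satellite/.
"""

import sys
from collections import Counter
from pathlib import Path

from cactascan import fixtures
from cactascan.captures import detect_tandem_array, locate_array_in_element
from cactascan.ends import ElementModel, self_dotplot
from cactascan.sequence import Interval, interval_length
from cactascan.simulate import ElementSpec, build_element

OUT = Path(__file__).resolve().parents[1] / "results" / "satellite"


def main() -> int:
    OUT.mkdir(parents=True, exist_ok=True)
    construction = (fixtures.SAT_MONOMER_171 * 33)[:5550]
    (arr,) = detect_tandem_array(construction)
    print(f"monomer construction (5550 bp): monomer {arr.monomer_len} bp, "
          f"copy number {arr.copy_number}")
    print(f"published interval {fixtures.SAT_ARRAY_INTERVAL}: length "
          f"{interval_length(Interval(*fixtures.SAT_ARRAY_INTERVAL))} bp")

    plot = self_dotplot(construction[:1200], word=20)
    offsets = Counter(b - a for a, b, _ in plot.hits if b > a)
    with open(OUT / "array_dotplot_offsets.tsv", "w") as fh:
        fh.write("diagonal_offset\tn_hits\n")
        for off, count in sorted(offsets.items()):
            fh.write(f"{off}\t{count}\n")
    print("dot-plot diagonal offsets (top 3):",
          offsets.most_common(3))

    spec = ElementSpec(
        tir=fixtures.TIRS["quinoa_scaffold3500"],
        subtir_motif=fixtures.SUBTIR_MOTIFS["iljinii"],
        n5=6, n3=6,
        sat_array=(fixtures.SAT_MONOMER_171, 32.5),
        tsd="TAC", seed=5)
    seq, gt = build_element(spec)
    arrays = detect_tandem_array(seq)
    elem = ElementModel(contig_id="sim", span=gt.element_span,
                        completeness="complete", coding_ivs=gt.coding_ivs)
    for a in arrays:
        loc = locate_array_in_element(elem, a)
        print(f"in-element array: {a.monomer_len} bp x {a.copy_number} at "
              f"{a.iv.start}-{a.iv.end}, region {loc.region}, "
              f"{loc.dist_to_3prime} bp from the 3' terminus")
    with open(OUT / "in_element_arrays.tsv", "w") as fh:
        fh.write("start\tend\tmonomer_len\tcopy_number\tregion\n")
        for a in arrays:
            loc = locate_array_in_element(elem, a)
            fh.write(f"{a.iv.start}\t{a.iv.end}\t{a.monomer_len}\t"
                     f"{a.copy_number}\t{loc.region}\n")
    return 0


if __name__ == "__main__":
    sys.exit(main())
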