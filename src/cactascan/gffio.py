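"""GFF3 / BED / TSV serialization of element annotations and truth sets.

GFF3 output is 1-based inclusive (converted from the internal
``length = end - start`` convention); BED is 0-based half-open. Feature
types follow the Sequence Ontology: transposable_element,
terminal_inverted_repeat, repeat_region (subTIR units), satellite_DNA,
sequence_feature (captured fragments), CDS.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .sequence import Interval, to_bed_coords, to_gff3_coords

__all__ = ["write_gff3", "write_bed", "element_to_gff3_rows",
           "truth_to_gff3_rows", "write_truth_hit_table"]

GFF3_HEADER = "##gff-version 3"


def _attrs(d: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in d.items() if v is not None)


def write_gff3(rows: Iterable[tuple], path: str | Path) -> None:
    """Write (seqid, source, type, Interval, score, attrs-dict) rows."""
    with open(path, "w") as fh:
        fh.write(GFF3_HEADER + "\n")
        for seqid, source, ftype, iv, score, attrs in rows:
            g0, g1 = to_gff3_coords(iv)
            fh.write("\t".join([
                seqid, source, ftype, str(g0), str(g1),
                score if isinstance(score, str) else f"{score:g}",
                iv.strand, ".", _attrs(attrs)]) + "\n")


def write_bed(intervals: Sequence[tuple[str, Interval, str]],
              path: str | Path) -> None:
    """Write (seqid, Interval, name) triples as BED."""
    with open(path, "w") as fh:
        for seqid, iv, name in intervals:
            b0, b1 = to_bed_coords(iv)
            fh.write(f"{seqid}\t{b0}\t{b1}\t{name}\t0\t{iv.strand}\n")


def element_to_gff3_rows(element, index: int = 1,
                         source: str = "cactascan") -> list[tuple]:
    """Flatten an ElementModel into parent/child GFF3 rows.

    Child features are emitted in contig coordinates (the element's
    sub-annotations are element-local and shifted by the span start).
    """
    eid = f"element{index}"
    seqid = element.contig_id
    off = element.span.start - 1
    rows = [(seqid, source, "transposable_element", element.span, ".",
             {"ID": eid, "completeness": element.completeness,
              "cda": element.cda.label if element.cda else None,
              "tsd": element.tsd})]
    if element.tir is not None:
        for tag, iv in (("left", element.tir.left_iv),
                        ("right", element.tir.right_iv)):
            rows.append((seqid, source, "terminal_inverted_repeat",
                         iv.shift(off), f"{element.tir.pair_identity:.3f}",
                         {"ID": f"{eid}.tir_{tag}", "Parent": eid}))
    if element.subtir is not None:
        for k, copy in enumerate(element.subtir.copies, 1):
            rows.append((seqid, source, "repeat_region",
                         copy.iv.shift(off), f"{copy.identity:.3f}",
                         {"ID": f"{eid}.subtir{k}", "Parent": eid,
                          "orientation": copy.orientation,
                          "motif": element.subtir.motif}))
    for k, iv in enumerate(element.coding_ivs, 1):
        rows.append((seqid, source, "CDS", iv.shift(off), ".",
                     {"ID": f"{eid}.orf{k}", "Parent": eid}))
    for k, hit in enumerate(element.domains, 1):
        rows.append((seqid, source, "protein_match", hit.iv.shift(off),
                     f"{hit.identity:.3f}",
                     {"ID": f"{eid}.domain{k}", "Parent": eid,
                      "Name": hit.name, "orf": hit.orf}))
    for k, cap in enumerate(element.captures, 1):
        rows.append((seqid, source, "sequence_feature", cap.iv.shift(off),
                     ".", {"ID": f"{eid}.capture{k}", "Parent": eid,
                           "Name": cap.fragment_label,
                           "region": cap.element_region,
                           "dist_to_tad": cap.dist_to_tad}))
    for k, arr in enumerate(element.arrays, 1):
        rows.append((seqid, source, "satellite_DNA", arr.iv.shift(off),
                     f"{arr.mean_copy_identity:.3f}",
                     {"ID": f"{eid}.satellite{k}", "Parent": eid,
                      "monomer_len": arr.monomer_len,
                      "copy_number": arr.copy_number}))
    return rows


def truth_to_gff3_rows(contig_id: str, truths,
                       source: str = "cactascan_sim") -> list[tuple]:
    """Ground-truth features of embedded synthetic elements as GFF3 rows."""
    rows = []
    for n, gt in enumerate(truths, 1):
        eid = f"truth{n}"
        rows.append((contig_id, source, "transposable_element",
                     gt.element_span, ".",
                     {"ID": eid, "tsd": gt.tsd, "motif": gt.motif}))
        for tag, iv in zip(("left", "right"), gt.tir_ivs):
            rows.append((contig_id, source, "terminal_inverted_repeat", iv,
                         ".", {"ID": f"{eid}.tir_{tag}", "Parent": eid}))
        for k, (iv, orient) in enumerate(gt.subtir_copy_ivs, 1):
            rows.append((contig_id, source, "repeat_region", iv, ".",
                         {"ID": f"{eid}.subtir{k}", "Parent": eid,
                          "orientation": orient}))
        for k, iv in enumerate(gt.coding_ivs, 1):
            rows.append((contig_id, source, "CDS", iv, ".",
                         {"ID": f"{eid}.orf{k}", "Parent": eid}))
        for k, (name, iv, orf) in enumerate(gt.domain_ivs, 1):
            rows.append((contig_id, source, "protein_match", iv, ".",
                         {"ID": f"{eid}.domain{k}", "Parent": eid,
                          "Name": name, "orf": orf}))
        for k, (label, iv) in enumerate(gt.capture_ivs, 1):
            rows.append((contig_id, source, "sequence_feature", iv, ".",
                         {"ID": f"{eid}.capture{k}", "Parent": eid,
                          "Name": label}))
        if gt.array_iv is not None:
            rows.append((contig_id, source, "satellite_DNA", gt.array_iv,
                         ".", {"ID": f"{eid}.satellite", "Parent": eid}))
    return rows


def write_truth_hit_table(contig_id: str, truths, path: str | Path,
                          dialect: str = "gff3") -> None:
    """Emit the ground-truth protein-domain hits of embedded elements as a
    DANTE-style hit table (perfect hits: identity/similarity 1.0, zero
    interruptions), consumable by the domain-architecture reader."""
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write(GFF3_HEADER + "\n")
            for gt in truths:
                for name, iv, _orf in gt.domain_ivs:
                    g0, g1 = to_gff3_coords(iv)
                    fh.write("\t".join([
                        contig_id, "cactascan_sim", "protein_match",
                        str(g0), str(g1), ".", "+", ".",
                        _attrs({"Name": name, "Identity": "1.0",
                                "Similarity": "1.0", "Relat_Length": "1.0",
                                "Interruptions": "0",
                                "Length_Proportion": "1.0"})]) + "\n")
    elif dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("seqid\tname\tstart\tend\tstrand\tidentity\t"
                     "similarity\taln_len_prop\tinterruptions\tlength_prop\n")
            for gt in truths:
                for name, iv, _orf in gt.domain_ivs:
                    g0, g1 = to_gff3_coords(iv)
                    fh.write(f"{contig_id}\t{name}\t{g0}\t{g1}\t+\t1.0\t"
                             f"1.0\t1.0\t0\t1.0\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
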