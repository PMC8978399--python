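"""End-to-end orchestration: anchor on transposase hits, delimit elements,
type their domain architecture, annotate captures and satellite arrays.

The scan follows the published recovery order: full-length transposase
(tnp2) domains are positioned first, then TIRs/subTIRs are searched in the
surrounding sequence. Captured fragments are taken from the non-canonical
domain hits falling inside each element; satellite arrays are detected on
the element sequence. Runs are deterministic: same configuration and
inputs give byte-identical GFF3/TSV outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .captures import annotate_capture, detect_tandem_array
from .domains import (architecture_of, assign_orfs, classify_cda, filter_hits,
                      load_domain_hits, select_full_length_tnp2)
from .ends import DetectionConfig, ElementModel, call_element
from .gffio import element_to_gff3_rows, write_gff3
from .phylo import distance_matrix, nj_tree
from .sequence import Interval, find_orfs, read_fasta

__all__ = ["PipelineConfig", "run_scan", "run_compare"]

log = logging.getLogger("cactascan")


@dataclass
class PipelineConfig:
    """Effective configuration of a run; echoed verbatim into the report."""

    contigs: Optional[str] = None
    hits: Optional[str] = None
    hits_dialect: str = "gff3"
    coding: Optional[str] = None
    alignment: Optional[str] = None
    model: str = "t92"
    gamma_shape: Optional[float] = None
    out_dir: str = "cactascan_out"
    seed: int = 0
    log_level: str = "INFO"
    # domain-hit filtering
    min_identity: float = 0.35
    min_similarity: float = 0.45
    min_aln_len: float = 0.8
    max_interruptions: int = 0
    max_len_prop: float = 1.2
    tnp2_target_len: int = 630
    tnp2_tolerance: float = 0.1
    min_orf_len: int = 900
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        det_known = {f.name for f in fields(DetectionConfig)}
        det = data.pop("detection", {}) or {}
        unknown = (set(data) - known) | (set(det) - det_known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "unit_range" in det:
            det["unit_range"] = tuple(det["unit_range"])
        cfg = cls(**data, detection=DetectionConfig(**det))
        return replace(cfg, **overrides)

    def echo(self) -> dict:
        d = asdict(self)
        d["detection"]["unit_range"] = list(d["detection"]["unit_range"])
        return d


def _coding_intervals_from_gff3(path: str | Path) -> dict[str, list[Interval]]:
    """CDS/gene intervals per seqid from an AUGUSTUS-style GFF3."""
    out: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8 or cols[2] not in ("CDS", "gene", "mRNA"):
                continue
            strand = cols[6] if cols[6] in "+-" else "+"
            out.setdefault(cols[0], []).append(
                Interval(int(cols[3]), int(cols[4]) + 1, strand))
    return out


def _infer_coding(elem_seq: str, domain_hits, min_orf_len: int
                  ) -> list[Interval]:
    """Coding intervals from the element's own ORFs: the ORFs that contain
    at least one canonical domain hit, longest first, non-overlapping."""
    orfs = find_orfs(elem_seq, max(3, min_orf_len // 3 * 3))
    chosen: list[Interval] = []
    for orf in sorted(orfs, key=lambda iv: -(iv.end - iv.start)):
        holds = any(orf.contains(h.iv) for h in domain_hits
                    if not h.name.startswith("other:"))
        if holds and not any(orf.overlaps(c) for c in chosen):
            chosen.append(orf)
    return sorted(chosen, key=lambda iv: iv.start)


def _scan_contig(contig, hits, config: PipelineConfig,
                 coding_map: Optional[dict[str, list[Interval]]]
                 ) -> list[ElementModel]:
    kept = filter_hits(hits, config.min_identity, config.min_similarity,
                       config.min_aln_len, config.max_interruptions,
                       config.max_len_prop)
    anchors = select_full_length_tnp2(kept, config.tnp2_target_len,
                                      config.tnp2_tolerance)
    elements = []
    seen_spans: list[Interval] = []
    for anchor in anchors:
        element = call_element(contig, anchor.iv,
                               config.detection.max_flank, config.detection)
        if any(element.span.overlaps(s) for s in seen_spans):
            continue
        seen_spans.append(element.span)
        off = element.span.start - 1
        local_hits = [replace(h, iv=h.iv.shift(-off))
                      for h in kept if element.span.contains(h.iv)]
        elem_seq = element.span.slice(contig.seq)
        if coding_map and contig.id in coding_map:
            coding = [iv.shift(-off) for iv in coding_map[contig.id]
                      if element.span.contains(iv)]
        else:
            coding = _infer_coding(elem_seq, local_hits, config.min_orf_len)
        canonical = [h for h in local_hits if not h.name.startswith("other:")]
        try:
            assign_orfs(element, coding, canonical)
            element.cda = classify_cda(architecture_of(element.domains))
        except ValueError as exc:
            log.warning("%s: element at %d-%d not classifiable: %s",
                        contig.id, element.span.start, element.span.end, exc)
            element.domains = sorted(canonical,
                                     key=lambda h: (h.iv.start, h.iv.end))
            element.coding_ivs = coding
        fragments = [(h.name.removeprefix("other:"), h.iv)
                     for h in local_hits if h.name.startswith("other:")]
        if fragments and any(h.name == "TAD" for h in element.domains):
            element.captures = annotate_capture(element, fragments)
        if len(elem_seq) >= 30 * 3:
            element.arrays = detect_tandem_array(elem_seq)
        elements.append(element)
    return elements


def run_scan(config: PipelineConfig) -> dict:
    """Scan contigs for CACTA elements; write GFF3 + TSV + JSON reports.

    Returns the run report (also written to ``scan_report.json``).
    """
    if not config.contigs or not config.hits:
        raise ValueError("scan requires contigs and hits paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = read_fasta(config.contigs)
    all_hits = load_domain_hits(config.hits, config.hits_dialect)
    coding_map = (_coding_intervals_from_gff3(config.coding)
                  if config.coding else None)
    by_contig: dict[str, list] = {}
    for h in all_hits:
        by_contig.setdefault(h.seqid, []).append(h)

    rows = []
    table_lines = ["contig\tstart\tend\tlength\tcompleteness\tcda\t"
                   "tir_len\ttir_identity\tsubtir_motif\tn_5prime\t"
                   "n_3prime\ttsd\tn_captures\tn_arrays"]
    n_elem = 0
    elements_all = []
    for contig in contigs:
        hits = by_contig.get(contig.id, [])
        if not hits:
            continue
        for element in _scan_contig(contig, hits, config, coding_map):
            n_elem += 1
            elements_all.append(element)
            rows.extend(element_to_gff3_rows(element, n_elem))
            st = element.subtir
            table_lines.append("\t".join(map(str, [
                element.contig_id, element.span.start, element.span.end,
                element.length, element.completeness,
                element.cda.label if element.cda else ".",
                element.tir.length if element.tir else ".",
                f"{element.tir.pair_identity:.3f}" if element.tir else ".",
                st.motif if st else ".",
                st.n_5prime if st else 0, st.n_3prime if st else 0,
                element.tsd or ".", len(element.captures),
                len(element.arrays)])))
    write_gff3(rows, out / "elements.gff3")
    (out / "elements.tsv").write_text("\n".join(table_lines) + "\n")
    report = {
        "tool": "cactascan", "version": __version__,
        "command": "scan", "config": config.echo(),
        "n_contigs": len(contigs), "n_elements": n_elem,
        "completeness_counts": {
            c: sum(e.completeness == c for e in elements_all)
            for c in ("complete", "subtir_only", "incomplete")},
    }
    (out / "scan_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def run_compare(config: PipelineConfig) -> dict:
    """Distance matrix + NJ tree from a pre-aligned FASTA of TPase/ORF
    sequences; writes PHYLIP, TSV and Newick outputs plus a JSON report."""
    if not config.alignment:
        raise ValueError("compare requires an alignment path")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_fasta(config.alignment)
    seqs = [(r.id, r.seq) for r in records]
    dm = distance_matrix(seqs, config.model, config.gamma_shape)
    dm.to_tsv(out / "distances.tsv")
    dm.to_phylip(out / "distances.phylip")
    newick = nj_tree(dm) if len(seqs) >= 3 else None
    if newick:
        (out / "tree.nwk").write_text(newick + "\n")
    finite = [dm.d[i, j] for i in range(len(seqs))
              for j in range(i + 1, len(seqs))
              if dm.d[i, j] == dm.d[i, j] and dm.d[i, j] != float("inf")]
    report = {
        "tool": "cactascan", "version": __version__,
        "command": "compare", "config": config.echo(),
        "n_sequences": len(seqs),
        "n_saturated_pairs": len(dm.saturated_pairs),
        "min_distance": min(finite) if finite else None,
        "max_distance": max(finite) if finite else None,
        "tree_written": newick is not None,
    }
    (out / "compare_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
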