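"""Protein-domain hit tables and conserved-domain-architecture typing.

Hit tables follow the DANTE dialect: either a 9-column GFF3 whose
attributes carry Name, Identity, Similarity, Relat_Length (aligned-length
proportion), Interruptions (frameshifts + stop codons) and optionally
Length_Proportion, or a flat TSV with the same fields as columns. Hits are
filtered with the standard thresholds (identity >= 0.35, similarity >=
0.45, aligned-length proportion >= 0.8, zero interruptions, length
proportion <= 1.2), full-length tnp2 (Transposase_21, ~630 bp) hits are
selected as element anchors, and the positional order of the retained
domains is classified into the four published conserved-domain
architectures:

* type1 -- TAD, Transposase_21, DUF4218, DUF4216 (the "basic" ORF1 set)
* type2 -- basic + Peptidase_C48
* type3 -- basic + Transposase_24
* type4 -- basic + Transposase_24 + Peptidase_C48 (in that order)

Any other multiset or order is ``other``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .sequence import Interval

__all__ = [
    "CANONICAL_DOMAINS",
    "DomainHit",
    "CDAType",
    "SchemaError",
    "load_domain_hits",
    "filter_hits",
    "select_full_length_tnp2",
    "assign_orfs",
    "classify_cda",
    "architecture_of",
]

CANONICAL_DOMAINS = ("TAD", "Transposase_21", "DUF4218", "DUF4216",
                     "Transposase_24", "Peptidase_C48")
_BASIC = ("TAD", "Transposase_21", "DUF4218", "DUF4216")


class SchemaError(ValueError):
    """Raised when a hit table lacks required columns or attributes."""


@dataclass
class DomainHit:
    name: str
    iv: Interval
    frame_strand: str = "+"
    identity: float = 1.0
    similarity: float = 1.0
    aln_len_prop: float = 1.0
    interruptions: int = 0
    length_prop: float = 1.0
    seqid: str = ""
    orf: Optional[str] = None
    straddles_boundary: bool = False

    def __post_init__(self) -> None:
        if self.name not in CANONICAL_DOMAINS and not self.name.startswith("other:"):
            self.name = f"other:{self.name}"
        if self.interruptions < 0:
            raise ValueError("interruptions must be >= 0")

    @property
    def length(self) -> int:
        return self.iv.end - self.iv.start


@dataclass(frozen=True)
class CDAType:
    label: str  # type1..type4 | other
    basis: tuple[str, ...]


_GFF_REQUIRED = ("Name", "Identity", "Similarity", "Relat_Length",
                 "Interruptions")
_TSV_REQUIRED = ("name", "start", "end", "strand", "identity", "similarity",
                 "aln_len_prop", "interruptions", "length_prop")


def _parse_attrs(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def load_domain_hits(path: str | Path, dialect: str = "gff3") -> list[DomainHit]:
    """Read a protein-domain hit table in the GFF3 or TSV dialect.

    GFF3/TSV start and end are 1-based inclusive and converted to the
    internal ``length = end - start`` convention. Unknown domain names map
    to ``other:<label>``. Missing required columns raise SchemaError.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    if dialect == "gff3":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise SchemaError(
                        f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
                attrs = _parse_attrs(cols[8])
                missing = [k for k in _GFF_REQUIRED if k not in attrs]
                if missing:
                    raise SchemaError(
                        f"{path}:{lineno}: missing attributes {missing}")
                start, end = int(cols[3]), int(cols[4])
                hits.append(DomainHit(
                    name=attrs["Name"],
                    iv=Interval(start, end + 1, cols[6] if cols[6] in "+-" else "+"),
                    frame_strand=cols[6] if cols[6] in "+-" else "+",
                    identity=float(attrs["Identity"]),
                    similarity=float(attrs["Similarity"]),
                    aln_len_prop=float(attrs["Relat_Length"]),
                    interruptions=int(attrs["Interruptions"]),
                    length_prop=float(attrs.get("Length_Proportion", 1.0)),
                    seqid=cols[0],
                ))
    elif dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            return []
        missing = [c for c in _TSV_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        for row in df.to_dict("records"):
            hits.append(DomainHit(
                name=str(row["name"]),
                iv=Interval(int(row["start"]), int(row["end"]) + 1,
                            str(row["strand"])),
                frame_strand=str(row["strand"]),
                identity=float(row["identity"]),
                similarity=float(row["similarity"]),
                aln_len_prop=float(row["aln_len_prop"]),
                interruptions=int(row["interruptions"]),
                length_prop=float(row["length_prop"]),
                seqid=str(row.get("seqid", "")),
            ))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return hits


def filter_hits(hits: Sequence[DomainHit], min_identity: float = 0.35,
                min_similarity: float = 0.45, min_aln_len: float = 0.8,
                max_interruptions: int = 0,
                max_len_prop: float = 1.2) -> list[DomainHit]:
    """Keep hits satisfying all five DANTE-style thresholds; order preserved."""
    return [h for h in hits
            if h.identity >= min_identity
            and h.similarity >= min_similarity
            and h.aln_len_prop >= min_aln_len
            and h.interruptions <= max_interruptions
            and h.length_prop <= max_len_prop]


def select_full_length_tnp2(hits: Sequence[DomainHit], target_len: int = 630,
                            tolerance: float = 0.1) -> list[DomainHit]:
    """Keep Transposase_21 hits whose nucleotide length lies within
    ``target_len * (1 +/- tolerance)`` (closed interval); remnants drop."""
    if not 0 <= tolerance < 1:
        raise ValueError("tolerance must be in [0, 1)")
    lo = target_len * (1 - tolerance)
    hi = target_len * (1 + tolerance)
    return [h for h in hits
            if h.name == "Transposase_21" and lo <= h.length <= hi]


def assign_orfs(element, coding_ivs: Sequence[Interval],
                hits: Sequence[DomainHit]):
    """Label hits ORF1/ORF2 by the coding interval holding Transposase_21.

    A hit contained in the Transposase_21-bearing coding interval is ORF1,
    anything else ORF2; a hit straddling a coding boundary is assigned by
    its midpoint and flagged. The element's ``domains`` and ``coding_ivs``
    are updated in positional order; raises when no Transposase_21 hit is
    present (the element is then not classifiable).
    """
    tnp = [h for h in hits if h.name == "Transposase_21"]
    if not tnp:
        raise ValueError("no Transposase_21 hit: element not classifiable")
    anchor = max(tnp, key=lambda h: h.identity)
    mid_anchor = (anchor.iv.start + anchor.iv.end) // 2
    orf1 = next((iv for iv in coding_ivs
                 if iv.start <= mid_anchor < iv.end), None)
    if orf1 is None:
        raise ValueError("no coding interval contains the Transposase_21 hit")
    labeled = []
    for h in hits:
        contained = orf1.contains(h.iv)
        mid = (h.iv.start + h.iv.end) // 2
        by_mid = orf1.start <= mid < orf1.end
        straddle = (not contained) and any(
            h.iv.overlaps(iv) and not iv.contains(h.iv) for iv in coding_ivs)
        labeled.append(replace(h, orf="ORF1" if (contained or by_mid) else "ORF2",
                               straddles_boundary=straddle))
    labeled.sort(key=lambda h: (h.iv.start, h.iv.end))
    element.domains = labeled
    element.coding_ivs = sorted(coding_ivs, key=lambda iv: (iv.start, iv.end))
    return element


def architecture_of(hits: Sequence[DomainHit]) -> list[str]:
    """Positional domain order for classification: one hit per canonical
    domain name (the highest-identity one), ordered by start position."""
    best: dict[str, DomainHit] = {}
    for h in hits:
        if h.name.startswith("other:"):
            continue
        if h.name not in best or h.identity > best[h.name].identity:
            best[h.name] = h
    ordered = sorted(best.values(), key=lambda h: (h.iv.start, h.iv.end))
    return [h.name for h in ordered]


def classify_cda(domains_in_order: Sequence[str]) -> CDAType:
    """Map an ordered domain-name list onto the four published CDA types.

    Exactly the four canonical ordered lists map to type1-type4; any other
    multiset or order (including rearranged canonical sets) classifies as
    ``other`` with the observed order recorded as the basis.
    """
    if not domains_in_order:
        raise ValueError("empty domain list")
    names = tuple(domains_in_order)
    table = {
        _BASIC: "type1",
        _BASIC + ("Peptidase_C48",): "type2",
        _BASIC + ("Transposase_24",): "type3",
        _BASIC + ("Transposase_24", "Peptidase_C48"): "type4",
    }
    label = table.get(names, "other")
    if label == "other" and sorted(names) in [sorted(k) for k in table]:
        warnings.warn(
            f"canonical domain set in non-canonical order: {names}",
            stacklevel=2)
    return CDAType(label=label, basis=names)
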