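"""Terminal-structure detection for CACTA elements.

A complete CACTA element is bounded by two ~28-bp terminal inverted
repeats (TIRs), each anchored by an intact 5'-CACTA motif, and carries
subterminal repeat (subTIR) regions built from 10-20-bp units repeated in
direct orientation at the 5' end and inverted orientation at the 3' end.
Elements whose TIR termini have decayed but whose subTIR unit arrays are
still detectable are classified ``subtir_only``; everything else around a
transposase anchor is ``incomplete``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sequence import Interval, SeqRecord, majority_consensus, revcomp, ungapped_identity

__all__ = [
    "DotPlot",
    "TIRPair",
    "SubTIRCopy",
    "SubTIRAnnotation",
    "ElementModel",
    "DetectionConfig",
    "self_dotplot",
    "find_tir",
    "estimate_unit_length",
    "detect_subtir",
    "check_tsd",
    "call_element",
]

CACTA_MOTIF = "CACTA"


@dataclass
class DotPlot:
    """Exact k-mer match list between a sequence and itself.

    ``hits`` holds 1-based (position_a, position_b, orientation) triples;
    orientation is "direct" or "inverted". Direct hits are symmetric and
    include the main diagonal.
    """

    word: int
    hits: list[tuple[int, int, str]]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pos_a\tpos_b\torientation\n")
            for a, b, o in self.hits:
                fh.write(f"{a}\t{b}\t{o}\n")


@dataclass
class TIRPair:
    left_seq: str
    right_seq: str
    left_iv: Interval
    right_iv: Interval
    length: int
    pair_identity: float
    cacta_intact: bool


@dataclass(frozen=True)
class SubTIRCopy:
    iv: Interval
    orientation: str  # "direct" | "inverted"
    identity: float


@dataclass
class SubTIRAnnotation:
    motif: str
    copies: list[SubTIRCopy]
    n_5prime: int
    n_3prime: int

    @property
    def n_total(self) -> int:
        return self.n_5prime + self.n_3prime


@dataclass
class ElementModel:
    """One candidate CACTA element anchored on a transposase hit."""

    contig_id: str
    span: Interval
    completeness: str  # complete | subtir_only | incomplete
    tir: Optional[TIRPair] = None
    subtir: Optional[SubTIRAnnotation] = None
    tsd: Optional[str] = None
    coding_ivs: list = field(default_factory=list)
    domains: list = field(default_factory=list)
    cda: Optional[object] = None
    captures: list = field(default_factory=list)
    arrays: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.span.end - self.span.start


@dataclass
class DetectionConfig:
    """Thresholds for terminal-structure detection (module defaults)."""

    tir_motif: str = CACTA_MOTIF
    tir_min_len: int = 25
    tir_max_len: int = 40
    tir_min_pair_identity: float = 0.70
    end_window: int = 600
    unit_range: tuple[int, int] = (10, 20)
    min_copy_identity: float = 0.80
    min_cluster_copies: int = 3
    tsd_len: int = 3
    max_flank: int = 15000


def self_dotplot(s: str, word: int, include_inverted: bool = False) -> DotPlot:
    """All exact word-length matches of a sequence against itself (and
    against its reverse complement when ``include_inverted``)."""
    if not 1 <= word <= len(s):
        raise ValueError(f"word {word} out of range for length {len(s)}")
    index: dict[str, list[int]] = {}
    for i in range(len(s) - word + 1):
        index.setdefault(s[i:i + word], []).append(i + 1)
    hits: list[tuple[int, int, str]] = []
    for positions in index.values():
        for a in positions:
            for b in positions:
                hits.append((a, b, "direct"))
    if include_inverted:
        for j in range(len(s) - word + 1):
            rc = revcomp(s[j:j + word])
            for a in index.get(rc, ()):
                hits.append((a, j + 1, "inverted"))
    hits.sort()
    return DotPlot(word=word, hits=hits)


def find_tir(s: str, motif: str = CACTA_MOTIF, min_len: int = 25,
             max_len: int = 40,
             min_pair_identity: float = 0.70) -> Optional[TIRPair]:
    """Detect a CACTA-anchored TIR pair at the termini of an element.

    Requires the 5' terminus to begin with ``motif`` and the 3' terminus to
    end with its reverse complement; the inverted comparison of the 5'
    prefix against the reverse complement of the 3' suffix is evaluated at
    every length in [min_len, max_len], and the length maximizing the pair
    identity (longest among ties) is returned when that identity reaches
    ``min_pair_identity``, else None. Maximizing identity rather than
    length keeps the call at the conserved terminal repeat instead of
    greedily absorbing matching subterminal sequence.
    """
    if len(s) < 2 * max_len:
        raise ValueError(
            f"sequence length {len(s)} shorter than 2*max_len ({2 * max_len})")
    if not (s.startswith(motif) and s.endswith(revcomp(motif))):
        return None
    best = None
    for L in range(max_len, min_len - 1, -1):
        pid = ungapped_identity(s[:L], revcomp(s[-L:]))
        if pid >= min_pair_identity and (best is None or pid > best[0]):
            best = (pid, L)
    if best is None:
        return None
    pid, L = best
    return TIRPair(
        left_seq=s[:L],
        right_seq=s[-L:],
        left_iv=Interval(1, L + 1),
        right_iv=Interval(len(s) - L + 1, len(s) + 1),
        length=L,
        pair_identity=pid,
        cacta_intact=True,
    )


def estimate_unit_length(window: str,
                         unit_range: tuple[int, int] = (10, 20)) -> int:
    """Tandem-unit period estimate by shifted self-identity.

    Returns the period p in ``unit_range`` maximizing the mean identity
    between ``window[i]`` and ``window[i+p]`` over the window; ties break
    toward the smaller period.
    """
    lo, hi = unit_range
    if len(window) < 4 * hi:
        raise ValueError(
            f"window length {len(window)} < 4*max unit length {4 * hi}")
    a = np.frombuffer(window.encode(), dtype=np.uint8)
    best_p, best_score = lo, -1.0
    for p in range(lo, hi + 1):
        score = float(np.mean(a[:-p] == a[p:]))
        if score > best_score:
            best_p, best_score = p, score
    return best_p


def _chain_mean_identity(a: np.ndarray, i: int, p: int, n: int) -> float:
    """Mean identity of the n phased unit copies at i, i+p, ... to their
    own majority consensus."""
    M = a[i:i + n * p].reshape(n, p)
    counts = np.stack([(M == b).sum(axis=0)
                       for b in np.frombuffer(b"ACGT", dtype=np.uint8)])
    cons = np.frombuffer(b"ACGT", dtype=np.uint8)[np.argmax(counts, axis=0)]
    return float((M == cons).mean())


def _best_unit_cluster(seq: str, unit_range: tuple[int, int],
                       min_copy_identity: float, min_copies: int = 2,
                       ) -> Optional[tuple[int, int, int]]:
    """Best tandem cluster of short units in ``seq``.

    Seed-and-chain search: for each period p and seed offset i, count how
    many consecutive unit-length windows starting at i match their
    successor at >= ``min_copy_identity``. Because adjacent shifted
    windows share p-m bases, chains can seed slightly off-phase with the
    true unit array; among maximal-count chains the phase with the
    highest mean identity to its own consensus wins (ties: smaller
    period, then leftmost seed). Returns (start0, period, n_copies), or
    None when no chain of >= ``min_copies`` copies exists.
    """
    lo, hi = unit_range
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(a)
    per_p: list[tuple[int, int, int]] = []  # (n, p, i) best count per p
    for p in range(lo, hi + 1):
        if L < 2 * p:
            continue
        eq = a[:-p] == a[p:]
        need = int(np.ceil(min_copy_identity * p))
        csum = np.concatenate(([0], np.cumsum(eq)))
        nmax = L - 2 * p
        if nmax < 0:
            continue
        ok = (csum[p:p + nmax + 1] - csum[:nmax + 1]) >= need
        # ok[i]: unit at i matches the unit at i+p; chain[i] counts the
        # run of units starting at i (each full unit counts itself).
        # Computed per phase class (i mod p) as suffix run lengths of ok.
        n_pos = L - p + 1
        ok_ext = np.zeros(n_pos, dtype=bool)
        ok_ext[:nmax + 1] = ok
        chain = np.ones(n_pos, dtype=np.int32)
        for r in range(p):
            o = ok_ext[r::p][::-1]
            if not len(o):
                continue
            c = np.cumsum(o)
            run = c - np.maximum.accumulate(np.where(o, 0, c))
            chain[r::p] = run[::-1] + 1
        n_p = int(chain.max())
        if n_p >= min_copies:
            for i in np.flatnonzero(chain[:L - p + 1] == n_p):
                per_p.append((n_p, p, int(i)))
    if not per_p:
        return None
    n_best = max(n for n, _, _ in per_p)
    tied = [(n, p, i) for n, p, i in per_p if n == n_best]
    # identity quantized so substitution noise cannot flip the phase
    # preference away from the leftmost seed among equivalent phases
    scored = [(round(_chain_mean_identity(a, i, p, n), 2), -p, -i, i, p, n)
              for n, p, i in tied]
    _, _, _, i, p, n = max(scored)
    return i, p, n


def _extend_cluster(seq: str, i: int, p: int, n: int,
                    min_copy_identity: float) -> tuple[int, int]:
    """Extend a chained unit cluster outward on its own phase lattice,
    bridging at most two consecutive decayed copies; returns the 0-based
    (start, end) of the outermost qualifying copies."""
    a_copies = [seq[i + k * p: i + (k + 1) * p] for k in range(n)]
    target = majority_consensus(a_copies)

    def walk(start: int, step: int) -> int:
        pos = start
        last_good = None
        misses = 0
        while misses <= 2:
            nxt = pos + step
            if nxt < 0 or nxt + p > len(seq):
                break
            if ungapped_identity(seq[nxt:nxt + p], target) \
                    >= min_copy_identity:
                last_good = nxt
                misses = 0
            else:
                misses += 1
            pos = nxt
        return last_good if last_good is not None else start

    lo = walk(i, -p)
    hi_start = walk(i + (n - 1) * p, p)
    return lo, hi_start + p


def detect_subtir(s: str, end_window: int = 600,
                  unit_range: tuple[int, int] = (10, 20),
                  min_copy_identity: float = 0.80) -> SubTIRAnnotation:
    """Annotate the phased subTIR unit arrays of an element sequence.

    The unit period and motif are estimated in the 5' terminal window (the
    motif is the majority-rule consensus of the phased copies, reported in
    5' direct orientation); both terminal windows are then scanned greedily
    left-to-right for non-overlapping unit copies at >= ``min_copy_identity``
    -- direct copies at the 5' end, reverse-complement copies at the 3' end.
    When no qualifying unit cluster exists in the 5' window the annotation
    has zero copies.
    """
    if len(s) < 2 * end_window:
        raise ValueError(
            f"sequence length {len(s)} < 2*end_window ({2 * end_window})")
    w5 = s[:end_window]
    w3 = s[-end_window:]
    cluster = _best_unit_cluster(w5, unit_range, min_copy_identity,
                                 min_copies=3)
    if cluster is None:
        return SubTIRAnnotation(motif="", copies=[], n_5prime=0, n_3prime=0)
    i0, p, n = cluster
    phased = [w5[i0 + k * p: i0 + (k + 1) * p] for k in range(n)]
    motif = majority_consensus(phased)

    def tiled_scan(window: str, target: str, offset: int,
                   orientation: str) -> list[SubTIRCopy]:
        """Count non-overlapping unit copies on the best phase lattice.

        For each of the p phase classes, unit-length windows are tiled at
        stride p and the contiguous run holding the most qualifying
        copies is taken (runs may bridge at most two consecutive decayed
        copies, so interior copies that drifted below the threshold do
        not truncate the array). The phase with the most qualifying
        copies wins; ties go to the leftmost first copy. Tiling at a
        fixed stride avoids the re-synchronization artifacts of a
        sliding scan on noisy arrays.
        """
        best: Optional[tuple[int, int, list[SubTIRCopy]]] = None
        for r in range(p):
            idents = []
            positions = list(range(r, len(window) - p + 1, p))
            for i in positions:
                idents.append(ungapped_identity(window[i:i + p], target))
            quals = [x >= min_copy_identity for x in idents]
            # contiguous runs of qualifying tiles, bridging <= 2 misses
            runs: list[tuple[int, int, int]] = []  # (n_qual, start, end)
            k = 0
            while k < len(quals):
                if not quals[k]:
                    k += 1
                    continue
                start = k
                n_qual = 0
                gap = 0
                last_true = k
                while k < len(quals) and gap <= 2:
                    if quals[k]:
                        n_qual += 1
                        gap = 0
                        last_true = k
                    else:
                        gap += 1
                    k += 1
                k = last_true + 1
                runs.append((n_qual, start, last_true))
            if not runs:
                continue
            n_qual, start, end = max(runs,
                                     key=lambda x: (x[0], -x[1]))
            copies = [SubTIRCopy(
                iv=Interval(offset + positions[j] + 1,
                            offset + positions[j] + 1 + p),
                orientation=orientation, identity=idents[j])
                for j in range(start, end + 1) if quals[j]]
            key = (n_qual, -copies[0].iv.start)
            if best is None or key > (best[0], best[1]):
                best = (n_qual, -copies[0].iv.start, copies)
        return best[2] if best else []

    copies5 = tiled_scan(w5, motif, 0, "direct")
    copies3 = tiled_scan(w3, revcomp(motif), len(s) - end_window, "inverted")
    # second pass: rebuild the consensus from every detected copy (both
    # ends) to denoise the motif, then canonicalize its rotation -- a
    # decayed copy can rotate the seed chain's phase, and a rotated
    # target fits one fewer full window per array -- by keeping the
    # rotation that maximizes the total copy count. Count ties resolve
    # to the rotation with the highest summed copy identity: a boundary
    # window straddling the terminal repeat or a copy junction qualifies
    # near the threshold, while true copies score near 1, so the aligned
    # rotation wins.
    observed = [c.iv.slice(s) for c in copies5] + \
               [revcomp(c.iv.slice(s)) for c in copies3]
    if observed:
        refined = majority_consensus(observed)
        best = None
        for k in range(p):
            rot = refined[k:] + refined[:k]
            c5 = tiled_scan(w5, rot, 0, "direct")
            c3 = tiled_scan(w3, revcomp(rot), len(s) - end_window,
                            "inverted")
            ident_sum = sum(c.identity for c in c5 + c3)
            key = (len(c5) + len(c3), ident_sum,
                   tuple(-ord(ch) for ch in rot))
            if best is None or key > best[0]:
                best = (key, rot, c5, c3)
        _, motif, copies5, copies3 = best
    return SubTIRAnnotation(motif=motif, copies=copies5 + copies3,
                            n_5prime=len(copies5), n_3prime=len(copies3))


def check_tsd(contig: SeqRecord, span: Interval,
              tsd_len: int = 3) -> Optional[str]:
    """Return the target-site duplication flanking ``span`` if present.

    The ``tsd_len``-mer immediately 5' of the span is returned when it
    equals the ``tsd_len``-mer immediately 3' of it; otherwise None.
    """
    left_start = span.start - 1 - tsd_len
    right_end = span.end - 1 + tsd_len
    if left_start < 0 or right_end > contig.length:
        raise ValueError("insufficient flank for TSD check")
    left = contig.seq[left_start:span.start - 1]
    right = contig.seq[span.end - 1:right_end]
    return left if left == right else None


def _find_candidates(window: str, motif: str) -> tuple[list[int], list[int]]:
    """0-based starts of the TIR motif and 0-based (exclusive) ends of its
    reverse complement within a search window."""
    rc = revcomp(motif)
    starts, ends = [], []
    i = window.find(motif)
    while i != -1:
        starts.append(i)
        i = window.find(motif, i + 1)
    j = window.find(rc)
    while j != -1:
        ends.append(j + len(rc))
        j = window.find(rc, j + 1)
    return starts, ends


def call_element(contig: SeqRecord, tpase_iv: Interval,
                 max_flank: int = 15000,
                 config: Optional[DetectionConfig] = None) -> ElementModel:
    """Delimit and classify the CACTA element surrounding a transposase hit.

    Searches up to ``max_flank`` bp on either side of the transposase
    interval. Completeness is ``complete`` when a CACTA-intact TIR pair
    with subTIR units on both ends bounds the element, ``subtir_only``
    when terminal unit arrays are found without an intact TIR pair, and
    ``incomplete`` otherwise (span then covers the searched window).
    """
    cfg = config or DetectionConfig()
    if not (1 <= tpase_iv.start and tpase_iv.end <= contig.length + 1):
        raise ValueError("transposase interval outside contig")
    wstart = max(1, tpase_iv.start - max_flank)
    wend = min(contig.length + 1, tpase_iv.end + max_flank)
    window = contig.seq[wstart - 1:wend - 1]
    tp_lo = tpase_iv.start - wstart  # 0-based within window
    tp_hi = tpase_iv.end - wstart

    starts, ends = _find_candidates(window, cfg.tir_motif)
    starts = [i for i in starts if i < tp_lo]
    ends = [j for j in ends if j > tp_hi]

    best: Optional[tuple[float, int, int, int, TIRPair]] = None
    for i in starts:
        for j in ends:
            if j - i < 2 * cfg.tir_max_len:
                continue
            pair = find_tir(window[i:j], cfg.tir_motif, cfg.tir_min_len,
                            cfg.tir_max_len, cfg.tir_min_pair_identity)
            if pair is None:
                continue
            key = (pair.pair_identity, j - i)
            if best is None or key > (best[0], best[1]):
                best = (pair.pair_identity, j - i, i, j, pair)

    if best is not None:
        _, _, i, j, pair = best
        span = Interval(wstart + i, wstart + j)
        elem_seq = window[i:j]
        ew = min(cfg.end_window, len(elem_seq) // 2)
        subtir = detect_subtir(elem_seq, ew, cfg.unit_range,
                               cfg.min_copy_identity)
        # In a well-mirrored element the inverted terminal match continues
        # through the subTIR arrays; bound the TIR at the first subTIR copy
        # so the reported TIR is the terminal repeat proper.
        pseudo = False
        if subtir.n_5prime and subtir.n_3prime:
            first5 = min(c.iv.start for c in subtir.copies
                         if c.orientation == "direct")
            last3 = max(c.iv.end for c in subtir.copies
                        if c.orientation == "inverted")
            anchor = len(cfg.tir_motif)
            if (first5 <= anchor
                    or last3 > len(elem_seq) + 1 - anchor):
                # subTIR units overlap the terminal anchor motif itself:
                # the "TIR" is mirrored subterminal sequence (unit
                # junctions can regenerate a CACTA), not a terminal repeat
                pseudo = True
            bound = min(first5 - 1, len(elem_seq) + 1 - last3)
            if not pseudo and cfg.tir_min_len <= bound < pair.length:
                refined = find_tir(elem_seq, cfg.tir_motif, cfg.tir_min_len,
                                   bound, cfg.tir_min_pair_identity)
                if refined is not None:
                    pair = refined
        if not pseudo:
            tsd = None
            if (span.start - 1 - cfg.tsd_len >= 0
                    and span.end - 1 + cfg.tsd_len <= contig.length):
                tsd = check_tsd(contig, span, cfg.tsd_len)
            if subtir.n_5prime >= 1 and subtir.n_3prime >= 1:
                return ElementModel(contig_id=contig.id, span=span,
                                    completeness="complete", tir=pair,
                                    subtir=subtir, tsd=tsd)
            return ElementModel(contig_id=contig.id, span=span,
                                completeness="incomplete", tir=pair,
                                subtir=subtir, tsd=tsd)

    # no intact TIR pair: look for terminal unit arrays on both flanks
    left_flank = window[:tp_lo]
    right_flank = window[tp_hi:]
    lcl = _best_unit_cluster(left_flank, cfg.unit_range, cfg.min_copy_identity)
    rcl = _best_unit_cluster(right_flank, cfg.unit_range, cfg.min_copy_identity)
    if (lcl is not None and rcl is not None
            and lcl[2] >= cfg.min_cluster_copies
            and rcl[2] >= cfg.min_cluster_copies):
        li, lp, ln = lcl
        ri, rp, rn = rcl
        # extend each cluster across decayed units (at most 2 consecutive
        # below-threshold copies) so an interior broken unit does not
        # truncate the detected array
        l_lo, l_hi = _extend_cluster(left_flank, li, lp, ln,
                                     cfg.min_copy_identity)
        r_lo, r_hi = _extend_cluster(right_flank, ri, rp, rn,
                                     cfg.min_copy_identity)
        c_lo = l_lo                      # 0-based cluster bounds in window
        c_hi = tp_hi + r_hi
        # a decayed TIR may still flank the unit arrays: admit terminal
        # anchors with at most one mismatch to the CACTA motif, searched
        # independently on each side (cluster phases can be offset), and
        # validate the inverted pair before extending the span
        m = len(cfg.tir_motif)
        rc_motif = revcomp(cfg.tir_motif)

        def anchor_candidates(positions, target):
            # decayed anchors are admitted permissively (>= 3/5); the
            # inverted-pair identity check below is the decisive gate
            out = []
            for i0 in positions:
                if 0 <= i0 and i0 + m <= len(window):
                    if ungapped_identity(window[i0:i0 + m], target) >= 0.6:
                        out.append(i0)
            return out

        lefts = anchor_candidates(range(c_lo - cfg.tir_max_len,
                                        c_lo - cfg.tir_min_len + 1),
                                  cfg.tir_motif)
        rights = anchor_candidates(range(c_hi + cfg.tir_min_len - m,
                                         c_hi + cfg.tir_max_len - m + 1),
                                   rc_motif)
        span = Interval(wstart + c_lo, wstart + c_hi)
        anchored = False
        best_pair = None
        for i0 in lefts:
            for j0 in rights:
                t = min(c_lo - i0, j0 + m - c_hi, cfg.tir_max_len)
                if t < cfg.tir_min_len:
                    continue
                pid = ungapped_identity(
                    window[i0:i0 + t],
                    revcomp(window[j0 + m - t:j0 + m]))
                if pid >= cfg.tir_min_pair_identity and (
                        best_pair is None or pid > best_pair[0]):
                    best_pair = (pid, i0, j0)
        if best_pair is not None:
            _, i0, j0 = best_pair
            span = Interval(wstart + i0, wstart + j0 + m)
            anchored = True
        elem_seq = contig.seq[span.start - 1:span.end - 1]
        ew = min(cfg.end_window, len(elem_seq) // 2)
        subtir = detect_subtir(elem_seq, ew, cfg.unit_range,
                               cfg.min_copy_identity)
        tsd = None
        if (anchored
                and span.start - 1 - cfg.tsd_len >= 0
                and span.end - 1 + cfg.tsd_len <= contig.length):
            tsd = check_tsd(contig, span, cfg.tsd_len)
        return ElementModel(contig_id=contig.id, span=span,
                            completeness="subtir_only", subtir=subtir,
                            tsd=tsd)

    return ElementModel(contig_id=contig.id, span=Interval(wstart, wend),
                        completeness="incomplete")
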