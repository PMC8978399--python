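"""Synthetic element generator: determinism, noise model, embedding, and
round trips of the detectors against ground truth."""

import numpy as np
import pytest

from cactascan import fixtures
from cactascan.captures import detect_tandem_array
from cactascan.domains import classify_cda
from cactascan.ends import call_element, detect_subtir
from cactascan.sequence import revcomp
from cactascan.simulate import (ElementSpec, build_element,
                                embed_in_background, mutate,
                                published_family_spec)


class TestMutate:
    def test_rate_zero_is_identity(self, make_random_dna):
        s = make_random_dna(1000, 1)
        assert mutate(s, 0.0, seed=5) == s

    def test_substituted_fraction_near_rate(self, make_random_dna):
        s = make_random_dna(10000, 2)
        m = mutate(s, 0.1, seed=3)
        frac = sum(a != b for a, b in zip(s, m)) / len(s)
        assert abs(frac - 0.1) <= 0.01
        assert len(m) == len(s)

    def test_seeded_reproducibility(self, make_random_dna):
        s = make_random_dna(2000, 4)
        assert mutate(s, 0.05, seed=11) == mutate(s, 0.05, seed=11)
        assert mutate(s, 0.05, seed=11) != mutate(s, 0.05, seed=12)

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            mutate("ACGT", 0.5, seed=1)


class TestElementSpecValidation:
    def test_tir_must_start_with_cacta(self):
        with pytest.raises(ValueError):
            ElementSpec(tir="GACTA" + "A" * 23,
                        subtir_motif="TATTTGTAACTA", n5=3, n3=3)

    def test_motif_length_bounds(self):
        with pytest.raises(ValueError):
            ElementSpec(tir="CACTA" + "A" * 23, subtir_motif="ACGT",
                        n5=3, n3=3)

    def test_capture_overflow_rejected(self):
        spec = ElementSpec(tir=fixtures.TIRS["iljinii"],
                           subtir_motif="TATTTGCGTCAC", n5=3, n3=3,
                           captures=[("x", "A" * 100, 99999)], seed=1)
        with pytest.raises(ValueError, match="does not fit"):
            build_element(spec)

    def test_total_length_too_small_rejected(self):
        spec = ElementSpec(tir=fixtures.TIRS["iljinii"],
                           subtir_motif="TATTTGCGTCAC", n5=3, n3=3,
                           total_length=100, seed=1)
        with pytest.raises(ValueError, match="total_length"):
            build_element(spec)


class TestBuildElement:
    def test_deterministic_for_same_spec(self):
        spec = published_family_spec("pamiricum", seed=9)
        s1, _ = build_element(spec)
        s2, _ = build_element(published_family_spec("pamiricum", seed=9))
        assert s1 == s2

    def test_layout_grammar(self):
        spec = published_family_spec("iljinii", seed=2)
        seq, gt = build_element(spec)
        tir = fixtures.TIRS["iljinii"]
        assert seq.startswith(tir)
        assert seq.endswith(revcomp(tir))
        # direct motif copies immediately after the TIR
        motif = fixtures.SUBTIR_MOTIFS["iljinii"]
        assert seq[28:28 + 12] == motif
        # inverted copies immediately before the right TIR
        assert seq[-40:-28] == revcomp(motif)
        # truth intervals slice back to the features they describe
        for name, iv, orf in gt.domain_ivs:
            assert len(iv.slice(seq)) == iv.end - iv.start
        left, right = gt.tir_ivs
        assert left.slice(seq) == tir
        assert right.slice(seq) == revcomp(tir)

    def test_ground_truth_matches_emitted_gff(self):
        seq, gt = build_element(published_family_spec("vulvaria", seed=6))
        assert gt.element_span.end - gt.element_span.start == len(seq)
        for label, iv in gt.capture_ivs:
            assert 1 <= iv.start < iv.end <= len(seq) + 1

    def test_published_vulvaria_capture_coordinates(self):
        _, gt = build_element(published_family_spec("vulvaria", seed=0))
        got = {(label, iv.start, iv.end) for label, iv in gt.capture_ivs}
        assert got == set(fixtures.NEPROSIN_FRAGMENTS)

    def test_mut_rate_preserves_length_and_coordinates(self):
        spec = published_family_spec("iljinii", mut_rate=0.05, seed=4)
        seq, gt = build_element(spec)
        assert len(seq) == fixtures.ELEMENT_LENGTHS["iljinii"]


class TestEmbedInBackground:
    def test_truth_span_matches_placement(self):
        seq, gt = build_element(published_family_spec("sosnowskyi", seed=3))
        contig, (lifted,) = embed_in_background([(seq, gt)], 30000, 0.4,
                                                seed=8)
        assert lifted.element_span.slice(contig.seq) == seq

    def test_tsd_duplicated_flanking(self):
        seq, gt = build_element(published_family_spec("iljinii", seed=3))
        contig, (lifted,) = embed_in_background([(seq, gt)], 30000, 0.4,
                                                seed=9)
        sp = lifted.element_span
        assert contig.seq[sp.start - 4:sp.start - 1] == "TAC"
        assert contig.seq[sp.end - 1:sp.end + 2] == "TAC"

    def test_two_elements_non_overlapping(self):
        e1 = build_element(published_family_spec("iljinii", seed=1))
        e2 = build_element(published_family_spec("pamiricum", seed=2))
        contig, lifted = embed_in_background([e1, e2], 60000, 0.4, seed=3)
        (a, b) = sorted([g.element_span for g in lifted],
                        key=lambda iv: iv.start)
        assert a.end <= b.start

    def test_background_gc_concentration(self):
        contig, _ = embed_in_background([], 100000, 0.35, seed=4)
        gc = sum(c in "GC" for c in contig.seq) / contig.length
        assert abs(gc - 0.35) <= 0.02

    def test_overfull_background_rejected(self):
        seq, gt = build_element(published_family_spec("iljinii", seed=1))
        with pytest.raises(ValueError):
            embed_in_background([(seq, gt)], len(seq), 0.4, seed=1)


class TestPublishedFamilies:
    @pytest.mark.parametrize("name", ["pamiricum", "sosnowskyi", "iljinii",
                                      "vulvaria", "quinoa_scaffold3500"])
    def test_reconstructed_total_length(self, name):
        seq, _ = build_element(published_family_spec(name, seed=0))
        assert len(seq) == fixtures.ELEMENT_LENGTHS[name]

    @pytest.mark.parametrize("name", ["pamiricum", "sosnowskyi", "iljinii",
                                      "vulvaria"])
    def test_published_per_end_subtir_counts(self, name):
        seq, _ = build_element(published_family_spec(name, seed=0))
        ann = detect_subtir(seq)
        assert (ann.n_5prime, ann.n_3prime) == fixtures.SUBTIR_COUNTS[name]

    def test_pamiricum_total_19_copies(self):
        # printed layout: 19 copies of TATTTGTAACTA, 9 at 5' + 10 at 3'
        seq, _ = build_element(published_family_spec("pamiricum", seed=1))
        assert detect_subtir(seq).n_total == 19


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(12))
    def test_noise_free_pipeline_reproduces_ground_truth(self, seed,
                                                         make_random_dna):
        """Noise-free round trip: boundary call, completeness, subTIR
        counts, CDA type and satellite monomer/copies all equal ground
        truth."""
        rng = np.random.default_rng(seed)
        cda = ("type1", "type2", "type3", "type4")[seed % 4]
        extras = [d for d in fixtures.CDA_DOMAIN_SETS[cda]
                  if d in ("Transposase_24", "Peptidase_C48")]
        layout = [("TAD", 393), ("Transposase_21", 630),
                  ("DUF4218", 525), ("DUF4216", 456)]
        layout += [(d, 300) for d in extras]
        with_array = seed % 3 == 0
        mono = make_random_dna(int(rng.integers(60, 200)), seed + 700)
        spec = ElementSpec(
            tir="CACTA" + make_random_dna(23, seed + 300),
            subtir_motif=make_random_dna(int(rng.integers(10, 21)),
                                         seed + 400),
            n5=int(rng.integers(3, 12)), n3=int(rng.integers(3, 12)),
            orf_layout=layout,
            sat_array=(mono, float(rng.integers(4, 12)) + 0.5)
            if with_array else None,
            tsd="TAC", seed=seed)
        seq, gt = build_element(spec)
        contig, (lifted,) = embed_in_background([(seq, gt)], 40000, 0.45,
                                                seed=seed + 1)
        tnp = next(iv for n, iv, o in lifted.domain_ivs
                   if n == "Transposase_21")
        elem = call_element(contig, tnp)
        assert elem.completeness == "complete"
        assert (elem.span.start, elem.span.end) == \
            (lifted.element_span.start, lifted.element_span.end)
        assert elem.tsd == "TAC"
        assert (elem.subtir.n_5prime, elem.subtir.n_3prime) == \
            (spec.n5, spec.n3)
        names = [n for n, iv, orf in gt.domain_ivs]
        assert classify_cda(names).label == cda
        arrays = detect_tandem_array(seq)
        if with_array:
            assert any(a.monomer_len == len(mono) for a in arrays)
            (arr,) = [a for a in arrays if a.monomer_len == len(mono)]
            true_cn = (gt.array_iv.end - gt.array_iv.start) / len(mono)
            assert abs(arr.copy_number - true_cn) <= 0.5
        else:
            assert arrays == []

    def test_noisy_subtir_count_recovery(self):
        """At 5 % substitution the detector recovers the surviving copy
        counts (copies still above the 0.80 identity threshold after
        mutation -- copies drop below it only by chance) exactly in
        >= 80 % of 100 replicates and within +/-1 in >= 98 %."""
        from cactascan.sequence import revcomp, ungapped_identity

        exact = 0
        within1 = 0
        n = 100
        for seed in range(n):
            spec = published_family_spec("sosnowskyi", mut_rate=0.05, seed=seed)
            seq, gt = build_element(spec)
            motif = spec.subtir_motif
            surv5 = surv3 = 0
            for iv, orient in gt.subtir_copy_ivs:
                target = motif if orient == "direct" else revcomp(motif)
                if ungapped_identity(iv.slice(seq), target) >= 0.80:
                    if orient == "direct":
                        surv5 += 1
                    else:
                        surv3 += 1
            ann = detect_subtir(seq)
            d5 = abs(ann.n_5prime - surv5)
            d3 = abs(ann.n_3prime - surv3)
            if d5 == 0 and d3 == 0:
                exact += 1
            if d5 <= 1 and d3 <= 1:
                within1 += 1
        assert exact >= 0.80 * n
        assert within1 >= 0.98 * n
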