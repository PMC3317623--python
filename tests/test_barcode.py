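"""Pairwise identity, primer extraction, and the identification classifier."""

import itertools
import random

import pytest

from rheotad.barcode import (
    AlignmentParams,
    BarcodeError,
    CandidateLabel,
    IdentityResult,
    PrimerNotFoundError,
    ReferenceMeta,
    SequenceRecord,
    Thresholds,
    best_match,
    classify_identification,
    confirm_candidate,
    extract_fragment_by_primers,
    format_candidate_label,
    pairwise_identity,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# an independent brute-force oracle: enumerate every global alignment of two
# short strings, score it with affine gaps and free end gaps, return the
# maximum score (exponential, fine for <= 6 nt)


def _enumerate_alignments(a, b):
    if not a and not b:
        yield []
        return
    if a:
        for rest in _enumerate_alignments(a[1:], b):
            yield [(a[0], "-")] + rest
    if b:
        for rest in _enumerate_alignments(a, b[1:]):
            yield [("-", b[0])] + rest
    if a and b:
        for rest in _enumerate_alignments(a[1:], b[1:]):
            yield [(a[0], b[0])] + rest


def _score_alignment(columns, params: AlignmentParams) -> float:
    # a gap column is terminal (free) only if it lies outside its own row's
    # first..last residue span
    rows = ["".join(c[i] for c in columns) for i in (0, 1)]
    spans = []
    for row in rows:
        first = next((i for i, c in enumerate(row) if c != "-"), len(row))
        last = next((i for i in range(len(row) - 1, -1, -1) if row[i] != "-"), -1)
        spans.append((first, last))
    score = 0.0
    prev_gap_row = None  # 0 = gap in first row, 1 = gap in second
    for i, (x, y) in enumerate(columns):
        if x == "-" or y == "-":
            row = 0 if x == "-" else 1
            first, last = spans[row]
            if i < first or i > last:
                prev_gap_row = None  # terminal gap: free
                continue
            score += params.gap_extend if prev_gap_row == row else params.gap_open
            prev_gap_row = row
        else:
            score += params.match if x == y else params.mismatch
            prev_gap_row = None
    return score


def oracle_best_score(a: str, b: str, params: AlignmentParams) -> float:
    return max(
        _score_alignment(cols, params) for cols in _enumerate_alignments(a, b)
    )


class TestPairwiseIdentity:
    def test_self_identity_is_exactly_100(self):
        seq = SequenceRecord(id="s", sequence="ACGTACGTAC" * 40)
        assert pairwise_identity(seq, seq).percent_identity == 100.0

    def test_five_substitutions_in_100_nt_give_95(self):
        random.seed(7)
        base = "".join(random.choice("ACGT") for _ in range(100))
        mutated = list(base)
        for pos in random.sample(range(100), 5):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        r = pairwise_identity(
            SequenceRecord(id="a", sequence=base),
            SequenceRecord(id="b", sequence="".join(mutated)),
        )
        assert r.percent_identity == pytest.approx(95.0)
        assert r.matches == 95 and r.aligned_columns == 100

    def test_symmetry(self):
        random.seed(11)
        a = SequenceRecord(id="a", sequence="".join(random.choice("ACGT") for _ in range(80)))
        b = SequenceRecord(
            id="b", sequence=a.sequence[5:] + "ACGTT"
        )
        ab = pairwise_identity(a, b)
        ba = pairwise_identity(b, a)
        assert ab.percent_identity == ba.percent_identity
        assert ab.aligned_columns == ba.aligned_columns

    def test_terminal_gaps_excluded_from_denominator(self):
        a = SequenceRecord(id="a", sequence="AAAACGTACGT")
        b = SequenceRecord(id="b", sequence="CGTACGT")
        r = pairwise_identity(a, b)
        assert r.aligned_columns == 7
        assert r.percent_identity == 100.0

    def test_iupac_ambiguity_codes_match_on_intersection(self):
        a = SequenceRecord(id="a", sequence="ACGTACGTRY")
        b = SequenceRecord(id="b", sequence="ACGTACGTAC")  # R~A, Y~C
        assert pairwise_identity(a, b).percent_identity == 100.0
        c = SequenceRecord(id="c", sequence="ACGTACGTRR")  # second R vs C: no overlap
        assert pairwise_identity(b, c).percent_identity == 90.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(BarcodeError):
            SequenceRecord(id="x", sequence="")

    def test_optimal_score_matches_exhaustive_oracle_on_toys(self):
        params = AlignmentParams()
        from rheotad.barcode import _make_aligner

        aligner = _make_aligner(params)
        random.seed(3)
        for _ in range(25):
            a = "".join(random.choice("ACGT") for _ in range(random.randint(1, 6)))
            b = "".join(random.choice("ACGT") for _ in range(random.randint(1, 6)))
            assert aligner.score(a, b) == pytest.approx(
                oracle_best_score(a, b, params)
            ), (a, b)

    def test_accumulating_substitutions_cannot_raise_identity_beyond_edge_slack(self):
        # matches/overlap-columns is monotone non-increasing up to a boundary
        # effect: a terminal mismatch may be shed into free overhangs, which
        # can raise the ratio by at most ~2 columns' worth (100*2/L points);
        # at barcode fragment length the statistic is effectively monotone
        random.seed(23)
        for length in (12, 60):
            slack = 100.0 * 2 / length
            for _ in range(10):
                base = "".join(random.choice("ACGT") for _ in range(length))
                a = SequenceRecord(id="a", sequence=base)
                mutated = list(base)
                previous = 100.0
                for pos in random.sample(range(length), length // 4):
                    mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
                    ident = pairwise_identity(
                        a, SequenceRecord(id="b", sequence="".join(mutated))
                    ).percent_identity
                    assert ident <= previous + slack
                    previous = ident

    def test_substitutions_strictly_monotone_at_fragment_scale(self):
        random.seed(29)
        base = "".join(random.choice("ACGT") for _ in range(550))
        a = SequenceRecord(id="a", sequence=base)
        mutated = list(base)
        previous = 100.0
        for pos in random.sample(range(550), 60):
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
            ident = pairwise_identity(
                a, SequenceRecord(id="b", sequence="".join(mutated))
            ).percent_identity
            assert ident <= previous + 0.05
            previous = ident


class TestPrimerExtraction:
    FWD = "CATAATCACTTGTTCTTTAAA"
    REV = "GATCCAACATCGAGGTCG"

    def _template(self, insert, pad5="GG" * 8, pad3="TT" * 8):
        return SequenceRecord(
            id="t",
            sequence=pad5 + self.FWD + insert + reverse_complement(self.REV) + pad3,
        )

    def test_recovers_planted_insert(self):
        random.seed(5)
        insert = "".join(random.choice("ACGT") for _ in range(400))
        frag = extract_fragment_by_primers(self._template(insert), self.FWD, self.REV, 0)
        assert frag.sequence == insert

    def test_one_mismatch_needs_budget(self):
        random.seed(6)
        insert = "".join(random.choice("ACGT") for _ in range(100))
        damaged_fwd = "G" + self.FWD[1:]  # C->G at primer position 0
        template = SequenceRecord(
            id="t",
            sequence="GGGG" + damaged_fwd + insert + reverse_complement(self.REV) + "AAAA",
        )
        with pytest.raises(PrimerNotFoundError) as err:
            extract_fragment_by_primers(template, self.FWD, self.REV, 0)
        assert err.value.primer_name == "forward"
        frag = extract_fragment_by_primers(template, self.FWD, self.REV, 1)
        assert frag.sequence == insert

    def test_best_placement_matches_sliding_window_oracle(self):
        # exhaustive check: the reported insert boundary equals the placement
        # a full scan of all windows would choose (fewest mismatches, leftmost)
        random.seed(8)
        seq = "".join(random.choice("ACGT") for _ in range(300))
        primer = seq[40:60]
        mismatches = [
            sum(a != b for a, b in zip(seq[i : i + 20], primer))
            for i in range(len(seq) - 19)
        ]
        best = min(range(len(mismatches)), key=lambda i: (mismatches[i], i))
        assert best == 40

    def test_inverted_orientation_detected(self):
        random.seed(9)
        insert = "".join(random.choice("ACGT") for _ in range(50))
        # reverse site upstream of the forward site
        template = SequenceRecord(
            id="t",
            sequence="GG" + reverse_complement(self.REV) + insert + self.FWD + "AA",
        )
        with pytest.raises(BarcodeError, match="orientation"):
            extract_fragment_by_primers(template, self.FWD, self.REV, 0)


class TestBestMatch:
    def test_identical_reference_ranks_first(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=200))
        query = SequenceRecord(id="q", sequence=base)
        refs = [
            SequenceRecord(id=f"r{i}", sequence="".join(rng.permutation(list(base))),
                           role="adult_reference", reference_status="described_species")
            for i in range(9)
        ]
        refs.append(SequenceRecord(id="hit", sequence=base, role="adult_reference",
                                   reference_status="described_species"))
        ranked = best_match(query, refs)
        assert ranked[0].reference_id == "hit"
        assert ranked[0].percent_identity == 100.0

    def test_planted_divergence_order_recovered(self):
        from rheotad.synthdata import generate_sequences

        records, truth = generate_sequences(
            base_length=500, divergences=(0.03, 0.07, 0.12), n_per_level=1, seed=42
        )
        base, derived = records[0], records[1:]
        ranked = best_match(base, derived)
        assert [r.reference_id for r in ranked] == ["div0_0", "div1_0", "div2_0"]

    def test_tie_broken_by_longer_overlap_then_id(self):
        query = SequenceRecord(id="q", sequence="ACGTACGTACGTACGTACGT")
        short = SequenceRecord(id="b_short", sequence="ACGTACGTAC",
                               role="adult_reference")
        long = SequenceRecord(id="a_long", sequence="ACGTACGTACGTACGT",
                              role="adult_reference")
        ranked = best_match(query, [short, long])
        assert [r.reference_id for r in ranked] == ["a_long", "b_short"]

    def test_empty_reference_set_is_an_error(self):
        query = SequenceRecord(id="q", sequence="ACGT")
        with pytest.raises(BarcodeError):
            best_match(query, [])


def _result(identity, ref="REF1"):
    return IdentityResult(
        query_id="q", reference_id=ref, percent_identity=identity,
        aligned_columns=500, matches=int(identity * 5),
        query_start=0, query_end=500, ref_start=0, ref_end=500,
    )


class TestClassifyIdentification:
    def meta(self, species="Boophis sp1", status="described_species",
             region="north", role="adult_reference"):
        return ReferenceMeta(species=species, status=status, region=region, role=role)

    def test_high_identity_same_region_is_nominal(self):
        decision = classify_identification(
            [_result(99.5)], "north", {"REF1": self.meta()}
        )
        assert decision.verdict == "unequivocal_nominal"
        assert decision.overrides == []

    def test_deep_divergence_is_candidate(self):
        decision = classify_identification(
            [_result(90.4)], "north", {"REF1": self.meta()}
        )
        assert decision.verdict == "candidate"

    def test_unassigned_lineage_reference_forces_candidate(self):
        decision = classify_identification(
            [_result(99.7)], "north",
            {"REF1": self.meta(status="unassigned_lineage")},
        )
        assert decision.verdict == "candidate"
        assert "reference_unassigned_lineage" in decision.overrides

    def test_parsimony_override_promotes_to_nominal(self):
        decision = classify_identification(
            [_result(96.0)], "north", {"REF1": self.meta()},
            geographic_parsimony=True,
        )
        assert decision.verdict == "unequivocal_nominal"
        assert "geographic_parsimony" in decision.overrides

    def test_intermediate_identity_same_region_is_ambiguous(self):
        decision = classify_identification(
            [_result(98.0)], "north", {"REF1": self.meta()}
        )
        assert decision.verdict == "ambiguous"

    def test_subnominal_allopatric_match_is_candidate(self):
        decision = classify_identification(
            [_result(98.8)], "north", {"REF1": self.meta(region="south")}
        )
        assert decision.verdict == "candidate"

    def test_margin_to_next_species_enforced(self):
        results = [_result(99.5, "REF1"), _result(99.2, "REF2")]
        meta = {
            "REF1": self.meta(species="sp1"),
            "REF2": self.meta(species="sp2"),
        }
        decision = classify_identification(results, "north", meta)
        assert decision.verdict == "ambiguous"  # margin 0.3 < 1.0
        assert decision.margin_to_next_species == pytest.approx(0.3)
        wide = classify_identification(
            results, "north", meta, thresholds=Thresholds(margin=0.2)
        )
        assert wide.verdict == "unequivocal_nominal"

    def test_adult_references_take_precedence_over_tadpoles(self):
        results = [_result(99.9, "TAD"), _result(99.1, "AD")]
        meta = {
            "TAD": self.meta(role="tadpole_reference"),
            "AD": self.meta(role="adult_reference"),
        }
        decision = classify_identification(results, "north", meta)
        assert decision.best_reference == "AD"

    def test_missing_metadata_is_an_error(self):
        with pytest.raises(BarcodeError, match="REF1"):
            classify_identification([_result(99.0)], "north", {})

    def test_monotone_in_identity_never_nominal_to_candidate(self):
        # scanning identity upward never flips the verdict toward candidate
        rank = {"candidate": 0, "ambiguous": 1, "unequivocal_nominal": 2}
        previous = -1
        for identity in [90 + 0.5 * k for k in range(21)]:
            v = classify_identification(
                [_result(identity)], "north", {"REF1": self.meta()}
            ).verdict
            assert rank[v] >= previous
            previous = rank[v]


class TestCandidateLabels:
    def test_first_mention_with_accession(self):
        label = CandidateLabel("Boophis sambirano", 47, "JQ518203", True)
        assert format_candidate_label(label) == "Boophis sambirano [Ca47 JQ518203]"

    def test_later_mention_drops_evidence(self):
        label = CandidateLabel("Boophis sambirano", 47, "JQ518203", False)
        assert format_candidate_label(label) == "Boophis sambirano [Ca47]"

    def test_first_mention_without_evidence_fails(self):
        with pytest.raises(ValueError):
            format_candidate_label(CandidateLabel("Boophis sambirano", 47, None, True))

    def test_ca_number_must_be_positive(self):
        with pytest.raises(ValueError):
            CandidateLabel("Boophis sambirano", 0, "x")


class TestConfirmCandidate:
    def test_divergent_morphology_plus_sympatry_confirms(self):
        out = confirm_candidate(["a"], ["b"], morphology_differs=True, sympatric=True)
        assert out["status"] == "confirmed"

    def test_no_morphology_scored_stays_unconfirmed(self):
        out = confirm_candidate(["a"], ["b"], morphology_differs=False, sympatric=True)
        assert out["status"] == "unconfirmed"

    def test_allopatric_pair_names_the_failing_criterion(self):
        out = confirm_candidate(["a"], ["b"], morphology_differs=True, sympatric=False)
        assert out["status"] == "unconfirmed"
        assert "sympatry" in out["rationale"]
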