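import itertools
import random
from dataclasses import replace

import pytest

from rna2dbarcode.barcode import (
    GAP,
    CladePartition,
    align_stemloops,
    basepair_distance,
    classify_columns,
    consensus_from_alignment,
    consensus_structure,
    detect_cbc,
    rank_variability,
)
from rna2dbarcode.fold import PairTable, SecondaryStructure, fold_maxpair
from rna2dbarcode.io import SequenceRecord
from rna2dbarcode.stemloops import extract_stemloops

COMP = {"G": "C", "C": "G", "A": "U", "U": "A"}


def hairpin_stemloop(taxon, stem5, loop, stem3=None, label="L7"):
    """A single-hairpin structure and its extracted stem-loop."""
    stem3 = stem3 if stem3 is not None else "".join(COMP[c] for c in reversed(stem5))
    seq = stem5 + loop + stem3
    db = "(" * len(stem5) + "." * len(loop) + ")" * len(stem3)
    st = SecondaryStructure(
        SequenceRecord(id=taxon, residues=seq), PairTable.from_dotbracket(db), 0.0
    )
    (sl,) = extract_stemloops(st)
    return replace(sl, label=label)


class TestAlignment:
    def test_identical_stemloops_align_without_gaps(self):
        loops = {t: hairpin_stemloop(t, "GCGGC", "ACAACCAAA") for t in ("a", "b", "c")}
        aln = align_stemloops(loops)
        assert aln.columns == 19
        assert all(GAP not in row for row in aln.rows.values())
        assert aln.pairing_mask[:5] == ("stem",) * 5
        assert aln.pairing_mask[5:14] == ("loop",) * 9

    def test_loop_length_difference_gives_exactly_one_gap(self):
        loops = {
            "long": hairpin_stemloop("long", "GCGGC", "ACAACCAAA"),
            "short": hairpin_stemloop("short", "GCGGC", "ACACCAAA"),
        }
        aln = align_stemloops(loops)
        assert aln.rows["short"].count(GAP) == 1
        assert aln.rows["long"].count(GAP) == 0
        # score of the returned loop alignment equals the brute-force optimum
        a, b = "ACAACCAAA", "ACACCAAA"
        def score(ra, rb):
            return sum(
                -1 if GAP in (x, y) else (1 if x == y else 0) for x, y in zip(ra, rb)
            )
        best = max(
            score(a, b[:k] + GAP + b[k:]) for k in range(len(b) + 1)
        )
        loop_cols = [c for c, m in enumerate(aln.pairing_mask) if m == "loop"]
        ra = "".join(aln.rows["long"][c] for c in loop_cols)
        rb = "".join(aln.rows["short"][c] for c in loop_cols)
        assert score(ra, rb) == best

    def test_shorter_stem_gaps_at_the_outer_rank(self):
        loops = {
            "five": hairpin_stemloop("five", "GCGGC", "AAACAA"),
            "four": hairpin_stemloop("four", "CGGC", "AAACAA"),
        }
        aln = align_stemloops(loops)
        c5, c3 = aln.stem_rank_columns[0]
        assert aln.rows["four"][c5] == GAP and aln.rows["four"][c3] == GAP
        assert aln.rows["five"][c5] != GAP

    def test_single_taxon_is_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            align_stemloops({"a": hairpin_stemloop("a", "GCG", "AAAA")})

    def test_label_mismatch_is_rejected(self):
        with pytest.raises(ValueError, match="different labels"):
            align_stemloops(
                {
                    "a": hairpin_stemloop("a", "GCG", "AAAA", label="L7"),
                    "b": hairpin_stemloop("b", "GCG", "AAAA", label="L8"),
                }
            )

    def test_degapped_rows_reproduce_the_input_stemloops(self):
        loops = {
            "a": hairpin_stemloop("a", "GCGGC", "ACAACCAAA"),
            "b": hairpin_stemloop("b", "GCGC", "ACACCAAA"),
        }
        aln = align_stemloops(loops)
        for taxon, sl in loops.items():
            assert aln.rows[taxon].replace(GAP, "") == sl.sequence


class TestVariabilityRanking:
    def test_planted_divergence_puts_l7_first(self, clade_cbc):
        _, _, v_domains = clade_cbc
        by_label = {}
        for taxon, vd in v_domains.items():
            for sl in vd.stem_loops:
                by_label.setdefault(sl.label, {})[taxon] = sl
        alignments = {lb: align_stemloops(loops) for lb, loops in by_label.items()}
        ranking = rank_variability(alignments)
        assert ranking[0][0] == "L7"
        assert ranking[0][1] > 0

    def test_identical_rows_score_zero_in_label_order(self):
        alignments = {
            lb: align_stemloops(
                {t: hairpin_stemloop(t, "GCGGC", "ACAACCAAA", label=lb) for t in "ab"}
            )
            for lb in ("L9", "L7", "L8")
        }
        ranking = rank_variability(alignments)
        assert ranking == [("L7", 0.0), ("L8", 0.0), ("L9", 0.0)]

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            rank_variability({})


class TestCBC:
    def pair_states_scan(self, stem_a, stem_b, loop="AAAA"):
        loops = {
            "t1": hairpin_stemloop("t1", stem_a[0], loop, stem_a[1]),
            "t2": hairpin_stemloop("t2", stem_b[0], loop, stem_b[1]),
        }
        return detect_cbc(align_stemloops(loops))

    def test_both_sides_changed_with_pairing_kept_is_cbc(self):
        scan = self.pair_states_scan(("G", "C"), ("A", "U"))
        (rec,) = scan.records
        assert rec.type == "CBC" and rec.states == ("GC", "AU")

    def test_one_side_changed_with_pairing_kept_is_semicbc(self):
        scan = self.pair_states_scan(("G", "C"), ("G", "U"))
        assert scan.records[0].type == "semiCBC"

    def test_identical_pair_is_none_and_broken_pair_is_flagged(self):
        assert self.pair_states_scan(("G", "C"), ("G", "C")).records[0].type == "none"
        assert self.pair_states_scan(("G", "C"), ("A", "C")).records[0].type == "pair_broken"

    def test_scan_is_symmetric_in_taxon_order(self, clade_cbc):
        _, _, v_domains = clade_cbc
        loops = {t: vd.by_label()["L8"] for t, vd in v_domains.items()}
        forward = detect_cbc(align_stemloops(loops))
        reversed_loops = dict(reversed(list(loops.items())))
        backward = detect_cbc(align_stemloops(reversed_loops))
        assert forward.n_cbc == backward.n_cbc
        assert forward.n_semicbc == backward.n_semicbc

    def test_gapped_ranks_are_skipped_and_counted(self):
        loops = {
            "five": hairpin_stemloop("five", "GCGGC", "AAACAA"),
            "four": hairpin_stemloop("four", "CGGC", "AAACAA"),
        }
        scan = detect_cbc(align_stemloops(loops))
        assert scan.skipped_gapped == 1
        assert len(scan.records) == 4

    def test_row_structure_mismatch_is_an_error(self):
        loops = {
            "t1": hairpin_stemloop("t1", "GCGGC", "ACAACCAAA"),
            "t2": hairpin_stemloop("t2", "GCGGC", "ACAACCAAA"),
        }
        aln = align_stemloops(loops)
        wrong = SecondaryStructure(
            SequenceRecord(id="t1", residues="A" * 19),
            PairTable.from_dotbracket("." * 19),
            0.0,
        )
        with pytest.raises(ValueError, match="does not match"):
            detect_cbc(aln, structures={"t1": wrong})


class TestClassification:
    def two_group_alignment(self, seqs):
        loops = {
            t: hairpin_stemloop(t, "GCGGC", loop) for t, loop in seqs.items()
        }
        aln = align_stemloops(loops)
        part = CladePartition(
            "genus",
            {
                "G1": frozenset(t for t in seqs if t.startswith("a")),
                "G2": frozenset(t for t in seqs if t.startswith("b")),
            },
        )
        return aln, part

    def test_all_identical_rows_are_all_landmark(self):
        aln, part = self.two_group_alignment(
            {"a1": "ACAACCAAA", "a2": "ACAACCAAA", "b1": "ACAACCAAA", "b2": "ACAACCAAA"}
        )
        cls = classify_columns(aln, part)
        assert set(cls.verdicts) == {"landmark"}
        assert cls.counts["landmark"] == aln.columns

    def test_group_fixed_difference_is_diagnostic(self):
        aln, part = self.two_group_alignment(
            {"a1": "ACAACCAAA", "a2": "ACAACCAAA", "b1": "CCAACCAAA", "b2": "CCAACCAAA"}
        )
        cls = classify_columns(aln, part)
        loop_start = 5
        assert cls.verdicts[loop_start] == "diagnostic"
        assert cls.counts["diagnostic"] == 1

    def test_within_group_polymorphism_is_variable_not_diagnostic(self):
        aln, part = self.two_group_alignment(
            {"a1": "ACAACCAAA", "a2": "CCAACCAAA", "b1": "GCAACCAAA", "b2": "GCAACCAAA"}
        )
        cls = classify_columns(aln, part)
        assert cls.verdicts[5] == "variable"

    def test_relaxed_fixation_threshold_recovers_majority_diagnostic(self):
        seqs = {f"a{i}": "ACAACCAAA" for i in range(9)} | {"a9": "CCAACCAAA"}
        seqs |= {f"b{i}": "CCAACCAAA" for i in range(10)}
        aln, part = self.two_group_alignment(seqs)
        strict = classify_columns(aln, part)
        relaxed = classify_columns(aln, part, fixation_threshold=0.9)
        assert strict.verdicts[5] == "variable"
        assert relaxed.verdicts[5] == "diagnostic"

    def test_gap_and_ambiguity_columns_are_set_aside(self):
        part = CladePartition(
            "genus", {"G1": frozenset({"a1"}), "G2": frozenset({"b1"})}
        )
        ambiguous = align_stemloops(
            {
                "a1": hairpin_stemloop("a1", "GCGGC", "ACAANCAAA"),
                "b1": hairpin_stemloop("b1", "GCGGC", "ACAACCAAA"),
            }
        )
        cls = classify_columns(ambiguous, part)
        assert cls.counts["ambiguous"] == 1 and cls.counts["gapped"] == 0
        gapped = align_stemloops(
            {
                "a1": hairpin_stemloop("a1", "GCGGC", "ACAACCAAA"),
                "b1": hairpin_stemloop("b1", "GCGGC", "ACAACCAA"),
            }
        )
        cls = classify_columns(gapped, part)
        assert cls.counts["gapped"] == 1
        for c in (cls, classify_columns(ambiguous, part)):
            assert sum(c.counts.values()) == len(c.verdicts)  # exhaustive verdicts

    def test_taxon_missing_from_partition_is_an_error(self):
        aln, _ = self.two_group_alignment(
            {"a1": "ACAACCAAA", "a2": "ACAACCAAA", "b1": "ACAACCAAA", "b2": "ACAACCAAA"}
        )
        part = CladePartition("genus", {"G1": frozenset({"a1"}), "G2": frozenset({"a2"})})
        with pytest.raises(KeyError):
            classify_columns(aln, part)

    def test_single_group_is_rejected(self):
        aln, _ = self.two_group_alignment(
            {"a1": "ACAACCAAA", "a2": "ACAACCAAA", "b1": "ACAACCAAA", "b2": "ACAACCAAA"}
        )
        part = CladePartition("genus", {"G1": frozenset({"a1", "a2", "b1", "b2"})})
        with pytest.raises(ValueError, match=">= 2 groups"):
            classify_columns(aln, part)


class TestBackgroundNoise:
    def test_classification_disagreement_grows_with_background_rate(self, template_stemloops):
        """Background mutations erode the planted architecture: the number of
        L7 columns whose verdict departs from the noise-free classification is
        zero at rate 0 and does not decrease as the rate rises."""
        from rna2dbarcode.synth import example_clade_spec, synthesize_clade

        totals = {}
        for rate in (0.0, 0.05, 0.15):
            disagree = 0
            for seed in range(10):
                records, _ = synthesize_clade(
                    example_clade_spec(seed=seed, background_mutation_rate=rate)
                )
                part = CladePartition.from_records(records, rank="genus")
                cls = classify_columns(align_stemloops(template_stemloops(records)), part)
                if rate == 0.0:
                    baseline = totals.setdefault("baseline", {})
                    baseline[seed] = cls.verdicts
                else:
                    base = totals["baseline"][seed]
                    disagree += sum(a != b for a, b in zip(base, cls.verdicts))
            totals[rate] = disagree
        assert totals[0.05] <= totals[0.15]
        assert totals[0.15] > 0


def toy_structure(db, seq=None):
    pt = PairTable.from_dotbracket(db)
    if seq is None:
        chars = ["A"] * len(db)
        for i, j in pt.pairs():
            chars[i], chars[j] = "G", "C"
        seq = "".join(chars)
    return SecondaryStructure(SequenceRecord(id="s", residues=seq), pt, 0.0)


class TestConsensus:
    def test_identical_inputs_give_identical_consensus(self):
        sts = [toy_structure("((((....))))", "GGGGAAAACCCC") for _ in range(3)]
        cons = consensus_structure(sts)
        assert cons.dotbracket == "((((....))))"
        assert cons.record.residues == "GGGGAAAACCCC"

    def test_two_thirds_majority_keeps_the_innermost_pair(self):
        sts = [
            toy_structure("((((....))))", "GGGGAAAACCCC"),
            toy_structure("((((....))))", "GGGGAAAACCCC"),
            toy_structure("(((......)))", "GGGGAAAACCCC"),
        ]
        assert consensus_structure(sts).dotbracket == "((((....))))"

    def test_disjoint_pairs_give_open_chain(self):
        sts = [
            toy_structure("((((....))))"),
            toy_structure("(....)(....)"),
        ]
        cons = consensus_structure(sts)
        assert cons.dotbracket == "." * 12

    def test_tied_states_become_iupac_degeneracy(self):
        sts = [
            toy_structure("............", "GGGGAAAACCCC"),
            toy_structure("............", "AGGGAAAACCCC"),
        ]
        assert consensus_structure(sts).record.residues[0] == "R"  # A/G

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            consensus_structure([toy_structure("((((....))))"), toy_structure("((...))")])

    def test_alignment_consensus_of_identical_rows_is_the_row(self):
        loops = {t: hairpin_stemloop(t, "GCGGC", "ACAACCAAA") for t in "abc"}
        aln = align_stemloops(loops)
        cseq, cdb = consensus_from_alignment(aln)
        assert cseq == "GCGGCACAACCAAAGCCGC"
        assert cdb == "(((((.........)))))"


class TestBasePairDistance:
    def test_identical_structures_are_at_distance_zero(self):
        assert basepair_distance(toy_structure("((((....))))"), toy_structure("((((....))))")) == 0

    def test_one_missing_pair_is_distance_one(self):
        assert (
            basepair_distance(toy_structure("((((....))))"), toy_structure("(((......)))")) == 1
        )

    def test_metric_axioms_on_random_structures(self):
        rng = random.Random(23)
        structures = []
        while len(structures) < 6:
            seq = "".join(rng.choice("ACGU") for _ in range(14))
            structures.append(fold_maxpair(seq))
            structures.append(
                SecondaryStructure(
                    SequenceRecord(id=f"open{len(structures)}", residues=seq),
                    PairTable.from_dotbracket("." * 14),
                    0.0,
                )
            )
        for s1, s2, s3 in itertools.combinations(structures, 3):
            d12, d21 = basepair_distance(s1, s2), basepair_distance(s2, s1)
            assert d12 == d21
            assert basepair_distance(s1, s3) <= d12 + basepair_distance(s2, s3)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="length"):
            basepair_distance(toy_structure("((((....))))"), toy_structure("((...))"))
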