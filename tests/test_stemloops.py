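import itertools
import logging

import pytest

from rna2dbarcode.fold import PairTable, SecondaryStructure, fold_mfe
from rna2dbarcode.io import SequenceRecord
from rna2dbarcode.stemloops import (
    assign_loop_labels,
    delimit_v_domain,
    extract_stemloops,
    stemloop_table,
)

COMP = {"G": "C", "C": "G", "A": "U", "U": "A"}


def structure_from_dotbracket(db: str, rec_id: str = "toy") -> SecondaryStructure:
    """Build a structure whose sequence is consistent with the dot-bracket."""
    pt = PairTable.from_dotbracket(db)
    seq = ["A"] * len(db)
    for i, j in pt.pairs():
        seq[i], seq[j] = "G", "C"
    rec = SequenceRecord(id=rec_id, residues="".join(seq))
    return SecondaryStructure(rec, pt, 0.0)


class TestExtraction:
    def test_clean_hairpin_decomposes_definitionally(self):
        (sl,) = extract_stemloops(structure_from_dotbracket("((((....))))"))
        assert sl.stem_bp == 4 and sl.loop_nt == 4 and sl.bulges == ()
        assert sl.total_nt == 12 and sl.closing_pair == (0, 11)

    def test_two_hairpins_come_back_five_prime_first(self):
        loops = extract_stemloops(structure_from_dotbracket("..((...))((....))."))
        assert [sl.closing_pair for sl in loops] == [(2, 8), (9, 16)]

    def test_small_bulge_merges_into_one_stem(self):
        (sl,) = extract_stemloops(structure_from_dotbracket("((.((...))))"))
        assert sl.stem_bp == 4
        assert sl.bulges == (("5p", 2, 3),)
        assert sl.total_nt == 8 + 3 + 1

    def test_interruption_above_threshold_splits_the_stem(self):
        # 3-nt gap between helices: inner helix is its own stem-loop
        (sl,) = extract_stemloops(structure_from_dotbracket("((...((...))))"))
        assert sl.stem_bp == 2 and sl.closing_pair == (5, 11)

    def test_structure_without_hairpins_gives_empty_list(self):
        assert extract_stemloops(structure_from_dotbracket("......")) == []

    def test_position_conservation_on_hairpin_only_structures(self, model):
        import random

        rng = random.Random(17)
        for _ in range(10):
            # hairpin-rich random sequences: GC arms with A loops
            n_h = rng.randint(1, 3)
            seq = ""
            for _ in range(n_h):
                arm = "".join(rng.choice("GC") for _ in range(4))
                seq += "A" * rng.randint(0, 3) + arm + "A" * 4 + "".join(
                    COMP[c] for c in reversed(arm)
                )
            seq += "A" * rng.randint(0, 3)
            st = fold_mfe(seq, model)
            loops = extract_stemloops(st)
            covered = sum(sl.total_nt for sl in loops)
            spans = set()
            for sl in loops:
                spans.update(range(sl.closing_pair[0], sl.closing_pair[1] + 1))
            exterior = sum(
                1 for i in range(st.n)
                if i not in spans and st.pairs.partner[i] == -1
            )
            enclosing_pairs = sum(
                1 for i, j in st.pairs.pairs() if (i, j) not in
                {p for sl in loops for p in sl.stem_pairs}
            )
            assert covered + exterior + 2 * enclosing_pairs == st.n

    def test_extraction_invariant_under_dotbracket_round_trip(self, reference):
        st = reference.source
        again = SecondaryStructure(
            st.record, PairTable.from_dotbracket(st.dotbracket), st.energy
        )
        assert [
            (sl.closing_pair, sl.stem_pairs, sl.loop_span) for sl in extract_stemloops(st)
        ] == [
            (sl.closing_pair, sl.stem_pairs, sl.loop_span) for sl in extract_stemloops(again)
        ]


def brute_force_assignment(qpos, rpos, max_offset=40.0):
    """Best order-preserving matching by exhaustive search: maximise matches,
    then minimise total offset."""
    best = (0, 0.0, ())
    nq, nr = len(qpos), len(rpos)
    for k in range(min(nq, nr) + 1):
        for qi in itertools.combinations(range(nq), k):
            for ri in itertools.combinations(range(nr), k):
                offs = [abs(qpos[a] - rpos[b]) for a, b in zip(qi, ri)]
                if any(o > max_offset for o in offs):
                    continue
                cand = (-k, sum(offs), tuple(zip(qi, ri)))
                if (cand[0], cand[1]) < (best[0], best[1]):
                    best = cand
    return best


class TestLabelAssignment:
    def make_vdomain(self, db, labels):
        from dataclasses import replace

        from rna2dbarcode.stemloops import VDomain

        st = structure_from_dotbracket(db, "ref")
        loops = extract_stemloops(st)
        assert len(loops) == len(labels)
        labelled = tuple(replace(sl, label=lb) for sl, lb in zip(loops, labels))
        return VDomain(st, (0, len(db)), labelled, ())

    def test_identical_query_gets_identical_labels(self):
        ref = self.make_vdomain("((...))..((...))..((...))", ["L7", "L8", "L9"])
        query = extract_stemloops(structure_from_dotbracket("((...))..((...))..((...))"))
        labelled, unassigned = assign_loop_labels(query, ref, query_origin=0)
        assert [sl.label for sl in labelled] == ["L7", "L8", "L9"]
        assert unassigned == []

    def test_missing_middle_hairpin_preserves_flank_labels(self):
        ref = self.make_vdomain("((...))..((...))..((...))", ["L7", "L8", "L9"])
        query = extract_stemloops(
            structure_from_dotbracket("((...))...........((...))")
        )
        labelled, unassigned = assign_loop_labels(query, ref, query_origin=0)
        assert [sl.label for sl in labelled] == ["L7", "L9"]
        assert unassigned == []
        # agreement with exhaustive search over all order-preserving matchings
        qpos = [sl.midpoint for sl in query]
        rpos = [sl.midpoint for sl in ref.stem_loops]
        n_match, _, pairs = brute_force_assignment(qpos, rpos)
        assert -n_match == len(labelled) and pairs == ((0, 0), (1, 2))

    def test_extra_hairpin_is_flagged_unassigned(self):
        ref = self.make_vdomain("((...))...........((...))", ["L7", "L8"])
        query = extract_stemloops(
            structure_from_dotbracket("((...))..((...))..((...))")
        )
        labelled, unassigned = assign_loop_labels(query, ref, query_origin=0)
        assert [sl.label for sl in labelled] == ["L7", "L8"]
        assert [sl.closing_pair for sl in unassigned] == [(9, 15)]

    def test_empty_reference_is_an_error(self, reference):
        from rna2dbarcode.stemloops import VDomain

        empty = VDomain(reference.source, reference.region, (), ())
        query = extract_stemloops(structure_from_dotbracket("((...))"))
        with pytest.raises(ValueError, match="empty reference"):
            assign_loop_labels(query, empty)


class TestVDomain:
    def test_template_delimits_to_seven_labelled_hairpins(self, model, reference, anchors):
        st = fold_mfe(reference.source.record, model)
        vd = delimit_v_domain(st, anchors=anchors, reference=reference)
        assert [sl.label for sl in vd.stem_loops] == [f"L{k}" for k in range(7, 14)]
        assert vd.unassigned == ()
        l7 = vd.by_label()["L7"]
        assert (l7.total_nt, l7.stem_bp, l7.loop_nt) == (19, 5, 9)

    def test_unmatched_anchors_fall_back_to_three_prime_half(self, model, reference, caplog):
        st = fold_mfe(reference.source.record, model)
        with caplog.at_level(logging.WARNING):
            vd = delimit_v_domain(
                st, anchors=("GGGGGGGG", "GGGGGGGG"), reference=reference
            )
        assert vd.region == (st.n // 2, st.n)
        assert "anchor" in caplog.text

    def test_labels_stable_under_exterior_flanks(self, reference, anchors):
        src = reference.source
        pad = 15
        seq = "A" * pad + src.record.residues + "A" * pad
        db = "." * pad + src.dotbracket + "." * pad
        rec = SequenceRecord(id="padded", residues=seq)
        st = SecondaryStructure(rec, PairTable.from_dotbracket(db), src.energy)
        vd = delimit_v_domain(st, anchors=anchors, reference=reference)
        assert [sl.label for sl in vd.stem_loops] == [f"L{k}" for k in range(7, 14)]
        l7 = vd.by_label()["L7"]
        ref_l7 = reference.by_label()["L7"]
        assert l7.closing_pair == (
            ref_l7.closing_pair[0] + pad,
            ref_l7.closing_pair[1] + pad,
        )

    def test_stemloop_table_reports_one_based_coordinates(self, reference):
        df = stemloop_table({"ref": reference})
        l7 = df[df.label == "L7"].iloc[0]
        ref_l7 = reference.by_label()["L7"]
        assert l7.start == ref_l7.closing_pair[0] + 1
        assert l7.end == ref_l7.closing_pair[1] + 1
        assert l7.total_nt == 19
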