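"""SNP and INDEL covariates against naive oracle recomputation."""

import random

import numpy as np
import pytest

from exocall.alignment import GAP, ReadObservation, SiteStack, build_site_stack
from exocall.features.indel import (
    IndelCandidate,
    IndelSupport,
    extract_indel_candidates,
    indel_feature_vector,
    left_normalize,
    nvs,
    read_end_ratio,
)
from exocall.features.snp import mean_nbq, snp_feature_vector, strand_direction_standard
from tests.conftest import make_read


def stack_from_reads(reads, chrom, pos, reference):
    return build_site_stack(reads, chrom, pos, reference)


def make_stack(obs, ref_base="A"):
    return SiteStack("ref1", 10, ref_base, observations=list(obs))


def obs(base, qual=30, dist3=10, strand="+", vrate=0.0, near=False,
        rid="r", wsum=None, wn=None):
    return ReadObservation(
        base=base,
        base_quality=qual if base != GAP else None,
        dist3=dist3,
        strand=strand,
        variation_rate=vrate,
        near_read_end=near,
        source_read_id=rid,
        window_qual_sum=wsum if wsum is not None else float(qual) * 11,
        window_qual_n=wn if wn is not None else 11,
    )


class TestMeanNbq:
    def test_uniform_qualities(self):
        ref = {"ref1": "A" * 30}
        read = make_read(pos=0, sequence="C" + "A" * 19, quals=[30] * 20)
        stack = build_site_stack([read], "ref1", 0, ref)
        assert mean_nbq(stack, "C") == 30.0

    def test_truncated_window_at_read_start(self):
        """Variant at read position 0: window is base + 5 on the right only."""
        ref = {"ref1": "A" * 30}
        quals = [10, 20, 20, 20, 20, 20] + [40] * 14
        read = make_read(pos=0, sequence="C" + "A" * 19, quals=quals)
        stack = build_site_stack([read], "ref1", 0, ref)
        assert mean_nbq(stack, "C") == pytest.approx(110 / 6)

    def test_no_variant_reads_fails(self):
        stack = make_stack([obs("A")])
        with pytest.raises(ValueError):
            mean_nbq(stack, "G")

    def test_matches_naive_window_oracle(self, rng):
        ref = {"ref1": "".join(rng.choice(list("ACGT"), size=60))}
        for _ in range(40):
            pos = int(rng.integers(0, 40))
            reads = []
            for i in range(int(rng.integers(1, 6))):
                start = int(rng.integers(max(0, pos - 14), pos + 1))
                rl = int(rng.integers(pos - start + 1, 16))
                seq = list(ref["ref1"][start : start + rl])
                seq[pos - start] = "T" if ref["ref1"][pos] != "T" else "G"
                reads.append(
                    make_read(
                        pos=start, sequence="".join(seq),
                        quals=list(rng.integers(2, 41, size=rl)),
                        read_id=f"r{i}",
                    )
                )
            stack = build_site_stack(reads, "ref1", pos, ref)
            alt = "T" if ref["ref1"][pos] != "T" else "G"
            # oracle: pool qualities of variant base +-5 within each read
            pooled = []
            for r in reads:
                qi = pos - r.pos
                lo, hi = max(0, qi - 5), min(len(r.sequence), qi + 6)
                pooled.extend(r.base_qualities[lo:hi])
            assert mean_nbq(stack, alt) == pytest.approx(
                sum(pooled) / len(pooled), abs=1e-9
            )


class TestStrandStandard:
    def test_single_strand_is_zero(self):
        stack = make_stack([obs("G", strand="+")] * 3 + [obs("A")])
        assert strand_direction_standard(stack, "G") == 0

    def test_both_strands_is_one(self):
        stack = make_stack([obs("G", strand="+"), obs("G", strand="-")])
        assert strand_direction_standard(stack, "G") == 1


class TestSnpFeatureVector:
    def test_ratio_ten_ref_two_alt(self):
        stack = make_stack([obs("A")] * 10 + [obs("G"), obs("G", strand="-")])
        feats = snp_feature_vector(stack, "G")
        assert feats.ref_var_ratio == 5.0
        assert feats.var_depth == 2
        assert feats.ref_depth == 10

    def test_zero_ref_reads_ratio_zero(self):
        stack = make_stack([obs("G")] * 4)
        assert snp_feature_vector(stack, "G").ref_var_ratio == 0.0

    def test_no_variant_reads_fails(self):
        stack = make_stack([obs("A")] * 4)
        with pytest.raises(ValueError):
            snp_feature_vector(stack, "G")

    def test_fields_match_naive_recomputation(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 25))
            observations = [
                obs(
                    base=str(rng.choice(["A", "G", "C"])),
                    qual=int(rng.integers(2, 41)),
                    dist3=int(rng.integers(0, 50)),
                    strand=str(rng.choice(["+", "-"])),
                    wsum=float(rng.integers(20, 400)),
                    wn=int(rng.integers(1, 12)),
                )
                for _ in range(n)
            ]
            stack = make_stack(observations, ref_base="A")
            alts = {o.base for o in observations} - {"A"}
            for alt in alts:
                v = [o for o in observations if o.base == alt]
                feats = snp_feature_vector(stack, alt)
                assert feats.var_depth == len(v)
                assert feats.ref_depth == sum(
                    1 for o in observations if o.base == "A"
                )
                assert feats.ref_var_ratio == pytest.approx(
                    feats.ref_depth / len(v)
                )
                assert feats.mean_dist3 == pytest.approx(
                    np.mean([o.dist3 for o in v]), abs=1e-9
                )
                assert feats.mean_var_qual == pytest.approx(
                    np.mean([o.base_quality for o in v]), abs=1e-9
                )
                assert feats.mean_nbq == pytest.approx(
                    sum(o.window_qual_sum for o in v)
                    / sum(o.window_qual_n for o in v),
                    abs=1e-9,
                )
                both = {o.strand for o in v} == {"+", "-"}
                assert feats.strand_both == int(both)
                assert feats.nbq_x_dist3 == feats.mean_nbq * feats.mean_dist3
                assert feats.strand_x_dist3 == feats.strand_both * feats.mean_dist3

    def test_permutation_invariance(self, rng):
        observations = [
            obs(str(rng.choice(["A", "G"])), qual=int(rng.integers(2, 41)),
                dist3=int(rng.integers(0, 50)), strand=str(rng.choice(["+", "-"])))
            for _ in range(12)
        ]
        if not any(o.base == "G" for o in observations):
            observations.append(obs("G"))
        base = snp_feature_vector(make_stack(observations), "G")
        shuffled = observations[:]
        random.Random(0).shuffle(shuffled)
        assert snp_feature_vector(make_stack(shuffled), "G") == base

    def test_adding_ref_read_only_increases_ratio(self):
        observations = [obs("G"), obs("G", strand="-"), obs("A")]
        before = snp_feature_vector(make_stack(observations), "G")
        after = snp_feature_vector(make_stack(observations + [obs("A")]), "G")
        assert after.ref_var_ratio > before.ref_var_ratio
        for f in ("mean_dist3", "mean_nbq", "mean_var_qual", "strand_both",
                  "nbq_x_dist3", "strand_x_dist3", "var_depth"):
            assert getattr(after, f) == getattr(before, f)


HOMOPOLYMER_REF = {"ref1": "ACGTTTTTACGTACGTACGT"}


class TestIndelCandidates:
    def test_all_match_cigar_yields_nothing(self):
        ref = {"ref1": "ACGTACGTACGTACGT"}
        read = make_read(pos=0, sequence=ref["ref1"][:12])
        assert extract_indel_candidates(read, ref) == []

    def test_deletion_from_cigar(self):
        ref = {"ref1": "AACGGTCATGCATTAC"}
        # 4M2D8M: deletes ref[4:6] == "GT", anchored at ref[3] == "G"
        seq = ref["ref1"][:4] + ref["ref1"][6:14]
        read = make_read(pos=0, sequence=seq, cigar=[("M", 4), ("D", 2), ("M", 8)])
        (cand, support), = extract_indel_candidates(read, ref)
        assert cand.kind == "DEL" and cand.length == 2
        assert (cand.pos, cand.ref_allele, cand.alt_allele) == (3, "GGT", "G")

    def test_homopolymer_placements_normalize_identically(self):
        """Every aligner placement of a 1 bp T-deletion in TTTTT is one form."""
        ref = HOMOPOLYMER_REF
        forms = set()
        for gap_at in range(4, 8):  # delete any single T of ref[4:8]
            m1 = gap_at
            seq = ref["ref1"][:gap_at] + ref["ref1"][gap_at + 1 : 13]
            read = make_read(
                pos=0, sequence=seq, cigar=[("M", m1), ("D", 1), ("M", 12 - m1)]
            )
            (cand, _), = extract_indel_candidates(read, ref)
            forms.add((cand.pos, cand.ref_allele, cand.alt_allele))
        assert len(forms) == 1
        pos, ref_allele, alt_allele = forms.pop()
        # homopolymer run is ref[3:8]; canonical anchor is the G before it
        assert pos == 2 and ref_allele == "GT" and alt_allele == "G"

    def test_normalization_idempotent(self):
        ref = HOMOPOLYMER_REF
        c1 = left_normalize("ref1", 6, "TT", "T", ref)
        c2 = left_normalize("ref1", c1.pos, c1.ref_allele, c1.alt_allele, ref)
        assert c1 == c2

    def test_insertion_extraction(self):
        ref = {"ref1": "AACGGTCATGCATTAC"}
        seq = ref["ref1"][:5] + "CC" + ref["ref1"][5:11]
        read = make_read(pos=0, sequence=seq, cigar=[("M", 5), ("I", 2), ("M", 6)])
        (cand, _), = extract_indel_candidates(read, ref)
        assert cand.kind == "INS" and cand.length == 2
        assert cand.pos == 4
        assert cand.alt_allele == ref["ref1"][4] + "CC"


class TestIndelFeatures:
    def test_nvs_examples(self):
        assert nvs(3, 10) == pytest.approx(0.9)
        for d in (1, 7, 30):
            assert nvs(d, d) == pytest.approx(d)
        with pytest.raises(ValueError):
            nvs(1, 0)
        with pytest.raises(ValueError):
            nvs(5, 3)

    def test_nvs_scales_with_depth_at_fixed_ratio(self, rng):
        for _ in range(30):
            total = int(rng.integers(1, 200))
            var = int(rng.integers(0, total + 1))
            assert nvs(var, total) == pytest.approx(var * var / total)
            assert nvs(2 * var, 2 * total) == pytest.approx(2 * nvs(var, total))

    def test_read_end_ratio(self):
        mk = lambda near: IndelSupport("r", "+", 0.0, near, 100.0, 10)
        assert read_end_ratio([mk(False)] * 3) == 0.0
        assert read_end_ratio([mk(True), mk(True), mk(False), mk(False)]) == 0.5
        with pytest.raises(ValueError):
            read_end_ratio([])

    def test_feature_vector_examples(self):
        sup = [
            IndelSupport("a", "+", 0.02, False, 25.0 * 10, 10),
            IndelSupport("b", "-", 0.04, True, 25.0 * 8, 8),
        ]
        feats = indel_feature_vector(sup, total_depth=20)
        assert feats.nvs == pytest.approx(4 / 20)
        assert feats.mean_nbq == pytest.approx(25.0)
        assert feats.mean_variation_rate == pytest.approx(0.03)
        assert feats.read_end_ratio == 0.5
        assert feats.var_depth == 2 and feats.total_depth == 20

    def test_same_event_same_key_across_reads(self):
        ref = HOMOPOLYMER_REF
        reads = []
        for start, gap_at in ((0, 5), (2, 6), (1, 7)):
            m1 = gap_at - start
            seq = ref["ref1"][start:gap_at] + ref["ref1"][gap_at + 1 : start + 13]
            reads.append(
                make_read(pos=start, sequence=seq,
                          cigar=[("M", m1), ("D", 1), ("M", 12 - m1)])
            )
        keys = set()
        for read in reads:
            (cand, _), = extract_indel_candidates(read, ref)
            keys.add((cand.chrom, cand.pos, cand.ref_allele, cand.alt_allele))
        assert len(keys) == 1

    def test_invalid_candidate_rejected(self):
        with pytest.raises(ValueError):
            IndelCandidate("ref1", 3, "AT", "AG")
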