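"""Adapter trimming and isomiR-tolerant alignment, checked against an
exhaustive end-variant enumeration oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evmir.quant import AlignmentPolicy, align_read, quantify, trim_adapter
from evmir.synthetic import IsomirProfile, generate_reads, generate_reference


def oracle_align(read, reference, policy):
    """Independent exhaustive search over all end-variant tuples.

    Enumerates every (add5, add3, miss5, miss3) within bounds for every
    reference, keeps candidates whose core lengths agree and whose core
    Hamming distance is within budget, and applies the documented
    preference order.  Returns (feature, mismatches, tuple) or a status.
    """
    read = read.upper().replace("U", "T")
    if len(read) < policy.min_trimmed_length:
        return "too_short"
    per_ref = {}
    for name, mature in reference.items():
        mature = mature.upper().replace("U", "T")
        best = None
        for add5, add3, miss5, miss3 in itertools.product(
            range(policy.max_additional_upstream + 1),
            range(policy.max_additional_downstream + 1),
            range(policy.max_missing_upstream + 1),
            range(policy.max_missing_downstream + 1),
        ):
            core = read[add5: len(read) - add3] if add3 else read[add5:]
            ref_core = mature[miss5: len(mature) - miss3] if miss3 else mature[miss5:]
            if len(core) != len(ref_core) or not core:
                continue
            mm = sum(a != b for a, b in zip(core, ref_core))
            if mm > policy.max_mismatches:
                continue
            key = (mm, add5 + add3 + miss5 + miss3, add5)
            if best is None or key < best[0]:
                best = (key, (add5, add3, miss5, miss3))
        if best is not None:
            per_ref[name] = best
    if not per_ref:
        return "unaligned"
    scores = {name: b[0][:2] for name, b in per_ref.items()}
    top = min(scores.values())
    winners = sorted(n for n, s in scores.items() if s == top)
    if len(winners) > 1 and policy.ambiguous_policy == "discard":
        return "ambiguous"
    name = winners[0]
    return name, per_ref[name][0][0], per_ref[name][1]


class TestTrimAdapter:
    ADAPTER = "TGGAATTCTCGG"

    def test_read_without_adapter_unchanged(self):
        assert trim_adapter("ACGTACGTACGTACGT", self.ADAPTER) == "ACGTACGTACGTACGT"

    def test_leftmost_full_match(self):
        insert = "ACGTACGTACGTACGTAC"
        read = insert + self.ADAPTER
        # brute-force confirmation of the leftmost full occurrence
        positions = [
            i for i in range(len(read) - len(self.ADAPTER) + 1)
            if read[i: i + len(self.ADAPTER)] == self.ADAPTER
        ]
        assert trim_adapter(read, self.ADAPTER) == read[: positions[0]] == insert

    def test_adapter_only_read_trims_to_empty(self):
        assert trim_adapter(self.ADAPTER, self.ADAPTER) == ""

    def test_partial_suffix_overlap(self):
        insert = "ACGTACGTACGTACGTAC"
        assert trim_adapter(insert + self.ADAPTER[:9], self.ADAPTER) == insert
        # below min_overlap the partial suffix is kept
        assert trim_adapter(insert + self.ADAPTER[:5], self.ADAPTER) \
            == insert + self.ADAPTER[:5]

    def test_mismatch_tolerance(self):
        insert = "ACGTACGTACGTACGTAC"
        mutated = "A" + self.ADAPTER[1:]
        assert trim_adapter(insert + mutated, self.ADAPTER) == insert

    def test_empty_read(self):
        assert trim_adapter("", self.ADAPTER) == ""


@pytest.fixture(scope="module")
def reference():
    return generate_reference(10, seed=31)


class TestAlignRead:
    POLICY = AlignmentPolicy()

    def test_identity(self, reference):
        name, seq = next(iter(reference.items()))
        a = align_read("r", seq, reference, self.POLICY)
        assert (a.status, a.feature, a.n_mismatches, a.end_variant) == (
            "assigned", name, 0, (0, 0, 0, 0))

    def test_three_substitutions_unaligned(self):
        mature = "UGGAGUGUGACAAUGGUGUUUG"
        read = list(mature)
        for pos in (5, 10, 15):  # internal, nowhere near the 2-base end slack
            read[pos] = {"A": "C", "C": "A", "G": "U", "U": "G"}[read[pos]]
        a = align_read("r", "".join(read), {"m": mature}, self.POLICY)
        assert a.status == "unaligned"

    def test_end_variant_with_substitution(self):
        mature = "TGGAGTGTGACAATGGTGTTTG"
        read = mature[2:] + "A"  # missing 2 upstream bases, 1 extra 3' base
        read = read[:5] + ("C" if read[5] != "C" else "G") + read[6:]
        a = align_read("r", read, {"m": mature}, self.POLICY)
        assert a.status == "assigned"
        assert a.end_variant == (0, 1, 2, 0)
        assert a.n_mismatches == 1
        assert oracle_align(read, {"m": mature}, self.POLICY) == ("m", 1, (0, 1, 2, 0))

    def test_too_short(self, reference):
        assert align_read("r", "ACGTACG", reference, self.POLICY).status == "too_short"

    def test_ambiguous_between_identical_references(self):
        seq = "TGGAGTGTGACAATGGTGTTTG"
        ref = {"b-mir": seq, "a-mir": seq}
        assert align_read("r", seq, ref, self.POLICY).status == "ambiguous"
        first = align_read(
            "r", seq, ref,
            AlignmentPolicy(ambiguous_policy="first_by_name"),
        )
        assert (first.status, first.feature) == ("assigned", "a-mir")

    def test_alphabet_invariance(self, reference):
        name, seq = list(reference.items())[3]
        read_rna = seq[1:] + "A"
        read_dna = read_rna.replace("U", "T")
        a = align_read("r", read_rna, reference, self.POLICY)
        b = align_read("r", read_dna, reference, self.POLICY)
        assert (a.feature, a.n_mismatches, a.end_variant, a.status) == (
            b.feature, b.n_mismatches, b.end_variant, b.status)

    def test_monotonicity_tightening_never_assigns(self, reference):
        rng = np.random.default_rng(17)
        seqs = list(reference.values())
        loose = AlignmentPolicy()
        tight = AlignmentPolicy(max_mismatches=1, max_additional_upstream=1,
                                max_additional_downstream=1,
                                max_missing_upstream=1, max_missing_downstream=1)
        for _ in range(200):
            base = seqs[int(rng.integers(len(seqs)))].replace("U", "T")
            read = "".join(
                b if rng.random() > 0.15 else "ACGT"[int(rng.integers(4))]
                for b in base
            )
            got_loose = align_read("r", read, reference, loose).status
            got_tight = align_read("r", read, reference, tight).status
            if got_tight == "assigned":
                assert got_loose in ("assigned", "ambiguous")

    def test_matches_exhaustive_oracle_on_random_reads(self, reference, rng):
        bases = "ACGT"
        mismatch = 0
        for i in range(400):
            if i % 2:
                read = "".join(rng.choice(list(bases), size=int(rng.integers(15, 31))))
            else:  # reads derived from a reference, more likely to align
                src = list(reference.values())[int(rng.integers(len(reference)))]
                src = src.replace("U", "T")
                read = "".join(
                    b if rng.random() > 0.1 else bases[int(rng.integers(4))]
                    for b in src
                )
            got = align_read("r", read, reference, self.POLICY)
            want = oracle_align(read, reference, self.POLICY)
            if isinstance(want, str):
                assert got.status == want, read
            else:
                assert got.status == "assigned"
                assert (got.feature, got.n_mismatches, got.end_variant) == want, read

    @given(st.text(alphabet="ACGT", min_size=15, max_size=30))
    def test_oracle_equivalence_property(self, read):
        reference = generate_reference(5, seed=47)
        got = align_read("r", read, reference, self.POLICY)
        want = oracle_align(read, reference, self.POLICY)
        if isinstance(want, str):
            assert got.status == want
        else:
            assert (got.feature, got.n_mismatches, got.end_variant) == want


class TestQuantify:
    def test_zero_edit_roundtrip_matches_ground_truth(self):
        reference = generate_reference(15, seed=51)
        profile = IsomirProfile(end_edit_prob=0.0, sub_prob=0.0)
        adapter = "TGGAATTCTCGGGTGCCAAGG"
        reads, truth = generate_reads(
            reference, dict.fromkeys(reference, 1.0), profile, 300,
            adapter=adapter, seed=52,
        )
        counts, summary = quantify({"s1": reads}, reference, adapter=adapter)
        expected = {}
        for rt in truth.reads:
            expected[rt.source] = expected.get(rt.source, 0) + 1
        for name in reference:
            assert counts.at[name, "s1"] == expected.get(name, 0)
        assert summary.at["s1", "assigned"] == 300
        assert counts["s1"].sum() == summary.at["s1", "assigned"]

    def test_isomir_reads_recover_true_source(self):
        reference = generate_reference(20, seed=53)
        reads, truth = generate_reads(
            reference, dict.fromkeys(reference, 1.0), IsomirProfile(), 500,
            adapter="TGGAATTCTCGGGTGCCAAGG", seed=54,
        )
        trimmed = {rt.read_id: rt for rt in truth.reads}
        policy = AlignmentPolicy()
        hits = 0
        for rid, seq in reads:
            insert = seq[: len(seq) - len("TGGAATTCTCGGGTGCCAAGG")]
            a = align_read(rid, insert, reference, policy)
            if a.status == "assigned" and a.feature == trimmed[rid].source:
                hits += 1
        # random 18-25mers are far apart, so within-bounds edits stay assignable
        assert hits / len(reads) > 0.99

    def test_ambiguous_reads_count_nowhere_under_discard(self):
        seq = "TGGAGTGTGACAATGGTGTTTG"
        reference = {"mirA": seq, "mirB": seq}
        counts, summary = quantify({"s": [("r1", seq)]}, reference)
        assert counts.to_numpy().sum() == 0
        assert summary.at["s", "ambiguous"] == 1

    def test_empty_sample_logged_and_kept(self, caplog):
        reference = generate_reference(3, seed=55)
        with caplog.at_level("WARNING"):
            counts, summary = quantify({"s": []}, reference)
        assert (counts["s"] == 0).all()
        assert "zero assigned" in caplog.text
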