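"""Per-trial dependent measures: grouping, ratio, response time."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from activegaze.errors import InvalidInputError
from activegaze.metrics import (
    fixation_ratio,
    grouping_profile,
    normalized_response_time,
    response_time,
)

O1, O2, ENV = "object1", "object2", "environment"


def _oracle_runs(labels, split):
    """Brute-force run-length oracle, written independently of the
    implementation: filter (or split on) environment, then count runs."""
    seqs = []
    if split:
        cur = []
        for lab in labels:
            if lab == ENV:
                if cur:
                    seqs.append(cur)
                cur = []
            else:
                cur.append(lab)
        if cur:
            seqs.append(cur)
    else:
        seqs = [[lab for lab in labels if lab != ENV]]
    runs = []
    for seq in seqs:
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            runs.append(j - i)
            i = j
    return runs


class TestGroupingProfile:
    def test_alternating_labels_are_all_singles(self):
        prof = grouping_profile([O1, O2, O1, O2])
        assert prof.total_runs == 4
        assert prof.shares[0] == pytest.approx(100.0)

    def test_environment_removed_without_splitting(self):
        prof = grouping_profile([O1, O1, ENV, O2, O2, O2])
        assert prof.counts[1] == 1  # couple
        assert prof.counts[2] == 1  # triple
        assert prof.total_runs == 2

    def test_environment_glance_does_not_split_a_run(self):
        # o1 run interrupted by env and continued: one quadruple by default
        prof = grouping_profile([O1, O1, ENV, O1, O1])
        assert prof.counts[3] == 1
        split = grouping_profile([O1, O1, ENV, O1, O1], split_on_environment=True)
        assert split.counts[1] == 2  # two couples in split mode

    def test_higher_bin_boundary(self):
        prof = grouping_profile([O1] * 12 + [O2])
        assert prof.counts[8] == 1  # ">8"
        assert prof.counts[0] == 1  # single
        exactly8 = grouping_profile([O1] * 8 + [O2])
        assert exactly8.counts[7] == 1

    def test_empty_sequence_gives_zero_profile(self):
        prof = grouping_profile([])
        assert prof.total_runs == 0
        assert np.all(prof.shares == 0)

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        """10,000 random sequences of length <= 12, exact bin agreement."""
        labels = np.array([O1, O2, ENV])
        for _ in range(10_000):
            seq = list(labels[rng.integers(0, 3, rng.integers(0, 13))])
            for split in (False, True):
                prof = grouping_profile(seq, split_on_environment=split)
                runs = _oracle_runs(seq, split)
                expected = np.zeros(9, dtype=int)
                for r in runs:
                    expected[min(r, 9) - 1] += 1
                assert np.array_equal(prof.counts, expected)
                assert prof.n_fixations == sum(runs)

    def test_shares_sum_to_100_and_fixation_total_tracked(self, rng):
        seq = list(np.array([O1, O2, ENV])[rng.integers(0, 3, 40)])
        prof = grouping_profile(seq)
        if prof.total_runs:
            assert prof.shares.sum() == pytest.approx(100.0, abs=1e-9)
        assert prof.n_fixations == sum(1 for s in seq if s != ENV)


class TestFixationRatio:
    def test_three_to_one(self):
        assert fixation_ratio([O1, O1, O1, O2]) == (75.0, 25.0, O1)

    def test_tie_breaks_to_first_fixated(self):
        assert fixation_ratio([O1, O2]) == (50.0, 50.0, O1)
        assert fixation_ratio([O2, O1]) == (50.0, 50.0, O2)

    def test_primary_share_at_least_half_exhaustively(self):
        """All label sequences up to length 6: primary share >= 50 and the
        shares always sum to 100."""
        import itertools

        for n in range(1, 7):
            for seq in itertools.product([O1, O2, ENV], repeat=n):
                if all(s == ENV for s in seq):
                    continue
                p, s, _ = fixation_ratio(list(seq))
                assert p >= 50.0
                assert p + s == pytest.approx(100.0)

    def test_relabel_swap_preserves_shares(self):
        seq = [O1, O1, O2, O1, O2]
        swapped = [O2 if s == O1 else O1 if s == O2 else s for s in seq]
        p1, s1, id1 = fixation_ratio(seq)
        p2, s2, id2 = fixation_ratio(swapped)
        assert (p1, s1) == (p2, s2)
        assert id1 != id2

    def test_no_object_fixations_rejected(self):
        with pytest.raises(InvalidInputError):
            fixation_ratio([ENV, ENV])


class TestResponseTime:
    def test_difference(self):
        assert response_time(1.0, 5.2) == pytest.approx(4.2)

    def test_answer_before_first_fixation_rejected(self):
        with pytest.raises(InvalidInputError):
            response_time(5.0, 4.0)


class TestNormalizedResponseTime:
    @pytest.mark.parametrize(
        "mean_rt,n,expected",
        [(40.03, 7, 5.72), (42.01, 10, 4.20), (60.53, 18, 3.36)],
    )
    def test_per_element_normalization(self, mean_rt, n, expected):
        assert normalized_response_time(mean_rt, n) == expected

    def test_zero_blocks_rejected(self):
        with pytest.raises(InvalidInputError):
            normalized_response_time(10.0, 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([O1, O2, ENV]), max_size=30))
def test_grouping_total_runs_bounded_by_object_fixations(seq):
    prof = grouping_profile(seq)
    n_obj = sum(1 for s in seq if s != ENV)
    assert prof.total_runs <= n_obj
    # equality iff every run is a single
    if prof.total_runs == n_obj and n_obj:
        assert prof.counts[0] == prof.total_runs
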