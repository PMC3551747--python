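import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from osedax16s.core_io import SequenceRecord
from osedax16s.synthetic_data import generate_trace
from osedax16s.trace_calling import (
    CloneLibrary,
    ConsensusCall,
    TraceColumn,
    UncallableColumnError,
    call_base,
    call_consensus,
    decompose_single_ambiguity,
    detection_probability,
    detection_threshold,
    filter_clone_singletons,
    flag_singletons,
    resolve_phases,
    simulate_dilution_series,
)


def _col(**heights):
    return TraceColumn(heights=heights)


class TestCallBase:
    @pytest.mark.parametrize(
        "heights,expected",
        [
            (dict(A=100.0), "A"),
            (dict(C=100.0, T=50.0), "Y"),  # exactly half: inclusive rule
            (dict(C=100.0, T=49.0), "C"),
            (dict(A=80.0, G=40.0, T=10.0), "R"),  # tertiary peak ignored
            (dict(A=50.0, T=50.0), "W"),
            (dict(G=10.0, T=4.9), "G"),
        ],
    )
    def test_half_height_rule(self, heights, expected):
        assert call_base(_col(**heights)) == expected

    def test_all_zero_column_uncallable(self):
        with pytest.raises(UncallableColumnError):
            call_base(_col(A=0.0, C=0.0))

    def test_custom_threshold(self):
        assert call_base(_col(C=100.0, T=30.0), ratio_threshold=0.25) == "Y"

    @given(
        st.lists(st.floats(0.0, 1000.0), min_size=4, max_size=4),
        st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, heights, scale):
        if max(heights) < 1e-3:  # degenerate: signal underflows when rescaled
            return
        col = _col(**dict(zip("ACGT", heights)))
        scaled = _col(**{b: h * scale for b, h in zip("ACGT", heights)})
        assert call_base(col) == call_base(scaled)


class TestCallConsensus:
    def test_pure_strain_recovered(self):
        strain = SequenceRecord(id="s", seq="ACGTACGT")
        trace = generate_trace({strain: 1.0}, efficiency_sd=0.0, seed=0)
        call = call_consensus(trace)
        assert call.seq.seq == strain.seq
        assert not call.mixed

    def test_even_mixture_flags_the_differing_site(self):
        a = SequenceRecord(id="a", seq="ACGTACGT")
        b = SequenceRecord(id="b", seq="ACGTACGA")
        trace = generate_trace({a: 0.5, b: 0.5}, efficiency_sd=0.0, seed=0)
        call = call_consensus(trace)
        assert call.mixed
        assert call.ambiguous_positions == (8,)
        assert call.seq.seq[7] == "W"

    def test_minority_below_threshold_dropped(self):
        a = SequenceRecord(id="a", seq="ACGTACGT")
        b = SequenceRecord(id="b", seq="ACGTACGA")
        trace = generate_trace({a: 0.8, b: 0.2}, efficiency_sd=0.0, seed=0)
        call = call_consensus(trace)
        assert not call.mixed
        assert call.seq.seq == a.seq

    def test_uncallable_column_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            call_consensus([_col(A=1.0), _col(A=0.0)])

    def test_remix_of_decomposed_pair_is_identity(self):
        call = ConsensusCall(
            seq=SequenceRecord(id="w", seq="ACYTACGT"), ambiguous_positions=(3,)
        )
        first, second = decompose_single_ambiguity(call)
        trace = generate_trace({first: 0.5, second: 0.5}, efficiency_sd=0.0, seed=0)
        recalled = call_consensus(trace)
        assert recalled.seq.seq == call.seq.seq
        assert recalled.ambiguous_positions == call.ambiguous_positions


class TestDecompose:
    def test_forced_phasing(self):
        call = ConsensusCall(
            seq=SequenceRecord(id="x", seq="ACYT"), ambiguous_positions=(3,)
        )
        first, second = decompose_single_ambiguity(call)
        assert {first.seq, second.seq} == {"ACCT", "ACTT"}

    def test_no_ambiguity_errors(self):
        call = ConsensusCall(
            seq=SequenceRecord(id="x", seq="ACGT"), ambiguous_positions=()
        )
        with pytest.raises(ValueError, match="clone"):
            decompose_single_ambiguity(call)

    def test_two_ambiguities_error_directs_to_clones(self):
        call = ConsensusCall(
            seq=SequenceRecord(id="x", seq="RCYT"), ambiguous_positions=(1, 3)
        )
        with pytest.raises(ValueError, match="clone"):
            decompose_single_ambiguity(call)


class TestCloneLibrary:
    def test_singleton_filter(self):
        lib = CloneLibrary(counts={"ACCT": 5, "ACGT": 1, "ACTT": 2})
        assert filter_clone_singletons(lib).counts == {"ACCT": 5, "ACTT": 2}

    def test_empty_and_all_singletons(self):
        assert filter_clone_singletons(CloneLibrary(counts={})).counts == {}
        lib = CloneLibrary(counts={"ACCT": 1, "ACTT": 1})
        assert filter_clone_singletons(lib).n_clones == 0

    def test_flag_singletons(self):
        assert flag_singletons({"rt1": 3, "rt2": 1}) == {"rt2"}
        assert flag_singletons({"rt1": 3, "rt2": 2}) == set()

    def test_singleton_fraction_matches_observed_survey_scale(self):
        # 29 ribotypes of which 15 observed once: about half are singletons
        counts = {f"rt{i}": 1 for i in range(15)}
        counts.update({f"rt{i}": 2 + i % 3 for i in range(15, 29)})
        flagged = flag_singletons(counts)
        assert len(flagged) == 15
        assert len(flagged) / len(counts) == pytest.approx(0.517, abs=0.01)


class TestResolvePhases:
    def _two_site_call(self):
        # R at position 2 and Y at position 6 of an 8-mer
        return ConsensusCall(
            seq=SequenceRecord(id="w", seq="ARGTAYGT"), ambiguous_positions=(2, 6)
        )

    def test_two_phases_resolved(self):
        call = self._two_site_call()
        lib = CloneLibrary(counts={"AAGTATGT": 8, "AGGTACGT": 7})
        result = resolve_phases(call, lib)
        assert {r.seq for r in result.ribotypes} == {"AAGTATGT", "AGGTACGT"}
        assert result.unresolved_positions == ()

    def test_consensus_without_ambiguities_is_returned(self):
        call = ConsensusCall(
            seq=SequenceRecord(id="w", seq="ACGT"), ambiguous_positions=()
        )
        result = resolve_phases(call, CloneLibrary(counts={"TTTT": 9}))
        assert result.ribotypes == (call.seq,)

    def test_uncovered_position_masked(self):
        call = self._two_site_call()
        # both retained clones agree at the Y position: phase unresolved there
        lib = CloneLibrary(counts={"AAGTACGT": 8, "AGGTACGT": 7})
        result = resolve_phases(call, lib)
        assert result.unresolved_positions == (6,)
        assert all(r.seq[5] == "N" for r in result.ribotypes)

    def test_inconsistent_clone_flagged(self):
        call = self._two_site_call()
        lib = CloneLibrary(counts={"AAGTATGT": 8, "ATGTACGT": 5})  # T not in R
        result = resolve_phases(call, lib)
        assert result.inconsistent_clones == ("ATGTACGT",)
        # a single surviving clone leaves both positions unresolved and masked
        assert result.unresolved_positions == (2, 6)
        assert {r.seq for r in result.ribotypes} == {"ANGTANGT"}

    def test_empty_library_leaves_all_unresolved(self):
        call = self._two_site_call()
        result = resolve_phases(call, CloneLibrary(counts={}))
        assert result.ribotypes == ()
        assert result.unresolved_positions == (2, 6)

    def test_optional_complement_inference(self):
        call = self._two_site_call()
        lib = CloneLibrary(counts={"AAGTATGT": 8})
        default = resolve_phases(call, lib)
        assert default.unresolved_positions == (2, 6)
        inferred = resolve_phases(call, lib, infer_complement=True)
        assert {r.seq for r in inferred.ribotypes} == {"AAGTATGT", "AGGTACGT"}


class TestDilutionSeries:
    def test_noiseless_window_is_the_middle_of_the_grid(self):
        a = SequenceRecord(id="a", seq="ACGTACGT")
        b = SequenceRecord(id="b", seq="ACGTACGA")
        result = simulate_dilution_series(a, b, efficiency_sd=0.0)
        assert result.ambiguous_ratios(8) == (0.4, 0.5, 0.6)

    def test_window_position_independent_without_noise(self):
        a = SequenceRecord(id="a", seq="TTTTTTTTTT")
        b = SequenceRecord(id="b", seq="ATTTTATTTA")
        result = simulate_dilution_series(a, b, efficiency_sd=0.0)
        for pos in result.snp_positions:
            assert result.ambiguous_ratios(pos) == (0.4, 0.5, 0.6)

    def test_pure_endpoints(self):
        a = SequenceRecord(id="a", seq="ACGT")
        b = SequenceRecord(id="b", seq="TCGT")
        result = simulate_dilution_series(a, b, efficiency_sd=0.0)
        assert set(result.calls.loc[0.0][1]) == {"T"}  # pure b
        assert set(result.calls.loc[1.0][1]) == {"A"}  # pure a

    def test_identical_templates_rejected(self):
        a = SequenceRecord(id="a", seq="ACGT")
        with pytest.raises(ValueError, match="polymorphic"):
            simulate_dilution_series(a, SequenceRecord(id="b", seq="ACGT"))

    def test_deterministic_given_seed(self):
        a = SequenceRecord(id="a", seq="ACGTACGT")
        b = SequenceRecord(id="b", seq="TCGTACGA")
        r1 = simulate_dilution_series(a, b, efficiency_sd=0.4, seed=11)
        r2 = simulate_dilution_series(a, b, efficiency_sd=0.4, seed=11)
        assert r1.calls.equals(r2.calls)

    def test_noise_widens_or_shifts_detection_stochastically(self):
        a = SequenceRecord(id="a", seq="ACGTACGT")
        b = SequenceRecord(id="b", seq="ACGTACGA")
        noisy = simulate_dilution_series(
            a, b, replicates=30, efficiency_sd=0.6, seed=3
        )
        calls = noisy.calls[8].unstack(level=1)
        amb30 = (calls.loc[0.3] == "W").mean()
        assert 0.0 < amb30 < 1.0

    def test_empirical_fixture_loads_with_expected_shape(self, dilution_calls):
        result = dilution_calls["AxB"]
        assert len(result.ratios) == 11
        assert result.calls.shape == (33, 1)
        assert result.ambiguous_ratios(666) == (0.3, 0.4, 0.5, 0.6)


class TestDetectionAnalytics:
    @pytest.mark.parametrize(
        "ratio,expected", [(0.5, 1 / 3), (1.0, 0.5), (0.25, 0.2)]
    )
    def test_threshold_closed_form(self, ratio, expected):
        assert detection_threshold(ratio) == pytest.approx(expected)

    def test_threshold_validates_input(self):
        with pytest.raises(ValueError):
            detection_threshold(0.0)

    def test_point_masses(self):
        assert detection_probability(0.4, 1 / 3).probability == 1.0
        assert detection_probability(0.2, 1 / 3).probability == 0.0

    def test_uniform_minority_distribution(self):
        result = detection_probability(stats.uniform(0, 0.5), 1 / 3)
        assert result.probability == pytest.approx(1 / 3)
        assert result.underestimation_factor == pytest.approx(3.0)

    def test_monotone_in_minority_fraction_under_noise(self):
        a = SequenceRecord(id="a", seq="ACGTACGT")
        b = SequenceRecord(id="b", seq="ACGTACGA")
        rates = []
        for fraction in (0.2, 0.3, 0.4):
            result = simulate_dilution_series(
                a, b, ratios=[fraction], replicates=400, efficiency_sd=0.3, seed=5
            )
            calls = result.calls[8]
            rates.append((calls == "W").mean())
        assert rates[0] < rates[1] < rates[2]
        assert 0.0 < rates[1] < 1.0
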