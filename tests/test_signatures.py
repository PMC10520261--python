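import numpy as np
import pytest

from oncosieve.sequence_io import CodingSequence, MutationRecord
from oncosieve.signatures import (
    CHANNELS,
    Signature,
    Spectrum,
    channel_index,
    collapse_channel,
    expected_profile,
    mutation_spectrum,
    obs_exp_track,
    refit_signature,
    site_rates,
)

_COMP = str.maketrans("ACGT", "TGCA")


def mk_mut(context, ref, alt, gene="g", pos=4):
    return MutationRecord(
        sample="s", gene=gene, cds_pos=pos, ref=ref, alt=alt,
        consequence="missense", context=context,
    )


class TestSpectrum:
    def test_single_pyrimidine_event(self):
        spec = mutation_spectrum([mk_mut("ACG", "C", "T")])
        assert spec.counts[channel_index("A[C>T]G")] == 1
        assert spec.total == 1

    def test_purine_event_collapses_by_reverse_complement(self):
        spec = mutation_spectrum([mk_mut("CGT", "G", "A")])
        assert spec.counts[channel_index("A[C>T]G")] == 1

    def test_strand_collapse_invariance(self, rng):
        """The spectrum of a mutation set equals that of the same events
        expressed on the opposite strand."""
        bases = "ACGT"
        muts_fwd, muts_rev = [], []
        for _ in range(500):
            ref = bases[rng.integers(4)]
            alt = bases[(bases.index(ref) + rng.integers(1, 4)) % 4]
            l, r = bases[rng.integers(4)], bases[rng.integers(4)]
            ctx = l + ref + r
            muts_fwd.append(mk_mut(ctx, ref, alt))
            rc_ctx = ctx.translate(_COMP)[::-1]
            muts_rev.append(mk_mut(rc_ctx, ref.translate(_COMP), alt.translate(_COMP)))
        np.testing.assert_allclose(
            mutation_spectrum(muts_fwd).counts, mutation_spectrum(muts_rev).counts
        )

    def test_mass_conservation_with_n_flanks(self):
        spec = mutation_spectrum(
            [mk_mut("NCG", "C", "T"), mk_mut("ACN", "C", "T"), mk_mut("ACG", "C", "T")]
        )
        assert spec.total == pytest.approx(3.0)
        assert spec.n_skipped == 0
        # each N flank spreads 1/4 over four channels; both N records put
        # 0.25 on A[C>T]G, on top of the fully resolved event
        assert spec.counts[channel_index("A[C>T]G")] == pytest.approx(1.5)

    def test_unresolvable_record_skipped_and_tallied(self):
        spec = mutation_spectrum([mk_mut("ANG", "N", "T"), mk_mut("ACG", "C", "T")])
        assert spec.n_skipped == 1
        assert spec.total == pytest.approx(1.0)


class TestRefit:
    def test_pseudocount_smoothing_formula(self):
        counts = np.zeros(96)
        counts[7] = 20
        sig, weights = refit_signature(Spectrum(counts))
        assert weights is None
        assert sig.probs[7] == pytest.approx(20.5 / 68)
        assert sig.probs[0] == pytest.approx(0.5 / 68)

    def test_identity_reference_reproduces_empirical(self, rng):
        counts = rng.integers(0, 50, size=96).astype(float)
        counts[0] += 1  # ensure non-zero
        sig, weights = refit_signature(Spectrum(counts), reference=np.eye(96))
        np.testing.assert_allclose(sig.probs, counts / counts.sum(), atol=1e-9)
        np.testing.assert_allclose(weights, counts / counts.sum(), atol=1e-9)

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            refit_signature(Spectrum(np.zeros(96)))


class TestSiteRates:
    def test_uniform_signature_gives_flat_rates(self, uniform_sig):
        cds = CodingSequence("g", "ATGTGCCTGTAA", flank5="C", flank3="G")
        rates = site_rates(cds, uniform_sig)
        nonref = rates.cons >= 0
        np.testing.assert_allclose(rates.rate[nonref], 1 / 96)

    def test_codon_class_enumeration(self, uniform_sig):
        # Met (ATG) has no synonymous neighbour; Leu (CTG) has four.
        cds = CodingSequence("g", "ATGCTG")
        rates = site_rates(cds, uniform_sig)
        atg = rates.cons[0:3]
        ctg = rates.cons[3:6]
        assert (atg == 0).sum() == 0 and (atg == 1).sum() == 9
        assert (ctg == 0).sum() == 4 and (ctg == 1).sum() == 5


class TestExpectedProfile:
    def test_two_codon_missense_split(self, uniform_sig):
        """ATG+CTG under the uniform signature splits 14 missense
        expectations 9:5 between the two residues (exact enumeration)."""
        cds = CodingSequence("g", "ATGCTG")
        profile = expected_profile(site_rates(cds, uniform_sig), "missense", 14)
        np.testing.assert_allclose(profile.per_residue, [9.0, 5.0])

    def test_zero_total_gives_zero_profile(self, uniform_sig):
        cds = CodingSequence("g", "ATGCTG")
        profile = expected_profile(site_rates(cds, uniform_sig), "missense", 0)
        assert (profile.per_residue == 0).all()

    def test_mass_conservation_random_pairs(self, rng):
        from oncosieve.synthetic import SimConfig, gen_cds

        for i in range(5):
            cds = gen_cds(SimConfig(seed=int(rng.integers(2**31)), cds_length_codons=30))
            probs = rng.dirichlet(np.ones(96))
            sig = Signature(probs / probs.sum())
            total = float(rng.integers(1, 500))
            profile = expected_profile(site_rates(cds, sig), "missense", total)
            assert profile.per_residue.sum() == pytest.approx(total, abs=1e-9)


class TestObsExpTrack:
    def test_self_consistent_observed_gives_unit_ratios(self, uniform_sig):
        from oncosieve.synthetic import SimConfig, gen_cds

        cds = gen_cds(SimConfig(seed=5, cds_length_codons=100))
        rates = site_rates(cds, uniform_sig)
        observed = rates.class_rate_by_base("missense") * 1000  # exactly proportional
        track = obs_exp_track(observed, rates, "missense", window_bases=50)
        np.testing.assert_allclose(track.ratio, 1.0, atol=1e-9)

    def test_concentrated_observations_peak_matches_hand_count(self, uniform_sig):
        from oncosieve.synthetic import SimConfig, gen_cds

        cds = gen_cds(SimConfig(seed=6, cds_length_codons=100))
        L = len(cds.seq)
        rates = site_rates(cds, uniform_sig)
        observed = np.zeros(L)
        observed[120:140] = 1  # 20 mutations in a 20-base run
        track = obs_exp_track(observed, rates, "missense", window_bases=50)
        exp_base = rates.class_rate_by_base("missense")
        exp_base = exp_base / exp_base.sum() * observed.sum()
        best = int(np.nanargmax(track.ratio))  # track entries are indexed by window start
        start = best
        # the best window must cover the whole 20-base run
        assert 140 - 50 <= start <= 120
        hand = observed[start : start + 50].sum() / exp_base[start : start + 50].sum()
        assert track.ratio[best] == pytest.approx(hand)

    def test_zero_observed_gives_zero_ratios(self, uniform_sig):
        cds = CodingSequence("g", "ATG" + "CTG" * 30)
        rates = site_rates(cds, uniform_sig)
        track = obs_exp_track(np.zeros(len(cds.seq)), rates, "missense", window_bases=10)
        assert np.nanmax(track.ratio) == 0.0

    def test_oversized_window_is_error(self, uniform_sig):
        cds = CodingSequence("g", "ATGCTG")
        with pytest.raises(ValueError, match="window"):
            obs_exp_track(np.zeros(6), site_rates(cds, uniform_sig), "missense", window_bases=50)
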