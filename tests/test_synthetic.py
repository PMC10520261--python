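import numpy as np
import pytest
from Bio.Seq import Seq

from oncosieve.copy_number import classify_cn
from oncosieve.signatures import mutation_spectrum, site_rates
from oncosieve.synthetic import (
    SimConfig,
    gen_alteration_matrix,
    gen_cds,
    gen_cn_table,
    gen_helix_coords,
    gen_mutations,
    resolve_signature,
    write_simulation,
)


class TestGenCds:
    def test_deterministic_given_seed(self):
        a = gen_cds(SimConfig(seed=1, cds_length_codons=100))
        b = gen_cds(SimConfig(seed=1, cds_length_codons=100))
        assert a == b

    def test_structure_invariants(self):
        cds = gen_cds(SimConfig(seed=2, cds_length_codons=50))
        assert cds.seq.startswith("ATG")
        assert cds.seq[-3:] in ("TAA", "TAG", "TGA")
        aa = str(Seq(cds.seq).translate())
        assert "*" not in aa[:-1]

    def test_gc_fraction_tracks_target(self):
        cds = gen_cds(SimConfig(seed=3, cds_length_codons=3000, gc_fraction=0.6))
        gc = sum(c in "GC" for c in cds.seq) / len(cds.seq)
        assert abs(gc - 0.6) < 0.03

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(cds_length_codons=1)


class TestGenMutations:
    def test_neutral_spectrum_converges_to_signature(self):
        config = SimConfig(seed=4, cds_length_codons=400, n_mutations=10_000)
        cds = gen_cds(config)
        muts, _ = gen_mutations(cds, config)
        spec = mutation_spectrum(muts)
        # expected channel mass under the uniform signature: every site's
        # channel weight, i.e. the CDS's own context composition
        from oncosieve.signatures import collapse_channel

        expected = np.zeros(96)
        for pos in range(len(cds.seq)):
            ctx = cds.context(pos)
            for alt in "ACGT":
                if alt == cds.seq[pos]:
                    continue
                for idx, w in collapse_channel(ctx, alt):
                    expected[idx] += w
        expected = expected / expected.sum() * spec.total
        keep = expected > 5
        chi2 = float(((spec.counts[keep] - expected[keep]) ** 2 / expected[keep]).sum())
        from scipy.stats import chi2 as chi2_dist

        p = chi2_dist.sf(chi2, df=int(keep.sum()) - 1)
        assert p > 0.01

    def test_hotspot_enrichment(self):
        span = (100, 104, 20.0)
        config = SimConfig(seed=5, cds_length_codons=500, n_mutations=200, hotspot=span)
        cds = gen_cds(config)
        muts, truth = gen_mutations(cds, config)
        in_span = sum(1 for m in muts if span[0] <= m.residue <= span[1])
        frac_in = in_span / len(muts)
        width_frac = 5 / 500
        assert frac_in / width_frac >= 8.0
        assert truth["hotspot"] == list(span)

    def test_omega_one_matches_rate_fraction(self, uniform_sig):
        config = SimConfig(seed=6, cds_length_codons=300, n_mutations=5000)
        cds = gen_cds(config)
        muts, _ = gen_mutations(cds, config)
        rates = site_rates(cds, uniform_sig)
        e_n = rates.total_class_rate({"missense", "nonsense"})
        e_s = rates.total_class_rate("synonymous")
        pi = e_n / (e_n + e_s)
        realized = sum(m.consequence != "synonymous" for m in muts) / len(muts)
        assert abs(realized - pi) < 0.03


class TestGenCnTable:
    def test_planted_states_recovered_exactly_by_classifier(self):
        config = SimConfig(
            seed=7,
            amplified_fractions={"GENE1": 0.2},
            deleted_fractions={"GENE2": 0.15},
        )
        records, truth = gen_cn_table(config)
        truth_map = {(r["sample"], r["gene"]): r["state"] for r in truth.to_dict("records")}
        for rec in records:
            want = truth_map[(rec.sample, rec.gene)]
            got = classify_cn(rec.total_cn, rec.ploidy)
            assert got == (want if want != "neutral" else "neutral")

    def test_no_planting_gives_all_neutral(self):
        records, truth = gen_cn_table(SimConfig(seed=8))
        assert (truth["state"] == "neutral").all()
        assert all(classify_cn(r.total_cn, r.ploidy) == "neutral" for r in records)

    def test_planted_fraction_within_binomial_error(self):
        config = SimConfig(seed=9, n_samples=400, amplified_fractions={"GENE3": 0.2})
        _, truth = gen_cn_table(config)
        frac = (truth[truth.gene == "GENE3"]["state"] == "amplified").mean()
        assert abs(frac - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 400)


class TestGenAlterationMatrix:
    def test_margins_reproducible_under_seed(self):
        a, _ = gen_alteration_matrix(SimConfig(seed=10))
        b, _ = gen_alteration_matrix(SimConfig(seed=10))
        assert a.equals(b)

    def test_xor_pair_never_overlaps(self):
        matrix, truth = gen_alteration_matrix(
            SimConfig(seed=11, n_samples=60, exclusivity_pairs=(("GA", "GB"),))
        )
        assert (matrix["GA"] + matrix["GB"] == 1).all()
        assert truth["exclusivity_pairs"] == [["GA", "GB"]]


class TestGenHelixCoords:
    def test_rise_per_residue_exact(self):
        helix = gen_helix_coords(50)
        dz = np.diff(helix.xyz[:, 2])
        np.testing.assert_allclose(dz, 1.5)

    def test_consecutive_ca_distance_is_canonical(self):
        helix = gen_helix_coords(50)
        d = np.linalg.norm(np.diff(helix.xyz, axis=0), axis=1)
        assert np.allclose(d, d[0])
        assert 3.7 < d[0] < 3.9

    def test_deterministic_without_seed(self):
        a = gen_helix_coords(30)
        b = gen_helix_coords(30)
        np.testing.assert_array_equal(a.xyz, b.xyz)


class TestWriteSimulation:
    def test_roundtrip_through_readers(self, tmp_path):
        from oncosieve.copy_number import read_cn_table
        from oncosieve.sequence_io import read_fasta, read_mutations
        from oncosieve.spatial3d import read_ca_coords

        config = SimConfig(seed=12, cds_length_codons=80, n_mutations=50,
                           exclusivity_pairs=(("GA", "GB"),))
        truth = write_simulation(config, tmp_path)
        (cds,) = read_fasta(tmp_path / "cds.fasta")
        records, rejects = read_mutations(tmp_path / "mutations.tsv", {cds.gene: cds})
        assert not rejects and len(records) == 50
        assert len(read_cn_table(tmp_path / "cn.tsv")) == 100 * 3
        coords = read_ca_coords(tmp_path / "helix.pdb")
        assert len(coords) == config.helix_n_residues
        assert truth["mutations"]["n_mutations"] == 50
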