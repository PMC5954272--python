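import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

import orcel
from orcel.annotation import CircIsoform
from orcel.io import BackSplicedJunction
from orcel.sponge import (
    SEED_LENGTHS,
    SEED_TYPES,
    MiRNA,
    build_background,
    count_sites,
    extract_seeds,
    score_pair,
    seed_frequency,
    z_to_p,
)


def naive_scan(seq, site):
    """Independent position-by-position oracle for overlapping matches."""
    return sum(seq[i : i + len(site)] == site for i in range(len(seq) - len(site) + 1))


def make_iso(seq, iso_id="c1", host="G1"):
    j = BackSplicedJunction("chr1", 0, len(seq), "+", name=iso_id)
    return CircIsoform(
        isoform_id=iso_id, junction=j, host_gene=host, source_transcript=None,
        blocks=((0, len(seq)),), sequence=seq, rule_applied="intergenic",
    )


class TestExtractSeeds:
    def test_let7_like_sites_match_hand_reverse_complement(self):
        # mature let-7-ish: positions 2-7 = GAGGUA -> DNA GAGGTA, revcomp TACCTC
        seeds = extract_seeds("UGAGGUAGUAGGUUGUAUAGUU")
        assert seeds["6mer"] == "TACCTC"
        assert seeds["7mer-m8"] == "CTACCTC"   # revcomp of GAGGTAG
        assert seeds["7mer-A1"] == "TACCTCA"
        assert seeds["8mer"] == "CTACCTCA"

    def test_eight_nt_mature_defines_all_four_seeds(self):
        seeds = extract_seeds("ACGTACGT")
        assert set(seeds) == set(SEED_TYPES)
        assert all(len(seeds[t]) == SEED_LENGTHS[t] for t in SEED_TYPES)

    def test_shorter_than_eight_rejected(self):
        with pytest.raises(ValueError):
            extract_seeds("ACGTACG")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=8, max_size=25))
    def test_a1_seeds_append_target_side_adenine(self, mature):
        seeds = extract_seeds(mature)
        assert seeds["7mer-A1"] == seeds["6mer"] + "A"
        assert seeds["8mer"] == seeds["7mer-m8"] + "A"
        assert seeds["7mer-m8"][1:] == seeds["6mer"]


class TestCountSites:
    def test_overlapping_linear_and_wraparound_counts(self):
        assert count_sites("AAAA", "AA", circular=False) == 3
        assert count_sites("AAAA", "AA", circular=True) == 4

    def test_empty_site_rejected(self):
        with pytest.raises(ValueError):
            count_sites("ACGT", "")

    def test_equals_naive_scan_oracle_on_random_pairs(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(100):
            seq = "".join(bases[rng.integers(0, 4, size=2000)])
            site = "".join(bases[rng.integers(0, 4, size=7)])
            assert count_sites(seq, site, circular=False) == naive_scan(seq, site)
            assert count_sites(seq, site, circular=True) == naive_scan(
                seq + seq[: len(site) - 1], site
            )

    def test_circular_at_least_linear_and_bounded(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(bases[rng.integers(0, 4, size=300)])
            site = "".join(bases[rng.integers(0, 4, size=6)])
            lin = count_sites(seq, site, circular=False)
            circ = count_sites(seq, site, circular=True)
            assert lin <= circ <= lin + len(site) - 1


class TestSeedFrequency:
    def test_direct_arithmetic(self):
        assert seed_frequency(0, 6, 500) == 0.0
        assert seed_frequency(3, 6, 1000) == 0.5
        assert seed_frequency(7, 8, 350) == 2.5

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            seed_frequency(1, 6, 0)


class TestBackground:
    def test_two_transcripts_mean_and_population_sd(self):
        # sequences engineered to hold exactly 6 and 12 copies of the 6mer
        # site GGGCCC in 5000 nt: frequencies 0.2 and 0.4
        mirna = MiRNA.from_mature("m1", "AGGGCCCGATCGATCGATCGAT")
        assert mirna.seeds["6mer"] == "GGGCCC"
        def with_sites(k):
            filler = "T" * ((5000 - 6 * k) // k)
            s = ("GGGCCC" + filler) * k
            return s + "T" * (5000 - len(s))
        t1, t2 = with_sites(6), with_sites(12)
        assert naive_scan(t1, "GGGCCC") == 6 and len(t1) == 5000
        bg = build_background([t1, t2], [mirna])
        stat = bg.get("m1", "6mer")
        assert stat.mean == pytest.approx(0.3)
        assert stat.sd == pytest.approx(0.1)
        assert not stat.degenerate

    def test_identical_transcripts_flagged_degenerate(self):
        mirna = MiRNA.from_mature("m1", "ACGTACGTACGT")
        bg = build_background(["ACGT" * 100] * 3, [mirna])
        assert all(bg.get("m1", t).degenerate for t in SEED_TYPES)

    def test_fewer_than_two_transcripts_rejected(self):
        with pytest.raises(ValueError):
            build_background(["ACGTACGT" * 10], [MiRNA.from_mature("m1", "ACGTACGTACGT")])

    def test_mean_matches_poisson_expectation_on_iid_sequences(self, rng):
        # analytic null: E[count] = (L - N + 1) / 4^N for linear counting
        bases = np.array(list("ACGT"))
        L, n = 1000, 300
        seqs = ["".join(bases[rng.integers(0, 4, size=L)]) for _ in range(n)]
        mirna = MiRNA.from_mature("m1", "UGAGGUAGUAGGUUGUAUAGUU")
        bg = build_background(seqs, [mirna])
        stat = bg.get("m1", "6mer")
        expected = (L - 6 + 1) / 4**6 * 1000 / (6 * L)
        se = stat.sd / math.sqrt(n)
        assert abs(stat.mean - expected) < 3 * se


class TestZToP:
    def test_symmetry_and_limits(self):
        assert z_to_p(0.0) == pytest.approx(0.5, abs=1e-12)
        assert z_to_p(50) < 1e-100
        assert z_to_p(-50) > 1 - 1e-12
        for z in (-3.0, -0.7, 1.2, 4.5):
            assert z_to_p(z) + z_to_p(-z) == pytest.approx(1.0, abs=1e-12)

    def test_against_quadrature_of_normal_density(self):
        for z in (0.5, 1.0, 2.576, 3.2):
            oracle, _ = integrate.quad(
                lambda x: math.exp(-x * x / 2) / math.sqrt(2 * math.pi), z, math.inf
            )
            assert z_to_p(z) == pytest.approx(oracle, abs=1e-10)

    def test_strictly_decreasing(self):
        zs = np.linspace(-6, 6, 1000)
        ps = [z_to_p(z) for z in zs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            z_to_p(float("nan"))


class TestScorePair:
    @pytest.fixture()
    def background_setup(self, rng):
        bases = np.array(list("ACGT"))
        mirna = MiRNA.from_mature("m1", "UGAGGUAGUAGGUUGUAUAGUU")
        seqs = ["".join(bases[rng.integers(0, 4, size=1500)]) for _ in range(200)]
        return mirna, build_background(seqs, [mirna])

    def test_zero_sites_vs_positive_background_is_not_a_sponge(self, background_setup):
        mirna, bg = background_setup
        # circle free of every seed site
        seq = "T" * 800
        iso = make_iso(seq)
        r = score_pair(iso, mirna, bg)
        assert all(sc.count == 0 for sc in r.seed_counts.values())
        assert all(z < 0 for t, z in r.z.items() if t not in r.degenerate_seeds)
        assert all(p > 0.5 for t, p in r.p.items() if t not in r.degenerate_seeds)
        assert not r.is_sponge

    def test_planted_sites_at_tenfold_density_called_sponge(self, background_setup, rng):
        mirna, bg = background_setup
        bases = np.array(list("ACGT"))
        L = 1000
        seq = list("".join(bases[rng.integers(0, 4, size=L)]))
        site = mirna.seeds["6mer"]
        n_sites = max(3, round(10 * L / 4**6))
        for k in range(n_sites):
            p = 40 * k
            seq[p : p + 6] = site
        r = score_pair(make_iso("".join(seq)), mirna, bg)
        assert r.is_sponge
        assert r.p["6mer"] < 0.005

    def test_combined_p_is_minimum_of_per_seed_p(self, background_setup, rng):
        mirna, bg = background_setup
        bases = np.array(list("ACGT"))
        for _ in range(10):
            seq = "".join(bases[rng.integers(0, 4, size=700)])
            r = score_pair(make_iso(seq), mirna, bg)
            assert r.combined_p == min(r.p.values())
            assert all(r.combined_p <= p for p in r.p.values())

    def test_degenerate_background_forces_p_of_one(self):
        mirna = MiRNA.from_mature("m1", "ACGTACGTACGT")
        bg = build_background(["TTTT" * 200] * 5, [mirna])
        r = score_pair(make_iso("ACGT" * 100), mirna, bg)
        assert set(r.degenerate_seeds) == set(SEED_TYPES)
        assert all(p == 1.0 for p in r.p.values())
        assert not r.is_sponge

    def test_missing_background_entry_rejected(self, background_setup):
        _, bg = background_setup
        other = MiRNA.from_mature("m2", "CCCCGGGGAAAATTTT")
        with pytest.raises(KeyError):
            score_pair(make_iso("ACGT" * 50), other, bg)
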