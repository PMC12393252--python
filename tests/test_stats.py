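"""Poisson-Binomial counts, on/off tallies, specificity load, SNR."""

import itertools
import math

import numpy as np
import pytest

from probekit.equilibrium import ConcentrationProfile, solve_equilibrium
from probekit.homology import AlignmentHit, build_site_map
from probekit.reference import Biotype, ExpressionMode, Transcriptome, TranscriptRecord
from probekit.stats import (
    BoundCountDistribution,
    SignalStats,
    bound_count_distribution,
    identify_problem_probes,
    offtarget_accumulation,
    on_off_counts,
    site_bound_probability,
    snr,
    specificity_load,
    target_pmfs,
)
from probekit.thermo import DissociationConstants


def enumeration_pmf(ps):
    """Exhaustive 2^N enumeration over site occupancy outcomes."""
    pmf = np.zeros(len(ps) + 1)
    for states in itertools.product([0, 1], repeat=len(ps)):
        prob = 1.0
        for p, s in zip(ps, states):
            prob *= p if s else (1 - p)
        pmf[sum(states)] += prob
    return pmf


def generating_function_pmf(ps):
    """Symbolic expansion of the probability generating function product
    prod_s ((1 - p_s) + p_s z); coefficients of z^n are the pmf."""
    import sympy

    z = sympy.Symbol("z")
    poly = sympy.prod([(1 - sympy.Rational(p) ) + sympy.Rational(p) * z for p in ps])
    poly = sympy.Poly(sympy.expand(poly), z)
    coeffs = [float(poly.coeff_monomial(z**n)) for n in range(len(ps) + 1)]
    return np.array(coeffs)


class TestPoissonBinomial:
    def test_iid_half_is_binomial(self):
        assert np.allclose(bound_count_distribution([0.5] * 3), [1 / 8, 3 / 8, 3 / 8, 1 / 8])

    def test_certainty(self):
        assert np.allclose(bound_count_distribution([1.0]), [0.0, 1.0])

    @pytest.mark.parametrize("n", [5, 12])
    def test_matches_exhaustive_enumeration(self, n, rng):
        ps = rng.random(n).tolist()
        assert np.allclose(bound_count_distribution(ps), enumeration_pmf(ps), atol=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_matches_symbolic_generating_function(self, n, rng):
        # exact rationals through sympy: the convolution pmf equals the
        # expanded generating-function product coefficient-for-coefficient
        ps = [round(p, 3) for p in rng.random(n)]
        assert np.allclose(
            bound_count_distribution(ps), generating_function_pmf(ps), atol=1e-12
        )

    @pytest.mark.parametrize("n", [1, 7, 20])
    def test_pmf_sums_to_one_and_mean_identity(self, n, rng):
        ps = rng.random(n)
        pmf = bound_count_distribution(ps.tolist())
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.arange(n + 1) * pmf).sum() == pytest.approx(ps.sum(), abs=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            bound_count_distribution([1.5])


class TestSiteBoundProbability:
    def solve(self, kd_map, probe_totals, site_totals):
        kds = DissociationConstants()
        kds.kd_site.update(kd_map)
        conc = ConcentrationProfile(probe_totals, site_totals)
        st = solve_equilibrium(kds, conc)
        return st, kds

    def test_unit_ratio_gives_half(self):
        # one probe, negligible target: C_free/Kd == 1 => p = 1/2
        st, kds = self.solve({("p", "T", "s"): 5e-9}, {"p": 5e-9}, {("T", "s"): 1e-18})
        probs = site_bound_probability(st, kds)
        assert probs.p[("T", "s")] == pytest.approx(0.5, rel=1e-6)

    def test_two_probes_unit_ratio_two_thirds(self):
        st, kds = self.solve(
            {("a", "T", "s"): 5e-9, ("b", "T", "s"): 5e-9},
            {"a": 5e-9, "b": 5e-9},
            {("T", "s"): 1e-18},
        )
        probs = site_bound_probability(st, kds)
        assert probs.p[("T", "s")] == pytest.approx(2 / 3, rel=1e-6)

    def test_no_binder_site_probability_zero(self):
        st, kds = self.solve({("p", "T", "s1"): 1e-9}, {"p": 5e-9}, {("T", "s1"): 1e-13, ("T", "s2"): 1e-13})
        probs = site_bound_probability(st, kds)
        assert probs.p[("T", "s2")] == 0.0


def make_dists(pmfs):
    return BoundCountDistribution(pmf={k: np.asarray(v) for k, v in pmfs.items()})


class TestOnOffCounts:
    def test_point_mass_scaled_by_expression(self):
        dists = make_dists({"on": [0, 0, 1.0]})
        n_on, n_off = on_off_counts(dists, {"on": 7.0}, {"on"})
        assert np.allclose(n_on, [0, 0, 7.0])
        assert np.allclose(n_off, 0.0)

    def test_zero_expression_off_targets_vanish(self):
        dists = make_dists({"on": [0, 1.0], "off": [0.2, 0.8]})
        _, n_off = on_off_counts(dists, {"on": 1.0, "off": 0.0}, {"on"})
        assert np.allclose(n_off, 0.0)

    def test_linearity_two_identical_off_targets(self):
        pmf = [0.3, 0.7]
        d1 = make_dists({"on": [0, 1.0], "o1": pmf})
        d2 = make_dists({"on": [0, 1.0], "o1": pmf, "o2": pmf})
        _, off1 = on_off_counts(d1, {"on": 1, "o1": 2.0, "o2": 2.0}, {"on"})
        _, off2 = on_off_counts(d2, {"on": 1, "o1": 2.0, "o2": 2.0}, {"on"})
        assert np.allclose(off2, 2 * off1)

    def test_unknown_on_target_errors(self):
        dists = make_dists({"a": [1.0]})
        with pytest.raises(ValueError, match="unknown"):
            on_off_counts(dists, {"a": 1.0}, {"nope"})


class TestSpecificityLoad:
    def test_worked_arithmetic(self):
        # one on-target molecule with exactly 10 probes bound; off-targets
        # carry 20 total probe bindings => load = 20 / 10 = 2
        n_on = np.zeros(11)
        n_on[10] = 1.0
        n_off = np.zeros(11)
        n_off[2] = 10.0  # 10 molecules x 2 bound = 20 bindings
        assert specificity_load(n_on, n_off) == pytest.approx(2.0)

    def test_no_off_binding_zero_load(self):
        n_on = np.array([0.0, 1.0])
        assert specificity_load(n_on, np.zeros(2)) == 0.0

    def test_doubling_off_doubles_load(self):
        n_on = np.array([0.0, 0.5, 0.5])
        n_off = np.array([1.0, 0.25, 0.5])
        assert specificity_load(n_on, 2 * n_off) == pytest.approx(
            2 * specificity_load(n_on, n_off)
        )

    def test_no_on_target_binding_undefined(self):
        with pytest.raises(ValueError):
            specificity_load(np.array([1.0, 0.0]), np.array([0.0, 1.0]))


def tiny_transcriptome():
    return Transcriptome(
        [
            TranscriptRecord("ON", "G", "A" * 60, Biotype.MRNA),
            TranscriptRecord("OFF", "H", "C" * 60, Biotype.MRNA),
        ]
    )


def shared_site_scenario():
    """Two probes binding one off-target site plus their own on-target sites."""
    tr = tiny_transcriptome()
    pair = ("T" * 20, "T" * 20)
    hits = [
        AlignmentHit("a", "ON", (0, 20), (0, 20), 20, 20, pair),
        AlignmentHit("b", "ON", (0, 20), (30, 50), 20, 20, pair),
        AlignmentHit("a", "OFF", (0, 16), (10, 26), 16, 16, (pair[0][:16], pair[1][:16])),
        AlignmentHit("b", "OFF", (0, 15), (12, 27), 15, 15, (pair[0][:15], pair[1][:15])),
    ]
    sm = build_site_map(hits, tr)
    kds = DissociationConstants()
    kds.kd_site.update(
        {
            ("a", "ON", "ON:s0"): 1e-12,
            ("b", "ON", "ON:s1"): 1e-12,
            ("a", "OFF", "OFF:s0"): 2e-9,
            ("b", "OFF", "OFF:s0"): 8e-9,
        }
    )
    conc = ConcentrationProfile(
        {"a": 5e-9, "b": 5e-9},
        {("ON", "ON:s0"): 4e-13, ("ON", "ON:s1"): 4e-13, ("OFF", "OFF:s0"): 4e-13},
    )
    st = solve_equilibrium(kds, conc)
    probs = site_bound_probability(st, kds)
    expr = {"ON": 1.0, "OFF": 1.0}
    return tr, sm, kds, st, probs, expr


class TestAccumulation:
    def test_contributions_sum_to_site_occupancy(self):
        tr, sm, kds, st, probs, expr = shared_site_scenario()
        per_probe, cumulative, ratio = offtarget_accumulation(
            probs, sm, expr, {"ON"}, ["a", "b"]
        )
        expected_occ = expr["OFF"] * probs.p[("OFF", "OFF:s0")]
        assert per_probe["a"] + per_probe["b"] == pytest.approx(expected_occ, rel=1e-12)
        # probe a binds the shared site 4x more strongly: larger share
        assert per_probe["a"] > per_probe["b"]
        assert cumulative == sorted(cumulative)
        assert cumulative[-1] == pytest.approx(expected_occ, rel=1e-12)

    def test_clean_probe_contributes_zero(self):
        tr, sm, kds, st, probs, expr = shared_site_scenario()
        kds.kd_site.pop(("b", "OFF", "OFF:s0"))
        st = solve_equilibrium(
            kds,
            ConcentrationProfile(
                {"a": 5e-9, "b": 5e-9},
                {("ON", "ON:s0"): 4e-13, ("ON", "ON:s1"): 4e-13, ("OFF", "OFF:s0"): 4e-13},
            ),
        )
        probs = site_bound_probability(st, kds)
        per_probe, _, _ = offtarget_accumulation(probs, sm, expr, {"ON"}, ["a", "b"])
        assert per_probe["b"] == 0.0


class TestProblemProbes:
    def test_owner_of_all_offtargets_ranks_first_in_both(self):
        tr, sm, kds, st, probs, expr = shared_site_scenario()
        kds.kd_site.pop(("b", "OFF", "OFF:s0"))
        probs = site_bound_probability(st, kds)
        by_total, by_multi = identify_problem_probes(probs, sm, expr, {"ON"}, ["a", "b"])
        assert by_total[0][0] == "a"
        assert by_multi[0][0] == "a"
        assert by_total[1][1] == 0.0

    def test_removing_top_probe_reduces_multisite_offtargets(self):
        tr, sm, kds, st, probs, expr = shared_site_scenario()
        by_total, by_multi = identify_problem_probes(probs, sm, expr, {"ON"}, ["a", "b"])
        assert all(red >= 0 for _, red in by_multi)


class TestSNR:
    def test_worked_example(self):
        assert snr(SignalStats(100, 60, 20)) == pytest.approx(2.0)

    def test_zero_when_signal_equals_background(self):
        assert snr(SignalStats(60, 60, 20)) == 0.0

    def test_linear_in_signal(self):
        base = snr(SignalStats(80, 60, 10))
        assert snr(SignalStats(100, 60, 10)) == pytest.approx(base + 2.0)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            snr(SignalStats(1, 0, 0.0))
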