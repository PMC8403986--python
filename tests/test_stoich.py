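"""Enumerator tests, including an independent brute-force oracle.

The oracle re-states every feasibility rule directly as arithmetic over
a quintuple loop on the bounded count grid; it shares no code with the
pruned production enumerator.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcstoich import (
    ComponentSpec,
    EnumerationConstraints,
    Stoichiometry,
    check_conditions,
    complex_extinction,
    complex_mass,
    enumerate_stoichiometries,
    pair_wt_m3,
)
from dcstoich.stoich import FeasibleSet, pair_frames


def brute_force_feasible(masses, epses, constraints):
    """Independent oracle: filter the full bounded grid with explicit rules.

    ``masses``/``epses`` are (APC, AXIN1, CK1, GSK, bcat) tuples.
    """
    m_apc, m_axin, m_ck1, m_gsk, m_b = masses
    e_apc, e_axin, e_ck1, e_gsk, e_b = epses
    lo = constraints.mn_mean - constraints.ci_multiplier * constraints.mn_sd
    hi = constraints.mn_mean + constraints.ci_multiplier * constraints.mn_sd
    if constraints.eps_mean is not None:
        elo = constraints.eps_mean - constraints.ci_multiplier * constraints.eps_sd
        ehi = constraints.eps_mean + constraints.ci_multiplier * constraints.eps_sd
    out = []
    for a in range(1, int(hi // m_apc) + 1):
        if a * m_apc > hi:
            break
        for b in range(1, int(hi // m_axin) + 1):
            if a * m_apc + b * m_axin > hi:
                break
            for c in range(1, int(hi // m_ck1) + 1):
                if a * m_apc + b * m_axin + c * m_ck1 > hi:
                    break
                for g in range(1, int(hi // m_gsk) + 1):
                    if a * m_apc + b * m_axin + c * m_ck1 + g * m_gsk > hi:
                        break
                    for e in range(1, int(hi // m_b) + 1):
                        mass = a * m_apc + b * m_axin + c * m_ck1 + g * m_gsk + e * m_b
                        if mass > hi:
                            break
                        if mass < lo:
                            continue
                        if constraints.eps_mean is not None:
                            eps = a * e_apc + b * e_axin + c * e_ck1 + g * e_gsk + e * e_b
                            if not (elo <= eps <= ehi):
                                continue
                        if constraints.variant == "wt" and b < 2:
                            continue
                        if not (-(-b // 2) <= c <= b):  # ceil(b/2)
                            continue
                        if not (-(-b // 2) <= g <= b):
                            continue
                        if constraints.bcat_lower_rule == "max":
                            if e < max(a, b):
                                continue
                        else:
                            if e < a + b:
                                continue
                        if e > b + 10 * a + (2 * b - c - g):
                            continue
                        if b < a:
                            continue
                        if constraints.variant == "m3" and b > 3 * a:
                            continue
                        out.append((a, b, c, g, e))
    return sorted(out)


def make_table(masses, epses):
    names = ("APC", "AXIN1", "CK1a", "GSK3b", "bcat")
    roles = ("scaffold_a", "scaffold_b", "kinase", "kinase", "substrate")
    return [ComponentSpec(n, m, e, r) for n, m, e, r in zip(names, masses, epses, roles)]


def as_tuples(feasible: FeasibleSet):
    return sorted(
        (s["APC"], s["AXIN1"], s["CK1a"], s["GSK3b"], s["bcat"])
        for s in feasible.stoichiometries
    )


class TestComplexMassAndExtinction:
    def test_fully_loaded_complex_is_1951_kda(self, components, dc_stoichiometry):
        assert complex_mass(dc_stoichiometry, components) == pytest.approx(1_951_000.0)

    def test_single_axin(self, components):
        assert complex_mass(Stoichiometry({"AXIN1": 1}), components) == pytest.approx(92_000.0)

    def test_empty_counts_raise(self, components):
        with pytest.raises(ValueError):
            complex_mass(Stoichiometry({}), components)
        with pytest.raises(KeyError):
            complex_mass(Stoichiometry({"WNT": 1}), components)

    def test_extinction_identity_and_linearity(self, components):
        single = Stoichiometry({"CK1a": 1})
        assert complex_extinction(single, components) == components[2].eps
        s1 = Stoichiometry({"APC": 1, "AXIN1": 2, "bcat": 3})
        s2 = Stoichiometry({"APC": 2, "AXIN1": 4, "bcat": 6})
        assert complex_extinction(s2, components) == pytest.approx(
            2 * complex_extinction(s1, components)
        )

    def test_extinction_hand_sum(self, components, dc_stoichiometry):
        # independent hand sum over the default table
        expected = 280_000 + 3 * 90_000 + 3 * 35_000 + 3 * 50_000 + 13 * 75_000
        assert complex_extinction(dc_stoichiometry, components) == pytest.approx(expected)


class TestCheckConditions:
    def wide(self, variant="m3", **kw):
        return EnumerationConstraints(mn_mean=2e6, mn_sd=1e6, eps_mean=None,
                                      variant=variant, **kw)

    def test_minimal_m3_complex_passes_everything(self, components):
        s = Stoichiometry({"APC": 1, "AXIN1": 1, "CK1a": 1, "GSK3b": 1, "bcat": 2})
        report = check_conditions(s, self.wide("m3"), components)
        assert report.passed, report.failed()

    def test_wt_needs_two_axin(self, components):
        s = Stoichiometry({"APC": 1, "AXIN1": 1, "CK1a": 1, "GSK3b": 1, "bcat": 2})
        report = check_conditions(s, self.wide("wt"), components)
        assert "axin_minimum" in report.failed()

    def test_missing_kinase_fails_presence_and_occupancy(self, components):
        s = Stoichiometry({"APC": 1, "AXIN1": 2, "CK1a": 0, "GSK3b": 2, "bcat": 2})
        report = check_conditions(s, self.wide("wt"), components)
        failed = report.failed()
        assert "one_of_each" in failed and "kinase_occupancy" in failed

    def test_mass_window_condition(self, components, dc_stoichiometry):
        tight = EnumerationConstraints(mn_mean=1_951_000.0, mn_sd=1.0, eps_mean=None, variant="wt")
        assert check_conditions(dc_stoichiometry, tight, components).passed
        shifted = EnumerationConstraints(mn_mean=1_000_000.0, mn_sd=1.0, eps_mean=None, variant="wt")
        assert "mass_window" in check_conditions(dc_stoichiometry, shifted, components).failed()

    def test_vacant_kinase_sites_raise_bcat_bound(self, components):
        # 2 AXIN1 with one kinase of each: 2 vacancies allow 2 extra bcat
        base = dict(APC=1, AXIN1=2, CK1a=1, GSK3b=1)
        ok = Stoichiometry({**base, "bcat": 2 + 10 + 2})
        over = Stoichiometry({**base, "bcat": 2 + 10 + 3})
        assert check_conditions(ok, self.wide("wt"), components).passed
        assert "bcat_upper" in check_conditions(over, self.wide("wt"), components).failed()


class TestEnumeration:
    def test_unique_660_kda_m3_complex(self, components):
        constraints = EnumerationConstraints(mn_mean=660_000.0, mn_sd=5_000.0 / 1.96,
                                             eps_mean=None, variant="m3")
        feasible = enumerate_stoichiometries(components, constraints)
        assert as_tuples(feasible) == [(1, 1, 1, 1, 2)]
        assert complex_mass(feasible.stoichiometries[0], components) == pytest.approx(660_000.0)

    def test_window_below_minimum_complex_is_empty(self, components):
        constraints = EnumerationConstraints(mn_mean=50_000.0, mn_sd=50_000.0 / 1.96,
                                             eps_mean=None, variant="wt")
        assert len(enumerate_stoichiometries(components, constraints)) == 0

    def test_matches_brute_force_on_default_table(self, components):
        masses = tuple(c.mass for c in components)
        epses = tuple(c.eps for c in components)
        for variant in ("wt", "m3"):
            constraints = EnumerationConstraints(
                mn_mean=1_100_000.0, mn_sd=60_000.0, eps_mean=1_000_000.0,
                eps_sd=250_000.0, variant=variant,
            )
            feasible = enumerate_stoichiometries(components, constraints)
            assert as_tuples(feasible) == brute_force_feasible(masses, epses, constraints)

    @given(
        masses=st.tuples(*[st.integers(60, 150) for _ in range(5)]),
        epses=st.tuples(*[st.integers(40, 160) for _ in range(5)]),
        mean_k=st.integers(300, 900),
        sd_k=st.integers(0, 80),
        use_eps=st.booleans(),
        variant=st.sampled_from(["wt", "m3"]),
        rule=st.sampled_from(["max", "sum"]),
    )
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_randomized(self, masses, epses, mean_k, sd_k, use_eps,
                                           variant, rule):
        masses = tuple(1000.0 * m for m in masses)
        epses = tuple(1000.0 * e for e in epses)
        constraints = EnumerationConstraints(
            mn_mean=1000.0 * mean_k,
            mn_sd=1000.0 * sd_k,
            eps_mean=sum(epses) * 1.2 if use_eps else None,
            eps_sd=sum(epses) * 0.15 if use_eps else 0.0,
            variant=variant,
            bcat_lower_rule=rule,
        )
        table = make_table(masses, epses)
        feasible = enumerate_stoichiometries(table, constraints)
        assert as_tuples(feasible) == brute_force_feasible(masses, epses, constraints)

    def test_widening_ci_never_shrinks_the_set(self, components):
        narrow = EnumerationConstraints(mn_mean=1_072_000.0, mn_sd=68_000.0,
                                        eps_mean=980_087.0, eps_sd=275_179.0,
                                        ci_multiplier=1.0, variant="m3")
        wide = EnumerationConstraints(mn_mean=1_072_000.0, mn_sd=68_000.0,
                                      eps_mean=980_087.0, eps_sd=275_179.0,
                                      ci_multiplier=1.96, variant="m3")
        a = set(as_tuples(enumerate_stoichiometries(components, narrow)))
        b = set(as_tuples(enumerate_stoichiometries(components, wide)))
        assert a <= b and len(b) > 0

    def test_every_entry_is_inside_the_windows(self, components):
        constraints = EnumerationConstraints(mn_mean=2_395_000.0, mn_sd=141_000.0,
                                             eps_mean=2_024_161.0, eps_sd=367_667.0,
                                             variant="wt")
        feasible = enumerate_stoichiometries(components, constraints)
        assert len(feasible) > 0
        mlo, mhi = constraints.mass_window
        elo, ehi = constraints.eps_window
        for s in feasible.stoichiometries:
            assert mlo <= complex_mass(s, components) <= mhi
            assert elo <= complex_extinction(s, components) <= ehi

    def test_deterministic_and_sorted(self, components):
        constraints = EnumerationConstraints(mn_mean=1_072_000.0, mn_sd=68_000.0,
                                             eps_mean=None, variant="m3")
        a = enumerate_stoichiometries(components, constraints).to_frame()
        b = enumerate_stoichiometries(components, constraints).to_frame()
        assert a.equals(b)
        tuples = list(map(tuple, a[["n_APC", "n_AXIN1", "n_CK1a", "n_GSK3b", "n_bcat"]].values))
        assert tuples == sorted(tuples)


class TestPairing:
    def fs(self, entries, variant, components):
        constraints = EnumerationConstraints(mn_mean=2e6, mn_sd=2e6, eps_mean=None,
                                             variant=variant)
        stoichs = [
            Stoichiometry(dict(zip(("APC", "AXIN1", "CK1a", "GSK3b", "bcat"), t)))
            for t in entries
        ]
        reports = [check_conditions(s, constraints, components) for s in stoichs]
        return FeasibleSet(stoichs, constraints, components, reports)

    def test_m3_kept_when_strictly_below_wt(self, components):
        wt = self.fs([(1, 2, 1, 1, 4)], "wt", components)
        m3 = self.fs([(1, 2, 1, 1, 3)], "m3", components)
        w2, m2 = pair_wt_m3(wt, m3)
        assert len(w2) == 1 and len(m2) == 1

    def test_m3_dropped_when_reaching_wt_maximum(self, components):
        wt = self.fs([(1, 2, 1, 1, 4)], "wt", components)
        m3 = self.fs([(1, 2, 1, 1, 5), (1, 2, 1, 1, 4)], "m3", components)
        _, m2 = pair_wt_m3(wt, m3)
        assert as_tuples(m2) == []  # both 5 and 4 violate <= 4 - 1

    def test_m3_only_pair_is_retained(self, components):
        wt = self.fs([(1, 2, 1, 1, 4)], "wt", components)
        m3 = self.fs([(1, 1, 1, 1, 2)], "m3", components)  # no WT counterpart at (1, 1)
        _, m2 = pair_wt_m3(wt, m3)
        assert as_tuples(m2) == [(1, 1, 1, 1, 2)]

    def test_frame_variant_agrees(self, components):
        wt = self.fs([(1, 2, 1, 1, 4), (2, 2, 1, 1, 6)], "wt", components)
        m3 = self.fs([(1, 2, 1, 1, 3), (2, 2, 1, 1, 6), (1, 1, 1, 1, 2)], "m3", components)
        _, m2 = pair_wt_m3(wt, m3)
        filtered = pair_frames(wt.to_frame(), m3.to_frame())
        assert as_tuples(m2) == sorted(
            map(tuple, filtered[["n_APC", "n_AXIN1", "n_CK1a", "n_GSK3b", "n_bcat"]].values)
        )
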