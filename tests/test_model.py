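"""Forward-model kinetics: weights, occupancy, degradation, state updates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from trnfit.io import PROFILE_COLUMNS
from trnfit.model import (
    ModelParams,
    TRNModel,
    activator_contribution,
    degrade,
    gene_regulation,
    occupancy,
    site_weight,
)
from trnfit.motifs import BindingSite


def site(sp, tf="TFA", rep=None, sq=None):
    return BindingSite(tf, "r", 0, "+", sp, repressor_id=rep, sq=sq)


def make_model(prom_rows, body_rows=(), tfs=("TFA",), rep_only=(), params=None):
    """Tiny model from literal profile rows (gene, tf, rank, sp, rep, sq)."""
    def frame(rows):
        recs = [
            (g, t, r, 10 * r, "+", sp, rep or "", np.nan if sq is None else sq)
            for (g, t, r, sp, rep, sq) in rows
        ]
        return pd.DataFrame(recs, columns=PROFILE_COLUMNS)

    tf_table = pd.DataFrame(
        {
            "tf_id": list(tfs),
            "gene_id": [f"g_{t}" for t in tfs],
            "is_repressor_only": [t in rep_only for t in tfs],
        }
    ).set_index("tf_id", drop=False)
    return TRNModel(frame(prom_rows), frame(body_rows), tf_table, params)


class TestSiteWeight:
    @pytest.mark.parametrize(
        "sp,a,expected", [(1.0, 10, 1.0), (0.9, 10, 0.1), (0.0, 10, 1e-10), (1.0, 2.5, 1.0)]
    )
    def test_values(self, sp, a, expected):
        assert site_weight(sp, a) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            site_weight(1.2, 10)
        with pytest.raises(ValueError):
            site_weight(0.5, -1)


class TestDegrade:
    def test_d_zero_is_identity(self):
        x = np.array([0.1, 1.0, 5.0, 50.0])
        assert degrade(x, 0.0) == pytest.approx(x)

    def test_zero_stays_zero(self):
        assert degrade(0.0, 1.0) == 0.0

    def test_lambert_w_of_one(self):
        # solve w e^w = 1 by bisection, independently of scipy
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if mid * np.exp(mid) < 1.0:
                lo = mid
            else:
                hi = mid
        assert degrade(1.0, 1.0) == pytest.approx(lo, abs=1e-12)

    def test_bounds_and_monotonicity(self, rng):
        x = rng.uniform(0.01, 10, 200)
        d = 0.7
        g = degrade(x, d)
        assert np.all(g >= 0) and np.all(g <= x)
        xs = np.sort(x)
        assert np.all(np.diff(degrade(xs, d)) >= 0)  # increasing in x
        assert np.all(degrade(xs, 1.5) <= degrade(xs, 0.5))  # decreasing in d

    def test_matches_rk4_integration(self):
        """Closed form equals RK4 integration of dx/dt = -d x/(1+x)."""
        xs = np.linspace(0.05, 10, 25)
        for d in np.linspace(0.1, 5, 25):
            x = xs.copy()
            n = 400
            dt = 1.0 / n

            def f(v):
                return -d * v / (1.0 + v)

            for _ in range(n):
                k1 = f(x)
                k2 = f(x + dt / 2 * k1)
                k3 = f(x + dt / 2 * k2)
                k4 = f(x + dt * k3)
                x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            assert np.max(np.abs(degrade(xs, d) - x)) < 1e-6


class TestKineticsProperties:
    """Order and bound invariants of the elementary kinetics."""

    @settings(max_examples=60, derandomize=True)
    @given(
        x=st.floats(min_value=0.0, max_value=500.0),
        d=st.floats(min_value=0.0, max_value=10.0),
    )
    def test_degrade_bounded_by_input(self, x, d):
        g = degrade(x, d)
        assert 0.0 <= g <= x + 1e-12

    @settings(max_examples=60, derandomize=True)
    @given(
        sp=st.floats(min_value=0.0, max_value=1.0),
        a=st.floats(min_value=0.1, max_value=30.0),
    )
    def test_site_weight_in_unit_interval(self, sp, a):
        w = site_weight(sp, a)
        assert 0.0 < w <= 1.0

    @settings(max_examples=60, derandomize=True)
    @given(
        sp=st.lists(st.floats(min_value=0.0, max_value=0.74), min_size=1, max_size=4),
        A=st.floats(min_value=0.0, max_value=50.0),
        kd=st.floats(min_value=0.01, max_value=50.0),
    )
    def test_occupancy_bounded_by_site_count(self, sp, A, kd):
        sites = [site(v) for v in sp]
        r = occupancy(sites, A, kd, {}, {}, a=10, se_threshold=3.0)
        assert 0.0 <= r <= len(sites)


class TestActivatorContribution:
    def test_limits(self):
        assert activator_contribution(0.0, 1.0) == 0.0
        assert activator_contribution(1e12, 2.0) == pytest.approx(2.0, rel=1e-10)
        assert activator_contribution(1.0, 1.0) == pytest.approx(np.exp(-1))

    def test_monotone_in_r(self, rng):
        r = np.sort(rng.uniform(0, 5, 100))
        assert np.all(np.diff(activator_contribution(r, 1.3)) >= 0)


def naive_occupancy(sites, A, kd, ki_map, R_map, a, se_threshold):
    """Independent per-site transcription of the occupancy formula."""
    if not sites or A == 0:
        return 0.0
    total_sp = sum(s.sp for s in sites)
    terms = []
    reps = []
    for s in sites:
        w = 10 ** (-a * (1 - s.sp))
        rep = 0.0
        if s.repressor_id is not None:
            wq = 10 ** (-a * (1 - s.sq))
            rep = wq * (kd / ki_map.get(s.repressor_id, kd)) * R_map.get(s.repressor_id, 0.0)
        terms.append(w)
        reps.append(rep)
    if total_sp <= se_threshold:
        return sum(w * A / (kd + w * A + q) for w, q in zip(terms, reps))
    num = sum(w * A ** (p + 1) for p, w in enumerate(terms))
    return num / (kd ** len(sites) + num + sum(reps))


class TestOccupancy:
    def test_half_saturation(self):
        for p in (1, 2, 3):
            sites = [site(1.0)] * p
            # sub-threshold requires sum(sp) <= 3
            r = occupancy(sites, A=2.0, kd=2.0, ki_map={}, R_conc_map={}, a=10,
                          se_threshold=3.0)
            assert r == pytest.approx(p / 2)

    def test_zero_concentration(self):
        assert occupancy([site(1.0)], 0.0, 1.0, {}, {}, 10) == 0.0

    def test_symmetric_competition_one_third(self):
        s = site(1.0, rep="R1", sq=1.0)
        r = occupancy([s], A=1.0, kd=1.0, ki_map={"R1": 1.0}, R_conc_map={"R1": 1.0}, a=10)
        assert r == pytest.approx(1 / 3)

    def test_more_than_four_sites_rejected(self):
        with pytest.raises(ValueError):
            occupancy([site(0.5)] * 5, 1.0, 1.0, {}, {}, 10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_evaluator(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(1, 5))
        sites = []
        for _ in range(p):
            sp = float(rng.uniform(0.3, 0.7))  # keeps sum below threshold
            if rng.random() < 0.5:
                sites.append(site(sp, rep="RX", sq=float(rng.uniform(0.3, 0.9))))
            else:
                sites.append(site(sp))
        A, kd = float(rng.uniform(0.1, 5)), float(rng.uniform(0.2, 4))
        ki = {"RX": float(rng.uniform(0.2, 4))}
        R = {"RX": float(rng.uniform(0, 3))}
        got = occupancy(sites, A, kd, ki, R, a=10, se_threshold=3.0)
        ref = naive_occupancy(sites, A, kd, ki, R, a=10, se_threshold=3.0)
        assert got == pytest.approx(ref, abs=1e-12)

    def test_super_enhancer_regime_bounded(self):
        sites = [site(1.0)] * 4  # sum sp = 4 > 3
        r = occupancy(sites, A=3.0, kd=1.0, ki_map={}, R_conc_map={}, a=10)
        ref = naive_occupancy(sites, 3.0, 1.0, {}, {}, 10, 3.0)
        assert r == pytest.approx(ref, abs=1e-12)
        assert 0 <= r <= 1

    def test_monotonicity_probes(self, rng):
        sites = [site(0.9, rep="RX", sq=0.8), site(0.7)]
        base = occupancy(sites, 1.0, 1.0, {"RX": 1.0}, {"RX": 1.0}, 10)
        up_A = occupancy(sites, 1.01, 1.0, {"RX": 1.0}, {"RX": 1.0}, 10)
        up_kd = occupancy(sites, 1.0, 1.01, {"RX": 1.0}, {"RX": 1.0}, 10)
        up_R = occupancy(sites, 1.0, 1.0, {"RX": 1.0}, {"RX": 1.01}, 10)
        assert up_A >= base >= up_kd and base >= up_R


class TestGeneRegulation:
    params = ModelParams(a=10, kc=1.0, d=0.5)

    def test_no_binding_gives_zero(self):
        assert gene_regulation({}, {}, {}, {}, {}, self.params) == 0.0

    def test_clamped_at_zero_when_repression_wins(self):
        prom = {"TFA": [site(1.0)]}
        body = {"TFB": [site(1.0, tf="TFB")] * 3}
        state = {"TFA": 0.3, "TFB": 5.0}
        kd = {"TFA": 1.0, "TFB": 1.0}
        f = gene_regulation(prom, body, state, kd, {}, self.params)
        assert f == 0.0

    def test_single_activator_reduces_to_exponential_form(self):
        prom = {"TFA": [site(1.0)]}
        state = {"TFA": 1.0}
        f = gene_regulation(prom, {}, state, {"TFA": 1.0}, {}, self.params)
        r = 0.5
        assert f == pytest.approx(np.exp(-1 / r))

    def test_repressor_only_tf_subtracts(self):
        prom = {"TFA": [site(1.0)], "TFR": [site(1.0, tf="TFR")]}
        state = {"TFA": 1.0, "TFR": 1.0}
        kd = {"TFA": 1.0, "TFR": 1.0}
        both = gene_regulation(prom, {}, state, kd, {}, self.params, repressor_only={"TFR"})
        act_only = gene_regulation(
            {"TFA": prom["TFA"]}, {}, state, kd, {}, self.params
        )
        assert both == pytest.approx(max(act_only - np.exp(-2), 0.0))


class TestStep:
    def test_zero_state_is_fixed_point(self):
        m = make_model([("gA", "TFA", 1, 1.0, None, None)], tfs=("TFA",))
        # roster gene is gA; TFA's own gene g_TFA is frozen outside roster
        x0 = pd.Series({"gA": 0.0})
        assert m.step(x0).tolist() == [0.0]

    def test_pure_degradation_decays_monotonically(self):
        params = ModelParams(a=10, kc=1.0, d=0.8)
        m = make_model([("gA", "TFA", 1, 0.5, None, None)], tfs=("TFA",), params=params)
        x = pd.Series({"gA": 3.0})  # TFA itself unexpressed -> no flux
        traj = [x["gA"]]
        for _ in range(10):
            x = m.step(x, kd=1.0)
            traj.append(x["gA"])
        assert all(b <= a for a, b in zip(traj, traj[1:]))
        assert traj[-1] < 0.1

    def test_self_activating_tf_converges_to_root(self):
        """Iterated map lands on the fixed point found by bracketed root solve."""
        params = ModelParams(a=10, kc=1.0, d=0.7)
        tf_table = pd.DataFrame(
            {"tf_id": ["TFA"], "gene_id": ["gA"], "is_repressor_only": [False]}
        ).set_index("tf_id", drop=False)
        prom = pd.DataFrame(
            [("gA", "TFA", 1, 10, "+", 1.0, "", np.nan),
             ("gA", "TFA", 2, 40, "+", 1.0, "", np.nan)],
            columns=PROFILE_COLUMNS,
        )
        m = TRNModel(prom, None, tf_table, params)
        x = pd.Series({"gA": 2.0})
        for _ in range(3000):
            x = m.step(x, kd=1.0)
        x_star = float(x["gA"])

        def residual(v):
            r = 2 * v / (1.0 + v)
            flux = np.exp(-1.0 / r) if r > 0 else 0.0
            return flux + degrade(v, 0.7) - v

        root = brentq(residual, 0.5, 8.0, xtol=1e-12)
        assert x_star == pytest.approx(root, abs=1e-5)

    def test_state_stays_non_negative(self, bundle, rng):
        m = bundle.model
        x = pd.Series(rng.uniform(0, 4, len(m.genes)), index=m.genes)
        for _ in range(8):
            x = m.step(x, kd=1.0)
            assert (x >= 0).all()

    def test_engine_matches_scalar_gene_regulation(self, bundle):
        """Vectorized per-gene flux equals the scalar reference path."""
        m = bundle.model
        x = bundle.x_init
        kd_val = 1.3
        # engine fluxes
        xa = m._as_state(x)
        frozen = m._frozen_from(x)
        KD = np.full((1, len(m.tfs)), kd_val)
        prom, body = m._flux_terms(xa[None, :], KD, KD.copy(), frozen)
        f_engine = np.maximum(prom - body, 0.0)[0]

        tf_gene = bundle.tf_table["gene_id"]
        state = {t: float(x[tf_gene[t]]) for t in m.tfs}
        kd_map = {t: kd_val for t in m.tfs}

        def sites_of(df, gene):
            out = {}
            for rec in df[df.gene_id == gene].itertuples(index=False):
                rep = rec.repressor_id if isinstance(rec.repressor_id, str) and rec.repressor_id else None
                sq = None if rep is None else float(rec.sq)
                out.setdefault(rec.tf_id, []).append(
                    BindingSite(rec.tf_id, gene, rec.offset, rec.strand, rec.sp, rep, sq)
                )
            return out

        for gi, gene in enumerate(m.genes[::7]):
            f_ref = gene_regulation(
                sites_of(bundle.promoter_profiles, gene),
                sites_of(bundle.gene_body_profiles, gene),
                state,
                kd_map,
                kd_map,
                m.params,
                repressor_only=m.repressor_only,
            )
            assert f_engine[m.genes.index(gene)] == pytest.approx(f_ref, abs=1e-10)

    def test_high_weighting_suppresses_weak_sites(self):
        """With a >= 20 only consensus sites contribute within 1e-8."""
        params = ModelParams(a=20, kc=1.0, d=0.5)
        rows_full = [
            ("gA", "TFA", 1, 1.0, None, None),
            ("gA", "TFA", 2, 0.5, None, None),
            ("gA", "TFA", 3, 0.45, None, None),
        ]
        rows_strong = [("gA", "TFA", 1, 1.0, None, None)]
        m_full = make_model(rows_full, tfs=("TFA",), params=params)
        m_strong = make_model(rows_strong, tfs=("TFA",), params=params)
        xa = m_full._as_state(pd.Series({"gA": 1.0}))
        KD = np.ones((1, 1))
        frozen = np.array([2.0])  # TFA concentration (frozen gene g_TFA)
        p_full, _ = m_full._flux_terms(xa[None, :], KD, KD, frozen)
        p_strong, _ = m_strong._flux_terms(xa[None, :], KD, KD, frozen)
        assert abs(p_full[0, 0] - p_strong[0, 0]) < 1e-8


class TestModelConstruction:
    def test_empty_promoters_rejected(self):
        tf_table = pd.DataFrame(
            {"tf_id": ["TFA"], "gene_id": ["gA"], "is_repressor_only": [False]}
        ).set_index("tf_id", drop=False)
        with pytest.raises(ValueError, match="empty"):
            TRNModel(pd.DataFrame(columns=PROFILE_COLUMNS), None, tf_table)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(a=-1)
        with pytest.raises(ValueError):
            ModelParams(d=-0.1)
        with pytest.raises(ValueError):
            ModelParams(p_max=5)
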