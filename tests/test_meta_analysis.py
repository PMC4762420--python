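"""Random-effects pooling: Fisher transform identities, DerSimonian-Laird
against an independent oracle (explicit formulas and statsmodels), Cochran Q
truncation and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prscog import (
    MetaStudy,
    PrscogError,
    fisher_z,
    random_effects_meta,
    run_meta_grid,
)


def dl_oracle(rs, ns, k_cov=0):
    """Independent DerSimonian-Laird implementation on the z scale."""
    z = np.arctanh(np.asarray(rs, dtype=float))
    v = 1.0 / (np.asarray(ns, dtype=float) - 3 - k_cov)
    w = 1 / v
    zbar = np.sum(w * z) / np.sum(w)
    Q = np.sum(w * (z - zbar) ** 2)
    m = len(z)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - (m - 1)) / c)
    ws = 1 / (v + tau2)
    pooled = np.sum(ws * z) / np.sum(ws)
    se = np.sqrt(1 / np.sum(ws))
    return pooled, se, tau2, Q


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        z, v = fisher_z(0.0, 103)
        assert z == 0.0
        assert v == pytest.approx(0.01)

    def test_closed_form_value(self):
        z, v = fisher_z(0.5, 103, k_cov=0)
        assert z == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert z == pytest.approx(0.5493, abs=1e-4)
        assert v == pytest.approx(0.01)

    def test_round_trip_identity(self):
        for r in (-0.9, -0.3, 0.0, 0.42, 0.99):
            z, _ = fisher_z(r, 50)
            assert np.tanh(z) == pytest.approx(r, abs=1e-12)

    def test_covariate_correction_in_variance(self):
        _, v = fisher_z(0.1, 108, k_cov=5)
        assert v == pytest.approx(1 / 100)

    def test_domain_errors(self):
        with pytest.raises(PrscogError):
            fisher_z(1.0, 100)
        with pytest.raises(PrscogError):
            fisher_z(0.5, 4, k_cov=2)


class TestRandomEffectsMeta:
    def test_identical_studies_are_homogeneous(self):
        studies = [MetaStudy(c, 0.23, 150) for c in ("a", "b", "c")]
        res = random_effects_meta(studies)
        assert res.Q == pytest.approx(0.0, abs=1e-12)
        assert res.tau2 == 0.0
        assert res.omnibus_r == pytest.approx(0.23, abs=1e-12)

    def test_three_study_fixture_matches_oracle(self):
        rs, ns = [0.1, 0.2, -0.05], [103, 203, 403]
        studies = [MetaStudy(f"c{i}", r, n) for i, (r, n) in enumerate(zip(rs, ns))]
        res = random_effects_meta(studies)
        pooled, se, tau2, Q = dl_oracle(rs, ns)
        assert res.omnibus_r == pytest.approx(np.tanh(pooled), abs=1e-10)
        assert res.se_z == pytest.approx(se, abs=1e-10)
        assert res.tau2 == pytest.approx(tau2, abs=1e-10)
        assert res.Q == pytest.approx(Q, abs=1e-10)
        assert res.p_Q == pytest.approx(sps.chi2.sf(Q, 2), abs=1e-10)

    def test_matches_statsmodels_combine_effects(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rs, ns = [0.15, -0.02, 0.30, 0.05], [120, 250, 80, 500]
        z = np.arctanh(rs)
        v = 1.0 / (np.asarray(ns) - 3)
        ref = combine_effects(z, v, method_re="dl")
        studies = [MetaStudy(f"c{i}", r, n) for i, (r, n) in enumerate(zip(rs, ns))]
        res = random_effects_meta(studies)
        frame = ref.summary_frame()
        assert res.tau2 == pytest.approx(ref.tau2, abs=1e-10)
        assert np.arctanh(res.omnibus_r) == pytest.approx(
            frame.loc["random effect", "eff"], abs=1e-10
        )

    def test_q_truncation_rule(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            rs = rng.uniform(-0.3, 0.3, size=3)
            ns = rng.integers(50, 500, size=3)
            studies = [MetaStudy(f"c{i}", r, int(n)) for i, (r, n) in enumerate(zip(rs, ns))]
            res = random_effects_meta(studies)
            if res.Q <= len(studies) - 1:
                assert res.tau2 == 0.0

    def test_pooled_within_study_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            rs = rng.uniform(-0.5, 0.5, size=4)
            studies = [MetaStudy(f"c{i}", r, 100) for i, r in enumerate(rs)]
            res = random_effects_meta(studies)
            z = np.arctanh(rs)
            assert z.min() - 1e-12 <= np.arctanh(res.omnibus_r) <= z.max() + 1e-12

    def test_fixed_effect_limit_when_tau2_zero(self):
        rs, ns = [0.1, 0.12, 0.11], [500, 600, 700]
        studies = [MetaStudy(f"c{i}", r, n) for i, (r, n) in enumerate(zip(rs, ns))]
        res = random_effects_meta(studies)
        assert res.tau2 == 0.0
        z = np.arctanh(rs)
        w = np.asarray(ns) - 3
        fe = np.sum(w * z) / np.sum(w)
        assert np.arctanh(res.omnibus_r) == pytest.approx(fe, abs=1e-12)

    def test_single_study_rejected(self):
        with pytest.raises(PrscogError):
            random_effects_meta([MetaStudy("a", 0.1, 100)])

    def test_raw_r_scale_option(self):
        rs, ns = [0.1, 0.3], [100, 200]
        studies = [MetaStudy(f"c{i}", r, n) for i, (r, n) in enumerate(zip(rs, ns))]
        res = random_effects_meta(studies, scale="r")
        assert min(rs) <= res.omnibus_r <= max(rs)


def _assoc_table(rng, scores, phenos, n):
    rows = []
    for s in scores:
        for ph in phenos:
            rows.append(
                {
                    "score": s,
                    "phenotype": ph,
                    "n": n,
                    "r": rng.uniform(-0.2, 0.2),
                    "p": rng.uniform(),
                    "df": n - 7,
                    "covariates": "nn,C1,C2,C3,C4",
                }
            )
    return pd.DataFrame(rows)


class TestRunMetaGrid:
    def test_three_cohorts_sixty_rows(self):
        rng = np.random.default_rng(5)
        scores = [f"PH{i}_p{t}" for i in range(4) for t in (0.8, 0.5, 0.1, 0.05, 0.01)]
        phenos = ["gf", "general", "crystallized"]
        tables = {
            c: _assoc_table(rng, scores, phenos, n)
            for c, n in (("c1", 900), ("c2", 450), ("c3", 5000))
        }
        out = run_meta_grid(tables, phenotypes=phenos)
        assert len(out) == 60
        assert (out["n_studies"] == 3).all()

    def test_single_cohort_gives_empty_output(self):
        rng = np.random.default_rng(6)
        tables = {"only": _assoc_table(rng, ["A_p0.5"], ["gf"], 500)}
        out = run_meta_grid(tables, phenotypes=["gf"])
        assert out.empty

    def test_common_sign_is_preserved(self):
        tables = {}
        for i, c in enumerate(("c1", "c2", "c3")):
            t = _assoc_table(np.random.default_rng(7 + i), ["A_p0.5"], ["gf"], 400)
            t["r"] = [-0.05 * (i + 1)]
            tables[c] = t
        out = run_meta_grid(tables, phenotypes=["gf"])
        assert (out["omnibus_r"] < 0).all()

    def test_per_cohort_phenotype_name_mapping(self):
        rng = np.random.default_rng(11)
        t1 = _assoc_table(rng, ["A_p0.5"], ["NART"], 400)
        t2 = _assoc_table(rng, ["A_p0.5"], ["MillHill"], 700)
        out = run_meta_grid(
            {"lbc": t1, "gs": t2},
            phenotypes={"crystallized": {"lbc": "NART", "gs": "MillHill"}},
        )
        assert len(out) == 1
        assert out.loc[0, "phenotype"] == "crystallized"


def test_q_calibration_homogeneous_quick():
    """Under homogeneity Q ~ chi-square(m-1): quick 500-rep check (the
    2,000-rep version runs in the acceptance suite)."""
    rng = np.random.default_rng(12)
    ns = [400, 800, 1500]
    crit = sps.chi2.ppf(0.95, 2)
    hits = 0
    reps = 500
    for _ in range(reps):
        z0 = 0.05
        zs = z0 + rng.standard_normal(3) / np.sqrt(np.asarray(ns) - 3)
        studies = [
            MetaStudy(f"c{i}", float(np.tanh(z)), n) for i, (z, n) in enumerate(zip(zs, ns))
        ]
        if random_effects_meta(studies).Q > crit:
            hits += 1
    assert 0.025 <= hits / reps <= 0.075
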