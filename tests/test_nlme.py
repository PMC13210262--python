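"""FOCEI engine: likelihood kernel, conditional modes, objective, fitting."""

import itertools

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss

from pedallo.growth import Subject
from pedallo.nlme import (
    EstimationSpec,
    SubjectRecords,
    _FoceiProblem,
    _NatParams,
    fit_nlme,
    focei_objective,
    individual_neg2ll,
    inner_ebe,
)
from pedallo.pk import (
    SCHEMES,
    DosingRegimen,
    EtaVector,
    IndividualPKParams,
    PKDataset,
    PopulationPKParams,
    SamplingScheme,
    conc_profile,
    simulate_dataset,
)


def direct_neg2ll(pop, eta, rec):
    """Independent transcription of the joint -2 log-density formula."""
    wr = rec.weight_kg / pop.ref_weight
    p = IndividualPKParams(
        v=pop.tv_v * np.exp(eta[0]) * wr**pop.exp_v,
        cl=pop.tv_cl * np.exp(eta[1]) * wr**pop.exp_cl,
        ka=pop.tv_ka * np.exp(eta[2]),
    )
    f = conc_profile(p, rec.dose_mg, rec.times)
    g2 = (pop.sigma_prop * f) ** 2
    total = 0.0
    for y, fi, g2i in zip(rec.dv, f, g2):
        total += np.log(2 * np.pi * g2i) + (y - fi) ** 2 / g2i
    om = pop.eta_cov()
    total += eta @ np.linalg.inv(om) @ eta
    total += np.log(np.linalg.det(2 * np.pi * om))
    return total


def toy_records(pop, weights=(15.0, 35.0, 60.0), seed=11, scheme="sparse"):
    subjects = [Subject(f"s{i}", "pediatric", 100, w) for i, w in enumerate(weights)]
    ds = simulate_dataset(subjects, DosingRegimen(), SCHEMES[scheme], pop, seed=seed)
    recs = []
    for sid in ds.df["ID"].unique():
        sub = ds.df[ds.df["ID"] == sid]
        obs = sub[sub["EVID"] == 0]
        recs.append(SubjectRecords(
            dose_mg=float(sub[sub["EVID"] == 1]["AMT"].iloc[0]),
            weight_kg=float(sub["WT"].iloc[0]),
            times=obs["TIME"].to_numpy(),
            dv=obs["DV"].to_numpy(),
        ))
    return ds, recs


def agh_neg2ll(dataset, pop, nodes=11):
    """Independent oracle: adaptive Gauss-Hermite marginal -2 log-likelihood."""
    prob = _FoceiProblem.from_dataset(dataset)
    p = _NatParams.from_population(pop)
    oinv, ld = prob._omega_terms(p)
    eta_hat, h_hat, H_hat, ok = prob.inner(
        p, np.zeros((prob.n, 3)), oinv, ld, gtol=1e-8, max_iter=200)
    assert ok
    zs, ws = hermgauss(nodes)
    grid = np.array(list(itertools.product(range(nodes), repeat=3)))
    z = zs[grid]                       # (K, 3)
    logw = np.log(ws)[grid].sum(axis=1) + (z**2).sum(axis=1)
    total = 0.0
    for i in range(prob.n):
        Sigma = 2 * np.linalg.inv(H_hat[i])
        A = np.linalg.cholesky(Sigma)
        etas = eta_hat[i] + np.sqrt(2.0) * z @ A.T
        hv = prob.h(p, etas[:, None, :], oinv, ld, rows=np.array([i]))[:, 0]
        log_integrand = logw - 0.5 * (hv - h_hat[i])
        m = log_integrand.max()
        acc = np.exp(m) * np.exp(log_integrand - m).sum()
        lnL = (-0.5 * h_hat[i] + 1.5 * np.log(2.0)
               + np.sum(np.log(np.diag(A))) + np.log(acc))
        total += -2.0 * lnL
    return total


class TestIndividualNeg2LL:
    def test_matches_direct_transcription(self, pop):
        _, recs = toy_records(pop, weights=(20.0, 55.0), scheme="peak_terminal_5")
        for rec in recs:
            for eta in (np.zeros(3), np.array([0.2, -0.3, 0.1])):
                mine = individual_neg2ll(pop, EtaVector(*eta), rec)
                assert mine == pytest.approx(direct_neg2ll(pop, eta, rec), rel=1e-10)

    def test_zero_residual_contribution_at_perfect_fit(self, pop):
        # one observation placed exactly on the eta=0 prediction
        w = 40.0
        p_typ = IndividualPKParams(18.0 * w / 70.0, (w / 70.0) ** 0.75, 0.9)
        f = conc_profile(p_typ, 2.0 * w, [14.0])[0]
        rec = SubjectRecords(dose_mg=2.0 * w, weight_kg=w, times=[14.0], dv=[f])
        om = pop.eta_cov()
        expected = (np.log(2 * np.pi * (pop.sigma_prop * f) ** 2)
                    + np.log(np.linalg.det(2 * np.pi * om)))
        assert individual_neg2ll(pop, EtaVector(), rec) == pytest.approx(expected)

    def test_prior_term_tracks_omega_logdet(self, pop):
        rec = SubjectRecords(dose_mg=80.0, weight_kg=40.0, times=[14.0], dv=[2.0])
        big = pop.with_(cv_v=4.0, cv_cl=4.0, cv_ka=4.0)
        diff = individual_neg2ll(big, EtaVector(), rec) - individual_neg2ll(pop, EtaVector(), rec)
        logdet_diff = (np.log(np.linalg.det(2 * np.pi * big.eta_cov()))
                       - np.log(np.linalg.det(2 * np.pi * pop.eta_cov())))
        assert diff == pytest.approx(logdet_diff, rel=1e-10)


class TestInnerEBE:
    def test_mode_matches_dense_grid_search(self, pop):
        _, recs = toy_records(pop, weights=(30.0,), seed=5)
        rec = recs[0]
        mode = inner_ebe(pop, rec).as_array()
        # 3-d grid oracle at 0.05 resolution around the origin
        axis = np.arange(-1.2, 1.2001, 0.05)
        grid = np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T
        vals = np.array([direct_neg2ll(pop, eta, rec) for eta in grid])
        best = grid[vals.argmin()]
        assert np.all(np.abs(mode - best) <= 0.05 + 1e-9)

    def test_noise_free_data_gives_near_zero_mode(self, pop, noise_free_pop):
        # data generated at eta=0 without residual error: the mode sits close
        # to zero, displaced only by the interaction term (the ln f^2 part of
        # the likelihood pulls predictions down at a scale ~ sigma)
        _, recs = toy_records(noise_free_pop, weights=(25.0,), seed=1,
                              scheme="peak_terminal_5")
        mode = inner_ebe(pop, recs[0]).as_array()
        assert np.all(np.abs(mode) < 0.1)

    def test_start_point_does_not_change_mode(self, pop):
        _, recs = toy_records(pop, weights=(50.0,), seed=8)
        a = inner_ebe(pop, recs[0], start_eta=EtaVector()).as_array()
        b = inner_ebe(pop, recs[0], start_eta=EtaVector(0.8, -0.8, 0.5)).as_array()
        assert np.all(np.abs(a - b) < 1e-4)


class TestFoceiObjective:
    def test_within_half_unit_of_quadrature(self, pop):
        ds, _ = toy_records(pop, seed=11)
        assert focei_objective(pop, ds) == pytest.approx(agh_neg2ll(ds, pop), abs=0.5)

    def test_quadrature_agreement_second_instance(self, pop):
        ds, _ = toy_records(pop, weights=(18.0, 42.0, 70.0), seed=23,
                            scheme="peak_terminal_5")
        assert focei_objective(pop, ds) == pytest.approx(agh_neg2ll(ds, pop), abs=0.5)

    def test_vanishing_omega_approaches_pooled_regression(self, pop):
        ds, recs = toy_records(pop, seed=2)
        tiny = pop.with_(cv_v=1e-3, cv_cl=1e-3, cv_ka=1e-3, corr_v_cl=0.0)
        pooled = 0.0  # fixed-effects -2LL at eta = 0
        for rec in recs:
            wr = rec.weight_kg / 70.0
            p = IndividualPKParams(18.0 * wr, wr**0.75, 0.9)
            f = conc_profile(p, rec.dose_mg, rec.times)
            g2 = (pop.sigma_prop * f) ** 2
            pooled += np.sum(np.log(2 * np.pi * g2) + (rec.dv - f) ** 2 / g2)
        assert focei_objective(tiny, ds) == pytest.approx(pooled, abs=0.05)

    def test_invariant_to_subject_order(self, pop):
        ds, _ = toy_records(pop, weights=(15.0, 35.0, 60.0), seed=4)
        obj = focei_objective(pop, ds)
        # rebuild with subjects permuted and IDs renumbered
        df = ds.df.copy()
        remap = {1: 3, 2: 1, 3: 2}
        df["ID"] = df["ID"].map(remap)
        df = df.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)
        assert focei_objective(pop, PKDataset(df)) == pytest.approx(obj, abs=1e-8)


class TestFitNLME:
    def test_noise_free_recovery(self, lms_table, noise_free_pop):
        # identifiability check: no IIV, no residual error, dense sampling,
        # wide weight range -> exact recovery of structure and exponents
        rng = np.random.default_rng(3)
        weights = rng.uniform(12.0, 70.0, size=50)
        cohort = [Subject(f"s{i}", "pediatric", 100, w) for i, w in enumerate(weights)]
        scheme = SamplingScheme("dense0", (1, 2, 4, 7, 14, 28, 42, 56), window_days=0.0)
        ds = simulate_dataset(cohort, DosingRegimen(), scheme, noise_free_pop, seed=0)
        fit = fit_nlme(ds, EstimationSpec(ftol=1e-12))
        assert fit.converged
        est = fit.estimates
        assert est["tv_v"] == pytest.approx(18.0, rel=1e-3)
        assert est["tv_cl"] == pytest.approx(1.0, rel=1e-3)
        assert est["tv_ka"] == pytest.approx(0.9, rel=1e-3)
        assert est["exp_v"] == pytest.approx(1.0, abs=1e-3)
        assert est["exp_cl"] == pytest.approx(0.75, abs=1e-3)

    def test_fixed_exponents_respected_and_nested_inequality(self, pop, lms_table):
        rng = np.random.default_rng(9)
        weights = rng.uniform(15.0, 65.0, size=14)
        cohort = [Subject(f"s{i}", "pediatric", 100, w) for i, w in enumerate(weights)]
        ds = simulate_dataset(cohort, DosingRegimen(), SCHEMES["peak_terminal_5"], pop,
                              seed=21)
        free = fit_nlme(ds, EstimationSpec(ftol=1e-12))
        fixed = fit_nlme(ds, EstimationSpec(estimate_exp_v=False, estimate_exp_cl=False,
                                            ftol=1e-12))
        assert fixed.estimates["exp_v"] == 1.0
        assert fixed.estimates["exp_cl"] == 0.75
        # the constrained optimum cannot beat the free one
        assert fixed.objective >= free.objective - 1e-6

    def test_fixing_exponents_stabilizes_other_estimates(self, lms_table):
        # on sparse, small-n, narrow-age data, holding the allometric
        # exponents at truth sharply reduces the replicate-to-replicate
        # spread of the typical-value estimates (the rationale for fixing
        # exponents in data-limited pediatric analyses)
        from pedallo.scenarios import ScenarioSpec, run_scenario

        free = ScenarioSpec("2-5", 20, "sparse", n_replicates=10, master_seed=42)
        fixed = free.with_(estimation=EstimationSpec(estimate_exp_v=False,
                                                     estimate_exp_cl=False))
        spreads = {}
        for name, spec in (("free", free), ("fixed", fixed)):
            res = run_scenario(spec, lms_table, keep_fits=True)
            cl = np.array([f.estimates["tv_cl"]
                           for f, r in zip(res.fits, res.replicates) if r.converged])
            spreads[name] = np.std(np.log(cl))
        assert spreads["fixed"] < spreads["free"]

    def test_ebes_shrink_toward_zero(self, pop):
        ds, _ = toy_records(pop, seed=13)
        fit = fit_nlme(ds)
        assert fit.ebes.shape == (3, 3)
        assert np.all(np.abs(fit.ebes) < 2.0)

    def test_non_convergence_is_flagged_not_raised(self, pop):
        # a 1-subject, 2-observation dataset cannot identify 10 parameters
        subjects = [Subject("s0", "pediatric", 100, 30.0)]
        scheme = SamplingScheme("two", (4, 28), window_days=0.0)
        ds = simulate_dataset(subjects, DosingRegimen(), scheme, pop, seed=0)
        spec = EstimationSpec(max_outer_iters=10, max_retries=1)
        fit = fit_nlme(ds, spec)  # must not raise
        assert isinstance(fit.converged, bool)
        assert fit.messages
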