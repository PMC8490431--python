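"""Tests for the two-round distributed protocol and surrogate likelihood."""

import numpy as np
import pytest

from odah import (
    DistributedHurdleRegressor,
    HurdleDataset,
    HurdleParams,
    InitialEstimates,
    SiteSummary,
    aggregate_gradients,
    compute_gradients,
    fit_hurdle,
    lead_initialize,
    logistic_gradient,
    meta_initialize,
    odah_solve,
    run_protocol,
    summarize_fit,
    surrogate_loglik,
    ztp_gradient,
)
from odah.baselines import concat_datasets
from odah.messages import (
    MessageError,
    gradient_from_dict,
    gradient_to_dict,
    init_from_dict,
    init_to_dict,
    summary_from_dict,
    summary_to_dict,
)

from conftest import make_dataset, make_multisite


def make_summary(site_id, beta, var, gamma=None, gvar=None, n=100):
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    var = np.atleast_1d(np.asarray(var, dtype=float))
    gamma = beta if gamma is None else np.atleast_1d(np.asarray(gamma, dtype=float))
    gvar = var if gvar is None else np.atleast_1d(np.asarray(gvar, dtype=float))
    return SiteSummary(
        site_id=site_id,
        n=n,
        n_pos=n // 2,
        beta_hat=beta,
        gamma_hat=gamma,
        beta_var_diag=var,
        gamma_var_diag=gvar,
    )


class TestMetaInitialize:
    def test_single_site_identity(self):
        s = make_summary("a", [1.0, -2.0], [0.5, 0.25])
        init = meta_initialize([s])
        assert np.allclose(init.beta_bar, [1.0, -2.0])
        assert init.source == "meta"

    def test_equal_weights_average(self):
        init = meta_initialize(
            [make_summary("a", [1.0], [2.0]), make_summary("b", [3.0], [2.0])]
        )
        assert init.beta_bar[0] == pytest.approx(2.0)

    def test_inverse_variance_weighting(self):
        # (2*1 + 0.5*2) / 2.5 = 1.2
        init = meta_initialize(
            [make_summary("a", [1.0], [0.5]), make_summary("b", [2.0], [2.0])]
        )
        assert init.beta_bar[0] == pytest.approx(1.2)

    def test_rejects_bad_variances_and_dims(self):
        with pytest.raises(ValueError):
            meta_initialize([make_summary("a", [1.0], [0.0])])
        with pytest.raises(ValueError, match="mismatched"):
            meta_initialize(
                [make_summary("a", [1.0], [1.0]), make_summary("b", [1.0, 2.0], [1.0, 1.0])]
            )

    def test_unconverged_sites_excluded(self):
        good = make_summary("a", [1.0], [1.0])
        bad = make_summary("b", [50.0], [1.0])
        bad.converged_ztp = False
        init = meta_initialize([good, bad])
        # logistic still pools both; ZTP uses only the converged site
        assert init.beta_bar[0] == pytest.approx(25.5)
        assert init.gamma_bar[0] == pytest.approx(1.0)
        bad.converged_logistic = False
        good.converged_logistic = False
        with pytest.raises(ValueError, match="no converged logistic"):
            meta_initialize([good, bad])


class TestLeadInitialize:
    def test_identity_and_unconverged_rejection(self, dataset):
        fit = fit_hurdle(dataset)
        init = lead_initialize(fit)
        assert np.array_equal(init.beta_bar, fit.params.beta)
        assert init.source == "lead"
        fit.converged = False
        with pytest.raises(ValueError, match="converge"):
            lead_initialize(fit)


class TestComputeGradients:
    def test_duplication_leaves_averages_unchanged(self, dataset):
        init = InitialEstimates(np.zeros(dataset.p), np.zeros(dataset.q))
        payload = compute_gradients(dataset, init)
        doubled = HurdleDataset(
            y=np.concatenate([dataset.y, dataset.y]),
            X=np.vstack([dataset.X, dataset.X]),
            Z=np.vstack([dataset.Z, dataset.Z]),
        )
        payload2 = compute_gradients(doubled, init)
        assert payload2.n == 2 * payload.n
        assert np.allclose(payload.grad1_logistic, payload2.grad1_logistic)
        assert np.allclose(payload.hess_ztp, payload2.hess_ztp)

    def test_average_gradient_matches_finite_differences(self, dataset):
        from odah.hurdle import logistic_loglik, ztp_loglik

        init = InitialEstimates(
            np.array([0.2, -0.1, 0.3]), np.array([-0.2, 0.1, 0.0])
        )
        payload = compute_gradients(dataset, init)
        h = 1e-6
        for k in range(dataset.p):
            e = np.zeros(dataset.p)
            e[k] = h
            fd = (
                logistic_loglik(init.beta_bar + e, dataset)
                - logistic_loglik(init.beta_bar - e, dataset)
            ) / (2 * h * dataset.n)
            assert payload.grad1_logistic[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)
        for k in range(dataset.q):
            e = np.zeros(dataset.q)
            e[k] = h
            fd = (
                ztp_loglik(init.gamma_bar + e, dataset)
                - ztp_loglik(init.gamma_bar - e, dataset)
            ) / (2 * h * dataset.n_pos)
            assert payload.grad1_ztp[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_site_without_positive_counts_flags_ztp_absent(self):
        ones = np.ones((20, 1))
        x = np.random.default_rng(0).normal(size=20)
        X = np.column_stack([np.ones(20), x])
        data = HurdleDataset(y=np.zeros(20), X=X, Z=X)
        init = InitialEstimates(np.zeros(2), np.zeros(2))
        payload = compute_gradients(data, init)
        assert payload.grad1_ztp is None and payload.hess_ztp is None
        assert payload.n_pos == 0


class TestAggregateGradients:
    def test_single_payload_identity(self, dataset):
        init = InitialEstimates(np.zeros(dataset.p), np.zeros(dataset.q))
        payload = compute_gradients(dataset, init)
        agg = aggregate_gradients([payload])
        assert np.array_equal(agg.grad1_logistic, payload.grad1_logistic)
        assert np.array_equal(agg.hess_ztp, payload.hess_ztp)

    def test_weighted_average_matches_pooled_gradient(self):
        sizes = (100, 200, 700)
        datasets = [
            make_dataset(300 + j, n=n, site_id=f"s{j}") for j, n in enumerate(sizes)
        ]
        init = InitialEstimates(
            np.array([0.1, -0.2, 0.05]), np.array([-0.1, 0.2, 0.1])
        )
        agg = aggregate_gradients([compute_gradients(d, init) for d in datasets])
        pooled = concat_datasets(datasets)
        g1 = logistic_gradient(init.beta_bar, pooled) / pooled.n
        g2 = ztp_gradient(init.gamma_bar, pooled) / pooled.n_pos
        assert np.allclose(agg.grad1_logistic, g1, atol=1e-12)
        assert np.allclose(agg.grad1_ztp, g2, atol=1e-12)

    def test_differing_evaluation_points_rejected(self, multisite):
        init_a = InitialEstimates(np.zeros(3), np.zeros(3))
        init_b = InitialEstimates(np.full(3, 0.1), np.zeros(3))
        payloads = [
            compute_gradients(multisite[0], init_a),
            compute_gradients(multisite[1], init_b),
        ]
        with pytest.raises(ValueError, match="evaluation points differ"):
            aggregate_gradients(payloads)


class TestSurrogate:
    def test_gradient_at_init_equals_aggregated_gradient(self, multisite):
        fits = [fit_hurdle(d) for d in multisite]
        init = meta_initialize([summarize_fit(f, d) for f, d in zip(fits, multisite)])
        agg = aggregate_gradients([compute_gradients(d, init) for d in multisite])
        lead = multisite[0]
        # analytic surrogate gradient at the expansion point
        g_lead = logistic_gradient(init.beta_bar, lead) / lead.n
        sur_grad = g_lead + (agg.grad1_logistic - g_lead)
        assert np.allclose(sur_grad, agg.grad1_logistic, atol=1e-15)
        # numerically: directional finite differences of the surrogate
        h = 1e-7
        for k in range(lead.p):
            e = np.zeros(lead.p)
            e[k] = h
            up = surrogate_loglik(
                HurdleParams(init.beta_bar + e, init.gamma_bar), lead, agg, init
            )[0]
            dn = surrogate_loglik(
                HurdleParams(init.beta_bar - e, init.gamma_bar), lead, agg, init
            )[0]
            assert (up - dn) / (2 * h) == pytest.approx(
                agg.grad1_logistic[k], rel=5e-4, abs=1e-6
            )

    def test_single_site_corrections_vanish(self, dataset):
        from odah.hurdle import logistic_loglik, ztp_loglik

        fit = fit_hurdle(dataset)
        init = lead_initialize(fit)
        agg = aggregate_gradients([compute_gradients(dataset, init)])
        theta = HurdleParams(fit.params.beta + 0.05, fit.params.gamma - 0.05)
        l1, l2 = surrogate_loglik(theta, dataset, agg, init)
        assert l1 == pytest.approx(
            logistic_loglik(theta.beta, dataset) / dataset.n, abs=1e-12
        )
        assert l2 == pytest.approx(
            ztp_loglik(theta.gamma, dataset) / dataset.n_pos, abs=1e-12
        )


class TestOdahSolve:
    def test_single_site_reduces_to_lead_mle(self, dataset):
        fit = fit_hurdle(dataset)
        init = lead_initialize(fit)
        agg = aggregate_gradients([compute_gradients(dataset, init)])
        result = odah_solve(dataset, agg, init)
        assert np.allclose(result.params.beta, fit.params.beta, atol=1e-8)
        assert np.allclose(result.params.gamma, fit.params.gamma, atol=1e-8)
        # covariance equals the local observed-information covariance
        assert np.allclose(result.beta_var, fit.beta_var, rtol=1e-6)
        assert np.allclose(result.gamma_var, fit.gamma_var, rtol=1e-6)

    def test_lead_holding_everything_reduces_to_pooled(self, multisite):
        pooled_data = concat_datasets(multisite)
        pooled = fit_hurdle(pooled_data)
        # lead holds all rows; collaborators exist but are empty
        empty = HurdleDataset(
            y=np.zeros(0),
            X=np.zeros((0, 3)),
            Z=np.zeros((0, 3)),
            site_id="empty",
        )
        init = meta_initialize(
            [summarize_fit(fit_hurdle(d), d) for d in multisite]
        )
        payloads = [compute_gradients(pooled_data, init)] + [
            compute_gradients(empty, init) for _ in range(2)
        ]
        agg = aggregate_gradients(payloads)
        result = odah_solve(pooled_data, agg, init)
        assert np.allclose(result.params.beta, pooled.params.beta, atol=1e-8)
        assert np.allclose(result.params.gamma, pooled.params.gamma, atol=1e-8)

    def test_non_concave_surrogate_raises_with_eigenvalue(self, dataset):
        fit = fit_hurdle(dataset)
        init = lead_initialize(fit)
        agg = aggregate_gradients([compute_gradients(dataset, init)])
        # corrupt the correction so the corrected Hessian is indefinite
        agg.hess_logistic = agg.hess_logistic + 10.0 * np.eye(dataset.p)
        with pytest.raises(ValueError, match="eigenvalue"):
            odah_solve(dataset, agg, init)

    def test_variance_scale_matches_pooled_information(self, multisite):
        # with homogeneous sites the ODAH covariance should approximate the
        # pooled-fit covariance
        fits = [fit_hurdle(d) for d in multisite]
        init = meta_initialize([summarize_fit(f, d) for f, d in zip(fits, multisite)])
        agg = aggregate_gradients([compute_gradients(d, init) for d in multisite])
        result = odah_solve(multisite[0], agg, init)
        pooled = fit_hurdle(concat_datasets(multisite))
        assert np.allclose(
            np.diag(result.beta_var), np.diag(pooled.beta_var), rtol=0.3
        )
        assert np.allclose(
            np.diag(result.gamma_var), np.diag(pooled.gamma_var), rtol=0.3
        )


class TestProtocolDriver:
    def test_one_shot_message_counts(self, multisite):
        _, transcript = run_protocol(multisite, initializer="meta")
        assert all(c == 2 for c in transcript["messages_per_site"].values())
        _, transcript = run_protocol(multisite, initializer="lead")
        assert all(c == 1 for c in transcript["messages_per_site"].values())

    def test_meta_and_lead_paths_agree_on_homogeneous_data(self, multisite):
        res_meta, _ = run_protocol(multisite, initializer="meta")
        res_lead, _ = run_protocol(multisite, initializer="lead")
        se = np.sqrt(np.diag(res_meta.beta_var))
        assert np.all(
            np.abs(res_meta.params.beta - res_lead.params.beta) < 3 * se
        )

    def test_distributed_regressor_wrapper(self, multisite):
        fits = [fit_hurdle(d) for d in multisite]
        init = meta_initialize([summarize_fit(f, d) for f, d in zip(fits, multisite)])
        agg = aggregate_gradients([compute_gradients(d, init) for d in multisite])
        lead = multisite[0]
        est = DistributedHurdleRegressor().fit(
            lead.X[:, 1:], lead.y, aggregated=agg, init=init
        )
        direct = odah_solve(lead, agg, init)
        assert np.allclose(est.beta_, direct.params.beta)
        assert np.allclose(est.gamma_, direct.params.gamma)


class TestMessages:
    def test_roundtrips_are_bit_exact(self, multisite):
        fit = fit_hurdle(multisite[0])
        summary = summarize_fit(fit, multisite[0])
        back = summary_from_dict(
            __import__("json").loads(
                __import__("json").dumps(summary_to_dict(summary))
            )
        )
        assert np.array_equal(back.beta_hat, summary.beta_hat)
        assert np.array_equal(back.gamma_var_diag, summary.gamma_var_diag)

        init = lead_initialize(fit)
        back_init = init_from_dict(init_to_dict(init))
        assert np.array_equal(back_init.beta_bar, init.beta_bar)

        payload = compute_gradients(multisite[1], init)
        back_p = gradient_from_dict(gradient_to_dict(payload))
        assert np.array_equal(back_p.grad1_logistic, payload.grad1_logistic)
        assert np.array_equal(back_p.hess_ztp, payload.hess_ztp)
        assert np.array_equal(
            back_p.evaluated_at.gamma_bar, payload.evaluated_at.gamma_bar
        )

    def test_validation_fails_loudly(self):
        with pytest.raises(MessageError, match="missing key"):
            summary_from_dict({"site_id": "a"})
        with pytest.raises(MessageError, match="matrix"):
            gradient_from_dict(
                {
                    "site_id": "a",
                    "n": 10,
                    "n_pos": 5,
                    "evaluated_at": {"beta_bar": [0.0], "gamma_bar": [0.0]},
                    "grad1_logistic": [0.0],
                    "hess_logistic": [[0.0], [0.0]],
                    "grad1_ztp": [0.0],
                    "hess_ztp": [[0.0]],
                }
            )

    def test_privacy_contract_bounded_payload_dimensions(self, multisite):
        """No serialized message may contain anything but fixed-dimension
        aggregates: vectors no longer than the coefficient dimension and
        matrices no larger than its square -- never n-length data."""
        lead = multisite[0]
        p, q = lead.p, lead.q
        fit = fit_hurdle(lead)
        summary_doc = summary_to_dict(summarize_fit(fit, lead))
        init = lead_initialize(fit)
        payload_doc = gradient_to_dict(compute_gradients(lead, init))

        def walk(node):
            if isinstance(node, dict):
                for v in node.values():
                    yield from walk(v)
            elif isinstance(node, list):
                yield node
                for v in node:
                    yield from walk(v)

        for doc in (summary_doc, payload_doc):
            float_count = 0
            for arr in walk(doc):
                assert len(arr) <= max(p, q), "array longer than coefficient dim"
                float_count += sum(1 for v in arr if isinstance(v, float))
            assert float_count <= (p + q) ** 2 + (p + q) * 4
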