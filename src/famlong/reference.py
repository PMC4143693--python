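"""Brute-force reference implementations used for validation.

Each routine here recomputes a quantity the main code paths obtain by a
faster or more structured algorithm, using a deliberately literal method:

* :func:`step1_fullvec` — the step-1 variance regression built exactly as a
  full-vectorization GLS with an explicit Kronecker weight ``V^-1 (x) V^-1``
  (the engine uses the equivalent trace form and never forms the Kronecker
  product);
* :func:`ml_fit` — direct numerical maximization of the exact multivariate
  normal log-likelihood (profile likelihood over the covariance
  coefficients, closed-form GLS for the fixed effects);
* :func:`gene_dropping_kinship` — Monte-Carlo identity-by-descent sharing
  down a pedigree, an independent estimate of kinship coefficients.

They are validation tools, not the implementation: slow, dense, and
restricted to small problems.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .covariance import CovarianceDesign, assemble_V
from .igls import LongitudinalData, igls_step_beta
from .pedigree import Pedigree

__all__ = ["step1_fullvec", "ml_fit", "gene_dropping_kinship"]


def step1_fullvec(
    data: LongitudinalData,
    beta: np.ndarray,
    design: CovarianceDesign,
    V,
    *,
    basis: str = "est",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Literal full-vec GLS for the variance step.

    Builds, per family, the n^2 x p design ``X* = [vec(S_1) ... vec(S_p)]``
    and the n^2 x n^2 weight ``W = V^-1 (x) V^-1`` explicitly, accumulates
    ``M = X*'WX*`` and ``b = X*'W vec(r r')`` over families, and solves by
    minimum-norm least squares (the five-component basis is exactly rank
    deficient because the serial diagonal matrix equals the identity; the
    pseudoinverse solution splits their shared coefficient equally, which is
    the engine's reporting convention).

    ``basis`` selects the component set: ``"est"`` (reduced identifiable) or
    ``"full"`` (the printed five matrices).
    """
    layout = data.layout
    resid = data.y - data.X @ beta
    get = design.est_matrices if basis == "est" else design.full_matrices
    p = len(get(0))
    M = np.zeros((p, p))
    b = np.zeros(p)
    for k, fid in enumerate(layout.families):
        sl = layout.family_slices[fid]
        r_k = resid[sl]
        n = sl.stop - sl.start
        Vinv = V.solve(k, np.eye(n))
        W = np.kron(Vinv, Vinv)
        Xstar = np.column_stack([S.reshape(-1) for S in get(k)])
        ystar = np.outer(r_k, r_k).reshape(-1)
        M += Xstar.T @ W @ Xstar
        b += Xstar.T @ W @ ystar
    theta, *_ = np.linalg.lstsq(M, b, rcond=None)
    return M, b, theta


def _neg_profile_loglik(
    theta: np.ndarray, data: LongitudinalData, design: CovarianceDesign
) -> tuple[float, np.ndarray]:
    """-log L profiled over beta, with its analytic gradient in theta.

    At the profiling optimum the beta-dependence drops out of the gradient
    (envelope theorem):  dl/dtheta_r = -0.5 tr(V^-1 S_r)
    + 0.5 r' V^-1 S_r V^-1 r  with r the GLS residual.
    """
    V = assemble_V(design, theta)
    if not V.all_pd:
        return np.inf, np.zeros_like(theta)
    beta, _ = igls_step_beta(data, V)
    resid = data.y - data.X @ beta
    layout = data.layout
    p = len(theta)
    ll = -0.5 * layout.n_obs * np.log(2.0 * np.pi)
    grad = np.zeros(p)
    for k, fid in enumerate(layout.families):
        sl = layout.family_slices[fid]
        r_k = resid[sl]
        w = V.solve(k, r_k)
        ll -= 0.5 * (V.logdet(k) + r_k @ w)
        mats = design.est_matrices(k)
        n = sl.stop - sl.start
        Vinv = V.solve(k, np.eye(n))
        for r in range(p):
            grad[r] += -0.5 * np.sum(Vinv * mats[r].T) + 0.5 * (w @ mats[r] @ w)
    return -ll, -grad


def ml_fit(
    data: LongitudinalData,
    design: CovarianceDesign,
    start: np.ndarray | None = None,
) -> dict:
    """Maximize the exact multivariate-normal log-likelihood numerically.

    Works in the identifiable covariance basis (profile likelihood with
    analytic gradient, quasi-Newton iterations), then reports the five
    printed components through the same convention as the engine.  Returns a
    dict with ``beta``, ``theta_est``, ``vc``, ``loglik``, ``success``.
    """
    if start is None:
        beta0, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
        resid = data.y - data.X @ beta0
        s2 = float(resid @ resid) / len(resid)
        start = np.zeros(len(design.est_names))
        names = design.est_names
        i_var = names.index("within_variance" if design.serial else "sigma_e2")
        start[i_var] = 0.5 * s2
        start[names.index("sigma_u2")] = 0.2 * s2
        start[names.index("sigma_g2")] = 0.3 * s2
    res = minimize(
        _neg_profile_loglik, start, args=(data, design), jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-10},
    )
    # polish from the solution; cheap and tightens the gradient norm
    res2 = minimize(
        _neg_profile_loglik, res.x, args=(data, design), jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-12},
    )
    best = res2 if res2.fun <= res.fun else res
    theta = best.x
    V = assemble_V(design, theta)
    beta, cov_beta = igls_step_beta(data, V)
    vc, _ = design.expand(theta)
    return {
        "beta": beta,
        "cov_beta": cov_beta,
        "theta_est": theta,
        "vc": vc,
        "loglik": -float(best.fun),
        "success": bool(best.success),
    }


def gene_dropping_kinship(
    ped: Pedigree,
    family_id: str,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo kinship estimate by gene dropping.

    Founders carry unique allele labels; alleles are transmitted down the
    pedigree, one uniformly chosen per parent and replicate.  The kinship
    coefficient phi(a, b) is estimated as the probability that one allele
    sampled from each individual is identical by descent, i.e. the mean over
    replicates of the fraction of the four allele pairings that match.

    Returns ``(phi_hat, se)`` in the family's member order.
    """
    rng = np.random.default_rng(seed)
    members = ped.members(family_id)
    order = ped.topological_order(family_id)
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    label = 0
    for iid in order:
        rec = ped.record(family_id, iid)
        inherited = []
        for parent in (rec.father_id, rec.mother_id):
            if parent is None:
                inherited.append(np.full(n_replicates, label, dtype=np.int32))
                label += 1
            else:
                pa, pb = alleles[parent]
                pick = rng.integers(0, 2, size=n_replicates)
                inherited.append(np.where(pick == 0, pa, pb))
        alleles[iid] = (inherited[0], inherited[1])
    n = len(members)
    phi_hat = np.zeros((n, n))
    se = np.zeros((n, n))
    for i in range(n):
        ai = alleles[members[i]]
        for j in range(i, n):
            aj = alleles[members[j]]
            share = np.zeros(n_replicates)
            for x in ai:
                for z in aj:
                    share += (x == z).astype(float)
            share /= 4.0
            phi_hat[i, j] = phi_hat[j, i] = share.mean()
            se[i, j] = se[j, i] = share.std(ddof=1) / np.sqrt(n_replicates)
    return phi_hat, se
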