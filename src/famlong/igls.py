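"""Iterative generalized least squares (IGLS) for the three-level model.

The estimator alternates two steps until convergence:

* step 1 — given the fixed effects, regress the residual cross-products on
  the known covariance component matrices by generalized least squares with
  weight ``V^-1 (x) V^-1``; computed in the algebraically equivalent trace
  form ``M[r,s] = sum_k tr(V_k^-1 S_rk V_k^-1 S_sk)``,
  ``b[r] = sum_k r_k' V_k^-1 S_rk V_k^-1 r_k``, never materializing a
  Kronecker product;
* step 2 — given V, weighted least squares for the fixed effects,
  ``beta = (X'V^-1 X)^-1 X'V^-1 y`` accumulated per family block.

The fixed point of the iteration solves the Gaussian maximum-likelihood
score equations, so the converged estimate is the ML estimate.  Association
is tested per coefficient with a Wald Z statistic and a two-sided normal
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariance import (
    CovarianceDesign,
    ObservationLayout,
    VAssembly,
    VarianceComponents,
    assemble_V,
    build_components,
    build_layout,
)
from .pedigree import KinshipMatrix, Pedigree, kinship_matrices

__all__ = [
    "CollinearityError",
    "LongitudinalData",
    "FitResult",
    "longitudinal_data_from_table",
    "igls_step_variance",
    "igls_step_beta",
    "fit_igls",
    "assoc_scan",
    "write_assoc",
    "read_assoc",
]

ASSOC_COLUMNS = [
    "snv_id", "beta", "se", "z", "p",
    "sigma_u2", "sigma_g2", "sigma_v2", "rho", "sigma_e2",
    "n_iter", "converged", "reason",
]


class CollinearityError(ValueError):
    """Exactly collinear covariance components or design columns."""


@dataclass
class LongitudinalData:
    """Response vector and fixed-effect design aligned with a canonical
    observation layout.  Rows with missing response/covariates are dropped
    before layout construction; ``n_dropped`` reports how many."""

    layout: ObservationLayout
    y: np.ndarray
    X: np.ndarray
    x_names: tuple[str, ...]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.y) != self.layout.n_obs or self.X.shape[0] != self.layout.n_obs:
            raise ValueError("y/X not aligned with layout")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("missing values in y or X after row filtering")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise CollinearityError(
                f"design matrix rank-deficient; columns {self.x_names}"
            )

    def with_column(self, name: str, values: np.ndarray, position: int = 1) -> "LongitudinalData":
        """Return a copy with an extra fixed-effect column inserted."""
        X = np.insert(self.X, position, values, axis=1)
        names = list(self.x_names)
        names.insert(position, name)
        return LongitudinalData(self.layout, self.y, X, tuple(names), self.n_dropped)


def longitudinal_data_from_table(
    table: pd.DataFrame,
    ped: Pedigree,
    *,
    response: str = "y",
    covariates: Sequence[str] = (),
    family_col: str = "FID",
    individual_col: str = "IID",
    visit_col: str = "visit",
) -> LongitudinalData:
    """Build :class:`LongitudinalData` from a long-format phenotype table.

    An intercept column is always included; covariate columns are appended
    after it in the order given.
    """
    cols = [family_col, individual_col, visit_col, response, *covariates]
    df = table[cols].copy()
    n0 = len(df)
    df = df.dropna()
    n_dropped = n0 - len(df)
    layout = build_layout(df, ped, family_col=family_col,
                          individual_col=individual_col, visit_col=visit_col)
    df["_fam"] = df[family_col].astype(str)
    df["_ind"] = df[individual_col].astype(str)
    df["_vis"] = df[visit_col]
    merged = layout.rows.merge(
        df, left_on=["family", "individual", "visit"],
        right_on=["_fam", "_ind", "_vis"], how="left", validate="one_to_one",
    )
    y = merged[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(merged))] + [merged[c].to_numpy(dtype=float) for c in covariates]
    )
    return LongitudinalData(layout, y, X, ("intercept", *covariates), n_dropped)


@dataclass
class FitResult:
    """Converged IGLS estimate.

    ``est`` holds the identifiable covariance coefficients (the basis the
    step-1 regression actually solves); ``vc`` reports the five printed
    components via the documented minimum-norm split of the within-individual
    variance.
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    vc: VarianceComponents
    z: np.ndarray
    p: np.ndarray
    n_iter: int
    converged: bool
    history: list[dict]
    n_obs: int
    n_families: int
    x_names: tuple[str, ...]
    est: dict[str, float]
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _identity_theta(design: CovarianceDesign) -> np.ndarray:
    """Estimation-basis coefficients assembling V = I (IGLS bootstrap)."""
    theta = np.zeros(len(design.est_names))
    theta[design.est_names.index("within_variance" if design.serial else "sigma_e2")] = 1.0
    return theta


def _residuals(data: LongitudinalData, beta: np.ndarray) -> np.ndarray:
    return data.y - data.X @ beta


def _normal_equations(
    data: LongitudinalData,
    beta: np.ndarray,
    design: CovarianceDesign,
    V: VAssembly,
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate the step-1 GLS normal equations in the estimable basis."""
    layout = data.layout
    p = len(design.est_names)
    M = np.zeros((p, p))
    b = np.zeros(p)
    resid = _residuals(data, beta)
    for k, fid in enumerate(layout.families):
        sl = layout.family_slices[fid]
        r_k = resid[sl]
        mats = design.est_matrices(k)
        w = V.solve(k, r_k)
        T = [V.solve(k, S) for S in mats]
        for r in range(p):
            b[r] += w @ mats[r] @ w
            for s in range(r, p):
                val = float(np.sum(T[r] * T[s].T))
                M[r, s] += val
                if s != r:
                    M[s, r] += val
    return M, b


def _solve_normalized(M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least-squares solve of the diagonally normalized system; invariant to
    the very different natural scales of the components and stable when V
    sits close to the PD boundary (M nearly rank one)."""
    d = np.sqrt(np.diag(M))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = M / np.outer(d, d)
    x, *_ = np.linalg.lstsq(corr, b / d, rcond=None)
    return x / d


def _solve_nonneg_active_set(
    M: np.ndarray,
    b: np.ndarray,
    nonneg: list[int],
    active: set[int] | None = None,
) -> tuple[np.ndarray, set[int]]:
    """Solve the normal equations with selected coordinates constrained to
    be non-negative, by zeroing the active (negative) set and re-solving.
    ``active`` seeds coordinates already pinned at zero; the final active
    set is returned with the solution."""
    p = len(b)
    active = set() if active is None else set(active)
    theta = np.zeros(p)
    for _ in range(p + 1):
        idx = [i for i in range(p) if i not in active]
        theta = np.zeros(p)
        if not idx:
            break
        sub = np.ix_(idx, idx)
        theta[idx] = _solve_normalized(M[sub], b[idx])
        neg = [i for i in idx if i in nonneg and theta[i] < 0]
        if not neg:
            break
        active.update(neg)
    return theta, active


def _step_variance_est(
    data: LongitudinalData,
    beta: np.ndarray,
    design: CovarianceDesign,
    V: VAssembly,
) -> np.ndarray:
    """Solve the step-1 GLS normal equations in the estimable basis."""
    _check_structural_collinearity(design)
    M, b = _normal_equations(data, beta, design, V)
    return _solve_normalized(M, b)


def _check_structural_collinearity(design: CovarianceDesign) -> None:
    """Raise when the layout cannot separate two (already reduced)
    components, e.g. all-singleton single-visit families where the family,
    polygenic and error matrices coincide.  The check uses the unweighted
    Frobenius Gram of the component matrices, so it is a property of the
    design, independent of the current V."""
    p = len(design.est_names)
    G = np.zeros((p, p))
    for k in range(len(design.matrices)):
        mats = design.est_matrices(k)
        for r in range(p):
            for s in range(r, p):
                G[r, s] += float(np.sum(mats[r] * mats[s]))
                G[s, r] = G[r, s]
    d = np.sqrt(np.diag(G))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = G / np.outer(d, d)
    pairs = [
        (design.est_names[r], design.est_names[s])
        for r in range(p)
        for s in range(r + 1, p)
        if not np.isfinite(corr[r, s]) or abs(abs(corr[r, s]) - 1.0) < 1e-12
    ]
    if np.any(d == 0) or pairs or np.linalg.matrix_rank(corr, tol=1e-10) < p:
        raise CollinearityError(
            "step-1 normal equations singular; confounded components: "
            f"{pairs or design.est_names}"
        )


def igls_step_variance(
    data: LongitudinalData,
    beta: np.ndarray,
    design: CovarianceDesign,
    V: VAssembly,
) -> tuple[VarianceComponents, float]:
    """One step-1 update: raw (unclamped) variance components and the raw
    within-individual covariance coefficient rho*sigma_v2."""
    theta = _step_variance_est(data, beta, design, V)
    vc, _ = design.expand(theta)
    rho_sigma_v2 = float(theta[design.est_names.index("rho_sigma_v2")]) if design.serial else 0.0
    return vc, rho_sigma_v2


def igls_step_beta(
    data: LongitudinalData, V: VAssembly
) -> tuple[np.ndarray, np.ndarray]:
    """One step-2 update: weighted least squares accumulated per family."""
    layout = data.layout
    q = data.X.shape[1]
    XtViX = np.zeros((q, q))
    XtViy = np.zeros(q)
    for k, fid in enumerate(layout.families):
        sl = layout.family_slices[fid]
        Xk = data.X[sl]
        ViX = V.solve(k, Xk)
        XtViX += Xk.T @ ViX
        XtViy += ViX.T @ data.y[sl]
    # scale-invariant rank check (raw cond reflects column units, not rank);
    # near-singular but full-rank systems (V close to the PD boundary) are
    # solved by least squares on the diagonally normalized system
    d = np.sqrt(np.diag(XtViX))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = XtViX / np.outer(d, d)
    exact_dup = any(
        abs(abs(corr[i, j]) - 1.0) < 1e-12
        for i in range(q) for j in range(i + 1, q)
    )
    if np.any(d == 0) or not np.isfinite(corr).all() or exact_dup:
        u, s, vt = np.linalg.svd(XtViX)
        dep = [data.x_names[i] for i in np.argsort(np.abs(vt[-1]))[::-1][:2]]
        raise CollinearityError(f"X'V^-1X rank-deficient; dependent columns {dep}")
    corr_inv = np.linalg.pinv(corr, rcond=1e-14)
    cov_beta = corr_inv / np.outer(d, d)
    beta = cov_beta @ XtViy
    return beta, 0.5 * (cov_beta + cov_beta.T)


def _clamp_est(
    theta: np.ndarray, design: CovarianceDesign, n_visits_max: int, mode: str
) -> np.ndarray:
    if mode == "allow":
        return theta
    if mode != "truncate":
        raise ValueError(f"unknown clamp_mode {mode!r}")
    theta = theta.copy()
    names = design.est_names
    for i, name in enumerate(names):
        if name in ("sigma_u2", "sigma_g2", "sigma_e2", "within_variance"):
            theta[i] = max(theta[i], 0.0)
    if design.serial:
        i_c2 = names.index("rho_sigma_v2")
        i_w = names.index("within_variance")
        sigma_v2 = theta[i_w] / 2.0
        lo = -1.0 / (n_visits_max - 1) if n_visits_max > 1 else -1.0
        eps = 1e-8
        lo_c2, hi_c2 = (lo + eps) * sigma_v2, (1.0 - eps) * sigma_v2
        theta[i_c2] = min(max(theta[i_c2], lo_c2), hi_c2) if sigma_v2 > 0 else 0.0
    return theta


def fit_igls(
    data: LongitudinalData,
    design: CovarianceDesign,
    *,
    max_iter: int = 50,
    tol: float = 1e-6,
    clamp_mode: str = "truncate",
) -> FitResult:
    """Fit the model by alternating steps 1 and 2 until the maximum relative
    change over all parameters drops below ``tol``.

    Iteration 0 takes the fixed effects from ordinary least squares and uses
    identity weights for the first variance step.  Step-1 solutions with
    negative variances are legitimate least-squares values and are kept
    during iteration; clamping (per ``clamp_mode``) happens only at
    finalization.  A non-PD V candidate triggers step-halving back toward the
    previous admissible point (at most 10 halvings).
    """
    X, y = data.X, data.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    theta = _identity_theta(design)
    V = assemble_V(design, theta)
    resid0 = y - X @ beta
    s2_0 = float(resid0 @ resid0) / max(len(y) - X.shape[1], 1)
    cov_beta = s2_0 * np.linalg.inv(X.T @ X)  # provisional; replaced in the loop
    history: list[dict] = []
    converged = False
    pd_failure = False
    n_iter = 0
    # a candidate is accepted only if every family block is PD and safely
    # conditioned; V drifting onto the PD boundary would make the GLS
    # weights, and with them the whole iteration, numerically meaningless
    def _admissible(assembly: VAssembly) -> bool:
        return assembly.all_pd and not any(assembly.near_singular)

    _check_structural_collinearity(design)
    nonneg = [
        i for i, name in enumerate(design.est_names)
        if name in ("sigma_u2", "sigma_g2", "sigma_e2", "within_variance")
    ]
    # Negative variance solutions are legitimate (kept for ML equivalence),
    # but a strongly negative family component can push V onto the PD
    # boundary in large families, where the GLS weights are meaningless.
    # Inadmissible candidates are replaced for that iteration by the
    # non-negativity-constrained (active set) solution of the same normal
    # equations; after repeated refusals the fit switches permanently to
    # the constrained iteration, whose fixed point is well-defined, instead
    # of cycling toward the boundary.
    constrained_mode = False
    refusals = 0
    nvmax = data.layout.n_visits_max
    for n_iter in range(1, max_iter + 1):
        M, b = _normal_equations(data, beta, design, V)
        if constrained_mode:
            theta_new, _ = _solve_nonneg_active_set(M, b, nonneg)
            theta_new = _clamp_est(theta_new, design, nvmax, "truncate")
        else:
            theta_new = _solve_normalized(M, b)
        V_new = assemble_V(design, theta_new, cond_threshold=1e5)
        halvings = 0
        if not _admissible(V_new) and not constrained_mode:
            refusals += 1
            theta_con, _ = _solve_nonneg_active_set(M, b, nonneg)
            theta_con = _clamp_est(theta_con, design, nvmax, "truncate")
            V_con = assemble_V(design, theta_con, cond_threshold=1e5)
            if _admissible(V_con):
                theta_new, V_new = theta_con, V_con
            if refusals >= 2:
                constrained_mode = True
        while not _admissible(V_new) and halvings < 10:
            theta_new = 0.5 * (theta_new + theta)
            V_new = assemble_V(design, theta_new, cond_threshold=1e5)
            halvings += 1
        if not _admissible(V_new):
            pd_failure = True
            break
        beta_new, cov_beta = igls_step_beta(data, V_new)
        prev = np.concatenate([beta, theta])
        cur = np.concatenate([beta_new, theta_new])
        denom = np.maximum(np.maximum(np.abs(prev), np.abs(cur)), 1e-3)
        delta = float(np.max(np.abs(cur - prev) / denom))
        beta, theta, V = beta_new, theta_new, V_new
        history.append(
            {"iteration": n_iter, "beta": beta.copy(),
             "theta": dict(zip(design.est_names, theta)), "delta": delta,
             "halvings": halvings}
        )
        if delta < tol:
            converged = True
            break

    nvmax = data.layout.n_visits_max
    theta_final = _clamp_est(theta, design, nvmax, clamp_mode)
    clamped = not np.allclose(theta_final, theta, rtol=0, atol=0)
    if clamped:
        V_final = assemble_V(design, theta_final)
        if V_final.all_pd:
            beta, cov_beta = igls_step_beta(data, V_final)
        else:  # keep the last admissible weights for the Wald test
            theta_final = theta
    vc, rho_undefined = design.expand(theta_final)
    if clamp_mode == "truncate" and design.serial and vc.sigma_v2 > 0:
        lo, hi = vc.rho_interval(nvmax)
        if not (lo < vc.rho < hi):  # numerical edge after clamping
            vc = VarianceComponents(vc.sigma_u2, vc.sigma_g2, vc.sigma_v2,
                                    min(max(vc.rho, lo + 1e-8), hi - 1e-8), vc.sigma_e2)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    return FitResult(
        beta=beta,
        cov_beta=cov_beta,
        vc=vc,
        z=z,
        p=p,
        n_iter=n_iter,
        converged=converged and not pd_failure,
        history=history,
        n_obs=data.layout.n_obs,
        n_families=data.layout.n_families,
        x_names=data.x_names,
        est=dict(zip(design.est_names, theta_final)),
        flags={"rho_undefined": rho_undefined, "clamped": clamped,
               "pd_failure": pd_failure},
    )


def _resolve_dosage_columns(
    genotypes: pd.DataFrame, layout: ObservationLayout
) -> dict[tuple[str, str], str]:
    """Map (family, individual) to a genotype matrix column, accepting either
    bare individual ids or FID:IID composites."""
    cols = set(map(str, genotypes.columns))
    mapping: dict[tuple[str, str], str] = {}
    for fid in layout.families:
        for iid in layout.members[fid]:
            if f"{fid}:{iid}" in cols:
                mapping[(fid, iid)] = f"{fid}:{iid}"
            elif iid in cols:
                mapping[(fid, iid)] = iid
            else:
                raise KeyError(
                    f"no genotype column for individual {iid!r} (family {fid!r})"
                )
    return mapping


def assoc_scan(
    genotypes: pd.DataFrame,
    table: pd.DataFrame,
    ped: Pedigree,
    *,
    response: str = "y",
    covariates: Sequence[str] = (),
    kinship_scale: float = 2.0,
    first_visit_only: bool = False,
    max_iter: int = 50,
    tol: float = 1e-6,
    clamp_mode: str = "truncate",
    kinships: Mapping[str, KinshipMatrix] | None = None,
) -> pd.DataFrame:
    """Per-SNV association scan: one IGLS fit per genotype column.

    ``genotypes`` is a dosage matrix (rows = SNVs, columns = individuals,
    values in [0, 2]).  The dosage enters the fixed-effect design as one
    column, constant across an individual's visits.  ``first_visit_only``
    restricts the data to each individual's earliest visit and drops the
    serial components from the covariance design (the cross-sectional
    baseline).  Monomorphic SNVs and failed fits produce rows with missing
    statistics and a reason code.
    """
    dos = genotypes.to_numpy(dtype=float)
    if dos.size and (np.nanmin(dos) < 0 or np.nanmax(dos) > 2):
        raise ValueError("dosage values must lie in [0, 2]")
    if first_visit_only:
        tab = table.copy()
        tab["_v"] = tab["visit"]
        first = tab.groupby(["FID", "IID"], sort=False)["_v"].transform("min")
        table = tab[tab["_v"] == first].drop(columns="_v")
    data = longitudinal_data_from_table(
        table, ped, response=response, covariates=covariates
    )
    if kinships is None:
        kinships = kinship_matrices(ped)
    design = build_components(
        data.layout, kinships, kinship_scale=kinship_scale,
        serial=not first_visit_only,
    )
    colmap = _resolve_dosage_columns(genotypes, data.layout)
    obs_cols = [
        colmap[(f, i)]
        for f, i in zip(data.layout.rows["family"], data.layout.rows["individual"])
    ]
    rows = []
    na = float("nan")
    for snv_id, snv in genotypes.iterrows():
        dose = snv[obs_cols].to_numpy(dtype=float)
        base = dict.fromkeys(ASSOC_COLUMNS, na)
        base["snv_id"] = snv_id
        base["converged"] = False
        base["reason"] = ""
        if np.var(dose) == 0:
            base["reason"] = "monomorphic"
            rows.append(base)
            continue
        try:
            fit = fit_igls(
                data.with_column("dosage", dose),
                design, max_iter=max_iter, tol=tol, clamp_mode=clamp_mode,
            )
        except (CollinearityError, np.linalg.LinAlgError) as err:
            base["reason"] = f"fit_error: {err}"
            rows.append(base)
            continue
        j = fit.x_names.index("dosage")
        base.update(
            beta=fit.beta[j], se=fit.se[j], z=fit.z[j], p=fit.p[j],
            sigma_u2=fit.vc.sigma_u2, sigma_g2=fit.vc.sigma_g2,
            sigma_v2=fit.vc.sigma_v2, rho=fit.vc.rho, sigma_e2=fit.vc.sigma_e2,
            n_iter=fit.n_iter, converged=fit.converged, reason="",
        )
        rows.append(base)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def write_assoc(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)


def read_assoc(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snv_id": str, "reason": str})
    df["reason"] = df["reason"].fillna("")
    return df
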