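"""Per-family covariance components for the three-level longitudinal model.

The trait covariance is modelled as

    V = A * sigma_u2 + B * sigma_g2 + C1 * sigma_v2 + C2 * (rho*sigma_v2)
        + I * sigma_e2

block-diagonal over families.  For family ``k`` with balanced visits the
blocks are Kronecker products: ``A_k = J_k (x) J*`` (family clustering),
``B_k = D_k (x) J*`` with ``D_k`` the genetic correlation matrix
(``2*phi``), and the serial part ``C_k = I_k (x) R`` with compound-symmetry
correlation ``R = I + rho*(J - I)`` among an individual's repeated measures,
split into the known matrices ``C1`` (diagonal) and ``C2`` (off-diagonal).
Unbalanced visit patterns are handled by deleting the missing rows/columns
from the balanced Kronecker forms.

Identifiability note: ``C1`` coincides with the observation-level identity
``I``, so only the four combinations (sigma_u2, sigma_g2, rho*sigma_v2,
sigma_v2 + sigma_e2) are estimable from second moments.  The design exposes
both the full five-matrix decomposition and the reduced estimable basis; see
:meth:`CovarianceDesign.expand` for the reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .pedigree import KinshipMatrix, Pedigree, PedigreeError, relationship_matrix

__all__ = [
    "ObservationLayout",
    "VarianceComponents",
    "CovarianceDesign",
    "VAssembly",
    "build_layout",
    "build_components",
    "assemble_V",
    "vech_upper",
    "duplication_weights",
]

FULL_NAMES = ("sigma_u2", "sigma_g2", "sigma_v2", "rho_sigma_v2", "sigma_e2")
EST_NAMES_SERIAL = ("sigma_u2", "sigma_g2", "rho_sigma_v2", "within_variance")
EST_NAMES_CROSS = ("sigma_u2", "sigma_g2", "sigma_e2")


@dataclass(frozen=True)
class VarianceComponents:
    """The five variance parameters of the three-level model.

    Variances are in squared trait units; ``rho`` is the compound-symmetry
    correlation among an individual's repeated measures attributable to the
    serial component.
    """

    sigma_u2: float
    sigma_g2: float
    sigma_v2: float
    rho: float
    sigma_e2: float

    @property
    def within_covariance(self) -> float:
        """Covariance between two visits of one individual beyond the
        family/genetic terms: rho * sigma_v2 (identifiable)."""
        return self.rho * self.sigma_v2

    @property
    def within_variance(self) -> float:
        """sigma_v2 + sigma_e2 (identifiable)."""
        return self.sigma_v2 + self.sigma_e2

    def as_array(self) -> np.ndarray:
        """Coefficients in estimation order (sigma_u2, sigma_g2, sigma_v2,
        rho*sigma_v2, sigma_e2)."""
        return np.array(
            [self.sigma_u2, self.sigma_g2, self.sigma_v2, self.within_covariance, self.sigma_e2]
        )

    def rho_interval(self, n_visits_max: int) -> tuple[float, float]:
        lo = -1.0 / (n_visits_max - 1) if n_visits_max > 1 else -1.0
        return (lo, 1.0)

    def is_admissible(self, n_visits_max: int) -> bool:
        lo, hi = self.rho_interval(n_visits_max)
        return (
            min(self.sigma_u2, self.sigma_g2, self.sigma_v2, self.sigma_e2) >= 0
            and lo < self.rho < hi
        )


@dataclass
class ObservationLayout:
    """Canonical ordering of (family, individual, visit) observations.

    Rows are sorted by family (pedigree file order), then individual
    (pedigree file order within family), then visit number; this ordering is
    the bijection between model indices and rows of the response, the design
    matrix and every covariance block.
    """

    rows: pd.DataFrame  # columns: family, individual, visit (canonical order)
    families: list[str]
    family_slices: dict[str, slice]
    members: dict[str, list[str]]  # phenotyped members per family, ped order
    visit_masks: dict[tuple[str, str], tuple[int, ...]]
    n_visits_max: int

    @property
    def n_obs(self) -> int:
        return len(self.rows)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_individual_index(self, fid: str) -> np.ndarray:
        """Per observation of family ``fid``, the index of its individual in
        ``members[fid]``."""
        pos = {m: i for i, m in enumerate(self.members[fid])}
        sub = self.rows.iloc[self.family_slices[fid]]
        return np.array([pos[i] for i in sub["individual"]])


def build_layout(
    table: pd.DataFrame,
    ped: Pedigree,
    *,
    family_col: str = "FID",
    individual_col: str = "IID",
    visit_col: str = "visit",
) -> ObservationLayout:
    """Build the canonical observation layout from a long-format table.

    Every (family, individual) in ``table`` must exist in the pedigree.
    Input row order is irrelevant: the layout is canonically sorted.
    """
    req = {family_col, individual_col, visit_col}
    missing_cols = req - set(table.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns {sorted(missing_cols)}")
    df = pd.DataFrame(
        {
            "family": table[family_col].astype(str).to_numpy(),
            "individual": table[individual_col].astype(str).to_numpy(),
            "visit": table[visit_col].to_numpy(),
        }
    )
    fam_order = {f: i for i, f in enumerate(ped.family_ids)}
    for fam, ind in df[["family", "individual"]].drop_duplicates().itertuples(index=False):
        if fam not in fam_order:
            raise PedigreeError(f"phenotyped family {fam!r} absent from pedigree")
        if ind not in ped.members(fam):
            raise PedigreeError(
                f"phenotyped individual {ind!r} (family {fam!r}) absent from pedigree"
            )
    member_order = {
        (f, m): j for f in ped.family_ids for j, m in enumerate(ped.members(f))
    }
    df["_f"] = df["family"].map(fam_order)
    df["_m"] = [member_order[(f, m)] for f, m in zip(df["family"], df["individual"])]
    df = df.sort_values(["_f", "_m", "visit"], kind="stable").reset_index(drop=True)
    dup = df.duplicated(["family", "individual", "visit"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            f"duplicate observation for individual {first['individual']!r} "
            f"visit {first['visit']!r}"
        )
    families = [f for f in ped.family_ids if f in set(df["family"])]
    family_slices: dict[str, slice] = {}
    members: dict[str, list[str]] = {}
    visit_masks: dict[tuple[str, str], tuple[int, ...]] = {}
    start = 0
    for fid in families:
        sub = df[df["family"] == fid]
        family_slices[fid] = slice(start, start + len(sub))
        start += len(sub)
        mem = []
        for ind, grp in sub.groupby("individual", sort=False):
            mem.append(ind)
            visit_masks[(fid, ind)] = tuple(int(v) for v in grp["visit"])
        members[fid] = mem
    n_visits_max = max(len(v) for v in visit_masks.values())
    return ObservationLayout(
        rows=df[["family", "individual", "visit"]].copy(),
        families=families,
        family_slices=family_slices,
        members=members,
        visit_masks=visit_masks,
        n_visits_max=n_visits_max,
    )


@dataclass
class CovarianceDesign:
    """Known per-family component matrices and their estimation basis.

    ``matrices[k][name]`` is the dense component matrix of family
    ``layout.families[k]``.  ``est_names`` is the reduced identifiable basis
    actually used by the step-1 regression; for the serial (longitudinal)
    design the aliased pair (``sigma_v2``, ``sigma_e2``) is merged into
    ``within_variance``.
    """

    layout: ObservationLayout
    names: tuple[str, ...]
    matrices: list[dict[str, np.ndarray]]
    est_names: tuple[str, ...]
    serial: bool
    kinship_scale: float

    def est_matrices(self, k: int) -> list[np.ndarray]:
        fam = self.matrices[k]
        if self.serial:
            return [fam["sigma_u2"], fam["sigma_g2"], fam["rho_sigma_v2"], fam["sigma_e2"]]
        return [fam[name] for name in self.est_names]

    def full_matrices(self, k: int) -> list[np.ndarray]:
        return [self.matrices[k][name] for name in self.names]

    def est_from_vc(self, vc: VarianceComponents) -> np.ndarray:
        if self.serial:
            return np.array(
                [vc.sigma_u2, vc.sigma_g2, vc.within_covariance, vc.within_variance]
            )
        return np.array([vc.sigma_u2, vc.sigma_g2, vc.sigma_e2])

    def expand(self, theta_est: np.ndarray) -> tuple[VarianceComponents, bool]:
        """Map estimable coefficients to the five reported components.

        The serial/error split is not identified (``C1`` equals ``I``); the
        within-individual variance is divided equally between ``sigma_v2``
        and ``sigma_e2`` (minimum-norm convention) and
        ``rho = within_covariance / sigma_v2``.  Returns the components and a
        flag that is True when ``rho`` was undefined (``sigma_v2 ~ 0``) and
        was set to 0.
        """
        if not self.serial:
            u, g, e = theta_est
            return VarianceComponents(u, g, 0.0, 0.0, e), False
        u, g, c2, w = theta_est
        sigma_v2 = w / 2.0
        sigma_e2 = w / 2.0
        if abs(sigma_v2) < 1e-12:
            return VarianceComponents(u, g, sigma_v2, 0.0, sigma_e2), True
        return VarianceComponents(u, g, sigma_v2, c2 / sigma_v2, sigma_e2), False


def _expand_over_visits(per_individual: np.ndarray, ind_index: np.ndarray) -> np.ndarray:
    """Expand an individual-level matrix to observation level: entry (p, q)
    becomes M[ind(p), ind(q)] (the J* Kronecker factor, rows/cols of missing
    visits already absent)."""
    return per_individual[np.ix_(ind_index, ind_index)]


def build_components(
    layout: ObservationLayout,
    kinships: Mapping[str, KinshipMatrix],
    *,
    structure: str = "compound_symmetry",
    kinship_scale: float = 2.0,
    serial: bool = True,
) -> CovarianceDesign:
    """Build the per-family component matrices A, B, C1, C2, I.

    ``serial=False`` builds the cross-sectional design (components A, B, I
    only), used for single-visit analyses where the serial terms are not
    estimable.  Only the compound-symmetry structure is supported; richer
    serial correlation would need additional known matrices, each linear in
    one parameter.
    """
    if structure != "compound_symmetry":
        raise ValueError(
            f"unsupported serial correlation structure {structure!r}; "
            "only 'compound_symmetry' is implemented"
        )
    matrices: list[dict[str, np.ndarray]] = []
    for fid in layout.families:
        kin = kinships[fid]
        mem = layout.members[fid]
        D = relationship_matrix(kin.submatrix(mem), scale=kinship_scale)
        ind_index = layout.family_individual_index(fid)
        n = len(ind_index)
        same_ind = ind_index[:, None] == ind_index[None, :]
        A = np.ones((n, n))
        B = _expand_over_visits(D, ind_index)
        I = np.eye(n)
        fam: dict[str, np.ndarray] = {"sigma_u2": A, "sigma_g2": B, "sigma_e2": I}
        if serial:
            fam["sigma_v2"] = I.copy()  # C1: per-individual identity blocks == I
            fam["rho_sigma_v2"] = same_ind.astype(float) - I  # C2: within-ind off-diag
        matrices.append(fam)
    names = FULL_NAMES if serial else EST_NAMES_CROSS
    est_names = EST_NAMES_SERIAL if serial else EST_NAMES_CROSS
    return CovarianceDesign(
        layout=layout,
        names=tuple(names),
        matrices=matrices,
        est_names=tuple(est_names),
        serial=serial,
        kinship_scale=kinship_scale,
    )


@dataclass
class VAssembly:
    """Assembled per-family covariance blocks with Cholesky factorizations."""

    blocks: list[np.ndarray]
    factors: list[tuple[np.ndarray, bool] | None]  # cho_factor output or None
    pd_flags: list[bool]
    near_singular: list[bool]

    @property
    def all_pd(self) -> bool:
        return all(self.pd_flags)

    def solve(self, k: int, rhs: np.ndarray) -> np.ndarray:
        fac = self.factors[k]
        if fac is None:
            raise np.linalg.LinAlgError(f"family block {k} is not positive definite")
        return cho_solve(fac, rhs)

    def logdet(self, k: int) -> float:
        fac = self.factors[k]
        if fac is None:
            raise np.linalg.LinAlgError(f"family block {k} is not positive definite")
        return 2.0 * float(np.sum(np.log(np.diag(fac[0]))))


def assemble_V(
    design: CovarianceDesign,
    vc: VarianceComponents | np.ndarray,
    *,
    cond_threshold: float = 1e7,
) -> VAssembly:
    """Assemble V_k for every family and attempt a Cholesky factorization.

    ``vc`` may be a :class:`VarianceComponents` or a vector of coefficients
    in the design's estimation basis.  Non-PD blocks are flagged, not raised
    (the IGLS engine decides the fallback).
    """
    theta = design.est_from_vc(vc) if isinstance(vc, VarianceComponents) else np.asarray(vc, float)
    blocks: list[np.ndarray] = []
    factors: list[tuple[np.ndarray, bool] | None] = []
    pd_flags: list[bool] = []
    near_singular: list[bool] = []
    for k in range(len(design.matrices)):
        mats = design.est_matrices(k)
        V = np.zeros_like(mats[0])
        for coef, S in zip(theta, mats):
            V += coef * S
        V = 0.5 * (V + V.T)
        blocks.append(V)
        try:
            fac = cho_factor(V, lower=True)
            pd_flags.append(True)
            factors.append(fac)
            ev = np.linalg.eigvalsh(V)
            near_singular.append(bool(ev[0] <= 0 or ev[-1] / ev[0] > cond_threshold))
        except np.linalg.LinAlgError:
            factors.append(None)
            pd_flags.append(False)
            near_singular.append(True)
    return VAssembly(blocks, factors, pd_flags, near_singular)


def vech_upper(M: np.ndarray) -> np.ndarray:
    """Row-major vectorization of the upper triangle (column >= row)."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("vech_upper requires a square matrix")
    iu = np.triu_indices(M.shape[0])
    return M[iu]


def duplication_weights(n: int) -> np.ndarray:
    """Weights (1 on diagonal entries, 2 off-diagonal) such that
    ``sum(w * vech_upper(A) * vech_upper(B)) == trace(A @ B)`` for symmetric
    A, B."""
    iu = np.triu_indices(n)
    return np.where(iu[0] == iu[1], 1.0, 2.0)
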