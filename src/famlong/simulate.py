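"""Synthetic pedigrees, Mendelian dosage genotypes and longitudinal traits.

The generator emulates the kind of data produced by large family studies of
blood-pressure traits: multi-generation pedigrees, diallelic SNV dosages
transmitted from founder genotypes drawn at a given minor allele frequency,
and a quantitative trait with three repeated measures per person generated
directly under the three-level model

    y_ijk = x_ijk' beta + u_k + g_jk + v_ij + e_ijk

with family effect u ~ N(0, sigma_u2), polygenic effect g ~ N(0,
sigma_g2 * 2*Phi), serial effect v ~ N(0, sigma_v2 * R) with
compound-symmetry correlation rho, and iid error e.  The random part is
drawn from the very covariance blocks the estimator assembles (one shared
covariance code path), so parameter-recovery experiments probe estimation
rather than two divergent writings of the model.

A heritable null trait (default heritability 0.68, the kind of null
response family studies distribute for type-I-error assessment) and
per-SNV genotype permutation complete the type-I/power experiment inputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .covariance import VarianceComponents, assemble_V, build_components, build_layout
from .pedigree import PedRecord, Pedigree, kinship_matrices

__all__ = [
    "Trio",
    "Nuclear",
    "ThreeGeneration",
    "SimConfig",
    "SimData",
    "simulate_pedigrees",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_null_trait",
    "permute_genotypes",
    "simulate_dataset",
    "write_ped",
    "write_dosage",
    "read_dosage",
    "write_phenotypes",
    "read_phenotypes",
]


# ---------------------------------------------------------------------------
# family templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trio:
    """Father, mother, one child."""

    def build(self, rng: np.random.Generator) -> list[tuple[int, int | None, int | None, int]]:
        return [(1, None, None, 1), (2, None, None, 2), (3, 1, 2, int(rng.integers(1, 3)))]

    def expected_size(self) -> float:
        return 3.0


@dataclass(frozen=True)
class Nuclear:
    """Two parents and a fixed number of children."""

    n_children: int = 2

    def build(self, rng: np.random.Generator) -> list[tuple[int, int | None, int | None, int]]:
        members = [(1, None, None, 1), (2, None, None, 2)]
        for c in range(self.n_children):
            members.append((3 + c, 1, 2, int(rng.integers(1, 3))))
        return members

    def expected_size(self) -> float:
        return 2.0 + self.n_children


@dataclass(frozen=True)
class ThreeGeneration:
    """Founder couple, their children (sibship ~ 1 + Poisson(mean-1)), and
    grandchildren through married-in spouses.

    Expected family size has the closed form
    ``2 + Ec + Ec * m * (1 + Eg)`` with ``Ec`` the mean sibship,
    ``m`` the marriage probability and ``Eg`` the mean grandchild sibship.
    """

    mean_children: float = 3.0
    spouse_prob: float = 0.8
    mean_grandchildren: float = 2.5

    def build(self, rng: np.random.Generator) -> list[tuple[int, int | None, int | None, int]]:
        members = [(1, None, None, 1), (2, None, None, 2)]
        next_id = 3
        n_children = 1 + int(rng.poisson(max(self.mean_children - 1.0, 0.0)))
        for _ in range(n_children):
            child = next_id
            sex = int(rng.integers(1, 3))
            members.append((child, 1, 2, sex))
            next_id += 1
            if rng.random() < self.spouse_prob:
                spouse = next_id
                members.append((spouse, None, None, 3 - sex))
                next_id += 1
                father, mother = (child, spouse) if sex == 1 else (spouse, child)
                n_grand = 1 + int(rng.poisson(max(self.mean_grandchildren - 1.0, 0.0)))
                for _ in range(n_grand):
                    members.append((next_id, father, mother, int(rng.integers(1, 3))))
                    next_id += 1
        return members

    def expected_size(self) -> float:
        return 2.0 + self.mean_children * (1.0 + self.spouse_prob * (1.0 + self.mean_grandchildren))


TEMPLATES = {"trio": Trio, "nuclear": Nuclear, "three_generation": ThreeGeneration}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    ``seed`` is mandatory: there is no implicit entropy anywhere.  Defaults
    describe a modest multi-generation family study with three visits per
    person and the variance decomposition used throughout the package's
    validation experiments.
    """

    seed: int
    n_families: int = 20
    template: Trio | Nuclear | ThreeGeneration = field(default_factory=ThreeGeneration)
    n_visits: int = 3
    n_snvs: int = 1
    maf: float = 0.3
    dosage_jitter: float = 0.0  # uniform +-jitter mimicking imputed doses
    vc_true: VarianceComponents = field(
        default_factory=lambda: VarianceComponents(0.5, 1.0, 0.8, 0.4, 1.0)
    )
    beta0: float = 0.0
    snv_effects: dict[int, float] = field(default_factory=dict)  # snv index -> effect
    age_effect: float = 0.0
    sex_effect: float = 0.0
    medication_effect: float = 0.0
    age_baseline_mean: float = 45.0
    age_baseline_sd: float = 12.0
    age_increment: float = 5.0
    medication_prob: float = 0.3
    h2_null: float = 0.68

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        if not 0.0 < self.maf < 1.0:
            raise ValueError("maf must be in (0, 1)")
        if not 0.0 <= self.h2_null < 1.0:
            raise ValueError("h2_null must be in [0, 1)")
        if self.n_families < 1 or self.n_visits < 1 or self.n_snvs < 1:
            raise ValueError("n_families, n_visits, n_snvs must be positive")
        if not self.vc_true.is_admissible(self.n_visits):
            raise ValueError("vc_true not admissible for the visit count")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["template"] = {
            "kind": type(self.template).__name__,
            **dataclasses.asdict(self.template),
        }
        return d


@dataclass
class SimData:
    """One simulated dataset: pedigree, dosages and phenotype table."""

    ped: Pedigree
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_pedigrees(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Draw ``n_families`` independent pedigrees from the family template.

    Individual ids are globally unique (``F<k>-<j>``)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    records: list[PedRecord] = []
    for k in range(cfg.n_families):
        fid = f"F{k + 1:03d}"
        members = cfg.template.build(rng)
        if not members:
            raise ValueError("family template produced an empty family")
        name = {local: f"{fid}-{local}" for local, *_ in members}
        for local, father, mother, sex in members:
            records.append(
                PedRecord(
                    family_id=fid,
                    individual_id=name[local],
                    father_id=name[father] if father is not None else None,
                    mother_id=name[mother] if mother is not None else None,
                    sex=sex,
                )
            )
    return Pedigree(records)


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Diallelic dosages by gene dropping: founder alleles ~ Bernoulli(maf),
    children inherit one uniformly chosen allele per parent.  Returns an
    (SNV x individual) matrix of allele counts; optional uniform jitter
    within ``+-dosage_jitter`` (clipped to [0, 2]) mimics imputed doses."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    m = cfg.n_snvs
    alleles: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    columns: dict[str, np.ndarray] = {}
    for fid in ped.family_ids:
        for iid in ped.topological_order(fid):
            rec = ped.record(fid, iid)
            inherited = []
            for parent in (rec.father_id, rec.mother_id):
                if parent is None:
                    inherited.append((rng.random(m) < cfg.maf).astype(np.int8))
                else:
                    pa, pb = alleles[parent]
                    pick = rng.integers(0, 2, size=m)
                    inherited.append(np.where(pick == 0, pa, pb))
            a1, a2 = inherited
            alleles[iid] = (a1, a2)
            dose = (a1 + a2).astype(float)
            if cfg.dosage_jitter > 0:
                dose = np.clip(
                    dose + rng.uniform(-cfg.dosage_jitter, cfg.dosage_jitter, size=m),
                    0.0, 2.0,
                )
            columns[iid] = dose
    index = pd.Index([f"snv{j + 1}" for j in range(m)], name="snv_id")
    return pd.DataFrame(columns, index=index)


def _covariate_table(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for fid in ped.family_ids:
        for iid in ped.members(fid):
            rec = ped.record(fid, iid)
            age0 = rng.normal(cfg.age_baseline_mean, cfg.age_baseline_sd)
            med = float(rng.random() < cfg.medication_prob)
            sex_cov = 1.0 if rec.sex == 2 else 0.0  # indicator of female
            for visit in range(1, cfg.n_visits + 1):
                rows.append(
                    {
                        "FID": fid, "IID": iid, "visit": visit,
                        "age": age0 + (visit - 1) * cfg.age_increment,
                        "sex": sex_cov, "medication": med,
                    }
                )
    return pd.DataFrame(rows)


def simulate_phenotypes(
    ped: Pedigree,
    genotypes: pd.DataFrame | None,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    *,
    vc: VarianceComponents | None = None,
    snv_effects: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Longitudinal trait drawn exactly under the three-level model.

    The random part is sampled per family as ``L z`` where ``L`` is the
    Cholesky factor of the assembled covariance block V_k — the same
    assembly the estimator uses.  Covariates (age, sex, medication) are
    generated alongside and enter the mean only through the configured
    effects (zero by default)."""
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    vc = cfg.vc_true if vc is None else vc
    snv_effects = cfg.snv_effects if snv_effects is None else dict(snv_effects)
    table = _covariate_table(ped, cfg, rng)
    layout = build_layout(table, ped)
    kinships = kinship_matrices(ped)
    design = build_components(layout, kinships, kinship_scale=2.0)
    V = assemble_V(design, vc)
    for k, ok in enumerate(V.pd_flags):
        if not ok and not np.allclose(V.blocks[k], 0.0):
            raise ValueError("vc_true yields a non-positive-definite covariance")
    # align covariates to the canonical layout before adding the mean
    table = layout.rows.merge(
        table.assign(FID=table["FID"].astype(str), IID=table["IID"].astype(str)),
        left_on=["family", "individual", "visit"],
        right_on=["FID", "IID", "visit"], how="left",
    )
    mean = np.full(layout.n_obs, cfg.beta0)
    mean += cfg.age_effect * table["age"].to_numpy()
    mean += cfg.sex_effect * table["sex"].to_numpy()
    mean += cfg.medication_effect * table["medication"].to_numpy()
    if genotypes is not None and snv_effects:
        for j, effect in snv_effects.items():
            snv = genotypes.iloc[j]
            dose = snv[table["individual"]].to_numpy(dtype=float)
            mean += effect * dose
    y = mean.copy()
    for k, fid in enumerate(layout.families):
        sl = layout.family_slices[fid]
        if np.allclose(V.blocks[k], 0.0):
            continue  # degenerate config: trait is its mean exactly
        L = np.linalg.cholesky(V.blocks[k])
        y[sl] += L @ rng.standard_normal(len(V.blocks[k]))
    out = table[["family", "individual", "visit", "age", "sex", "medication"]].rename(
        columns={"family": "FID", "individual": "IID"}
    )
    out.insert(3, "y", y)
    return out


def simulate_null_trait(
    ped: Pedigree,
    h2: float | None = None,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Heritable null trait: polygenic variance ``h2``, residual ``1 - h2``,
    no genotype effect and no covariate effects.  Default ``h2`` is the
    config's ``h2_null`` (0.68)."""
    if cfg is None:
        raise ValueError("cfg is required")
    h2 = cfg.h2_null if h2 is None else h2
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must be in [0, 1)")
    null_vc = VarianceComponents(0.0, h2, 0.0, 0.0, 1.0 - h2)
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    null_cfg = dataclasses.replace(
        cfg, beta0=0.0, snv_effects={}, age_effect=0.0, sex_effect=0.0,
        medication_effect=0.0,
    )
    return simulate_phenotypes(ped, None, null_cfg, rng, vc=null_vc)


def permute_genotypes(
    genotypes: pd.DataFrame,
    seed: int,
    *,
    ped: Pedigree | None = None,
    within_family: bool = False,
) -> pd.DataFrame:
    """Permute each SNV's dosages over individuals (independently per SNV),
    destroying genotype-phenotype association while leaving the phenotype
    and covariate structure untouched.  ``within_family=True`` permutes only
    within each family (requires ``ped``)."""
    rng = np.random.default_rng(seed)
    values = genotypes.to_numpy(dtype=float).copy()
    cols = list(map(str, genotypes.columns))
    if within_family:
        if ped is None:
            raise ValueError("within_family permutation requires the pedigree")
        groups = []
        col_pos = {c: i for i, c in enumerate(cols)}
        for fid in ped.family_ids:
            idx = [col_pos[i] for i in ped.members(fid) if i in col_pos]
            groups.append(np.array(idx, dtype=int))
    else:
        groups = [np.arange(len(cols))]
    for r in range(values.shape[0]):
        for idx in groups:
            values[r, idx] = values[r, rng.permutation(idx)]
    return pd.DataFrame(values, index=genotypes.index, columns=genotypes.columns)


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Pedigree + genotypes + phenotypes from one seeded generator chain."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigrees(cfg, rng)
    genotypes = simulate_genotypes(ped, cfg, rng)
    phenotypes = simulate_phenotypes(ped, genotypes, cfg, rng)
    return SimData(ped, genotypes, phenotypes, cfg)


# ---------------------------------------------------------------------------
# file round-trips (the exact formats the CLI reads)
# ---------------------------------------------------------------------------

def write_ped(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in ped.records:
            fh.write(
                f"{rec.family_id}\t{rec.individual_id}\t"
                f"{rec.father_id or '0'}\t{rec.mother_id or '0'}\t{rec.sex}\n"
            )


def write_dosage(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.rename_axis("snv_id").to_csv(path, sep="\t")  # index name kept stable


def read_dosage(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="snv_id")


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"FID": str, "IID": str})
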