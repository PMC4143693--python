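"""Type-I-error and power experiments for the association scan.

Mirrors the two standard calibration designs for family-based tests: a
heritable null trait (association absent by construction, familial
correlation present) and genotype permutation (phenotype/covariate structure
retained, genotype-phenotype association destroyed), plus true-positive-rate
power curves over a grid of p-value cutoffs comparing the longitudinal
analysis with a first-visit-only (cross-sectional) baseline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .igls import assoc_scan
from .simulate import (
    SimConfig,
    permute_genotypes,
    simulate_genotypes,
    simulate_null_trait,
    simulate_pedigrees,
    simulate_phenotypes,
)

__all__ = [
    "ErrorPowerCurve",
    "default_cutoffs",
    "error_rates",
    "power_curve",
    "type1_experiment",
    "power_experiment",
    "write_table",
    "plot_curves",
]


def default_cutoffs(n: int = 40) -> np.ndarray:
    """Log-spaced p-value cutoffs in [1e-6, 0.5]."""
    return np.geomspace(1e-6, 0.5, n)


@dataclass
class ErrorPowerCurve:
    """Fraction of tests with p <= cutoff, over a cutoff grid."""

    cutoffs: np.ndarray
    rate: np.ndarray
    n_tests: int
    condition: str  # null_trait | permuted | causal
    n_na: int = 0

    def at(self, alpha: float) -> float:
        idx = int(np.argmin(np.abs(self.cutoffs - alpha)))
        return float(self.rate[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "rate": self.rate,
                "n_tests": self.n_tests,
                "condition": self.condition,
            }
        )


def _rate_curve(p: np.ndarray, cutoffs: np.ndarray, condition: str, n_na: int) -> ErrorPowerCurve:
    rate = np.array([(p <= c).mean() if len(p) else np.nan for c in cutoffs])
    return ErrorPowerCurve(np.asarray(cutoffs, float), rate, len(p), condition, n_na)


def error_rates(
    pvals: Sequence[float] | np.ndarray,
    truth_mask: Sequence[bool] | np.ndarray,
    cutoffs: Sequence[float] | np.ndarray | None = None,
) -> tuple[ErrorPowerCurve | None, ErrorPowerCurve | None]:
    """False-positive rate over null tests and true-positive rate over causal
    tests.  NA p-values are excluded (their count is reported on the curve).
    Either curve is None when its test set is empty."""
    p = np.asarray(pvals, dtype=float)
    mask = np.asarray(truth_mask, dtype=bool)
    if p.shape != mask.shape:
        raise ValueError("pvals and truth_mask must have the same length")
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must be in [0, 1] or NA")
    cutoffs = default_cutoffs() if cutoffs is None else np.asarray(cutoffs, float)
    fpr = tpr = None
    if np.any(~mask):
        sel = ~mask
        fpr = _rate_curve(p[sel & finite], cutoffs, "null", int((sel & ~finite).sum()))
    if np.any(mask):
        tpr = _rate_curve(p[mask & finite], cutoffs, "causal", int((mask & ~finite).sum()))
    return fpr, tpr


def power_curve(
    pvals: Sequence[float] | np.ndarray,
    cutoffs: Sequence[float] | np.ndarray | None = None,
) -> ErrorPowerCurve:
    """True-positive-rate curve over a set of causal tests; raises when the
    causal set is empty."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("power requested for an empty causal test set")
    _, tpr = error_rates(p, np.ones(len(p), dtype=bool), cutoffs)
    return tpr


def _config_provenance(cfg: SimConfig, extra: dict | None = None) -> dict:
    d = cfg.to_dict()
    if extra:
        d.update(extra)
    digest = hashlib.sha1(
        json.dumps(d, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return {"seed": cfg.seed, "cfg_sha1": digest, **(extra or {})}


def type1_experiment(
    cfg: SimConfig,
    mode: str = "null_trait",
    n_snvs: int = 10,
    n_reps: int = 10,
    *,
    h2: float | None = None,
    covariates: Sequence[str] = (),
    cutoffs: np.ndarray | None = None,
    alphas: Sequence[float] = (0.01, 0.05, 0.1),
) -> dict:
    """Empirical type-I error aggregated over ``n_snvs x n_reps`` null tests.

    ``null_trait`` mode regresses a heritable null response on real
    (unpermuted) genotypes; ``permuted`` mode regresses the configured trait
    (including any causal SNV effects) on per-SNV permuted genotypes.  Fit
    failures are counted, not fatal.  Returns the FPR curve, a summary table
    with Clopper-Pearson 95% intervals at ``alphas``, and provenance.
    """
    if mode not in ("null_trait", "permuted"):
        raise ValueError(f"unknown type-I mode {mode!r}")
    cutoffs = default_cutoffs() if cutoffs is None else cutoffs
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_reps)
    pvals: list[float] = []
    n_failures = 0
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        rep_cfg = dataclasses.replace(cfg, n_snvs=n_snvs)
        ped = simulate_pedigrees(rep_cfg, rng)
        genotypes = simulate_genotypes(ped, rep_cfg, rng)
        if mode == "null_trait":
            phen = simulate_null_trait(ped, h2, rep_cfg, rng)
        else:
            phen = simulate_phenotypes(ped, genotypes, rep_cfg, rng)
            genotypes = permute_genotypes(
                genotypes, int(rng.integers(0, 2**31 - 1))
            )
        res = assoc_scan(genotypes, phen, ped, covariates=covariates)
        for _, row in res.iterrows():
            if np.isfinite(row["p"]):
                pvals.append(float(row["p"]))
            else:
                n_failures += 1
    p = np.asarray(pvals)
    curve = _rate_curve(p, cutoffs, mode, n_failures)
    summary = []
    for a in alphas:
        k = int((p <= a).sum())
        ci = binomtest(k, len(p)).proportion_ci(0.95)
        summary.append(
            {"alpha": a, "fpr": k / len(p), "ci_low": ci.low, "ci_high": ci.high,
             "n_tests": len(p)}
        )
    return {
        "curve": curve,
        "summary": pd.DataFrame(summary),
        "pvals": p,
        "n_failures": n_failures,
        "provenance": _config_provenance(cfg, {"mode": mode, "n_snvs": n_snvs,
                                               "n_reps": n_reps}),
    }


def power_experiment(
    cfg: SimConfig,
    effect_grid: Sequence[float],
    n_reps: int = 100,
    *,
    analyses: Sequence[str] = ("longitudinal", "first_visit_only"),
    covariates: Sequence[str] = (),
    cutoffs: np.ndarray | None = None,
) -> dict:
    """Empirical power per (effect size, analysis mode, cutoff).

    Each replicate simulates one causal SNV with the given effect and tests
    it with each analysis mode on the same data; the first-visit-only mode
    restricts to each individual's earliest visit and drops the serial
    covariance terms (the cross-sectional baseline).  A zero effect row
    reproduces the type-I calibration.
    """
    if not len(effect_grid):
        raise ValueError("effect_grid must be non-empty")
    for a in analyses:
        if a not in ("longitudinal", "first_visit_only"):
            raise ValueError(f"unknown analysis mode {a!r}")
    cutoffs = default_cutoffs() if cutoffs is None else cutoffs
    rows = []
    pval_store: dict[tuple[float, str], np.ndarray] = {}
    for effect in effect_grid:
        seeds = np.random.SeedSequence((cfg.seed, int(1e6 * effect) & 0x7FFFFFFF)).spawn(n_reps)
        pvals = {a: [] for a in analyses}
        for ss in seeds:
            rng = np.random.default_rng(ss)
            rep_cfg = dataclasses.replace(cfg, n_snvs=1, snv_effects={0: float(effect)})
            ped = simulate_pedigrees(rep_cfg, rng)
            genotypes = simulate_genotypes(ped, rep_cfg, rng)
            phen = simulate_phenotypes(ped, genotypes, rep_cfg, rng)
            for a in analyses:
                res = assoc_scan(
                    genotypes, phen, ped, covariates=covariates,
                    first_visit_only=(a == "first_visit_only"),
                )
                pvals[a].append(float(res["p"].iloc[0]))
        for a in analyses:
            p = np.asarray(pvals[a])
            finite = np.isfinite(p)
            pval_store[(float(effect), a)] = p
            for c in cutoffs:
                rows.append(
                    {"effect": effect, "analysis": a, "cutoff": float(c),
                     "power": float((p[finite] <= c).mean()),
                     "n_reps": int(finite.sum()), "n_na": int((~finite).sum())}
                )
    return {
        "table": pd.DataFrame(rows),
        "pvals": pval_store,
        "provenance": _config_provenance(cfg, {"n_reps": n_reps,
                                               "effects": list(map(float, effect_grid))}),
    }


def write_table(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """TSV writer with ``#``-prefixed provenance header lines."""
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def plot_curves(
    curves: Iterable[ErrorPowerCurve],
    path: str | Path,
    *,
    title: str = "",
    diagonal: bool = True,
) -> None:
    """FPR/TPR vs cutoff on a log x-axis; the diagonal marks the nominal
    level for type-I curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for curve in curves:
        ax.plot(curve.cutoffs, curve.rate, marker=".", label=curve.condition)
    if diagonal:
        lims = ax.get_xlim()
        grid = np.geomspace(max(lims[0], 1e-12), 1, 50)
        ax.plot(grid, grid, "k--", lw=0.8, label="nominal")
    ax.set_xscale("log")
    ax.set_xlabel("p-value cutoff")
    ax.set_ylabel("rate")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
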