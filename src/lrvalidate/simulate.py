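"""Synthetic pedigrees, phenotype replicates, and the replication harness.

The harness reproduces the study design of a random-mating, no-selection
pedigree population: a multi-generation pedigree, phenotypes drawn per
replicate from ``MVN(Xb, Z A Z' sigma_a2 + I sigma_e2)`` over a grid of
heritabilities and phenotyping proportions, whole/partial BLUP solves, the
five validation statistics with analytical / approximated / bootstrap
intervals, the empirical ("true") sampling distribution across replicates,
coverage rates, and mean-squared-difference summaries per statistic x method.

All randomness derives from one master seed through ``numpy`` SeedSequence
spawning: stream (0,) for the pedigree, (1, prop_index) for phenotype
assignment, (2, scenario_index, replicate) for phenotype draws, and
(3, scenario_index, replicate) for bootstrap resampling — an entire run is
bit-reproducible from (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from . import lrstats
from .blup import (
    Dataset,
    ModelSpec,
    TruncationScheme,
    ValidationInputs,
    build_mme,
    pev_block,
    solve_for_phenotypes,
    truncate_data,
)
from .pedigree import (
    Pedigree,
    additive_relationship,
    pedigree_from_records,
    subset_matrix,
    validation_genetic_variance,
)

__all__ = [
    "PedigreeParams",
    "SimulationConfig",
    "SimulationReport",
    "generate_pedigree",
    "assign_phenotypes",
    "sample_phenotypes",
    "run_replicates",
    "coverage",
    "msd_table",
]


@dataclass(frozen=True)
class PedigreeParams:
    """Random-mating pedigree generator settings (non-overlapping generations)."""

    founders: int = 120
    generations: int = 5
    matings: int = 60
    offspring_per_mating: int = 2

    def __post_init__(self):
        if self.founders < 4:
            raise ValueError("need at least 4 founders")
        if self.generations < 2:
            raise ValueError("need at least 2 generations")
        if self.matings * self.offspring_per_mating < 2:
            raise ValueError("each generation must contain at least 2 animals")


@dataclass(frozen=True)
class SimulationConfig:
    """Grid, replication and interval settings for the harness.

    Defaults are desk-scale: a ~600-animal pedigree (5 generations of ~120),
    a small h2 x prop grid, 500 phenotype replicates per scenario, and
    ``sigma_e2 = sigma_a2 (1/h2 - 1)`` so that phenotypic variance follows the
    heritability.  The full 9x9 grid of h2 and prop in steps of 0.1 with an
    external pedigree is reached by passing ``pedigree_file`` and wider grids.
    """

    pedigree: PedigreeParams = field(default_factory=PedigreeParams)
    pedigree_file: str | None = None
    h2_grid: tuple = (0.1, 0.3, 0.6)
    prop_grid: tuple = (0.3, 0.6, 0.9)
    replicates: int = 500
    sigma_a2: float = 1.0
    seed: int = 0
    alpha: float = 0.05
    bootstrap: bool = True
    bootstrap_B: int = 1000
    bootstrap_kind: str = "percentile"

    def __post_init__(self):
        for h2 in self.h2_grid:
            if not 0 < h2 < 1:
                raise ValueError("h2 values must lie in (0, 1)")
        for p in self.prop_grid:
            if not 0 < p < 1:
                raise ValueError("prop values must lie in (0, 1)")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")


def generate_pedigree(params: PedigreeParams, seed) -> Pedigree:
    """Discrete-generation random-mating pedigree, no selection.

    Both parents of each offspring are drawn uniformly (and distinctly) from
    the previous generation; generation labels are attached.
    """
    rng = np.random.default_rng(seed)
    animals: list[int] = []
    sires: list[int] = []
    dams: list[int] = []
    gens: list[int] = []
    next_id = 1
    current: list[int] = []
    for _ in range(params.founders):
        animals.append(next_id); sires.append(0); dams.append(0); gens.append(0)
        current.append(next_id)
        next_id += 1
    for g in range(1, params.generations):
        newgen: list[int] = []
        for _ in range(params.matings):
            s, d = rng.choice(current, size=2, replace=False)
            for _ in range(params.offspring_per_mating):
                animals.append(next_id)
                sires.append(int(s)); dams.append(int(d)); gens.append(g)
                newgen.append(next_id)
                next_id += 1
        if len(newgen) < 2:
            raise ValueError("generation with fewer than 2 animals")
        current = newgen
    return pedigree_from_records(animals, sires, dams, gens)


def assign_phenotypes(ped: Pedigree, prop: float, seed,
                      max_redraws: int = 100) -> Dataset:
    """Dataset skeleton: a uniform random ``round(prop * N)`` animals receive a
    record slot, with pedigree generation as the fixed-effect level.

    The draw is repeated (with a warning) if any generation would be left with
    zero records or the last generation with fewer than 2 (the validation set
    must be usable).  Phenotype values start at zero; the harness fills them
    per replicate.
    """
    if not 0 < prop <= 1:
        raise ValueError("prop must lie in (0, 1]")
    if ped.generation is None:
        raise ValueError("pedigree needs generation labels")
    rng = np.random.default_rng(seed)
    N = len(ped)
    k = int(round(prop * N))
    gen_levels = np.unique(ped.generation)
    last = ped.generation.max()
    for attempt in range(max_redraws):
        chosen = np.sort(rng.choice(N, size=k, replace=False))
        gens = ped.generation[chosen]
        counts = {g: int(np.sum(gens == g)) for g in gen_levels}
        if all(counts[g] >= 1 for g in gen_levels) and counts[last] >= 2:
            if attempt > 0:
                warnings.warn(f"phenotype assignment redrawn {attempt} time(s) to "
                              "keep every generation represented", stacklevel=2)
            frame = pd.DataFrame({
                "animal": [ped.ids[i] for i in chosen],
                "generation": gens,
                "phenotype": np.zeros(k),
            })
            return Dataset(frame=frame, animal_col="animal", trait_col="phenotype")
    raise ValueError("could not assign phenotypes covering every generation")


def sample_phenotypes(L_A: np.ndarray, Z: np.ndarray, Xb: np.ndarray,
                      model: ModelSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    """One phenotype draw ``y = Xb + Z u + e`` with ``u = L_A xi sqrt(sigma_g2)``.

    ``L_A`` is a matrix square root of A, so the draw is distributionally
    identical to ``MVN(Xb, Z A Z' sigma_g2 + I sigma_e2)``.  Returns (y, u):
    the simulator keeps the true breeding values for diagnostic checks.
    """
    q = L_A.shape[0]
    u = L_A @ rng.standard_normal(q) * np.sqrt(model.sigma_g2)
    e = rng.standard_normal(Z.shape[0]) * np.sqrt(model.sigma_e2)
    return Xb + Z @ u + e, u


def chol_A(A: np.ndarray) -> np.ndarray:
    """Cholesky square root of A with an eigenvalue fallback for PSD edge cases."""
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(A)
        if w.min() < -1e-8:
            raise ValueError("relationship matrix is not PSD")
        return V * np.sqrt(np.clip(w, 0.0, None))


@dataclass
class ScenarioStructure:
    """Everything that does not depend on the phenotype draw (computed once)."""

    h2: float
    prop: float
    inputs_template: dict
    mme_w: object
    mme_p: object
    data: Dataset
    focal: tuple
    focal_pos: np.ndarray
    focal_mask: np.ndarray
    focal_perm: np.ndarray
    analytical_var: dict
    approx_var: dict
    sigma_gi2: float
    model: ModelSpec


@dataclass
class SimulationReport:
    """Per-replicate statistics and intervals plus scenario-level constants."""

    replicates: pd.DataFrame      # scenario, replicate, statistic, value, true_u cols
    intervals: pd.DataFrame       # scenario, replicate, statistic, method, var, lo, up
    scenarios: pd.DataFrame       # h2, prop, n_validation, sigma_gi2, analytical vars
    config: SimulationConfig
    n_failed: int = 0

    def empirical(self, alpha: float | None = None) -> pd.DataFrame:
        """Empirical ("true") SE, variance and quantile CI per scenario/statistic."""
        alpha = self.config.alpha if alpha is None else alpha
        rows = []
        for (scen, stat), grp in self.replicates.groupby(["scenario", "statistic"]):
            v = grp["value"].to_numpy()
            rows.append({
                "scenario": scen, "statistic": stat,
                "mean": v.mean(), "variance": v.var(ddof=1),
                "se": v.std(ddof=1),
                "lower": np.quantile(v, alpha / 2),
                "upper": np.quantile(v, 1 - alpha / 2),
                "replicates": len(v),
            })
        return pd.DataFrame(rows)


def _scenario_structure(ped: Pedigree, A, L_A, data: Dataset, h2: float,
                        prop: float, sigma_a2: float) -> ScenarioStructure:
    model = ModelSpec.from_h2(h2, sigma_g2=sigma_a2, fixed_effects=("generation",))
    scheme = TruncationScheme.latest_generation()
    partial, focal = truncate_data(data, scheme, ped)
    mme_w = build_mme(ped, data, model, A=A)
    mme_p = build_mme(ped, partial, model, A=A)
    mme_w.factor(); mme_p.factor()
    pos = ped.positions(focal)
    A_vv = subset_matrix(A, focal)
    G = model.sigma_g2 * A_vv.values
    C22_w = pev_block(mme_w, focal)
    C22_p = pev_block(mme_p, focal)
    diag_prior = np.diag(G)
    rel_w = np.clip(1.0 - np.diag(C22_w) / diag_prior, 0.0, 1.0)
    rel_p = np.clip(1.0 - np.diag(C22_p) / diag_prior, 0.0, 1.0)
    sigma_gi2 = validation_genetic_variance(A_vv, model.sigma_g2)
    n = len(focal)
    summary = iv.reliability_summary(rel_p, rel_w)
    analytical_var = {
        "bias": iv.var_bias_analytical(C22_p, C22_w, n),
        "dispersion": iv.var_dispersion_analytical(G, C22_p, C22_w),
        "reliability": iv.var_reliability_analytical(G, C22_p, C22_w, n, sigma_gi2),
    }
    approx_var = {
        "bias": iv.var_bias_approx(summary, model.sigma_g2, n),
        "dispersion": iv.var_dispersion_approx(summary, n),
        "reliability": iv.var_reliability_approx(summary, model.sigma_g2,
                                                 sigma_gi2, n),
    }
    focal_mask = np.isin(data.animals, list(focal))
    order = pd.Series(np.arange(n), index=list(focal))
    focal_perm = order[data.frame.loc[focal_mask, data.animal_col]].to_numpy()
    return ScenarioStructure(
        h2=h2, prop=prop,
        inputs_template=dict(G=G, C22_w=C22_w, C22_p=C22_p, rel_w=rel_w,
                             rel_p=rel_p),
        mme_w=mme_w, mme_p=mme_p, data=data, focal=focal, focal_pos=pos,
        focal_mask=focal_mask, focal_perm=focal_perm,
        analytical_var=analytical_var, approx_var=approx_var,
        sigma_gi2=sigma_gi2, model=model)


def run_replicates(config: SimulationConfig, ped: Pedigree | None = None,
                   progress=None) -> SimulationReport:
    """Run the full grid: per scenario the PEV structure once, then
    ``config.replicates`` phenotype draws with statistics and intervals."""
    master = np.random.SeedSequence(config.seed)
    if ped is None:
        if config.pedigree_file is not None:
            from .pedigree import read_pedigree
            ped = read_pedigree(config.pedigree_file)
        else:
            ped = generate_pedigree(config.pedigree, master.spawn(1)[0])
    A = additive_relationship(ped)
    L_A = chol_A(A.values)
    spec = iv.IntervalSpec(alpha=config.alpha)

    # phenotype assignment fixed per prop (constant validation set across h2)
    datasets = {}
    for j, prop in enumerate(config.prop_grid):
        datasets[prop] = assign_phenotypes(
            ped, prop, np.random.SeedSequence(entropy=master.entropy,
                                              spawn_key=(1, j)))

    rep_rows, int_rows, scen_rows = [], [], []
    n_failed = 0
    scen_idx = 0
    for prop in config.prop_grid:
        data = datasets[prop]
        Z = np.zeros((len(data), len(ped)))
        Z[np.arange(len(data)), ped.positions(data.animals)] = 1.0
        Xb = np.zeros(len(data))  # b = 0 per generation (cancels in BLUP)
        for h2 in config.h2_grid:
            scen = f"h2={h2}_prop={prop}"
            struct = _scenario_structure(ped, A, L_A, data, h2, prop,
                                         config.sigma_a2)
            n = len(struct.focal)
            scen_rows.append({
                "scenario": scen, "h2": h2, "prop": prop, "n_validation": n,
                "sigma_gi2": struct.sigma_gi2,
                **{f"var_{k}_analytical": v for k, v in struct.analytical_var.items()},
                **{f"var_{k}_approximated": v for k, v in struct.approx_var.items()},
            })
            if progress is not None:
                progress(scen, n)
            for rep in range(config.replicates):
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=master.entropy, spawn_key=(2, scen_idx, rep)))
                y, u = sample_phenotypes(L_A, Z, Xb, struct.model, rng)
                try:
                    row_stats, row_ints = _one_replicate(
                        struct, y, u, spec, config,
                        boot_seed=np.random.SeedSequence(
                            entropy=master.entropy,
                            spawn_key=(3, scen_idx, rep)))
                except (ValueError, np.linalg.LinAlgError) as exc:
                    n_failed += 1
                    warnings.warn(f"replicate {rep} of {scen} failed: {exc}",
                                  stacklevel=2)
                    continue
                for name, val, tru in row_stats:
                    rep_rows.append({"scenario": scen, "replicate": rep,
                                     "statistic": name, "value": val,
                                     "true_value": tru})
                for name, method, var, lo, up in row_ints:
                    int_rows.append({"scenario": scen, "replicate": rep,
                                     "statistic": name, "method": method,
                                     "variance": var, "lower": lo, "upper": up})
            scen_idx += 1
    return SimulationReport(
        replicates=pd.DataFrame(rep_rows), intervals=pd.DataFrame(int_rows),
        scenarios=pd.DataFrame(scen_rows), config=config, n_failed=n_failed)


def _one_replicate(struct: ScenarioStructure, y, u, spec, config, boot_seed):
    data = struct.data
    bhat_w, uhat_w_all = solve_for_phenotypes(struct.mme_w, data, y)
    keep = ~struct.focal_mask
    _, uhat_p_all = solve_for_phenotypes(struct.mme_p, data, y[keep])
    uhat_w = uhat_w_all[struct.focal_pos]
    uhat_p = uhat_p_all[struct.focal_pos]
    fitted = (struct.mme_w.X @ bhat_w)[struct.focal_mask]
    ystar = np.empty(len(struct.focal))
    ystar[struct.focal_perm] = y[struct.focal_mask] - fitted

    inputs = ValidationInputs(
        ids=struct.focal, uhat_w=uhat_w, uhat_p=uhat_p, ystar=ystar,
        sigma_gi2=struct.sigma_gi2, model=struct.model,
        **struct.inputs_template)
    stats = lrstats.compute_statistics(inputs)
    u_focal = u[struct.focal_pos]
    true_vals = {
        "bias": 0.0,
        "dispersion": 1.0,
        "ratio_accuracies": np.nan,
        "reliability": float(np.corrcoef(u_focal, uhat_p)[0, 1] ** 2),
        "predictivity": float(np.corrcoef(u_focal, uhat_p)[0, 1]),
    }
    row_stats = [(k, s.value, true_vals[k]) for k, s in stats.items()]

    n = inputs.n
    row_ints = []
    for name in ("bias", "dispersion", "reliability"):
        v = struct.analytical_var[name]
        ci = iv.ci_wald(stats[name].value, v, spec, name, "analytical")
        row_ints.append((name, "analytical", v, ci.lower, ci.upper))
        va = struct.approx_var[name]
        ci = iv.ci_wald(stats[name].value, va, spec, name, "approximated")
        row_ints.append((name, "approximated", va, ci.lower, ci.upper))
    ci = iv.fisher_ci(stats["ratio_accuracies"].value, n, spec)
    row_ints.append(("ratio_accuracies", "analytical", np.nan, ci.lower, ci.upper))
    try:
        ci = iv.predictivity_ci(stats["predictivity"].value, struct.model.h, n,
                                spec)
        row_ints.append(("predictivity", "analytical", np.nan, ci.lower, ci.upper))
    except ValueError:
        # |rho| >= 1 leaves the Fisher-type transform undefined; record a
        # missing interval for this replicate instead of discarding it
        row_ints.append(("predictivity", "analytical", np.nan, np.nan, np.nan))
    if config.bootstrap:
        for name in stats:
            ci = iv.bootstrap_ci(inputs, name, B=config.bootstrap_B, spec=spec,
                                 seed=boot_seed, kind=config.bootstrap_kind)
            row_ints.append((name, "bootstrap", ci.variance, ci.lower, ci.upper))
    return row_stats, row_ints


def coverage(report: SimulationReport, alpha: float | None = None,
             targets: dict | None = None) -> pd.DataFrame:
    """Fraction of replicates whose CI (per scenario/statistic/method) contains
    the target: 0 for bias, 1 for dispersion, and the mean of the replicate
    distribution for the correlation-type statistics unless overridden."""
    rows = []
    emp = report.empirical(alpha)
    emp_mean = emp.set_index(["scenario", "statistic"])["mean"]
    for (scen, stat, method), grp in report.intervals.groupby(
            ["scenario", "statistic", "method"]):
        if targets is not None and stat in targets:
            target = targets[stat]
        elif stat == "bias":
            target = 0.0
        elif stat == "dispersion":
            target = 1.0
        else:
            target = emp_mean.loc[(scen, stat)]
        ok = np.isfinite(grp["lower"]) & np.isfinite(grp["upper"])
        grp = grp[ok]
        if len(grp) == 0:
            continue
        hit = ((grp["lower"] <= target) & (target <= grp["upper"])).mean()
        rows.append({"scenario": scen, "statistic": stat, "method": method,
                     "target": target, "coverage": float(hit),
                     "replicates": len(grp)})
    return pd.DataFrame(rows)


def msd_table(report: SimulationReport, by: str | None = None) -> pd.DataFrame:
    """Mean squared differences between estimated and empirical ("true")
    variance and CI bounds, per statistic x method, averaged over scenarios.

    ``by`` groups the average by ``"h2"`` or ``"prop"`` instead of pooling all
    scenarios.
    """
    emp = report.empirical().set_index(["scenario", "statistic"])
    scen_meta = report.scenarios.set_index("scenario")
    per_rep = report.intervals.copy()
    rows = []
    for (scen, stat, method), grp in per_rep.groupby(
            ["scenario", "statistic", "method"]):
        true = emp.loc[(scen, stat)]
        grp = grp[np.isfinite(grp["lower"]) & np.isfinite(grp["upper"])]
        if len(grp) == 0:
            continue
        d_var = np.nan
        if grp["variance"].notna().all():
            d_var = float(np.mean((grp["variance"] - true["variance"]) ** 2))
        rows.append({
            "scenario": scen, "statistic": stat, "method": method,
            "h2": scen_meta.loc[scen, "h2"], "prop": scen_meta.loc[scen, "prop"],
            "msd_var": d_var,
            "msd_lower": float(np.mean((grp["lower"] - true["lower"]) ** 2)),
            "msd_upper": float(np.mean((grp["upper"] - true["upper"]) ** 2)),
        })
    frame = pd.DataFrame(rows)
    keys = ["statistic", "method"] + ([by] if by else [])
    return (frame.groupby(keys)[["msd_var", "msd_lower", "msd_upper"]]
            .mean().reset_index())
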