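"""End-to-end orchestration: configuration, file I/O, evaluation tables.

``run_all`` simulates (or reads) a dataset, runs the requested prediction
methods (bayesB, bayesCpi, bayesCpi-dom, G1, G2, G3), maps QTL from each
method's marker effects, and writes TSV artifacts: per-SNP effects, a
variance-component table, GEBV, window variances, QTL calls, a detection
table, validation accuracies and the between-method GEBV correlation
matrix.  Every output file carries a header with the config hash, seed and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import gblup, qtlmap, syndata, wgr

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "AnalysisConfig",
    "MappingConfig",
    "RunConfig",
    "EvaluationReport",
    "read_dataset",
    "accuracy",
    "method_correlations",
    "run_all",
    "scaled_study_config",
]

BAYES_METHODS = ("bayesB", "bayesCpi", "bayesCpi-dom")
GBLUP_METHODS = ("G1", "G2", "G3")


class DatasetError(ValueError):
    """Raised on malformed or inconsistent dataset files."""


# ---------------------------------------------------------------------------
# configuration


def _from_dict(cls, data: dict, path: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulationConfig:
    n_sires: int = 20
    n_dams_per_sire: int = 10
    n_progeny_per_dam: int = 15
    n_snps: int = 1998
    n_chrom: int = 5
    chrom_length: float = 1.0
    maf_low: float = 0.1
    maf_high: float = 0.5
    n_phenotyped_per_family: int = 10
    minor_effect: float = 1.0
    major_ratio: float = 4.0
    pair_spacing: float = 0.1
    mu: float = 0.0
    sigma2_a: float = 26.35
    sigma2_e: float = 61.49
    seed: int = 0


@dataclass(frozen=True)
class AnalysisConfig:
    methods: tuple = ("bayesCpi", "G1")
    pi: float = 0.995
    n_iter: int = 41_000
    burn_in: int = 1_000
    thin: int = 10
    seed: int = 1
    reml_tol: float = 1e-8
    reml_max_iter: int = 200
    epistasis_mode: str = "hadamard"

    def __post_init__(self):
        bad = [m for m in self.methods
               if m not in BAYES_METHODS + GBLUP_METHODS]
        if bad:
            raise ValueError(f"unknown method(s): {bad}")


@dataclass(frozen=True)
class MappingConfig:
    window_size: int = 10
    sliding: bool = True
    bayesb_multiplier: float = 10.0
    k_sd: float = 4.0
    merge_within: int = 10
    tolerance_morgans: float = 0.05
    use_posterior_samples: bool = False


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        sim = _from_dict(SimulationConfig, data.get("simulation", {}),
                         "simulation")
        ana = data.get("analysis", {})
        if "methods" in ana:
            ana = dict(ana, methods=tuple(ana["methods"]))
        return cls(
            simulation=sim,
            analysis=_from_dict(AnalysisConfig, ana, "analysis"),
            mapping=_from_dict(MappingConfig, data.get("mapping", {}),
                               "mapping"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(
            yaml.safe_load(yaml.safe_dump(self.to_dict())), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# dataset I/O


@dataclass
class Dataset:
    """Row-aligned genotype/phenotype/pedigree/map structures."""

    ids: np.ndarray
    X: np.ndarray
    phenotype: np.ndarray
    pedigree: pd.DataFrame
    marker_map: syndata.MarkerMap

    @property
    def is_phenotyped(self) -> np.ndarray:
        return ~np.isnan(self.phenotype)


def read_dataset(paths: dict[str, str | Path]) -> Dataset:
    """Read and cross-validate the plain-text dataset files.

    ``paths`` needs keys genotypes, phenotypes, pedigree, map (the formats
    written by :func:`genopred.syndata.write_population`).  Ids must be
    consistent across files; dosages must be 0/1/2; map positions sorted.
    """
    gpath = Path(paths["genotypes"])
    ids, rows = [], []
    with open(gpath) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            ids.append(int(parts[0]))
            try:
                row = np.array(parts[1:], dtype=int)
            except ValueError as exc:
                raise DatasetError(
                    f"{gpath}:{ln}: non-integer dosage ({exc})") from exc
            bad = np.flatnonzero((row < 0) | (row > 2))
            if bad.size:
                raise DatasetError(
                    f"{gpath}:{ln}: dosage {row[bad[0]]} at SNP column "
                    f"{bad[0] + 1} outside {{0,1,2}}")
            rows.append(row)
    X = np.vstack(rows)
    ids = np.array(ids)
    if len(set(ids.tolist())) != len(ids):
        raise DatasetError(f"{gpath}: duplicate individual ids")

    ped = pd.read_csv(paths["pedigree"], comment="#")
    if not np.array_equal(ped["id"].to_numpy(), ids):
        raise DatasetError("pedigree ids do not match genotype rows")

    phen = pd.read_csv(paths["phenotypes"], comment="#")
    known = set(ids.tolist())
    for pid in phen["id"]:
        if int(pid) not in known:
            raise DatasetError(f"phenotype file has unknown id {pid}")
    y = np.full(len(ids), np.nan)
    pos_of = {int(i): r for r, i in enumerate(ids)}
    vals = pd.to_numeric(phen["trait"], errors="coerce")
    for pid, v in zip(phen["id"], vals):
        y[pos_of[int(pid)]] = v

    mp = pd.read_csv(paths["map"], sep="\t", comment="#")
    if len(mp) != X.shape[1]:
        raise DatasetError(
            f"map lists {len(mp)} SNPs but genotypes have {X.shape[1]}")
    try:
        marker_map = syndata.MarkerMap(
            chromosome=mp["chrom"].to_numpy(),
            position=mp["position_morgans"].to_numpy(),
        )
    except ValueError as exc:
        raise DatasetError(f"{paths['map']}: {exc}") from exc
    return Dataset(ids=ids, X=X, phenotype=y, pedigree=ped,
                   marker_map=marker_map)


# ---------------------------------------------------------------------------
# evaluation


def accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation of predicted and true breeding values."""
    gebv = np.asarray(gebv, dtype=float).ravel()
    tbv = np.asarray(tbv, dtype=float).ravel()
    if gebv.shape != tbv.shape or len(gebv) < 3:
        raise ValueError("need >= 3 aligned records")
    if np.std(gebv) == 0 or np.std(tbv) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def method_correlations(gebv_by_method: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of GEBV across methods."""
    names = list(gebv_by_method)
    if len(names) < 2:
        raise ValueError("need >= 2 methods")
    mat = np.eye(len(names))
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            r = accuracy(gebv_by_method[a], gebv_by_method[names[j]])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


@dataclass
class EvaluationReport:
    accuracies: dict[str, float]
    correlations: pd.DataFrame | None
    variance_table: pd.DataFrame
    detection_table: pd.DataFrame | None
    calls: dict[str, list]
    effects: dict[str, np.ndarray] = field(default_factory=dict)
    gebv: dict[str, np.ndarray] = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    population: "syndata.SimulatedPopulation | None" = None


def scaled_study_config(seed: int = 1) -> "RunConfig":
    """Desk-scale variant of the full study design.

    Halves the number of dams per sire (20 x 5 x 15 -> 1,500 progeny, 1,000
    phenotyped, 500 validation) and the SNP panel (1,000 SNPs over 5 x 1
    Morgan), and shortens the chains to 12,000 iterations (2,000 burn-in,
    thin 10).  Trait parameters, QTL architecture and the 10-per-family
    phenotyping scheme are unchanged.
    """
    return RunConfig(
        simulation=SimulationConfig(n_dams_per_sire=5, n_snps=1000,
                                    seed=seed),
        analysis=AnalysisConfig(
            methods=("bayesB", "bayesCpi", "bayesCpi-dom", "G1", "G2"),
            n_iter=12_000, burn_in=2_000, thin=10, seed=seed + 1),
    )


# ---------------------------------------------------------------------------
# orchestration


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA",
                  float_format="%.10g")


def run_all(config: RunConfig, out_dir: str | Path | None = None
            ) -> EvaluationReport:
    """Simulate, analyse, map and evaluate according to ``config``."""
    sim = config.simulation
    ana = config.analysis
    mp = config.mapping
    hdr = [
        f"genopred {__version__}",
        f"config_hash {config.config_hash}",
        f"simulation_seed {sim.seed} analysis_seed {ana.seed}",
        "windows sliding" if mp.sliding else "windows non-overlapping",
        f"minor_effect {sim.minor_effect} major_ratio {sim.major_ratio} "
        f"pair_spacing_morgans {sim.pair_spacing} maf [{sim.maf_low}, "
        f"{sim.maf_high}]",
    ]
    log.info("defaults in effect: chain %d/%d/%d, pi=%s, window_size=%d, "
             "bayesb_multiplier=%s, k_sd=%s",
             ana.n_iter, ana.burn_in, ana.thin, ana.pi, mp.window_size,
             mp.bayesb_multiplier, mp.k_sd)

    pop = syndata.simulate_population(
        n_sires=sim.n_sires, n_dams_per_sire=sim.n_dams_per_sire,
        n_progeny_per_dam=sim.n_progeny_per_dam, n_snps=sim.n_snps,
        n_chrom=sim.n_chrom, chrom_length=sim.chrom_length,
        maf_low=sim.maf_low, maf_high=sim.maf_high,
        minor_effect=sim.minor_effect, major_ratio=sim.major_ratio,
        pair_spacing=sim.pair_spacing,
        trait=syndata.TraitParams(mu=sim.mu, sigma2_a=sim.sigma2_a,
                                  sigma2_e=sim.sigma2_e),
        n_phenotyped_per_family=sim.n_phenotyped_per_family, seed=sim.seed,
    )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        syndata.write_population(pop, out, header_lines=hdr)

    X_all = pop.genotypes.astype(float)
    obs = pop.is_phenotyped
    val = pop.is_validation
    y = pop.phenotype[obs]
    X = X_all[obs]
    W_all = pop.heterozygosity.astype(float)
    p_obs = X.mean(axis=0) / 2.0

    gebv_all: dict[str, np.ndarray] = {}
    effects: dict[str, np.ndarray] = {}
    var_rows: list[dict] = []
    calls: dict[str, list] = {}
    windows_out: dict[str, qtlmap.WindowVarianceTable] = {}
    chain = wgr.McmcConfig(n_iter=ana.n_iter, burn_in=ana.burn_in,
                           thin=ana.thin, seed=ana.seed)
    prior = wgr.PriorSpec(pi=ana.pi)

    sub_seed = ana.seed
    for method in ana.methods:
        sub_seed += 1  # sequential sub-seeds per chain
        mchain = dataclasses.replace(chain, seed=sub_seed)
        if method == "bayesB":
            post = wgr.run_bayesb(y, X, prior, mchain)
        elif method == "bayesCpi":
            post = wgr.run_bayescpi(y, X, prior, mchain)
        elif method == "bayesCpi-dom":
            post = wgr.run_bayescpi_dominance(y, X, W_all[obs], prior, mchain)
        else:
            vc, sol, eff, _rels = gblup.run_gblup(
                pop.phenotype, X_all, model=method,
                epistasis_mode=ana.epistasis_mode, tol=ana.reml_tol,
                max_iter=ana.reml_max_iter)
            g = sol.a_hat - sol.a_hat.mean()
            gebv_all[method] = g
            effects[method] = eff.alpha
            var_rows.append({
                "method": method, "additive": vc.sigma2_a,
                "epistasis": vc.sigma2_aa, "dominance": vc.sigma2_d,
                "residual": vc.sigma2_e, "total": vc.total, "h2": vc.h2,
            })
            wt = qtlmap.window_variances(X_all, eff.alpha, pop.marker_map,
                                         mp.window_size, mp.sliding)
            windows_out[method] = wt
            mcalls, flagged = qtlmap.call_qtl_gblup(
                eff.alpha, pop.marker_map, k_sd=mp.k_sd,
                merge_within=mp.merge_within, per_snp_share=wt.per_snp)
            calls[method] = mcalls
            log.info("%s: %d raw flagged SNPs, %d calls", method,
                     int(flagged.sum()), len(mcalls))
            continue

        # Bayesian branch
        gebv_all[method] = wgr.gebv_from_effects(
            X_all, post.effect_mean_a, post.effect_mean_d,
            allele_freq=p_obs)
        effects[method] = post.effect_mean_a
        var_rows.append({
            "method": method, "additive": post.var_additive,
            "epistasis": None,
            "dominance": post.var_dominance if method == "bayesCpi-dom"
            else None,
            "residual": post.var_residual, "total": post.var_total,
            "h2": post.h2,
        })
        src = post.a_samples if mp.use_posterior_samples else post.effect_mean_a
        wt = qtlmap.window_variances(X_all, src, pop.marker_map,
                                     mp.window_size, mp.sliding)
        windows_out[method] = wt
        if method == "bayesB":
            calls[method] = qtlmap.call_qtl_bayes(
                wt, mode="bayesB", bayesb_multiplier=mp.bayesb_multiplier)
        else:
            calls[method] = qtlmap.call_qtl_bayes(
                wt, pi_hat=post.pi_mean, mode="bayesCpi")

    # evaluation
    acc = {}
    for m, g in gebv_all.items():
        acc[m] = accuracy(g[val], pop.tbv_additive[val])
    corr = method_correlations({m: g[val] for m, g in gebv_all.items()}) \
        if len(gebv_all) >= 2 else None
    var_table = pd.DataFrame(
        var_rows, columns=["method", "additive", "epistasis", "dominance",
                           "residual", "total", "h2"])
    det_rows = []
    for m, cl in calls.items():
        tab = qtlmap.evaluate_calls(cl, pop.qtl, pop.marker_map,
                                    mp.tolerance_morgans)
        tab.insert(0, "method", m)
        tab.attrs = {}
        det_rows.append(tab)
    detection = pd.concat(det_rows, ignore_index=True) if det_rows else None

    if out is not None:
        _write_tsv(var_table, out / "variance_components.tsv", hdr)
        ids = pop.pedigree["id"].to_numpy()
        for m, g in gebv_all.items():
            _write_tsv(pd.DataFrame({
                "id": ids, "gebv": g, "is_validation": val.astype(int)}),
                out / f"gebv_{m}.tsv", hdr)
        mapdf = pop.marker_map.to_frame()
        for m, e in effects.items():
            df = mapdf.copy()
            df["effect"] = e
            _write_tsv(df, out / f"effects_{m}.tsv", hdr)
        for m, wt in windows_out.items():
            _write_tsv(wt.windows, out / f"windows_{m}.tsv", hdr)
        call_rows = [{
            "method": c.method if c.method != "bayesCpi" else m,
            "chrom": c.chromosome, "snp": c.snp_index + 1,
            "position_morgans": pop.marker_map.position[c.snp_index],
            "variance_share": c.variance_share,
        } for m, cl in calls.items() for c in cl]
        _write_tsv(pd.DataFrame(
            call_rows, columns=["method", "chrom", "snp", "position_morgans",
                                "variance_share"]),
            out / "qtl_calls.tsv", hdr)
        if detection is not None:
            _write_tsv(detection, out / "qtl_detection.tsv", hdr)
        if acc:
            _write_tsv(pd.DataFrame(
                {"method": list(acc), "accuracy": list(acc.values())}),
                out / "accuracy.tsv", hdr)
        if corr is not None:
            _write_tsv(corr.reset_index(names="method"),
                       out / "gebv_correlations.tsv", hdr)

    return EvaluationReport(accuracies=acc, correlations=corr,
                            variance_table=var_table,
                            detection_table=detection, calls=calls,
                            effects=effects, gebv=gebv_all,
                            windows=windows_out, population=pop)
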