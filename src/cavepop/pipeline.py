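"""End-to-end orchestration: ingest or simulate, filter, structure,
differentiation, diversity, migration, and the diversity-vs-cave-length
regression.  Every stage writes plain TSV (plus Newick for the dendrogram)
into the configured output directory, and the run log records seeds and
input/output counts so a run is reproducible from its artefacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import io as cio
from .containers import GenotypeLikelihoodTensor, GenotypeMatrix, PopulationMap
from .diversity import DEFAULT_MU, pi_gl, pi_hard
from .filters import GLFilterParams, HardFilterParams, filter_gl_sites, filter_hard_calls
from .fst import migration_from_fst, pairwise_stats
from .simulate import IslandModelConfig, ReadObservationConfig, simulate_island_model, simulate_reads
from .structure import admixture_em, classical_mds, hierarchical_cluster, ibs_distance_matrix, select_k_bic

logger = logging.getLogger("cavepop")

__all__ = [
    "PipelineConfig",
    "RegressionResult",
    "run_all",
    "pi_length_regression",
    "migration_report",
]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    predictor: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")


@dataclass
class PipelineConfig:
    """Configuration for a full run.  Exactly one input source is used:
    a VCF + population map, a BEAGLE GL file + population map, or the
    island-model simulator."""

    out_dir: str = "cavepop_out"
    vcf: str | None = None
    beagle: str | None = None
    popmap: str | None = None
    simulate: IslandModelConfig | None = None
    reads: ReadObservationConfig | None = None
    hard_filters: HardFilterParams = field(default_factory=HardFilterParams)
    gl_filters: GLFilterParams = field(default_factory=GLFilterParams)
    min_maf: float = 0.01
    linkage: str = "average"
    k_range: tuple[int, int] = (1, 8)
    admixture_k: int | None = None
    n_restarts: int = 5
    mu: float = DEFAULT_MU
    total_positions: int | None = None
    cave_lengths: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [self.vcf is not None, self.beagle is not None, self.simulate is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one input source (vcf | beagle | simulate) is required")
        if (self.vcf or self.beagle) and self.popmap is None:
            raise ValueError("file input requires a population map")

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
             for k, v in asdict(self).items() if k != "out_dir"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def pi_length_regression(
    pi_values: np.ndarray | list[float],
    lengths_m: np.ndarray | list[float],
    species: list[str] | None = None,
) -> RegressionResult:
    """OLS of nucleotide diversity on log10(cave length), optional species term.

    Returns the slope on log10(length), its t-test p-value, and the model
    R^2.  A positive slope is the expected longer-caves-hold-more-diversity
    pattern.
    """
    pi_values = np.asarray(pi_values, dtype=float)
    lengths = np.asarray(lengths_m, dtype=float)
    if len(pi_values) < 3:
        raise ValueError("regression needs at least 3 populations")
    if (lengths <= 0).any():
        raise ValueError("cave lengths must be positive")
    x = np.log10(lengths)
    cols = {"log10_length": x}
    predictor = "pi ~ log10(length)"
    if species is not None:
        levels = sorted(set(species))
        for lev in levels[1:]:
            cols[f"species[{lev}]"] = (np.asarray(species) == lev).astype(float)
        predictor += " + species"
    X = sm.add_constant(pd.DataFrame(cols))
    fit = sm.OLS(pi_values, X).fit()
    return RegressionResult(
        slope=float(fit.params["log10_length"]),
        intercept=float(fit.params["const"]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues["log10_length"]),
        n=len(pi_values),
        predictor=predictor,
    )


def migration_report(
    fst_table: pd.DataFrame,
    ne_by_pop: dict[str, float],
    fst_column: str = "wc_fst",
    ne_source: str = "mean",
) -> pd.DataFrame:
    """Per-pair migration rates from F_ST and effective sizes.

    For each pair: M = 1/F_ST - 1 and m = M / (4 Ne), with the pair's Ne
    taken as the mean ('mean'), minimum ('min') or maximum ('max') of the
    two populations' Ne.  Pairs with missing Ne are skipped with a warning.
    """
    if ne_source not in ("mean", "min", "max"):
        raise ValueError("ne_source must be 'mean', 'min' or 'max'")
    combine = {"mean": np.mean, "min": np.min, "max": np.max}[ne_source]
    rows = []
    for rec in fst_table.itertuples():
        pop_a, pop_b = rec.pop_a, rec.pop_b
        fst = getattr(rec, fst_column)
        if pop_a not in ne_by_pop or pop_b not in ne_by_pop:
            logger.warning("migration: missing Ne for pair %s-%s; skipped", pop_a, pop_b)
            continue
        ne = float(combine([ne_by_pop[pop_a], ne_by_pop[pop_b]]))
        est = migration_from_fst(fst, ne, pop_a, pop_b)
        rows.append(
            {
                "pop_a": pop_a,
                "pop_b": pop_b,
                "fst": fst,
                "M": est.M,
                "m": est.m if est.defined else np.nan,
                "ne_used": ne,
                "defined": est.defined,
            }
        )
    return pd.DataFrame(rows)


def _load_inputs(config: PipelineConfig):
    matrix = tensor = None
    if config.simulate is not None:
        ds = simulate_island_model(config.simulate)
        matrix, popmap = ds.genotypes, ds.population_map
        if config.reads is not None:
            tensor, depth = simulate_reads(ds, config.reads)
            matrix = GenotypeMatrix(matrix.samples, matrix.sites, matrix.dosage, depth)
    elif config.vcf is not None:
        matrix = cio.read_vcf(config.vcf)
        popmap = cio.read_popmap(config.popmap)
        popmap.validate_against(matrix.samples)
    else:
        tensor = cio.read_beagle_gl(config.beagle)
        popmap = cio.read_popmap(config.popmap)
        popmap.validate_against(tensor.samples)
    return matrix, tensor, popmap


def run_all(config: PipelineConfig) -> dict[str, object]:
    """Run every applicable stage and persist its outputs.

    Returns a dict of in-memory results keyed by stage; on a stage failure
    the exception is re-raised annotated with the stage name, with the
    outputs of completed stages already on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {"config_hash": config.config_hash()}
    log_lines = [f"config_hash={config.config_hash()} seed={config.seed}"]

    stage = "input"
    try:
        matrix, tensor, popmap = _load_inputs(config)
        cio.write_popmap(popmap, out / "popmap.tsv")
        if matrix is not None:
            cio.write_vcf(matrix, out / "genotypes.vcf")

        stage = "filter"
        if matrix is not None:
            hard_params = config.hard_filters
            if matrix.depth is None and hard_params.min_genotype_depth > 0:
                hard_params = HardFilterParams(
                    min_genotype_depth=0,
                    require_biallelic_snv=hard_params.require_biallelic_snv,
                    drop_singletons=hard_params.drop_singletons,
                    min_call_rate=hard_params.min_call_rate,
                    excess_het_p_threshold=hard_params.excess_het_p_threshold,
                )
                log_lines.append("filter: no depth in input; depth rule disabled")
            matrix, report = filter_hard_calls(matrix, hard_params)
            report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
            results["filter_report"] = report
            log_lines.append(
                f"filter: sites_in={report.n_input_sites} sites_out={report.n_retained}"
            )
        if tensor is not None:
            tensor, gl_report = filter_gl_sites(tensor, config.gl_filters)
            gl_report.to_frame().to_csv(out / "filter_gl_report.tsv", sep="\t", index=False)
            results["filter_gl_report"] = gl_report
            log_lines.append(
                f"filter-gl: sites_in={gl_report.n_input_sites} sites_out={gl_report.n_retained}"
            )

        work = matrix if matrix is not None else tensor

        stage = "structure"
        if matrix is not None:
            dm = ibs_distance_matrix(matrix, min_maf=config.min_maf, seed=config.seed)
            cio.write_distance_tsv(dm, out / "ibs_distance.tsv")
            z, newick = hierarchical_cluster(dm, method=config.linkage)
            (out / "dendrogram.nwk").write_text(newick + "\n")
            coords, evals = classical_mds(dm, n_axes=3)
            pd.DataFrame(
                coords, index=dm.samples, columns=["mds1", "mds2", "mds3"]
            ).to_csv(out / "mds_coords.tsv", sep="\t", index_label="sample")
            ksel = select_k_bic(
                coords, range(config.k_range[0], config.k_range[1] + 1), seed=config.seed
            )
            ksel.table.to_csv(out / "bic_table.tsv", sep="\t", index=False)
            results.update(distance=dm, linkage=z, newick=newick, mds=coords, k_selection=ksel)
            log_lines.append(f"structure: n_pairs={len(dm.samples)} selected_k={ksel.selected_k}")
            k_admix = config.admixture_k or len(popmap.populations)
        else:
            k_admix = config.admixture_k or len(popmap.populations)

        stage = "admixture"
        admix = admixture_em(
            work, K=k_admix, seed=config.seed, n_restarts=config.n_restarts
        )
        admix.q_frame().to_csv(out / f"admixture_q_k{k_admix}.tsv", sep="\t", index_label="sample")
        results["admixture"] = admix
        log_lines.append(f"admixture: K={k_admix} loglik={admix.log_likelihood:.2f}")

        stage = "differentiation"
        if matrix is not None:
            fst_df = pairwise_stats(matrix, popmap)
            fst_df.to_csv(out / "pairwise_fst.tsv", sep="\t", index=False)
            results["fst"] = fst_df
            log_lines.append(f"differentiation: n_pairs={len(fst_df)}")

        stage = "diversity"
        total = config.total_positions
        if total is None:
            total = work.n_sites
            log_lines.append("diversity: total_positions defaulted to retained site count")
        div_rows = []
        for pop in popmap.populations:
            if matrix is not None:
                est = pi_hard(matrix, popmap, pop, total, mu=config.mu)
            else:
                est, _ = pi_gl(tensor, popmap, pop, total, mu=config.mu)
            div_rows.append(
                {
                    "population": pop,
                    "pi_per_site": est.pi_per_site,
                    "S": est.S,
                    "total_positions": est.total_positions,
                    "method": est.method,
                    "mu": est.mu,
                    "ne": est.ne,
                }
            )
        div_df = pd.DataFrame(div_rows)
        div_df.to_csv(out / "diversity.tsv", sep="\t", index=False)
        results["diversity"] = div_df
        log_lines.append(f"diversity: n_pops={len(div_df)} mu={config.mu}")

        stage = "migration"
        if matrix is not None:
            ne_by_pop = dict(zip(div_df["population"], div_df["ne"]))
            mig_df = migration_report(results["fst"], ne_by_pop)
            mig_df.to_csv(out / "migration.tsv", sep="\t", index=False)
            results["migration"] = mig_df
            log_lines.append(f"migration: n_pairs={len(mig_df)}")

        stage = "regression"
        if config.cave_lengths:
            pops = [p for p in div_df["population"] if p in config.cave_lengths]
            if len(pops) >= 3:
                sub = div_df.set_index("population").loc[pops]
                reg = pi_length_regression(
                    sub["pi_per_site"].to_numpy(),
                    [config.cave_lengths[p] for p in pops],
                )
                pd.DataFrame([asdict(reg)]).to_csv(out / "regression.tsv", sep="\t", index=False)
                results["regression"] = reg
                log_lines.append(f"regression: slope={reg.slope:.3g} r2={reg.r_squared:.3f}")
            else:
                log_lines.append("regression: fewer than 3 populations with lengths; skipped")
        else:
            log_lines.append("regression: no cave-length table; skipped")
    except Exception as exc:
        log_lines.append(f"FAILED at stage {stage}: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return results
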