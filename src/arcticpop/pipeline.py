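"""Configuration-driven orchestration of the full analysis workflow.

``run_pipeline`` executes the requested stages in dependency order —
autosomal: QC -> kinship -> LD pruning -> {F_ST, PCA, admixture} -> Mantel;
the mtDNA and Y-STR branches are independent — writing every output table
plus a machine-readable JSON report with per-stage filter counts and a
seed registry, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import autosomal, formats_io, matrix_stats, mt_phylo, y_lineage
from .core import InvalidArgument

logger = logging.getLogger(__name__)

ALL_STAGES = ("mt", "ystr", "qc", "kinship", "prune", "fst", "pca",
              "admixture", "mantel")


@dataclass
class PipelineConfig:
    """All inputs, toggles and numeric parameters of the workflow.

    Numeric defaults are the study-scale settings (MAF 0.01, call rate
    0.97, r^2 0.4 in 200-SNP windows stepped by 25, K from 2 to 14 with 100
    runs, 100,000 permutations, mtDNA clock 1.665e-8 subs/site/year);
    desk-scale runs override them explicitly.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: list[str] = field(default_factory=list)

    # inputs
    ped_path: Optional[str] = None
    map_path: Optional[str] = None
    mt_table_path: Optional[str] = None
    str_table_path: Optional[str] = None
    metadata_path: Optional[str] = None
    mt_tree_path: Optional[str] = None
    y_tree_path: Optional[str] = None

    # autosomal parameters
    maf_min: float = 0.01
    call_rate_min: float = 0.97
    kinship_threshold: float = 0.0884
    r2_max: float = 0.4
    ld_window: int = 200
    ld_step: int = 25
    min_pop_n: int = 4
    n_components: int = 10
    k_min: int = 2
    k_max: int = 14
    n_runs: int = 100
    cv_mask_fraction: float = 0.1
    em_tol: float = 1e-4
    em_max_iter: int = 2000

    # uniparental parameters
    rate_mu: float = 1.665e-8
    seq_length: int = 16569
    mu_locus: float = 6.9e-4
    generation_years: float = 25.0
    mj_epsilon: int = 0

    # Mantel
    n_perm: int = 100_000

    def validate(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise InvalidArgument(f"maf_min {self.maf_min} out of range [0, 0.5)")
        if not 0 < self.call_rate_min <= 1:
            raise InvalidArgument("call_rate_min must be in (0, 1]")
        if not 0 < self.r2_max <= 1:
            raise InvalidArgument("r2_max must be in (0, 1]")
        if self.ld_window < 2 or self.ld_step < 1:
            raise InvalidArgument("ld_window must be >= 2 and ld_step >= 1")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise InvalidArgument("need 1 <= k_min <= k_max")
        if self.n_perm < 1 or self.n_runs < 1:
            raise InvalidArgument("n_perm and n_runs must be >= 1")
        if self.rate_mu <= 0 or self.seq_length <= 0 or self.mu_locus <= 0:
            raise InvalidArgument("rates and lengths must be positive")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise InvalidArgument(f"unknown stage(s) {unknown}; "
                                  f"valid: {list(ALL_STAGES)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


# ---------------------------------------------------------------------------
# Haplogroup grouping for frequency reports
# ---------------------------------------------------------------------------

WEST_EURASIAN_ROOTS = frozenset({"H", "HV1", "J", "U", "R1", "T2", "W", "I",
                                 "I1", "I2a", "E1b1b1", "R1a", "R1b",
                                 "R1a-M458", "R1b-M412", "G2a-west"})
NE_SIBERIAN_LINEAGES = frozenset({"C4b2", "C5a2a", "G1b", "Z1a2a"})


def macro_origin(haplogroup: str, tree) -> str:
    """Coarse geographic-origin class of a haplogroup given the tree."""
    node = tree.root.find(haplogroup)
    if node is None:
        return "unassigned"
    path = {n.name for n in node.path_from_root()}
    if path & WEST_EURASIAN_ROOTS:
        return "west_eurasian"
    if "M" in path or path & {"A", "Y", "N1b", "N1c", "C", "O", "K", "N"}:
        return "east_asian"
    return "unassigned"


def make_frequency_report(spectrum: "mt_phylo.SpectrumResult", tree,
                          pool_map: Optional[dict[str, str]] = None) -> dict:
    """Per-population haplogroup percentage tables plus coarse summaries.

    Returns a dict with a ``per_population`` percentage table (rows sum to
    100), and overall percentages of East Asian vs West Eurasian ancestry,
    of the major haplogroups C and D, and of the Northeast-Siberian-
    specific lineages.
    """
    import pandas as pd

    freq = spectrum.frequency_table
    pct = freq * 100.0 if len(freq) else freq

    classes = list(spectrum.classifications.values())
    n = len(classes)
    if n == 0:
        return {"per_population": pct, "n_samples": 0}

    def share(pred) -> float:
        return 100.0 * sum(1 for h in classes if pred(h)) / n

    def in_clade(h: str, clade: str) -> bool:
        node = tree.root.find(h)
        return node is not None and clade in {x.name for x in node.path_from_root()}

    return {
        "per_population": pct,
        "n_samples": n,
        "east_asian_pct": share(lambda h: macro_origin(h, tree) == "east_asian"),
        "west_eurasian_pct": share(lambda h: macro_origin(h, tree) == "west_eurasian"),
        "hap_C_pct": share(lambda h: in_clade(h, "C")),
        "hap_D_pct": share(lambda h: in_clade(h, "D")),
        "ne_siberian_pct": share(lambda h: h in NE_SIBERIAN_LINEAGES),
    }


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the configured stages and write outputs + JSON report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=asdict(config))
    report.seeds["master"] = config.seed
    stages = list(config.stages)

    def record(stage: str, **info) -> None:
        report.stages[stage] = info

    def emit(name: str) -> str:
        path = str(out / name)
        report.outputs.append(path)
        return path

    # ---------------- mtDNA branch ----------------
    if "mt" in stages:
        if not config.mt_table_path:
            raise InvalidArgument("stage 'mt' requires mt_table_path")
        tree = (mt_phylo.load_marker_tree(config.mt_tree_path)
                if config.mt_tree_path else mt_phylo.default_mt_tree())
        table = formats_io.read_mt_table(config.mt_table_path)
        spectrum = mt_phylo.haplotype_spectrum(table, tree)
        freq_report = make_frequency_report(spectrum, tree)
        freq_report["per_population"].to_csv(emit("mt_frequencies.tsv"), sep="\t")
        record("mt", n_samples=len(table),
               n_haplotypes=spectrum.n_haplotypes,
               n_subhaplogroups=spectrum.n_subhaplogroups,
               n_unclassified=len(spectrum.unclassified),
               east_asian_pct=freq_report.get("east_asian_pct"),
               west_eurasian_pct=freq_report.get("west_eurasian_pct"),
               hap_C_pct=freq_report.get("hap_C_pct"),
               hap_D_pct=freq_report.get("hap_D_pct"),
               ne_siberian_pct=freq_report.get("ne_siberian_pct"))

    # ---------------- Y-STR branch ----------------
    if "ystr" in stages:
        if not config.str_table_path:
            raise InvalidArgument("stage 'ystr' requires str_table_path")
        haps = formats_io.read_str_table(config.str_table_path)
        network = y_lineage.mj_network(haps, epsilon=config.mj_epsilon)
        formats_io.write_network_gml(network, emit("ystr_network.gml"))
        founder = y_lineage.modal_founder(haps)
        years = y_lineage.asd_dating(haps, founder,
                                     mu_locus=config.mu_locus,
                                     generation_years=config.generation_years)
        record("ystr", n_haplotypes=len({h.repeats for h in haps}),
               n_chromosomes=sum(h.count for h in haps),
               n_median_nodes=len(network.median_nodes),
               network_length=network.length,
               founder=list(founder.repeats), age_years=years)

    # ---------------- autosomal branch ----------------
    gm = None
    if any(s in stages for s in ("qc", "kinship", "prune", "fst", "pca",
                                 "admixture", "mantel")):
        if not (config.ped_path and config.map_path):
            needed = [s for s in stages if s not in ("mt", "ystr")]
            raise InvalidArgument(
                f"stage(s) {needed} require ped_path and map_path")
        gm = formats_io.read_plink_text(config.ped_path, config.map_path)

    if "qc" in stages:
        gm, qc_report = autosomal.qc_filter(
            gm, maf_min=config.maf_min, call_rate_min=config.call_rate_min,
            return_report=True)
        record("qc", **asdict(qc_report))

    if "kinship" in stages:
        n_before = gm.n_samples
        gm, removed = autosomal.remove_relatives(
            gm, threshold=config.kinship_threshold, return_removed=True)
        record("kinship", n_input=n_before, n_removed=len(removed),
               n_kept=gm.n_samples, removed_ids=removed)

    if "prune" in stages:
        n_before = gm.n_snps
        kept_ids = autosomal.ld_prune(gm, r2_max=config.r2_max,
                                      window=config.ld_window,
                                      step=config.ld_step)
        keep_set = set(kept_ids)
        gm = gm.subset(snp_idx=[j for j, s in enumerate(gm.snp_ids)
                                if s in keep_set])
        record("prune", n_input=n_before, n_kept=gm.n_snps,
               n_removed=n_before - gm.n_snps)

    fst_matrix = None
    if "fst" in stages:
        fst_matrix = autosomal.wc_fst(gm, min_pop_n=config.min_pop_n)
        dm = fst_matrix.to_distance_matrix()
        formats_io.write_distance_phylip(dm, emit("fst_matrix.phy"))
        record("fst", populations=fst_matrix.labels,
               mean_fst=float(np.mean(fst_matrix.values[
                   np.triu_indices(len(fst_matrix.labels), k=1)])))

    if "pca" in stages:
        coords, eigvals = autosomal.pca(gm, n_components=config.n_components)
        import pandas as pd
        df = pd.DataFrame(coords,
                          columns=[f"PC{i + 1}" for i in range(coords.shape[1])])
        df.insert(0, "sample_id", gm.sample_ids)
        df.insert(1, "population", gm.populations)
        df.to_csv(emit("pca_coords.tsv"), sep="\t", index=False)
        record("pca", eigenvalues=list(map(float, eigvals)))

    if "admixture" in stages:
        admix_info = {}
        rng = np.random.default_rng(config.seed)
        for K in range(config.k_min, config.k_max + 1):
            fits = []
            for run in range(config.n_runs):
                run_seed = int(rng.integers(2 ** 31 - 1))
                report.seeds[f"admixture_K{K}_run{run}"] = run_seed
                fits.append(autosomal.admixture_em(
                    gm, K, seed=run_seed, tol=config.em_tol,
                    max_iter=config.em_max_iter))
            summary = autosomal.multirun_summary(fits)
            cv_seed = int(rng.integers(2 ** 31 - 1))
            report.seeds[f"cv_K{K}"] = cv_seed
            cv = autosomal.cv_index(gm, K, config.cv_mask_fraction,
                                    seed=cv_seed, tol=config.em_tol,
                                    max_iter=config.em_max_iter)
            np.savetxt(emit(f"admixture_Q_K{K}.tsv"), summary.best.Q,
                       delimiter="\t")
            admix_info[str(K)] = {"best_ll": summary.best.loglik,
                                  "ll_spread": summary.ll_spread,
                                  "converged": summary.converged, "cv": cv}
        best_k = min(admix_info, key=lambda k: admix_info[k]["cv"])
        record("admixture", runs=admix_info, best_K_by_cv=int(best_k))

    if "mantel" in stages:
        if not config.metadata_path:
            raise InvalidArgument("stage 'mantel' requires metadata_path")
        if fst_matrix is None:
            raise InvalidArgument("stage 'mantel' requires stage 'fst'")
        meta = formats_io.read_metadata(config.metadata_path)
        meta = [m for m in meta if m.label in fst_matrix.labels]
        order = [m.label for m in meta]
        geo = matrix_stats.great_circle_matrix(meta)
        lang = matrix_stats.linguistic_matrix(meta)
        gen = fst_matrix.to_distance_matrix().reorder(order)
        seed_m = int(np.random.default_rng(config.seed).integers(2 ** 31 - 1))
        report.seeds["mantel"] = seed_m
        res_geo = matrix_stats.mantel(gen, geo, n_perm=config.n_perm,
                                      seed=seed_m)
        info = {"genetics_vs_geography":
                {"r": res_geo.r, "p": res_geo.p,
                 "pct_var": res_geo.variance_explained_pct}}
        if gen.n >= 4:
            res_lang = matrix_stats.partial_mantel(
                gen, lang, geo, n_perm=config.n_perm, seed=seed_m)
            info["genetics_vs_language_partial"] = {"r": res_lang.r,
                                                    "p": res_lang.p}
        else:
            info["genetics_vs_language_partial"] = None
        record("mantel", **info)

    report.to_json(out / "report.json")
    return report
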