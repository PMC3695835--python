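#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/inputs/:
  * an mtDNA haplotype table for five populations whose clade composition
    mirrors a Northeast-Siberian survey (C- and D-dominated East Asian
    pool, minor West Eurasian fraction, rare Northeast-Siberian lineages);
  * a Y-STR haplotype table simulated under stepwise mutation from a
    modal founder (a star-like expansion of known age, 64 generations);
  * a diploid PLINK PED/MAP cohort of four Balding-Nichols populations
    with Dirichlet admixture;
  * population metadata (coordinates + linguistic classification).
"""

from pathlib import Path

from arcticpop import formats_io as fio, mt_phylo as mp, synthdata as sd
from arcticpop.core import StrHaplotype

SEED = 20130619
OUT = Path("results/inputs")

MT_COMPOSITION = {
    "CY": {"C4a1c": 0.22, "C4a2": 0.14, "C5b1b": 0.09, "D5a2a2": 0.27,
           "D4j2": 0.09, "G2a5": 0.03, "A8": 0.03, "Z3a": 0.03,
           "H8": 0.05, "J": 0.05},
    "VY": {"C4a1c": 0.23, "C4a2": 0.12, "C5b1b": 0.08, "D5a2a2": 0.29,
           "D4o2": 0.08, "G2a5": 0.04, "A8": 0.03, "H20a": 0.06,
           "J": 0.04, "Y1a": 0.03},
    "EK": {"C4b9": 0.25, "C4a1c": 0.10, "C5a1": 0.08, "D4j2": 0.16,
           "D4i2": 0.10, "G1b": 0.01, "Z3a": 0.04, "A8": 0.08,
           "HV1a1a": 0.05, "H8": 0.04, "Y1a": 0.09},
    "EN": {"C4b3a": 0.19, "C4b7": 0.10, "C5d1": 0.12, "C5a2a": 0.02,
           "Z1a1b": 0.08, "Z1a3": 0.04, "D4b1a2a": 0.15, "D4o2": 0.10,
           "G1b": 0.01, "A8": 0.10, "Y1a": 0.06, "J": 0.03},
    "YK": {"C4b3a": 0.17, "C5d1": 0.12, "C4b2": 0.02, "C5a2a": 0.02,
           "Z1a1b": 0.12, "Z1a2a": 0.02, "Z1a3": 0.08, "D4j2": 0.13,
           "D4o2": 0.08, "A8": 0.09, "Y1a": 0.07, "H8": 0.05, "J": 0.03},
}
MT_N = {"CY": 250, "VY": 150, "EK": 120, "EN": 180, "YK": 129}

METADATA = [
    # label, lat, lon, family, branch, language (approximate site centroids)
    ("CY", 62.0, 129.7, "Altaic", "Turkic", "Yakut"),
    ("VY", 63.75, 121.6, "Altaic", "Turkic", "Yakut"),
    ("EK", 63.3, 118.3, "Altaic", "Tungusic", "Evenk"),
    ("EN", 67.8, 130.8, "Altaic", "Tungusic", "Even"),
    ("YK", 65.4, 151.3, "Yukaghir", "Kolymic", "Yukaghir"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    tree = mp.default_mt_tree()
    table = sd.sim_mt_cohort(tree, MT_COMPOSITION, MT_N, seed=SEED)
    fio.write_mt_table(table, OUT / "mt_haplotypes.tsv")
    print(f"mtDNA table: {len(table)} samples, "
          f"{len(table.populations)} populations")

    founder = StrHaplotype(("DYS19", "DYS390", "DYS391", "DYS392", "DYS393",
                            "DYS388"), (14, 23, 10, 14, 13, 12))
    haps = sd.sim_str_evolution(300, 6, 64, 6.9e-4, founder, seed=SEED + 1)
    fio.write_str_table(haps, OUT / "ystr_haplotypes.tsv")
    distinct = len({h.repeats for h in haps})
    print(f"Y-STR table: 300 chromosomes, {distinct} distinct haplotypes "
          f"(simulated expansion age: 64 generations = 1600 years)")

    coh = sd.sim_admixed_genotypes(
        [40, 40, 40, 40], 4000, 4, 0.08, [8.0, 0.05, 0.05, 0.05],
        seed=SEED + 2, missing_rate=0.02,
        pop_labels=[m[0] for m in METADATA[:4]])
    fio.write_plink_text(coh.genotypes, OUT / "cohort.ped", OUT / "cohort.map")
    print(f"autosomal cohort: {coh.genotypes.n_samples} samples x "
          f"{coh.genotypes.n_snps} SNPs (F = 0.08, 2% missing calls)")

    fio.write_metadata(
        [fio.PopulationMeta(*m) for m in METADATA], OUT / "metadata.tsv")
    print("metadata written; inputs complete")


if __name__ == "__main__":
    main()
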