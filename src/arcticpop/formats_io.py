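"""Readers and writers for every on-disk artifact the pipeline touches.

Text formats only: PLINK PED/MAP, TSV haplotype/metadata tables, PHYLIP
square distance matrices, GML networks, newick trees, YAML marker-tree and
pipeline configs. Readers never silently drop rows; row counts are logged
at DEBUG level and malformed input raises with the offending line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DistanceMatrix,
    GenotypeMatrix,
    InvalidArgument,
    MISSING,
    ParseError,
    StrHaplotype,
    Variant,
)
from .mt_phylo import parse_variant_list

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mtDNA haplotype tables (TSV: sample_id, population, variants[, haplogroup])
# ---------------------------------------------------------------------------

@dataclass
class MtRecord:
    sample_id: str
    population: str
    variants: list[Variant]
    raw_variants: str
    haplogroup: Optional[str] = None


@dataclass
class MtHaplotypeTable:
    records: list[MtRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ParseError(f"duplicate sample_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def populations(self) -> list[str]:
        return sorted({r.population for r in self.records})


def read_mt_table(path) -> MtHaplotypeTable:
    """Read a TSV haplotype table with header
    ``sample_id  population  variants  [haplogroup]``.

    The ``variants`` column is a space-separated variant string, preserved
    verbatim for round-tripping.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "population", "variants"}
    if not required.issubset(df.columns):
        raise ParseError(f"mt table must have columns {sorted(required)}; "
                         f"got {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        records.append(MtRecord(
            sample_id=row["sample_id"],
            population=row["population"],
            variants=parse_variant_list(row["variants"]),
            raw_variants=row["variants"],
            haplogroup=row.get("haplogroup") or None,
        ))
    logger.debug("read %d mtDNA records from %s", len(records), path)
    return MtHaplotypeTable(records)


def write_mt_table(table: MtHaplotypeTable, path) -> None:
    rows = []
    for r in table.records:
        row = {"sample_id": r.sample_id, "population": r.population,
               "variants": r.raw_variants}
        if r.haplogroup is not None:
            row["haplogroup"] = r.haplogroup
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Population metadata
# ---------------------------------------------------------------------------

@dataclass
class PopulationMeta:
    label: str
    lat: float
    lon: float
    language_family: str
    language_branch: str
    language: str


def read_metadata(path) -> list[PopulationMeta]:
    """Read population metadata TSV with columns
    ``population  lat  lon  language_family  language_branch  language``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["population", "lat", "lon",
                "language_family", "language_branch", "language"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"metadata missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        lat, lon = float(row["lat"]), float(row["lon"])
        if not -90 <= lat <= 90:
            raise ParseError(f"latitude {lat} out of range at row {i + 1}")
        if not -180 <= lon <= 180:
            raise ParseError(f"longitude {lon} out of range at row {i + 1}")
        for col in ("language_family", "language_branch", "language"):
            if not row[col]:
                raise ParseError(f"empty {col} at row {i + 1}")
        out.append(PopulationMeta(row["population"], lat, lon,
                                  row["language_family"],
                                  row["language_branch"], row["language"]))
    return out


def write_metadata(meta: Sequence[PopulationMeta], path) -> None:
    pd.DataFrame([{
        "population": m.label, "lat": m.lat, "lon": m.lon,
        "language_family": m.language_family,
        "language_branch": m.language_branch, "language": m.language,
    } for m in meta]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PLINK PED/MAP text
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read genotypes from PLINK text PED/MAP into minor-allele dosages.

    Allele pairs collapse to counts of the per-SNP minor allele (determined
    from the file itself; a 50/50 tie breaks to the lexicographically
    smaller allele); ``0 0`` becomes missing.
    """
    snp_ids, chroms, positions = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 columns")
            chroms.append(int(tok[0]))
            snp_ids.append(tok[1])
            positions.append(int(tok[3]))
    L = len(snp_ids)

    sample_ids, pops = [], []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * L:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * L} tokens "
                    f"(6 + 2x{L} alleles), got {len(tok)}")
            pops.append(tok[0])       # family ID doubles as population label
            sample_ids.append(tok[1])
            allele_rows.append(tok[6:])
    n = len(sample_ids)
    a = np.array(allele_rows, dtype="U4").reshape(n, L, 2) if n else \
        np.empty((0, L, 2), dtype="U4")

    calls = np.full((n, L), MISSING, dtype=np.int8)
    allele_pairs: list[tuple[str, str]] = []
    for j in range(L):
        col = a[:, j, :]
        valid = col != "0"
        obs, counts = np.unique(col[valid], return_counts=True)
        if len(obs) == 0:
            allele_pairs.append(("0", "0"))
            continue
        if len(obs) == 1:
            # monomorphic: the (unobserved) minor allele has frequency 0
            major = str(obs[0])
            allele_pairs.append(("0", major))
            pair_valid = valid.all(axis=1)
            calls[pair_valid, j] = 0
            continue
        else:
            if len(obs) > 2:
                raise ParseError(f"SNP {snp_ids[j]} has >2 alleles: {list(obs)}")
            order = np.argsort(counts, kind="stable")
            if counts[0] == counts[1]:
                minor, major = sorted(obs)
            else:
                minor, major = obs[order[0]], obs[order[1]]
        allele_pairs.append((str(minor), str(major)))
        pair_valid = valid.all(axis=1)
        dosage = (col == minor).sum(axis=1)
        calls[pair_valid, j] = dosage[pair_valid]

    logger.debug("read %d samples x %d SNPs from %s", n, L, ped_path)
    return GenotypeMatrix(calls=calls, sample_ids=sample_ids, populations=pops,
                          snp_ids=snp_ids, chromosomes=np.array(chroms),
                          positions=np.array(positions), alleles=allele_pairs)


def write_plink_text(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP (inverse of :func:`read_plink_text`)."""
    with open(map_path, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.chromosomes[j]}\t{gm.snp_ids[j]}\t0\t{gm.positions[j]}\n")
    alleles = gm.alleles or [("A", "B")] * gm.n_snps
    with open(ped_path, "w") as fh:
        for i in range(gm.n_samples):
            fields = [gm.populations[i], gm.sample_ids[i], "0", "0", "0", "-9"]
            for j in range(gm.n_snps):
                g = gm.calls[i, j]
                minor, major = alleles[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [major, major]
                elif g == 1:
                    fields += [minor, major]
                else:
                    fields += [minor, minor]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Y-STR haplotype tables
# ---------------------------------------------------------------------------

def read_str_table(path) -> list[StrHaplotype]:
    """Read Y-STR haplotypes from TSV: locus columns + per-population counts.

    Layout: first columns are STR locus names (values = repeat counts);
    remaining columns are population labels (values = carrier counts).
    Locus columns are those whose names start with ``DYS`` (or ``Y-``).
    """
    df = pd.read_csv(path, sep="\t")
    locus_cols = [c for c in df.columns if c.upper().startswith(("DYS", "Y-"))]
    if not locus_cols:
        raise ParseError("no STR locus columns (DYS*) found")
    pop_cols = [c for c in df.columns if c not in locus_cols]
    haps = []
    for _, row in df.iterrows():
        repeats = tuple(int(row[c]) for c in locus_cols)
        for pop in pop_cols:
            cnt = int(row[pop])
            if cnt > 0:
                haps.append(StrHaplotype(tuple(locus_cols), repeats,
                                         count=cnt, population=pop))
    return haps


def write_str_table(haps: Sequence[StrHaplotype], path) -> None:
    if not haps:
        raise InvalidArgument("no haplotypes to write")
    loci = haps[0].loci
    pops = sorted({h.population or "ALL" for h in haps})
    counts: dict[tuple[int, ...], dict[str, int]] = {}
    for h in haps:
        if h.loci != loci:
            raise InvalidArgument("inconsistent locus sets")
        d = counts.setdefault(h.repeats, {p: 0 for p in pops})
        d[h.population or "ALL"] += h.count
    rows = []
    for repeats, d in sorted(counts.items()):
        rows.append(dict(zip(loci, repeats)) | d)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------

def write_distance_phylip(matrix: DistanceMatrix, path, strict: bool = False) -> None:
    """Write a PHYLIP square distance matrix.

    Relaxed dialect by default (full labels, tab-separated); ``strict=True``
    pads/truncates labels to 10 characters (a truncation is logged).
    """
    with open(path, "w") as fh:
        fh.write(f"{matrix.n}\n")
        for i, label in enumerate(matrix.labels):
            if strict:
                if len(label) > 10:
                    logger.warning("PHYLIP strict mode: truncating label %r", label)
                name = label[:10].ljust(10)
                row = " ".join(f"{v:.6f}" for v in matrix.values[i])
                fh.write(f"{name}{row}\n")
            else:
                row = "\t".join(f"{v:.6f}" for v in matrix.values[i])
                fh.write(f"{label}\t{row}\n")


def read_distance_phylip(path) -> DistanceMatrix:
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1:1 + n]:
        tok = line.split()
        labels.append(tok[0])
        rows.append([float(x) for x in tok[1:1 + n]])
    return DistanceMatrix(labels, np.array(rows))


# ---------------------------------------------------------------------------
# GML network output
# ---------------------------------------------------------------------------

def write_network_gml(network, path) -> None:
    """Write a haplotype network to GML; nodes carry ``median`` (0/1) and
    ``frequency`` attributes."""
    import networkx as nx

    g = network.graph.copy()
    relabel = {node: "|".join(str(x) for x in node) for node in g.nodes}
    g = nx.relabel_nodes(g, relabel)
    for node, data in g.nodes(data=True):
        data["median"] = int(bool(data.get("median", False)))
        data["frequency"] = float(data.get("frequency", 0.0))
    for u, v, data in g.edges(data=True):
        data["weight"] = float(data.get("weight", 1.0))
        if "steps" in data:
            data["steps"] = str(data["steps"])
    nx.write_gml(g, path)
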