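"""Readers and writers for the package's external formats.

* cross-CSV — the r/qtl "csv" cross dialect: a block of phenotype
  columns followed by marker columns; under each marker name, row 2
  carries the chromosome and row 3 the cM position; genotype codes
  NN/NS/SS, missing "-".
* map TSV — marker, chrom, cM, optional bp.
* haplotype TSV and VCF (phased haploid sample columns) for binary
  haplotype matrices.
* BED exports (0-based half-open; internal bp coordinates are 1-based
  inclusive).
* YAML configuration / truth-manifest round-trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cross_sim import F2GenotypeTable, GENO_CODES, MISSING
from .gmap import GeneticMap
from .pop_sim import HaplotypeMatrix

__all__ = [
    "write_cross_csv",
    "read_cross_csv",
    "write_map_tsv",
    "read_map_tsv",
    "write_haplotypes",
    "read_haplotypes",
    "write_bed",
    "write_yaml",
    "read_yaml",
    "load_parental_means",
    "load_qtl_effect_table",
]

_CODE_TO_INT = {"NN": 0, "NS": 1, "SS": 2, "-": MISSING}


# ---------------------------------------------------------------------------
# cross CSV (r/qtl dialect)
# ---------------------------------------------------------------------------
def write_cross_csv(
    table: F2GenotypeTable, path, phenotypes: pd.DataFrame | None = None
) -> None:
    """Write genotypes (+ optional phenotypes/covariates) as cross-CSV."""
    path = Path(path)
    gmap = table.gmap.table
    pheno_cols = ["id"]
    pheno_data = {"id": list(table.ids)}
    if phenotypes is not None:
        aligned = phenotypes.reindex(table.ids)
        for c in phenotypes.columns:
            pheno_cols.append(c)
            pheno_data[c] = aligned[c].tolist()
    else:
        for c in table.covariates.columns:
            pheno_cols.append(c)
            pheno_data[c] = table.covariates[c].tolist()
    genos = table.geno_strings()
    with open(path, "w") as fh:
        fh.write(",".join(pheno_cols + gmap["marker"].tolist()) + "\n")
        fh.write(",".join([""] * len(pheno_cols) + [str(c) for c in gmap["chrom"]]) + "\n")
        fh.write(",".join([""] * len(pheno_cols) + [repr(float(x)) for x in gmap["cM"]]) + "\n")
        for i in range(table.n_individuals):
            ph = []
            for c in pheno_cols:
                v = pheno_data[c][i]
                ph.append("" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v))
            fh.write(",".join(ph + list(genos[i])) + "\n")


def read_cross_csv(path):
    """Read a cross-CSV file.

    Returns (F2GenotypeTable, phenotype DataFrame, GeneticMap).  Unknown
    genotype codes raise with the offending row/column named.
    """
    path = Path(path)
    raw = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    header = raw.iloc[0].tolist()
    chrom_row = raw.iloc[1].tolist()
    cm_row = raw.iloc[2].tolist()
    n_pheno = sum(1 for c in chrom_row if c == "")
    if n_pheno == 0 or n_pheno == len(header):
        raise ValueError("no marker columns found (chromosome row empty or full)")
    marker_names = header[n_pheno:]
    chroms = []
    for c in chrom_row[n_pheno:]:
        try:
            chroms.append(int(c))
        except ValueError:
            chroms.append(c)
    cms = [float(x) for x in cm_row[n_pheno:]]
    gmap = GeneticMap(pd.DataFrame({"marker": marker_names, "chrom": chroms, "cM": cms}))

    body = raw.iloc[3:].reset_index(drop=True)
    pheno = body.iloc[:, :n_pheno].copy()
    pheno.columns = header[:n_pheno]
    if "id" in pheno.columns:
        ids = pheno["id"].tolist()
        pheno = pheno.drop(columns="id")
    else:
        ids = [f"ind_{i + 1}" for i in range(len(body))]
    pheno.index = pd.Index(ids, name="id")
    for c in pheno.columns:
        col = pheno[c].replace("", np.nan)
        try:
            pheno[c] = pd.to_numeric(col)
        except (ValueError, TypeError):
            pheno[c] = col

    geno_str = body.iloc[:, n_pheno:].to_numpy(dtype=object)
    genos = np.full(geno_str.shape, np.int8(-99))
    for code, val in _CODE_TO_INT.items():
        genos[geno_str == code] = np.int8(val)
    genos[geno_str == ""] = np.int8(MISSING)
    bad = np.argwhere(genos == -99)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"unknown genotype code {geno_str[i, j]!r} at row {i + 4}, "
            f"column {marker_names[j]!r}"
        )
    genos = genos.astype(np.int8)
    cov_cols = [c for c in ("cross_direction", "tray") if c in pheno.columns]
    cov = pheno[cov_cols].copy() if cov_cols else pd.DataFrame(index=pheno.index)
    table = F2GenotypeTable(ids=ids, genotypes=genos, gmap=gmap, covariates=cov)
    return table, pheno, gmap


# ---------------------------------------------------------------------------
# map TSV
# ---------------------------------------------------------------------------
def write_map_tsv(gmap: GeneticMap, path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False)


def read_map_tsv(path) -> GeneticMap:
    t = pd.read_csv(path, sep="\t")
    return GeneticMap(t)


# ---------------------------------------------------------------------------
# haplotype matrices
# ---------------------------------------------------------------------------
def write_haplotypes(hm: HaplotypeMatrix, path, fmt: str = "tsv") -> None:
    """Write a haplotype matrix as TSV or VCF (phased haploid columns)."""
    path = Path(path)
    if fmt == "tsv":
        L = hm.metadata.get("demography", {}).get("L", "")
        with open(path, "w") as fh:
            fh.write(f"#L={L}\n")
            fh.write("hap_id\tpop\t" + "\t".join(str(p) for p in hm.positions) + "\n")
            for i in range(hm.n_haplotypes):
                row = "\t".join(str(int(v)) for v in hm.matrix[i])
                fh.write(f"h{i + 1}\t{hm.pops[i]}\t{row}\n")
    elif fmt == "vcf":
        samples = [f"{hm.pops[i]}_h{i + 1}" for i in range(hm.n_haplotypes)]
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            L = hm.metadata.get("demography", {}).get("L")
            if L:
                fh.write(f"##contig=<ID=1,length={L}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            for j, pos in enumerate(hm.positions):
                gts = "\t".join(str(int(v)) for v in hm.matrix[:, j])
                fh.write(f"1\t{int(pos)}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
    else:
        raise ValueError("fmt must be 'tsv' or 'vcf'")


def read_haplotypes(path, fmt: str | None = None) -> HaplotypeMatrix:
    """Read a haplotype matrix from TSV or VCF.

    Non-biallelic VCF records are skipped (counted in metadata).  Sample
    names of the form ``<pop>_h<i>`` recover population labels; phased
    diploid VCF samples contribute two haplotypes each.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if fmt == "tsv":
        with open(path) as fh:
            first = fh.readline().strip()
            meta = {}
            if first.startswith("#L="):
                val = first[3:]
                if val:
                    meta = {"demography": {"L": int(float(val))}}
                header = fh.readline().strip().split("\t")
            else:
                header = first.split("\t")
            positions = np.array([int(p) for p in header[2:]], dtype=np.int64)
            pops, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                pops.append(parts[1])
                rows.append([int(v) for v in parts[2:]])
        m = np.array(rows, dtype=np.uint8)
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("positions not strictly increasing")
        return HaplotypeMatrix(m, positions, pops, meta)
    if fmt == "vcf":
        from cyvcf2 import VCF

        v = VCF(str(path))
        samples = v.samples
        cols, positions = [], []
        skipped = 0
        for var in v:
            if len(var.ALT) != 1:
                skipped += 1
                continue
            col = []
            for g in var.genotypes:
                alleles = [a for a in g[:-1] if a is not None and a >= 0]
                col.extend(alleles)
            cols.append(np.array(col, dtype=np.uint8))
            positions.append(var.POS)
        positions = np.array(positions, dtype=np.int64)
        m = np.array(cols, dtype=np.uint8).T if cols else np.zeros((0, 0), np.uint8)
        haps_per_sample = m.shape[0] // max(len(samples), 1) if cols else 1
        pops = []
        for s in samples:
            pop = s.rsplit("_h", 1)[0] if "_h" in s else s
            pops.extend([pop] * haps_per_sample)
        if positions.size and np.any(np.diff(positions) <= 0):
            raise ValueError("positions not strictly increasing")
        return HaplotypeMatrix(m, positions, pops, {"skipped_records": skipped})
    raise ValueError("fmt must be 'tsv' or 'vcf'")


# ---------------------------------------------------------------------------
# BED / YAML
# ---------------------------------------------------------------------------
def write_bed(df: pd.DataFrame, path, score_col: str | None = None) -> None:
    """Write spans with 1-based inclusive start/end as 0-based half-open BED."""
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            line = f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}"
            if score_col is not None:
                line += f"\t{r[score_col]}"
            fh.write(line + "\n")


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _yaml_safe(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_yaml_safe(obj), fh, sort_keys=False)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# bundled reference tables
# ---------------------------------------------------------------------------
def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def load_parental_means() -> pd.DataFrame:
    """Published parental trait means for the Arabis nemorensis x
    A. sagittata common-garden comparison (35 replicates per species)."""
    return pd.read_csv(_data_path("parental_trait_means.tsv"), sep="\t")


def load_qtl_effect_table() -> pd.DataFrame:
    """Published QTL peak table (58 QTLs, 20 traits) for the Arabis
    hybrid F2 mapping population: peak positions, LOD, percent variance
    and standardized additive/dominance effects of the S allele."""
    return pd.read_csv(_data_path("qtl_effects_f2.tsv"), sep="\t")
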