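"""Reading and writing cohort files.

Formats
-------
Phenotype TSV: one row per subject with columns

    sample_id  status  stratum  ER  PR  HER2  grade  PC1 ... PCk

ER/PR/HER2 coded 0 (negative) / 1 (positive); grade coded 1/2/3; missing
markers empty or "NA".  Controls may leave all markers missing.

Dosage TSV: one row per variant,

    variant_id  effect_allele  <sample_id_1> ... <sample_id_n>

with dosages in [0, 2].

VCF: per-variant dosages read from the DS FORMAT field (uncompressed or
bgzipped VCF, via cyvcf2); sample order must match the phenotype file.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .markers import ObservedPattern, default_schema
from .model import CohortData

MARKER_COLS = ("ER", "PR", "HER2", "grade")
_BINARY_LEVELS = {0.0: "neg", 1.0: "pos"}
_GRADE_LEVELS = {1.0: "1", 2.0: "2", 3.0: "3"}


class CohortValidationError(ValueError):
    pass


def write_phenotypes(data: CohortData, path, sample_ids=None) -> None:
    n = data.n
    ids = sample_ids or [f"S{i:06d}" for i in range(n)]
    rows = {"sample_id": ids, "status": data.status, "stratum": data.stratum}
    schema = data.schema
    codes = {m: np.full(n, np.nan) for m in MARKER_COLS}
    for i, pat in enumerate(data.patterns):
        if data.status[i] != 1:
            continue
        for j, m in enumerate(MARKER_COLS):
            v = pat.values[j]
            if v is not None:
                levels = schema.levels(m)
                codes[m][i] = levels.index(v) + (1 if m == "grade" else 0)
    for m in MARKER_COLS:
        rows[m] = codes[m]
    for j in range(data.covariates.shape[1]):
        rows[f"PC{j + 1}"] = data.covariates[:, j]
    df = pd.DataFrame(rows)
    for m in MARKER_COLS:
        df[m] = df[m].map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def write_dosages(data: CohortData, path, sample_ids=None,
                  effect_alleles=None) -> None:
    ids = sample_ids or [f"S{i:06d}" for i in range(data.n)]
    with open(path, "w") as fh:
        fh.write("variant_id\teffect_allele\t" + "\t".join(ids) + "\n")
        for vi, vid in enumerate(data.variant_ids):
            ea = (effect_alleles or {}).get(vid, "A")
            vals = "\t".join(f"{v:.4g}" for v in data.dosages[vi])
            fh.write(f"{vid}\t{ea}\t{vals}\n")


def write_vcf(data: CohortData, path, sample_ids=None) -> None:
    """Minimal VCF 4.2 with a DS FORMAT field carrying the dosages."""
    ids = sample_ids or [f"S{i:06d}" for i in range(data.n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Genotype dosage">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for vi, vid in enumerate(data.variant_ids):
            vals = "\t".join(f"{v:.4g}" for v in data.dosages[vi])
            fh.write(f"1\t{vi + 1}\t{vid}\tG\tA\t.\tPASS\t.\tDS\t{vals}\n")


def write_truth(truth, path) -> None:
    obj = {
        "theta_true": {k: v.tolist() for k, v in truth.theta_true.items()},
        "beta_true": {k: v.tolist() for k, v in truth.beta_true.items()},
        "subtype_logor": truth.subtype_logor,
        "design_kind": truth.design_kind,
        "cell_freqs": truth.cell_freqs.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def _parse_marker(df, col, allowed, path):
    raw = df[col].astype(str)
    numeric = pd.to_numeric(raw.replace({"NA": None, "nan": None, "": None}),
                            errors="coerce")
    bad = numeric.notna() & ~numeric.isin(allowed)
    unparsed = raw.notna() & ~raw.isin(["NA", "nan", ""]) & numeric.isna()
    if bad.any() or unparsed.any():
        row = int(np.flatnonzero(bad | unparsed)[0])
        raise CohortValidationError(
            f"{path}: invalid {col} code {raw.iloc[row]!r} at row {row + 2} "
            f"(allowed: {sorted(allowed)} or NA)")
    return numeric


def read_phenotypes(path, stratum_col: str = "stratum", pc_cols=None):
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "status", stratum_col, *MARKER_COLS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CohortValidationError(f"{path}: duplicated sample ID {dup!r}")
    if not df["status"].isin([0, 1]).all():
        row = int(np.flatnonzero(~df["status"].isin([0, 1]))[0])
        raise CohortValidationError(
            f"{path}: status must be 0/1 (row {row + 2})")
    if pc_cols is None:
        pc_cols = [c for c in df.columns if c.startswith("PC")]
    schema = default_schema()
    coded = {}
    for m in MARKER_COLS:
        allowed = [1, 2, 3] if m == "grade" else [0, 1]
        coded[m] = _parse_marker(df, m, allowed, path)
    patterns = []
    for i in range(len(df)):
        vals = []
        for m in MARKER_COLS:
            v = coded[m].iloc[i]
            if np.isnan(v):
                vals.append(None)
            elif m == "grade":
                vals.append(_GRADE_LEVELS[v])
            else:
                vals.append(_BINARY_LEVELS[v])
        patterns.append(ObservedPattern(tuple(vals)))
    return df, patterns, pc_cols


def read_dosage_tsv(path, expected_samples=None):
    """Yields (variant_id, effect_allele, dosage array) per variant."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = header[2:]
        if expected_samples is not None and samples != list(expected_samples):
            raise CohortValidationError(
                f"{path}: sample columns do not match the phenotype file")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            vid, ea = parts[0], parts[1]
            g = np.array(parts[2:], dtype=float)
            if g.min() < 0 or g.max() > 2:
                j = int(np.flatnonzero((g < 0) | (g > 2))[0])
                raise CohortValidationError(
                    f"{path}: dosage {g[j]} outside [0,2] for variant {vid} "
                    f"(line {ln}, sample {samples[j]})")
            yield vid, ea, g


def read_vcf_dosages(path, expected_samples=None):
    """Yields (variant_id, effect_allele, DS dosage array) from a VCF."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    if expected_samples is not None and list(vcf.samples) != list(expected_samples):
        raise CohortValidationError(
            f"{path}: VCF samples do not match the phenotype file")
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise CohortValidationError(
                f"{path}: variant {var.ID} has no DS format field")
        g = np.asarray(ds, dtype=float).ravel()
        if g.min() < 0 or g.max() > 2:
            raise CohortValidationError(
                f"{path}: dosage outside [0,2] for variant {var.ID}")
        yield var.ID, var.ALT[0] if var.ALT else "A", g


def read_cohort(pheno_path, geno_path, stratum_col: str = "stratum",
                pc_cols=None) -> CohortData:
    """Load a full cohort (phenotypes + all variant dosages) into memory."""
    df, patterns, pc_cols = read_phenotypes(pheno_path, stratum_col, pc_cols)
    reader = (read_vcf_dosages if str(geno_path).endswith((".vcf", ".vcf.gz"))
              else read_dosage_tsv)
    ids, eas, rows = [], {}, []
    for vid, ea, g in reader(geno_path, expected_samples=df["sample_id"]):
        if g.shape[0] != len(df):
            raise CohortValidationError(
                f"{geno_path}: variant {vid} has {g.shape[0]} dosages for "
                f"{len(df)} subjects")
        ids.append(vid)
        eas[vid] = ea
        rows.append(g)
    data = CohortData(
        status=df["status"].to_numpy(), patterns=patterns,
        covariates=df[pc_cols].to_numpy(dtype=float) if pc_cols else np.zeros((len(df), 0)),
        stratum=df[stratum_col].to_numpy(), dosages=np.vstack(rows),
        variant_ids=ids)
    data.effect_alleles = eas
    data.sample_ids = df["sample_id"].tolist()
    return data
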