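"""Plain-text readers and writers for the pipeline's three table dialects.

Twin samples: CSV with columns family_id, zygosity_group, age_band, sex_t1,
sex_t2, pheno1_t1, pheno2_t1, pheno1_t2, pheno2_t2 (binary; empty cell =
missing).  Summary statistics: tab-separated SNP, A1, A2, Z, N, L2.  MR
cohorts: CSV with one dosage_<rsid> column per SNP.  Writers prefix a
comment header (tool version, seed, config hash); readers skip ``#`` lines.
Unknown extra columns pass through untouched.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .ldsc import SumstatsTable
from .mr import MRCohort
from .twin_model import TwinPairRecord

__all__ = [
    "read_twin_csv",
    "write_twin_csv",
    "read_sumstats",
    "write_sumstats",
    "read_cohort_csv",
    "write_cohort_csv",
]

TWIN_COLUMNS = [
    "family_id", "zygosity_group", "age_band", "sex_t1", "sex_t2",
    "pheno1_t1", "pheno2_t1", "pheno1_t2", "pheno2_t2",
]


def _header_lines(seed=None, config=None):
    lines = [f"# genoverlap {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config: {digest}")
    return lines


def _write_with_header(df, path, sep, seed, config):
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False)


def write_twin_csv(records, path, seed=None, config=None) -> None:
    rows = []
    for r in records:
        rows.append({
            "family_id": r.family_id, "zygosity_group": r.zygosity_group,
            "age_band": r.age_band, "sex_t1": r.sex_t1, "sex_t2": r.sex_t2,
            "pheno1_t1": r.pheno1_t1, "pheno2_t1": r.pheno2_t1,
            "pheno1_t2": r.pheno1_t2, "pheno2_t2": r.pheno2_t2,
        })
    df = pd.DataFrame(rows, columns=TWIN_COLUMNS)
    for c in TWIN_COLUMNS[5:]:
        df[c] = df[c].astype("Int64")
    _write_with_header(df, path, ",", seed, config)


def read_twin_csv(path):
    """Validated twin-pair records; malformed rows are rejected with their
    line numbers."""
    df = pd.read_csv(path, comment="#", dtype={"sex_t1": str, "sex_t2": str})
    if len(df) == 0:
        raise ValueError(f"no records in {path}")
    missing = [c for c in TWIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"twin CSV missing column(s): {missing}")
    records = []
    errors = []
    for i, row in df.iterrows():
        try:
            phen = [
                None if pd.isna(row[c]) else int(row[c])
                for c in ("pheno1_t1", "pheno2_t1", "pheno1_t2", "pheno2_t2")
            ]
            records.append(TwinPairRecord(
                family_id=str(row["family_id"]),
                zygosity_group=str(row["zygosity_group"]),
                age_band=int(row["age_band"]),
                sex_t1=str(row["sex_t1"]), sex_t2=str(row["sex_t2"]),
                pheno1_t1=phen[0], pheno2_t1=phen[1],
                pheno1_t2=phen[2], pheno2_t2=phen[3],
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")
    if errors:
        raise ValueError("invalid twin CSV rows:\n" + "\n".join(errors[:20]))
    return records


def write_sumstats(table: SumstatsTable, path, seed=None, config=None) -> None:
    _write_with_header(table.to_frame(), path, "\t", seed, config)


def read_sumstats(path) -> SumstatsTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    if len(df) == 0:
        raise ValueError(f"no records in {path}")
    for col in ("Z", "N", "L2"):
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric values in column {col}")
    return SumstatsTable.from_frame(df)


def write_cohort_csv(cohort: MRCohort, path, seed=None, config=None) -> None:
    df = cohort.table.copy()
    df.attrs["snp_ids"] = list(cohort.snp_ids)
    _write_with_header(df, path, ",", seed, config)


def read_cohort_csv(path) -> MRCohort:
    df = pd.read_csv(path, comment="#")
    if len(df) == 0:
        raise ValueError(f"no records in {path}")
    snp_ids = tuple(
        c.removeprefix("dosage_") for c in df.columns if c.startswith("dosage_")
    )
    if not snp_ids:
        raise ValueError("cohort CSV has no dosage_<rsid> columns")
    return MRCohort(table=df, snp_ids=snp_ids)
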