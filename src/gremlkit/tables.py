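"""Delimited phenotype/covariate tables and GWAS summary statistics."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical summary-statistic columns
SUMSTAT_COLUMNS = ["id", "allele1", "allele2", "beta", "se", "p", "n"]


def read_phenotype_table(path: str | Path, id_column: str = "sample_id") -> pd.DataFrame:
    """Read a delimited table with a header row and one sample-id column."""
    df = pd.read_csv(path, sep=None, engine="python")
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing id column {id_column!r}")
    df[id_column] = df[id_column].astype(str)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read GWAS summary statistics, tolerating the public PGC dialect.

    Canonical columns: id, allele1, allele2, beta, se, p, n.  The PGC
    case-control dialect (SNP, A1, A2, OR, SE, P) is recognised and odds
    ratios are converted to log scale (logged).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}

    rename = {}
    for canon, aliases in {
        "id": ["id", "snp", "rsid", "markername"],
        "allele1": ["allele1", "a1", "effect_allele"],
        "allele2": ["allele2", "a2", "other_allele"],
        "se": ["se", "stderr"],
        "p": ["p", "pval", "p_value", "pvalue"],
        "n": ["n", "nmiss", "n_total"],
    }.items():
        for al in aliases:
            if al in cols:
                rename[cols[al]] = canon
                break
    if "beta" in cols:
        rename[cols["beta"]] = "beta"
    df = df.rename(columns=rename)

    if "beta" not in df.columns:
        if "or" in cols:
            df["beta"] = np.log(df[cols["or"]].astype(float))
            logger.info("%s: odds ratios converted to log scale", path)
        else:
            raise ValueError(f"{path}: no beta or OR column found")
    missing = {"id", "allele1", "allele2", "beta"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    bad_p = df["p"].notna() & ((df["p"] <= 0) | (df["p"] > 1)) if "p" in df else None
    if bad_p is not None and bad_p.any():
        raise ValueError(f"{path}: {int(bad_p.sum())} p-values outside (0,1]")
    return df


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMSTAT_COLUMNS + ["chi_square"] if c in df.columns]
    write_table(df[cols], path)
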