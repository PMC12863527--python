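"""Readers and writers for the pipeline's on-disk formats.

Tab-separated text is canonical (comma-separated accepted on read);
missing values are empty fields; UTF-8 throughout.  The cohort file has
one row per participant (pair_id, is_case, covariates, metabolite
columns); metabolite columns are identified by the companion annotation
file (name, class).  Summary statistics use the usual
snp/chr/pos/alleles/eaf/beta/se/pval/n schema.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from adipomet.mr import SUMSTATS_COLUMNS

COHORT_KEY_COLUMNS = ("pair_id", "is_case")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def write_cohort(
    cohort: pd.DataFrame,
    metabolites: pd.DataFrame,
    annotations: pd.DataFrame,
    cohort_path: str | Path,
    annotation_path: str | Path,
) -> None:
    table = pd.concat(
        [cohort.reset_index(drop=True), metabolites.reset_index(drop=True)],
        axis=1,
    )
    table.to_csv(cohort_path, sep="\t", index=False)
    annotations.to_csv(annotation_path, sep="\t", index=False)


def read_cohort(
    cohort_path: str | Path,
    annotation_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Load and validate a cohort table plus its metabolite annotations.

    Returns (cohort, metabolites, annotations, validation_report).  The
    pairing structure is checked — every pair id must appear exactly twice
    with one case and one control — and per-column missingness is
    reported.  Non-numeric metabolite concentrations and broken pairings
    raise ValueError naming the offender.
    """
    table = _read_table(cohort_path)
    annotations = _read_table(annotation_path)
    met_cols = [c for c in annotations["name"] if c in table.columns]
    missing_ann = [c for c in annotations["name"] if c not in table.columns]
    if missing_ann:
        raise ValueError(f"annotated metabolites absent from cohort: "
                         f"{missing_ann[:5]}")
    for key in COHORT_KEY_COLUMNS:
        if key not in table.columns:
            raise ValueError(f"cohort table lacks required column {key!r}")

    counts = table.groupby("pair_id")["is_case"].agg(["size", "sum"])
    bad_size = counts.index[counts["size"] != 2].tolist()
    if bad_size:
        raise ValueError(f"pair ids without exactly 2 members: {bad_size[:5]}")
    bad_roles = counts.index[counts["sum"] != 1].tolist()
    if bad_roles:
        raise ValueError(
            f"pairs without exactly one case and one control: {bad_roles[:5]}"
        )

    metabolites = table[met_cols].apply(pd.to_numeric, errors="coerce")
    bad_numeric = metabolites.columns[metabolites.isna().any()].tolist()
    if bad_numeric and table[bad_numeric].notna().any().any():
        raise ValueError(
            f"non-numeric metabolite concentrations in: {bad_numeric[:5]}"
        )
    cohort = table.drop(columns=met_cols)
    report = {
        "n_participants": len(table),
        "n_pairs": table["pair_id"].nunique(),
        "n_metabolites": len(met_cols),
        "missing_per_column": cohort.isna().sum().to_dict(),
    }
    return cohort, metabolites, annotations, report


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> None:
    stats[list(SUMSTATS_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    missing = set(SUMSTATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-statistics file lacks columns: "
                         f"{sorted(missing)}")
    return df
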